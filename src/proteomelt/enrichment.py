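"""Proteoform-aware over-representation analysis, flanking-motif proportion
tests, and the pulldown replication filter.

ORA entities are proteoform-group IDs mapped to gene symbols, so a gene with
several proteoform groups contributes several entries to both the hit list
and the background universe.  This makes the hypergeometric background
reflect each gene's chance of random identification across its measured
proteoform contexts.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .nparc import bh_adjust
from .types import ComplexSet

logger = logging.getLogger(__name__)

MOTIF_PATTERNS = ("GCL", "GSL", "GTL", "GYL")
_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


def hypergeom_tail(overlap: int, universe: int, set_size: int, hits: int) -> Fraction:
    """Exact upper-tail P(X >= overlap) for Hypergeom(N, K, n), as a rational."""
    if overlap < 0 or set_size > universe or hits > universe:
        raise ValueError("inconsistent hypergeometric configuration")
    total = math.comb(universe, hits)
    acc = 0
    for j in range(overlap, min(set_size, hits) + 1):
        acc += math.comb(set_size, j) * math.comb(universe - set_size, hits - j)
    return Fraction(acc, total)


def ora_complexes(
    hits: Sequence[str],
    universe: Mapping[str, str],
    complexes: Iterable[ComplexSet],
    min_size: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of hit entities in complex gene sets.

    ``universe`` maps entity id (proteoform group) -> gene symbol; ``hits``
    must be a subset of its keys.  Complexes whose universe coverage spans
    fewer than ``min_size`` distinct genes are skipped.  p-values are exact
    hypergeometric upper tails, BH-adjusted across the tested complexes.
    """
    hit_set = set(hits)
    unknown = hit_set - set(universe)
    if unknown:
        raise ValueError(f"hit entities not in universe: {sorted(unknown)[:5]}")
    N = len(universe)
    n = len(hit_set)
    rows = []
    for cx in complexes:
        member_entities = [e for e, g in universe.items() if g in cx.members]
        genes_covered = {universe[e] for e in member_entities}
        if len(genes_covered) < min_size:
            continue
        K = len(member_entities)
        overlap = sum(1 for e in member_entities if e in hit_set)
        p = float(hypergeom_tail(overlap, N, K, n))
        rows.append(
            {
                "complex": cx.name,
                "universe_size": N,
                "n_hits": n,
                "set_size": K,
                "overlap": overlap,
                "expected": n * K / N if N else np.nan,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["p_adj"] < alpha
    return df


def _sanitize(seq: str) -> str:
    bad = [c for c in seq if c not in _VALID_AA]
    if bad:
        logger.warning("skipping %d non-amino-acid character(s)", len(bad))
        seq = "".join(c for c in seq if c in _VALID_AA)
    return seq


def count_flank_motifs(
    sequences: Mapping[str, str],
    patterns: Sequence[str] = MOTIF_PATTERNS,
    general_gxl: bool = False,
) -> pd.DataFrame:
    """Presence counts of G-x-L tripeptide motifs across protein sequences.

    Scoring is at sequence-presence level (does the protein contain the
    motif at least once), not occurrence counts.  The combined "any G*L"
    pattern matches G[STCY]L by default (the phospho-capable or cysteine
    middle residues), or any G.L when ``general_gxl`` is set.
    """
    any_re = re.compile("G.L" if general_gxl else "G[STCY]L")
    counts = {p: 0 for p in patterns}
    counts["any_GxL"] = 0
    total = 0
    for _, seq in sorted(sequences.items()):
        seq = _sanitize(str(seq).upper())
        total += 1
        for p in patterns:
            if p in seq:
                counts[p] += 1
        if any_re.search(seq):
            counts["any_GxL"] += 1
    return pd.DataFrame(
        {"pattern": list(counts), "count": list(counts.values()), "total": total}
    )


def two_prop_test_yates(x1: int, n1: int, x2: int, n2: int) -> Tuple[float, float]:
    """Two-sample equality-of-proportions chi-square with Yates correction.

    Returns (chi2, two-sided p) for the 2x2 table with a 0.5 continuity
    correction capped so |O - E| - 0.5 never goes negative.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], float)
    if table.sum(axis=0).min() == 0:  # degenerate margin: no evidence either way
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


def motif_enrichment(
    hit_sequences: Mapping[str, str],
    background_sequences: Mapping[str, str],
    patterns: Sequence[str] = MOTIF_PATTERNS,
    general_gxl: bool = False,
) -> pd.DataFrame:
    """Per-pattern proportion tests of motif presence, hits vs background."""
    hit_tab = count_flank_motifs(hit_sequences, patterns, general_gxl)
    bg_tab = count_flank_motifs(background_sequences, patterns, general_gxl)
    rows = []
    for (_, h), (_, b) in zip(hit_tab.iterrows(), bg_tab.iterrows()):
        chi2, p = two_prop_test_yates(
            int(h["count"]), int(h["total"]), int(b["count"]), int(b["total"])
        )
        rows.append(
            {
                "pattern": h["pattern"],
                "hit_count": int(h["count"]),
                "hit_total": int(h["total"]),
                "background_count": int(b["count"]),
                "background_total": int(b["total"]),
                "chi2": chi2,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def pulldown_replication_filter(
    detections: Mapping[str, Mapping[str, Set]],
    min_drug_reps: int = 2,
) -> List[str]:
    """Hits replicated in >= 2 of 3 drug-probe preparations with zero vehicle
    (DMSO) detection; any vehicle detection excludes the entity."""
    hits = []
    for entity in sorted(detections):
        det = detections[entity]
        drug = set(det.get("ibrutinib", set()))
        dmso = set(det.get("dmso", set()))
        if len(drug) >= min_drug_reps and not dmso:
            hits.append(entity)
    return hits
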