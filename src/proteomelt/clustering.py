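"""Per-gene peptide graphs, Leiden community detection, and the acceptance
gates that turn communities into functional proteoform groups.

A gene enters clustering only if at least ``min_peptides`` peptides map to it
and every sample (TMT set) contains at least ``min_per_sample`` of them.
Distances between peptides are weighted Euclidean over their concatenated
fold-change profiles (all sets jointly), with per-position weights inversely
proportional to the cross-peptide variance at that position within the gene
(down-weighting the noisy high-temperature tail).  Distances map to edge
weights through a Gaussian kernel with a per-gene bandwidth equal to the
median pairwise distance.  Communities come from Leiden modularity
maximization (resolution 1); a clustering is accepted only if the partition
modularity Q exceeds ``modularity_floor`` and the gene's peptide ambiguity
ratio is below ``max_ambiguity``, and every community must keep at least
``min_community`` peptides (smaller communities are merged into the most
similar accepted one, preserving the partition property).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd

from .preprocess import to_fold_changes, vsn_fit
from .types import PeptideQuantRecord, TemperatureGrid

logger = logging.getLogger(__name__)

_VAR_EPS = 1e-12


@dataclass
class ClusterThresholds:
    """Acceptance gates for proteoform-group assignment."""

    min_peptides: int = 10
    min_per_sample: int = 2
    min_community: int = 3
    modularity_floor: float = 1e-13
    max_ambiguity: float = 0.5


@dataclass
class GeneGraph:
    """Complete weighted peptide graph for one gene."""

    gene: str
    peptide_ids: List[str]
    distances: np.ndarray  # pairwise, NaN where undefined
    similarities: np.ndarray  # Gaussian kernel of distances
    bandwidth: float
    graph: ig.Graph


@dataclass
class ProteoformGroupAssignment:
    """Final peptide -> group labels for one gene, plus gate diagnostics."""

    gene: str
    membership: Dict[str, str]
    modularity: float
    ambiguity_ratio: float
    accepted: bool
    reason: str
    merged_peptides: Set[str] = field(default_factory=set)

    @property
    def groups(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for pep, lab in self.membership.items():
            out.setdefault(lab, []).append(pep)
        return {k: sorted(v) for k, v in out.items()}


def melt_distance(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    weights: Optional[np.ndarray] = None,
    min_shared: int = 3,
) -> Optional[float]:
    """Weighted Euclidean distance over shared non-missing positions.

    Weights are renormalized to sum to the number of shared positions, so the
    distance scale is comparable across pairs with different missingness.
    Returns None when fewer than ``min_shared`` positions are shared.
    """
    a = np.asarray(profile_a, float)
    b = np.asarray(profile_b, float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    w = np.ones_like(a) if weights is None else np.asarray(weights, float)
    shared = np.isfinite(a) & np.isfinite(b) & np.isfinite(w)
    n = int(shared.sum())
    if n < min_shared:
        return None
    ws = w[shared]
    ws = ws * (n / ws.sum())
    return float(np.sqrt(np.sum(ws * (a[shared] - b[shared]) ** 2)))


def similarity_from_distance(d: float, bandwidth: float) -> float:
    """Gaussian kernel exp(-d^2 / (2 h^2)); 1 at d = 0, decreasing in d."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if d < 0:
        raise ValueError("distance must be non-negative")
    return float(np.exp(-(d**2) / (2.0 * bandwidth**2)))


def inverse_variance_weights(profiles: pd.DataFrame) -> np.ndarray:
    """Per-position weights 1 / (cross-peptide variance + eps) within a gene."""
    var = profiles.var(axis=0, ddof=1).to_numpy()
    var = np.where(np.isfinite(var), var, np.nan)
    med = np.nanmedian(var[var > 0]) if np.any(var > 0) else 1.0
    w = 1.0 / (np.where(np.isfinite(var), var, med) + _VAR_EPS * max(med, 1.0))
    return w


def build_gene_graph(
    gene: str,
    profiles: pd.DataFrame,
    weights: Optional[np.ndarray] = None,
) -> GeneGraph:
    """Complete similarity graph over a gene's peptides.

    ``profiles`` is peptide x concatenated-position fold changes.  The kernel
    bandwidth is the median of the defined pairwise distances.
    """
    peptides = list(profiles.index)
    n = len(peptides)
    if n < 2:
        raise ValueError(f"{gene}: need at least two peptides to build a graph")
    if weights is None:
        weights = inverse_variance_weights(profiles)
    arr = profiles.to_numpy(float)
    dist = np.full((n, n), np.nan)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            d = melt_distance(arr[i], arr[j], weights)
            if d is not None:
                dist[i, j] = dist[j, i] = d
    offdiag = dist[np.triu_indices(n, k=1)]
    defined = offdiag[np.isfinite(offdiag)]
    if defined.size == 0:
        raise ValueError(f"{gene}: no defined pairwise distances")
    bandwidth = float(np.median(defined))
    if bandwidth <= 0:
        bandwidth = 1.0  # all profiles identical; any kernel width works
    sim = np.exp(-(dist**2) / (2.0 * bandwidth**2))
    edges, eweights = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(sim[i, j]):
                edges.append((i, j))
                eweights.append(float(sim[i, j]))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = eweights
    g.vs["name"] = peptides
    return GeneGraph(
        gene=gene,
        peptide_ids=peptides,
        distances=dist,
        similarities=sim,
        bandwidth=bandwidth,
        graph=g,
    )


def leiden_communities(
    gene_graph: GeneGraph, seed: int = 0, resolution: float = 1.0, n_iterations: int = 10
) -> Tuple[np.ndarray, float]:
    """Leiden partition maximizing weighted modularity, plus its Q.

    Deterministic for a fixed seed; Q is computed for the returned partition
    with igraph's weighted modularity.
    """
    g = gene_graph.graph
    if g.vcount() < 2:
        raise ValueError("graph must have at least two vertices")
    if resolution == 1.0:
        part = leidenalg.find_partition(
            g,
            leidenalg.ModularityVertexPartition,
            weights="weight",
            seed=seed,
            n_iterations=n_iterations,
        )
    else:
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            seed=seed,
            n_iterations=n_iterations,
            resolution_parameter=resolution,
        )
    membership = np.asarray(part.membership)
    q = float(g.modularity(list(membership), weights="weight"))
    return membership, q


def ambiguity_ratio(gene_flags: Iterable[bool]) -> float:
    """Ambiguous / (specific + ambiguous) peptides for one gene."""
    flags = list(gene_flags)
    if not flags:
        raise ValueError("gene has no peptides")
    return sum(flags) / len(flags)


def _order_labels(groups: Dict[int, List[str]], gene: str) -> Dict[str, str]:
    """gene_1, gene_2, ... by descending size, ties by smallest member id."""
    ordered = sorted(
        groups.values(), key=lambda members: (-len(members), min(members))
    )
    out: Dict[str, str] = {}
    for k, members in enumerate(ordered, start=1):
        for pep in members:
            out[pep] = f"{gene}_{k}"
    return out


def _single_group(gene, peptides, reason, q=np.nan, r=np.nan, merged=None):
    return ProteoformGroupAssignment(
        gene=gene,
        membership={p: f"{gene}_1" for p in peptides},
        modularity=q,
        ambiguity_ratio=r,
        accepted=False,
        reason=reason,
        merged_peptides=merged or set(),
    )


def assign_gene(
    gene: str,
    profiles: pd.DataFrame,
    ambiguous_flags: Mapping[str, bool],
    thresholds: ClusterThresholds,
    seed: int = 0,
) -> ProteoformGroupAssignment:
    """Cluster one gene's peptides and apply every acceptance gate."""
    peptides = list(profiles.index)
    r = ambiguity_ratio([ambiguous_flags.get(p, False) for p in peptides])
    n_sets = profiles.columns.get_level_values(0).unique()
    per_sample = {
        s: int(profiles[s].notna().any(axis=1).sum()) for s in n_sets
    }
    if len(peptides) < thresholds.min_peptides or any(
        c < thresholds.min_per_sample for c in per_sample.values()
    ):
        return _single_group(gene, peptides, "below_min_peptides", r=r)
    gg = build_gene_graph(gene, profiles)
    membership, q = leiden_communities(gg, seed=seed)
    if not q > thresholds.modularity_floor:
        return _single_group(gene, peptides, "low_modularity", q=q, r=r)
    if not r < thresholds.max_ambiguity:
        return _single_group(gene, peptides, "high_ambiguity", q=q, r=r)

    groups: Dict[int, List[str]] = {}
    for pep, lab in zip(gg.peptide_ids, membership):
        groups.setdefault(int(lab), []).append(pep)

    # merge communities below the peptide-support gate into the most similar
    # accepted community (highest mean edge weight), preserving the partition
    merged: Set[str] = set()
    small = [c for c, members in groups.items() if len(members) < thresholds.min_community]
    big = [c for c in groups if c not in small]
    if big:
        idx = {p: i for i, p in enumerate(gg.peptide_ids)}
        for c in sorted(small, key=lambda c: len(groups[c])):
            members = groups.pop(c)
            sims = {
                t: float(
                    np.nanmean(
                        [
                            gg.similarities[idx[p], idx[tp]]
                            for p in members
                            for tp in groups[t]
                        ]
                    )
                )
                for t in big
            }
            target = max(sorted(sims), key=lambda t: sims[t])
            groups[target].extend(members)
            merged.update(members)
    else:
        # every community below support: collapse to a single group
        return _single_group(
            gene, peptides, "small_community_merged", q=q, r=r,
            merged=set(peptides),
        )

    labels = _order_labels(groups, gene)
    return ProteoformGroupAssignment(
        gene=gene,
        membership=labels,
        modularity=q,
        ambiguity_ratio=r,
        accepted=len(groups) > 1,
        reason="clustered",
        merged_peptides=merged,
    )


def assign_proteoform_groups(
    fold_changes: pd.DataFrame,
    gene_map: pd.DataFrame,
    thresholds: Optional[ClusterThresholds] = None,
    seed: int = 0,
) -> List[ProteoformGroupAssignment]:
    """Assign every gene's peptides to proteoform groups.

    ``fold_changes``: peptide x (set, channel) profile matrix (from
    :func:`proteomelt.preprocess.peptide_fold_change_matrix`).
    ``gene_map``: columns peptide_id, gene, ambiguous (one row per
    peptide-gene mapping; ambiguous peptides appear under each mapped gene).
    Always returns a partition for every gene.
    """
    thresholds = thresholds or ClusterThresholds()
    out: List[ProteoformGroupAssignment] = []
    counts: Dict[str, int] = {}
    for gene, sub in gene_map.groupby("gene", sort=True):
        peps = [p for p in sub["peptide_id"] if p in fold_changes.index]
        if not peps:
            continue
        flags = dict(zip(sub["peptide_id"], sub["ambiguous"]))
        assignment = assign_gene(
            gene,
            fold_changes.loc[sorted(set(peps))],
            flags,
            thresholds,
            seed=seed,
        )
        out.append(assignment)
        counts[assignment.reason] = counts.get(assignment.reason, 0) + 1
    logger.info("gene gate decisions: %s", dict(sorted(counts.items())))
    return out


def assignments_to_frame(assignments: Iterable[ProteoformGroupAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        for pep, lab in sorted(a.membership.items()):
            rows.append(
                {
                    "gene": a.gene,
                    "peptide_id": pep,
                    "membership": lab,
                    "modularity": a.modularity,
                    "ambiguity_ratio": a.ambiguity_ratio,
                    "accepted": a.accepted,
                    "reason": "small_community_merged"
                    if pep in a.merged_peptides
                    else a.reason,
                }
            )
    return pd.DataFrame(rows)


def summarize_groups(
    records: Sequence[PeptideQuantRecord],
    assignments: Iterable[ProteoformGroupAssignment],
    grid: TemperatureGrid,
    trim_fraction: float = 0.25,
) -> pd.DataFrame:
    """Proteoform-group melt curves from summed raw member intensities.

    Member peptides' raw (non-normalized) reporter intensities are summed
    channelwise per group per set, the group x set matrix is VSN-normalized
    per temperature channel, and fold changes to the reference temperature
    are formed.  Returns group x (set, channel) fold changes with an
    ``n_member_peptides`` attribute column in ``.attrs``.
    """
    label_of: Dict[Tuple[str, str], str] = {}
    for a in assignments:
        for pep, lab in a.membership.items():
            label_of[(a.gene, pep)] = lab
    sums: Dict[Tuple[str, str], np.ndarray] = {}
    members: Dict[str, Set[str]] = {}
    for r in records:
        for gene in r.gene_symbols:
            lab = label_of.get((gene, r.peptide_id))
            if lab is None:
                continue
            members.setdefault(lab, set()).add(r.peptide_id)
            key = (lab, r.set_id)
            if key not in sums:
                sums[key] = np.full(len(grid), np.nan)
            prev = sums[key]
            cur = r.intensities
            both = np.isfinite(prev) & np.isfinite(cur)
            take_cur = ~np.isfinite(prev) & np.isfinite(cur)
            prev[both] += cur[both]
            prev[take_cur] = cur[take_cur]
    set_ids = sorted({s for (_, s) in sums})
    group_ids = sorted({g for (g, _) in sums})
    raw = pd.DataFrame(
        np.nan,
        index=group_ids,
        columns=pd.MultiIndex.from_product([set_ids, range(len(grid))]),
    )
    for (g, s), vals in sums.items():
        raw.loc[g, s] = vals

    # per-temperature VSN across groups, columns = sets at that temperature
    calibrated = raw.copy()
    for t in range(len(grid)):
        sub = raw.loc[:, pd.IndexSlice[:, t]]
        fit = vsn_fit(sub.droplevel(1, axis=1), trim_fraction)
        cal = fit.calibrated
        for s in set_ids:
            calibrated[(s, t)] = cal[s]

    pieces = []
    for s in set_ids:
        fc = to_fold_changes(calibrated[s], grid)
        fc.columns = pd.MultiIndex.from_product([[s], fc.columns])
        pieces.append(fc)
    out = pd.concat(pieces, axis=1)
    out = out.loc[sorted(out.index)]
    out.attrs["n_member_peptides"] = {g: len(members[g]) for g in out.index}
    out.index.name = "group_id"
    return out
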