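"""End-to-end orchestration of the TPP and cohort analyses.

Stages run in a fixed order with all randomness derived from one root seed
via named substreams, so re-running with an identical configuration
reproduces byte-identical result tables.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import enrichment as enrich_mod
from .clustering import (
    ClusterThresholds,
    assign_proteoform_groups,
    assignments_to_frame,
    summarize_groups,
)
from .io_formats import read_fasta, read_gmt, read_peptide_table, write_results_table
from .nparc import NparcFits, filter_complete_curves, nparc_f_test, nparc_rss
from .preprocess import peptide_fold_change_matrix, summarize_psm_to_peptides
from .synthetic import CohortSimConfig, TppSimConfig, simulate_cohort, simulate_tpp_experiment
from .types import PeptideQuantRecord, TemperatureGrid

logger = logging.getLogger(__name__)


def substream_seed(root_seed: int, name: str) -> int:
    """Stable per-stage seed below 2^31 derived from the root seed."""
    return (int(root_seed) * 1000003 + zlib.crc32(name.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Declarative configuration for both pipelines.

    Threshold defaults are the acceptance gates of the clustering method
    (min 10 peptides per gene, 2 per sample, communities of >= 3 peptides,
    modularity floor 1e-13, ambiguity ratio < 0.5) and alpha = 0.05.
    """

    out_dir: str = "results"
    seed: int = 0
    alpha: float = 0.05
    grid_temperatures: Tuple[float, ...] = tuple(np.linspace(37.0, 67.0, 10))
    thresholds: ClusterThresholds = field(default_factory=ClusterThresholds)
    nparc_min_groups: int = 50
    peptide_table: Optional[str] = None
    gmt_path: Optional[str] = None
    fasta_path: Optional[str] = None
    tpp_sim: TppSimConfig = field(default_factory=TppSimConfig)
    cohort_sim: CohortSimConfig = field(default_factory=CohortSimConfig)

    @property
    def grid(self) -> TemperatureGrid:
        return TemperatureGrid(tuple(self.grid_temperatures), 0)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        th = self.thresholds
        if min(th.min_peptides, th.min_per_sample, th.min_community) < 1:
            raise ValueError("clustering thresholds must be positive")

    def manifest(self) -> dict:
        m = asdict(self)
        m["grid_temperatures"] = list(self.grid_temperatures)
        return m


def gene_map_from_records(records: Sequence[PeptideQuantRecord]) -> pd.DataFrame:
    """(peptide, gene, ambiguous) rows; ambiguous peptides appear per gene."""
    rows = {}
    for r in records:
        amb = r.is_ambiguous
        for g in sorted(r.gene_symbols):
            rows[(r.peptide_id, g)] = amb
    return pd.DataFrame(
        [{"peptide_id": p, "gene": g, "ambiguous": a} for (p, g), a in sorted(rows.items())]
    )


def set_metadata(records: Sequence[PeptideQuantRecord]) -> pd.DataFrame:
    seen = {}
    for r in records:
        seen[r.set_id] = r.sample_key
    return pd.DataFrame(
        [
            {
                "set_id": s,
                "cell_line": k.cell_line,
                "condition": k.condition,
                "replicate": k.replicate,
            }
            for s, k in sorted(seen.items())
        ]
    )


def group_curves_long(
    group_fc: pd.DataFrame, set_meta: pd.DataFrame, grid: TemperatureGrid
) -> pd.DataFrame:
    """Long-form group melt curves joined with sample metadata."""
    meta = set_meta.set_index("set_id")
    temps = grid.array
    rows = []
    for gid, row in group_fc.iterrows():
        for (set_id, chan), val in row.items():
            m = meta.loc[set_id]
            rows.append(
                {
                    "group_id": gid,
                    "set_id": set_id,
                    "cell_line": m["cell_line"],
                    "condition": m["condition"],
                    "replicate": f"{m['cell_line']}_r{m['replicate']}",
                    "T": temps[int(chan)],
                    "value": val,
                }
            )
    return pd.DataFrame(rows)


def run_nparc_scope(
    curves: pd.DataFrame,
    scope: str,
    grid: TemperatureGrid,
    cell_line: Optional[str] = None,
    min_groups: int = 50,
) -> pd.DataFrame:
    """Filter to complete designs within a scope and run the F-test screen."""
    sub = curves if cell_line is None else curves[curves["cell_line"] == cell_line]
    if sub.empty:
        return nparc_f_test([], scope=scope)
    design = sorted(
        {(c, r) for c, r in zip(sub["condition"], sub["replicate"])}
    )
    by_group = {g: df for g, df in sub.groupby("group_id")}
    kept = filter_complete_curves(by_group, design, len(grid))
    fits: List[NparcFits] = []
    for gid in kept:
        fits.append(nparc_rss(by_group[gid], group_id=gid))
    return nparc_f_test(fits, scope=scope, min_groups=min_groups)


def run_tpp_pipeline(config: PipelineConfig) -> Dict[str, pd.DataFrame]:
    """read -> preprocess -> cluster -> summarize -> NPARC -> enrichment/motif.

    Returns the result tables and writes them (plus a manifest) under
    ``config.out_dir``.
    """
    config.validate()
    grid = config.grid
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.peptide_table:
        psm_records = read_peptide_table(config.peptide_table, grid)
        truth = None
    else:
        psm_records, truth = simulate_tpp_experiment(
            config.tpp_sim, seed=substream_seed(config.seed, "tpp_sim")
        )
    records = summarize_psm_to_peptides(psm_records)
    fc = peptide_fold_change_matrix(records, grid)
    gene_map = gene_map_from_records(records)
    assignments = assign_proteoform_groups(
        fc, gene_map, config.thresholds, seed=substream_seed(config.seed, "leiden")
    )
    assign_df = assignments_to_frame(assignments)
    group_fc = summarize_groups(records, assignments, grid)
    meta = set_metadata(records)
    curves = group_curves_long(group_fc, meta, grid)

    scopes = [("all", None)] + [(cl, cl) for cl in sorted(meta["cell_line"].unique())]
    nparc_tables = [
        run_nparc_scope(curves, scope, grid, cell_line=cl, min_groups=config.nparc_min_groups)
        for scope, cl in scopes
    ]
    nparc_df = pd.concat(nparc_tables, ignore_index=True)

    results: Dict[str, pd.DataFrame] = {
        "assignments": assign_df,
        "group_curves": curves,
        "nparc": nparc_df,
    }

    if config.gmt_path:
        complexes = read_gmt(config.gmt_path)
        all_scope = nparc_df[nparc_df["scope"] == "all"]
        gene_of = {
            gid: gid.rsplit("_", 1)[0] for gid in all_scope["group_id"]
        }
        hits = list(all_scope.loc[all_scope["p_adj"] < config.alpha, "group_id"])
        results["ora"] = enrich_mod.ora_complexes(
            hits, gene_of, complexes, alpha=config.alpha
        )
    if config.fasta_path:
        seqs = read_fasta(config.fasta_path)
        any_scope_hits = set(
            nparc_df.loc[nparc_df["p"] < config.alpha, "group_id"].map(
                lambda g: g.rsplit("_", 1)[0]
            )
        )
        hit_seqs = {g: s for g, s in seqs.items() if g in any_scope_hits}
        results["motifs"] = enrich_mod.motif_enrichment(hit_seqs, seqs)

    for name, df in results.items():
        write_results_table(df.reset_index(drop=True), out_dir / f"{name}.tsv")
    manifest = {"pipeline": "tpp", "config": config.manifest()}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    if truth is not None:
        truth.to_json(out_dir / "truth.json")
    return results


def run_cohort_pipeline(
    config: PipelineConfig,
    psm_table: Optional[pd.DataFrame] = None,
    annotations: Optional[pd.DataFrame] = None,
) -> Dict[str, pd.DataFrame]:
    """sum -> normalize -> randomized null -> F-test -> Wilcoxon -> correlations."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = None
    if psm_table is None:
        psm_table, annotations, truth = simulate_cohort(
            config.cohort_sim, seed=substream_seed(config.seed, "cohort_sim")
        )
    normalized = cohort_mod.normalize_psms_by_set(psm_table)

    peptide_groups = {
        pep: (gene, memb)
        for pep, gene, memb in psm_table[["peptide_id", "gene", "membership"]]
        .drop_duplicates()
        .itertuples(index=False)
    }
    null_map = cohort_mod.randomize_membership(
        peptide_groups, seed=substream_seed(config.seed, "membership_null")
    )

    mats = {}
    for grouping in ("gene", "proteoform", "randomized"):
        raw = cohort_mod.sum_to_grouping(
            normalized,
            grouping,
            membership_map=null_map if grouping == "randomized" else None,
        )
        mats[grouping] = cohort_mod.log_median_center(raw)

    pep_per_real: Dict[str, set] = {}
    pep_per_null: Dict[str, set] = {}
    for pep, (gene, memb) in peptide_groups.items():
        pep_per_real.setdefault(memb, set()).add(pep)
        pep_per_null.setdefault(null_map[pep], set()).add(pep)
    ftest = cohort_mod.variance_f_test(
        mats["proteoform"],
        mats["randomized"],
        sizes_real={g: len(s) for g, s in pep_per_real.items()},
        sizes_null={g: len(s) for g, s in pep_per_null.items()},
    )
    significant = list(ftest.loc[ftest["p_adj"] < config.alpha, "entity"])

    treated = list(annotations.loc[annotations["treated"], "patient"])
    untreated = list(annotations.loc[~annotations["treated"], "patient"])
    wilcoxon = cohort_mod.wilcoxon_treatment_test(
        mats["proteoform"].loc[[g for g in significant if g in mats["proteoform"].index]]
        if significant
        else mats["proteoform"].iloc[:0],
        treated,
        untreated,
    )

    labels = dict(zip(annotations["patient"], annotations["subgroup"]))
    response = dict(zip(annotations["patient"], annotations["response"]))
    correlations = cohort_mod.subgroup_analysis(
        mats["proteoform"],
        labels,
        response,
        subgroup="subgroupA",
        significant_entities=significant,
    )

    results = {
        "cohort_ftest": ftest,
        "cohort_wilcoxon": wilcoxon,
        "cohort_correlations": correlations,
    }
    for name, df in results.items():
        write_results_table(df.reset_index(drop=True), out_dir / f"{name}.tsv")
    manifest = {"pipeline": "cohort", "config": config.manifest()}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    if truth is not None:
        truth.to_json(out_dir / "cohort_truth.json")
    results["abundance_proteoform"] = mats["proteoform"]
    results["abundance_gene"] = mats["gene"]
    results["abundance_randomized"] = mats["randomized"]
    return results
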