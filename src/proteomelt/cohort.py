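"""Cohort-scale proteoform-group abundance statistics.

The pipeline mirrors a clinical proteomics workflow: PSM reporter values are
VSN-normalized per TMT set, summed to a chosen grouping (gene symbol, real
proteoform group, or a randomized within-gene null grouping), log2
transformed and median-centered per patient.  The randomized grouping keeps
each gene's group-size multiset and peptide universe, isolating within-gene
peptide-sampling noise; paired variance F-tests against it flag groups whose
abundance varies more across patients than peptide re-sampling alone can
explain.  Treatment contrasts use two-sided Wilcoxon rank-sum tests, and
drug-response associations use Spearman correlations with Fisher-z
confidence intervals, optionally stratified by patient subgroup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .nparc import bh_adjust
from .preprocess import vsn_fit

logger = logging.getLogger(__name__)

PSM_COLUMNS = ["psm_id", "peptide_id", "gene", "membership", "set_id", "patient", "intensity"]


def normalize_psms_by_set(psm_table: pd.DataFrame, trim_fraction: float = 0.25) -> pd.DataFrame:
    """Per-set VSN calibration of the PSM x patient intensity matrix.

    Returns the long table with an extra ``calibrated`` column (natural
    scale, per-patient scale factors absorbed).
    """
    out = []
    for set_id, sub in psm_table.groupby("set_id", sort=True):
        wide = sub.pivot_table(
            index="psm_id", columns="patient", values="intensity", aggfunc="first"
        )
        fit = vsn_fit(wide, trim_fraction)
        cal = fit.calibrated.stack().rename("calibrated").reset_index()
        merged = sub.merge(cal, on=["psm_id", "patient"], how="left")
        out.append(merged)
    return pd.concat(out, ignore_index=True)


def sum_to_grouping(
    psm_table: pd.DataFrame,
    grouping: str = "proteoform",
    membership_map: Optional[Mapping[str, str]] = None,
    value_column: str = "calibrated",
) -> pd.DataFrame:
    """Sum PSM values per entity per patient under one of three groupings.

    grouping: "gene" (sum by gene symbol), "proteoform" (sum by the real
    membership labels), or "randomized" (sum by a caller-supplied
    peptide -> null-label map from :func:`randomize_membership`).
    """
    df = psm_table.copy()
    if grouping == "gene":
        df["entity"] = df["gene"]
    elif grouping == "proteoform":
        df["entity"] = df["membership"]
    elif grouping == "randomized":
        if membership_map is None:
            raise ValueError("randomized grouping requires a membership_map")
        df["entity"] = df["peptide_id"].map(membership_map)
        if df["entity"].isna().any():
            missing = df.loc[df["entity"].isna(), "peptide_id"].unique()
            raise ValueError(f"grouping references unknown peptides: {missing[:5]}")
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    mat = df.pivot_table(
        index="entity", columns="patient", values=value_column, aggfunc="sum"
    )
    mat.index.name = "entity"
    return mat


def randomize_membership(
    peptide_groups: Mapping[str, Tuple[str, str]], seed: int = 0
) -> Dict[str, str]:
    """Permute proteoform-group labels within each gene, sizes preserved.

    ``peptide_groups`` maps peptide_id -> (gene, membership label).  The
    returned peptide -> label map covers the same peptides and keeps each
    gene's group-size multiset; only the identification is shuffled.
    """
    rng = np.random.default_rng(seed)
    by_gene: Dict[str, List[str]] = {}
    for pep in sorted(peptide_groups):
        gene, _ = peptide_groups[pep]
        by_gene.setdefault(gene, []).append(pep)
    out: Dict[str, str] = {}
    for gene in sorted(by_gene):
        peps = by_gene[gene]
        labels = [peptide_groups[p][1] for p in peps]
        if len(set(labels)) <= 1:
            out.update(dict(zip(peps, labels)))
            continue
        perm = rng.permutation(len(labels))
        for p, k in zip(peps, perm):
            out[p] = labels[int(k)]
    return out


def log_median_center(matrix: pd.DataFrame, base: float = 2.0) -> pd.DataFrame:
    """log (base 2) transform then per-patient (column) median centering."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logged = np.log(matrix.where(matrix > 0)) / np.log(base)
    return logged.sub(logged.median(axis=0, skipna=True), axis=1)


def average_replicate_columns(
    matrix: pd.DataFrame, sample_to_patient: Mapping[str, str]
) -> pd.DataFrame:
    """Average replicate samples of the same patient (post-normalization)."""
    groups = matrix.T.groupby(lambda s: sample_to_patient.get(s, s))
    return groups.mean().T


def variance_f_test(
    real_matrix: pd.DataFrame,
    null_matrix: pd.DataFrame,
    pairing: Optional[Mapping[str, str]] = None,
    method: str = "pooled",
    sizes_real: Optional[Mapping[str, int]] = None,
    sizes_null: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Per-group variance excess over the randomized-membership null.

    ``method="pooled"`` (default) models the size-matched null groups'
    across-patient variances as a scaled chi-square fitted robustly to the
    body of their distribution (:func:`proteomelt.nparc.fit_scaled_chi2`),
    then refers each real group's variance to that parametric null's upper
    tail.  Pooling is needed because a shuffled group shares peptides with
    its own real counterpart, which makes the one-to-one paired ratio
    underdispersed; the robust body fit is needed because shuffled groups
    from genes carrying true effects inherit part of the signal and
    contaminate the null pool's tail.  ``method="paired"`` keeps the classic
    per-gene ratio F = var(real)/var(own null) with a one-sided F(n-1, n-1)
    tail.  BH correction is applied across groups either way.
    """
    from .nparc import fit_scaled_chi2

    if method not in ("pooled", "paired"):
        raise ValueError(f"unknown method {method!r}")
    pairing = pairing or {g: g for g in real_matrix.index}
    var_real = real_matrix.var(axis=1, ddof=1, skipna=True)
    var_null = null_matrix.var(axis=1, ddof=1, skipna=True)
    n_pat = real_matrix.notna().sum(axis=1)

    null_model: Dict[int, Optional[Tuple[float, float]]] = {}
    if method == "pooled":
        by_size: Dict[int, List[float]] = {}
        for gid, v in var_null.items():
            if not np.isfinite(v) or v <= 0:
                continue
            size = int(sizes_null[gid]) if sizes_null else 0
            by_size.setdefault(size, []).append(float(v))
        for s, vs in by_size.items():
            null_model[s] = fit_scaled_chi2(np.asarray(vs)) if len(vs) >= 20 else None

    rows = []
    for gid in real_matrix.index:
        null_id = pairing.get(gid)
        if null_id is None or null_id not in null_matrix.index:
            continue
        vx = float(var_real[gid])
        vy = float(var_null[null_id])
        n = int(n_pat[gid])
        if n < 3 or not np.isfinite(vx):
            continue
        degenerate = vy <= 0 or not np.isfinite(vy)
        F = np.inf if degenerate else vx / vy
        if method == "pooled":
            size = int(sizes_real[gid]) if sizes_real else 0
            model = null_model.get(size)
            if model is None:
                # too few size-matched nulls for a parametric fit: fall back
                # to the paired ratio for this group
                p = 1.0 if degenerate else float(stats.f.sf(F, n - 1, n - 1))
            else:
                d, scale = model
                p = float(stats.chi2.sf(vx / scale, d))
        else:
            p = 1.0 if degenerate else float(stats.f.sf(F, n - 1, n - 1))
        rows.append(
            {"entity": gid, "F": F, "p": p, "n": n, "degenerate_null": degenerate}
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df


def wilcoxon_treatment_test(
    matrix: pd.DataFrame,
    treated: Sequence[str],
    untreated: Sequence[str],
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per group, treated vs untreated.

    Exact null distribution when both arms have <= 10 samples and there are
    no ties; normal approximation with tie correction otherwise.  BH across
    groups.
    """
    treated = [p for p in treated if p in matrix.columns]
    untreated = [p for p in untreated if p in matrix.columns]
    if not treated or not untreated:
        raise ValueError("both arms need at least one sample")
    rows = []
    for gid in matrix.index:
        x = matrix.loc[gid, treated].dropna().to_numpy(float)
        y = matrix.loc[gid, untreated].dropna().to_numpy(float)
        if x.size < 1 or y.size < 1:
            continue
        pooled = np.concatenate([x, y])
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (x.size <= 10 and y.size <= 10 and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append(
            {"entity": gid, "W": float(res.statistic), "p": float(res.pvalue),
             "n_treated": x.size, "n_untreated": y.size}
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df


def spearman_with_ci(
    values: Sequence[float],
    response: Sequence[float],
    conf: float = 0.95,
) -> Dict[str, float]:
    """Spearman rho with a Fisher-z confidence interval (var 1.06/(n-3)).

    Average ranks handle ties; p is the two-sided t-approximation.  Constant
    input yields NaN with ``degenerate=True``.
    """
    x = np.asarray(values, float)
    y = np.asarray(response, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 paired observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return {
            "rho": np.nan, "p": np.nan, "ci_low": np.nan, "ci_high": np.nan,
            "n": n, "degenerate": True,
        }
    rho, p = stats.spearmanr(x, y)
    rho = float(np.clip(rho, -1.0, 1.0))
    z = np.arctanh(np.clip(rho, -0.999999, 0.999999))
    se = np.sqrt(1.06 / (n - 3))
    zcrit = stats.norm.ppf(0.5 + conf / 2.0)
    return {
        "rho": rho,
        "p": float(p),
        "ci_low": float(np.tanh(z - zcrit * se)),
        "ci_high": float(np.tanh(z + zcrit * se)),
        "n": n,
        "degenerate": False,
    }


def subgroup_analysis(
    matrix: pd.DataFrame,
    subgroup_labels: Mapping[str, str],
    response: Mapping[str, float],
    subgroup: str,
    significant_entities: Optional[Sequence[str]] = None,
    min_n: int = 5,
) -> pd.DataFrame:
    """Response correlations in three strata: all, subgroup, complement.

    Entities are optionally pre-filtered to those passing the variance
    F-test (significant abundance variation relative to the randomized
    null).  Strata smaller than ``min_n`` are skipped with a notice.
    """
    entities = (
        [e for e in matrix.index if e in set(significant_entities)]
        if significant_entities is not None
        else list(matrix.index)
    )
    patients = [p for p in matrix.columns if p in response]
    in_sub = [p for p in patients if subgroup_labels.get(p) == subgroup]
    out_sub = [p for p in patients if subgroup_labels.get(p) != subgroup]
    strata = {"all": patients, "subgroup": in_sub, "complement": out_sub}
    rows = []
    for stratum, cols in strata.items():
        if len(cols) < min_n:
            logger.info("stratum %s skipped: only %d patients", stratum, len(cols))
            continue
        resp = np.array([response[p] for p in cols], float)
        for e in entities:
            res = spearman_with_ci(matrix.loc[e, cols].to_numpy(float), resp)
            res.update({"entity": e, "stratum": stratum})
            rows.append(res)
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adj"] = np.nan
        for stratum in df["stratum"].unique():
            mask = (df["stratum"] == stratum) & df["p"].notna()
            if mask.any():
                df.loc[mask, "p_adj"] = bh_adjust(df.loc[mask, "p"].to_numpy())
    return df
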