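"""Reporter-intensity preprocessing: PSM summarization, variance-stabilizing
normalization, and relative melt profiles.

VSN here is the affine-calibration + generalized-log model: each sample
(column) j gets a robust positive scale factor c_j, and all samples share a
glog parameter b, giving

    h(x) = arsinh( (x / c_j) / b )

For x >> b the transform behaves like log(x) (multiplicative noise is
flattened); for x near zero it is linear (additive noise is not inflated).
``b`` is fitted so that feature standard deviations are approximately
constant across intensity strata.  The fit is deterministic: robust
median-of-ratios calibration followed by a bracketed 1-d search for ``b``.

Fold changes are formed on the ratio scale after back-transforming to
calibrated intensities, since the melt models downstream operate on
"fraction non-denatured" relative to the lowest temperature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import PeptideQuantRecord, TemperatureGrid

logger = logging.getLogger(__name__)


def summarize_psm_to_peptides(records: Iterable[PeptideQuantRecord]) -> List[PeptideQuantRecord]:
    """Sum PSM-level reporter signals to peptides within each set.

    Missing channels are treated as absent (the sum of the present values);
    a channel missing in every PSM stays missing.  Gene mappings are the
    union across PSMs of the peptide.
    """
    grouped: Dict[Tuple[str, str], List[PeptideQuantRecord]] = {}
    order: List[Tuple[str, str]] = []
    for r in records:
        key = (r.peptide_id, r.set_id)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(r)
    out: List[PeptideQuantRecord] = []
    for key in order:
        rs = grouped[key]
        n_chan = {len(r.intensities) for r in rs}
        if len(n_chan) != 1:
            raise ValueError(
                f"inconsistent channel counts {sorted(n_chan)} for peptide "
                f"{key[0]} in set {key[1]}"
            )
        stack = np.vstack([r.intensities for r in rs])
        with np.errstate(invalid="ignore"):
            summed = np.nansum(stack, axis=0)
        summed[np.all(np.isnan(stack), axis=0)] = np.nan
        first = rs[0]
        out.append(
            PeptideQuantRecord(
                peptide_id=first.peptide_id,
                sequence=first.sequence,
                gene_symbols=frozenset().union(*(r.gene_symbols for r in rs)),
                sample_key=first.sample_key,
                set_id=first.set_id,
                intensities=summed,
            )
        )
    return out


@dataclass
class VsnFit:
    """Fitted VSN calibration for one intensity matrix."""

    transformed: pd.DataFrame  # glog scale
    scale_factors: pd.Series  # per-sample c_j
    glog_param: float  # shared b

    @property
    def calibrated(self) -> pd.DataFrame:
        """Back-transformed (natural-scale) calibrated intensities x / c_j."""
        return self.transformed.apply(np.sinh) * self.glog_param


def _robust_scale_factors(matrix: pd.DataFrame, trim_fraction: float) -> pd.Series:
    """Per-column scale via trimmed mean of log-ratios to a reference profile."""
    log_m = np.log(matrix.where(matrix > 0))
    ref = log_m.mean(axis=1, skipna=True)
    log_ratios = log_m.sub(ref, axis=0)
    limit = min(max(trim_fraction, 0.0), 0.49)
    factors = {}
    for col in matrix.columns:
        vals = log_ratios[col].dropna().to_numpy()
        if vals.size == 0:
            factors[col] = 1.0
        else:
            factors[col] = float(np.exp(stats.trim_mean(vals, limit)))
    return pd.Series(factors)


def _stratum_sd_imbalance(calibrated: pd.DataFrame, b: float) -> float:
    """Squared log-ratio of mean feature sd in the bottom vs top tertile."""
    h = np.arcsinh(calibrated / b)
    sd = h.std(axis=1, ddof=1)
    mean = calibrated.mean(axis=1)
    ok = sd.notna() & mean.notna()
    sd, mean = sd[ok], mean[ok]
    if len(sd) < 6:
        return 0.0
    q = mean.rank(pct=True)
    low = sd[q <= 1 / 3].mean()
    high = sd[q > 2 / 3].mean()
    if not np.isfinite(low) or not np.isfinite(high) or low <= 0 or high <= 0:
        return 0.0
    return float(np.log(low / high) ** 2)


def vsn_fit(matrix: pd.DataFrame, trim_fraction: float = 0.25) -> VsnFit:
    """Fit the calibration + glog model to a features x samples matrix."""
    matrix = pd.DataFrame(matrix).astype(float)
    if matrix.shape[1] < 2:
        raise ValueError("VSN needs at least two samples")
    if (matrix < 0).any().any():
        raise ValueError("negative intensities are not allowed in VSN input")
    if matrix.isna().all(axis=0).any():
        bad = matrix.columns[matrix.isna().all(axis=0)].tolist()
        raise ValueError(f"all-missing sample column(s): {bad}")

    c = _robust_scale_factors(matrix, trim_fraction)
    calibrated = matrix.div(c, axis=1)

    positive = calibrated.to_numpy()
    positive = positive[np.isfinite(positive) & (positive > 0)]
    if positive.size == 0:
        # degenerate (all-zero) input: identity-ish transform
        b = 1.0
    else:
        lo = float(np.quantile(positive, 0.001)) / 100.0
        hi = float(np.quantile(positive, 0.999)) * 10.0
        lo = max(lo, 1e-12)
        grid = np.geomspace(lo, hi, 25)
        scores = [_stratum_sd_imbalance(calibrated, g) for g in grid]
        k = int(np.argmin(scores))
        left = grid[max(k - 1, 0)]
        right = grid[min(k + 1, len(grid) - 1)]
        if left < right:
            res = optimize.minimize_scalar(
                lambda lb: _stratum_sd_imbalance(calibrated, float(np.exp(lb))),
                bounds=(np.log(left), np.log(right)),
                method="bounded",
            )
            b = float(np.exp(res.x))
        else:
            b = float(grid[k])
    transformed = np.arcsinh(calibrated / b)
    return VsnFit(transformed=transformed, scale_factors=c, glog_param=b)


def vsn_normalize(matrix: pd.DataFrame, trim_fraction: float = 0.25) -> pd.DataFrame:
    """Variance-stabilized (glog-scale) matrix; see :func:`vsn_fit`."""
    return vsn_fit(matrix, trim_fraction).transformed


def to_fold_changes(calibrated: pd.DataFrame, grid: TemperatureGrid) -> pd.DataFrame:
    """Relative melt profiles: each row divided by its reference channel.

    ``calibrated`` is features x channels on the natural (back-transformed)
    scale with columns ordered like the grid.  Rows whose reference value is
    missing or zero are dropped with a logged warning.
    """
    if calibrated.shape[1] != len(grid):
        raise ValueError(
            f"expected {len(grid)} channels, got {calibrated.shape[1]}"
        )
    ref = calibrated.iloc[:, grid.reference_index]
    bad = ~(ref > 0) | ref.isna()
    if bad.any():
        logger.warning(
            "dropping %d profile(s) with missing or zero reference channel",
            int(bad.sum()),
        )
    kept = calibrated.loc[~bad]
    fc = kept.div(kept.iloc[:, grid.reference_index], axis=0)
    return fc


def peptide_fold_change_matrix(
    records: Iterable[PeptideQuantRecord],
    grid: TemperatureGrid,
    trim_fraction: float = 0.25,
) -> pd.DataFrame:
    """Per-set VSN + fold changes, concatenated across sets.

    Returns a peptide x (set_id, channel) DataFrame of fold changes relative
    to the reference temperature; peptides absent from a set carry NaN there.
    """
    records = list(records)
    by_set: Dict[str, List[PeptideQuantRecord]] = {}
    for r in records:
        by_set.setdefault(r.set_id, []).append(r)
    pieces = []
    for set_id in sorted(by_set):
        rs = by_set[set_id]
        mat = pd.DataFrame(
            {r.peptide_id: r.intensities for r in rs}
        ).T
        mat.columns = list(range(len(grid)))
        fit = vsn_fit(mat, trim_fraction)
        fc = to_fold_changes(fit.calibrated, grid)
        fc.columns = pd.MultiIndex.from_product([[set_id], fc.columns])
        pieces.append(fc)
    out = pd.concat(pieces, axis=1)
    out.index.name = "peptide_id"
    return out
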