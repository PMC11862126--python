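"""Synthetic TPP experiments and patient cohorts with known proteoform truth.

The TPP generator emulates the structure of a lysate thermal-shift study:
per-gene peptide pools drawn from one or two latent proteoforms with
four-parameter-logistic (4PL) melting, two treatment arms (drug / vehicle) in
technical duplicate across two cell lines, one TMT set per melt curve,
drug-induced melting-point shifts on a target subset of proteoforms,
log-normal multiplicative reporter noise, and a configurable share of
ambiguous multi-gene peptides.

The cohort generator emulates a patient proteomics study: PSM-level rows per
proteoform group per patient, a small ibrutinib-treated arm, a biologically
distinct patient subgroup, and an ex vivo viability response correlated with
designated groups.  Both generators return the latent truth needed to score
recovery downstream.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    CONDITIONS,
    FourPLParams,
    PeptideQuantRecord,
    SampleKey,
    TemperatureGrid,
)


def four_pl_curve(T, params: FourPLParams) -> np.ndarray:
    """Fraction non-denatured at temperature(s) ``T`` under a 4PL model.

    f(T) = bottom + (top - bottom) / (1 + exp((T - tm) / scale)); with
    scale > 0 the curve decreases from ``top`` toward ``bottom`` and crosses
    the plateau midpoint exactly at ``tm``.
    """
    T = np.asarray(T, dtype=float)
    z = np.clip((T - params.tm) / params.scale, -700.0, 700.0)
    return params.bottom + (params.top - params.bottom) / (1.0 + np.exp(z))


# ---------------------------------------------------------------------------
# TPP experiment
# ---------------------------------------------------------------------------


@dataclass
class TppSimConfig:
    """Study-design parameters for the synthetic TPP experiment.

    Defaults follow the emulated design: 200 genes with 12 peptides each,
    30% of genes carrying two latent proteoforms separated by a 4 degree C
    baseline melting-point difference, a 10% target subset shifted by
    3 degrees C under drug, technical duplicates in two cell lines, and
    multiplicative log-normal reporter noise (sd 0.05 on the log scale).
    """

    n_genes: int = 200
    peptides_per_gene: int = 12
    fraction_two_proteoform: float = 0.3
    delta_tm_proteoforms: float = 4.0
    target_fraction: float = 0.1
    drug_delta_tm: float = 3.0
    noise_sd: float = 0.05
    additive_sd: float = 0.0
    ambiguous_peptide_rate: float = 0.05
    cell_lines: Tuple[str, ...] = ("RCHACV", "SW13")
    replicates: int = 2
    grid: TemperatureGrid = field(default_factory=TemperatureGrid.default)
    tm_range: Tuple[float, float] = (44.0, 56.0)
    tm_cell_line_sd: float = 0.0
    bottom_range: Tuple[float, float] = (0.0, 0.15)
    scale_range: Tuple[float, float] = (1.3, 2.2)
    abundance_log10_mean: float = 5.0
    abundance_log10_sd: float = 1.0

    def validate(self) -> None:
        if not 0.0 <= self.fraction_two_proteoform <= 1.0:
            raise ValueError("fraction_two_proteoform must be in [0, 1]")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError("target_fraction must be in [0, 1]")
        if self.peptides_per_gene < 1 or self.n_genes < 1:
            raise ValueError("need at least one gene and one peptide")
        if self.noise_sd < 0 or self.additive_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")


@dataclass
class SyntheticTruth:
    """Latent ground truth of a simulated experiment or cohort."""

    peptide_proteoform: Dict[str, Dict[str, str]] = field(default_factory=dict)
    proteoform_params: Dict[str, Dict[str, dict]] = field(default_factory=dict)
    shifted_proteoforms: Dict[str, float] = field(default_factory=dict)
    differential_groups: List[str] = field(default_factory=list)
    response_groups: List[str] = field(default_factory=list)
    treated_patients: List[str] = field(default_factory=list)
    subgroup_patients: List[str] = field(default_factory=list)

    def gene_memberships(self, gene: str) -> Dict[str, str]:
        """peptide_id -> latent proteoform label for one gene."""
        return self.peptide_proteoform[gene]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _draw_params(rng: np.random.Generator, cfg: TppSimConfig, tm: float) -> FourPLParams:
    return FourPLParams(
        bottom=float(rng.uniform(*cfg.bottom_range)),
        top=1.0,
        tm=float(tm),
        scale=float(rng.uniform(*cfg.scale_range)),
    )


def simulate_tpp_experiment(
    config: Optional[TppSimConfig] = None, seed: int = 0
) -> Tuple[List[PeptideQuantRecord], SyntheticTruth]:
    """Generate one full TPP experiment plus its latent truth.

    Each peptide's intensity in a set is
    ``base_abundance * f(T | proteoform, cell line, condition) * exp(eps)``
    with ``eps ~ N(0, noise_sd)``; an optional additive Gaussian floor
    (``additive_sd``, truncated at zero) models low-intensity censoring.
    Identical seeds yield identical output.
    """
    cfg = config or TppSimConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    grid = cfg.grid
    temps = grid.array

    genes = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
    n_two = int(round(cfg.n_genes * cfg.fraction_two_proteoform))
    two_pf_genes = set(rng.choice(genes, size=n_two, replace=False))

    truth = SyntheticTruth()
    proteoform_ids: List[str] = []
    # latent structure per gene
    pf_of_peptide: Dict[str, str] = {}
    peptides_of_gene: Dict[str, List[str]] = {}
    for gene in genes:
        k = cfg.peptides_per_gene
        pep_ids = [f"{gene}_pep{j:02d}" for j in range(1, k + 1)]
        peptides_of_gene[gene] = pep_ids
        if gene in two_pf_genes and k >= 6:
            cut = int(rng.integers(3, k - 2))  # both proteoforms >= 3 peptides
            perm = rng.permutation(k)
            labels = {f"{gene}:pf1": [pep_ids[i] for i in sorted(perm[:cut])],
                      f"{gene}:pf2": [pep_ids[i] for i in sorted(perm[cut:])]}
        else:
            labels = {f"{gene}:pf1": pep_ids}
        truth.peptide_proteoform[gene] = {}
        for pf, members in labels.items():
            proteoform_ids.append(pf)
            for p in members:
                truth.peptide_proteoform[gene][p] = pf
                pf_of_peptide[p] = pf

    # drug-shift targets drawn over proteoforms
    n_targets = int(round(len(proteoform_ids) * cfg.target_fraction))
    targets = set(rng.choice(proteoform_ids, size=n_targets, replace=False))

    # condition- and cell-line-specific 4PL parameters per proteoform
    params: Dict[str, Dict[str, FourPLParams]] = {}
    gene_tm: Dict[str, float] = {}
    for pf in proteoform_ids:
        gene = pf.split(":")[0]
        if pf.endswith("pf1"):
            tm0 = float(rng.uniform(*cfg.tm_range))
            gene_tm[gene] = tm0
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            tm0 = gene_tm[gene] + sign * cfg.delta_tm_proteoforms
        base = _draw_params(rng, cfg, tm0)
        params[pf] = {}
        shift = cfg.drug_delta_tm if pf in targets else 0.0
        if pf in targets:
            truth.shifted_proteoforms[pf] = shift
        for cl in cfg.cell_lines:
            cl_off = float(rng.normal(0.0, cfg.tm_cell_line_sd)) if cfg.tm_cell_line_sd else 0.0
            for cond in CONDITIONS:
                tm = base.tm + cl_off + (shift if cond == "drug" else 0.0)
                p = FourPLParams(base.bottom, base.top, tm, base.scale)
                params[pf][f"{cl}|{cond}"] = p
                truth.proteoform_params.setdefault(pf, {})[f"{cl}|{cond}"] = {
                    "bottom": p.bottom, "top": p.top, "tm": p.tm, "scale": p.scale,
                }

    # ambiguous peptides: add a second gene symbol to a random subset
    all_peps = [p for g in genes for p in peptides_of_gene[g]]
    n_amb = int(round(len(all_peps) * cfg.ambiguous_peptide_rate))
    ambiguous = set(rng.choice(all_peps, size=n_amb, replace=False)) if n_amb else set()
    second_gene: Dict[str, str] = {}
    for p in sorted(ambiguous):
        own = p.split("_pep")[0]
        others = [g for g in genes if g != own]
        second_gene[p] = str(rng.choice(others))

    base_abund = {
        p: 10.0 ** rng.normal(cfg.abundance_log10_mean, cfg.abundance_log10_sd)
        for p in all_peps
    }

    sample_keys = [
        SampleKey(cl, cond, rep)
        for cl in cfg.cell_lines
        for cond in CONDITIONS
        for rep in range(1, cfg.replicates + 1)
    ]

    records: List[PeptideQuantRecord] = []
    aa = "ACDEFGHIKLMNPQRSTVWY"
    seqs = {
        p: "".join(rng.choice(list(aa), size=int(rng.integers(8, 16))))
        for p in all_peps
    }
    for key in sample_keys:
        set_id = str(key)
        for gene in genes:
            for p in peptides_of_gene[gene]:
                pf = pf_of_peptide[p]
                curve = four_pl_curve(temps, params[pf][f"{key.cell_line}|{key.condition}"])
                vals = base_abund[p] * curve
                if cfg.noise_sd > 0:
                    vals = vals * np.exp(rng.normal(0.0, cfg.noise_sd, size=len(temps)))
                if cfg.additive_sd > 0:
                    vals = vals + np.abs(rng.normal(0.0, cfg.additive_sd, size=len(temps)))
                symbols = {gene}
                if p in second_gene:
                    symbols.add(second_gene[p])
                records.append(
                    PeptideQuantRecord(
                        peptide_id=p,
                        sequence=seqs[p],
                        gene_symbols=frozenset(symbols),
                        sample_key=key,
                        set_id=set_id,
                        intensities=vals,
                    )
                )
    return records, truth


def simulate_melt_observations(
    params_by_condition: Dict[str, FourPLParams],
    grid: TemperatureGrid,
    n_replicates: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Observed fraction-non-denatured points for one group's melt curves.

    Gaussian measurement noise on the fraction scale; one row per
    (condition, replicate, temperature).  Used by the NPARC and 4PL
    calibration studies.
    """
    rows = []
    temps = grid.array
    for cond, params in params_by_condition.items():
        f = four_pl_curve(temps, params)
        for rep in range(1, n_replicates + 1):
            obs = f + rng.normal(0.0, noise_sd, size=len(temps))
            for T, y in zip(temps, obs):
                rows.append({"condition": cond, "replicate": rep, "T": T, "value": y})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Patient cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortSimConfig:
    """Design of the synthetic patient cohort.

    Defaults mirror the emulated clinical design: 68 independent patients of
    whom 4 are ibrutinib treated/pretreated, a 12-patient biologically
    distinct subgroup, PSM-level rows (4 per group) so the summation stages
    are exercised, treatment effects of 1.5 log2 units on designated groups,
    and iid log-normal PSM noise (sd 0.4 on the log2 scale).
    """

    n_patients: int = 68
    n_treated: int = 4
    n_subgroup: int = 12
    n_genes: int = 150
    fraction_two_group: float = 0.4
    psms_per_group: int = 4
    n_effect_groups: int = 20
    effect_size: float = 1.5
    n_response_groups: int = 2
    response_rho: float = -0.65
    response_in_subgroup_only: bool = True
    psm_noise_sd: float = 0.4
    group_signal_sd: float = 0.6
    n_signal_groups: int = 0
    patients_per_set: int = 10
    abundance_log2_mean: float = 16.0
    abundance_log2_sd: float = 2.0
    # spread between sibling proteoform groups of one gene; zero keeps the
    # randomized-membership null variance-matched to the real grouping
    within_gene_base_sd: float = 0.0
    peptide_ionization_sd: float = 0.5

    def validate(self) -> None:
        if self.n_treated > self.n_patients or self.n_subgroup > self.n_patients:
            raise ValueError("treated/subgroup sizes exceed cohort size")
        total_groups = self._n_groups()
        if self.n_effect_groups + self.n_response_groups + self.n_signal_groups > total_groups:
            raise ValueError("more designated groups than simulated groups")

    def _n_groups(self) -> int:
        n_two = int(round(self.n_genes * self.fraction_two_group))
        return self.n_genes + n_two


def simulate_cohort(
    config: Optional[CohortSimConfig] = None, seed: int = 0
) -> Tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (psm_table, patient_annotations, truth) for a cohort study.

    ``psm_table`` is long form: psm_id, peptide_id, gene, membership
    (the real proteoform-group label), set_id, patient, intensity (raw,
    natural scale).  Group log2 abundance is baseline + treatment effect
    (designated groups x treated patients) + group-level signal for
    designated variable/response groups + iid PSM noise.
    """
    cfg = config or CohortSimConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    patients = [f"P{i:03d}" for i in range(1, cfg.n_patients + 1)]
    treated = sorted(rng.choice(patients, size=cfg.n_treated, replace=False))
    subgroup = sorted(rng.choice(patients, size=cfg.n_subgroup, replace=False))

    genes = [f"CG{i:04d}" for i in range(1, cfg.n_genes + 1)]
    n_two = int(round(cfg.n_genes * cfg.fraction_two_group))
    two_group_genes = set(rng.choice(genes, size=n_two, replace=False))

    groups: List[str] = []
    truth = SyntheticTruth(treated_patients=list(treated), subgroup_patients=list(subgroup))
    for gene in genes:
        n_g = 2 if gene in two_group_genes else 1
        members = {}
        for k in range(1, n_g + 1):
            gid = f"{gene}_{k}"
            groups.append(gid)
            for j in range(1, cfg.psms_per_group + 1):
                members[f"{gid}_pep{j}"] = gid
        truth.peptide_proteoform[gene] = members

    designable = list(rng.permutation(groups))
    effect_groups = designable[: cfg.n_effect_groups]
    response_groups = designable[
        cfg.n_effect_groups : cfg.n_effect_groups + cfg.n_response_groups
    ]
    signal_groups = designable[
        cfg.n_effect_groups
        + cfg.n_response_groups : cfg.n_effect_groups
        + cfg.n_response_groups
        + cfg.n_signal_groups
    ]
    truth.differential_groups = sorted(effect_groups)
    truth.response_groups = sorted(response_groups)

    # latent patient factor driving response-correlated groups
    u = {p: float(rng.normal()) for p in patients}
    active = set(subgroup) if cfg.response_in_subgroup_only else set(patients)

    gene_base = {g: float(rng.normal(cfg.abundance_log2_mean, cfg.abundance_log2_sd)) for g in genes}
    group_base = {
        g: gene_base[g.rsplit("_", 1)[0]]
        + (float(rng.normal(0.0, cfg.within_gene_base_sd)) if cfg.within_gene_base_sd else 0.0)
        for g in groups
    }
    group_signal: Dict[str, Dict[str, float]] = {}
    for g in groups:
        sig = {}
        for p in patients:
            s = 0.0
            if g in effect_groups and p in treated:
                s += cfg.effect_size
            if g in response_groups and p in active:
                s += cfg.group_signal_sd * u[p]
            if g in signal_groups:
                s += float(rng.normal(0.0, cfg.group_signal_sd))
            sig[p] = s
        group_signal[g] = sig

    # response: anti-correlated with the mean response-group signal inside
    # the active patient stratum, pure noise elsewhere
    rho = abs(cfg.response_rho)
    sign = -1.0 if cfg.response_rho < 0 else 1.0
    response = {}
    for p in patients:
        if p in active and response_groups:
            z = sign * rho * u[p] + np.sqrt(max(1 - rho**2, 0.0)) * rng.normal()
        else:
            z = rng.normal()
        response[p] = float(np.clip(0.5 + 0.12 * z, 0.0, 1.0))

    n_sets = int(np.ceil(cfg.n_patients / cfg.patients_per_set))
    set_of_patient = {
        p: f"cset{1 + i // cfg.patients_per_set}" for i, p in enumerate(patients)
    }

    rows = []
    psm_counter = 0
    for gene in genes:
        for pep, gid in truth.peptide_proteoform[gene].items():
            pep_offset = float(rng.normal(0.0, cfg.peptide_ionization_sd))
            eps = rng.normal(0.0, cfg.psm_noise_sd, size=len(patients))
            for p, e in zip(patients, eps):
                log2v = group_base[gid] + pep_offset + group_signal[gid][p] + e
                psm_counter += 1
                rows.append(
                    {
                        "psm_id": f"psm{psm_counter:07d}",
                        "peptide_id": pep,
                        "gene": gene,
                        "membership": gid,
                        "set_id": set_of_patient[p],
                        "patient": p,
                        "intensity": float(2.0**log2v),
                    }
                )
    psm_table = pd.DataFrame(rows)

    annotations = pd.DataFrame(
        {
            "patient": patients,
            "treated": [p in set(treated) for p in patients],
            "subgroup": ["subgroupA" if p in set(subgroup) else "other" for p in patients],
            "response": [response[p] for p in patients],
        }
    )
    return psm_table, annotations, truth
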