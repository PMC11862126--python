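import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proteomelt.cohort import (
    average_replicate_columns,
    log_median_center,
    normalize_psms_by_set,
    randomize_membership,
    spearman_with_ci,
    subgroup_analysis,
    sum_to_grouping,
    variance_f_test,
    wilcoxon_treatment_test,
)
from proteomelt.synthetic import CohortSimConfig, simulate_cohort


@pytest.fixture(scope="module")
def small_cohort():
    cfg = CohortSimConfig(
        n_genes=40, fraction_two_group=0.5, n_effect_groups=5, n_response_groups=1
    )
    psm, annot, truth = simulate_cohort(cfg, seed=2)
    return cfg, psm, annot, truth


class TestSummation:
    def test_single_peptide_group_equals_its_own_value(self):
        psm = pd.DataFrame(
            {
                "psm_id": ["a", "b"],
                "peptide_id": ["pep1", "pep2"],
                "gene": ["G", "G"],
                "membership": ["G_1", "G_2"],
                "set_id": ["s", "s"],
                "patient": ["P1", "P1"],
                "intensity": [5.0, 7.0],
            }
        )
        mat = sum_to_grouping(psm, "proteoform", value_column="intensity")
        assert mat.loc["G_1", "P1"] == 5.0
        assert mat.loc["G_2", "P1"] == 7.0

    def test_gene_total_equals_sum_of_group_totals(self, small_cohort):
        _, psm, _, _ = small_cohort
        genes = sum_to_grouping(psm, "gene", value_column="intensity")
        groups = sum_to_grouping(psm, "proteoform", value_column="intensity")
        group_gene = groups.index.str.rsplit("_", n=1).str[0]
        rollup = groups.groupby(group_gene).sum()
        pd.testing.assert_frame_equal(
            genes.sort_index(), rollup.sort_index(), check_names=False
        )

    def test_randomized_grouping_conserves_gene_totals(self, small_cohort):
        _, psm, _, _ = small_cohort
        pg = {
            pep: (g, m)
            for pep, g, m in psm[["peptide_id", "gene", "membership"]]
            .drop_duplicates()
            .itertuples(index=False)
        }
        null_map = randomize_membership(pg, seed=3)
        real = sum_to_grouping(psm, "proteoform", value_column="intensity")
        null = sum_to_grouping(
            psm, "randomized", membership_map=null_map, value_column="intensity"
        )
        key = real.index.str.rsplit("_", n=1).str[0]
        nkey = null.index.str.rsplit("_", n=1).str[0]
        pd.testing.assert_frame_equal(
            real.groupby(key).sum().sort_index(),
            null.groupby(nkey).sum().sort_index(),
            check_names=False,
        )

    def test_unknown_peptides_in_grouping_rejected(self, small_cohort):
        _, psm, _, _ = small_cohort
        with pytest.raises(ValueError, match="unknown peptides"):
            sum_to_grouping(psm, "randomized", membership_map={}, value_column="intensity")


class TestRandomizedMembership:
    def test_single_group_gene_unchanged(self):
        pg = {"p1": ("G", "G_1"), "p2": ("G", "G_1")}
        assert randomize_membership(pg, seed=0) == {"p1": "G_1", "p2": "G_1"}

    def test_group_size_multiset_preserved(self):
        pg = {f"p{i}": ("G", "G_1" if i < 4 else "G_2") for i in range(10)}
        null = randomize_membership(pg, seed=1)
        from collections import Counter

        assert Counter(null.values()) == Counter(
            {"G_1": 4, "G_2": 6}
        )
        assert set(null) == set(pg)

    def test_same_seed_reproducible(self):
        pg = {f"p{i}": ("G", f"G_{1 + i % 3}") for i in range(12)}
        assert randomize_membership(pg, seed=5) == randomize_membership(pg, seed=5)


class TestCentering:
    def test_per_patient_median_is_zero(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.lognormal(10, 1, (31, 6)))
        centered = log_median_center(mat)
        np.testing.assert_allclose(centered.median(axis=0), 0.0, atol=1e-10)

    def test_centering_is_idempotent(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.lognormal(10, 1, (15, 5)))
        once = log_median_center(mat)
        twice = once.sub(once.median(axis=0), axis=1)
        pd.testing.assert_frame_equal(once, twice)

    def test_replicates_averaged_by_patient(self):
        mat = pd.DataFrame(
            [[1.0, 3.0, 10.0]], columns=["P1_a", "P1_b", "P2"]
        )
        out = average_replicate_columns(mat, {"P1_a": "P1", "P1_b": "P1", "P2": "P2"})
        assert out.loc[0, "P1"] == 2.0
        assert out.loc[0, "P2"] == 10.0


class TestVarianceTest:
    def test_paired_identity_gives_f_one_p_half(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(0, 1, (3, 20)))
        res = variance_f_test(mat, mat.copy(), method="paired")
        assert np.allclose(res["F"], 1.0)
        assert np.allclose(res["p"], 0.5)

    def test_paired_tail_value_for_fourfold_variance(self):
        # n = 61 patients, variance ratio 4: p = P(F(60,60) >= 4) ~ 1.3e-7
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, (1, 61))
        real = pd.DataFrame(2.0 * base)
        null = pd.DataFrame(base)
        res = variance_f_test(real, null, method="paired")
        assert res["F"].iloc[0] == pytest.approx(4.0)
        assert res["p"].iloc[0] == pytest.approx(stats.f.sf(4, 60, 60), rel=1e-9)
        assert stats.f.sf(4, 60, 60) == pytest.approx(1.3e-7, rel=0.05)

    def test_degenerate_null_flagged_conservative(self):
        real = pd.DataFrame(np.random.default_rng(0).normal(0, 1, (1, 10)))
        null = pd.DataFrame(np.zeros((1, 10)))
        res = variance_f_test(real, null, method="paired")
        assert res["degenerate_null"].iloc[0]
        assert res["p"].iloc[0] == 1.0

    def test_pooled_detects_excess_variance_group(self):
        rng = np.random.default_rng(2)
        null = pd.DataFrame(rng.normal(0, 1, (200, 40)))
        real = pd.DataFrame(rng.normal(0, 1, (200, 40)))
        real.iloc[0] = rng.normal(0, 3, 40)  # one genuinely variable group
        res = variance_f_test(real, null).set_index("entity")
        assert res.loc[0, "p"] < 0.001
        assert res["p"].iloc[1:].min() > res.loc[0, "p"]


class TestWilcoxon:
    def test_exact_two_sided_worked_example(self):
        mat = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
            columns=[f"P{i}" for i in range(6)],
        )
        res = wilcoxon_treatment_test(mat, ["P0", "P1", "P2"], ["P3", "P4", "P5"])
        assert res["p"].iloc[0] == pytest.approx(0.1, rel=1e-12)

    def test_enumeration_oracle_for_worked_example(self):
        """All 20 assignments of {1..6} into two arms of 3: the observed
        rank sum is the most extreme, so two-sided p = 2/20."""
        import itertools

        values = [1, 2, 3, 4, 5, 6]
        observed = sum([1, 2, 3])
        sums = [sum(c) for c in itertools.combinations(values, 3)]
        lo = sum(1 for s in sums if s <= observed)
        hi = sum(1 for s in sums if s >= sum(values) - observed + 0)
        p = min(1.0, 2 * min(lo, len(sums) - lo + 1) / len(sums))
        assert lo == 1
        assert p == pytest.approx(0.1)

    def test_shift_increases_significance_monotonically(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 30)
        cols = [f"P{i}" for i in range(30)]
        treated, untreated = cols[:10], cols[10:]
        ps = []
        for shift in (0.0, 1.0, 2.5):
            vals = base.copy()
            vals[:10] += shift
            mat = pd.DataFrame([vals], columns=cols)
            res = wilcoxon_treatment_test(mat, treated, untreated)
            ps.append(res["p"].iloc[0])
        assert ps[0] > ps[1] > ps[2]

    def test_empty_arm_rejected(self):
        mat = pd.DataFrame([[1.0, 2.0]], columns=["P0", "P1"])
        with pytest.raises(ValueError):
            wilcoxon_treatment_test(mat, [], ["P0", "P1"])


class TestSpearman:
    def test_perfect_monotone_pairs(self):
        x = np.arange(10.0)
        up = spearman_with_ci(x, x + 3)
        down = spearman_with_ci(x, -x)
        assert up["rho"] == pytest.approx(1.0)
        assert down["rho"] == pytest.approx(-1.0)

    def test_constant_input_flagged(self):
        res = spearman_with_ci(np.ones(8), np.arange(8.0))
        assert res["degenerate"] and np.isnan(res["rho"])

    def test_fisher_ci_matches_bootstrap_oracle(self):
        # n = 12 pairs with strong negative association, as in a small
        # patient subgroup; Fisher-z CI cross-checked by bootstrap
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 12)
        y = -0.8 * x + rng.normal(0, 0.55, 12)
        res = spearman_with_ci(x, y)
        assert res["rho"] < -0.5
        boots = []
        for _ in range(4000):
            idx = rng.integers(0, 12, 12)
            if len(np.unique(x[idx])) < 3:
                continue
            boots.append(stats.spearmanr(x[idx], y[idx]).statistic)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert res["ci_low"] == pytest.approx(lo, abs=0.2)
        assert res["ci_high"] == pytest.approx(hi, abs=0.2)
        assert res["ci_low"] < res["rho"] < res["ci_high"]

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_with_ci([1, 2, 3], [1, 2, 3])


class TestSubgroupAnalysis:
    def _setup(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        patients = [f"P{i}" for i in range(n)]
        labels = {p: ("subgroupA" if i < 10 else "other") for i, p in enumerate(patients)}
        u = rng.normal(0, 1, n)
        g1 = np.where([labels[p] == "subgroupA" for p in patients], u, rng.normal(0, 1, n))
        g2 = rng.normal(0, 1, n)
        mat = pd.DataFrame([g1, g2], index=["G1_1", "G2_1"], columns=patients)
        response = {
            p: (-0.9 * u[i] + 0.3 * rng.normal() if labels[p] == "subgroupA" else rng.normal())
            for i, p in enumerate(patients)
        }
        return mat, labels, response

    def test_all_stratum_equals_direct_call(self):
        mat, labels, response = self._setup()
        df = subgroup_analysis(mat, labels, response, "subgroupA")
        direct = spearman_with_ci(
            mat.loc["G1_1"].to_numpy(), [response[p] for p in mat.columns]
        )
        row = df[(df["stratum"] == "all") & (df["entity"] == "G1_1")].iloc[0]
        assert row["rho"] == pytest.approx(direct["rho"])

    def test_subgroup_specific_association_detected_only_in_subgroup(self):
        mat, labels, response = self._setup(seed=1)
        df = subgroup_analysis(mat, labels, response, "subgroupA").set_index(
            ["stratum", "entity"]
        )
        assert abs(df.loc[("subgroup", "G1_1"), "rho"]) > 0.6
        assert abs(df.loc[("complement", "G1_1"), "rho"]) < 0.45

    def test_empty_complement_emits_two_strata(self):
        mat, labels, response = self._setup()
        labels = {p: "subgroupA" for p in labels}
        df = subgroup_analysis(mat, labels, response, "subgroupA")
        assert set(df["stratum"]) == {"all", "subgroup"}

    def test_filtering_to_significant_entities(self):
        mat, labels, response = self._setup()
        df = subgroup_analysis(
            mat, labels, response, "subgroupA", significant_entities=["G1_1"]
        )
        assert set(df["entity"]) == {"G1_1"}


class TestNormalization:
    def test_calibrated_column_added_per_set(self, small_cohort):
        _, psm, _, _ = small_cohort
        norm = normalize_psms_by_set(psm)
        assert "calibrated" in norm.columns
        assert norm["calibrated"].notna().all()
        assert len(norm) == len(psm)
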