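"""Diet-stratified Spearman screen, trend classification, cohort checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nutrimir import (
    CohortSpec,
    ScreenConfig,
    classify_trend,
    cohort_checks,
    generate_cohort,
    screen,
    size_factors,
    spearman,
)
from nutrimir.intake import IntakeTable
from nutrimir.normalization import CountMatrix

from _oracles import chi2_2x2_oracle, spearman_oracle, spearman_sum_d2, trend_oracle


class TestSpearman:
    def test_perfect_monotonicity(self):
        x = np.arange(10.0)
        rho, p = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p == 0.0

    def test_small_example_matches_rank_oracle_and_closed_form(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        rho, p = spearman(np.array(x, float), np.array(y, float))
        o_rho, o_p = spearman_oracle(x, y)
        assert rho == pytest.approx(o_rho, abs=1e-12)
        assert p == pytest.approx(o_p, abs=1e-12)
        assert rho == pytest.approx(spearman_sum_d2(x, y), abs=1e-12)

    def test_tied_values_use_midranks(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 4.0]
        y = [3.0, 1.0, 4.0, 4.0, 6.0, 5.0]
        rho, p = spearman(np.array(x), np.array(y))
        o_rho, o_p = spearman_oracle(x, y)
        assert rho == pytest.approx(o_rho, abs=1e-12)
        assert p == pytest.approx(o_p, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_invariance_under_monotone_transforms(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=12)
        y = r.normal(size=12)
        rho, _ = spearman(x, y)
        rho_t, _ = spearman(np.exp(x), y**3 + 5 * y)
        assert rho_t == pytest.approx(rho, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(8), np.arange(8.0))

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="n >= 4"):
            spearman(np.arange(3.0), np.arange(3.0))

    def test_agrees_with_scipy(self, rng):
        for _ in range(10):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            rho, p = spearman(x, y)
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


def _screen_fixture(n_per_group=10, n_mirna=6, n_nc=4, seed=3):
    spec = CohortSpec(n_per_group=n_per_group, n_mirna=n_mirna, n_nc=n_nc, seed=seed)
    cm, meta, intake, _ = generate_cohort(spec)
    return size_factors(cm), meta, intake


class TestScreen:
    def test_enumerates_all_pairs(self):
        cm, meta, intake = _screen_fixture()
        res = screen(cm, intake, meta)
        assert res.n_tested == 6 * 4
        assert len(res.records) + res.n_dropped_constant == res.n_tested

    def test_records_match_per_pair_spearman(self):
        cm, meta, intake = _screen_fixture()
        res = screen(cm, intake, meta)
        rec = res.records.iloc[7]
        for g in ("omnivore", "vegetarian", "vegan"):
            subj = meta.loc[meta["diet_group"] == g, "subject_id"]
            rho, p = spearman_oracle(
                intake.normalized.loc[subj, rec["nc_id"]].tolist(),
                cm.normalized.loc[rec["mirna_id"], subj].tolist(),
            )
            assert rec[f"rho_{g}"] == pytest.approx(rho, abs=1e-10)
            assert rec[f"p_{g}"] == pytest.approx(p, abs=1e-10)
        assert rec["average_rho"] == pytest.approx(
            np.mean([rec[f"rho_{g}"] for g in ("omnivore", "vegetarian", "vegan")])
        )

    def test_sign_clash_breaks_coherence(self):
        cm, meta, intake = _screen_fixture(seed=5)
        res = screen(cm, intake, meta)
        rho_cols = [f"rho_{g}" for g in res.groups]
        signs = np.sign(res.records[rho_cols].to_numpy())
        expected = (signs > 0).all(axis=1) | (signs < 0).all(axis=1)
        assert (res.records["coherent"].to_numpy() == expected).all()

    def test_significance_requires_coherence_and_thresholds(self):
        cm, meta, intake = _screen_fixture(n_per_group=25, seed=8)
        cfg = ScreenConfig(rho_threshold=0.3, min_sig_groups=2)
        res = screen(cm, intake, meta, cfg)
        rec = res.records
        assert (rec.loc[rec["significant"], "coherent"]).all()
        assert (rec.loc[rec["significant"], "n_sig_groups"] >= 2).all()
        assert (rec.loc[rec["significant"], "average_rho"].abs() > 0.3).all()

    def test_subject_order_invariance(self):
        cm, meta, intake = _screen_fixture(seed=13)
        res1 = screen(cm, intake, meta)
        r = np.random.default_rng(0)
        perm = r.permutation(len(meta))
        meta2 = meta.iloc[perm].reset_index(drop=True)
        res2 = screen(cm, intake, meta2)
        m1 = res1.records.set_index(["mirna_id", "nc_id"]).sort_index()
        m2 = res2.records.set_index(["mirna_id", "nc_id"]).sort_index()
        pd.testing.assert_frame_equal(m1, m2, rtol=1e-10)

    def test_small_group_raises(self):
        cm, meta, intake = _screen_fixture(n_per_group=10)
        meta_small = meta[meta["subject_id"] != "S0001"]
        meta_small = pd.concat(
            [meta_small[meta_small["diet_group"] != "vegan"],
             meta_small[meta_small["diet_group"] == "vegan"].head(3)]
        )
        with pytest.raises(ValueError, match="vegan"):
            screen(cm, intake, meta_small)

    def test_constant_mirna_dropped_and_counted(self):
        cm, meta, intake = _screen_fixture()
        counts = cm.counts.copy()
        counts.iloc[0, :] = 7  # constant across all samples
        cm2 = CountMatrix(counts=counts, size_factors=pd.Series(1.0, index=counts.columns))
        res = screen(cm2, intake, meta)
        assert res.n_dropped_constant == intake.normalized.shape[1]
        assert counts.index[0] not in set(res.records["mirna_id"])


class TestTrend:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((0.20, 0.30, 0.45), "increasing"),
            ((-0.20, -0.30, -0.45), "increasing"),  # absolute values
            ((0.50, 0.40, 0.10), "decreasing"),
            ((0.40, 0.40, 0.45), "none"),  # tie breaks strictness
            ((0.40, 0.10, 0.45), "none"),
        ],
    )
    def test_examples(self, values, expected):
        assert classify_trend(values) == expected

    def test_mapping_input_with_group_order(self):
        rec = {"omnivore": 0.1, "vegetarian": -0.2, "vegan": 0.3}
        assert classify_trend(rec, ("omnivore", "vegetarian", "vegan")) == "increasing"
        with pytest.raises(ValueError, match="missing"):
            classify_trend({"omnivore": 0.1}, ("omnivore", "vegan"))

    def test_random_records_match_pairwise_oracle(self, rng):
        for _ in range(200):
            vals = rng.normal(size=3).round(2)
            assert classify_trend(vals) == trend_oracle(vals)


class TestCohortChecks:
    def test_identical_compositions_give_nonsignificant_chi2(self):
        meta = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(60)],
                "diet_group": np.repeat(["a", "b", "c"], 20),
                "sex": ["F", "M"] * 30,
                "age": np.tile(np.linspace(20, 60, 20), 3),
                "bmi": np.tile(np.linspace(19, 30, 20), 3),
            }
        )
        meta["bmi_class"] = "healthy"
        rep = cohort_checks(meta)
        assert rep["sex_chi2"]["p_value"] == pytest.approx(1.0)
        assert rep["age_kruskal"]["p_value"] > 0.9

    def test_bmi_shift_detected_by_wilcoxon(self, rng):
        meta = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(120)],
                "diet_group": np.repeat(["omnivore", "vegetarian", "vegan"], 40),
                "sex": rng.choice(["F", "M"], 120),
                "age": rng.normal(45, 10, 120),
                "bmi": rng.normal(23, 3, 120),
            }
        )
        meta.loc[meta["diet_group"] == "omnivore", "bmi"] += 5.0
        meta["bmi_class"] = "healthy"
        rep = cohort_checks(meta)
        assert rep["bmi_wilcoxon_pairwise"]["omnivore_vs_vegan"]["p_value"] < 0.05
        assert rep["bmi_wilcoxon_pairwise"]["omnivore_vs_vegetarian"]["p_value"] < 0.05

    def test_chi2_statistic_matches_closed_form(self):
        meta = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(60)],
                "diet_group": ["a"] * 30 + ["b"] * 30,
                "sex": ["F"] * 10 + ["M"] * 20 + ["F"] * 20 + ["M"] * 10,
                "age": list(range(60)),
                "bmi": [22.0 + (i % 7) for i in range(60)],
            }
        )
        meta["bmi_class"] = "healthy"
        rep = cohort_checks(meta)
        assert rep["sex_chi2"]["statistic"] == pytest.approx(
            chi2_2x2_oracle(10, 20, 20, 10), abs=1e-10
        )
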