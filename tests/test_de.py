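"""Median-split NB-LRT differential expression and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nutrimir import bh_adjust, de_analysis, median_split, nb_lrt
from nutrimir.intake import IntakeTable

from _oracles import bh_oracle, median_split_oracle


def _meta(n=120, rng=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "diet_group": np.repeat(["omnivore", "vegetarian", "vegan"], n // 3),
            "age": rng.normal(45, 10, n),
            "sex": rng.choice(["F", "M"], n),
            "bmi": rng.normal(23, 3, n),
        }
    )


def _labels(meta, rng):
    lab = np.where(np.arange(len(meta)) % 2 == 0, "high", "low")
    return pd.Series(rng.permutation(lab), index=meta["subject_id"], name="intake_group")


def _nb(rng, mu, alpha=0.2, size=None):
    return rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * np.asarray(mu)), size=size)


class TestMedianSplit:
    def test_clean_even_split(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        labels = median_split(s)
        assert labels.tolist() == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        s = pd.Series([1.0, 2.0, 2.0, 5.0], index=list("abcd"))
        labels = median_split(s)
        assert labels.tolist() == ["low", "low", "low", "high"]

    def test_random_vector_matches_sort_oracle(self, rng):
        vals = rng.normal(size=31)
        s = pd.Series(vals, index=[f"s{i}" for i in range(31)])
        assert median_split(s).tolist() == median_split_oracle(vals)

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            median_split(pd.Series([2.0] * 6, index=list("abcdef")))

    def test_intake_table_input_requires_nc_id(self):
        it = IntakeTable(
            raw=pd.DataFrame({"sodium": [1.0, 2, 3, 4]}, index=list("abcd")),
            energy_kcal_day=pd.Series([2000.0] * 4, index=list("abcd")),
            normalized=pd.DataFrame({"sodium": [1.0, 2, 3, 4]}, index=list("abcd")),
        )
        with pytest.raises(ValueError, match="nc_id"):
            median_split(it)
        assert median_split(it, "sodium").tolist() == ["low", "low", "high", "high"]


class TestNbLrt:
    def test_null_by_construction(self, rng):
        meta = _meta()
        labels = _labels(meta, rng)
        counts = pd.Series(np.full(120, 300), index=meta["subject_id"])
        sf = pd.Series(1.0, index=meta["subject_id"])
        res = nb_lrt(counts, meta, labels, sf)
        assert abs(res.log2fc) < 0.05
        assert res.p_value > 0.5

    def test_label_swap_negates_log2fc_and_preserves_p(self, rng):
        meta = _meta()
        labels = _labels(meta, rng)
        counts = pd.Series(
            _nb(rng, np.where(labels == "high", 400.0, 200.0)), index=meta["subject_id"]
        )
        sf = pd.Series(rng.uniform(0.8, 1.2, 120), index=meta["subject_id"])
        res1 = nb_lrt(counts, meta, labels, sf)
        swapped = labels.map({"high": "low", "low": "high"})
        res2 = nb_lrt(counts, meta, swapped, sf)
        assert res2.log2fc == pytest.approx(-res1.log2fc, abs=1e-6)
        assert res2.p_value == pytest.approx(res1.p_value, abs=1e-8)

    def test_statistic_invariant_to_global_size_factor_rescaling(self, rng):
        meta = _meta()
        labels = _labels(meta, rng)
        counts = pd.Series(_nb(rng, 300.0, size=120), index=meta["subject_id"])
        sf = pd.Series(rng.uniform(0.8, 1.2, 120), index=meta["subject_id"])
        res1 = nb_lrt(counts, meta, labels, sf)
        res2 = nb_lrt(counts, meta, labels, sf * 7.5)
        assert res2.p_value == pytest.approx(res1.p_value, abs=1e-6)
        assert res2.log2fc == pytest.approx(res1.log2fc, abs=1e-6)

    def test_two_fold_shift_recovered(self, rng):
        meta = _meta()
        labels = _labels(meta, rng)
        sf = pd.Series(1.0, index=meta["subject_id"])
        fcs = []
        for _ in range(25):
            counts = pd.Series(
                _nb(rng, np.where(labels == "high", 400.0, 200.0)), index=meta["subject_id"]
            )
            fcs.append(nb_lrt(counts, meta, labels, sf).log2fc)
        assert np.mean(fcs) == pytest.approx(1.0, abs=0.15)

    def test_poisson_limit_agreement(self, rng):
        """At tiny dispersion and large counts the NB LRT p matches a
        Poisson LRT p within 10% relative error."""
        import statsmodels.api as sm

        meta = _meta(60)
        labels = _labels(meta, rng)
        mu = np.where(labels == "high", 1100.0, 1000.0)
        counts = pd.Series(rng.poisson(mu), index=meta["subject_id"])
        sf = pd.Series(1.0, index=meta["subject_id"])
        res = nb_lrt(counts, meta, labels, sf)

        from nutrimir.de import _design

        X_full, X_red, _ = _design(meta, labels, sorted(meta["diet_group"].unique()))
        y = counts.to_numpy(dtype=float)
        llf_full = sm.GLM(y, X_full, family=sm.families.Poisson()).fit().llf
        llf_red = sm.GLM(y, X_red, family=sm.families.Poisson()).fit().llf
        p_pois = stats.chi2.sf(2 * (llf_full - llf_red), df=1)
        assert res.p_value == pytest.approx(p_pois, rel=0.1)

    def test_non_integer_counts_rejected(self, rng):
        meta = _meta(12)
        labels = _labels(meta, rng)
        counts = pd.Series(np.linspace(0.5, 5.5, 12), index=meta["subject_id"])
        sf = pd.Series(1.0, index=meta["subject_id"])
        with pytest.raises(ValueError, match="integers"):
            nb_lrt(counts, meta, labels, sf)


class TestBhAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.04]).tolist() == [0.04]

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_oracle_and_monotone(self, rng):
        p = rng.uniform(size=37)
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, bh_oracle(p), rtol=1e-12)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestDeAnalysis:
    def test_planted_pair_detected_with_coherent_direction(self, planted_cohort):
        """A positively planted NC–miRNA pair shows positive log2FC in
        high- vs low-intake subjects."""
        _, cm, meta, intake, truth = planted_cohort
        table = de_analysis(cm, intake, meta, "calcium", mirna_ids=["miR-0005", "miR-0001"])
        row = table.set_index("mirna_id").loc["miR-0005"]
        assert row["significant"]
        assert row["log2fc"] > 0
        assert row["expressed"]
        # adjusted p computed across tested miRNAs
        assert row["adjusted_p"] >= row["p_value"]

    def test_negative_planting_gives_negative_log2fc(self, planted_cohort):
        _, cm, meta, intake, _ = planted_cohort
        table = de_analysis(cm, intake, meta, "iron", mirna_ids=["miR-0012"])
        assert table.iloc[0]["log2fc"] < 0

    def test_significance_requires_expression(self, planted_cohort):
        _, cm, meta, intake, _ = planted_cohort
        table = de_analysis(cm, intake, meta, "calcium", mirna_ids=["miR-0005"], threshold=1e9)
        assert not table.iloc[0]["expressed"]
        assert not table.iloc[0]["significant"]
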