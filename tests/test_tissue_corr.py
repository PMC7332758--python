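"""Extreme-beta filter, covariate adjustment and cross-tissue correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylqc.tissue_corr import (
    adjust_mvalues,
    extreme_beta_filter,
    stratified_comparison,
    within_cpg_correlation,
    within_individual_correlation,
)


def _beta(values, probes=None):
    arr = np.atleast_2d(values)
    probes = probes or [f"cg{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=probes,
                        columns=[f"s{j}" for j in range(arr.shape[1])])


class TestExtremeBetaFilter:
    def test_all_high_in_both_tissues_removed(self):
        b = _beta([[0.95] * 4])
        c = _beta([[0.96] * 4])
        assert len(extreme_beta_filter(b, c)) == 0

    def test_one_nonextreme_value_retains(self):
        b = _beta([[0.95] * 4])
        c = _beta([[0.95, 0.95, 0.5, 0.95]])
        assert list(extreme_beta_filter(b, c)) == ["cg0"]

    def test_all_low_in_both_tissues_removed(self):
        b = _beta([[0.05] * 4])
        c = _beta([[0.02] * 4])
        assert len(extreme_beta_filter(b, c)) == 0

    def test_idempotent_and_sample_order_invariant(self):
        rng = np.random.default_rng(0)
        b = _beta(rng.uniform(0, 1, (50, 6)))
        c = _beta(rng.uniform(0, 1, (50, 6)))
        keep = extreme_beta_filter(b, c)
        again = extreme_beta_filter(b.loc[keep], c.loc[keep])
        assert list(again) == list(keep)
        shuffled = extreme_beta_filter(b[b.columns[::-1]], c)
        assert list(shuffled) == list(keep)


class TestAdjustMvalues:
    def test_linear_in_age_gives_zero_residuals(self):
        age = np.array([40.0, 50.0, 60.0, 70.0])
        M = pd.DataFrame(np.outer([1.0, 2.0, -1.0], age),
                         columns=[f"s{i}" for i in range(4)])
        adj = adjust_mvalues(M, pd.DataFrame({"age": age}))
        assert np.linalg.norm(adj.to_numpy()) < 1e-8

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(1)
        n = 30
        cov = pd.DataFrame({"age": rng.uniform(30, 70, n),
                            "sex": rng.choice(["F", "M"], n)})
        svs = pd.DataFrame(rng.normal(0, 1, (n, 2)))
        M = pd.DataFrame(rng.normal(0, 1, (100, n)),
                         columns=[f"s{i}" for i in range(n)])
        adj = adjust_mvalues(M, cov, svs)
        sex_code = pd.factorize(cov["sex"])[0].astype(float)
        design = np.column_stack([np.ones(n), cov["age"], sex_code,
                                  svs.to_numpy()])
        assert np.max(np.abs(adj.to_numpy() @ design)) < 1e-8

    def test_rank_deficiency_rejected(self):
        n = 10
        cov = pd.DataFrame({"a": np.arange(n, dtype=float),
                            "b": 2.0 * np.arange(n, dtype=float)})
        M = pd.DataFrame(np.random.default_rng(0).normal(0, 1, (5, n)),
                         columns=[f"s{i}" for i in range(n)])
        with pytest.raises(ValueError, match="rank"):
            adjust_mvalues(M, cov)


def _pairs(n):
    return pd.DataFrame({"subject_id": [f"p{i}" for i in range(n)],
                         "blood_sample": [f"s{i}" for i in range(n)],
                         "csf_sample": [f"s{i}" for i in range(n)]})


class TestWithinCpgCorrelation:
    def test_identical_profiles_give_unit_r(self):
        M = _beta(np.random.default_rng(0).normal(0, 1, (20, 5)))
        r = within_cpg_correlation(M, M, _pairs(5))
        assert np.allclose(r, 1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        M = _beta(rng.normal(0, 1, (20, 6)))
        r = within_cpg_correlation(M, 2.0 * M + 3.0, _pairs(6))
        assert np.allclose(r - 1.0, 0.0, atol=1e-12)

    def test_hand_computed_pearson(self):
        b = _beta([[1.0, 2.0, 3.0, 4.0]])
        c = _beta([[2.0, 1.0, 4.0, 3.0]])
        r = within_cpg_correlation(b, c, _pairs(4))
        assert r["cg0"] == pytest.approx(0.6)

    def test_zero_variance_gives_na(self):
        b = _beta([[1.0, 1.0, 1.0, 1.0]])
        c = _beta([[2.0, 1.0, 4.0, 3.0]])
        r = within_cpg_correlation(b, c, _pairs(4))
        assert np.isnan(r["cg0"])

    def test_requires_three_pairs(self):
        M = _beta([[1.0, 2.0]])
        with pytest.raises(ValueError, match="pairs"):
            within_cpg_correlation(M, M, _pairs(2))


class TestWithinIndividualCorrelation:
    def test_identical_profiles_give_unit_r(self):
        M = _beta(np.random.default_rng(2).normal(0, 1, (50, 4)))
        r = within_individual_correlation(M, M, _pairs(4))
        assert np.allclose(r, 1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(3)
        b = _beta(rng.normal(0, 1, (10_000, 4)))
        c = _beta(rng.normal(0, 1, (10_000, 4)))
        r = within_individual_correlation(b, c, _pairs(4))
        assert np.all(np.abs(r) < 0.05)

    def test_shared_architecture_dissociation(self):
        """Shared probe-level means across tissues: within-individual r is
        high while within-CpG r stays low."""
        rng = np.random.default_rng(4)
        n_probes, n_subj = 2000, 10
        mu = rng.normal(0, 3, n_probes)           # methylome architecture
        b = _beta(mu[:, None] + rng.normal(0, 0.7, (n_probes, n_subj)))
        c = _beta(mu[:, None] + rng.normal(0, 0.7, (n_probes, n_subj)))
        r_ind = within_individual_correlation(b, c, _pairs(n_subj))
        r_cpg = within_cpg_correlation(b, c, _pairs(n_subj))
        assert r_ind.mean() > 0.9
        assert abs(r_cpg.mean()) < 0.1

    def test_requires_ten_cpgs(self):
        M = _beta(np.random.default_rng(5).normal(0, 1, (5, 4)))
        with pytest.raises(ValueError, match="CpGs"):
            within_individual_correlation(M, M, _pairs(4))


class TestStratifiedComparison:
    def _annotation(self, regions):
        probes = [f"cg{i}" for i in range(len(regions))]
        return pd.DataFrame({"probe_id": probes, "region": regions,
                             "orientation": "body"}, index=probes)

    def test_null_omnibus_p_roughly_uniform(self):
        rng = np.random.default_rng(6)
        pvals = []
        regions = ["island", "shore", "shelf", "open_sea"] * 100
        ann = self._annotation(regions)
        for _ in range(60):
            r = pd.Series(rng.normal(0.2, 0.1, 400), index=ann.index)
            res = stratified_comparison(r, ann, "region")
            pvals.append(res.omnibus_p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_separated_strata_detected_and_ordered(self):
        rng = np.random.default_rng(7)
        regions = ["island"] * 500 + ["open_sea"] * 500
        ann = self._annotation(regions)
        r = pd.Series(np.concatenate([rng.normal(0.6, 0.2, 500),
                                      rng.normal(0.1, 0.2, 500)]),
                      index=ann.index)
        res = stratified_comparison(r, ann, "region")
        assert res.omnibus_p < 0.001
        assert res.per_stratum.loc["island", "mean"] > \
            res.per_stratum.loc["open_sea", "mean"]
        assert (res.pairwise["p_bonferroni"] < 0.001).all()

    def test_single_stratum_rejected(self):
        ann = self._annotation(["island"] * 50)
        r = pd.Series(np.random.default_rng(8).normal(0, 1, 50), index=ann.index)
        with pytest.raises(ValueError, match="strata"):
            stratified_comparison(r, ann, "region")

    def test_small_stratum_excluded_with_warning(self):
        ann = self._annotation(["island"] * 50 + ["shore"] * 3 + ["shelf"] * 50)
        r = pd.Series(np.random.default_rng(9).normal(0, 1, 103), index=ann.index)
        with pytest.warns(UserWarning, match="excluded"):
            res = stratified_comparison(r, ann, "region")
        assert "shore" not in res.per_stratum.index


class TestRegionRecoveryOnSynthetic:
    def test_region_correlation_ordering_recovered(self, pipeline_run):
        """Planted coupling rho: island > shore > shelf > open sea must
        reappear in the mean within-CpG r per region."""
        report, bundle = pipeline_run
        day1 = report["tissue_correlation"]["day1"]
        means = day1["region_mean_r"]
        assert means["island"] > means["shore"] > means["shelf"] > means["open_sea"]
        assert day1["region_omnibus_p"] < 0.001

    def test_within_individual_versus_within_cpg_dissociation(self, pipeline_run):
        report, _ = pipeline_run
        day1 = report["tissue_correlation"]["day1"]
        assert day1["mean_within_individual_r"] > 0.5
        assert day1["mean_r"] < 0.5
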