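"""Day subsets, trait permutation, SVA recovery/protection, EWAS calibration
and the genomic inflation factor."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylqc import sva_ewas
from methylqc.sva_ewas import (
    compute_surrogate_variables,
    csf_day_subsets,
    estimate_num_sv,
    genomic_inflation,
    permute_trait,
    run_ewas,
)


def _sheet(day_map):
    """CSF sheet: subject -> list of collection days."""
    rows = []
    i = 0
    for subj, days in day_map.items():
        for d in days:
            rows.append(dict(sample_id=f"s{i}", subject_id=subj, tissue="csf",
                             collection_day=d, is_control_sample=False,
                             replicate_group=None))
            i += 1
    return pd.DataFrame(rows)


class TestDaySubsets:
    def test_exact_days_fill_all_targets(self):
        sheet = _sheet({"a": [1, 4, 7, 10, 13]})
        subsets = csf_day_subsets(sheet)
        assert all(len(v) == 1 for v in subsets.values())

    def test_plus_minus_one_substitution(self):
        sheet = _sheet({"a": [2, 5]})
        subsets = csf_day_subsets(sheet)
        days = sheet.set_index("sample_id")["collection_day"]
        assert [days[s] for s in subsets[1]] == [2]
        assert [days[s] for s in subsets[4]] == [5]
        assert subsets[7] == subsets[10] == subsets[13] == []

    def test_minus_day_preferred_over_plus(self):
        sheet = _sheet({"a": [3, 5]})
        subsets = csf_day_subsets(sheet)
        days = sheet.set_index("sample_id")["collection_day"]
        assert [days[s] for s in subsets[4]] == [3]

    def test_no_sample_assigned_twice(self, sim_default):
        ds, _, _ = sim_default
        subsets = csf_day_subsets(ds.samples)
        all_ids = [s for v in subsets.values() for s in v]
        assert len(all_ids) == len(set(all_ids))

    def test_at_most_one_sample_per_subject_per_target(self, sim_default):
        ds, _, _ = sim_default
        sheet = ds.samples.set_index("sample_id")
        for ids in csf_day_subsets(ds.samples).values():
            subjects = sheet.loc[ids, "subject_id"]
            assert not subjects.duplicated().any()


class TestPermuteTrait:
    def test_class_counts_preserved(self):
        trait = np.array([0, 0, 0, 1, 1, 1, 1])
        perm = permute_trait(trait, seed=3)
        assert sorted(perm) == sorted(trait)

    def test_seed_reproducible(self):
        trait = np.array([0, 1] * 10)
        assert np.array_equal(permute_trait(trait, 5), permute_trait(trait, 5))

    def test_positionwise_frequency_matches_prevalence(self):
        trait = np.array([1] * 6 + [0] * 14)
        hits = np.zeros(len(trait))
        n_seeds = 1000
        for s in range(n_seeds):
            hits += permute_trait(trait, seed=s)
        prev = trait.mean()
        sd = np.sqrt(prev * (1 - prev) / n_seeds)
        assert np.all(np.abs(hits / n_seeds - prev) < 3 * sd + 1e-12)

    def test_degenerate_trait_rejected(self):
        with pytest.raises(ValueError):
            permute_trait(np.array([1, 0, 0, 0]), seed=0)


class TestEstimateNumSv:
    def test_pure_noise_gives_zero(self):
        hits = 0
        for s in range(5):
            rng = np.random.default_rng(s)
            M = pd.DataFrame(rng.normal(0, 1, (300, 40)))
            hits += (estimate_num_sv(M, seed=s) == 0)
        assert hits >= 4    # parallel-analysis null calibration

    def test_planted_factor_detected(self):
        rng = np.random.default_rng(0)
        f = rng.normal(0, 1, 40)
        L = rng.normal(0, 5, 300)
        M = pd.DataFrame(np.outer(L, f) + rng.normal(0, 1, (300, 40)))
        assert estimate_num_sv(M, seed=0) >= 1

    def test_covariate_signal_only_gives_zero(self):
        rng = np.random.default_rng(1)
        age = rng.uniform(30, 70, 40)
        M = pd.DataFrame(np.outer(rng.normal(0, 2, 300), age)
                         + rng.normal(0, 1, (300, 40)))
        cov = pd.DataFrame({"age": age})
        assert estimate_num_sv(M, cov, seed=1) == 0


class TestSurrogateVariables:
    def _planted(self, seed, confounded):
        rng = np.random.default_rng(seed)
        n, p = 80, 800
        trait = (np.arange(n) < n // 2).astype(float)
        rng.shuffle(trait)
        f = (trait - trait.mean()) if confounded else rng.normal(0, 1, n)
        L = rng.normal(0, 1, p) * (rng.random(p) < 0.4)
        M = pd.DataFrame(np.outer(L, f) + rng.normal(0, 1, (p, n)),
                         columns=[f"s{i}" for i in range(n)])
        return M, trait, f

    def test_orthogonal_factor_recovered(self):
        M, trait, f = self._planted(0, confounded=False)
        svs = compute_surrogate_variables(M, trait, 1)
        assert abs(np.corrcoef(svs.values.iloc[:, 0], f)[0, 1]) > 0.9

    def test_trait_confounded_factor_protected(self):
        for seed in range(3):
            M, trait, f = self._planted(seed, confounded=True)
            svs = compute_surrogate_variables(M, trait, 1)
            assert abs(np.corrcoef(svs.values.iloc[:, 0], f)[0, 1]) < 0.3

    def test_columns_orthonormal(self):
        M, trait, _ = self._planted(2, confounded=False)
        svs = compute_surrogate_variables(M, trait, 3)
        V = svs.values.to_numpy()
        assert np.allclose(V.T @ V, np.eye(3), atol=1e-8)

    def test_excessive_n_sv_rejected(self):
        M, trait, _ = self._planted(3, confounded=False)
        with pytest.raises(ValueError, match="n_sv"):
            compute_surrogate_variables(M, trait, M.shape[1])

    def test_noise_with_one_sv_keeps_ewas_calibrated(self):
        rng = np.random.default_rng(4)
        n = 60
        M = pd.DataFrame(rng.normal(0, 1, (1500, n)),
                         columns=[f"s{i}" for i in range(n)])
        trait = permute_trait(np.array([0, 1] * (n // 2)), seed=4)
        svs = compute_surrogate_variables(M, trait, 1)
        res = run_ewas(M, trait, svs=svs)
        assert 0.9 <= res.inflation <= 1.1


class TestRunEwas:
    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(5)
        n = 50
        M = pd.DataFrame(rng.normal(0, 1, (2000, n)))
        trait = np.array([0, 1] * (n // 2))
        res = run_ewas(M, trait)
        ks = stats.kstest(res.pvalues, "uniform")
        assert ks.pvalue > 0.01

    def test_planted_effects_rank_first(self):
        rng = np.random.default_rng(6)
        n, p = 100, 1000
        trait = np.array([0, 1] * (n // 2))
        M = rng.normal(0, 1, (p, n))
        M[:10, :] += 2.0 * trait[None, :]      # delta M = 2 at 10 probes
        res = run_ewas(pd.DataFrame(M), trait)
        top10 = set(res.pvalues.nsmallest(10).index)
        assert top10 == set(range(10))

    def test_duplicate_covariate_rejected(self):
        rng = np.random.default_rng(7)
        n = 30
        M = pd.DataFrame(rng.normal(0, 1, (100, n)))
        trait = np.array([0, 1] * (n // 2))
        cov = pd.DataFrame({"age": np.arange(n, dtype=float),
                            "age2": np.arange(n, dtype=float)})
        with pytest.raises(ValueError, match="rank"):
            run_ewas(M, trait, cov)

    def test_qq_coordinates_shape(self):
        rng = np.random.default_rng(8)
        M = pd.DataFrame(rng.normal(0, 1, (200, 20)))
        res = run_ewas(M, np.array([0, 1] * 10))
        qq = res.qq_coordinates()
        assert list(qq.columns) == ["expected", "observed"]
        assert len(qq) == 200


class TestGenomicInflation:
    def test_median_p_gives_unity(self):
        assert genomic_inflation(np.full(100, 0.5)) == pytest.approx(1.0)

    def test_quarter_p_quantile_arithmetic(self):
        expected = stats.chi2.isf(0.25, 1) / stats.chi2.ppf(0.5, 1)
        assert genomic_inflation(np.full(50, 0.25)) == pytest.approx(expected)
        assert expected == pytest.approx(2.9088, abs=1e-4)

    def test_uniform_order_statistics_approach_unity(self):
        n = 10_000
        p = np.arange(1, n + 1) / (n + 1)
        assert genomic_inflation(p) == pytest.approx(1.0, abs=0.02)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation([])
        with pytest.raises(ValueError):
            genomic_inflation([0.0, 0.5])
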