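"""Background/dye corrections, functional normalization, replicate concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from methylqc import normalize
from methylqc.data_model import m_from_beta
from methylqc.normalize import (
    _normexp_signal,
    background_correct,
    control_summaries,
    dye_bias_correct,
    functional_normalize,
    replicate_concordance_test,
)

from conftest import make_tiny_dataset


class TestNormexp:
    def test_asymptote_far_above_background(self):
        x = np.array([5000.0])
        out = _normexp_signal(x, mu=200.0, sigma=30.0, alpha=2000.0)
        assert out[0] == pytest.approx(5000.0 - 200.0, rel=0.01)

    def test_positivity_at_zero_observation(self):
        out = _normexp_signal(np.array([0.0]), mu=200.0, sigma=30.0, alpha=500.0)
        assert out[0] > 0

    def test_matches_quadrature_oracle(self):
        mu, sigma, alpha, x = 100.0, 10.0, 500.0, 150.0
        num = integrate.quad(
            lambda s: s * np.exp(-s / alpha) * stats.norm.pdf(x - s - mu, 0, sigma),
            0, 2000, limit=200)[0]
        den = integrate.quad(
            lambda s: np.exp(-s / alpha) * stats.norm.pdf(x - s - mu, 0, sigma),
            0, 2000, limit=200)[0]
        out = _normexp_signal(np.array([x]), mu, sigma, alpha)
        assert out[0] == pytest.approx(num / den, abs=1e-4)

    def test_dataset_correction_positive_and_idempotent(self):
        ds = make_tiny_dataset(n_probes=40, n_samples=6)
        out = background_correct(ds)
        assert (out.meth.to_numpy() > 0).all()
        again = background_correct(out)
        assert np.allclose(out.meth.to_numpy(), again.meth.to_numpy(), atol=1e-6)


class TestDyeBias:
    def _imbalanced(self, factors):
        ds = make_tiny_dataset(n_probes=40, n_samples=len(factors))
        ids = ds.sample_ids
        red = ds.controls.channel == "red"
        ds.controls.loc[red, ids] = ds.controls.loc[red, ids].to_numpy() * factors
        ds.unmeth.iloc[:, :] = ds.unmeth.to_numpy() * np.asarray(factors)[None, :]
        return ds

    def test_channel_means_equal_after_correction(self):
        ds = self._imbalanced([2.0, 2.0, 2.0, 2.0])
        out = dye_bias_correct(ds)
        g = out.control_intensities("norm_grn", "green").mean(axis=0)
        r = out.control_intensities("norm_red", "red").mean(axis=0)
        assert np.allclose(g.to_numpy(), r.to_numpy(), atol=1e-9)

    def test_balanced_channels_identity(self):
        ds = make_tiny_dataset(n_probes=40, n_samples=4)
        ids = ds.sample_ids
        # make the two norm control groups identical per sample
        grn = ds.controls.control_type == "norm_grn"
        red = ds.controls.control_type == "norm_red"
        ds.controls.loc[red, ids] = ds.controls.loc[grn, ids].to_numpy()
        out = dye_bias_correct(ds)
        assert np.allclose(out.meth.to_numpy(), ds.meth.to_numpy(), atol=1e-9)

    def test_random_imbalance_ratio_one_per_sample(self):
        rng = np.random.default_rng(2)
        ds = self._imbalanced(list(rng.uniform(0.5, 2.0, 6)))
        out = dye_bias_correct(ds)
        g = out.control_intensities("norm_grn", "green").mean(axis=0)
        r = out.control_intensities("norm_red", "red").mean(axis=0)
        assert np.allclose((g / r).to_numpy(), 1.0, atol=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        ds = self._imbalanced(list(rng.uniform(0.5, 2.0, 5)))
        once = dye_bias_correct(ds)
        twice = dye_bias_correct(once)
        assert np.allclose(once.meth.to_numpy(), twice.meth.to_numpy(), atol=1e-6)


class TestFunctionalNormalize:
    def test_k0_is_plain_quantile_normalization(self):
        ds = make_tiny_dataset(n_probes=200, n_samples=6, seed=5)
        # with anchors at every order statistic the QN mapping is exact
        out, _ = functional_normalize(ds, k=0, n_quantiles=500)
        q = np.quantile(out.meth.to_numpy(), np.linspace(0.05, 0.95, 19), axis=0)
        assert np.max(q.std(axis=1)) < 1e-6

    def test_identical_samples_fixed_point(self):
        ds = make_tiny_dataset(n_probes=150, n_samples=5, seed=6)
        base = ds.meth.iloc[:, 0].to_numpy().copy()
        for j in range(ds.meth.shape[1]):
            ds.meth.iloc[:, j] = base
            ds.unmeth.iloc[:, j] = base[::-1]
        out, _ = functional_normalize(ds, k=2, n_quantiles=80)
        assert np.allclose(out.meth.to_numpy(), ds.meth.to_numpy(), atol=1e-6)

    def test_control_correlated_distortion_removed(self):
        """Samples identical up to a scale distortion tracked by the
        controls: post-normalization quantile spread shrinks by > 90%."""
        rng = np.random.default_rng(7)
        n_probes, n_samples = 500, 10
        ds = make_tiny_dataset(n_probes=n_probes, n_samples=n_samples, seed=8)
        base = np.sort(rng.uniform(500, 6000, n_probes))
        scale = np.exp(rng.normal(0, 0.15, n_samples))
        for j in range(n_samples):
            ds.meth.iloc[:, j] = base * scale[j]
            ds.unmeth.iloc[:, j] = base[::-1] * scale[j]
        ids = ds.sample_ids
        # controls carry the distortion exactly (constant baseline x scale)
        baseline = ds.controls[ids].mean(axis=1).to_numpy()
        ds.controls.loc[:, ids] = baseline[:, None] * scale[None, :]
        levels = np.linspace(0.05, 0.95, 19)
        sd_before = np.quantile(ds.meth.to_numpy(), levels, axis=0).std(axis=1)
        out, _ = functional_normalize(ds, k=2, n_quantiles=500)
        sd_after = np.quantile(out.meth.to_numpy(), levels, axis=0).std(axis=1)
        assert sd_after.mean() < 0.1 * sd_before.mean()

    def test_rank_order_preserved_within_stratum(self):
        ds = make_tiny_dataset(n_probes=300, n_samples=6, seed=9)
        out, _ = functional_normalize(ds, k=2, n_quantiles=100)
        for j in range(6):
            before = ds.meth.iloc[:, j].rank(method="first")
            after = out.meth.iloc[:, j].rank(method="first")
            assert stats.spearmanr(before, after).statistic > 0.999

    def test_k_too_large_rejected(self):
        ds = make_tiny_dataset(n_samples=4)
        with pytest.raises(ValueError, match="k"):
            functional_normalize(ds, k=4)

    def test_batch_effects_reduce_replicate_discordance(self, sim_csf):
        """Planted chip/row/dye artifacts: replicate median-M squared
        differences strictly decrease in the mean after normalization."""
        from methylqc import sample_qc
        ds, truth, ann = sim_csf
        rep = sample_qc.flag_low_quality_samples(ds, annotation=ann)
        ds = ds.subset_samples(rep.passed)
        M0 = m_from_beta(ds.beta())
        d = background_correct(ds, ann)
        d = dye_bias_correct(d, ann)
        d, mv = functional_normalize(d, ann, k=2)
        groups = normalize.replicate_groups_from_sheet(ds.samples)
        res = replicate_concordance_test(M0, mv.values, groups)
        assert res.pairs["d_after"].mean() < res.pairs["d_before"].mean()


class TestReplicateConcordance:
    def _m(self, medians, probes=50):
        cols = {f"s{i}": np.full(probes, m) for i, m in enumerate(medians)}
        return pd.DataFrame(cols)

    def test_no_change_gives_undefined_test(self):
        M = self._m([1.0, 1.2, 0.4, 0.5])
        groups = {"a": ["s0", "s1"], "b": ["s2", "s3"]}
        res = replicate_concordance_test(M, M, groups)
        assert res.p_value is None and res.reason is not None

    def test_hand_computed_paired_t(self):
        # d_before = (4, 9, 16, 25), d_after = (1, 1, 4, 4); df = 3
        M_before = self._m([0, 2, 0, 3, 0, 4, 0, 5])
        M_after = self._m([0, 1, 0, 1, 0, 2, 0, 2])
        groups = {f"g{i}": [f"s{2*i}", f"s{2*i+1}"] for i in range(4)}
        res = replicate_concordance_test(M_before, M_after, groups)
        assert res.pairs["d_before"].tolist() == [4.0, 9.0, 16.0, 25.0]
        assert res.pairs["d_after"].tolist() == [1.0, 1.0, 4.0, 4.0]
        assert res.t_statistic == pytest.approx(-2.888741522913896, abs=1e-9)
        assert res.p_value == pytest.approx(0.031538834154785804, abs=1e-9)

    def test_perfect_equalization_detected(self):
        M_before = self._m([0, 2.0, 0, 2.2, 0, 1.8, 0, 2.1])
        M_after = self._m([0, 0, 0, 0, 0, 0, 0, 0])
        groups = {f"g{i}": [f"s{2*i}", f"s{2*i+1}"] for i in range(4)}
        res = replicate_concordance_test(M_before, M_after, groups)
        assert res.p_value < 0.05

    def test_groups_of_three_expand_to_all_pairs(self):
        M = self._m([0, 1, 2, 5, 5])
        groups = {"a": ["s0", "s1", "s2"], "b": ["s3", "s4"]}
        res = replicate_concordance_test(M, M * 0.5, groups)
        assert len(res.pairs) == 4   # 3 choose 2 + 1

    def test_requires_two_pairs(self):
        M = self._m([0, 1])
        with pytest.raises(ValueError, match="pairs"):
            replicate_concordance_test(M, M, {"a": ["s0", "s1"]})


def test_control_summaries_features_complete(tiny_dataset):
    summ = control_summaries(tiny_dataset)
    assert set(summ.columns) == {
        "negative.green", "negative.red", "bisulfite.green", "bisulfite.red",
        "norm_grn.green", "norm_red.red"}
    assert not summ.isna().any().any()
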