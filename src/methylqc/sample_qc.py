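"""Sample-level quality control.

Implements detection p-values from negative-control probes, the sample
failure flags (low bisulfite-conversion control intensity, excess poorly
detected probes, total-intensity outliers, beta-distribution outliers) and
Fisher's exact test comparing failure counts between tissues.

QC is intended to run separately per tissue batch: thresholds such as the
bisulfite mean - 3 SD fence are computed over the samples handed in.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import MethylationDataset, beta_from_intensities


@dataclasses.dataclass
class SampleQCReport:
    """Per-sample QC metrics, flags and the thresholds that produced them."""

    metrics: pd.DataFrame          # index sample_id; metric + flag columns
    thresholds: dict

    @property
    def failed(self) -> list:
        return list(self.metrics.index[~self.metrics["pass"]])

    @property
    def passed(self) -> list:
        return list(self.metrics.index[self.metrics["pass"]])

    def to_json_dict(self) -> dict:
        return {
            "thresholds": self.thresholds,
            "samples": self.metrics.reset_index()
                           .rename(columns={"index": "sample_id"})
                           .to_dict(orient="records"),
        }


# ---------------------------------------------------------------------------
# detection p-values
# ---------------------------------------------------------------------------

def detection_pvalues(dataset: MethylationDataset,
                      annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Probability that a probe's total signal arose from background.

    Background is modelled per sample as a normal whose mean and SD are the
    sums of the per-channel negative-control means and SDs (green + red for
    Type II probes; a single channel doubled for Type I designs when an
    annotation is provided).  ``p = 1 - Phi((meth+unmeth - mu_bg)/sd_bg)``.
    """
    neg_g = dataset.control_intensities("negative", "green")
    neg_r = dataset.control_intensities("negative", "red")
    if len(neg_g) < 3 or len(neg_r) < 3:
        raise ValueError("need at least 3 negative controls per channel")
    mu_g, sd_g = neg_g.mean(axis=0), neg_g.std(axis=0, ddof=1)
    mu_r, sd_r = neg_r.mean(axis=0), neg_r.std(axis=0, ddof=1)
    total = dataset.total_intensity().to_numpy()

    n_probes = len(dataset.probes)
    mu = np.tile((mu_g + mu_r).to_numpy()[None, :], (n_probes, 1))
    sd = np.tile((sd_g + sd_r).to_numpy()[None, :], (n_probes, 1))
    if annotation is not None:
        dt = annotation.reindex(dataset.probes)["design_type"].to_numpy()
        ig = dt == "I-green"
        ir = dt == "I-red"
        mu[ig] = 2 * mu_g.to_numpy()[None, :]
        sd[ig] = 2 * sd_g.to_numpy()[None, :]
        mu[ir] = 2 * mu_r.to_numpy()[None, :]
        sd[ir] = 2 * sd_r.to_numpy()[None, :]
    p = stats.norm.sf((total - mu) / sd)
    return pd.DataFrame(p, index=dataset.probes, columns=dataset.sample_ids)


def poorly_detected(detp: pd.DataFrame, beads: pd.DataFrame,
                    p_thresh: float = 0.01, bead_thresh: int = 3) -> pd.DataFrame:
    """Boolean matrix: probe inadequately detected (p > thresh or beads < thresh)."""
    return (detp > p_thresh) | (beads < bead_thresh)


# ---------------------------------------------------------------------------
# sample flags
# ---------------------------------------------------------------------------

def flag_intensity_outliers(dataset: MethylationDataset, mad_mult: float = 3.0) -> pd.Series:
    """Flag samples whose median log2 total intensity falls below
    ``median - mad_mult * 1.4826 * MAD`` across samples (low-intensity fence)."""
    if len(dataset.sample_ids) < 5:
        raise ValueError("need at least 5 samples for outlier detection")
    med_int = np.log2(dataset.total_intensity().clip(lower=1)).median(axis=0)
    center = med_int.median()
    mad = (med_int - center).abs().median()
    fence = center - mad_mult * 1.4826 * mad
    return med_int < fence


def flag_beta_outliers(beta: pd.DataFrame, ks_thresh: float = 0.15) -> pd.Series:
    """Flag samples whose beta distribution is far (KS distance) from the
    cohort's pooled reference distribution.

    The reference is the pooled empirical distribution of all samples'
    betas, so it carries the cohort's typical shape including ordinary
    between-sample variation; each sample is compared against the pool with
    itself left out.
    """
    if beta.shape[1] < 5:
        raise ValueError("need at least 5 samples for outlier detection")
    arr = beta.to_numpy(dtype=float)
    pooled_sorted = np.sort(arr, axis=None)
    n_total = pooled_sorted.size
    n_per = arr.shape[0]
    flags = {}
    for j, sid in enumerate(beta.columns):
        vals = np.sort(arr[:, j])
        # leave-one-out pooled ECDF evaluated at the sample's own points;
        # tie-safe: self counts come from searchsorted, not the rank index
        pos_all = np.searchsorted(pooled_sorted, vals, side="right")
        pos_self = np.searchsorted(vals, vals, side="right")
        ecdf_pool = (pos_all - pos_self) / (n_total - n_per)
        ecdf_self = pos_self / n_per
        ks = float(np.max(np.abs(ecdf_self - ecdf_pool)))
        flags[sid] = bool(ks > ks_thresh)
    return pd.Series(flags)


def bisulfite_mean_intensity(dataset: MethylationDataset) -> pd.Series:
    """Mean intensity over all bisulfite-conversion control probes, both channels."""
    bis = dataset.control_intensities("bisulfite")
    return bis.mean(axis=0)


def flag_low_quality_samples(dataset: MethylationDataset,
                             detp: pd.DataFrame | None = None,
                             annotation: pd.DataFrame | None = None,
                             p_thresh: float = 0.01,
                             bead_thresh: int = 3,
                             frac_thresh: float = 0.01,
                             sd_mult: float = 3.0,
                             ks_thresh: float = 0.15,
                             mad_mult: float = 3.0) -> SampleQCReport:
    """Full sample-level QC: combine all four failure flags into a report.

    A sample fails iff at least one flag is set:

    * ``low_bisulfite`` — bisulfite-control mean below mean - sd_mult*SD of
      all samples in the batch;
    * ``high_detection_failure`` — more than ``frac_thresh`` of probes with
      detection p > ``p_thresh`` or fewer than ``bead_thresh`` beads;
    * ``intensity_outlier`` — low median log2 total intensity (MAD fence);
    * ``beta_outlier`` — beta distribution far from the cohort's (KS distance).
    """
    ids = dataset.sample_ids
    if len(ids) < 2:
        raise ValueError("sample QC needs at least 2 samples (SD undefined otherwise)")
    if detp is None:
        detp = detection_pvalues(dataset, annotation)
    bis_mean = bisulfite_mean_intensity(dataset)
    bis_fence = bis_mean.mean() - sd_mult * bis_mean.std(ddof=1)
    low_bis = bis_mean < bis_fence

    poor = poorly_detected(detp, dataset.beads, p_thresh, bead_thresh)
    frac_poor = poor.mean(axis=0)
    high_fail = frac_poor > frac_thresh

    int_out = flag_intensity_outliers(dataset, mad_mult)
    beta_out = flag_beta_outliers(dataset.beta(), ks_thresh)

    metrics = pd.DataFrame({
        "bisulfite_mean_intensity": bis_mean,
        "fraction_poor_probes": frac_poor,
        "low_bisulfite": low_bis,
        "high_detection_failure": high_fail,
        "intensity_outlier": int_out,
        "beta_outlier": beta_out,
    }).loc[ids]
    metrics["pass"] = ~(metrics[["low_bisulfite", "high_detection_failure",
                                 "intensity_outlier", "beta_outlier"]].any(axis=1))
    thresholds = {
        "p_thresh": p_thresh, "bead_thresh": bead_thresh,
        "frac_thresh": frac_thresh, "sd_mult": sd_mult,
        "bisulfite_fence": float(bis_fence),
        "ks_thresh": ks_thresh, "mad_mult": mad_mult,
    }
    return SampleQCReport(metrics=metrics, thresholds=thresholds)


# ---------------------------------------------------------------------------
# tissue comparison
# ---------------------------------------------------------------------------

def tissue_failure_test(n_fail_a: int, n_total_a: int,
                        n_fail_b: int, n_total_b: int):
    """Two-sided Fisher's exact test on pass/fail counts of two tissues.

    Returns (p_value, odds_ratio).  Uses the point-probability rule (sum of
    hypergeometric probabilities <= the observed table's).  A zero-margin
    table returns p = 1 by convention.
    """
    for fail, total in ((n_fail_a, n_total_a), (n_fail_b, n_total_b)):
        if fail < 0 or total < 0 or fail > total:
            raise ValueError("counts must satisfy 0 <= fail <= total")
    table = np.array([[n_fail_a, n_total_a - n_fail_a],
                      [n_fail_b, n_total_b - n_fail_b]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0, np.nan
    res = stats.fisher_exact(table, alternative="two-sided")
    return float(res.pvalue), float(res.statistic)
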