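"""Probe-level quality control: sequential filters and the paired
blood-vs-CSF filter-outcome comparison.

Filters run in a fixed order — SNP-overlapping probes, cross-reactive
probes, sex-chromosome probes, probes with multimodal beta distributions,
probes inadequately detected in too many samples — and the report bookkeeps
filtered/retained counts per step (each step counts only probes that
survived the previous ones, so the counts telescope to the final retained
set).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

FILTER_STEPS = ("snp_overlap", "cross_reactive", "sex_chromosome",
                "multimodal", "low_detection")


@dataclasses.dataclass
class ProbeFilterReport:
    """Sequential probe-filter outcome."""

    steps: pd.DataFrame            # step, filtered, retained (in order)
    probe_status: pd.DataFrame     # index probe_id; pass flag + first failing step
    parameters: dict

    @property
    def retained(self) -> list:
        return list(self.probe_status.index[self.probe_status["pass"]])

    def check_bookkeeping(self) -> None:
        n0 = self.parameters["n_input"]
        filt = self.steps["filtered"].to_numpy()
        ret = self.steps["retained"].to_numpy()
        expect = n0 - np.cumsum(filt)
        if not np.array_equal(expect, ret):
            raise AssertionError("sequential filter counts do not telescope")
        if ret[-1] != len(self.retained):
            raise AssertionError("final retained count mismatch")


# ---------------------------------------------------------------------------
# multimodality
# ---------------------------------------------------------------------------

def _merge_shallow_peaks(peaks: np.ndarray, dens: np.ndarray,
                         merge_ratio: float) -> np.ndarray:
    """Merge adjacent KDE peaks whose connecting valley is shallow.

    A peak only counts as a separate mode if the density dips below
    ``merge_ratio`` times the smaller of the two peak heights between it and
    its neighbour; otherwise the smaller peak is a wiggle of the larger mode
    and is dropped.
    """
    peaks = list(peaks)
    while len(peaks) > 1:
        ratios = []
        for a, b in zip(peaks[:-1], peaks[1:]):
            valley = dens[a:b + 1].min()
            ratios.append(valley / min(dens[a], dens[b]))
        i = int(np.argmax(ratios))
        if ratios[i] <= merge_ratio:
            break
        a, b = peaks[i], peaks[i + 1]
        peaks.pop(i if dens[a] < dens[b] else i + 1)
    return np.array(peaks, dtype=int)


def _mode_structure(betas: np.ndarray, bandwidth: float, grid: np.ndarray,
                    merge_ratio: float = 0.7):
    """KDE on [0,1] with a fixed Gaussian bandwidth; returns (peak positions,
    per-peak sample mass) using watershed boundaries at local minima, after
    merging non-prominent peaks."""
    x = betas[:, None] - grid[None, :]
    dens = np.exp(-0.5 * (x / bandwidth) ** 2).sum(axis=0)
    interior = np.arange(1, len(grid) - 1)
    peaks = interior[(dens[interior] > dens[interior - 1])
                     & (dens[interior] >= dens[interior + 1])]
    if len(peaks) == 0:
        return np.array([]), np.array([])
    peaks = _merge_shallow_peaks(peaks, dens, merge_ratio)
    # basin boundaries: minima between consecutive peaks
    bounds = [grid[0] - 1e-9]
    for a, b in zip(peaks[:-1], peaks[1:]):
        seg = np.arange(a, b + 1)
        bounds.append(grid[seg[np.argmin(dens[seg])]])
    bounds.append(grid[-1] + 1e-9)
    mass = np.array([
        np.mean((betas > lo) & (betas <= hi))
        for lo, hi in zip(bounds[:-1], bounds[1:])
    ])
    return grid[peaks], mass


def detect_multimodal_probes(beta: pd.DataFrame,
                             min_mode_frac: float = 0.05,
                             min_separation: float = 0.2,
                             bandwidth: float = 0.05,
                             merge_ratio: float = 0.7,
                             min_mode_count: int = 3,
                             grid_size: int = 201) -> pd.Series:
    """Flag probes whose beta distribution has >= 2 well-separated modes,
    each holding at least ``min_mode_frac`` of the samples.

    Kernel density estimation on [0, 1]; ``bandwidth`` is a floor — the
    effective bandwidth per probe is the larger of it and Silverman's
    rule-of-thumb, so small cohorts are not under-smoothed.  Modes whose
    basins hold too little mass (fraction below ``min_mode_frac`` or fewer
    than ``min_mode_count`` samples) are ignored, and the surviving peaks
    must be at least ``min_separation`` apart.
    """
    import warnings
    if beta.shape[1] < 20:
        warnings.warn("fewer than 20 samples; multimodality detection is unreliable")
    grid = np.linspace(0, 1, grid_size)
    flags = {}
    for probe, row in beta.iterrows():
        vals = row.to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        sd = vals.std(ddof=1)
        iqr = np.subtract(*np.percentile(vals, [75, 25]))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        bw = max(bandwidth, 0.9 * spread * len(vals) ** (-0.2))
        peaks, mass = _mode_structure(vals, bw, grid, merge_ratio)
        frac = max(min_mode_frac, min_mode_count / max(len(vals), 1))
        major = peaks[mass >= frac]
        flagged = len(major) >= 2 and (major.max() - major.min()) >= min_separation
        flags[probe] = bool(flagged)
    return pd.Series(flags, name="multimodal")


# ---------------------------------------------------------------------------
# sequential filtering
# ---------------------------------------------------------------------------

def filter_probes(beta: pd.DataFrame,
                  detp: pd.DataFrame,
                  beads: pd.DataFrame,
                  annotation: pd.DataFrame,
                  p_thresh: float = 0.01,
                  bead_thresh: int = 3,
                  sample_frac: float = 0.01,
                  multimodal_kwargs: dict | None = None) -> ProbeFilterReport:
    """Apply the five sequential probe filters and bookkeep counts.

    Steps, in order: (1) SNP-overlapping probes, (2) cross-reactive probes,
    (3) sex-chromosome probes, (4) multimodal beta distributions, (5) probes
    with detection p > ``p_thresh`` or beads < ``bead_thresh`` in more than
    ``sample_frac`` of samples.
    """
    probes = beta.index
    missing = sorted(set(probes) - set(annotation.index))
    if missing:
        raise ValueError(f"annotation missing probes: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    ann = annotation.reindex(probes)

    fail_step = pd.Series("", index=probes, dtype=object)
    alive = pd.Series(True, index=probes)

    def apply_step(name: str, mask: pd.Series):
        hit = alive & mask
        fail_step[hit] = name
        alive[hit] = False
        return int(hit.sum())

    records = []
    records.append(("snp_overlap", apply_step("snp_overlap", ann["snp_overlap"].astype(bool))))
    records.append(("cross_reactive",
                    apply_step("cross_reactive", ann["cross_reactive"].astype(bool))))
    records.append(("sex_chromosome",
                    apply_step("sex_chromosome", ann["chromosome"].isin(["X", "Y"]))))

    mm = detect_multimodal_probes(beta.loc[alive[alive].index], **(multimodal_kwargs or {}))
    mm_full = pd.Series(False, index=probes)
    mm_full.loc[mm.index] = mm.to_numpy()
    records.append(("multimodal", apply_step("multimodal", mm_full)))

    poor = ((detp > p_thresh) | (beads < bead_thresh)).mean(axis=1)
    records.append(("low_detection", apply_step("low_detection", poor > sample_frac)))

    n0 = len(probes)
    steps = pd.DataFrame(records, columns=["step", "filtered"])
    steps["retained"] = n0 - steps["filtered"].cumsum()
    status = pd.DataFrame({"pass": alive, "first_failing_step": fail_step})
    report = ProbeFilterReport(
        steps=steps,
        probe_status=status,
        parameters={"n_input": n0, "p_thresh": p_thresh, "bead_thresh": bead_thresh,
                    "sample_frac": sample_frac},
    )
    report.check_bookkeeping()
    return report


# ---------------------------------------------------------------------------
# tissue comparison of filter outcomes
# ---------------------------------------------------------------------------

def mcnemar_filter_test(pass_blood: pd.Series, pass_csf: pd.Series):
    """McNemar's chi-square (with continuity correction) on paired per-probe
    pass/fail outcomes in the two tissues.

    Returns (chi2 statistic, p value).  ``b`` counts probes passing in blood
    but failing in CSF, ``c`` the converse; with b + c = 0, p = 1.
    """
    if not pass_blood.index.equals(pass_csf.index):
        pass_csf = pass_csf.reindex(pass_blood.index)
        if pass_csf.isna().any():
            raise ValueError("probe universes differ between tissues")
    pb = pass_blood.astype(bool).to_numpy()
    pc = pass_csf.astype(bool).to_numpy()
    b = int(np.sum(pb & ~pc))
    c = int(np.sum(~pb & pc))
    if b + c == 0:
        return 0.0, 1.0
    chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p
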