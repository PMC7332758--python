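"""Background correction, dye-bias correction, functional normalization and
the technical-replicate concordance test.

Order of operations used by the pipeline: normal-exponential background
correction (per sample, per channel, background estimated from negative
controls), linear dye-bias rescaling anchored on the normalization control
probes, then functional normalization — a control-probe-guided extension of
quantile normalization in which, within each probe stratum (Infinium design
type x meth/unmeth channel), the per-sample quantile curves are adjusted by
removing the component of their deviation from the mean curve that is
explained by the first k principal components of the control-probe
summaries.  Biological variation unexplained by the controls is retained;
with k = 0 the procedure degenerates to plain within-stratum quantile
normalization (every sample mapped to the mean quantile curve).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .data_model import MethylationDataset, MValueMatrix, m_from_beta


# ---------------------------------------------------------------------------
# channel assignment
# ---------------------------------------------------------------------------

def _channel_masks(dataset: MethylationDataset, annotation: pd.DataFrame | None):
    """Boolean probe masks (meth_green, unmeth_green) from the design type.

    Type II probes read meth in green and unmeth in red; Type I probes read
    both alleles in their design channel.  Without annotation all probes are
    treated as Type II.
    """
    n = len(dataset.probes)
    if annotation is None:
        dt = np.array(["II"] * n)
    else:
        dt = annotation.reindex(dataset.probes)["design_type"].to_numpy()
    meth_green = (dt == "II") | (dt == "I-green")
    unmeth_green = dt == "I-green"
    return dt, meth_green, unmeth_green


# ---------------------------------------------------------------------------
# normexp background correction
# ---------------------------------------------------------------------------

def _normexp_signal(x: np.ndarray, mu: float, sigma: float, alpha: float) -> np.ndarray:
    """Posterior mean of the true signal under the normal+exponential
    convolution model (signal ~ Exp(alpha), background ~ N(mu, sigma^2))."""
    mu_sf = x - mu - sigma**2 / alpha
    z = mu_sf / sigma
    # log-space ratio phi(z)/Phi(z) for numerical stability in the far tail
    log_ratio = stats.norm.logpdf(z) - stats.norm.logcdf(z)
    signal = mu_sf + sigma * np.exp(log_ratio)
    return np.clip(signal, 1e-6, None)


def background_correct(dataset: MethylationDataset,
                       annotation: pd.DataFrame | None = None) -> MethylationDataset:
    """Normal-exponential background deconvolution per sample per channel.

    Background mean/SD come from the negative-control probes of the matching
    channel; the exponential signal mean is estimated by moments from the
    channel's intensities.  All corrected intensities are strictly positive.
    Already-corrected datasets (stage tag present) are returned unchanged.
    """
    if "background" in dataset.stages:
        return dataset.copy()
    out = dataset.copy()
    _, meth_green, unmeth_green = _channel_masks(dataset, annotation)
    neg = {ch: dataset.control_intensities("negative", ch) for ch in ("green", "red")}
    meth = out.meth.to_numpy(dtype=float)
    unmeth = out.unmeth.to_numpy(dtype=float)
    for j, sid in enumerate(dataset.sample_ids):
        for channel in ("green", "red"):
            gmask = meth_green if channel == "green" else ~meth_green
            umask = unmeth_green if channel == "green" else ~unmeth_green
            vals = np.concatenate([meth[gmask, j], unmeth[umask, j]])
            if vals.size == 0:
                continue
            mu = float(neg[channel][sid].mean())
            sigma = float(neg[channel][sid].std(ddof=1))
            if not np.isfinite(sigma) or sigma <= 0:
                # degenerate background estimate: simple subtraction floor
                meth[gmask, j] = np.clip(meth[gmask, j] - mu, 1.0, None)
                unmeth[umask, j] = np.clip(unmeth[umask, j] - mu, 1.0, None)
                continue
            alpha = max(float(vals.mean()) - mu, sigma)
            meth[gmask, j] = _normexp_signal(meth[gmask, j], mu, sigma, alpha)
            unmeth[umask, j] = _normexp_signal(unmeth[umask, j], mu, sigma, alpha)
    out.meth.iloc[:, :] = meth
    out.unmeth.iloc[:, :] = unmeth
    out.stages = dataset.stages + ["background"]
    return out


# ---------------------------------------------------------------------------
# dye-bias correction
# ---------------------------------------------------------------------------

def dye_bias_correct(dataset: MethylationDataset,
                     annotation: pd.DataFrame | None = None) -> MethylationDataset:
    """Per-sample linear rescaling of each channel so that the green and red
    normalization-control means agree (both pulled to their grand mean).

    The control table is rescaled with the data, which makes the operation
    exactly idempotent.
    """
    out = dataset.copy()
    grn = dataset.control_intensities("norm_grn", "green")
    red = dataset.control_intensities("norm_red", "red")
    g_mean = grn.mean(axis=0)
    r_mean = red.mean(axis=0)
    if (g_mean <= 0).any() or (r_mean <= 0).any():
        raise ValueError("zero or negative normalization-control mean")
    grand = (g_mean + r_mean) / 2.0
    f_g = (grand / g_mean).to_numpy()
    f_r = (grand / r_mean).to_numpy()

    _, meth_green, unmeth_green = _channel_masks(dataset, annotation)
    meth = out.meth.to_numpy(dtype=float)
    unmeth = out.unmeth.to_numpy(dtype=float)
    meth *= np.where(meth_green[:, None], f_g[None, :], f_r[None, :])
    unmeth *= np.where(unmeth_green[:, None], f_g[None, :], f_r[None, :])
    out.meth.iloc[:, :] = meth
    out.unmeth.iloc[:, :] = unmeth

    # rescale control intensities by their channel factor
    ids = dataset.sample_ids
    ctrl = out.controls
    for channel, f in (("green", f_g), ("red", f_r)):
        mask = ctrl["channel"] == channel
        ctrl.loc[mask, ids] = ctrl.loc[mask, ids].to_numpy(dtype=float) * f[None, :]
    if "dye_bias" not in out.stages:
        out.stages = dataset.stages + ["dye_bias"]
    return out


# ---------------------------------------------------------------------------
# functional normalization
# ---------------------------------------------------------------------------

def control_summaries(dataset: MethylationDataset) -> pd.DataFrame:
    """Sample x feature table of mean log2 control intensities, one feature
    per (control_type, channel) present on the array."""
    rows = {}
    for (ctype, channel), grp in dataset.controls.groupby(["control_type", "channel"]):
        vals = grp[dataset.sample_ids].to_numpy(dtype=float)
        rows[f"{ctype}.{channel}"] = np.log2(np.clip(vals, 1.0, None)).mean(axis=0)
    summ = pd.DataFrame(rows, index=dataset.sample_ids)
    if summ.isna().any().any():
        raise ValueError("control summaries contain missing values")
    return summ


def _control_pcs(dataset: MethylationDataset, k: int) -> np.ndarray:
    summ = control_summaries(dataset)
    x = summ.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    k_eff = min(k, z.shape[1], z.shape[0] - 1)
    if k_eff < k:
        raise ValueError(f"cannot extract {k} control PCs from {z.shape} summaries")
    return PCA(n_components=k).fit_transform(z)


def _normalize_stratum(x: np.ndarray, pcs: np.ndarray | None,
                       n_quantiles: int) -> np.ndarray:
    """Quantile-anchored adjustment of one stratum (probes x samples)."""
    n_probes, n_samples = x.shape
    if n_probes < 2:
        return x
    levels = np.linspace(0, 1, min(n_quantiles, n_probes))
    q = np.quantile(x, levels, axis=0)                  # levels x samples
    mean_q = q.mean(axis=1)
    if pcs is None:
        adj = np.tile(mean_q[:, None], (1, n_samples))  # plain QN
    else:
        z = pcs - pcs.mean(axis=0)
        # per level: q_s = mean + z beta + resid; remove the control-explained part
        coef, *_ = np.linalg.lstsq(z, (q - mean_q[:, None]).T, rcond=None)
        adj = q - (z @ coef).T
    adj = np.maximum.accumulate(adj, axis=0)            # keep anchors monotone
    out = np.empty_like(x)
    for j in range(n_samples):
        out[:, j] = np.interp(x[:, j], q[:, j], adj[:, j])
    return out


def functional_normalize(dataset: MethylationDataset,
                         annotation: pd.DataFrame | None = None,
                         k: int = 2,
                         n_quantiles: int = 500) -> tuple[MethylationDataset, MValueMatrix]:
    """Functional normalization of intensities; returns the normalized
    dataset and the recomputed M-value matrix.

    Strata are (design type) x (meth / unmeth).  Within a stratum each
    sample's empirical quantile curve is adjusted by removing the deviation
    from the mean curve explained by the first ``k`` control-probe principal
    components, then intensities are mapped through monotone interpolation
    between the raw and adjusted anchors.  ``k = 0`` degenerates to plain
    quantile normalization.
    """
    n_samples = len(dataset.sample_ids)
    if k >= n_samples:
        raise ValueError("k must be smaller than the number of samples")
    if k > 0 and n_samples < k + 2:
        raise ValueError("need at least k + 2 samples")
    pcs = _control_pcs(dataset, k) if k > 0 else None
    dt, _, _ = _channel_masks(dataset, annotation)
    out = dataset.copy()
    for mat_name in ("meth", "unmeth"):
        mat = getattr(out, mat_name).to_numpy(dtype=float)
        for stratum in np.unique(dt):
            mask = dt == stratum
            mat[mask, :] = _normalize_stratum(mat[mask, :], pcs, n_quantiles)
        getattr(out, mat_name).iloc[:, :] = mat
    out.stages = dataset.stages + ["funnorm"]
    mvals = MValueMatrix(values=m_from_beta(out.beta()), provenance="funnorm")
    return out, mvals


# ---------------------------------------------------------------------------
# replicate concordance
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConcordanceResult:
    t_statistic: float | None
    p_value: float | None
    pairs: pd.DataFrame          # pair id, d_before, d_after
    reason: str | None = None


def _replicate_pairs(replicate_groups: dict) -> list[tuple[str, str]]:
    pairs = []
    for _, members in sorted(replicate_groups.items()):
        members = sorted(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.append((members[i], members[j]))
    return pairs


def replicate_concordance_test(M_before: pd.DataFrame, M_after: pd.DataFrame,
                               replicate_groups: dict) -> ConcordanceResult:
    """One-sided paired t-test on squared differences of technical-replicate
    median M-values, before vs after normalization (alternative: after < before).

    ``replicate_groups`` maps group id -> sample ids; groups larger than two
    contribute all unordered pairs.
    """
    pairs = _replicate_pairs(replicate_groups)
    if len(pairs) < 2:
        raise ValueError("need at least 2 replicate pairs")
    rows = []
    for a, b in pairs:
        d_before = float((M_before[a].median() - M_before[b].median()) ** 2)
        d_after = float((M_after[a].median() - M_after[b].median()) ** 2)
        rows.append({"pair": f"{a}|{b}", "d_before": d_before, "d_after": d_after})
    tab = pd.DataFrame(rows)
    diff = tab["d_after"] - tab["d_before"]
    if np.allclose(diff.std(ddof=1), 0.0):
        return ConcordanceResult(None, None, tab, reason="zero variance in paired differences")
    t, p = stats.ttest_rel(tab["d_after"], tab["d_before"], alternative="less")
    return ConcordanceResult(float(t), float(p), tab)


def replicate_groups_from_sheet(samples: pd.DataFrame) -> dict:
    """Extract replicate groups (>= 2 members) from a sample sheet."""
    groups = {}
    for name, grp in samples.dropna(subset=["replicate_group"]).groupby("replicate_group"):
        if len(grp) >= 2:
            groups[name] = list(grp["sample_id"])
    return groups
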