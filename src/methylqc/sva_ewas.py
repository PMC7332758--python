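"""Surrogate variable analysis, day-subset construction, permuted-trait null
EWAS and the genomic inflation factor.

The surrogate variables estimate latent sample-level covariates (cell-type
mixture axes, residual batch structure) from the M-value matrix itself,
conditional on the primary model (trait + covariates) so that variation
attributable to the trait is protected from absorption.  The number of
surrogate variables is chosen by permutation parallel analysis; the
surrogate variables themselves come from an iteratively reweighted SVD in
which probes likely to be driven by latent structure — but not by the
trait — receive high weight.

A null EWAS is produced by permuting an observed binary trait, regressing
each CpG's M-value on it (plus age, sex and optionally the surrogate
variables) and summarising test calibration with the genomic inflation
factor λ, the ratio of the observed to expected median of the per-CpG
chi-square statistic.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

CHI2_NULL_MEDIAN = stats.chi2.ppf(0.5, 1)   # 0.4549364...


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def _as_design(covariates: pd.DataFrame | None, n: int,
               intercept: bool = True) -> np.ndarray:
    cols = [np.ones(n)] if intercept else []
    names = ["intercept"] if intercept else []
    if covariates is not None:
        for c in covariates.columns:
            v = covariates[c]
            if v.dtype == object or str(v.dtype) == "category":
                codes, _ = pd.factorize(v)
                cols.append(codes.astype(float))
            else:
                cols.append(v.to_numpy(dtype=float))
            names.append(str(c))
    D = np.column_stack(cols)
    return D


def _check_full_rank(D: np.ndarray, names=None) -> None:
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError(f"design matrix is rank deficient (columns: {names})")


def _residualize(M: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Residuals of each probe (row of M) on the design D (samples x p)."""
    coef, *_ = np.linalg.lstsq(D, M.T, rcond=None)
    return M - (D @ coef).T


# ---------------------------------------------------------------------------
# CSF day subsets
# ---------------------------------------------------------------------------

def csf_day_subsets(samples: pd.DataFrame,
                    targets=(1, 4, 7, 10, 13)) -> dict[int, list[str]]:
    """Group CSF samples into per-target-day subsets with ±1-day substitution.

    Per subject and target day the exact-day sample is preferred, then
    day − 1, then day + 1; each subject contributes at most one sample per
    target and no sample is assigned to two targets.  Control samples and
    technical replicates are ignored.
    """
    bio = samples[(samples["tissue"] == "csf")
                  & ~samples["is_control_sample"].astype(bool)]
    csf = bio[~bio.duplicated(subset=["subject_id", "collection_day"])]
    used: set = set()
    subsets: dict[int, list[str]] = {t: [] for t in targets}
    for t in targets:
        for subject, grp in csf.groupby("subject_id"):
            chosen = None
            for day in (t, t - 1, t + 1):           # preference order
                cand = grp[(grp["collection_day"] == day)
                           & ~grp["sample_id"].isin(used)]
                if len(cand):
                    chosen = cand["sample_id"].iloc[0]
                    break
            if chosen is not None:
                subsets[t].append(chosen)
                used.add(chosen)
    return subsets


# ---------------------------------------------------------------------------
# trait permutation
# ---------------------------------------------------------------------------

def permute_trait(trait, seed: int = 0) -> np.ndarray:
    """Uniform random permutation of a binary trait vector (class counts
    preserved); requires at least two members of each class."""
    arr = np.asarray(trait)
    values, counts = np.unique(arr, return_counts=True)
    if len(values) < 2 or counts.min() < 2:
        raise ValueError("trait needs at least 2 members of each class")
    rng = np.random.default_rng(seed)
    return arr[rng.permutation(len(arr))]


# ---------------------------------------------------------------------------
# number of surrogate variables
# ---------------------------------------------------------------------------

def estimate_num_sv(M: pd.DataFrame, covariates: pd.DataFrame | None = None,
                    n_perm: int = 20, seed: int = 0,
                    quantile: float = 0.95) -> int:
    """Permutation parallel analysis for the latent dimension.

    The M matrix is residualized on the covariate model; singular values of
    the residual are compared, component by component, with the chosen
    percentile of singular values obtained after independently permuting
    each probe's residuals across samples.  The count of leading components
    exceeding their permutation threshold is returned.
    """
    X = M.to_numpy(dtype=float)
    n_probes, n_samples = X.shape
    D = _as_design(covariates, n_samples)
    if n_samples <= D.shape[1] + 2:
        raise ValueError("too few samples for the covariate model")
    R = _residualize(X, D)
    sv_obs = np.linalg.svd(R, compute_uv=False)
    rng = np.random.default_rng(seed)
    perm_svs = np.empty((n_perm, len(sv_obs)))
    for b in range(n_perm):
        P = np.array([row[rng.permutation(n_samples)] for row in R])
        P = _residualize(P, D)
        perm_svs[b] = np.linalg.svd(P, compute_uv=False)
    thresh = np.quantile(perm_svs, quantile, axis=0)
    exceeds = sv_obs > thresh
    n_sv = 0
    for e in exceeds:              # leading run only
        if e:
            n_sv += 1
        else:
            break
    return n_sv


# ---------------------------------------------------------------------------
# surrogate variables (iteratively reweighted SVD)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SurrogateVariables:
    """Orthonormal sample x n_sv surrogate-variable matrix plus metadata."""

    values: pd.DataFrame
    n_sv: int
    n_iter: int

    def __post_init__(self):
        V = self.values.to_numpy()
        if np.max(np.abs(V.T @ V - np.eye(V.shape[1]))) > 1e-8:
            raise ValueError("surrogate variable columns must be orthonormal")


def _f_pvalues(M: np.ndarray, D_small: np.ndarray, D_big: np.ndarray) -> np.ndarray:
    """Per-probe F-test p-values for adding the extra columns of D_big."""
    n = M.shape[1]
    rss_small = np.sum(_residualize(M, D_small) ** 2, axis=1)
    rss_big = np.sum(_residualize(M, D_big) ** 2, axis=1)
    df1 = D_big.shape[1] - D_small.shape[1]
    df2 = n - D_big.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_small - rss_big) / df1) / (rss_big / df2)
    f = np.nan_to_num(f, nan=0.0, posinf=np.inf)
    return stats.f.sf(f, df1, df2)


def _null_posterior(pvals: np.ndarray) -> np.ndarray:
    """Empirical probability that each test is null, given its p-value.

    A Storey-type estimate: pi0 from the upper half of the p distribution,
    then a monotone q-value-like quantity ``min(1, pi0 * p * n / rank)``.
    When the p-values are globally uniform (no real associations) this is
    ~1 everywhere; when many tests are truly associated their posterior
    drops toward 0.
    """
    n = len(pvals)
    pi0 = min(1.0, 2.0 * float(np.mean(pvals > 0.5)))
    order = np.argsort(pvals)
    ranked = pi0 * pvals[order] * n / np.arange(1, n + 1)
    # enforce monotonicity in p (as for q-values)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def compute_surrogate_variables(M: pd.DataFrame, trait, n_sv: int,
                                covariates: pd.DataFrame | None = None,
                                n_iter: int = 5) -> SurrogateVariables:
    """Iteratively reweighted surrogate-variable estimation.

    Per iteration: residualize M on the full primary model (trait +
    covariates), SVD for candidate factors, weight each probe by the
    evidence that it tracks the candidate factors but not the trait, then
    SVD of the weighted null-model residuals.  The trait-protection term is
    the empirical null posterior of the per-probe trait F-test: when the
    trait has no real associations the term is ~1 everywhere (no
    protection needed); when a latent factor is confounded with the trait
    the loaded probes are downweighted so the surrogate variables do not
    absorb trait variation.  The top ``n_sv`` right singular vectors
    (orthonormal) are returned.
    """
    if n_sv < 1:
        raise ValueError("n_sv must be >= 1")
    X = M.to_numpy(dtype=float)
    n_probes, n_samples = X.shape
    trait_arr = np.asarray(trait, dtype=float)
    cov = covariates
    D_null = _as_design(cov, n_samples)
    D_full = np.column_stack([D_null, trait_arr])
    _check_full_rank(D_full)
    if n_sv >= n_samples - np.linalg.matrix_rank(D_full):
        raise ValueError("n_sv must be < n_samples - rank(primary model)")

    R_full = _residualize(X, D_full)
    R_null = _residualize(X, D_null)
    _, _, Vt = np.linalg.svd(R_full, full_matrices=False)
    V = Vt[:n_sv].T
    for _ in range(n_iter):
        D_with_v = np.column_stack([D_null, V])
        p_factor = _f_pvalues(X, D_null, D_with_v)
        p_trait = _f_pvalues(X, D_with_v, np.column_stack([D_with_v, trait_arr]))
        w = (1.0 - p_factor) * _null_posterior(p_trait)
        _, _, Vt = np.linalg.svd(w[:, None] * R_null, full_matrices=False)
        V = Vt[:n_sv].T
    values = pd.DataFrame(V, index=M.columns,
                          columns=[f"SV{i + 1}" for i in range(n_sv)])
    return SurrogateVariables(values=values, n_sv=n_sv, n_iter=n_iter)


# ---------------------------------------------------------------------------
# EWAS
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EwasResult:
    """Per-CpG trait association results under a linear model on M-values."""

    pvalues: pd.Series
    effects: pd.Series
    inflation: float
    model: str

    def qq_coordinates(self) -> pd.DataFrame:
        """Expected vs observed -log10 p for a QQ plot."""
        obs = np.sort(self.pvalues.to_numpy())
        n = len(obs)
        exp = (np.arange(1, n + 1) - 0.5) / n
        return pd.DataFrame({"expected": -np.log10(exp), "observed": -np.log10(obs)})


def run_ewas(M: pd.DataFrame, trait, covariates: pd.DataFrame | None = None,
             svs: SurrogateVariables | pd.DataFrame | None = None) -> EwasResult:
    """Per-CpG least-squares fit M ~ trait + covariates [+ SVs]; two-sided
    t-test for the trait coefficient; genomic inflation factor attached."""
    X = M.to_numpy(dtype=float)
    n_probes, n_samples = X.shape
    trait_arr = np.asarray(trait, dtype=float)
    D = _as_design(covariates, n_samples)
    names = ["intercept"] + (list(covariates.columns) if covariates is not None else [])
    D = np.column_stack([D, trait_arr])
    names.append("trait")
    if svs is not None:
        V = svs.values if isinstance(svs, SurrogateVariables) else svs
        D = np.column_stack([D, np.asarray(V, dtype=float)])
        names += [f"SV{i + 1}" for i in range(np.asarray(V).shape[1])]
    _check_full_rank(D, names)
    trait_col = names.index("trait")

    DtD_inv = np.linalg.inv(D.T @ D)
    coef = (DtD_inv @ D.T @ X.T)                 # p x probes
    resid = X.T - D @ coef
    df = n_samples - D.shape[1]
    sigma2 = np.sum(resid ** 2, axis=0) / df
    se = np.sqrt(sigma2 * DtD_inv[trait_col, trait_col])
    tstat = coef[trait_col] / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    pvalues = pd.Series(pvals, index=M.index, name="p")
    effects = pd.Series(coef[trait_col], index=M.index, name="effect")
    lam = genomic_inflation(pvalues)
    model = " + ".join(names[1:])
    return EwasResult(pvalues=pvalues, effects=effects, inflation=lam, model=model)


def genomic_inflation(pvalues) -> float:
    """λ = median(observed chi-square quantiles) / null median (0.4549...).

    The observed statistic for each test is recovered from its p-value via
    the chi-square(1 df) quantile function.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_NULL_MEDIAN)
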