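"""Reference-based cell-type deconvolution and composition-outlier flagging.

Each sample's beta profile at cell-type-discriminating probes is modelled as
a convex combination of reference cell-type methylomes; the mixing weights
are the estimated cell fractions.  The fit is a simplex-constrained least
squares problem, min ||y - Xw||^2 with w >= 0 and sum(w) = 1, solved exactly
by enumerating active sets of the KKT conditions (the number of cell types
is small, so all 2^k - 1 support sets are checked).
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd


@dataclasses.dataclass
class CellProportions:
    """Sample x cell-type fraction estimates plus per-sample fit residuals."""

    fractions: pd.DataFrame
    residual_norm: pd.Series
    reference_id: str = ""

    def __post_init__(self):
        f = self.fractions.to_numpy()
        if np.any(f < -1e-9):
            raise ValueError("fractions must be non-negative")
        if np.max(np.abs(f.sum(axis=1) - 1.0)) > 1e-6:
            raise ValueError("fractions must sum to 1 per sample")


def select_discriminating_probes(reference: pd.DataFrame, n: int = 100) -> pd.Index:
    """Top-``n`` probes ranked by between-cell-type variance of the
    reference betas (the probes that carry mixture information)."""
    score = reference.var(axis=1, ddof=1)
    return score.sort_values(ascending=False).head(n).index


def _simplex_lsq(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact solution of min ||y - Xw||^2 s.t. w >= 0, sum w = 1 by
    enumeration of support sets."""
    k = X.shape[1]
    best_w, best_obj = None, np.inf
    for r in range(1, k + 1):
        for support in itertools.combinations(range(k), r):
            Xs = X[:, support]
            # KKT system for equality-constrained LS on the support
            A = Xs.T @ Xs
            g = Xs.T @ y
            kkt = np.zeros((r + 1, r + 1))
            kkt[:r, :r] = A
            kkt[:r, r] = 1.0
            kkt[r, :r] = 1.0
            rhs = np.append(g, 1.0)
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            w_s = sol[:r]
            if np.any(w_s < -1e-10):
                continue
            w = np.zeros(k)
            w[list(support)] = np.clip(w_s, 0.0, None)
            w /= w.sum()
            obj = float(np.sum((y - X @ w) ** 2))
            if obj < best_obj - 1e-15:
                best_obj, best_w = obj, w
    return best_w


def estimate_cell_proportions(beta_samples: pd.DataFrame,
                              reference: pd.DataFrame,
                              n_discriminating: int = 100,
                              reference_id: str = "") -> CellProportions:
    """Estimate per-sample cell-type fractions by simplex-constrained least
    squares against the reference methylome on discriminating probes.

    ``beta_samples``: probe x sample betas; ``reference``: probe x cell-type
    betas.  Probes are matched by id; the ``n_discriminating`` most
    cell-type-variable reference probes are used for the fit.
    """
    shared = reference.index.intersection(beta_samples.index)
    if len(shared) < reference.shape[1]:
        raise ValueError("samples and reference share too few probes")
    ref = reference.loc[shared]
    probes = select_discriminating_probes(ref, n_discriminating)
    X = ref.loc[probes].to_numpy(dtype=float)
    cond = np.linalg.cond(X.T @ X)
    if not np.isfinite(cond) or cond > 1e10:
        raise ValueError(
            f"reference columns are collinear on selected probes (condition number {cond:.2e})"
        )
    Y = beta_samples.loc[probes].to_numpy(dtype=float)
    weights, resid = [], []
    for j in range(Y.shape[1]):
        w = _simplex_lsq(X, Y[:, j])
        weights.append(w)
        resid.append(float(np.linalg.norm(Y[:, j] - X @ w)))
    fractions = pd.DataFrame(np.vstack(weights), index=beta_samples.columns,
                             columns=reference.columns)
    return CellProportions(
        fractions=fractions,
        residual_norm=pd.Series(resid, index=beta_samples.columns, name="residual_norm"),
        reference_id=reference_id,
    )


def flag_composition_outliers(proportions: CellProportions | pd.DataFrame,
                              cell_type: str,
                              z_thresh: float = 4.0) -> pd.Series:
    """Flag samples whose fraction of ``cell_type`` exceeds
    ``median + z_thresh * 1.4826 * MAD`` across samples.

    With MAD = 0 (homogeneous cohort) any sample more than 0.1 above the
    median is flagged instead.
    """
    frac = proportions.fractions if isinstance(proportions, CellProportions) else proportions
    if len(frac) < 10:
        raise ValueError("need at least 10 samples to flag composition outliers")
    x = frac[cell_type].astype(float)
    med = x.median()
    mad = (x - med).abs().median()
    if mad == 0:
        return (x - med) > 0.1
    return x > med + z_thresh * 1.4826 * mad
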