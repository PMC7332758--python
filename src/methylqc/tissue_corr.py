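"""Blood-vs-CSF methylomic concordance.

Pipeline: drop CpGs that are uniformly extreme (all betas > 90% or < 10% in
both tissues — such sites correlate for uninteresting reasons), adjust
M-values for age, sex and surrogate variables, then compute Pearson
correlations two ways: per CpG across paired subjects (within-CpG) and per
subject across CpGs (within-individual).  Within-CpG correlations are
summarised by genomic-region and gene-orientation strata with a
Kruskal-Wallis omnibus test and Bonferroni-corrected pairwise Mann-Whitney
comparisons.  Correlation is used precisely because it is invariant to the
systematic mean/scale shifts expected when the two tissues are assayed on
different plates.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class CorrelationResult:
    """Cross-tissue concordance for one blood/CSF paired subset."""

    per_cpg: pd.DataFrame        # index probe_id: r, region, orientation
    per_subject: pd.Series       # index subject_id: r across CpGs
    n_subjects: int
    n_cpgs: int
    n_na_cpgs: int

    def summary(self) -> dict:
        r = self.per_cpg["r"].dropna()
        return {
            "n_subjects": self.n_subjects,
            "n_cpgs": self.n_cpgs,
            "n_na_cpgs": self.n_na_cpgs,
            "mean_r": float(r.mean()),
            "median_r": float(r.median()),
            "mean_within_individual_r": float(self.per_subject.mean()),
            "median_within_individual_r": float(self.per_subject.median()),
        }


# ---------------------------------------------------------------------------
# extreme-beta filter
# ---------------------------------------------------------------------------

def extreme_beta_filter(beta_blood: pd.DataFrame, beta_csf: pd.DataFrame,
                        lo: float = 0.10, hi: float = 0.90) -> pd.Index:
    """Retain CpGs unless *every* beta in *both* tissues is above ``hi`` or
    every beta in both tissues is below ``lo``."""
    shared = beta_blood.index.intersection(beta_csf.index)
    b = beta_blood.loc[shared].to_numpy(dtype=float)
    c = beta_csf.loc[shared].to_numpy(dtype=float)
    all_high = (b > hi).all(axis=1) & (c > hi).all(axis=1)
    all_low = (b < lo).all(axis=1) & (c < lo).all(axis=1)
    return shared[~(all_high | all_low)]


# ---------------------------------------------------------------------------
# covariate adjustment
# ---------------------------------------------------------------------------

def adjust_mvalues(M: pd.DataFrame, covariates: pd.DataFrame,
                   svs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Residuals of each CpG's M-values on intercept + covariates [+ SVs].

    Categorical covariate columns (e.g. sex) are factor-coded.  The design
    must be full rank; residuals are orthogonal to every design column.
    """
    n = M.shape[1]
    cols = [np.ones(n)]
    names = ["intercept"]
    for c in covariates.columns:
        v = covariates[c]
        if v.dtype == object or str(v.dtype) == "category":
            codes, _ = pd.factorize(v)
            cols.append(codes.astype(float))
        else:
            cols.append(v.to_numpy(dtype=float))
        names.append(str(c))
    if svs is not None:
        arr = np.asarray(svs, dtype=float)
        for i in range(arr.shape[1]):
            cols.append(arr[:, i])
            names.append(f"SV{i + 1}")
    D = np.column_stack(cols)
    # constant covariates carry no information; drop them rather than reject
    keep = [0] + [i for i in range(1, D.shape[1]) if np.ptp(D[:, i]) > 0]
    D = D[:, keep]
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError(f"rank-deficient adjustment design: {[names[i] for i in keep]}")
    X = M.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(D, X.T, rcond=None)
    return pd.DataFrame(X - (D @ coef).T, index=M.index, columns=M.columns)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _paired_matrices(adjM_blood: pd.DataFrame, adjM_csf: pd.DataFrame,
                     subject_pairs: pd.DataFrame):
    """Align the two matrices to (probe x subject) using the pairing table
    (columns: subject_id, blood_sample, csf_sample)."""
    shared = adjM_blood.index.intersection(adjM_csf.index)
    b = adjM_blood.loc[shared, subject_pairs["blood_sample"]].to_numpy(dtype=float)
    c = adjM_csf.loc[shared, subject_pairs["csf_sample"]].to_numpy(dtype=float)
    return shared, b, c


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matching rows of two equally shaped matrices;
    rows with zero variance give NaN."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = np.sum(a * b, axis=1)
    den = np.sqrt(np.sum(a ** 2, axis=1) * np.sum(b ** 2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return r


def within_cpg_correlation(adjM_blood: pd.DataFrame, adjM_csf: pd.DataFrame,
                           subject_pairs: pd.DataFrame,
                           method: str = "pearson") -> pd.Series:
    """Correlation across paired subjects at each CpG (r per CpG)."""
    if len(subject_pairs) < 3:
        raise ValueError("need at least 3 complete subject pairs")
    shared, b, c = _paired_matrices(adjM_blood, adjM_csf, subject_pairs)
    if method == "spearman":
        b = stats.rankdata(b, axis=1)
        c = stats.rankdata(c, axis=1)
    r = _rowwise_pearson(b, c)
    return pd.Series(r, index=shared, name="r")


def within_individual_correlation(adjM_blood: pd.DataFrame, adjM_csf: pd.DataFrame,
                                  subject_pairs: pd.DataFrame,
                                  method: str = "pearson") -> pd.Series:
    """Correlation across CpGs for each paired subject (r per subject)."""
    shared, b, c = _paired_matrices(adjM_blood, adjM_csf, subject_pairs)
    if len(shared) < 10:
        raise ValueError("need at least 10 retained CpGs")
    if method == "spearman":
        b = stats.rankdata(b, axis=0)
        c = stats.rankdata(c, axis=0)
    r = _rowwise_pearson(b.T, c.T)
    return pd.Series(r, index=pd.Index(subject_pairs["subject_id"], name="subject_id"),
                     name="r")


# ---------------------------------------------------------------------------
# stratified comparison
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StrataComparison:
    per_stratum: pd.DataFrame     # n, mean, median, q25, q75 per stratum
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame        # stratum_a, stratum_b, U, p_bonferroni


def stratified_comparison(r_per_cpg: pd.Series, annotation: pd.DataFrame,
                          strata_field: str, min_stratum: int = 10) -> StrataComparison:
    """Per-stratum summaries of within-CpG r plus a Kruskal-Wallis omnibus
    test and Bonferroni-corrected pairwise Mann-Whitney comparisons.

    Strata with fewer than ``min_stratum`` CpGs (after dropping NaN r) are
    excluded with a warning; at least two usable strata are required.
    """
    import warnings
    labels = annotation.reindex(r_per_cpg.index)[strata_field]
    df = pd.DataFrame({"r": r_per_cpg, "stratum": labels}).dropna()
    groups = {}
    for name, grp in df.groupby("stratum"):
        if len(grp) < min_stratum:
            warnings.warn(f"stratum {name!r} has {len(grp)} CpGs; excluded")
            continue
        groups[name] = grp["r"].to_numpy()
    if len(groups) < 2:
        raise ValueError("need at least 2 strata with enough CpGs")
    summary = pd.DataFrame({
        name: {"n": len(v), "mean": np.mean(v), "median": np.median(v),
               "q25": np.quantile(v, 0.25), "q75": np.quantile(v, 0.75)}
        for name, v in groups.items()
    }).T
    stat, p = stats.kruskal(*groups.values())
    rows = []
    pairs = list(itertools.combinations(sorted(groups), 2))
    for a, b in pairs:
        u, pp = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append({"stratum_a": a, "stratum_b": b, "U": float(u),
                     "p_bonferroni": min(1.0, float(pp) * len(pairs))})
    return StrataComparison(per_stratum=summary, omnibus_stat=float(stat),
                            omnibus_p=float(p), pairwise=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# convenience: full comparison for one day subset
# ---------------------------------------------------------------------------

def compare_tissues(beta_blood: pd.DataFrame, M_blood: pd.DataFrame,
                    beta_csf: pd.DataFrame, M_csf: pd.DataFrame,
                    subject_pairs: pd.DataFrame,
                    covariates_blood: pd.DataFrame, covariates_csf: pd.DataFrame,
                    annotation: pd.DataFrame,
                    svs_blood: pd.DataFrame | None = None,
                    svs_csf: pd.DataFrame | None = None,
                    lo: float = 0.10, hi: float = 0.90,
                    method: str = "pearson") -> CorrelationResult:
    """Extreme-beta filter, per-tissue adjustment and both correlation views
    for one paired blood/CSF subset."""
    bcols = list(subject_pairs["blood_sample"])
    ccols = list(subject_pairs["csf_sample"])
    keep = extreme_beta_filter(beta_blood[bcols], beta_csf[ccols], lo, hi)
    adj_b = adjust_mvalues(M_blood.loc[keep, bcols], covariates_blood, svs_blood)
    adj_c = adjust_mvalues(M_csf.loc[keep, ccols], covariates_csf, svs_csf)
    r_cpg = within_cpg_correlation(adj_b, adj_c, subject_pairs, method)
    # within-individual correlation is computed on adjusted values with the
    # per-CpG mean retained: covariate effects are removed but the methylome
    # architecture (which CpGs are high vs low) is what subjects share across
    # tissues.  Within-CpG r is unaffected by a per-CpG constant.
    mean_b = M_blood.loc[keep, bcols].mean(axis=1)
    mean_c = M_csf.loc[keep, ccols].mean(axis=1)
    r_subj = within_individual_correlation(adj_b.add(mean_b, axis=0),
                                           adj_c.add(mean_c, axis=0),
                                           subject_pairs, method)
    ann = annotation.reindex(keep)
    per_cpg = pd.DataFrame({"r": r_cpg, "region": ann["region"],
                            "orientation": ann["orientation"]})
    return CorrelationResult(
        per_cpg=per_cpg,
        per_subject=r_subj,
        n_subjects=len(subject_pairs),
        n_cpgs=len(keep),
        n_na_cpgs=int(r_cpg.isna().sum()),
    )
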