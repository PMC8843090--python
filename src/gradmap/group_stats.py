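"""Group-level statistics on connectivity modes and trend-surface coefficients.

Covers the statistical surface of a connectopic-mapping study: spatial
correlations of a mode against a reference density map (voxel-wise, and in
trend-surface coefficient space, where coefficients are orthogonal and
spatial autocorrelation is not an issue), subject quality filtering against
a group-average mode, test–retest reliability via ICC(2,k) with bootstrap
confidence intervals and a within- vs between-subject permutation test, and
omnibus likelihood-ratio tests of full coefficient vectors against a binary
diagnosis (logistic regression) or a continuous outcome (Gaussian GLM), with
post-hoc per-coefficient Pearson correlations and Bonferroni control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "OmnibusResult",
    "ReliabilityResult",
    "spatial_correlation",
    "coefficient_correlation",
    "filter_by_reference",
    "icc_2k",
    "within_between_permutation",
    "omnibus_lr_binary",
    "omnibus_lr_continuous",
    "change_score_analysis",
    "posthoc_pearson",
    "bonferroni",
]


@dataclass
class OmnibusResult:
    """Likelihood-ratio omnibus test of a full coefficient vector."""

    statistic: float  # X^2
    df: int
    p_value: float
    model_full: str
    model_null: str
    n: int
    separation_flag: bool = False


@dataclass
class ReliabilityResult:
    icc: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    within_r: float | None = None
    between_r: float | None = None
    perm_p: float | None = None
    n_perm: int = 0
    n_boot: int = 0


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def spatial_correlation(map1: np.ndarray, map2: np.ndarray):
    """Voxel-wise Pearson correlation of two maps on the same ROI support.

    The p-value comes from the t-approximation and does not account for
    spatial autocorrelation; prefer :func:`coefficient_correlation` for
    inference on smooth maps.
    """
    map1 = np.asarray(map1, dtype=np.float64).ravel()
    map2 = np.asarray(map2, dtype=np.float64).ravel()
    if map1.shape != map2.shape:
        raise ValueError("maps must share the same ROI voxel support")
    if np.std(map1) == 0 or np.std(map2) == 0:
        raise ValueError("zero-variance map")
    return _pearson(map1, map2)


def coefficient_correlation(beta_a: np.ndarray, beta_b: np.ndarray):
    """Pearson correlation across concatenated trend-surface coefficients.

    Both vectors must use the identical concatenation order (same ROIs, same
    degrees, same column order).
    """
    beta_a = np.asarray(beta_a, dtype=np.float64).ravel()
    beta_b = np.asarray(beta_b, dtype=np.float64).ravel()
    if beta_a.shape != beta_b.shape:
        raise ValueError("coefficient vectors differ in length")
    return _pearson(beta_a, beta_b)


def filter_by_reference(modes: dict, reference: np.ndarray,
                        r_min: float = 0.5):
    """Keep subjects whose mode correlates with the group reference at r > r_min.

    Strict inequality: a subject at exactly ``r_min`` is dropped. Returns
    (kept subject ids, report DataFrame with per-subject r and kept flag).
    """
    reference = np.asarray(reference, dtype=np.float64).ravel()
    rows = []
    kept = []
    for subject, values in modes.items():
        r, _ = spatial_correlation(values, reference)
        keep = r > r_min
        rows.append({"subject": subject, "r": r, "kept": keep})
        if keep:
            kept.append(subject)
    report = pd.DataFrame(rows)
    logger.info("quality filter r > %.3g: kept %d / %d subjects",
                r_min, len(kept), len(rows))
    return kept, report


def _icc_2k(M: np.ndarray) -> float:
    """ICC(2,k): two-way random effects, absolute agreement, average measures.

    From the two-way ANOVA decomposition of a subjects x sessions matrix:
    ICC(2,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n).
    """
    n, k = M.shape
    grand = M.mean()
    row_m = M.mean(axis=1)
    col_m = M.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_err = np.sum((M - row_m[:, None] - col_m[None, :] + grand) ** 2)
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (ms_c - ms_e) / n
    if denom == 0:
        raise ValueError("degenerate variance: MS_R = MS_E = 0")
    return float((ms_r - ms_e) / denom)


def icc_2k(measure_matrix: np.ndarray, n_boot: int = 1000,
           seed: int = 0) -> ReliabilityResult:
    """ICC(2,k) with a nonparametric percentile bootstrap CI over subjects."""
    M = np.asarray(measure_matrix, dtype=np.float64)
    if M.ndim != 2 or M.shape[1] < 2 or M.shape[0] < 3:
        raise ValueError("need a subjects x sessions matrix, >=3 x >=2")
    if not np.all(np.isfinite(M)):
        raise ValueError("measure matrix must be complete")
    icc = _icc_2k(M)
    rng = np.random.default_rng(seed)
    boots = []
    n = M.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            boots.append(_icc_2k(M[idx]))
        except ValueError:
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = icc
    return ReliabilityResult(icc=icc, ci_low=float(min(lo, icc)),
                             ci_high=float(max(hi, icc)), n_boot=n_boot)


def within_between_permutation(modes_s1: np.ndarray, modes_s2: np.ndarray,
                               n_perm: int = 10000,
                               seed: int = 0) -> ReliabilityResult:
    """Within- vs between-subject mode correlation with a permutation test.

    within_r: mean over subjects of r(subject i session 1, subject i
    session 2); between_r: mean over ordered pairs i != j. The null permutes
    the session-2 subject labels and recomputes within_r - between_r; the
    p-value uses the add-one estimator (1 + #{perm >= obs}) / (1 + n_perm).
    """
    S1 = np.asarray(modes_s1, dtype=np.float64)
    S2 = np.asarray(modes_s2, dtype=np.float64)
    if S1.shape != S2.shape:
        raise ValueError("session matrices must match (subjects x voxels)")
    n = S1.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    Z1 = (S1 - S1.mean(axis=1, keepdims=True))
    Z1 /= np.linalg.norm(Z1, axis=1, keepdims=True)
    Z2 = (S2 - S2.mean(axis=1, keepdims=True))
    Z2 /= np.linalg.norm(Z2, axis=1, keepdims=True)
    R = Z1 @ Z2.T  # R[i, j] = r(subject i s1, subject j s2)

    def statistic(perm):
        Rp = R[:, perm]
        within = np.trace(Rp) / n
        between = (Rp.sum() - np.trace(Rp)) / (n * (n - 1))
        return within - between, within, between

    obs, within_r, between_r = statistic(np.arange(n))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        stat, _, _ = statistic(rng.permutation(n))
        if stat >= obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return ReliabilityResult(within_r=float(within_r),
                             between_r=float(between_r),
                             perm_p=float(p), n_perm=n_perm)


def _design(coeffs: pd.DataFrame, beta_cols, covariates,
            standardize: bool = False) -> np.ndarray:
    cols = list(beta_cols) + list(covariates or [])
    X = coeffs[cols].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("missing or non-finite coefficient entries")
    if standardize:
        # LR statistics are invariant to affine predictor rescaling; fitting
        # on z-scored columns keeps the optimizer and the separation
        # diagnostic scale-free
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return X


def omnibus_lr_binary(coeffs: pd.DataFrame, group_col: str = "group",
                      beta_cols=None, covariates=None,
                      bartlett_correction: bool = True) -> OmnibusResult:
    """Omnibus LR test: logistic regression of group on all coefficients.

    Full model: group ~ beta (+ covariates); null: intercept (+ covariates).
    X^2 = ((n - p) / n) * 2 (ll_full - ll_null), df = number of beta columns,
    where p is the full model's parameter count; the Bartlett-type scaling
    keeps the chi-square reference calibrated at small n (the uncorrected
    statistic is available via ``bartlett_correction=False``). Perfect
    separation is detected (diverging coefficients) and flagged.
    """
    if beta_cols is None:
        beta_cols = [c for c in coeffs.columns if c.startswith("b")]
    labels = coeffs[group_col]
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, found {uniq}")
    y = (labels == uniq[1]).to_numpy(dtype=np.float64)
    df = len(beta_cols)
    n = len(y)
    if min((y == 0).sum(), (y == 1).sum()) < df + 5:
        warnings.warn("fewer than df + 5 subjects in a group; "
                      "likelihood-ratio asymptotics may be poor")
    X_full = sm.add_constant(_design(coeffs, beta_cols, covariates,
                                     standardize=True))
    X_null = (sm.add_constant(_design(coeffs, [], covariates,
                                      standardize=True))
              if covariates else np.ones((n, 1)))
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = sm.Logit(y, X_full).fit(disp=0, maxiter=200)
            null = sm.Logit(y, X_null).fit(disp=0, maxiter=200)
            if not full.mle_retvals.get("converged", True) or \
                    np.max(np.abs(full.params)) > 50:
                separation = True
        except Exception:  # statsmodels raises on exact separation
            separation = True
            full = sm.Logit(y, X_full).fit_regularized(disp=0, alpha=1e-4)
            null = sm.Logit(y, X_null).fit(disp=0, maxiter=200)
    p_full = X_full.shape[1]
    scale = (n - p_full) / n if bartlett_correction else 1.0
    x2 = max(0.0, scale * 2.0 * (full.llf - null.llf))
    p = float(stats.chi2.sf(x2, df))
    if separation:
        logger.warning("perfect separation detected; omnibus result flagged")
    return OmnibusResult(statistic=float(x2), df=df, p_value=max(p, 1e-300),
                         model_full=f"logit(group ~ {'+'.join(beta_cols)})",
                         model_null="logit(group ~ 1)", n=n,
                         separation_flag=separation)


def omnibus_lr_continuous(coeffs: pd.DataFrame, outcome_col: str = "outcome",
                          beta_cols=None, covariates=None,
                          bartlett_correction: bool = True) -> OmnibusResult:
    """Omnibus LR test: Gaussian GLM of a continuous outcome on coefficients.

    X^2 = (n - p) log(RSS_null / RSS_full), df = number of beta columns,
    p from the chi-square distribution; p is the full model's parameter
    count (the classic degrees-of-freedom correction of the Gaussian LR —
    the raw n-scaled statistic is anti-conservative at small n and is
    available via ``bartlett_correction=False``). The exact F test is
    equivalent and available through statsmodels directly.
    """
    if beta_cols is None:
        beta_cols = [c for c in coeffs.columns if c.startswith("b")]
    y = coeffs[outcome_col].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise ValueError("outcome contains missing values")
    if np.std(y) == 0:
        raise ValueError("zero-variance outcome")
    n = len(y)
    df = len(beta_cols)
    X_full = sm.add_constant(_design(coeffs, beta_cols, covariates))
    X_null = (sm.add_constant(_design(coeffs, [], covariates))
              if covariates else np.ones((n, 1)))
    rss_full = sm.OLS(y, X_full).fit().ssr
    rss_null = sm.OLS(y, X_null).fit().ssr
    scale = (n - X_full.shape[1]) if bartlett_correction else n
    x2 = max(0.0, scale * np.log(rss_null / rss_full))
    p = float(stats.chi2.sf(x2, df))
    return OmnibusResult(statistic=float(x2), df=df, p_value=max(p, 1e-300),
                         model_full=f"ols({outcome_col} ~ {'+'.join(beta_cols)})",
                         model_null=f"ols({outcome_col} ~ 1)", n=n)


def change_score_analysis(coeffs_a: pd.DataFrame, coeffs_b: pd.DataFrame,
                          outcome_col: str = "outcome",
                          beta_cols=None) -> OmnibusResult:
    """Paired change-score omnibus: Δbeta and Δoutcome with Δ = B − A.

    Rows are paired on the ``subject`` column; an unpaired subject is an
    error. Delegates to :func:`omnibus_lr_continuous` on the differences.
    """
    if beta_cols is None:
        beta_cols = [c for c in coeffs_a.columns if c.startswith("b")]
    a = coeffs_a.set_index("subject")
    b = coeffs_b.set_index("subject")
    if set(a.index) != set(b.index):
        missing = set(a.index) ^ set(b.index)
        raise ValueError(f"unpaired subject(s): {sorted(missing)}")
    b = b.loc[a.index]
    delta = b[list(beta_cols) + [outcome_col]] - a[list(beta_cols) + [outcome_col]]
    delta = delta.reset_index()
    return omnibus_lr_continuous(delta, outcome_col=outcome_col,
                                 beta_cols=beta_cols)


def posthoc_pearson(coeffs: pd.DataFrame, outcome_col: str = "outcome",
                    beta_cols=None) -> pd.DataFrame:
    """Per-coefficient Pearson correlations with the outcome (uncorrected).

    Deliberately uncorrected: these are post-hoc descriptives run only after
    a significant omnibus test, to show which coefficients drive the effect.
    """
    if beta_cols is None:
        beta_cols = [c for c in coeffs.columns if c.startswith("b")]
    y = coeffs[outcome_col].to_numpy(dtype=np.float64)
    rows = []
    for c in beta_cols:
        x = coeffs[c].to_numpy(dtype=np.float64)
        if np.std(x) == 0:
            raise ValueError(f"constant coefficient column {c}")
        r, p = _pearson(x, y)
        rows.append({"coefficient": c, "r": r, "p": p})
    return pd.DataFrame(rows)


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test alpha level: alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
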