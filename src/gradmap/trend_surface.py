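"""Trend surface models: polynomial spatial summaries of connectivity modes.

A connectivity mode (one scalar per ROI voxel) is regressed on a polynomial
basis of the voxels' world coordinates — powers x^1..x^d, y^1..y^d, z^1..z^d
of per-axis normalized coordinates, so a degree-d model has exactly 3·d
coefficients (no intercept: the mode's mean is absorbed by centring; no
cross-terms). The fit is a Bayesian linear regression with an isotropic
Gaussian prior (precision alpha) and Gaussian noise (precision lam); the two
hyperparameters are set by empirical Bayes, i.e. by maximizing the closed-form
log marginal likelihood (evidence) with a gradient-based optimizer. The
reported coefficient vector is the posterior mean, which at the optimum
equals the ridge solution with penalty alpha/lam.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialBasis",
    "TrendSurfaceFit",
    "DegreeSelection",
    "build_basis",
    "fit_blr",
    "variance_explained",
    "select_degree",
    "reconstruct_surface",
]

DEGREE_CANDIDATES = (2, 3, 4, 5)


@dataclass
class SpatialBasis:
    """Polynomial design matrix over normalized world coordinates.

    ``normalization`` stores the per-axis (offset, scale) of the affine map
    onto [-1, 1]; it must be computed once per ROI mask so that coefficient
    vectors are comparable across subjects sharing that ROI.
    """

    degree: int
    design: np.ndarray  # V x 3d
    normalization: np.ndarray  # 3 x 2 rows of (offset, scale)
    condition_number: float = field(init=False)

    def __post_init__(self) -> None:
        self.condition_number = float(np.linalg.cond(self.design))

    @property
    def n_coefficients(self) -> int:
        return 3 * self.degree


@dataclass
class TrendSurfaceFit:
    degree: int
    beta: np.ndarray  # 3d MAP coefficients
    noise_variance: float  # 1 / lam
    weight_variance: float  # 1 / alpha
    log_evidence: float
    variance_explained: float
    y_mean: float  # stored centring offset
    design_means: np.ndarray | None = None  # column means removed before fitting


@dataclass
class DegreeSelection:
    candidates: tuple
    scores: dict  # degree -> score
    chosen: int
    criterion: str


def build_basis(world_coords: np.ndarray, degree: int,
                normalization: np.ndarray | None = None) -> SpatialBasis:
    """Build the V x 3·degree polynomial design for an ROI.

    Coordinates are affinely mapped per axis onto [-1, 1] before powering
    (raw mm coordinates to the 4th or 5th power are catastrophically
    ill-conditioned). Pass a precomputed ``normalization`` to reuse the map
    of a reference ROI mask.
    """
    coords = np.asarray(world_coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("world_coords must be V x 3")
    if degree not in (2, 3, 4, 5):
        raise ValueError(f"degree must be in 2..5, got {degree}")
    V = coords.shape[0]
    if V <= 3 * degree:
        raise ValueError(f"need more than {3 * degree} voxels for degree {degree}")
    if normalization is None:
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        span = hi - lo
        degenerate = span <= 0
        if np.any(degenerate):
            ax = "xyz"[int(np.nonzero(degenerate)[0][0])]
            raise ValueError(f"degenerate axis '{ax}': all coordinates equal")
        normalization = np.c_[-(lo + hi) / span, 2.0 / span]  # u = off + scale * x
    else:
        normalization = np.asarray(normalization, dtype=np.float64)
    u = normalization[:, 0] + coords * normalization[:, 1]
    cols = [u[:, ax] ** p for ax in range(3) for p in range(1, degree + 1)]
    design = np.column_stack(cols)
    if not np.all(np.isfinite(design)):
        raise ValueError("non-finite design entries")
    return SpatialBasis(degree=degree, design=design, normalization=normalization)


def _evidence_and_grad(theta: np.ndarray, lam_eig: np.ndarray, b: np.ndarray,
                       yty: float, n: int):
    """Negative log evidence and gradient in (log alpha, log lam_noise).

    Uses the eigendecomposition X'X = Q diag(lam_eig) Q', b = Q' X' y, so each
    evaluation is O(M).
    """
    alpha, lam = np.exp(theta)
    m = b.shape[0]
    denom = alpha + lam * lam_eig
    mt = lam * b / denom  # posterior mean in rotated coordinates
    r2 = yty - 2.0 * mt @ b + mt @ (lam_eig * mt)  # ||y - X m||^2
    m2 = mt @ mt
    log_ev = 0.5 * (m * np.log(alpha) + n * np.log(lam) - lam * r2 - alpha * m2
                    - np.sum(np.log(denom)) - n * np.log(2.0 * np.pi))
    # envelope theorem: dE/dm = 0 at the posterior mean
    d_alpha = 0.5 * (m / alpha - m2 - np.sum(1.0 / denom))
    d_lam = 0.5 * (n / lam - r2 - np.sum(lam_eig / denom))
    grad = -np.array([alpha * d_alpha, lam * d_lam])
    return -log_ev, grad


def fit_blr(basis: SpatialBasis, y: np.ndarray,
            hyperparameters: tuple[float, float] | None = None,
            max_iter: int = 200) -> TrendSurfaceFit:
    """Fit the trend surface by empirical-Bayes Bayesian linear regression.

    ``y`` is centred internally (mean stored). When ``hyperparameters``
    (alpha, lam) are given they are held fixed and the posterior mean — the
    ridge solution with penalty alpha/lam — is returned directly; otherwise
    (alpha, lam) maximize the log marginal likelihood, optimized over
    (log alpha, log lam) by L-BFGS with analytic gradients from several
    documented starting points.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    if y.shape[0] != basis.design.shape[0]:
        raise ValueError("y length does not match design")
    # centre y and the design columns: the intercept is handled entirely by
    # the stored means (even powers of the coordinates have nonzero mean)
    design_means = basis.design.mean(axis=0)
    X = basis.design - design_means
    y_mean = float(y.mean())
    yc = y - y_mean
    n = y.shape[0]

    XtX = X.T @ X
    lam_eig, Q = scipy.linalg.eigh(XtX)
    lam_eig = np.clip(lam_eig, 0.0, None)
    b = Q.T @ (X.T @ yc)
    yty = float(yc @ yc)

    if hyperparameters is not None:
        alpha, lam = hyperparameters
        if alpha <= 0 or lam <= 0:
            raise ValueError("hyperparameters must be positive")
    else:
        y_var = max(yty / n, 1e-12)
        starts = [(1.0, 1.0 / y_var), (1e-2, 1.0 / y_var),
                  (1e2, 1.0 / y_var), (1.0, 1e2 / y_var)]
        best = None
        for a0, l0 in starts:
            res = minimize(_evidence_and_grad, np.log([a0, l0]), jac=True,
                           args=(lam_eig, b, yty, n), method="L-BFGS-B",
                           bounds=[(-30.0, 30.0)] * 2,
                           options={"maxiter": max_iter})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.all(np.isfinite(best.x)):
            raise RuntimeError(
                f"evidence optimization failed to converge after {max_iter} "
                f"iterations (last evidence {-best.fun if best else np.nan:.6g})")
        alpha, lam = np.exp(best.x)

    neg_ev, _ = _evidence_and_grad(np.log([alpha, lam]), lam_eig, b, yty, n)
    denom = alpha + lam * lam_eig
    beta = Q @ (lam * b / denom)  # posterior mean = MAP

    resid = yc - X @ beta
    ss_tot = yty
    ve = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    return TrendSurfaceFit(degree=basis.degree, beta=beta,
                           noise_variance=1.0 / lam, weight_variance=1.0 / alpha,
                           log_evidence=-float(neg_ev),
                           variance_explained=ve, y_mean=y_mean,
                           design_means=design_means)


def log_evidence_at(basis: SpatialBasis, y: np.ndarray,
                    alpha: float, lam: float) -> float:
    """Log marginal likelihood at fixed hyperparameters (for diagnostics)."""
    X = basis.design - basis.design.mean(axis=0)
    yc = np.asarray(y, dtype=np.float64).ravel()
    yc = yc - yc.mean()
    lam_eig, Q = scipy.linalg.eigh(X.T @ X)
    lam_eig = np.clip(lam_eig, 0.0, None)
    b = Q.T @ (X.T @ yc)
    neg_ev, _ = _evidence_and_grad(np.log([alpha, lam]), lam_eig, b,
                                   float(yc @ yc), yc.shape[0])
    return -float(neg_ev)


def variance_explained(fit: TrendSurfaceFit, basis: SpatialBasis,
                       y: np.ndarray, clamp: bool = False) -> float:
    """Fraction of variance explained: 1 − Σ(y−ŷ)² / Σ(y−ȳ)².

    Can be negative for a mis-specified forced degree; ``clamp`` truncates
    reporting at 0 (documented — the unclamped value is always computable).
    """
    if fit.degree != basis.degree:
        raise ValueError("fit/basis degree mismatch")
    y = np.asarray(y, dtype=np.float64).ravel()
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("zero-variance y")
    yhat = reconstruct_surface(fit, basis)
    ve = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    return max(ve, 0.0) if clamp else ve


def reconstruct_surface(fit: TrendSurfaceFit, basis: SpatialBasis) -> np.ndarray:
    """Evaluate the fitted surface on the basis voxels: design·β + stored mean."""
    if fit.degree != basis.degree:
        raise ValueError("fit/basis degree mismatch")
    mu = fit.design_means if fit.design_means is not None else 0.0
    return (basis.design - mu) @ fit.beta + fit.y_mean


def select_degree(world_coords: np.ndarray, y: np.ndarray,
                  candidates: tuple = DEGREE_CANDIDATES,
                  criterion: str = "scree", tau: float = 0.05) -> DegreeSelection:
    """Choose the polynomial degree by scree analysis of per-degree scores.

    Scores are the variance explained of the empirical-Bayes fit at each
    candidate degree. The elbow is operationalized as the largest degree whose
    relative score gain over the previous candidate exceeds ``tau``; if no
    gain exceeds ``tau`` the smallest candidate is chosen (logged).
    With ``criterion='evidence'`` the degree maximizing log evidence is
    chosen instead.
    """
    candidates = tuple(sorted(candidates))
    scores: dict[int, float] = {}
    evidences: dict[int, float] = {}
    for d in candidates:
        basis = build_basis(world_coords, d)
        fit = fit_blr(basis, y)
        scores[d] = fit.variance_explained
        evidences[d] = fit.log_evidence
    if criterion == "evidence":
        chosen = max(candidates, key=lambda d: evidences[d])
        return DegreeSelection(candidates=candidates, scores=evidences,
                               chosen=chosen, criterion="evidence")
    if criterion != "scree":
        raise ValueError(f"unknown criterion '{criterion}'")
    chosen = None
    for prev, d in zip(candidates[:-1], candidates[1:]):
        gain = (scores[d] - scores[prev]) / max(abs(scores[prev]), 0.05)
        if gain > tau:
            chosen = d
    if chosen is None:
        chosen = candidates[0]
        logger.info("no scree elbow above tau=%.3g; choosing smallest degree %d",
                    tau, chosen)
    return DegreeSelection(candidates=candidates, scores=scores,
                           chosen=chosen, criterion="scree")
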