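"""Connectopic mapping: from voxel time series to ordered connectivity modes.

The pipeline decomposes an ROI's voxel-wise whole-brain functional
connectivity into spatial modes:

1. the reference (non-ROI) time-series matrix B is losslessly reduced by a
   singular value decomposition, giving an orthonormal temporal basis;
2. each ROI voxel's connectivity fingerprint is its vector of Pearson
   correlations with those temporal components;
3. pairwise fingerprint similarity is quantified with the η² coefficient;
4. Laplacian eigenmaps applied to the similarity graph yield connectivity
   modes — eigenvectors of L v = λ D v ordered by eigenvalue, each varying
   smoothly over voxels with similar connectivity.

Mode order 0 denotes the first nontrivial eigenvector (the trivial constant
vector at λ≈0 is discarded), so the field's "second-order mode" is the third
nontrivial eigenvector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.stats import pearsonr

from .imaging_io import BoldSeries, RoiSpec, extract_timeseries

logger = logging.getLogger(__name__)

__all__ = [
    "ReducedReference",
    "ConnectivityMode",
    "reduce_reference",
    "compute_fingerprints",
    "eta2_similarity",
    "laplacian_eigenmaps",
    "align_mode",
    "group_similarity",
    "map_subject",
]


@dataclass
class ReducedReference:
    """Orthonormal temporal basis of the reference matrix B (economy SVD)."""

    components: np.ndarray  # t x r, orthonormal columns (left singular vectors)
    singular_values: np.ndarray  # r

    @property
    def rank(self) -> int:
        return self.components.shape[1]


@dataclass
class ConnectivityMode:
    """One connectivity mode: a per-voxel map with its eigenvalue.

    ``order`` counts nontrivial eigenvectors from 0. ``values`` has zero
    D-weighted mean and unit Euclidean norm; ``aligned_to`` records the
    reference the sign was matched against (None before alignment).
    """

    order: int
    values: np.ndarray
    eigenvalue: float
    aligned_to: str | None = None


def reduce_reference(B: np.ndarray) -> ReducedReference:
    """Lossless SVD reduction of the reference matrix B (t x W, demeaned).

    Retains components up to the numerical rank (singular values above
    ``max(t, W) * eps * sigma_1``). Projecting B onto the retained left
    singular vectors preserves all of its column-space information, which is
    all the Pearson-correlation fingerprints depend on.
    """
    B = np.asarray(B, dtype=np.float64)
    if not np.any(B):
        raise ValueError("reference matrix is all zeros")
    U, s, _ = scipy.linalg.svd(B, full_matrices=False)
    tol = max(B.shape) * np.finfo(np.float64).eps * s[0]
    r = int(np.sum(s > tol))
    return ReducedReference(components=U[:, :r], singular_values=s[:r])


def compute_fingerprints(A: np.ndarray, ref: ReducedReference) -> np.ndarray:
    """Connectivity fingerprints C (V x r): Pearson correlation of each ROI
    voxel's time series with each temporal component of the reduced reference.
    """
    A = np.asarray(A, dtype=np.float64)
    U = ref.components
    if A.shape[0] != U.shape[0]:
        raise ValueError("timepoint mismatch between A and reference")
    Ac = A - A.mean(axis=0, keepdims=True)
    Uc = U - U.mean(axis=0, keepdims=True)
    a_norm = np.sqrt(np.einsum("tv,tv->v", Ac, Ac))
    u_norm = np.sqrt(np.einsum("tr,tr->r", Uc, Uc))
    if np.any(a_norm <= 0):
        raise ValueError("zero-variance ROI column")
    if np.any(u_norm <= 0):
        raise ValueError("zero-variance reference component")
    C = (Ac / a_norm).T @ (Uc / u_norm)
    return np.clip(C, -1.0, 1.0)


def eta2_similarity(C: np.ndarray) -> np.ndarray:
    """η² similarity between every pair of fingerprint rows of C (V x r).

    For fingerprints x, y with per-position means m_j = (x_j + y_j)/2 and
    grand mean M over all entries of both vectors:

        η² = 1 − Σ_j [(x_j − m_j)² + (y_j − m_j)²]
                 / Σ_j [(x_j − M)²  + (y_j − M)²]

    η² = 1 for identical profiles and 0 when all within-pair variance equals
    the total variance. A pair of identical constant profiles (denominator 0)
    is defined as similarity 1, with a warning.
    """
    C = np.asarray(C, dtype=np.float64)
    V, r = C.shape
    if V < 2 or r < 2:
        raise ValueError("need at least 2 voxels and 2 fingerprint entries")
    # numerator_ab = ||x - y||^2 / 2
    sq = np.einsum("vr,vr->v", C, C)
    G = C @ C.T
    num = 0.5 * (sq[:, None] + sq[None, :] - 2.0 * G)
    # denominator_ab = ||x||^2 + ||y||^2 - (sum(x) + sum(y))^2 / (2 r)
    rs = C.sum(axis=1)
    den = sq[:, None] + sq[None, :] - (rs[:, None] + rs[None, :]) ** 2 / (2.0 * r)
    degenerate = den <= 0
    if np.any(degenerate & (num > 1e-24)):
        raise ValueError("negative total variance: inconsistent fingerprints")
    if np.any(degenerate):
        logger.warning("constant identical fingerprint pair(s); similarity set to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        S = 1.0 - num / den
    S[degenerate] = 1.0
    S = np.clip(S, 0.0, 1.0)
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 1.0)
    return S


def _sign_convention(v: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Deterministic sign: first entry with |v| > tol is made positive."""
    nz = np.nonzero(np.abs(v) > tol)[0]
    if nz.size and v[nz[0]] < 0:
        return -v
    return v


def laplacian_eigenmaps(S: np.ndarray, n_modes: int,
                        knn: int | None = None) -> list[ConnectivityMode]:
    """Solve the generalized eigenproblem L v = λ D v on the similarity graph.

    The weight matrix is S with a zeroed diagonal (optionally sparsified to a
    symmetrized k-nearest-neighbour graph when ``knn`` is given); D is the
    degree matrix and L = D − W. The trivial constant eigenvector at λ ≈ 0 is
    discarded and the next ``n_modes`` eigenvectors are returned in ascending
    eigenvalue order, each with zero D-weighted mean, unit Euclidean norm and
    a deterministic sign convention.
    """
    S = np.asarray(S, dtype=np.float64)
    V = S.shape[0]
    if S.shape != (V, V):
        raise ValueError("similarity matrix must be square")
    if n_modes >= V:
        raise ValueError(f"n_modes={n_modes} must be < number of voxels {V}")
    W = S.copy()
    np.fill_diagonal(W, 0.0)
    if knn is not None:
        keep = np.zeros_like(W, dtype=bool)
        order = np.argsort(-W, axis=1)[:, :knn]
        rows = np.repeat(np.arange(V), knn)
        keep[rows, order.ravel()] = True
        keep |= keep.T  # symmetrize by max: keep an edge if either endpoint keeps it
        W = np.where(keep, W, 0.0)

    n_comp, labels = connected_components((W > 0).astype(np.int8), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"similarity graph is disconnected: {n_comp} components "
            f"with sizes {sizes.tolist()}")

    d = W.sum(axis=1)
    L = np.diag(d) - W
    eigvals, eigvecs = scipy.linalg.eigh(L, np.diag(d))
    # eigh returns ascending eigenvalues; index 0 is the trivial constant mode
    if eigvals[0] > 1e-8 * max(1.0, abs(eigvals[-1])):
        logger.warning("trivial eigenvalue unexpectedly large: %g", eigvals[0])
    modes = []
    for order_idx in range(n_modes):
        v = eigvecs[:, order_idx + 1]
        v = v - (d @ v) / d.sum()  # zero D-weighted mean (numerical cleanup)
        v = v / np.linalg.norm(v)
        v = _sign_convention(v)
        modes.append(ConnectivityMode(order=order_idx, values=v,
                                      eigenvalue=float(eigvals[order_idx + 1])))
    return modes


def align_mode(mode: ConnectivityMode, reference: ConnectivityMode,
               reference_id: str = "group") -> ConnectivityMode:
    """Sign-align a mode to a reference: negate iff Pearson r < 0."""
    if mode.values.shape != reference.values.shape:
        raise ValueError("mode/reference length mismatch")
    if np.std(mode.values) == 0 or np.std(reference.values) == 0:
        raise ValueError("zero-variance mode cannot be aligned")
    r = pearsonr(mode.values, reference.values)[0]
    values = -mode.values if r < 0 else mode.values.copy()
    return ConnectivityMode(order=mode.order, values=values,
                            eigenvalue=mode.eigenvalue, aligned_to=reference_id)


def group_similarity(matrices: list[np.ndarray]) -> np.ndarray:
    """Group-level similarity: element-wise mean of per-subject η² matrices."""
    if not matrices:
        raise ValueError("no similarity matrices given")
    shape = matrices[0].shape
    for m in matrices:
        if m.shape != shape:
            raise ValueError("similarity matrix size mismatch")
    return np.mean(np.stack(matrices), axis=0)


def map_subject(bold: BoldSeries, roi: RoiSpec, brain_mask: np.ndarray,
                n_modes: int, knn: int | None = None,
                return_similarity: bool = False):
    """Full subject-level mapping: extract → reduce → fingerprints → η² → eigenmaps.

    Returns the list of connectivity modes (and optionally the similarity
    matrix, for group-level averaging).
    """
    pair = extract_timeseries(bold, roi, brain_mask)
    ref = reduce_reference(pair.B)
    logger.debug("reference rank %d (t=%d, W=%d)", ref.rank, *pair.B.shape)
    C = compute_fingerprints(pair.A, ref)
    S = eta2_similarity(C)
    modes = laplacian_eigenmaps(S, n_modes, knn=knn)
    if return_similarity:
        return modes, S
    return modes
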