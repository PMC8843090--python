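"""Volumetric image I/O and the voxel-ordering conventions of the pipeline.

All spatial products downstream of this module (connectivity fingerprints,
similarity matrices, connectivity modes, trend-surface designs) index ROI
voxels identically: by the lexicographic order of their 0-based (i, j, k)
indices recorded in :class:`RoiSpec`. World coordinates in mm are obtained
through the image affine; nothing depends on the specific template frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BoldSeries",
    "RoiSpec",
    "TimeseriesPair",
    "DensityMap",
    "load_volume",
    "make_roi",
    "extract_timeseries",
    "save_mode_map",
    "normalize_density",
]


@dataclass
class BoldSeries:
    """A 4D BOLD image: ``data[x, y, z, t]`` with a voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BoldSeries requires 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("BoldSeries requires at least 2 timepoints")
        if not np.all(np.isfinite(self.data)):
            n_bad = int(np.sum(~np.isfinite(self.data)))
            raise ValueError(f"non-finite values in BOLD data ({n_bad} voxels)")
        _check_affine(self.affine)
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class DensityMap:
    """A 3D scalar map (e.g. SPECT-like uptake) on the same kind of grid."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"DensityMap requires 3D data, got {self.data.ndim}D")
        _check_affine(self.affine)


@dataclass
class RoiSpec:
    """A named ROI: binary mask, fixed voxel ordering and world coordinates.

    ``voxel_index_list`` is the single source of truth for per-voxel products:
    row v of any fingerprint/similarity/mode array refers to voxel
    ``voxel_index_list[v]``. The order is lexicographic in (i, j, k).
    """

    name: str
    mask: np.ndarray
    voxel_index_list: np.ndarray  # V x 3 int array
    world_coords: np.ndarray  # V x 3 float array, mm

    n_voxels: int = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.voxel_index_list = np.asarray(self.voxel_index_list, dtype=np.intp)
        self.world_coords = np.asarray(self.world_coords, dtype=np.float64)
        self.n_voxels = self.voxel_index_list.shape[0]
        if self.world_coords.shape != (self.n_voxels, 3):
            raise ValueError("world_coords must be V x 3")


@dataclass
class TimeseriesPair:
    """Demeaned ROI (A: t x V) and reference (B: t x W) time-series matrices."""

    A: np.ndarray
    B: np.ndarray
    brain_mask: np.ndarray
    n_dropped_reference: int = 0


def _check_affine(affine: np.ndarray) -> None:
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is not invertible")


def load_volume(path, expect_4d: bool = False):
    """Load a NIfTI image as a :class:`BoldSeries` (4D) or :class:`DensityMap` (3D).

    No resampling is performed; the stored affine is passed through.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    affine = np.asarray(img.affine, dtype=np.float64)
    if expect_4d:
        if data.ndim != 4:
            raise ValueError(f"expected 4D image, got {data.ndim}D: {path}")
        return BoldSeries(data=data, affine=affine)
    if data.ndim == 4:
        return BoldSeries(data=data, affine=affine)
    if data.ndim != 3:
        raise ValueError(f"expected 3D or 4D image, got {data.ndim}D: {path}")
    if not np.all(np.isfinite(data)):
        n_bad = int(np.sum(~np.isfinite(data)))
        raise ValueError(f"non-finite values in volume ({n_bad} voxels): {path}")
    return DensityMap(data=data, affine=affine)


def make_roi(mask_volume, threshold: float = 0.0, name: str = "roi",
             affine: np.ndarray | None = None) -> RoiSpec:
    """Threshold a (probabilistic) mask volume into an ordered ROI.

    A voxel is included iff its value exceeds ``threshold * max(volume)``
    (strict inequality). Voxels are ordered lexicographically by (i, j, k).
    ``mask_volume`` may be a :class:`DensityMap` or a raw 3D array plus
    ``affine``.
    """
    if isinstance(mask_volume, DensityMap):
        data, aff = mask_volume.data, mask_volume.affine
    else:
        data = np.asarray(mask_volume, dtype=np.float64)
        if affine is None:
            raise ValueError("affine required when mask_volume is a raw array")
        aff = np.asarray(affine, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError("mask volume must be 3D")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    vmax = data.max()
    mask = data > threshold * vmax if vmax > 0 else np.zeros(data.shape, bool)
    idx = np.argwhere(mask)  # argwhere is already lexicographic in (i, j, k)
    if idx.shape[0] == 0:
        raise ValueError(f"empty ROI '{name}' after thresholding at {threshold}")
    homog = np.c_[idx, np.ones(len(idx))]
    world = (aff @ homog.T).T[:, :3]
    return RoiSpec(name=name, mask=mask, voxel_index_list=idx, world_coords=world)


def extract_timeseries(bold: BoldSeries, roi: RoiSpec,
                       brain_mask: np.ndarray) -> TimeseriesPair:
    """Extract demeaned ROI (A) and non-ROI reference (B) time-series matrices.

    Columns of A follow ``roi.voxel_index_list`` order. Zero-variance columns
    of B are dropped (with a logged count); a zero-variance ROI voxel is fatal
    because every ROI voxel needs a connectivity fingerprint.
    """
    brain_mask = np.asarray(brain_mask).astype(bool)
    if brain_mask.shape != bold.grid_shape or roi.mask.shape != bold.grid_shape:
        raise ValueError("mask grid does not match BOLD grid")
    if np.any(roi.mask & ~brain_mask):
        raise ValueError("brain_mask must contain the ROI mask")

    i, j, k = roi.voxel_index_list.T
    A = bold.data[i, j, k, :].T.astype(np.float64)  # t x V

    ref_mask = brain_mask & ~roi.mask
    ri, rj, rk = np.nonzero(ref_mask)
    B = bold.data[ri, rj, rk, :].T.astype(np.float64)  # t x W

    A = A - A.mean(axis=0, keepdims=True)
    B = B - B.mean(axis=0, keepdims=True)

    a_var = np.einsum("tv,tv->v", A, A)
    if np.any(a_var <= 0):
        bad = int(np.sum(a_var <= 0))
        raise ValueError(f"{bad} ROI voxel(s) have zero temporal variance")
    b_var = np.einsum("tv,tv->v", B, B)
    keep = b_var > 0
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("dropped %d zero-variance reference voxels", n_dropped)
        B = B[:, keep]
    return TimeseriesPair(A=A, B=B, brain_mask=brain_mask,
                          n_dropped_reference=n_dropped)


def save_mode_map(values: np.ndarray, roi: RoiSpec, affine: np.ndarray,
                  path) -> None:
    """Write per-voxel mode values into a 32-bit float NIfTI volume.

    ROI voxels carry their mode value (in ``voxel_index_list`` order); all
    other voxels are zero.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.shape[0] != roi.n_voxels:
        raise ValueError(
            f"mode length {values.shape[0]} != ROI voxel count {roi.n_voxels}")
    vol = np.zeros(roi.mask.shape, dtype=np.float32)
    i, j, k = roi.voxel_index_list.T
    vol[i, j, k] = values
    nib.save(nib.Nifti1Image(vol, np.asarray(affine, dtype=np.float64)), str(path))


def normalize_density(density: DensityMap, brain_mask: np.ndarray) -> DensityMap:
    """Z-score a density map within a mask (affine intensity normalization).

    All downstream uses are Pearson correlations, which are invariant to
    affine rescaling, so within-mask standardization is sufficient.
    """
    brain_mask = np.asarray(brain_mask).astype(bool)
    if not brain_mask.any():
        raise ValueError("empty normalization mask")
    vals = density.data[brain_mask]
    sd = vals.std()
    if sd <= 0:
        raise ValueError("zero within-mask variance; cannot normalize")
    out = np.zeros_like(density.data)
    out[brain_mask] = (vals - vals.mean()) / sd
    return DensityMap(data=out, affine=density.affine.copy())
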