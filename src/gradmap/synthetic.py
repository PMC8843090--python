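"""Synthetic 4D phantoms with planted connectivity gradients.

The generator produces data with exactly the statistical structure the
mapping pipeline assumes, so that every downstream stage has a known ground
truth:

* each ROI carries one or more *planted gradients* — smooth, mutually
  orthogonal, unit-norm spatial fields built from low-order polynomials of
  world coordinates;
* a small set of "network" time courses (smoothed Gaussian noise) is shared
  by the whole brain; every non-ROI voxel carries one network's series plus
  white noise, and every ROI voxel carries a weighted mixture of networks
  whose weights vary smoothly with the voxel's planted-gradient values, so
  voxels close in gradient value have similar connectivity fingerprints —
  the property Laplacian eigenmaps recovers;
* cohorts add subject- and session-level gradient perturbations, a group
  shift expressed in trend-surface coefficient space, and linear
  coefficient→outcome couplings, all with per-subject RNG streams so that
  adding subjects never changes earlier subjects' data.

Everything is deterministic given the seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .imaging_io import BoldSeries, RoiSpec, make_roi
from .trend_surface import build_basis

__all__ = [
    "PhantomScene",
    "CohortDesign",
    "Cohort",
    "build_scene",
    "synthesize_bold",
    "derive_density_map",
    "simulate_cohort",
]

# decreasing influence of successive gradients on the fingerprints; the ratio
# must stay above 1/2 so the k-th eigenmap tracks the k-th planted gradient
# rather than a higher harmonic of an earlier one
_GRADIENT_SCALE_DECAY = 0.7


@dataclass
class PhantomScene:
    """Geometry + planted structure shared by all phantoms of one scenario."""

    grid_shape: tuple
    affine: np.ndarray
    brain_mask: np.ndarray
    roi_specs: list  # RoiSpec per blob
    planted_gradients: list  # per ROI: V x n_grad array, orthonormal columns
    anchors: list  # per ROI: n_networks x n_grad network anchor positions
    kernel_width: list  # per ROI: scalar bandwidth in gradient space
    network_assignment: np.ndarray  # network id per non-ROI brain voxel
    n_networks: int
    snr: float
    seed: int


@dataclass
class CohortDesign:
    """Study design for a simulated multi-subject, multi-session cohort.

    Perturbations and group effects are expressed in the orthonormalized
    trend-surface coefficient space of the target ROI (degree ``tsm_degree``)
    and mapped to voxel space through the basis, so ground-truth effect sizes
    for the omnibus tests are known exactly. ``group_effect`` is either a
    length-3·degree vector or a scalar magnitude applied along a fixed
    deterministic direction; ``outcome_coupling`` likewise.
    """

    n_subjects_per_group: tuple = (10, 10)
    n_sessions: int = 2
    within_subject_sd: float = 0.05
    between_subject_sd: float = 0.15
    group_effect: float | np.ndarray = 0.0
    outcome_coupling: float | np.ndarray = 0.0
    outcome_noise_sd: float = 1.0
    usage_coupling: float = 0.0
    tsm_degree: int = 2
    roi_index: int = 0
    target_gradient: int = 0
    n_timepoints: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions not in (1, 2):
            raise ValueError("n_sessions must be 1 or 2")
        if self.within_subject_sd < 0 or self.between_subject_sd < 0:
            raise ValueError("perturbation sds must be >= 0")


@dataclass
class Cohort:
    """A simulated cohort: phenotypes plus deterministic BOLD regeneration.

    Session images are regenerated on demand from stored seeds and
    perturbation fields rather than held in memory.
    """

    scene: PhantomScene
    design: CohortDesign
    phenotype: pd.DataFrame  # subject, session, group, outcome, usage_count
    true_coefficients: pd.DataFrame  # subject-level generating coefficients
    _session_fields: dict = field(repr=False, default_factory=dict)
    _session_seeds: dict = field(repr=False, default_factory=dict)

    @property
    def roi(self) -> RoiSpec:
        return self.scene.roi_specs[self.design.roi_index]

    def session_bold(self, subject: str, session: int) -> BoldSeries:
        perturb = self._session_fields[(subject, session)]  # dict per ROI
        seed = self._session_seeds[(subject, session)]
        bold, _ = synthesize_bold(self.scene, self.design.n_timepoints,
                                  session_perturbation=perturb, seed=seed)
        return bold


def _grid_affine(grid_shape, voxel_mm: float = 2.0) -> np.ndarray:
    aff = np.diag([voxel_mm] * 3 + [1.0])
    aff[:3, 3] = -voxel_mm * (np.asarray(grid_shape) - 1) / 2.0
    return aff


def _smooth_series(rng: np.random.Generator, t: int, k: int,
                   window: int = 5) -> np.ndarray:
    """k independent smooth unit-variance time courses (t x k)."""
    raw = rng.standard_normal((t + 2 * window, k))
    sm = uniform_filter1d(raw, size=window, axis=0)[window:window + t]
    sm = sm - sm.mean(axis=0)
    return sm / sm.std(axis=0)


def build_scene(grid_shape, n_roi_blobs: int = 1,
                gradient_degrees=(1,), n_networks: int = 12,
                snr: float = 5.0, seed: int = 0,
                roi_shape=None, voxel_mm: float = 2.0) -> PhantomScene:
    """Lay out non-overlapping box ROIs and plant orthonormal gradients.

    The k-th gradient of an ROI is a degree-``gradient_degrees[k]``
    polynomial of the normalized world coordinate along axis ``k mod 3``,
    centred, Gram-Schmidt-orthogonalized against the earlier gradients and
    unit-normalized. Network anchors are spread over the (scaled) gradient
    coordinate range so the mixing weights tile the manifold.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    n_grad = len(gradient_degrees)
    if n_networks < n_grad + 1:
        raise ValueError(
            f"n_networks={n_networks} must exceed the number of planted "
            f"gradients ({n_grad})")
    rng = np.random.default_rng(seed)
    affine = _grid_affine(grid_shape, voxel_mm)
    nx, ny, nz = grid_shape

    if roi_shape is None:
        bx = (nx - (n_roi_blobs + 1)) // n_roi_blobs
        roi_shape = (min(bx, max(4, nx // 2)), max(4, ny // 2), max(3, nz // 2))
    bx, by, bz = roi_shape
    if bx * n_roi_blobs + (n_roi_blobs + 1) > nx or by + 2 > ny or bz + 2 > nz:
        raise ValueError(f"{n_roi_blobs} blobs of shape {roi_shape} do not fit "
                         f"in grid {grid_shape}")

    brain_mask = np.ones(grid_shape, dtype=bool)
    roi_specs, gradients, anchors, widths = [], [], [], []
    for b in range(n_roi_blobs):
        x0 = 1 + b * (bx + 1)
        y0, z0 = (ny - by) // 2, (nz - bz) // 2
        vol = np.zeros(grid_shape)
        vol[x0:x0 + bx, y0:y0 + by, z0:z0 + bz] = 1.0
        roi = make_roi(vol, threshold=0.0, name=f"blob{b}", affine=affine)
        coords = roi.world_coords
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        u = 2.0 * (coords - lo) / span - 1.0  # per-axis normalized in [-1, 1]

        G = np.empty((roi.n_voxels, n_grad))
        for k, deg in enumerate(gradient_degrees):
            g = u[:, k % 3] ** int(deg)
            g = g - g.mean()
            for prev in range(k):
                g = g - (g @ G[:, prev]) * G[:, prev]
            nrm = np.linalg.norm(g)
            if nrm < 1e-10:
                raise ValueError(
                    f"planted gradient {k} (degree {deg}) is degenerate on "
                    f"this geometry")
            G[:, k] = g / nrm
        roi_specs.append(roi)
        gradients.append(G)

        scales = _GRADIENT_SCALE_DECAY ** np.arange(n_grad)
        pos = G * scales  # voxel positions in scaled gradient space
        lo_p, hi_p = pos.min(axis=0), pos.max(axis=0)
        if n_grad == 1:
            a = np.linspace(lo_p[0], hi_p[0], n_networks)[:, None]
        else:
            a = rng.uniform(lo_p, hi_p, size=(n_networks, n_grad))
        # bandwidth: half the mean per-dimension anchor range, so mixing
        # weights decay smoothly over the whole manifold and the similarity
        # matrix carries a global ordering (local-only decay distorts the
        # recovered modes at the gradient extremes)
        h = 0.5 * float(np.mean(hi_p - lo_p))
        anchors.append(a)
        widths.append(max(h, 1e-3))

    roi_union = np.zeros(grid_shape, dtype=bool)
    for roi in roi_specs:
        roi_union |= roi.mask
    n_ref = int(brain_mask.sum() - roi_union.sum())
    assignment = np.arange(n_ref) % n_networks
    return PhantomScene(grid_shape=grid_shape, affine=affine,
                        brain_mask=brain_mask, roi_specs=roi_specs,
                        planted_gradients=gradients, anchors=anchors,
                        kernel_width=widths, network_assignment=assignment,
                        n_networks=n_networks, snr=snr, seed=seed)


def _mixing_weights(scene: PhantomScene, roi_index: int,
                    gradient_values: np.ndarray) -> np.ndarray:
    """Gaussian-kernel mixture weights (V x K), rows summing to one."""
    scales = _GRADIENT_SCALE_DECAY ** np.arange(gradient_values.shape[1])
    pos = gradient_values * scales
    a = scene.anchors[roi_index]
    h = scene.kernel_width[roi_index]
    d2 = np.sum((pos[:, None, :] - a[None, :, :]) ** 2, axis=-1)
    w = np.exp(-d2 / (2.0 * h * h))
    return w / w.sum(axis=1, keepdims=True)


def synthesize_bold(scene: PhantomScene, t: int,
                    session_perturbation: np.ndarray | None = None,
                    seed: int = 0, roi_index: int = 0):
    """Render one 4D phantom: returns (BoldSeries, brain_mask).

    Non-ROI brain voxels carry their assigned network's time course plus
    white noise at the scene's SNR (signal sd / noise sd); ROI voxels carry
    the gradient-weighted network mixture plus noise. ``snr = 0`` yields pure
    noise everywhere. ``session_perturbation`` is added to planted gradient
    values before weights are computed: either a single array (V or
    V x n_grad) applied to ``roi_index``, or a dict mapping ROI index to
    such an array.
    """
    if t < 50:
        raise ValueError("need at least 50 timepoints")
    rng = np.random.default_rng(seed)
    nets = _smooth_series(rng, t, scene.n_networks)
    snr = scene.snr
    noise_sd = 0.0 if np.isinf(snr) else (1.0 / snr if snr > 0 else 1.0)
    signal_gain = 0.0 if snr == 0 else 1.0

    data = np.zeros(scene.grid_shape + (t,))
    roi_union = np.zeros(scene.grid_shape, dtype=bool)
    for roi in scene.roi_specs:
        roi_union |= roi.mask

    ref_idx = np.argwhere(scene.brain_mask & ~roi_union)
    ref_signal = nets[:, scene.network_assignment].T  # W x t
    ref_noise = rng.standard_normal(ref_signal.shape)
    ri, rj, rk = ref_idx.T
    data[ri, rj, rk, :] = signal_gain * ref_signal + noise_sd * ref_noise

    if session_perturbation is None:
        perturbations = {}
    elif isinstance(session_perturbation, dict):
        perturbations = session_perturbation
    else:
        perturbations = {roi_index: session_perturbation}

    for b, roi in enumerate(scene.roi_specs):
        g = scene.planted_gradients[b].copy()
        if b in perturbations:
            p = np.asarray(perturbations[b], dtype=np.float64)
            if p.ndim == 1:
                g[:, 0] = g[:, 0] + p
            else:
                g[:, :p.shape[1]] = g[:, :p.shape[1]] + p
        w = _mixing_weights(scene, b, g)
        sig = w @ nets.T  # V x t
        sig = sig - sig.mean(axis=1, keepdims=True)
        sd = sig.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        sig = sig / sd
        noise = rng.standard_normal(sig.shape)
        i, j, k = roi.voxel_index_list.T
        data[i, j, k, :] = signal_gain * sig + noise_sd * noise

    bold = BoldSeries(data=data, affine=scene.affine.copy(), tr_seconds=1.0)
    return bold, scene.brain_mask.copy()


def derive_density_map(scene: PhantomScene, roi_index: int = 0,
                       transform: str = "identity", gradient_index: int = 0,
                       slope: float = 1.0, intercept: float = 0.0):
    """A density map that is a monotone transform of a planted gradient.

    Emulates an external molecular-imaging reference map (e.g. transporter
    density) whose spatial profile follows the same underlying organization
    as a connectivity mode. Density is 0 outside the ROI.
    """
    from .imaging_io import DensityMap

    roi = scene.roi_specs[roi_index]
    g = scene.planted_gradients[roi_index][:, gradient_index]
    z = g / g.std()  # unit-sd values so the logistic is exercised sensibly
    if transform == "identity":
        vals = z
    elif transform == "affine":
        vals = slope * z + intercept
    elif transform == "logistic":
        vals = 1.0 / (1.0 + np.exp(-slope * z))
    else:
        raise ValueError(f"unknown transform '{transform}'")
    vol = np.zeros(scene.grid_shape)
    i, j, k = roi.voxel_index_list.T
    vol[i, j, k] = vals
    return DensityMap(data=vol, affine=scene.affine.copy())


def _coef_direction(vec_or_scalar, m: int) -> np.ndarray:
    v = np.asarray(vec_or_scalar, dtype=np.float64)
    if v.ndim == 0:
        return float(v) * np.ones(m) / np.sqrt(m)
    if v.shape != (m,):
        raise ValueError(f"expected scalar or length-{m} vector")
    return v


def simulate_cohort(scene: PhantomScene, design: CohortDesign) -> Cohort:
    """Simulate a two-group, multi-session cohort over one scene.

    Subject gradient = planted gradient + between-subject perturbation;
    session gradient = subject gradient + within-subject perturbation. All
    perturbations are Gaussian in the orthonormalized TSM coefficient space
    of the target ROI (so they are smooth and their effect on fitted
    coefficients is exact). Group "B" subjects additionally receive
    ``group_effect`` as a coefficient-space shift; the continuous outcome is
    ``outcome_coupling · (subject coefficients) + noise``.

    RNG streams are spawned per subject from the design seed, so earlier
    subjects' data are invariant to the total cohort size.
    """
    bases = []
    for roi in scene.roi_specs:
        basis = build_basis(roi.world_coords, design.tsm_degree)
        Q, _ = np.linalg.qr(basis.design - basis.design.mean(axis=0))
        bases.append(Q)
    m = bases[design.roi_index].shape[1]
    shift = _coef_direction(design.group_effect, m)
    coupling = _coef_direction(design.outcome_coupling, m)

    n_a, n_b = design.n_subjects_per_group
    groups = ["A"] * n_a + ["B"] * n_b
    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(n_a + n_b)

    rows, coef_rows = [], []
    fields, seeds = {}, {}
    for si, (grp, child) in enumerate(zip(groups, children)):
        sub = f"sub{si:03d}"
        srng = np.random.default_rng(child)
        # every ROI gets between-subject variability; only the target ROI
        # carries the group shift and drives the outcome
        subj_coefs = []
        for Q in bases:
            mb = Q.shape[1]
            subj_coefs.append(srng.standard_normal(mb)
                              * (design.between_subject_sd / np.sqrt(mb)))
        subj_coefs[design.roi_index] = subj_coefs[design.roi_index] + (
            shift if grp == "B" else 0.0)
        target_coef = subj_coefs[design.roi_index]
        outcome = float(coupling @ target_coef
                        + srng.standard_normal() * design.outcome_noise_sd)
        usage = float(max(0.0, 5.0 + design.usage_coupling * target_coef.sum()
                          + srng.standard_normal()))
        coef_rows.append({"subject": sub, "group": grp,
                          **{f"b{j}": target_coef[j] for j in range(m)}})
        for sess in range(1, design.n_sessions + 1):
            perturb = {}
            for b, (Q, roi) in enumerate(zip(bases, scene.roi_specs)):
                mb = Q.shape[1]
                b_within = srng.standard_normal(mb) * (
                    design.within_subject_sd / np.sqrt(mb))
                field_vec = Q @ (subj_coefs[b] + b_within)
                if design.target_gradient == 0:
                    perturb[b] = field_vec
                else:
                    n_grad = scene.planted_gradients[b].shape[1]
                    p = np.zeros((roi.n_voxels, n_grad))
                    p[:, design.target_gradient] = field_vec
                    perturb[b] = p
            sess_seed = int(srng.integers(0, 2**31 - 1))
            fields[(sub, sess)] = perturb
            seeds[(sub, sess)] = sess_seed
            rows.append({"subject": sub, "session": sess, "group": grp,
                         "outcome": outcome, "usage_count": usage})

    phen = pd.DataFrame(rows)
    true_coef = pd.DataFrame(coef_rows)
    return Cohort(scene=scene, design=design, phenotype=phen,
                  true_coefficients=true_coef,
                  _session_fields=fields, _session_seeds=seeds)
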