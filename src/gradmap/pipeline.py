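"""End-to-end orchestration: subject-level mapping runs and group statistics.

``run_subject_level`` maps every subject/session of a cohort (connectopic
mapping → alignment to the group-average mode → trend-surface fit) into a
versioned coefficient table; ``run_group_level`` consumes that table and the
phenotype table and produces the statistical results bundle (reliability,
density-map correlations, omnibus tests). Both are deterministic given the
config and its seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .connectopic import align_mode, group_similarity, laplacian_eigenmaps, map_subject
from .group_stats import (
    bonferroni,
    filter_by_reference,
    icc_2k,
    omnibus_lr_binary,
    omnibus_lr_continuous,
    within_between_permutation,
)
from .synthetic import Cohort
from .trend_surface import build_basis, fit_blr

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = ["RunConfig", "SubjectLevelResult", "run_subject_level",
           "run_group_level"]


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected on load."""

    n_modes: int = 3
    selected_order: int = 2
    degree: int = 2
    alpha: float = 0.05
    bonferroni_m: int = 4
    n_perm: int = 1000
    n_boot: int = 500
    r_min: float = 0.5
    knn: int | None = None
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema {cfg.schema_version}")
        if cfg.selected_order >= cfg.n_modes:
            raise ValueError("selected_order must be < n_modes")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SubjectLevelResult:
    coefficients: pd.DataFrame  # one row per (subject, session)
    group_mode: np.ndarray  # group-average reference mode (V)
    modes: dict  # (subject, session) -> aligned mode values
    failures: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def run_subject_level(cohort: Cohort, config: RunConfig,
                      roi_index: int | None = None) -> SubjectLevelResult:
    """Map every subject/session of a cohort into a coefficient table.

    Single pass: each session's similarity matrix feeds the group average
    while its modes are cached; the group-level mode (eigenmaps of the
    averaged similarity) is then used to sign-align every subject mode
    before the trend-surface fit. Per-subject failures are isolated and
    reported; the run does not abort.
    """
    idx = cohort.design.roi_index if roi_index is None else roi_index
    roi = cohort.scene.roi_specs[idx]
    basis = build_basis(roi.world_coords, config.degree)
    sim_sum = None
    n_sim = 0
    raw_modes: dict = {}
    failures: list = []

    pairs = cohort.phenotype[["subject", "session"]].drop_duplicates()
    for subject, session in pairs.itertuples(index=False):
        try:
            bold = cohort.session_bold(subject, int(session))
            modes, S = map_subject(bold, roi, cohort.scene.brain_mask,
                                   config.n_modes, knn=config.knn,
                                   return_similarity=True)
            raw_modes[(subject, int(session))] = modes[config.selected_order]
            sim_sum = S if sim_sum is None else sim_sum + S
            n_sim += 1
        except Exception as exc:  # noqa: BLE001 - isolate per-subject failures
            logger.warning("subject %s session %s failed: %s", subject,
                           session, exc)
            failures.append({"subject": subject, "session": int(session),
                             "error": str(exc)})
    if sim_sum is None:
        raise RuntimeError("all subjects failed; no group similarity")

    S_group = group_similarity([sim_sum / n_sim])
    group_modes = laplacian_eigenmaps(S_group, config.n_modes, knn=config.knn)
    group_mode = group_modes[config.selected_order]

    phen = cohort.phenotype.set_index(["subject", "session"])
    rows = []
    aligned: dict = {}
    for (subject, session), mode in raw_modes.items():
        am = align_mode(mode, group_mode, reference_id="group")
        aligned[(subject, session)] = am.values
        fit = fit_blr(basis, am.values)
        meta = phen.loc[(subject, session)]
        row = {"subject": subject, "session": session,
               "group": meta["group"], "outcome": meta["outcome"],
               "usage_count": meta["usage_count"],
               "variance_explained": fit.variance_explained}
        row.update({f"b{j}": fit.beta[j] for j in range(len(fit.beta))})
        rows.append(row)
    coef = pd.DataFrame(rows).sort_values(["subject", "session"],
                                          ignore_index=True)
    provenance = {"config": config.to_dict(), "config_hash": config.config_hash,
                  "version": __version__, "n_mapped": n_sim,
                  "n_failed": len(failures)}
    return SubjectLevelResult(coefficients=coef, group_mode=group_mode.values,
                              modes=aligned, failures=failures,
                              provenance=provenance)


def run_group_level(subject_level: SubjectLevelResult, config: RunConfig,
                    roi=None, density_mode_values: np.ndarray | None = None) -> dict:
    """Run the enabled group analyses on a subject-level result bundle.

    Returns a dict with reliability (ICC over coefficients, within/between
    permutation on modes), the binary omnibus test (session 1), the
    continuous-outcome omnibus test, the quality-filter report, and — when a
    reference density map restricted to the ROI is supplied — voxel-wise and
    coefficient-space correlations against it.
    """
    from .group_stats import coefficient_correlation, spatial_correlation

    coef = subject_level.coefficients
    beta_cols = [c for c in coef.columns if c.startswith("b")]
    results: dict = {"config_hash": config.config_hash, "version": __version__,
                     "alpha_corrected": bonferroni(config.alpha,
                                                   config.bonferroni_m)}

    s1 = coef[coef.session == 1].reset_index(drop=True)
    modes_s1 = {s: subject_level.modes[(s, 1)] for s in s1.subject}
    kept, report = filter_by_reference(modes_s1, subject_level.group_mode,
                                       r_min=config.r_min)
    results["quality_filter"] = report

    sessions = sorted(coef.session.unique())
    if len(sessions) >= 2:
        wide = coef.pivot(index="subject", columns="session", values=beta_cols)
        iccs = {}
        for b in beta_cols:
            M = wide[b].to_numpy()
            iccs[b] = icc_2k(M, n_boot=config.n_boot, seed=config.seed)
        results["icc_per_coefficient"] = iccs
        results["icc_mean"] = float(np.mean([r.icc for r in iccs.values()]))
        subjects = sorted({s for s, _ in subject_level.modes})
        M1 = np.array([subject_level.modes[(s, sessions[0])] for s in subjects])
        M2 = np.array([subject_level.modes[(s, sessions[1])] for s in subjects])
        results["within_between"] = within_between_permutation(
            M1, M2, n_perm=config.n_perm, seed=config.seed)

    if s1.group.nunique() == 2:
        results["omnibus_binary"] = omnibus_lr_binary(s1, beta_cols=beta_cols)
    if s1.outcome.std() > 0:
        results["omnibus_continuous"] = omnibus_lr_continuous(
            s1, beta_cols=beta_cols)

    if density_mode_values is not None:
        r, p = spatial_correlation(subject_level.group_mode,
                                   density_mode_values)
        results["density_voxel_r"] = (r, p)
        if roi is not None:
            # both fits share the same ROI basis (same normalization), so
            # their coefficient vectors are directly comparable
            basis = build_basis(roi.world_coords, config.degree)
            fit_mode = fit_blr(basis, subject_level.group_mode)
            fit_density = fit_blr(basis, np.asarray(density_mode_values))
            results["density_coefficient_r"] = coefficient_correlation(
                fit_mode.beta, fit_density.beta)
    return results
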