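"""Synthetic CZT-SPECT myocardial-perfusion phantoms.

The left ventricle is modeled as a half-ellipsoid shell (apex capped, base
open) of elevated tracer uptake over a cold background, with a blood-pool
cavity inside the endocardial surface. The long axis is oblique to the grid
axes by default, as in clinical axial acquisitions. Reconstruction is
emulated by Gaussian blurring of the expected-intensity field followed by
independent per-voxel Poisson counting noise (blur-then-noise); a
"variance-0" mode replaces draws with expectations for exact tests.

A triple-vessel-disease (TVD) subject is a phantom whose stress acquisition
has globally reduced expected counts (balanced ischemia): the stress field is
``stress_scale`` times the rest field, re-posed by a small rigid jitter to
mimic repositioning between acquisitions. Optional regional defects carve
angular sectors of reduced uptake out of the shell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .volumes import Grid, MaskVolume, Volume3D

__all__ = [
    "Pose",
    "Defect",
    "PhantomSpec",
    "SimulatedSubject",
    "CohortPopulation",
    "make_lv_phantom",
    "simulate_cohort",
    "simulate_template_normals",
    "calibrate_stress_scale",
    "fit_stress_response",
    "StressResponseCurve",
    "half_shell_volume",
]

DEFAULT_GRID = Grid(dims=(70, 70, 50), spacing=(4.0, 4.0, 4.0))


def _rotation_matrix(rotation_deg: Sequence[float]) -> np.ndarray:
    rx, ry, rz = np.deg2rad(rotation_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass(frozen=True)
class Pose:
    """Rigid pose of the LV frame: intrinsic rotation (deg) and translation
    (mm) of the LV center relative to the grid center."""

    rotation_deg: tuple[float, float, float] = (0.0, 40.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def perturb(self, rng: np.random.Generator, max_rot_deg: float, max_trans_mm: float) -> "Pose":
        dr = rng.uniform(-max_rot_deg, max_rot_deg, size=3)
        dt = rng.uniform(-max_trans_mm, max_trans_mm, size=3)
        return Pose(
            tuple(np.asarray(self.rotation_deg) + dr),
            tuple(np.asarray(self.translation_mm) + dt),
        )


@dataclass(frozen=True)
class Defect:
    """A regional perfusion defect: an angular sector of the shell with
    uptake reduced by ``severity`` over an axial range.

    ``axial_range`` is expressed as fractions of the base-to-apex distance,
    0 = base plane, 1 = apex.
    """

    sector_center_deg: float
    sector_width_deg: float
    axial_range: tuple[float, float] = (0.0, 1.0)
    severity: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"defect severity must be in [0, 1], got {self.severity}")


@dataclass(frozen=True)
class PhantomSpec:
    """All parameters needed to simulate one rest/stress subject.

    Uptakes are expected counts per voxel in the reconstructed image at rest;
    the stress acquisition multiplies every expected count by ``stress_scale``.
    """

    grid: Grid = DEFAULT_GRID
    epi_axes: tuple[float, float, float] = (33.0, 33.0, 47.0)
    endo_axes: tuple[float, float, float] = (22.0, 22.0, 36.0)
    wall_uptake: float = 18.0
    background_uptake: float = 2.0
    cavity_uptake: float = 6.0
    defects: tuple[Defect, ...] = ()
    stress_scale: float = 1.0
    psf_fwhm: float = 7.0
    pose: Pose = Pose()
    pose_jitter_rot_deg: float = 5.0
    pose_jitter_trans_mm: float = 6.0
    noise: str = "poisson"  # "poisson" or "none" (variance-0 mode)
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(n < e for n, e in zip(self.endo_axes, self.epi_axes)):
            raise ValueError("endocardial axes must be smaller than epicardial axes (nonempty shell)")
        if self.wall_uptake <= self.background_uptake or self.background_uptake < 0:
            raise ValueError("need wall_uptake > background_uptake >= 0")
        if self.cavity_uptake < 0:
            raise ValueError("cavity uptake must be nonnegative")
        if self.stress_scale <= 0:
            raise ValueError("stress_scale must be positive")
        if self.noise not in ("poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass
class SimulatedSubject:
    """One simulated rest/stress study with ground truth."""

    subject_id: str
    rest: Volume3D
    stress: Volume3D
    truth_mask_rest: MaskVolume
    truth_mask_stress: MaskVolume
    covariates: dict
    label: str  # "control" or "TVD"
    spec: PhantomSpec


def half_shell_volume(epi_axes: Sequence[float], endo_axes: Sequence[float]) -> float:
    """Analytic volume (mm^3) of the open-base half-ellipsoid shell."""
    ae, be, ce = epi_axes
    an, bn, cn = endo_axes
    return 2.0 * np.pi / 3.0 * (ae * be * ce - an * bn * cn)


def _lv_frame_coords(grid: Grid, pose: Pose) -> np.ndarray:
    """Voxel-center coordinates expressed in the LV frame, shape (3,nx,ny,nz)."""
    pts = grid.voxel_centers() - grid.center().reshape(3, 1, 1, 1)
    R = _rotation_matrix(pose.rotation_deg)
    t = np.asarray(pose.translation_mm).reshape(3, 1, 1, 1)
    return np.einsum("ji,jxyz->ixyz", R, pts - t)


def _expected_field(spec: PhantomSpec, pose: Pose) -> tuple[np.ndarray, np.ndarray]:
    """Unblurred expected counts and the boolean shell (truth) mask."""
    p = _lv_frame_coords(spec.grid, pose)

    def inside(axes: Sequence[float]) -> np.ndarray:
        return (p[0] / axes[0]) ** 2 + (p[1] / axes[1]) ** 2 + (p[2] / axes[2]) ** 2 <= 1.0

    apex_half = p[2] <= 0.0  # apex at z' = -c, base plane at z' = 0
    shell = inside(spec.epi_axes) & ~inside(spec.endo_axes) & apex_half
    cavity = inside(spec.endo_axes) & apex_half

    lam = np.full(spec.grid.dims, float(spec.background_uptake))
    lam[cavity] = spec.cavity_uptake
    wall = np.full(spec.grid.dims, float(spec.wall_uptake))
    if spec.defects:
        phi = np.rad2deg(np.arctan2(p[1], p[0]))  # circumferential angle
        depth = -p[2] / spec.epi_axes[2]  # 0 at base, 1 at apex
        for d in spec.defects:
            dphi = (phi - d.sector_center_deg + 180.0) % 360.0 - 180.0
            in_sector = np.abs(dphi) <= d.sector_width_deg / 2.0
            in_axial = (depth >= d.axial_range[0]) & (depth <= d.axial_range[1])
            wall = np.where(in_sector & in_axial, wall * (1.0 - d.severity), wall)
    lam[shell] = wall[shell]
    return lam, shell


def _reconstruct(lam: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    sigma_vox = [spec.psf_fwhm / 2.354820045 / s for s in spec.grid.spacing]
    lam_b = gaussian_filter(lam, sigma_vox) if spec.psf_fwhm > 0 else lam
    lam_b = np.clip(lam_b, 0.0, None)
    if spec.noise == "none":
        return lam_b
    return rng.poisson(lam_b).astype(float)


def make_lv_phantom(
    spec: PhantomSpec,
    subject_id: str = "phantom",
    covariates: dict | None = None,
    label: str = "control",
    stress_pose: Pose | None = None,
) -> SimulatedSubject:
    """Simulate one paired rest/stress study from ``spec``.

    The rest acquisition uses ``spec.pose``; the stress acquisition uses
    ``stress_pose`` if given, otherwise a rigid perturbation of the rest pose
    drawn from the spec's pose-jitter bounds. Stress expected counts are
    ``stress_scale`` times the rest field. Truth masks are the unblurred
    shell region in each pose.
    """
    rng = np.random.default_rng(spec.seed)
    lam_rest, shell_rest = _expected_field(spec, spec.pose)
    if stress_pose is None:
        stress_pose = spec.pose.perturb(rng, spec.pose_jitter_rot_deg, spec.pose_jitter_trans_mm)
    lam_stress, shell_stress = _expected_field(spec, stress_pose)
    rest_vals = _reconstruct(lam_rest, spec, rng)
    stress_vals = _reconstruct(spec.stress_scale * lam_stress, spec, rng)
    if not shell_rest.any() or not shell_stress.any():
        raise ValueError("phantom shell does not intersect the grid (empty truth mask)")
    cov = covariates or {"age": 60.0, "sex": "M", "bmi": 26.0}
    return SimulatedSubject(
        subject_id=subject_id,
        rest=Volume3D(rest_vals, spec.grid),
        stress=Volume3D(stress_vals, spec.grid),
        truth_mask_rest=MaskVolume(shell_rest.astype(np.uint8), spec.grid),
        truth_mask_stress=MaskVolume(shell_stress.astype(np.uint8), spec.grid),
        covariates=cov,
        label=label,
        spec=spec,
    )


def truth_mask_rsnr(subject: SimulatedSubject) -> float:
    """RSNR computed over the ground-truth shell masks (no segmentation).

    Used as a fast evaluator for calibration; the full pipeline replaces the
    truth masks with template-based segmentations.
    """
    def snr(vol: Volume3D, mask: MaskVolume) -> float:
        vals = vol.values[mask.as_bool()]
        return float(vals.mean() / vals.std(ddof=1))

    return snr(subject.stress, subject.truth_mask_stress) / snr(
        subject.rest, subject.truth_mask_rest
    )


# ---------------------------------------------------------------------------
# stress-scale calibration
# ---------------------------------------------------------------------------


@dataclass
class StressResponseCurve:
    """Monotone mapping between the stress count-scale f and the mean RSNR.

    Fitted by Monte-Carlo probing of the simulator at a grid of f values with
    common random numbers across f (the same subject seeds are reused at every
    f, so the fitted mean response is smooth and monotone).
    """

    f_values: np.ndarray
    mean_rsnr: np.ndarray
    sd_rsnr: np.ndarray  # within-subject (noise + pose) SD at each knot

    def scale_for_rsnr(self, target: float | np.ndarray) -> np.ndarray:
        """Invert the response: stress scale giving mean RSNR = target.

        Targets outside the probed range are clipped to it.
        """
        t = np.clip(np.asarray(target, dtype=float), self.mean_rsnr[0], self.mean_rsnr[-1])
        return np.exp(np.interp(t, self.mean_rsnr, np.log(self.f_values)))

    def noise_sd_at(self, target: float) -> float:
        """Within-subject RSNR SD at the f whose mean response is ``target``."""
        t = np.clip(target, self.mean_rsnr[0], self.mean_rsnr[-1])
        return float(np.interp(t, self.mean_rsnr, self.sd_rsnr))


def _probe_mean_rsnr(
    spec: PhantomSpec,
    f: float,
    evaluator: Callable[[SimulatedSubject], float],
    seeds: np.ndarray,
) -> tuple[float, float]:
    vals = []
    for s in seeds:
        sub = make_lv_phantom(replace(spec, stress_scale=float(f), seed=int(s)))
        vals.append(evaluator(sub))
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std(ddof=1))


def fit_stress_response(
    spec: PhantomSpec,
    evaluator: Callable[[SimulatedSubject], float] = truth_mask_rsnr,
    f_grid: Sequence[float] | None = None,
    n_rep: int = 60,
    seed: int = 0,
) -> StressResponseCurve:
    """Probe mean RSNR as a function of the stress count-scale f."""
    if f_grid is None:
        f_grid = np.geomspace(0.15, 6.0, 9)
    f_grid = np.sort(np.asarray(f_grid, dtype=float))
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_rep)
    means, sds = [], []
    for f in f_grid:
        m, s = _probe_mean_rsnr(spec, f, evaluator, seeds)
        means.append(m)
        sds.append(s)
    means = np.maximum.accumulate(np.asarray(means))  # enforce monotone response
    # strictly increasing knots for interpolation
    eps = 1e-9 * np.arange(len(means))
    return StressResponseCurve(f_grid, means + eps, np.asarray(sds))


def calibrate_stress_scale(
    target_rsnr: float,
    spec: PhantomSpec,
    evaluator: Callable[[SimulatedSubject], float] = truth_mask_rsnr,
    n_subjects: int = 100,
    tol: float = 0.02,
    f_bounds: tuple[float, float] = (0.1, 10.0),
    seed: int = 0,
    max_iter: int = 40,
) -> float:
    """Find the stress count-scale f whose mean evaluated RSNR hits a target.

    Monotone bisection on f with common random numbers: each candidate f is
    scored by the mean RSNR of ``n_subjects`` simulated subjects that share
    the same seed sequence, so the objective is a fixed monotone function of
    f and bisection converges to within ``tol`` of the target.
    """
    if target_rsnr <= 0:
        raise ValueError("target RSNR must be positive")
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_subjects)
    lo, hi = f_bounds
    m_lo, _ = _probe_mean_rsnr(spec, lo, evaluator, seeds)
    m_hi, _ = _probe_mean_rsnr(spec, hi, evaluator, seeds)
    if not (m_lo - tol <= target_rsnr <= m_hi + tol):
        raise ValueError(
            f"target RSNR {target_rsnr} outside the reachable range "
            f"[{m_lo:.3f}, {m_hi:.3f}] for f in {f_bounds}"
        )
    f = float(np.sqrt(lo * hi))
    for _ in range(max_iter):
        f = float(np.sqrt(lo * hi))
        m, _ = _probe_mean_rsnr(spec, f, evaluator, seeds)
        if abs(m - target_rsnr) <= tol / 2.0:
            return f
        if m < target_rsnr:
            lo = f
        else:
            hi = f
        if hi / lo < 1.0005:
            break
    return f


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortPopulation:
    """Distributions over phantom geometry, uptake and covariates for a cohort.

    Group RSNR targets emulate the clinical contrast between controls and
    TVD subjects: per-subject target RSNRs are drawn from the group normal
    distribution (stratified normal quantiles, randomly permuted, so the
    sample mean of the targets equals the group mean by construction) and
    mapped to a per-subject stress count-scale through ``response`` when a
    fitted :class:`StressResponseCurve` is attached. Without a curve the
    square-root count law f = target**2 is used as a first approximation.

    When ``deflate_target_sd`` is set, the target SD is reduced by the
    within-subject RSNR noise variance measured on the response curve so the
    *total* simulated group SD matches the configured value.
    """

    base_spec: PhantomSpec = field(default_factory=PhantomSpec)
    control_rsnr: tuple[float, float] = (1.06, 0.17)  # mean, SD
    tvd_rsnr: tuple[float, float] = (0.83, 0.15)
    response: StressResponseCurve | None = None
    deflate_target_sd: bool = True
    geometry_cv: float = 0.05
    sex_size_factor: dict = field(default_factory=lambda: {"M": 1.05, "F": 0.93})
    female_fraction: dict = field(default_factory=lambda: {"control": 19 / 61, "TVD": 18 / 41})
    age_dist: dict = field(default_factory=lambda: {"control": (60.3, 13.3), "TVD": (66.0, 10.5)})
    bmi_dist: dict = field(default_factory=lambda: {"control": (26.5, 5.2), "TVD": (25.1, 4.4)})
    pose_scatter_rot_deg: float = 8.0
    pose_scatter_trans_mm: float = 10.0

    def _group_targets(self, label: str, n: int, rng: np.random.Generator) -> np.ndarray:
        from scipy.stats import norm

        mean, sd = self.control_rsnr if label == "control" else self.tvd_rsnr
        if self.response is not None and self.deflate_target_sd:
            noise_sd = self.response.noise_sd_at(mean)
            sd = float(np.sqrt(max(sd**2 - noise_sd**2, (0.25 * sd) ** 2)))
        # stratified normal quantiles: sample mean of targets == group mean
        z = norm.ppf((np.arange(n) + 0.5) / n)
        return mean + sd * rng.permutation(z)

    def _scale_for(self, target: float) -> float:
        if self.response is not None:
            return float(self.response.scale_for_rsnr(target))
        return float(np.clip(target, 0.3, 2.5)) ** 2  # sqrt-count first approximation


def _draw_subject_spec(
    pop: CohortPopulation, sex: str, rng: np.random.Generator
) -> PhantomSpec:
    base = pop.base_spec
    size = pop.sex_size_factor.get(sex, 1.0) * (1.0 + pop.geometry_cv * rng.standard_normal())
    size = float(np.clip(size, 0.8, 1.25))
    long_axis = float(np.clip(1.0 + pop.geometry_cv * rng.standard_normal(), 0.85, 1.2))
    epi = tuple(a * size * (long_axis if i == 2 else 1.0) for i, a in enumerate(base.epi_axes))
    endo = tuple(a * size * (long_axis if i == 2 else 1.0) for i, a in enumerate(base.endo_axes))
    pose = base.pose.perturb(rng, pop.pose_scatter_rot_deg, pop.pose_scatter_trans_mm)
    return replace(base, epi_axes=epi, endo_axes=endo, pose=pose)


def _draw_covariates(pop: CohortPopulation, label: str, rng: np.random.Generator) -> dict:
    sex = "F" if rng.random() < pop.female_fraction[label] else "M"
    age_m, age_s = pop.age_dist[label]
    bmi_m, bmi_s = pop.bmi_dist[label]
    return {
        "sex": sex,
        "age": float(np.clip(age_m + age_s * rng.standard_normal(), 30.0, 92.0)),
        "bmi": float(np.clip(bmi_m + bmi_s * rng.standard_normal(), 15.0, 45.0)),
    }


def simulate_cohort(
    n_control: int,
    n_tvd: int,
    population: CohortPopulation | None = None,
    seed: int = 0,
) -> list[SimulatedSubject]:
    """Simulate a labeled cohort of ``n_control`` controls and ``n_tvd`` TVD
    subjects, reproducible per seed."""
    if n_control < 0 or n_tvd < 0:
        raise ValueError("cohort counts must be nonnegative")
    pop = population or CohortPopulation()
    rng = np.random.default_rng(seed)
    subjects: list[SimulatedSubject] = []
    for label, n in (("control", n_control), ("TVD", n_tvd)):
        targets = pop._group_targets(label, n, rng) if n else np.empty(0)
        for i in range(n):
            cov = _draw_covariates(pop, label, rng)
            spec = _draw_subject_spec(pop, cov["sex"], rng)
            f = pop._scale_for(float(targets[i]))
            spec = replace(spec, stress_scale=f, seed=int(rng.integers(0, 2**31 - 1)))
            subjects.append(
                make_lv_phantom(
                    spec,
                    subject_id=f"{label.lower()}_{i:03d}",
                    covariates=cov,
                    label=label,
                )
            )
    return subjects


def simulate_template_normals(
    n_per_sex: int,
    population: CohortPopulation | None = None,
    seed: int = 1,
) -> dict[str, list[SimulatedSubject]]:
    """Simulate the separate normal subjects used only for template building.

    Returns rest-condition normal subjects keyed by sex. These subjects are
    disjoint from any study cohort (separate seed stream), mirroring template
    construction from scans that are not part of the evaluated groups.
    """
    pop = population or CohortPopulation()
    rng = np.random.default_rng(seed)
    out: dict[str, list[SimulatedSubject]] = {"M": [], "F": []}
    for sex in ("M", "F"):
        for i in range(n_per_sex):
            cov = {"sex": sex, "age": 62.0, "bmi": 27.0}
            spec = _draw_subject_spec(pop, sex, rng)
            spec = replace(spec, stress_scale=1.0, seed=int(rng.integers(0, 2**31 - 1)))
            out[sex].append(
                make_lv_phantom(spec, subject_id=f"normal_{sex}_{i:02d}", covariates=cov)
            )
    return out
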