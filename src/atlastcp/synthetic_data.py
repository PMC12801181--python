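"""Synthetic phantoms, atlases, reports and calibration cohorts.

Every pipeline input can be generated here with a known ground truth, so the
full analysis — segmentation, parameter adjustment, TCP mapping, calibration
and statistical evaluation — runs without any external data.

The phantom is an ellipsoidal prostate on a regular voxel grid with a
posterior peripheral-zone (PZ) shell, a log-normally heterogeneous cell
density elevated in the PZ, a tumor-probability field concentrated in the
PZ and in focal lesions, and spherical tumor lesions carrying a Gleason
score; designated relapse lesions form the GTV.  Cell densities are
*effective clonogen* densities on the scale that population TCP calibration
yields (whole-prostate totals of order 10^5-10^6), so that baseline overall
TCP falls in the high-80s to mid-90s percent for standard prescriptions.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .calibration import CalibrationCohort, OutcomeTarget, cohort_mean_tcp
from .histo_adjust import HistopathReport, SegmentFinding, SegmentLabelMap
from .tcp_core import (
    GS_LABELS,
    RadiosensitivityParams,
    TreatmentSchedule,
    VoxelGrid,
)

__all__ = [
    "Lesion",
    "PhantomSpec",
    "Phantom",
    "make_phantom",
    "make_report",
    "make_dose",
    "make_calibration_cohort",
    "chhip_like_schedules",
    "recovery_schedules",
    "gp_recovery_schedules",
]


@dataclass(frozen=True)
class Lesion:
    """Spherical tumor focus inside the prostate."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    gleason: str  # "a+b"
    density_multiplier: float = 3.0
    relapse: bool = True

    def __post_init__(self) -> None:
        if self.gleason not in GS_LABELS:
            raise ValueError(f"unknown Gleason score {self.gleason!r}")
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be > 0")
        if self.density_multiplier <= 0:
            raise ValueError("density multiplier must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a synthetic prostate phantom.

    The grid defaults to 40x40x30 voxels at 2 mm isotropic spacing — large
    enough for 6/12-segment division, small enough for seconds-scale runs.
    ``cd_median`` is the median effective clonogen density (cells/voxel);
    ``cd_sigma`` the log-scale SD of its log-normal voxel field;
    ``pz_cd_factor`` the density elevation inside the posterior PZ shell;
    ``shell_frac`` the radial thickness fraction of that shell.
    """

    shape: tuple[int, int, int] = (40, 40, 30)
    spacing_mm: float = 2.0
    semi_axes_mm: tuple[float, float, float] = (24.0, 20.0, 22.0)
    shell_frac: float = 0.35
    cd_median: float = 60.0
    cd_sigma: float = 0.4
    pz_cd_factor: float = 2.0
    tp_base: float = 0.10
    tp_shell: float = 0.35
    tp_lesion: float = 0.90
    lesions: tuple[Lesion, ...] = ()
    patient_id: str = "synthetic-01"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lesions", tuple(self.lesions))
        if not (0.0 < self.shell_frac < 1.0):
            raise ValueError("shell_frac must lie in (0, 1)")
        if self.cd_median <= 0 or self.cd_sigma < 0:
            raise ValueError("invalid cell-density parameters")

    @property
    def grid(self) -> VoxelGrid:
        s = self.spacing_mm
        return VoxelGrid(self.shape, (s, s, s))

    @property
    def center_mm(self) -> np.ndarray:
        return np.array(self.shape) * self.spacing_mm / 2.0


class Phantom(NamedTuple):
    grid: VoxelGrid
    mask: np.ndarray
    cd_atlas: np.ndarray
    tp_atlas: np.ndarray
    gtv_mask: np.ndarray


def _ellipsoid_radius(spec: PhantomSpec) -> np.ndarray:
    """Normalized ellipsoidal radius of every voxel center (1 = surface)."""
    coords = spec.grid.voxel_centers_mm() - spec.center_mm
    scaled = coords / np.asarray(spec.semi_axes_mm)
    return np.sqrt(np.sum(scaled**2, axis=-1))


def _lesion_mask(spec: PhantomSpec, lesion: Lesion) -> np.ndarray:
    coords = spec.grid.voxel_centers_mm()
    dist = np.sqrt(np.sum((coords - np.asarray(lesion.center_mm)) ** 2, axis=-1))
    return dist <= lesion.radius_mm


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Generate mask, cell-density atlas, tumor-probability atlas and GTV.

    Deterministic for a fixed spec (including its seed).  Raises if any
    lesion voxel falls outside the prostate mask.
    """
    rng = np.random.default_rng(spec.seed)
    r = _ellipsoid_radius(spec)
    mask = r <= 1.0
    if not mask.any():
        raise ValueError("phantom mask is empty; enlarge the semi-axes")

    # posterior peripheral-zone shell
    coords = spec.grid.voxel_centers_mm()
    posterior = coords[..., 1] >= spec.center_mm[1]
    shell = mask & posterior & (r >= 1.0 - spec.shell_frac)

    cd = np.zeros(spec.shape)
    n_m = int(mask.sum())
    cd[mask] = spec.cd_median * np.exp(
        rng.normal(0.0, spec.cd_sigma, size=n_m)
    )
    cd[shell] *= spec.pz_cd_factor

    tp = np.zeros(spec.shape)
    tp[mask] = spec.tp_base
    tp[shell] = spec.tp_shell

    gtv = np.zeros(spec.shape, dtype=bool)
    for i, lesion in enumerate(spec.lesions):
        lm = _lesion_mask(spec, lesion)
        if not lm.any():
            raise ValueError(f"lesion {i} covers no voxel")
        if np.any(lm & ~mask):
            raise ValueError(f"lesion {i} extends outside the prostate mask")
        cd[lm] *= lesion.density_multiplier
        tp[lm] = np.maximum(tp[lm], spec.tp_lesion)
        if lesion.relapse:
            gtv |= lm
    tp = np.clip(tp, 0.0, 1.0)
    return Phantom(spec.grid, mask, cd, tp, gtv)


def make_report(
    labelmap: SegmentLabelMap, spec: PhantomSpec
) -> HistopathReport:
    """Biopsy-style report implied by the phantom's lesions.

    Each segment intersecting a lesion reports the most aggressive
    intersecting lesion's Gleason score and a % adenocarcinoma equal to the
    lesions' voxel share of the segment; all other segments report benign.
    """
    gs_rank = {s: i for i, s in enumerate(GS_LABELS)}
    lesion_masks = [_lesion_mask(spec, l) for l in spec.lesions]
    findings = []
    for name in labelmap.names:
        seg = labelmap.mask_for(name)
        seg_n = int(seg.sum())
        covered = np.zeros(spec.shape, dtype=bool)
        best_gs: Optional[str] = None
        for lesion, lm in zip(spec.lesions, lesion_masks):
            inter = seg & lm
            if inter.any():
                covered |= inter
                if best_gs is None or gs_rank[lesion.gleason] > gs_rank[best_gs]:
                    best_gs = lesion.gleason
        if best_gs is None:
            findings.append(SegmentFinding(name, None, None, 0.0))
        else:
            pct = 100.0 * covered.sum() / seg_n
            a, b = (int(x) for x in best_gs.split("+"))
            findings.append(SegmentFinding(name, a, b, min(100.0, pct)))
    return HistopathReport(spec.patient_id, tuple(findings))


def make_dose(
    mask: np.ndarray,
    schedule: TreatmentSchedule,
    heterogeneity_sd: float = 0.0,
    boost: Optional[tuple[np.ndarray, float]] = None,
    seed: int = 0,
) -> np.ndarray:
    """Dose-per-fraction grid: uniform prescription with optional
    multiplicative Gaussian heterogeneity and an optional boost region
    (mask, extra total Gy)."""
    mask = np.asarray(mask, dtype=bool)
    d0 = schedule.dose_per_fraction
    dose = np.zeros(mask.shape)
    dose[mask] = d0
    if heterogeneity_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(1.0, heterogeneity_sd, size=int(mask.sum()))
        dose[mask] *= np.clip(noise, 0.0, None)
    if boost is not None:
        bmask, extra_gy = boost
        bmask = np.asarray(bmask, dtype=bool)
        if bmask.shape != mask.shape:
            raise ValueError("boost mask grid mismatch")
        dose[bmask & mask] += extra_gy / schedule.n_fractions
    return dose


# ---------------------------------------------------------------------------
# Calibration cohorts
# ---------------------------------------------------------------------------


def chhip_like_schedules() -> list[TreatmentSchedule]:
    """Three conventional/moderately-hypofractionated EBRT schedules of the
    kind used for population outcome calibration."""
    return [
        TreatmentSchedule.weekday(37, 74.0),
        TreatmentSchedule.weekday(20, 60.0),
        TreatmentSchedule.weekday(19, 57.0),
    ]


def recovery_schedules() -> list[TreatmentSchedule]:
    """Twelve schedules spanning conventional fractionation to SBRT dose
    levels.  Identifying nine score-dependent alpha/beta ratios from
    cohort-mean targets needs at least as many independent schedules, with
    fraction sizes spread widely enough to separate the quadratic term."""
    specs = [
        (39, 78.0), (37, 74.0), (30, 70.0), (28, 70.0),
        (25, 68.0), (20, 60.0), (19, 57.0), (15, 54.0),
        (10, 48.0), (7, 42.7), (6, 42.0), (5, 36.25),
    ]
    return [TreatmentSchedule.weekday(n, dose) for n, dose in specs]


def gp_recovery_schedules() -> list[TreatmentSchedule]:
    """Six reduced-dose schedules for identifying the Gleason-Pattern alpha
    quadruple.  With fixed (unsampled) alpha the per-clonogen kill at
    curative dose levels is so large that cohort TCP saturates near one and
    carries no information; informative targets require dose levels where
    the fixed-alpha model leaves control probabilities mid-range."""
    specs = [
        (30, 57.0), (28, 53.2), (25, 52.5), (22, 50.6), (20, 48.0), (15, 42.0),
    ]
    return [TreatmentSchedule.weekday(n, dose) for n, dose in specs]


#: Dirichlet concentrations for partitioning patient clonogens over Gleason
#: patterns (GP2..GP5) and scores (2+2..5+5): mid grades dominate, extreme
#: grades are present but rare, mirroring surgical-cohort histology.
GP_CONCENTRATION = (0.8, 4.0, 4.0, 1.2)
GS_CONCENTRATION = (0.5, 1.2, 3.0, 3.0, 2.5, 2.0, 1.2, 0.8, 0.5)


def make_calibration_cohort(
    n_patients: int = 27,
    ground_truth: Optional[RadiosensitivityParams] = None,
    schedules: Optional[Sequence[TreatmentSchedule]] = None,
    mode: str = "total",
    noise_sd: float = 0.0,
    seed: int = 0,
    n_median: float = 3e5,
    n_sigma: float = 0.6,
    n_alpha: int = 128,
) -> tuple[CalibrationCohort, list[OutcomeTarget]]:
    """Synthetic secondary cohort plus outcome targets with known truth.

    Per-patient clonogen totals are log-normal (median ``n_median``,
    log-SD ``n_sigma``) and are partitioned over Gleason patterns and
    scores with Dirichlet weights, so partition sums reconcile exactly.
    Targets are the forward-model cohort-mean TCPs under ``ground_truth``
    (mode ``'total'``, ``'by_gp'`` or ``'by_gs'``), evaluated by
    deterministic quadrature, plus optional Gaussian noise.
    """
    gt = ground_truth or RadiosensitivityParams()
    scheds = list(schedules) if schedules is not None else chhip_like_schedules()
    rng = np.random.default_rng(seed)

    total = n_median * np.exp(rng.normal(0.0, n_sigma, size=n_patients))
    gp_w = rng.dirichlet(GP_CONCENTRATION, size=n_patients)
    gs_w = rng.dirichlet(GS_CONCENTRATION, size=n_patients)
    cohort = CalibrationCohort(
        total=total,
        gp=total[:, None] * gp_w,
        gs=total[:, None] * gs_w,
    )

    targets = []
    for sched in scheds:
        tcp = cohort_mean_tcp(cohort, sched, gt, mode, n_alpha=n_alpha)
        if noise_sd > 0:
            tcp += rng.normal(0.0, noise_sd)
        tcp = float(np.clip(tcp, 1e-4, 1.0 - 1e-4))
        targets.append(OutcomeTarget(sched, tcp))
    return cohort, targets
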