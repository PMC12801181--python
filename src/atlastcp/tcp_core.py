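"""Voxel-wise Poisson linear-quadratic tumor control probability model.

The model treats every voxel of the prostate as an independent Poisson
population of clonogenic tumor cells.  With ``N_i`` clonogens in voxel *i*,
dose per fraction ``d_i`` delivered in ``n`` fractions over ``T_exp`` days,
LQ radiosensitivity ``alpha`` (Gy^-1), alpha/beta ratio (Gy) and potential
doubling time ``T_pot`` (days), the per-clonogen surviving fraction is

    SF_i = exp(-alpha*n*d_i - (alpha/(alpha/beta))*n*d_i^2
               + ln(2)*T_exp/T_pot)

and the voxel control probability is ``TCP_i = exp(-N_i * SF_i)``.  The
whole-prostate TCP is the product of voxel TCPs.  Inter-patient variability
in radiosensitivity is modelled by sampling ``alpha`` from a truncated
log-normal distribution; the overall TCP is the Monte-Carlo mean of the
whole-prostate TCP across sampled "virtual patients".
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "GP_LABELS",
    "GS_LABELS",
    "RadiosensitivityParams",
    "TreatmentSchedule",
    "VoxelGrid",
    "ProstateModel",
    "TCPResult",
    "sample_alpha",
    "alpha_quadrature",
    "surviving_fraction",
    "voxel_tcp",
    "overall_tcp",
    "tcp_map",
]

#: Gleason patterns, least to most aggressive.
GP_LABELS: tuple[int, ...] = (2, 3, 4, 5)

#: Gleason scores (primary+secondary), least to most aggressive.
GS_LABELS: tuple[str, ...] = (
    "2+2", "3+2", "3+3", "3+4", "4+3", "4+4", "4+5", "5+4", "5+5",
)

# Truncation windows narrower than this probability mass cannot be sampled
# reliably in double precision.
_MIN_WINDOW_MASS = 1e-12


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RadiosensitivityParams:
    """Radiosensitivity parameter set for the LQ-Poisson TCP model.

    Parameters
    ----------
    alpha_mean, alpha_sd :
        Arithmetic mean and standard deviation (Gy^-1) of the *untruncated*
        log-normal alpha distribution modelling inter-patient variability.
    alpha_low, alpha_high :
        Hard truncation window for sampled alpha values (Gy^-1).
    ab_single :
        Gleason-grade-independent alpha/beta ratio (Gy).
    gp_alpha :
        Optional Gleason-Pattern-dependent alpha values (Gy^-1), keyed by
        pattern ``{2, 3, 4, 5}``; must be strictly decreasing with pattern.
    gs_ab :
        Optional Gleason-Score-dependent alpha/beta ratios (Gy), keyed by the
        nine score labels; must be strictly increasing along ``GS_LABELS``
        and lie in [1, 8.3] Gy.
    """

    alpha_mean: float = 0.15
    alpha_sd: float = 0.04
    alpha_low: float = 0.05
    alpha_high: float = 0.40
    ab_single: float = 1.77
    gp_alpha: Optional[Mapping[int, float]] = None
    gs_ab: Optional[Mapping[str, float]] = None

    #: Allowed window for GS-dependent alpha/beta ratios (Gy).
    GS_AB_BOUNDS = (1.0, 8.3)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_low < self.alpha_high):
            raise ValueError(
                f"require 0 < alpha_low < alpha_high, got "
                f"[{self.alpha_low}, {self.alpha_high}]"
            )
        if not (self.alpha_low < self.alpha_mean < self.alpha_high):
            raise ValueError("alpha_mean must lie inside the truncation window")
        if self.alpha_sd <= 0:
            raise ValueError("alpha_sd must be > 0")
        if self.ab_single <= 0:
            raise ValueError("ab_single must be > 0")
        if self.gp_alpha is not None:
            missing = [g for g in GP_LABELS if g not in self.gp_alpha]
            if missing:
                raise ValueError(f"gp_alpha missing patterns {missing}")
            vals = [float(self.gp_alpha[g]) for g in GP_LABELS]
            if not all(a > b for a, b in zip(vals, vals[1:])):
                raise ValueError(
                    "gp_alpha must be strictly decreasing with Gleason pattern"
                )
        if self.gs_ab is not None:
            missing = [s for s in GS_LABELS if s not in self.gs_ab]
            if missing:
                raise ValueError(f"gs_ab missing scores {missing}")
            vals = [float(self.gs_ab[s]) for s in GS_LABELS]
            if not all(a < b for a, b in zip(vals, vals[1:])):
                raise ValueError(
                    "gs_ab must be strictly increasing with Gleason score"
                )
            lo, hi = self.GS_AB_BOUNDS
            if min(vals) < lo or max(vals) > hi:
                raise ValueError(f"gs_ab values must lie in [{lo}, {hi}] Gy")

    # -- log-normal machinery ------------------------------------------------

    @property
    def _log_params(self) -> tuple[float, float]:
        """(mu, sigma) of the underlying normal so that the untruncated
        log-normal has arithmetic mean ``alpha_mean`` and SD ``alpha_sd``."""
        cv2 = (self.alpha_sd / self.alpha_mean) ** 2
        sigma2 = math.log1p(cv2)
        mu = math.log(self.alpha_mean) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)

    def alpha_distribution(self):
        """Frozen scipy log-normal (untruncated) for alpha."""
        mu, sigma = self._log_params
        return stats.lognorm(sigma, scale=math.exp(mu))

    def window_mass(self) -> float:
        """Probability mass of the truncation window under the log-normal."""
        d = self.alpha_distribution()
        return float(d.cdf(self.alpha_high) - d.cdf(self.alpha_low))

    @classmethod
    def reference(cls) -> "RadiosensitivityParams":
        """Load the packaged reference parameter set (calibrated literature
        values: single alpha/beta 1.77 Gy, the GP-dependent alpha quadruple
        and the GS-dependent alpha/beta nonuple)."""
        src = importlib.resources.files("atlastcp.data") / "default_params.yaml"
        raw = yaml.safe_load(src.read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RadiosensitivityParams":
        gp = raw.get("gp_alpha")
        gs = raw.get("gs_ab")
        return cls(
            alpha_mean=float(raw["alpha_mean"]),
            alpha_sd=float(raw["alpha_sd"]),
            alpha_low=float(raw["alpha_low"]),
            alpha_high=float(raw["alpha_high"]),
            ab_single=float(raw["ab_single"]),
            gp_alpha={int(k): float(v) for k, v in gp.items()} if gp else None,
            gs_ab={str(k): float(v) for k, v in gs.items()} if gs else None,
        )

    def to_dict(self) -> dict:
        out = {
            "alpha_mean": self.alpha_mean,
            "alpha_sd": self.alpha_sd,
            "alpha_low": self.alpha_low,
            "alpha_high": self.alpha_high,
            "ab_single": self.ab_single,
        }
        if self.gp_alpha is not None:
            out["gp_alpha"] = {int(k): float(v) for k, v in self.gp_alpha.items()}
        if self.gs_ab is not None:
            out["gs_ab"] = {str(k): float(v) for k, v in self.gs_ab.items()}
        return out

    def with_(self, **kw) -> "RadiosensitivityParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


@dataclass(frozen=True)
class TreatmentSchedule:
    """Dose-fractionation schedule.

    ``t_exp`` is the overall treatment time in days (first to last fraction)
    entering the repopulation term; ``t_pot`` the potential doubling time.
    """

    n_fractions: int
    prescription_dose: Optional[float] = None  # total dose, Gy
    t_exp: float = 0.0
    t_pot: float = 42.0

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.t_exp < 0:
            raise ValueError("t_exp must be >= 0")
        if self.t_pot <= 0:
            raise ValueError("t_pot must be > 0")
        if self.prescription_dose is not None and self.prescription_dose < 0:
            raise ValueError("prescription_dose must be >= 0")

    @classmethod
    def weekday(
        cls,
        n_fractions: int,
        prescription_dose: Optional[float] = None,
        t_pot: float = 42.0,
    ) -> "TreatmentSchedule":
        """Schedule delivered at 5 fractions/week (Mon-Fri).

        Overall time is the elapsed days from first to last fraction:
        ``t_exp = 7*((n-1)//5) + ((n-1) % 5)``.
        """
        n = int(n_fractions)
        t_exp = 7 * ((n - 1) // 5) + ((n - 1) % 5)
        return cls(n, prescription_dose, float(t_exp), t_pot)

    @property
    def dose_per_fraction(self) -> float:
        if self.prescription_dose is None:
            raise ValueError("schedule has no prescription dose")
        return self.prescription_dose / self.n_fractions

    @property
    def repopulation_log(self) -> float:
        """ln(2) * T_exp / T_pot, the repopulation term of the log-survival."""
        return math.log(2.0) * self.t_exp / self.t_pot


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid: shape, isotropic-or-not spacing (mm) and a 4x4
    world affine mapping voxel indices (i,j,k,1) to mm coordinates.

    Axis convention used throughout: axis 0 runs patient right to left,
    axis 1 anterior to posterior, axis 2 inferior to superior.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ValueError("grid must be three-dimensional")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.affine is None:
            aff = np.diag((*self.spacing, 1.0))
            object.__setattr__(self, "affine", aff)
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4):
                raise ValueError("affine must be 4x4")
            object.__setattr__(self, "affine", aff)

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def voxel_centers_mm(self) -> np.ndarray:
        """World coordinates (mm) of all voxel centers, shape (*shape, 3)."""
        idx = np.indices(self.shape, dtype=float)
        pts = np.stack([*idx, np.ones(self.shape)], axis=-1)
        world = pts @ self.affine.T
        return world[..., :3]

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


# ---------------------------------------------------------------------------
# alpha sampling
# ---------------------------------------------------------------------------


def sample_alpha(
    params: RadiosensitivityParams, count: int, seed: Optional[int] = None
) -> np.ndarray:
    """Draw ``count`` alpha values (Gy^-1) from the truncated log-normal.

    Sampling is by inverse-CDF restricted to the truncation window, so a
    degenerate (arbitrarily narrow) window is handled exactly and every draw
    lies strictly inside ``[alpha_low, alpha_high]``.  Deterministic for a
    fixed ``seed``.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    dist = params.alpha_distribution()
    lo_q = float(dist.cdf(params.alpha_low))
    hi_q = float(dist.cdf(params.alpha_high))
    if hi_q - lo_q < _MIN_WINDOW_MASS:
        raise ValueError(
            "truncation window "
            f"[{params.alpha_low}, {params.alpha_high}] Gy^-1 carries "
            f"negligible probability mass ({hi_q - lo_q:.3e}); "
            "sampling is infeasible"
        )
    rng = np.random.default_rng(seed)
    u = rng.uniform(lo_q, hi_q, size=count)
    vals = dist.ppf(u)
    return np.clip(vals, params.alpha_low, params.alpha_high)


def alpha_quadrature(
    params: RadiosensitivityParams, n_nodes: int = 128
) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights for expectations over the truncated
    log-normal alpha density.

    Returns ``(nodes, weights)`` with weights normalized to sum to one, so
    ``E[f(alpha)] ~= sum(w * f(nodes))``.
    """
    x, w = np.polynomial.legendre.leggauss(int(n_nodes))
    lo, hi = params.alpha_low, params.alpha_high
    nodes = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    dens = params.alpha_distribution().pdf(nodes)
    weights = w * dens
    total = weights.sum()
    if total <= 0:
        raise ValueError("alpha density vanishes on the truncation window")
    return nodes, weights / total


# ---------------------------------------------------------------------------
# LQ survival and voxel TCP
# ---------------------------------------------------------------------------


def surviving_fraction(alpha, ab, schedule: TreatmentSchedule, d) -> np.ndarray:
    """Per-clonogen surviving fraction after the full schedule.

    ``exp(-alpha*n*d - (alpha/ab)*n*d^2 + ln2*T_exp/T_pot)``.  Not clamped at
    one: at zero dose, repopulation legitimately yields values above unity.
    """
    alpha = np.asarray(alpha, dtype=float)
    ab = np.asarray(ab, dtype=float)
    d = np.asarray(d, dtype=float)
    if not (np.all(np.isfinite(alpha)) and np.all(np.isfinite(ab)) and np.all(np.isfinite(d))):
        raise ValueError("non-finite alpha, alpha/beta or dose")
    if np.any(alpha <= 0) or np.any(ab <= 0) or np.any(d < 0):
        raise ValueError("require alpha > 0, ab > 0, d >= 0")
    n = schedule.n_fractions
    log_sf = -alpha * n * d - (alpha / ab) * n * d**2 + schedule.repopulation_log
    return np.exp(log_sf)


def voxel_tcp(n_clonogens, sf) -> np.ndarray:
    """Poisson voxel control probability ``exp(-N * SF)``."""
    n_clonogens = np.asarray(n_clonogens, dtype=float)
    sf = np.asarray(sf, dtype=float)
    if np.any(n_clonogens < 0) or np.any(sf < 0):
        raise ValueError("clonogen count and surviving fraction must be >= 0")
    return np.exp(-n_clonogens * sf)


# ---------------------------------------------------------------------------
# Whole-prostate model
# ---------------------------------------------------------------------------


@dataclass
class ProstateModel:
    """Complete voxel model of one prostate.

    Per-voxel fields over the mask use the flattened C-order of
    ``np.flatnonzero(mask)``.  Each mask voxel carries either a *sampled*
    alpha (drawn from the log-normal per Monte-Carlo realization) or a fixed
    mixture of alpha values with weights summing to one (used for
    Gleason-Pattern mixtures, realized as independent Poisson
    subpopulations splitting ``N_i`` by the weights).

    Attributes
    ----------
    grid : VoxelGrid
    mask : bool array, full grid shape
    clonogens : float array, full grid shape; ``N_i`` on mask voxels
    dose_per_fraction : float array, full grid shape; ``d_i`` in Gy
    alpha_sample : (n_mask,) bool — True where alpha is sampled
    alpha_values : (n_mask, K) float — fixed alpha entries, NaN-padded
    alpha_weights : (n_mask, K) float — mixture weights, 0-padded
    ab_per_voxel : (n_mask,) float — alpha/beta ratio (Gy)
    """

    grid: VoxelGrid
    mask: np.ndarray
    clonogens: np.ndarray
    dose_per_fraction: np.ndarray
    alpha_sample: np.ndarray
    alpha_values: np.ndarray
    alpha_weights: np.ndarray
    ab_per_voxel: np.ndarray

    @property
    def n_mask(self) -> int:
        return int(np.count_nonzero(self.mask))

    @classmethod
    def homogeneous(
        cls,
        grid: VoxelGrid,
        mask: np.ndarray,
        clonogens_per_voxel: float,
        dose_per_fraction: float,
        ab: float,
        fixed_alpha: Optional[Sequence[tuple[float, float]]] = None,
    ) -> "ProstateModel":
        """Spatially uniform model; ``fixed_alpha`` is a list of
        (value, weight) pairs, or None to sample alpha."""
        mask = np.asarray(mask, dtype=bool)
        n_m = int(np.count_nonzero(mask))
        cl = np.zeros(mask.shape)
        cl[mask] = clonogens_per_voxel
        d = np.zeros(mask.shape)
        d[mask] = dose_per_fraction
        if fixed_alpha is None:
            sample = np.ones(n_m, dtype=bool)
            vals = np.full((n_m, 1), np.nan)
            wts = np.zeros((n_m, 1))
        else:
            sample = np.zeros(n_m, dtype=bool)
            vals = np.tile([v for v, _ in fixed_alpha], (n_m, 1)).astype(float)
            wts = np.tile([w for _, w in fixed_alpha], (n_m, 1)).astype(float)
        ab_v = np.full(n_m, float(ab))
        return cls(grid, mask, cl, d, sample, vals, wts, ab_v)

    def validate(self) -> None:
        if self.mask.dtype != bool or self.mask.shape != self.grid.shape:
            raise ValueError("mask must be boolean with the grid's shape")
        n_m = self.n_mask
        if n_m == 0:
            raise ValueError("empty prostate mask")
        for name in ("clonogens", "dose_per_fraction"):
            arr = getattr(self, name)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} must have the grid's shape")
            vals = arr[self.mask]
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"{name} has non-finite values on the mask")
            if np.any(vals < 0):
                raise ValueError(f"{name} has negative values on the mask")
        if self.alpha_sample.shape != (n_m,):
            raise ValueError("alpha_sample must have one entry per mask voxel")
        if self.alpha_values.shape != self.alpha_weights.shape or (
            self.alpha_values.shape[0] != n_m
        ):
            raise ValueError("alpha_values/alpha_weights shape mismatch")
        if self.ab_per_voxel.shape != (n_m,):
            raise ValueError("ab_per_voxel must have one entry per mask voxel")
        if np.any(self.ab_per_voxel <= 0):
            raise ValueError("alpha/beta must be > 0 on every mask voxel")
        has_fixed = np.nansum(self.alpha_weights, axis=1) > 0
        both = self.alpha_sample & has_fixed
        if np.any(both):
            raise ValueError(
                f"{int(both.sum())} voxel(s) carry both a sampling and a "
                "fixed-alpha specification"
            )
        fixed = ~self.alpha_sample
        if np.any(fixed):
            wsum = np.nansum(self.alpha_weights[fixed], axis=1)
            if not np.allclose(wsum, 1.0, atol=1e-9):
                raise ValueError("fixed-alpha weights must sum to 1 per voxel")
            w = self.alpha_weights[fixed]
            v = self.alpha_values[fixed]
            if np.any((w > 0) & ~np.isfinite(v)):
                raise ValueError("fixed-alpha entries with weight > 0 must be finite")


@dataclass(frozen=True)
class TCPResult:
    """Overall TCP and the per-voxel mean TCP map of one computation."""

    overall_tcp: float
    voxel_map: np.ndarray  # full grid, NaN outside the mask
    n_realizations: int
    seed: Optional[int]

    def __post_init__(self) -> None:
        if not (0.0 <= self.overall_tcp <= 1.0):
            raise ValueError("overall_tcp must lie in [0, 1]")


def _log_voxel_tcp_fixed(model: ProstateModel, schedule: TreatmentSchedule,
                         c: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    """log TCP_i for fixed-alpha voxels: mixture over (value, weight) pairs,
    each a Poisson subpopulation with w*N clonogens."""
    vals = model.alpha_values[fixed]          # (f, K)
    wts = model.alpha_weights[fixed]          # (f, K)
    n_cl = model.clonogens[model.mask][fixed]  # (f,)
    sf = np.where(
        wts > 0,
        np.exp(-np.nan_to_num(vals) * c[fixed][:, None] + schedule.repopulation_log),
        0.0,
    )
    return -n_cl * np.sum(wts * sf, axis=1)


def overall_tcp(
    model: ProstateModel,
    schedule: TreatmentSchedule,
    params: RadiosensitivityParams,
    n_realizations: int = 1000,
    seed: Optional[int] = None,
    per_voxel_sampling: bool = False,
) -> TCPResult:
    """Overall TCP and voxel TCP map by Monte-Carlo over alpha.

    Each realization draws one alpha shared by all sampling voxels (one
    "virtual patient"); with ``per_voxel_sampling`` every sampling voxel
    draws independently.  The whole-prostate TCP of a realization is the
    product of voxel TCPs over the mask (accumulated in log space) and the
    overall TCP is the mean across realizations.  The map holds per-voxel
    mean TCP.  Deterministic for fixed seed.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    model.validate()
    mask = model.mask
    d = model.dose_per_fraction[mask]
    n_cl = model.clonogens[mask]
    ab = model.ab_per_voxel
    n = schedule.n_fractions
    # log SF = -alpha * c_i + R with c_i = n*d + n*d^2/ab
    c = n * d + n * d**2 / ab
    r = schedule.repopulation_log

    sampling = model.alpha_sample
    fixed = ~sampling
    n_m = model.n_mask
    log_map = np.zeros(n_m)
    if np.any(fixed):
        log_map[fixed] = _log_voxel_tcp_fixed(model, schedule, c, fixed)
    log_fixed_total = float(np.sum(log_map[fixed]))

    if np.any(sampling):
        n_s = int(sampling.sum())
        alphas = sample_alpha(params, n_realizations * (n_s if per_voxel_sampling else 1), seed)
        c_s = c[sampling]
        n_s_cl = n_cl[sampling]
        mean_voxel = np.zeros(n_s)
        tcp_sum = 0.0
        chunk = max(1, int(5e6 / max(n_s, 1)))
        for start in range(0, n_realizations, chunk):
            stop = min(start + chunk, n_realizations)
            if per_voxel_sampling:
                a = alphas[start * n_s : stop * n_s].reshape(stop - start, n_s)
            else:
                a = alphas[start:stop][:, None]
            log_v = -n_s_cl[None, :] * np.exp(-a * c_s[None, :] + r)  # (k, n_s)
            tcp_sum += float(np.sum(np.exp(log_v.sum(axis=1) + log_fixed_total)))
            mean_voxel += np.exp(log_v).sum(axis=0)
        overall = tcp_sum / n_realizations
        voxel_mean = np.exp(log_map)
        voxel_mean[sampling] = mean_voxel / n_realizations
    else:
        overall = math.exp(log_fixed_total)
        voxel_mean = np.exp(log_map)

    vm = np.full(model.grid.shape, np.nan)
    vm[mask] = voxel_mean
    return TCPResult(
        overall_tcp=float(min(1.0, max(0.0, overall))),
        voxel_map=vm,
        n_realizations=int(n_realizations),
        seed=seed,
    )


def tcp_map(
    model: ProstateModel,
    schedule: TreatmentSchedule,
    params: RadiosensitivityParams,
    n_realizations: int = 1000,
    seed: Optional[int] = None,
    per_voxel_sampling: bool = False,
) -> np.ndarray:
    """Per-voxel mean-TCP field on the grid (NaN outside the mask)."""
    return overall_tcp(
        model, schedule, params, n_realizations, seed, per_voxel_sampling
    ).voxel_map
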