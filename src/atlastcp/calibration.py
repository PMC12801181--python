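"""Calibration of radiosensitivity parameters against outcome targets.

Given a secondary cohort of per-patient clonogen counts (total, and
stratified by Gleason Pattern and Gleason Score) and per-schedule observed
5-year control fractions, differential evolution (DE) fits

* a single grade-independent alpha/beta ratio,
* four Gleason-Pattern-dependent alpha values (strictly decreasing with
  pattern), or
* nine Gleason-Score-dependent alpha/beta ratios (strictly increasing with
  score, within [1, 8.3] Gy),

by minimizing the discrepancy between the model's cohort-mean TCP and the
observed control fraction per schedule.  Ranking constraints are enforced
by construction through a monotone reparameterization (a chain of bounded
increments), so every candidate the optimizer evaluates is feasible.

The expectation over the log-normal alpha distribution is evaluated by
fixed-node Gauss-Legendre quadrature on the truncated density by default,
giving the optimizer a smooth deterministic objective; a common-random-
numbers Monte-Carlo rule is available instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .tcp_core import (
    GP_LABELS,
    GS_LABELS,
    RadiosensitivityParams,
    TreatmentSchedule,
    alpha_quadrature,
    sample_alpha,
)

__all__ = [
    "OutcomeTarget",
    "CalibrationCohort",
    "CalibrationResult",
    "DEConfig",
    "cohort_mean_tcp",
    "discrepancy",
    "calibrate_single_ab",
    "calibrate_gp_alpha",
    "calibrate_gs_ab",
    "load_cohort_csv",
    "write_cohort_csv",
    "load_targets_csv",
    "write_targets_csv",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutcomeTarget:
    """One dose-fractionation schedule with its observed control fraction
    (e.g. 5-year biochemical/clinical failure-free rate)."""

    schedule: TreatmentSchedule
    observed_control: float

    def __post_init__(self) -> None:
        if not (0.0 < self.observed_control < 1.0):
            raise ValueError("observed_control must lie strictly in (0, 1)")


@dataclass(frozen=True)
class CalibrationCohort:
    """Per-patient clonogen counts: total, by Gleason Pattern (4 columns,
    order ``GP_LABELS``) and by Gleason Score (9 columns, order
    ``GS_LABELS``).  Partition sums must reconcile with the totals."""

    total: np.ndarray
    gp: Optional[np.ndarray] = None
    gs: Optional[np.ndarray] = None
    patient_ids: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        total = np.asarray(self.total, dtype=float)
        object.__setattr__(self, "total", total)
        if total.ndim != 1 or total.size == 0:
            raise ValueError("cohort must contain at least one patient")
        if np.any(total < 0) or not np.all(np.isfinite(total)):
            raise ValueError("clonogen totals must be finite and >= 0")
        for name, arr, k in (("gp", self.gp, 4), ("gs", self.gs, 9)):
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (total.size, k):
                raise ValueError(f"{name} counts must have shape (n, {k})")
            if np.any(arr < 0):
                raise ValueError(f"{name} counts must be >= 0")
            sums = arr.sum(axis=1)
            if not np.allclose(sums, total, rtol=1e-6, atol=1e-6):
                raise ValueError(
                    f"per-patient {name} counts do not sum to the totals"
                )

    @property
    def n_patients(self) -> int:
        return int(self.total.size)


@dataclass(frozen=True)
class DEConfig:
    """Differential-evolution and objective settings.

    ``n_alpha`` is the number of quadrature nodes (or Monte-Carlo samples
    when ``alpha_rule='monte-carlo'``) for the expectation over alpha.
    Remaining fields map onto :func:`scipy.optimize.differential_evolution`.
    """

    maxiter: int = 500
    popsize: int = 15
    mutation: tuple[float, float] = (0.5, 1.0)
    recombination: float = 0.7
    tol: float = 1e-8
    polish: bool = True
    n_alpha: int = 128
    alpha_rule: str = "quadrature"  # or "monte-carlo"
    metric: str = "mean_abs"  # or "rms"
    # multi-parameter fits refine the DE solution with multi-start bounded
    # least squares in the natural parameter space (see calibrate_gs_ab)
    refine: bool = True
    refine_restarts: int = 10
    refine_jitter_frac: float = 0.03


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted parameter set with objective value and optimizer metadata."""

    params: RadiosensitivityParams
    fitted: dict
    discrepancy: float
    n_iterations: int
    converged: bool
    seed: Optional[int]
    popsize: int
    metric: str
    message: str = ""
    sensitivity: dict = field(default_factory=dict)
    flat_parameters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.discrepancy < 0:
            raise ValueError("discrepancy must be >= 0")


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def _alpha_rule(
    params: RadiosensitivityParams, config: DEConfig, seed: Optional[int]
) -> tuple[np.ndarray, np.ndarray]:
    """(nodes, weights) for the expectation over alpha."""
    if config.alpha_rule == "quadrature":
        return alpha_quadrature(params, config.n_alpha)
    if config.alpha_rule == "monte-carlo":
        nodes = sample_alpha(params, config.n_alpha, seed)
        return nodes, np.full(nodes.size, 1.0 / nodes.size)
    raise ValueError(f"unknown alpha rule {config.alpha_rule!r}")


def _expected_cohort_tcp(
    counts: np.ndarray,  # (n_patients, n_groups)
    ab: np.ndarray,  # (n_groups,)
    schedule: TreatmentSchedule,
    alpha_nodes: np.ndarray,
    alpha_weights: np.ndarray,
) -> float:
    """Mean over patients of E_alpha[exp(-sum_g N_g * SF_g(alpha))], with one
    alpha draw shared by all groups of a patient (a 'virtual patient')."""
    n = schedule.n_fractions
    d = schedule.dose_per_fraction
    r = schedule.repopulation_log
    c = n * d + n * d * d / np.asarray(ab, dtype=float)  # (G,)
    sf = np.exp(-np.multiply.outer(alpha_nodes, c) + r)  # (K, G)
    log_surv = counts @ sf.T  # (P, K): total surviving clonogens
    tcp = np.exp(-log_surv)  # (P, K)
    per_patient = tcp @ alpha_weights
    return float(per_patient.mean())


def _deterministic_cohort_tcp(
    counts: np.ndarray,
    alpha: np.ndarray,  # (n_groups,)
    ab: float,
    schedule: TreatmentSchedule,
) -> float:
    """Mean patient TCP with fixed per-group alpha (no sampling)."""
    n = schedule.n_fractions
    d = schedule.dose_per_fraction
    r = schedule.repopulation_log
    sf = np.exp(-alpha * n * d - (alpha / ab) * n * d * d + r)  # (G,)
    tcp = np.exp(-(counts @ sf))
    return float(tcp.mean())


def cohort_mean_tcp(
    cohort: CalibrationCohort,
    schedule: TreatmentSchedule,
    params: RadiosensitivityParams,
    mode: str = "total",
    *,
    n_alpha: int = 128,
    alpha_rule: str = "quadrature",
    seed: Optional[int] = None,
    alpha_grid: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> float:
    """Unweighted cohort-mean TCP for one schedule.

    ``mode='total'`` uses the per-patient total counts with ``ab_single``
    and alpha integrated over its distribution; ``'by_gp'`` uses the fixed
    Gleason-Pattern alpha quadruple (deterministic); ``'by_gs'`` uses the
    Gleason-Score alpha/beta nonuple with alpha integrated.
    """
    if mode == "by_gp":
        if cohort.gp is None:
            raise ValueError("cohort carries no Gleason-Pattern counts")
        if params.gp_alpha is None:
            raise ValueError("params carry no Gleason-Pattern alpha values")
        alpha = np.array([params.gp_alpha[g] for g in GP_LABELS])
        return _deterministic_cohort_tcp(
            cohort.gp, alpha, params.ab_single, schedule
        )

    if alpha_grid is None:
        cfg = DEConfig(n_alpha=n_alpha, alpha_rule=alpha_rule)
        alpha_grid = _alpha_rule(params, cfg, seed)
    nodes, weights = alpha_grid

    if mode == "total":
        counts = cohort.total[:, None]
        ab = np.array([params.ab_single])
    elif mode == "by_gs":
        if cohort.gs is None:
            raise ValueError("cohort carries no Gleason-Score counts")
        if params.gs_ab is None:
            raise ValueError("params carry no Gleason-Score alpha/beta ratios")
        counts = cohort.gs
        ab = np.array([params.gs_ab[s] for s in GS_LABELS])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _expected_cohort_tcp(counts, ab, schedule, nodes, weights)


def discrepancy(
    model_tcps: Sequence[float],
    targets: Sequence,
    metric: str = "mean_abs",
) -> float:
    """Percent discrepancy between model TCPs and observed control rates.

    ``mean_abs``: 100 x mean |model - observed|; ``rms``: 100 x RMS of the
    differences.  ``targets`` may be :class:`OutcomeTarget` objects or plain
    fractions.
    """
    model = np.asarray(model_tcps, dtype=float)
    obs = np.asarray(
        [t.observed_control if isinstance(t, OutcomeTarget) else float(t)
         for t in targets]
    )
    if model.shape != obs.shape or model.size == 0:
        raise ValueError("model and target vectors must have equal length >= 1")
    diff = model - obs
    if metric == "mean_abs":
        return float(100.0 * np.mean(np.abs(diff)))
    if metric == "rms":
        return float(100.0 * np.sqrt(np.mean(diff**2)))
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# Monotone reparameterization
# ---------------------------------------------------------------------------

# DE searches u in [EPS, 1]^k; chains below map u to strictly ordered
# parameter tuples inside the bounds, so ranking constraints hold for every
# candidate at every iteration.
_U_EPS = 1e-3


def _chain_increasing(u: np.ndarray, low: float, high: float) -> np.ndarray:
    vals = np.empty(u.size)
    prev = low
    for i, ui in enumerate(u):
        prev = prev + ui * (high - prev)
        vals[i] = prev
    # increments underflow when the chain saturates at the upper bound;
    # cap at the bound and restore numerical strictness from the top down
    gap = (high - low) * 1e-12
    vals[-1] = min(vals[-1], high)
    for i in range(vals.size - 2, -1, -1):
        vals[i] = min(vals[i], vals[i + 1] - gap)
    return vals


def _chain_decreasing(u: np.ndarray, low: float, high: float) -> np.ndarray:
    vals = np.empty(u.size)
    prev = high
    for i, ui in enumerate(u):
        prev = prev - ui * (prev - low)
        vals[i] = prev
    gap = (high - low) * 1e-12
    vals[-1] = max(vals[-1], low)
    for i in range(vals.size - 2, -1, -1):
        vals[i] = max(vals[i], vals[i + 1] + gap)
    return vals


def _strictify_increasing(vals: np.ndarray, low: float, high: float) -> np.ndarray:
    """Clip an ascending vector into [low, high] and restore strict
    ordering broken by clipping or floating-point saturation."""
    gap = (high - low) * 1e-12
    vals = np.clip(np.asarray(vals, dtype=float), low, high)
    for i in range(vals.size - 2, -1, -1):
        vals[i] = min(vals[i], vals[i + 1] - gap)
    vals[0] = max(vals[0], low)
    for i in range(1, vals.size):
        vals[i] = max(vals[i], vals[i - 1] + gap)
    return vals


def _refine_ordered(
    resid_fn,
    x0: np.ndarray,
    low: float,
    high: float,
    config: DEConfig,
    seed: Optional[int],
) -> tuple[np.ndarray, float]:
    """Multi-start bounded least-squares refinement of an ordered parameter
    vector (ascending internal representation).

    The discrepancy surface has long, nearly flat curved valleys when some
    grade carries few clonogens; a trust-region least-squares pass on the
    smooth residual vector, restarted from jittered copies of the incumbent,
    locates the valley floor far more precisely than DE alone.  Returns the
    ascending solution and the final residual cost.
    """
    from scipy.optimize import least_squares

    rng = np.random.default_rng(seed)
    jitter = config.refine_jitter_frac * (high - low)
    best_x = np.sort(np.asarray(x0, dtype=float))
    best_cost = float(np.sum(np.square(resid_fn(best_x))) / 2.0)
    for k in range(config.refine_restarts + 1):
        if k == 0:
            start = best_x
        else:
            start = np.clip(
                np.sort(best_x + rng.normal(0.0, jitter, best_x.size)),
                low, high,
            )
        try:
            r = least_squares(
                resid_fn, start, bounds=(low, high),
                xtol=3e-16, ftol=3e-16, gtol=3e-16,
            )
        except Exception:  # pragma: no cover - optimizer edge failures
            continue
        if r.cost < best_cost:
            best_cost = float(r.cost)
            best_x = np.sort(r.x)
        if best_cost < 1e-20:
            break
    return best_x, best_cost


# ---------------------------------------------------------------------------
# Calibrations
# ---------------------------------------------------------------------------


def _run_de(objective, n_dim, config: DEConfig, seed, bounds=None):
    if bounds is None:
        bounds = [(_U_EPS, 1.0)] * n_dim
    return differential_evolution(
        objective,
        bounds,
        maxiter=config.maxiter,
        popsize=config.popsize,
        mutation=config.mutation,
        recombination=config.recombination,
        tol=config.tol,
        polish=config.polish,
        seed=seed,
        init="latinhypercube",
    )


def _sensitivity(objective, x_opt: np.ndarray, names: Sequence[str],
                 lo: float = _U_EPS, hi: float = 1.0,
                 flat_tol: float = 1e-6):
    """Central finite-difference |d objective / d parameter| at the optimum
    (in the optimizer's search space, clipped to [lo, hi]); parameters with
    negligible slope are reported as flat."""
    sens = {}
    flat = []
    f0 = objective(x_opt)
    h = (hi - lo) * 1e-3
    for i, name in enumerate(names):
        xp = x_opt.copy()
        xp[i] = min(hi, x_opt[i] + h)
        xm = x_opt.copy()
        xm[i] = max(lo, x_opt[i] - h)
        span = xp[i] - xm[i]
        g = abs(objective(xp) - objective(xm)) / span if span > 0 else 0.0
        sens[name] = float(g)
        if g < flat_tol * max(1.0, abs(f0)):
            flat.append(name)
    return sens, tuple(flat)


def calibrate_single_ab(
    cohort: CalibrationCohort,
    targets: Sequence[OutcomeTarget],
    de_config: Optional[DEConfig] = None,
    bounds: tuple[float, float] = (1.0, 8.3),
    seed: Optional[int] = 0,
    base_params: Optional[RadiosensitivityParams] = None,
) -> CalibrationResult:
    """Fit the single grade-independent alpha/beta ratio."""
    if len(targets) < 1:
        raise ValueError("at least one outcome target is required")
    if not (0 < bounds[0] < bounds[1]):
        raise ValueError("bounds must be positive and increasing")
    config = de_config or DEConfig()
    params0 = base_params or RadiosensitivityParams()
    grid = _alpha_rule(params0, config, seed)
    obs = [t.observed_control for t in targets]

    def objective(x):
        p = params0.with_(ab_single=float(x[0]))
        tcps = [
            cohort_mean_tcp(cohort, t.schedule, p, "total", alpha_grid=grid)
            for t in targets
        ]
        return discrepancy(tcps, obs, config.metric)

    res = _run_de(objective, 1, config, seed, bounds=[bounds])
    ab = float(res.x[0])
    sens, flat = _sensitivity(
        objective, res.x.astype(float), ["ab_single"],
        lo=bounds[0], hi=bounds[1],
    )
    return CalibrationResult(
        params=params0.with_(ab_single=ab),
        fitted={"ab_single": ab},
        discrepancy=float(res.fun),
        n_iterations=int(res.nit),
        converged=bool(res.success),
        seed=seed,
        popsize=config.popsize,
        metric=config.metric,
        message=str(res.message),
        sensitivity=sens,
        flat_parameters=flat,
    )


def calibrate_gp_alpha(
    cohort: CalibrationCohort,
    targets: Sequence[OutcomeTarget],
    ab_fixed: float,
    de_config: Optional[DEConfig] = None,
    bounds: tuple[float, float] = (0.05, 0.40),
    seed: Optional[int] = 0,
    base_params: Optional[RadiosensitivityParams] = None,
) -> CalibrationResult:
    """Fit the four Gleason-Pattern-dependent alpha values (Gy^-1), strictly
    decreasing with pattern, inside ``bounds``."""
    if cohort.gp is None:
        raise ValueError("cohort carries no Gleason-Pattern counts")
    if len(targets) < 1:
        raise ValueError("at least one outcome target is required")
    config = de_config or DEConfig()
    params0 = (base_params or RadiosensitivityParams()).with_(ab_single=float(ab_fixed))
    obs = [t.observed_control for t in targets]
    names = [f"alpha_gp{g}" for g in GP_LABELS]

    def model_tcps(alpha_desc):
        # alpha ordered GP2..GP5 (descending values)
        return np.array([
            _deterministic_cohort_tcp(cohort.gp, alpha_desc, ab_fixed, t.schedule)
            for t in targets
        ])

    def nat_disc(alpha_desc):
        return discrepancy(model_tcps(alpha_desc), obs, config.metric)

    def objective(u):
        return nat_disc(_chain_decreasing(np.asarray(u, float), *bounds))

    res = _run_de(objective, 4, config, seed)
    quad = _chain_decreasing(res.x.astype(float), *bounds)
    refine_cost = np.inf
    if config.refine:
        # ascending internal representation = (GP5..GP2)
        def resid(v_asc):
            return model_tcps(np.sort(v_asc)[::-1]) - np.asarray(obs)

        asc, refine_cost = _refine_ordered(resid, quad[::-1], *bounds, config, seed)
        quad = _strictify_increasing(asc, *bounds)[::-1]
    p_fit = params0.with_(gp_alpha=dict(zip(GP_LABELS, quad)))
    sens, flat = _sensitivity(nat_disc, quad.copy(), names,
                              lo=bounds[0], hi=bounds[1])
    return CalibrationResult(
        params=p_fit,
        fitted={n: float(p_fit.gp_alpha[g]) for n, g in zip(names, GP_LABELS)},
        discrepancy=nat_disc(quad),
        n_iterations=int(res.nit),
        converged=bool(res.success) or (config.refine and refine_cost < 1e-12),
        seed=seed,
        popsize=config.popsize,
        metric=config.metric,
        message=str(res.message),
        sensitivity=sens,
        flat_parameters=flat,
    )


def calibrate_gs_ab(
    cohort: CalibrationCohort,
    targets: Sequence[OutcomeTarget],
    alpha_dist: Optional[RadiosensitivityParams] = None,
    de_config: Optional[DEConfig] = None,
    bounds: tuple[float, float] = RadiosensitivityParams.GS_AB_BOUNDS,
    seed: Optional[int] = 0,
) -> CalibrationResult:
    """Fit the nine Gleason-Score-dependent alpha/beta ratios (Gy), strictly
    increasing with score, inside ``bounds`` (default [1, 8.3] Gy)."""
    if cohort.gs is None:
        raise ValueError("cohort carries no Gleason-Score counts")
    if len(targets) < 1:
        raise ValueError("at least one outcome target is required")
    config = de_config or DEConfig()
    params0 = alpha_dist or RadiosensitivityParams()
    grid = _alpha_rule(params0, config, seed)
    obs = [t.observed_control for t in targets]
    names = [f"ab_gs_{s}" for s in GS_LABELS]

    nodes, weights = grid

    def model_tcps(ab_asc):
        return np.array([
            _expected_cohort_tcp(cohort.gs, ab_asc, t.schedule, nodes, weights)
            for t in targets
        ])

    def nat_disc(ab_asc):
        return discrepancy(model_tcps(ab_asc), obs, config.metric)

    def objective(u):
        return nat_disc(_chain_increasing(np.asarray(u, float), *bounds))

    res = _run_de(objective, 9, config, seed)
    nonuple = _chain_increasing(res.x.astype(float), *bounds)
    refine_cost = np.inf
    if config.refine:
        def resid(v_asc):
            return model_tcps(np.sort(v_asc)) - np.asarray(obs)

        asc, refine_cost = _refine_ordered(resid, nonuple, *bounds, config, seed)
        nonuple = _strictify_increasing(asc, *bounds)
    p_fit = params0.with_(gs_ab=dict(zip(GS_LABELS, nonuple)))
    sens, flat = _sensitivity(nat_disc, nonuple.copy(), names,
                              lo=bounds[0], hi=bounds[1])
    return CalibrationResult(
        params=p_fit,
        fitted={n: float(p_fit.gs_ab[s]) for n, s in zip(names, GS_LABELS)},
        discrepancy=nat_disc(nonuple),
        n_iterations=int(res.nit),
        converged=bool(res.success) or (config.refine and refine_cost < 1e-12),
        seed=seed,
        popsize=config.popsize,
        metric=config.metric,
        message=str(res.message),
        sensitivity=sens,
        flat_parameters=flat,
    )


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

_GS_COLS = [f"gs_{s}" for s in GS_LABELS]
_GP_COLS = [f"gp{g}" for g in GP_LABELS]


def write_cohort_csv(cohort: CalibrationCohort, path: Union[str, Path]) -> None:
    """Columns: patient, total, gp2..gp5, gs_2+2..gs_5+5 (clonogen counts)."""
    n = cohort.n_patients
    ids = cohort.patient_ids or tuple(f"P{i+1:02d}" for i in range(n))
    df = pd.DataFrame({"patient": ids, "total": cohort.total})
    if cohort.gp is not None:
        for j, col in enumerate(_GP_COLS):
            df[col] = cohort.gp[:, j]
    if cohort.gs is not None:
        for j, col in enumerate(_GS_COLS):
            df[col] = cohort.gs[:, j]
    df.to_csv(path, index=False)


def load_cohort_csv(path: Union[str, Path]) -> CalibrationCohort:
    df = pd.read_csv(path)
    gp = df[_GP_COLS].to_numpy() if set(_GP_COLS) <= set(df.columns) else None
    gs = df[_GS_COLS].to_numpy() if set(_GS_COLS) <= set(df.columns) else None
    return CalibrationCohort(
        total=df["total"].to_numpy(),
        gp=gp,
        gs=gs,
        patient_ids=tuple(df["patient"].astype(str)),
    )


def write_targets_csv(
    targets: Sequence[OutcomeTarget], path: Union[str, Path],
    names: Optional[Sequence[str]] = None,
) -> None:
    """Columns: schedule, total_dose_gy, n_fractions, t_exp_days, t_pot_days,
    observed_control."""
    rows = []
    for i, t in enumerate(targets):
        rows.append(
            {
                "schedule": names[i] if names else f"S{i+1}",
                "total_dose_gy": t.schedule.prescription_dose,
                "n_fractions": t.schedule.n_fractions,
                "t_exp_days": t.schedule.t_exp,
                "t_pot_days": t.schedule.t_pot,
                "observed_control": t.observed_control,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_targets_csv(path: Union[str, Path]) -> list[OutcomeTarget]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        sched = TreatmentSchedule(
            n_fractions=int(r["n_fractions"]),
            prescription_dose=float(r["total_dose_gy"]),
            t_exp=float(r["t_exp_days"]),
            t_pot=float(r.get("t_pot_days", 42.0)),
        )
        out.append(OutcomeTarget(sched, float(r["observed_control"])))
    return out
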