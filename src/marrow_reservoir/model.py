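"""Idealised bone-marrow reservoir model of proinflammatory monocyte production.

The model tracks two state variables over the course of disease progression:

``m(t)``
    the fraction of the bone marrow's proinflammatory-cell resources that has
    been mobilised into the circulation; the remaining reservoir is ``1 - m``.
``c(t)``
    the marrow's capacity for readily producing such cells, a proxy that is
    indirectly coupled to the migration (chemotactic) capacity of circulating
    monocytes.

An exogenous signal ``I(t) >= 0`` drives production.  The governing equations
used throughout this package are::

    flux  = c * I * (1 - m)                      # production flux p(t)
    dm/dt = flux - (m - m0) / tau_m              # mobilisation vs replenishment
    dc/dt = (c0 - c) / tau_c - alpha * flux      # recovery vs depletion

Production is proportional to the remaining reservoir ``1 - m``, so even under
a constant signal the flux saturates as resources are consumed.  ``tau_m`` is
the natural replenishment time constant of the marrow, ``tau_c`` the recovery
time constant of its capacity towards the healthy baseline ``c0``, and
``alpha`` couples the synthesis flux to capacity depletion.

.. note::
   This algebraic form is a *reconstruction*: the published description of the
   model is verbal (a Markov state diagram plus the constraints quoted above),
   and no equations or parameter values are printed.  The form here is the
   minimal two-state law consistent with every stated constraint, and every
   coefficient is exposed so alternatives can be explored.

Integration uses the classical fixed-step 4th-order Runge-Kutta scheme.  Two
published scenarios are provided: *pathological* (constant signal; production
saturates and capacity declines monotonically through the SMC, MCI and AD
stages) and *rescue* (the signal is therapeutically removed at ``t_off``; both
state variables relax back to their healthy baselines).
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import IntegrationError, ValidationError

__all__ = [
    "ModelParams",
    "SignalSpec",
    "ModelState",
    "Trajectory",
    "StageMap",
    "DEFAULT_STAGE_MAP",
    "STAGES",
    "derivatives",
    "rk4_step",
    "analytic_relaxation",
    "simulate",
    "run_scenario",
    "stage_summaries",
]

logger = logging.getLogger(__name__)

#: Clinical stage labels in progression order.
STAGES = ("H", "SMC", "MCI", "AD")

_BOUND_TOL = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the reservoir model.

    Defaults place both relaxation time constants well beyond the simulated
    40-unit progression horizon, so that on the timescale of the disease the
    depletion of resources dominates replenishment — this is the regime in
    which a constant signal produces the published qualitative picture
    (monotone saturation of ``m``, strictly declining ``c``, near-zero flux by
    the AD stage).  See ``docs/methods.md`` for the full rationale.
    """

    tau_m: float = 1000.0  #: reservoir replenishment time constant (> 0)
    tau_c: float = 1000.0  #: capacity recovery time constant (> 0)
    alpha: float = 3.0     #: capacity depletion per unit production flux (>= 0)
    c0: float = 1.0        #: healthy baseline capacity, in (0, 1]
    m0: float = 0.05       #: healthy baseline circulating fraction, in (0, 1)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.tau_m) and self.tau_m > 0):
            raise ValidationError(f"tau_m must be > 0, got {self.tau_m}")
        if not (math.isfinite(self.tau_c) and self.tau_c > 0):
            raise ValidationError(f"tau_c must be > 0, got {self.tau_c}")
        if not (math.isfinite(self.alpha) and self.alpha >= 0):
            raise ValidationError(f"alpha must be >= 0, got {self.alpha}")
        if not (0 < self.c0 <= 1):
            raise ValidationError(f"c0 must be in (0, 1], got {self.c0}")
        if not (0 < self.m0 < 1):
            raise ValidationError(f"m0 must be in (0, 1), got {self.m0}")


@dataclass(frozen=True)
class SignalSpec:
    """Exogenous signal I(t).

    Kinds:

    - ``constant``: ``I(t) = level`` for all t.
    - ``step_off``: ``I(t) = level`` for ``t < t_off`` and 0 afterwards
      (the rescue intervention).
    - ``piecewise``: constant on the intervals delimited by ``breakpoints``;
      ``levels`` must have one more entry than ``breakpoints``.
    """

    kind: str = "constant"
    level: float = 0.1
    t_off: float | None = None
    breakpoints: tuple[float, ...] = ()
    levels: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "step_off", "piecewise"):
            raise ValidationError(
                f"signal.kind must be one of constant, step_off, piecewise; got {self.kind!r}"
            )
        if not (math.isfinite(self.level) and self.level >= 0):
            raise ValidationError(f"signal.level must be >= 0, got {self.level}")
        if self.kind == "step_off":
            if self.t_off is None or not (math.isfinite(self.t_off) and self.t_off >= 0):
                raise ValidationError(f"signal.t_off must be >= 0 for step_off, got {self.t_off}")
        if self.kind == "piecewise":
            if len(self.levels) != len(self.breakpoints) + 1:
                raise ValidationError(
                    "signal.levels must have exactly one more entry than signal.breakpoints"
                )
            if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
                raise ValidationError("signal.breakpoints must be strictly increasing")
            if any(not (math.isfinite(v) and v >= 0) for v in self.levels):
                raise ValidationError("signal.levels must all be >= 0")

    def value(self, t: float) -> float:
        """Signal magnitude at time ``t``."""
        if self.kind == "constant":
            return self.level
        if self.kind == "step_off":
            return self.level if t < self.t_off else 0.0
        return self.levels[bisect.bisect_right(self.breakpoints, t)]


@dataclass(frozen=True)
class ModelState:
    """A point of the model's phase space: (t, m, c).

    Only ``m`` is stored for the reservoir: its complement ``1 - m`` *is* the
    reservoir fraction, so the conservation ``reservoir + circulating = 1``
    holds identically by representation.
    """

    t: float
    m: float
    c: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.t):
            raise ValidationError(f"state.t must be finite, got {self.t}")
        if not (-_BOUND_TOL <= self.m <= 1 + _BOUND_TOL):
            raise ValidationError(f"state.m must be in [0, 1], got {self.m}")
        if not (math.isfinite(self.c) and self.c >= -_BOUND_TOL):
            raise ValidationError(f"state.c must be >= 0, got {self.c}")

    @property
    def reservoir(self) -> float:
        """Remaining reservoir fraction, 1 - m."""
        return 1.0 - self.m


@dataclass(frozen=True)
class StageMap:
    """Ordered assignment of clinical stages H < SMC < MCI < AD to model times."""

    times: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = tuple(self.times)
        if keys != STAGES:
            raise ValidationError(
                f"stage map must contain exactly the stages {STAGES} in order, got {keys}"
            )
        vals = [self.times[s] for s in STAGES]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValidationError(f"stage times must be strictly increasing in stage order, got {vals}")

    def __getitem__(self, stage: str) -> float:
        return self.times[stage]

    def items(self) -> Iterator[tuple[str, float]]:
        return ((s, self.times[s]) for s in STAGES)


DEFAULT_STAGE_MAP = StageMap({"H": 0.0, "SMC": 8.0, "MCI": 20.0, "AD": 35.0})


@dataclass(frozen=True)
class Trajectory:
    """A simulated path: state and production flux on a strictly increasing grid."""

    times: np.ndarray
    m_series: np.ndarray
    c_series: np.ndarray
    flux_series: np.ndarray
    params: ModelParams
    signal: SignalSpec

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.m_series) == len(self.c_series) == len(self.flux_series) == n):
            raise ValidationError("trajectory series must all have the same length")
        if n < 2 or np.any(np.diff(self.times) <= 0):
            raise ValidationError("trajectory times must be strictly increasing with >= 2 points")
        if np.any(self.flux_series < -_BOUND_TOL):
            raise ValidationError("trajectory flux_series must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with columns t, m, c, flux."""
        return pd.DataFrame(
            {"t": self.times, "m": self.m_series, "c": self.c_series, "flux": self.flux_series}
        )

    def to_csv(self, path, comment: str | None = None) -> None:
        """Write the trajectory as CSV, optionally preceded by a '#' comment line."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            if comment:
                fh.write(f"# {comment}\n")
            self.to_frame().to_csv(fh, index=False, lineterminator="\n")


def derivatives(
    state: ModelState, params: ModelParams, i_value: float
) -> tuple[float, float, float]:
    """Right-hand side of the reservoir ODEs.

    Returns ``(dm, dc, flux)`` where ``flux = c * I * (1 - m)`` is the
    instantaneous production flux of proinflammatory cells.
    """
    if not (math.isfinite(i_value) and i_value >= 0):
        raise ValidationError(f"i_value must be >= 0, got {i_value}")
    if state.c > params.c0 + 1e-9:
        raise ValidationError(
            f"state.c must not exceed params.c0 ({params.c0}), got {state.c}"
        )
    flux = state.c * i_value * (1.0 - state.m)
    dm = flux - (state.m - params.m0) / params.tau_m
    dc = (params.c0 - state.c) / params.tau_c - params.alpha * flux
    return dm, dc, flux


def rk4_step(state: ModelState, h: float, params: ModelParams, signal: SignalSpec) -> ModelState:
    """One classical four-stage Runge-Kutta step of size ``h``.

    The signal is evaluated at t, t + h/2 and t + h.  The returned state is
    clamped to the physical box m in [0, 1], c in [0, c0]; a clamp event is
    logged at debug level (with valid parameters and a nonnegative signal the
    dynamics stay inside the box up to roundoff, so clamping is a safety net
    for very large steps).
    """
    if not (math.isfinite(h) and h > 0):
        raise ValidationError(f"step size h must be > 0, got {h}")
    t, m, c = state.t, state.m, state.c
    i0 = signal.value(t)
    i1 = signal.value(t + h / 2.0)
    i2 = signal.value(t + h)

    def _der(mm: float, cc: float, ii: float) -> tuple[float, float]:
        f = cc * ii * (1.0 - mm)
        return f - (mm - params.m0) / params.tau_m, (params.c0 - cc) / params.tau_c - params.alpha * f

    k1m, k1c = _der(m, c, i0)
    k2m, k2c = _der(m + h / 2.0 * k1m, c + h / 2.0 * k1c, i1)
    k3m, k3c = _der(m + h / 2.0 * k2m, c + h / 2.0 * k2c, i1)
    k4m, k4c = _der(m + h * k3m, c + h * k3c, i2)
    m_new = m + h / 6.0 * (k1m + 2.0 * k2m + 2.0 * k3m + k4m)
    c_new = c + h / 6.0 * (k1c + 2.0 * k2c + 2.0 * k3c + k4c)
    if not (math.isfinite(m_new) and math.isfinite(c_new)):
        raise IntegrationError(f"non-finite state after RK4 step at t={t} with h={h}")
    m_cl = min(max(m_new, 0.0), 1.0)
    c_cl = min(max(c_new, 0.0), params.c0)
    if m_cl != m_new or c_cl != c_new:
        logger.debug(
            "clamped state at t=%g: m %.6g -> %.6g, c %.6g -> %.6g", t + h, m_new, m_cl, c_new, c_cl
        )
    return ModelState(t=t + h, m=m_cl, c=c_cl)


def analytic_relaxation(state0: ModelState, params: ModelParams, t: float) -> ModelState:
    """Closed-form state after elapsed time ``t`` with the signal identically zero.

    With I = 0 the two equations decouple into independent linear relaxations::

        m(t) = m0 + (m_init - m0) * exp(-t / tau_m)
        c(t) = c0 + (c_init - c0) * exp(-t / tau_c)

    This serves as the exact oracle for the numerical integrator.
    """
    if not (math.isfinite(t) and t >= 0):
        raise ValidationError(f"elapsed time t must be >= 0, got {t}")
    m = params.m0 + (state0.m - params.m0) * math.exp(-t / params.tau_m)
    c = params.c0 + (state0.c - params.c0) * math.exp(-t / params.tau_c)
    return ModelState(t=state0.t + t, m=m, c=c)


def simulate(
    params: ModelParams,
    signal: SignalSpec,
    initial: ModelState | None = None,
    t_end: float = 40.0,
    h: float = 0.01,
) -> Trajectory:
    """Integrate the model on a uniform grid from ``initial.t`` to ``t_end``.

    The grid has step ``h``; if the horizon is not an integer multiple of
    ``h``, one final shorter step lands exactly on ``t_end``.  The healthy
    baseline ``(m0, c0)`` at t = 0 is the default initial state.
    """
    if initial is None:
        initial = ModelState(t=0.0, m=params.m0, c=params.c0)
    if not (t_end > initial.t):
        raise ValidationError(f"t_end ({t_end}) must exceed the initial time ({initial.t})")
    if not (math.isfinite(h) and h > 0):
        raise ValidationError(f"step size h must be > 0, got {h}")
    span = t_end - initial.t
    if h > span * (1 + 1e-12):
        raise ValidationError(f"step size h ({h}) must not exceed the horizon ({span})")

    n_full = int(math.floor(span / h + 1e-9))
    remainder = span - n_full * h
    times = [initial.t]
    m_series = [initial.m]
    c_series = [initial.c]
    flux_series = [initial.c * signal.value(initial.t) * (1.0 - initial.m)]
    state = initial
    for _ in range(n_full):
        state = rk4_step(state, h, params, signal)
        times.append(state.t)
        m_series.append(state.m)
        c_series.append(state.c)
        flux_series.append(state.c * signal.value(state.t) * (1.0 - state.m))
    if remainder > 1e-9 * max(1.0, abs(t_end)):
        state = rk4_step(state, remainder, params, signal)
        times.append(t_end)  # land exactly on the requested horizon
        m_series.append(state.m)
        c_series.append(state.c)
        flux_series.append(state.c * signal.value(t_end) * (1.0 - state.m))
    return Trajectory(
        times=np.asarray(times, dtype=float),
        m_series=np.asarray(m_series, dtype=float),
        c_series=np.asarray(c_series, dtype=float),
        flux_series=np.asarray(flux_series, dtype=float),
        params=params,
        signal=signal,
    )


#: Recognised scenario names.
SCENARIOS = ("pathological", "rescue")


def run_scenario(
    name: str,
    params: ModelParams | None = None,
    *,
    level: float = 0.1,
    t_off: float = 10.0,
    t_end: float | None = None,
    h: float | None = None,
    stage_map: StageMap | None = None,
    initial: ModelState | None = None,
) -> tuple[Trajectory, StageMap]:
    """Simulate one of the two published scenarios and attach the stage map.

    ``pathological``
        constant exogenous signal over a 40-unit horizon; production rises at
        the SMC stage, declines through MCI and is nearly zero at AD while
        capacity falls monotonically.
    ``rescue``
        the same signal switched off at ``t_off``; the default horizon
        ``t_off + 6 * max(tau_m, tau_c)`` is long enough for both state
        variables to return to within 1% of their healthy baselines (the
        default step is coarser there because the post-rescue dynamics are a
        pure slow relaxation).

    ``t_off`` is aligned to the integration grid by construction (it must be
    an integer multiple of the step), so the signal discontinuity never falls
    inside an RK4 step.
    """
    if name not in SCENARIOS:
        raise ValidationError(f"unknown scenario {name!r}; valid scenarios: {', '.join(SCENARIOS)}")
    params = params or ModelParams()
    if name == "pathological":
        signal = SignalSpec(kind="constant", level=level)
        t_end = 40.0 if t_end is None else t_end
        h = 0.01 if h is None else h
    else:
        h = 0.05 if h is None else h
        k = round(t_off / h)
        if abs(k * h - t_off) > 1e-9:
            raise ValidationError(
                f"rescue t_off ({t_off}) must be an integer multiple of the step h ({h})"
            )
        signal = SignalSpec(kind="step_off", level=level, t_off=t_off)
        if t_end is None:
            t_end = t_off + 6.0 * max(params.tau_m, params.tau_c)
    traj = simulate(params, signal, initial=initial, t_end=t_end, h=h)
    return traj, (stage_map or DEFAULT_STAGE_MAP)


def stage_summaries(traj: Trajectory, stages: StageMap) -> pd.DataFrame:
    """State and flux at each clinical stage, one row per stage in H -> AD order.

    Stage times are resolved to the nearest grid point; exact ties break
    toward the earlier point.
    """
    times = traj.times
    rows = []
    for stage, t_stage in stages.items():
        if t_stage < times[0] - 1e-9 or t_stage > times[-1] + 1e-9:
            raise ValidationError(
                f"stage {stage!r} time {t_stage} lies outside the simulated horizon "
                f"[{times[0]}, {times[-1]}]"
            )
        j = int(np.searchsorted(times, t_stage))
        j = min(j, len(times) - 1)
        if j > 0 and abs(times[j - 1] - t_stage) <= abs(times[j] - t_stage):
            j -= 1  # ties (and closer-left) resolve to the earlier grid point
        rows.append(
            {
                "stage": stage,
                "t": times[j],
                "m": traj.m_series[j],
                "c": traj.c_series[j],
                "flux": traj.flux_series[j],
            }
        )
    return pd.DataFrame(rows)
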