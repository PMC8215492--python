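"""Model-to-data bridge and loss-based calibration.

The reservoir model is formulated in abstract state variables; this module
maps them onto the two stage-wise quantities a cohort actually measures:

- the *inflammatory share* — the summed percentage of the intermediate and
  non-classical monocyte subsets — predicted affinely from the circulating
  fraction, ``share = a_m + b_m * m(t_stage)``;
- the *relative chemotaxis* — group-mean basal migrated-cell counts
  normalised to the healthy group — predicted as ``c(t_stage) / c0``.

The affine bridge is a deliberately simple, swappable choice (the study
asserts qualitative agreement between model and data without defining the
correspondence).  ``fit`` minimises a weighted stage-wise sum of squared
differences by a coarse full-factorial grid scan followed by Nelder-Mead
refinement of the best grid points.

Identifiability: eight data points (four stages, two observables) cannot pin
down many parameters.  By default only ``{alpha, level, a_m, b_m}`` are free
with both time constants fixed, and even that set is sloppy — ``level``
trades off against the affine map — so the parameter-recovery study in the
test suite profiles the mechanistic pair ``{alpha, level}`` with the map
fixed.  See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cohort import GROUPS
from .errors import IntegrationError, ValidationError
from .model import DEFAULT_STAGE_MAP, ModelParams, StageMap, Trajectory, stage_summaries

__all__ = [
    "ObservableMap",
    "FitConfig",
    "FitResult",
    "FIT_PARAM_NAMES",
    "predict_observables",
    "observed_stage_vector",
    "loss",
    "fit",
]

#: Model-side quantities that ``fit`` may treat as free.
FIT_PARAM_NAMES = ("tau_m", "tau_c", "alpha", "level", "a_m", "b_m")

_GROUP_TO_STAGE = dict(zip(GROUPS, ("H", "SMC", "MCI", "AD")))


@dataclass(frozen=True)
class ObservableMap:
    """Affine bridge from model state to measured stage-wise observables."""

    a_m: float = 6.0   #: inflammatory-share intercept (percent)
    b_m: float = 27.0  #: inflammatory-share slope per unit m (percent)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a_m)):
            raise ValidationError(f"a_m must be finite, got {self.a_m}")
        if not (math.isfinite(self.b_m) and self.b_m >= 0):
            raise ValidationError(f"b_m must be >= 0, got {self.b_m}")


@dataclass(frozen=True)
class FitResult:
    theta_hat: dict[str, float]
    loss: float
    n_evals: int
    converged: bool


@dataclass
class FitConfig:
    """Configuration of the calibration forward model and optimiser."""

    params: ModelParams = field(default_factory=ModelParams)
    level: float = 0.1
    observable_map: ObservableMap = field(default_factory=ObservableMap)
    stage_map: StageMap = DEFAULT_STAGE_MAP
    h: float = 0.5            # integration step; dynamics are slow, RK4 error is negligible
    weight_share: float = 1.0   # percent^-2
    weight_chemo: float = 100.0  # balances the unit-scale chemotaxis observable
    grid_points: int = 8
    n_starts: int = 3
    jitter: float = 0.01      # relative jitter on the refinement starts (seeded)
    seed: int = 0
    fatol: float = 1e-10
    xatol: float = 1e-8
    maxiter: int = 1000


def predict_observables(
    traj: Trajectory, stages: StageMap, observable_map: ObservableMap
) -> pd.DataFrame:
    """Apply the observable maps at each stage time of a simulated trajectory."""
    summary = stage_summaries(traj, stages)
    return pd.DataFrame(
        {
            "stage": summary["stage"],
            "inflammatory_share_pct": observable_map.a_m
            + observable_map.b_m * summary["m"].to_numpy(),
            "relative_chemotaxis": summary["c"].to_numpy() / traj.params.c0,
        }
    )


def observed_stage_vector(cohort: pd.DataFrame) -> pd.DataFrame:
    """Stage-wise observed vector from a cohort table.

    Returns one row per stage (H -> AD, from the HC/SMC/MCI/AD groups) with
    the group-mean intermediate + non-classical percentage and the group-mean
    basal chemotaxis normalised to the healthy-control mean.
    """
    present = set(cohort["group"].unique())
    missing = [g for g in GROUPS if g not in present]
    if missing:
        raise ValidationError(f"cohort is missing group(s): {', '.join(missing)}")
    hc_mean = cohort.loc[cohort["group"] == "HC", "chemo_basal"].mean()
    if hc_mean <= 0:
        raise ValidationError("healthy-control mean chemotaxis must be > 0 for normalisation")
    rows = []
    for group in GROUPS:
        sub = cohort[cohort["group"] == group]
        share = (sub["intermediate_pct"] + sub["nonclassical_pct"]).mean()
        rows.append(
            {
                "stage": _GROUP_TO_STAGE[group],
                "inflammatory_share_pct": float(share),
                "relative_chemotaxis": float(sub["chemo_basal"].mean() / hc_mean),
            }
        )
    return pd.DataFrame(rows)


def loss(predicted, observed, weights=None) -> float:
    """Weighted sum of squared differences between two stage vectors.

    ``predicted`` and ``observed`` are flat numeric vectors of equal length
    (or the DataFrames returned by :func:`predict_observables` /
    :func:`observed_stage_vector`, which are flattened share-then-chemotaxis);
    ``weights`` is a scalar or per-entry vector, default 1.
    """
    p = _as_vector(predicted)
    o = _as_vector(observed)
    if p.shape != o.shape:
        raise ValidationError(f"predicted and observed lengths differ: {p.shape} vs {o.shape}")
    w = np.ones_like(p) if weights is None else np.broadcast_to(
        np.asarray(weights, dtype=float), p.shape
    )
    if np.any(w < 0):
        raise ValidationError("weights must be nonnegative")
    return float(np.sum(w * (p - o) ** 2))


def _as_vector(x) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        return np.concatenate(
            [
                x["inflammatory_share_pct"].to_numpy(dtype=float),
                x["relative_chemotaxis"].to_numpy(dtype=float),
            ]
        )
    return np.asarray(x, dtype=float).ravel()


def _stage_grid(stage_map: StageMap, h: float) -> tuple[list[int], int]:
    """Grid indices of the stage times; stages must sit on the step grid."""
    idx = []
    for stage, t_s in stage_map.items():
        k = round(t_s / h)
        if abs(k * h - t_s) > 1e-9:
            raise ValidationError(
                f"stage {stage!r} time {t_s} is not a multiple of the fit step h={h}"
            )
        idx.append(int(k))
    return idx, idx[-1]


def _stage_states_batch(
    tau_m, tau_c, alpha, level, m0: float, c0: float, stage_idx: list[int], n_steps: int, h: float
):
    """Vectorised RK4 over a batch of parameter vectors.

    All of ``tau_m, tau_c, alpha, level`` broadcast to a common batch shape;
    returns ``(m_stages, c_stages)`` of shape (n_stages, batch).  The
    arithmetic mirrors :func:`marrow_reservoir.model.rk4_step` exactly so that
    batched grid evaluation and the scalar simulator agree to roundoff.
    """
    tau_m, tau_c, alpha, level = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (tau_m, tau_c, alpha, level))
    )
    shape = tau_m.shape
    m = np.full(shape, m0)
    c = np.full(shape, c0)
    out_m = np.empty((len(stage_idx),) + shape)
    out_c = np.empty_like(out_m)
    pos = 0
    while pos < len(stage_idx) and stage_idx[pos] == 0:
        out_m[pos], out_c[pos] = m, c
        pos += 1

    def _der(mm, cc):
        f = cc * level * (1.0 - mm)
        return f - (mm - m0) / tau_m, (c0 - cc) / tau_c - alpha * f

    for i in range(n_steps):
        k1m, k1c = _der(m, c)
        k2m, k2c = _der(m + h / 2.0 * k1m, c + h / 2.0 * k1c)
        k3m, k3c = _der(m + h / 2.0 * k2m, c + h / 2.0 * k2c)
        k4m, k4c = _der(m + h * k3m, c + h * k3c)
        m = m + h / 6.0 * (k1m + 2.0 * k2m + 2.0 * k3m + k4m)
        c = c + h / 6.0 * (k1c + 2.0 * k2c + 2.0 * k3c + k4c)
        while pos < len(stage_idx) and stage_idx[pos] == i + 1:
            out_m[pos], out_c[pos] = m, c
            pos += 1
    return out_m, out_c


def fit(
    observed,
    free_params: tuple[str, ...] = ("alpha", "level", "a_m", "b_m"),
    bounds: dict[str, tuple[float, float]] | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Calibrate free model parameters to an observed stage vector.

    ``observed`` is the DataFrame from :func:`observed_stage_vector` (or any
    equivalent stage table).  A full-factorial grid of ``grid_points`` values
    per free dimension is scanned first (vectorised), then the ``n_starts``
    best grid points seed bounded Nelder-Mead refinements; the seed controls
    only the small jitter applied to the refinement starts.  The returned
    point always lies within the bounds.
    """
    config = config or FitConfig()
    free_params = tuple(free_params)
    for name in free_params:
        if name not in FIT_PARAM_NAMES:
            raise ValidationError(
                f"unknown free parameter {name!r}; valid names: {', '.join(FIT_PARAM_NAMES)}"
            )
    if len(set(free_params)) != len(free_params) or not free_params:
        raise ValidationError("free_params must be a non-empty set of distinct names")
    default_bounds = {
        "tau_m": (10.0, 5000.0),
        "tau_c": (10.0, 5000.0),
        "alpha": (0.5, 8.0),
        "level": (0.02, 0.3),
        "a_m": (0.0, 14.0),
        "b_m": (7.0, 42.0),
    }
    bounds = {**default_bounds, **(bounds or {})}
    for name in free_params:
        lo, hi = bounds[name]
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValidationError(f"bounds for {name!r} must be finite with lo < hi")

    y = _as_vector(observed)
    n_stages = len(list(config.stage_map.items()))
    if y.shape != (2 * n_stages,):
        raise ValidationError(
            f"observed vector must have {2 * n_stages} entries (shares then chemotaxis)"
        )
    w = np.concatenate(
        [np.full(n_stages, config.weight_share), np.full(n_stages, config.weight_chemo)]
    )
    stage_idx, n_steps = _stage_grid(config.stage_map, config.h)

    base = {
        "tau_m": config.params.tau_m,
        "tau_c": config.params.tau_c,
        "alpha": config.params.alpha,
        "level": config.level,
        "a_m": config.observable_map.a_m,
        "b_m": config.observable_map.b_m,
    }
    m0, c0 = config.params.m0, config.params.c0

    def _loss_batch(theta_cols: dict[str, np.ndarray]) -> np.ndarray:
        p = {name: theta_cols.get(name, base[name]) for name in FIT_PARAM_NAMES}
        sm, sc = _stage_states_batch(
            p["tau_m"], p["tau_c"], p["alpha"], p["level"], m0, c0, stage_idx, n_steps, config.h
        )
        share = np.asarray(p["a_m"]) + np.asarray(p["b_m"]) * sm
        chemo = sc / c0
        pred = np.concatenate([share, chemo], axis=0)  # (2*n_stages, batch)
        resid = pred - y[:, None] if pred.ndim == 2 else pred - y
        return (w[:, None] * resid**2).sum(axis=0) if pred.ndim == 2 else float((w * resid**2).sum())

    # --- coarse full-factorial grid scan (vectorised over candidates) ---
    axes = [np.linspace(*bounds[name], config.grid_points) for name in free_params]
    mesh = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([m.ravel() for m in mesh], axis=1)  # (n_cand, d)
    if len(grid) > 200_000:
        raise ValidationError(
            f"grid of {len(grid)} candidate points is too large; reduce grid_points"
        )
    grid_losses = _loss_batch({name: grid[:, j] for j, name in enumerate(free_params)})
    if not np.all(np.isfinite(grid_losses)):
        bad = grid[int(np.argmax(~np.isfinite(grid_losses)))]
        raise IntegrationError(f"non-finite loss at grid point {dict(zip(free_params, bad))}")
    n_evals = len(grid)

    def _loss_scalar(theta: np.ndarray) -> float:
        cols = {name: np.asarray([theta[j]]) for j, name in enumerate(free_params)}
        return float(_loss_batch(cols)[0])

    # --- Nelder-Mead refinement from the best (jittered) grid points ---
    rng = np.random.default_rng(config.seed)
    order = np.argsort(grid_losses)[: max(1, config.n_starts)]
    nm_bounds = [bounds[name] for name in free_params]
    best = None
    converged = False
    for rank, j in enumerate(order):
        x0 = grid[j].copy()
        if rank > 0 and config.jitter > 0:  # keep the best grid point pristine
            span = np.array([hi - lo for lo, hi in nm_bounds])
            x0 = np.clip(
                x0 + config.jitter * span * rng.uniform(-1, 1, size=len(x0)),
                [lo for lo, _ in nm_bounds],
                [hi for _, hi in nm_bounds],
            )
        res = minimize(
            _loss_scalar,
            x0,
            method="Nelder-Mead",
            bounds=nm_bounds,
            options={
                "fatol": config.fatol,
                "xatol": config.xatol,
                "maxiter": config.maxiter,
                "maxfev": 2 * config.maxiter,
            },
        )
        n_evals += int(res.nfev)
        converged = converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    theta_hat = {name: float(v) for name, v in zip(free_params, best.x)}
    return FitResult(theta_hat=theta_hat, loss=float(best.fun), n_evals=n_evals, converged=converged)
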