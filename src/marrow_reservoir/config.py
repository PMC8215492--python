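"""Run configuration: loading, validation, serialisation and seed derivation.

A run configuration is a YAML (or JSON) document with up to five top-level
keys — ``model``, ``cohort``, ``analysis``, ``calibration`` and ``seed``.
Every key is optional and defaults are filled in; an *empty* file therefore
yields the all-defaults configuration with every pipeline stage enabled.
Setting a block explicitly to ``null`` disables that stage (and the stages
that depend on it).  Unknown keys anywhere are rejected with an error naming
the offending path.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibrate import FIT_PARAM_NAMES
from .cohort import CohortConfig
from .errors import ValidationError
from .model import DEFAULT_STAGE_MAP, ModelParams, SignalSpec, StageMap

__all__ = [
    "ModelRunConfig",
    "AnalysisConfig",
    "CalibrationConfig",
    "RunConfig",
    "load_config",
    "save_config",
    "config_to_dict",
    "config_hash",
    "derive_seed",
]


@dataclass
class ModelRunConfig:
    params: ModelParams = field(default_factory=ModelParams)
    signal: SignalSpec = field(default_factory=SignalSpec)
    t_end: float = 40.0
    h: float = 0.01
    stage_map: StageMap = DEFAULT_STAGE_MAP


@dataclass
class AnalysisConfig:
    plan: list | None = None  # None -> stats.default_plan()
    alpha: float = 0.05
    n_mc: int = 200_000


@dataclass
class CalibrationConfig:
    free_params: tuple[str, ...] = ("alpha", "level", "a_m", "b_m")
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    level: float = 0.1
    a_m: float = 6.0
    b_m: float = 27.0
    h: float = 0.5
    weight_share: float = 1.0
    weight_chemo: float = 100.0
    grid_points: int = 8
    n_starts: int = 3
    jitter: float = 0.01


@dataclass
class RunConfig:
    model: ModelRunConfig = field(default_factory=ModelRunConfig)
    cohort: CohortConfig | None = field(default_factory=CohortConfig)
    analysis: AnalysisConfig | None = field(default_factory=AnalysisConfig)
    calibration: CalibrationConfig | None = field(default_factory=CalibrationConfig)
    seed: int = 0


def _check_keys(d: dict, allowed: set[str], path: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        name = sorted(unknown)[0]
        raise ValidationError(f"unknown configuration key {path}{name!r}")


def _num(d: dict, key: str, default, path: str):
    v = d.get(key, default)
    if not isinstance(v, (int, float)) or isinstance(v, bool):
        raise ValidationError(f"{path}{key} must be a number, got {v!r}")
    return v


def _build_model(d: dict) -> ModelRunConfig:
    _check_keys(
        d, {"tau_m", "tau_c", "alpha", "c0", "m0", "signal", "t_end", "h", "stage_map"}, "model."
    )
    dflt = ModelParams()
    try:
        params = ModelParams(
            tau_m=_num(d, "tau_m", dflt.tau_m, "model."),
            tau_c=_num(d, "tau_c", dflt.tau_c, "model."),
            alpha=_num(d, "alpha", dflt.alpha, "model."),
            c0=_num(d, "c0", dflt.c0, "model."),
            m0=_num(d, "m0", dflt.m0, "model."),
        )
    except ValidationError as exc:
        raise ValidationError(f"model.{exc}") from None
    sig = d.get("signal", {}) or {}
    _check_keys(sig, {"kind", "level", "t_off", "breakpoints", "levels"}, "model.signal.")
    try:
        signal = SignalSpec(
            kind=sig.get("kind", "constant"),
            level=_num(sig, "level", 0.1, "model.signal."),
            t_off=sig.get("t_off"),
            breakpoints=tuple(sig.get("breakpoints", ())),
            levels=tuple(sig.get("levels", ())),
        )
    except ValidationError as exc:
        raise ValidationError(f"model.{exc}") from None
    sm = d.get("stage_map")
    stage_map = DEFAULT_STAGE_MAP if sm is None else StageMap({k: float(v) for k, v in sm.items()})
    return ModelRunConfig(
        params=params,
        signal=signal,
        t_end=_num(d, "t_end", 40.0, "model."),
        h=_num(d, "h", 0.01, "model."),
        stage_map=stage_map,
    )


def _build_cohort(d: dict) -> CohortConfig:
    allowed = {
        "sizes",
        "subset_means",
        "subset_logratio_sd",
        "chemo_means",
        "chemo_dispersion",
        "ros_props",
        "ros_cells_counted",
        "mfi_logmeans",
        "mfi_logsd",
        "seed",
    }
    _check_keys(d, allowed, "cohort.")
    cfg = CohortConfig()
    if "sizes" in d:
        cfg.sizes = {str(k): int(v) for k, v in d["sizes"].items()}
    if "subset_means" in d:
        cfg.subset_means = {str(k): tuple(map(float, v)) for k, v in d["subset_means"].items()}
    if "chemo_means" in d:
        cfg.chemo_means = {str(k): tuple(map(float, v)) for k, v in d["chemo_means"].items()}
    if "ros_props" in d:
        cfg.ros_props = {str(k): tuple(map(float, v)) for k, v in d["ros_props"].items()}
    if "mfi_logmeans" in d:
        cfg.mfi_logmeans = {
            str(g): {str(a): {str(c): float(x) for c, x in conds.items()} for a, conds in by_a.items()}
            for g, by_a in d["mfi_logmeans"].items()
        }
    cfg.subset_logratio_sd = _num(d, "subset_logratio_sd", cfg.subset_logratio_sd, "cohort.")
    cfg.chemo_dispersion = _num(d, "chemo_dispersion", cfg.chemo_dispersion, "cohort.")
    cfg.ros_cells_counted = int(_num(d, "ros_cells_counted", cfg.ros_cells_counted, "cohort."))
    cfg.mfi_logsd = _num(d, "mfi_logsd", cfg.mfi_logsd, "cohort.")
    cfg.seed = int(_num(d, "seed", cfg.seed, "cohort."))
    try:
        cfg.validate()
    except ValidationError as exc:
        raise ValidationError(f"cohort.{exc}") from None
    return cfg


def _build_analysis(d: dict) -> AnalysisConfig:
    _check_keys(d, {"plan", "alpha", "n_mc"}, "analysis.")
    alpha = _num(d, "alpha", 0.05, "analysis.")
    if not (0 < alpha < 1):
        raise ValidationError(f"analysis.alpha must be in (0, 1), got {alpha}")
    return AnalysisConfig(
        plan=d.get("plan"),
        alpha=alpha,
        n_mc=int(_num(d, "n_mc", 200_000, "analysis.")),
    )


def _build_calibration(d: dict) -> CalibrationConfig:
    allowed = {
        "free_params",
        "bounds",
        "level",
        "a_m",
        "b_m",
        "h",
        "weight_share",
        "weight_chemo",
        "grid_points",
        "n_starts",
        "jitter",
    }
    _check_keys(d, allowed, "calibration.")
    cfg = CalibrationConfig()
    if "free_params" in d:
        names = tuple(str(x) for x in d["free_params"])
        for name in names:
            if name not in FIT_PARAM_NAMES:
                raise ValidationError(f"calibration.free_params contains unknown name {name!r}")
        cfg.free_params = names
    if "bounds" in d:
        cfg.bounds = {str(k): (float(v[0]), float(v[1])) for k, v in d["bounds"].items()}
    cfg.level = _num(d, "level", cfg.level, "calibration.")
    cfg.a_m = _num(d, "a_m", cfg.a_m, "calibration.")
    cfg.b_m = _num(d, "b_m", cfg.b_m, "calibration.")
    cfg.h = _num(d, "h", cfg.h, "calibration.")
    cfg.weight_share = _num(d, "weight_share", cfg.weight_share, "calibration.")
    cfg.weight_chemo = _num(d, "weight_chemo", cfg.weight_chemo, "calibration.")
    cfg.grid_points = int(_num(d, "grid_points", cfg.grid_points, "calibration."))
    cfg.n_starts = int(_num(d, "n_starts", cfg.n_starts, "calibration."))
    cfg.jitter = _num(d, "jitter", cfg.jitter, "calibration.")
    return cfg


def build_config(raw: dict | None) -> RunConfig:
    """Validate a parsed configuration mapping and fill in defaults."""
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ValidationError("configuration root must be a mapping")
    _check_keys(raw, {"model", "cohort", "analysis", "calibration", "seed"}, "")
    cfg = RunConfig()
    cfg.model = _build_model(raw.get("model") or {})
    for key, builder in (
        ("cohort", _build_cohort),
        ("analysis", _build_analysis),
        ("calibration", _build_calibration),
    ):
        if key in raw and raw[key] is None:
            setattr(cfg, key, None)  # explicit null disables the stage
        else:
            setattr(cfg, key, builder(raw.get(key) or {}))
    cfg.seed = int(_num(raw, "seed", 0, ""))
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration file."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValidationError(f"could not parse configuration {path}: {exc}") from None
    return build_config(raw)


def config_to_dict(cfg: RunConfig) -> dict:
    """Plain-data representation; round-trips through build_config."""
    out: dict = {
        "seed": cfg.seed,
        "model": {
            "tau_m": cfg.model.params.tau_m,
            "tau_c": cfg.model.params.tau_c,
            "alpha": cfg.model.params.alpha,
            "c0": cfg.model.params.c0,
            "m0": cfg.model.params.m0,
            "signal": {
                "kind": cfg.model.signal.kind,
                "level": cfg.model.signal.level,
                "t_off": cfg.model.signal.t_off,
                "breakpoints": list(cfg.model.signal.breakpoints),
                "levels": list(cfg.model.signal.levels),
            },
            "t_end": cfg.model.t_end,
            "h": cfg.model.h,
            "stage_map": dict(cfg.model.stage_map.items()),
        },
    }
    if cfg.cohort is None:
        out["cohort"] = None
    else:
        c = cfg.cohort
        out["cohort"] = {
            "sizes": dict(c.sizes),
            "subset_means": {g: list(v) for g, v in c.subset_means.items()},
            "subset_logratio_sd": c.subset_logratio_sd,
            "chemo_means": {g: list(v) for g, v in c.chemo_means.items()},
            "chemo_dispersion": c.chemo_dispersion,
            "ros_props": {g: list(v) for g, v in c.ros_props.items()},
            "ros_cells_counted": c.ros_cells_counted,
            "mfi_logmeans": c.mfi_logmeans,
            "mfi_logsd": c.mfi_logsd,
            "seed": c.seed,
        }
    if cfg.analysis is None:
        out["analysis"] = None
    else:
        out["analysis"] = {
            "plan": cfg.analysis.plan,
            "alpha": cfg.analysis.alpha,
            "n_mc": cfg.analysis.n_mc,
        }
    if cfg.calibration is None:
        out["calibration"] = None
    else:
        k = cfg.calibration
        out["calibration"] = {
            "free_params": list(k.free_params),
            "bounds": {name: list(v) for name, v in k.bounds.items()},
            "level": k.level,
            "a_m": k.a_m,
            "b_m": k.b_m,
            "h": k.h,
            "weight_share": k.weight_share,
            "weight_chemo": k.weight_chemo,
            "grid_points": k.grid_points,
            "n_starts": k.n_starts,
            "jitter": k.jitter,
        }
    return out


def save_config(cfg: RunConfig, path) -> None:
    """Write the configuration as YAML (load_config inverts this exactly)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest of the full configuration."""
    payload = json.dumps(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


def derive_seed(global_seed: int, stream: str) -> int:
    """Deterministic per-module substream seed (< 2**31) from the global seed.

    The derivation hashes ``"<global_seed>:<stream>"`` with SHA-256 and keeps
    the low 31 bits, so modules can be re-run in isolation with the same
    stream seed the pipeline used.
    """
    digest = hashlib.sha256(f"{global_seed}:{stream}".encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
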