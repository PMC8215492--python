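"""Synthetic immunophenotyping cohorts for the four clinical groups.

The study's subject-level data are not public; this module generates cohorts
that reproduce, in expectation, the stage-wise group structure the study
reports: per-group sample sizes (HC 15, SMC 10, MCI 14, AD 14), monocyte
subset composition means (classical / intermediate / non-classical,
e.g. 88/3/4 in healthy controls and 74/7/9 at the AD stage), a stage-ordered
decline in Boyden-chamber chemotaxis counts, ROS responder fractions under
control reagent, fMLP, opsonized E. coli and PMA stimulation (anchored at
2.5%, 60% and 20% in healthy subjects), and lognormal cytokine MFI panels.

Distributional choices:

- subset composition: logistic-normal on additive-log-ratio coordinates
  (exact degenerate limit at zero dispersion).  The reported subset means do
  not sum to 100% — flow gating leaves an ungated remainder — so a configured
  3-part mean vector summing to < 100 is completed with an implicit residual
  "other" component before sampling; the three reported columns then match
  the configured means in expectation.
- chemotaxis counts: negative binomial (Poisson in the large-dispersion
  limit).
- ROS responder percentages: binomial per subject over a fixed number of
  counted cells.
- MFIs: lognormal.

Only the group means printed in the study constrain the defaults; all
dispersions are design choices (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "GROUPS",
    "SUBSETS",
    "CHEMO_CONDITIONS",
    "ROS_CONDITIONS",
    "ANALYTES",
    "MFI_CONDITIONS",
    "CohortConfig",
    "generate_subset_composition",
    "generate_counts",
    "generate_percent_positive",
    "generate_cohort",
    "cohort_columns",
    "write_cohort",
]

GROUPS = ("HC", "SMC", "MCI", "AD")
SUBSETS = ("classical", "intermediate", "nonclassical")
CHEMO_CONDITIONS = ("basal", "mcp50", "mcp100")
ROS_CONDITIONS = ("control", "fmlp", "ecoli", "pma")
ANALYTES = ("il1b", "il6", "tnfa", "il4", "il10")
MFI_CONDITIONS = ("basal", "lps", "pg")

_PRO_INFLAMMATORY = ("il1b", "il6", "tnfa")


def _default_sizes() -> dict[str, int]:
    return {"HC": 15, "SMC": 10, "MCI": 14, "AD": 14}


def _default_subset_means() -> dict[str, tuple[float, float, float]]:
    # classical, intermediate, non-classical group means (percent)
    return {
        "HC": (88.0, 3.0, 4.0),
        "SMC": (80.0, 5.0, 8.0),
        "MCI": (80.0, 6.0, 8.0),
        "AD": (74.0, 7.0, 9.0),
    }


def _default_chemo_means() -> dict[str, tuple[float, float, float]]:
    # migrated-cell counts for basal / MCP-1 50 ng/ml / MCP-1 100 ng/ml;
    # healthy scale by 1.5x / 1.8x, patient groups respond but less strongly
    return {
        "HC": (100.0, 150.0, 180.0),
        "SMC": (70.0, 91.0, 105.0),
        "MCI": (70.0, 91.0, 105.0),
        "AD": (50.0, 65.0, 75.0),
    }


def _default_ros_props() -> dict[str, tuple[float, float, float, float]]:
    # responder probabilities under control / fMLP / E. coli / PMA
    return {
        "HC": (0.025, 0.025, 0.60, 0.20),
        "SMC": (0.0375, 0.0375, 0.50, 0.25),
        "MCI": (0.0375, 0.0375, 0.45, 0.28),
        "AD": (0.0375, 0.0375, 0.40, 0.15),
    }


def _default_mfi_logmeans() -> dict[str, dict[str, dict[str, float]]]:
    # directions only: proinflammatory analytes are stimulated most strongly
    # at the MCI stage and least in AD; regulatory analytes respond weakly
    basal = math.log(100.0)
    folds = {"HC": 3.0, "SMC": 3.5, "MCI": 4.0, "AD": 2.0}
    out: dict[str, dict[str, dict[str, float]]] = {}
    for group in GROUPS:
        out[group] = {}
        for analyte in ANALYTES:
            fold = folds[group] if analyte in _PRO_INFLAMMATORY else 1.5
            out[group][analyte] = {
                "basal": basal,
                "lps": basal + math.log(fold),
                "pg": basal + math.log(fold),
            }
    return out


@dataclass
class CohortConfig:
    """Full parameterisation of a synthetic cohort; defaults follow the study."""

    sizes: dict[str, int] = field(default_factory=_default_sizes)
    subset_means: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_subset_means
    )
    subset_logratio_sd: float = 0.15
    chemo_means: dict[str, tuple[float, float, float]] = field(default_factory=_default_chemo_means)
    chemo_dispersion: float = 10.0
    ros_props: dict[str, tuple[float, float, float, float]] = field(
        default_factory=_default_ros_props
    )
    ros_cells_counted: int = 5000
    mfi_logmeans: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=_default_mfi_logmeans
    )
    mfi_logsd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for group in GROUPS:
            for name, table in (
                ("sizes", self.sizes),
                ("subset_means", self.subset_means),
                ("chemo_means", self.chemo_means),
                ("ros_props", self.ros_props),
                ("mfi_logmeans", self.mfi_logmeans),
            ):
                if group not in table:
                    raise ValidationError(f"{name} is missing group {group!r}")
            n = self.sizes[group]
            if not (isinstance(n, (int, np.integer)) and n >= 1):
                raise ValidationError(f"sizes[{group!r}] must be an integer >= 1, got {n}")
            means = np.asarray(self.subset_means[group], dtype=float)
            if means.shape != (3,) or np.any(means < 0):
                raise ValidationError(f"subset_means[{group!r}] must be 3 nonnegative percentages")
            if means.sum() > 100.0 + 1e-9:
                raise ValidationError(
                    f"subset_means[{group!r}] must sum to at most 100, got {means.sum()}"
                )
            if any(m <= 0 for m in self.chemo_means[group]):
                raise ValidationError(f"chemo_means[{group!r}] must all be > 0")
            if any(not (0.0 <= p <= 1.0) for p in self.ros_props[group]):
                raise ValidationError(f"ros_props[{group!r}] must all lie in [0, 1]")
        if not (self.subset_logratio_sd >= 0):
            raise ValidationError(f"subset_logratio_sd must be >= 0, got {self.subset_logratio_sd}")
        if not (self.chemo_dispersion > 0):
            raise ValidationError(f"chemo_dispersion must be > 0, got {self.chemo_dispersion}")
        if not (isinstance(self.ros_cells_counted, (int, np.integer)) and self.ros_cells_counted >= 1):
            raise ValidationError(
                f"ros_cells_counted must be an integer >= 1, got {self.ros_cells_counted}"
            )
        if not (self.mfi_logsd >= 0):
            raise ValidationError(f"mfi_logsd must be >= 0, got {self.mfi_logsd}")


def generate_subset_composition(
    means, logratio_sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``n`` monocyte subset compositions (percent) around ``means``.

    ``means`` is the 3-vector of expected (classical, intermediate,
    non-classical) percentages; if it sums to less than 100, the remainder is
    treated as an implicit fourth "other/ungated" component so that the full
    composition lives on the simplex.  Sampling draws additive-log-ratio
    coordinates centred on the configured composition with standard deviation
    ``logratio_sd`` and back-transforms; at zero dispersion every row equals
    ``means`` exactly.

    Returns an ``(n, 3)`` array of the three subset percentages.
    """
    means = np.asarray(means, dtype=float)
    if means.shape != (3,) or np.any(means < 0) or np.any(~np.isfinite(means)):
        raise ValidationError("means must be 3 finite nonnegative percentages")
    total = float(means.sum())
    if total <= 0:
        raise ValidationError("means must have a positive sum")
    if total > 100.0 + 1e-9:
        raise ValidationError(f"means must sum to at most 100, got {total}")
    if not (math.isfinite(logratio_sd) and logratio_sd >= 0):
        raise ValidationError(f"logratio_sd must be >= 0, got {logratio_sd}")
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValidationError(f"n must be an integer >= 1, got {n}")

    if logratio_sd == 0:
        return np.tile(means, (n, 1))

    residual = 100.0 - total
    parts = np.append(means, residual) if residual > 1e-12 else means
    if np.any(parts == 0):
        raise ValidationError(
            "means with zero entries are incompatible with logratio_sd > 0 "
            "(log-ratio coordinates are undefined)"
        )
    p = parts / 100.0
    alr0 = np.log(p[:-1] / p[-1])
    z = alr0 + rng.normal(0.0, logratio_sd, size=(n, len(p) - 1))
    ez = np.exp(z)
    denom = 1.0 + ez.sum(axis=1, keepdims=True)
    comp = np.hstack([ez, np.ones((n, 1))]) / denom * 100.0
    return comp[:, :3]


def generate_counts(mean: float, dispersion: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` negative-binomial migrated-cell counts.

    ``dispersion`` is the NB size parameter k: variance = mean + mean**2 / k,
    so the Poisson limit is approached as k grows.
    """
    if not (math.isfinite(mean) and mean > 0):
        raise ValidationError(f"mean must be > 0, got {mean}")
    if not (math.isfinite(dispersion) and dispersion > 0):
        raise ValidationError(f"dispersion must be > 0, got {dispersion}")
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValidationError(f"n must be an integer >= 1, got {n}")
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def generate_percent_positive(
    p: float, cells: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-subject percentage of responder cells out of ``cells`` counted.

    Each subject contributes binomial(cells, p) / cells * 100.
    """
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"responder probability p must be in [0, 1], got {p}")
    if not (isinstance(cells, (int, np.integer)) and cells >= 1):
        raise ValidationError(f"cells must be an integer >= 1, got {cells}")
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValidationError(f"n must be an integer >= 1, got {n}")
    return rng.binomial(cells, p, size=n) / cells * 100.0


def cohort_columns() -> list[str]:
    """The fixed cohort CSV column schema, in order."""
    cols = ["subject_id", "group"]
    cols += [f"{s}_pct" for s in SUBSETS]
    cols += [f"chemo_{c}" for c in CHEMO_CONDITIONS]
    cols += [f"ros_{c}_pct" for c in ROS_CONDITIONS]
    cols += [f"{a}_{c}_mfi" for a in ANALYTES for c in MFI_CONDITIONS]
    return cols


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Assemble a full subject-level cohort table.

    Deterministic given the seed (``seed`` overrides ``config.seed``); groups
    are generated in the fixed order HC, SMC, MCI, AD.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frames = []
    for group in GROUPS:
        n = int(config.sizes[group])
        comp = generate_subset_composition(
            config.subset_means[group], config.subset_logratio_sd, n, rng
        )
        row: dict[str, object] = {
            "subject_id": [f"{group}-{i + 1:03d}" for i in range(n)],
            "group": group,
        }
        for j, s in enumerate(SUBSETS):
            row[f"{s}_pct"] = comp[:, j]
        for j, cond in enumerate(CHEMO_CONDITIONS):
            row[f"chemo_{cond}"] = generate_counts(
                config.chemo_means[group][j], config.chemo_dispersion, n, rng
            )
        for j, cond in enumerate(ROS_CONDITIONS):
            row[f"ros_{cond}_pct"] = generate_percent_positive(
                config.ros_props[group][j], config.ros_cells_counted, n, rng
            )
        for analyte in ANALYTES:
            for cond in MFI_CONDITIONS:
                logmean = config.mfi_logmeans[group][analyte][cond]
                if config.mfi_logsd == 0:
                    mfi = np.full(n, math.exp(logmean))
                else:
                    mfi = rng.lognormal(logmean, config.mfi_logsd, size=n)
                row[f"{analyte}_{cond}_mfi"] = mfi
        frames.append(pd.DataFrame(row))
    return pd.concat(frames, ignore_index=True)[cohort_columns()]


def write_cohort(cohort: pd.DataFrame, path, comment: str | None = None) -> None:
    """Write the cohort as UTF-8, LF-terminated CSV with an optional '#' header comment."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        cohort.to_csv(fh, index=False, lineterminator="\n")
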