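"""Classification of spots/proteins into the four condition-trajectory
groups, and the condition-of-maximum label.

Across the control -> anoxia -> re-aeration sequence, four abundance
patterns are distinguished:

    1  decline through anoxia continuing into re-aeration
    2  anoxia-specific peak with a drop after re-aeration
    3  rise starting in anoxia, peaking in re-aeration
    4  dip during anoxia followed by accumulation in re-aeration

The rule is scale-free and total: comparisons use a relative tolerance
delta (x exceeds y only when x > y * (1 + delta) on the intensity scale),
anoxia being the strict maximum gives group 2, anoxia the strict minimum
gives group 4, otherwise a non-increasing C >= A >= R profile gives group 1
and everything else group 3.  Groups 1 and 3 are the "continuing"
trajectories (the anoxia-triggered change persists through re-aeration);
groups 2 and 4 are anoxia- and re-aeration-specific, respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CONDITIONS, SpotTable

CONTINUING_GROUPS = (1, 3)
CONDITION_SPECIFIC_GROUPS = (2, 4)


@dataclass
class TrajectoryCall:
    id: str
    mean_C: float
    mean_A: float
    mean_R: float
    group: int
    max_condition: str
    delta: float


def condition_means(table: SpotTable) -> pd.DataFrame:
    """Arithmetic per-condition replicate means for every spot (missing
    values dropped); errors if some condition has no observation for a spot."""
    sheet = table.sheet
    out = {}
    for cond in CONDITIONS:
        cols = table.matrix[:, sheet.conditions == cond]
        if cols.shape[1] == 0:
            raise ValueError(f"no samples for condition {cond!r}")
        n_obs = (~np.isnan(cols)).sum(axis=1)
        if (n_obs == 0).any():
            bad = [s for s, n in zip(table.spot_ids, n_obs) if n == 0]
            raise ValueError(f"condition {cond!r} has no observation for spots {bad}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[f"mean_{cond[0].upper()}"] = np.nanmean(cols, axis=1)
    return pd.DataFrame(out, index=pd.Index(table.spot_ids, name="id"))


def _gt(x: float, y: float, delta: float) -> bool:
    return x > y * (1.0 + delta)


def _ge(x: float, y: float, delta: float) -> bool:
    return not _gt(y, x, delta)


def classify_trajectory(mean_C: float, mean_A: float, mean_R: float,
                        delta: float = 0.05) -> int:
    """Assign one of the four trajectory groups to a triple of positive
    condition means (intensity scale).  Total over finite triples."""
    c, a, r = float(mean_C), float(mean_A), float(mean_R)
    if not all(np.isfinite([c, a, r])):
        raise ValueError("condition means must be finite")
    if _gt(a, c, delta) and _gt(a, r, delta):
        return 2
    if _gt(c, a, delta) and _gt(r, a, delta):
        return 4
    if _ge(c, a, delta) and _ge(a, r, delta):
        return 1
    return 3


def condition_of_max(mean_C: float, mean_A: float, mean_R: float) -> str:
    """Arg-max condition; exact ties resolve in C > A > R priority order."""
    means = (mean_C, mean_A, mean_R)
    if not all(np.isfinite(means)):
        raise ValueError("condition means must be finite")
    return CONDITIONS[int(np.argmax(means))]


def classify_table(table: SpotTable, delta: float = 0.05,
                   on_log_scale: bool | None = None) -> pd.DataFrame:
    """Trajectory calls for every spot of a table.

    Log2 tables are converted back to the intensity scale before applying
    the relative-tolerance comparisons (``on_log_scale`` overrides the
    table's flag).
    """
    means = condition_means(table)
    log_scale = table.log_transformed if on_log_scale is None else on_log_scale
    scale = (lambda x: 2.0 ** x) if log_scale else (lambda x: x)
    rows = []
    for spot_id, row in means.iterrows():
        c, a, r = scale(row["mean_C"]), scale(row["mean_A"]), scale(row["mean_R"])
        rows.append(
            {
                "id": spot_id,
                "mean_C": row["mean_C"],
                "mean_A": row["mean_A"],
                "mean_R": row["mean_R"],
                "group": classify_trajectory(c, a, r, delta),
                "max_condition": condition_of_max(c, a, r),
                "delta": delta,
            }
        )
    return pd.DataFrame(rows).set_index("id")


def group_counts(calls: pd.DataFrame) -> dict[int, int]:
    counts = calls["group"].value_counts().to_dict()
    return {g: int(counts.get(g, 0)) for g in (1, 2, 3, 4)}


def headline_fractions(calls: pd.DataFrame) -> dict[str, float]:
    """Summary fractions: share of continuing (groups 1+3) versus
    condition-specific (groups 2+4) trajectories, plus the anoxia- and
    re-aeration-specific counts."""
    counts = group_counts(calls)
    total = sum(counts.values())
    continuing = counts[1] + counts[3]
    return {
        "n": total,
        "continuing": continuing,
        "condition_specific": counts[2] + counts[4],
        "anoxia_specific": counts[2],
        "reaeration_specific": counts[4],
        "continuing_pct": 100.0 * continuing / total if total else float("nan"),
        "condition_specific_pct": 100.0 * (counts[2] + counts[4]) / total if total else float("nan"),
    }
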