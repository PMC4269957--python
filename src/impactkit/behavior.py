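"""Behavioral injury indices and cohort helpers.

Covers the standard rodent closed-head-injury readouts: the open-field
thigmotaxis index over a 60-square arena partition, the 10-task
neurological severity score, passive-avoidance latency capping, and the
fold-change / Bonferroni helpers used for biochemical endpoints.  Group
inference (repeated-measures ANOVA, post-hoc tests) is deliberately left to
standard statistics packages; this module produces the tidy per-animal
quantities those routines consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OpenFieldZoning",
    "zone_partition",
    "thigmotaxis_index",
    "nss_score",
    "pa_latency",
    "fold_change",
    "bonferroni_alpha",
    "NSS_TASK_COUNT",
    "PA_LATENCY_CAP",
]

#: number of pass/fail tasks in the neurological severity score
NSS_TASK_COUNT = 10

#: passive-avoidance session cap (s): animals that never cross are assigned
#: the full 5-minute latency
PA_LATENCY_CAP = 300.0


@dataclass(frozen=True)
class OpenFieldZoning:
    """Peripheral/central partition of a rectangular open-field arena.

    The arena is divided into ``n_rows x n_cols`` equal cells; the single
    ring of cells along the walls forms the peripheral zone and the interior
    the central zone.  For the 6 x 10 partition of a 14 in x 24 in arena
    this yields 28 peripheral and 32 central squares.
    """

    arena_width: float
    arena_height: float
    n_rows: int
    n_cols: int
    peripheral_mask: np.ndarray  # (n_rows, n_cols) bool, True = peripheral

    @property
    def n_peripheral(self) -> int:
        return int(self.peripheral_mask.sum())

    @property
    def n_central(self) -> int:
        return int((~self.peripheral_mask).sum())


def zone_partition(
    arena_width: float, arena_height: float, n_rows: int, n_cols: int
) -> OpenFieldZoning:
    """Partition an arena into equal cells and classify perimeter vs interior.

    The perimeter count is ``2*(rows + cols) - 4`` (every cell is peripheral
    when either dimension is <= 2).
    """
    if arena_width <= 0 or arena_height <= 0:
        raise ValueError("arena dimensions must be positive")
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be positive integers")
    mask = np.ones((n_rows, n_cols), dtype=bool)
    if n_rows > 2 and n_cols > 2:
        mask[1:-1, 1:-1] = False
    return OpenFieldZoning(
        arena_width=float(arena_width),
        arena_height=float(arena_height),
        n_rows=int(n_rows),
        n_cols=int(n_cols),
        peripheral_mask=mask,
    )


def _zone_times(track: pd.DataFrame, zoning: OpenFieldZoning) -> tuple[float, float]:
    """Peripheral and central dwell times (sample counts / rate).

    Samples on a cell boundary belong to the cell whose half-open interval
    (left/bottom edge inclusive) contains them; points on the far arena
    edge are folded into the last cell.
    """
    x = np.asarray(track["x"], dtype=float)
    y = np.asarray(track["y"], dtype=float)
    if x.size == 0:
        raise ValueError("track has no samples")
    if (
        x.min() < 0
        or y.min() < 0
        or x.max() > zoning.arena_width
        or y.max() > zoning.arena_height
    ):
        raise ValueError("track leaves the arena bounds")
    t = np.asarray(track["time_s"], dtype=float)
    if t.size > 1:
        rate = 1.0 / np.median(np.diff(t))
    else:
        rate = 1.0
    col = np.minimum(
        (x / (zoning.arena_width / zoning.n_cols)).astype(int), zoning.n_cols - 1
    )
    row = np.minimum(
        (y / (zoning.arena_height / zoning.n_rows)).astype(int), zoning.n_rows - 1
    )
    peripheral = zoning.peripheral_mask[row, col]
    t_p = peripheral.sum() / rate
    t_c = (~peripheral).sum() / rate
    return float(t_p), float(t_c)


def thigmotaxis_index(
    track: pd.DataFrame,
    arena_size: tuple[float, float] = (14.0, 24.0),
    grid: tuple[int, int] = (10, 6),
) -> float:
    """Thigmotaxis index TI = (T_P - T_C) / (T_P + T_C).

    ``T_P`` and ``T_C`` are times spent in the peripheral and central zones
    of the ``grid`` partition (rows, cols) of the arena.  TI is 1 for a
    purely wall-hugging animal, -1 for a purely central one.
    """
    zoning = zone_partition(arena_size[0], arena_size[1], grid[0], grid[1])
    t_p, t_c = _zone_times(track, zoning)
    total = t_p + t_c
    if total <= 0:
        raise ValueError("zero total dwell time")
    return (t_p - t_c) / total


def nss_score(task_failures) -> int:
    """Neurological severity score: one point per failed task, 0-10.

    ``task_failures`` is an iterable of exactly 10 booleans (True = the
    animal failed the task / lacked the reflex); the score is the failure
    count, 10 indicating severe neurological dysfunction.
    """
    failures = list(task_failures)
    if len(failures) != NSS_TASK_COUNT:
        raise ValueError(
            f"NSS requires exactly {NSS_TASK_COUNT} task outcomes, got {len(failures)}"
        )
    for f in failures:
        if not isinstance(f, (bool, np.bool_)):
            raise ValueError("task outcomes must be booleans")
    return int(sum(bool(f) for f in failures))


def pa_latency(crossing_time: float | None, cap: float = PA_LATENCY_CAP) -> float:
    """Passive-avoidance crossing latency with session cap.

    An animal that never crosses into the darkened compartment
    (``crossing_time`` absent) is assigned the full session cap; crossings
    are truncated at the cap.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    if crossing_time is None or (
        isinstance(crossing_time, float) and np.isnan(crossing_time)
    ):
        return float(cap)
    if crossing_time < 0:
        raise ValueError("crossing time must be non-negative")
    return float(min(crossing_time, cap))


def fold_change(group_values, sham_values) -> float:
    """Group mean expressed as a fold change over the sham mean."""
    group = np.asarray(group_values, dtype=float)
    sham = np.asarray(sham_values, dtype=float)
    if group.size == 0 or sham.size == 0:
        raise ValueError("both groups must be non-empty")
    sham_mean = sham.mean()
    if sham_mean == 0:
        raise ValueError("sham mean is zero; fold change undefined")
    return float(group.mean() / sham_mean)


def bonferroni_alpha(family_size: int, alpha: float = 0.05) -> float:
    """Bonferroni-adjusted per-comparison significance threshold."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return alpha / family_size
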