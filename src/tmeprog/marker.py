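"""Combined CD8/stroma marker: threshold grid search driven by the C-index.

A patient is classified on a three-level ordinal marker from a CD8+
fraction threshold and a stroma fraction threshold:

* FAVORABLE (0) — high CD8 (fraction > t_cd8) and low stroma (< t_stroma),
* INTERMEDIATE (1) — exactly one adverse feature,
* ADVERSE (2) — low CD8 (<= t_cd8) and high stroma (>= t_stroma).

For every admissible threshold pair (each side of each dichotomy must keep
at least ``min_group_size`` patients), Harrell's concordance index of the
ordinal marker against time-to-recurrence is computed, and the pair with
the highest C-index is selected.  Because the marker is a single ordinal
covariate, the risk ordering of a univariable Cox fit equals the ordinal
ordering whenever the fitted coefficient is positive, so the C-index is
computed directly on the levels; the Cox sign is checked once on the
selected pair.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import GridConfig


class MarkerLevel(enum.IntEnum):
    FAVORABLE = 0
    INTERMEDIATE = 1
    ADVERSE = 2


@dataclass(frozen=True)
class MarkerThresholds:
    cd8_threshold: float
    stroma_threshold: float

    def __post_init__(self) -> None:
        for t in (self.cd8_threshold, self.stroma_threshold):
            if not 0.0 < t < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class GridSearchResult:
    table: pd.DataFrame  # columns cd8_threshold, stroma_threshold, c_index
    best: MarkerThresholds
    best_c_index: float
    n_combinations: int
    cd8_thresholds: np.ndarray
    stroma_thresholds: np.ndarray
    cox_sign: int | None = None


def threshold_grid(lower: float, upper: float, step: float) -> np.ndarray:
    """All multiples of ``step`` from ``lower`` to ``upper`` inclusive."""
    k_lo = int(round(lower / step))
    k_hi = int(round(upper / step))
    return np.round(np.arange(k_lo, k_hi + 1) * step, 12)


def admissible_thresholds(
    values, step: float, min_group_size: int = 5
) -> tuple[float, float, np.ndarray]:
    """Grid thresholds keeping >= ``min_group_size`` patients on each side.

    Candidates are the multiples of ``step`` between the smallest and
    largest observed value; a candidate t is admissible when both
    {v <= t} and {v > t} hold at least ``min_group_size`` patients.
    Returns ``(lower, upper, thresholds)`` in ascending order.
    """
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if v.size < 2 * min_group_size:
        raise ValueError("too few values to dichotomize")
    candidates = threshold_grid(
        math.ceil(v.min() / step - 1e-9) * step,
        math.floor(v.max() / step + 1e-9) * step,
        step,
    )
    n_le = (v[None, :] <= candidates[:, None] + 1e-12).sum(axis=1)
    ok = (n_le >= min_group_size) & (v.size - n_le >= min_group_size)
    admissible = candidates[ok]
    if admissible.size == 0:
        raise ValueError("no admissible threshold")
    return float(admissible[0]), float(admissible[-1]), admissible


def classify_patient(
    cd8_fraction: float, stroma_fraction: float, thresholds: MarkerThresholds
) -> MarkerLevel:
    """Three-level marker class for one patient (boundaries are adverse)."""
    if np.isnan(cd8_fraction) or np.isnan(stroma_fraction):
        raise ValueError("missing marker fraction")
    cd8_low = cd8_fraction <= thresholds.cd8_threshold
    stroma_high = stroma_fraction >= thresholds.stroma_threshold
    return MarkerLevel(int(cd8_low) + int(stroma_high))


def classify_cohort(
    cd8_fractions, stroma_fractions, thresholds: MarkerThresholds
) -> np.ndarray:
    """Vectorized three-level classification; NaN fractions raise."""
    cd8 = np.asarray(cd8_fractions, float)
    stroma = np.asarray(stroma_fractions, float)
    if np.isnan(cd8).any() or np.isnan(stroma).any():
        raise ValueError("missing marker fraction")
    return (cd8 <= thresholds.cd8_threshold).astype(int) + (
        stroma >= thresholds.stroma_threshold
    ).astype(int)


def _usable_pairs(times: np.ndarray, events: np.ndarray):
    """Index arrays (i, j) of Harrell-usable pairs with i the first failer.

    Usable: t_i < t_j with event i, or t_i == t_j with event i and
    censoring j.  Tied event times are not comparable.
    """
    t = times[:, None]
    e = events.astype(bool)
    earlier = (t < times[None, :]) & e[:, None]
    tied = (t == times[None, :]) & e[:, None] & ~e[None, :]
    usable = earlier | tied
    np.fill_diagonal(usable, False)
    return np.nonzero(usable)


def concordance_index(times, events, risk_scores) -> float:
    """Harrell's C over usable pairs; 0.5 when no pair is usable.

    The patient with the shorter time and an event is the first failer; a
    pair is concordant when that patient carries the higher risk score,
    counts 0.5 on tied scores, and 0 otherwise.
    """
    t = np.asarray(times, float)
    e = np.asarray(events)
    r = np.asarray(risk_scores, float)
    if not (t.shape == e.shape == r.shape):
        raise ValueError("times, events and risk_scores must have equal length")
    i_idx, j_idx = _usable_pairs(t, e)
    if i_idx.size == 0:
        return 0.5
    ri, rj = r[i_idx], r[j_idx]
    score = np.count_nonzero(ri > rj) + 0.5 * np.count_nonzero(ri == rj)
    return float(score / i_idx.size)


def _cox_sign(times, events, levels) -> int | None:
    """Sign of the univariable Cox coefficient for the ordinal marker."""
    from lifelines import CoxPHFitter

    df = pd.DataFrame({"time": times, "event": events, "level": levels})
    if df["level"].nunique() < 2 or df["event"].sum() == 0:
        return None
    try:
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
    except Exception:
        return None
    return int(np.sign(cph.params_["level"])) or 1


def grid_search(
    cohort: pd.DataFrame,
    grid: GridConfig = GridConfig(),
    time_col: str = "time",
    event_col: str = "event",
    cd8_col: str = "cd8_fraction",
    stroma_col: str = "stroma_fraction",
) -> GridSearchResult:
    """Exhaustive C-index search over the admissible threshold grid.

    Ties in C-index break toward the smaller CD8 threshold, then the
    smaller stroma threshold.  Combinations where the marker collapses to a
    single level yield C = 0.5 (no usable discrimination).
    """
    times = cohort[time_col].to_numpy(float)
    events = cohort[event_col].to_numpy()
    cd8 = cohort[cd8_col].to_numpy(float)
    stroma = cohort[stroma_col].to_numpy(float)

    _, _, cd8_ts = admissible_thresholds(cd8, grid.cd8_step, grid.min_group_size)
    _, _, stroma_ts = admissible_thresholds(stroma, grid.stroma_step, grid.min_group_size)

    i_idx, j_idx = _usable_pairs(times, events)
    n_pairs = i_idx.size

    rows = []
    best = (-np.inf, np.inf, np.inf)  # (c, cd8_t, stroma_t) with c maximized
    stroma_high_all = stroma[None, :] >= stroma_ts[:, None]
    for cd8_t in cd8_ts:
        cd8_low = (cd8 <= cd8_t).astype(np.int8)
        for stroma_t, s_high in zip(stroma_ts, stroma_high_all):
            level = cd8_low + s_high
            if n_pairs == 0:
                c = 0.5
            else:
                li, lj = level[i_idx], level[j_idx]
                c = (np.count_nonzero(li > lj) + 0.5 * np.count_nonzero(li == lj)) / n_pairs
            rows.append((cd8_t, stroma_t, c))
            key = (c, -cd8_t, -stroma_t)
            if key > (best[0], -best[1], -best[2]):
                best = (c, cd8_t, stroma_t)

    table = pd.DataFrame(rows, columns=["cd8_threshold", "stroma_threshold", "c_index"])
    best_thresholds = MarkerThresholds(best[1], best[2])
    best_levels = classify_cohort(cd8, stroma, best_thresholds)
    sign = _cox_sign(times, events, best_levels)
    return GridSearchResult(
        table=table,
        best=best_thresholds,
        best_c_index=float(best[0]),
        n_combinations=len(rows),
        cd8_thresholds=cd8_ts,
        stroma_thresholds=stroma_ts,
        cox_sign=sign,
    )
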