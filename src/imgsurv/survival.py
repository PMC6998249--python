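"""Discrete-time survival primitives.

Follow-up is cut into ``J`` half-open intervals ``[t_{j-1}, t_j)``. A network
(or any model) emits one conditional failure probability ("hazard") per
subject and interval; the negative log-likelihood of the observed
(event, at-risk) pattern under those hazards is the training loss, and the
cumulative product of ``1 - h`` recovers a per-subject survival curve.

This module holds the interval grid construction, the (d, r) target encoding,
the likelihood loss and its analytic gradient, hazard-to-survival conversion,
step-function curve evaluation, and the Kaplan-Meier product-limit estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalRecord",
    "IntervalGrid",
    "DiscreteTargets",
    "SurvivalCurve",
    "EPS_HAZARD",
    "make_interval_grid",
    "encode_targets",
    "discrete_survival_loss",
    "discrete_survival_loss_gradient",
    "hazards_to_survival",
    "survival_at",
    "kaplan_meier",
    "read_survival_csv",
    "write_survival_csv",
    "records_to_frame",
    "records_from_frame",
]

#: Hazards are clipped into [EPS_HAZARD, 1 - EPS_HAZARD] before any logarithm;
#: the likelihood is undefined at exactly 0 or 1.
EPS_HAZARD = 1e-7


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's follow-up: duration in days and whether the event was seen.

    ``event == 1`` means failure (e.g. death) observed at ``time``;
    ``event == 0`` means follow-up was censored at ``time``.
    """

    subject_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(
                f"subject {self.subject_id!r}: time must be positive, got {self.time}"
            )
        if self.event not in (0, 1):
            raise ValueError(
                f"subject {self.subject_id!r}: event must be 0 or 1, got {self.event}"
            )


@dataclass(frozen=True)
class IntervalGrid:
    """Strictly increasing boundaries ``t_0 = 0 < t_1 < ... < t_J`` (days)."""

    boundaries: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        object.__setattr__(self, "boundaries", b)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("grid needs at least two boundaries (one interval)")
        if b[0] != 0:
            raise ValueError("first boundary must be 0")
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_intervals(self) -> int:
        return self.boundaries.size - 1

    def interval_of(self, t: float) -> int:
        """1-based index of the interval ``[t_{j-1}, t_j)`` containing ``t``.

        ``t == t_J`` maps to the last interval J; ``t`` outside ``[0, t_J]``
        raises.
        """
        b = self.boundaries
        if t < 0 or t > b[-1]:
            raise ValueError(f"time {t} outside grid range [0, {b[-1]}]")
        if t == b[-1]:
            return self.n_intervals
        return int(np.searchsorted(b, t, side="right"))

    def to_json_list(self) -> list[float]:
        return [float(x) for x in self.boundaries]


@dataclass(frozen=True)
class DiscreteTargets:
    """Per-subject (event, at-risk) flags over the grid's intervals.

    ``event_flags[i, j] == 1`` iff subject i failed during interval j+1;
    ``atrisk_flags[i, j] == 1`` iff subject i was in view (under observation
    and event-free at the interval start, and not censored within it).
    """

    event_flags: np.ndarray
    atrisk_flags: np.ndarray
    subject_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        d = np.asarray(self.event_flags, dtype=np.int8)
        r = np.asarray(self.atrisk_flags, dtype=np.int8)
        object.__setattr__(self, "event_flags", d)
        object.__setattr__(self, "atrisk_flags", r)
        if d.shape != r.shape or d.ndim != 2:
            raise ValueError("event and at-risk flags must share one (n, J) shape")
        if np.any(d > r):
            raise ValueError("a failure flag requires the subject to be at risk")
        if np.any(d.sum(axis=1) > 1):
            raise ValueError("at most one failure interval per subject")
        # at-risk must be a prefix pattern: once 0, always 0
        if np.any(np.diff(r, axis=1) > 0):
            raise ValueError("at-risk flags must be a prefix pattern")

    @property
    def n_subjects(self) -> int:
        return self.event_flags.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.event_flags.shape[1]


@dataclass(frozen=True)
class SurvivalCurve:
    """Survival probabilities at the right endpoints of a grid's intervals."""

    probabilities: np.ndarray
    grid: IntervalGrid
    subject_id: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", s)
        if s.ndim != 1 or s.size != self.grid.n_intervals:
            raise ValueError("need one probability per grid interval")
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival probabilities must be non-increasing")

    def __call__(self, t: float) -> float:
        return survival_at(self, t)


def make_interval_grid(
    records: Iterable[SurvivalRecord], n_intervals: int = 12
) -> IntervalGrid:
    """Quantile-based interval grid over the uncensored event times.

    Boundaries sit at the empirical quantiles (NumPy linear-interpolation
    rule) of the observed event times at levels ``k/J`` for ``k = 1..J``,
    with ``t_0 = 0`` prepended and the last boundary extended to the maximum
    follow-up time over *all* records. Duplicate quantiles are collapsed, so
    the returned grid may have fewer than ``n_intervals`` intervals.

    Quantile placement balances per-interval event counts, which keeps every
    interval informative for the likelihood.
    """
    records = list(records)
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    event_times = np.array([r.time for r in records if r.event == 1], dtype=float)
    if event_times.size == 0:
        raise ValueError("cannot build a grid without any uncensored events")
    max_followup = max(r.time for r in records)
    levels = np.arange(1, n_intervals + 1) / n_intervals
    inner = np.unique(np.quantile(event_times, levels))
    inner[-1] = max_followup
    inner = np.unique(inner)
    boundaries = np.concatenate([[0.0], inner[inner > 0]])
    return IntervalGrid(boundaries)


def encode_targets(
    records: Sequence[SurvivalRecord],
    grid: IntervalGrid,
    censored_midpoint_rule: bool = False,
) -> DiscreteTargets:
    """Encode each record into length-J (d, r) flag vectors on ``grid``.

    An event at time T in interval ``j*`` sets ``d_{j*} = 1`` and marks the
    subject at risk for intervals ``1..j*``. A censored subject is at risk
    only for the intervals it fully survived: ``r_j = 1`` for ``j < j*`` and
    ``r_{j*} = 0``. With ``censored_midpoint_rule=True`` a subject censored at
    or past the midpoint of interval ``j*`` also counts as at risk there.

    Follow-up at or beyond ``t_J`` is clamped: the subject is treated as
    event-free and at risk through all J intervals, except that an event at
    exactly ``t_J`` is counted in the last interval.
    """
    J = grid.n_intervals
    n = len(records)
    d = np.zeros((n, J), dtype=np.int8)
    r = np.zeros((n, J), dtype=np.int8)
    t_end = grid.boundaries[-1]
    for i, rec in enumerate(records):
        if rec.time <= 0:
            raise ValueError(f"subject {rec.subject_id!r}: non-positive time")
        if rec.time > t_end or (rec.time == t_end and rec.event == 0):
            r[i, :] = 1
            continue
        j_star = grid.interval_of(rec.time)  # 1-based
        if rec.event == 1:
            d[i, j_star - 1] = 1
            r[i, :j_star] = 1
        else:
            r[i, : j_star - 1] = 1
            if censored_midpoint_rule:
                lo = grid.boundaries[j_star - 1]
                hi = grid.boundaries[j_star]
                if rec.time >= (lo + hi) / 2:
                    r[i, j_star - 1] = 1
    return DiscreteTargets(d, r, tuple(rec.subject_id for rec in records))


def _clip_hazards(hazards: np.ndarray) -> np.ndarray:
    h = np.asarray(hazards, dtype=float)
    if h.ndim == 1:
        h = h[None, :]
    return np.clip(h, EPS_HAZARD, 1.0 - EPS_HAZARD)


def discrete_survival_loss(hazards: np.ndarray, targets: DiscreteTargets) -> float:
    """Negative log-likelihood of (d, r) targets under per-interval hazards.

    Summed over subjects and intervals: an at-risk cell contributes
    ``-ln(h)`` if the subject failed there and ``-ln(1 - h)`` if it survived
    it; cells where the subject is out of view contribute nothing. Hazards
    are clipped to ``[EPS_HAZARD, 1 - EPS_HAZARD]`` first.
    """
    h = _clip_hazards(hazards)
    d = targets.event_flags
    r = targets.atrisk_flags
    if h.shape != d.shape:
        raise ValueError(f"hazards shape {h.shape} != targets shape {d.shape}")
    fail = d * r
    surv = (1 - d) * r
    return float(-(fail * np.log(h)).sum() - (surv * np.log1p(-h)).sum())


def discrete_survival_loss_gradient(
    hazards: np.ndarray, targets: DiscreteTargets
) -> np.ndarray:
    """Analytic d(loss)/d(hazard) per cell: ``-d/h + (1-d)/(1-h)`` where at risk."""
    h = _clip_hazards(hazards)
    d = targets.event_flags
    r = targets.atrisk_flags
    if h.shape != d.shape:
        raise ValueError(f"hazards shape {h.shape} != targets shape {d.shape}")
    return r * (-d / h + (1 - d) / (1.0 - h))


def hazards_to_survival(
    hazards: np.ndarray,
    grid: IntervalGrid,
    subject_ids: Sequence[str] | None = None,
) -> list[SurvivalCurve]:
    """Cumulative-product conversion ``S_j = prod_{k<=j} (1 - h_k)`` per subject."""
    h = np.atleast_2d(np.asarray(hazards, dtype=float))
    if h.shape[1] != grid.n_intervals:
        raise ValueError(
            f"hazards have {h.shape[1]} intervals, grid has {grid.n_intervals}"
        )
    if np.any(h < 0) or np.any(h > 1):
        raise ValueError("hazards must lie in [0, 1]")
    surv = np.cumprod(1.0 - h, axis=1)
    ids = subject_ids if subject_ids is not None else [""] * h.shape[0]
    return [SurvivalCurve(surv[i], grid, str(ids[i])) for i in range(h.shape[0])]


def survival_at(curve: SurvivalCurve, t: float) -> float:
    """Right-continuous step evaluation of a survival curve.

    Convention: ``S(t) = S_{j-1}`` for ``t`` inside interval ``[t_{j-1}, t_j)``
    with ``S_0 = 1``, and ``S(t_J) = S_J`` at the final boundary. No
    extrapolation past ``t_J``.
    """
    b = curve.grid.boundaries
    if t < 0 or t > b[-1]:
        raise ValueError(f"time {t} outside curve range [0, {b[-1]}]")
    if t == b[-1]:
        return float(curve.probabilities[-1])
    j = int(np.searchsorted(b, t, side="right"))  # interval index, 1-based
    if j <= 1:
        return 1.0
    return float(curve.probabilities[j - 2])


def kaplan_meier(records: Iterable[SurvivalRecord]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator on the grid of distinct event times.

    ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)`` with ``d_i`` events and ``n_i``
    subjects at risk at event time ``t_i``.
    """
    records = list(records)
    if not records:
        raise ValueError("kaplan_meier needs at least one record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    s_vals, t_vals = _km_steps(times, events)
    if t_vals.size == 0:
        # no events: flat curve over a single interval to max follow-up
        return SurvivalCurve(np.array([1.0]), IntervalGrid([0.0, times.max()]))
    t_max = times.max()
    if t_max > t_vals[-1]:
        # censored follow-up past the last event: carry the curve flat
        t_vals = np.append(t_vals, t_max)
        s_vals = np.append(s_vals, s_vals[-1])
    return SurvivalCurve(s_vals, IntervalGrid(np.concatenate([[0.0], t_vals])))


def _km_steps(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distinct event times and the KM survival value just after each."""
    order = np.argsort(times, kind="stable")
    times = times[order]
    events = events[order]
    n = times.size
    event_times = np.unique(times[events == 1])
    s = np.empty(event_times.size)
    cur = 1.0
    for k, t in enumerate(event_times):
        n_risk = int(np.sum(times >= t))
        n_events = int(np.sum((times == t) & (events == 1)))
        cur *= 1.0 - n_events / n_risk
        s[k] = cur
    return s, event_times


def km_evaluator(records: Iterable[SurvivalRecord]):
    """Return ``G(t, left_limit=False)`` evaluating the KM curve of ``records``.

    Unlike :func:`survival_at`, the returned callable extends the curve as a
    constant beyond the last observed time (the usual convention for IPCW
    weights) and supports left limits ``G(t-)``.
    """
    records = list(records)
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    s_vals, t_vals = _km_steps(times, events)

    def evaluate(t: float, left_limit: bool = False) -> float:
        if t_vals.size == 0:
            return 1.0
        side = "left" if left_limit else "right"
        k = int(np.searchsorted(t_vals, t, side=side))
        return 1.0 if k == 0 else float(s_vals[k - 1])

    return evaluate


# ---------------------------------------------------------------------------
# CSV interfaces: header `subject_id,time_days,event`


def records_to_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.subject_id, r.time, r.event) for r in records],
        columns=["subject_id", "time_days", "event"],
    )


def records_from_frame(df: pd.DataFrame) -> list[SurvivalRecord]:
    required = {"subject_id", "time_days", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}")
    return [
        SurvivalRecord(str(row.subject_id), float(row.time_days), int(row.event))
        for row in df.itertuples(index=False)
    ]


def read_survival_csv(path) -> list[SurvivalRecord]:
    return records_from_frame(pd.read_csv(path))


def write_survival_csv(records: Iterable[SurvivalRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)
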