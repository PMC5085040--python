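"""Synthetic single-cell interval datasets with the study's censoring structure.

Emulates time-lapse single-RNA microscopy: each cell is observed for a
window (default 120 min) sampled every 60 s, RNA productions are detected at
the first sample at or after their true time, and the interval still open
when observation ends is right-censored.  The generator is the stand-in for
the microscopy measurements and produces the two CSV-shaped tables
(conditions, intervals) consumed by the inference modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import InitiationModel

INTERVAL_COLUMNS = [
    "interval_id",
    "condition_id",
    "lb_s",
    "ub_s",
    "prev_interval_id",
    "cell_id",
]


@dataclass(frozen=True)
class ObservationDesign:
    """Observation operator of the time-lapse experiment.

    ``cell_lifetime_model`` is ``("constant",)`` (windows equal the movie
    length) or ``("lognormal", median_s, sigma)`` emulating division-limited
    observation windows.
    """

    movie_length: float = 7200.0
    sampling_interval: float = 60.0
    n_cells: int = 100
    cell_lifetime_model: tuple = ("constant",)

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.movie_length < self.sampling_interval:
            raise ValueError("movie_length must be >= sampling_interval")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    def draw_lifetimes(self, rng: np.random.Generator) -> np.ndarray:
        kind = self.cell_lifetime_model[0]
        if kind == "constant":
            return np.full(self.n_cells, self.movie_length)
        if kind == "lognormal":
            _, median, sigma = self.cell_lifetime_model
            life = rng.lognormal(np.log(median), sigma, self.n_cells)
            return np.minimum(life, self.movie_length)
        raise ValueError(f"unknown cell_lifetime_model {kind!r}")


@dataclass(frozen=True)
class ConditionMeta:
    condition_id: str
    promoter: str = "synthetic"
    iptg_mM: float = 0.0
    ara_pct: float = 0.0
    atc_ng_ml: float = 0.0
    temperature_C: float = 37.0


@dataclass(frozen=True)
class IntervalRecord:
    """One observed inter-production interval, bounds in seconds.

    ``ub_s = inf`` marks a right-censored interval (only the elapsed time
    since the previous production is known).
    """

    interval_id: str
    condition_id: str
    lb_s: float
    ub_s: float
    prev_interval_id: str | None = None
    cell_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.lb_s < self.ub_s):
            raise ValueError(f"bounds must satisfy 0 <= lb < ub, got ({self.lb_s}, {self.ub_s})")


def sample_intervals(model: InitiationModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` inter-production intervals exactly (vectorized).

    Uses the race identities of the chain: an on-period ends after an
    Exp(k_off + k1) dwell and commits with probability k1/(k1 + k_off), so
    the number of on-visits is geometric and the switching phase is a sum of
    gamma variates; the post-commit steps add independent exponentials.
    Distribution-identical to the event-by-event simulation.
    """
    k1 = model.seq_rates[0]
    if model.has_switching:
        p_commit = k1 / (k1 + model.k_off)
        visits = rng.geometric(p_commit, size=n)  # on-visits until commitment
        w = rng.gamma(visits, 1.0 / (model.k_off + k1))
        off_visits = visits - 1
        mask = off_visits > 0
        w[mask] += rng.gamma(off_visits[mask], 1.0 / model.k_on)
    else:
        w = rng.exponential(1.0 / k1, size=n)
    for r in model.seq_rates[1:]:
        w += rng.exponential(1.0 / r, size=n)
    return w


def simulate_event_times(
    model: InitiationModel, window: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact event-driven simulation of production times in [0, window].

    The chain starts in the on state at step 1 and restarts there after each
    production.  Each transition is an exponential race between the
    competing reactions.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    k1 = model.seq_rates[0]
    times: list[float] = []
    t = 0.0
    while True:
        # pre-commit stage
        if model.has_switching:
            total = model.k_off + k1
            while True:
                t += rng.exponential(1.0 / total)
                if rng.random() < k1 / total:
                    break
                t += rng.exponential(1.0 / model.k_on)
        else:
            t += rng.exponential(1.0 / k1)
        for r in model.seq_rates[1:]:
            t += rng.exponential(1.0 / r)
        if t > window:
            break
        times.append(t)
    return np.asarray(times)


def censor_to_records(
    event_times: Sequence[float],
    design: ObservationDesign,
    condition: ConditionMeta,
    cell_id: str = "cell1",
    window: float | None = None,
    id_prefix: str = "",
) -> list[IntervalRecord]:
    """Apply the sampling-grid observation operator to true production times.

    A production at true time t is detected at the smallest grid multiple
    >= t; consecutive detections d1 < d2 give bounds
    (d2 - d1 - delta, d2 - d1]; productions sharing a grid point give
    (0, delta].  The interval open at the end of the observation window
    yields a right-censored record with lb = grid-aligned elapsed time since
    the last detection.  The first detection of a cell opens the chain but
    is not itself an interval (its start is not a production event).
    """
    delta = design.sampling_interval
    w = design.movie_length if window is None else window
    events = np.sort(np.asarray(event_times, dtype=float))
    if events.size and (events[0] < 0 or events[-1] > w):
        raise ValueError("event times must lie within the observation window")
    end = math.floor(w / delta) * delta
    detections = np.ceil(events / delta - 1e-12) * delta
    detections = detections[detections <= end]
    records: list[IntervalRecord] = []
    prev_id: str | None = None
    for i in range(1, len(detections)):
        gap = detections[i] - detections[i - 1]
        lb = max(gap - delta, 0.0)
        ub = max(gap, delta)
        iid = f"{id_prefix}{cell_id}-i{i}"
        records.append(
            IntervalRecord(iid, condition.condition_id, lb, ub, prev_id, cell_id)
        )
        prev_id = iid
    if len(detections) and end - detections[-1] > 0:
        iid = f"{id_prefix}{cell_id}-c"
        records.append(
            IntervalRecord(
                iid, condition.condition_id, end - detections[-1], math.inf, prev_id, cell_id
            )
        )
    return records


def records_to_frame(records: Iterable[IntervalRecord]) -> pd.DataFrame:
    rows = [
        (r.interval_id, r.condition_id, r.lb_s, r.ub_s, r.prev_interval_id, r.cell_id)
        for r in records
    ]
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def simulate_condition(
    model: InitiationModel,
    design: ObservationDesign,
    condition: ConditionMeta,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate all cells of one condition and return the interval table."""
    lifetimes = design.draw_lifetimes(rng)
    records: list[IntervalRecord] = []
    for c, life in enumerate(lifetimes):
        events = simulate_event_times(model, life, rng)
        records.extend(
            censor_to_records(
                events,
                design,
                condition,
                cell_id=f"{condition.condition_id}-c{c}",
                window=life,
            )
        )
    return records_to_frame(records)


def generate_study(
    design: ObservationDesign,
    schemes: Mapping[str, "TemperatureLaw"],
    temperatures: Sequence[float],
    seed: int,
    promoter: str = "synthetic",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the full scheme x temperature study design.

    ``schemes`` maps an induction-scheme name to a
    :class:`~txinit.temperature.TemperatureLaw` that instantiates the model
    at each temperature.  Returns (conditions table, intervals table) in the
    conditions.csv / intervals.csv schemas; fully reproducible from ``seed``.
    """
    from .temperature import TemperatureLaw  # noqa: F401  (type only)

    rng = np.random.default_rng(seed)
    cond_rows = []
    frames = []
    cid = 0
    for scheme, law in schemes.items():
        for T in temperatures:
            cid += 1
            model = law.model_at(T)
            cond = ConditionMeta(
                condition_id=f"C{cid}",
                promoter=promoter,
                temperature_C=float(T),
            )
            cond_rows.append(
                (cond.condition_id, promoter, scheme, cond.iptg_mM, cond.ara_pct,
                 cond.atc_ng_ml, float(T))
            )
            frames.append(simulate_condition(model, design, cond, rng))
    conditions = pd.DataFrame(
        cond_rows,
        columns=["condition_id", "promoter", "scheme", "iptg_mM", "ara_pct",
                 "atc_ng_ml", "temperature_C"],
    )
    intervals = pd.concat(frames, ignore_index=True) if frames else records_to_frame([])
    return conditions, intervals
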