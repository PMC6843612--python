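"""Life-table restructuring of individual time-to-event records.

Grouped (life-table) hazard modelling treats follow-up time as a covariate
rather than as the outcome: individual records ``(time, event)`` are binned
into equal-width intervals, and each interval contributes an event count, a
censoring count and an "at-risk" exposure.  Censoring then needs no special
likelihood term — it only reduces the exposure.  All model fitting in this
package consumes the :class:`LifeTable` produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "LifeTable",
    "MONTH",
    "at_risk_exposure",
    "read_subjects",
    "build_lifetable",
    "truncate_followup",
]

#: Default interval width: one month, with times measured in years.
MONTH = 1.0 / 12.0


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's follow-up: outcome time in years and event indicator.

    ``event == 1`` means the event was observed at ``time``; ``event == 0``
    means follow-up was censored at ``time``.
    """

    time: float
    event: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"outcome time must be a nonnegative real, got {self.time!r}")
        if self.event not in (0, 1):
            raise ValueError(f"event indicator must be 0 or 1, got {self.event!r}")


def at_risk_exposure(n: float, events: float, censorings: float) -> float:
    """Actuarial at-risk exposure for one interval: ``n - censorings / 2``.

    Subjects censored during the interval contribute half an interval of
    exposure; subjects with an event contribute the full interval.
    """
    del events  # events carry full exposure; present for a self-documenting call
    return n - censorings / 2.0


@dataclass
class LifeTable:
    """Discretized follow-up: counts and exposure per equal-width interval.

    Attributes
    ----------
    width:
        Interval width in years (default one month, ``1/12``).
    n:
        Sample size entering each interval.
    events:
        Events (deaths) within each interval.
    censorings:
        Censorings within each interval.
    """

    width: float
    n: np.ndarray
    events: np.ndarray
    censorings: np.ndarray
    at_risk: np.ndarray = field(init=False)
    hazard: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        self.events = np.asarray(self.events, dtype=float)
        self.censorings = np.asarray(self.censorings, dtype=float)
        self.at_risk = at_risk_exposure(self.n, self.events, self.censorings)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.hazard = np.where(self.at_risk > 0, self.events / np.where(self.at_risk > 0, self.at_risk, 1.0), 0.0)

    def __len__(self) -> int:
        return len(self.n)

    @property
    def starts(self) -> np.ndarray:
        """Interval start times in years."""
        return np.arange(len(self)) * self.width

    @property
    def midpoints(self) -> np.ndarray:
        """Interval midpoints in years — the time covariate for all fits."""
        return (np.arange(len(self)) + 0.5) * self.width

    def to_frame(self) -> pd.DataFrame:
        """Tabular form with the canonical column order."""
        idx = np.arange(len(self))
        return pd.DataFrame(
            {
                "month_start": idx,
                "month_end": idx + 1,
                "n": self.n.astype(int),
                "events": self.events.astype(int),
                "censorings": self.censorings.astype(int),
                "at_risk": self.at_risk,
                "hazard": self.hazard,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_subjects(
    path,
    time_column: str = "time",
    event_column: str = "event",
    delimiter: str = ",",
) -> list[SubjectRecord]:
    """Read individual-level records from a delimited text file.

    Parameters
    ----------
    path:
        CSV/TSV file with one row per subject.
    time_column, event_column:
        Names of the outcome-time (years) and event-indicator columns.

    Raises
    ------
    KeyError
        If a configured column is absent.
    ValueError
        If a row has a negative time or a non-binary indicator; the message
        names the offending row.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    for col in (time_column, event_column):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path} (columns: {list(df.columns)})")
    records = []
    for i, (t, e) in enumerate(zip(df[time_column], df[event_column])):
        try:
            records.append(SubjectRecord(float(t), int(e)))
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return records


def build_lifetable(records: Sequence[SubjectRecord], width: float = MONTH) -> LifeTable:
    """Bin individual records into a :class:`LifeTable`.

    Intervals are half-open ``[start, start + width)`` spanning
    ``[0, max outcome time]``; a time falling exactly on a boundary is
    assigned to the interval beginning there.

    Raises
    ------
    ValueError
        If ``records`` is empty or ``width <= 0``.
    """
    if width <= 0:
        raise ValueError(f"interval width must be positive, got {width}")
    if len(records) == 0:
        raise ValueError("cannot build a life table from zero records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    # index of the half-open interval containing each time; a time equal to
    # the overall maximum still needs a containing interval
    idx = np.floor(times / width + 1e-12).astype(int)
    n_int = int(idx.max()) + 1
    y = np.bincount(idx[events == 1], minlength=n_int)
    c = np.bincount(idx[events == 0], minlength=n_int)
    removed = np.concatenate([[0], np.cumsum(y + c)[:-1]])
    n = len(records) - removed
    return LifeTable(width=width, n=n, events=y, censorings=c)


def truncate_followup(records: Iterable[SubjectRecord], cutoff: float) -> list[SubjectRecord]:
    """Administratively censor all follow-up beyond ``cutoff`` years.

    Records with ``time > cutoff`` become ``(cutoff, event=0)``; all others
    are returned unchanged.  Used for the data-splitting extrapolation
    assessment (fit on the first years, score on the remainder).
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    return [r if r.time <= cutoff else SubjectRecord(cutoff, 0) for r in records]
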