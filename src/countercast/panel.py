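"""Intervention time-series panels and deterministic preprocessing transforms.

A :class:`TimeSeriesPanel` holds one focal outcome series together with a
named matrix of reference ("counterfactual") series on a regular weekly or
monthly calendar.  An :class:`InterventionStudy` pairs a panel with the date
of the event whose impact is being evaluated; everything downstream fits on
the strictly-pre-intervention rows only and forecasts the rest.

The transforms here are the deterministic preprocessing steps of the
counterfactual pipeline: decimal-date conversion, two-standard-deviation
time standardization (frozen on the fitting period), substitution of exact
0/1 values before beta-likelihood fitting, rescaling of 0-100 search indices
to unit-interval proportions, and the strict pre/post split.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import enum
import warnings
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Frequency",
    "OutcomeKind",
    "TimeSeriesPanel",
    "InterventionStudy",
    "StandardizedTime",
    "to_decimal_date",
    "decimal_dates",
    "standardize_time",
    "substitute_unit_boundary",
    "rescale_relative",
    "split_pre_post",
    "read_panel_csv",
    "write_panel_csv",
]


class Frequency(str, enum.Enum):
    weekly = "weekly"
    monthly = "monthly"


class OutcomeKind(str, enum.Enum):
    """What the focal series measures, which fixes the likelihood family."""

    proportion = "proportion"     # relative search frequency in [0, 1]
    count = "count"               # non-negative integer imports
    positive_real = "positive_real"  # visits (in 100,000-visit units)


def _as_date(value) -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    return pd.Timestamp(value).date()


@dataclass(frozen=True)
class TimeSeriesPanel:
    """A dated focal series plus named reference series.

    Parameters
    ----------
    times
        Strictly increasing calendar dates, one per period.
    focal
        The outcome series (length ``len(times)``).
    references
        Mapping of reference-series name to values, each of the same length.
    frequency
        ``weekly`` or ``monthly``; the calendar must already be regular.
    outcome_kind
        Declares the measurement scale (checked against the values).
    """

    times: Tuple[_dt.date, ...]
    focal: np.ndarray
    references: Dict[str, np.ndarray]
    frequency: Frequency
    outcome_kind: OutcomeKind

    def __init__(self, times, focal, references, frequency, outcome_kind):
        times = tuple(_as_date(t) for t in times)
        if len(times) == 0:
            raise ValueError("panel must contain at least one row")
        diffs_ok = all(a < b for a, b in zip(times[:-1], times[1:]))
        if not diffs_ok:
            raise ValueError("times must be strictly increasing with no duplicates")
        focal = np.asarray(focal, dtype=float)
        if focal.ndim != 1 or focal.shape[0] != len(times):
            raise ValueError(
                f"focal has {focal.shape[0] if focal.ndim == 1 else 'bad'} entries, "
                f"expected {len(times)}"
            )
        refs = {}
        for name, col in dict(references).items():
            col = np.asarray(col, dtype=float)
            if col.shape != (len(times),):
                raise ValueError(f"reference {name!r} length != number of times")
            refs[str(name)] = col
        frequency = Frequency(frequency)
        outcome_kind = OutcomeKind(outcome_kind)
        _check_outcome_values(outcome_kind, focal, refs)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "focal", focal)
        object.__setattr__(self, "references", refs)
        object.__setattr__(self, "frequency", frequency)
        object.__setattr__(self, "outcome_kind", outcome_kind)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def reference_names(self) -> Tuple[str, ...]:
        return tuple(self.references)

    @property
    def reference_matrix(self) -> np.ndarray:
        """References as an (n, k) column matrix, in insertion order."""
        if not self.references:
            return np.empty((len(self), 0))
        return np.column_stack([self.references[n] for n in self.references])

    def take(self, mask: np.ndarray) -> "TimeSeriesPanel":
        """Row subset, preserving order (``mask`` boolean or index array)."""
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return TimeSeriesPanel(
            times=[self.times[i] for i in idx],
            focal=self.focal[idx],
            references={n: v[idx] for n, v in self.references.items()},
            frequency=self.frequency,
            outcome_kind=self.outcome_kind,
        )

    def with_focal(self, focal: np.ndarray) -> "TimeSeriesPanel":
        return TimeSeriesPanel(self.times, focal, self.references,
                               self.frequency, self.outcome_kind)

    def with_references(self, references) -> "TimeSeriesPanel":
        return TimeSeriesPanel(self.times, self.focal, references,
                               self.frequency, self.outcome_kind)

    def to_frame(self) -> pd.DataFrame:
        data = {"date": [t.isoformat() for t in self.times], "focal": self.focal}
        data.update(self.references)
        return pd.DataFrame(data)


def _check_outcome_values(kind: OutcomeKind, focal, refs) -> None:
    if kind is OutcomeKind.proportion:
        for name, col in [("focal", focal), *refs.items()]:
            if np.any(col < 0) or np.any(col > 1):
                raise ValueError(
                    f"outcome_kind=proportion but series {name!r} has values "
                    "outside [0, 1]; rescale_relative may help"
                )
    elif kind is OutcomeKind.count:
        for name, col in [("focal", focal), *refs.items()]:
            if np.any(col < 0) or not np.allclose(col, np.round(col)):
                raise ValueError(
                    f"outcome_kind=count but series {name!r} is not "
                    "non-negative integer"
                )
    elif kind is OutcomeKind.positive_real:
        if np.any(focal <= 0):
            raise ValueError("outcome_kind=positive_real but focal has values <= 0")


@dataclass(frozen=True)
class InterventionStudy:
    """A panel plus the intervention date splitting it into pre and post.

    The intervention date must lie strictly inside the panel's time range,
    and the pre-period must hold at least twice as many rows as the widest
    design matrix any of the model families would build from the panel
    (checked at fit time, when the design is known).
    """

    panel: TimeSeriesPanel
    intervention_date: _dt.date

    def __init__(self, panel: TimeSeriesPanel, intervention_date):
        intervention_date = _as_date(intervention_date)
        if not (panel.times[0] < intervention_date <= panel.times[-1]):
            raise ValueError(
                f"intervention_date {intervention_date} must lie strictly "
                f"inside the panel range [{panel.times[0]}, {panel.times[-1]}]"
            )
        object.__setattr__(self, "panel", panel)
        object.__setattr__(self, "intervention_date", intervention_date)

    @property
    def pre_mask(self) -> np.ndarray:
        return np.array([t < self.intervention_date for t in self.panel.times])

    def require_identifiable(self, n_design_columns: int) -> None:
        """Refuse fitting when the pre-period is too short to identify the fit."""
        n_pre = int(self.pre_mask.sum())
        if n_pre < 2 * n_design_columns:
            raise ValueError(
                f"pre-period has {n_pre} observations but the design has "
                f"{n_design_columns} columns; need at least {2 * n_design_columns}"
            )


@dataclass(frozen=True)
class StandardizedTime:
    """Decimal dates centred and scaled by twice the fitting-period SD."""

    values: np.ndarray
    center: float
    scale: float

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("standardization scale must be > 0")

    def unstandardize(self) -> np.ndarray:
        return self.values * self.scale + self.center


def to_decimal_date(date) -> float:
    """Calendar date -> decimal years, e.g. 2014-02-01 -> 2014.085.

    Defined as ``year + (day_of_year - 1) / days_in_year`` so January 1st is
    exactly the integer year; leap years use 366 days.
    """
    date = _as_date(date)
    doy = date.timetuple().tm_yday
    days = 366 if calendar.isleap(date.year) else 365
    return date.year + (doy - 1) / days


def decimal_dates(dates: Sequence) -> np.ndarray:
    return np.array([to_decimal_date(d) for d in dates], dtype=float)


def standardize_time(dates: Sequence, fit_dates: Sequence) -> StandardizedTime:
    """Standardize decimal dates by the fitting period's mean and 2 x SD.

    The centre and scale are computed from ``fit_dates`` only (the
    pre-intervention rows) and then applied to ``dates``, so forecast rows
    are transformed with frozen constants and never influence the scaling.
    When ``dates == fit_dates`` the result has mean 0 and sample SD 0.5.
    """
    fit = decimal_dates(fit_dates)
    if len(fit) < 2:
        raise ValueError("need at least two fitting dates to standardize time")
    sd = float(np.std(fit, ddof=1))
    if sd == 0.0:
        raise ValueError("fitting dates are constant; cannot standardize time")
    center = float(np.mean(fit))
    scale = 2.0 * sd
    values = (decimal_dates(dates) - center) / scale
    return StandardizedTime(values=values, center=center, scale=scale)


def substitute_unit_boundary(series, sub: float = 0.99) -> np.ndarray:
    """Replace exact 0/1 values so a beta likelihood is defined.

    The beta distribution has no mass at 0 or 1, so the single period at the
    series maximum (1.0 after relative rescaling) is replaced by ``sub``
    (default 0.99), and exact zeros by ``(1 - sub) / 2`` (default 0.005).
    All interior values pass through unchanged; the transform is idempotent.
    """
    series = np.asarray(series, dtype=float)
    if np.any(series < 0) or np.any(series > 1):
        raise ValueError("substitute_unit_boundary expects values in [0, 1]")
    if not 0 < sub < 1:
        raise ValueError("sub must lie strictly inside (0, 1)")
    eps = (1.0 - sub) / 2.0
    out = series.copy()
    ones = series == 1.0
    zeros = series == 0.0
    out[ones] = sub
    out[zeros] = eps
    if zeros.any():
        warnings.warn(
            f"substituted {eps} for {int(zeros.sum())} exact zero(s); the beta "
            "likelihood cannot model 0s",
            stacklevel=2,
        )
    return out


def rescale_relative(series) -> np.ndarray:
    """Convert a 0-100 search-index series to unit-interval proportions.

    Series already on the unit scale are returned unchanged; an all-zero
    series is rejected because relative frequencies are undefined for it.
    """
    series = np.asarray(series, dtype=float)
    if np.any(series < 0):
        raise ValueError("relative series must be non-negative")
    mx = series.max(initial=0.0)
    if mx == 0.0:
        raise ValueError("all-zero series has no relative scale")
    if mx <= 100 and np.any(series > 1):
        return series / 100.0
    return series


def split_pre_post(study: InterventionStudy) -> Tuple[TimeSeriesPanel, TimeSeriesPanel]:
    """Partition the panel into (pre, post) around the intervention date.

    Rows strictly before the intervention date form the pre panel (the
    fitting data); the intervention period itself and everything after form
    the post panel (the forecast window).  The two partitions are exact: no
    row is lost or duplicated and ordering is preserved.
    """
    mask = study.pre_mask
    if mask.all():
        raise ValueError("post-period is empty; nothing to evaluate")
    if not mask.any():
        raise ValueError("pre-period is empty; nothing to fit")
    return study.panel.take(mask), study.panel.take(~mask)


def read_panel_csv(path, frequency, outcome_kind) -> TimeSeriesPanel:
    """Read a panel from ``date,focal,<ref_1>,...`` CSV with ISO-8601 dates.

    Missing values are not permitted and are rejected with the offending
    row number.
    """
    df = pd.read_csv(path)
    if "date" not in df.columns or "focal" not in df.columns:
        raise ValueError("panel CSV must have 'date' and 'focal' columns")
    na_rows = df.index[df.isna().any(axis=1)]
    if len(na_rows) > 0:
        raise ValueError(
            f"missing value in panel CSV at data row {int(na_rows[0]) + 1}"
        )
    ref_cols = [c for c in df.columns if c not in ("date", "focal")]
    return TimeSeriesPanel(
        times=[_as_date(d) for d in df["date"]],
        focal=df["focal"].to_numpy(dtype=float),
        references={c: df[c].to_numpy(dtype=float) for c in ref_cols},
        frequency=frequency,
        outcome_kind=outcome_kind,
    )


def write_panel_csv(panel: TimeSeriesPanel, path) -> None:
    panel.to_frame().to_csv(path, index=False)
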