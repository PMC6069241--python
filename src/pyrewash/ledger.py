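"""Daily pesticide mass-availability ledger.

Converts monthly pesticide-use records (California PUR style) into a daily
per-analyte series of mass available for wash-off at the catchment. Monthly
totals are scaled by the catchment-to-county developed-area ratio, spread
uniformly over the days of their month, accumulated with first-order
degradation, and depleted by the pesticide mass washed off in prior storms:

    M_avail(t) = M_app(t) + M_avail(t-1) * exp(-k_deg * dt) - M_w(t-1)

The mass reported for a storm event is the ledger state at the start of the
event day, before that day's wash-off is subtracted.
"""

from __future__ import annotations

import calendar
import datetime as dt
import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

#: Relative tolerance for mass-balance checks when subtracting washed mass.
MASS_BALANCE_RTOL = 1e-9


@dataclass(frozen=True)
class ApplicationRecord:
    """One pesticide-use entry: mass of an active ingredient applied in a
    county under a use category, dated (typically) the first of the month."""

    date: dt.date
    use_category: str
    active_ingredient: str
    mass_applied: float  # g
    county: str = ""

    def __post_init__(self) -> None:
        if self.mass_applied < 0:
            raise ValueError(f"mass_applied must be >= 0, got {self.mass_applied}")


@dataclass(frozen=True)
class AreaScaling:
    """County-to-catchment apportionment ratio.

    County-level use totals are assumed uniform over the county's developed
    area, so the catchment receives the fraction catchment_area /
    reference_area of every reported mass.
    """

    catchment_area: float  # m^2, A_F
    reference_area: float  # m^2, A_S (developed area of the county)

    def __post_init__(self) -> None:
        if self.reference_area <= 0:
            raise ValueError("reference_area must be > 0")
        if not 0 < self.catchment_area <= self.reference_area:
            raise ValueError(
                "need 0 < catchment_area <= reference_area, got "
                f"{self.catchment_area} / {self.reference_area}"
            )

    @property
    def ratio(self) -> float:
        return self.catchment_area / self.reference_area


@dataclass(frozen=True)
class AvailableMassState:
    """Ledger state for one calendar day (all masses in g)."""

    day: dt.date
    applied: float  # mass applied on this day
    available: float  # mass available at the START of this day
    washed: float  # mass washed off on this day (0 on dry days)
    degradation_rate: float  # k_deg, 1/day

    def __post_init__(self) -> None:
        if self.available < 0 or self.washed < 0:
            raise ValueError("available and washed must be >= 0")
        if self.degradation_rate < 0:
            raise ValueError("degradation_rate must be >= 0")


def filter_use_records(
    records: Iterable[ApplicationRecord],
    allowed_categories: set[str],
    allowed_ingredients: set[str],
) -> list[ApplicationRecord]:
    """Keep only records whose use category AND active ingredient are in the
    allowed sets (e.g. structural pest control / landscape maintenance for the
    monitored pyrethroids); input order is preserved."""
    return [
        r
        for r in records
        if r.use_category in allowed_categories
        and r.active_ingredient in allowed_ingredients
    ]


def daily_application_rate(
    monthly_records: Sequence[ApplicationRecord],
    scaling: AreaScaling,
) -> float:
    """Average daily mass applied to the catchment during one month (g/day).

    Sums the reported masses for the month, scales by the catchment/county
    area ratio and divides by the month's calendar day count. All records
    must fall within a single calendar month.
    """
    if not monthly_records:
        return 0.0
    months = {(r.date.year, r.date.month) for r in monthly_records}
    if len(months) > 1:
        raise ValueError(f"records span multiple months: {sorted(months)}")
    (year, month), = months
    n_days = calendar.monthrange(year, month)[1]
    total = sum(r.mass_applied for r in monthly_records)
    if total < 0:
        raise ValueError("negative total applied mass")
    return total * scaling.ratio / n_days


def step_available_mass(
    prev: AvailableMassState,
    applied_today: float,
    washed_prev: float,
    dt_days: float = 1.0,
) -> AvailableMassState:
    """Advance the ledger one step.

    available(t) = applied(t) + available(t-1)*exp(-k_deg*dt) - washed(t-1).
    Degradation acts on the previous availability before the previous day's
    wash-off is subtracted. Small negative results (within mass-balance
    tolerance, e.g. from measurement noise in washed loads) are clipped to
    zero with a warning; larger over-subtraction is an error.
    """
    if dt_days <= 0:
        raise ValueError(f"dt_days must be > 0, got {dt_days}")
    if washed_prev < 0:
        raise ValueError("washed mass must be >= 0")
    if washed_prev > prev.available * (1 + MASS_BALANCE_RTOL):
        raise ValueError(
            f"washed mass {washed_prev} exceeds previous availability "
            f"{prev.available}"
        )
    decayed = prev.available * math.exp(-prev.degradation_rate * dt_days)
    new_available = applied_today + decayed - washed_prev
    if new_available < 0:
        # Legitimate for a full dissolved-regime wash-off (washed equals the
        # pre-degradation availability), whose deficit is bounded by one
        # day's degradation loss; anything larger points at noisy washed
        # loads and is flagged loudly.
        deficit = -new_available
        level = logging.DEBUG if deficit <= 0.05 * max(prev.available, 1e-300) else logging.WARNING
        logger.log(
            level, "clipping negative available mass %.3e to 0 on %s", new_available, prev.day
        )
        new_available = 0.0
    day = prev.day + dt.timedelta(days=dt_days)
    return replace(
        prev, day=day, applied=applied_today, available=new_available, washed=0.0
    )


def _daily_applications(
    applications: Iterable[ApplicationRecord],
    start: dt.date,
    end: dt.date,
    scaling: AreaScaling | None,
) -> dict[dt.date, float]:
    """Spread monthly records uniformly over their month, restricted to
    [start, end]; returns g/day per calendar day."""
    ratio = scaling.ratio if scaling is not None else 1.0
    daily: dict[dt.date, float] = {}
    for rec in applications:
        year, month = rec.date.year, rec.date.month
        n_days = calendar.monthrange(year, month)[1]
        rate = rec.mass_applied * ratio / n_days
        if rate == 0:
            continue
        for dom in range(1, n_days + 1):
            day = dt.date(year, month, dom)
            if start <= day <= end:
                daily[day] = daily.get(day, 0.0) + rate
    return daily


def build_available_series(
    applications: Sequence[ApplicationRecord],
    washoff_events: Sequence[tuple[dt.date, float]],
    k_deg: float,
    event_day: dt.date,
    window_days: int = 90,
    scaling: AreaScaling | None = None,
) -> list[AvailableMassState]:
    """Daily availability ledger over the lookback window ending at a storm.

    Runs the recursion day by day from ``event_day - window_days`` to
    ``event_day``, starting from zero availability. Prior storms inside the
    window (``washoff_events`` as (day, washed mass in g) pairs) deplete the
    ledger on the following day's step. The last state's ``available`` is the
    mass available at the start of ``event_day``, before any wash-off that
    day.
    """
    if k_deg < 0:
        raise ValueError("k_deg must be >= 0")
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    start = event_day - dt.timedelta(days=window_days)
    washed_by_day: dict[dt.date, float] = {}
    for day, mass in washoff_events:
        if not start <= day <= event_day:
            raise ValueError(
                f"wash-off event on {day} outside window [{start}, {event_day}]"
            )
        washed_by_day[day] = washed_by_day.get(day, 0.0) + mass

    daily_applied = _daily_applications(applications, start, end=event_day, scaling=scaling)

    state = AvailableMassState(
        day=start,
        applied=daily_applied.get(start, 0.0),
        available=daily_applied.get(start, 0.0),
        washed=washed_by_day.get(start, 0.0),
        degradation_rate=k_deg,
    )
    series = [state]
    day = start
    while day < event_day:
        washed_prev = min(washed_by_day.get(day, 0.0), state.available)
        if washed_prev < washed_by_day.get(day, 0.0):
            logger.debug(
                "washed load on %s capped at available mass %.3e", day, state.available
            )
        day = day + dt.timedelta(days=1)
        state = step_available_mass(
            state, applied_today=daily_applied.get(day, 0.0), washed_prev=washed_prev
        )
        state = replace(state, washed=washed_by_day.get(day, 0.0))
        series.append(state)
    return series


def available_at_event(
    applications: Sequence[ApplicationRecord],
    washoff_events: Sequence[tuple[dt.date, float]],
    k_deg: float,
    event_day: dt.date,
    window_days: int = 90,
    scaling: AreaScaling | None = None,
) -> float:
    """Mass available (g) at the start of ``event_day``; convenience wrapper
    around :func:`build_available_series`."""
    series = build_available_series(
        applications, washoff_events, k_deg, event_day, window_days, scaling
    )
    return series[-1].available


def fit_degradation_rate(
    applications: Sequence[ApplicationRecord],
    dissolved_events: Sequence[tuple[dt.date, float]],
    washoff_history: Sequence[tuple[dt.date, float]] | None = None,
    k0: float = 0.01,
    window_days: int = 90,
    scaling: AreaScaling | None = None,
) -> tuple[float, float]:
    """Estimate k_deg (1/day) from dissolved-regime storm loads.

    In the dissolved regime the whole available mass washes off, so each
    observed load in ``dissolved_events`` (day, load g) equals the ledger
    availability at that day, which depends on k_deg. Fits log observed
    load against log modelled availability (loads are positive and
    multiplicatively noisy) by nonlinear least squares.

    ``washoff_history`` lists ALL observed storm loads (every regime) so
    earlier particle-bound storms also deplete the candidate ledger; when
    omitted, the dissolved events themselves are used as the history.

    Because the history loads are themselves noisy observations, storms
    whose availability is dominated by recent wash-off subtraction (rather
    than accumulated application) inherit amplified noise. A second,
    weighted pass propagates that history noise into a per-event relative
    variance, sigma_i^2 = sigma^2 * (1 + sum_j (w_j e^{-k dt_ij} /
    avail_i)^2), which downweights such low-information events.

    Returns ``(k_hat, standard_error)``.
    """
    events = sorted(dissolved_events, key=lambda e: e[0])
    if len(events) < 2:
        raise ValueError("need at least 2 dissolved events to fit k_deg")
    obs = np.asarray([w for _, w in events], dtype=float)
    if np.any(obs <= 0):
        raise ValueError("observed loads must be positive for log-space fitting")
    history = sorted(washoff_history, key=lambda e: e[0]) if washoff_history else events

    def _prior(day: dt.date) -> list[tuple[dt.date, float]]:
        window_start = day - dt.timedelta(days=window_days)
        return [(d, float(w)) for d, w in history if window_start <= d < day]

    def model_avail(k: float) -> np.ndarray:
        return np.array(
            [
                available_at_event(applications, _prior(day), k, day, window_days, scaling)
                for day, _ in events
            ]
        )

    def log_model(_x: np.ndarray, k: float) -> np.ndarray:
        return np.log(np.maximum(model_avail(k), 1e-300))

    x = np.arange(obs.size, dtype=float)
    (k1,), _ = optimize.curve_fit(
        log_model, x, np.log(obs), p0=[k0], bounds=(0.0, 1.0)
    )
    avail = np.maximum(model_avail(k1), 1e-300)
    rel_sigma = np.empty(obs.size)
    for i, (day, _) in enumerate(events):
        carried = [
            w * math.exp(-k1 * (day - d).days) / avail[i] for d, w in _prior(day)
        ]
        rel_sigma[i] = math.sqrt(1.0 + sum(c * c for c in carried))
    popt, pcov = optimize.curve_fit(
        log_model,
        x,
        np.log(obs),
        p0=[k1],
        bounds=(0.0, 1.0),
        sigma=rel_sigma,
        absolute_sigma=False,
    )
    return float(popt[0]), float(np.sqrt(pcov[0, 0]))
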