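"""Synthetic monitoring campaigns with stored ground truth.

Emulates the data a multi-year residential stormwater monitoring programme
produces: wet-season storm sequences with exponential dry gaps, monthly
county-level pesticide-use reports concentrated in summer, sediment loads
driven by dry-weather build-up and storm wash-off, and pyrethroid loads
generated by the threshold-switched regime model plus observation noise.
Every generator is deterministic under a fixed seed, and the generating
parameters travel with the campaign so recovery tests can compare fitted
coefficients against truth.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catchment import CatchmentParams, Hyetograph, TssState, event_runoff, tss_buildup, tss_washoff
from .ledger import ApplicationRecord, AreaScaling, available_at_event
from .washoff import (
    DISSOLVED,
    PARTICLE_BOUND,
    WashoffParams,
    dissolved_fraction,
    dissolved_washoff,
    particle_bound_washoff,
    select_regime,
)

ANALYTES = ("bifenthrin", "cyfluthrin", "cypermethrin")

# Rough first-order surface-degradation rates on concrete (1/day);
# order-of-magnitude defaults (half-lives of weeks to months), to be
# replaced by site-specific values for publication-grade runs.
DEFAULT_K_DEG: dict[str, float] = {
    "bifenthrin": 0.0077,
    "cyfluthrin": 0.0139,
    "cypermethrin": 0.0173,
}

# Sediment-water partitioning coefficients (L/kg); bifenthrin is the most
# particle-associated of the three.
DEFAULT_KD: dict[str, float] = {
    "bifenthrin": 1.0e5,
    "cyfluthrin": 5.0e4,
    "cypermethrin": 5.0e4,
}

# Two-catchment residential templates (Folsom-like basins).
F1_CATCHMENT = CatchmentParams(
    area=21_634.0,
    impervious_fraction=0.496,
    depression_storage=1.5,
    horton_f0=76.0,
    horton_fc=13.0,
    horton_k=4.14,
)
F2_CATCHMENT = CatchmentParams(
    area=30_202.0,
    impervious_fraction=0.524,
    depression_storage=1.5,
    horton_f0=76.0,
    horton_fc=13.0,
    horton_k=4.14,
)

SUMMER_MONTHS = (6, 7, 8)
WET_MONTHS = (10, 11, 12, 1, 2, 3, 4)


@dataclass(frozen=True)
class Storm:
    """One synthetic storm: date, antecedent dry period and hyetograph."""

    date: dt.date
    adp_day: float
    depth_mm: float
    duration_h: float
    hyetograph: Hyetograph


@dataclass
class SyntheticTruth:
    """Complete generating configuration for a campaign.

    The defaults are the study conditions the generators emulate; noise
    sigmas are 0 (noise-free) unless a campaign asks otherwise.
    load_noise_sigma is the sigma of a multiplicative lognormal factor on
    every load; fraction_noise_sigma is the sigma of additive Gaussian
    noise on the particle-bound washed fraction.
    """

    catchment: CatchmentParams = F1_CATCHMENT
    site: str = "F1"
    scaling: AreaScaling = field(
        default_factory=lambda: AreaScaling(
            catchment_area=21_634.0, reference_area=5.0e8
        )
    )
    analytes: tuple[str, ...] = ANALYTES
    k_deg: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_K_DEG))
    washoff: dict[str, WashoffParams] = field(
        default_factory=lambda: {
            a: WashoffParams(
                transfer_intercept=0.1,
                transfer_slope=0.3,
                tss_threshold=10.0,
                regression_space="log10",
                kd=DEFAULT_KD[a],
                analyte=a,
            )
            for a in ANALYTES
        }
    )
    # county-scale monthly base application mass (g) per analyte
    monthly_use: dict[str, float] = field(
        default_factory=lambda: {
            "bifenthrin": 1.2e5,
            "cyfluthrin": 0.6e5,
            "cypermethrin": 0.8e5,
        }
    )
    summer_factor: float = 2.5
    tss_buildup_max: float = 500.0  # mg at catchment scale
    tss_buildup_rate: float = 0.03  # 1/day
    tss_washoff_coeff: float = 0.02  # 1/mm
    tss_washoff_exponent: float = 1.0
    load_noise_sigma: float = 0.0
    fraction_noise_sigma: float = 0.0
    masking_rate: float = 0.0
    window_days: int = 90
    seed: int = 0

    def tss_state(self) -> TssState:
        return TssState(
            buildup_max=self.tss_buildup_max,
            buildup_rate=self.tss_buildup_rate,
            washoff_coeff=self.tss_washoff_coeff,
            washoff_exponent=self.tss_washoff_exponent,
        )


@dataclass
class Campaign:
    """A generated monitoring campaign plus its ground truth."""

    table: pd.DataFrame  # observed (noisy, possibly masked) event table
    truth_table: pd.DataFrame  # noise-free loads, regimes, availabilities
    truth: SyntheticTruth
    storms: list[Storm]
    use_records: list[ApplicationRecord]


def _next_wet_day(day: dt.date, wet_months: Sequence[int]) -> dt.date:
    while day.month not in wet_months:
        year = day.year + (1 if day.month == 12 else 0)
        month = 1 if day.month == 12 else day.month + 1
        day = dt.date(year, month, 1)
    return day


def generate_storm_sequence(
    n_events: int,
    seed: int | np.random.Generator = 0,
    start: dt.date = dt.date(2007, 10, 1),
    mean_gap_days: float = 10.0,
    depth_median_mm: float = 8.0,
    depth_sigma: float = 0.9,
    duration_median_h: float = 6.0,
    duration_sigma: float = 0.5,
    min_depth_mm: float = 2.0,
    wet_months: Sequence[int] = WET_MONTHS,
    step_h: float = 0.25,
) -> list[Storm]:
    """Wet-season storm dates with exponential dry gaps and lognormal
    depth/duration marks.

    Gaps shorter than one day are rounded up; dates falling in the dry
    season jump to the start of the next wet season, which produces the
    long antecedent dry periods of first-of-season storms. Depths below
    ``min_depth_mm`` (the sampling trigger) are resampled. Hyetographs are
    constant-intensity blocks at ``step_h`` resolution.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    storms: list[Storm] = []
    prev = start
    for _ in range(n_events):
        gap = max(1, int(round(rng.exponential(mean_gap_days))))
        day = _next_wet_day(prev + dt.timedelta(days=gap), wet_months)
        adp = (day - prev).days
        depth = 0.0
        while depth < min_depth_mm:
            depth = float(rng.lognormal(np.log(depth_median_mm), depth_sigma))
        duration = float(
            np.clip(rng.lognormal(np.log(duration_median_h), duration_sigma), 0.5, 48.0)
        )
        storms.append(
            Storm(
                date=day,
                adp_day=float(adp),
                depth_mm=depth,
                duration_h=duration,
                hyetograph=Hyetograph.constant(depth, duration, step_h),
            )
        )
        prev = day
    return storms


def generate_use_reports(
    monthly_use: Mapping[str, float],
    years: Sequence[int],
    summer_factor: float = 2.5,
    summer_months: Sequence[int] = SUMMER_MONTHS,
    use_category: str = "structural pest control",
    county: str = "Sacramento",
    jitter_sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[ApplicationRecord]:
    """Monthly county-level application records dated the first of each
    month, with summer months upweighted by ``summer_factor``.

    With ``jitter_sigma`` = 0 (default) the masses are exactly the
    configured pattern, so annual totals equal the pattern sum.
    """
    if summer_factor < 0:
        raise ValueError("summer_factor must be >= 0")
    if any(m < 0 for m in monthly_use.values()):
        raise ValueError("monthly_use masses must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records: list[ApplicationRecord] = []
    for year in years:
        for month in range(1, 13):
            weight = summer_factor if month in summer_months else 1.0
            for analyte, base in monthly_use.items():
                mass = base * weight
                if jitter_sigma > 0:
                    mass *= float(rng.lognormal(0.0, jitter_sigma))
                if mass == 0:
                    continue
                records.append(
                    ApplicationRecord(
                        date=dt.date(year, month, 1),
                        use_category=use_category,
                        active_ingredient=analyte,
                        mass_applied=mass,
                        county=county,
                    )
                )
    return records


def generate_campaign(
    truth: SyntheticTruth,
    n_events: int,
    seed: int | None = None,
) -> Campaign:
    """Forward-simulate a monitoring campaign under ``truth``.

    Runs the full chain — use-report ledger, event runoff, sediment
    build-up/wash-off, regime-switched pesticide wash-off — then applies
    the configured observation noise and missingness to produce the
    observed table. True (noise-free) loads feed back into the ledger, so
    at zero noise the campaign is exactly reproducible by the forward
    pipeline.
    """
    if seed is None:
        seed = truth.seed
    ss = np.random.SeedSequence(seed)
    rng_storm, rng_use, rng_noise, rng_mask = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    storms = generate_storm_sequence(n_events, seed=rng_storm)
    first, last = storms[0].date, storms[-1].date
    years = range(
        (first - dt.timedelta(days=truth.window_days + 31)).year, last.year + 1
    )
    use_records = generate_use_reports(
        truth.monthly_use,
        years=list(years),
        summer_factor=truth.summer_factor,
        seed=rng_use,
    )

    tss = truth.tss_state()
    history: dict[str, list[tuple[dt.date, float]]] = {a: [] for a in truth.analytes}
    obs_rows, truth_rows = [], []
    for i, storm in enumerate(storms):
        event_id = f"E{i + 1:03d}"
        volume, eff_depth = event_runoff(storm.hyetograph, truth.catchment)
        tss_buildup(tss, storm.adp_day)
        mw_tss, emc_tss = tss_washoff(tss, eff_depth, volume)
        mw_tss_obs = mw_tss * float(rng_noise.lognormal(0.0, truth.load_noise_sigma))
        emc_tss_obs = mw_tss_obs / (volume * 1000.0) if volume > 0 else 0.0

        obs = {
            "event_id": event_id,
            "date": storm.date,
            "site": truth.site,
            "adp_day": storm.adp_day,
            "rain_mm": storm.depth_mm,
            "duration_h": storm.duration_h,
            "runoff_m3": volume,
            "emc_tss_mg_l": emc_tss_obs,
            "eml_tss_mg": mw_tss_obs,
        }
        tru = {
            "event_id": event_id,
            "date": storm.date,
            "eml_tss_mg": mw_tss,
            "runoff_m3": volume,
        }
        c_tss_kg_l = emc_tss / 1.0e6  # mg/L -> kg/L
        for analyte in truth.analytes:
            params = truth.washoff[analyte]
            window_start = storm.date - dt.timedelta(days=truth.window_days)
            prior = [(d, w) for d, w in history[analyte] if d >= window_start]
            m_avail = available_at_event(
                [r for r in use_records if r.active_ingredient == analyte],
                prior,
                truth.k_deg[analyte],
                storm.date,
                truth.window_days,
                truth.scaling,
            )
            regime = select_regime(mw_tss, params)
            if regime == DISSOLVED:
                load = dissolved_washoff(m_avail)
            else:
                load = particle_bound_washoff(m_avail, mw_tss, params)
                if truth.fraction_noise_sigma > 0 and m_avail > 0:
                    frac = load / m_avail + float(
                        rng_noise.normal(0.0, truth.fraction_noise_sigma)
                    )
                    load = float(np.clip(frac, 0.0, 1.0)) * m_avail
            history[analyte].append((storm.date, load))
            load_obs = load * float(rng_noise.lognormal(0.0, truth.load_noise_sigma))
            obs[f"m_avail_{analyte}_g"] = m_avail
            obs[f"eml_{analyte}_ug"] = load_obs * 1.0e6
            obs[f"emc_{analyte}_ng_l"] = (
                load_obs * 1.0e6 / volume if volume > 0 else 0.0
            )
            tru[f"m_avail_{analyte}_g"] = m_avail
            tru[f"eml_{analyte}_g"] = load
            tru[f"regime_{analyte}"] = regime
            tru[f"f_diss_{analyte}"] = dissolved_fraction(params.kd, c_tss_kg_l)
        obs_rows.append(obs)
        truth_rows.append(tru)

    table = pd.DataFrame(obs_rows).set_index("event_id")
    truth_table = pd.DataFrame(truth_rows).set_index("event_id")

    if truth.masking_rate > 0:
        for event_id in table.index:
            if rng_mask.random() < truth.masking_rate:
                analyte = truth.analytes[rng_mask.integers(len(truth.analytes))]
                table.loc[event_id, [f"eml_{analyte}_ug", f"emc_{analyte}_ng_l"]] = np.nan

    return Campaign(
        table=table,
        truth_table=truth_table,
        truth=truth,
        storms=storms,
        use_records=use_records,
    )
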