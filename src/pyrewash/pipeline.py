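"""Forward pipeline and coefficient fitting.

Chains the modules into the event loop a campaign run needs: the use-report
ledger supplies each storm's available pesticide mass, the sediment load
comes either from the monitored table ("observed") or from the catchment
simulator ("simulated"), the threshold rule selects dissolved or
particle-bound wash-off, and the evaluation layer scores predictions
against observations per analyte and pooled (EMC and EML blocks).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catchment import CatchmentParams, Hyetograph, TssState, event_runoff, tss_buildup, tss_washoff
from .evaluate import GofReport, gof_report
from .ledger import (
    ApplicationRecord,
    AreaScaling,
    available_at_event,
    fit_degradation_rate,
)
from .washoff import (
    TransferFit,
    WashoffParams,
    fit_load_regression,
    fit_transfer_coefficients,
    predict_event,
)

logger = logging.getLogger(__name__)

UG_PER_G = 1.0e6


@dataclass
class RunConfig:
    """Everything a forward run needs besides the input tables."""

    analytes: tuple[str, ...]
    k_deg: dict[str, float]
    washoff: dict[str, WashoffParams]
    scaling: AreaScaling
    window_days: int = 90
    tss_source: str = "observed"  # or "simulated"
    catchment: CatchmentParams | None = None
    tss_params: dict | None = None  # buildup/washoff coefficients for "simulated"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tss_source not in ("observed", "simulated"):
            raise ValueError(f"unknown tss_source {self.tss_source!r}")
        if self.tss_source == "simulated" and (
            self.catchment is None or self.tss_params is None
        ):
            raise ValueError("simulated TSS source needs catchment and tss_params")
        for a in self.analytes:
            if a not in self.k_deg or a not in self.washoff:
                raise ValueError(f"missing k_deg or washoff params for {a!r}")

    @classmethod
    def from_truth(cls, truth) -> "RunConfig":
        """Closed-loop configuration carrying a synthetic campaign's own
        generating parameters."""
        return cls(
            analytes=tuple(truth.analytes),
            k_deg=dict(truth.k_deg),
            washoff=dict(truth.washoff),
            scaling=truth.scaling,
            window_days=truth.window_days,
            tss_source="observed",
            catchment=truth.catchment,
            tss_params={
                "buildup_max": truth.tss_buildup_max,
                "buildup_rate": truth.tss_buildup_rate,
                "washoff_coeff": truth.tss_washoff_coeff,
                "washoff_exponent": truth.tss_washoff_exponent,
            },
            seed=truth.seed,
        )


@dataclass
class RunResult:
    """Per-event predictions plus the goodness-of-fit blocks."""

    predictions: pd.DataFrame
    gof_eml: dict[str, GofReport]  # per analyte + "pooled", loads in g
    gof_emc: dict[str, GofReport]  # per analyte + "pooled", EMC in ng/L


def _simulated_tss(table: pd.DataFrame, config: RunConfig) -> pd.Series:
    """Re-simulate each event's sediment load from rainfall descriptors,
    carrying the build-up residual across events in date order."""
    state = TssState(**config.tss_params)
    loads = {}
    for event_id, row in table.sort_values("date").iterrows():
        hyeto = Hyetograph.constant(float(row.rain_mm), float(row.duration_h))
        volume, eff_depth = event_runoff(hyeto, config.catchment)
        tss_buildup(state, float(row.adp_day))
        washed, _ = tss_washoff(state, eff_depth, volume)
        loads[event_id] = washed
    return pd.Series(loads).reindex(table.index)


def run_forward(
    table: pd.DataFrame,
    use_records: list[ApplicationRecord],
    config: RunConfig,
) -> RunResult:
    """Run the threshold-switched wash-off model over a campaign table.

    Observed pesticide loads of earlier storms feed the ledger (the model's
    own prediction substitutes where an observation is masked). Returns
    per-event, per-analyte predictions and skill scores computed against
    the observed EML (g) and EMC (ng/L) columns, per analyte and pooled.
    """
    table = table.sort_values("date")
    if config.tss_source == "simulated":
        tss_loads = _simulated_tss(table, config)
    else:
        tss_loads = table["eml_tss_mg"]

    records_by_analyte = {
        a: [r for r in use_records if r.active_ingredient == a]
        for a in config.analytes
    }
    history: dict[str, list[tuple[dt.date, float]]] = {a: [] for a in config.analytes}
    rows = []
    for event_id, row in table.iterrows():
        mw_tss = float(tss_loads.loc[event_id])
        volume = float(row.runoff_m3)
        c_tss_kg_l = (
            mw_tss / (volume * 1000.0) / 1.0e6 if volume > 0 else 0.0
        )  # mg -> kg/L
        for analyte in config.analytes:
            params = config.washoff[analyte]
            window_start = row.date - dt.timedelta(days=config.window_days)
            prior = [(d, w) for d, w in history[analyte] if d >= window_start]
            m_avail = available_at_event(
                records_by_analyte[analyte],
                prior,
                config.k_deg[analyte],
                row.date,
                config.window_days,
                config.scaling,
            )
            pred = predict_event(
                str(event_id), m_avail, mw_tss, volume * 1000.0, params
            )
            load = pred.m_w_pest
            obs_ug = row.get(f"eml_{analyte}_ug", np.nan)
            fed_back = obs_ug / UG_PER_G if np.isfinite(obs_ug) else load
            history[analyte].append((row.date, float(fed_back)))
            rows.append(
                {
                    "event_id": event_id,
                    "date": row.date,
                    "analyte": analyte,
                    "regime": pred.regime,
                    "m_avail_g": m_avail,
                    "mw_tss_mg": mw_tss,
                    "mw_pest_g": load,
                    "emc_pest_ng_l": load * UG_PER_G / volume if volume > 0 else 0.0,
                    "f_diss": pred.f_diss,
                    "obs_eml_g": obs_ug / UG_PER_G if np.isfinite(obs_ug) else np.nan,
                    "obs_emc_ng_l": row.get(f"emc_{analyte}_ng_l", np.nan),
                }
            )
    predictions = pd.DataFrame(rows)

    gof_eml: dict[str, GofReport] = {}
    gof_emc: dict[str, GofReport] = {}
    pooled_obs_eml, pooled_sim_eml = [], []
    pooled_obs_emc, pooled_sim_emc = [], []
    for analyte in config.analytes:
        sub = predictions[
            (predictions.analyte == analyte) & predictions.obs_eml_g.notna()
        ]
        if len(sub) >= 2:
            gof_eml[analyte] = gof_report(sub.obs_eml_g, sub.mw_pest_g)
            gof_emc[analyte] = gof_report(sub.obs_emc_ng_l, sub.emc_pest_ng_l)
            pooled_obs_eml.append(sub.obs_eml_g.to_numpy())
            pooled_sim_eml.append(sub.mw_pest_g.to_numpy())
            pooled_obs_emc.append(sub.obs_emc_ng_l.to_numpy())
            pooled_sim_emc.append(sub.emc_pest_ng_l.to_numpy())
        else:
            logger.warning("analyte %s: fewer than 2 observed events, no GOF", analyte)
    if pooled_obs_eml:
        gof_eml["pooled"] = gof_report(
            np.concatenate(pooled_obs_eml), np.concatenate(pooled_sim_eml)
        )
        gof_emc["pooled"] = gof_report(
            np.concatenate(pooled_obs_emc), np.concatenate(pooled_sim_emc)
        )
    return RunResult(predictions=predictions, gof_eml=gof_eml, gof_emc=gof_emc)


@dataclass
class AnalyteFits:
    """Both §-style predictor variants for one analyte."""

    fraction_on_tss: TransferFit  # washed fraction vs sediment load
    load_on_tss: TransferFit  # pesticide load vs sediment load


def fit_washoff(
    table: pd.DataFrame,
    use_records: list[ApplicationRecord],
    config: RunConfig,
    particle_only: bool = True,
) -> dict[str, AnalyteFits]:
    """Fit the two transfer-function variants per analyte.

    The washed fraction uses ledger availability recomputed from the use
    records and observed wash-off history. With ``particle_only`` (default)
    the fits are restricted to storms above the sediment threshold, where
    the particle-bound relation applies.
    """
    table = table.sort_values("date")
    fits: dict[str, AnalyteFits] = {}
    for analyte in config.analytes:
        params = config.washoff[analyte]
        records = [r for r in use_records if r.active_ingredient == analyte]
        history: list[tuple[dt.date, float]] = []
        frac_pairs, load_pairs = [], []
        for _, row in table.iterrows():
            obs_ug = row.get(f"eml_{analyte}_ug", np.nan)
            if not np.isfinite(obs_ug):
                continue
            load = obs_ug / UG_PER_G
            window_start = row.date - dt.timedelta(days=config.window_days)
            prior = [(d, w) for d, w in history if d >= window_start]
            m_avail = available_at_event(
                records, prior, config.k_deg[analyte], row.date,
                config.window_days, config.scaling,
            )
            history.append((row.date, min(load, m_avail)))
            mw_tss = float(row.eml_tss_mg)
            if particle_only and mw_tss <= params.tss_threshold:
                continue
            if m_avail > 0:
                frac_pairs.append((mw_tss, load / m_avail))
            load_pairs.append((mw_tss, load))
        if len(frac_pairs) < 3 or len(load_pairs) < 3:
            logger.warning("analyte %s: fewer than 3 usable events, skipped", analyte)
            continue
        fits[analyte] = AnalyteFits(
            fraction_on_tss=fit_transfer_coefficients(
                frac_pairs, space=params.regression_space
            ),
            load_on_tss=fit_load_regression(load_pairs, space="linear"),
        )
    return fits


def fit_k_deg(
    table: pd.DataFrame,
    use_records: list[ApplicationRecord],
    config: RunConfig,
    analyte: str,
    k0: float = 0.01,
) -> tuple[float, float]:
    """Estimate an analyte's surface degradation rate from its
    dissolved-regime storms (sediment load at or below the threshold),
    using every observed storm as ledger history. Returns (k, SE)."""
    table = table.sort_values("date")
    params = config.washoff[analyte]
    records = [r for r in use_records if r.active_ingredient == analyte]
    dissolved, history = [], []
    for _, row in table.iterrows():
        obs_ug = row.get(f"eml_{analyte}_ug", np.nan)
        if not np.isfinite(obs_ug):
            continue
        load = obs_ug / UG_PER_G
        history.append((row.date, load))
        if float(row.eml_tss_mg) <= params.tss_threshold and load > 0:
            dissolved.append((row.date, load))
    return fit_degradation_rate(
        records,
        dissolved,
        washoff_history=history,
        k0=k0,
        window_days=config.window_days,
        scaling=config.scaling,
    )


def config_digest(config: RunConfig) -> str:
    """Stable SHA-256 digest of the run configuration."""

    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        return obj

    blob = json.dumps(plain(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def write_manifest(config: RunConfig, out_dir: str | Path) -> Path:
    """Reproducibility manifest: config digest, seed and version."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    path.write_text(
        json.dumps(
            {
                "package": "pyrewash",
                "version": __version__,
                "seed": config.seed,
                "config_sha256": config_digest(config),
            },
            indent=2,
        )
    )
    return path
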