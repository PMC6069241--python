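"""Threshold-switched pyrethroid wash-off model.

Storm export of a pyrethroid is controlled by the sediment load the storm
mobilises. Below a sediment-load threshold (default 10 mg) dissolution
dominates and the entire available pesticide mass is assumed washed off
(conservative fallback in place of mechanistic dissolved-phase kinetics).
Above the threshold, transport is particle-bound and the washed fraction
M_w/M_avail is a linear transfer function of the sediment load (optionally
of its log10), fitted from monitoring data. Equilibrium two-phase
partitioning (Kd) gives the dissolved fraction of the exported mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm

DISSOLVED = "dissolved"
PARTICLE_BOUND = "particle_bound"
Regime = Literal["dissolved", "particle_bound"]

RegressionSpace = Literal["linear", "log10"]


@dataclass(frozen=True)
class WashoffParams:
    """Per-analyte wash-off parameters.

    tss_threshold: sediment load (mg) separating dissolved from
        particle-bound control; strictly above -> particle-bound.
    transfer_intercept/transfer_slope: coefficients of the washed-fraction
        transfer function fraction = a + b * g(M_w_TSS).
    regression_space: ``"linear"`` (g = identity, M_w_TSS in mg) or
        ``"log10"`` (g = log10 of M_w_TSS in mg).
    kd: solid-water partitioning coefficient, L/kg.
    """

    transfer_intercept: float
    transfer_slope: float
    tss_threshold: float = 10.0
    regression_space: RegressionSpace = "log10"
    kd: float = 0.0
    analyte: str = ""

    def __post_init__(self) -> None:
        if self.tss_threshold <= 0:
            raise ValueError("tss_threshold must be > 0")
        if self.kd < 0:
            raise ValueError("kd must be >= 0")
        if self.regression_space not in ("linear", "log10"):
            raise ValueError(f"unknown regression_space {self.regression_space!r}")


@dataclass(frozen=True)
class EventPrediction:
    """Predicted pesticide export for one storm and analyte."""

    event_id: str
    analyte: str
    regime: Regime
    m_avail: float  # g
    m_w_tss: float  # mg
    m_w_pest: float  # g
    emc_pest: float  # g/L (0 when runoff volume unknown)
    f_diss: float


@dataclass(frozen=True)
class TransferFit:
    """OLS fit of the washed-fraction (or load) transfer function."""

    intercept: float
    slope: float
    r_squared: float
    stderr_intercept: float
    stderr_slope: float
    n: int
    space: RegressionSpace


def _g(m_w_tss: np.ndarray | float, space: RegressionSpace):
    if space == "log10":
        return np.log10(m_w_tss)
    return m_w_tss


def select_regime(m_w_tss: float, params: WashoffParams) -> Regime:
    """Particle-bound iff the sediment load is strictly greater than the
    threshold; a load exactly at the threshold is dissolved-controlled."""
    if m_w_tss < 0:
        raise ValueError("m_w_tss must be >= 0")
    return PARTICLE_BOUND if m_w_tss > params.tss_threshold else DISSOLVED


def dissolved_washoff(m_avail: float) -> float:
    """Dissolved-regime export: the whole available mass is washed off.

    Mechanistic first-order rainfall-extraction kinetics are deliberately
    out of scope; this identity is the conservative upper bound for
    low-sediment storms.
    """
    if m_avail < 0:
        raise ValueError("m_avail must be >= 0")
    return m_avail


def particle_bound_washoff(
    m_avail: float, m_w_tss: float, params: WashoffParams
) -> float:
    """Particle-bound export: fraction = a + b * g(M_w_TSS), clipped to
    [0, 1], applied to the available mass."""
    if m_avail < 0:
        raise ValueError("m_avail must be >= 0")
    fraction = params.transfer_intercept + params.transfer_slope * float(
        _g(m_w_tss, params.regression_space)
    )
    fraction = min(1.0, max(0.0, fraction))
    return fraction * m_avail


def predict_washoff(
    m_avail: float, m_w_tss: float, params: WashoffParams
) -> tuple[Regime, float]:
    """Regime selection plus the matching wash-off rule; never returns more
    than the available mass."""
    regime = select_regime(m_w_tss, params)
    if regime == DISSOLVED:
        return regime, dissolved_washoff(m_avail)
    return regime, particle_bound_washoff(m_avail, m_w_tss, params)


def predict_event(
    event_id: str,
    m_avail: float,
    m_w_tss: float,
    runoff_volume_l: float,
    params: WashoffParams,
) -> EventPrediction:
    """Full per-event prediction: regime, washed mass, EMC and the
    equilibrium dissolved fraction (TSS concentration from the washed
    sediment load and runoff volume in litres)."""
    regime, m_w_pest = predict_washoff(m_avail, m_w_tss, params)
    c_tss = m_w_tss / runoff_volume_l / 1.0e6 if runoff_volume_l > 0 else 0.0  # kg/L
    return EventPrediction(
        event_id=event_id,
        analyte=params.analyte,
        regime=regime,
        m_avail=m_avail,
        m_w_tss=m_w_tss,
        m_w_pest=m_w_pest,
        emc_pest=m_w_pest / runoff_volume_l if runoff_volume_l > 0 else 0.0,
        f_diss=dissolved_fraction(params.kd, c_tss),
    )


def regime_discontinuity(m_avail: float, params: WashoffParams) -> float:
    """Jump in predicted load across the threshold (dissolved side minus the
    particle-bound limit from above), in the same mass units as m_avail."""
    below = dissolved_washoff(m_avail)
    above = particle_bound_washoff(m_avail, params.tss_threshold, params)
    return below - above


def dissolved_fraction(kd: float, c_tss: float) -> float:
    """Equilibrium dissolved fraction f_diss = 1 / (1 + Kd * C_TSS), with
    TSS (kg/L) as the sole sorbent phase and Kd in L/kg."""
    if kd < 0 or c_tss < 0:
        raise ValueError("kd and c_tss must be >= 0")
    return 1.0 / (1.0 + kd * c_tss)


def fit_transfer_coefficients(
    pairs: Sequence[tuple[float, float]],
    space: RegressionSpace = "log10",
) -> TransferFit:
    """OLS fit of washed fraction on g(sediment load).

    ``pairs`` are (M_w_TSS in mg, M_w_pest / M_avail) observations, usually
    restricted to particle-bound storms. Returns coefficients with their
    standard errors and the coefficient of determination.
    """
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 pairs to fit, got {len(pairs)}")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if space == "log10" and np.any(x <= 0):
        raise ValueError("sediment loads must be > 0 for log10 space")
    gx = np.asarray(_g(x, space), dtype=float)
    if np.ptp(gx) == 0:
        raise ValueError("degenerate predictor: zero variance in g(M_w_TSS)")
    model = sm.OLS(y, sm.add_constant(gx)).fit()
    return TransferFit(
        intercept=float(model.params[0]),
        slope=float(model.params[1]),
        r_squared=float(model.rsquared),
        stderr_intercept=float(model.bse[0]),
        stderr_slope=float(model.bse[1]),
        n=len(pairs),
        space=space,
    )


def fit_load_regression(
    pairs: Sequence[tuple[float, float]],
    space: RegressionSpace = "linear",
) -> TransferFit:
    """Alternative predictor: pesticide load regressed directly on sediment
    load (load-on-load), same return contract as
    :func:`fit_transfer_coefficients`. The fitted line converts to an EMC
    relation on division by the event runoff volume."""
    return fit_transfer_coefficients(pairs, space=space)
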