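"""Event-lumped catchment hydrology and sediment surrogate.

A single-bucket representation of a small residential catchment: the
impervious fraction loses only depression storage, the pervious fraction
loses Horton infiltration, and total suspended solids (TSS) accumulate
during dry weather (saturating exponential build-up) and are mobilised
during storms (exponential-in-depth wash-off). One runoff volume and one
TSS load per storm — no within-event pollutograph and no sewer routing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class CatchmentParams:
    """Lumped catchment descriptors.

    area in m^2; depression_storage in mm (impervious fraction only);
    Horton parameters f0 >= fc in mm/h with decay constant k in 1/h.
    """

    area: float
    impervious_fraction: float
    depression_storage: float
    horton_f0: float
    horton_fc: float
    horton_k: float

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be > 0")
        if not 0.0 <= self.impervious_fraction <= 1.0:
            raise ValueError("impervious_fraction must be in [0, 1]")
        if min(self.depression_storage, self.horton_f0, self.horton_fc, self.horton_k) < 0:
            raise ValueError("depression storage and Horton parameters must be >= 0")
        if self.horton_fc > self.horton_f0:
            raise ValueError("horton_fc must not exceed horton_f0")


@dataclass(frozen=True)
class Hyetograph:
    """Uniformly sampled rainfall intensity series.

    timestamps: hours from an arbitrary origin, uniform spacing;
    intensities: mm/h over the interval starting at each timestamp.
    """

    timestamps: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        ints = np.asarray(self.intensities, dtype=float)
        if ts.ndim != 1 or ts.size != ints.size or ts.size == 0:
            raise ValueError("timestamps and intensities must be equal-length 1-D")
        if ts.size > 1:
            steps = np.diff(ts)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("timestamps must be uniformly increasing")
        if np.any(ints < 0):
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "intensities", ints)

    @property
    def step(self) -> float:
        """Sampling interval in hours (1.0 for a single-sample hyetograph)."""
        ts = self.timestamps
        return float(ts[1] - ts[0]) if ts.size > 1 else 1.0

    @property
    def depth(self) -> float:
        """Total rainfall depth in mm."""
        return float(np.sum(self.intensities) * self.step)

    @property
    def duration(self) -> float:
        """Event duration in hours."""
        return self.step * self.timestamps.size

    @classmethod
    def constant(cls, depth_mm: float, duration_h: float, step_h: float = 0.25) -> "Hyetograph":
        """Block hyetograph with uniform intensity depth/duration."""
        n = max(1, int(round(duration_h / step_h)))
        intensity = depth_mm / (n * step_h)
        return cls(np.arange(n) * step_h, np.full(n, intensity))


def horton_rate(params: CatchmentParams, t: float) -> float:
    """Horton infiltration capacity f(t) = fc + (f0 - fc) * exp(-k*t), mm/h,
    with t hours since the start of the event."""
    if t < 0:
        raise ValueError("elapsed time must be >= 0")
    return params.horton_fc + (params.horton_f0 - params.horton_fc) * math.exp(
        -params.horton_k * t
    )


def event_runoff(hyeto: Hyetograph, params: CatchmentParams) -> tuple[float, float]:
    """Event runoff volume (m^3) and effective runoff depth (mm).

    Impervious fraction: total depth minus depression storage (floored at 0).
    Pervious fraction: per-step rainfall excess over the Horton capacity,
    with the infiltration clock starting at the first timestamp. Each
    contribution is weighted by its areal fraction; the effective depth is
    their sum and the volume is depth * area.
    """
    depth = hyeto.depth
    imp = params.impervious_fraction
    imp_depth = max(0.0, depth - params.depression_storage) * imp

    t_rel = hyeto.timestamps - hyeto.timestamps[0]
    capacities = np.array([horton_rate(params, float(t)) for t in t_rel])
    excess = np.maximum(0.0, hyeto.intensities - capacities)
    perv_depth = float(np.sum(excess) * hyeto.step) * (1.0 - imp)

    effective_depth = imp_depth + perv_depth
    volume = effective_depth / 1000.0 * params.area  # mm * m^2 -> m^3
    return volume, effective_depth


@dataclass
class TssState:
    """Sediment build-up/wash-off state (masses in mg at catchment scale).

    buildup_max is the saturation mass, buildup_rate (1/day) the approach
    rate, washoff_coeff (1/mm^washoff_exponent) and washoff_exponent shape
    the depth-driven wash-off. ``residual`` carries post-storm leftovers
    into the next dry period.
    """

    buildup_max: float
    buildup_rate: float
    washoff_coeff: float
    washoff_exponent: float = 1.0
    available: float = 0.0
    washed: float = 0.0
    residual: float = 0.0

    def __post_init__(self) -> None:
        if min(
            self.buildup_max,
            self.buildup_rate,
            self.washoff_coeff,
            self.washoff_exponent,
            self.available,
            self.washed,
            self.residual,
        ) < 0:
            raise ValueError("TSS state fields must be >= 0")


def tss_buildup(state: TssState, dry_days: float) -> float:
    """Sediment mass available at the start of a storm after ``dry_days``
    of dry weather: residual + (max - residual) * (1 - exp(-rate * ADP))."""
    if dry_days < 0:
        raise ValueError("dry_days must be >= 0")
    gain = (state.buildup_max - state.residual) * (
        1.0 - math.exp(-state.buildup_rate * dry_days)
    )
    state.available = state.residual + max(0.0, gain)
    return state.available


def tss_washoff(
    state: TssState, effective_depth: float, runoff_volume: float
) -> tuple[float, float]:
    """Storm TSS wash-off: load (mg) and event mean concentration (mg/L).

    washed = available * (1 - exp(-coeff * depth^exponent)), capped at the
    available mass; the residual is rolled forward. A storm with zero runoff
    volume can only wash nothing.
    """
    if effective_depth < 0:
        raise ValueError("effective_depth must be >= 0")
    if effective_depth == 0:
        frac = 0.0
    else:
        frac = 1.0 - math.exp(
            -state.washoff_coeff * effective_depth**state.washoff_exponent
        )
    washed = min(state.available, state.available * frac)
    if runoff_volume <= 0:
        if washed > 0:
            raise ValueError("positive TSS wash-off with zero runoff volume")
        state.washed = 0.0
        return 0.0, 0.0
    state.washed = washed
    state.residual = state.available - washed
    emc = washed / (runoff_volume * 1000.0)  # mg / L
    return washed, emc
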