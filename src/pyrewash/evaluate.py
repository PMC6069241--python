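"""Measurement and model-assessment layer.

Event mean concentrations and loads from discrete flow-weighted samples,
root-mean-square error and the Nash–Sutcliffe / Kling–Gupta efficiencies
for observed-vs-simulated series, principal component analysis of the
event × variable monitoring matrix with complete-case handling, and plain
ordinary-least-squares regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA


@dataclass(frozen=True)
class SampleSeries:
    """Discrete within-event samples: concentration C_i and the runoff
    volume V_i discharged during each sampling increment."""

    concentrations: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        if c.ndim != 1 or c.size != v.size or c.size == 0:
            raise ValueError("concentrations and volumes must be equal-length 1-D")
        if np.any(v < 0):
            raise ValueError("volumes must be >= 0")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "volumes", v)


def emc(samples: SampleSeries) -> float:
    """Flow-weighted event mean concentration: sum(C_i V_i) / sum(V_i)."""
    total = float(np.sum(samples.volumes))
    if total <= 0:
        raise ValueError("total sampled volume must be > 0")
    return float(np.sum(samples.concentrations * samples.volumes) / total)


def eml(emc_value: float, volume: float) -> float:
    """Event mean load: EMC times total runoff volume."""
    if volume < 0:
        raise ValueError("volume must be >= 0")
    return emc_value * volume


def _as_pairs(obs, sim) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(obs, dtype=float)
    s = np.asarray(sim, dtype=float)
    if o.shape != s.shape or o.ndim != 1:
        raise ValueError("observed and simulated series must be equal-length 1-D")
    return o, s


def rmse(obs, sim) -> float:
    """Root mean square error, same units as the series."""
    o, s = _as_pairs(obs, sim)
    if o.size < 1:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean((o - s) ** 2)))


def nse(obs, sim) -> float:
    """Nash–Sutcliffe efficiency: 1 minus the error variance normalised by
    the observed variance about its mean. 1 is perfect; 0 matches the
    observed-mean benchmark."""
    o, s = _as_pairs(obs, sim)
    if o.size < 2:
        raise ValueError("need at least two pairs")
    denom = float(np.sum((o - o.mean()) ** 2))
    if denom == 0:
        raise ValueError("NSE undefined for constant observations")
    return 1.0 - float(np.sum((o - s) ** 2)) / denom


@dataclass(frozen=True)
class GofReport:
    """Goodness-of-fit summary for one observed/simulated series pair.

    alpha = sigma_sim/sigma_obs (relative variability), beta =
    mu_sim/mu_obs (bias), r the Pearson correlation;
    KGE = 1 - sqrt((r-1)^2 + (alpha-1)^2 + (beta-1)^2).
    """

    rmse: float
    nse: float
    kge: float
    r: float
    alpha: float
    beta: float
    mu_obs: float
    mu_sim: float
    sigma_obs: float
    sigma_sim: float
    n: int


def kge(obs, sim) -> tuple[float, float, float, float]:
    """Kling–Gupta efficiency and its (r, alpha, beta) components.

    Uses Pearson correlation and sample (N-1) standard deviations; requires
    non-constant observations with nonzero mean.
    """
    o, s = _as_pairs(obs, sim)
    if o.size < 2:
        raise ValueError("need at least two pairs")
    mu_o, mu_s = float(o.mean()), float(s.mean())
    sd_o, sd_s = float(o.std(ddof=1)), float(s.std(ddof=1))
    if sd_o == 0:
        raise ValueError("KGE undefined for constant observations")
    if mu_o == 0:
        raise ValueError("KGE undefined for zero observed mean")
    if sd_s == 0:
        r = 0.0  # constant simulation carries no correlation information
    else:
        r = float(np.corrcoef(o, s)[0, 1])
    alpha = sd_s / sd_o
    beta = mu_s / mu_o
    value = 1.0 - float(np.sqrt((r - 1) ** 2 + (alpha - 1) ** 2 + (beta - 1) ** 2))
    return value, r, alpha, beta


def gof_report(obs, sim) -> GofReport:
    """All three skill scores plus the KGE decomposition in one report."""
    o, s = _as_pairs(obs, sim)
    kge_value, r, alpha, beta = kge(o, s)
    return GofReport(
        rmse=rmse(o, s),
        nse=nse(o, s),
        kge=kge_value,
        r=r,
        alpha=alpha,
        beta=beta,
        mu_obs=float(o.mean()),
        mu_sim=float(s.mean()),
        sigma_obs=float(o.std(ddof=1)),
        sigma_sim=float(s.std(ddof=1)),
        n=o.size,
    )


@dataclass(frozen=True)
class EventMatrix:
    """Event × variable matrix with complete-case bookkeeping."""

    full: pd.DataFrame
    complete: pd.DataFrame
    complete_case_ids: list
    incomplete_case_ids: list


def event_matrix(
    events: pd.DataFrame,
    analytes: tuple[str, ...] | list[str],
    site_column: str = "site",
) -> EventMatrix:
    """Assemble the monitoring matrix for multivariate analysis.

    One row per storm; the variables are the site indicator (binary), the
    antecedent dry period, total rainfall, runoff volume, each analyte's
    available mass, and the event mean loads of TSS and each analyte. Rows
    with any missing value are flagged and excluded from the complete-case
    subset (no imputation).
    """
    cols = [site_column, "adp_day", "rain_mm", "runoff_m3"]
    cols += [f"m_avail_{a}_g" for a in analytes]
    cols += ["eml_tss_mg"] + [f"eml_{a}_ug" for a in analytes]
    missing_cols = [c for c in cols if c not in events.columns]
    if missing_cols:
        raise KeyError(f"events table lacks columns: {missing_cols}")
    mat = events[cols].copy()
    site = mat[site_column]
    if not pd.api.types.is_numeric_dtype(site):
        labels = sorted(site.dropna().unique())
        if len(labels) > 2:
            raise ValueError(f"site indicator supports at most 2 labels, got {labels}")
        mat[site_column] = site.map({lab: i for i, lab in enumerate(labels)})
    complete_mask = mat.notna().all(axis=1)
    return EventMatrix(
        full=mat,
        complete=mat.loc[complete_mask],
        complete_case_ids=list(mat.index[complete_mask]),
        incomplete_case_ids=list(mat.index[~complete_mask]),
    )


@dataclass(frozen=True)
class PcaResult:
    """Principal component decomposition of the (standardized) matrix."""

    scores: np.ndarray  # events x components
    loadings: np.ndarray  # variables x components, orthonormal columns
    variance_fraction: np.ndarray  # per component, sums to 1
    retained_count: int
    column_names: list[str]


def pca(
    matrix: pd.DataFrame | np.ndarray,
    standardize: bool = True,
    retain_variance: float = 0.70,
) -> PcaResult:
    """PCA of a complete-case event matrix.

    With ``standardize`` (default) each column is centred and scaled to
    unit sample variance, so the decomposition is of the correlation
    matrix — appropriate when the variables mix units (days, mm, m^3,
    masses). ``retained_count`` is the smallest number of leading
    components whose cumulative variance fraction reaches
    ``retain_variance``.
    """
    if isinstance(matrix, pd.DataFrame):
        names = [str(c) for c in matrix.columns]
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        names = [f"var{i}" for i in range(X.shape[1])]
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; pass the complete-case subset")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("cannot standardize a zero-variance column")
        Xc = Xc / sd
    model = _SkPCA(n_components=min(Xc.shape))
    scores = model.fit_transform(Xc)
    fractions = model.explained_variance_ratio_
    cumulative = np.cumsum(fractions)
    retained = int(np.searchsorted(cumulative, retain_variance - 1e-12) + 1)
    retained = min(retained, fractions.size)
    return PcaResult(
        scores=scores,
        loadings=model.components_.T,
        variance_fraction=fractions,
        retained_count=retained,
        column_names=names,
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


def regress(x, y) -> RegressionResult:
    """Ordinary least squares y = intercept + slope * x with R^2."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(xa) == 0:
        raise ValueError("degenerate predictor: zero variance in x")
    if np.ptp(ya) == 0:
        # constant response: flat line explains none of (the zero) variance
        return RegressionResult(slope=0.0, intercept=float(ya[0]), r_squared=0.0)
    fit = stats.linregress(xa, ya)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )
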