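"""From raw culture measurements to model constraints.

Growth curves (viable-cell counts over time) are fitted with a Gompertz
law; extracellular concentration time courses are reduced to signed
consumption-and-release (CORE) values and to biomass-specific exchange
rates (mmol/gDW/h) that feed directly into model contextualization.

Gompertz parameterization (3 parameters + optional lag):

    N(t) = K * exp( ln(N0/K) * exp(-b * (t - lag)) )

with N0 the inoculum, K the carrying capacity and b (1/h) the Gompertz
rate constant; the curve is sigmoidal on a log scale with maximum
specific growth rate b * ln(K/N0) at t = lag.  ``mu_max`` in the fit
result is the rate constant b.

Specific exchange rate: for a metabolite whose extracellular
concentration changes by dC (mM) over [t0, t1] in a culture of volume V
(L) with biomass X(t) (gDW, from the Gompertz fit and a per-cell dry
weight), the constant specific rate consistent with the data is

    q = dC * V / integral_{t0}^{t1} X(t) dt     [mmol/gDW/h]

negative q = net consumption, matching the exchange-flux sign
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import curve_fit

__all__ = [
    "GrowthCurve",
    "GompertzFit",
    "ConcentrationSeries",
    "fit_gompertz",
    "gompertz",
    "core_value",
    "specific_exchange_rate",
    "DEFAULT_DRY_WEIGHT_PER_CELL",
]

#: Per-cell dry weight used to convert cell counts to gDW; representative
#: for adherent mammalian tumor lines (~400 pg dry mass per cell).
DEFAULT_DRY_WEIGHT_PER_CELL = 4.0e-10  # gDW/cell


@dataclass
class GrowthCurve:
    """Viable-cell counts over time for one replicate well."""

    times: np.ndarray  # h
    counts: np.ndarray  # cells
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape:
            raise ValueError("times and counts must have equal length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class GompertzFit:
    n0: float  # cells
    carrying_capacity: float  # cells
    mu_max: float  # Gompertz rate constant b, 1/h
    lag: float  # h
    rss: float

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return gompertz(np.asarray(t, dtype=float), self.n0,
                        self.carrying_capacity, self.mu_max, self.lag)


def gompertz(t, n0, k, b, lag=0.0):
    """N(t) = K exp(ln(N0/K) exp(-b (t - lag)))."""
    return k * np.exp(np.log(n0 / k) * np.exp(-b * (np.asarray(t, dtype=float) - lag)))


def fit_gompertz(curve: GrowthCurve, fit_lag: bool = False) -> GompertzFit:
    """Least-squares Gompertz fit with a deterministic initialization.

    Initialization: N0 = first count, K = 1.5 * max count, b from the
    log-log slope between the first and last points, lag = 0.  Raises on
    non-convergence, carrying the residual in the message.
    """
    if len(curve.times) < 4:
        raise ValueError("need at least 4 time points to fit a Gompertz curve")
    t, n = curve.times, curve.counts
    if np.any(n <= 0):
        raise ValueError("Gompertz fit requires strictly positive counts")
    n0_init = float(n[0])
    k_init = float(1.5 * n.max())
    span = t[-1] - t[0]
    b_init = max(np.log(max(n[-1] / n[0], 1.0 + 1e-6)) / span, 1e-4)

    if np.allclose(n, n[0], rtol=1e-12):
        # degenerate flat curve: no growth
        return GompertzFit(n0=n0_init, carrying_capacity=n0_init, mu_max=0.0,
                           lag=0.0, rss=0.0)

    if fit_lag:
        def f(tt, n0, k, b, lag):
            return gompertz(tt, n0, k, b, lag)
        p0 = [n0_init, k_init, b_init, 0.0]
        lower = [1e-6, 1e-6, 0.0, -span]
        upper = [np.inf, np.inf, 10.0, span]
    else:
        def f(tt, n0, k, b):
            return gompertz(tt, n0, k, b)
        p0 = [n0_init, k_init, b_init]
        lower = [1e-6, 1e-6, 0.0]
        upper = [np.inf, np.inf, 10.0]
    try:
        popt, _ = curve_fit(f, t, n, p0=p0, bounds=(lower, upper), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"Gompertz fit did not converge (init {p0}): {exc}") from exc
    resid = n - f(t, *popt)
    rss = float(resid @ resid)
    lag = float(popt[3]) if fit_lag else 0.0
    n0_fit, k_fit = float(popt[0]), float(popt[1])
    if k_fit < n0_fit:  # enforce the carrying-capacity invariant
        n0_fit, k_fit = min(n0_fit, k_fit), max(n0_fit, k_fit)
    return GompertzFit(n0=n0_fit, carrying_capacity=k_fit, mu_max=float(popt[2]),
                       lag=lag, rss=rss)


@dataclass
class ConcentrationSeries:
    """Concentration time course of one metabolite (mM)."""

    metabolite: str
    times: np.ndarray  # h
    concentrations: np.ndarray  # mM
    compartment: str = "extracellular"
    cell_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must have equal length")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if self.cell_counts is not None:
            self.cell_counts = np.asarray(self.cell_counts, dtype=float)
            if self.cell_counts.shape != self.times.shape:
                raise ValueError("cell_counts must parallel times")


def core_value(series: ConcentrationSeries, t0: float = 0.0, t1: float = 96.0,
               interpolate: bool = False) -> float:
    """Consumption-and-release value: C(t1) - C(t0), mM.

    Negative = net consumption over the window, positive = net release.
    Endpoints must be measured time points unless ``interpolate`` allows
    linear interpolation.
    """
    def at(t: float) -> float:
        hits = np.where(np.isclose(series.times, t))[0]
        if hits.size:
            return float(series.concentrations[hits[0]])
        if not interpolate:
            raise ValueError(
                f"time {t} h not measured for {series.metabolite!r} "
                "(pass interpolate=True to allow linear interpolation)")
        if not series.times.min() <= t <= series.times.max():
            raise ValueError(f"time {t} h outside measured range")
        return float(np.interp(t, series.times, series.concentrations))

    return at(t1) - at(t0)


def specific_exchange_rate(
    series: ConcentrationSeries,
    fit: GompertzFit,
    culture_volume: float,
    dry_weight_per_cell: float = DEFAULT_DRY_WEIGHT_PER_CELL,
    t0: float | None = None,
    t1: float | None = None,
) -> float:
    """Biomass-specific exchange rate q = dC * V / int X(t) dt.

    culture_volume in liters, dry_weight_per_cell in gDW/cell.  The
    biomass trajectory X(t) = N(t) * dry_weight_per_cell comes from the
    Gompertz fit; the integral is evaluated by adaptive quadrature.
    Returns mmol/gDW/h, negative for consumption.
    """
    if culture_volume <= 0 or dry_weight_per_cell <= 0:
        raise ValueError("culture volume and per-cell dry weight must be positive")
    t0 = float(series.times[0]) if t0 is None else t0
    t1 = float(series.times[-1]) if t1 is None else t1
    d_conc = core_value(series, t0, t1, interpolate=True)  # mM = mmol/L
    integral_cells, _ = quad(lambda t: fit.predict(t), t0, t1, limit=200)
    biomass_hours = integral_cells * dry_weight_per_cell  # gDW * h
    if biomass_hours <= 0:
        raise ValueError("biomass integral is zero; cannot normalize the rate")
    return d_conc * culture_volume / biomass_hours
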