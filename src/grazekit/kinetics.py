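"""Growth, grazing, efficiency and survival estimates from batch-culture counts.

A bacterivorous flagellate grown in a closed bottle with a bacterial prey
follows a characteristic trajectory: the predator grows exponentially at a
specific rate ``mu`` while the prey decays exponentially at a grazing-driven
rate ``g``; once the prey is exhausted the predator enters a stationary phase
and declines slowly at a rate ``d``.  All estimators here work on the log-linear
parts of count time series:

* growth rate  ``mu``  — OLS slope of ln(predator) vs time over the exponential window
* grazing loss ``g``   — minus the OLS slope of ln(prey) over the same window
* ingestion    ``I = g * Bbar / Fbar``  (bacteria flagellate^-1 h^-1)
* clearance    ``C = I / Bbar = g / Fbar``  (mL flagellate^-1 h^-1)
* gross growth efficiency  ``GE = mu * C_F / (I * C_B)`` with per-cell carbon
  contents ``C_F`` (predator) and ``C_B`` (prey)
* stationary half-life  ``t_1/2 = ln 2 / d``

``Bbar`` and ``Fbar`` are mean abundances over the window, either the geometric
mean of the endpoints or the time-averaged mean of an exponential trajectory
(the Frost/Heinbokel convention), selected per population.

Units are hours and cells mL^-1 throughout; rates are natural-log based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountSeries",
    "GrowthFit",
    "GrazingEstimate",
    "CarbonModel",
    "EfficiencyResult",
    "fit_log_linear",
    "select_exponential_window",
    "doubling_time",
    "mean_abundance",
    "grazing_estimate",
    "cell_carbon_from_esd",
    "growth_efficiency",
    "decay_half_life",
    "read_count_series",
    "write_count_series",
]


@dataclass(frozen=True)
class CountSeries:
    """Timestamped cell abundances for one organism in one bottle.

    ``times`` are hours, strictly increasing; ``abundances`` are cells mL^-1
    and must be strictly positive (zeros are rejected up front because every
    estimator works on ln(abundance)).
    """

    times: np.ndarray
    abundances: np.ndarray
    organism: str = ""
    bottle: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.abundances, dtype=float)
        if t.ndim != 1 or a.ndim != 1 or len(t) != len(a):
            raise ValueError("times and abundances must be 1-D and the same length")
        if len(t) == 0:
            raise ValueError("empty count series")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        bad = np.flatnonzero(a <= 0)
        if bad.size:
            raise ValueError(
                f"nonpositive abundance at t={t[bad[0]]} h "
                f"(index {bad[0]}); counts must be > 0 before log transform"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "abundances", a)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class GrowthFit:
    """OLS fit of ln(abundance) on time: rate is mu (>0) or -d (<0)."""

    rate: float
    intercept: float
    r_squared: float
    window: tuple[int, int]
    n_points: int


@dataclass(frozen=True)
class GrazingEstimate:
    prey_decay_rate: float
    prey_mean: float
    predator_mean: float
    ingestion_rate: float
    clearance_rate: float
    mean_method_prey: str
    mean_method_predator: str


@dataclass(frozen=True)
class CarbonModel:
    """Volume-to-carbon allometry: carbon [pg] = a * V^b with V in um^3.

    Defaults are conventional protist coefficients; both are configurable
    since carbon conversions vary between taxa and fixation protocols.
    """

    coefficient_a: float = 0.216
    exponent_b: float = 0.939

    def __post_init__(self) -> None:
        if self.coefficient_a <= 0 or self.exponent_b <= 0:
            raise ValueError("carbon model coefficients must be positive")


@dataclass(frozen=True)
class EfficiencyResult:
    growth_efficiency: float
    predator_carbon: float
    prey_carbon: float


def _resolve_window(series: CountSeries, window: tuple[int, int] | None) -> tuple[int, int]:
    if window is None:
        return (0, len(series))
    start, stop = window
    if not (0 <= start < stop <= len(series)):
        raise ValueError(f"window {window} out of range for series of length {len(series)}")
    return (start, stop)


def fit_log_linear(series: CountSeries, window: tuple[int, int] | None = None) -> GrowthFit:
    """Ordinary least squares of ln(abundance) on time over ``window``.

    ``window`` is a half-open index range ``(start, stop)``; ``None`` uses the
    whole series.  A constant series has zero slope and its R^2 (0/0) is
    reported as 0 by convention.
    """
    start, stop = _resolve_window(series, window)
    n = stop - start
    if n < 3:
        raise ValueError(f"log-linear fit needs >= 3 points, window has {n}")
    t = series.times[start:stop]
    y = np.log(series.abundances[start:stop])
    tbar, ybar = t.mean(), y.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    sxy = float(np.sum((t - tbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    ss_tot = float(np.sum((y - ybar) ** 2))
    ss_res = float(np.sum((y - (intercept + slope * t)) ** 2))
    r2 = 0.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    return GrowthFit(rate=slope, intercept=intercept, r_squared=r2,
                     window=(start, stop), n_points=n)


def select_exponential_window(
    series: CountSeries,
    min_points: int = 4,
    r2_threshold: float = 0.99,
) -> tuple[int, int]:
    """Longest contiguous window whose log-linear fit reaches ``r2_threshold``.

    Ties are broken toward steeper absolute slope, then toward the earlier
    start, so the selection is deterministic.  Raises if no window qualifies.
    """
    n = len(series)
    if n < min_points:
        raise ValueError(f"series has {n} points, fewer than min_points={min_points}")
    best: tuple[int, float, int, tuple[int, int]] | None = None
    for start in range(0, n - min_points + 1):
        for stop in range(start + min_points, n + 1):
            fit = fit_log_linear(series, (start, stop))
            if fit.r_squared < r2_threshold:
                continue
            key = (stop - start, abs(fit.rate), -start)
            if best is None or key > best[:3]:
                best = (stop - start, abs(fit.rate), -start, (start, stop))
    if best is None:
        raise ValueError(
            f"no window of >= {min_points} points reaches R^2 >= {r2_threshold}; "
            "consider relaxing r2_threshold"
        )
    return best[3]


def doubling_time(rate: float) -> float:
    """ln(2)/rate, in hours, for a positive specific growth rate."""
    if rate <= 0:
        raise ValueError("doubling time requires a positive growth rate")
    return math.log(2.0) / rate


def mean_abundance(x_start: float, x_end: float, method: str = "geometric") -> float:
    """Mean abundance between two endpoints of an exponential trajectory.

    ``geometric``  -> sqrt(x_start * x_end)
    ``integral``   -> (x_end - x_start) / ln(x_end / x_start), the time average
                      of an exponential between the endpoints (the logarithmic
                      mean used by the Frost/Heinbokel grazing formulas)

    Equal endpoints return that value under both methods.
    """
    if x_start <= 0 or x_end <= 0:
        raise ValueError("abundances must be positive")
    if method == "geometric":
        return math.sqrt(x_start * x_end)
    if method == "integral":
        if x_start == x_end:
            return x_start
        return (x_end - x_start) / math.log(x_end / x_start)
    raise ValueError(f"unknown mean method {method!r}; use 'geometric' or 'integral'")


def grazing_estimate(
    prey: CountSeries,
    predator: CountSeries,
    window: tuple[int, int] | None = None,
    predator_growth_rate: float | None = None,
    mean_method_prey: str = "geometric",
    mean_method_predator: str = "integral",
) -> GrazingEstimate:
    """Frost/Heinbokel grazing estimate from aligned predator/prey windows.

    The prey decay coefficient ``g`` is minus the log-linear slope of the prey
    counts over the window.  Mean abundances come from the window's endpoint
    observations; for a growing predator the ``integral`` mean uses Heinbokel's
    form (F_end - F_start)/(mu * dt) when ``predator_growth_rate`` is supplied
    (equivalently the logarithmic mean when mu matches the endpoints).
    Then I = g * Bbar / Fbar and C = g / Fbar.
    """
    pw = _resolve_window(prey, window)
    fw = _resolve_window(predator, window)
    prey_fit = fit_log_linear(prey, pw)
    if prey_fit.rate >= 0:
        raise ValueError("no net grazing signal: prey counts do not decline over window")
    g = -prey_fit.rate
    b1, b2 = prey.abundances[pw[0]], prey.abundances[pw[1] - 1]
    f1, f2 = predator.abundances[fw[0]], predator.abundances[fw[1] - 1]
    bbar = mean_abundance(b1, b2, mean_method_prey)
    if mean_method_predator == "integral" and predator_growth_rate is not None:
        if predator_growth_rate <= 0:
            raise ValueError("integral predator mean needs a positive growth rate")
        dt = predator.times[fw[1] - 1] - predator.times[fw[0]]
        fbar = (f2 - f1) / (predator_growth_rate * dt)
    else:
        fbar = mean_abundance(f1, f2, mean_method_predator)
    ingestion = g * bbar / fbar
    clearance = g / fbar
    return GrazingEstimate(
        prey_decay_rate=g,
        prey_mean=bbar,
        predator_mean=fbar,
        ingestion_rate=ingestion,
        clearance_rate=clearance,
        mean_method_prey=mean_method_prey,
        mean_method_predator=mean_method_predator,
    )


def cell_carbon_from_esd(esd: float, model: CarbonModel = CarbonModel()) -> float:
    """Per-cell carbon (pg) from the equivalent spherical diameter (um).

    V = (pi/6) * esd^3, then carbon = a * V^b.
    """
    if esd <= 0:
        raise ValueError("ESD must be positive")
    volume = (math.pi / 6.0) * esd**3
    return model.coefficient_a * volume**model.exponent_b


def growth_efficiency(
    mu: float,
    ingestion: float,
    predator_carbon: float,
    prey_carbon: float,
) -> float:
    """Gross growth efficiency GE = (mu * C_F) / (I * C_B), a carbon fraction."""
    if ingestion <= 0:
        raise ValueError("ingestion rate must be positive")
    if predator_carbon <= 0 or prey_carbon <= 0:
        raise ValueError("per-cell carbon must be positive")
    if mu < 0:
        raise ValueError("growth rate must be nonnegative")
    return (mu * predator_carbon) / (ingestion * prey_carbon)


def decay_half_life(series: CountSeries, window: tuple[int, int] | None = None) -> float:
    """Half-life (hours) of an exponentially declining population."""
    fit = fit_log_linear(series, window)
    if fit.rate >= 0:
        raise ValueError("population not declining: fitted slope is nonnegative")
    return math.log(2.0) / abs(fit.rate)


def read_count_series(path) -> dict[tuple[str, str], CountSeries]:
    """Read a counts TSV (time_h, organism, bottle, cells_per_ml) into
    one CountSeries per (organism, bottle)."""
    df = pd.read_csv(path, sep="\t")
    required = {"time_h", "organism", "bottle", "cells_per_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    out: dict[tuple[str, str], CountSeries] = {}
    for (org, bottle), grp in df.groupby(["organism", "bottle"], sort=True):
        grp = grp.sort_values("time_h")
        out[(str(org), str(bottle))] = CountSeries(
            times=grp["time_h"].to_numpy(float),
            abundances=grp["cells_per_ml"].to_numpy(float),
            organism=str(org),
            bottle=str(bottle),
        )
    return out


def write_count_series(series: Sequence[CountSeries], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "time_h": s.times,
                "organism": s.organism,
                "bottle": s.bottle,
                "cells_per_ml": s.abundances,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
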