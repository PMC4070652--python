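"""Specific growth and conversion rates from batch and chemostat cultures.

Rates follow the fermentation-table sign convention: consumption negative,
production positive, units mmol per gram dry cell weight per hour; the
specific growth rate mu is carried separately in h^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MOLAR_MASS",
    "BatchTimeCourse",
    "ChemostatState",
    "RateVector",
    "estimate_mu_loglinear",
    "batch_specific_rates",
    "chemostat_rates",
    "residence_time",
    "balance_error",
]

#: g/mol of the routinely assayed fermentation species.
MOLAR_MASS: dict[str, float] = {
    "glucose": 180.16,
    "fructose": 180.16,
    "ethanol": 46.07,
    "glycerol": 92.09,
    "acetate": 60.05,
    "succinate": 118.09,
    "lactate": 90.08,
    "co2": 44.01,
}


@dataclass
class BatchTimeCourse:
    """A batch fermentation time course: time grid (h, strictly increasing),
    biomass (gDCW/L), and one concentration series (g/L) per species.
    ``phase_windows`` names (start, end) intervals in hours."""

    time: np.ndarray
    biomass: np.ndarray
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)
    phase_windows: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.biomass.shape != self.time.shape:
            raise ValueError("biomass series must share the time grid")
        for name, series in self.concentrations.items():
            series = np.asarray(series, dtype=float)
            if series.shape != self.time.shape:
                raise ValueError(f"series {name!r} must share the time grid")
            if np.any(series < -1e-12):
                raise ValueError(f"negative concentration in series {name!r}")
            self.concentrations[name] = series

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        if lo >= hi:
            raise ValueError("window start must precede its end")
        return (self.time >= lo) & (self.time <= hi)


@dataclass
class ChemostatState:
    """One chemostat steady state.  At steady state mu = D; a state sampled
    before three residence times have elapsed is not considered steady."""

    D: float
    X: float
    feed: Mapping[str, float]
    residual: Mapping[str, float] = field(default_factory=dict)
    products: Mapping[str, float] = field(default_factory=dict)
    residence_times_elapsed: float = 3.0
    feed_sd: Mapping[str, float] = field(default_factory=dict)
    residual_sd: Mapping[str, float] = field(default_factory=dict)
    products_sd: Mapping[str, float] = field(default_factory=dict)
    X_sd: float = 0.0

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("dilution rate must be positive")
        if self.X <= 0:
            raise ValueError("biomass concentration must be positive")

    @property
    def is_steady(self) -> bool:
        return self.residence_times_elapsed >= 3.0

    @property
    def mu(self) -> float:
        return self.D


@dataclass
class RateVector:
    """Signed specific rates with standard deviations and the growth rate."""

    rates: dict[str, float]
    sd: dict[str, float] = field(default_factory=dict)
    mu: float = 0.0
    mu_sd: float = 0.0
    condition_label: str = ""

    def __post_init__(self):
        for k, v in self.sd.items():
            if v < 0:
                raise ValueError(f"negative sd for {k!r}")

    @property
    def species(self) -> list[str]:
        return list(self.rates)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "rate_mmol_gDCW_h": [self.rates[s] for s in self.species],
                "sd_mmol_gDCW_h": [self.sd.get(s, 0.0) for s in self.species],
            }
        )


# ---------------------------------------------------------------------------
# batch estimation
# ---------------------------------------------------------------------------

def estimate_mu_loglinear(
    tc: BatchTimeCourse, window: tuple[float, float]
) -> tuple[float, float, float]:
    """Specific growth rate over a phase window as the least-squares slope of
    ln(biomass) versus time.  Returns ``(mu, sd, r2)`` with ``sd`` the slope's
    standard error.  For a perfect fit (zero residual) r2 is 1 by convention,
    including the constant-biomass case mu = 0."""
    mask = tc.window_mask(window)
    t = tc.time[mask]
    x = tc.biomass[mask]
    if t.size < 3:
        raise ValueError(f"need >= 3 points in window {window}, found {t.size}")
    if np.any(x <= 0):
        raise ValueError("nonpositive biomass inside the fit window")
    y = np.log(x)
    A = np.column_stack([t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    mu, intercept = coef
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    dof = t.size - 2
    s2 = ss_res / dof if dof > 0 else 0.0
    sd = float(np.sqrt(s2 / np.sum((t - t.mean()) ** 2)))
    r2 = 1.0 if ss_res <= 1e-14 * max(1.0, ss_tot) else 1.0 - ss_res / ss_tot
    return float(mu), sd, r2


def batch_specific_rates(
    tc: BatchTimeCourse,
    window: tuple[float, float],
    fit: str = "polynomial",
    degree: int = 3,
    molar_mass: Mapping[str, float] | None = None,
    n_grid: int = 50,
) -> dict[str, tuple[float, float]]:
    """Specific conversion rates over a phase window, as the envelope
    (min, max) of q(t) = (dC/dt) / X(t) evaluated on a dense grid.

    Concentrations are fitted with a polynomial (``degree >= 2``; exponential
    phases) or a straight line (``fit="linear"``; late, near-linear phases);
    the derivative of the fit divided by interpolated biomass and converted
    from g to mmol via the molar-mass table gives q in mmol/gDCW/h.
    """
    if fit not in ("polynomial", "linear"):
        raise ValueError(f"unknown fit kind {fit!r}")
    if fit == "polynomial" and degree < 2:
        raise ValueError("polynomial fit requires degree >= 2")
    deg = 1 if fit == "linear" else degree
    masses = MOLAR_MASS if molar_mass is None else molar_mass

    mask = tc.window_mask(window)
    t = tc.time[mask]
    if t.size < deg + 1:
        raise ValueError("too few points in window for the requested fit degree")
    if window[0] < tc.time[0] or window[1] > tc.time[-1]:
        raise ValueError("window extends beyond the data range")

    grid = np.linspace(t[0], t[-1], n_grid)
    X = np.interp(grid, tc.time, tc.biomass)
    out: dict[str, tuple[float, float]] = {}
    for species, series in tc.concentrations.items():
        if species not in masses:
            raise KeyError(f"no molar mass for species {species!r}")
        c = series[mask]
        with warnings.catch_warnings():
            warnings.simplefilter("error", np.exceptions.RankWarning)
            try:
                poly = np.polynomial.Polynomial.fit(t, c, deg)
            except np.exceptions.RankWarning:
                warnings.warn(f"ill-conditioned {fit} fit for {species!r}")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    poly = np.polynomial.Polynomial.fit(t, c, deg)
        dcdt = poly.deriv()(grid)  # g/L/h
        q = dcdt * 1000.0 / masses[species] / X
        out[species] = (float(q.min()), float(q.max()))
    return out


# ---------------------------------------------------------------------------
# chemostat steady states
# ---------------------------------------------------------------------------

def chemostat_rates(
    cs: ChemostatState,
    molar_mass: Mapping[str, float] | None = None,
    condition_label: str = "",
) -> RateVector:
    """Steady-state specific rates from a chemostat mass balance.

    Substrates: q = -D (C_feed - C_residual) / X; products: q = +D C / X
    (g -> mmol via molar mass); mu = D.  Standard deviations of feed,
    residual, product and biomass measurements propagate to rate sds by the
    first-order variance formula.  A substrate whose residual exceeds its
    feed yields a positive (production-signed) rate and a warning — that is
    measurement noise, not an error.
    """
    masses = MOLAR_MASS if molar_mass is None else molar_mass
    if not cs.is_steady:
        warnings.warn(
            f"state sampled at {cs.residence_times_elapsed:.2g} residence times; "
            "steadiness is verified from three residence times on"
        )
    rates: dict[str, float] = {}
    sds: dict[str, float] = {}
    for species, c_feed in cs.feed.items():
        if species not in masses:
            raise KeyError(f"no molar mass for species {species!r}")
        m = masses[species]
        c_res = float(cs.residual.get(species, 0.0))
        delta = c_feed - c_res
        q = -cs.D * delta / cs.X * 1000.0 / m
        if q > 0:
            warnings.warn(
                f"declared substrate {species!r} shows net production "
                f"(residual {c_res} > feed {c_feed}); check the measurements"
            )
        var_c = cs.feed_sd.get(species, 0.0) ** 2 + cs.residual_sd.get(species, 0.0) ** 2
        var = (cs.D / cs.X * 1000.0 / m) ** 2 * var_c + (q / cs.X) ** 2 * cs.X_sd**2
        rates[species] = q
        sds[species] = float(np.sqrt(var))
    for species, c_prod in cs.products.items():
        if species not in masses:
            raise KeyError(f"no molar mass for species {species!r}")
        m = masses[species]
        q = cs.D * c_prod / cs.X * 1000.0 / m
        var = (cs.D / cs.X * 1000.0 / m) ** 2 * cs.products_sd.get(species, 0.0) ** 2
        var += (q / cs.X) ** 2 * cs.X_sd**2
        rates[species] = q
        sds[species] = float(np.sqrt(var))
    return RateVector(rates=rates, sd=sds, mu=cs.D, condition_label=condition_label)


def residence_time(D: float) -> float:
    """Mean residence time of the vessel, 1/D hours."""
    if D <= 0:
        raise ValueError("dilution rate must be positive")
    return 1.0 / D


# ---------------------------------------------------------------------------
# elemental balance error
# ---------------------------------------------------------------------------

def balance_error(
    rates: RateVector,
    E: pd.DataFrame,
    element: str = "C",
    species_to_column: Mapping[str, str] | None = None,
    mu_column: str | None = "BIOMASS",
) -> float:
    """Percent closure error of an element balance over a measured rate set:
    ``100 |sum inflow + sum outflow| / sum inflow`` with inflow the element
    carried by consumption terms and biomass counted as an outflow at rate
    mu.  The raw (pre-reconciliation) carbon error of wine-must chemostats is
    typically in the single digits to ~10%."""
    if element not in E.index:
        raise KeyError(f"element {element!r} not in E")
    row = E.loc[element]
    mapping = species_to_column or {}
    inflow = 0.0
    net = 0.0
    for species, q in rates.rates.items():
        col = mapping.get(species, species)
        if col not in E.columns:
            raise KeyError(f"species {species!r} has no column in E")
        carried = row[col] * q
        net += carried
        if q < 0:
            inflow += -carried  # element entering the cell
    if mu_column is not None and mu_column in E.columns:
        net += row[mu_column] * rates.mu
    if inflow <= 0:
        raise ValueError("zero element inflow; balance error undefined")
    return 100.0 * abs(net) / inflow
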