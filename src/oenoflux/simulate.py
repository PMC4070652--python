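"""Synthetic ground truth for every pipeline stage.

Three generators, all pure functions of (configuration, seed):

* :func:`generate_flux_state` — an exactly balanced flux distribution of the
  packaged network, centred on the published steady-state exchange rates of a
  fermentation stage;
* :func:`generate_measurements` — noisy chemostat measurement-set replicates
  around a truth state (Gaussian, independent across species, sd = CV x
  |rate|), optionally with an injected gross error;
* :func:`generate_batch_profile` — a multi-phase batch fermentation time
  course integrated from stage growth rates 0.29 / 0.04 / 0.02 / 0.007 h^-1
  with carbon-closed conversion rates.

A small redundancy-3 exchange system (:func:`toy_exchange_system`) supports
the consistency-test calibration experiments without dragging in the full
network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import (
    STAGES,
    load_batch_ranges,
    load_biomass_composition,
    load_chemostat_rates,
)
from .mfa import EXCHANGE_BY_SPECIES, FluxState
from .network import StoichiometricModel, degree_of_reduction
from .rates import MOLAR_MASS, BatchTimeCourse, RateVector
from .reconcile import MeasurementSet

__all__ = [
    "GeneratorConfig",
    "generate_flux_state",
    "generate_measurements",
    "generate_batch_profile",
    "toy_exchange_system",
    "generate_toy_truth",
]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic world.  ``noise_cv`` is the relative sd of the
    Gaussian measurement error (5% emulates routine HPLC / off-gas accuracy);
    ``gross_error`` injects a systematic bias of ``magnitude`` standard
    deviations into one species."""

    seed: int = 0
    noise_cv: float = 0.05
    sd_floor: float = 1e-3
    gross_error: tuple[str, float] | None = None
    stage: str = "II"
    n_replicates: int = 1

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {list(STAGES)}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# balanced flux-state truth
# ---------------------------------------------------------------------------

def _null_space(A: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    u, s, vt = np.linalg.svd(A)
    rank = int(np.sum(s > rtol * s[0])) if s.size and s[0] > 0 else 0
    return vt[rank:].T


def generate_flux_state(
    model: StoichiometricModel,
    stage: str,
    mapping: Mapping[str, str] | None = None,
    ridge: float = 1e-4,
) -> FluxState:
    """Ground-truth flux state for a fermentation stage: the flux vector in
    the balance space (N v = 0, constrained reactions at zero) closest — in
    measurement-sd-weighted least squares — to the published steady-state
    exchange rates of that stage, with the growth rate pinned to the stage's
    dilution rate.

    Deterministic: no randomness enters; the published targets and the
    network fully define the truth.
    """
    if model.N is None:
        raise ValueError("model must be assembled")
    mapping = dict(EXCHANGE_BY_SPECIES if mapping is None else mapping)
    targets = load_chemostat_rates(stage)
    D = STAGES[stage]
    rxn_ids = model.reaction_ids
    col_of = {rid: j for j, rid in enumerate(rxn_ids)}

    # constraint rows: balances plus pinned-zero reactions
    rows = [model.N]
    for rid in sorted(model.constrained_zero_ids):
        e = np.zeros(len(rxn_ids))
        e[col_of[rid]] = 1.0
        rows.append(e[None, :])
    A = np.vstack(rows)
    Z = _null_space(A)
    if Z.shape[1] == 0:
        raise RuntimeError("balance space is trivial; no flux mode available")

    target = np.zeros(len(rxn_ids))
    weight = np.full(len(rxn_ids), ridge)
    for species, rate in targets.rates.items():
        j = col_of[mapping[species]]
        target[j] = rate
        sd = targets.sd.get(species) or 0.05 * max(abs(rate), 0.01)
        weight[j] = 1.0 / sd**2
    # exchanges without a published rate are held at exactly zero (except the
    # free CO2 / ammonium channels): no hidden carbon or nitrogen enters the
    # truth, and the flux solver's measured-zero policy recovers it exactly
    targeted = {col_of[mapping[s]] for s in targets.rates}
    hard_rows = []
    for rxn in model.reactions:
        j = col_of[rxn.id]
        if rxn.is_exchange and j not in targeted and rxn.id not in ("EX_co2", "EX_nh4"):
            e = np.zeros(len(rxn_ids))
            e[j] = 1.0
            hard_rows.append(e)

    # growth is a hard constraint: biomass flux = D exactly
    j_bio = col_of["BIOMASS"]
    e_bio = np.zeros(len(rxn_ids))
    e_bio[j_bio] = 1.0
    A = np.vstack([A, *[e[None, :] for e in hard_rows], e_bio[None, :]])
    b = np.zeros(A.shape[0])
    b[-1] = D

    irreversible = [
        j
        for j, rxn in enumerate(model.reactions)
        if not rxn.reversible and rxn.id not in model.constrained_zero_ids
    ]

    def _solve(extra_zero: set[int]) -> np.ndarray:
        rows = [A] + [np.eye(len(rxn_ids))[j][None, :] for j in sorted(extra_zero)]
        Ak = np.vstack(rows)
        bk = np.concatenate([b, np.zeros(len(extra_zero))])
        v_p, *_ = np.linalg.lstsq(Ak, bk, rcond=None)
        Zk = _null_space(Ak)
        Wh = np.sqrt(weight)[:, None]
        alpha, *_ = np.linalg.lstsq(Wh * Zk, np.sqrt(weight) * (target - v_p), rcond=None)
        return v_p + Zk @ alpha

    # active-set loop on irreversibility: pin offending fluxes to zero and
    # re-project (the relaxed-centering retry of the truth generator)
    active: set[int] = set()
    for _ in range(len(irreversible) + 1):
        v = _solve(active)
        tol = 1e-9 * max(1.0, float(np.abs(v).max()))
        neg = [j for j in irreversible if v[j] < -tol and j not in active]
        if not neg:
            break
        worst = min(neg, key=lambda j: v[j])
        warnings.warn(
            "truth projection pinned a negative irreversible flux to zero: "
            f"{rxn_ids[worst]}"
        )
        active.add(worst)

    v[np.abs(v) < 1e-12] = 0.0

    return FluxState(v=pd.Series(v, index=rxn_ids), condition=f"stage {stage} (D={D:g} h^-1)")


def generate_measurements(
    truth: FluxState,
    cfg: GeneratorConfig,
    species: Sequence[str] | None = None,
    mapping: Mapping[str, str] | None = None,
) -> list[MeasurementSet]:
    """Noisy measurement-set replicates around a truth state.

    Each measured rate is the truth exchange flux plus independent Gaussian
    noise with sd = ``noise_cv`` x |rate| (floored at ``sd_floor``); the
    recorded covariance is the true one.  A configured gross error adds
    ``magnitude`` x sd to one species in every replicate.
    """
    mapping = dict(EXCHANGE_BY_SPECIES if mapping is None else mapping)
    if species is None:
        species = [s for s in mapping if mapping[s] in truth.v.index]
    names = list(species)
    r_true = np.array([truth[mapping[s]] for s in names])
    sd = np.maximum(cfg.noise_cv * np.abs(r_true), cfg.sd_floor)
    rng = cfg.rng()
    out = []
    for k in range(cfg.n_replicates):
        noise = rng.normal(0.0, sd) if cfg.noise_cv > 0 else np.zeros_like(sd)
        r = r_true + noise
        if cfg.gross_error is not None:
            sp, magnitude = cfg.gross_error
            i = names.index(sp)
            r[i] += magnitude * sd[i]
        out.append(
            MeasurementSet(
                names=names,
                r_m=r,
                sd=sd.copy(),
                condition_label=f"{truth.condition} replicate {k}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# redundancy-3 toy system
# ---------------------------------------------------------------------------

#: formulas of the toy exchange species (biomass per C-mol, CH1.8O0.5N0.145)
_TOY_FORMULAS: dict[str, dict[str, float]] = {
    "glucose": {"C": 6, "H": 12, "O": 6, "N": 0},
    "fructose": {"C": 6, "H": 12, "O": 6, "N": 0},
    "ethanol": {"C": 2, "H": 6, "O": 1, "N": 0},
    "glycerol": {"C": 3, "H": 8, "O": 3, "N": 0},
    "succinate": {"C": 4, "H": 6, "O": 4, "N": 0},
    "co2": {"C": 1, "H": 0, "O": 2, "N": 0},
    "ammonium": {"C": 0, "H": 3, "O": 0, "N": 1},
    "biomass": {"C": 1, "H": 1.8, "O": 0.5, "N": 0.145},
}


def toy_exchange_system() -> tuple[list[str], np.ndarray]:
    """A fully measured exchange system with three independent conservation
    constraints — carbon, nitrogen and degree of reduction — over the routine
    fermentation species.  With every rate measured the redundancy matrix is
    the constraint matrix itself and the redundancy is 3, the configuration
    of the published consistency tests."""
    names = list(_TOY_FORMULAS)
    E = np.zeros((3, len(names)))
    for j, name in enumerate(names):
        f = _TOY_FORMULAS[name]
        E[0, j] = f["C"]
        E[1, j] = f["N"]
        E[2, j] = degree_of_reduction(f)
    return names, E


def generate_toy_truth(stage: str = "II") -> tuple[list[str], np.ndarray, np.ndarray]:
    """Exactly balanced toy exchange-rate vector for a stage: the published
    chemostat rates (biomass in C-mol units, ammonium closing the nitrogen
    balance, CO2 the carbon balance) projected onto the null space of the
    three-constraint matrix.  Returns ``(names, E, r_true)``."""
    names, E = toy_exchange_system()
    rates = load_chemostat_rates(stage)
    comp = load_biomass_composition()
    D = STAGES[stage]
    mu_cmol = D * comp.carbon_mmol_per_gdcw  # mmol C-mol biomass / gDCW / h

    r0 = np.zeros(len(names))
    for j, name in enumerate(names):
        if name == "biomass":
            r0[j] = mu_cmol
        elif name == "ammonium":
            r0[j] = -0.145 * mu_cmol
        elif name == "co2":
            r0[j] = rates.rates.get("ethanol", 0.0)  # fermentation stoichiometry
        else:
            r0[j] = rates.rates.get(name, 0.0)
    # minimal adjustment onto E r = 0 (unweighted projection)
    r_true = r0 - E.T @ np.linalg.pinv(E @ E.T) @ (E @ r0)
    assert np.allclose(E @ r_true, 0.0, atol=1e-9)
    return names, E, r_true


# ---------------------------------------------------------------------------
# batch profile
# ---------------------------------------------------------------------------

#: strict generation schedule (start_h, end_h, mu): the published fitting
#: windows overlap, so generation uses contiguous intervals with the same
#: growth rates; phase_windows on the output keep the published windows.
BATCH_SCHEDULE: list[tuple[float, float, float, str | None]] = [
    (0.0, 8.0, 0.0, None),          # lag
    (8.0, 17.0, 0.29, "I"),
    (17.0, 35.0, 0.04, "II"),
    (35.0, 58.0, 0.02, "earlyIII"),
    (58.0, 106.0, 0.007, "lateIII"),
    (106.0, 120.0, 0.0, "lateIII"),  # stationary; residual sugar still ferments
]

PHASE_WINDOWS = {"I": (8.0, 17.0), "II": (20.0, 35.0), "earlyIII": (30.0, 58.0), "lateIII": (60.0, 106.0)}

_SPECIES_CARBON = {
    "glucose": 6.0, "fructose": 6.0, "ethanol": 2.0, "glycerol": 3.0,
    "acetate": 2.0, "succinate": 4.0, "lactate": 3.0, "co2": 1.0,
}


def _balanced_stage_rates(stage: str, mu: float, biomass_c: float) -> dict[str, float]:
    """Stage conversion rates: bracket midpoints of the published batch
    envelopes, with exact carbon closure.  Sugar uptake defines the carbon
    inflow and stays at the bracket midpoints (glucose preferred, so it
    depletes first); the production rates (ethanol, glycerol, acids, CO2)
    absorb the closure residual, minimally adjusted with inverse-variance
    weights from the bracket half-widths."""
    _, ranges = load_batch_ranges(stage)
    species = list(ranges) + ["co2"]
    q0, hw = [], []
    for s in species[:-1]:
        lo, hi = ranges[s]
        q0.append(0.5 * (lo + hi))
        hw.append(max(0.5 * (hi - lo), 0.01))
    q_etoh = q0[species.index("ethanol")]
    q0.append(q_etoh)          # CO2 ~ ethanol (pyruvate decarboxylase)
    hw.append(max(0.5 * abs(q_etoh), 0.01))
    q0 = np.array(q0)
    c = np.array([_SPECIES_CARBON[s] for s in species])
    free = np.array([s not in ("glucose", "fructose") for s in species])
    w = 1.0 / np.array(hw) ** 2
    # one linear constraint on the free (product) rates:
    #   c_free . q_free = -biomass_c mu - c_sugar . q_sugar
    rhs = -biomass_c * mu - c[~free] @ q0[~free]
    cf, wf = c[free], w[free]
    lam = (rhs - cf @ q0[free]) / (cf @ (cf / wf))
    q = q0.copy()
    q[free] = q0[free] + (cf / wf) * lam
    return dict(zip(species, q))


def generate_batch_profile(
    cfg: GeneratorConfig,
    x0: float = 0.08,
    sugars0: float = 120.0,
    t_end: float = 120.0,
    dt: float = 0.1,
    sample_every: int = 5,
) -> BatchTimeCourse:
    """Forward-integrated multi-phase batch fermentation (Euler, dt = 0.1 h).

    Growth follows the stage schedule; conversion rates are the carbon-closed
    stage rates; sugars clip at zero, and once an inflow is exhausted the
    production rates scale down with the remaining carbon inflow so that the
    carbon ledger stays closed.  Glucose is the preferred carbon source, so
    it depletes first.  ``noise_cv`` adds multiplicative observation noise to
    the sampled series; the truth trajectory is noise-free.
    """
    comp = load_biomass_composition()
    biomass_c = comp.carbon_mmol_per_gdcw  # mmol C / gDCW
    segment_rates = [
        _balanced_stage_rates(name, mu, biomass_c) if name is not None else None
        for (_, _, mu, name) in BATCH_SCHEDULE
    ]

    n = int(round(t_end / dt)) + 1
    t = np.linspace(0.0, t_end, n)
    species = ["glucose", "fructose", "ethanol", "glycerol", "acetate", "succinate", "lactate", "co2"]
    C = {s: np.zeros(n) for s in species}
    C["glucose"][0] = sugars0
    C["fructose"][0] = sugars0
    X = np.zeros(n)
    X[0] = x0

    def _stage_at(time: float) -> tuple[float, dict[str, float] | None]:
        for k, (start, end, mu, _name) in enumerate(BATCH_SCHEDULE):
            if start <= time < end:
                return mu, segment_rates[k]
        return 0.0, segment_rates[-1]

    clipped = False
    for i in range(1, n):
        time = t[i - 1]
        mu, seg = _stage_at(time)
        q = seg if seg is not None else {s: 0.0 for s in species}

        # remaining carbon inflow after substrate depletion; growth is
        # nitrogen-limited (full stage mu while any sugar remains) and the
        # production rates scale down so that the carbon ledger stays closed
        nominal_in = sum(-_SPECIES_CARBON[s] * q.get(s, 0.0) for s in ("glucose", "fructose") if q.get(s, 0.0) < 0)
        actual_in = sum(
            -_SPECIES_CARBON[s] * q.get(s, 0.0)
            for s in ("glucose", "fructose")
            if q.get(s, 0.0) < 0 and C[s][i - 1] > 0
        )
        sugar_left = C["glucose"][i - 1] > 0 or C["fructose"][i - 1] > 0
        mu_eff = mu if sugar_left else 0.0
        bio_c = biomass_c * mu_eff
        scale = (
            max(actual_in - bio_c, 0.0) / (nominal_in - bio_c)
            if nominal_in - bio_c > 0
            else 0.0
        )

        X[i] = X[i - 1] * float(np.exp(mu_eff * dt))
        for s in species:
            rate = q.get(s, 0.0)
            if rate < 0 and C[s][i - 1] <= 0:
                rate = 0.0
            elif rate > 0:
                rate *= scale
            dC = rate * X[i - 1] * MOLAR_MASS[s] / 1000.0 * dt
            new = C[s][i - 1] + dC
            if new < 0:
                clipped = True
                new = 0.0
            C[s][i] = new
    if clipped:
        warnings.warn("substrate depleted inside a stage; concentrations clipped at zero")

    idx = np.arange(0, n, sample_every)
    rng = cfg.rng()
    obs = {}
    for s in species:
        series = C[s][idx]
        if cfg.noise_cv > 0:
            series = np.clip(series * (1.0 + rng.normal(0.0, cfg.noise_cv, series.size)), 0.0, None)
        obs[s] = series
    x_obs = X[idx]
    if cfg.noise_cv > 0:
        x_obs = np.clip(x_obs * (1.0 + rng.normal(0.0, cfg.noise_cv, x_obs.size)), 1e-9, None)

    return BatchTimeCourse(
        time=t[idx],
        biomass=x_obs,
        concentrations=obs,
        phase_windows=dict(PHASE_WINDOWS),
    )
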