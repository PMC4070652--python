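"""Metabolic flux analysis on the anaerobic wine-yeast network.

With the stoichiometric matrix split by the measured / calculated flux
partition, N v = N_c v_c + N_m v_m = 0, the internal fluxes solve the
(weighted) least-squares system N_c v_c = -N_m v_m.  When more balances than
unknowns remain, the surplus yields a flux-level consistency index tested
against the chi-square distribution, exactly as in measurement
reconciliation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import StoichiometricModel, SUCCINYL_COA_SYNTHETASE, biomass_carbon_content
from .rates import RateVector
from .reconcile import PINV_RTOL, redundancy_matrix
from scipy import stats

__all__ = [
    "FluxState",
    "EXCHANGE_BY_SPECIES",
    "apply_anaerobic_constraints",
    "solve_fluxes",
    "normalize_fluxes",
    "stage_summaries",
    "reaction_carbon",
]

#: measurement species -> exchange reaction of the packaged network
EXCHANGE_BY_SPECIES: dict[str, str] = {
    "glucose": "EX_glc",
    "fructose": "EX_frc",
    "ethanol": "EX_etoh",
    "glycerol": "EX_glyc",
    "acetate": "EX_ac",
    "succinate": "EX_succ",
    "lactate": "EX_lac",
    "co2": "EX_co2",
    "ammonium": "EX_nh4",
    "biomass": "BIOMASS",
}


@dataclass
class FluxState:
    """A full flux distribution: ``v`` indexed by reaction id
    (mmol/gDCW/h; the biomass flux is mu in h^-1), with an optional
    carbon-normalised view (% C-mol per C-mol of glucose uptake)."""

    v: pd.Series
    condition: str = ""
    h_flux: float = float("nan")
    df: int = 0
    p_value: float = float("nan")
    residual_norm: float = 0.0
    v_normalized: pd.Series | None = None
    irreversibility_violations: list[str] = field(default_factory=list)

    def __getitem__(self, rxn_id: str) -> float:
        return float(self.v[rxn_id])


def apply_anaerobic_constraints(model: StoichiometricModel) -> StoichiometricModel:
    """Pin succinyl-CoA synthetase to zero flux (its activity is negligible
    without oxygen), splitting the TCA cycle into an oxidative branch to
    2-oxoglutarate and a reductive branch to succinate.  Idempotent."""
    if SUCCINYL_COA_SYNTHETASE not in model.reaction_ids:
        raise KeyError(f"reaction {SUCCINYL_COA_SYNTHETASE!r} absent from the model")
    out = model.copy()
    out.constrained_zero_ids.add(SUCCINYL_COA_SYNTHETASE)
    return out


def _null_space(A: np.ndarray, rtol: float = PINV_RTOL) -> np.ndarray:
    if A.size == 0:
        return np.eye(A.shape[1])
    u, s, vt = np.linalg.svd(A)
    rank = int(np.sum(s > rtol * s[0])) if s.size and s[0] > 0 else 0
    return vt[rank:].T


#: exchange fluxes left free (calculated) when no measurement is supplied:
#: CO2 evolution and ammonium uptake close the carbon and nitrogen balances.
DEFAULT_FREE_EXCHANGES = frozenset({"EX_co2", "EX_nh4"})


def solve_fluxes(
    model: StoichiometricModel,
    measured: RateVector,
    species_to_reaction: Mapping[str, str] | None = None,
    significance: float = 0.05,
    irreversibility_tol: float = 1e-6,
    condition: str = "",
    free_exchanges: frozenset[str] | set[str] = DEFAULT_FREE_EXCHANGES,
) -> FluxState:
    """Estimate the full flux vector from measured exchange rates.

    Measured rates (plus mu for the biomass reaction and zeros for the
    constrained reactions) fix v_m; the remaining fluxes solve
    ``N_c v_c = -N_m v_m`` by least squares.  ``N_c`` must have full column
    rank, otherwise the undetermined directions are reported by name.  With
    surplus balances the consistency index of the residual is computed with
    degrees of freedom = rank of the constraint set projected onto the
    measured rates.  Irreversible reactions driven negative are flagged, not
    clipped — the least-squares solution stays unique and auditable.
    """
    if model.N is None:
        raise ValueError("model is not assembled; call build_matrix first")
    mapping = EXCHANGE_BY_SPECIES if species_to_reaction is None else dict(species_to_reaction)
    rxn_ids = model.reaction_ids
    col_of = {rid: j for j, rid in enumerate(rxn_ids)}

    v_m: dict[int, float] = {}
    for species, rate in measured.rates.items():
        rid = mapping.get(species, species)
        if rid not in col_of:
            raise KeyError(f"measured species {species!r} maps to no model reaction")
        v_m[col_of[rid]] = float(rate)
    bio = model.biomass_reaction
    if bio is not None and col_of[bio.id] not in v_m:
        v_m[col_of[bio.id]] = measured.mu
    for rid in model.constrained_zero_ids:
        v_m.setdefault(col_of[rid], 0.0)
    # an exchange with no measurement and no free role carries zero flux:
    # "not detected" is information, and dropping it would change the
    # redundancy of the system
    for rxn in model.reactions:
        if rxn.is_exchange and rxn.id not in free_exchanges:
            v_m.setdefault(col_of[rxn.id], 0.0)

    measured_cols = sorted(v_m)
    free_cols = [j for j in range(len(rxn_ids)) if j not in v_m]
    N = model.N
    N_m = N[:, measured_cols]
    N_c = N[:, free_cols]
    vm_vec = np.array([v_m[j] for j in measured_cols])

    # column-rank check with named null directions
    ns = _null_space(N_c)
    if ns.shape[1] > 0:
        basis = []
        for k in range(ns.shape[1]):
            involved = [rxn_ids[free_cols[i]] for i in np.flatnonzero(np.abs(ns[:, k]) > 1e-8)]
            basis.append(involved)
        raise ValueError(
            "calculated-flux system is rank deficient; undetermined directions: "
            f"{basis}"
        )

    # flux-level consistency: constraints expressible in measured fluxes alone
    R_flux = redundancy_matrix(N, measured=measured_cols, unmeasured=free_cols)
    s = np.linalg.svd(R_flux, compute_uv=False)
    # rank relative to the scale of the measured block, so a numerically
    # vanishing projection (no redundancy) yields df = 0
    ref = max(float(s[0]) if s.size else 0.0, float(np.linalg.norm(N_m)))
    df = int(np.sum(s > PINV_RTOL * ref)) if s.size and ref > 0 else 0
    if df > 0:
        # measurement variances mapped onto the measured columns, floored at
        # half the detection limit so "not detected" zeros stay softly
        # adjustable; constrained-zero reactions are hard (variance 0)
        var = np.array(
            [
                0.0
                if rxn_ids[j] in model.constrained_zero_ids
                else max(_variance_for(measured, rxn_ids[j], mapping), 0.005**2)
                for j in measured_cols
            ]
        )
        eps = R_flux @ vm_vec
        P = R_flux @ np.diag(var) @ R_flux.T
        P_inv = np.linalg.pinv(P, rcond=PINV_RTOL)
        h_flux = float(eps @ P_inv @ eps)
        p_value = float(stats.chi2.sf(h_flux, df))
        # reconcile the measured fluxes onto the balance space, then the
        # calculated fluxes satisfy N v = 0 exactly
        vm_vec = vm_vec - np.diag(var) @ R_flux.T @ P_inv @ eps
    else:
        h_flux, p_value = float("nan"), float("nan")

    b = -N_m @ vm_vec
    v_c, _, _, _ = np.linalg.lstsq(N_c, b, rcond=None)
    resid = N_c @ v_c - b
    residual_norm = float(np.linalg.norm(resid))
    v_m = dict(zip(measured_cols, vm_vec))
    v = _assemble(v_m, free_cols, v_c, len(rxn_ids))
    scale = max(1.0, float(np.abs(v).max()))
    violations = []
    for j, rid in enumerate(rxn_ids):
        rxn = model.reactions[j]
        if not rxn.reversible and rid not in model.constrained_zero_ids and v[j] < -irreversibility_tol * scale:
            violations.append(rid)
    if violations:
        warnings.warn(f"negative flux on irreversible reactions: {violations}")

    return FluxState(
        v=pd.Series(v, index=rxn_ids),
        condition=condition or measured.condition_label,
        h_flux=h_flux,
        df=df,
        p_value=p_value,
        residual_norm=residual_norm,
        irreversibility_violations=violations,
    )


def _assemble(v_m: Mapping[int, float], free_cols: Sequence[int], v_c: np.ndarray, n: int) -> np.ndarray:
    v = np.zeros(n)
    for j, val in v_m.items():
        v[j] = val
    for i, j in enumerate(free_cols):
        v[j] = v_c[i]
    return v


def _variance_for(measured: RateVector, rxn_id: str, mapping: Mapping[str, str]) -> float:
    for species, rid in mapping.items():
        if rid == rxn_id and species in measured.sd:
            return measured.sd[species] ** 2
    if rxn_id == "BIOMASS":
        return measured.mu_sd**2 if measured.mu_sd > 0 else (0.05 * abs(measured.mu)) ** 2
    return 0.0


def reaction_carbon(model: StoichiometricModel, rxn_id: str) -> float:
    """C-mol carried per unit flux of a reaction: atoms of carbon in its
    consumed (substrate) side; for the biomass reaction, the carbon content
    of 1 g of cells."""
    rxn = model.reaction(rxn_id)
    if rxn.is_biomass:
        return biomass_carbon_content(rxn)
    return float(
        sum(
            -coef * model.metabolite(met).atoms("C")
            for met, coef in rxn.stoichiometry.items()
            if coef < 0
        )
    )


def normalize_fluxes(
    model: StoichiometricModel,
    fs: FluxState,
    glucose_exchange: str = "EX_glc",
) -> FluxState:
    """Carbon-normalised view: each flux as
    100 * (C-mol carried) / (C-mol of glucose uptake)."""
    q_glc = fs[glucose_exchange]
    if q_glc == 0:
        raise ValueError("glucose uptake flux is zero; cannot normalise")
    glc_cmol = abs(q_glc) * reaction_carbon(model, glucose_exchange)
    values = {
        rid: 100.0 * fs[rid] * reaction_carbon(model, rid) / glc_cmol
        for rid in fs.v.index
    }
    fs.v_normalized = pd.Series(values)
    return fs


def stage_summaries(
    fs: FluxState | None,
    rates: RateVector,
    model: StoichiometricModel | None = None,
) -> dict[str, float]:
    """Stage-level carbon partition statistics.

    * ``glucose_share_pct`` — glucose fraction of hexose carbon uptake,
      6|q_glc| / (6|q_glc| + 6|q_frc|): ~90% at the onset of fermentation,
      falling towards ~60% once glucose is preferentially depleted.
    * ``ethanol_carbon_pct`` / ``glycerol_carbon_pct`` — share of assimilated
      carbon leaving through each fermentative pathway.
    * ``glycolysis_share_pct`` / ``oxPPP_share_pct`` — split of hexose-P
      carbon at the G6P node (requires a solved FluxState and model).
    """
    q_glc = rates.rates.get("glucose", 0.0)
    q_frc = rates.rates.get("fructose", 0.0)
    hexose_c = 6.0 * abs(q_glc) + 6.0 * abs(q_frc)
    if hexose_c == 0:
        raise ValueError("zero hexose uptake; no carbon to partition")
    out: dict[str, float] = {
        "glucose_share_pct": 100.0 * 6.0 * abs(q_glc) / hexose_c,
    }
    carbon_in = hexose_c + sum(
        _species_carbon(s) * abs(q) for s, q in rates.rates.items()
        if q < 0 and s not in ("glucose", "fructose")
    )
    # the ethanol pathway carries 3 C per ethanol: 2 in the product plus the
    # CO2 released at pyruvate decarboxylase
    q_etoh = rates.rates.get("ethanol", 0.0)
    out["ethanol_pathway_carbon_pct"] = 100.0 * 3.0 * max(q_etoh, 0.0) / carbon_in
    q_glyc = rates.rates.get("glycerol", 0.0)
    out["glycerol_carbon_pct"] = 100.0 * 3.0 * max(q_glyc, 0.0) / carbon_in

    if fs is not None and model is not None:
        v_pgi = fs["PGI"]
        v_zwf = fs["ZWF"]
        # carbon entering the G6P node and leaving towards glycolysis vs oxPPP
        glyco_c = 6.0 * v_pgi if v_pgi > 0 else 0.0
        ppp_c = 6.0 * v_zwf
        total = glyco_c + ppp_c
        if total > 0:
            out["glycolysis_share_pct"] = 100.0 * glyco_c / total
            out["oxPPP_share_pct"] = 100.0 * ppp_c / total
    return out


def _species_carbon(species: str) -> float:
    counts = {
        "glucose": 6.0, "fructose": 6.0, "ethanol": 2.0, "glycerol": 3.0,
        "acetate": 2.0, "succinate": 4.0, "lactate": 3.0, "co2": 1.0,
    }
    return counts.get(species, 0.0)
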