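"""Stoichiometric network of anaerobic wine-yeast central carbon metabolism.

The model is a classical small-scale MFA network: a stoichiometric matrix ``N``
over *balanced* (intracellular) metabolites, a partition of reactions into
measured exchange fluxes and calculated internal fluxes, and a biomass
reaction assembled from a measured macromolecular composition.  Cofactor
pairs (NAD(P)H, ATP/ADP) are represented by single zero-formula carrier
species, so element bookkeeping covers carbon and nitrogen — the two balances
used for data reconciliation of fermentation measurements.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "BiomassComposition",
    "StoichiometricModel",
    "FeedMedium",
    "NetworkParseError",
    "load_reaction_network",
    "build_matrix",
    "check_element_balance",
    "build_biomass_reaction",
    "select_amino_acid_pathways",
    "elemental_balance_matrix",
    "degree_of_reduction",
    "make_feed",
    "FEED_PRESETS",
    "AMINO_ACID_RESIDUES",
]

ELEMENTS = ("C", "H", "O", "N")
COMPARTMENTS = ("cytosol", "mitochondrion", "extracellular")

PATHWAY_TAGS = (
    "glycolysis", "PPP", "TCA_oxidative", "TCA_reductive", "fermentation",
    "glycerol", "anaplerosis", "amino_acid_synthesis", "amino_acid_degradation",
    "transport", "exchange", "biomass",
)

#: Succinyl-CoA synthetase: negligible activity under strict anaerobiosis, so
#: anaerobic assemblies pin its flux to zero and the TCA cycle splits into an
#: oxidative and a reductive branch.
SUCCINYL_COA_SYNTHETASE = "SCS"

#: (molecular mass, C, N) of the proteinogenic amino acids carried by the
#: packaged network; residue mass in a peptide chain is mass - 18.015 (water).
AMINO_ACID_RESIDUES: dict[str, tuple[float, int, int]] = {
    "ala": (89.094, 3, 1),
    "arg": (174.203, 6, 4),
    "asp": (133.104, 4, 1),
    "glu": (147.131, 5, 1),
    "gln": (146.146, 5, 2),
    "ser": (105.093, 3, 1),
    "thr": (119.120, 4, 1),
    "val": (117.148, 5, 1),
    "leu": (131.175, 6, 1),
    "ile": (131.175, 6, 1),
    "phe": (165.192, 9, 1),
    "trp": (204.229, 11, 2),
}

_WATER_MASS = 18.015


class NetworkParseError(ValueError):
    """Raised when a reaction-network file cannot be parsed; carries the line."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Metabolite:
    """A chemical species; ``formula`` maps element symbol to (possibly
    fractional) atom count.  Only extracellular species may carry net
    exchange flux."""

    id: str
    name: str = ""
    formula: Mapping[str, float] = field(default_factory=dict)
    compartment: str = "cytosol"

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r} for {self.id}")
        if self.formula.get("C", 0.0) < 0:
            raise ValueError(f"negative carbon count for {self.id}")

    @property
    def is_extracellular(self) -> bool:
        return self.compartment == "extracellular"

    def atoms(self, element: str) -> float:
        return float(self.formula.get(element, 0.0))


@dataclass
class Reaction:
    """A reaction; stoichiometry maps metabolite id to a signed coefficient
    (negative = consumed).  Exchange and biomass reactions are exempt from
    element-balance checks (they cross the system boundary)."""

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    pathway_tag: str = "transport"

    def __post_init__(self):
        if self.pathway_tag not in PATHWAY_TAGS:
            raise ValueError(f"unknown pathway tag {self.pathway_tag!r} on {self.id}")

    @property
    def is_exchange(self) -> bool:
        return self.pathway_tag == "exchange"

    @property
    def is_biomass(self) -> bool:
        return self.pathway_tag == "biomass" and self.id.lower().startswith("biomass")


@dataclass
class BiomassComposition:
    """Measured biomass make-up: per-C-mol elemental formula CH_aO_bN_c,
    macromolecular mass fractions of dry weight, and the molar fractions of
    amino-acid residues in total cell protein.

    The macromolecular fractions may sum to less than 1; the remainder is an
    inert "other" pool (ash, polyphosphate, ...).  ``molar_mass_per_cmol`` is
    the dry-weight mass carrying one mole of carbon (g / C-mol), ash included.
    """

    elemental: tuple[float, float, float] = (1.8, 0.5, 0.2)
    macromolecular: dict[str, float] = field(default_factory=dict)
    amino_acid_fractions: dict[str, float] = field(default_factory=dict)
    molar_mass_per_cmol: float = 26.4

    def __post_init__(self):
        a, b, c = self.elemental
        if min(a, b, c) < 0:
            raise ValueError("elemental subscripts must be nonnegative")
        for name, frac in self.macromolecular.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"macromolecular fraction {name}={frac} outside [0, 1]")
        total = sum(self.macromolecular.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"macromolecular fractions sum to {total:.4f} > 1")
        if self.amino_acid_fractions:
            aa_total = sum(self.amino_acid_fractions.values())
            if abs(aa_total - 1.0) > 1e-9:
                raise ValueError(
                    f"amino-acid molar fractions sum to {aa_total!r}, expected 1"
                )
            if min(self.amino_acid_fractions.values()) < 0:
                raise ValueError("negative amino-acid fraction")
        if self.molar_mass_per_cmol <= 0:
            raise ValueError("molar_mass_per_cmol must be positive")

    @property
    def carbon_mmol_per_gdcw(self) -> float:
        """mmol of carbon in one gram of dry cells (1000 / M_Cmol)."""
        return 1000.0 / self.molar_mass_per_cmol


@dataclass
class StoichiometricModel:
    """Reaction network plus, once assembled, the stoichiometric matrix ``N``
    (one row per balanced metabolite, one column per reaction)."""

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    N: np.ndarray | None = None
    balanced_ids: list[str] = field(default_factory=list)
    measured_ids: list[str] = field(default_factory=list)
    constrained_zero_ids: set[str] = field(default_factory=set)

    # -- lookup helpers -------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except AttributeError:
            self._met_index = {m.id: m for m in self.metabolites}
            return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def exchange_ids(self) -> list[str]:
        """Boundary-crossing reactions: exchanges plus the biomass reaction."""
        return [r.id for r in self.reactions if r.is_exchange or r.is_biomass]

    @property
    def biomass_reaction(self) -> Reaction | None:
        hits = [r for r in self.reactions if r.is_biomass]
        if len(hits) > 1:
            raise ValueError("model contains more than one biomass reaction")
        return hits[0] if hits else None

    def add_reaction(self, reaction: Reaction) -> None:
        if reaction.id in self.reaction_ids:
            raise ValueError(f"duplicate reaction id {reaction.id!r}")
        if reaction.is_biomass and self.biomass_reaction is not None:
            raise ValueError("model already contains a biomass reaction")
        known = {m.id for m in self.metabolites}
        missing = set(reaction.stoichiometry) - known
        if missing:
            raise KeyError(f"reaction {reaction.id} references unknown metabolites {sorted(missing)}")
        self.reactions.append(reaction)
        self.N = None  # invalidate

    def add_metabolite(self, met: Metabolite) -> None:
        if any(m.id == met.id for m in self.metabolites):
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)
        if hasattr(self, "_met_index"):
            del self._met_index

    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(
            metabolites=list(self.metabolites),
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            N=None if self.N is None else self.N.copy(),
            balanced_ids=list(self.balanced_ids),
            measured_ids=list(self.measured_ids),
            constrained_zero_ids=set(self.constrained_zero_ids),
        )


@dataclass
class FeedMedium:
    """A feed recipe.  ``components`` maps id -> {amount, unit, role?,
    assimilable?}; amino acids are tagged by role so presets can rescale the
    whole group uniformly."""

    components: dict[str, dict] = field(default_factory=dict)
    amino_acid_scale: float = 1.0
    ammonium_present: bool = True
    stage_preset: str = "custom"

    def amount(self, component: str) -> float:
        return float(self.components[component]["amount"])

    def amino_acids(self) -> list[str]:
        return [k for k, v in self.components.items() if v.get("role") == "amino_acid"]

    def copy(self) -> "FeedMedium":
        return FeedMedium(
            components={k: dict(v) for k, v in self.components.items()},
            amino_acid_scale=self.amino_acid_scale,
            ammonium_present=self.ammonium_present,
            stage_preset=self.stage_preset,
        )


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?([A-Za-z_][A-Za-z0-9_]*)$")


def _parse_side(text: str, line_no: int) -> dict[str, float]:
    text = text.strip()
    if not text:
        return {}
    out: dict[str, float] = {}
    for term in text.split("+"):
        term = term.strip()
        m = _TERM_RE.match(term)
        if m is None:
            raise NetworkParseError(f"cannot parse term {term!r}", line_no)
        coef = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        out[met] = out.get(met, 0.0) + coef
    return out


def parse_reaction_equation(line: str, line_no: int = 0) -> Reaction:
    """Parse ``"id : lhs -> rhs"`` (or ``<->``), with an optional trailing
    ``| pathway_tag`` annotation."""
    if line.count("(") != line.count(")"):
        raise NetworkParseError("unbalanced parentheses in equation", line_no)
    tag = None
    if "|" in line:
        line, tag_text = line.split("|", 1)
        tag = tag_text.split("#", 1)[0].strip()
    if ":" not in line:
        raise NetworkParseError("missing ':' between id and equation", line_no)
    rxn_id, eqn = line.split(":", 1)
    rxn_id = rxn_id.strip()
    if not rxn_id:
        raise NetworkParseError("empty reaction id", line_no)
    if "<->" in eqn:
        reversible = True
        lhs, rhs = eqn.split("<->", 1)
    elif "->" in eqn:
        reversible = False
        lhs, rhs = eqn.split("->", 1)
    else:
        raise NetworkParseError("missing '->' or '<->' arrow", line_no)
    stoich: dict[str, float] = {}
    for met, coef in _parse_side(lhs, line_no).items():
        stoich[met] = stoich.get(met, 0.0) - coef
    for met, coef in _parse_side(rhs, line_no).items():
        stoich[met] = stoich.get(met, 0.0) + coef
    if not stoich:
        raise NetworkParseError("reaction has empty stoichiometry", line_no)
    if tag:
        return Reaction(rxn_id, stoich, reversible=reversible, pathway_tag=tag)
    # heuristic default: boundary reactions are exchanges
    default_tag = "exchange" if rxn_id.startswith("EX_") else "transport"
    return Reaction(rxn_id, stoich, reversible=reversible, pathway_tag=default_tag)


def _read_metabolite_table(path: Path) -> list[Metabolite]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"id", "compartment"}
    if not required <= set(df.columns):
        raise ValueError(f"metabolite table {path} lacks columns {required - set(df.columns)}")
    mets = []
    for row in df.itertuples(index=False):
        formula = {e: float(getattr(row, e, 0.0) or 0.0) for e in ELEMENTS if hasattr(row, e)}
        mets.append(
            Metabolite(
                id=row.id,
                name=getattr(row, "name", row.id),
                formula=formula,
                compartment=row.compartment,
            )
        )
    return mets


def load_reaction_network(
    reactions_path: str | Path,
    metabolites_path: str | Path | None = None,
) -> StoichiometricModel:
    """Read a reaction file ("id : equation" records, '#' comments) plus an
    optional metabolite TSV (id, name, C, H, O, N, compartment).

    Without a metabolite table, species are created on the fly with empty
    formulas (sufficient for toy models).  Returns a model with ``N`` unbuilt.
    """
    reactions_path = Path(reactions_path)
    model = StoichiometricModel()
    if metabolites_path is not None:
        for met in _read_metabolite_table(Path(metabolites_path)):
            model.add_metabolite(met)
        declared = {m.id for m in model.metabolites}
    else:
        declared = None

    seen: set[str] = set()
    for line_no, raw in enumerate(reactions_path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip() if not raw.lstrip().startswith("#") else ""
        if not line:
            continue
        rxn = parse_reaction_equation(line, line_no)
        if rxn.id in seen:
            raise NetworkParseError(f"duplicate reaction id {rxn.id!r}", line_no)
        seen.add(rxn.id)
        for met_id in rxn.stoichiometry:
            if declared is not None:
                if met_id not in declared:
                    raise NetworkParseError(
                        f"unknown metabolite id {met_id!r} in reaction {rxn.id}", line_no
                    )
            elif all(m.id != met_id for m in model.metabolites):
                compartment = "extracellular" if met_id.endswith("_e") else "cytosol"
                model.add_metabolite(Metabolite(id=met_id, name=met_id, compartment=compartment))
        model.reactions.append(rxn)
    model.N = None
    return model


# ---------------------------------------------------------------------------
# assembly and checks
# ---------------------------------------------------------------------------

def build_matrix(model: StoichiometricModel) -> StoichiometricModel:
    """Populate ``model.N`` with one row per balanced (non-extracellular)
    metabolite, one column per reaction (declared order).

    A balanced metabolite that never appears in any reaction triggers a
    structural warning (it cannot carry flux and its row is all zeros).
    """
    balanced = [m for m in model.metabolites if not m.is_extracellular]
    used = {met for r in model.reactions for met in r.stoichiometry}
    for m in balanced:
        if m.id not in used:
            warnings.warn(f"balanced metabolite {m.id!r} participates in no reaction")
    model.balanced_ids = [m.id for m in balanced]
    row_of = {mid: i for i, mid in enumerate(model.balanced_ids)}
    N = np.zeros((len(balanced), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            i = row_of.get(met_id)
            if i is not None:
                N[i, j] = coef
    model.N = N
    return model


def check_element_balance(
    model: StoichiometricModel,
    elements: Sequence[str] = ("C", "N"),
    tol: float = 1e-9,
) -> dict[str, dict[str, float]]:
    """Verify element conservation for every non-exchange, non-biomass
    reaction.  Returns ``{reaction_id: {element: imbalance}}`` for offenders
    and raises ``ValueError`` if any imbalance exceeds ``tol``."""
    bad: dict[str, dict[str, float]] = {}
    for rxn in model.reactions:
        if rxn.is_exchange or rxn.is_biomass:
            continue
        imbalance = {}
        for e in elements:
            net = sum(
                coef * model.metabolite(met_id).atoms(e)
                for met_id, coef in rxn.stoichiometry.items()
            )
            if abs(net) > tol:
                imbalance[e] = net
        if imbalance:
            bad[rxn.id] = imbalance
    if bad:
        raise ValueError(f"element imbalance in reactions: {bad}")
    return bad


# ---------------------------------------------------------------------------
# biomass
# ---------------------------------------------------------------------------

#: Default precursor stoichiometry, mmol of network precursor per gram of
#: macromolecule.  Storage and structural carbohydrates polymerise from
#: hexose phosphate (anhydroglucose, 162.14 g/mol); lipid is accounted as a
#: C18 fatty-acyl equivalent (stearate, 284.48 g/mol); RNA as an average
#: nucleotide residue (321 g/mol).  Protein is handled separately from the
#: amino-acid molar fractions.
DEFAULT_PRECURSOR_TABLE: dict[str, dict[str, float]] = {
    "carbohydrate": {"g6p": 1000.0 / 162.14},
    "glycogen": {"g6p": 1000.0 / 162.14},
    "trehalose": {"g6p": 1000.0 / 162.14},
    "lipid": {"lip": 1000.0 / 284.48},
    "rna": {"rna": 1000.0 / 321.0},
}

#: Growth-associated ATP demand, mmol ATP per gram DCW (polymerisation plus
#: transport), a standard order of magnitude for anaerobic yeast.
GROWTH_ATP_MMOL_PER_GDCW = 30.0


def build_biomass_reaction(
    comp: BiomassComposition,
    precursor_table: Mapping[str, Mapping[str, float]] | None = None,
    growth_atp: float = GROWTH_ATP_MMOL_PER_GDCW,
    elemental_tol: float = 0.35,
) -> Reaction:
    """Assemble the biomass reaction on a per-gram-DCW basis: the reaction
    consumes ``coef`` mmol of each precursor and produces one unit (1 g) of
    the ``biomass`` species, so its flux is the specific growth rate (h^-1).

    Protein precursors are the model amino acids at
    ``1000 * fraction_i / mean_residue_mass`` mmol per gram protein, scaled by
    the protein mass fraction.  The assembled carbon content is compared with
    the declared ``1000 / molar_mass_per_cmol``; a relative deviation above
    ``elemental_tol`` warns (compositions are measured quantities and need not
    be perfectly self-consistent).
    """
    table = dict(DEFAULT_PRECURSOR_TABLE if precursor_table is None else precursor_table)
    stoich: dict[str, float] = {}

    protein_fraction = comp.macromolecular.get("protein", 0.0)
    if protein_fraction > 0:
        if not comp.amino_acid_fractions:
            raise ValueError("protein fraction > 0 requires amino_acid_fractions")
        mean_residue = sum(
            frac * (AMINO_ACID_RESIDUES[aa][0] - _WATER_MASS)
            for aa, frac in comp.amino_acid_fractions.items()
        )
        residues_per_g = 1000.0 / mean_residue  # mmol residues / g protein
        for aa, frac in comp.amino_acid_fractions.items():
            if aa not in AMINO_ACID_RESIDUES:
                raise KeyError(f"amino acid {aa!r} not in the model residue table")
            coef = protein_fraction * residues_per_g * frac
            if coef:
                stoich[aa] = stoich.get(aa, 0.0) - coef

    for macro, fraction in comp.macromolecular.items():
        if macro == "protein" or fraction == 0.0:
            continue
        if macro not in table:
            raise KeyError(f"no precursor entry for macromolecule {macro!r}")
        for precursor, per_gram in table[macro].items():
            stoich[precursor] = stoich.get(precursor, 0.0) - fraction * per_gram

    if growth_atp:
        stoich["atp"] = stoich.get("atp", 0.0) - growth_atp
    stoich["biomass"] = 1.0

    rxn = Reaction("BIOMASS", stoich, reversible=False, pathway_tag="biomass")

    declared_c = comp.carbon_mmol_per_gdcw
    assembled_c = biomass_carbon_content(rxn)
    if declared_c > 0 and abs(assembled_c - declared_c) / declared_c > elemental_tol:
        warnings.warn(
            "assembled biomass carbon content "
            f"({assembled_c:.2f} mmol C/gDCW) deviates from the declared "
            f"formula ({declared_c:.2f} mmol C/gDCW)"
        )
    return rxn


def biomass_carbon_content(rxn: Reaction, element: str = "C") -> float:
    """Element content of 1 g of assembled biomass, mmol atoms per gDCW,
    from the precursor coefficients (exact bookkeeping basis of E)."""
    counts = _PRECURSOR_ELEMENTS[element]
    return sum(-coef * counts.get(met, 0.0) for met, coef in rxn.stoichiometry.items() if coef < 0)


# element counts of biomass precursors (must mirror the packaged network)
_PRECURSOR_ELEMENTS: dict[str, dict[str, float]] = {
    "C": {
        "g6p": 6.0, "lip": 18.0, "rna": 9.5,
        **{aa: AMINO_ACID_RESIDUES[aa][1] for aa in AMINO_ACID_RESIDUES},
    },
    "N": {
        "rna": 3.75,
        **{aa: AMINO_ACID_RESIDUES[aa][2] for aa in AMINO_ACID_RESIDUES},
    },
}


# ---------------------------------------------------------------------------
# pathway selection
# ---------------------------------------------------------------------------

def select_amino_acid_pathways(
    incorporation: Mapping[str, float],
    uptake: Mapping[str, float],
) -> dict[str, str]:
    """Decide, per amino acid, whether the biosynthetic or the degradation
    pathway enters the model: a ratio incorporation/uptake >= 1 (including
    zero uptake with nonzero incorporation) selects synthesis, a ratio < 1
    selects degradation; an amino acid with neither flux is omitted."""
    out: dict[str, str] = {}
    for aa in set(incorporation) | set(uptake):
        inc = float(incorporation.get(aa, 0.0))
        upt = float(uptake.get(aa, 0.0))
        if inc < 0 or upt < 0:
            raise ValueError(f"negative rate for {aa!r}")
        if inc == 0.0 and upt == 0.0:
            continue
        if upt == 0.0 or inc / upt >= 1.0:
            out[aa] = "synthesis"
        else:
            out[aa] = "degradation"
    return out


# ---------------------------------------------------------------------------
# elemental balance matrix
# ---------------------------------------------------------------------------

def degree_of_reduction(formula: Mapping[str, float]) -> float:
    """Electrons available per unit on combustion to CO2, H2O and NH3:
    4C + H - 2O - 3N."""
    return (
        4.0 * formula.get("C", 0.0)
        + formula.get("H", 0.0)
        - 2.0 * formula.get("O", 0.0)
        - 3.0 * formula.get("N", 0.0)
    )


def elemental_balance_matrix(
    model: StoichiometricModel,
    elements: Sequence[str] = ("C", "N"),
    biomass_composition: BiomassComposition | None = None,
) -> pd.DataFrame:
    """Element x exchange-reaction matrix ``E``: atoms of each element carried
    out of the system per unit flux of each boundary reaction.

    ``elements`` may include ``"gamma"`` for the degree-of-reduction balance.
    The biomass column is derived from the assembled biomass reaction
    (precursor bookkeeping), which makes carbon closure of any flux vector
    with ``N v = 0`` exact; ``biomass_composition`` supplies the H and O
    subscripts needed only for the gamma row.
    """
    cols = model.exchange_ids
    E = pd.DataFrame(0.0, index=list(elements), columns=cols)
    for rxn_id in cols:
        rxn = model.reaction(rxn_id)
        if rxn.is_biomass:
            carbon = biomass_carbon_content(rxn, "C")
            nitrogen = biomass_carbon_content(rxn, "N")
            for e in elements:
                if e == "C":
                    E.loc[e, rxn_id] = carbon
                elif e == "N":
                    E.loc[e, rxn_id] = nitrogen
                elif e == "gamma":
                    comp = biomass_composition or BiomassComposition()
                    a, b, c = comp.elemental
                    E.loc[e, rxn_id] = carbon * (4.0 + a - 2.0 * b - 3.0 * c) / 1.0
                else:
                    E.loc[e, rxn_id] = 0.0
            continue
        ext = [
            (met_id, coef)
            for met_id, coef in rxn.stoichiometry.items()
            if model.metabolite(met_id).is_extracellular
        ]
        if not ext:
            raise ValueError(f"exchange reaction {rxn_id} moves no extracellular species")
        for met_id, coef in ext:
            met = model.metabolite(met_id)
            if not met.formula or all(v == 0 for v in met.formula.values()):
                raise ValueError(f"exchanged species {met_id!r} has no formula")
            for e in elements:
                carried = degree_of_reduction(met.formula) if e == "gamma" else met.atoms(e)
                E.loc[e, rxn_id] += coef * carried
    return E


# ---------------------------------------------------------------------------
# feed media
# ---------------------------------------------------------------------------

#: Stage presets: amino-acid rescaling of the synthetic must emulating the
#: nitrogen depletion along a wine fermentation (stage II/early III feed: no
#: ammonium, 70% amino acids; late III: no ammonium, 40% amino acids).
FEED_PRESETS: dict[str, tuple[float, bool]] = {
    "stage_I": (1.0, True),
    "stage_II_earlyIII": (0.70, False),
    "late_III": (0.40, False),
}


def make_feed(preset: str, base_recipe: FeedMedium) -> FeedMedium:
    """Derive a stage feed from the base synthetic must: every amino acid is
    scaled by the preset factor (uniformly — individual consumption rates are
    deliberately not tracked), ammonium is zeroed when absent from the preset,
    and proline stays in the recipe but flagged non-assimilable."""
    if preset == "custom":
        return base_recipe.copy()
    try:
        scale, ammonium = FEED_PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown feed preset {preset!r}") from None
    feed = base_recipe.copy()
    for comp_id, entry in feed.components.items():
        role = entry.get("role")
        if role == "amino_acid":
            entry["amount"] = entry["amount"] * scale
        elif role == "ammonium" and not ammonium:
            entry["amount"] = 0.0
    feed.amino_acid_scale = base_recipe.amino_acid_scale * scale
    feed.ammonium_present = ammonium and base_recipe.ammonium_present
    feed.stage_preset = preset
    return feed
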