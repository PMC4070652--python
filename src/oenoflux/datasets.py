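"""Loaders for the data shipped with the package: the reconstructed anaerobic
wine-yeast network, a default biomass composition, the synthetic-must feed
recipe, and the published steady-state / batch-phase specific-rate tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .network import (
    BiomassComposition,
    FeedMedium,
    StoichiometricModel,
    build_biomass_reaction,
    build_matrix,
    check_element_balance,
    load_reaction_network,
)
from .rates import RateVector

__all__ = [
    "STAGES",
    "data_path",
    "load_biomass_composition",
    "load_feed_recipe",
    "load_wine_model",
    "load_chemostat_rates",
    "load_batch_ranges",
]

#: fermentation stage -> dilution rate of the chemostat emulating it (h^-1)
STAGES: dict[str, float] = {"I": 0.27, "II": 0.04, "earlyIII": 0.02, "lateIII": 0.007}

_DATA = Path(__file__).parent / "data"


def data_path(name: str) -> Path:
    return _DATA / name


def load_biomass_composition(path: str | Path | None = None) -> BiomassComposition:
    raw = yaml.safe_load(Path(path or data_path("biomass.yaml")).read_text())
    e = raw["elemental"]
    return BiomassComposition(
        elemental=(float(e["a"]), float(e["b"]), float(e["c"])),
        macromolecular={k: float(v) for k, v in raw["macromolecular"].items()},
        amino_acid_fractions={k: float(v) for k, v in raw["amino_acid_fractions"].items()},
        molar_mass_per_cmol=float(raw["molar_mass_per_cmol"]),
    )


def load_feed_recipe(path: str | Path | None = None) -> FeedMedium:
    raw = yaml.safe_load(Path(path or data_path("feed_medium.yaml")).read_text())
    return FeedMedium(
        components=raw["components"],
        amino_acid_scale=float(raw.get("amino_acid_scale", 1.0)),
        ammonium_present=bool(raw.get("ammonium_present", True)),
        stage_preset=raw.get("stage_preset", "custom"),
    )


def load_wine_model(
    biomass: BiomassComposition | None = None,
    anaerobic: bool = True,
) -> StoichiometricModel:
    """The assembled central-carbon model: packaged network + biomass reaction
    from ``biomass`` (default composition if omitted), element-balance
    checked, with the anaerobic succinyl-CoA synthetase constraint applied
    and the amino-acid degradation shunts pinned to zero (re-enable them via
    pathway selection when uptake exceeds incorporation)."""
    from .mfa import apply_anaerobic_constraints

    comp = biomass or load_biomass_composition()
    model = load_reaction_network(data_path("reactions.txt"), data_path("metabolites.tsv"))
    model.add_reaction(build_biomass_reaction(comp))
    build_matrix(model)
    check_element_balance(model, elements=("C", "N"), tol=1e-9)
    model.constrained_zero_ids |= {"GLUD", "ARGD"}
    if anaerobic:
        model = apply_anaerobic_constraints(model)
        build_matrix(model)
    return model


def load_chemostat_rates(
    stage_or_D: str | float,
    nd_detection_limit: float = 0.01,
    path: str | Path | None = None,
) -> RateVector:
    """Steady-state rate vector of one chemostat condition.

    ``n.d.`` (below detection) entries are information, not gaps: they enter
    as measured zero with sd = detection limit / 2, which keeps the
    redundancy of the measurement set intact."""
    D = STAGES[stage_or_D] if isinstance(stage_or_D, str) else float(stage_or_D)
    df = pd.read_csv(path or data_path("chemostat_rates.tsv"), sep="\t")
    sub = df[df["dilution_rate_h"] == D]
    if sub.empty:
        raise KeyError(f"no packaged rates at D = {D} h^-1")
    rates: dict[str, float] = {}
    sds: dict[str, float] = {}
    for row in sub.itertuples(index=False):
        if str(row.rate_mmol_gDCW_h).strip() == "n.d.":
            rates[row.species] = 0.0
            sds[row.species] = nd_detection_limit / 2.0
        else:
            rates[row.species] = float(row.rate_mmol_gDCW_h)
            sds[row.species] = float(row.sd_mmol_gDCW_h)
    label = f"D={D:g} h^-1"
    return RateVector(rates=rates, sd=sds, mu=D, condition_label=label)


def load_batch_ranges(stage: str, path: str | Path | None = None):
    """Batch-phase rate envelopes: ``(window, {species: (q_min, q_max)})``."""
    df = pd.read_csv(path or data_path("batch_ranges.tsv"), sep="\t")
    sub = df[df["stage"] == stage]
    if sub.empty:
        raise KeyError(f"unknown batch stage {stage!r}")
    window = (float(sub["window_start_h"].iloc[0]), float(sub["window_end_h"].iloc[0]))
    ranges = {
        row.species: (float(row.q_min), float(row.q_max))
        for row in sub.itertuples(index=False)
    }
    return window, ranges
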