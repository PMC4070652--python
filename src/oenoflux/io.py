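"""Readers and writers for the pipeline's tabular formats, plus the run
configuration.  All outputs are TSV/JSON/YAML; every file written carries a
provenance header (tool version, configuration hash, seed)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .network import BiomassComposition  # noqa: F401 (re-exported reader type)
from .rates import RateVector

__all__ = [
    "PipelineConfig",
    "read_rate_table",
    "write_rate_table",
    "read_biomass",
    "write_flux_map",
    "provenance_header",
]

#: rate column headers accepted as mmol/gDCW/h
_RATE_UNITS = {"mmol/gDCW/h", "mmol_gDCW_h", "mmol gDCW-1 h-1"}

#: flux-map column order follows the fermentation sequence of dilution rates
FLUX_MAP_ORDER = (0.27, 0.04, 0.02, 0.007)


@dataclass
class PipelineConfig:
    """Validated run configuration.  Unknown keys in a YAML file are
    rejected; the resolved configuration is written next to the outputs so a
    run can be reproduced from its artifacts alone."""

    rates_path: str = ""
    biomass_path: str = ""
    output_dir: str = "results"
    stage: str = "II"
    significance: float = 0.05
    noise_floor_cv: float = 0.05
    nd_detection_limit: float = 0.01
    constraint_elements: tuple[str, ...] = ("C", "N", "gamma")
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.significance < 1.0:
            raise ValueError("significance must lie in (0, 1)")
        if self.noise_floor_cv < 0:
            raise ValueError("noise_floor_cv must be nonnegative")
        self.constraint_elements = tuple(self.constraint_elements)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance_header(config: PipelineConfig | None = None, seed: int | None = None) -> str:
    parts = [f"oenoflux {__version__}"]
    if config is not None:
        parts.append(f"config {config.digest}")
        seed = config.seed if seed is None else seed
    if seed is not None:
        parts.append(f"seed {seed}")
    return "# " + " | ".join(parts)


def read_rate_table(path: str | Path, mu: float = 0.0) -> RateVector:
    """Read a rate TSV (species, rate, sd).  The rate column header must
    declare mmol/gDCW/h — a concentration unit on a rate column is a hard
    error, not a warning."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.split("[")[0].strip(): c for c in df.columns}
    if "species" not in cols:
        raise ValueError(f"{path}: missing 'species' column")
    rate_col = sd_col = None
    for c in df.columns:
        base = c.split("[")[0].strip().lower()
        unit = c.split("[")[1].rstrip("]").strip() if "[" in c else None
        if base in ("rate", "rate_mmol_gdcw_h", "q"):
            if unit is not None and unit not in _RATE_UNITS:
                raise ValueError(f"{path}: unit {unit!r} is not a specific-rate unit")
            rate_col = c
        elif base in ("sd", "sd_mmol_gdcw_h"):
            sd_col = c
    if rate_col is None:
        raise ValueError(f"{path}: missing rate column")
    rates, sds = {}, {}
    for _, row in df.iterrows():
        species = row["species"]
        rates[species] = float(row[rate_col])
        if sd_col is not None:
            sds[species] = float(row[sd_col])
    return RateVector(rates=rates, sd=sds, mu=mu)


def write_rate_table(
    rv: RateVector,
    path: str | Path,
    config: PipelineConfig | None = None,
) -> Path:
    path = Path(path)
    lines = [provenance_header(config), "species\trate [mmol/gDCW/h]\tsd [mmol/gDCW/h]"]
    for s in rv.species:
        lines.append(f"{s}\t{rv.rates[s]:.12g}\t{rv.sd.get(s, 0.0):.12g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_biomass(path: str | Path) -> BiomassComposition:
    from .datasets import load_biomass_composition

    return load_biomass_composition(path)


def write_flux_map(
    flux_by_D: dict[float, pd.Series],
    path: str | Path,
    config: PipelineConfig | None = None,
) -> Path:
    """Flux-map TSV: one row per reaction, one column per dilution rate in
    the fermentation-sequence order 0.27, 0.04, 0.02, 0.007 h^-1."""
    path = Path(path)
    order = [d for d in FLUX_MAP_ORDER if d in flux_by_D]
    extra = [d for d in flux_by_D if d not in FLUX_MAP_ORDER]
    order += sorted(extra, reverse=True)
    reactions = list(flux_by_D[order[0]].index)
    lines = [
        provenance_header(config),
        "reaction\t" + "\t".join(f"D_{d:g}" for d in order),
    ]
    for rid in reactions:
        vals = "\t".join(f"{float(flux_by_D[d][rid]):.12g}" for d in order)
        lines.append(f"{rid}\t{vals}")
    path.write_text("\n".join(lines) + "\n")
    return path
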