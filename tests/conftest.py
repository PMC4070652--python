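import warnings

import numpy as np
import pytest
from hypothesis import settings

import oenoflux as of

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from oenoflux.network import Metabolite, Reaction, StoichiometricModel, build_matrix


@pytest.fixture(scope="session")
def wine_model():
    """Assembled anaerobic wine-yeast network with the default biomass."""
    return of.load_wine_model()


@pytest.fixture(scope="session")
def stage_rates():
    return {stage: of.load_chemostat_rates(stage) for stage in of.STAGES}


@pytest.fixture(scope="session")
def stage2_truth(wine_model):
    from oenoflux.simulate import generate_flux_state

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_flux_state(wine_model, "II")


@pytest.fixture
def chain_model():
    """A -> B -> C with A and C extracellular: one balanced metabolite."""
    model = StoichiometricModel()
    model.add_metabolite(Metabolite("a_e", compartment="extracellular", formula={"C": 1}))
    model.add_metabolite(Metabolite("b", compartment="cytosol", formula={"C": 1}))
    model.add_metabolite(Metabolite("c_e", compartment="extracellular", formula={"C": 1}))
    model.add_reaction(Reaction("UPT", {"a_e": -1.0, "b": 1.0}, reversible=True, pathway_tag="exchange"))
    model.add_reaction(Reaction("CONV", {"b": -1.0, "c_e": 1.0}, reversible=True, pathway_tag="exchange"))
    return build_matrix(model)


@pytest.fixture
def branch_model():
    """Branched toy: uptake a splits into products b and c (both measured)."""
    model = StoichiometricModel()
    for mid in ("a_e", "b_e", "c_e"):
        model.add_metabolite(Metabolite(mid, compartment="extracellular", formula={"C": 1}))
    for mid in ("a", "b", "c"):
        model.add_metabolite(Metabolite(mid, compartment="cytosol", formula={"C": 1}))
    model.add_reaction(Reaction("EX_a", {"a": -1.0, "a_e": 1.0}, reversible=True, pathway_tag="exchange"))
    model.add_reaction(Reaction("R1", {"a": -1.0, "b": 1.0}))
    model.add_reaction(Reaction("R2", {"a": -1.0, "c": 1.0}))
    model.add_reaction(Reaction("EX_b", {"b": -1.0, "b_e": 1.0}, reversible=True, pathway_tag="exchange"))
    model.add_reaction(Reaction("EX_c", {"c": -1.0, "c_e": 1.0}, reversible=True, pathway_tag="exchange"))
    return build_matrix(model)


@pytest.fixture(scope="session")
def toy_system():
    from oenoflux.simulate import generate_toy_truth

    return generate_toy_truth("II")


def rate_vector_from(ms):
    """MeasurementSet -> RateVector with growth split off (test helper)."""
    i = ms.names.index("biomass")
    rates = {n: r for n, r in zip(ms.names, ms.r_m) if n != "biomass"}
    sds = {n: s for n, s in zip(ms.names, ms.sd) if n != "biomass"}
    return of.RateVector(rates=rates, sd=sds, mu=float(ms.r_m[i]), mu_sd=float(ms.sd[i]))
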