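"""Flux solving, anaerobic constraints, normalization and stage summaries."""

import warnings

import numpy as np
import pytest

import oenoflux as of
from oenoflux.mfa import (
    apply_anaerobic_constraints,
    normalize_fluxes,
    reaction_carbon,
    solve_fluxes,
    stage_summaries,
)
from oenoflux.network import Metabolite, Reaction, StoichiometricModel, build_matrix
from oenoflux.rates import RateVector


class TestSolveFluxes:
    def test_linear_chain_conservation(self, chain_model):
        rv = RateVector(rates={"A": -10.0})
        fs = solve_fluxes(chain_model, rv, species_to_reaction={"A": "UPT"}, free_exchanges={"CONV"})
        # uptake written excretion-positive: flux -10 moves 10 units in,
        # which must leave through the conversion reaction
        assert fs["UPT"] == pytest.approx(-10.0)
        assert fs["CONV"] == pytest.approx(-10.0)  # b -> c_e carries the 10

    def test_branch_matches_hand_solved_system(self, branch_model):
        # rows b and c give R1 = q_b, R2 = q_c; row a is the surplus balance
        rv = RateVector(rates={"a": -10.0, "b": 6.0, "c": 4.0})
        fs = solve_fluxes(
            branch_model,
            rv,
            species_to_reaction={"a": "EX_a", "b": "EX_b", "c": "EX_c"},
            free_exchanges=set(),
        )
        assert fs["R1"] == pytest.approx(6.0)
        assert fs["R2"] == pytest.approx(4.0)
        assert fs.df == 1  # total balance a is redundant
        assert fs.h_flux == pytest.approx(0.0, abs=1e-16)

    def test_rank_deficiency_reports_directions(self, branch_model):
        # leaving both products free makes the split undetermined
        rv = RateVector(rates={"a": -10.0})
        with pytest.raises(ValueError, match="R1"):
            solve_fluxes(
                branch_model, rv, species_to_reaction={"a": "EX_a"}, free_exchanges={"EX_b", "EX_c"}
            )

    def test_published_rates_within_flux_consistency_bound(self, wine_model):
        # late-exponential chemostat data: flux-level consistency index stays
        # below the 95% chi-square bound at redundancy 4 (9.48)
        rv = of.load_chemostat_rates("II")
        fs = solve_fluxes(wine_model, rv)
        assert fs.h_flux < 9.48
        assert fs.df >= 1

    def test_balance_residual_and_constrained_zero(self, wine_model, stage_rates):
        for stage, rv in stage_rates.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fs = solve_fluxes(wine_model, rv)
            resid = np.abs(wine_model.N @ fs.v.to_numpy()).max()
            assert resid < 1e-6 * max(1.0, np.abs(fs.v).max())
            assert fs["SCS"] == 0.0

    def test_matches_normal_equations_oracle(self):
        # random full-rank toy networks, consistent measurements: the solver
        # reproduces the brute-force normal-equations solution to 1e-8
        rng = np.random.default_rng(31)
        for trial in range(5):
            n_met, n_rxn = 6, 9
            model = StoichiometricModel()
            for i in range(n_met):
                model.add_metabolite(Metabolite(f"m{i}", compartment="cytosol"))
            model.add_metabolite(Metabolite("x_e", compartment="extracellular"))
            N = np.round(rng.integers(-2, 3, size=(n_met, n_rxn)).astype(float))
            N[0, np.abs(N).sum(axis=0) == 0] = 1.0  # no all-zero columns
            for j in range(n_rxn):
                stoich = {f"m{i}": N[i, j] for i in range(n_met) if N[i, j] != 0}
                stoich["x_e"] = 1.0  # boundary species keeps rows unchanged
                model.add_reaction(Reaction(f"r{j}", stoich, reversible=True, pathway_tag="exchange"))
            build_matrix(model)
            if np.linalg.matrix_rank(model.N) < n_met:
                continue
            # consistent measured set: sample a null-space vector
            _, _, vt = np.linalg.svd(model.N)
            Z = vt[np.linalg.matrix_rank(model.N):].T
            v_true = Z @ rng.normal(size=Z.shape[1])
            measured = [0, 1, 2]
            free = [j for j in range(n_rxn) if j not in measured]
            if np.linalg.matrix_rank(model.N[:, free]) < len(free):
                continue
            rv = RateVector(rates={f"r{j}": float(v_true[j]) for j in measured})
            fs = solve_fluxes(
                model, rv, species_to_reaction={f"r{j}": f"r{j}" for j in measured},
                free_exchanges={f"r{j}" for j in free},
            )
            N_c = model.N[:, free]
            b = -model.N[:, measured] @ v_true[measured]
            oracle = np.linalg.solve(N_c.T @ N_c, N_c.T @ b)
            assert np.allclose(fs.v.to_numpy()[free], oracle, atol=1e-8)


class TestAnaerobicConstraints:
    def test_scs_flux_zero_in_solved_states(self, wine_model, stage_rates):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rv in stage_rates.values():
                assert solve_fluxes(wine_model, rv)["SCS"] == 0.0

    def test_idempotent(self, wine_model):
        twice = apply_anaerobic_constraints(wine_model)
        assert twice.constrained_zero_ids == wine_model.constrained_zero_ids

    def test_missing_reaction_rejected(self, chain_model):
        with pytest.raises(KeyError):
            apply_anaerobic_constraints(chain_model)

    def test_no_through_cycle_tca_mode(self, wine_model):
        # with succinyl-CoA synthetase pinned, the succinyl-CoA node forces
        # the oxidative branch to stop at 2-oxoglutarate: no null-space mode
        # carries flux around the full cycle
        rxn_ids = wine_model.reaction_ids
        n = len(rxn_ids)
        rows = [wine_model.N]
        for rid in wine_model.constrained_zero_ids:
            e = np.zeros(n)
            e[rxn_ids.index(rid)] = 1.0
            rows.append(e[None, :])
        A = np.vstack(rows)
        _, s, vt = np.linalg.svd(A)
        rank = int(np.sum(s > 1e-10 * s[0]))
        Z = vt[rank:].T
        for rid in ("SCS", "OGDH"):
            assert np.abs(Z[rxn_ids.index(rid)]).max() < 1e-10


class TestNormalization:
    def test_glucose_uptake_is_hundred_percent(self, wine_model, stage_rates):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fs = normalize_fluxes(wine_model, solve_fluxes(wine_model, stage_rates["II"]))
        assert abs(fs.v_normalized["EX_glc"]) == pytest.approx(100.0)

    def test_ethanol_carbon_fraction_arithmetic(self, wine_model):
        # equal molar ethanol production and glucose uptake -> 2/6 of the
        # glucose C-mol, i.e. 33.3%
        import pandas as pd
        from oenoflux.mfa import FluxState

        v = pd.Series(0.0, index=wine_model.reaction_ids)
        v["EX_glc"] = -6.0
        v["EX_etoh"] = 6.0
        fs = normalize_fluxes(wine_model, FluxState(v=v))
        assert fs.v_normalized["EX_etoh"] == pytest.approx(100 * 2.0 / 6.0)

    def test_scale_invariance(self, wine_model, stage_rates):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fs = normalize_fluxes(wine_model, solve_fluxes(wine_model, stage_rates["II"]))
            scaled = fs.v * 3.7
            from oenoflux.mfa import FluxState

            fs2 = normalize_fluxes(wine_model, FluxState(v=scaled))
        assert np.allclose(fs.v_normalized, fs2.v_normalized)

    def test_zero_glucose_rejected(self, wine_model):
        import pandas as pd
        from oenoflux.mfa import FluxState

        fs = FluxState(v=pd.Series(0.0, index=wine_model.reaction_ids))
        with pytest.raises(ValueError, match="glucose"):
            normalize_fluxes(wine_model, fs)


class TestStageSummaries:
    def test_glucose_shares_reproduce_stage_pattern(self, stage_rates):
        # onset of fermentation: ~90% of hexose carbon from glucose; at the
        # lowest dilution rate the share falls to ~60%
        s1 = stage_summaries(None, stage_rates["I"])
        s4 = stage_summaries(None, stage_rates["lateIII"])
        assert round(s1["glucose_share_pct"], -1) == 90.0
        assert round(s4["glucose_share_pct"], -1) == 60.0

    def test_equal_uptake_is_even_split(self):
        rv = RateVector(rates={"glucose": -3.0, "fructose": -3.0})
        assert stage_summaries(None, rv)["glucose_share_pct"] == pytest.approx(50.0)

    def test_zero_hexose_rejected(self):
        with pytest.raises(ValueError):
            stage_summaries(None, RateVector(rates={"glucose": 0.0, "fructose": 0.0}))

    def test_g6p_node_split_sums_to_hundred(self, wine_model, stage_rates):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rv in stage_rates.values():
                fs = solve_fluxes(wine_model, rv)
                s = stage_summaries(fs, rv, wine_model)
                if "glycolysis_share_pct" in s:
                    assert 0.0 <= s["glycolysis_share_pct"] <= 100.0
                    assert s["glycolysis_share_pct"] + s["oxPPP_share_pct"] == pytest.approx(100.0)

    def test_anaplerosis_is_main_oxaloacetate_source(self, wine_model, stage_rates):
        # pyruvate carboxylase exceeds any alternative route into
        # mitochondrial oxaloacetate in every solved stage
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rv in stage_rates.values():
                fs = solve_fluxes(wine_model, rv)
                assert fs["PYC"] > 0
                assert fs["PYC"] >= fs["OAAT"] - 1e-9  # transport feeds from PYC


def test_reaction_carbon_counts(wine_model):
    assert reaction_carbon(wine_model, "EX_glc") == 6.0
    assert reaction_carbon(wine_model, "EX_etoh") == 2.0
    assert reaction_carbon(wine_model, "BIOMASS") > 30.0  # mmol C per gDCW
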