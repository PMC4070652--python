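"""Network parsing, matrix assembly, biomass construction, pathway selection,
elemental bookkeeping and feed presets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oenoflux as of
from oenoflux.network import (
    AMINO_ACID_RESIDUES,
    BiomassComposition,
    NetworkParseError,
    biomass_carbon_content,
    build_biomass_reaction,
    build_matrix,
    check_element_balance,
    degree_of_reduction,
    elemental_balance_matrix,
    load_reaction_network,
    make_feed,
    parse_reaction_equation,
    select_amino_acid_pathways,
)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

class TestParsing:
    def test_single_reaction_file(self, tmp_path):
        f = tmp_path / "net.txt"
        f.write_text("ADH: acald + nadh -> etoh + nad\n")
        model = load_reaction_network(f)
        assert len(model.reactions) == 1
        assert len(model.metabolites) == 4
        rxn = model.reaction("ADH")
        assert rxn.stoichiometry == {"acald": -1.0, "nadh": -1.0, "etoh": 1.0, "nad": 1.0}
        assert not rxn.reversible

    def test_empty_file(self, tmp_path):
        f = tmp_path / "empty.txt"
        f.write_text("# nothing here\n\n")
        model = load_reaction_network(f)
        assert model.reactions == [] and model.metabolites == []

    def test_parse_error_names_line(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("# ok\nBAD: a + (b -> c\n")
        with pytest.raises(NetworkParseError, match="line 2"):
            load_reaction_network(f)

    def test_duplicate_reaction_id_rejected(self, tmp_path):
        f = tmp_path / "dup.txt"
        f.write_text("R1: a -> b\nR1: b -> c\n")
        with pytest.raises(NetworkParseError, match="duplicate"):
            load_reaction_network(f)

    def test_unknown_metabolite_against_declared_table(self, tmp_path):
        rxn = tmp_path / "net.txt"
        rxn.write_text("R1: a -> zz\n")
        met = tmp_path / "mets.tsv"
        met.write_text("id\tname\tC\tH\tO\tN\tcompartment\na\ta\t1\t0\t0\t0\tcytosol\n")
        with pytest.raises(NetworkParseError, match="zz"):
            load_reaction_network(rxn, met)

    @pytest.mark.parametrize(
        "line,reversible,coef",
        [
            ("R: 2 a -> b", False, -2.0),
            ("R: a <-> 3 b", True, -1.0),
        ],
    )
    def test_coefficients_and_reversibility(self, line, reversible, coef):
        rxn = parse_reaction_equation(line)
        assert rxn.reversible is reversible
        assert rxn.stoichiometry["a"] == coef


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

class TestBuildMatrix:
    def test_linear_chain_single_row(self, chain_model):
        # only B is balanced; UPT feeds it, CONV drains it
        assert chain_model.N.shape == (1, 2)
        assert chain_model.N.tolist() == [[1.0, -1.0]]

    def test_no_internal_metabolites(self, tmp_path):
        f = tmp_path / "net.txt"
        f.write_text("EX_a: a_e -> b_e\n")
        model = build_matrix(load_reaction_network(f))
        assert model.N.shape == (0, 1)

    def test_cycle_rank_matches_elimination_oracle(self, tmp_path):
        f = tmp_path / "net.txt"
        f.write_text("R1: a -> b\nR2: b -> c\nR3: c -> a\n")
        model = build_matrix(load_reaction_network(f))

        def gaussian_rank(M):
            M = M.astype(float).copy()
            rank = 0
            for col in range(M.shape[1]):
                pivot = None
                for row in range(rank, M.shape[0]):
                    if abs(M[row, col]) > 1e-12:
                        pivot = row
                        break
                if pivot is None:
                    continue
                M[[rank, pivot]] = M[[pivot, rank]]
                M[rank] /= M[rank, col]
                for row in range(M.shape[0]):
                    if row != rank and abs(M[row, col]) > 1e-12:
                        M[row] -= M[row, col] * M[rank]
                rank += 1
            return rank

        assert np.linalg.matrix_rank(model.N) == gaussian_rank(model.N) == 2

    def test_wine_model_element_balance(self, wine_model):
        # every internal reaction conserves C and N exactly
        assert check_element_balance(wine_model, elements=("C", "N"), tol=1e-9) == {}


# ---------------------------------------------------------------------------
# biomass reaction
# ---------------------------------------------------------------------------

class TestBiomassReaction:
    def test_pure_carbohydrate_composition(self):
        comp = BiomassComposition(
            macromolecular={"carbohydrate": 1.0},
            molar_mass_per_cmol=162.14 / 6.0,
        )
        rxn = build_biomass_reaction(comp, growth_atp=0.0)
        # 1 g of glucan polymerises from 1000/162.14 mmol anhydroglucose units
        assert rxn.stoichiometry["g6p"] == pytest.approx(-1000.0 / 162.14)
        assert rxn.stoichiometry["biomass"] == 1.0

    def test_zero_protein_has_no_amino_acids(self):
        comp = BiomassComposition(macromolecular={"carbohydrate": 0.5, "lipid": 0.1})
        rxn = build_biomass_reaction(comp, growth_atp=0.0)
        assert not set(rxn.stoichiometry) & set(AMINO_ACID_RESIDUES)

    def test_carbon_content_matches_elemental_bookkeeping(self):
        # protein + carbohydrate composition; expected carbon computed by an
        # independent hand ledger over the precursor coefficients
        aa = {"ala": 0.5, "ser": 0.5}
        comp = BiomassComposition(
            macromolecular={"protein": 0.5, "carbohydrate": 0.5},
            amino_acid_fractions=aa,
            molar_mass_per_cmol=26.0,
        )
        rxn = build_biomass_reaction(comp, growth_atp=0.0, elemental_tol=10.0)
        mean_res = 0.5 * (89.094 - 18.015) + 0.5 * (105.093 - 18.015)
        residues = 0.5 * 1000.0 / mean_res
        expected_c = residues * (0.5 * 3 + 0.5 * 3) + 0.5 * 1000.0 / 162.14 * 6
        assert biomass_carbon_content(rxn) == pytest.approx(expected_c, rel=1e-12)

    def test_declared_formula_consistency_check(self):
        comp = BiomassComposition(
            macromolecular={"carbohydrate": 1.0},
            molar_mass_per_cmol=162.14 / 6.0,  # exactly consistent
        )
        rxn = build_biomass_reaction(comp, growth_atp=0.0)
        assert biomass_carbon_content(rxn) == pytest.approx(comp.carbon_mmol_per_gdcw)

    def test_missing_precursor_entry(self):
        comp = BiomassComposition(macromolecular={"carbohydrate": 0.9})
        with pytest.raises(KeyError):
            build_biomass_reaction(comp, precursor_table={"lipid": {"lip": 1.0}})

    def test_amino_acid_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            BiomassComposition(amino_acid_fractions={"ala": 0.6, "ser": 0.3})


# ---------------------------------------------------------------------------
# amino-acid pathway selection
# ---------------------------------------------------------------------------

class TestPathwaySelection:
    @pytest.mark.parametrize(
        "inc,upt,expected",
        [
            (1.2, 1.0, "synthesis"),
            (0.5, 1.0, "degradation"),
            (1.0, 1.0, "synthesis"),   # the >= 1 boundary includes equality
            (0.3, 0.0, "synthesis"),   # no uptake at all
        ],
    )
    def test_ratio_rule(self, inc, upt, expected):
        assert select_amino_acid_pathways({"leu": inc}, {"leu": upt}) == {"leu": expected}

    def test_zero_both_omitted(self):
        assert select_amino_acid_pathways({"leu": 0.0}, {"leu": 0.0}) == {}

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            select_amino_acid_pathways({"leu": -0.1}, {"leu": 1.0})

    @given(
        rates=st.dictionaries(
            st.sampled_from(sorted(AMINO_ACID_RESIDUES)),
            st.tuples(
                st.floats(0, 10, allow_nan=False),
                st.floats(0, 10, allow_nan=False),
            ),
            min_size=1,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_pure_function_of_inputs(self, rates):
        inc = {aa: v[0] for aa, v in rates.items()}
        upt = {aa: v[1] for aa, v in rates.items()}
        forward = select_amino_acid_pathways(inc, upt)
        reversed_order = select_amino_acid_pathways(
            dict(reversed(list(inc.items()))), dict(reversed(list(upt.items())))
        )
        assert forward == reversed_order


# ---------------------------------------------------------------------------
# elemental balance matrix
# ---------------------------------------------------------------------------

class TestElementalMatrix:
    def test_exchange_carbon_counts(self, wine_model):
        E = elemental_balance_matrix(wine_model, elements=("C",))
        assert E.loc["C", "EX_glc"] == 6.0
        assert E.loc["C", "EX_etoh"] == 2.0
        assert E.loc["C", "EX_glyc"] == 3.0

    def test_carbon_closure_of_balanced_flux_modes(self, wine_model):
        # any v with N v = 0 conserves exchanged carbon exactly
        E = elemental_balance_matrix(wine_model, elements=("C", "N"))
        _, _, vt = np.linalg.svd(wine_model.N)
        rank = np.linalg.matrix_rank(wine_model.N)
        Z = vt[rank:].T
        rng = np.random.default_rng(11)
        cols = [wine_model.reaction_ids.index(rid) for rid in E.columns]
        for _ in range(5):
            v = Z @ rng.normal(size=Z.shape[1])
            closure = float(E.loc["C"].to_numpy() @ v[cols])
            assert abs(closure) < 1e-9 * max(1.0, np.abs(v).max())

    def test_degree_of_reduction_values(self):
        assert degree_of_reduction({"C": 6, "H": 12, "O": 6}) == 24.0
        assert degree_of_reduction({"C": 2, "H": 6, "O": 1}) == 12.0
        assert degree_of_reduction({"H": 3, "N": 1}) == 0.0

    def test_missing_formula_rejected(self, chain_model):
        chain_model.metabolites[0] = type(chain_model.metabolites[0])(
            id="a_e", name="a", formula={}, compartment="extracellular"
        )
        with pytest.raises(ValueError, match="formula"):
            elemental_balance_matrix(chain_model, elements=("C",))


# ---------------------------------------------------------------------------
# feed media
# ---------------------------------------------------------------------------

class TestFeedPresets:
    def test_stage_II_scales_arginine(self):
        base = of.load_feed_recipe()
        feed = make_feed("stage_II_earlyIII", base)
        assert feed.amount("arginine") == pytest.approx(0.70 * 245.0)
        assert feed.ammonium_present is False
        assert feed.amount("nh4cl") == 0.0

    def test_late_III_zeroes_ammonium(self):
        feed = make_feed("late_III", of.load_feed_recipe())
        assert feed.amount("nh4cl") == 0.0
        assert feed.amino_acid_scale == pytest.approx(0.40)

    def test_stage_I_is_identity(self):
        base = of.load_feed_recipe()
        feed = make_feed("stage_I", base)
        assert feed.components == base.components
        assert make_feed("stage_I", feed).components == base.components  # idempotent

    def test_scales_compose_multiplicatively(self):
        base = of.load_feed_recipe()
        nested = make_feed("late_III", make_feed("stage_II_earlyIII", base))
        for aa in base.amino_acids():
            assert nested.amount(aa) == pytest.approx(0.28 * base.amount(aa))
        assert nested.amino_acid_scale == pytest.approx(0.28)

    def test_proline_retained_but_non_assimilable(self):
        feed = make_feed("late_III", of.load_feed_recipe())
        assert feed.amount("proline") > 0
        assert feed.components["proline"].get("assimilable") is False

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="preset"):
            make_feed("stage_V", of.load_feed_recipe())

    def test_glucose_fructose_equal_in_presets(self):
        for preset in ("stage_I", "stage_II_earlyIII", "late_III"):
            feed = make_feed(preset, of.load_feed_recipe())
            assert feed.amount("glucose") == feed.amount("fructose")
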