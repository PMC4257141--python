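"""Model construction, parsing, derived constants and conservation laws."""

import io

import numpy as np
import pytest

from psfopt import (
    NetworkModel,
    ParameterVector,
    apply_parameters,
    conserved_moieties,
    derived_constants,
    load_default_model,
    load_model,
    mass_action_rhs,
    save_model,
    simulate,
)
from psfopt.network import ModelValidationError, ReactionParseError, parse_reaction

from conftest import model_from_text


class TestDefaultModel:
    def test_structure_counts(self, default_model):
        """The packaged compartment model: 23 reactions, 27 molecular species
        (Michaelis complexes excluded), 12 nonzero initial concentrations."""
        m = default_model
        assert len(m.reactions) == 23
        assert m.n_molecular_species == 27
        assert m.n_nonzero_initial == 12
        assert sum(s.is_michaelis_complex for s in m.species) == 14

    def test_atp_initial_concentration(self, default_model):
        i = default_model.species_index("ATP")
        assert default_model.species[i].initial_conc == 1e6

    def test_ligand_is_clamped(self, default_model):
        i = default_model.species_index("L")
        assert default_model.species[i].clamped

    def test_stoichiometric_prefixes_parsed(self, default_model):
        """'1PKA + 2cAMP' means one PKA holoenzyme binding two cAMP."""
        rxn = next(
            r for r in default_model.reactions
            if r.complex_species == "PKAr2c2cAMP2"
        )
        assert dict(rxn.reactants) == {"PKA": 1, "cAMP": 2}

    def test_pka_binding_flux_is_second_order_in_camp(self, default_model):
        """Forward flux of PKA + 2cAMP is kon*[PKA]*[cAMP]^2."""
        m = default_model
        state = np.zeros(m.n_species)
        state[m.species_index("PKA")] = 50.0
        state[m.species_index("cAMP")] = 200.0
        dy = mass_action_rhs(m, state)
        expected = 3.5e-8 * 50.0 * 200.0 ** 2
        i = m.species_index("PKAr2c2cAMP2")
        assert dy[i] == pytest.approx(expected, rel=1e-12)
        # two cAMP consumed per complex formed
        assert dy[m.species_index("cAMP")] == pytest.approx(-2 * expected, rel=1e-12)

    def test_round_trip_serialization(self, default_model, tmp_path):
        save_model(default_model, tmp_path / "r.tsv", tmp_path / "c.tsv")
        again = load_model(tmp_path / "r.tsv", tmp_path / "c.tsv")
        assert again == default_model
        save_model(again, tmp_path / "r2.tsv", tmp_path / "c2.tsv")
        assert (tmp_path / "r.tsv").read_text() == (tmp_path / "r2.tsv").read_text()
        assert (tmp_path / "c.tsv").read_text() == (tmp_path / "c2.tsv").read_text()


class TestParsing:
    def test_empty_reaction_table_is_valid(self):
        m = model_from_text(
            "reaction_string\tkon\tkoff\tkcat\n",
            "species\tconc0_nM\nX\t5\n",
            input_species="X", output_species="X",
        )
        assert m.reactions == []

    def test_ascii_arrows_accepted(self):
        rxn = parse_reaction("A + B <-> C -> D + E", 1.0, 2.0, 3.0)
        assert rxn.form == "catalytic"
        assert rxn.complex_species == "C"

    def test_parse_error_names_the_row(self):
        with pytest.raises(ReactionParseError, match="row 2"):
            model_from_text(
                "reaction_string\tkon\tkoff\tkcat\n"
                "A = B\t1\t1\t\n",
                "species\tconc0_nM\nA\t1\n",
            )

    def test_negative_rate_rejected(self):
        with pytest.raises(ModelValidationError, match="negative"):
            model_from_text(
                "reaction_string\tkon\tkoff\tkcat\n"
                "A + B <-> C\t-1\t1\t\n",
                "species\tconc0_nM\nA\t1\n",
            )

    def test_rate_pattern_enforced_per_form(self):
        # a conversion must not carry kon/koff
        with pytest.raises(ReactionParseError):
            parse_reaction("A -> B", 1.0, None, 0.5)
        # a pure binding must not carry kcat
        with pytest.raises(ReactionParseError):
            parse_reaction("A + B <-> C", 1.0, 1.0, 0.5)


class TestRHS:
    def test_zero_state_gives_zero_derivative(self, default_model):
        dy = mass_action_rhs(default_model, np.zeros(default_model.n_species))
        assert np.all(dy == 0)

    def test_clamped_species_has_zero_derivative(self, default_model):
        m = default_model
        state = m.initial_state()
        state[m.species_index("L")] = 100.0
        assert mass_action_rhs(m, state)[m.species_index("L")] == 0.0

    def test_wrong_length_state_rejected(self, default_model):
        with pytest.raises(ValueError, match="length"):
            mass_action_rhs(default_model, np.zeros(3))

    def test_jacobian_matches_finite_differences(self, default_model):
        m = default_model
        rng = np.random.default_rng(0)
        y = rng.uniform(0.5, 100.0, m.n_species)
        J = m.jac(0.0, y)
        eps = 1e-6
        for k in rng.choice(m.n_species, 8, replace=False):
            yp = y.copy(); yp[k] += eps * max(1.0, y[k])
            col = (m.rhs(0.0, yp) - m.rhs(0.0, y)) / (eps * max(1.0, y[k]))
            assert np.allclose(J[:, k], col, rtol=1e-4, atol=1e-6)


class TestMoieties:
    def test_single_binding_has_two_conserved_totals(self):
        m = model_from_text(
            "reaction_string\tkon\tkoff\tkcat\nA + B <-> C\t0.001\t0.1\t\n",
            "species\tconc0_nM\nA\t10\nB\t20\n",
            input_species="X", output_species="C",
        )
        moi = conserved_moieties(m)
        sets = sorted(frozenset(mem.items()) for _, mem in moi)
        assert len(moi) == 2
        assert frozenset({"A": 1, "C": 1}.items()) in sets
        assert frozenset({"B": 1, "C": 1}.items()) in sets

    def test_clamped_open_chain_not_conserved(self):
        # clamped input A feeds an open conversion chain: nothing to conserve
        m = model_from_text(
            "reaction_string\tkon\tkoff\tkcat\nA -> B\t\t\t0.1\n",
            "species\tconc0_nM\nA\t10\n",
            input_species="A", output_species="B",
        )
        assert conserved_moieties(m) == []

    def test_rgs_moiety_constant_on_trajectory(self, default_model):
        m = default_model
        traj = simulate(m, clamp=100.0, t_end=500.0)
        total = (
            traj.series("RGS") + traj.series("RGSGsaGTP") + traj.series("RGSGiGTP")
        )
        assert np.max(np.abs(total - total[0])) / total[0] < 1e-6

    def test_all_moieties_constant_on_trajectory(self, default_model):
        """Every left-null-space relation is conserved to <1e-6 relative."""
        m = default_model
        traj = simulate(m, clamp=250.0, t_end=800.0)
        for label, members in conserved_moieties(m):
            total = sum(w * traj.series(n) for n, w in members.items())
            scale = max(abs(total[0]), 1.0)
            assert np.max(np.abs(total - total[0])) / scale < 1e-6, label


class TestParameters:
    def test_identity_round_trip(self, default_model):
        pv = ParameterVector.from_model(default_model, "both")
        assert apply_parameters(default_model, pv) == default_model

    def test_doubling_kon_touches_only_kon(self, default_model):
        pv = ParameterVector.from_model(default_model, "rates_only")
        keys = pv.keys()
        mult = np.array([2.0 if k[2] == "kon" else 1.0 for k in keys])
        m2 = apply_parameters(default_model, pv.scaled(mult))
        for r1, r2 in zip(default_model.reactions, m2.reactions):
            if r1.kon is not None:
                assert r2.kon == pytest.approx(2 * r1.kon)
            assert r2.koff == r1.koff
            assert r2.kcat == r1.kcat

    def test_knockdown_concentration(self, default_model):
        pv = ParameterVector({("conc", "RGS", "conc0"): 10.0})
        m2 = apply_parameters(default_model, pv)
        assert m2.species[m2.species_index("RGS")].initial_conc == 10.0
        assert default_model.species[
            default_model.species_index("RGS")
        ].initial_conc == 100.0

    def test_nonpositive_value_rejected(self, default_model):
        with pytest.raises(ModelValidationError):
            apply_parameters(
                default_model, ParameterVector({("conc", "RGS", "conc0"): 10.0})
                .with_values(np.array([0.0]))
            )

    def test_log_view_round_trips(self, default_model):
        pv = ParameterVector.from_model(default_model, "both")
        again = pv.with_log10_values(pv.log10_values)
        assert np.allclose(again.values, pv.values, rtol=1e-12)


class TestDerivedConstants:
    def test_receptor_kd(self, default_model):
        df = derived_constants(default_model).set_index("reaction_index")
        # b2 + L binding: Kd = 0.1/0.0003
        assert df.loc[0, "Kd_nM"] == pytest.approx(333.333, rel=1e-3)

    def test_rgs_km(self, default_model):
        df = derived_constants(default_model).set_index("reaction_index")
        # GsaGTP + RGS: KM = (1.2+16)/0.0008
        assert df.loc[4, "KM_nM"] == pytest.approx(21500.0, rel=1e-9)

    def test_km_equals_kd_without_kcat(self, default_model):
        df = derived_constants(default_model)
        binding = df[df["reaction"].str.contains("bARR")]
        assert np.allclose(binding["Kd_nM"], binding["KM_nM"])

    def test_one_row_per_kon_reaction(self, default_model):
        df = derived_constants(default_model)
        n_with_kon = sum(r.kon is not None for r in default_model.reactions)
        assert len(df) == n_with_kon == 21
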