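"""Bioenergetics: reaction balancing, dG, thresholds, partitioning, COD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect

from sipsyn import thermo
from sipsyn.thermo import (
    BUTYRATE_OXIDATION,
    ChemicalSpecies,
    EnvironmentalConditions,
    Reaction,
    balance_check,
    cod_per_gram,
    delta_g,
    methane_yield_mol,
    partition_energy,
    standard_delta_g,
    theoretical_methane_volume,
    threshold_activity,
)


class TestBalanceCheck:
    def test_butyrate_oxidation_balances(self, species_table):
        assert balance_check(BUTYRATE_OXIDATION, species_table)

    def test_missing_proton_breaks_charge(self, species_table):
        rxn = Reaction("bad", {"butyrate": -1, "H2O": -2, "acetate": 2, "H2": 2})
        assert not balance_check(rxn, species_table)

    def test_acetoclastic_methanogenesis_balances(self, species_table):
        # acetate- + H2O -> CH4 + HCO3-: C 2=2, H 5=5, O 3=3, charge -1=-1
        rxn = Reaction("aceticlastic", {"acetate": -1, "H2O": -1, "CH4": 1, "HCO3-": 1})
        assert balance_check(rxn, species_table)

    def test_unknown_species_raises(self, species_table):
        rxn = Reaction("ghost", {"unobtainium": -1})
        with pytest.raises(KeyError, match="unobtainium"):
            balance_check(rxn, species_table)


class TestStandardDeltaG:
    def test_butyrate_oxidation_thauer_values(self, species_table):
        # 2(-369.41) - (-352.63) - 2(-237.17) + RT ln 1e-7 = +48.2 kJ/mol
        expected = (
            2 * -369.41 - -352.63 - 2 * -237.17
            + thermo.R_KJ * 298.15 * math.log(1e-7)
        )
        assert standard_delta_g(BUTYRATE_OXIDATION, species_table) == pytest.approx(expected)
        assert round(standard_delta_g(BUTYRATE_OXIDATION, species_table), 1) == 48.2

    def test_empty_reaction_is_zero(self, species_table):
        assert standard_delta_g(Reaction("nil", {}), species_table) == 0.0

    def test_reverse_antisymmetry(self, species_table):
        fwd = standard_delta_g(BUTYRATE_OXIDATION, species_table)
        rev = standard_delta_g(BUTYRATE_OXIDATION.reversed(), species_table)
        assert fwd + rev == pytest.approx(0.0, abs=1e-12)

    def test_missing_formation_energy_raises(self, species_table):
        rxn = Reaction("cod_only", {"butyric_acid": -1})
        with pytest.raises(ValueError, match="dgf0_prime"):
            standard_delta_g(rxn, species_table)


class TestDeltaG:
    def test_bioreactor_conditions_give_minus_21(self, bioreactor_conditions):
        dg = delta_g(BUTYRATE_OXIDATION, 53.0, bioreactor_conditions)
        assert dg == pytest.approx(-21.2, abs=0.05)

    def test_unit_activities_recover_dg0(self):
        cond = EnvironmentalConditions(activities={"butyrate": 1.0, "acetate": 1.0, "H2": 1.0})
        assert delta_g(BUTYRATE_OXIDATION, 53.0, cond) == pytest.approx(53.0)

    def test_ten_millimolar_acetate(self, bioreactor_conditions):
        cond = bioreactor_conditions.with_activity("acetate", 1e-2)
        assert delta_g(BUTYRATE_OXIDATION, 53.0, cond) == pytest.approx(-9.8, abs=0.05)

    def test_affine_in_log_activity(self, bioreactor_conditions):
        """dG is affine in ln(activity) with slope nu*R*T for each species."""
        rt = thermo.R_KJ * bioreactor_conditions.temperature
        for sid, nu in (("acetate", 2), ("H2", 2), ("butyrate", -1)):
            acts = np.logspace(-6, -1, 7)
            dgs = [
                delta_g(BUTYRATE_OXIDATION, 53.0, bioreactor_conditions.with_activity(sid, a))
                for a in acts
            ]
            slopes = np.diff(dgs) / np.diff(np.log(acts))
            assert slopes == pytest.approx([nu * rt] * 6, rel=1e-9)

    def test_reverse_reaction_negates(self, bioreactor_conditions):
        fwd = delta_g(BUTYRATE_OXIDATION, 53.0, bioreactor_conditions)
        rev = delta_g(BUTYRATE_OXIDATION.reversed(), -53.0, bioreactor_conditions)
        assert fwd + rev == pytest.approx(0.0, abs=1e-9)

    def test_ph_deviation_enters_through_proton(self, bioreactor_conditions):
        cond6 = EnvironmentalConditions(pH=6.0, activities=dict(bioreactor_conditions.activities))
        shift = delta_g(BUTYRATE_OXIDATION, 53.0, cond6) - delta_g(
            BUTYRATE_OXIDATION, 53.0, bioreactor_conditions
        )
        # one proton produced: +RT ln 10 per pH unit below 7
        assert shift == pytest.approx(thermo.R_KJ * 298.15 * math.log(10), rel=1e-9)

    def test_missing_activity_names_species(self):
        cond = EnvironmentalConditions(activities={"butyrate": 1e-3})
        with pytest.raises(ValueError, match="acetate|H2"):
            delta_g(BUTYRATE_OXIDATION, 53.0, cond)


class TestThresholdActivity:
    def test_acetate_threshold_rounds_to_10_mM(self, bioreactor_conditions):
        a = threshold_activity(BUTYRATE_OXIDATION, 53.0, bioreactor_conditions, "acetate", -10.0)
        assert a * 1e3 == pytest.approx(9.6, abs=0.05)
        assert round(a * 1e3) == 10

    def test_fixed_point(self, bioreactor_conditions):
        current = delta_g(BUTYRATE_OXIDATION, 53.0, bioreactor_conditions)
        a = threshold_activity(
            BUTYRATE_OXIDATION, 53.0, bioreactor_conditions, "acetate", current
        )
        assert a == pytest.approx(1e-3, rel=1e-9)

    def test_inverse_property(self, bioreactor_conditions):
        a = threshold_activity(BUTYRATE_OXIDATION, 53.0, bioreactor_conditions, "H2", 0.0)
        cond = bioreactor_conditions.with_activity("H2", a)
        assert delta_g(BUTYRATE_OXIDATION, 53.0, cond) == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_bisection_oracle(self, bioreactor_conditions):
        def f(ln_a):
            cond = bioreactor_conditions.with_activity("H2", math.exp(ln_a))
            return delta_g(BUTYRATE_OXIDATION, 53.0, cond) - 0.0

        ln_a_oracle = bisect(f, -60, 10, xtol=1e-12)
        a = threshold_activity(BUTYRATE_OXIDATION, 53.0, bioreactor_conditions, "H2", 0.0)
        assert math.log(a) == pytest.approx(ln_a_oracle, abs=1e-6)

    def test_zero_coefficient_raises(self, bioreactor_conditions):
        with pytest.raises(ValueError, match="coefficient 0"):
            threshold_activity(BUTYRATE_OXIDATION, 53.0, bioreactor_conditions, "CH4", -10.0)


class TestPartitionEnergy:
    def test_butyrate_chain_shares(self):
        shares = partition_energy(
            [("acetogen", -21.1), ("h2_methanogen", -9.4), ("ac_methanogen", -58.9)]
        )
        assert 100 * shares["acetogen"] == pytest.approx(23.6, abs=0.05)
        assert round(100 * shares["acetogen"]) == 24
        assert 100 * shares["h2_methanogen"] == pytest.approx(10.5, abs=0.05)
        assert 100 * shares["ac_methanogen"] == pytest.approx(65.9, abs=0.05)

    def test_oleate_chain_acetogen_rounds_to_40(self):
        shares = partition_energy(
            [("acetogen", -219.9), ("h2_methanogen", -70.6), ("ac_methanogen", -264.9)]
        )
        assert 100 * shares["acetogen"] == pytest.approx(39.6, abs=0.05)
        assert round(100 * shares["acetogen"]) == 40

    def test_single_guild_gets_everything(self):
        assert partition_energy([("solo", -12.3)]) == {"solo": 1.0}

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=-500, max_value=-0.1), min_size=1, max_size=6))
    def test_fractions_sum_to_one(self, yields):
        shares = partition_energy([(f"g{i}", y) for i, y in enumerate(yields)])
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)

    def test_endergonic_component_rejected(self):
        with pytest.raises(ValueError, match="non-exergonic"):
            partition_energy([("a", -10.0), ("b", 0.5)])


class TestCOD:
    def test_butyric_acid(self, species_table):
        assert cod_per_gram(species_table["butyric_acid"]) == pytest.approx(1.816, abs=0.002)
        assert round(cod_per_gram(species_table["butyric_acid"]), 2) == 1.82

    def test_methane(self, species_table):
        assert cod_per_gram(species_table["CH4"]) == pytest.approx(3.99, abs=0.01)

    def test_co2_fully_oxidized(self, species_table):
        assert cod_per_gram(species_table["CO2"]) == 0.0

    def test_unsupported_element_raises(self):
        sp = ChemicalSpecies("thiol", "CH4S", 0)
        with pytest.raises(NotImplementedError):
            cod_per_gram(sp)

    @pytest.mark.parametrize("species_id", ["butyric_acid", "acetic_acid", "oleic_acid"])
    def test_cod_conserved_through_methanization(self, species_table, species_id):
        """The CH4 from complete methanization carries the substrate's COD."""
        sub = species_table[species_id]
        ch4 = species_table["CH4"]
        cod_substrate = cod_per_gram(sub) * sub.molar_mass  # g O2 per mol substrate
        mol_ch4 = methane_yield_mol(sub)
        cod_methane = cod_per_gram(ch4) * ch4.molar_mass * mol_ch4
        assert cod_methane == pytest.approx(cod_substrate, rel=1e-12)


class TestMethaneVolume:
    def test_forty_millimolar_butyrate_at_35C(self, species_table):
        v = theoretical_methane_volume(0.040, 0.010, species_table["butyric_acid"], 308.15)
        assert v == pytest.approx(25.3, abs=0.05)

    def test_zero_concentration(self, species_table):
        assert theoretical_methane_volume(0.0, 0.010, species_table["butyric_acid"]) == 0.0

    def test_ideal_gas_temperature_scaling(self, species_table):
        v35 = theoretical_methane_volume(0.040, 0.010, species_table["butyric_acid"], 308.15)
        v0 = theoretical_methane_volume(0.040, 0.010, species_table["butyric_acid"], 273.15)
        assert v0 == pytest.approx(v35 * 273.15 / 308.15, rel=1e-12)
        assert v0 == pytest.approx(22.4, abs=0.05)

    def test_negative_volume_rejected(self, species_table):
        with pytest.raises(ValueError):
            theoretical_methane_volume(0.040, -0.010, species_table["butyric_acid"])


class TestSpeciesTable:
    def test_tsv_round_trip(self, tmp_path, species_table):
        rows = ["id\tformula\tcharge\tdgf0_prime_kj_mol\tphase\tmolar_mass"]
        for sp in species_table.values():
            formula = "".join(
                f"{el}{n if n > 1 else ''}" for el, n in sorted(sp.formula.items())
            )
            dgf = "" if sp.dgf0_prime is None else repr(sp.dgf0_prime)
            rows.append(f"{sp.id}\t{formula}\t{sp.charge}\t{dgf}\t{sp.phase}\t{sp.molar_mass!r}")
        path = tmp_path / "species.tsv"
        path.write_text("\n".join(rows) + "\n")
        loaded = thermo.load_species_table(path)
        assert set(loaded) == set(species_table)
        for sid, sp in species_table.items():
            assert loaded[sid].formula == sp.formula
            assert loaded[sid].charge == sp.charge
            if sp.dgf0_prime is None:
                assert loaded[sid].dgf0_prime is None
            else:
                assert loaded[sid].dgf0_prime == pytest.approx(sp.dgf0_prime)

    def test_trophic_chain_intermediate_balance(self, species_table):
        acetogenesis = BUTYRATE_OXIDATION
        hydrogenotrophic = Reaction(
            "h2_methanogenesis",
            {"H2": -4, "HCO3-": -1, "H+": -1, "CH4": 1, "H2O": 3},
            guild="hydrogenotrophic_methanogen",
        )
        aceticlastic = Reaction(
            "aceticlastic",
            {"acetate": -1, "H2O": -1, "CH4": 1, "HCO3-": 1},
            guild="acetoclastic_methanogen",
        )
        assert balance_check(hydrogenotrophic, species_table)
        assert balance_check(aceticlastic, species_table)
        chain = thermo.TrophicChain(
            substrate="butyrate",
            reactions=[(acetogenesis, 1.0), (hydrogenotrophic, 0.5), (aceticlastic, 2.0)],
        )
        chain.validate_intermediates(species_table, ["H2", "acetate"])
        broken = thermo.TrophicChain(
            substrate="butyrate",
            reactions=[(acetogenesis, 1.0), (hydrogenotrophic, 0.5)],
        )
        with pytest.raises(ValueError, match="acetate"):
            broken.validate_intermediates(species_table, ["H2", "acetate"])
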