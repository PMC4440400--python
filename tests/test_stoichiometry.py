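"""Reaction builders: published coefficients, balance, linearity, round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sulfurox import (
    InadmissibleParameterError,
    RateSet,
    Stoichiometry,
    adjust_for_host,
    assimilation_equation,
    check_balance,
    energy_equation,
    overall_equation,
    ret_equation,
    solve_xy,
)

SUBSTRATE_TEA = [("sulfide", "aerobic"), ("sulfide", "denitrification"),
                 ("sulfide", "dnra"), ("thiosulfate", "aerobic"),
                 ("thiosulfate", "denitrification"), ("thiosulfate", "dnra")]


def assert_coefficients(stoich, expected, abs_tol=1e-9):
    for sp, nu in expected.items():
        assert stoich.coefficient(sp) == pytest.approx(nu, abs=abs_tol), sp
    extras = set(stoich.coefficients) - set(expected)
    assert not extras, f"unexpected species {extras}"


class TestEnergyEquation:
    def test_incomplete_sulfide_oxidation(self):
        """H2S + 0.5 O2 -> S0 + H2O."""
        assert_coefficients(energy_equation("sulfide", "aerobic", 1.0),
                            {"H2S": -1, "O2": -0.5, "S0": 1, "H2O": 1})

    def test_complete_sulfide_oxidation(self):
        """H2S + 2 O2 -> SO4^2- + 2 H+."""
        assert_coefficients(energy_equation("sulfide", "aerobic", 0.0),
                            {"H2S": -1, "O2": -2, "SO4": 1, "H+": 2})

    def test_generalized_sulfide_coefficients(self):
        """nu_O2 = 2 - 1.5x, nu_H2O = x, nu_H+ = 2 - 2x for arbitrary x."""
        x = 0.4
        assert_coefficients(energy_equation("sulfide", "aerobic", x),
                            {"H2S": -1, "O2": -(2 - 1.5 * x), "S0": x,
                             "SO4": 1 - x, "H2O": x, "H+": 2 - 2 * x})

    def test_sulfide_denitrification(self):
        """H2S + 1.6 NO3- -> SO4^2- + 0.8 N2 + 0.8 H2O + 0.4 H+."""
        assert_coefficients(energy_equation("sulfide", "denitrification", 0.0),
                            {"H2S": -1, "NO3": -1.6, "SO4": 1, "N2": 0.8,
                             "H2O": 0.8, "H+": 0.4})

    def test_sulfide_dnra_nitrate_coefficient(self):
        """DNRA consumes (8 - 6x)/8 nitrate per sulfide."""
        for x in (0.0, 0.5):
            eq = energy_equation("sulfide", "dnra", x)
            assert eq.coefficient("NO3") == pytest.approx(-(8 - 6 * x) / 8)
            assert eq.coefficient("NH4") == pytest.approx((8 - 6 * x) / 8)

    def test_thiosulfate_complete_oxidation(self):
        """S2O3^2- + 2 O2 + H2O -> 2 SO4^2- + 2 H+."""
        assert_coefficients(energy_equation("thiosulfate", "aerobic", 0.0),
                            {"S2O3": -1, "O2": -2, "H2O": -1, "SO4": 2, "H+": 2})

    @pytest.mark.parametrize("substrate,x", [("sulfide", 1.2), ("sulfide", -11),
                                             ("thiosulfate", 0.7)])
    def test_inadmissible_x_rejected(self, substrate, x):
        with pytest.raises(InadmissibleParameterError):
            energy_equation(substrate, "aerobic", x)

    def test_negative_x_means_stored_sulfur_consumption(self):
        eq = energy_equation("sulfide", "aerobic", -1.12)
        assert eq.coefficient("S0") == pytest.approx(-1.12)  # reactant
        assert eq.coefficient("SO4") == pytest.approx(2.12)


class TestAssimilationEquation:
    def test_incomplete(self):
        """H2S + 0.5 CO2 -> S0 + 0.5 CH2O + 0.5 H2O."""
        assert_coefficients(assimilation_equation("sulfide", 1.0),
                            {"H2S": -1, "CO2": -0.5, "S0": 1, "CH2O": 0.5,
                             "H2O": 0.5})

    def test_complete(self):
        """H2S + 2 CO2 + 2 H2O -> SO4^2- + 2 CH2O + 2 H+."""
        assert_coefficients(assimilation_equation("sulfide", 0.0),
                            {"H2S": -1, "CO2": -2, "H2O": -2, "SO4": 1,
                             "CH2O": 2, "H+": 2})

    def test_thiosulfate_complete(self):
        """S2O3^2- + 2 CO2 + 3 H2O -> 2 SO4^2- + 2 CH2O + 2 H+."""
        assert_coefficients(assimilation_equation("thiosulfate", 0.0),
                            {"S2O3": -1, "CO2": -2, "H2O": -3, "SO4": 2,
                             "CH2O": 2, "H+": 2})

    def test_co2_equals_organic_carbon(self):
        for x in (-0.5, 0.0, 0.3, 1.0):
            eq = assimilation_equation("sulfide", x)
            assert -eq.coefficient("CO2") == pytest.approx(eq.coefficient("CH2O"))


class TestRetEquation:
    def test_calvin_incomplete(self):
        """H2S + NAD+ -> S0 + NADH + H+."""
        assert_coefficients(ret_equation("sulfide", "calvin", 1.0),
                            {"H2S": -1, "NAD+": -1, "S0": 1, "NADH": 1, "H+": 1})

    def test_calvin_complete(self):
        """H2S + 4 NAD+ + 4 H2O -> SO4^2- + 4 NADH + 6 H+."""
        assert_coefficients(ret_equation("sulfide", "calvin", 0.0),
                            {"H2S": -1, "NAD+": -4, "H2O": -4, "SO4": 1,
                             "NADH": 4, "H+": 6})

    def test_rtca_incomplete(self):
        """0.5 NADH + 2/3 Fd_red + 1/6 FADH2 carry the two electrons at x = 1."""
        eq = ret_equation("sulfide", "rtca", 1.0)
        assert eq.coefficient("NADH") == pytest.approx(0.5)
        assert eq.coefficient("Fd_red") == pytest.approx(2 / 3)
        assert eq.coefficient("FADH2") == pytest.approx(1 / 6)
        assert eq.coefficient("H+") == pytest.approx(7 / 6)  # 1.17 when rounded

    def test_rtca_generalized_coefficients(self):
        """(2-1.5x) NADH, (8/3-2x) Fd_red, (2/3-x/2) FADH2 at arbitrary x."""
        x = 0.4
        eq = ret_equation("sulfide", "rtca", x)
        assert eq.coefficient("NADH") == pytest.approx(2 - 1.5 * x)
        assert eq.coefficient("Fd_red") == pytest.approx(8 / 3 - 2 * x)
        assert eq.coefficient("FADH2") == pytest.approx(2 / 3 - 0.5 * x)

    @pytest.mark.parametrize("substrate,pathway,x", [
        ("sulfide", "calvin", 0.0), ("sulfide", "rtca", 0.5),
        ("thiosulfate", "calvin", 0.3), ("thiosulfate", "rtca", 0.0),
    ])
    def test_carrier_electrons_match_substrate_yield(self, substrate, pathway, x):
        from sulfurox.stoichiometry import CARRIER_ELECTRONS, get_substrate
        eq = ret_equation(substrate, pathway, x)
        carried = sum(eq.coefficient(c) * n for c, n in CARRIER_ELECTRONS.items())
        assert carried == pytest.approx(get_substrate(substrate).electron_yield(x))


class TestOverallEquation:
    def test_published_beggiatoa_equation(self):
        """H2S + 1.65 O2 + 0.35 CO2 + 0.35 H2O -> SO4^2- + 0.35 CH2O + 2 H+."""
        assert_coefficients(overall_equation("sulfide", "aerobic", 0.0, 0.825),
                            {"H2S": -1, "O2": -1.65, "CO2": -0.35, "H2O": -0.35,
                             "SO4": 1, "CH2O": 0.35, "H+": 2})

    def test_published_tubeworm_symbiont_equation(self):
        """Stored S0 co-oxidation: 1.12 S0 consumed, 2.12 SO4^2- produced."""
        assert_coefficients(overall_equation("sulfide", "aerobic", -1.12, 0.375),
                            {"H2S": -1, "S0": -1.12, "O2": -1.38, "CO2": -2.3,
                             "H2O": -3.42, "SO4": 2.12, "CH2O": 2.3, "H+": 4.24},
                            abs_tol=1e-9)

    def test_pure_energy_limit(self):
        """y = 1 reduces the overall equation to the energy equation."""
        assert_coefficients(overall_equation("sulfide", "aerobic", 0.0, 1.0),
                            {"H2S": -1, "O2": -2, "SO4": 1, "H+": 2})

    def test_y_out_of_range(self):
        with pytest.raises(InadmissibleParameterError):
            overall_equation("sulfide", "aerobic", 0.0, 1.2)

    @given(x=st.floats(0, 1), y=st.floats(0, 1))
    @settings(derandomize=True, max_examples=50)
    def test_linearity_in_energy_and_assimilation(self, x, y):
        """Overall coefficients are the y : 1-y blend of the two halves."""
        overall = overall_equation("sulfide", "aerobic", x, y)
        energy = energy_equation("sulfide", "aerobic", x)
        assim = assimilation_equation("sulfide", x)
        for sp in set(overall.species()) | set(energy.species()) | set(assim.species()):
            blended = y * energy.coefficient(sp) + (1 - y) * assim.coefficient(sp)
            assert overall.coefficient(sp) == pytest.approx(blended, abs=1e-12)

    @given(x=st.floats(0, 1), y=st.floats(0.01, 1))
    @settings(derandomize=True, max_examples=50)
    def test_electron_conservation(self, x, y):
        """4 nu_O2 + 4 nu_CO2 = 8 - 6x for every aerobic sulfide equation."""
        eq = overall_equation("sulfide", "aerobic", x, y)
        electrons = 4 * abs(eq.coefficient("O2")) + 4 * abs(eq.coefficient("CO2"))
        assert electrons == pytest.approx(8 - 6 * x, abs=1e-9)


class TestBalance:
    @pytest.mark.parametrize("substrate,tea", SUBSTRATE_TEA)
    @pytest.mark.parametrize("x", [-0.8, 0.0, 0.3, 0.64])
    def test_every_builder_is_balanced(self, substrate, tea, x):
        for stoich in (energy_equation(substrate, tea, x),
                       assimilation_equation(substrate, x),
                       ret_equation(substrate, "calvin", x),
                       ret_equation(substrate, "rtca", x),
                       overall_equation(substrate, tea, x, 0.6)):
            report = check_balance(stoich)
            assert report.ok, (stoich.kind, report.residuals)
            assert report.max_residual < 1e-9

    def test_corrupted_coefficient_is_flagged(self):
        eq = energy_equation("sulfide", "aerobic", 0.0)
        coeffs = dict(eq.coefficients)
        coeffs["O2"] += 0.01
        report = check_balance(Stoichiometry(coefficients=coeffs,
                                             substrate="sulfide", kind="energy"))
        assert not report.ok
        assert report.residuals["O"] == pytest.approx(0.02)


class TestSolveXY:
    def test_beggiatoa_rate_ratios(self):
        x, y, _ = solve_xy(RateSet(ratios={"O2:H2S": 1.65, "CO2:H2S": 0.35}),
                           "sulfide", "aerobic")
        assert x == pytest.approx(0.0, abs=1e-12)
        assert y == pytest.approx(0.825, abs=1e-12)

    def test_symbiont_rate_ratios_negative_x(self):
        with pytest.warns(UserWarning, match="stored S0"):
            x, y, _ = solve_xy(RateSet(ratios={"O2:H2S": 1.38, "CO2:H2S": 2.3}),
                               "sulfide", "aerobic")
        assert x == pytest.approx(-1.12, abs=1e-12)
        assert y == pytest.approx(0.375, abs=1e-12)

    def test_no_fixation_limit(self):
        x, y, eq = solve_xy(RateSet(ratios={"O2:H2S": 2.0, "CO2:H2S": 0.0}),
                            "sulfide", "aerobic")
        assert (x, y) == (0.0, 1.0)
        assert eq.coefficient("O2") == pytest.approx(-2.0)

    def test_rates_instead_of_ratios(self):
        rates = RateSet(rates={"H2S": 6.75, "O2": 9.3, "CO2": 15.55})
        with pytest.warns(UserWarning):
            x, y, _ = solve_xy(rates, "sulfide", "aerobic")
        assert x == pytest.approx(-1.12, abs=5e-3)
        assert y == pytest.approx(0.375, abs=5e-3)

    @given(x=st.floats(-1.5, 0.99), y=st.floats(0.05, 0.95))
    @settings(derandomize=True, max_examples=60)
    def test_round_trip_from_overall_equation(self, x, y):
        """Ratios read off the overall equation recover (x, y) to 1e-12."""
        eq = overall_equation("sulfide", "aerobic", x, y)
        rateset = RateSet(ratios={"O2:H2S": eq.ratio("O2", "H2S"),
                                  "CO2:H2S": eq.ratio("CO2", "H2S")})
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            x2, y2, _ = solve_xy(rateset, "sulfide", "aerobic")
        assert x2 == pytest.approx(x, abs=1e-12)
        assert y2 == pytest.approx(y, abs=1e-12)

    def test_inconsistent_ratios_rejected(self):
        with pytest.raises(InadmissibleParameterError, match="y"):
            solve_xy(RateSet(ratios={"O2:H2S": 3.0, "CO2:H2S": -1.5}),
                     "sulfide", "aerobic")


class TestHostCorrection:
    def test_published_tubeworm_correction(self):
        """25% host O2 share: O2 12.4 -> 9.3, CO2 12.45 -> 15.55."""
        whole = RateSet(rates={"H2S": 6.75, "O2": 12.4, "CO2": 12.45})
        sym = adjust_for_host(whole, host_o2_fraction=0.25, respiratory_quotient=1.0)
        assert sym.rates["O2"] == pytest.approx(9.3)
        assert sym.rates["CO2"] == pytest.approx(15.55)
        assert sym.rates["H2S"] == pytest.approx(6.75)

    def test_zero_fraction_is_identity(self):
        whole = RateSet(rates={"O2": 10.0, "CO2": 3.0})
        sym = adjust_for_host(whole, 0.0)
        assert sym.rates == whole.rates

    def test_half_fraction_arithmetic(self):
        sym = adjust_for_host(RateSet(rates={"O2": 10.0, "CO2": 0.0}), 0.5, 1.0)
        assert sym.rates["O2"] == pytest.approx(5.0)
        assert sym.rates["CO2"] == pytest.approx(5.0)

    def test_fraction_out_of_range(self):
        with pytest.raises(InadmissibleParameterError):
            adjust_for_host(RateSet(rates={"O2": 1.0, "CO2": 1.0}), 1.0)


class TestRendering:
    def test_equation_text_moves_reactants_left(self):
        text = overall_equation("sulfide", "aerobic", 0.0, 0.825).to_text()
        assert text.startswith("H2S + 1.65 O2")
        assert "SO4^2-" in text.split("->")[1]

    def test_machine_readable_records(self):
        records = dict(energy_equation("sulfide", "aerobic", 1.0).to_records())
        assert records == {"H2S": -1.0, "O2": -0.5, "S0": 1.0, "H2O": 1.0}
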