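"""Rancimat induction-period kinetics: Arrhenius and Eyring fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oxikin import datasets
from oxikin.rancimat import (
    arrhenius_fit,
    eyring_fit,
    eyring_params,
    fit_from_line,
    rate_constants,
    slope_to_ea,
    to_kelvin,
)
from oxikin.simulate import DEFAULT_TEMPERATURES_K, generate_rancimat


def make_rates(ea=66.29, ln_a=20.55, sigma=0.0, seed=None, sample="synthetic"):
    ip = generate_rancimat(ea, ln_a, noise_sigma=sigma, seed=seed, sample=sample)
    return rate_constants(ip)


class TestRateConstants:
    @pytest.mark.parametrize("ip,expected_k", [(1.0, 1.0), (4.0, 0.25)])
    def test_reciprocal(self, ip, expected_k):
        df = pd.DataFrame(
            {"sample": ["s"], "temperature_K": [373.15], "ip_hours": [ip]})
        assert rate_constants(df)["k_per_hour"].iloc[0] == pytest.approx(expected_k)

    def test_non_positive_ip_names_row(self):
        df = pd.DataFrame({"sample": ["s", "s"], "temperature_K": [373.15, 383.15],
                           "ip_hours": [1.0, 0.0]})
        with pytest.raises(ValueError, match=r"rows: \[1\]"):
            rate_constants(df)

    def test_celsius_conversion(self):
        assert to_kelvin(100.0, "C") == pytest.approx(373.15)
        assert to_kelvin(373.15, "K") == pytest.approx(373.15)
        with pytest.raises(ValueError, match="'C' or 'K'"):
            to_kelvin(100.0, "F")


class TestSlopeToEa:
    # slopes of the published ln k vs 1000/T lines and the activation
    # energies they imply, kJ/mol
    @pytest.mark.parametrize("slope,ea", [
        (-6.085, 50.59),     # lipid alone
        (-7.9738, 66.29),    # with carnosic acid
        (-6.8938, 57.32),    # with TBHQ
        (0.0, 0.0),
    ])
    def test_published_slopes(self, slope, ea):
        assert slope_to_ea(slope) == pytest.approx(ea, abs=0.01)

    @given(st.floats(min_value=-100, max_value=100, allow_nan=False))
    def test_linear_and_odd(self, s):
        assert slope_to_ea(-s) == pytest.approx(-slope_to_ea(s), abs=1e-9)
        assert slope_to_ea(2 * s) == pytest.approx(2 * slope_to_ea(s), rel=1e-12, abs=1e-12)


class TestArrheniusFit:
    def test_noiseless_round_trip(self):
        """Exact inversion of the generating Arrhenius law."""
        fit = arrhenius_fit(make_rates(ea=66.29, ln_a=20.55), "synthetic")
        assert fit.ea_kj_mol == pytest.approx(66.29, abs=0.01)
        assert fit.ln_a == pytest.approx(20.55, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.method == "arrhenius"
        assert fit.delta_h_kj_mol is None  # only the matching pair is populated

    def test_two_points_exact_line(self):
        df = pd.DataFrame({"sample": ["s"] * 2, "temperature_K": [373.15, 403.15],
                           "ip_hours": [10.0, 2.0]})
        with pytest.warns(UserWarning, match="distinct temperatures"):
            fit = arrhenius_fit(rate_constants(df), "s")
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_single_temperature_rejected(self):
        df = pd.DataFrame({"sample": ["s"] * 2, "temperature_K": [373.15] * 2,
                           "ip_hours": [10.0, 9.0]})
        with pytest.raises(ValueError, match=">=2 distinct temperatures"):
            arrhenius_fit(rate_constants(df), "s")

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError, match="no rows"):
            arrhenius_fit(make_rates(), "missing")

    def test_noisy_recovery_is_accurate(self):
        """Mean recovered Ea over 200 noisy replicates is within 2% of truth."""
        truth = 66.29
        eas = []
        for seed in range(200):
            fit = arrhenius_fit(make_rates(ea=truth, sigma=0.05, seed=seed),
                                "synthetic")
            eas.append(fit.ea_kj_mol)
        assert np.mean(eas) == pytest.approx(truth, rel=0.02)


class TestEyringFit:
    # published ln(k/T) vs 1000/T lines and the activation parameters they
    # imply with the tabulated ln(kB/h) = 21.46
    @pytest.mark.parametrize("slope,intercept,dh,ds", [
        (-5.6975, 8.9535, 47.37, -103.95),   # lipid alone
        (-6.5083, 10.912, 54.11, -87.66),    # with TBHQ
        (-7.5879, 13.594, 63.09, -65.36),    # with carnosic acid
    ])
    def test_published_lines(self, slope, intercept, dh, ds):
        got_dh, got_ds = eyring_params(slope, intercept, ln_kb_over_h=21.46)
        assert got_dh == pytest.approx(dh, abs=0.01)
        assert got_ds == pytest.approx(ds, abs=0.1)

    def test_intercept_at_convention_gives_zero_entropy(self):
        _, ds = eyring_params(-5.0, 21.46, ln_kb_over_h=21.46)
        assert ds == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_fit_recovers_line(self):
        """ln(k/T) data generated from a known Eyring line is fitted exactly."""
        slope, intercept = -5.6975, 8.9535
        T = np.asarray(DEFAULT_TEMPERATURES_K)
        k = T * np.exp(slope * 1000.0 / T + intercept)
        rates = pd.DataFrame({"sample": "s", "temperature_K": T, "k_per_hour": k})
        fit = eyring_fit(rates, "s")
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert fit.delta_h_kj_mol == pytest.approx(47.37, abs=0.01)
        assert fit.delta_s_j_mol_k == pytest.approx(-103.98, abs=0.05)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.ea_kj_mol is None

    def test_fit_from_line_populates_matching_pair(self):
        fit = fit_from_line("s", "eyring", -6.5083, 10.912)
        assert fit.delta_h_kj_mol == pytest.approx(54.11, abs=0.01)
        assert fit.ln_a is None
        with pytest.raises(ValueError, match="method"):
            fit_from_line("s", "nonsense", 1.0, 1.0)


class TestPublishedLineTable:
    def test_activation_energy_ordering(self):
        """Both antioxidants raise the activation barrier; carnosic acid most."""
        lines = datasets.regression_lines("arrhenius").set_index("sample")
        ea = {s: slope_to_ea(lines.loc[s, "slope"]) for s in lines.index}
        assert ea["CA+OA"] > ea["TBHQ+OA"] > ea["OA"]
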