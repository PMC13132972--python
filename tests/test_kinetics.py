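"""ITC one-site fit, inhibition-mode classification, 4PL IC50, Cheng–Prusoff."""

import numpy as np
import pandas as pd
import pytest

from lysoscreen.kinetics import (
    DEFAULT_DOSE_GRID,
    ITCProtocol,
    cheng_prusoff,
    fit_ic50,
    fit_inhibition,
    fit_itc,
    four_parameter_logistic,
    itc_isotherm,
    mm_rate,
)
from lysoscreen.synthetic import (
    DEFAULT_GEN_I_GRID,
    gen_dose_response,
    gen_itc,
    gen_kinetics,
)


class TestITCProtocol:
    def test_defaults_match_titration_design(self):
        p = ITCProtocol()
        assert p.syringe_conc_um == 300.0 and p.cell_conc_um == 15.0
        assert p.cell_volume_ul == 300.0
        assert p.n_injections == 20  # 1 discardable + 19 x 2 uL
        assert p.injection_volumes_ul[0] == 0.2
        assert set(p.injection_volumes_ul[1:]) == {2.0}

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ITCProtocol(cell_conc_um=0.0)


class TestIsotherm:
    def test_no_binding_limit_heats_equal_offset(self):
        heats = itc_isotherm(1e8, 1.0, -10.0, dilution_offset_ucal=0.5)
        assert np.allclose(heats[1:], 0.5, atol=1e-3)

    def test_zero_enthalpy_gives_offset_only(self):
        heats = itc_isotherm(2.3, 1.0, 0.0, dilution_offset_ucal=0.7)
        assert np.allclose(heats, 0.7)

    def test_saturation_heats_approach_offset(self):
        heats = itc_isotherm(0.01, 1.0, -10.0, dilution_offset_ucal=0.5)
        assert abs(heats[-1] - 0.5) < 0.1

    def test_heat_conservation_at_saturation(self):
        """Total binding heat approaches N * [cell] * V0 * ΔH as titration saturates."""
        proto = ITCProtocol()
        n, dh = 1.0, -10.0
        heats = itc_isotherm(0.001, n, dh, proto)  # tight binding saturates fully
        total_ucal = heats.sum()
        # injection dilution removes a few percent of the loaded protein
        # before saturation, so the total sits just under the initial-moles bound
        expected = dh * (n * proto.cell_conc_um * 1e-6 * proto.cell_volume_ul * 1e-6) * 1e9
        assert total_ucal == pytest.approx(expected, rel=0.10)
        assert abs(total_ucal) < abs(expected)

    def test_nonphysical_parameters_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            itc_isotherm(-1.0, 1.0, -10.0)


class TestITCFit:
    def test_zero_noise_round_trip_exact(self):
        heats = itc_isotherm(2.30, 1.0, -10.0, dilution_offset_ucal=0.5)
        fit = fit_itc(heats)
        assert fit.converged and fit.identifiable
        assert fit.kd_um == pytest.approx(2.30, rel=1e-4)
        assert fit.n_sites == pytest.approx(1.0, rel=1e-4)
        assert fit.dh_kcal_mol == pytest.approx(-10.0, rel=1e-4)
        assert fit.dilution_offset_ucal == pytest.approx(0.5, rel=1e-3)

    def test_recovers_affinity_from_noisy_fixture(self):
        df, truth = gen_itc(kd_um=2.30, n_sites=1.0, noise=0.03, seed=1)
        fit = fit_itc(df["heat_ucal"].to_numpy())
        assert abs(fit.kd_um - truth["kd_um"]) / truth["kd_um"] < 0.15
        assert 0.9 <= fit.n_sites <= 1.1

    def test_buffer_only_control_flagged_unidentifiable(self):
        rng = np.random.default_rng(0)
        heats = 0.5 + 0.05 * rng.standard_normal(20)
        fit = fit_itc(heats)
        assert not fit.identifiable

    def test_too_few_injections_rejected(self):
        proto = ITCProtocol(injection_volumes_ul=(0.2,) + (2.0,) * 5)
        with pytest.raises(ValueError, match=">= 10"):
            fit_itc(np.zeros(6), proto)


class TestRateLaws:
    @pytest.mark.parametrize("mode", ["competitive", "noncompetitive", "uncompetitive"])
    def test_uninhibited_half_vmax_at_km(self, mode):
        assert mm_rate(25.0, 0.0, 25.0, 100.0, 10.0, mode) == pytest.approx(50.0)

    def test_competitive_hand_value(self):
        # v = 100*25 / (25*(1 + 10/10) + 25) = 2500/75
        assert mm_rate(25.0, 10.0, 25.0, 100.0, 10.0, "competitive") == pytest.approx(100.0 / 3.0)

    def test_competitive_apparent_km_shift_identity(self):
        km, ki, i = 25.0, 8.5, 12.0
        s = km * (1 + i / ki)
        assert mm_rate(s, i, km, 100.0, ki, "competitive") == pytest.approx(50.0)

    def test_competitive_vmax_invariance_at_high_substrate(self):
        v = mm_rate(1e7, 15.0, 25.0, 100.0, 8.5, "competitive")
        assert v == pytest.approx(100.0, rel=1e-3)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown inhibition mode"):
            mm_rate(25.0, 0.0, 25.0, 100.0, 10.0, "mixed")


class TestInhibitionFit:
    def test_generator_default_inhibitor_grid(self):
        assert DEFAULT_GEN_I_GRID == (10.0, 15.0)

    @pytest.mark.parametrize("mode", ["competitive", "noncompetitive", "uncompetitive"])
    def test_mode_classification_over_seeds(self, mode):
        """>= 95% correct mode calls at 3% noise on the default grids."""
        correct = 0
        for seed in range(20):
            rates, _ = gen_kinetics(mode=mode, i_grid=(0.0, 10.0, 15.0), noise=0.03, seed=seed)
            correct += fit_inhibition(rates).mode == mode
        assert correct >= 19

    def test_competitive_lb_intercepts_agree(self):
        """Double-reciprocal lines share the 1/v-axis intercept (constant
        Vmax); seed-averaged intercepts agree within 5% across [I]."""
        intercepts: dict[float, list[float]] = {}
        for seed in range(10):
            rates, _ = gen_kinetics(mode="competitive", i_grid=(0.0, 10.0, 15.0),
                                    noise=0.03, seed=seed)
            for lev, val in fit_inhibition(rates).lb_intercepts.items():
                intercepts.setdefault(lev, []).append(val)
        means = np.array([np.mean(v) for v in intercepts.values()])
        assert (means.max() - means.min()) / means.mean() < 0.05

    def test_competitive_apparent_km_rises_vmax_flat(self):
        rates, truth = gen_kinetics(mode="competitive", i_grid=(0.0, 10.0, 15.0),
                                    noise=0.02, seed=6)
        kms, vmaxes = [], []
        from scipy.optimize import curve_fit

        for lev, grp in rates.groupby("I_uM"):
            popt, _ = curve_fit(
                lambda s, km, vm: vm * s / (km + s),
                grp["S_uM"], grp["rate"], p0=[25.0, 100.0],
            )
            kms.append(popt[0]); vmaxes.append(popt[1])
        assert kms == sorted(kms)  # apparent Km increases with [I]
        assert (max(vmaxes) - min(vmaxes)) / np.mean(vmaxes) < 0.05

    def test_insufficient_grid_rejected(self):
        rates = pd.DataFrame({"S_uM": [25, 50, 100], "I_uM": [0, 0, 0], "rate": [1, 2, 3]})
        with pytest.raises(ValueError, match="inhibitor levels"):
            fit_inhibition(rates)

    def test_ki_recovered(self):
        rates, truth = gen_kinetics(mode="competitive", i_grid=(0.0, 10.0, 15.0),
                                    noise=0.02, seed=8)
        fit = fit_inhibition(rates)
        assert fit.ki_um == pytest.approx(truth["ki_um"], rel=0.25)
        assert fit.km_um == pytest.approx(truth["km_um"], rel=0.15)


class TestDoseResponse:
    def test_default_grid_has_ten_doses(self):
        assert len(DEFAULT_DOSE_GRID) == 10

    def test_midpoint_identity(self):
        resp = four_parameter_logistic(np.array([16.97]), 16.97, 1.3, 100.0, 10.0)
        assert resp[0] == pytest.approx(55.0)

    def test_zero_noise_round_trip(self):
        doses = np.array(DEFAULT_DOSE_GRID)
        resp = four_parameter_logistic(doses, 16.97, 1.0, 100.0, 0.0)
        fit = fit_ic50(doses, resp)
        assert fit.converged
        assert fit.ic50_um == pytest.approx(16.97, rel=1e-4)
        assert fit.hill == pytest.approx(1.0, rel=1e-4)

    def test_recovers_potency_from_noisy_fixture(self):
        df, truth = gen_dose_response(ic50_um=16.97, noise=0.05, replicates=5, seed=2)
        fit = fit_ic50(df["dose_uM"].to_numpy(), df["response"].to_numpy())
        assert abs(fit.ic50_um - truth["ic50_um"]) / truth["ic50_um"] < 0.10

    def test_too_few_dose_levels_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_ic50([0, 1, 10, 100], [100, 90, 50, 10])


class TestChengPrusoff:
    def test_zero_substrate_limit(self):
        assert cheng_prusoff(16.97, 0.0, 25.0) == pytest.approx(16.97)

    def test_relation(self):
        assert cheng_prusoff(16.97, 25.0, 25.0) == pytest.approx(16.97 / 2.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cheng_prusoff(-1.0, 25.0, 25.0)
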