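"""Mass-balance free-ligand solution, binding fits, thermodynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from albind.binding import (
    BindingFit,
    BindingSystem,
    compare_systems,
    fit_binding,
    fraction_bound,
    free_ligand,
    gibbs_free_energy,
    system_from_curve,
)
from albind.errors import DataError, FitError, InvariantError
from albind.quenching import build_quenching_curve
from albind.synth import simulate_titration
from tests.conftest import KD_AML_BINARY, KD_Q_BINARY


def bisection_free_ligand(l_total, p_total, k_d):
    """Independent oracle: bisection on the mass-balance residual."""
    if l_total == 0:
        return 0.0

    def residual(lf):
        # bound ligand implied by lf must close the ligand mass balance
        pl = p_total * lf / (lf + k_d)
        return lf + pl - l_total

    return brentq(residual, 0.0, l_total, xtol=1e-300, rtol=8.9e-16)


class TestFreeLigand:
    def test_no_protein_means_all_free(self):
        assert free_ligand(10e-6, 0.0, 1e-6) == pytest.approx(10e-6, rel=1e-12)

    def test_no_ligand_means_zero(self):
        assert free_ligand(0.0, 5e-6, 1e-6) == 0.0

    def test_against_bisection_oracle_at_study_conditions(self):
        value = free_ligand(10e-6, 5e-6, KD_Q_BINARY)
        oracle = bisection_free_ligand(10e-6, 5e-6, KD_Q_BINARY)
        assert value == pytest.approx(oracle, rel=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.floats(1e-9, 1e-2),
        st.floats(0.0, 1e-3),
        st.floats(1e-9, 1e-2),
    )
    def test_matches_bisection_oracle(self, l_total, p_total, k_d):
        value = free_ligand(l_total, p_total, k_d)
        oracle = bisection_free_ligand(l_total, p_total, k_d)
        assert value == pytest.approx(oracle, rel=1e-10, abs=1e-300)

    def test_satisfies_both_balance_equations(self):
        lt, pt, kd = 20e-6, 5e-6, 3e-6
        lf = free_ligand(lt, pt, kd)
        pl = lt - lf
        assert (pt - pl) * lf / pl == pytest.approx(kd, rel=1e-10)

    def test_negative_input_rejected(self):
        with pytest.raises(DataError):
            free_ligand(-1e-6, 5e-6, 1e-6)


class TestFractionBound:
    def test_zero_ligand_gives_zero(self):
        assert fraction_bound(0.0, 5e-6, 1e-6) == 0.0

    def test_half_saturation_at_free_ligand_equal_kd(self):
        kd, pt = 2e-6, 5e-6
        l_total = kd + pt / 2  # L_free = K_D exactly at 50% occupancy
        assert fraction_bound(l_total, pt, kd) == pytest.approx(0.5, rel=1e-10)

    def test_approaches_one_at_large_excess(self):
        kd = 1e-6
        assert fraction_bound(1e4 * kd, 5e-6, kd) > 0.999

    def test_monotone_in_l_total_and_affinity(self):
        lts = np.linspace(0, 50e-6, 40)
        occ = fraction_bound(lts, 5e-6, 2e-6)
        assert np.all(np.diff(occ) > 0)
        tighter = fraction_bound(lts[1:], 5e-6, 1e-6)
        assert np.all(tighter > occ[1:])

    def test_zero_protein_undefined(self):
        with pytest.raises(DataError):
            fraction_bound(1e-6, 0.0, 1e-6)


class TestFitBinding:
    @pytest.mark.parametrize("scenario_fixture, kd_true", [
        ("q_scenario_noise_free", KD_Q_BINARY),
        ("aml_scenario_noise_free", KD_AML_BINARY),
    ])
    def test_noise_free_recovery_within_0p1_percent(
        self, scenario_fixture, kd_true, request
    ):
        scenario = request.getfixturevalue(scenario_fixture)
        series = simulate_titration(scenario)
        curve = build_quenching_curve(series)
        fit = fit_binding(system_from_curve(curve, scenario.p_total))
        assert abs(fit.K_D - kd_true) / kd_true < 1e-3
        assert fit.ratio_at_saturation == pytest.approx(
            scenario.ratio_at_saturation, rel=1e-3
        )

    def test_halfway_point_equals_fitted_kd(self, q_scenario_noise_free):
        series = simulate_titration(q_scenario_noise_free)
        curve = build_quenching_curve(series)
        fit = fit_binding(system_from_curve(curve, q_scenario_noise_free.p_total))
        assert fit.free_ligand_at_half == pytest.approx(fit.K_D, rel=1e-2)

    def test_flat_signal_unidentifiable(self):
        system = BindingSystem(
            p_total=5e-6,
            l_totals=np.linspace(0, 50e-6, 8),
            signal_ratios=np.ones(8),
            temperature=310.15,
        )
        with pytest.raises(FitError):
            fit_binding(system)

    def test_too_few_points_rejected(self):
        system = BindingSystem(
            p_total=5e-6,
            l_totals=np.array([0.0, 1e-6, 2e-6, 4e-6]),
            signal_ratios=np.array([1.0, 0.9, 0.8, 0.7]),
            temperature=310.15,
        )
        with pytest.raises(FitError):
            fit_binding(system)

    def test_unsaturated_series_flagged(self):
        lts = np.linspace(0.0, 4e-6, 9)  # stops far below saturation
        ratios = 1.0 - 0.9 * np.array(
            [fraction_bound(lt, 5e-6, 50e-6) if lt else 0.0 for lt in lts]
        )
        system = BindingSystem(
            p_total=5e-6, l_totals=lts, signal_ratios=ratios, temperature=310.15
        )
        with pytest.warns(UserWarning, match="occupancy"):
            fit = fit_binding(system)
        assert not fit.saturation_reached


class TestGibbsFreeEnergy:
    # printed-table closure: K_D in mol/L at 310.15 K -> kJ/mol; agreement
    # is bounded by the rounding of the published K_D (±half-ulp) plus the
    # rounding of the published energy itself
    @pytest.mark.parametrize("kd_um, dg_printed", [
        (183.77, -22.181),
        (6.48, -30.807),
        (192.81, -22.057),
        (2.39, -33.379),
    ])
    def test_published_closure_within_print_rounding(self, kd_um, dg_printed):
        value = gibbs_free_energy(kd_um * 1e-6, 310.15)
        kd_rounding = 8.314 * 310.15 * (0.005 / kd_um) / 1000.0
        assert abs(value - dg_printed) <= kd_rounding + 0.0005

    def test_reference_concentration_gives_zero(self):
        assert gibbs_free_energy(1.0, 310.15) == 0.0
        assert gibbs_free_energy(1.0, 298.15) == 0.0

    def test_strictly_increasing_in_kd_and_sign(self):
        kds = np.logspace(-9, 1, 30)
        values = [gibbs_free_energy(k, 310.15) for k in kds]
        assert np.all(np.diff(values) > 0)
        assert all(v < 0 for k, v in zip(kds, values) if k < 1.0)
        assert all(v > 0 for k, v in zip(kds, values) if k > 1.0)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(DataError):
            gibbs_free_energy(0.0, 310.15)
        with pytest.raises(DataError):
            gibbs_free_energy(1e-6, 0.0)


def make_fit(kd, temperature=310.15):
    return BindingFit(
        K_D=kd,
        ratio_at_saturation=0.1,
        delta_g=gibbs_free_energy(kd, temperature),
        residual_norm=0.0,
        free_ligand_at_half=kd,
        temperature=temperature,
    )


class TestCompareSystems:
    def test_amlodipine_affinity_unchanged_by_quercetin(self):
        report = compare_systems(
            make_fit(183.77e-6), make_fit(192.81e-6), threshold=0.10
        )
        assert report.call == "unchanged"

    def test_quercetin_affinity_enhanced_by_amlodipine(self):
        report = compare_systems(make_fit(6.48e-6), make_fit(2.39e-6),
                                 threshold=0.10)
        assert report.call == "enhanced"
        assert report.ratio == pytest.approx(2.39 / 6.48, rel=1e-12)

    def test_identical_fits_unchanged_with_unit_ratio(self):
        report = compare_systems(make_fit(5e-6), make_fit(5e-6))
        assert report.call == "unchanged" and report.ratio == 1.0

    def test_weakened_call(self):
        assert compare_systems(make_fit(5e-6), make_fit(20e-6)).call == "weakened"

    def test_temperature_mismatch_rejected(self):
        with pytest.raises(DataError):
            compare_systems(make_fit(5e-6, 310.15), make_fit(5e-6, 298.15))
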