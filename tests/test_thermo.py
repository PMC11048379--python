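"""Effective-temperature conversion, rate/quotient calculus and extrapolations."""

import math
import warnings

import numpy as np
import pytest

from cidtherm.boltzmann import BoltzmannFit
from cidtherm.model import BreakdownModel
from cidtherm.synthetic import simulate_course, simulate_thermo_course, study_spec
from cidtherm.thermo import (
    TemperaturePoint,
    ThermoConfig,
    ThermoResult,
    arrhenius_extrapolate,
    consistency_report,
    cv_to_temperature,
    delta_g_from_kd,
    equilibrium_quotient,
    gibbs_helmholtz_extrapolate,
    steep_region_points,
    survival_to_rate,
)

from conftest import TABLE3

R = 8.31446261815324


class TestCvToTemperature:
    def test_zero_voltage_gives_t0(self, cfg):
        assert cv_to_temperature(0.0, 5, 9238.73, 1299, cfg) == cfg.t0

    def test_affine_in_voltage(self, cfg):
        t1 = cv_to_temperature(10.0, 5, 9238.73, 1299, cfg)
        t2 = cv_to_temperature(20.0, 5, 9238.73, 1299, cfg)
        assert (t2 - cfg.t0) == pytest.approx(2 * (t1 - cfg.t0), rel=1e-12)
        assert t2 > t1 > cfg.t0

    def test_hand_arithmetic(self, cfg):
        # centre-of-mass energy of n_coll collisions over 3N-6 modes, by hand
        e, kb = 1.602176634e-19, 1.380649e-23
        expected = cfg.t0 + (
            cfg.n_collisions * 5 * e * 17.03 * (39.948 / (39.948 + 9238.73))
        ) / ((3 * 1299 - 6) * kb)
        got = cv_to_temperature(17.03, 5, 9238.73, 1299, cfg)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_too_few_atoms_rejected(self, cfg):
        with pytest.raises(ValueError, match="atoms"):
            cv_to_temperature(10.0, 5, 100.0, 1, cfg)

    def test_pluggable_model(self):
        cfg = ThermoConfig(temperature_model=lambda dcv, z, m, n, c: c.t0 + 7.0 * dcv)
        assert cv_to_temperature(3.0, 5, 9238.73, 1299, cfg) == pytest.approx(321.0)


class TestSurvivalToRate:
    def test_full_survival_zero_rate(self, cfg):
        assert survival_to_rate(1.0, cfg) == 0.0

    def test_one_over_e(self):
        cfg = ThermoConfig(residence_time=1.0)
        assert survival_to_rate(math.exp(-1.0), cfg) == pytest.approx(1.0, rel=1e-12)

    def test_half_survival_hand_value(self, cfg):
        assert survival_to_rate(0.5, cfg) == pytest.approx(math.log(2) * 1e4, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_domain(self, bad, cfg):
        with pytest.raises(ValueError):
            survival_to_rate(bad, cfg)


class TestEquilibriumQuotient:
    @pytest.mark.parametrize(
        "t, d, m, expected",
        [(0.5, 0.25, 0.25, 0.125), (0.8, 0.1, 0.1, 0.0125), (0.5, 0.3, 0.0, 0.0)],
    )
    def test_examples(self, t, d, m, expected):
        assert equilibrium_quotient(t, d, m) == pytest.approx(expected, rel=1e-12)

    def test_zero_trimer_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_quotient(0.0, 0.5, 0.5)


def _points_from_arrhenius(a, ea, temps):
    pts = []
    for t in temps:
        k = a * math.exp(-ea / (R * t))
        pts.append(TemperaturePoint(dcv=0.0, t_eff=t, survival=0.5, k=k, keq=1.0))
    return pts


def _points_from_line(dh, ds, temps):
    pts = []
    for t in temps:
        keq = math.exp(-(dh - t * ds) / (R * t))
        pts.append(TemperaturePoint(dcv=0.0, t_eff=t, survival=0.5, k=1.0, keq=keq))
    return pts


class TestArrhenius:
    def test_exact_recovery(self, cfg):
        a, ea = 2.4e8, 7.4e4
        pts = _points_from_arrhenius(a, ea, np.linspace(700, 1000, 12))
        fit = arrhenius_extrapolate(pts, cfg)
        assert fit.ea == pytest.approx(ea, rel=1e-6)
        assert math.exp(fit.ln_a) == pytest.approx(a, rel=1e-6)
        assert fit.k_amb == pytest.approx(a * math.exp(-ea / (R * cfg.t_amb)), rel=1e-6)
        assert fit.line.r2 == pytest.approx(1.0, abs=1e-12)

    def test_flat_line_returns_prefactor(self, cfg):
        pts = _points_from_arrhenius(5.0e3, 0.0, np.linspace(400, 900, 5))
        fit = arrhenius_extrapolate(pts, cfg)
        assert fit.k_amb == pytest.approx(5.0e3, rel=1e-9)

    def test_singular_design_rejected(self, cfg):
        pts = _points_from_arrhenius(1e8, 5e4, [500.0, 500.0, 500.0])
        with pytest.raises(ValueError, match="singular"):
            arrhenius_extrapolate(pts, cfg)

    def test_too_few_points_rejected(self, cfg):
        with pytest.raises(ValueError, match=">= 3"):
            arrhenius_extrapolate(_points_from_arrhenius(1e8, 5e4, [500.0, 600.0]), cfg)


class TestGibbsHelmholtz:
    def test_exact_recovery_of_reference_row(self, cfg):
        """ΔH=3.32, TΔS=-62.29 kJ/mol regenerate ΔG(298)=65.61 kJ/mol."""
        dh = 3.32e3
        ds = -62.29e3 / 298.0
        pts = _points_from_line(dh, ds, np.linspace(300, 1000, 10))
        fit = gibbs_helmholtz_extrapolate(pts, cfg)
        assert fit.dh == pytest.approx(dh, rel=1e-9)
        assert cfg.t_amb * fit.ds == pytest.approx(-62.29e3, rel=1e-9)
        assert fit.dg_amb / 1e3 == pytest.approx(65.61, abs=0.005)

    def test_zero_entropy_constant_dg(self, cfg):
        pts = _points_from_line(5.0e4, 0.0, np.linspace(400, 800, 5))
        fit = gibbs_helmholtz_extrapolate(pts, cfg)
        assert fit.ds == pytest.approx(0.0, abs=1e-9)
        assert fit.dg_amb == pytest.approx(5.0e4, rel=1e-9)

    def test_single_temperature_rejected(self, cfg):
        pts = _points_from_line(5e4, -100.0, [600.0, 600.0, 600.0])
        with pytest.raises(ValueError, match="singular"):
            gibbs_helmholtz_extrapolate(pts, cfg)


class TestDeltaGFromKd:
    @pytest.mark.parametrize(
        "kd, expected", [(3.16e-12, 65.61), (3.58e-12, 65.30), (1.0, 0.0)]
    )
    def test_reference_values(self, kd, expected):
        assert delta_g_from_kd(kd, 298.0) == pytest.approx(expected, abs=0.005)

    def test_domain(self):
        with pytest.raises(ValueError):
            delta_g_from_kd(0.0, 298.0)
        with pytest.raises(ValueError):
            delta_g_from_kd(1.0, -1.0)


def _result(k, kd, dg, dh, tds):
    return ThermoResult(k_amb=k, kd_amb=kd, dg=dg, dh=dh, tds=tds, t_amb=298.0)


class TestConsistencyReport:
    def test_reference_row_one_passes(self):
        checks = consistency_report(_result(*TABLE3["I"][1:]))
        assert all(c.ok for c in checks)
        assert max(abs(c.deviation) for c in checks) <= 0.01

    def test_reference_row_four_flagged(self):
        # printed ΔH - TΔS = 65.69 vs printed ΔG = 65.68: rounding leak
        checks = consistency_report(_result(*TABLE3["IV"][1:]))
        by_name = {c.name: c for c in checks}
        flag = by_name["dg == dh - tds"]
        assert not flag.ok
        assert flag.deviation == pytest.approx(0.01, abs=2e-3)

    def test_perturbed_enthalpy_fails(self):
        k, kd, dg, dh, tds = TABLE3["I"][1:]
        checks = consistency_report(_result(k, kd, dg, dh + 1.0, tds))
        assert not all(c.ok for c in checks)


class TestSteepRegionPipeline:
    def test_steep_region_spans_10_to_90_percent(self, ions, proteoforms, cfg):
        fit = BoltzmannFit(100.0, 0.0, 17.0, 1.7)
        pts = steep_region_points(fit, ions["F-F-F"], proteoforms, cfg)
        fracs = [p.survival for p in pts]
        assert fracs[0] == pytest.approx(0.9, abs=1e-6)
        assert fracs[-1] == pytest.approx(0.1, abs=1e-6)
        temps = [p.t_eff for p in pts]
        assert all(b > a for a, b in zip(temps, temps[1:]))

    def test_noiseless_forward_model_recovery(self, ions, proteoforms, cfg):
        """Full-pipeline inversion of the thermodynamic forward model."""
        dh, ds = 1.6e5, -93.0
        course, truth = simulate_thermo_course(
            ions["F-F-F"], proteoforms, dh=dh, ds=ds, noise_sd=0.0
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = BreakdownModel(course, ions["F-F-F"], proteoforms, cfg).fit()
        assert res.thermo.dh * 1e3 == pytest.approx(dh, rel=2e-3)
        assert res.thermo.tds * 1e3 == pytest.approx(truth["tds_amb"], rel=2e-3)
        assert res.thermo.dg * 1e3 == pytest.approx(truth["dg_amb"], rel=2e-3)

    def test_sign_pattern_for_fixture_complexes(self, ions, proteoforms, cfg):
        """Endergonic, endothermic, entropy-disfavored dissociation throughout."""
        for symbol in ("F-F-F", "F-F-bF", "F-bF-bF", "bF-bF-bF"):
            course, _ = simulate_course(study_spec(symbol, noise_sd=0.0))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = BreakdownModel(course, ions[symbol], proteoforms, cfg).fit()
            t = res.thermo
            assert t.dg > 0 and t.dh > 0 and t.tds < 0
            assert 0 < t.kd_amb < 1
            assert all(c.ok for c in res.consistency())

    def test_internal_identities_of_pipeline_result(self, ions, proteoforms, cfg):
        course, _ = simulate_course(study_spec("F-F-F", noise_sd=0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = BreakdownModel(course, ions["F-F-F"], proteoforms, cfg).fit()
        t = res.thermo
        assert t.dg == pytest.approx(t.dh - t.tds, abs=0.02)
        assert t.dg == pytest.approx(delta_g_from_kd(t.kd_amb, t.t_amb), abs=0.02)

    def test_residence_time_scales_rate_only(self, ions, proteoforms):
        course, _ = simulate_course(study_spec("F-F-F", noise_sd=0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = BreakdownModel(course, ions["F-F-F"], proteoforms, ThermoConfig()).fit()
            r2 = BreakdownModel(
                course, ions["F-F-F"], proteoforms, ThermoConfig(residence_time=1e-3)
            ).fit()
        assert r2.thermo.k_amb == pytest.approx(r1.thermo.k_amb / 10.0, rel=1e-6)
        assert r2.thermo.dg == pytest.approx(r1.thermo.dg, rel=1e-9)
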