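"""Curve fitting (sigmoid, threshold-linear) and release-parameter calibration."""

import numpy as np
import pytest

from nmcirc import (
    BaselineTargets,
    CalibrationError,
    DoseResponseTable,
    ReleaseKineticsMM,
    SigmoidParams,
    SyntheticDoseResponseSpec,
    calibrate_release,
    fit_sigmoid,
    fit_threshold_linear,
    generate_dose_response,
    sigmoid_response,
)

from conftest import single_projection_circuit

TRUTH = SigmoidParams(lower=3.8, upper=54.0, shift=-2.3, slope=0.341)
#: Well-scaled benchmark for noisy recovery: both asymptotes are commensurate
#: with the response range, so a 5% per-parameter band is several standard
#: errors wide at n = 50 and 2%-of-range noise.  (The lower asymptote of
#: TRUTH is only ~8% of its range, which makes 5% of it a sub-sigma bound.)
BENCH = SigmoidParams(lower=20.0, upper=60.0, shift=-2.3, slope=0.341)


def _rel_errors(fit: SigmoidParams, truth: SigmoidParams):
    return {
        f: abs(getattr(fit, f) - getattr(truth, f)) / abs(getattr(truth, f))
        for f in ("lower", "upper", "shift", "slope")
    }


class TestFitSigmoid:
    def test_noiseless_self_consistency(self):
        data = generate_dose_response(SyntheticDoseResponseSpec(TRUTH, n_points=8))
        fit = fit_sigmoid(data)
        assert fit.converged and not fit.degenerate
        assert max(_rel_errors(fit.params, TRUTH).values()) < 1e-6

    def test_noisy_recovery_within_5_percent(self):
        sd = 0.02 * (BENCH.upper - BENCH.lower)
        data = generate_dose_response(
            SyntheticDoseResponseSpec(BENCH, n_points=50, noise_sd=sd, seed=0)
        )
        fit = fit_sigmoid(data)
        assert fit.converged
        assert max(_rel_errors(fit.params, BENCH).values()) < 0.05

    def test_constant_response_flagged_degenerate(self):
        c = np.logspace(-4, 0, 8)
        fit = fit_sigmoid(DoseResponseTable(c, np.full(8, 7.0)))
        assert fit.degenerate
        assert fit.params.lower == pytest.approx(fit.params.upper)

    def test_all_equal_concentrations_rejected(self):
        with pytest.raises(CalibrationError, match="unidentifiable"):
            fit_sigmoid(DoseResponseTable(np.full(6, 1.0), np.arange(6.0)))

    def test_too_few_points_rejected(self):
        with pytest.raises(CalibrationError, match=">= 4"):
            fit_sigmoid(DoseResponseTable(np.array([1.0, 2, 3]), np.zeros(3)))

    def test_scale_consistency_shift_plus_one(self):
        """x10 on all concentrations moves the recovered shift by exactly +1."""
        data = generate_dose_response(
            SyntheticDoseResponseSpec(TRUTH, n_points=20, noise_sd=0.5, seed=3)
        )
        fit1 = fit_sigmoid(data)
        fit2 = fit_sigmoid(DoseResponseTable(10 * data.concentrations, data.responses))
        assert fit2.params.shift - fit1.params.shift == pytest.approx(1.0, abs=1e-6)
        assert fit2.params.slope == pytest.approx(fit1.params.slope, rel=1e-6)

    def test_recovery_degrades_with_noise(self):
        """Mean slope-recovery error grows with the noise level."""
        rng_seeds = range(20)
        sds = [0.25, 1.0, 4.0]
        means = []
        for sd in sds:
            errs = []
            for seed in rng_seeds:
                data = generate_dose_response(
                    SyntheticDoseResponseSpec(TRUTH, n_points=25, noise_sd=sd, seed=seed)
                )
                fit = fit_sigmoid(data)
                errs.append(_rel_errors(fit.params, TRUTH)["slope"])
            means.append(np.mean(errs))
        assert means[0] < means[1] < means[2]


class TestFitThresholdLinear:
    def test_exact_recovery(self):
        # points on f = 0.2 * [I + 11.5]_+  (orexin-neuron f-I line)
        i = np.linspace(-30, 40, 15)
        f = 0.2 * np.maximum(i + 11.5, 0.0)
        fit = fit_threshold_linear(i, f, bias=0.0)
        assert fit.gain == pytest.approx(0.2, rel=1e-8)
        assert -fit.threshold == pytest.approx(11.5, rel=1e-8)

    def test_two_points_underdetermined(self):
        with pytest.raises(CalibrationError, match="under-determined"):
            fit_threshold_linear([0.0, 1.0], [0.0, 0.2])

    def test_all_subthreshold_flagged(self):
        fit = fit_threshold_linear([-30, -20, -15], [0.0, 0.0, 0.0], bias=0.0)
        assert fit.degenerate

    def test_noisy_gain_within_10_percent(self):
        rng = np.random.default_rng(7)
        i = np.linspace(-30, 40, 20)
        f = np.maximum(0.2 * np.maximum(i + 11.5, 0.0) + rng.normal(0, 0.05, 20), 0.0)
        fit = fit_threshold_linear(i, f, bias=0.0)
        assert fit.gain == pytest.approx(0.2, rel=0.10)


class TestCalibrateRelease:
    def test_single_projection_closed_form(self):
        """y_p = V_max c*/((K_m + c*) f) in one iteration for an isolated pathway."""
        kin = ReleaseKineticsMM(release_per_stimulus=1.0, v_max=1800.0, k_m=170.0)
        spec = single_projection_circuit(kin, source_rate=0.8)
        targets = BaselineTargets(concentrations={"y:A->B": 1.6})
        res = calibrate_release(spec, targets, free=["y:A->B"], verify=False)
        got = res.spec.projection("y:A->B").kinetics.release_per_stimulus
        assert got == pytest.approx(1800 * 1.6 / ((170 + 1.6) * 0.8), rel=1e-9)
        assert got == pytest.approx(20.979, rel=1e-4)

    def test_targets_already_met_is_identity(self, preset):
        res = calibrate_release(
            preset.circuit, preset.baselines,
            free=[p.key for p in preset.circuit.projections], verify=False,
        )
        assert res.spec == preset.circuit
        assert res.iterations == 1

    def test_zero_source_rate_reported(self):
        kin = ReleaseKineticsMM(release_per_stimulus=1.0, v_max=100.0, k_m=10.0)
        spec = single_projection_circuit(kin, source_rate=0.0)
        targets = BaselineTargets(concentrations={"y:A->B": 1.0})
        with pytest.raises(CalibrationError, match="source rate is zero"):
            calibrate_release(spec, targets, free=["y:A->B"], verify=False)

    def test_overdetermined_free_set_rejected(self, preset):
        targets = BaselineTargets(concentrations={"5-HT:DRN->LHA": 1.6})
        with pytest.raises(CalibrationError, match="exceed"):
            calibrate_release(
                preset.circuit, targets,
                free=["5-HT:DRN->LHA", "5-HT:DRN->LC"], verify=False,
            )

    def test_preset_calibration_converges_to_baselines(self, preset):
        """The bundled circuit's own tuning run: every basal target met to 1%."""
        assert preset.calibration is not None
        assert preset.calibration.converged
        assert max(abs(v) for v in preset.calibration.residuals.values()) < 0.01


class TestSyntheticGenerator:
    def test_zero_noise_points_on_curve(self):
        data = generate_dose_response(SyntheticDoseResponseSpec(TRUTH, n_points=10))
        assert np.allclose(data.responses, sigmoid_response(data.concentrations, TRUTH))

    def test_seeded_determinism(self):
        s = SyntheticDoseResponseSpec(TRUTH, n_points=12, noise_sd=1.0, seed=42)
        a, b = generate_dose_response(s), generate_dose_response(s)
        assert np.array_equal(a.responses, b.responses)
        assert np.array_equal(a.concentrations, b.concentrations)

    def test_grid_spans_three_decades(self):
        with pytest.raises(ValueError, match="3 decades"):
            SyntheticDoseResponseSpec(TRUTH, decades_below=0.5, decades_above=1.0).grid()

    def test_csv_round_trip(self, tmp_path):
        data = generate_dose_response(
            SyntheticDoseResponseSpec(TRUTH, n_points=9, noise_sd=0.3, seed=5)
        )
        p = tmp_path / "dr.csv"
        data.to_csv(p)
        back = DoseResponseTable.from_csv(p)
        assert np.allclose(back.concentrations, data.concentrations)
        assert np.allclose(back.responses, data.responses)
        assert back.mode == data.mode
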