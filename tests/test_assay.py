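"""Signal transduction, log-linear calibration and 3*sigma/S detection limit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chaforge.assay import (
    BlankStats,
    CalibrationFit,
    ReadoutTable,
    delta_f,
    f_over_f0,
    fit_log_linear,
    lod_3sigma,
    predict_signal,
    signal_from_species,
)

# the published calibration of the fluorescence assay: Y = 721.64 lg X + 3432.27
SLOPE, INTERCEPT = 721.64, 3432.27


def table_from_line(concs, slope=SLOPE, intercept=INTERCEPT, reps=1, noise=None):
    rows = []
    rng = np.random.default_rng(0)
    for c in concs:
        for rep in range(1, reps + 1):
            y = slope * np.log10(c) + intercept if c > 0 else 1000.0
            if noise:
                y += rng.normal(0, noise)
            rows.append(
                dict(concentration_nM=c, replicate=rep, signal=y, channel="fluorescence")
            )
    return ReadoutTable(pd.DataFrame(rows))


class TestSignalTransduction:
    def test_background_only(self):
        assert signal_from_species(0.0, background=100.0) == 100.0

    def test_two_quadruplexes_per_duplex(self):
        assert signal_from_species(10.0, gain=1.0, background=0.0) == 20.0

    def test_linearity(self):
        s1 = signal_from_species(5.0, background=50.0)
        s2 = signal_from_species(10.0, background=50.0)
        assert s2 - 50.0 == 2 * (s1 - 50.0)

    @given(
        st.floats(0, 1e3), st.floats(0, 1e3), st.floats(0, 1e3), st.floats(0, 1e3)
    )
    @settings(deadline=None)
    def test_superposition(self, d1, d2, h1, h2):
        f = lambda d, h: signal_from_species(d, h, gain=1.5, leak_weight=0.01)
        assert f(d1 + d2, h1 + h2) == pytest.approx(
            f(d1, h1) + f(d2, h2) - f(0, 0), rel=1e-9, abs=1e-9
        )

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError):
            signal_from_species(1.0, gain=-1.0)


class TestMetrics:
    def test_identity_point(self):
        assert delta_f(100.0, 100.0) == 0.0
        assert f_over_f0(100.0, 100.0) == 1.0

    def test_doubling(self):
        assert f_over_f0(200.0, 100.0) == 2.0

    def test_delta_antisymmetric(self):
        assert delta_f(150.0, 100.0) == -delta_f(100.0, 150.0)

    def test_ratio_needs_positive_blank(self):
        with pytest.raises(ValueError):
            f_over_f0(1.0, 0.0)


class TestCalibrationFit:
    def test_recovers_generating_line_exactly(self):
        """Noise-free points on the published line are recovered to 1e-6."""
        table = table_from_line([0.01, 0.05, 0.1, 0.5, 1.0])
        fit = fit_log_linear(table)
        assert fit.slope == pytest.approx(SLOPE, abs=1e-6)
        assert fit.intercept == pytest.approx(INTERCEPT, abs=1e-6)
        assert fit.r == pytest.approx(1.0, abs=1e-9)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-6)

    def test_two_points_interpolated_exactly(self):
        table = table_from_line([0.1, 10.0], slope=5.0, intercept=2.0)
        fit = fit_log_linear(table)
        assert fit.slope == pytest.approx(5.0, abs=1e-9)
        assert fit.intercept == pytest.approx(2.0, abs=1e-9)

    def test_blanks_excluded_and_range_applied(self):
        table = table_from_line([0.0, 0.01, 0.1, 1.0, 10.0, 50.0], reps=3)
        fit = fit_log_linear(table, x_range=(0.01, 1.0))
        assert fit.n_points == 3
        assert fit.x_range == (0.01, 1.0)

    def test_degenerate_inputs_rejected(self):
        table = table_from_line([0.5])
        with pytest.raises(ValueError):
            fit_log_linear(table)
        with pytest.raises(ValueError):
            fit_log_linear(table_from_line([0.1, 1.0]), x_range=(0.0, 1.0))

    def test_noise_recovery_within_standard_errors(self):
        """Refitting noisy replicates recovers the generator slope within
        3 standard errors in nearly all seeded runs. The SE is the one the
        known noise level implies (sigma/sqrt(reps) per mean), so the check
        has its nominal normal coverage."""
        lg = np.log10([0.01, 0.05, 0.1, 0.5, 1.0])
        se = (50.0 / np.sqrt(3)) / np.sqrt(((lg - lg.mean()) ** 2).sum())
        ok = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            rows = []
            for c in (0.01, 0.05, 0.1, 0.5, 1.0):
                for rep in range(3):
                    rows.append(
                        dict(
                            concentration_nM=c,
                            replicate=rep + 1,
                            signal=SLOPE * np.log10(c) + INTERCEPT + rng.normal(0, 50.0),
                            channel="fluorescence",
                        )
                    )
            fit = fit_log_linear(ReadoutTable(pd.DataFrame(rows)))
            if abs(fit.slope - SLOPE) <= 3 * se:
                ok += 1
        assert ok >= 198  # >= 99 %


class TestPrediction:
    def test_at_one_nanomolar_returns_intercept(self):
        fit = CalibrationFit(SLOPE, INTERCEPT, 1.0, 0.0, (0.01, 1.0), 5)
        assert predict_signal(fit, 1.0) == pytest.approx(INTERCEPT, abs=1e-12)

    def test_one_decade_adds_one_slope(self):
        fit = CalibrationFit(SLOPE, INTERCEPT, 1.0, 0.0, (0.01, 1.0), 5)
        assert predict_signal(fit, 10.0) == pytest.approx(INTERCEPT + SLOPE, abs=1e-9)

    def test_refit_on_predictions_is_idempotent(self):
        fit = CalibrationFit(SLOPE, INTERCEPT, 1.0, 0.0, (0.01, 1.0), 5)
        concs = [0.02, 0.2, 2.0]
        rows = [
            dict(
                concentration_nM=c,
                replicate=1,
                signal=predict_signal(fit, c),
                channel="fluorescence",
            )
            for c in concs
        ]
        refit = fit_log_linear(ReadoutTable(pd.DataFrame(rows)))
        assert refit.slope == pytest.approx(fit.slope, abs=1e-9)
        assert refit.intercept == pytest.approx(fit.intercept, abs=1e-9)

    def test_nonpositive_concentration_rejected(self):
        fit = CalibrationFit(SLOPE, INTERCEPT, 1.0, 0.0, (0.01, 1.0), 5)
        with pytest.raises(ValueError):
            predict_signal(fit, 0.0)


class TestLimitOfDetection:
    def fit(self, slope=SLOPE):
        return CalibrationFit(slope, INTERCEPT, 1.0, 0.0, (0.01, 1.0), 5)

    def test_zero_blank_sd_gives_zero(self):
        lod = lod_3sigma(BlankStats(100.0, 0.0, 3), self.fit())
        assert lod.decades == 0.0

    def test_hand_arithmetic(self):
        assert lod_3sigma(BlankStats(0.0, 1.0, 3), self.fit(3.0)).decades == 1.0
        blanks = BlankStats.from_values([100.0, 102.0, 98.0])
        assert blanks.sd == pytest.approx(2.0, abs=1e-12)
        lod = lod_3sigma(blanks, self.fit())
        assert lod.decades == pytest.approx(3 * 2.0 / 721.64, rel=1e-9)
        assert lod.decades == pytest.approx(8.31e-3, rel=1e-2)

    def test_inversion_form_consistent(self):
        """The concentration form maps F0 + 3*sigma through the calibration."""
        blanks = BlankStats(2000.0, 10.0, 5)
        lod = lod_3sigma(blanks, self.fit())
        y = predict_signal(self.fit(), lod.concentration_nM)
        assert y == pytest.approx(2000.0 + 30.0, rel=1e-9)

    @given(st.floats(0.1, 100.0), st.floats(10.0, 5000.0))
    @settings(deadline=None)
    def test_scaling(self, sigma, slope):
        lod = lod_3sigma(BlankStats(0.0, sigma, 3), self.fit(slope))
        assert lod.decades == pytest.approx(3 * sigma / slope, rel=1e-12)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            lod_3sigma(BlankStats(0.0, 1.0, 3), self.fit(0.0))

    def test_too_few_blanks_rejected(self):
        with pytest.raises(ValueError):
            BlankStats.from_values([1.0])
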