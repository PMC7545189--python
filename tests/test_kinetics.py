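"""1:1 Langmuir simulation and global fitting: closed-form checks and recovery."""

import numpy as np
import pytest
from scipy.stats import linregress

from epimimic.kinetics import (
    KineticModel,
    Sensorgram,
    dilution_series,
    fit_1to1,
    langmuir_response,
    simulate_bivalent,
    simulate_sensorgram,
)

TRUTH = KineticModel(kon=2.2e5, koff=1.6e-1, rmax=1.0)


class TestModel:
    def test_kd_is_exactly_koff_over_kon(self):
        m = KineticModel(kon=3.1e5, koff=2.7e-2, rmax=0.8)
        assert m.kd == m.koff / m.kon  # exact identity, not approximate

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            KineticModel(kon=-1.0, koff=0.1, rmax=1.0)

    def test_dilution_series_arithmetic(self):
        series = dilution_series(500e-9, 6)
        expected = [500e-9, 250e-9, 125e-9, 62.5e-9, 31.25e-9, 15.625e-9]
        assert series == pytest.approx(expected, rel=1e-12)


class TestSimulate:
    def test_plateau_at_kd_is_half_rmax(self):
        data = simulate_sensorgram(TRUTH, [TRUTH.kd], t_assoc=2000.0, t_dissoc=10.0)
        assoc = data.traces[0].response[data.traces[0].time <= 2000.0]
        assert assoc[-1] == pytest.approx(TRUTH.rmax / 2, rel=1e-4)

    def test_dissociation_log_linear_with_slope_koff(self):
        data = simulate_sensorgram(TRUTH, [500e-9], t_assoc=180.0, t_dissoc=30.0)
        tr = data.traces[0]
        mask = tr.time > 180.0
        res = linregress(tr.time[mask], np.log(tr.response[mask]))
        assert -res.slope == pytest.approx(TRUTH.koff, rel=1e-9)

    def test_kobs_recovered_from_noiseless_association(self):
        for conc in dilution_series(500e-9, 4):
            data = simulate_sensorgram(TRUTH, [conc], t_assoc=180.0, t_dissoc=1.0, dt=0.25)
            tr = data.traces[0]
            assoc = tr.time <= 180.0
            req = TRUTH.rmax * conc / (conc + TRUTH.kd)
            mask = assoc & (req - tr.response > 1e-9 * req) & (tr.time > 0)
            slope = linregress(tr.time[mask], np.log(req - tr.response[mask])).slope
            assert -slope == pytest.approx(TRUTH.kon * conc + TRUTH.koff, rel=1e-6)

    def test_noise_determinism_and_mean(self):
        a = simulate_sensorgram(TRUTH, [125e-9], noise_sd=0.02, seed=42)
        b = simulate_sensorgram(TRUTH, [125e-9], noise_sd=0.02, seed=42)
        c = simulate_sensorgram(TRUTH, [125e-9], noise_sd=0.02, seed=43)
        assert np.array_equal(a.traces[0].response, b.traces[0].response)
        assert not np.array_equal(a.traces[0].response, c.traces[0].response)
        clean = langmuir_response(a.traces[0].time, 125e-9, TRUTH, 180.0)
        assert np.allclose(a.traces[0].response - clean, c.traces[0].response - clean, atol=0.2)

    def test_frame_round_trip(self):
        data = simulate_sensorgram(TRUTH, dilution_series(500e-9, 3), noise_sd=0.01, seed=1)
        back = Sensorgram.from_frame(data.to_frame())
        assert back.concentrations == sorted(data.concentrations)
        assert back.t_assoc == data.t_assoc


class TestFit:
    def test_noiseless_recovery_to_tenth_percent(self):
        data = simulate_sensorgram(TRUTH, dilution_series(500e-9, 6))
        fit = fit_1to1(data)
        assert fit.converged
        assert fit.model.kon == pytest.approx(TRUTH.kon, rel=1e-3)
        assert fit.model.koff == pytest.approx(TRUTH.koff, rel=1e-3)
        assert fit.model.rmax == pytest.approx(TRUTH.rmax, rel=1e-3)

    def test_noisy_recovery_within_five_percent(self):
        data = simulate_sensorgram(TRUTH, dilution_series(500e-9, 6), noise_sd=0.02, seed=7)
        fit = fit_1to1(data)
        assert fit.converged
        assert fit.model.kon == pytest.approx(TRUTH.kon, rel=0.05)
        assert fit.model.koff == pytest.approx(TRUTH.koff, rel=0.05)
        assert set(fit.stderr) == {"kon", "koff", "rmax", "kd"}
        assert all(v > 0 for v in fit.stderr.values())

    def test_median_kd_error_under_five_percent_over_seeds(self):
        errors = []
        for seed in range(100):
            data = simulate_sensorgram(TRUTH, dilution_series(500e-9, 6), noise_sd=0.02, seed=seed)
            fit = fit_1to1(data)
            if fit.converged:
                errors.append(abs(fit.model.kd / TRUTH.kd - 1.0))
        assert len(errors) >= 95
        assert np.median(errors) < 0.05

    def test_koff_from_dissociation_only_within_stderr_of_global(self):
        from scipy.optimize import curve_fit

        data = simulate_sensorgram(TRUTH, dilution_series(500e-9, 6), noise_sd=0.02, seed=11)
        fit = fit_1to1(data)
        # independent dissociation-only estimate: single-exponential fit to the
        # dissociation phases of all traces (no association information used)
        def decay(t, amp, koff):
            return amp * np.exp(-koff * t)

        koffs = []
        for tr in data.traces[:3]:  # traces with usable signal
            mask = tr.time > data.t_assoc
            popt, _ = curve_fit(
                decay, tr.time[mask] - data.t_assoc, tr.response[mask], p0=(tr.response[mask][0], 0.1)
            )
            koffs.append(popt[1])
        koff_dissoc = float(np.mean(koffs))
        assert abs(koff_dissoc - fit.model.koff) < 3 * fit.stderr["koff"] + 0.02 * fit.model.koff

    def test_response_scaling_moves_only_rmax(self):
        data = simulate_sensorgram(TRUTH, dilution_series(500e-9, 6), noise_sd=0.005, seed=3)
        fit_base = fit_1to1(data)
        for tr in data.traces:
            tr.response = tr.response * 7.5
        fit_scaled = fit_1to1(data)
        assert fit_scaled.model.rmax == pytest.approx(7.5 * fit_base.model.rmax, rel=1e-3)
        assert fit_scaled.model.kon == pytest.approx(fit_base.model.kon, rel=1e-3)
        assert fit_scaled.model.koff == pytest.approx(fit_base.model.koff, rel=1e-3)

    def test_degenerate_design_flagged_not_raised(self):
        single = simulate_sensorgram(TRUTH, [TRUTH.kd], t_assoc=180.0, t_dissoc=0.4, dt=1.0)
        fit = fit_1to1(single)
        assert not fit.converged
        assert "non-identifiable" in fit.message

    def test_narrow_span_flagged(self):
        data = simulate_sensorgram(TRUTH, [500e-9, 400e-9])
        assert not fit_1to1(data).converged


class TestAvidity:
    def test_bivalent_apparent_affinity_at_least_tenfold_tighter(self):
        biv = simulate_bivalent(TRUTH, dilution_series(500e-9, 6))
        fit = fit_1to1(biv)
        assert fit.converged
        assert TRUTH.kd / fit.model.kd >= 10.0

    def test_bivalent_reduces_to_1to1_without_crosslinking(self):
        biv = simulate_bivalent(TRUTH, [125e-9], k_crosslink=0.0)
        # with no second step, kinetics are 1:1 with kon doubled (two free arms)
        doubled = KineticModel(kon=2 * TRUTH.kon, koff=TRUTH.koff, rmax=TRUTH.rmax)
        clean = langmuir_response(biv.traces[0].time, 125e-9, doubled, 180.0)
        assert np.allclose(biv.traces[0].response, clean, atol=5e-4)
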