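"""Sequential photocycle kinetics: closed form vs numerical ODE oracle,
intermediate detection, decay fitting, turnover, pyranine signals, and the
global two-rate fit."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from rhodotools import synthgen
from rhodotools.photocycle import (
    KineticScheme,
    SpectralTimeSeries,
    detect_intermediates,
    fit_exponential_decay,
    global_fit,
    photocycle_turnover,
    pyranine_signal,
    solve_sequential,
)


def ode_oracle(k_km, k_mp, f, times):
    """Adaptive numerical integration of the two-intermediate chain."""

    def rhs(_t, y):
        ck, cm = y
        return [-k_km * ck, k_km * ck - k_mp * cm]

    sol = solve_ivp(
        rhs, (0.0, times[-1]), [f, 0.0], t_eval=times,
        method="LSODA", rtol=1e-12, atol=1e-14,
    )
    return sol.y[0], sol.y[1]


class TestSolveSequential:
    def test_initial_condition(self):
        scheme = KineticScheme(0.5, 0.0009, excited_fraction=0.2)
        c = solve_sequential(scheme, np.array([0.0]))
        assert c["K"][0] == pytest.approx(0.2)
        assert c["M"][0] == pytest.approx(0.0)

    def test_full_recovery_at_long_times(self):
        scheme = KineticScheme(0.5, 0.0009, excited_fraction=0.2)
        c = solve_sequential(scheme, np.array([1e7]))
        assert c["K"][0] < 1e-12 and c["M"][0] < 1e-12

    def test_conservation_and_bounds(self):
        scheme = KineticScheme(0.5, 0.0009, excited_fraction=0.2)
        t = synthgen.default_time_grid()
        c = solve_sequential(scheme, t)
        total = c["K"] + c["M"]
        assert np.allclose(c["ground_deficit"], total, atol=1e-12)
        for s in ("K", "M"):
            assert np.all(c[s] >= 0) and np.all(c[s] <= 0.2 + 1e-12)

    def test_against_ode_oracle_default_rates(self):
        scheme = KineticScheme(0.5, 0.001, excited_fraction=1.0)
        t = synthgen.default_time_grid()
        c = solve_sequential(scheme, t)
        ck, cm = ode_oracle(0.5, 0.001, 1.0, t)
        assert np.max(np.abs(c["K"] - ck)) < 1e-8
        assert np.max(np.abs(c["M"] - cm)) < 1e-8

    @pytest.mark.parametrize("seed", range(10))
    def test_against_ode_oracle_random_rates(self, seed):
        rng = np.random.default_rng(seed)
        k1, k2 = 10.0 ** rng.uniform(-3, 1, 2)
        scheme = KineticScheme(k1, k2, excited_fraction=1.0)
        t = np.logspace(-3, 3, 61)
        c = solve_sequential(scheme, t)
        ck, cm = ode_oracle(k1, k2, 1.0, t)
        assert np.max(np.abs(c["K"] - ck)) < 1e-8
        assert np.max(np.abs(c["M"] - cm)) < 1e-8

    def test_degenerate_equal_rates_limit(self):
        t = np.logspace(-2, 3, 50)
        c_eq = solve_sequential(KineticScheme(0.01, 0.01, excited_fraction=1.0), t)
        c_near = solve_sequential(
            KineticScheme(0.01 * (1 + 1e-9), 0.01, excited_fraction=1.0), t
        )
        assert np.allclose(c_eq["M"], c_near["M"], atol=1e-7)


class TestDetectIntermediates:
    def test_default_fixture_assignments(self, default_photocycle):
        series, _ = default_photocycle
        calls = {c.label: c for c in detect_intermediates(series, 570.0)}
        assert set(calls) == {"K", "M", "bleach"}
        assert abs(calls["M"].band_center - 415.0) <= 10.0
        assert abs(calls["K"].band_center - 675.0) <= 10.0
        assert abs(calls["bleach"].band_center - 570.0) <= 5.0
        assert calls["K"].peak_amplitude > 0 and calls["M"].peak_amplitude > 0
        assert calls["bleach"].peak_amplitude < 0

    def test_k_rises_before_m(self, default_photocycle):
        """With K->M much faster than M decay, K is populated first."""
        series, _ = default_photocycle
        calls = {c.label: c for c in detect_intermediates(series, 570.0)}
        assert calls["K"].rise_time < calls["M"].decay_time
        assert calls["K"].decay_time < calls["M"].decay_time

    def test_zero_matrix_empty(self):
        t = np.logspace(-3, 4, 30)
        wl = np.arange(370.0, 721.0, 5.0)
        series = SpectralTimeSeries(t, wl, np.zeros((t.size, wl.size)))
        assert detect_intermediates(series, 570.0) == []

    def test_labels_invariant_to_amplitude_scaling(self, default_photocycle):
        series, _ = default_photocycle
        scaled = SpectralTimeSeries(series.times, series.wavelengths,
                                    17.3 * series.delta_a)
        a = [(c.label, c.band_center) for c in detect_intermediates(series, 570.0)]
        b = [(c.label, c.band_center) for c in detect_intermediates(scaled, 570.0)]
        assert a == b

    def test_wavelength_mask_respected(self, default_photocycle):
        series, _ = default_photocycle
        calls = detect_intermediates(series, 570.0, mask=[565.0, 570.0])
        bleach = next(c for c in calls if c.label == "bleach")
        assert bleach.band_center not in (565.0, 570.0)


class TestFitExponentialDecay:
    def test_pure_exponential_round_trip(self):
        t = np.logspace(-1, 4.5, 120)
        y = 0.5 * np.exp(-0.01 * t)
        fit = fit_exponential_decay((t, y), n_exp=1)
        assert fit["rates"][0] == pytest.approx(0.01, abs=1e-4)

    def test_m_band_trace_recovers_table_rate(self, default_photocycle):
        """The 415-nm trace of the long-lived M fixture yields its decay rate."""
        series, truth = default_photocycle
        fit = fit_exponential_decay(series.trace(415.0))
        assert fit["rates"][0] == pytest.approx(truth.params["k_mp"], rel=0.05)

    def test_two_exponential_vs_grid_oracle(self):
        """Two well-separated rates: the fit matches a log-spaced grid search
        (amplitudes profiled linearly) within 2%."""
        t = np.logspace(-3, 4, 150)
        y = 0.6 * np.exp(-0.5 * t) + 0.4 * np.exp(-0.001 * t)
        fit = fit_exponential_decay((t, y), n_exp=2, seed=1)

        grid = np.logspace(-4, 1, 400)
        best = (np.inf, None)
        for i, k1 in enumerate(grid):
            e1 = np.exp(-k1 * t)
            for k2 in grid[: i]:
                X = np.column_stack([np.ones_like(t), e1, np.exp(-k2 * t)])
                beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
                rss = float(np.sum((X @ beta - y) ** 2))
                if rss < best[0]:
                    best = (rss, (k1, k2))
        assert fit["rates"][0] == pytest.approx(best[1][0], rel=0.02)
        assert fit["rates"][1] == pytest.approx(best[1][1], rel=0.02)

    def test_recovery_sweep(self):
        """Median relative error across the physiological rate range stays
        below 1% / 3% / 10% at 0 / 1% / 5% peak noise."""
        rates = [0.0003, 0.0009, 0.003, 0.01]
        bounds = {0.0: 0.01, 0.01: 0.03, 0.05: 0.10}
        t = synthgen.default_time_grid()
        rng_global = np.random.default_rng(99)
        for noise, bound in bounds.items():
            errs = []
            for k in rates:
                for _ in range(10):
                    y = np.exp(-k * t)
                    if noise:
                        y = y + rng_global.normal(0, noise, t.size)
                    fit = fit_exponential_decay((t, y), n_exp=1, n_starts=4)
                    errs.append(abs(fit["rates"][0] - k) / k)
            assert np.median(errs) < bound

    def test_too_few_points_raise(self):
        t = np.linspace(0, 10, 5)
        with pytest.raises(ValueError):
            fit_exponential_decay((t, np.exp(-t)))


class TestTurnover:
    def test_matches_closed_form_recovery_time(self, default_photocycle):
        """99% recovery of a single-exponential bleach happens at ln(100)/k."""
        series, truth = default_photocycle
        res = photocycle_turnover(series, 570.0, recovery_fraction=0.99)
        expected = np.log(100.0) / truth.params["k_mp"]  # ~5117 ms
        assert res["complete"] is True
        # log grid at 20 pts/decade: allow one grid step (~12%)
        assert res["time_ms"] == pytest.approx(expected, rel=0.15)

    def test_instantaneous_scheme_recovers_immediately(self):
        scheme = synthgen.make_default_scheme(k_km=1e4, k_mp=5e3)
        series, _ = synthgen.make_photocycle_series(scheme)
        res = photocycle_turnover(series, 570.0)
        assert res["time_ms"] < 0.01

    def test_zero_recovery_fraction_is_bleach_minimum(self, default_photocycle):
        series, _ = default_photocycle
        res = photocycle_turnover(series, 570.0, recovery_fraction=0.0)
        t, y = series.trace(570.0)
        assert res["time_ms"] == pytest.approx(t[np.argmin(y)])

    def test_incomplete_recovery_flagged(self):
        scheme = synthgen.make_default_scheme(k_mp=1e-6)
        series, _ = synthgen.make_photocycle_series(
            scheme, time_grid=np.logspace(-3, 3, 60)
        )
        res = photocycle_turnover(series, 570.0)
        assert res["complete"] is False
        assert res["time_ms"] == pytest.approx(1e3)


class TestPyranine:
    @staticmethod
    def _with_dye(sign=-1.0):
        series, truth = synthgen.make_photocycle_series(seed=0)
        k_mp = truth.params["k_mp"]
        t = series.times
        wl = series.wavelengths
        dye_col = np.argmin(np.abs(wl - 450.0))
        # proton release tracks M decay: dye absorbance falls as solvent acidifies
        release = sign * 0.05 * (1.0 - np.exp(-k_mp * t))
        da = series.delta_a.copy()
        da[:, dye_col] += release
        dyed = SpectralTimeSeries(t, wl, da)
        return dyed, series, k_mp

    def test_identical_series_classified_none(self, default_photocycle):
        series, _ = default_photocycle
        res = pyranine_signal(series, series)
        assert res["classification"] == "none"
        assert np.allclose(res["dye_trace"], 0.0)

    def test_release_coupled_to_m_decay(self):
        dyed, plain, k_mp = self._with_dye(sign=-1.0)
        res = pyranine_signal(dyed, plain)
        assert res["classification"] == "release"
        # signal essentially complete by ~5/k_mp
        t = res["times"]
        i = np.argmin(np.abs(t - 5.0 / k_mp))
        assert abs(res["dye_trace"][i]) > 0.99 * abs(res["dye_trace"][-1])
        assert np.all(np.diff(res["dye_trace"]) <= 1e-12)

    def test_inverted_fixture_is_uptake(self):
        dyed, plain, _ = self._with_dye(sign=+1.0)
        assert pyranine_signal(dyed, plain)["classification"] == "uptake"

    def test_grid_mismatch_raises(self, default_photocycle):
        series, _ = default_photocycle
        other = SpectralTimeSeries(series.times[:-1], series.wavelengths,
                                   series.delta_a[:-1])
        with pytest.raises(ValueError):
            pyranine_signal(series, other)


class TestGlobalFit:
    def test_noiseless_round_trip(self, default_photocycle):
        series, truth = default_photocycle
        res = global_fit(series, excited_fraction=truth.params["excited_fraction"],
                         seed=0)
        assert res["k_km"] == pytest.approx(truth.params["k_km"], rel=0.01)
        assert res["k_mp"] == pytest.approx(truth.params["k_mp"], rel=0.01)

    def test_recovered_spectra_and_recomposition(self, default_photocycle):
        series, truth = default_photocycle
        scheme = synthgen.make_default_scheme()
        res = global_fit(series, excited_fraction=truth.params["excited_fraction"],
                         seed=0)
        for s in ("K", "M"):
            assert np.sqrt(np.mean((res["spectra"][s] - scheme.delta_eps[s]) ** 2)) < 0.01
        conc = solve_sequential(
            KineticScheme(res["k_km"], res["k_mp"],
                          excited_fraction=truth.params["excited_fraction"]),
            series.times,
        )
        recomposed = np.outer(conc["K"], res["spectra"]["K"]) + np.outer(
            conc["M"], res["spectra"]["M"]
        )
        assert np.sqrt(np.mean((recomposed - series.delta_a) ** 2)) < 1e-6

    def test_reported_solution_independent_of_start_labels(self, default_photocycle):
        """Different seeds (hence different, possibly swapped initial guesses)
        converge to the same rate-ordered solution."""
        series, truth = default_photocycle
        f = truth.params["excited_fraction"]
        r1 = global_fit(series, excited_fraction=f, seed=0)
        r2 = global_fit(series, excited_fraction=f, seed=12345)
        assert r1["k_km"] == pytest.approx(r2["k_km"], rel=1e-4)
        assert r1["k_mp"] == pytest.approx(r2["k_mp"], rel=1e-4)
        assert r1["k_km"] > r1["k_mp"]
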