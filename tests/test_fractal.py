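"""Periodogram / Allan-factor estimators against hand-computed oracles."""
import numpy as np
import pytest

from minifract.events import EventSeries
from minifract.fractal import (
    allan_factor,
    count_periodogram,
    default_tau_grid,
    estimate_alpha_af,
    estimate_alpha_pg,
    AllanFactorResult,
    PeriodogramResult,
)
from minifract.significance import poisson_series


def brute_force_periodogram(counts: np.ndarray) -> np.ndarray:
    """Direct DFT-sum evaluation of |W(f)|^2 / M for one window."""
    M = counts.size
    out = np.empty(M // 2 + 1)
    for k in range(M // 2 + 1):
        w = np.sum(counts * np.exp(-2j * np.pi * k * np.arange(M) / M))
        out[k] = abs(w) ** 2 / M
    return out


def naive_allan_factor(counts: np.ndarray) -> float:
    """Two-pass textbook evaluation of E[(Z_{k+1}-Z_k)^2] / (2 E[Z])."""
    diffs = [(counts[i + 1] - counts[i]) ** 2 for i in range(len(counts) - 1)]
    return (sum(diffs) / len(diffs)) / (2 * sum(counts) / len(counts))


class TestCountPeriodogram:
    def test_unit_impulse_window_is_flat(self):
        """A single event in one window has |W(f)|^2 = 1 at every frequency."""
        s = EventSeries(times=np.array([0.001]), span=0.08)
        pg = count_periodogram(s, window_length=0.08)
        assert pg.n_bins_per_window == 8
        np.testing.assert_allclose(pg.power, 1 / 8, atol=1e-12)

    def test_constant_counts_have_no_ac_power(self):
        # one event per 10 ms bin: all power at DC
        t = np.arange(16) * 0.01 + 0.005
        s = EventSeries(times=t, span=0.16)
        pg = count_periodogram(s, window_length=0.16)
        assert pg.power[0] == pytest.approx(16.0)
        np.testing.assert_allclose(pg.power[1:], 0.0, atol=1e-12)

    def test_matches_brute_force_dft(self, rng):
        t = np.sort(rng.uniform(0, 1.28, 200))
        s = EventSeries(times=t, span=1.28)
        pg = count_periodogram(s, window_length=1.28)
        counts = np.bincount((t // 0.01).astype(int), minlength=128)[:128]
        np.testing.assert_allclose(
            pg.power, brute_force_periodogram(counts), rtol=1e-10
        )

    def test_rejects_degenerate_window(self):
        s = EventSeries(times=np.array([0.01]), span=0.05)
        with pytest.raises(ValueError, match="8 bins"):
            count_periodogram(s, window_length=0.05)

    def test_rejects_window_beyond_span(self, small_series):
        with pytest.raises(ValueError, match="span"):
            count_periodogram(small_series, window_length=1.0)


class TestAlphaFromPeriodogram:
    @pytest.mark.parametrize("alpha", [0.5, 0.0, 1.0])
    def test_exact_power_law_recovered(self, alpha):
        f = np.fft.rfftfreq(4096, d=0.01)
        power = np.ones_like(f)
        power[1:] = 10.0 / f[1:] ** alpha
        pg = PeriodogramResult(
            frequencies=f, power=power, n_windows=1,
            window_length=40.96, n_bins_per_window=4096,
        )
        est = estimate_alpha_pg(pg)
        assert est.alpha == pytest.approx(alpha, abs=1e-9)
        assert est.r_squared == pytest.approx(1.0, abs=1e-9) or alpha == 0.0

    def test_zero_power_points_dropped_and_counted(self):
        f = np.fft.rfftfreq(4096, d=0.01)
        power = np.ones_like(f)
        power[3] = 0.0
        pg = PeriodogramResult(
            frequencies=f, power=power, n_windows=1,
            window_length=40.96, n_bins_per_window=4096,
        )
        est = estimate_alpha_pg(pg)
        assert est.n_dropped == 1


class TestAllanFactor:
    def test_hand_example(self):
        """Counts [2,4,6] -> AF = ((2^2 + 2^2)/2) / (2 * 4) = 0.5."""
        times = np.concatenate(
            [np.linspace(0.0, 0.9, 2), np.linspace(1.0, 1.9, 4), np.linspace(2.0, 2.9, 6)]
        )
        s = EventSeries(times=np.sort(times), span=3.0)
        af = allan_factor(s, np.array([1.0]))
        assert af.af[0] == pytest.approx(0.5)

    def test_periodic_events_have_zero_af(self):
        t = np.arange(100) * 0.1 + 0.05
        s = EventSeries(times=t, span=10.0)
        af = allan_factor(s, np.array([1.0]))
        assert af.af[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_two_pass(self, rng):
        t = np.sort(rng.uniform(0, 100, 500))
        s = EventSeries(times=t, span=100.0)
        for tau in (0.5, 1.0, 7.3):
            got = allan_factor(s, np.array([tau])).af[0]
            counts = np.bincount(
                (t[t < (100.0 // tau) * tau] // tau).astype(int),
                minlength=int(100.0 // tau),
            )
            assert got == pytest.approx(naive_allan_factor(counts))

    def test_long_taus_excluded(self):
        s = EventSeries(times=np.linspace(0.1, 9.9, 50), span=10.0)
        af = allan_factor(s, np.array([1.0, 4.0, 8.0]))
        assert af.taus.tolist() == [1.0, 4.0]


class TestAlphaFromAllanFactor:
    @pytest.mark.parametrize("alpha", [0.7, 0.0])
    def test_exact_power_law(self, alpha):
        taus = np.geomspace(1.0, 100.0, 12)
        af = AllanFactorResult(taus=taus, af=taus**alpha)
        est = estimate_alpha_af(af)
        assert est.alpha == pytest.approx(alpha, abs=1e-9)

    def test_one_plus_tau_slope(self):
        """AF = 1 + Tau on log-spaced [1, 1000] fits a slope just below 1."""
        taus = np.geomspace(1.0, 1000.0, 20)
        est = estimate_alpha_af(AllanFactorResult(taus=taus, af=1.0 + taus))
        assert 0.90 < est.alpha < 1.00

    def test_too_few_points_error(self):
        af = AllanFactorResult(taus=np.array([1.0, 2.0]), af=np.array([1.0, 1.1]))
        with pytest.raises(ValueError, match="3"):
            estimate_alpha_af(af)


def fractal_rate_events(alpha, span, mean_rate, cv, f_max, seed):
    """Doubly stochastic (Cox) surrogate with a 1/f^alpha rate spectrum.

    A Gaussian rate with spectral density K f^-alpha inside (1/span, f_max)
    is synthesized by FFT shaping, clipped at zero, integrated, and events are
    drawn by time rescaling of unit exponential waits.
    """
    rng = np.random.default_rng(seed)
    dt = 0.05
    n = int(span / dt)
    f = np.fft.rfftfreq(n, d=dt)
    shape = np.zeros_like(f)
    band = (f > 0) & (f <= f_max)
    shape[band] = f[band] ** (-alpha / 2)
    white = rng.normal(size=n)
    spec = np.fft.rfft(white) * shape
    fluct = np.fft.irfft(spec, n)
    fluct *= (cv * mean_rate) / fluct.std()
    rate = np.clip(mean_rate + fluct, 0.0, None)
    cum = np.concatenate([[0.0], np.cumsum(rate) * dt])
    total = cum[-1]
    waits = rng.exponential(1.0, int(total * 1.2) + 50)
    arrival = np.cumsum(waits)
    arrival = arrival[arrival < total]
    times = np.interp(arrival, cum, np.arange(n + 1) * dt)
    return EventSeries(times=np.sort(times), span=span)


class TestPowerLawRecovery:
    @pytest.mark.parametrize("alpha", [0.5, 0.8])
    def test_both_estimators_recover_surrogate_alpha(self, alpha):
        """PG and AF recover the rate exponent of a Cox surrogate (+-0.15)."""
        pg_a, af_a = [], []
        for seed in range(10):
            s = fractal_rate_events(
                alpha, span=3600.0, mean_rate=20.0, cv=0.6, f_max=1.0, seed=seed
            )
            pg_a.append(estimate_alpha_pg(count_periodogram(s)).alpha)
            af_a.append(
                estimate_alpha_af(allan_factor(s, default_tau_grid(s.span))).alpha
            )
        assert np.mean(pg_a) == pytest.approx(alpha, abs=0.15)
        assert np.mean(af_a) == pytest.approx(alpha, abs=0.15)
        # method agreement on the same series
        assert np.mean(np.abs(np.array(pg_a) - np.array(af_a))) <= 0.2


class TestPoissonCalibration:
    def test_poisson_alpha_near_zero_both_methods(self):
        """Homogeneous Poisson trains give alpha ~ 0 for PG and AF."""
        pg_a, af_a = [], []
        for seed in range(20):
            s = poisson_series(3600.0, 7200, np.random.default_rng(100 + seed))
            pg_a.append(estimate_alpha_pg(count_periodogram(s)).alpha)
            af_a.append(
                estimate_alpha_af(allan_factor(s, default_tau_grid(s.span))).alpha
            )
        assert abs(np.mean(pg_a)) < 0.05
        assert abs(np.mean(af_a)) < 0.05
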