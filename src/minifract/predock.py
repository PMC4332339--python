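"""Pre-docking release simulator.

Model: at each of ``N`` independent release sites, the interval between
successive spontaneous fusion events is the sum of two independent waits:

1. the *first-return time* of a symmetric one-dimensional random walk to the
   release site.  The walker moves at 90 nm/s in discrete steps of +/-0.5 nm,
   so one step lasts ``ds / speed`` seconds; a walk is aborted and resampled
   if it exceeds 10^6 steps.  First-return times of a symmetric walk are
   heavy-tailed (survival ~ t^(-1/2), density ~ t^(-3/2)), which is the 1/f
   source of the model;
2. an exponential fusion delay with rate ``lambda`` (mean ``1/lambda``),
   the memoryless wait for a docked vesicle to fuse.

On the first cycle the walker starts at ``x0`` drawn uniformly between 0 and
-100 steps; after every release it restarts one step below the site
(``x0 = -0.5 nm``).  The observable train is the superposition of the ``N``
per-site series.

Sampling strategy: the number of steps to first return from one step below
the site has the exact distribution ``P(T = 2k - 1) = C(2k, k) / ((2k - 1) 4^k)``
with survival ``P(T > 2k - 1) = C(2k, k) / 4^k``.  The default "fast path"
samples step counts directly from this distribution by inverse CDF (a return
from ``m`` steps away is the sum of ``m`` independent one-step returns),
truncated at the abort limit; a literal step-by-step walker is provided for
validation and via ``literal_walk=True``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .events import EventSeries, superpose
from .fractal import (
    allan_factor,
    count_periodogram,
    default_tau_grid,
    estimate_alpha_af,
    estimate_alpha_pg,
)

__all__ = [
    "WalkParams",
    "SiteConfig",
    "SweepConfig",
    "BiExpFit",
    "PowerFit",
    "FirstReturnSampler",
    "first_return_time",
    "site_event_series",
    "run_sweep",
    "fit_alpha_lambda",
    "fit_power_function",
]


@dataclass(frozen=True)
class WalkParams:
    """Parameters of the pre-docking random walk."""

    step_size: float = 0.5  # nm
    speed: float = 90.0  # nm/s
    x0_first_max_steps: int = 100  # first x0 ~ U(-x0_first_max_steps * ds, 0)
    x0_reset: float = -0.5  # nm, restart position after each release
    max_steps: int = 10**6  # abort-and-resample limit

    def __post_init__(self) -> None:
        if self.step_size <= 0 or self.speed <= 0 or self.max_steps < 1:
            raise ValueError("step_size, speed and max_steps must be positive")

    @property
    def step_duration(self) -> float:
        """Duration of one step in seconds (ds / speed)."""
        return self.step_size / self.speed


@dataclass(frozen=True)
class SiteConfig:
    """A release site: fusion rate of docked vesicles plus walk parameters."""

    fusion_rate: float  # lambda, 1/s
    walk: WalkParams = field(default_factory=WalkParams)

    def __post_init__(self) -> None:
        if self.fusion_rate <= 0:
            raise ValueError("fusion_rate must be positive")


@dataclass(frozen=True)
class SweepConfig:
    """Grid of (N, lambda) conditions for the simulation sweep."""

    n_sites_values: tuple[int, ...]
    lambda_values: tuple[float, ...]
    reps: int = 10
    series_duration: float = 3600.0  # seconds per simulated series
    walk: WalkParams = field(default_factory=WalkParams)
    pg_window_length: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sites_values) < 1 or min(self.lambda_values) <= 0:
            raise ValueError("grid values must be positive")
        if self.reps < 1 or self.series_duration <= 0:
            raise ValueError("reps and series_duration must be positive")


class FirstReturnSampler:
    """Exact sampler of first-return step counts, truncated at ``max_steps``.

    The survival of the one-step return time, ``S(k) = P(T > 2k - 1)
    = C(2k, k) / 4^k``, is tabulated once by the stable recursion
    ``S(k) = S(k - 1) * (2k - 1) / (2k)``; draws use inverse-CDF lookup.
    """

    def __init__(self, max_steps: int = 10**6):
        self.max_steps = int(max_steps)
        kmax = max(1, (self.max_steps + 1) // 2)
        k = np.arange(1, kmax + 1, dtype=float)
        surv = np.cumprod((2 * k - 1) / (2 * k))
        self._cdf = 1.0 - surv  # P(T <= 2k - 1), increasing in k
        self._cdf_max = float(self._cdf[-1])

    def sample_steps_one(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n one-step first-return step counts, conditioned on T <= max_steps."""
        v = rng.uniform(0.0, self._cdf_max, n)
        k = np.searchsorted(self._cdf, v, side="left") + 1
        return 2 * k - 1

    def sample_steps_from(self, m: int, rng: np.random.Generator) -> int:
        """Step count to reach the site from ``m`` steps below.

        The return from distance ``m`` is the sum of ``m`` independent
        one-step returns; walks whose total would exceed ``max_steps`` are
        aborted and resampled, conditioning on completion within the limit.
        """
        if m == 0:
            return 0
        while True:
            v = rng.uniform(0.0, 1.0, m)
            if np.any(v > self._cdf_max):
                continue  # a sub-walk alone would exceed the limit: abort
            k = np.searchsorted(self._cdf, v, side="left") + 1
            total = int(np.sum(2 * k - 1))
            if total <= self.max_steps:
                return total


_SAMPLERS: dict[int, FirstReturnSampler] = {}


def _sampler(max_steps: int) -> FirstReturnSampler:
    if max_steps not in _SAMPLERS:
        _SAMPLERS[max_steps] = FirstReturnSampler(max_steps)
    return _SAMPLERS[max_steps]


def _literal_walk_steps(m: int, max_steps: int, rng: np.random.Generator) -> int:
    """Step-by-step walk from ``m`` steps below the site; resample on abort."""
    while True:
        pos = -m
        taken = 0
        while taken < max_steps:
            block = min(8192, max_steps - taken)
            steps = rng.choice((-1, 1), size=block)
            path = pos + np.cumsum(steps)
            hit = np.nonzero(path >= 0)[0]
            if hit.size:
                return taken + int(hit[0]) + 1
            pos = int(path[-1])
            taken += block
        # aborted: start a new walk


def first_return_time(
    walk: WalkParams,
    x0: float,
    rng: np.random.Generator,
    literal: bool = False,
) -> float:
    """Time in seconds for the walker to return to the site from ``x0 < 0``."""
    if x0 >= 0:
        raise ValueError("x0 must be below the release site (negative)")
    m = int(np.ceil(-x0 / walk.step_size - 1e-12))
    if literal:
        steps = _literal_walk_steps(m, walk.max_steps, rng)
    else:
        steps = _sampler(walk.max_steps).sample_steps_from(m, rng)
    return steps * walk.step_duration


def site_event_series(
    site: SiteConfig,
    duration: float,
    rng: np.random.Generator,
    literal_walk: bool = False,
) -> EventSeries:
    """Event train of one release site over ``duration`` seconds.

    Inter-event intervals are first-return times plus exponential fusion
    delays; the first cycle starts from a uniform ``x0`` in
    ``(-x0_first_max_steps * ds, 0)``, later cycles from ``x0_reset``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    walk = site.walk
    dt = walk.step_duration
    sampler = _sampler(walk.max_steps)
    m_reset = int(np.ceil(-walk.x0_reset / walk.step_size - 1e-12))

    x0 = rng.uniform(-walk.x0_first_max_steps * walk.step_size, 0.0)
    x0 = min(x0, -1e-12)
    if literal_walk:
        first_steps = _literal_walk_steps(
            int(np.ceil(-x0 / walk.step_size - 1e-12)), walk.max_steps, rng
        )
    else:
        first_steps = sampler.sample_steps_from(
            int(np.ceil(-x0 / walk.step_size - 1e-12)), rng
        )
    t = first_steps * dt + rng.exponential(1.0 / site.fusion_rate)
    times = []
    if t < duration:
        times.append(t)
        mean_interval = 1.5 * dt * 1600 + 1.0 / site.fusion_rate
        while True:
            n_more = max(16, int((duration - t) / mean_interval * 1.3))
            if literal_walk:
                frs = np.array(
                    [
                        _literal_walk_steps(m_reset, walk.max_steps, rng)
                        for _ in range(n_more)
                    ]
                )
            elif m_reset == 1:
                frs = sampler.sample_steps_one(n_more, rng)
            else:
                frs = np.array(
                    [sampler.sample_steps_from(m_reset, rng) for _ in range(n_more)]
                )
            iei = frs * dt + rng.exponential(1.0 / site.fusion_rate, n_more)
            cs = t + np.cumsum(iei)
            times.extend(cs[cs < duration])
            t = cs[-1]
            if t >= duration:
                break
    return EventSeries(times=np.asarray(times, dtype=float), span=duration)


def simulate_release_series(
    n_sites: int,
    fusion_rate: float,
    duration: float,
    rng: np.random.Generator,
    walk: WalkParams | None = None,
    literal_walk: bool = False,
) -> EventSeries:
    """Superposed release train of ``n_sites`` independent sites."""
    walk = walk or WalkParams()
    site = SiteConfig(fusion_rate=fusion_rate, walk=walk)
    series = [
        site_event_series(site, duration, rng, literal_walk)
        for _ in range(n_sites)
    ]
    return superpose(series)


def run_sweep(config: SweepConfig) -> "pd.DataFrame":
    """Simulate the (N, lambda) grid and estimate alpha per series.

    Returns a tidy table with one row per (n_sites, lam, rep) and columns
    ``alpha_pg`` / ``alpha_af`` (NaN where estimation failed, which is also
    tallied in the ``failed`` column of the aggregate).
    """
    import pandas as pd  # local import keeps module import light

    root = np.random.SeedSequence(config.seed)
    rows = []
    n_cells = len(config.n_sites_values) * len(config.lambda_values)
    cell_seeds = root.spawn(n_cells)
    i = 0
    for n_sites in config.n_sites_values:
        for lam in config.lambda_values:
            rep_seeds = cell_seeds[i].spawn(config.reps)
            i += 1
            for rep, ss in enumerate(rep_seeds):
                rng = np.random.default_rng(ss)
                series = simulate_release_series(
                    n_sites, lam, config.series_duration, rng, config.walk
                )
                row = {
                    "n_sites": n_sites,
                    "lam": lam,
                    "rep": rep,
                    "n_events": series.n_events,
                }
                try:
                    pg = count_periodogram(series, config.pg_window_length)
                    row["alpha_pg"] = estimate_alpha_pg(pg).alpha
                except ValueError:
                    row["alpha_pg"] = np.nan
                try:
                    af = allan_factor(series, default_tau_grid(series.span))
                    row["alpha_af"] = estimate_alpha_af(af).alpha
                except ValueError:
                    row["alpha_af"] = np.nan
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BiExpFit:
    """Saturating bi-exponential fit of alpha versus lambda.

    ``alpha(lam) = A1 (1 - exp(-k1 lam)) + A2 (1 - exp(-k2 lam)) + c``
    """

    a1: float
    a2: float
    k1: float
    k2: float
    c: float
    r_squared: float

    def __call__(self, lam: np.ndarray) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        return (
            self.a1 * (1 - np.exp(-self.k1 * lam))
            + self.a2 * (1 - np.exp(-self.k2 * lam))
            + self.c
        )


@dataclass(frozen=True)
class PowerFit:
    """Three-parameter power fit ``y = a x^b + c``."""

    a: float
    b: float
    c: float
    r_squared: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(x, dtype=float) ** self.b + self.c


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 0.0 if ss_res > 0 else 1.0
    return 1.0 - ss_res / ss_tot


def fit_alpha_lambda(
    lambdas: np.ndarray, alphas: np.ndarray, n_starts: int = 12, seed: int = 0
) -> BiExpFit:
    """Non-linear least-squares bi-exponential fit of alpha(lambda)."""
    lam = np.asarray(lambdas, dtype=float)
    alp = np.asarray(alphas, dtype=float)
    if lam.size < 6:
        raise ValueError("need at least 6 points for the bi-exponential fit")

    def model(x, a1, a2, k1, k2, c):
        # clip exponents: the optimizer may explore very large rates
        e1 = np.exp(np.clip(-k1 * x, -700.0, 50.0))
        e2 = np.exp(np.clip(-k2 * x, -700.0, 50.0))
        return a1 * (1 - e1) + a2 * (1 - e2) + c

    span = alp.max() - alp.min()
    rng = np.random.default_rng(seed)
    best = None
    starts = [(span / 2, span / 2, 1.0, 0.2, alp.min())]
    for _ in range(n_starts - 1):
        starts.append(
            (
                span * rng.uniform(0.1, 1.0),
                span * rng.uniform(0.1, 1.0),
                10 ** rng.uniform(-1.5, 1.5),
                10 ** rng.uniform(-1.5, 1.5),
                alp.min() + span * rng.uniform(-0.3, 0.3),
            )
        )
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(model, lam, alp, p0=p0, maxfev=20_000)
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        r2 = _r_squared(alp, model(lam, *popt))
        if best is None or r2 > best[1]:
            best = (popt, r2)
    if best is None:
        raise RuntimeError(
            "bi-exponential fit failed to converge from all starting points"
        )
    (a1, a2, k1, k2, c), r2 = best
    return BiExpFit(a1=a1, a2=a2, k1=k1, k2=k2, c=c, r_squared=r2)


def fit_power_function(
    x: np.ndarray, y: np.ndarray, n_starts: int = 8, seed: int = 0
) -> PowerFit:
    """Least-squares three-parameter power fit ``y = a x^b + c``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points for the power fit")
    if np.any(x <= 0):
        raise ValueError("x must be positive for a power fit")

    def model(xx, a, b, c):
        return a * xx**b + c

    rng = np.random.default_rng(seed)
    span = y.max() - y.min()
    starts = [(span if span else 1.0, 0.5, y.min())]
    for _ in range(n_starts - 1):
        starts.append(
            (
                (span if span else 1.0) * rng.uniform(0.1, 2.0) * rng.choice((-1, 1)),
                rng.uniform(-2.0, 2.0),
                y.min() + (span if span else 1.0) * rng.uniform(-0.5, 0.5),
            )
        )
    best = None
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=20_000)
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        r2 = _r_squared(y, model(x, *popt))
        if best is None or r2 > best[1]:
            best = (popt, r2)
    if best is None:
        raise RuntimeError("power fit failed to converge from all starting points")
    (a, b, c), r2 = best
    return PowerFit(a=a, b=b, c=c, r_squared=r2)
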