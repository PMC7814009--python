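"""Population growth models and genetic-variability projection.

Three deterministic growth models for a clonal population founded by a
single individual:

* exponential: ``N(t) = N0 * exp(g t)`` with per-capita log rate ``g``
  (``exp(g)`` offspring per animal per year),
* discrete logistic: ``N_{i+1} = N_i + (g dt) N_i (1 - N_i / N_max)``,
* strong Allee: ``dN = N (g dt) (1 - A / N)``; with a negative threshold
  ``A`` the per-capita rate exceeds the exponential rate at small ``N``.

Trajectories are converted into genetic-variability curves. For a clone,
every mutation event in any lineage creates a distinct heritable variant,
so the default "population-history" strategy integrates the expected
number of mutation events over the whole history:

    v(t) = mu * G * integral_0^t N(s) ds

with ``mu`` the per-bp per-year mutation rate and ``G`` the genome length
in bp. Two alternative reconstructions are available: "census-accumulated"
(``N(t) * mu * G * t``: per-lineage accumulation times census size) and
"annual-rate" (``N(t) * mu * G``: new variants arising per year). The
strategy used is always recorded in the result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GrowthParams",
    "VariabilityParams",
    "Trajectory",
    "IntersectionResult",
    "VARIABILITY_STRATEGIES",
    "step_exponential",
    "step_logistic",
    "step_allee",
    "simulate",
    "logistic_equilibrium",
    "variability_current",
    "variability_trajectory",
    "intersection_time",
    "growth_intersection",
]

#: growth-rate spread used for error bands: exp(g) = 200 +/- 100 offspring
#: per animal per year.
RATE_CENTRAL = 200.0
RATE_SPREAD = 100.0


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the growth simulation.

    offspring_rate is exp(g) in offspring per animal per year; n_max the
    logistic carrying capacity in animals; allee_threshold the strong-Allee
    parameter A (negative for the established crayfish value); dt the step
    in years; n0 the founding size; horizon the simulated span in years.
    """

    offspring_rate: float = RATE_CENTRAL
    n_max: float = 192_000.0
    allee_threshold: float = -3.1
    dt: float = 1.0 / 365.0
    n0: float = 1.0
    horizon: float = 6.0

    def __post_init__(self) -> None:
        if self.offspring_rate <= 0:
            raise ValueError("offspring_rate must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n0 < 1:
            raise ValueError("n0 must be at least 1")

    @property
    def g(self) -> float:
        """Per-year log growth rate, g = ln(offspring_rate)."""
        return math.log(self.offspring_rate)


@dataclass(frozen=True)
class VariabilityParams:
    """Mutation-process parameters for variability curves.

    mu: mutations per bp per year; genome_length: bp; snv_per_specimen:
    mean SNV count observed per sequenced specimen; current_n: census
    estimate of the present population.
    """

    mu: float = 3.6e-9
    genome_length: float = 3_511_656_756.0
    snv_per_specimen: float | None = None
    current_n: float | None = None

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.genome_length <= 0:
            raise ValueError("mu and genome_length must be positive")

    @property
    def mu_genome(self) -> float:
        """Expected mutations per lineage per year, mu * G."""
        return self.mu * self.genome_length


@dataclass(frozen=True)
class Trajectory:
    times: np.ndarray  # years, strictly increasing
    sizes: np.ndarray  # animals (real-valued)
    model: str

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.sizes < 0):
            raise ValueError("sizes must be nonnegative")


def step_exponential(n: float, g: float, dt: float) -> float:
    """One discrete exponential step; composes exactly to the closed form."""
    if n < 0:
        raise ValueError("population size must be nonnegative")
    return n * math.exp(g * dt)


def step_logistic(n: float, g: float, n_max: float, dt: float) -> float:
    """One discrete logistic step with per-step rate g*dt.

    N_max is a fixed point. For 0 < g*dt <= 1 and 0 <= N < N_max the
    approach is monotone; g*dt > 1 is the oscillatory/overshoot regime and
    triggers a warning (the value is still returned).
    """
    if n < 0:
        raise ValueError("population size must be nonnegative")
    r = g * dt
    if r > 1:
        warnings.warn(
            f"g*dt = {r:.3g} > 1: discrete logistic may overshoot/oscillate",
            stacklevel=2,
        )
    return n + r * n * (1.0 - n / n_max)


def step_allee(n: float, g: float, allee_threshold: float, dt: float) -> float:
    """One strong-Allee step, dN = N (g dt) (1 - A/N); N=0 is absorbing."""
    if n < 0:
        raise ValueError("population size must be nonnegative")
    if n == 0:
        return 0.0
    return n + n * (g * dt) * (1.0 - allee_threshold / n)


def simulate(model: str, params: GrowthParams) -> Trajectory:
    """Simulate a growth trajectory on the grid t = 0, dt, 2dt, ... horizon."""
    n_steps = int(round(params.horizon / params.dt))
    times = np.arange(n_steps + 1) * params.dt
    sizes = np.empty(n_steps + 1)
    sizes[0] = params.n0
    g = params.g
    if model == "exponential":
        # closed form: exact for any step partition
        sizes[:] = params.n0 * np.exp(g * times)
    elif model == "logistic":
        n = params.n0
        for i in range(1, n_steps + 1):
            n = step_logistic(n, g, params.n_max, params.dt)
            sizes[i] = n
    elif model == "allee":
        n = params.n0
        for i in range(1, n_steps + 1):
            n = step_allee(n, g, params.allee_threshold, params.dt)
            sizes[i] = n
    else:
        raise ValueError(f"unknown growth model {model!r}")
    return Trajectory(times=times, sizes=sizes, model=model)


def logistic_equilibrium(params: GrowthParams, tol: float = 1e-6, max_steps: int = 10_000_000) -> float:
    """Iterate the discrete logistic map until |N_{i+1} - N_i| < tol.

    Returns the converged population size (the carrying capacity for any
    0 < n0 < n_max with g*dt <= 1).
    """
    n = params.n0
    g = params.g
    for _ in range(max_steps):
        n_next = step_logistic(n, g, params.n_max, params.dt)
        if abs(n_next - n) < tol:
            return n_next
        n = n_next
    raise RuntimeError("logistic iteration did not converge")


def variability_current(vp: VariabilityParams) -> tuple[float, float]:
    """Current-population variability and its one-significant-figure level.

    v_now = snv_per_specimen * current_n. Returns (value, order of
    magnitude), e.g. (1.126e9, 1e9).
    """
    if vp.snv_per_specimen is None or vp.current_n is None:
        raise ValueError("snv_per_specimen and current_n must be set")
    v = vp.snv_per_specimen * vp.current_n
    if v == 0:
        return 0.0, 0.0
    exponent = math.floor(math.log10(v))
    mantissa = round(v / 10**exponent)
    if mantissa == 10:  # e.g. 9.7e8 rounds up a decade
        mantissa, exponent = 1, exponent + 1
    return v, mantissa * 10.0**exponent


def _v_population_history(traj: Trajectory, vp: VariabilityParams) -> np.ndarray:
    # cumulative trapezoid of N(t); v = mu G * integral N ds
    dt = np.diff(traj.times)
    seg = 0.5 * (traj.sizes[1:] + traj.sizes[:-1]) * dt
    integral = np.concatenate([[0.0], np.cumsum(seg)])
    return vp.mu_genome * integral


def _v_census_accumulated(traj: Trajectory, vp: VariabilityParams) -> np.ndarray:
    return traj.sizes * vp.mu_genome * traj.times


def _v_annual_rate(traj: Trajectory, vp: VariabilityParams) -> np.ndarray:
    return traj.sizes * vp.mu_genome


VARIABILITY_STRATEGIES = {
    "population-history": _v_population_history,
    "census-accumulated": _v_census_accumulated,
    "annual-rate": _v_annual_rate,
}


def variability_trajectory(
    traj: Trajectory,
    vp: VariabilityParams,
    strategy: str = "population-history",
) -> tuple[np.ndarray, dict]:
    """Map a population trajectory onto a genetic-variability curve.

    Returns (values aligned with traj.times, metadata recording the
    strategy and parameters used).
    """
    try:
        fn = VARIABILITY_STRATEGIES[strategy]
    except KeyError:
        raise ValueError(
            f"unknown variability strategy {strategy!r}; "
            f"choose from {sorted(VARIABILITY_STRATEGIES)}"
        ) from None
    values = fn(traj, vp)
    meta = {
        "strategy": strategy,
        "mu": vp.mu,
        "genome_length": vp.genome_length,
        "model": traj.model,
    }
    return values, meta


@dataclass(frozen=True)
class IntersectionResult:
    t_star: float  # years, central parameters
    band: tuple[float, float]  # t* at the fast (high-rate) and slow ends
    half_width: float
    strategy: str
    model: str
    target: float


class NoIntersectionError(RuntimeError):
    """The variability curve never reaches the target within the horizon."""


def intersection_time(
    times: np.ndarray,
    values: np.ndarray,
    target: float,
    tol: float = 1e-3,
) -> float:
    """Smallest t with v(t) >= target, refined between bracketing samples.

    The curve between adjacent samples is interpolated monotonically
    (linearly in log v when both endpoints are positive) and the crossing
    refined by bisection to ``tol`` years.
    """
    if target <= values[0]:
        return float(times[0])
    above = np.nonzero(values >= target)[0]
    if above.size == 0:
        raise NoIntersectionError(
            f"target {target:g} not reached within horizon {times[-1]:g} y"
        )
    i = int(above[0])
    t_lo, t_hi = float(times[i - 1]), float(times[i])
    v_lo, v_hi = float(values[i - 1]), float(values[i])

    if v_lo > 0 and v_hi > 0:
        def interp(t: float) -> float:
            w = (t - t_lo) / (t_hi - t_lo)
            return math.exp((1 - w) * math.log(v_lo) + w * math.log(v_hi))
    else:
        def interp(t: float) -> float:
            w = (t - t_lo) / (t_hi - t_lo)
            return (1 - w) * v_lo + w * v_hi

    while t_hi - t_lo > tol:
        mid = 0.5 * (t_lo + t_hi)
        if interp(mid) >= target:
            t_hi = mid
        else:
            t_lo = mid
    return 0.5 * (t_lo + t_hi)


def growth_intersection(
    gp: GrowthParams,
    vp: VariabilityParams,
    target: float,
    model: str = "exponential",
    strategy: str = "population-history",
    rate_spread: float = RATE_SPREAD,
) -> IntersectionResult:
    """Intersection time of the variability curve with a target level.

    The error band is taken from the stated offspring-rate spread
    (exp(g) = central +/- spread): the fast end of the band uses the high
    rate, the slow end the low rate. Reported as [t_fast, t_slow] with the
    half-width (t_slow - t_fast) / 2.
    """

    def t_at(rate: float) -> float:
        p = replace(gp, offspring_rate=rate)
        traj = simulate(model, p)
        values, _ = variability_trajectory(traj, vp, strategy)
        return intersection_time(traj.times, values, target)

    t_star = t_at(gp.offspring_rate)
    t_fast = t_at(gp.offspring_rate + rate_spread)
    t_slow = t_at(gp.offspring_rate - rate_spread)
    return IntersectionResult(
        t_star=t_star,
        band=(t_fast, t_slow),
        half_width=0.5 * (t_slow - t_fast),
        strategy=strategy,
        model=model,
        target=target,
    )
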