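"""Deterministic simulators for chaotic systems used as pseudoperiodic test data.

Three classic systems are provided: the Rössler and Lorenz flows (integrated
with a fixed-step classical Runge-Kutta 4 scheme) and the Duffing map.  Their
x-components serve as pseudoperiodic time series for network construction.
All simulators are bitwise deterministic given their specification.

The canonical chaotic parameter values are used as defaults:

* Rössler: ``a = b = 0.2, c = 5.7``
* Lorenz:  ``sigma = 10, rho = 28, beta = 8/3``
* Duffing map: ``a = 2.75, b = 0.2``
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .exceptions import DivergenceError, InsufficientDataError

__all__ = [
    "OdeSpec",
    "MapSpec",
    "TimeSeries",
    "ROSSLER_DEFAULTS",
    "LORENZ_DEFAULTS",
    "DUFFING_DEFAULTS",
    "OVERFLOW_GUARD",
    "rossler_rhs",
    "lorenz_rhs",
    "rk4_step",
    "simulate_rossler",
    "simulate_lorenz",
    "iterate_duffing",
    "make_series_factory",
]

#: Abort integration if any state component exceeds this magnitude.
OVERFLOW_GUARD = 1e6

ROSSLER_DEFAULTS = {"a": 0.2, "b": 0.2, "c": 5.7}
LORENZ_DEFAULTS = {"sigma": 10.0, "rho": 28.0, "beta": 8.0 / 3.0}
DUFFING_DEFAULTS = {"a": 2.75, "b": 0.2}


@dataclass(frozen=True)
class TimeSeries:
    """An ordered sequence of finite real samples.

    Parameters
    ----------
    values : array_like
        The samples, in temporal order.  All values must be finite.
    dt : float, optional
        Sampling interval in system time units.  Purely informational;
        the analysis operates on sample indices.
    """

    values: np.ndarray
    dt: float | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError("TimeSeries values must all be finite")
        if self.dt is not None and not (self.dt > 0):
            raise ValueError("dt must be positive when given")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def _check_common(dt_needed, dt, n_steps, transient_steps, parameters, initial_state, dim):
    if dt_needed and not (dt > 0):
        raise ValueError("dt must be > 0")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if transient_steps < 0:
        raise ValueError("transient_steps must be >= 0")
    state = np.asarray(initial_state, dtype=float)
    if state.shape != (dim,):
        raise ValueError(f"initial_state must be a {dim}-vector")
    if not np.all(np.isfinite(state)):
        raise ValueError("initial_state must be finite")
    for k, v in parameters.items():
        if not math.isfinite(v):
            raise ValueError(f"parameter {k!r} must be finite")
    return state


@dataclass(frozen=True)
class OdeSpec:
    """Specification of a continuous-flow simulation (Rössler or Lorenz).

    ``transient_steps`` integration steps are taken and discarded before
    ``n_steps`` samples of the x-component are recorded, so the recorded
    trajectory starts on (or near) the attractor.
    """

    system_name: str
    parameters: dict = field(default_factory=dict)
    initial_state: tuple = (1.0, 1.0, 1.0)
    dt: float = 0.05
    n_steps: int = 10_000
    transient_steps: int = 0

    def __post_init__(self):
        if self.system_name not in ("rossler", "lorenz"):
            raise ValueError(f"unknown system_name {self.system_name!r}")
        defaults = ROSSLER_DEFAULTS if self.system_name == "rossler" else LORENZ_DEFAULTS
        params = {**defaults, **dict(self.parameters)}
        unknown = set(params) - set(defaults)
        if unknown:
            raise ValueError(f"unknown parameters for {self.system_name}: {sorted(unknown)}")
        state = _check_common(True, self.dt, self.n_steps, self.transient_steps,
                              params, self.initial_state, 3)
        object.__setattr__(self, "parameters", params)
        object.__setattr__(self, "initial_state", tuple(state))


@dataclass(frozen=True)
class MapSpec:
    """Specification of a Duffing-map iteration."""

    parameters: dict = field(default_factory=dict)
    initial_state: tuple = (0.1, 0.1)
    n_steps: int = 10_000
    transient_steps: int = 0

    def __post_init__(self):
        params = {**DUFFING_DEFAULTS, **dict(self.parameters)}
        unknown = set(params) - set(DUFFING_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown Duffing parameters: {sorted(unknown)}")
        state = _check_common(False, None, self.n_steps, self.transient_steps,
                              params, self.initial_state, 2)
        object.__setattr__(self, "parameters", params)
        object.__setattr__(self, "initial_state", tuple(state))


def rossler_rhs(state: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """Right-hand side of the Rössler flow: (-y - z, x + a y, b + z (x - c))."""
    x, y, z = state
    return np.array([-y - z, x + a * y, b + z * (x - c)])


def lorenz_rhs(state: np.ndarray, sigma: float, rho: float, beta: float) -> np.ndarray:
    """Right-hand side of the Lorenz flow."""
    x, y, z = state
    return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])


def rk4_step(rhs: Callable[[np.ndarray], np.ndarray], state: np.ndarray, dt: float) -> np.ndarray:
    """One classical Runge-Kutta 4 step of size ``dt``."""
    k1 = rhs(state)
    k2 = rhs(state + 0.5 * dt * k1)
    k3 = rhs(state + 0.5 * dt * k2)
    k4 = rhs(state + dt * k3)
    return state + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def _integrate(rhs, spec: OdeSpec) -> TimeSeries:
    state = np.asarray(spec.initial_state, dtype=float)
    out = np.empty(spec.n_steps)
    step = 0
    for _ in range(spec.transient_steps):
        state = rk4_step(rhs, state, spec.dt)
        step += 1
        if np.max(np.abs(state)) > OVERFLOW_GUARD:
            raise DivergenceError(step)
    for k in range(spec.n_steps):
        out[k] = state[0]
        state = rk4_step(rhs, state, spec.dt)
        step += 1
        if np.max(np.abs(state)) > OVERFLOW_GUARD:
            raise DivergenceError(step)
    return TimeSeries(out, dt=spec.dt)


def simulate_rossler(spec: OdeSpec) -> TimeSeries:
    """Integrate the Rössler flow and return the sampled x-component.

    The first recorded sample is the state reached after discarding
    ``transient_steps`` steps.
    """
    if spec.system_name != "rossler":
        raise ValueError("spec.system_name must be 'rossler'")
    p = spec.parameters
    return _integrate(lambda s: rossler_rhs(s, p["a"], p["b"], p["c"]), spec)


def simulate_lorenz(spec: OdeSpec) -> TimeSeries:
    """Integrate the Lorenz flow and return the sampled x-component."""
    if spec.system_name != "lorenz":
        raise ValueError("spec.system_name must be 'lorenz'")
    p = spec.parameters
    return _integrate(lambda s: lorenz_rhs(s, p["sigma"], p["rho"], p["beta"]), spec)


def iterate_duffing(spec: MapSpec) -> TimeSeries:
    """Iterate the Duffing map and return the x-orbit.

    The map is ``x' = y``, ``y' = -b x + a y - y^3``.
    """
    a, b = spec.parameters["a"], spec.parameters["b"]
    x, y = spec.initial_state
    for step in range(spec.transient_steps):
        x, y = y, -b * x + a * y - y ** 3
        if abs(x) > OVERFLOW_GUARD or abs(y) > OVERFLOW_GUARD:
            raise DivergenceError(step + 1)
    out = np.empty(spec.n_steps)
    for k in range(spec.n_steps):
        out[k] = x
        x, y = y, -b * x + a * y - y ** 3
        if abs(x) > OVERFLOW_GUARD or abs(y) > OVERFLOW_GUARD:
            raise DivergenceError(spec.transient_steps + k + 1)
    return TimeSeries(out)


# rough samples-per-cycle at the default time steps, used only as an initial
# guess when sizing a simulation to a requested cycle count
_SPC_GUESS = {"rossler": 125, "lorenz": 80, "duffing": 4}
_BASE_IC = {"rossler": (1.0, 1.0, 1.0), "lorenz": (1.0, 1.0, 1.0), "duffing": (0.1, 0.1)}
_DEFAULT_DT = {"rossler": 0.05, "lorenz": 0.01}


def make_series_factory(system: str = "rossler", dt: float | None = None,
                        parameters: dict | None = None, min_len: int = 5,
                        transient_frac: float = 0.1):
    """Return ``factory(n_cycles, seed) -> TimeSeries`` for ensemble studies.

    Each call perturbs the canonical initial condition with a seeded uniform
    jitter, discards a transient (10% of the recorded length by default) and
    sizes the run so that at least ``n_cycles`` complete cycles are present;
    if the first guess falls short the run is enlarged and repeated.

    The returned series may contain more than ``n_cycles`` cycles; callers
    truncate to their cycle budget.
    """
    if system not in _SPC_GUESS:
        raise ValueError(f"unknown system {system!r}")
    dt = dt if dt is not None else _DEFAULT_DT.get(system)
    parameters = dict(parameters or {})

    def factory(n_cycles: int, seed: int) -> TimeSeries:
        from .segmentation import detect_cycles  # local import: avoids a cycle

        rng = np.random.default_rng(seed)
        base = np.asarray(_BASE_IC[system], dtype=float)
        ic = tuple(base + rng.uniform(-0.5, 0.5, size=base.size))
        n_steps = int(n_cycles * _SPC_GUESS[system] * 1.4) + 200
        for _ in range(8):
            transient = int(transient_frac * n_steps)
            if system == "rossler":
                ts = simulate_rossler(OdeSpec("rossler", parameters, ic, dt, n_steps, transient))
            elif system == "lorenz":
                ts = simulate_lorenz(OdeSpec("lorenz", parameters, ic, dt, n_steps, transient))
            else:
                ts = iterate_duffing(MapSpec(parameters, ic, n_steps, transient))
            try:
                cycles = detect_cycles(ts, min_len=min_len)
            except Exception:
                cycles = []
            if len(cycles) >= n_cycles:
                return ts
            n_steps = int(n_steps * 1.6)
        raise InsufficientDataError(
            f"could not obtain {n_cycles} cycles from system {system!r} (seed {seed})")

    factory.system = system
    return factory
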