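"""Dynamic models and their discretization.

A pathway model is an ordinary differential equation

    dx/dt = f(theta, x(t), u(t), t),    x(t0) = x0,

where ``x`` is the (scalar) state, ``u(t)`` a vector of externally supplied
forcing signals (cytokine concentrations, cell densities, ...), and ``theta``
the strictly positive parameters to be estimated.  The ODE is discretized
with the classical fourth-order Runge-Kutta (RK4) scheme, which yields both

* a *trajectory simulator* (chained RK4 steps from ``x0``), used to generate
  synthetic data, and
* a *one-step-ahead predictor*: the prediction at ``t_{i+1}`` is a single RK4
  step launched from the **observed** value ``y_i`` rather than from the
  propagated model state.  This is the prediction contract the inference
  likelihood is built on.

The worked instance is a TGF-beta secretion model for the post-myocardial-
infarction wound-healing response: macrophages, stimulated by IL-10, secrete
TGF-beta, which degrades at a first-order rate ``a``:

    dx/dt = -a*x + V*u(t)^H / (K + u(t)^H) * Mphi(t)

with ``u`` the IL-10 concentration, ``Mphi`` the macrophage density, and the
Hill parameters ``V`` (maximal rate) and ``K`` (saturation constant) the
quantities of biological interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "HillTerm",
    "hill_rate",
    "tgf_rhs",
    "DynamicsModel",
    "tgf_beta_model",
    "InputSignal",
    "TimeGrid",
    "ObservedSeries",
    "rk4_step",
    "simulate_trajectory",
    "predict_one_step_series",
    "OneStepPredictor",
]


def hill_rate(u, V: float, K: float, H: float = 2.0):
    """Hill reaction rate ``v = V * u^H / (K + u^H)``.

    Parameters
    ----------
    u : float or ndarray
        Reaction factor (e.g. stimulus concentration); must be nonnegative.
    V : float
        Maximal rate, strictly positive.
    K : float
        Saturation constant in units of ``u**H``, strictly positive.
    H : float
        Hill coefficient (number of cooperative binding sites), fixed and
        known; ``H >= 1``.

    Returns
    -------
    float or ndarray in ``[0, V)``, monotone increasing in ``u`` and ``V``
    and decreasing in ``K``.
    """
    if V <= 0 or K <= 0:
        raise ValueError(f"Hill parameters must be positive, got V={V}, K={K}")
    if H < 1:
        raise ValueError(f"Hill coefficient must be >= 1, got H={H}")
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("Hill rate is undefined for negative stimulus u")
    uH = u**H
    out = V * uH / (K + uH)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class HillTerm:
    """A Hill-equation rate law with maximal rate V, saturation constant K
    and fixed Hill coefficient H."""

    V: float
    K: float
    H: float = 2.0

    def __post_init__(self) -> None:
        if self.V <= 0 or self.K <= 0:
            raise ValueError("HillTerm requires V > 0 and K > 0")
        if self.H < 1:
            raise ValueError("HillTerm requires H >= 1")

    def __call__(self, u):
        return hill_rate(u, self.V, self.K, self.H)


def tgf_rhs(x, u, mphi, *, V: float, K: float, a: float = 15.0, H: float = 2.0):
    """State derivative of the TGF-beta model: ``-a*x + Hill(u)*Mphi``.

    ``x`` is the TGF-beta concentration, ``u`` the IL-10 concentration,
    ``mphi`` the macrophage density and ``a`` the TGF-beta degradation rate
    (per day; default 15, from half-life data).
    """
    mphi = np.asarray(mphi, dtype=float)
    if np.any(mphi < 0):
        raise ValueError("macrophage density must be nonnegative")
    return -a * np.asarray(x, dtype=float) + hill_rate(u, V, K, H) * mphi


@dataclass(frozen=True)
class DynamicsModel:
    """A parameterized scalar ODE right-hand side.

    ``rhs(params, x, u, t)`` receives a mapping of *all* parameter values
    (estimable ones merged over ``fixed_constants``), the state, a tuple of
    forcing values evaluated at ``t`` (one entry per input signal), and the
    time.  It must be numpy-vectorized over ``x``/``u``/``t`` and finite for
    strictly positive parameters and nonnegative states and inputs.
    """

    rhs: Callable
    param_names: tuple[str, ...]
    fixed_constants: Mapping[str, float] = field(default_factory=dict)
    state_dim: int = 1
    n_inputs: int = 1

    def __post_init__(self) -> None:
        if len(set(self.param_names)) != len(self.param_names):
            raise ValueError("parameter names must be unique")
        if self.state_dim != 1:
            raise NotImplementedError("only scalar-state models are supported")
        clash = set(self.param_names) & set(self.fixed_constants)
        if clash:
            raise ValueError(f"names both estimated and fixed: {sorted(clash)}")

    def full_params(self, theta) -> dict[str, float]:
        """Merge an ordered vector of estimable parameters with the fixed
        constants into one name->value mapping."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        if theta.shape != (len(self.param_names),):
            raise ValueError(
                f"expected {len(self.param_names)} parameter(s) "
                f"{self.param_names}, got shape {theta.shape}"
            )
        if np.any(theta <= 0):
            raise ValueError("all estimable parameters must be strictly positive")
        params = dict(self.fixed_constants)
        params.update(zip(self.param_names, theta))
        return params


def tgf_beta_model(
    estimate: Sequence[str] = ("V", "K"),
    *,
    V: float | None = None,
    K: float | None = None,
    a: float = 15.0,
    H: float = 2.0,
    x0: float = 0.21,
) -> DynamicsModel:
    """Build the TGF-beta `DynamicsModel` with a chosen set of estimable
    Hill parameters.

    Parameters not listed in ``estimate`` must be supplied as fixed values.
    The degradation rate ``a``, Hill coefficient ``H`` and initial
    concentration ``x0`` are always fixed per run.  The model takes two
    forcing signals, in order: IL-10 concentration and macrophage density.
    """
    estimate = tuple(estimate)
    bad = set(estimate) - {"V", "K"}
    if bad:
        raise ValueError(f"only V and K are estimable, got {sorted(bad)}")
    fixed: dict[str, float] = {"a": a, "H": H, "x0": x0}
    for name, value in (("V", V), ("K", K)):
        if name not in estimate:
            if value is None:
                raise ValueError(f"{name} is not estimated and needs a fixed value")
            fixed[name] = float(value)

    def rhs(params, x, u, t):
        il10, mphi = u
        return tgf_rhs(
            x, il10, mphi, V=params["V"], K=params["K"], a=params["a"], H=params["H"]
        )

    return DynamicsModel(rhs=rhs, param_names=estimate, fixed_constants=fixed, n_inputs=2)


class InputSignal:
    """A tabulated forcing signal with piecewise-linear interpolation.

    The RK4 stepper needs forcing values at half-steps ``t + h/2`` that are
    not observation times, so tabulated signals are interpolated linearly
    (monotone-safe: interpolated values stay within the bracketing samples).
    Evaluation outside the tabulated range raises.
    """

    def __init__(self, sample_times, sample_values) -> None:
        t = np.asarray(sample_times, dtype=float)
        v = np.asarray(sample_values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("an input signal needs at least two samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("input signal times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("input signal values must be nonnegative")
        self.sample_times = t
        self.sample_values = v

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        lo, hi = self.sample_times[0], self.sample_times[-1]
        if np.any(t < lo) or np.any(t > hi):
            raise ValueError(
                f"input signal evaluated at t outside covered range [{lo}, {hi}]"
            )
        out = np.interp(t, self.sample_times, self.sample_values)
        return out if out.ndim else float(out)

    def __len__(self) -> int:
        return self.sample_times.size


@dataclass(frozen=True)
class TimeGrid:
    """Uniform observation grid: times ``t0 + i*h`` for ``i = 0..m-1``."""

    t0: float
    h: float
    m: int

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("grid step h must be positive")
        if self.m < 2:
            raise ValueError("grid needs at least two points")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.h * np.arange(self.m)

    @property
    def t_end(self) -> float:
        return self.t0 + self.h * (self.m - 1)


# Default study grid: 500 observation points over a 20-day window,
# i.e. h = 0.04 day.
DEFAULT_GRID = TimeGrid(t0=0.0, h=0.04, m=500)


@dataclass(frozen=True)
class ObservedSeries:
    """Time-stamped observations of the state on a uniform grid."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("an observed series needs at least two points")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("observation times must be strictly increasing")
        h = dt[0]
        if not np.allclose(dt, h, rtol=1e-6, atol=1e-12):
            raise ValueError("observation grid must be uniform")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def m(self) -> int:
        return self.times.size

    @property
    def h(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid(t0=float(self.times[0]), h=self.h, m=self.m)


def _eval_inputs(inputs, t) -> tuple:
    return tuple(np.asarray(f(t), dtype=float) for f in inputs)


def rk4_step(model: DynamicsModel, theta, x_i, inputs, t_i: float, h: float):
    """One classical RK4 update of the state from ``t_i`` to ``t_i + h``.

    ``inputs`` is a sequence of callables (e.g. `InputSignal`) evaluable on
    ``[t_i, t_i + h]`` including the midpoint.  Vectorized over ``x_i``/
    ``t_i`` so a whole bank of independent steps can be taken at once.
    """
    params = model.full_params(theta)
    x_i = np.asarray(x_i, dtype=float)
    t_i = np.asarray(t_i, dtype=float)
    u0 = _eval_inputs(inputs, t_i)
    uh = _eval_inputs(inputs, t_i + 0.5 * h)
    u1 = _eval_inputs(inputs, t_i + h)
    return _rk4_kernel(model.rhs, params, x_i, t_i, h, u0, uh, u1)


def _rk4_kernel(rhs, params, x_i, t_i, h, u0, uh, u1):
    k1 = rhs(params, x_i, u0, t_i)
    k2 = rhs(params, x_i + 0.5 * h * k1, uh, t_i + 0.5 * h)
    k3 = rhs(params, x_i + 0.5 * h * k2, uh, t_i + 0.5 * h)
    k4 = rhs(params, x_i + h * k3, u1, t_i + h)
    for name, k in (("k1", k1), ("k2", k2), ("k3", k3), ("k4", k4)):
        if not np.all(np.isfinite(k)):
            raise FloatingPointError(f"non-finite RK4 increment {name}")
    return x_i + (h / 6.0) * (k1 + 2.0 * (k2 + k3) + k4)


def simulate_trajectory(model: DynamicsModel, theta, x0: float, grid: TimeGrid, inputs):
    """Integrate the model from ``x0`` across the grid by chaining RK4 steps.

    Returns the state series of length ``grid.m``; the first element is
    ``x0``.  Used for data generation; inference itself never propagates
    the state (see `predict_one_step_series`).
    """
    times = grid.times
    x = np.empty(grid.m)
    x[0] = x0
    for i in range(grid.m - 1):
        x[i + 1] = rk4_step(model, theta, x[i], inputs, times[i], grid.h)
    return x


class OneStepPredictor:
    """Vectorized one-step-ahead RK4 predictor on a fixed grid.

    Each prediction at ``t_{i+1}`` is one RK4 step launched from the observed
    ``y_i``; since the steps never share state they are all computed at once.
    Forcing values at the step endpoints and midpoints are evaluated once at
    construction, which makes repeated prediction (the MCMC inner loop)
    cheap.
    """

    def __init__(self, model: DynamicsModel, grid: TimeGrid, inputs) -> None:
        if len(inputs) != model.n_inputs:
            raise ValueError(
                f"model expects {model.n_inputs} input signal(s), got {len(inputs)}"
            )
        self.model = model
        self.grid = grid
        t = grid.times[:-1]
        self._t = t
        self._u0 = _eval_inputs(inputs, t)
        self._uh = _eval_inputs(inputs, t + 0.5 * grid.h)
        self._u1 = _eval_inputs(inputs, t + grid.h)

    def predict(self, theta, y: np.ndarray) -> np.ndarray:
        """Predicted series of length ``m - 1`` from observations ``y``."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.grid.m,):
            raise ValueError(f"expected {self.grid.m} observations, got {y.shape}")
        params = self.model.full_params(theta)
        return _rk4_kernel(
            self.model.rhs, params, y[:-1], self._t, self.grid.h,
            self._u0, self._uh, self._u1,
        )


def predict_one_step_series(model: DynamicsModel, theta, y: ObservedSeries, inputs):
    """One-step-ahead predictions for an observed series.

    Returns predictions for times ``t_1 .. t_{m-1}`` (length ``m - 1``),
    each obtained by a single RK4 step from the preceding observation.
    """
    return OneStepPredictor(model, y.grid, inputs).predict(theta, y.values)
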