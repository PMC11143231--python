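"""Delay kernels, the linear chain trick, and deterministic integration.

Distributed delays are Erlang (Gamma with integer shape) kernels

    K(tau) = rate**shape * tau**(shape-1) * exp(-rate*tau) / (shape-1)!

normalised to unit mass with mean shape/rate; shape 1 is the "weak" kernel,
shape 2 the "strong" kernel, and a discrete lag is the shape -> infinity
limit at fixed mean.  An Erlang delay attached to a state variable is exactly
equivalent to a chain of ``shape`` identical first-order relaxation stages
(the linear chain trick); :func:`expand_chain` performs that reduction so
distributed-delay models integrate as plain ODEs.

Discrete-delay systems are integrated by the method of steps: a fixed-step
explicit 4th-order Runge-Kutta scheme whose past values are read from the
stored solution through cubic Hermite interpolation (matching the scheme's
order), with a user-supplied history function for times before the start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "DelaySpec",
    "HistoryFunction",
    "Trajectory",
    "DelayedSystem",
    "ExpandedModel",
    "IntegrationError",
    "kernel_density",
    "expand_chain",
    "integrate",
    "erlang_to_discrete_limit_check",
]


class IntegrationError(RuntimeError):
    """Numerical integration failure (NaN state, bad history, bad step)."""


@dataclass(frozen=True)
class DelaySpec:
    """An Erlang (shape, rate) or discrete (lag) delay on one state variable.

    ``target`` names the state whose past value feeds the delayed term.
    Erlang mean is shape/rate, variance shape/rate**2.
    """

    kind: str  # "erlang" | "discrete"
    target: str
    shape: int | None = None  # erlang only, >= 1
    rate: float | None = None  # erlang only, 1/min
    lag: float | None = None  # discrete only, minutes

    def __post_init__(self) -> None:
        if self.kind == "erlang":
            if self.shape is None or self.rate is None:
                raise ValueError("erlang delay requires shape and rate")
            if not (isinstance(self.shape, (int, np.integer)) and self.shape >= 1):
                raise ValueError(f"erlang shape must be a positive integer, got {self.shape}")
            if not self.rate > 0:
                raise ValueError(f"erlang rate must be > 0, got {self.rate}")
        elif self.kind == "discrete":
            if self.lag is None or self.lag < 0:
                raise ValueError("discrete delay requires lag >= 0")
        else:
            raise ValueError(f"unknown delay kind {self.kind!r}")

    @property
    def mean(self) -> float:
        """Mean delay in minutes."""
        return self.shape / self.rate if self.kind == "erlang" else self.lag

    @property
    def variance(self) -> float:
        return self.shape / self.rate**2 if self.kind == "erlang" else 0.0

    @staticmethod
    def erlang(shape: int, rate: float, target: str = "x") -> "DelaySpec":
        return DelaySpec(kind="erlang", target=target, shape=shape, rate=rate)

    @staticmethod
    def weak(rate: float, target: str = "x") -> "DelaySpec":
        return DelaySpec.erlang(1, rate, target)

    @staticmethod
    def strong(rate: float, target: str = "x") -> "DelaySpec":
        return DelaySpec.erlang(2, rate, target)

    @staticmethod
    def discrete(lag: float, target: str = "x") -> "DelaySpec":
        return DelaySpec(kind="discrete", target=target, lag=lag)


def kernel_density(spec: DelaySpec, tau) -> float | np.ndarray:
    """Normalised Erlang delay-kernel density at lookback time ``tau`` (min).

    Shape 1 with rate g gives the weak kernel g*exp(-g*tau).  Integrates to
    one; mean shape/rate; variance shape/rate**2.  A discrete DelaySpec has a
    Dirac kernel and is rejected here.
    """
    if spec.kind != "erlang":
        raise ValueError("kernel_density is defined for erlang delays only")
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ValueError("lookback time tau must be >= 0")
    k, r = spec.shape, spec.rate
    out = r**k * tau_arr ** (k - 1) * np.exp(-r * tau_arr) / math.factorial(k - 1)
    return float(out) if out.ndim == 0 else out


class HistoryFunction:
    """State history for t <= t0, required by discrete-delay integration.

    Constructors: :meth:`constant` (defined for all past times) and
    :meth:`from_trajectory` (defined on the trajectory's time span; lookups
    before its start raise :class:`IntegrationError`).
    """

    def __init__(self, fn: Callable[[float], np.ndarray], t_min: float = -np.inf):
        self._fn = fn
        self.t_min = t_min

    def __call__(self, t: float) -> np.ndarray:
        if t < self.t_min:
            raise IntegrationError(
                f"history requested at t={t} before history start {self.t_min}"
            )
        return self._fn(t)

    @classmethod
    def constant(cls, y0) -> "HistoryFunction":
        y0 = np.atleast_1d(np.asarray(y0, dtype=float)).copy()
        return cls(lambda t: y0, t_min=-np.inf)

    @classmethod
    def from_trajectory(cls, traj: "Trajectory") -> "HistoryFunction":
        t, y = traj.t, traj.y

        def fn(s: float) -> np.ndarray:
            if s >= t[-1]:
                return y[-1]
            i = int(np.searchsorted(t, s, side="right")) - 1
            i = max(i, 0)
            w = (s - t[i]) / (t[i + 1] - t[i])
            return (1 - w) * y[i] + w * y[i + 1]

        return cls(fn, t_min=float(t[0]))


@dataclass
class Trajectory:
    """Dense solution of one integration: time grid + named state matrix."""

    t: np.ndarray
    y: np.ndarray  # shape (len(t), dim)
    state_names: tuple[str, ...]
    model: object = None

    def series(self, name: str) -> np.ndarray:
        try:
            return self.y[:, self.state_names.index(name)]
        except ValueError:
            raise KeyError(f"no state named {name!r}; have {self.state_names}") from None

    def final_state(self) -> np.ndarray:
        return self.y[-1]

    def window(self, t_lo: float, t_hi: float) -> "Trajectory":
        m = (self.t >= t_lo) & (self.t <= t_hi)
        return Trajectory(self.t[m], self.y[m], self.state_names, self.model)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            np.column_stack([self.t, self.y]), columns=("t_min",) + self.state_names
        )

    def to_csv(self, path, every: int = 1) -> None:
        """Write CSV (column 1 t_min, then states); ``every`` thins rows."""
        self.to_frame().iloc[::every].to_csv(path, index=False, float_format="%.10g")


@dataclass(frozen=True)
class DelayedSystem:
    """A minimal delay model: explicit rhs plus delay specs.

    ``rhs_fn(t, y, zs)`` receives ``zs``, the list of delayed *target* values
    (one scalar per entry of ``delays``, in order).  Used for small test
    systems and as the common structural contract that `CircuitModel`
    also satisfies.
    """

    rhs_fn: Callable
    state_names: tuple[str, ...]
    delays: tuple[DelaySpec, ...] = ()
    jacobians_fn: Callable | None = None
    fixed_point_fn: Callable | None = None
    tf_variable: str | None = None

    @property
    def dim(self) -> int:
        return len(self.state_names)

    def rhs_function(self):
        return self.rhs_fn

    def rhs(self, t, y, zs=()):
        return self.rhs_fn(t, y, zs)

    def jacobians(self):
        if self.jacobians_fn is None:
            raise NotImplementedError("no jacobians supplied for this system")
        return self.jacobians_fn()

    def fixed_point(self) -> np.ndarray:
        if self.fixed_point_fn is None:
            raise NotImplementedError("no fixed point supplied for this system")
        return np.atleast_1d(np.asarray(self.fixed_point_fn(), dtype=float))

    def with_delays(self, delays: tuple[DelaySpec, ...]) -> "DelayedSystem":
        return replace(self, delays=tuple(delays))


@dataclass(frozen=True)
class ExpandedModel:
    """A model whose Erlang delays were replaced by first-order stage chains.

    The expansion is exact (a reduction, not an approximation): each Erlang
    delay of shape k on target variable x becomes k auxiliary stages
    z_1..z_k with dz_i/dt = rate*(z_{i-1} - z_i), z_0 = x, and the delayed
    value is z_k.  State vector = inner states followed by all stages.
    """

    inner: object
    chains: tuple[tuple[int, int, float], ...]  # (target_index, shape, rate)
    state_names: tuple[str, ...]
    delays: tuple[DelaySpec, ...] = ()

    @property
    def dim(self) -> int:
        return len(self.state_names)

    @property
    def tf_variable(self):
        return getattr(self.inner, "tf_variable", None)

    def rhs_function(self):
        inner_rhs = self.inner.rhs_function()
        din = len(self.inner.state_names)
        chains = self.chains

        def rhs(t, y, zs=()):
            yin = y[:din]
            offset = din
            zvals = []
            spans = []
            for tgt, k, rate in chains:
                spans.append((offset, k, rate, tgt))
                zvals.append(y[offset + k - 1])
                offset += k
            dy = np.empty_like(y)
            dy[:din] = inner_rhs(t, yin, zvals)
            for (off, k, rate, tgt) in spans:
                prev = y[tgt]
                for i in range(k):
                    z = y[off + i]
                    dy[off + i] = rate * (prev - z)
                    prev = z
            return dy

        return rhs

    def rhs(self, t, y, zs=()):
        return self.rhs_function()(t, y, zs)

    def fixed_point(self) -> np.ndarray:
        fp_in = np.atleast_1d(self.inner.fixed_point())
        parts = [fp_in]
        for tgt, k, _rate in self.chains:
            parts.append(np.full(k, fp_in[tgt]))
        return np.concatenate(parts)

    def extend_state(self, y_inner) -> np.ndarray:
        """Lift an inner-model state to the expanded space (stages at target)."""
        y_inner = np.atleast_1d(np.asarray(y_inner, dtype=float))
        parts = [y_inner]
        for tgt, k, _rate in self.chains:
            parts.append(np.full(k, y_inner[tgt]))
        return np.concatenate(parts)

    def jacobians(self):
        """Assemble the expanded Jacobian from the inner (A, [(spec, b)])."""
        A_in, delayed = self.inner.jacobians()
        din = A_in.shape[0]
        d = self.dim
        A = np.zeros((d, d))
        A[:din, :din] = A_in
        offset = din
        for (tgt, k, rate), (_spec, b) in zip(self.chains, delayed):
            # inner rhs sees the last stage as the delayed value
            A[:din, offset + k - 1] += b
            prev_col = tgt
            for i in range(k):
                A[offset + i, prev_col] += rate
                A[offset + i, offset + i] -= rate
                prev_col = offset + i
            offset += k
        return A, []

    def perturbed_start(self, scale: float = 1.2) -> np.ndarray:
        if hasattr(self.inner, "perturbed_start"):
            return self.extend_state(self.inner.perturbed_start(scale))
        return self.fixed_point() * scale


def expand_chain(model) -> ExpandedModel:
    """Apply the linear chain trick: Erlang delays -> first-order stages.

    Every delay of the model must be Erlang; a discrete delay has no finite
    chain representation and raises ``ValueError``.
    """
    delays = tuple(model.delays)
    if not delays:
        return ExpandedModel(inner=model, chains=(), state_names=tuple(model.state_names))
    if any(d.kind != "erlang" for d in delays):
        raise ValueError("cannot chain-expand a model with discrete delays")
    names = list(model.state_names)
    chains = []
    for spec in delays:
        tgt = model.state_names.index(spec.target)
        chains.append((tgt, spec.shape, spec.rate))
        names.extend(f"{spec.target}_stage{i+1}" for i in range(spec.shape))
    return ExpandedModel(inner=model, chains=tuple(chains), state_names=tuple(names))


def _as_history(history_or_init, dim: int) -> HistoryFunction:
    if isinstance(history_or_init, HistoryFunction):
        return history_or_init
    if callable(history_or_init):
        return HistoryFunction(lambda t: np.atleast_1d(
            np.asarray(history_or_init(t), dtype=float)))
    y0 = np.atleast_1d(np.asarray(history_or_init, dtype=float))
    if y0.size != dim:
        raise ValueError(f"initial state has size {y0.size}, model dimension is {dim}")
    return HistoryFunction.constant(y0)


def integrate(
    model,
    history_or_init,
    t_span: tuple[float, float],
    step: float = 0.005,
    method: str = "rk4",
    check_every: int = 50,
) -> Trajectory:
    """Integrate a circuit model over ``t_span`` minutes.

    Erlang delays are chain-expanded first (exactly); discrete delays are
    handled by the method of steps with cubic Hermite interpolation of the
    stored solution.  ``history_or_init`` may be a state vector (constant
    history), a callable of time, or a :class:`HistoryFunction`.  The result
    is deterministic given inputs and step settings.

    ``method="lsoda"`` selects the stiff scipy fallback (delay-free systems
    only, i.e. plain ODEs or Erlang delays).
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ValueError(f"need t1 > t0, got {t_span}")
    if not step > 0:
        raise ValueError(f"step must be > 0, got {step}")

    delays = tuple(getattr(model, "delays", ()))
    if any(d.kind == "erlang" for d in delays):
        expanded = expand_chain(model)
        hist = _as_history(history_or_init, len(model.state_names))
        lifted = HistoryFunction(
            lambda t: expanded.extend_state(hist(t)), t_min=hist.t_min
        )
        return integrate(expanded, lifted, t_span, step=step, method=method)

    dim = model.dim
    hist = _as_history(history_or_init, dim)
    lag_specs = delays
    lags = [d.lag for d in lag_specs]
    tgt_idx = [model.state_names.index(d.target) for d in lag_specs]
    rhs = model.rhs_function()

    if method == "lsoda":
        if lag_specs:
            raise ValueError("stiff fallback supports delay-free systems only")
        from scipy.integrate import solve_ivp

        tgrid = np.arange(t0, t1 + 0.5 * step, step)
        sol = solve_ivp(
            lambda t, y: rhs(t, y, []), (t0, t1), hist(t0), t_eval=tgrid,
            method="LSODA", rtol=1e-9, atol=1e-10,
        )
        if not sol.success:
            raise IntegrationError(f"LSODA failed: {sol.message}")
        return Trajectory(sol.t, sol.y.T, tuple(model.state_names), model)
    if method != "rk4":
        raise ValueError(f"unknown method {method!r}")

    positive_lags = [L for L in lags if L > 0]
    if positive_lags and min(positive_lags) < step:
        raise IntegrationError(
            f"step {step} exceeds smallest lag {min(positive_lags)}; reduce the step"
        )

    n = int(round((t1 - t0) / step))
    h = (t1 - t0) / n
    y0 = hist(t0)
    T = t0 + h * np.arange(n + 1)
    Y = np.empty((n + 1, dim))
    F = np.empty((n + 1, dim))
    Y[0] = y0

    def lookup(s: float, i_known: int) -> np.ndarray:
        if s <= t0:
            return hist(s)
        idx = int((s - t0) / h)
        if idx >= i_known:
            idx = i_known - 1
            if idx < 0:
                raise IntegrationError(f"lookup at t={s} before any stored solution")
        th = (s - T[idx]) / h
        yl, yr = Y[idx], Y[idx + 1]
        fl, fr = F[idx], F[idx + 1]
        h00 = (1 + 2 * th) * (1 - th) ** 2
        h10 = th * (1 - th) ** 2
        h01 = th * th * (3 - 2 * th)
        h11 = th * th * (th - 1)
        return h00 * yl + h10 * h * fl + h01 * yr + h11 * h * fr

    if lags:
        def f(t, y, i_known, current=None):
            zs = []
            for L, j in zip(lags, tgt_idx):
                if L == 0.0:
                    zs.append((current if current is not None else y)[j])
                else:
                    zs.append(lookup(t - L, i_known)[j])
            return rhs(t, y, zs)
    else:
        def f(t, y, i_known, current=None):
            return rhs(t, y, [])

    F[0] = f(T[0], Y[0], 0, current=Y[0])
    for i in range(n):
        t = T[i]
        y = Y[i]
        k1 = F[i]
        k2 = f(t + h / 2, y + (h / 2) * k1, i, current=y + (h / 2) * k1)
        k3 = f(t + h / 2, y + (h / 2) * k2, i, current=y + (h / 2) * k2)
        k4 = f(t + h, y + h * k3, i, current=y + h * k3)
        Y[i + 1] = y + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
        F[i + 1] = f(T[i + 1], Y[i + 1], i + 1, current=Y[i + 1])
        if (i + 1) % check_every == 0 and not np.all(np.isfinite(Y[i + 1])):
            raise IntegrationError(
                f"non-finite state at t={T[i+1]:.4f} min (step {h}); "
                "the step size is likely too large for the fastest rate"
            )
    if not np.all(np.isfinite(Y[-1])):
        raise IntegrationError(f"non-finite state at t={T[-1]:.4f} min")
    return Trajectory(T, Y, tuple(model.state_names), model)


def erlang_to_discrete_limit_check(
    base_model,
    history_or_init,
    t_span: tuple[float, float],
    mean_lag: float,
    shapes: Sequence[int],
    step: float = 0.005,
):
    """Trajectory distance of Erlang-kernel runs to the discrete-lag run.

    For each shape k the model's single delay is replaced by Erlang
    (k, k/mean_lag) — same mean, shrinking variance — and the sup-norm
    distance of the inner-state trajectory to the discrete-lag (= infinite
    shape) trajectory is tabulated.  The distance must be monotonically
    non-increasing in shape as the Erlang kernel converges to the Dirac lag.
    """
    shapes = list(shapes)
    if any(s2 <= s1 for s1, s2 in zip(shapes, shapes[1:])):
        raise ValueError("shapes must be strictly increasing")
    delays = tuple(base_model.delays)
    if len(delays) != 1:
        raise ValueError("limit check requires a model with exactly one delay")
    target = delays[0].target
    din = len(base_model.state_names)

    disc = base_model.with_delays((DelaySpec.discrete(mean_lag, target),))
    ref = integrate(disc, history_or_init, t_span, step=step)
    rows = []
    for k in shapes:
        spec = DelaySpec.erlang(int(k), int(k) / mean_lag, target)
        traj = integrate(base_model.with_delays((spec,)), history_or_init, t_span, step=step)
        dist = float(np.max(np.abs(traj.y[:, :din] - ref.y[:, :din])))
        rows.append({"shape": int(k), "variance": spec.variance, "sup_distance": dist})
    import pandas as pd

    return pd.DataFrame(rows)
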