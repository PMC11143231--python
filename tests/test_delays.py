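"""Delay kernels, chain-trick exactness, and the method-of-steps integrator."""

import numpy as np
import pytest
from scipy.integrate import quad

from genosc.delays import (
    DelayedSystem,
    DelaySpec,
    HistoryFunction,
    IntegrationError,
    erlang_to_discrete_limit_check,
    expand_chain,
    integrate,
    kernel_density,
)


def linear_feedback(b=1.5, u=3.0, g=1.0, delay=None):
    """dx/dt = u - b*z - g*x with z the delayed x; fixed point u/(b+g)."""
    fp = u / (b + g)
    return DelayedSystem(
        rhs_fn=lambda t, y, zs: np.array([u - b * zs[0] - g * y[0]]),
        state_names=("x",),
        delays=(delay,) if delay else (),
        fixed_point_fn=lambda: np.array([fp]),
    )


class TestKernelDensity:
    def test_weak_kernel_is_exponential(self):
        spec = DelaySpec.weak(4.6)
        tau = np.linspace(0, 3, 50)
        assert kernel_density(spec, tau) == pytest.approx(4.6 * np.exp(-4.6 * tau))

    @pytest.mark.parametrize("shape, rate", [(1, 0.23), (2, 4.0), (5, 1.7)])
    def test_normalization_mean_variance(self, shape, rate):
        spec = DelaySpec.erlang(shape, rate)
        mass, _ = quad(lambda t: kernel_density(spec, t), 0, 60 * spec.mean)
        mean, _ = quad(lambda t: t * kernel_density(spec, t), 0, 60 * spec.mean)
        var, _ = quad(lambda t: (t - mean) ** 2 * kernel_density(spec, t),
                      0, 60 * spec.mean)
        assert mass == pytest.approx(1.0, abs=1e-8)
        assert mean == pytest.approx(shape / rate, rel=1e-8)
        assert var == pytest.approx(shape / rate**2, rel=1e-6)
        assert spec.mean == shape / rate and spec.variance == shape / rate**2

    def test_validation(self):
        with pytest.raises(ValueError):
            kernel_density(DelaySpec.weak(1.0), -0.5)
        with pytest.raises(ValueError):
            kernel_density(DelaySpec.discrete(1.0), 0.5)
        with pytest.raises(ValueError):
            DelaySpec.erlang(0, 1.0)


class TestMethodOfSteps:
    def test_analytic_cosine_solution(self):
        """x'(t) = -x(t - pi/2) with history cos continues as cos(t)."""
        sys = DelayedSystem(
            rhs_fn=lambda t, y, zs: np.array([-zs[0]]),
            state_names=("x",),
            delays=(DelaySpec.discrete(np.pi / 2, "x"),),
        )
        hist = HistoryFunction(lambda s: np.array([np.cos(s)]))
        traj = integrate(sys, hist, (0.0, 4 * np.pi), step=1e-3)
        assert np.max(np.abs(traj.series("x") - np.cos(traj.t))) < 1e-6

    def test_error_scales_with_step(self):
        """Global error drops by ~order 4 per step decade on the cosine test."""
        sys = DelayedSystem(
            rhs_fn=lambda t, y, zs: np.array([-zs[0]]),
            state_names=("x",),
            delays=(DelaySpec.discrete(np.pi / 2, "x"),),
        )
        hist = HistoryFunction(lambda s: np.array([np.cos(s)]))
        errs = []
        for h in (2e-2, 2e-3):
            traj = integrate(sys, hist, (0.0, 2 * np.pi), step=h)
            errs.append(np.max(np.abs(traj.series("x") - np.cos(traj.t))))
        assert errs[0] / errs[1] > 1e3  # >= ~3 orders per decade

    def test_zero_lag_reduces_to_ode(self):
        delayed = linear_feedback(delay=DelaySpec.discrete(0.0, "x"))
        plain = DelayedSystem(
            rhs_fn=lambda t, y, zs: np.array([3.0 - 1.5 * y[0] - 1.0 * y[0]]),
            state_names=("x",),
        )
        a = integrate(delayed, [0.1], (0, 10), step=0.005)
        b = integrate(plain, [0.1], (0, 10), step=0.005)
        assert np.max(np.abs(a.y - b.y)) < 1e-8

    def test_history_from_trajectory_and_gap_error(self):
        sys = linear_feedback(delay=DelaySpec.discrete(1.0, "x"))
        first = integrate(sys, [0.1], (0.0, 5.0), step=0.005)
        hist = HistoryFunction.from_trajectory(first)
        cont = integrate(sys, hist, (5.0, 10.0), step=0.005)
        assert cont.t[0] == pytest.approx(5.0)
        with pytest.raises(IntegrationError, match="before history start"):
            hist(-1.0)

    def test_step_larger_than_lag_rejected(self):
        sys = linear_feedback(delay=DelaySpec.discrete(0.002, "x"))
        with pytest.raises(IntegrationError, match="exceeds smallest lag"):
            integrate(sys, [0.1], (0, 1), step=0.005)

    @pytest.mark.filterwarnings("ignore:overflow")
    def test_nan_blowup_reported_with_timestamp(self):
        stiff = DelayedSystem(
            rhs_fn=lambda t, y, zs: np.array([1e4 * y[0] ** 2]),
            state_names=("x",),
        )
        with pytest.raises(IntegrationError, match="non-finite state at t="):
            integrate(stiff, [1.0], (0, 10), step=0.01)


class TestChainTrick:
    def test_expansion_dimensions(self):
        from genosc import delayed_crs_model

        weak = delayed_crs_model("RM", 0.246, 30, 10, kernel="weak", lag=None, gamma=4.6)
        strong = delayed_crs_model("RM", 0.246, 30, 10, kernel="strong", lag=None, gamma=4.6)
        assert expand_chain(weak).dim == 5
        assert expand_chain(strong).dim == 6

    def test_discrete_delay_not_expandable(self):
        sys = linear_feedback(delay=DelaySpec.discrete(1.0, "x"))
        with pytest.raises(ValueError, match="discrete"):
            expand_chain(sys)

    @pytest.mark.parametrize("shape", [1, 2, 3])
    def test_exactness_vs_integrodifferential_quadrature(self, shape):
        """Chain expansion equals direct quadrature of the kernel integral.

        Oracle: trapezoidal evaluation of z(t) = int_0^inf K(tau) x(t-tau) dtau
        (constant pre-start history handled by the analytic kernel tail),
        advanced with the same RK4 stepping.
        """
        rate = shape / 1.0  # mean 1 min
        b, u, g = 1.5, 3.0, 1.0
        x0 = 0.1
        h = 0.005
        t_end = 12.0
        sys = linear_feedback(b, u, g, delay=DelaySpec.erlang(shape, rate, "x"))
        traj = integrate(sys, [x0], (0, t_end), step=h)
        x_chain = traj.series("x")

        # --- independent quadrature oracle -------------------------------
        from math import factorial

        from scipy.stats import gamma as gamma_dist

        n = int(round(t_end / h))
        xs = np.full(n + 1, np.nan)
        xs[0] = x0

        def kern(tau):
            return rate**shape * tau ** (shape - 1) * np.exp(-rate * tau) / factorial(shape - 1)

        def zval(i, xi):
            # history x = x0 for t <= 0; trapezoid over stored samples
            t_i = i * h
            taus = t_i - h * np.arange(0, i + 1)
            vals = kern(taus) * xs[: i + 1]
            z = np.trapezoid(vals[::-1], dx=h) if i > 0 else 0.0
            tail = gamma_dist.sf(t_i, a=shape, scale=1 / rate)  # analytic remainder
            return z + tail * x0

        def f(i, xi):
            return u - b * zval(i, xi) - g * xi

        # RK2 (midpoint) on the quadrature form; fine enough vs 1e-4 target
        for i in range(n):
            k1 = f(i, xs[i])
            xs[i + 1] = xs[i] + h * k1
            k2 = f(i + 1, xs[i + 1])
            xs[i + 1] = xs[i] + 0.5 * h * (k1 + k2)
        assert np.max(np.abs(xs - x_chain)) < 1e-4

    def test_erlang_to_discrete_monotone_convergence(self):
        """Distance to the discrete-lag run shrinks as kernel shape grows."""
        sys = linear_feedback(delay=DelaySpec.erlang(1, 1.0, "x"))
        table = erlang_to_discrete_limit_check(
            sys, [0.1], (0, 25), mean_lag=1.0, shapes=(1, 4, 16, 64), step=0.005
        )
        d = table["sup_distance"].to_numpy()
        assert np.all(np.diff(d) <= 0.05 * d[:-1])  # non-increasing, 5% slack
        assert d[-1] < d[0] / 5
        assert np.all(np.diff(table["variance"].to_numpy()) < 0)

    def test_same_fixed_point_all_kernels(self):
        """Weak, strong and discrete kernels relax to one steady state."""
        finals = []
        for spec in (DelaySpec.erlang(1, 1.0, "x"), DelaySpec.erlang(2, 2.0, "x"),
                     DelaySpec.discrete(1.0, "x")):
            sys = linear_feedback(delay=spec)
            traj = integrate(sys, [0.1], (0, 60), step=0.005)
            finals.append(traj.series("x")[-1])
        assert np.ptp(finals) < 1e-8
        assert finals[0] == pytest.approx(3.0 / 2.5, abs=1e-8)
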