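"""Linearization correctness, characteristic roots, classification, scans."""

import numpy as np
import pytest

from genosc import (
    DelaySpec,
    SynthesisParams,
    build_model,
    char_poly_degree,
    delayed_crs_model,
    fscan_model,
    hill_regulation,
    hopf_scan,
    linearize,
    classify,
    rightmost_roots,
)
from genosc.delays import DelayedSystem, expand_chain
from genosc.regulation import CooperativitySpec, cooperative_rates
from genosc.stability import Linearization, leading_real_part


def _fd_jacobians(model, y, zvals, h=1e-6):
    """Central finite differences of the rhs in state and delayed arguments."""
    d = y.size
    A = np.zeros((d, d))
    for j in range(d):
        e = np.zeros(d)
        e[j] = h * max(1.0, abs(y[j]))
        A[:, j] = (model.rhs(0, y + e, zvals) - model.rhs(0, y - e, zvals)) / (2 * e[j])
    Bs = []
    for k in range(len(zvals)):
        dz = h * max(1.0, abs(zvals[k]))
        zp = list(zvals); zp[k] += dz
        zm = list(zvals); zm[k] -= dz
        Bs.append((model.rhs(0, y, zp) - model.rhs(0, y, zm)) / (2 * dz))
    return A, Bs


def _models_for_jacobian_check(lewis):
    from dataclasses import replace

    kin = cooperative_rates(CooperativitySpec("RM", 0.246, 30.0, 10.0))
    reg = hill_regulation(40, 2)
    yield build_model("I", lewis, regulation=reg)
    yield build_model("II", replace(lewis, beta1=1 / 20.8, beta2=1 / 2.8), regulation=reg)
    yield build_model("chain", replace(lewis, r1=2.0, r2=2.0, N=3, M=2), regulation=reg)
    yield build_model("III", replace(lewis, r1=2.0, r2=2.0), regulation=reg,
                      delays=(DelaySpec.discrete(20.8, "m0"), DelaySpec.discrete(2.8, "c0")))
    yield build_model("IV_full", SynthesisParams(alpha=140, gamma=0.7), crs=kin)
    yield build_model("IV", SynthesisParams(alpha=140, gamma=0.7), crs=kin)
    yield build_model("QSS", SynthesisParams(alpha=140, gamma=0.7), crs=kin)
    yield build_model("V", replace(lewis, gamma=4.6), crs=kin)
    yield delayed_crs_model("SM", 0.246, 30, 10, kernel="discrete", lag=3.5, gamma=4.6)


def test_analytic_jacobians_match_finite_differences(lewis_synthesis):
    """Closed-form A and delayed-B columns agree with central differences."""
    for model in _models_for_jacobian_check(lewis_synthesis):
        fp = model.fixed_point()
        zvals = [fp[model.state_names.index(d.target)] for d in model.delays]
        A, delayed = model.jacobians()
        A_fd, B_fd = _fd_jacobians(model, fp, zvals)
        assert np.max(np.abs(A - A_fd)) < 1e-6 * (1 + np.max(np.abs(A))), model.variant
        for (spec, b), b_fd in zip(delayed, B_fd):
            assert np.max(np.abs(b - b_fd)) < 1e-6 * (1 + np.max(np.abs(b)))


def test_model_I_jacobian_closed_form(lewis_synthesis):
    model = build_model("I", lewis_synthesis, regulation=hill_regulation(40, 2))
    A, _ = model.jacobians()
    c = model.fixed_point()[-1]
    Rp = model.regulation.derivative(c)
    assert A == pytest.approx(np.array([[-0.23, 33 * Rp], [4.5, -0.23]]))


@pytest.mark.parametrize(
    "builder, degree",
    [
        (lambda: build_model(
            "V", SynthesisParams(alpha_m=33, gamma_m=0.23, alpha=4.5, gamma=4.6),
            crs=cooperative_rates(CooperativitySpec("RM", 0.246, 30, 10))), 5),
        (lambda: delayed_crs_model("RM", 0.246, 30, 10, kernel="weak", lag=None, gamma=4.6), 5),
        (lambda: delayed_crs_model("RM", 0.246, 30, 10, kernel="strong", lag=None, gamma=4.6), 6),
    ],
)
def test_characteristic_polynomial_degrees(builder, degree):
    """Model V is order 5; the strong-kernel expansion is order 6."""
    assert char_poly_degree(builder()) == degree


def test_model_I_degree_and_discrete_rejection(lewis_synthesis):
    model = build_model("I", lewis_synthesis, regulation=hill_regulation(40, 2))
    assert char_poly_degree(model) == 2
    dde = delayed_crs_model("RM", 0.246, 30, 10, kernel="discrete", lag=3.5, gamma=4.6)
    with pytest.raises(ValueError, match="transcendental"):
        char_poly_degree(dde)


class TestRightmostRoots:
    def scalar_lin(self, tau):
        """x' = -x(t - tau): stable iff tau < pi/2."""
        return Linearization(
            fixed_point=np.zeros(1),
            A=np.array([[0.0]]),
            delayed=((tau, np.array([[-1.0]])),),
        )

    def test_classical_stability_boundary(self):
        below = rightmost_roots(self.scalar_lin(1.0), search_box=(-5, 3, 0, 10))
        above = rightmost_roots(self.scalar_lin(2.0), search_box=(-5, 3, 0, 10))
        assert below[0].real < 0 < above[0].real

    def test_delay_free_roots_equal_eigenvalues(self, lewis_synthesis):
        from dataclasses import replace

        model = build_model("II", replace(lewis_synthesis, beta1=1 / 20.8, beta2=1 / 2.8),
                            regulation=hill_regulation(40, 2))
        lin = linearize(model)
        roots = rightmost_roots(lin, search_box=(-2, 1, 0, 2))
        eigs = sorted(np.linalg.eigvals(lin.A), key=lambda z: -z.real)
        for r, e in zip(roots[:4], [complex(z) for z in eigs][:4]):
            assert abs(r - e) < 1e-8

    def test_empty_result_warns(self):
        lin = self.scalar_lin(1.0)
        with pytest.warns(UserWarning, match="no characteristic root"):
            out = rightmost_roots(lin, search_box=(-1e-9, 1e-9, 5.0, 5.1),
                                  n_seeds=(2, 2), max_iter=1)
        assert out == []


class TestClassification:
    def test_fig2_models_I_and_II(self, fig2_bundle):
        """Instantaneous model converges; the 4-stage split is a damped spiral."""
        rep1 = fig2_bundle["I"].stability["I"]
        rep2 = fig2_bundle["II"].stability["II"]
        assert rep1.classification in ("stable_node", "stable_spiral")
        assert rep1.consistent
        assert rep2.classification == "stable_spiral"
        assert rep2.leading_roots[0].real < 0 < abs(rep2.leading_roots[0].imag)

    def test_model_IV_asymptotically_stable_at_fig5_parameters(self):
        kin = cooperative_rates(CooperativitySpec("RM", 0.246, 30.0, 10.0))
        model = build_model("IV", SynthesisParams(alpha=140.0, gamma=4.6), crs=kin)
        rep = classify(model, simulate=False)
        assert rep.classification in ("stable_node", "stable_spiral")
        assert all(z.real < 0 for z in rep.leading_roots)

    def test_discrete_delay_mechanism_split_at_slow_kinetics(self, fig6_bundle):
        """At f=0.03 recruitment oscillates while stabilization spirals in."""
        reps = fig6_bundle["a"].stability
        assert reps["RM"].classification == "unstable_oscillatory"
        assert reps["SM"].classification == "stable_spiral"
        assert reps["RM"].consistent and reps["SM"].consistent

    def test_model_IV_stable_over_parameter_hypercube(self):
        """No positive leading real part over a seeded Latin hypercube of
        (p, q, epsilon, alpha, gamma) in the physiological ranges."""
        from scipy.stats import qmc

        sampler = qmc.LatinHypercube(d=5, seed=20240531)
        pts = sampler.random(10_000)
        lows = np.log(np.array([1e-3, 0.6, 1.0, 1.0, 0.1]))
        highs = np.log(np.array([1.0, 30.0, 20.0, 100.0, 10.0]))
        X = np.exp(qmc.scale(pts, lows, highs))
        worst = -np.inf
        for i, (p, q, eps, alpha, gamma) in enumerate(X):
            mech = "RM" if i % 2 == 0 else "SM"
            kin = cooperative_rates(CooperativitySpec(mech, p, q, eps))
            model = build_model("IV", SynthesisParams(alpha=alpha, gamma=gamma), crs=kin)
            A, _ = model.jacobians()
            worst = max(worst, float(np.max(np.linalg.eigvals(A).real)))
        assert worst < 0


class TestHopfScan:
    def test_model_II_needs_hill_exponent_above_four(self, lewis_synthesis):
        """Equal-rate 4-stage loop: instability requires nH >= sec(pi/4)^4 = 4."""
        from dataclasses import replace

        syn = replace(lewis_synthesis, beta1=0.23, beta2=0.23)

        def family(nh):
            return build_model("II", syn, regulation=hill_regulation(40.0, nh))

        res = hopf_scan(family, 1.0, 10.0, tol=1e-4)
        assert res.found
        assert res.threshold >= 4.0
        assert res.threshold == pytest.approx(4.134, rel=1e-2)

    def test_fscan_thresholds_by_mechanism(self):
        """SM's oscillation threshold lies in (0.06, 0.09]; RM's below 0.03."""
        kw = dict(search_box=(-3.0, 2.0, 0.0, 6.0), n_seeds=(25, 25))
        res_sm = hopf_scan(lambda f: fscan_model(f, "SM"), 0.06, 0.09,
                           tol=1e-3, roots_kw=kw)
        assert res_sm.found and 0.06 < res_sm.threshold <= 0.09
        assert leading_real_part(fscan_model(0.03, "RM"), roots_kw=kw) > 0
        res_rm = hopf_scan(lambda f: fscan_model(f, "RM"), 0.005, 0.03,
                           tol=1e-3, roots_kw=kw)
        assert res_rm.found and res_rm.threshold < 0.03

    def test_no_threshold_in_range_reported(self, lewis_synthesis):
        def family(nh):
            return build_model("I", lewis_synthesis,
                               regulation=hill_regulation(40.0, nh))

        res = hopf_scan(family, 1.0, 8.0, tol=1e-2)
        assert not res.found and res.threshold is None
        assert "no threshold" in res.message
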