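"""Model construction, right-hand sides, fixed points, QSS reductions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from genosc import (
    DelaySpec,
    SynthesisParams,
    build_model,
    delayed_crs_model,
    hill_regulation,
    integrate,
    qss_reduce,
)
from genosc.regulation import (
    CooperativitySpec,
    adair_regulatory,
    cooperative_rates,
    equilibrium_constants,
)


def crs(mech="RM", p=0.246, q=30.0, eps=10.0):
    return cooperative_rates(CooperativitySpec(mech, p, q, eps))


@pytest.mark.parametrize(
    "variant, kwargs, dim",
    [
        ("I", dict(regulation=hill_regulation(40, 2)), 2),
        ("II", dict(regulation=hill_regulation(40, 2)), 4),
        ("chain", dict(regulation=hill_regulation(40, 2)), 9),  # N=3, M=2
        ("IV_full", dict(crs=crs()), 5),
        ("IV", dict(crs=crs()), 4),
        ("QSS", dict(crs=crs()), 1),
        ("V", dict(crs=crs()), 5),
    ],
)
def test_dimensions_per_variant(variant, kwargs, dim):
    syn = SynthesisParams(
        alpha_m=33, gamma_m=0.23, alpha=4.5, gamma=0.23,
        beta1=0.05, beta2=0.36, r1=2.0, r2=2.0, N=3, M=2,
    )
    model = build_model(variant, syn, **kwargs)
    assert model.dim == dim
    assert len(model.state_names) == dim


def test_build_rejects_inconsistent_combinations(lewis_synthesis):
    with pytest.raises(ValueError, match="Hill regulation is inconsistent"):
        build_model("IV", SynthesisParams(alpha=4.5, gamma=0.23),
                    regulation=hill_regulation(40, 2), crs=crs())
    with pytest.raises(ValueError, match="missing synthesis parameter"):
        build_model("I", SynthesisParams(alpha=4.5, gamma=0.23),
                    regulation=hill_regulation(40, 2))
    with pytest.raises(ValueError, match="requires explicit CRS"):
        build_model("V", lewis_synthesis)
    with pytest.raises(ValueError, match="no delay specs"):
        build_model("I", lewis_synthesis, regulation=hill_regulation(40, 2),
                    delays=(DelaySpec.discrete(1.0, "m"),))


def test_model_I_rhs_at_origin(lewis_synthesis):
    """Empty cell: transcription at full rate alpha_m, nothing else."""
    model = build_model("I", lewis_synthesis, regulation=hill_regulation(40, 2))
    dy = model.rhs(0.0, np.array([0.0, 0.0]))
    assert dy == pytest.approx([33.0, 0.0])


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=4, max_size=4),
       st.floats(min_value=0, max_value=500))
def test_full_promoter_model_conserves_occupancy_pointwise(avals, c):
    """The four occupancy derivatives of the sequestration model sum to zero."""
    model = build_model("IV_full", SynthesisParams(alpha=4.5, gamma=0.23), crs=crs())
    y = np.array(avals + [c])
    dy = model.rhs(0.0, y)
    assert abs(dy[:4].sum()) < 1e-10


def test_model_IV_rhs_vanishes_at_fixed_point():
    model = build_model("IV", SynthesisParams(alpha=140.0, gamma=0.7), crs=crs())
    fp = model.fixed_point()
    assert np.max(np.abs(model.rhs(0.0, fp))) < 1e-9
    # c* solves gamma*c = alpha * R_adair(c), independently via brentq
    ks = equilibrium_constants(crs())
    c_star = brentq(lambda c: 0.7 * c - 140.0 * adair_regulatory(c, ks), 0, 1e6)
    assert fp[-1] == pytest.approx(c_star, rel=1e-9)


def test_model_I_fixed_point_matches_cubic(lewis_synthesis):
    """c* of the Hill-2 model solves the equivalent cubic exactly."""
    model = build_model("I", lewis_synthesis, regulation=hill_regulation(40, 2))
    m_star, c_star = model.fixed_point()
    assert c_star == pytest.approx(161.76021, rel=1e-6)
    assert m_star == pytest.approx(8.2677442, rel=1e-6)
    G = 33 * 4.5 / (0.23 * 0.23)
    assert c_star**3 + 40**2 * c_star == pytest.approx(40**2 * G, rel=1e-9)


def test_fixed_point_shared_across_description_levels(lewis_synthesis):
    """Models I, II, III (and the chain) share one (m*, c*)."""
    from dataclasses import replace

    reg = hill_regulation(40, 2)
    syn2 = replace(lewis_synthesis, beta1=1 / 20.8, beta2=1 / 2.8)
    syn3 = replace(lewis_synthesis, r1=2.0, r2=2.0)
    synC = replace(lewis_synthesis, r1=2.0, r2=2.0, N=5, M=3)
    m1 = build_model("I", lewis_synthesis, regulation=reg)
    m2 = build_model("II", syn2, regulation=reg)
    m3 = build_model("III", syn3, regulation=reg,
                     delays=(DelaySpec.discrete(20.8, "m0"),
                             DelaySpec.discrete(2.8, "c0")))
    mc = build_model("chain", synC, regulation=reg)
    c_vals = [m.fixed_point()[-1] for m in (m1, m2, m3, mc)]
    m_vals = [m1.fixed_point()[0], m2.fixed_point()[1],
              m3.fixed_point()[1], mc.fixed_point()[6]]
    assert np.ptp(c_vals) < 1e-9 and np.ptp(m_vals) < 1e-9


def test_fixed_point_shared_across_crs_variants():
    """V and the delayed-CRS reduction share c*; IV shares with QSS."""
    syn = SynthesisParams(alpha_m=33, gamma_m=0.23, alpha=4.5, gamma=4.6)
    mv = build_model("V", syn, crs=crs())
    mdde = delayed_crs_model("RM", p=0.246, q=30, epsilon=10, kernel="weak",
                      lag=None, alpha_m=33, gamma_m=0.23, alpha=4.5, gamma=4.6)
    assert mv.fixed_point()[-1] == pytest.approx(mdde.fixed_point()[-1], abs=1e-9)
    assert mdde.fixed_point()[-1] == pytest.approx(20.2744457, rel=1e-6)
    miv = build_model("IV", SynthesisParams(alpha=140, gamma=0.7), crs=crs())
    assert qss_reduce(miv).fixed_point()[0] == pytest.approx(
        miv.fixed_point()[-1], abs=1e-9)


def test_qss_reduction_targets(lewis_synthesis):
    from dataclasses import replace

    miv = build_model("IV", SynthesisParams(alpha=140, gamma=0.7), crs=crs())
    assert qss_reduce(miv).variant == "QSS"
    syn2 = replace(lewis_synthesis, beta1=0.05, beta2=0.36)
    m2 = build_model("II", syn2, regulation=hill_regulation(40, 2))
    m1 = qss_reduce(m2)
    assert m1.variant == "I"
    assert m1.fixed_point()[-1] == pytest.approx(m2.fixed_point()[-1], abs=1e-9)
    with pytest.raises(ValueError, match="no supported QSS reduction"):
        qss_reduce(m1)


def test_occupancy_conservation_along_trajectory():
    """Sum(a_i) = 1 holds to 1e-9 over a 500 min sequestration-model run."""
    model = build_model("IV_full", SynthesisParams(alpha=140.0, gamma=0.7), crs=crs())
    y0 = np.array([1.0, 0.0, 0.0, 0.0, 10.0])
    traj = integrate(model, y0, (0.0, 500.0), step=0.005)
    total = traj.y[:, :4].sum(axis=1)
    assert np.max(np.abs(total - 1.0)) < 1e-9


def test_sequestration_negligible_at_high_copy_number():
    """IV_full and IV agree within 2% on c when TF copies >> binding sites."""
    kin = crs(p=0.01, q=30.0, eps=10.0)  # Kd ~ hundreds of molecules
    syn = SynthesisParams(alpha=400.0, gamma=0.5)
    full = build_model("IV_full", syn, crs=kin)
    reduced = build_model("IV", syn, crs=kin)
    c0 = 200.0
    a = full._promoter_equilibrium(c0)
    y_full = np.array([a[0], a[1], a[2], a[3], c0])
    y_red = np.array([a[0], a[1], a[2], c0])
    tf = integrate(full, y_full, (0, 60), step=0.002).series("c")
    tr = integrate(reduced, y_red, (0, 60), step=0.002).series("c")
    assert np.max(np.abs(tf - tr)) / np.max(np.abs(tf)) < 0.02


def test_planar_model_cannot_oscillate(lewis_synthesis):
    """Divergence -gamma_m - gamma < 0 everywhere: trajectories contract."""
    model = build_model("I", lewis_synthesis, regulation=hill_regulation(40, 2))
    A, _ = model.jacobians()
    assert np.trace(A) == pytest.approx(-0.23 - 0.23)
    traj = integrate(model, np.array([1.0, 0.0]), (0, 500), step=0.005)
    fp = model.fixed_point()
    assert np.linalg.norm(traj.y[-1] - fp) < 1e-6 * np.linalg.norm(fp)


def test_stiff_fallback_agrees_with_rk4():
    model = build_model("QSS", SynthesisParams(alpha=140.0, gamma=0.7), crs=crs())
    y0 = np.array([5.0])
    a = integrate(model, y0, (0, 30), step=0.005)
    b = integrate(model, y0, (0, 30), step=0.005, method="lsoda")
    assert np.max(np.abs(a.y - b.y)) < 1e-6


def test_rhs_validates_shape(lewis_synthesis):
    model = build_model("I", lewis_synthesis, regulation=hill_regulation(40, 2))
    with pytest.raises(ValueError, match="state has size"):
        model.rhs(0.0, np.zeros(3))
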