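"""Linearization, characteristic roots, classification, Hopf scans.

For a system with discrete delays the linearization about the fixed point is

    dx/dt = A x(t) + sum_j B_j x(t - tau_j),

whose characteristic function chi(lambda) = det(lambda*I - A - sum_j
B_j exp(-lambda*tau_j)) is transcendental; its rightmost roots are found by
damped Newton iterations started from a grid of complex seeds.  Erlang
delays are chain-expanded first, so their characteristic function is the
ordinary degree-n polynomial of the expanded ODE system and roots reduce to
a matrix eigenvalue problem.

Classification follows the root signs (stable node / stable spiral /
unstable oscillatory / unstable other) and is cross-checked against a long
simulation; a disagreement is reported as "inconclusive", never silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence
import warnings

import numpy as np

from .delays import expand_chain, integrate, Trajectory
from .oscillometry import summarize, OscillationSummary

__all__ = [
    "Linearization",
    "StabilityReport",
    "HopfScanResult",
    "linearize",
    "char_poly_degree",
    "rightmost_roots",
    "classify",
    "hopf_scan",
    "IM_TOL",
    "RE_TOL",
]

IM_TOL = 1e-8  # |Im| above this marks an oscillatory (spiral) pair
RE_TOL = 1e-7  # |Re| below this is marginal -> simulation cross-check decides


@dataclass
class Linearization:
    """Fixed point, instantaneous Jacobian A, delayed Jacobians B_j."""

    fixed_point: np.ndarray
    A: np.ndarray
    delayed: tuple[tuple[float, np.ndarray], ...]  # (lag, B matrix)

    @property
    def dim(self) -> int:
        return self.A.shape[0]

    def char(self, lam):
        """chi(lambda) = det(lambda I - A - sum B_j e^(-lambda tau_j)).

        Vectorised over an array of complex lambda values.
        """
        lam = np.asarray(lam, dtype=complex)
        scalar = lam.ndim == 0
        lam = np.atleast_1d(lam)
        d = self.dim
        eye = np.eye(d)
        M = lam[:, None, None] * eye - self.A
        for tau, B in self.delayed:
            M = M - np.exp(-lam * tau)[:, None, None] * B
        out = np.linalg.det(M)
        return complex(out[0]) if scalar else out


def linearize(model) -> Linearization:
    """Analytic linearization about the fixed point.

    Erlang delays are expanded exactly beforehand, so ``delayed`` is
    non-empty only for discrete lags.  The Jacobians come from closed-form
    differentiation of the model right-hand sides (validated against finite
    differences in the test suite).
    """
    delays = tuple(getattr(model, "delays", ()))
    if any(d.kind == "erlang" for d in delays):
        model = expand_chain(model)
    fp = np.atleast_1d(model.fixed_point())
    A, delayed_pairs = model.jacobians()
    delayed = []
    for spec, b in delayed_pairs:
        if spec.kind != "discrete":
            raise AssertionError("erlang delay survived expansion")
        names = tuple(model.state_names)
        j = names.index(spec.target)
        B = np.zeros_like(A)
        B[:, j] = b
        delayed.append((float(spec.lag), B))
    return Linearization(fixed_point=fp, A=np.asarray(A, dtype=float),
                         delayed=tuple(delayed))


def char_poly_degree(model) -> int:
    """Degree of the characteristic polynomial (= dimension after expansion).

    A model with discrete delays has a transcendental characteristic
    equation, not a polynomial one; use :func:`rightmost_roots` there.
    """
    delays = tuple(getattr(model, "delays", ()))
    if any(d.kind == "discrete" for d in delays):
        raise ValueError(
            "discrete-delay characteristic equation is transcendental; "
            "use rightmost_roots"
        )
    return len(expand_chain(model).state_names) if delays else model.dim


def rightmost_roots(
    lin: Linearization,
    search_box: tuple[float, float, float, float] = (-20.0, 5.0, 0.0, 60.0),
    n_seeds: tuple[int, int] = (40, 40),
    tol: float = 1e-10,
    max_iter: int = 80,
    dedupe_tol: float = 1e-6,
) -> list[complex]:
    """Roots of the characteristic function sorted by descending real part.

    Damped-Newton iterations (central-difference derivative of chi) are run
    from a grid of seeds over ``search_box`` (Re_lo, Re_hi, Im_lo, Im_hi),
    vectorised over all seeds; converged values are deduplicated and complex
    conjugates added by symmetry.  Without delays the result agrees with the
    eigenvalues of A (checked in the tests).  Returns an empty list (after a
    warning) when no seed converges.
    """
    re_lo, re_hi, im_lo, im_hi = search_box
    if not (np.isfinite(re_lo) and np.isfinite(re_hi)
            and np.isfinite(im_lo) and np.isfinite(im_hi)):
        raise ValueError("search box bounds must be finite")
    if not lin.delayed:
        # delay-free: chi is the char polynomial of A; Newton still used,
        # seeded at the eigenvalues for robustness plus the grid
        grid_re = np.linspace(re_lo, re_hi, n_seeds[0])
        grid_im = np.linspace(im_lo, im_hi, n_seeds[1])
        seeds = (grid_re[:, None] + 1j * grid_im[None, :]).ravel()
        seeds = np.concatenate([seeds, np.linalg.eigvals(lin.A)])
    else:
        grid_re = np.linspace(re_lo, re_hi, n_seeds[0])
        grid_im = np.linspace(im_lo, im_hi, n_seeds[1])
        seeds = (grid_re[:, None] + 1j * grid_im[None, :]).ravel()

    lam = seeds.astype(complex)
    active = np.ones(lam.shape, dtype=bool)
    converged = np.zeros(lam.shape, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        la = lam[active]
        hstep = 1e-7 * (1.0 + np.abs(la))
        chi_p = lin.char(la + hstep)
        chi_m = lin.char(la - hstep)
        dchi = (chi_p - chi_m) / (2 * hstep)
        chi0 = lin.char(la)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            step = np.where(dchi != 0, chi0 / dchi, np.inf)
            # damp huge steps to keep iterates in a sane region
            mag = np.abs(step)
            step = np.where(np.isfinite(mag) & (mag > 5.0), step * (5.0 / mag), step)
            step = np.where(np.isfinite(step), step, 5.0 + 0j)
        la_new = la - step
        done = np.abs(step) < tol * (1.0 + np.abs(la_new))
        bad = ~np.isfinite(la_new)
        la_new[bad] = la[bad]
        idx = np.flatnonzero(active)
        lam[idx] = la_new
        converged[idx[done & ~bad]] = True
        still = np.ones(idx.shape, dtype=bool)
        still[done | bad] = False
        active[idx] = still

    roots = lam[converged]
    roots = roots[(roots.real >= re_lo - 1.0) & (roots.real <= re_hi + 1.0)]
    roots = roots[np.abs(roots.imag) <= im_hi + 1.0]
    if roots.size == 0:
        warnings.warn("no characteristic root converged in the search box")
        return []
    # dedupe on a tolerance grid, fold conjugates to Im >= 0 then re-add
    folded = roots.real + 1j * np.abs(roots.imag)
    order = np.lexsort((folded.imag, folded.real))
    folded = folded[order]
    uniq: list[complex] = []
    for r in folded:
        if all(abs(r - u) > dedupe_tol for u in uniq):
            uniq.append(complex(r))
    out: list[complex] = []
    for r in uniq:
        out.append(r)
        if r.imag > IM_TOL:
            out.append(r.conjugate())
    out.sort(key=lambda z: -z.real)
    return out


@dataclass
class StabilityReport:
    """Classification of a fixed point with the evidence used to reach it."""

    fixed_point: np.ndarray
    classification: str  # stable_node | stable_spiral | unstable_oscillatory
    #                      | unstable_other | inconclusive
    leading_roots: list[complex]
    method: str  # "eigen" | "dde_roots"
    simulation: OscillationSummary | None = None
    consistent: bool | None = None  # roots vs simulation agreement

    def to_dict(self) -> dict:
        return {
            "classification": self.classification,
            "method": self.method,
            "fixed_point": [float(v) for v in np.atleast_1d(self.fixed_point)],
            "leading_roots": [
                {"re": z.real, "im": z.imag} for z in self.leading_roots[:6]
            ],
            "consistent": self.consistent,
            "simulation": None if self.simulation is None else self.simulation.to_dict(),
        }


def _root_classification(leading: complex) -> str:
    osc = abs(leading.imag) > IM_TOL
    if leading.real < -RE_TOL:
        return "stable_spiral" if osc else "stable_node"
    if leading.real > RE_TOL:
        return "unstable_oscillatory" if osc else "unstable_other"
    return "marginal"


def classify(
    model,
    *,
    simulate: bool = True,
    trajectory: Trajectory | None = None,
    t_end: float = 500.0,
    step: float = 0.005,
    perturb_scale: float = 1.2,
    transient_fraction: float = 0.5,
    variable: str | None = None,
    roots_kw: dict | None = None,
) -> StabilityReport:
    """Classify the fixed point from characteristic roots + simulation.

    Root-based classification: leading pair complex with negative real part
    -> stable spiral; leading root real and negative -> stable node;
    positive real part with imaginary part -> unstable oscillatory.  When
    ``simulate`` is true (or a precomputed ``trajectory`` is supplied) the
    verdict is cross-checked against the oscillation summary of a long run
    from a perturbed start; a conflict yields classification
    "inconclusive" rather than a silent answer.
    """
    lin = linearize(model)
    if lin.delayed:
        roots = rightmost_roots(lin, **(roots_kw or {}))
        method = "dde_roots"
    else:
        roots = sorted(np.linalg.eigvals(lin.A), key=lambda z: -z.real)
        roots = [complex(z) for z in roots]
        method = "eigen"
    if not roots:
        method = "simulation"
        label = "marginal"
    else:
        label = _root_classification(roots[0])

    summary = None
    consistent = None
    need_sim = simulate or trajectory is not None or label == "marginal"
    if need_sim:
        if trajectory is None:
            start = (
                model.perturbed_start(perturb_scale)
                if hasattr(model, "perturbed_start")
                else np.atleast_1d(model.fixed_point()) * perturb_scale
            )
            trajectory = integrate(model, start, (0.0, t_end), step=step)
        var = variable or getattr(trajectory.model, "tf_variable", None) \
            or getattr(model, "tf_variable", None) or model.state_names[-1]
        summary = summarize(trajectory, var, transient_fraction=transient_fraction)
        sim_osc = summary.sustained
        if label == "marginal":
            label = "unstable_oscillatory" if sim_osc else "stable_spiral"
            consistent = True
        elif label in ("stable_node", "stable_spiral"):
            consistent = not sim_osc
        elif label == "unstable_oscillatory":
            consistent = sim_osc
        else:  # unstable_other: bounded oscillation would contradict
            consistent = not sim_osc
        if not consistent:
            label = "inconclusive"
    return StabilityReport(
        fixed_point=lin.fixed_point,
        classification=label,
        leading_roots=roots[:10],
        method=method,
        simulation=summary,
        consistent=consistent,
    )


@dataclass
class HopfScanResult:
    """Outcome of a bisection for the stability boundary of a family."""

    found: bool
    threshold: float | None
    lo: float
    hi: float
    trace: list[tuple[float, float]] = field(default_factory=list)
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "found": self.found,
            "threshold": self.threshold,
            "bracket": [self.lo, self.hi],
            "trace": [[p, re] for p, re in self.trace],
            "message": self.message,
        }


def leading_real_part(model, roots_kw: dict | None = None) -> float:
    """Real part of the rightmost characteristic root of a model."""
    lin = linearize(model)
    if lin.delayed:
        roots = rightmost_roots(lin, **(roots_kw or {}))
        if not roots:
            raise ArithmeticError("no characteristic root found")
        return float(roots[0].real)
    return float(np.max(np.linalg.eigvals(lin.A).real))


def hopf_scan(
    model_family: Callable[[float], object],
    lo: float,
    hi: float,
    tol: float = 1e-3,
    roots_kw: dict | None = None,
) -> HopfScanResult:
    """Bisect the sign change of the leading root's real part over [lo, hi].

    ``model_family(p)`` builds the model at scan-parameter value p.  Returns
    the critical parameter where the leading characteristic-root pair
    crosses the imaginary axis (the Hopf threshold), or a "no threshold in
    range" result if the sign does not change across the interval.
    """
    trace: list[tuple[float, float]] = []

    def sgn(p: float) -> float:
        re = leading_real_part(model_family(p), roots_kw)
        trace.append((p, re))
        return re

    f_lo, f_hi = sgn(lo), sgn(hi)
    if np.sign(f_lo) == np.sign(f_hi):
        return HopfScanResult(
            found=False, threshold=None, lo=lo, hi=hi, trace=trace,
            message="no threshold in range: leading real part does not change sign",
        )
    a, b, fa = lo, hi, f_lo
    while b - a > tol:
        mid = 0.5 * (a + b)
        fm = sgn(mid)
        if np.sign(fm) == np.sign(fa):
            a, fa = mid, fm
        else:
            b = mid
    return HopfScanResult(found=True, threshold=0.5 * (a + b), lo=a, hi=b, trace=trace)
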