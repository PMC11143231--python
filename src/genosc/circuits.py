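"""Right-hand sides, parameters, and fixed points of the circuit variants.

All variants describe one gene whose protein product represses its own
transcription, at increasing levels of mechanistic detail:

=========  ====================================================================
variant    description (states)
=========  ====================================================================
I          instantaneous transcription/translation (m, c)
II         open-DNA and translation-initiation stages (m0, m, c0, c)
chain      step-by-step elongation, N + M single steps (m0, m1..mN, m,
           c0, c1..cM, c)
III        elongation replaced by two discrete delays (m0, m, c0, c with
           lags tau_N on m0 and tau_M on c0)
IV_full    explicit 3-site promoter kinetics with TF sequestration by
           binding (a0, a1, a2, a3, c); conserves a0+a1+a2+a3 = 1
IV         as IV_full, sequestration flux dropped (a0, a1, a2, c)
QSS        promoter at quasi-steady state: dc/dt = alpha*R_adair(c) - gamma*c
V          promoter kinetics plus separate transcription and translation
           (a0, a1, a2, m, c)
DDE_CRS    model V reduced by the chain trick to promoter + m' with the TF
           seen through a delay kernel (a0, a1, a2, mp); the kernel is the
           weak (shape-1 Erlang with rate gamma) form exactly, or a strong /
           discrete kernel to emulate further lumped processes
=========  ====================================================================

Rates are per minute, concentrations in molecules.  The shared scalar
fixed-point equation is ``gamma*gamma_m*c = alpha*alpha_m*R(c)`` for the
m/c variants and ``gamma*c = alpha*R(c)`` for IV/QSS.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import cached_property

import numpy as np
from scipy.optimize import brentq

from .delays import DelaySpec
from .regulation import (
    CRSKinetics,
    EquilibriumConstants,
    RegulationSpec,
    adair_regulation,
    equilibrium_constants,
)

__all__ = [
    "SynthesisParams",
    "CircuitModel",
    "build_model",
    "fixed_point",
    "qss_reduce",
    "VARIANTS",
]

VARIANTS = ("I", "II", "chain", "III", "IV_full", "IV", "QSS", "V", "DDE_CRS")
_CRS_VARIANTS = ("IV_full", "IV", "QSS", "V", "DDE_CRS")


@dataclass(frozen=True)
class SynthesisParams:
    """Transcription/translation/degradation rates (all per minute).

    ``alpha_m``: transcription rate (molecules/min); ``gamma_m``: mRNA
    degradation; ``alpha``: translation rate per mRNA; ``gamma``: protein
    degradation.  ``beta1, beta2``: effective elongation rates (model II).
    ``r1, r2``: single-step elongation rates with ``N, M`` steps (chain and
    III); the effective rates relate as beta1 = r1/N, beta2 = r2/M, and the
    lumped delays as tau_N = N/r1, tau_M = M/r2.
    """

    alpha_m: float | None = None
    gamma_m: float | None = None
    alpha: float | None = None
    gamma: float | None = None
    beta1: float | None = None
    beta2: float | None = None
    r1: float | None = None
    r2: float | None = None
    N: int | None = None
    M: int | None = None

    def __post_init__(self) -> None:
        for name in ("alpha_m", "gamma_m", "alpha", "gamma", "beta1", "beta2", "r1", "r2"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"synthesis rate {name} must be > 0, got {v}")
        for name in ("N", "M"):
            v = getattr(self, name)
            if v is not None and not (int(v) == v and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v}")

    @property
    def tau_N(self) -> float:
        return self.N / self.r1

    @property
    def tau_M(self) -> float:
        return self.M / self.r2

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(f"missing synthesis parameter(s): {', '.join(missing)}")


_REQUIRED = {
    "I": ("alpha_m", "gamma_m", "alpha", "gamma"),
    "II": ("alpha_m", "gamma_m", "alpha", "gamma", "beta1", "beta2"),
    "chain": ("alpha_m", "gamma_m", "alpha", "gamma", "r1", "r2", "N", "M"),
    "III": ("alpha_m", "gamma_m", "alpha", "gamma", "r1", "r2"),
    "IV_full": ("alpha", "gamma"),
    "IV": ("alpha", "gamma"),
    "QSS": ("alpha", "gamma"),
    "V": ("alpha_m", "gamma_m", "alpha", "gamma"),
    "DDE_CRS": ("alpha_m", "gamma_m", "alpha", "gamma"),
}


def _state_names(variant: str, syn: SynthesisParams) -> tuple[str, ...]:
    if variant == "I":
        return ("m", "c")
    if variant in ("II", "III"):
        return ("m0", "m", "c0", "c")
    if variant == "chain":
        return (
            ("m0",)
            + tuple(f"m{i}" for i in range(1, syn.N + 1))
            + ("m", "c0")
            + tuple(f"c{j}" for j in range(1, syn.M + 1))
            + ("c",)
        )
    if variant == "IV_full":
        return ("a0", "a1", "a2", "a3", "c")
    if variant == "IV":
        return ("a0", "a1", "a2", "c")
    if variant == "QSS":
        return ("c",)
    if variant == "V":
        return ("a0", "a1", "a2", "m", "c")
    if variant == "DDE_CRS":
        return ("a0", "a1", "a2", "mp")
    raise ValueError(f"unknown variant {variant!r}")


@dataclass(frozen=True)
class CircuitModel:
    """A named autoinhibitory-circuit dynamical system.

    Bundles the variant tag, synthesis rates, regulation (phenomenological
    Hill or kinetics-derived Adair), explicit promoter kinetics where
    applicable, and delay specs into a right-hand-side contract usable by
    :func:`genosc.delays.integrate` and :mod:`genosc.stability`.
    """

    variant: str
    synthesis: SynthesisParams
    regulation: RegulationSpec
    crs: CRSKinetics | None = None
    delays: tuple[DelaySpec, ...] = ()
    state_names: tuple[str, ...] = ()

    @property
    def dim(self) -> int:
        return len(self.state_names)

    @property
    def tf_variable(self) -> str:
        """The state carrying (or standing in for) the free-TF concentration."""
        return "mp" if self.variant == "DDE_CRS" else "c"

    def with_delays(self, delays) -> "CircuitModel":
        return replace(self, delays=tuple(delays))

    # ---- right-hand side -------------------------------------------------

    @cached_property
    def _rhs(self):
        v = self.variant
        syn = self.synthesis
        R = self.regulation

        if v == "I":
            am, gm, al, g = syn.alpha_m, syn.gamma_m, syn.alpha, syn.gamma

            def rhs(t, y, zs=()):
                m, c = y
                return np.array([am * R(c) - gm * m, al * m - g * c])

            return rhs

        if v == "II":
            am, gm, al, g = syn.alpha_m, syn.gamma_m, syn.alpha, syn.gamma
            b1, b2 = syn.beta1, syn.beta2

            def rhs(t, y, zs=()):
                m0, m, c0, c = y
                return np.array(
                    [am * R(c) - b1 * m0, b1 * m0 - gm * m,
                     al * m - b2 * c0, b2 * c0 - g * c]
                )

            return rhs

        if v == "chain":
            am, gm, al, g = syn.alpha_m, syn.gamma_m, syn.alpha, syn.gamma
            r1, r2, N, M = syn.r1, syn.r2, syn.N, syn.M

            def rhs(t, y, zs=()):
                dy = np.empty_like(y)
                c = y[-1]
                dy[0] = am * R(c) - r1 * y[0]
                for i in range(1, N + 1):
                    dy[i] = r1 * (y[i - 1] - y[i])
                dy[N + 1] = r1 * y[N] - gm * y[N + 1]  # free transcript m
                dy[N + 2] = al * y[N + 1] - r2 * y[N + 2]  # c0
                for j in range(1, M + 1):
                    dy[N + 2 + j] = r2 * (y[N + 1 + j] - y[N + 2 + j])
                dy[-1] = r2 * y[N + 2 + M] - g * c
                return dy

            return rhs

        if v == "III":
            am, gm, al, g = syn.alpha_m, syn.gamma_m, syn.alpha, syn.gamma
            r1, r2 = syn.r1, syn.r2

            def rhs(t, y, zs):
                m0, m, c0, c = y
                m0_lag, c0_lag = zs
                return np.array(
                    [am * R(c) - r1 * m0, r1 * m0_lag - gm * m,
                     al * m - r2 * c0, r2 * c0_lag - g * c]
                )

            return rhs

        k = self.crs
        if v == "IV_full":
            al, g = syn.alpha, syn.gamma
            k01, k12, k23, k10, k21, k32 = k.k01, k.k12, k.k23, k.k10, k.k21, k.k32

            def rhs(t, y, zs=()):
                a0, a1, a2, a3, c = y
                return np.array([
                    -k01 * a0 * c + k10 * a1,
                    -k12 * a1 * c + k21 * a2 + k01 * a0 * c - k10 * a1,
                    -k23 * a2 * c + k32 * a3 + k12 * a1 * c - k21 * a2,
                    k23 * a2 * c - k32 * a3,
                    al * a0 - g * c
                    + k10 * a1 + k21 * a2 + k32 * a3
                    - c * (k01 * a0 + k12 * a1 + k23 * a2),
                ])

            return rhs

        if v == "IV":
            al, g = syn.alpha, syn.gamma
            k01, k12, k23, k10, k21, k32 = k.k01, k.k12, k.k23, k.k10, k.k21, k.k32

            def rhs(t, y, zs=()):
                a0, a1, a2, c = y
                return np.array([
                    -k01 * a0 * c + k10 * a1,
                    -k12 * a1 * c + k21 * a2 + k01 * a0 * c - k10 * a1,
                    -k23 * a2 * c + k32 * (1 - a0 - a1 - a2)
                    + k12 * a1 * c - k21 * a2,
                    al * a0 - g * c,
                ])

            return rhs

        if v == "QSS":
            al, g = syn.alpha, syn.gamma

            def rhs(t, y, zs=()):
                c = y[0]
                return np.array([al * R(c) - g * c])

            return rhs

        if v == "V":
            am, gm, al, g = syn.alpha_m, syn.gamma_m, syn.alpha, syn.gamma
            k01, k12, k23, k10, k21, k32 = k.k01, k.k12, k.k23, k.k10, k.k21, k.k32

            def rhs(t, y, zs=()):
                a0, a1, a2, m, c = y
                return np.array([
                    -k01 * a0 * c + k10 * a1,
                    -k12 * a1 * c + k21 * a2 + k01 * a0 * c - k10 * a1,
                    -k23 * a2 * c + k32 * (1 - a0 - a1 - a2)
                    + k12 * a1 * c - k21 * a2,
                    am * a0 - gm * m,
                    al * m - g * c,
                ])

            return rhs

        if v == "DDE_CRS":
            am, gm, al, g = syn.alpha_m, syn.gamma_m, syn.alpha, syn.gamma
            k01, k12, k23, k10, k21, k32 = k.k01, k.k12, k.k23, k.k10, k.k21, k.k32
            A0 = am * al / g  # m' = (alpha/gamma) m rescaling

            def rhs(t, y, zs):
                a0, a1, a2, mp = y
                z = zs[0]  # delayed / kernel-filtered m', the TF seen by the CRS
                return np.array([
                    -k01 * a0 * z + k10 * a1,
                    -k12 * a1 * z + k21 * a2 + k01 * a0 * z - k10 * a1,
                    -k23 * a2 * z + k32 * (1 - a0 - a1 - a2)
                    + k12 * a1 * z - k21 * a2,
                    A0 * a0 - gm * mp,
                ])

            return rhs

        raise ValueError(f"unknown variant {v!r}")

    def rhs_function(self):
        return self._rhs

    def rhs(self, t, y, zs=()):
        """Evaluate the derivative vector (per minute) at (t, y).

        ``zs`` carries the delayed target values, one per entry of
        ``self.delays`` (required iff the variant has delays).
        """
        y = np.asarray(y, dtype=float)
        if y.size != self.dim:
            raise ValueError(f"state has size {y.size}, expected {self.dim}")
        if self.delays and len(zs) != len(self.delays):
            raise ValueError(
                f"variant {self.variant} needs {len(self.delays)} delayed value(s)"
            )
        return self._rhs(t, y, zs)

    # ---- fixed point -----------------------------------------------------

    @property
    def _loop_gain(self) -> float:
        """alpha*alpha_m/(gamma*gamma_m), or alpha/gamma for IV/QSS."""
        syn = self.synthesis
        if self.variant in ("IV_full", "IV", "QSS"):
            return syn.alpha / syn.gamma
        return syn.alpha * syn.alpha_m / (syn.gamma * syn.gamma_m)

    def fixed_point_tf(self) -> float:
        """Steady-state TF concentration: unique root of c = G * R(c)."""
        G = self._loop_gain
        R = self.regulation

        def g(c: float) -> float:
            return c - G * R(c)

        hi = max(G, 1.0)
        for _ in range(200):
            if g(hi) > 0:
                break
            hi *= 2
        else:
            raise ArithmeticError("could not bracket the fixed point")
        return float(brentq(g, 0.0, hi, xtol=1e-12, rtol=1e-15))

    def _promoter_equilibrium(self, c: float) -> tuple[float, float, float, float]:
        """Detailed-balance occupancies (a0..a3) at TF concentration c."""
        K1, K2, K3 = equilibrium_constants(self.crs).as_tuple()
        a0 = 1.0 / (1.0 + c * K1 + c**2 * K1 * K2 + c**3 * K1 * K2 * K3)
        return a0, K1 * c * a0, K1 * K2 * c**2 * a0, K1 * K2 * K3 * c**3 * a0

    def fixed_point(self) -> np.ndarray:
        """The unique steady state as a full state vector."""
        syn = self.synthesis
        c = self.fixed_point_tf()
        v = self.variant
        if v == "I":
            return np.array([syn.gamma * c / syn.alpha, c])
        if v == "II":
            m = syn.gamma * c / syn.alpha
            return np.array(
                [syn.alpha_m * self.regulation(c) / syn.beta1, m,
                 syn.alpha * m / syn.beta2, c]
            )
        if v == "chain":
            m = syn.gamma * c / syn.alpha
            m0 = syn.alpha_m * self.regulation(c) / syn.r1
            c0 = syn.alpha * m / syn.r2
            return np.array([m0] * (syn.N + 1) + [m] + [c0] * (syn.M + 1) + [c])
        if v == "III":
            m = syn.gamma * c / syn.alpha
            return np.array(
                [syn.alpha_m * self.regulation(c) / syn.r1, m,
                 syn.alpha * m / syn.r2, c]
            )
        if v == "IV_full":
            a0, a1, a2, a3 = self._promoter_equilibrium(c)
            return np.array([a0, a1, a2, a3, c])
        if v == "IV":
            a0, a1, a2, _ = self._promoter_equilibrium(c)
            return np.array([a0, a1, a2, c])
        if v == "QSS":
            return np.array([c])
        if v == "V":
            a0, a1, a2, _ = self._promoter_equilibrium(c)
            return np.array([a0, a1, a2, syn.gamma * c / syn.alpha, c])
        if v == "DDE_CRS":
            a0, a1, a2, _ = self._promoter_equilibrium(c)
            return np.array([a0, a1, a2, c])  # mp* = c* in the m' rescaling
        raise ValueError(f"unknown variant {v!r}")

    def perturbed_start(self, scale: float = 1.2) -> np.ndarray:
        """A physically consistent off-equilibrium start near the fixed point.

        The TF-like coordinates are scaled by ``scale``; promoter occupancies
        (where present) are set to detailed balance at the scaled TF level,
        which keeps fast binding terms within their steady operating range.
        """
        c = self.fixed_point_tf() * scale
        v = self.variant
        syn = self.synthesis
        if v in ("I", "II", "chain", "III", "QSS"):
            return self.fixed_point() * scale
        if v == "IV_full":
            a0, a1, a2, a3 = self._promoter_equilibrium(c)
            return np.array([a0, a1, a2, a3, c])
        if v == "IV":
            a0, a1, a2, _ = self._promoter_equilibrium(c)
            return np.array([a0, a1, a2, c])
        if v == "V":
            a0, a1, a2, _ = self._promoter_equilibrium(c)
            return np.array([a0, a1, a2, syn.gamma * c / syn.alpha, c])
        if v == "DDE_CRS":
            a0, a1, a2, _ = self._promoter_equilibrium(c)
            return np.array([a0, a1, a2, c])
        raise ValueError(f"unknown variant {v!r}")

    # ---- analytic linearization ------------------------------------------

    def jacobians(self, state: np.ndarray | None = None):
        """Analytic (A, [(DelaySpec, b)]) at ``state`` (default: fixed point).

        A is the instantaneous Jacobian with delayed arguments held fixed at
        their current-state values; each b is the derivative of the rhs with
        respect to one delayed target value.
        """
        y = self.fixed_point() if state is None else np.asarray(state, dtype=float)
        syn = self.synthesis
        v = self.variant
        if v == "I":
            m, c = y
            A = np.array([
                [-syn.gamma_m, syn.alpha_m * self.regulation.derivative(c)],
                [syn.alpha, -syn.gamma],
            ])
            return A, []
        if v == "II":
            c = y[3]
            Rp = self.regulation.derivative(c)
            A = np.array([
                [-syn.beta1, 0, 0, syn.alpha_m * Rp],
                [syn.beta1, -syn.gamma_m, 0, 0],
                [0, syn.alpha, -syn.beta2, 0],
                [0, 0, syn.beta2, -syn.gamma],
            ])
            return A, []
        if v == "chain":
            N, M = syn.N, syn.M
            d = self.dim
            A = np.zeros((d, d))
            Rp = self.regulation.derivative(y[-1])
            A[0, 0] = -syn.r1
            A[0, -1] = syn.alpha_m * Rp
            for i in range(1, N + 1):
                A[i, i - 1] = syn.r1
                A[i, i] = -syn.r1
            A[N + 1, N] = syn.r1
            A[N + 1, N + 1] = -syn.gamma_m
            A[N + 2, N + 1] = syn.alpha
            A[N + 2, N + 2] = -syn.r2
            for j in range(1, M + 1):
                A[N + 2 + j, N + 1 + j] = syn.r2
                A[N + 2 + j, N + 2 + j] = -syn.r2
            A[-1, N + 2 + M] = syn.r2
            A[-1, -1] = -syn.gamma
            return A, []
        if v == "III":
            c = y[3]
            Rp = self.regulation.derivative(c)
            A = np.array([
                [-syn.r1, 0, 0, syn.alpha_m * Rp],
                [0, -syn.gamma_m, 0, 0],
                [0, syn.alpha, -syn.r2, 0],
                [0, 0, 0, -syn.gamma],
            ])
            b1 = np.array([0.0, syn.r1, 0.0, 0.0])  # d rhs / d m0(t - tau_N)
            b2 = np.array([0.0, 0.0, 0.0, syn.r2])  # d rhs / d c0(t - tau_M)
            return A, [(self.delays[0], b1), (self.delays[1], b2)]
        k = self.crs
        if v == "IV_full":
            a0, a1, a2, a3, c = y
            A = np.array([
                [-k.k01 * c, k.k10, 0, 0, -k.k01 * a0],
                [k.k01 * c, -k.k12 * c - k.k10, k.k21, 0, k.k01 * a0 - k.k12 * a1],
                [0, k.k12 * c, -k.k23 * c - k.k21, k.k32, k.k12 * a1 - k.k23 * a2],
                [0, 0, k.k23 * c, -k.k32, k.k23 * a2],
                [syn.alpha - c * k.k01, k.k10 - c * k.k12, k.k21 - c * k.k23, k.k32,
                 -syn.gamma - (k.k01 * a0 + k.k12 * a1 + k.k23 * a2)],
            ])
            return A, []
        if v == "IV":
            a0, a1, a2, c = y
            A = np.array([
                [-k.k01 * c, k.k10, 0, -k.k01 * a0],
                [k.k01 * c, -k.k12 * c - k.k10, k.k21, k.k01 * a0 - k.k12 * a1],
                [-k.k32, k.k12 * c - k.k32, -k.k23 * c - k.k21 - k.k32,
                 k.k12 * a1 - k.k23 * a2],
                [syn.alpha, 0, 0, -syn.gamma],
            ])
            return A, []
        if v == "QSS":
            c = y[0]
            return np.array([[syn.alpha * self.regulation.derivative(c) - syn.gamma]]), []
        if v == "V":
            a0, a1, a2, m, c = y
            A = np.array([
                [-k.k01 * c, k.k10, 0, 0, -k.k01 * a0],
                [k.k01 * c, -k.k12 * c - k.k10, k.k21, 0, k.k01 * a0 - k.k12 * a1],
                [-k.k32, k.k12 * c - k.k32, -k.k23 * c - k.k21 - k.k32, 0,
                 k.k12 * a1 - k.k23 * a2],
                [syn.alpha_m, 0, 0, -syn.gamma_m, 0],
                [0, 0, 0, syn.alpha, -syn.gamma],
            ])
            return A, []
        if v == "DDE_CRS":
            a0, a1, a2, mp = y
            z = mp  # at the fixed point the delayed value equals mp*
            A0 = syn.alpha_m * syn.alpha / syn.gamma
            A = np.array([
                [-k.k01 * z, k.k10, 0, 0],
                [k.k01 * z, -k.k12 * z - k.k10, k.k21, 0],
                [-k.k32, k.k12 * z - k.k32, -k.k23 * z - k.k21 - k.k32, 0],
                [A0, 0, 0, -syn.gamma_m],
            ])
            b = np.array([
                -k.k01 * a0,
                k.k01 * a0 - k.k12 * a1,
                k.k12 * a1 - k.k23 * a2,
                0.0,
            ])
            return A, [(self.delays[0], b)]
        raise ValueError(f"unknown variant {v!r}")


def build_model(
    variant: str,
    synthesis: SynthesisParams,
    regulation: RegulationSpec | None = None,
    crs: CRSKinetics | None = None,
    delays=None,
) -> CircuitModel:
    """Validate a parameter combination and assemble a :class:`CircuitModel`.

    Variants I/II/chain/III take an explicit (typically Hill) regulation and
    no CRS kinetics; IV/IV_full/QSS/V/DDE_CRS take CRS kinetics from which
    the Adair regulation is derived (an explicit Hill regulation there is
    inconsistent and rejected).  III requires two discrete delays (targets
    m0 and c0); DDE_CRS exactly one delay targeting mp.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    synthesis.require(*_REQUIRED[variant])
    delays = tuple(delays) if delays else ()

    if variant in _CRS_VARIANTS:
        if variant != "QSS" and crs is None:
            raise ValueError(f"variant {variant} requires explicit CRS kinetics")
        if regulation is not None and regulation.form == "hill":
            raise ValueError(
                f"variant {variant} models the promoter explicitly; "
                "Hill regulation is inconsistent with it"
            )
        if crs is not None:
            regulation = adair_regulation(equilibrium_constants(crs))
        if regulation is None:
            raise ValueError("QSS requires CRS kinetics or an adair regulation")
    else:
        if regulation is None:
            raise ValueError(f"variant {variant} requires a regulation function")
        if crs is not None:
            raise ValueError(
                f"variant {variant} uses a phenomenological regulation; "
                "explicit CRS kinetics are not part of it"
            )

    if variant == "III":
        if not delays and synthesis.N is not None and synthesis.M is not None:
            delays = (
                DelaySpec.discrete(synthesis.tau_N, "m0"),
                DelaySpec.discrete(synthesis.tau_M, "c0"),
            )
        if len(delays) != 2 or {d.target for d in delays} != {"m0", "c0"}:
            raise ValueError("variant III needs two discrete delays on m0 and c0")
        delays = tuple(sorted(delays, key=lambda d: d.target != "m0"))
        if any(d.kind != "discrete" for d in delays):
            raise ValueError("variant III delays must be discrete lags")
    elif variant == "DDE_CRS":
        if len(delays) != 1 or delays[0].target != "mp":
            raise ValueError("DDE_CRS needs exactly one delay targeting mp")
    elif delays:
        raise ValueError(f"variant {variant} takes no delay specs")

    return CircuitModel(
        variant=variant,
        synthesis=synthesis,
        regulation=regulation,
        crs=crs if variant in _CRS_VARIANTS else None,
        delays=delays,
        state_names=_state_names(variant, synthesis),
    )


def fixed_point(model: CircuitModel) -> np.ndarray:
    """Module-level alias for ``model.fixed_point()``."""
    return model.fixed_point()


def qss_reduce(model: CircuitModel) -> CircuitModel:
    """Quasi-steady-state reduction to the coarser variant.

    IV -> QSS (promoter equilibrated, same equilibrium constants);
    II, chain -> I (elongation stages eliminated); V -> I with the Adair
    regulation (promoter equilibrated, transcription/translation kept).
    The fixed point is preserved exactly (same scalar equation).
    """
    v = model.variant
    syn = model.synthesis
    if v == "IV":
        return build_model(
            "QSS",
            SynthesisParams(alpha=syn.alpha, gamma=syn.gamma),
            regulation=model.regulation,
        )
    if v in ("II", "chain"):
        return build_model(
            "I",
            SynthesisParams(
                alpha_m=syn.alpha_m, gamma_m=syn.gamma_m,
                alpha=syn.alpha, gamma=syn.gamma,
            ),
            regulation=model.regulation,
        )
    if v == "V":
        return build_model(
            "I",
            SynthesisParams(
                alpha_m=syn.alpha_m, gamma_m=syn.gamma_m,
                alpha=syn.alpha, gamma=syn.gamma,
            ),
            regulation=model.regulation,
        )
    raise ValueError(f"variant {v} has no supported QSS reduction")
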