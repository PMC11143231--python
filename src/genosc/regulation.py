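"""Cooperative TF binding kinetics and regulatory functions.

A cis-regulatory system (CRS) with three identical binding sites is
parameterised by a bare binding rate ``p`` (per minute per molecule), a bare
unbinding rate ``q`` (per minute) and a cooperativity intensity
``epsilon >= 1``.  Cooperativity can act through two kinetically distinct
mechanisms that share the same equilibrium:

* recruitment (RM): bound TFs raise the binding rates,
  ``k_{i,i+1} = eps**i * (3-i) * p``, ``k_{i+1,i} = (i+1) * q``;
* stabilization (SM): bound TFs lower the unbinding rates,
  ``k_{i,i+1} = (3-i) * p``, ``k_{i+1,i} = (i+1) * q / eps**i``.

At quasi-steady state both give the Adair repressive regulatory function

    R(c) = 1 / (1 + c*K1 + c^2*K1*K2 + c^3*K1*K2*K3),

with equilibrium constants ``K_i = k_{i-1,i} / k_{i,i-1}``.  The module also
provides the phenomenological Hill function and the mapping from an Adair
curve to its effective (Kd, nH) pair: Kd is the half-repression
concentration and nH the magnitude of the Hill-plot slope there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Mechanism",
    "CooperativitySpec",
    "CRSKinetics",
    "EquilibriumConstants",
    "RegulationSpec",
    "cooperative_rates",
    "equilibrium_constants",
    "adair_regulatory",
    "adair_derivative",
    "hill_regulatory",
    "hill_derivative",
    "effective_hill",
    "phenomenological_fit",
    "hill_regulation",
    "adair_regulation",
    "regulation_from_cooperativity",
    "export_curve",
]

N_SITES = 3


class Mechanism(str, Enum):
    """Cooperative binding mechanism tag."""

    RM = "RM"  # recruitment
    SM = "SM"  # stabilization


@dataclass(frozen=True)
class CooperativitySpec:
    """Primitive CRS parameters: (mechanism, p, q, epsilon) for 3 sites."""

    mechanism: Mechanism
    p: float  # binding rate, 1/(min*molecule)
    q: float  # unbinding rate, 1/min
    epsilon: float  # cooperativity intensity, dimensionless
    n_sites: int = N_SITES

    def __post_init__(self) -> None:
        object.__setattr__(self, "mechanism", Mechanism(self.mechanism))
        if not self.p > 0:
            raise ValueError(f"binding rate p must be > 0, got {self.p}")
        if not self.q > 0:
            raise ValueError(f"unbinding rate q must be > 0, got {self.q}")
        if not self.epsilon >= 1:
            raise ValueError(
                f"cooperativity intensity epsilon must be >= 1, got {self.epsilon}"
            )
        if self.n_sites != N_SITES:
            raise ValueError(f"only {N_SITES} identical sites are supported")


@dataclass(frozen=True)
class CRSKinetics:
    """The six promoter binding/unbinding rates plus the mechanism tag.

    ``k01, k12, k23`` are forward binding rates (1/(min*molecule));
    ``k10, k21, k32`` are unbinding rates (1/min).
    """

    k01: float
    k12: float
    k23: float
    k10: float
    k21: float
    k32: float
    mechanism: Mechanism = Mechanism.RM

    def __post_init__(self) -> None:
        object.__setattr__(self, "mechanism", Mechanism(self.mechanism))
        for name in ("k01", "k12", "k23", "k10", "k21", "k32"):
            if not getattr(self, name) > 0:
                raise ValueError(f"rate {name} must be > 0, got {getattr(self, name)}")

    @property
    def forward(self) -> tuple[float, float, float]:
        return (self.k01, self.k12, self.k23)

    @property
    def backward(self) -> tuple[float, float, float]:
        return (self.k10, self.k21, self.k32)


@dataclass(frozen=True)
class EquilibriumConstants:
    """Per-molecule association constants K1, K2, K3 of sequential binding."""

    K1: float
    K2: float
    K3: float

    def __post_init__(self) -> None:
        for name in ("K1", "K2", "K3"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.K1, self.K2, self.K3)


def cooperative_rates(spec: CooperativitySpec) -> CRSKinetics:
    """Build the six CRS rates from (mechanism, p, q, epsilon).

    Recruitment scales binding up by eps**i; stabilization scales unbinding
    down by eps**i.  For epsilon == 1 the two mechanisms coincide.
    """
    p, q, eps = spec.p, spec.q, spec.epsilon
    if spec.mechanism is Mechanism.RM:
        fwd = [eps**i * (N_SITES - i) * p for i in range(N_SITES)]
        bwd = [(i + 1) * q for i in range(N_SITES)]
    else:
        fwd = [(N_SITES - i) * p for i in range(N_SITES)]
        bwd = [(i + 1) * q / eps**i for i in range(N_SITES)]
    return CRSKinetics(
        k01=fwd[0], k12=fwd[1], k23=fwd[2],
        k10=bwd[0], k21=bwd[1], k32=bwd[2],
        mechanism=spec.mechanism,
    )


def equilibrium_constants(k: CRSKinetics) -> EquilibriumConstants:
    """Componentwise ratios K_i = forward/backward; mechanism-independent."""
    return EquilibriumConstants(
        K1=k.k01 / k.k10, K2=k.k12 / k.k21, K3=k.k23 / k.k32
    )


def _adair_poly(c, Ks: EquilibriumConstants):
    K1, K2, K3 = Ks.as_tuple()
    return 1.0 + c * K1 + c**2 * K1 * K2 + c**3 * K1 * K2 * K3


def adair_regulatory(c, Ks: EquilibriumConstants):
    """Adair repressive regulatory function, the QSS promoter-vacancy fraction.

    R(c) = (1 + c K1 + c^2 K1 K2 + c^3 K1 K2 K3)^-1.  Accepts scalars or
    arrays; c must be >= 0.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("TF concentration c must be >= 0")
    out = 1.0 / _adair_poly(c, Ks)
    return float(out) if out.ndim == 0 else out


def adair_derivative(c, Ks: EquilibriumConstants):
    """dR/dc of the Adair function (always <= 0)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("TF concentration c must be >= 0")
    K1, K2, K3 = Ks.as_tuple()
    P = _adair_poly(c, Ks)
    dP = K1 + 2 * c * K1 * K2 + 3 * c**2 * K1 * K2 * K3
    out = -dP / P**2
    return float(out) if out.ndim == 0 else out


def hill_regulatory(c, Kd: float, nH: float):
    """Repressive Hill function R(c) = 1 / (1 + (c/Kd)**nH)."""
    if not Kd > 0:
        raise ValueError(f"Kd must be > 0, got {Kd}")
    if not nH > 0:
        raise ValueError(f"nH must be > 0, got {nH}")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("TF concentration c must be >= 0")
    out = 1.0 / (1.0 + (c / Kd) ** nH)
    return float(out) if out.ndim == 0 else out


def hill_derivative(c, Kd: float, nH: float):
    """dR/dc of the repressive Hill function."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("TF concentration c must be >= 0")
    x = (c / Kd) ** nH
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(c > 0, -(nH / np.where(c > 0, c, 1.0)) * x / (1.0 + x) ** 2, 0.0)
    return float(out) if out.ndim == 0 else out


def effective_hill(Ks: EquilibriumConstants) -> tuple[float, float]:
    """Map an Adair curve to its phenomenological (Kd_eff, nH_eff).

    Kd_eff is the unique root of R(c) = 1/2, i.e.
    ``c K1 + c^2 K1 K2 + c^3 K1 K2 K3 = 1`` (monotone, bracketed bisection).
    nH_eff is the Hill-plot slope magnitude -d log[R/(1-R)]/d log c there,
    which evaluates analytically to

        (K1 c + 2 K1 K2 c^2 + 3 K1 K2 K3 c^3) /
        (K1 c +   K1 K2 c^2 +   K1 K2 K3 c^3).

    For a true Hill curve this slope is constant and equals nH; for any valid
    Adair curve 1 <= nH_eff <= 3.
    """
    K1, K2, K3 = Ks.as_tuple()

    def g(c: float) -> float:
        return c * K1 + c**2 * K1 * K2 + c**3 * K1 * K2 * K3 - 1.0

    c_lo, c_hi = 1e-9, 1.0 / K1
    for _ in range(200):
        if g(c_hi) > 0:
            break
        c_hi *= 2.0
    else:
        raise ArithmeticError(
            f"could not bracket the half-repression point; K=({K1}, {K2}, {K3})"
        )
    kd = brentq(g, c_lo, c_hi, xtol=1e-10)
    c = kd
    num = K1 * c + 2 * K1 * K2 * c**2 + 3 * K1 * K2 * K3 * c**3
    den = K1 * c + K1 * K2 * c**2 + K1 * K2 * K3 * c**3
    return float(kd), float(num / den)


def phenomenological_fit(
    R: Callable[[float], float], c_hi: float = 1e9, rel_step: float = 1e-6
) -> tuple[float, float]:
    """Numerically estimate (Kd, nH) of any monotone repressive curve.

    Purely functional route: root-find R(c) = 1/2, then take the centred
    finite-difference Hill-plot slope on a log grid.  Independent of
    :func:`effective_hill`'s analytic formula; used to cross-validate it and
    to fit arbitrary callables.
    """
    kd = brentq(lambda c: R(c) - 0.5, 1e-12, c_hi, xtol=1e-12, rtol=1e-14)

    def logit(c: float) -> float:
        r = R(c)
        return math.log(r / (1.0 - r))

    h = rel_step
    slope = (logit(kd * math.exp(h)) - logit(kd * math.exp(-h))) / (2 * h)
    return float(kd), float(-slope)


@dataclass(frozen=True)
class RegulationSpec:
    """A repressive regulatory function: phenomenological Hill or Adair.

    ``form`` is "hill" (fields Kd, nH) or "adair" (field Ks).  Exposes the
    curve and its derivative as callables; R(0)=1, R is monotone decreasing.
    """

    form: str
    Kd: float | None = None
    nH: float | None = None
    Ks: EquilibriumConstants | None = None

    def __post_init__(self) -> None:
        if self.form == "hill":
            if self.Kd is None or self.nH is None:
                raise ValueError("hill regulation requires Kd and nH")
            if not self.Kd > 0 or not self.nH > 0:
                raise ValueError("hill regulation requires Kd > 0 and nH > 0")
        elif self.form == "adair":
            if self.Ks is None:
                raise ValueError("adair regulation requires equilibrium constants Ks")
        else:
            raise ValueError(f"unknown regulation form {self.form!r}")

    def __call__(self, c):
        if self.form == "hill":
            return hill_regulatory(c, self.Kd, self.nH)
        return adair_regulatory(c, self.Ks)

    def derivative(self, c):
        if self.form == "hill":
            return hill_derivative(c, self.Kd, self.nH)
        return adair_derivative(c, self.Ks)


def hill_regulation(Kd: float, nH: float) -> RegulationSpec:
    return RegulationSpec(form="hill", Kd=Kd, nH=nH)


def adair_regulation(Ks: EquilibriumConstants) -> RegulationSpec:
    return RegulationSpec(form="adair", Ks=Ks)


def regulation_from_cooperativity(spec: CooperativitySpec) -> RegulationSpec:
    """Adair regulation derived from (mechanism, p, q, epsilon)."""
    return adair_regulation(equilibrium_constants(cooperative_rates(spec)))


def export_curve(
    reg: RegulationSpec,
    c_grid: np.ndarray,
    path=None,
    hill_plot: bool = False,
):
    """Tabulate R over ``c_grid`` as a two-column frame; optionally write CSV.

    With ``hill_plot=True`` columns are (log10 c, log10[R/(1-R)]).
    """
    import pandas as pd

    c = np.asarray(c_grid, dtype=float)
    r = reg(c)
    if hill_plot:
        mask = (c > 0) & (r > 0) & (r < 1)
        df = pd.DataFrame(
            {"log10_c": np.log10(c[mask]), "log10_R_over_1mR": np.log10(r[mask] / (1 - r[mask]))}
        )
    else:
        df = pd.DataFrame({"c": c, "R": r})
    if path is not None:
        df.to_csv(path, index=False)
    return df
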