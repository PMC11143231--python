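"""Quantify trajectories: sustained vs damped oscillations, period, amplitude.

The estimator discards an initial transient, locates local maxima of the
mean-centred signal (with quadratic refinement of peak time and height),
and reports

* period: mean inter-peak interval (min), frequency = 1/period;
* amplitude: mean peak-to-trough excursion in state units;
* decay_ratio: geometric mean of consecutive centred peak-height ratios —
  1 for a limit cycle, < 1 for a damped spiral, > 1 for a growing
  oscillation.  "Sustained" means decay_ratio within 1 +/- delta and a
  non-negligible relative amplitude.

Peak heights are measured relative to the window mean because trajectories
orbit a fixed point far from zero; ratios of raw values would read ~1 even
for a strongly damped spiral.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.signal import find_peaks

from .delays import Trajectory

__all__ = [
    "OscillationSummary",
    "MechanismComparison",
    "summarize",
    "compare_mechanisms",
    "SUSTAINED_DELTA",
]

SUSTAINED_DELTA = 0.02  # |decay_ratio - 1| tolerance for "sustained"
MIN_PEAKS = 4
REL_AMP_FLOOR = 1e-5  # relative excursion below this is numerical ripple


@dataclass
class OscillationSummary:
    """Period/amplitude/sustainedness of one trajectory variable."""

    sustained: bool
    period: float | None
    frequency: float | None
    amplitude: float | None
    decay_ratio: float | None
    n_peaks: int
    analysis_window: tuple[float, float]
    variable: str
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "sustained": self.sustained,
            "period_min": self.period,
            "frequency_per_min": self.frequency,
            "amplitude": self.amplitude,
            "decay_ratio": self.decay_ratio,
            "n_peaks": self.n_peaks,
            "analysis_window": list(self.analysis_window),
            "variable": self.variable,
            "reason": self.reason,
        }


def _refine(t: np.ndarray, x: np.ndarray, idx: np.ndarray):
    """Quadratic (3-point parabola) refinement of extremum times/heights."""
    t_ref = np.empty(idx.size)
    x_ref = np.empty(idx.size)
    for k, i in enumerate(idx):
        if i == 0 or i == x.size - 1:
            t_ref[k], x_ref[k] = t[i], x[i]
            continue
        y0, y1, y2 = x[i - 1], x[i], x[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom == 0:
            t_ref[k], x_ref[k] = t[i], x[i]
            continue
        delta = 0.5 * (y0 - y2) / denom
        delta = float(np.clip(delta, -1.0, 1.0))
        h = t[i + 1] - t[i]
        t_ref[k] = t[i] + delta * h
        x_ref[k] = y1 - 0.25 * (y0 - y2) * delta
    return t_ref, x_ref


def summarize(
    traj: Trajectory,
    variable: str | None = None,
    transient_fraction: float = 0.5,
    delta: float = SUSTAINED_DELTA,
    min_peaks: int = MIN_PEAKS,
    prominence_fraction: float = 1e-6,
) -> OscillationSummary:
    """Oscillation summary of one state variable after transient discard.

    Deterministic; requires at least ``min_peaks`` maxima in the retained
    window, otherwise returns sustained=False with reason
    "insufficient peaks" (a constant trajectory has period None).
    """
    if variable is None:
        variable = getattr(traj.model, "tf_variable", None) or traj.state_names[-1]
    if not 0 <= transient_fraction < 1:
        raise ValueError("transient_fraction must be in [0, 1)")
    x_full = traj.series(variable)
    t_full = traj.t
    t_lo = t_full[0] + transient_fraction * (t_full[-1] - t_full[0])
    m = t_full >= t_lo
    t, x = t_full[m], x_full[m]
    window = (float(t[0]), float(t[-1]))

    rng = float(np.max(x) - np.min(x))
    center = float(np.mean(x))
    xc = x - center
    prom = max(prominence_fraction * rng, 1e-300)
    pk, _ = find_peaks(xc, prominence=prom)
    tr, _ = find_peaks(-xc, prominence=prom)

    if pk.size < min_peaks:
        return OscillationSummary(
            sustained=False, period=None, frequency=None, amplitude=None,
            decay_ratio=None, n_peaks=int(pk.size), analysis_window=window,
            variable=variable, reason="insufficient peaks",
        )

    t_pk, h_pk = _refine(t, xc, pk)
    period = float(np.mean(np.diff(t_pk)))
    frequency = 1.0 / period

    # amplitude: mean peak-to-trough of the raw signal
    if tr.size:
        _, h_tr = _refine(t, xc, tr)
        amplitude = float(np.mean(h_pk) - np.mean(h_tr))
    else:
        amplitude = float(np.max(xc) - np.min(xc))

    scale = max(abs(center), rng, 1e-300)
    if rng / scale < REL_AMP_FLOOR:
        return OscillationSummary(
            sustained=False, period=period, frequency=frequency,
            amplitude=amplitude, decay_ratio=None, n_peaks=int(pk.size),
            analysis_window=window, variable=variable,
            reason="negligible amplitude",
        )

    pos = h_pk[h_pk > 0]
    if pos.size >= 2:
        ratios = pos[1:] / pos[:-1]
        decay_ratio = float(np.exp(np.mean(np.log(ratios))))
    else:
        decay_ratio = 0.0
    sustained = abs(decay_ratio - 1.0) <= delta
    reason = "" if sustained else (
        "growing oscillation" if decay_ratio > 1 else "damped oscillation"
    )
    return OscillationSummary(
        sustained=sustained, period=period, frequency=frequency,
        amplitude=amplitude, decay_ratio=decay_ratio, n_peaks=int(pk.size),
        analysis_window=window, variable=variable, reason=reason,
    )


@dataclass
class MechanismComparison:
    """Paired recruitment-vs-stabilization oscillation summaries."""

    rm: OscillationSummary
    sm: OscillationSummary
    frequency_difference: float | None
    amplitude_difference: float | None

    def to_dict(self) -> dict:
        return {
            "RM": self.rm.to_dict(),
            "SM": self.sm.to_dict(),
            "frequency_difference_per_min": self.frequency_difference,
            "amplitude_difference": self.amplitude_difference,
        }


def compare_mechanisms(scenario, **overrides) -> MechanismComparison:
    """Run a scenario under both cooperative mechanisms and diff the output.

    ``scenario`` is a registry name or ScenarioSpec covering both RM and SM;
    everything except the mechanism is held identical.  Frequency and
    amplitude differences are RM minus SM when both define them.
    """
    from . import scenarios as _scen  # runtime import: scenarios builds on us

    result = _scen.run_scenario(scenario, overrides=overrides or None)
    try:
        rm = result.oscillation["RM"]
        sm = result.oscillation["SM"]
    except KeyError as exc:
        raise ValueError(
            f"scenario does not define both mechanisms: {exc}"
        ) from None
    fd = (
        rm.frequency - sm.frequency
        if rm.frequency is not None and sm.frequency is not None
        else None
    )
    ad = (
        rm.amplitude - sm.amplitude
        if rm.amplitude is not None and sm.amplitude is not None
        else None
    )
    return MechanismComparison(
        rm=rm, sm=sm, frequency_difference=fd, amplitude_difference=ad
    )


def peak_table(traj: Trajectory, variable: str | None = None,
               transient_fraction: float = 0.0):
    """Refined (t_peak, value) table of local maxima, as a DataFrame."""
    import pandas as pd

    if variable is None:
        variable = getattr(traj.model, "tf_variable", None) or traj.state_names[-1]
    x = traj.series(variable)
    t = traj.t
    t_lo = t[0] + transient_fraction * (t[-1] - t[0])
    m = t >= t_lo
    t, x = t[m], x[m]
    rng = float(np.max(x) - np.min(x)) if x.size else 0.0
    pk, _ = find_peaks(x - np.mean(x), prominence=max(1e-6 * rng, 1e-300))
    t_pk, h_pk = _refine(t, x, pk)
    return pd.DataFrame({"t_peak": t_pk, "value": h_pk})
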