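"""Synthetic parameter batches and perturbed initial conditions.

The circuits here consume printed rate constants, not datasets, so the
synthetic "data" are parameter draws with the structure the analyses
assume: TF residence times q^-1 log-uniform over 2-100 s (the range
single-molecule tracking reports for specific regulatory sites), binding
rates p log-uniform over 0.001-1 /min, cooperativity intensity epsilon
log-uniform over 1-20, and synthesis/degradation rates around the
segmentation-clock magnitudes.  All draws use numpy's PCG64 generator
seeded explicitly, so batches are reproducible across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .circuits import CircuitModel, SynthesisParams
from .delays import DelaySpec, HistoryFunction
from .regulation import CooperativitySpec, Mechanism

__all__ = ["FixtureBatch", "sample_crs_params", "perturbed_initials", "RANGES"]

RANGES = {
    "q_per_min": (60.0 / 100.0, 60.0 / 2.0),  # residence time 2-100 s
    "p_per_min": (1e-3, 1.0),
    "epsilon": (1.0, 20.0),
    "alpha_m": (5.0, 60.0),
    "gamma_m": (0.1, 1.0),
    "alpha": (1.0, 10.0),
    "gamma": (0.1, 5.0),
    "delay_mean_min": (1.0, 10.0),
}
GENERATOR = "PCG64"  # fixed algorithm so seeds are portable


@dataclass
class FixtureBatch:
    """Reproducible draws of cooperativity, synthesis and delay parameters."""

    seed: int
    cooperativity: list[CooperativitySpec] = field(default_factory=list)
    synthesis: list[SynthesisParams] = field(default_factory=list)
    delays: list[DelaySpec] = field(default_factory=list)
    provenance: str = "synthetic"

    def __len__(self) -> int:
        return len(self.cooperativity)

    def to_frame(self):
        import pandas as pd

        rows = []
        for coop, syn, d in zip(self.cooperativity, self.synthesis, self.delays):
            rows.append({
                "mechanism": coop.mechanism.value, "p": coop.p, "q": coop.q,
                "epsilon": coop.epsilon,
                "alpha_m": syn.alpha_m, "gamma_m": syn.gamma_m,
                "alpha": syn.alpha, "gamma": syn.gamma,
                "delay_kind": d.kind,
                "delay_shape": d.shape, "delay_rate": d.rate, "delay_lag": d.lag,
            })
        return pd.DataFrame(rows)

    def write(self, out_dir) -> None:
        """CSV of draws plus a JSON manifest (seed, generator, ranges)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "fixture_batch.csv", index=False)
        (out / "fixture_manifest.json").write_text(json.dumps({
            "seed": self.seed, "generator": GENERATOR,
            "provenance": self.provenance, "n": len(self),
            "ranges": {k: list(v) for k, v in RANGES.items()},
        }, indent=2))


def _loguniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def sample_crs_params(seed: int, n: int) -> FixtureBatch:
    """Draw ``n`` parameter sets; deterministic per seed.

    Mechanisms alternate RM/SM so every batch exercises both.  Delay draws
    alternate Erlang (shape 1, 2 or 4) and discrete kinds with means in the
    1-10 min range.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 draws, got {n}")
    rng = np.random.Generator(np.random.PCG64(seed))
    q = _loguniform(rng, *RANGES["q_per_min"], n)
    p = _loguniform(rng, *RANGES["p_per_min"], n)
    eps = _loguniform(rng, *RANGES["epsilon"], n)
    am = _loguniform(rng, *RANGES["alpha_m"], n)
    gm = _loguniform(rng, *RANGES["gamma_m"], n)
    al = _loguniform(rng, *RANGES["alpha"], n)
    g = _loguniform(rng, *RANGES["gamma"], n)
    means = _loguniform(rng, *RANGES["delay_mean_min"], n)
    shapes = rng.choice([1, 2, 4], size=n)

    batch = FixtureBatch(seed=seed)
    for i in range(n):
        mech = Mechanism.RM if i % 2 == 0 else Mechanism.SM
        batch.cooperativity.append(
            CooperativitySpec(mech, p=float(p[i]), q=float(q[i]), epsilon=float(eps[i]))
        )
        batch.synthesis.append(SynthesisParams(
            alpha_m=float(am[i]), gamma_m=float(gm[i]),
            alpha=float(al[i]), gamma=float(g[i]),
        ))
        if i % 2 == 0:
            batch.delays.append(
                DelaySpec.erlang(int(shapes[i]), int(shapes[i]) / float(means[i]), "mp")
            )
        else:
            batch.delays.append(DelaySpec.discrete(float(means[i]), "mp"))
    return batch


def perturbed_initials(
    model: CircuitModel,
    relative_amplitude: float,
    seed: int,
    max_retries: int = 100,
):
    """Random start near the fixed point, plus a constant history for DDEs.

    Each fixed-point component is multiplied by (1 + u), u ~ U(-a, +a) with
    a = ``relative_amplitude``; draws yielding an invalid state (negative
    component, or promoter occupancies exceeding the conservation bound)
    are redrawn a bounded number of times.  Returns ``(state, history)``.
    """
    if not 0 <= relative_amplitude < 1:
        raise ValueError("relative_amplitude must be in [0, 1)")
    fp = np.atleast_1d(model.fixed_point())
    if relative_amplitude == 0:
        return fp.copy(), HistoryFunction.constant(fp)
    rng = np.random.Generator(np.random.PCG64(seed))
    names = tuple(model.state_names)
    a_idx = [i for i, nm in enumerate(names) if nm.startswith("a")]
    for _ in range(max_retries):
        u = rng.uniform(-relative_amplitude, relative_amplitude, size=fp.size)
        y = fp * (1.0 + u)
        if np.any(y < 0):
            continue
        if a_idx:
            tot = float(np.sum(y[a_idx]))
            if model.variant == "IV_full":
                y[a_idx] /= tot  # restore the conserved total occupancy
            elif tot > 1.0:
                continue
        return y, HistoryFunction.constant(y)
    raise RuntimeError(
        f"could not draw a valid perturbed start in {max_retries} tries"
    )
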