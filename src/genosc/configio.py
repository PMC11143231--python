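"""Flat key-value configuration files for models and runs.

Format: one ``dotted.key = value`` pair per line; ``#`` starts a comment.
Values are parsed as int, float, bool or string.  Example::

    model.variant = DDE_CRS
    synthesis.alpha_m = 33
    synthesis.gamma_m = 0.23
    synthesis.alpha = 4.5
    synthesis.gamma = 0.23
    regulation.form = coop
    regulation.mechanism = RM
    regulation.p = 0.1
    regulation.q = 43
    regulation.epsilon = 8.5
    regulation.f = 0.09          # optional scale on p and q
    delays.kernel = discrete
    delays.lag = 3.5
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .circuits import CircuitModel, SynthesisParams, build_model
from .delays import DelaySpec
from .regulation import (
    CooperativitySpec,
    Mechanism,
    cooperative_rates,
    hill_regulation,
)
from .scenarios import delayed_crs_model

__all__ = ["load_config", "dump_config", "model_from_config", "initial_from_config"]


def _parse(value: str):
    v = value.strip()
    if v.lower() in ("true", "false"):
        return v.lower() == "true"
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    return v


def load_config(path) -> dict:
    """Read a flat ``key = value`` file into a dict."""
    cfg: dict = {}
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        cfg[key.strip()] = _parse(value)
    return cfg


def dump_config(cfg: dict, path) -> None:
    lines = [f"{k} = {v}" for k, v in cfg.items()]
    Path(path).write_text("\n".join(lines) + "\n")


_SYN_KEYS = ("alpha_m", "gamma_m", "alpha", "gamma", "beta1", "beta2", "r1", "r2", "N", "M")


def model_from_config(cfg: dict) -> CircuitModel:
    """Build a CircuitModel from a flat config dict."""
    variant = cfg.get("model.variant")
    if variant is None:
        raise ValueError("config missing model.variant")
    syn_kwargs = {k: cfg[f"synthesis.{k}"] for k in _SYN_KEYS if f"synthesis.{k}" in cfg}
    syn = SynthesisParams(**syn_kwargs)
    form = cfg.get("regulation.form", "hill")

    if variant in ("I", "II", "chain", "III"):
        if form != "hill":
            raise ValueError(f"variant {variant} expects regulation.form = hill")
        regulation = hill_regulation(cfg["regulation.Kd"], cfg["regulation.nH"])
        delays = None
        if variant == "III" and "delays.tau_N" in cfg:
            delays = (
                DelaySpec.discrete(cfg["delays.tau_N"], "m0"),
                DelaySpec.discrete(cfg["delays.tau_M"], "c0"),
            )
        return build_model(variant, syn, regulation=regulation, delays=delays)

    f = cfg.get("regulation.f", 1.0)
    coop = CooperativitySpec(
        Mechanism(cfg.get("regulation.mechanism", "RM")),
        p=cfg["regulation.p"] * f,
        q=cfg["regulation.q"] * f,
        epsilon=cfg["regulation.epsilon"],
    )
    crs = cooperative_rates(coop)
    if variant == "DDE_CRS":
        return delayed_crs_model(
            coop.mechanism, p=coop.p, q=coop.q, epsilon=coop.epsilon,
            kernel=cfg.get("delays.kernel", "discrete"),
            lag=cfg.get("delays.lag"),
            alpha_m=syn.alpha_m, gamma_m=syn.gamma_m,
            alpha=syn.alpha, gamma=syn.gamma,
            strong_preserves_mean=cfg.get("delays.strong_preserves_mean", True),
        )
    return build_model(variant, syn, crs=crs)


def initial_from_config(cfg: dict, model: CircuitModel) -> np.ndarray:
    """Initial state from ``init.<state_name>`` keys (default: fixed point)."""
    keys = [k for k in cfg if k.startswith("init.")]
    if not keys:
        return model.fixed_point()
    y0 = np.zeros(model.dim)
    for k in keys:
        name = k.split(".", 1)[1]
        if name not in model.state_names:
            raise ValueError(f"unknown state {name!r} in {k}")
        y0[model.state_names.index(name)] = float(cfg[k])
    return y0
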