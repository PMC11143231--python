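"""Shared fixtures: expensive scenario runs are computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from genosc import run_scenario


@pytest.fixture(scope="session")
def fig2_bundle():
    """Three-description-level runs: models I, II and III, shared regime."""
    return {v: run_scenario(f"fig2_{v}") for v in ("I", "II", "III")}


@pytest.fixture(scope="session")
def fig5_bundle():
    """Kernel-order comparison: weak/strong/discrete, RM and SM."""
    return {k: run_scenario(f"fig5_{k}") for k in ("weak", "strong", "discrete")}


@pytest.fixture(scope="session")
def fig6_bundle():
    """CRS-kinetics f-scan at f = 0.03, 0.06, 0.09 (RM and SM each)."""
    return {label: run_scenario(f"fig6_{label}") for label in ("a", "b", "c")}


@pytest.fixture(scope="session")
def fig7_bundle():
    """Fast-CRS limit f = 1.5 at lags 3.5 and 5.5 min (RM and SM each)."""
    return {label: run_scenario(f"fig7_{label}") for label in ("a", "b")}


@pytest.fixture(scope="session")
def lewis_synthesis():
    from genosc import SynthesisParams

    return SynthesisParams(alpha_m=33.0, gamma_m=0.23, alpha=4.5, gamma=0.23)
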