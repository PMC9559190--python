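"""Shared fixtures: toy parameter sets and solved kidneys.

Whole-kidney solves are expensive, so baselines are solved once per
session and shared; protocol tests reuse them through warm starts.
"""

from __future__ import annotations

import numpy as np
import pytest

from nephroflux.experiments import run_baseline
from nephroflux.parameters import build_model, build_toy_fixture


@pytest.fixture(scope="session")
def toy_models():
    """Toy-fidelity parameter sets for all four sex/species chains."""
    return {
        (sp, sx): build_toy_fixture(sp, sx)
        for sp in ("rat", "mouse")
        for sx in ("male", "female")
    }


@pytest.fixture(scope="session")
def toy_baselines(toy_models):
    """Solved toy baselines (delivery tables) for all four chains."""
    return {key: run_baseline(model) for key, model in toy_models.items()}


@pytest.fixture(scope="session")
def full_baselines():
    """Solved full (transcription-fidelity) baselines, all four models."""
    out = {}
    for sp in ("rat", "mouse"):
        for sx in ("male", "female"):
            out[(sp, sx)] = run_baseline(build_model(sp, sx))
    return out


@pytest.fixture()
def plasma_like():
    """A plasma-like 15-solute composition (electroneutral)."""
    from nephroflux.solutes import speciate

    totals = {
        "Na": 144.0, "K": 4.9, "Cl": 120.3, "bicarbonate": 24.0, "CO2": 1.5,
        "ammonia": 0.2, "phosphate": 2.0, "formate": 1.0, "urea": 5.0,
        "glucose": 5.0,
    }
    return speciate(totals)
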