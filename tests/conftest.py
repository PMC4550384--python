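"""Shared fixtures: heavy preset simulations are session-scoped so the
acceptance-level tests and unit tests reuse the same runs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from rfivm import synthetic
from rfivm.synthetic import NOISELESS

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

#: Paired seeds used for the replicate preset runs.
PAIRED_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def presets():
    """(treated, control) default scenarios at 256x256."""
    return synthetic.treated_control_presets()


@pytest.fixture(scope="session")
def paired_runs(presets):
    """Per-seed paired treated/control runs with default noise.

    Returns a list of dicts with keys ``treated`` / ``control``, each
    holding ``(network, scene, stack)``.  Treated and control share the
    seed, hence the vessel geometry — a paired design.
    """
    treated, control = presets
    runs = []
    for seed in PAIRED_SEEDS:
        runs.append({
            "seed": seed,
            "treated": synthetic.simulate_scenario(treated, seed),
            "control": synthetic.simulate_scenario(control, seed),
        })
    return runs


@pytest.fixture(scope="session")
def treated_run(paired_runs):
    """(network, scene, stack) of the first-seed treated run."""
    return paired_runs[0]["treated"]


@pytest.fixture(scope="session")
def control_run(paired_runs):
    return paired_runs[0]["control"]


@pytest.fixture(scope="session")
def noisefree_pair(presets):
    """Seed-1 treated/control runs rendered without noise or jitter."""
    treated, control = presets
    return {
        "treated": synthetic.simulate_scenario(treated, 1, noise=NOISELESS),
        "control": synthetic.simulate_scenario(control, 1, noise=NOISELESS),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def isotonic_fit(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators non-decreasing fit (test oracle)."""
    blocks: list[list[float]] = []
    for v in np.asarray(y, dtype=float):
        blocks.append([v, 1.0])
        while len(blocks) > 1 and blocks[-2][0] > blocks[-1][0]:
            v2, w2 = blocks.pop()
            v1, w1 = blocks.pop()
            blocks.append([(v1 * w1 + v2 * w2) / (w1 + w2), w1 + w2])
    out: list[float] = []
    for v, w in blocks:
        out.extend([v] * int(w))
    return np.asarray(out)
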