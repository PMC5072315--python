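"""Shared fixtures: benchmark datasets and (expensive) inference runs.

Inference on a fixture takes a few seconds, so runs reused by several
tests are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from lemnet.model_core import EdgeModel, ExpressionDataset, Sign, hill
from lemnet.simulate import build_fixture, default_config, simulate, gold_standard_edges
from lemnet.infer import InferenceSettings, infer_network
from lemnet.evaluate import GoldStandard


def make_single_edge_dataset(
    alpha: float,
    beta: float,
    gamma: float,
    n: float,
    K: float,
    sign: Sign,
    T: int = 60,
    t_end: float = 8.0,
    seed: int = 0,
    x0: float = 0.3,
) -> ExpressionDataset:
    """Two-gene dataset where Y is a smooth exogenous driver and X follows
    the single-edge ODE exactly (integrated on a fine grid, then sampled).

    The driver is a sum of two sinusoids with random phases, clipped
    positive, so the Hill term is informative across its range.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_end, T)
    y = (
        1.0
        + 0.8 * np.sin(2 * np.pi * t / t_end * 1.5 + rng.uniform(0, 2 * np.pi))
        + 0.3 * np.sin(2 * np.pi * t / t_end * 3.0 + rng.uniform(0, 2 * np.pi))
    )
    y = np.clip(y, 0.05, None)
    tf = np.linspace(0.0, t_end, 2000)
    yf = np.interp(tf, t, y)
    x = np.empty_like(tf)
    x[0] = x0
    for i in range(1, tf.size):
        dt = tf[i] - tf[i - 1]
        f = alpha * hill(yf[i - 1], K, n, sign) - beta * x[i - 1] + gamma
        x[i] = max(x[i - 1] + dt * f, 0.0)
    xs = np.interp(t, tf, x)
    return ExpressionDataset(["X", "Y"], t, np.vstack([xs, y]))


def _fixture_run(name: str):
    spec = build_fixture(name)
    data = simulate(spec, default_config(name))
    result = infer_network(data, settings=InferenceSettings(seed=0))
    gold = GoldStandard(spec.nodes, set(gold_standard_edges(spec)))
    return spec, data, result, gold


@pytest.fixture(scope="session")
def repressilator_run():
    """(spec, noiseless data, inference result, gold) for repressilator3."""
    return _fixture_run("repressilator3")


@pytest.fixture(scope="session")
def negfb_run():
    """(spec, noiseless data, inference result, gold) for negfb3."""
    return _fixture_run("negfb3")


@pytest.fixture(scope="session")
def nonperiodic_run():
    """(spec, noiseless data, inference result, gold) for nonperiodic5."""
    return _fixture_run("nonperiodic5")


@pytest.fixture
def small_dataset() -> ExpressionDataset:
    """Tiny hand-checkable dataset (3 genes, 5 timepoints)."""
    t = np.array([0.0, 1.0, 2.5, 3.0, 4.0])
    values = np.array(
        [
            [0.1, 0.4, 0.9, 1.0, 0.8],
            [1.0, 0.7, 0.3, 0.2, 0.4],
            [0.5, 0.5, 0.6, 0.8, 0.9],
        ]
    )
    return ExpressionDataset(["g1", "g2", "g3"], t, values)
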