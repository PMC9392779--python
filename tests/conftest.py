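"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from replom import LocalizationTable, SimulationConfig, simulate_aggregate
from replom.synthetic import simulate_background


@pytest.fixture(scope="session")
def disk_points():
    """500 points uniform in a 1000 nm-radius disk (area pi um^2)."""
    rng = np.random.default_rng(0)
    r = 1000.0 * np.sqrt(rng.uniform(0, 1, 500))
    th = rng.uniform(0, 2 * np.pi, 500)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


@pytest.fixture(scope="session")
def iso_sim():
    """A small isotropic aggregate movie with ground truth."""
    cfg = SimulationConfig(
        morphology="isotropic", r1=0.003, r2=0.00008, t0=300.0, t1=1400.0,
        tau=300.0, n_frames=100, label_density=20.0, seed=5,
    )
    return simulate_aggregate(cfg)


@pytest.fixture(scope="session")
def aniso_sim():
    """A small anisotropic aggregate movie with ground truth."""
    cfg = SimulationConfig(
        morphology="anisotropic", r1=0.0015, r2=0.008, t0=500.0, t1=1500.0,
        tau=300.0, n_frames=100, label_density=30.0, seed=6,
    )
    return simulate_aggregate(cfg)


@pytest.fixture(scope="session")
def two_aggregate_field():
    """Two well-separated aggregates plus sparse background in one field.

    Returns (table, core1, core2) with cores 34 um apart; background at
    a realistic sparse rate so the percentile cut lands among the long
    background edges rather than inside the aggregates.
    """
    core1, core2 = (12000.0, 12000.0), (-12000.0, -12000.0)
    cfg1 = SimulationConfig(
        morphology="isotropic", r1=0.003, r2=0.00008, t0=300.0, t1=1400.0,
        tau=300.0, n_frames=100, label_density=20.0, core_position=core1, seed=5,
    )
    cfg2 = SimulationConfig(
        morphology="anisotropic", r1=0.0015, r2=0.008, t0=500.0, t1=1500.0,
        tau=300.0, n_frames=100, label_density=30.0, core_position=core2, seed=6,
    )
    t1, tr1 = simulate_aggregate(cfg1)
    t2, tr2 = simulate_aggregate(cfg2)
    bg = simulate_background((-25000, -25000, 25000, 25000), 100, 600, seed=7)
    parts = [t1, t2, bg]
    import pandas as pd

    table = LocalizationTable(
        np.concatenate([t.frame for t in parts]),
        np.concatenate([t.x for t in parts]),
        np.concatenate([t.y for t in parts]),
        np.concatenate([t.intensity for t in parts]),
        frame_interval=t1.frame_interval,
        extra=pd.DataFrame({"source": np.repeat([0, 1, 2],
                                                [len(t) for t in parts])}),
    )
    return table, (core1, tr1, len(t1)), (core2, tr2, len(t2))
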