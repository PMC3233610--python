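"""Shared fixtures: small synthetic runs and the pairwise benchmark sweep."""

import logging

import numpy as np
import pytest

from scfia import ScfiaConfig, SimConfig
from scfia.pipeline import run_pairwise_experiment
from scfia.preprocess import PeakInterval
from scfia.synthetic import generate_runs

logging.getLogger("scfia").setLevel(logging.ERROR)


def make_interval(times, intensities) -> PeakInterval:
    """Build a PeakInterval directly from arrays (testing helper)."""
    t = np.asarray(times, dtype=float)
    i = np.asarray(intensities, dtype=float)
    k = int(np.argmax(i))
    return PeakInterval(start_time=float(t[0]), end_time=float(t[-1]),
                        apex_time=float(t[k]), apex_intensity=float(i[k]),
                        times=t, intensities=i)


def random_trace(rng, n_min=8, n_max=40):
    """A random smooth-ish positive peak trace on an arbitrary time axis."""
    n = int(rng.integers(n_min, n_max))
    t0 = rng.uniform(0, 500)
    dt = rng.uniform(0.5, 2.0)
    t = t0 + dt * np.arange(n)
    center = t0 + dt * n * rng.uniform(0.3, 0.7)
    width = dt * rng.uniform(1.5, 4.0)
    base = np.exp(-0.5 * ((t - center) / width) ** 2)
    bump = rng.uniform(0, 0.5) * np.exp(-0.5 * ((t - center - rng.uniform(-3, 3)) / width) ** 2)
    y = rng.uniform(100, 1e5) * (base + bump) + rng.uniform(0, 5, n)
    return t, y


@pytest.fixture(scope="session")
def small_sim_config():
    """A fast, feasible small simulation (two runs, ten peptides)."""
    return SimConfig(rng_seed=7, n_peptides=10, run_length=300.0,
                     mz_range=(400.0, 500.0), decoys_per_peptide=1,
                     decoy_offset_range=(15.0, 18.0), at_sigma=3.0)


@pytest.fixture(scope="session")
def small_runs(small_sim_config):
    return generate_runs(small_sim_config)


@pytest.fixture(scope="session")
def benchmark_sweep():
    """Twenty seeds of the default crowded-decoy pairwise benchmark.

    Shared by the separability, score-gain and baseline-ordering checks.
    """
    results = []
    for seed in range(1, 21):
        sim = SimConfig(rng_seed=seed)
        cfg = ScfiaConfig(rng_seed=seed, min_training_size=10)
        results.append(run_pairwise_experiment(sim, cfg, modes=("combined", "at", "gwarp")))
    return results
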