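"""Shared fixtures: simulated tracks and cached pipeline runs.

Everything is generated programmatically; the expensive full-design runs are
session-scoped so several test modules can share them.
"""
import numpy as np
import pytest

import abscna
from abscna.datamodel import NoiseModel


@pytest.fixture(scope="session")
def validation_sim():
    """Full 40k-locus eight-segment validation sample (alpha=0.40)."""
    cfg = abscna.default_validation_config(seed=1)
    track, truth = abscna.simulate_sample(cfg)
    return cfg, track, truth


@pytest.fixture(scope="session")
def validation_result(validation_sim):
    _, track, _ = validation_sim
    return abscna.run_pipeline(track, abscna.PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def legacy_result(validation_sim):
    _, track, _ = validation_sim
    return abscna.run_legacy(track, abscna.PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def true_noise():
    """Noise model at the simulator's configured parameters."""
    return NoiseModel(sigma2=0.25**2, rho=-0.042)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_track(a, b, chrom="chr1", het=None, sample_id="t"):
    """Small helper to build a track from plain signal lists."""
    n = len(a)
    return abscna.AllelicTrack.from_arrays(
        np.full(n, chrom, dtype=object),
        np.arange(1, n + 1, dtype=np.int64),
        np.asarray(a, dtype=float),
        np.asarray(b, dtype=float),
        het,
        sample_id=sample_id,
    )
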