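"""Shared fixtures: analytic beat templates and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from ecgkalemia.synthetic import (
    NoiseModel,
    default_template,
    generate_record,
)


def gaussian_beat(t, r_time, template):
    """Analytic clean waveform of one beat (oracle, independent of the
    generator's internal windowed evaluation)."""
    x = np.zeros_like(t)
    for w in ("P", "Q", "R", "S", "T"):
        p = template.waves[w]
        x += p.amp_mv * np.exp(-0.5 * ((t - r_time - p.center_s) / p.width_s) ** 2)
    return x


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free 30-s record at the reference potassium."""
    return generate_record(4.0, noise=NoiseModel.silent(), seed=11)


@pytest.fixture(scope="session")
def noisy_record():
    """Default-noise 30-s record at the reference potassium."""
    return generate_record(4.0, seed=12)


@pytest.fixture(scope="session")
def base_template():
    return default_template()
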