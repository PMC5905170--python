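"""Shared fixtures: synthetic studies generated once per session."""

from __future__ import annotations

import pytest

from plasmaquant.pipeline import PipelineConfig, run_pipeline
from plasmaquant.synth import SynthConfig, generate_study


@pytest.fixture(scope="session")
def zero_noise_study():
    """Noise-free study: identity drift, exact masses, no dropout."""
    config = SynthConfig(seed=11).zero_noise()
    records, design, truth = generate_study(config)
    return records, design, truth


@pytest.fixture(scope="session")
def zero_noise_run(zero_noise_study):
    records, design, truth = zero_noise_study
    result = run_pipeline(records, design, PipelineConfig())
    return result, truth


@pytest.fixture(scope="session")
def default_study():
    """Study under the default (noisy) conditions."""
    records, design, truth = generate_study(SynthConfig(seed=7))
    return records, design, truth


def make_record(**kwargs):
    """PeptideRecord factory with sensible defaults for unit tests."""
    from plasmaquant.io_formats import PeptideRecord

    defaults = dict(
        sample_id="S01",
        sequence="ELVISLIVESK",
        measured_mass=1200.5,
        theoretical_mass=1200.5,
        rt=100.0,
        area=1e6,
        xcorr=3.0,
        confidence="high",
        rank=1,
        proteins=("P12345",),
    )
    defaults.update(kwargs)
    return PeptideRecord(**defaults)
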