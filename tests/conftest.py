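"""Shared fixtures.

The trained-network fixtures are session-scoped: the sprite-study and
bouncing-study networks are trained once and reused by every acceptance
property that probes them.
"""

import numpy as np
import pytest

ACCEPTANCE_SEEDS = (0, 1, 2, 3, 4)


@pytest.fixture(scope="session")
def sprite_coders():
    """One flagship two-level network per acceptance seed."""

    from dpcnet.experiments import train_sprite_coder

    return {seed: train_sprite_coder(seed) for seed in ACCEPTANCE_SEEDS}


@pytest.fixture(scope="session")
def sprite_studies(sprite_coders):
    """Timescale + factorization metrics per seed (one filtering pass)."""

    from dpcnet.experiments import sprite_study

    return {seed: sprite_study(coder, seed) for seed, coder in sprite_coders.items()}


@pytest.fixture(scope="session")
def bounce_models():
    """Three-level networks trained on mixed bouncing corpora."""

    from dpcnet.experiments import train_bounce_model

    return {seed: train_bounce_model(seed)[0] for seed in ACCEPTANCE_SEEDS}


@pytest.fixture(scope="session")
def bounce_studies(bounce_models):
    from dpcnet.experiments import threelevel_experiment

    return {seed: threelevel_experiment(model, seed) for seed, model in bounce_models.items()}
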