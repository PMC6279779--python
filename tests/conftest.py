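"""Shared fixtures: deterministic presets and noiseless variants."""

from dataclasses import replace

import pytest

from ectspec.synthetic import SimPreset, get_preset


def noiseless(preset: SimPreset, **overrides) -> SimPreset:
    """Strip all stochastic ingredients from a preset."""
    return replace(preset, beta_sd=0.0, noise_mult_sigma=0.0,
                   noise_add_sigma=0.0, **overrides)


@pytest.fixture
def gold_preset() -> SimPreset:
    return get_preset("bare_gold")


@pytest.fixture
def protein_preset() -> SimPreset:
    return get_preset("pCc1_hCc")


@pytest.fixture
def gold_noiseless(gold_preset) -> SimPreset:
    return noiseless(gold_preset)


@pytest.fixture
def protein_noiseless(protein_preset) -> SimPreset:
    return noiseless(protein_preset)
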