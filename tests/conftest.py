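"""Shared fixtures: the packaged library, zero-noise generator configs and
small planted feature sets. All fixture data is generated at test time."""

from __future__ import annotations

import pytest

from cannatrace.spectral_library import load_default_library
from cannatrace.synthetic_data import GeneratorConfig, PEAKS, generate_day1


@pytest.fixture(scope="session")
def library():
    return load_default_library()


@pytest.fixture()
def zero_noise_cfg():
    return GeneratorConfig(seed=11).zero_noise()


@pytest.fixture()
def noisy_cfg():
    return GeneratorConfig(seed=11)  # defaults: 0.5 ppm, 0.02 min, 10 % CV


@pytest.fixture()
def day1_plant(zero_noise_cfg):
    return generate_day1("plant", zero_noise_cfg)


@pytest.fixture()
def day1_synthetic(zero_noise_cfg):
    return generate_day1("synthetic", zero_noise_cfg)


@pytest.fixture(scope="session")
def stressed_peak_roster():
    """The 20 stressed-storage chromatographic peaks (internal standard
    excluded), as (key, label, formula, rt)."""
    return [
        (p.key, p.label, p.formula, p.rt) for p in PEAKS if p.label != "IS-D3-THC"
    ]
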