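"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from eegtransfer import (DomainDataset, EEGSeqNet, FATIGUE3, SLEEP5,
                         FeatureExtractorSpec, ShiftSpec, generate_domain_pair)
from eegtransfer.synth import SOURCE_SIGNATURES, TARGET_CLASS_MAP, generate_epoch

#: Reduced geometry for training-loop tests: 10 s epochs at 100 Hz keep the
#: convolution arithmetic valid (input ≥ 400) at a tenth of the compute.
TINY_LEN_S = 10.0
TINY_SPEC = FeatureExtractorSpec(input_length=1000)


def make_tiny_pair(n_per_class: int, seed: int,
                   shift: ShiftSpec = ShiftSpec(gain=1.5, noise_sd=5.0)):
    """Small two-domain pair with 1000-sample epochs."""
    return generate_domain_pair(n_per_class, shift=shift, seed=seed,
                                length_s=TINY_LEN_S)


def make_tiny_net(seed: int) -> EEGSeqNet:
    return EEGSeqNet(extractor_spec=TINY_SPEC, seed=seed)


@pytest.fixture(scope="session")
def domain_pair():
    """Default-geometry (30 s / 100 Hz) pair, 6 epochs per class."""
    return generate_domain_pair(6, seed=7)


@pytest.fixture(scope="session")
def tiny_pair():
    return make_tiny_pair(4, seed=3)


@pytest.fixture(scope="session")
def alpha_epochs():
    """Eight wake-like (alpha-dominant) 30 s epochs."""
    return [generate_epoch(SOURCE_SIGNATURES["W"], seed=100 + i)
            for i in range(8)]
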