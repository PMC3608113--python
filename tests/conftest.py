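"""Shared fixtures: the standard burst and a simulated echo, computed once."""

import numpy as np
import pytest

from misovolterra import BubbleParams, BurstSpec, Signal, make_burst, simulate_echo


@pytest.fixture(scope="session")
def burst_spec():
    return BurstSpec()  # 4 MHz, 1.2 MPa, 18 cycles, 60 MHz


@pytest.fixture(scope="session")
def bubble_params():
    return BubbleParams()


@pytest.fixture(scope="session")
def burst(burst_spec):
    return make_burst(burst_spec)


@pytest.fixture(scope="session")
def echo(bubble_params, burst):
    """Simulated microbubble echo for the standard burst (expensive; shared)."""
    return simulate_echo(bubble_params, burst)


@pytest.fixture
def tone():
    """Unit cosine at 4 MHz sampled at 60 MHz, 18 carrier periods."""
    fs, f0, n = 60e6, 4e6, 270
    t = np.arange(n) / fs
    return Signal(np.cos(2 * np.pi * f0 * t), fs), f0
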