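"""Shared fixtures: validation swimmers, small wakes, oracle grids."""

import numpy as np
import pytest

from thrustwake import SwimmerSpec, WakeSpec

# Tail amplitude used throughout: 7% of a 0.19 m body.
A_TAIL = 0.07 * 0.19


def validation_swimmer(**overrides) -> SwimmerSpec:
    """Estimator-validation fixture: a uniform-envelope traveling wave
    sampled densely enough in space (41 markers) that the ground-truth
    overall phase lag is exactly 2 pi / lam."""
    defaults = dict(f=2.0, lam=1.0, a_head=A_TAIL, a_tail=A_TAIL,
                    duration=5.0, n_markers=41)
    defaults.update(overrides)
    return SwimmerSpec(**defaults)


@pytest.fixture
def swimmer_factory():
    return validation_swimmer


@pytest.fixture
def small_wake() -> WakeSpec:
    """Vortex street on a reduced grid, cheap enough for unit tests."""
    return WakeSpec(x_range=(0.0, 0.4), y_range=(-0.06, 0.06),
                    spacing=0.002, fps=100.0, n_vortices=4)


@pytest.fixture
def oracle_grid():
    """Square 101x101 grid for pressure-oracle comparisons."""
    x = np.linspace(-0.05, 0.05, 101)
    y = np.linspace(-0.05, 0.05, 101)
    return x, y
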