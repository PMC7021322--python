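"""Shared fixtures: deterministic RNGs and small lattice configurations."""

from __future__ import annotations

import numpy as np
import pytest

from angiocpm.config import LatticeConfig, PottsParameters
from angiocpm.lattice import LatticeState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def potts():
    return PottsParameters()


@pytest.fixture
def shape_only_potts():
    """Potts couplings with adhesion and taxis switched off (shape terms only)."""
    return PottsParameters(rho_adh_cell_cell=0.0, rho_adh_cell_ecm=0.0)


@pytest.fixture
def small_state():
    """12x12-pixel lattice (h = 2.5 um) with three well-separated cells."""
    st = LatticeState(12, 2.5)
    st.add_cell([(x, y) for x in range(2, 5) for y in range(2, 6)])
    st.add_cell([(x, y) for x in range(6, 9) for y in range(3, 7)])
    st.add_cell([(x, y) for x in range(3, 6) for y in range(8, 11)])
    return st


def random_blob(rng: np.random.Generator, n_pixels: int,
                start=(20, 20)) -> np.ndarray:
    """Connected random pixel blob grown by biased accretion (test helper)."""
    blob = {tuple(start)}
    frontier = [tuple(start)]
    while len(blob) < n_pixels:
        x, y = frontier[int(rng.integers(len(frontier)))]
        dx, dy = ((1, 0), (-1, 0), (0, 1), (0, -1))[int(rng.integers(4))]
        q = (x + dx, y + dy)
        if q not in blob:
            blob.add(q)
            frontier.append(q)
    return np.array(sorted(blob))
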