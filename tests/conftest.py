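"""Shared fixtures and construction helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from sseforest.structure_io import Residue


def residues_from_ss(ss: str, spacing: float = 3.8) -> list[Residue]:
    """Residues along a line with the given secondary-structure string."""
    return [
        Residue(index=i + 1, ca=np.array([i * spacing, 0.0, 0.0]), ss_code=c)
        for i, c in enumerate(ss)
    ]


def residues_from_coords(
    coords, kind_code: str = "H", accessibilities=None
) -> list[Residue]:
    coords = np.asarray(coords, dtype=float)
    return [
        Residue(
            index=i + 1,
            ca=coords[i],
            ss_code=kind_code,
            accessibility=0.0 if accessibilities is None else accessibilities[i],
        )
        for i in range(len(coords))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
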