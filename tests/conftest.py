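"""Shared fixtures: small random distance tables and helper builders."""

from __future__ import annotations

import numpy as np
import pytest

from lipgate.core import DistanceTable


def make_random_table(
    rng: np.random.Generator,
    n_frames: int = 5,
    n_lipids: int = 3,
    n_residues: int = 4,
    species=("PIP2", "PC"),
    dt: float = 0.1,
) -> DistanceTable:
    """A small random table with distances straddling the 0.6 nm cutoff."""
    distances = rng.uniform(0.2, 1.2, size=(n_frames, n_lipids, n_residues))
    lipid_species = rng.choice(list(species), size=n_lipids)
    return DistanceTable(
        times=np.arange(n_frames) * dt,
        distances=distances,
        lipid_species=lipid_species,
        residue_ids=np.arange(n_residues),
    )


def table_from_bool(occ: np.ndarray, dt: float = 1.0, species: str = "PIP2") -> DistanceTable:
    """DistanceTable realising a given boolean contact pattern exactly.

    True -> 0.4 nm (contact), False -> 1.0 nm.
    """
    occ = np.asarray(occ, dtype=bool)
    distances = np.where(occ, 0.4, 1.0)
    return DistanceTable(
        times=np.arange(occ.shape[0]) * dt,
        distances=distances,
        lipid_species=np.full(occ.shape[1], species, dtype=object),
        residue_ids=np.arange(occ.shape[2]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260918)
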