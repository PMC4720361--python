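"""Shared fixtures and independent oracles.

The brute-force oracles here deliberately avoid the package's closed-form
and vectorized code paths: the independent-model oracle materializes every
subset of every attainable burn size, and the expected-species oracle
loops patterns and species in pure Python.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np
import pytest

from firereserve import (BurnModel, BurnPattern, Reserve, SizeDistribution,
                         SpeciesMatrix, build_square_landscape,
                         enumerate_spread_patterns, size_distribution)


@pytest.fixture(scope="session")
def grid55():
    return build_square_landscape(5, 5, 1)


@pytest.fixture(scope="session")
def corr55(grid55):
    return enumerate_spread_patterns(grid55)


@pytest.fixture(scope="session")
def sizes55(corr55):
    return size_distribution(corr55)


def make_species(landscape, placements: Dict[int, Sequence[int]]) -> SpeciesMatrix:
    """Species matrix from {species index (1-based): parcel ids}."""
    J = landscape.n_focal
    n = max(placements)
    presence = np.zeros((J, n), dtype=np.int8)
    for i, parcels in placements.items():
        for p in parcels:
            presence[p - 1, i - 1] = 1
    return SpeciesMatrix(presence=presence,
                         parcel_ids=tuple(landscape.focal_ids),
                         species_ids=tuple(f"sp{i}" for i in range(1, n + 1)))


@pytest.fixture(scope="session")
def hotspot_species(grid55):
    """Both species on parcels 7, 8 and 20 (the three-hotspot layout)."""
    return make_species(grid55, {1: [7, 8, 20], 2: [7, 8, 20]})


# -- oracles -------------------------------------------------------------

def brute_force_independent_model(J: int, sizes: SizeDistribution) -> BurnModel:
    """Materialize the independent model: all C(J, n) subsets per size n,
    each with probability q_n / C(J, n).  Feasible for J <= 12."""
    patterns = []
    for n, q in sizes.probs.items():
        w = q / math.comb(J, n)
        for subset in itertools.combinations(range(1, J + 1), n):
            patterns.append(BurnPattern(burned=frozenset(subset), probability=w))
    return BurnModel(kind="independent", representation="enumerated",
                     patterns=tuple(patterns))


def naive_expected_species(reserve: Iterable[int], species: SpeciesMatrix,
                           model: BurnModel) -> float:
    """Pure-Python expected surviving species over explicit patterns."""
    row_of = species.row_index()
    reserve = set(reserve)
    total = 0.0
    for pat in model.patterns:
        alive = reserve - pat.burned
        surviving = set()
        for p in alive:
            row = species.presence[row_of[p]]
            surviving |= {i for i in range(species.n_species) if row[i]}
        total += pat.probability * len(surviving)
    return total


def naive_outcome_distribution(reserve: Iterable[int], species: SpeciesMatrix,
                               model: BurnModel) -> Dict[int, float]:
    row_of = species.row_index()
    reserve = set(reserve)
    dist: Dict[int, float] = {}
    for pat in model.patterns:
        alive = reserve - pat.burned
        mask = np.zeros(species.n_species, dtype=bool)
        for p in alive:
            mask |= species.presence[row_of[p]].astype(bool)
        k = int(mask.sum())
        dist[k] = dist.get(k, 0.0) + pat.probability
    return dist
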