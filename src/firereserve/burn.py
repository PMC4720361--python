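"""Burn-pattern models: spreading (spatially-correlated) fires and
risk-equalized spatially-independent nulls.

A fire ignites in a single parcel chosen uniformly over the ignition
domain and spreads to the contiguous neighbours (queen contiguity on
square grids, six edge neighbours on hexagons).  Enumerating one burn per
ignition parcel yields the correlated model.  The independent null keeps
the distribution of *how many* parcels burn but scatters the burned
parcels uniformly at random, so both scenarios destroy the same expected
amount of landscape and differ only in spatial pattern.

The independent model on the stylized grid has millions of explicit
patterns (all subsets of each attainable size), so it is represented in
closed form via the size distribution; survival queries reduce to
hypergeometric ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import numpy as np

__all__ = [
    "BurnPattern",
    "BurnModel",
    "SizeDistribution",
    "spread_burn",
    "enumerate_spread_patterns",
    "expected_burned",
    "size_distribution",
    "count_independent_patterns",
    "independent_model_closed_form",
    "sample_spread_patterns",
    "sample_matched_independent_patterns",
]

_PROB_TOL = 1e-12


class BurnModelError(ValueError):
    """Invalid burn-model construction or query."""


@dataclass(frozen=True)
class BurnPattern:
    """One stochastic disturbance outcome: the focal parcels destroyed."""

    burned: FrozenSet[int]
    probability: float
    ignitions: Tuple[int, ...] = ()

    def __post_init__(self):
        if not self.burned:
            raise BurnModelError("burn pattern must destroy at least one parcel")
        if not self.probability > 0:
            raise BurnModelError("burn pattern probability must be positive")

    @property
    def size(self) -> int:
        return len(self.burned)


@dataclass(frozen=True)
class SizeDistribution:
    """Probability that ``n`` focal parcels burn, for each attainable ``n``."""

    probs: Dict[int, float]

    def __post_init__(self):
        if any(n <= 0 for n in self.probs):
            raise BurnModelError("burn sizes must be positive")
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-9:
            raise BurnModelError(f"size probabilities sum to {total}, not 1")

    @property
    def support(self) -> List[int]:
        return sorted(self.probs)

    def mean(self) -> float:
        return sum(n * q for n, q in self.probs.items())


@dataclass(frozen=True)
class BurnModel:
    """A finite disturbance distribution: explicit patterns or closed form.

    ``kind`` distinguishes spatially-correlated (spreading) models from
    spatially-independent ones; ``representation`` is ``enumerated``,
    ``sampled`` or ``closed_form``.  Closed-form models store only the
    focal-parcel count ``J`` and the size distribution: conditional on
    ``n`` parcels burning, every ``n``-subset of focal parcels is equally
    likely.
    """

    kind: str  # "correlated" | "independent"
    representation: str  # "enumerated" | "sampled" | "closed_form"
    patterns: Tuple[BurnPattern, ...] = ()
    J: Optional[int] = None
    sizes: Optional[SizeDistribution] = None

    def __post_init__(self):
        if self.kind not in ("correlated", "independent"):
            raise BurnModelError(f"unknown model kind {self.kind!r}")
        if self.representation == "closed_form":
            if self.J is None or self.sizes is None:
                raise BurnModelError("closed-form model needs J and a size distribution")
            if any(n > self.J for n in self.sizes.support):
                raise BurnModelError("size support exceeds number of focal parcels")
        else:
            if not self.patterns:
                raise BurnModelError("explicit model has no patterns")
            total = sum(p.probability for p in self.patterns)
            if abs(total - 1.0) > _PROB_TOL * max(1, len(self.patterns)):
                raise BurnModelError(f"pattern probabilities sum to {total}, not 1")

    @property
    def is_closed_form(self) -> bool:
        return self.representation == "closed_form"

    # -- closed-form survival queries ------------------------------------

    def prob_all_burn(self, parcels: Iterable[int]) -> float:
        """P(every parcel in the given set burns) under this model.

        For closed-form models this is the hypergeometric identity
        ``sum_n q_n * C(J-r, n-r) / C(J, n)`` with ``r`` the set size;
        for explicit models it is summed over patterns.
        """
        pset = frozenset(parcels)
        r = len(pset)
        if r == 0:
            return 1.0
        if self.is_closed_form:
            J = self.J
            out = 0.0
            for n, q in self.sizes.probs.items():
                if n >= r:
                    out += q * math.comb(J - r, n - r) / math.comb(J, n)
            return out
        return sum(p.probability for p in self.patterns if pset <= p.burned)


def spread_burn(landscape, ignition: int) -> BurnPattern:
    """Burn pattern from a single ignition: the parcel plus its contiguous
    neighbours, intersected with the focal landscape."""
    if ignition not in landscape.ignition_ids:
        raise BurnModelError(f"parcel {ignition} is not in the ignition domain")
    spread = {ignition} | set(landscape.spread_neighbors(ignition))
    burned = frozenset(p for p in spread if landscape.is_focal(p))
    if not burned:
        raise BurnModelError(
            f"ignition at parcel {ignition} burns no focal parcel")
    return BurnPattern(burned=burned, probability=1.0, ignitions=(ignition,))


def enumerate_spread_patterns(landscape) -> BurnModel:
    """Correlated model: one equiprobable pattern per ignition parcel.

    Patterns with coincident burned sets are kept distinct — probability
    mass is per ignition event.
    """
    ignitions = list(landscape.ignition_ids)
    p = 1.0 / len(ignitions)
    patterns = tuple(
        BurnPattern(burned=spread_burn(landscape, ign).burned,
                    probability=p, ignitions=(ign,))
        for ign in ignitions
    )
    return BurnModel(kind="correlated", representation="enumerated", patterns=patterns)


def expected_burned(model: BurnModel) -> float:
    """Expected number of focal parcels destroyed, ``sum_b p_b |burned_b|``."""
    if model.is_closed_form:
        return model.sizes.mean()
    return sum(p.probability * p.size for p in model.patterns)


def size_distribution(model: BurnModel) -> SizeDistribution:
    """Aggregate pattern probabilities by number of parcels burned."""
    if model.is_closed_form:
        return model.sizes
    probs: Dict[int, float] = {}
    for p in model.patterns:
        probs[p.size] = probs.get(p.size, 0.0) + p.probability
    return SizeDistribution(probs=probs)


def count_independent_patterns(J: int, sizes: SizeDistribution) -> int:
    """Number of distinct burned sets in the independent model:
    ``sum over the size support of C(J, n)``."""
    if any(n > J for n in sizes.support):
        raise BurnModelError("size support exceeds J")
    return sum(math.comb(J, n) for n in sizes.support)


def independent_model_closed_form(J: int, sizes: SizeDistribution) -> BurnModel:
    """Risk-equalized independent model: same size distribution as the
    correlated scenario, burned parcels uniform over all ``n``-subsets."""
    return BurnModel(kind="independent", representation="closed_form",
                     J=J, sizes=sizes)


def sample_spread_patterns(landscape, n_sims: int, seed) -> BurnModel:
    """Monte-Carlo correlated model: ``n_sims`` single-ignition spreading
    fires with uniformly random ignition parcels, each weighted ``1/n_sims``."""
    if n_sims < 1:
        raise BurnModelError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    domain = np.asarray(list(landscape.ignition_ids))
    w = 1.0 / n_sims
    patterns = []
    for ign in rng.choice(domain, size=n_sims, replace=True):
        burned = spread_burn(landscape, int(ign)).burned
        patterns.append(BurnPattern(burned=burned, probability=w,
                                    ignitions=(int(ign),)))
    return BurnModel(kind="correlated", representation="sampled",
                     patterns=tuple(patterns))


def sample_matched_independent_patterns(landscape, correlated: BurnModel,
                                        seed) -> BurnModel:
    """Size-matched independent null of a correlated model.

    For each correlated pattern, draw a uniformly random focal-parcel
    subset of the same cardinality; weights are copied, so the expected
    burned area matches the correlated model exactly.
    """
    if correlated.is_closed_form:
        raise BurnModelError("matched sampling needs an explicit correlated model")
    rng = np.random.default_rng(seed)
    focal = np.asarray(list(landscape.focal_ids))
    patterns = []
    for src in correlated.patterns:
        burned = frozenset(int(x) for x in
                           rng.choice(focal, size=src.size, replace=False))
        patterns.append(BurnPattern(burned=burned, probability=src.probability))
    return BurnModel(kind="independent", representation=correlated.representation,
                     patterns=tuple(patterns))
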