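"""Reserve evaluation and exact optimization.

A reserve is a set of at most ``m`` focal parcels.  A species survives a
burn pattern iff it is present on at least one selected, unburned parcel;
the objective is the probability-weighted expected number of surviving
species over all burn patterns.  Explicit (enumerated/sampled) models are
evaluated pattern by pattern; closed-form independent models are evaluated
with hypergeometric survival probabilities and an inclusion–exclusion
outcome distribution over the reserve parcels' joint burn events.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Tuple

import numpy as np

from .burn import BurnModel, BurnPattern, spread_burn
from .synthetic import SpeciesMatrix

__all__ = [
    "Reserve",
    "CoverageResult",
    "species_surviving",
    "evaluate",
    "optimize_exact",
    "secondary_metrics",
    "multi_burn_ignitions",
    "percent_gain",
]

_TIE_TOL = 1e-9
_MAX_INCLUSION_EXCLUSION = 22  # 2^r joint burn events enumerated


class CoverageError(ValueError):
    pass


@dataclass(frozen=True)
class Reserve:
    """A selected set of focal parcels, at most ``m`` of them."""

    parcels: FrozenSet[int]
    m: int

    def __post_init__(self):
        object.__setattr__(self, "parcels", frozenset(self.parcels))
        if len(self.parcels) > self.m:
            raise CoverageError(
                f"reserve has {len(self.parcels)} parcels, exceeds m={self.m}")

    def sorted_parcels(self) -> Tuple[int, ...]:
        return tuple(sorted(self.parcels))


@dataclass(frozen=True)
class CoverageResult:
    """Expected surviving species with the full outcome distribution."""

    expected_species: float
    outcome_distribution: Dict[int, float]  # k surviving species -> probability
    species_survival: Tuple[float, ...]  # per-species survival probability

    def __post_init__(self):
        total = sum(self.outcome_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise CoverageError(f"outcome distribution sums to {total}")


def species_surviving(reserve: Reserve, species: SpeciesMatrix,
                      pattern: BurnPattern) -> FrozenSet[str]:
    """Species present on at least one selected, unburned parcel."""
    row_of = species.row_index()
    try:
        alive_rows = [row_of[p] for p in reserve.parcels if p not in pattern.burned]
    except KeyError as e:
        raise CoverageError(f"reserve parcel {e.args[0]} not in species matrix")
    if not alive_rows:
        return frozenset()
    mask = species.presence[alive_rows].any(axis=0)
    return frozenset(species.species_ids[i] for i in np.flatnonzero(mask))


def _check_alignment(species: SpeciesMatrix, parcels: Iterable[int]) -> None:
    row_of = species.row_index()
    for p in parcels:
        if p not in row_of:
            raise CoverageError(f"parcel {p} missing from species matrix")


def evaluate(reserve: Reserve, species: SpeciesMatrix,
             model: BurnModel) -> CoverageResult:
    """Expected species, outcome distribution and per-species survival for a
    fixed reserve under a burn model."""
    _check_alignment(species, reserve.parcels)
    if model.is_closed_form:
        return _evaluate_closed_form(reserve, species, model)
    return _evaluate_explicit(reserve, species, model)


def _evaluate_explicit(reserve: Reserve, species: SpeciesMatrix,
                       model: BurnModel) -> CoverageResult:
    row_of = species.row_index()
    parcels = reserve.sorted_parcels()
    idx = [row_of[p] for p in parcels]
    P = species.presence[idx].astype(np.int32)  # r x I
    w = np.array([p.probability for p in model.patterns])
    # unburned indicator, patterns x reserve parcels
    U = np.array([[p not in pat.burned for p in parcels]
                  for pat in model.patterns], dtype=np.int32)
    surv = (U @ P) > 0  # patterns x I
    counts = surv.sum(axis=1)
    expected = float(w @ counts)
    species_survival = tuple(float(x) for x in (w @ surv))
    outcome: Dict[int, float] = {}
    for c, p in zip(counts, w):
        outcome[int(c)] = outcome.get(int(c), 0.0) + float(p)
    return CoverageResult(expected_species=expected,
                          outcome_distribution=outcome,
                          species_survival=species_survival)


def _evaluate_closed_form(reserve: Reserve, species: SpeciesMatrix,
                          model: BurnModel) -> CoverageResult:
    parcels = reserve.sorted_parcels()
    r = len(parcels)
    if r > _MAX_INCLUSION_EXCLUSION:
        raise CoverageError(
            f"closed-form outcome distribution limited to reserves of "
            f"<= {_MAX_INCLUSION_EXCLUSION} parcels (got {r})")
    row_of = species.row_index()

    # P(all parcels of a fixed size-t subset burn) depends only on t.
    burn_all = [model.prob_all_burn(parcels[:t]) for t in range(r + 1)]

    # Per-species survival: dies iff its whole reserve footprint burns.
    footprint_sizes = species.presence[[row_of[p] for p in parcels]].sum(axis=0) \
        if r else np.zeros(species.n_species, dtype=int)
    species_survival = tuple(
        0.0 if t == 0 else 1.0 - burn_all[int(t)] for t in footprint_sizes)

    # Outcome distribution: Moebius inversion over subsets of the reserve.
    # p_exact[S] = sum_{T >= S} (-1)^{|T|-|S|} P(all of T burn).
    n_sub = 1 << r
    sizes = np.array([bin(s).count("1") for s in range(n_sub)])
    p_superset = np.array([burn_all[k] for k in sizes])
    p_exact = p_superset.copy()
    for bit in range(r):  # standard subset-sum Moebius transform
        step = 1 << bit
        for s in range(n_sub):
            if not s & step:
                p_exact[s] -= p_exact[s | step]
    p_exact = np.clip(p_exact, 0.0, None)

    # Species surviving each joint burn configuration of the reserve.
    footprints = np.zeros(species.n_species, dtype=np.int64)
    for k, p in enumerate(parcels):
        footprints |= (species.presence[row_of[p]].astype(np.int64) << k)
    outcome: Dict[int, float] = {}
    for s in range(n_sub):
        if p_exact[s] <= 0:
            continue
        unburned_mask = (n_sub - 1) ^ s
        k_surv = int(np.count_nonzero(footprints & unburned_mask))
        outcome[k_surv] = outcome.get(k_surv, 0.0) + float(p_exact[s])
    total = sum(outcome.values())
    outcome = {k: v / total for k, v in outcome.items()}
    expected = sum(k * v for k, v in outcome.items())
    return CoverageResult(expected_species=float(expected),
                          outcome_distribution=outcome,
                          species_survival=species_survival)


def _expected_only_explicit(species: SpeciesMatrix, model: BurnModel,
                            combos: Iterable[Tuple[int, ...]]) -> np.ndarray:
    """Expected species for many candidate reserves under an explicit model."""
    row_of = species.row_index()
    focal = sorted(row_of)
    col_of = {p: k for k, p in enumerate(focal)}
    P = species.presence[[row_of[p] for p in focal]].astype(np.int32)
    U = np.array([[p not in pat.burned for p in focal] for pat in model.patterns],
                 dtype=bool)
    w = np.array([p.probability for p in model.patterns])
    # per-pattern, per-parcel, per-species alive-presence
    M = U[:, :, None] & (P[None, :, :] > 0)  # B x J x I
    out = np.empty(0)
    vals = []
    for combo in combos:
        cols = [col_of[p] for p in combo]
        surv = M[:, cols, :].any(axis=1)  # B x I
        vals.append(float(w @ surv.sum(axis=1)))
    return np.array(vals)


def optimize_exact(landscape, species: SpeciesMatrix, model: BurnModel,
                   m: int, *, max_candidates: int = 10 ** 7
                   ) -> List[Tuple[Reserve, CoverageResult]]:
    """All expected-species maximizers among size-``m`` reserves.

    Enumerates every size-``m`` subset of focal parcels (by monotonicity a
    strictly smaller reserve is never strictly better).  Ties are
    preserved and returned sorted lexicographically by parcel ids.
    """
    J = landscape.n_focal
    if m > J:
        raise CoverageError(f"m={m} exceeds the {J} focal parcels")
    if m < 1:
        raise CoverageError("m must be >= 1")
    n_candidates = math.comb(J, m)
    if n_candidates > max_candidates:
        raise CoverageError(
            f"{n_candidates} candidate reserves exceed the exact-search cap "
            f"({max_candidates}); use the simulated-annealing solver")
    focal = sorted(landscape.focal_ids)
    _check_alignment(species, focal)
    combos = list(itertools.combinations(focal, m))

    if model.is_closed_form:
        row_of = species.row_index()
        burn_all = {}  # footprint size -> P(all burn)

        def die_prob(t: int) -> float:
            if t not in burn_all:
                burn_all[t] = model.prob_all_burn(focal[:t])
            return burn_all[t]

        pres = species.presence[[row_of[p] for p in focal]]
        col_of = {p: k for k, p in enumerate(focal)}
        vals = []
        for combo in combos:
            t = pres[[col_of[p] for p in combo]].sum(axis=0)
            vals.append(float(sum(0.0 if ti == 0 else 1.0 - die_prob(int(ti))
                                  for ti in t)))
        vals = np.array(vals)
    else:
        vals = _expected_only_explicit(species, model, combos)

    best = vals.max()
    winners = [combo for combo, v in zip(combos, vals) if v >= best - _TIE_TOL]
    winners.sort()
    return [(Reserve(parcels=frozenset(c), m=m),
             evaluate(Reserve(parcels=frozenset(c), m=m), species, model))
            for c in winners]


def secondary_metrics(reserve: Reserve, species: SpeciesMatrix,
                      model: BurnModel) -> Tuple[float, float]:
    """(P(zero species survive), P(all species survive))."""
    res = evaluate(reserve, species, model)
    return (res.outcome_distribution.get(0, 0.0),
            res.outcome_distribution.get(species.n_species, 0.0))


def multi_burn_ignitions(landscape, reserve: Reserve) -> int:
    """Dispersion metric: ignition locations whose spreading fire burns two
    or more reserve parcels."""
    count = 0
    for ign in landscape.ignition_ids:
        burned = spread_burn(landscape, ign).burned
        if len(burned & reserve.parcels) >= 2:
            count += 1
    return count


def percent_gain(expected_spatial: float, expected_naive: float) -> float:
    """Percent improvement of the spatially-aware design over a baseline."""
    if expected_naive <= 0:
        raise CoverageError("baseline expected species must be positive")
    return 100.0 * (expected_spatial - expected_naive) / expected_naive
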