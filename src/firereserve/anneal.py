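"""Simulated annealing for large-landscape reserve selection.

Start from a random size-``m`` reserve, repeatedly swap one parcel out and
one in, accept improving (or tying) moves always and worsening moves with
Metropolis probability ``exp(delta / T)`` under a geometrically cooling
temperature, and keep the best reserve seen.  By default the burn model is
fixed across all evaluations (common random numbers); with
``resample_each_step`` a fresh Monte-Carlo model is drawn for every
candidate, mirroring re-simulation of the fires at each step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .burn import BurnModel
from .coverage import CoverageError, Reserve, evaluate
from .synthetic import SpeciesMatrix

__all__ = [
    "AnnealingConfig",
    "SolveResult",
    "TraceStep",
    "initial_reserve",
    "swap_move",
    "accept",
    "anneal",
]


@dataclass(frozen=True)
class AnnealingConfig:
    initial_temperature: float = 10.0
    cooling_rate: float = 0.995
    n_burn_sims: int = 500
    max_iterations: int = 2000
    resample_each_step: bool = False
    temperature_floor: float = 1e-6
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0 < self.cooling_rate < 1:
            raise ValueError("cooling_rate must be in (0, 1)")
        if self.initial_temperature <= 0:
            raise ValueError("initial_temperature must be positive")
        if self.n_burn_sims < 1:
            raise ValueError("n_burn_sims must be >= 1")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")


@dataclass(frozen=True)
class TraceStep:
    iteration: int
    current_value: float
    best_value: float
    temperature: float
    accepted: bool


@dataclass(frozen=True)
class SolveResult:
    best_reserve: Reserve
    best_value: float
    initial_value: float
    trace: Tuple[TraceStep, ...]


def initial_reserve(landscape, m: int, seed) -> Reserve:
    """Uniform random size-``m`` reserve."""
    focal = sorted(landscape.focal_ids)
    if m > len(focal):
        raise CoverageError(f"m={m} exceeds the {len(focal)} focal parcels")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.asarray(focal), size=m, replace=False)
    return Reserve(parcels=frozenset(int(p) for p in chosen), m=m)


def swap_move(reserve: Reserve, landscape, rng) -> Reserve:
    """Remove one uniformly chosen member, add one uniformly chosen
    non-member; reserve size is preserved."""
    members = sorted(reserve.parcels)
    outside = sorted(set(landscape.focal_ids) - reserve.parcels)
    if not members or not outside:
        raise CoverageError("no legal swap move exists")
    j_out = int(rng.choice(members))
    j_in = int(rng.choice(outside))
    return Reserve(parcels=(reserve.parcels - {j_out}) | {j_in}, m=reserve.m)


def accept(delta: float, temperature: float, rng) -> bool:
    """Metropolis rule: improvements and ties always, worsenings with
    probability ``exp(delta / temperature)``."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta >= 0:
        return True
    return bool(rng.random() < math.exp(delta / temperature))


class _FixedModelEvaluator:
    """Incremental expected-species evaluation under a fixed explicit model.

    Maintains, per burn pattern and species, the number of unburned
    reserve parcels holding that species; a swap updates two rank-one
    terms.  Results equal naive re-evaluation (contract tested).
    """

    def __init__(self, model: BurnModel, species: SpeciesMatrix, landscape,
                 parcels: Sequence[int]):
        if model.is_closed_form:
            raise CoverageError("annealing needs an explicit burn model")
        row_of = species.row_index()
        self._focal = sorted(landscape.focal_ids)
        self._col_of = {p: k for k, p in enumerate(self._focal)}
        self._P = species.presence[[row_of[p] for p in self._focal]].astype(np.int32)
        self._U = np.array([[p not in pat.burned for p in self._focal]
                            for pat in model.patterns], dtype=np.int32)
        self._w = np.array([p.probability for p in model.patterns])
        cols = [self._col_of[p] for p in parcels]
        self._C = self._U[:, cols] @ self._P[cols]  # patterns x I

    def value(self) -> float:
        return float(self._w @ (self._C > 0).sum(axis=1))

    def propose(self, j_out: int, j_in: int) -> Tuple[float, np.ndarray]:
        ci, co = self._col_of[j_in], self._col_of[j_out]
        C_new = (self._C
                 + np.outer(self._U[:, ci], self._P[ci])
                 - np.outer(self._U[:, co], self._P[co]))
        return float(self._w @ (C_new > 0).sum(axis=1)), C_new

    def apply(self, C_new: np.ndarray) -> None:
        self._C = C_new


ModelOrFactory = Union[BurnModel, Callable[..., BurnModel]]


def _resolve_model(model_factory: ModelOrFactory, seed) -> BurnModel:
    if isinstance(model_factory, BurnModel):
        return model_factory
    return model_factory(seed)


def anneal(landscape, species: SpeciesMatrix, model_factory: ModelOrFactory,
           m: int, config: AnnealingConfig) -> SolveResult:
    """Run the annealing search and return the best reserve found.

    ``model_factory`` is either a fixed :class:`BurnModel` or a callable
    ``factory(seed) -> BurnModel``.  With ``resample_each_step`` the
    factory is invoked for every candidate evaluation; otherwise a single
    model (built once from the factory if needed) is shared by all
    evaluations, making runs bit-reproducible under a fixed seed.
    """
    seq = (config.seed if isinstance(config.seed, np.random.SeedSequence)
           else np.random.SeedSequence(config.seed))
    init_seed, model_seed, move_seed = seq.spawn(3)
    rng = np.random.default_rng(move_seed)
    model_rng = np.random.default_rng(model_seed)

    reserve = initial_reserve(landscape, m, init_seed)
    parcels = list(reserve.sorted_parcels())

    resample = config.resample_each_step
    if resample and isinstance(model_factory, BurnModel):
        raise CoverageError("resample_each_step requires a model factory")

    if resample:
        model = _resolve_model(model_factory, model_rng)
        current_value = evaluate(reserve, species, model).expected_species
        evaluator = None
    else:
        model = _resolve_model(model_factory, model_rng)
        evaluator = _FixedModelEvaluator(model, species, landscape, parcels)
        current_value = evaluator.value()

    initial_value = current_value
    best_parcels = tuple(sorted(parcels))
    best_value = current_value
    temperature = config.initial_temperature
    trace: List[TraceStep] = []

    current = set(parcels)
    focal = sorted(landscape.focal_ids)
    for it in range(1, config.max_iterations + 1):
        if temperature < config.temperature_floor:
            break
        members = sorted(current)
        outside = [p for p in focal if p not in current]
        if not outside:
            break
        j_out = int(rng.choice(members))
        j_in = int(rng.choice(outside))

        if resample:
            model = _resolve_model(model_factory, model_rng)
            cand = Reserve(parcels=(frozenset(current) - {j_out}) | {j_in}, m=m)
            cand_value = evaluate(cand, species, model).expected_species
            C_new = None
        else:
            cand_value, C_new = evaluator.propose(j_out, j_in)

        delta = cand_value - current_value
        accepted = accept(delta, temperature, rng)
        if accepted:
            current.discard(j_out)
            current.add(j_in)
            current_value = cand_value
            if C_new is not None:
                evaluator.apply(C_new)
            if current_value > best_value:
                best_value = current_value
                best_parcels = tuple(sorted(current))
        trace.append(TraceStep(iteration=it, current_value=current_value,
                               best_value=best_value, temperature=temperature,
                               accepted=accepted))
        temperature *= config.cooling_rate

    return SolveResult(best_reserve=Reserve(parcels=frozenset(best_parcels), m=m),
                       best_value=best_value, initial_value=initial_value,
                       trace=tuple(trace))
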