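import itertools

import numpy as np
import pytest

from firereserve import (Reserve, build_square_landscape,
                         enumerate_spread_patterns, evaluate,
                         independent_model_closed_form, multi_burn_ignitions,
                         optimize_exact, percent_gain, secondary_metrics,
                         size_distribution, species_surviving)
from firereserve.coverage import CoverageError

from conftest import (brute_force_independent_model, make_species,
                      naive_expected_species, naive_outcome_distribution)


class TestSpeciesSurviving:
    def test_survival_via_unburned_parcel(self, grid55, corr55):
        sp = make_species(grid55, {1: [7, 20], 2: [7, 20]})
        pattern = next(p for p in corr55.patterns if p.burned == frozenset({7})
                       or (7 in p.burned and 20 not in p.burned))
        out = species_surviving(Reserve(parcels={7, 20}, m=2), sp, pattern)
        assert out == frozenset({"sp1", "sp2"})

    def test_all_reserve_burned(self, grid55, corr55):
        sp = make_species(grid55, {1: [7], 2: [8]})
        pattern = next(p for p in corr55.patterns if {7, 8} <= p.burned)
        assert species_surviving(Reserve(parcels={7, 8}, m=2), sp, pattern) \
            == frozenset()

    def test_empty_reserve(self, grid55, corr55):
        sp = make_species(grid55, {1: [7], 2: [8]})
        for pattern in corr55.patterns:
            assert species_surviving(Reserve(parcels=set(), m=2), sp, pattern) \
                == frozenset()

    def test_mismatched_parcels_rejected(self, grid55, corr55):
        sp = make_species(grid55, {1: [7]})
        with pytest.raises(CoverageError):
            species_surviving(Reserve(parcels={99}, m=1), sp,
                              corr55.patterns[0])


class TestEvaluateTable1:
    """Two one-species parcels, no hotspots, correlated 5x5 model."""

    @pytest.mark.parametrize("pair,p0,p1,p2", [
        ((7, 8), 6, 6, 37),    # edge-adjacent
        ((7, 9), 3, 12, 34),   # separated by one
        ((7, 20), 0, 18, 31),  # separated by more than one
    ])
    def test_outcome_distribution(self, grid55, corr55, pair, p0, p1, p2):
        sp = make_species(grid55, {1: [pair[0]], 2: [pair[1]]})
        res = evaluate(Reserve(parcels=set(pair), m=2), sp, corr55)
        d = res.outcome_distribution
        assert d.get(0, 0.0) == pytest.approx(p0 / 49, abs=1e-12)
        assert d.get(1, 0.0) == pytest.approx(p1 / 49, abs=1e-12)
        assert d.get(2, 0.0) == pytest.approx(p2 / 49, abs=1e-12)
        assert res.expected_species == pytest.approx(80 / 49, abs=1e-12)

    def test_expected_invariant_across_placements(self, grid55, corr55):
        # each species on exactly one reserve parcel -> 80/49 regardless of
        # the pair's separation
        rng = np.random.default_rng(100)
        for _ in range(100):
            a, b = rng.choice(25, size=2, replace=False) + 1
            sp = make_species(grid55, {1: [int(a)], 2: [int(b)]})
            res = evaluate(Reserve(parcels={int(a), int(b)}, m=2), sp, corr55)
            assert res.expected_species == pytest.approx(80 / 49, abs=1e-12)


class TestEvaluateTable2:
    @pytest.mark.parametrize("pair,expected,p_both,p_zero", [
        ((7, 20), 2.0, 1.0, 0.0),
        ((7, 8), 86 / 49, 43 / 49, 6 / 49),
        ((8, 20), 96 / 49, 48 / 49, 1 / 49),
    ])
    def test_hotspot_reserves(self, grid55, corr55, hotspot_species,
                              pair, expected, p_both, p_zero):
        res = evaluate(Reserve(parcels=set(pair), m=2), hotspot_species, corr55)
        assert res.expected_species == pytest.approx(expected, abs=1e-12)
        assert res.outcome_distribution.get(2, 0.0) == pytest.approx(p_both, abs=1e-12)
        assert res.outcome_distribution.get(0, 0.0) == pytest.approx(p_zero, abs=1e-12)

    def test_printed_decimals(self, grid55, corr55, hotspot_species):
        res = evaluate(Reserve(parcels={7, 8}, m=2), hotspot_species, corr55)
        assert round(res.expected_species, 6) == 1.755102
        res = evaluate(Reserve(parcels={8, 20}, m=2), hotspot_species, corr55)
        assert round(res.expected_species, 6) == 1.959184


class TestLinearity:
    def test_expected_equals_sum_of_survival(self, grid55, corr55, sizes55):
        indep = independent_model_closed_form(25, sizes55)
        rng = np.random.default_rng(2)
        for _ in range(10):
            placements = {i: list(rng.choice(25, size=5, replace=False) + 1)
                          for i in (1, 2, 3)}
            sp = make_species(grid55, placements)
            parcels = {int(p) for p in rng.choice(25, size=3, replace=False) + 1}
            reserve = Reserve(parcels=parcels, m=3)
            for model in (corr55, indep):
                res = evaluate(reserve, sp, model)
                by_dist = sum(k * v for k, v in res.outcome_distribution.items())
                assert res.expected_species == pytest.approx(by_dist, abs=1e-12)
                assert res.expected_species == pytest.approx(
                    sum(res.species_survival), abs=1e-12)


class TestClosedFormOracle:
    """Closed-form independent evaluation vs full enumeration, J <= 9."""

    @pytest.mark.parametrize("rows,cols", [(1, 1), (2, 2), (3, 3), (2, 4), (1, 5)])
    def test_matches_brute_force(self, rows, cols):
        ls = build_square_landscape(rows, cols, 1)
        J = ls.n_focal
        sizes = size_distribution(enumerate_spread_patterns(ls))
        closed = independent_model_closed_form(J, sizes)
        brute = brute_force_independent_model(J, sizes)
        rng = np.random.default_rng(17)
        for _ in range(5):
            n_sp = int(rng.integers(1, 4))
            placements = {
                i + 1: list(rng.choice(J, size=int(rng.integers(1, J + 1)),
                                       replace=False) + 1)
                for i in range(n_sp)}
            sp = make_species(ls, placements)
            r = int(rng.integers(1, min(J, 4) + 1))
            parcels = {int(p) for p in rng.choice(J, size=r, replace=False) + 1}
            reserve = Reserve(parcels=parcels, m=r)
            res = evaluate(reserve, sp, closed)
            assert res.expected_species == pytest.approx(
                naive_expected_species(parcels, sp, brute), abs=1e-12)
            want_dist = naive_outcome_distribution(parcels, sp, brute)
            for k in set(want_dist) | set(res.outcome_distribution):
                assert res.outcome_distribution.get(k, 0.0) == pytest.approx(
                    want_dist.get(k, 0.0), abs=1e-12)


class TestOptimizeExact:
    def test_unique_correlated_optimum(self, grid55, corr55, hotspot_species):
        optima = optimize_exact(grid55, hotspot_species, corr55, 2)
        assert [r.sorted_parcels() for r, _ in optima] == [(7, 20)]
        assert optima[0][1].expected_species == pytest.approx(2.0, abs=1e-12)

    def test_independent_co_optima(self, grid55, sizes55, hotspot_species):
        indep = independent_model_closed_form(25, sizes55)
        optima = optimize_exact(grid55, hotspot_species, indep, 2)
        assert [r.sorted_parcels() for r, _ in optima] \
            == [(7, 8), (7, 20), (8, 20)]
        vals = [res.expected_species for _, res in optima]
        assert max(vals) - min(vals) < 1e-12

    def test_single_species_single_parcel(self, grid55, corr55):
        sp = make_species(grid55, {1: [14]})
        optima = optimize_exact(grid55, sp, corr55, 1)
        assert [r.sorted_parcels() for r, _ in optima] == [(14,)]

    def test_m_exceeds_J(self, grid55, corr55, hotspot_species):
        with pytest.raises(CoverageError):
            optimize_exact(grid55, hotspot_species, corr55, 26)

    def test_candidate_cap(self, grid55, corr55, hotspot_species):
        with pytest.raises(CoverageError, match="annealing"):
            optimize_exact(grid55, hotspot_species, corr55, 2, max_candidates=10)

    def test_matches_naive_search(self, grid55, corr55):
        sp = make_species(grid55, {1: [3, 11, 22], 2: [5, 11, 18]})
        optima = optimize_exact(grid55, sp, corr55, 2)
        best_naive = max(
            naive_expected_species(set(c), sp, corr55)
            for c in itertools.combinations(range(1, 26), 2))
        assert optima[0][1].expected_species == pytest.approx(best_naive, abs=1e-12)


class TestSecondaryMetrics:
    def test_adjacent_no_hotspot(self, grid55, corr55):
        sp = make_species(grid55, {1: [7], 2: [8]})
        p_zero, p_all = secondary_metrics(Reserve(parcels={7, 8}, m=2), sp, corr55)
        assert p_zero == pytest.approx(6 / 49, abs=1e-12)
        assert p_all == pytest.approx(37 / 49, abs=1e-12)

    def test_far_pair_zero_risk(self, grid55, corr55):
        sp = make_species(grid55, {1: [7], 2: [20]})
        p_zero, _ = secondary_metrics(Reserve(parcels={7, 20}, m=2), sp, corr55)
        assert p_zero == 0.0

    def test_reserve_covering_no_species(self, grid55, corr55):
        sp = make_species(grid55, {1: [7], 2: [8]})
        p_zero, p_all = secondary_metrics(Reserve(parcels={24, 25}, m=2), sp, corr55)
        assert p_zero == pytest.approx(1.0, abs=1e-12)
        assert p_all == 0.0


class TestMultiBurnIgnitions:
    def test_adjacent_pair(self, grid55):
        assert multi_burn_ignitions(grid55, Reserve(parcels={7, 8}, m=2)) == 6

    def test_separated_by_one(self, grid55):
        assert multi_burn_ignitions(grid55, Reserve(parcels={7, 9}, m=2)) == 3

    def test_distant_pair(self, grid55):
        assert multi_burn_ignitions(grid55, Reserve(parcels={7, 20}, m=2)) == 0


class TestPercentGain:
    def test_paper_gain(self):
        assert percent_gain(2.0, 86 / 49) == pytest.approx(1200 / 86, abs=1e-12)
        assert round(percent_gain(2.0, 86 / 49)) == 14

    def test_zero_gain(self):
        assert percent_gain(1.5, 1.5) == 0.0

    def test_table2_ratio(self):
        assert percent_gain(96 / 49, 86 / 49) == pytest.approx(11.6279, abs=1e-3)

    def test_rejects_nonpositive_baseline(self):
        with pytest.raises(CoverageError):
            percent_gain(2.0, 0.0)


class TestMonotonicity:
    def test_adding_parcel_never_decreases(self, grid55, corr55, sizes55):
        indep = independent_model_closed_form(25, sizes55)
        rng = np.random.default_rng(33)
        for _ in range(10):
            sp = make_species(grid55, {
                1: list(rng.choice(25, size=5, replace=False) + 1),
                2: list(rng.choice(25, size=5, replace=False) + 1)})
            parcels = [int(p) for p in rng.choice(25, size=4, replace=False) + 1]
            for model in (corr55, indep):
                prev = evaluate(Reserve(parcels=set(), m=4), sp, model)
                for k in range(1, 5):
                    cur = evaluate(Reserve(parcels=set(parcels[:k]), m=4),
                                   sp, model)
                    assert cur.expected_species >= prev.expected_species - 1e-12
                    prev = cur


class TestSymmetry:
    def test_expected_invariant_under_grid_symmetries(self, grid55, corr55):
        def transforms(n):
            return [lambda r, c: (r, c), lambda r, c: (c, n - 1 - r),
                    lambda r, c: (n - 1 - r, n - 1 - c),
                    lambda r, c: (n - 1 - c, r), lambda r, c: (r, n - 1 - c),
                    lambda r, c: (n - 1 - r, c), lambda r, c: (c, r),
                    lambda r, c: (n - 1 - c, n - 1 - r)]

        def remap(pid, f):
            r, c = divmod(pid - 1, 5)
            rr, cc = f(r, c)
            return rr * 5 + cc + 1

        rng = np.random.default_rng(8)
        sp_parcels = {1: list(rng.choice(25, size=5, replace=False) + 1),
                      2: list(rng.choice(25, size=5, replace=False) + 1)}
        reserve = [int(p) for p in rng.choice(25, size=2, replace=False) + 1]
        base = evaluate(Reserve(parcels=set(reserve), m=2),
                        make_species(grid55, sp_parcels), corr55).expected_species
        for f in transforms(5):
            sp_t = {i: [remap(p, f) for p in ps] for i, ps in sp_parcels.items()}
            res_t = [remap(p, f) for p in reserve]
            val = evaluate(Reserve(parcels=set(res_t), m=2),
                           make_species(grid55, sp_t), corr55).expected_species
            assert val == pytest.approx(base, abs=1e-12)
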