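"""Homolog pairing (vs a brute-force matching oracle) and consensus averaging."""

import itertools
import math

import numpy as np
import pytest

from karyokit import (
    ChromosomeMeasurement,
    MetaphaseCell,
    consensus_karyotype,
    pair_homologs,
    rank_pairs,
)
from karyokit.consensus import _cost_matrix


def _cell(lengths, ratios, acc="a", cid="c"):
    ms = [
        ChromosomeMeasurement(cid, f"chr{i}", L / (1 + r), L * r / (1 + r))
        for i, (L, r) in enumerate(zip(lengths, ratios))
    ]
    return MetaphaseCell(acc, cid, 2, len(ms), ms)


def brute_force_min_matching(cost):
    """Exhaustively enumerate all perfect matchings; the independent oracle."""
    n = cost.shape[0]

    def matchings(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for k, partner in enumerate(rest):
            for m in matchings(rest[:k] + rest[k + 1 :]):
                yield [(first, partner)] + m

    best, best_cost = None, math.inf
    for m in matchings(list(range(n))):
        c = sum(cost[i, j] for i, j in m)
        if c < best_cost:
            best, best_cost = m, c
    return best, best_cost


class TestPairHomologs:
    def test_unambiguous_by_size(self):
        cell = _cell([10.0, 5.1, 9.8, 5.0], [1.5] * 4)
        res = pair_homologs(cell)
        assert sorted(res.pairs) == [(0, 2), (1, 3)]
        assert res.method == "exact_matching"

    def test_similar_sizes_grouped_by_ratio(self):
        # a sex-pair-like situation: two pairs of near-equal length whose
        # members are told apart only by centromere position
        cell = _cell([5.0, 5.01, 5.0, 5.01], [2.2, 1.6, 2.2, 1.6])
        res = pair_homologs(cell)
        assert sorted(res.pairs) == [(0, 2), (1, 3)]

    def test_odd_count_rejected(self):
        ms = [ChromosomeMeasurement("c", f"x{i}", 1.0, 2.0) for i in range(3)]
        cell = MetaphaseCell("a", "c", 2, 4, ms + [ChromosomeMeasurement("c", "x3", 1.0, 2.0)])
        cell.measurements = ms  # force an odd complement past construction
        with pytest.raises(ValueError, match="odd"):
            pair_homologs(cell)

    @pytest.mark.parametrize("two_n", [4, 6, 8, 10])
    def test_matches_exhaustive_oracle(self, two_n):
        rng = np.random.default_rng(two_n)
        for _ in range(25):
            lengths = rng.uniform(1.0, 8.0, size=two_n)
            ratios = rng.uniform(1.0, 6.0, size=two_n)
            cell = _cell(lengths, ratios)
            cost = _cost_matrix(cell, (1.0, 1.0))
            res = pair_homologs(cell)
            _, oracle_cost = brute_force_min_matching(cost)
            assert res.cost == pytest.approx(oracle_cost, abs=1e-9)

    def test_greedy_fallback_is_labelled(self):
        cell = _cell([8.0, 8.0, 4.0, 4.0], [1.5] * 4)
        res = pair_homologs(cell, method="greedy")
        assert res.method == "greedy"
        assert sorted(res.pairs) == [(0, 1), (2, 3)]


class TestRankPairs:
    def test_sorted_by_decreasing_mean_length(self):
        cell = _cell([3.0, 3.0, 5.0, 5.0, 4.0, 4.0], [1.0] * 6)
        ranked = rank_pairs(cell, pair_homologs(cell))
        assert [rp.mean_length_um for rp in ranked] == [5.0, 4.0, 3.0]

    def test_length_tie_broken_by_smaller_ratio(self):
        cell = _cell([4.0, 4.0, 4.0, 4.0], [3.0, 3.0, 1.2, 1.2])
        ranked = rank_pairs(cell, pair_homologs(cell))
        assert ranked[0].ratios[0] == pytest.approx(1.2)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        lengths = [5.0, 5.0, 4.0, 4.0, 3.0, 3.0, 2.0, 2.0]
        ratios = [3.0, 3.0, 1.5, 1.5, 2.4, 2.4, 1.1, 1.1]
        cell = _cell(lengths, ratios)
        base = rank_pairs(cell, pair_homologs(cell))
        perm = rng.permutation(len(lengths))
        cell2 = _cell([lengths[i] for i in perm], [ratios[i] for i in perm])
        other = rank_pairs(cell2, pair_homologs(cell2))
        for a, b in zip(base, other):
            assert a.mean_length_um == pytest.approx(b.mean_length_um)
            assert a.ratios == pytest.approx(b.ratios)


class TestConsensus:
    LENGTHS = [5.0, 5.0, 4.0, 4.0, 3.0, 3.0, 2.0, 2.0]
    RATIOS = [3.5, 3.5, 2.4, 2.4, 1.5, 1.5, 1.1, 1.1]

    def _cells(self, scales=(1.0, 1.0, 1.0, 1.0, 1.0)):
        return [
            _cell([s * L for L in self.LENGTHS], self.RATIOS, cid=f"c{i}")
            for i, s in enumerate(scales)
        ]

    def test_idempotent_on_identical_cells(self):
        k = consensus_karyotype(self._cells(), min_cells=1)
        assert str(k.formula) == "1st+1sm+2m"
        assert [p.arm_ratio_a for p in k.pairs] == pytest.approx([3.5, 2.4, 1.5, 1.1])
        assert [p.mean_rel_length_pct for p in k.pairs] == pytest.approx(
            [100 * 5 / 14, 100 * 4 / 14, 100 * 3 / 14, 100 * 2 / 14]
        )

    def test_invariant_to_condensation_and_cell_order(self):
        base = consensus_karyotype(self._cells(), min_cells=1)
        scaled = consensus_karyotype(self._cells((0.8, 1.0, 1.3, 0.9, 1.1))[::-1], min_cells=1)
        for a, b in zip(base.pairs, scaled.pairs):
            assert b.mean_rel_length_pct == pytest.approx(a.mean_rel_length_pct)
            assert b.arm_ratio_a == pytest.approx(a.arm_ratio_a)
        assert str(base.stebbins) == str(scaled.stebbins)
        assert scaled.size_ratio == pytest.approx(base.size_ratio)

    def test_rank_mean_relative_lengths_non_increasing(self):
        rng = np.random.default_rng(11)
        cells = [
            _cell(
                np.repeat(np.linspace(6, 2, 8), 2) * rng.lognormal(0, 0.02, 16),
                np.full(16, 2.5),
                cid=f"c{i}",
            )
            for i in range(5)
        ]
        k = consensus_karyotype(cells, min_cells=1)
        rels = [p.mean_rel_length_pct for p in k.pairs]
        assert all(a >= b for a, b in zip(rels, rels[1:]))

    def test_warns_below_five_cells(self):
        with pytest.warns(UserWarning, match=">= 5"):
            consensus_karyotype(self._cells()[:2])

    def test_mixed_two_n_rejected(self):
        cells = self._cells()[:1] + [_cell([5.0, 5.0, 4.0, 4.0], [1.5] * 4, cid="c9")]
        with pytest.raises(ValueError, match="mixed 2n"):
            consensus_karyotype(cells, min_cells=1)

    def test_mixed_accession_rejected(self):
        cells = self._cells()[:1] + [
            _cell(self.LENGTHS, self.RATIOS, acc="other", cid="c9")
        ]
        with pytest.raises(ValueError, match="mixed accessions"):
            consensus_karyotype(cells, min_cells=1)

    def test_satellite_aggregation(self):
        cells = self._cells()[:2]
        # rank-1 pair: one homolog satellited in cell 0; both in cell 1
        for cell in cells:
            order = sorted(
                range(8), key=lambda i: -cell.measurements[i].total_um
            )
            cell.measurements[order[0]].satellite = True
        order1 = sorted(range(8), key=lambda i: -cells[1].measurements[i].total_um)
        cells[1].measurements[order1[1]].satellite = True
        k = consensus_karyotype(cells, min_cells=1)
        assert k.pairs[0].satellite_seen == "both"
        assert all(p.satellite_seen == "none" for p in k.pairs[1:])
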