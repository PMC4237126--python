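"""Grids, per-cell diversity/endemism estimators, GST/NST."""

import math

import numpy as np
import pandas as pd
import pytest

from phylogrid import gridstats as gs
from phylogrid import network as nw
from phylogrid.seqio import HaplotypeSet, InsufficientDataError, SampleTable


def make_assignment(cell_members, coords=None, cell_size=1.0):
    """Build a SampleTable + GridAssignment placing each cell's samples
    inside a distinct grid cell (or at explicit coords)."""
    rows = []
    for k, (cell_idx, members) in enumerate(sorted(cell_members.items())):
        for j, sid in enumerate(members):
            if coords and sid in coords:
                lat, lon = coords[sid]
            else:
                lat = cell_idx + 0.3 + 0.01 * j
                lon = cell_idx * 2 + 0.5
            rows.append((sid, "sp", lat, lon))
    table = SampleTable.from_records(rows)
    assign = gs.assign_cells(table, gs.GridSpec(cell_size))
    return table, assign


def hapset_from_assignment(sample_to_hap, vectors):
    carriers = {}
    for s, h in sample_to_hap.items():
        carriers.setdefault(h, []).append(s)
    return HaplotypeSet.from_vectors(
        {h: vectors[h] for h in vectors if h in carriers}, carriers=carriers
    )


class TestGreatCircle:
    def test_zero(self):
        assert gs.great_circle_km((0, 0), (0, 0)) == 0.0

    def test_one_degree_meridian(self):
        assert gs.great_circle_km((0, 0), (1, 0)) == pytest.approx(
            math.pi * 6371 / 180, abs=1e-3
        )

    def test_quarter_great_circle(self):
        assert gs.great_circle_km((0, 0), (0, 90)) == pytest.approx(
            math.pi * 6371 / 2, abs=1e-2
        )


class TestAssignCells:
    def test_floor_rule(self):
        t = SampleTable.from_records([("s1", "sp", 0.74, 0.01)])
        a = gs.assign_cells(t, gs.GridSpec(0.75))
        assert a.cell_of_sample["s1"] == "0_0"

    def test_half_open_edge(self):
        t = SampleTable.from_records([("s1", "sp", 0.75, 0.0)])
        a = gs.assign_cells(t, gs.GridSpec(0.75))
        assert a.cell_of_sample["s1"] == "0_1"

    def test_retention_threshold(self):
        t = SampleTable.from_records(
            [("a", "sp", 0.1, 0.1), ("b", "sp", 0.2, 0.2)]
            + [(f"c{i}", "sp", 5.1, 5.1 + i * 0.01) for i in range(3)]
        )
        a = gs.assign_cells(t, gs.GridSpec(1.0))
        assert not a.is_retained("0_0")
        assert a.is_retained("5_5")
        assert a.retained == ("5_5",)

    def test_centroid_is_coordinate_mean(self):
        t = SampleTable.from_records(
            [("a", "sp", 0.0, 0.0), ("b", "sp", 0.5, 0.4), ("c", "sp", 0.1, 0.2)]
        )
        a = gs.assign_cells(t, gs.GridSpec(1.0))
        assert a.centroids["0_0"] == pytest.approx((0.2, 0.2))


class TestCellEstimators:
    def test_monomorphic_cell(self):
        assert gs.gene_diversity([3]) == 0.0
        assert gs.nielsen_effective_haplotypes([3]) == pytest.approx(1.0)
        assert gs.ordered_gene_diversity([3], np.zeros((1, 1))) == 0.0

    def test_he_hand_example(self):
        # counts {A:2, B:1}: He = (3/2)(1 - 5/9) = 0.6667
        assert gs.gene_diversity([2, 1]) == pytest.approx(2 / 3)

    def test_v_and_nae_hand_example(self):
        # counts {A:2, B:2}, pi_AB = 3: v = (4/3)(2*0.25*3) = 2.0
        pi = np.array([[0, 3], [3, 0]], dtype=float)
        assert gs.ordered_gene_diversity([2, 2], pi) == pytest.approx(2.0)
        # NAe = 9 / (0.5*5*2 + 3 - 4) = 2.25
        assert gs.nielsen_effective_haplotypes([2, 2]) == pytest.approx(2.25)

    def test_nae_limits(self):
        # large n, even frequencies -> 1 / sum(p^2)
        assert gs.nielsen_effective_haplotypes([5000, 5000]) == pytest.approx(
            2.0, rel=1e-3
        )

    def test_invariance_under_haplotype_relabeling(self, rng):
        counts = [5, 3, 2]
        pi = np.array([[0, 1, 4], [1, 0, 3], [4, 3, 0]], dtype=float)
        perm = [2, 0, 1]
        cp = [counts[i] for i in perm]
        pp = pi[np.ix_(perm, perm)]
        assert gs.gene_diversity(cp) == pytest.approx(gs.gene_diversity(counts))
        assert gs.ordered_gene_diversity(cp, pp) == pytest.approx(
            gs.ordered_gene_diversity(counts, pi)
        )

    def test_v_scales_linearly_with_distances(self):
        counts = [4, 2, 3]
        pi = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        assert gs.ordered_gene_diversity(counts, 7 * pi) == pytest.approx(
            7 * gs.ordered_gene_diversity(counts, pi)
        )


class TestCellEndemism:
    def _setup(self):
        vectors = {"H1": (0, 0), "H2": (0, 1), "H3": (1, 1)}
        # H1 spans two distant cells (wide range); H2 local; H3 singleton
        sample_to_hap = {
            "a1": "H1", "a2": "H1", "a3": "H2", "a4": "H2", "a5": "H3",
            "b1": "H1", "b2": "H1", "b3": "H1",
        }
        cell_members = {0: ["a1", "a2", "a3", "a4", "a5"], 5: ["b1", "b2", "b3"]}
        table, assign = make_assignment(cell_members)
        haps = hapset_from_assignment(sample_to_hap, vectors)
        return table, assign, haps

    def test_endemism_fractions(self):
        table, assign, haps = self._setup()
        end, ranges = gs.cell_endemism(assign, haps, table, threshold_km=200)
        # H1 spans ~1000 km -> not endemic; H2 and H3 are local
        assert ranges["H1"] > 200
        assert ranges["H3"] == 0.0
        cells = sorted(end.index)
        assert end[cells[0]] == pytest.approx(3 / 5)
        assert end[cells[1]] == 0.0

    def test_range_is_dataset_wide(self):
        # carriers 300+ km apart but all within one cell's statistics:
        # the haplotype is still not endemic anywhere
        vectors = {"H1": (0,), "H2": (1,)}
        rows = [
            ("a1", "sp", 0.1, 0.1), ("a2", "sp", 0.2, 0.1), ("a3", "sp", 0.3, 0.1),
            ("b1", "sp", 5.1, 0.1), ("b2", "sp", 6.6, 0.1), ("b3", "sp", 8.3, 0.1),
        ]
        table = SampleTable.from_records(rows)
        assign = gs.assign_cells(table, gs.GridSpec(10.0))  # one big cell
        haps = hapset_from_assignment(
            {"a1": "H1", "a2": "H1", "a3": "H1", "b1": "H2", "b2": "H2", "b3": "H2"},
            vectors,
        )
        end, ranges = gs.cell_endemism(assign, haps, table, threshold_km=200)
        assert ranges["H1"] < 200 and end.iloc[0] == pytest.approx(0.5)


class TestDifferentiation:
    def _hapset(self, cell_members, sample_to_hap, vectors):
        table, assign = make_assignment(cell_members)
        haps = hapset_from_assignment(sample_to_hap, vectors)
        D = nw.mutation_distance_matrix(haps)
        return table, assign, haps, D

    def test_fixed_cells_gst_one(self):
        s2h = {f"a{i}": "H1" for i in range(4)} | {f"b{i}": "H2" for i in range(4)}
        _, assign, haps, D = self._hapset(
            {0: [f"a{i}" for i in range(4)], 3: [f"b{i}" for i in range(4)]},
            s2h, {"H1": (0, 0), "H2": (1, 1)},
        )
        res = gs.global_differentiation(assign, haps, D, n_perm=49, seed=0)
        assert res.h_s == pytest.approx(0.0)
        assert res.gst == pytest.approx(1.0)

    def test_equal_distances_make_nst_equal_gst(self):
        vectors = {"H1": ("A",), "H2": ("C",), "H3": ("G",)}
        s2h = {
            "a1": "H1", "a2": "H1", "a3": "H2", "a4": "H3",
            "b1": "H2", "b2": "H2", "b3": "H3", "b4": "H1",
        }
        _, assign, haps, D = self._hapset(
            {0: [f"a{i}" for i in range(1, 5)], 3: [f"b{i}" for i in range(1, 5)]},
            s2h, vectors,
        )
        assert np.all(D.matrix[~np.eye(3, dtype=bool)] == 1)
        res = gs.global_differentiation(assign, haps, D, n_perm=99, seed=0)
        assert res.nst == pytest.approx(res.gst, abs=1e-12)
        assert res.p_nst_gt_gst == 1.0

    def test_monomorphic_error(self):
        s2h = {f"a{i}": "H1" for i in range(3)} | {f"b{i}": "H1" for i in range(3)}
        table, assign = make_assignment(
            {0: [f"a{i}" for i in range(3)], 3: [f"b{i}" for i in range(3)]}
        )
        haps = hapset_from_assignment(s2h, {"H1": (0,)})
        D = nw.mutation_distance_matrix(haps)
        with pytest.raises(gs.MonomorphicError):
            gs.global_differentiation(assign, haps, D, n_perm=9, seed=0)

    def test_gst_unbiased_for_identical_cells(self):
        """Cells drawn i.i.d. from one frequency vector: GST has mean ~ 0."""
        rng = np.random.default_rng(2024)
        freqs = np.array([0.5, 0.3, 0.2])
        pi = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        vals = []
        for _ in range(500):
            C = rng.multinomial(8, freqs, size=4).astype(float)
            while (C.sum(axis=0) > 0).sum() < 2:
                C = rng.multinomial(8, freqs, size=4).astype(float)
            nk = C.sum(axis=1)
            comp = gs.pons_petit_components(C / nk[:, None], nk, pi)
            vals.append((comp["hT"] - comp["hS"]) / comp["hT"])
        assert abs(np.mean(vals)) < 0.02


class TestDifferentiationOracle:
    def test_matches_brute_force_estimators(self):
        """Vectorised estimators agree with loop-based transcriptions of the
        published formulas to 1e-12 on random instances."""
        from phylogrid.experiments import _brute_gst_nst, _brute_he, _brute_v

        rng = np.random.default_rng(7)
        for _ in range(25):
            n_haps = int(rng.integers(2, 6))
            pi = np.zeros((n_haps, n_haps))
            iu = np.triu_indices(n_haps, 1)
            v = rng.integers(1, 6, size=len(iu[0]))
            pi[iu] = v
            pi.T[iu] = v
            cells = [
                [int(h) for h in rng.integers(0, n_haps, size=rng.integers(3, 13))]
                for _ in range(int(rng.integers(2, 6)))
            ]
            while len({h for c in cells for h in c}) < 2:
                cells[0][0] = (cells[0][0] + 1) % n_haps
            P = np.stack([np.bincount(c, minlength=n_haps) / len(c) for c in cells])
            nk = np.array([len(c) for c in cells], dtype=float)
            comp = gs.pons_petit_components(P, nk, pi)
            gst = (comp["hT"] - comp["hS"]) / comp["hT"]
            nst = (comp["vT"] - comp["vS"]) / comp["vT"]
            bg, bn = _brute_gst_nst(cells, n_haps, pi)
            assert gst == pytest.approx(bg, abs=1e-12)
            assert nst == pytest.approx(bn, abs=1e-12)
            for c in cells:
                counts = np.bincount(c, minlength=n_haps)
                assert gs.gene_diversity(counts[counts > 0]) == pytest.approx(
                    _brute_he(c), abs=1e-12
                )
                assert gs.ordered_gene_diversity(counts, pi) == pytest.approx(
                    _brute_v(c, pi), abs=1e-12
                )


class TestEstimatorProperties:
    """Hypothesis-driven invariants of the per-cell estimators."""

    from hypothesis import given, settings, strategies as st

    counts_st = st.lists(st.integers(1, 12), min_size=1, max_size=5).filter(
        lambda c: sum(c) >= 3
    )

    @given(counts=counts_st)
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_bounds_and_relabeling(self, counts):
        he = gs.gene_diversity(counts)
        nae = gs.nielsen_effective_haplotypes(counts)
        assert 0.0 <= he <= 1.0 + 1e-12
        assert nae >= 1.0 - 1e-9
        # invariance under haplotype relabeling
        rev = list(reversed(counts))
        assert gs.gene_diversity(rev) == pytest.approx(he, abs=1e-12)
        assert gs.nielsen_effective_haplotypes(rev) == pytest.approx(
            nae, abs=1e-9
        )

    @given(counts=counts_st, seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_ordered_diversity_nonnegative_and_scales(self, counts, seed):
        rng = np.random.default_rng(seed)
        k = len(counts)
        pi = np.zeros((k, k))
        iu = np.triu_indices(k, 1)
        pi[iu] = rng.integers(1, 9, size=len(iu[0]))
        pi.T[iu] = pi[iu]
        v = gs.ordered_gene_diversity(counts, pi)
        assert v >= 0.0
        assert gs.ordered_gene_diversity(counts, 3 * pi) == pytest.approx(3 * v)
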