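"""Count preprocessing, time-0 construction and leakage-safe splits."""

import numpy as np
import pandas as pd
import pytest

from lazynet.core_model import ExpressionState, ValidationError
from lazynet.perturb_data import (
    CountMatrix,
    ExpressionMatrix,
    GuideTable,
    PerturbationSpec,
    SnapshotPair,
    build_snapshot_pairs,
    build_time0,
    control_baseline,
    group_split,
    guide_split,
    load_pairs,
    normalize_counts,
    qc_filter,
    save_pairs,
    select_hvg,
)


def make_matrix(counts, genes=None, barcodes=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    barcodes = barcodes or [f"bc{i}" for i in range(counts.shape[1])]
    return CountMatrix(counts, genes, barcodes)


def make_guides(rows):
    return GuideTable(
        pd.DataFrame(
            rows, columns=["barcode", "n_guides", "target_gene", "modality"]
        )
    )


class TestNormalize:
    def test_pseudocount_arithmetic(self):
        # cell (2, 2) scaled to library 4 then log(x + 1)
        m = make_matrix([[2.0], [2.0]])
        out = normalize_counts(m, pseudocount=1.0, target_library=4.0)
        assert np.allclose(out.values[:, 0], np.log(3.0))

    def test_all_zero_gene_becomes_constant_floor_row(self):
        m = make_matrix([[0, 0], [3, 5]])
        out = normalize_counts(m, pseudocount=1.0)
        assert np.allclose(out.values[0], np.log(1.0))

    def test_zero_total_cell_dropped_with_warning(self):
        m = make_matrix([[1, 0], [1, 0]])
        with pytest.warns(UserWarning, match="zero-total"):
            out = normalize_counts(m)
        assert out.values.shape[1] == 1

    def test_library_size_conservation(self, rng):
        counts = rng.poisson(5, size=(30, 40))
        counts[:, 0] += 1  # no zero-total cells
        out = normalize_counts(make_matrix(counts), pseudocount=1.0)
        scaled = np.exp(out.values) - 1.0
        assert np.allclose(scaled.sum(axis=0), out.target_library, atol=1e-9)


class TestQCFilter:
    def test_gene_detected_in_two_cells_removed(self):
        counts = np.zeros((2, 4), dtype=int)
        counts[0, :2] = 1  # detected in 2 cells only
        counts[1, :] = 1
        out = qc_filter(make_matrix(counts), 3, 1)
        assert out.gene_ids == ["g1"]

    def test_cell_boundary_is_inclusive(self):
        counts = np.ones((200, 2), dtype=int)
        counts[100:, 1] = 0  # cell 1 detects exactly 100 genes
        out = qc_filter(make_matrix(counts), 1, 200)
        assert out.barcodes == ["bc0"]

    def test_hand_enumerated_5x5(self):
        counts = np.array(
            [
                [1, 1, 1, 0, 0],  # detected in 3 -> keep
                [1, 0, 0, 0, 0],  # detected in 1 -> drop
                [1, 1, 0, 1, 1],  # keep
                [0, 1, 1, 1, 0],  # keep
                [1, 1, 1, 1, 1],  # keep
            ]
        )
        out = qc_filter(make_matrix(counts), 3, 3)
        assert out.gene_ids == ["g0", "g2", "g3", "g4"]
        # after the gene pass, cells detect (3,4,3,3,2) of 4 genes
        assert out.barcodes == ["bc0", "bc1", "bc2", "bc3"]

    def test_empty_result_raises(self):
        with pytest.raises(ValidationError):
            qc_filter(make_matrix(np.zeros((2, 2), dtype=int)))


class TestHVG:
    def test_constant_matrix_breaks_ties_lexicographically(self):
        vals = np.ones((4, 5))
        mat = ExpressionMatrix(vals, ["d", "b", "a", "c"], [f"c{i}" for i in range(5)])
        assert select_hvg(mat, 0.5) == ["a", "b"]

    def test_dominant_gene_always_selected(self, rng):
        vals = rng.normal(0, 1, (10, 50))
        vals[3] *= 10
        mat = ExpressionMatrix(vals, [f"g{i}" for i in range(10)], [f"c{i}" for i in range(50)])
        for frac in (0.1, 0.3, 0.8):
            assert "g3" in select_hvg(mat, frac)

    def test_matches_brute_force_sort(self, rng):
        vals = rng.normal(0, 1, (100, 30))
        genes = [f"g{i:03d}" for i in range(100)]
        mat = ExpressionMatrix(vals, genes, [f"c{i}" for i in range(30)])
        panel = select_hvg(mat, 0.25)
        disp = vals.var(axis=1)
        expected = [
            genes[i]
            for i in sorted(range(100), key=lambda i: (-disp[i], genes[i]))[:25]
        ]
        assert panel == expected


class TestBuildTime0:
    def controls(self, values, genes):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(
            values, genes, [f"c{i}" for i in range(values.shape[1])]
        )

    def test_knockout_floors_single_coordinate(self):
        ctrl = self.controls([[5, 5], [5, 5], [5, 5]], ["a", "b", "c"])
        spec = PerturbationSpec("b", "floor", 1e-3)
        out = build_time0(ctrl, spec)
        assert np.allclose(out.values, [5.0, 1e-3, 5.0])

    def test_activation_uses_observed_post_mean(self):
        ctrl = self.controls([[5, 5], [5, 5], [5, 5]], ["a", "b", "c"])
        post = self.controls([[9, 9], [1, 1], [2, 2]], ["a", "b", "c"])
        out = build_time0(ctrl, PerturbationSpec("a", "observed_post"), post)
        assert np.allclose(out.values, [9.0, 5.0, 5.0])

    def test_non_target_coordinates_bit_identical(self, rng):
        vals = rng.lognormal(1, 0.5, (10, 20))
        genes = [f"g{i}" for i in range(10)]
        ctrl = self.controls(vals, genes)
        baseline = vals.mean(axis=1)
        out = build_time0(ctrl, PerturbationSpec("g4", "floor", 0.5))
        keep = np.arange(10) != 4
        assert np.array_equal(out.values[keep], np.maximum(baseline, 1e-8)[keep])

    def test_missing_target_raises(self):
        ctrl = self.controls([[1.0]], ["a"])
        with pytest.raises(ValidationError):
            build_time0(ctrl, PerturbationSpec("zzz", "floor"))

    def test_empty_stratum_falls_back_with_warning(self):
        vals = np.array([[1.0, 3.0]])
        ctrl = ExpressionMatrix(vals, ["a"], ["c0", "c1"], batch=np.array(["x", "x"]))
        with pytest.warns(UserWarning, match="stratum"):
            out = build_time0(
                ctrl, PerturbationSpec("a", "floor", 0.5), stratum="y"
            )
        assert out.values[0] == 0.5


def make_pairs(n_groups, per_group=2):
    genes = ("a", "b")
    pairs = []
    for g in range(n_groups):
        for c in range(per_group):
            s = ExpressionState([1.0 + g, 2.0], genes)
            pairs.append(SnapshotPair(s, s, (f"t{g}", "g1", "")))
    return pairs


class TestGroupSplit:
    def test_ten_groups_split_8_1_1(self):
        tr, va, te = group_split(make_pairs(10), seed=0)
        key = lambda ps: {p.group_key for p in ps}  # noqa: E731
        assert (len(key(tr)), len(key(va)), len(key(te))) == (8, 1, 1)

    def test_deterministic_per_seed(self):
        pairs = make_pairs(7)
        a = group_split(pairs, seed=3)
        b = group_split(pairs, seed=3)
        assert all(
            [p.group_key for p in x] == [p.group_key for p in y]
            for x, y in zip(a, b)
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_no_group_straddles_partitions(self, seed):
        pairs = make_pairs(11, per_group=3)
        parts = group_split(pairs, seed=seed)
        groups = [{p.group_key for p in part} for part in parts]
        assert groups[0] | groups[1] | groups[2] == {p.group_key for p in pairs}
        assert not (groups[0] & groups[1] or groups[0] & groups[2] or groups[1] & groups[2])
        assert sum(len(part) for part in parts) == len(pairs)

    def test_fewer_than_three_groups_raises(self):
        with pytest.raises(ValidationError):
            group_split(make_pairs(2))


class TestGuideSplit:
    def test_hand_enumerated_partition(self):
        m = make_matrix(np.ones((2, 6), dtype=int), barcodes=list("ABCDEF"))
        guides = make_guides(
            [
                ("A", 0, None, None),
                ("B", 1, "g0", "CRISPRi"),
                ("C", 2, "g1", "CRISPRa"),
                ("D", 1, "g1", "CRISPRa"),
                ("E", 3, "g0", "KO"),
            ]
        )
        with pytest.warns(UserWarning, match="missing from guide table"):
            baseline, singlet, multiplet = guide_split(m, guides)
        assert baseline == ["A", "F"]  # F unknown -> baseline
        assert singlet == ["B", "D"]
        assert multiplet == ["C", "E"]

    def test_partition_property(self, small_screen):
        _, matrix, guides, _ = small_screen
        baseline, singlet, multiplet = guide_split(matrix, guides)
        all_bc = set(baseline) | set(singlet) | set(multiplet)
        assert all_bc == set(matrix.barcodes)
        assert not (set(baseline) & set(singlet))
        assert not (set(singlet) & set(multiplet))


class TestSnapshotPairs:
    def test_pairs_cover_singlets_and_respect_working_scale(self, small_screen):
        _, matrix, guides, truth = small_screen
        norm = normalize_counts(matrix)
        _, singlets, _ = guide_split(matrix, guides)
        pairs = build_snapshot_pairs(norm, guides, cells=singlets)
        assert len(pairs) == len(singlets)
        # linear working scale: values >= pseudocount floor region, positive
        assert all((p.time0.values > 0).all() for p in pairs[:10])

    def test_ko_pairs_edit_exactly_target(self, small_screen):
        _, matrix, guides, truth = small_screen
        norm = normalize_counts(matrix)
        _, singlets, _ = guide_split(matrix, guides)
        pairs = build_snapshot_pairs(norm, guides, cells=singlets)
        base = control_baseline(norm, guides)
        ko_targets = [g for g, m in truth["modality"].items() if m == "interference"]
        pair = next(p for p in pairs if p.group_key[0] == ko_targets[0])
        gi = pair.time0.gene_ids.index(ko_targets[0])
        keep = np.arange(len(base.values)) != gi
        assert np.array_equal(pair.time0.values[keep], base.values[keep])
        assert pair.time0.values[gi] == pytest.approx(1.0)  # pseudocount floor

    def test_round_trip_h5(self, small_screen, tmp_path):
        _, matrix, guides, _ = small_screen
        norm = normalize_counts(matrix)
        _, singlets, _ = guide_split(matrix, guides)
        pairs = build_snapshot_pairs(norm, guides, cells=singlets)[:20]
        base = control_baseline(norm, guides)
        path = tmp_path / "pairs.h5"
        save_pairs(pairs, path, baseline=base)
        loaded, loaded_base = load_pairs(path, with_baseline=True)
        assert len(loaded) == 20
        assert np.array_equal(loaded[3].time0.values, pairs[3].time0.values)
        assert loaded[3].group_key == pairs[3].group_key
        assert np.array_equal(loaded_base.values, base.values)
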