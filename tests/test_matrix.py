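import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcctools.core import BinGrid
from mcctools.junctions import JunctionTable, LigationJunction
from mcctools.matrix import (ContactMatrix, bin_junctions, density_points,
                             differential_matrix, downsample, ice_balance)

from conftest import random_region


def jx(read_id, pos1, pos2, chrom="chrT"):
    return LigationJunction(read_id, chrom, pos1, "+", chrom, pos2, "+",
                            pos1 - 50, pos2 + 50)


@pytest.fixture()
def grid():
    return BinGrid(random_region(40, length=5000), 500)


def random_matrix(seed, n, grid_region_len=None):
    rng = np.random.default_rng(seed)
    m = rng.uniform(0.5, 10.0, size=(n, n))
    m = (m + m.T) / 2
    region = random_region(seed + 100, length=n * 100)
    return ContactMatrix(BinGrid(region, 100), m)


class TestBinning:
    def test_single_offdiagonal_junction_counted_twice(self, grid):
        table = JunctionTable([jx("a", 100, 2600)])
        mat, stats = bin_junctions(table, grid)
        assert mat.counts.sum() == 2
        assert mat.counts[0, 5] == 1 and mat.counts[5, 0] == 1
        assert stats["binned"] == 1

    def test_same_bin_junction_hits_diagonal_once(self, grid):
        table = JunctionTable([jx("a", 100, 400)])
        mat, _ = bin_junctions(table, grid)
        assert mat.counts[0, 0] == 1
        assert mat.counts.sum() == 1

    def test_three_distinct_pairs_sum_six(self, grid):
        table = JunctionTable([jx("a", 100, 600), jx("b", 1100, 1600),
                               jx("c", 2100, 4600)])
        mat, _ = bin_junctions(table, grid)
        assert mat.counts.sum() == 6

    def test_outside_region_junctions_skipped_and_logged(self, grid):
        table = JunctionTable([jx("a", 100, 600), jx("b", 100, 9999)])
        mat, stats = bin_junctions(table, grid)
        assert stats["outside_region"] == 1
        assert mat.counts.sum() == 2

    @given(seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_mass_conservation(self, seed):
        rng = np.random.default_rng(seed)
        region = random_region(41, length=5000)
        grid = BinGrid(region, 500)
        pts = rng.integers(0, 5000, size=(30, 2))
        table = JunctionTable(
            [jx(f"r{i}", int(a), int(b)) for i, (a, b) in enumerate(pts)]
        )
        mat, _ = bin_junctions(table, grid)
        diag = sum((a // 500) == (b // 500) for a, b in pts)
        assert mat.counts.sum() == 2 * (30 - diag) + diag


class TestIce:
    def test_already_balanced_matrix_unchanged_up_to_scale(self):
        m = ContactMatrix(BinGrid(random_region(42, 200), 100),
                          np.array([[0.0, 4.0], [4.0, 0.0]]))
        out = ice_balance(m)
        assert np.allclose(out.balanced, m.counts)
        assert np.allclose(out.balanced.sum(axis=1), 4.0)

    def test_zero_row_masked_and_rest_balanced(self):
        counts = np.array([[2.0, 3.0, 0.0], [3.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
        out = ice_balance(ContactMatrix(BinGrid(random_region(43, 300), 100),
                                        counts))
        assert out.mask.tolist() == [False, False, True]
        sums = out.balanced.sum(axis=1)
        assert sums[2] == 0.0
        assert abs(sums[0] - sums[1]) / sums[0] < 1e-4

    @pytest.mark.parametrize("n", [10, 60, 200])
    def test_row_sums_equalized_on_random_matrices(self, n):
        out = ice_balance(random_matrix(n, n))
        sums = out.balanced.sum(axis=1)[~out.mask]
        assert (sums.max() - sums.min()) / sums.mean() < 1e-4

    def test_idempotent(self):
        out = ice_balance(random_matrix(5, 30))
        again = ice_balance(ContactMatrix(out.grid, out.balanced))
        assert np.abs(again.balanced - out.balanced).max() < 1e-3

    def test_mass_preserved(self):
        mat = random_matrix(6, 25)
        out = ice_balance(mat)
        assert out.balanced.sum() == pytest.approx(mat.counts.sum(), rel=1e-6)

    def test_all_zero_matrix_rejected(self):
        m = ContactMatrix(BinGrid(random_region(44, 300), 100), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            ice_balance(m)

    def test_log_display_uses_positive_pseudocount(self):
        mat = random_matrix(7, 10)
        mat.scale = "log"
        out = ice_balance(mat)
        out.scale = "log"
        disp = out.display_matrix()
        assert np.isfinite(disp).all()


class TestDownsample:
    def _tables(self, sizes):
        return {
            f"c{i}": JunctionTable(
                [jx(f"r{i}_{k}", 100 + 3 * k, 1000 + 3 * k) for k in range(n)]
            )
            for i, n in enumerate(sizes)
        }

    def test_all_tables_reduced_to_minimum(self):
        out = downsample(self._tables([100, 80]), seed=0)
        assert {len(t) for t in out.values()} == {80}

    def test_equal_sizes_left_untouched(self):
        tables = self._tables([50, 50])
        out = downsample(tables, seed=0)
        assert [j.read_id for j in out["c0"].junctions] == \
               [j.read_id for j in tables["c0"].junctions]

    def test_deterministic_for_fixed_seed(self):
        a = downsample(self._tables([100, 80]), seed=42)
        b = downsample(self._tables([100, 80]), seed=42)
        assert [j.read_id for j in a["c0"].junctions] == \
               [j.read_id for j in b["c0"].junctions]

    def test_sampling_without_replacement(self):
        out = downsample(self._tables([100, 30]), seed=1)
        ids = [j.read_id for j in out["c0"].junctions]
        assert len(ids) == len(set(ids)) == 30

    def test_empty_table_names_condition(self):
        tables = self._tables([10, 0])
        with pytest.raises(ValueError, match="c1"):
            downsample(tables, seed=0)

    def test_single_table_rejected(self):
        with pytest.raises(ValueError):
            downsample(self._tables([10]), seed=0)


class TestDifferential:
    def test_self_difference_is_zero(self):
        a = ice_balance(random_matrix(8, 20))
        d = differential_matrix(a, a)
        assert np.abs(d.balanced[~d.mask][:, ~d.mask]).max() == 0.0

    def test_masks_are_unioned(self):
        counts = random_matrix(9, 6).counts.copy()
        counts_b = counts.copy()
        counts_b[3, :] = 0.0
        counts_b[:, 3] = 0.0
        grid = BinGrid(random_region(45, 600), 100)
        a = ice_balance(ContactMatrix(grid, counts))
        b = ice_balance(ContactMatrix(grid, counts_b))
        d = differential_matrix(a, b)
        assert d.mask[3]
        assert np.all(d.balanced[3, :] == 0.0)

    def test_extra_contact_in_a_shows_positive(self):
        grid = BinGrid(random_region(46, 3000), 500)
        rng = np.random.default_rng(0)
        pts = rng.integers(0, 3000, size=(150, 2))
        base = [jx(f"r{k}", int(a), int(b)) for k, (a, b) in enumerate(pts)]
        loop = [jx(f"l{k}", 620 + (k % 3), 1830 + (k % 3)) for k in range(40)]
        a = ice_balance(bin_junctions(JunctionTable(base + loop), grid)[0])
        b = ice_balance(bin_junctions(JunctionTable(base), grid)[0])
        d = differential_matrix(a, b).balanced
        off = d.copy()
        np.fill_diagonal(off, -np.inf)
        assert np.unravel_index(np.argmax(off), off.shape) in {(1, 3), (3, 1)}

    def test_grid_mismatch_rejected(self):
        a = ice_balance(random_matrix(10, 10))
        b = ice_balance(random_matrix(11, 12))
        with pytest.raises(ValueError):
            differential_matrix(a, b)

    def test_unbalanced_inputs_rejected(self):
        a = random_matrix(12, 10)
        with pytest.raises(ValueError):
            differential_matrix(a, a)


class TestDensity:
    def test_single_point_density_is_kernel_self_weight(self):
        (p1,) = density_points(JunctionTable([jx("a", 1000, 2000)]))
        (p2,) = density_points(JunctionTable([jx("b", 5500, 9000)]))
        assert p1[2] == pytest.approx(p2[2])

    def test_two_identical_points_double_a_lone_density(self):
        lone = density_points(JunctionTable([jx("a", 1000, 2000)]))[0][2]
        both = density_points(
            JunctionTable([jx("a", 1000, 2000), jx("b", 1000, 2000)])
        )
        assert all(p[2] == pytest.approx(2 * lone) for p in both)

    def test_sorted_ascending_by_density(self):
        table = JunctionTable(
            [jx(f"r{k}", 1000 + (k % 2), 2000) for k in range(6)]
            + [jx("far", 9000, 12000)]
        )
        pts = density_points(table)
        dens = [p[2] for p in pts]
        assert dens == sorted(dens)
        assert pts[0][0] == 9000

    def test_empty_table_gives_empty_list(self):
        assert density_points(JunctionTable([])) == []
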