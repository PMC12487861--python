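"""Nearest-target distances, Near/Far strata and rank-sum comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from spatialniche.errors import EmptySubsetError, NoTargetCellsError
from spatialniche.gating import GatingResult
from spatialniche.proximity import (
    ProximityParams,
    compare_subsets,
    nearest_target_distance,
    pairwise_tests,
    proximity_table,
    rank_sum_test,
    stratify,
    subset_proportions,
)

from _oracles import brute_nearest
from conftest import make_dataset


def simple_dataset(points, fov=1):
    return make_dataset([(cid, fov, x, y, None) for cid, x, y in points])


class TestNearestDistance:
    def test_three_four_five(self):
        ds = simple_dataset([("1_q", 0, 0), ("1_t1", 3, 4), ("1_t2", 10, 0)])
        d = nearest_target_distance(ds, ["1_q"], ["1_t1", "1_t2"])
        assert d["1_q"] == pytest.approx(5.0)

    def test_coincident_target(self):
        ds = simple_dataset([("1_q", 2, 2), ("1_t", 2, 2)])
        d = nearest_target_distance(ds, ["1_q"], ["1_t"])
        assert d["1_q"] == 0.0

    def test_query_that_is_target_skips_itself(self):
        ds = simple_dataset([("1_a", 0, 0), ("1_b", 7, 0)])
        d = nearest_target_distance(ds, ["1_a"], ["1_a", "1_b"])
        assert d["1_a"] == pytest.approx(7.0)

    def test_sole_target_query_gets_nan(self):
        ds = simple_dataset([("1_a", 0, 0)])
        with pytest.warns(UserWarning, match="no in-scope target"):
            d = nearest_target_distance(ds, ["1_a"], ["1_a"])
        assert np.isnan(d["1_a"])

    def test_fov_without_targets_yields_nan(self):
        cells = [("1_q", 1, 0.0, 0.0, None), ("2_q", 2, 0.0, 0.0, None), ("1_t", 1, 1.0, 0.0, None)]
        ds = make_dataset(cells)
        with pytest.warns(UserWarning):
            d = nearest_target_distance(ds, ["1_q", "2_q"], ["1_t"], scope="within_fov")
        assert d["1_q"] == pytest.approx(1.0)
        assert np.isnan(d["2_q"])
        d_global = nearest_target_distance(ds, ["1_q", "2_q"], ["1_t"], scope="global")
        assert not np.isnan(d_global["2_q"])

    def test_empty_target_set_rejected(self):
        ds = simple_dataset([("1_q", 0, 0)])
        with pytest.raises(NoTargetCellsError):
            nearest_target_distance(ds, ["1_q"], [])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        cells = []
        for fov in (1, 2):
            for i in range(int(rng.integers(8, 30))):
                cells.append(
                    (f"{fov}_c{i}", fov, float(rng.uniform(0, 50)), float(rng.uniform(0, 50)), None)
                )
        ds = make_dataset(cells)
        ids = [c[0] for c in cells]
        targets = ids[:: 3]
        queries = ids[1::2] + targets[:2]
        expected = brute_nearest(
            [c[:4] for c in cells if c[0] in queries],
            [c[:4] for c in cells if c[0] in targets],
        )
        got = nearest_target_distance(ds, list(dict.fromkeys(queries)), targets)
        for qid, exp in expected.items():
            if exp is None:
                assert np.isnan(got[qid])
            else:
                assert got[qid] == pytest.approx(exp)

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        pts = [(f"1_c{i}", float(x), float(y)) for i, (x, y) in enumerate(rng.uniform(0, 30, (20, 2)))]
        ds = simple_dataset(pts)
        shifted = simple_dataset([(cid, x + 123.0, y - 45.0) for cid, x, y in pts])
        ids = [p[0] for p in pts]
        d1 = nearest_target_distance(ds, ids[:10], ids[10:])
        d2 = nearest_target_distance(shifted, ids[:10], ids[10:])
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), rtol=1e-9)


class TestStratification:
    @pytest.mark.parametrize(
        "distance,stratum", [(19.999, "Near"), (20.0, "Far"), (0.0, "Near"), (500.0, "Far")]
    )
    def test_boundary_semantics(self, distance, stratum):
        table = pd.DataFrame({"cell_id": ["a"], "subset": ["S"], "distance_um": [distance]})
        assert stratify(table)["stratum"].iloc[0] == stratum

    def test_empty_table(self):
        table = pd.DataFrame(columns=["cell_id", "subset", "distance_um"])
        out = stratify(table)
        assert len(out) == 0 and "stratum" in out.columns

    def test_proportions_partition(self):
        table = stratify(
            pd.DataFrame(
                {
                    "cell_id": list("abcde"),
                    "subset": ["S"] * 3 + ["T"] * 2,
                    "distance_um": [1.0, 5.0, 30.0, 10.0, 15.0],
                }
            )
        )
        props = subset_proportions(table).set_index("subset")
        assert props.loc["S", "prop_near"] == pytest.approx(2 / 3)
        assert props.loc["S", "prop_far"] == pytest.approx(1 / 3)
        assert props.loc["S", "n"] == 3
        assert props.loc["T", "prop_near"] == 1.0
        assert (props["prop_near"] + props["prop_far"]).eq(1.0).all()


class TestRankSum:
    def test_identical_samples_p1(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_small_sample(self):
        """A={1,2} vs B={10,11}: all ranks separate, exact two-sided p = 1/3."""
        _, p = rank_sum_test([1, 2], [10, 11])
        assert p == pytest.approx(1 / 3)

    def test_large_sample_shift_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        b = rng.normal(2, 1, 50)
        stat, p = rank_sum_test(a, b)
        assert p < 1e-3
        ref = mannwhitneyu(a, b, alternative="two-sided")
        assert stat == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))


def gating_from(assignments):
    names = tuple(sorted({lab for labs in assignments.values() for lab in labs}))
    return GatingResult(
        {cid: frozenset(labs) for cid, labs in assignments.items()}, names
    )


class TestSubsetComparisons:
    def build_table(self):
        return stratify(
            pd.DataFrame(
                {
                    "cell_id": [f"c{i}" for i in range(8)],
                    "subset": ["A"] * 4 + ["B"] * 4,
                    "distance_um": [1.0, 2.0, 3.0, 4.0, 30.0, 31.0, 32.0, 33.0],
                }
            )
        )

    def test_compare_subsets(self):
        _, p = compare_subsets(self.build_table(), "A", "B")
        assert p == pytest.approx(2 / 70)  # exact: all A below all B, C(8,4)=70

    def test_empty_subset_error(self):
        with pytest.raises(EmptySubsetError):
            compare_subsets(self.build_table(), "A", "missing")

    def test_pairwise_table_shape(self):
        out = pairwise_tests(self.build_table(), adjust=True)
        assert len(out) == 1
        assert {"p_distance", "p_near_far", "p_distance_bh"} <= set(out.columns)


def test_proximity_table_end_to_end():
    """Multi-gated target cell is query for its subset, excluded as its own target."""
    cells = [
        ("1_t1", 1, 0.0, 0.0, None),
        ("1_t2", 1, 10.0, 0.0, None),
        ("1_i1", 1, 3.0, 4.0, None),
    ]
    ds = make_dataset(cells)
    gating = gating_from(
        {"1_t1": {"IL36G_KC", "Treg"}, "1_t2": {"IL36G_KC"}, "1_i1": {"Treg"}}
    )
    table = proximity_table(ds, gating, ProximityParams())
    by_cell = table.set_index("cell_id")
    assert by_cell.at["1_i1", "distance_um"] == pytest.approx(5.0)
    assert by_cell.at["1_t1", "distance_um"] == pytest.approx(10.0)  # nearest OTHER target
    assert by_cell.at["1_i1", "stratum"] == "Near"
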