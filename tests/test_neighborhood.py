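"""k-NN graph, neighbor tabulation and the enrichment matrix."""

import numpy as np
import pandas as pd
import pytest

from spatialniche.errors import AllTypesExcludedError
from spatialniche.neighborhood import (
    NeighborhoodParams,
    enrichment_matrix,
    knn_within_fov,
    run_enrichment,
    tabulate_neighbor_types,
)

from _oracles import brute_enrichment, brute_knn
from conftest import make_dataset


def unlabelled(cells_xy, fov=1):
    return [(f"{fov}_c{i}", fov, x, y, None) for i, (x, y) in enumerate(cells_xy)]


def neighbor_map(dataset, k):
    return {ns.cell_id: list(ns.neighbor_ids) for ns in knn_within_fov(dataset, k)}


def test_collinear_three_cells_k1():
    ds = make_dataset(unlabelled([(0, 0), (1, 0), (3, 0)]))
    got = neighbor_map(ds, 1)
    assert got == {"1_c0": ["1_c1"], "1_c1": ["1_c0"], "1_c2": ["1_c1"]}


def test_saturation_when_k_exceeds_fov():
    ds = make_dataset(unlabelled([(0, 0), (1, 1), (2, 0), (5, 5)]))
    got = neighbor_map(ds, 50)
    for cid, neighbors in got.items():
        assert set(neighbors) == {c for c in got if c != cid}


def test_no_cross_fov_neighbors():
    """Interleaved global coordinates never mix FOVs."""
    cells = unlabelled([(0, 0), (2, 0), (4, 0)], fov=1) + unlabelled(
        [(1, 0), (3, 0), (5, 0)], fov=2
    )
    ds = make_dataset(cells)
    for ns in knn_within_fov(ds, 2):
        assert all(nid.startswith(ns.cell_id[:2]) for nid in ns.neighbor_ids)


def test_singleton_fov_gets_empty_set():
    cells = unlabelled([(0, 0), (1, 0)], fov=1) + unlabelled([(9, 9)], fov=2)
    ds = make_dataset(cells)
    got = neighbor_map(ds, 3)
    assert got["2_c0"] == []


def test_tie_break_by_cell_id():
    """Two equidistant candidates at the k-th slot: lower id wins."""
    ds = make_dataset(unlabelled([(0, 0), (1, 0), (-1, 0)]))
    got = neighbor_map(ds, 1)
    assert got["1_c0"] == ["1_c1"]  # 1_c1 < 1_c2 at equal distance 1


def test_tabulate_counts_and_unlabelled_drop():
    cells = unlabelled([(0, 0), (1, 0), (2, 0), (3, 0)])
    ds = make_dataset(cells)
    nsets = knn_within_fov(ds, 3)
    labels = {"1_c0": "A", "1_c1": "A", "1_c2": "B"}  # 1_c3 unlabelled
    with pytest.warns(UserWarning, match="unlabeled"):
        profiles = tabulate_neighbor_types(nsets, labels)
    by_id = {p.cell_id: p.neighbor_counts for p in profiles}
    assert by_id["1_c0"] == {"A": 1, "B": 1}
    with pytest.raises(ValueError):
        tabulate_neighbor_types(nsets, labels, unlabeled="error")


def test_six_cell_hand_tabulation():
    coords = [(0, 0), (1, 0), (2, 0), (0, 5), (1, 5), (2, 5)]
    labels_list = ["A", "A", "B", "B", "A", "B"]
    ds = make_dataset(unlabelled(coords))
    labels = {f"1_c{i}": lab for i, lab in enumerate(labels_list)}
    profiles = tabulate_neighbor_types(knn_within_fov(ds, 3), labels)
    by_id = {p.cell_id: p.neighbor_counts for p in profiles}
    # 1_c0 at (0,0): neighbors are 1_c1 (1), 1_c2 (2), then tie at 5 between
    # 1_c3 and ... distance to 1_c3 is 5, to 1_c4 sqrt(26): 1_c3 wins
    assert by_id["1_c0"] == {"A": 1, "B": 2}
    assert by_id["1_c4"] == {"B": 2, "A": 1}


def test_single_type_row_is_100():
    ds = make_dataset(unlabelled([(float(i), 0.0) for i in range(5)]))
    labels = {f"1_c{i}": "A" for i in range(5)}
    profiles = tabulate_neighbor_types(knn_within_fov(ds, 2), labels)
    matrix = enrichment_matrix(profiles, labels, NeighborhoodParams(k=2, min_cells_per_type=1))
    assert matrix.shape == (1, 1)
    assert matrix.iloc[0, 0] == pytest.approx(100.0)


def test_min_cells_exclusion():
    """25 A, 25 B, 10 C cells at the default 20-cell floor: C vanishes."""
    rng = np.random.default_rng(5)
    labels_list = ["A"] * 25 + ["B"] * 25 + ["C"] * 10
    coords = rng.uniform(0, 100, size=(60, 2))
    ds = make_dataset(unlabelled(map(tuple, coords)))
    labels = {f"1_c{i}": lab for i, lab in enumerate(labels_list)}
    profiles = tabulate_neighbor_types(knn_within_fov(ds, 5), labels)
    matrix = enrichment_matrix(profiles, labels, NeighborhoodParams(k=5, min_cells_per_type=20))
    assert list(matrix.index) == ["A", "B"]
    assert list(matrix.columns) == ["A", "B"]


def test_all_types_excluded_error():
    ds = make_dataset(unlabelled([(0, 0), (1, 0)]))
    labels = {"1_c0": "A", "1_c1": "B"}
    profiles = tabulate_neighbor_types(knn_within_fov(ds, 1), labels)
    with pytest.raises(AllTypesExcludedError):
        enrichment_matrix(profiles, labels, NeighborhoodParams(k=1, min_cells_per_type=20))


def random_instance(rng, n_fovs=2, max_cells=120, n_types=3):
    cells, labels = [], {}
    type_names = [chr(ord("A") + t) for t in range(n_types)]
    for fov in range(1, n_fovs + 1):
        n = int(rng.integers(25, max_cells // n_fovs + 25))
        xy = rng.uniform(0, 200, size=(n, 2))
        for i in range(n):
            cid = f"{fov}_c{i:03d}"
            cells.append((cid, fov, float(xy[i, 0]), float(xy[i, 1]), None))
            labels[cid] = type_names[int(rng.integers(0, n_types))]
    return cells, labels


@pytest.mark.parametrize("seed", range(5))
def test_knn_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    cells, _ = random_instance(rng)
    ds = make_dataset(cells)
    k = int(rng.integers(1, 12))
    expected = brute_knn([(c[0], c[1], c[2], c[3]) for c in cells], k)
    assert neighbor_map(ds, k) == expected


@pytest.mark.parametrize("abundance_normalize", [True, False])
def test_pipeline_matches_bruteforce(abundance_normalize):
    rng = np.random.default_rng(42)
    cells, labels = random_instance(rng)
    ds = make_dataset(cells)
    params = NeighborhoodParams(k=5, min_cells_per_type=20)
    profiles = tabulate_neighbor_types(knn_within_fov(ds, params.k), labels)
    matrix = enrichment_matrix(profiles, labels, params, abundance_normalize)
    retained, expected = brute_enrichment(
        [(c[0], c[1], c[2], c[3]) for c in cells],
        labels,
        params.k,
        params.min_cells_per_type,
        abundance_normalize,
    )
    assert list(matrix.index) == retained
    np.testing.assert_allclose(matrix.to_numpy(), np.array(expected), rtol=1e-12)


def test_row_sums_and_order_invariance(planted_dataset):
    dataset, truth, _ = planted_dataset
    params = NeighborhoodParams(k=10, min_cells_per_type=20)
    matrix, _ = run_enrichment(dataset, truth.to_dict(), params)
    np.testing.assert_allclose(matrix.sum(axis=1), 100.0, rtol=1e-9)
    assert (matrix.to_numpy() >= 0).all()
    # shuffle cell order: identical matrix
    rng = np.random.default_rng(1)
    perm = rng.permutation(dataset.n_cells)
    shuffled = dataset.subset_cells(np.ones(dataset.n_cells, dtype=bool))
    shuffled.cells = shuffled.cells.iloc[perm].reset_index(drop=True)
    shuffled.counts = shuffled.counts[:, perm]
    matrix2, _ = run_enrichment(shuffled, truth.to_dict(), params)
    pd.testing.assert_frame_equal(matrix, matrix2)
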