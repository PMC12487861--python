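"""k-nearest-neighbor neighborhood enrichment.

For every cell, its k nearest neighbors (Euclidean distance, default
k = 150) are found *within its own field of view* — tiles are imaged
independently and stitched coordinates across non-adjacent tiles carry no
biological meaning. Neighbor cell-type counts are tabulated per cell and
aggregated across FOVs into a sender x receiver matrix:

1. cell types with fewer than ``min_cells_per_type`` total cells (default
   20, counted across all FOVs) are excluded from both axes;
2. ``raw[s, r]`` sums, over all focal cells of sender type ``s``, the
   number of their neighbors of receiver type ``r``;
3. each column is divided by the total number of cells of that receiver
   type — the pool of "potential neighbors" — correcting for abundance;
4. each row is rescaled to sum to 100, yielding percentages.

Step 3 can be disabled (``abundance_normalize=False``) to obtain raw
neighborhood composition percentages instead.

Neighbor search is exact: blocked all-pairs distances with ties at the
k-th distance broken by ascending cell id, so results are deterministic
and invariant under permutation of cell order. FOVs with fewer than k+1
cells contribute all their ``n - 1`` neighbors rather than being dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import AllTypesExcludedError
from .io_cosmx import SpatialDataset

logger = logging.getLogger(__name__)

_BLOCK = 512  # rows per cdist block; caps memory on large FOVs


@dataclass(frozen=True)
class NeighborhoodParams:
    k: int = 150
    min_cells_per_type: int = 20

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.min_cells_per_type < 0:
            raise ValueError("min_cells_per_type must be >= 0")


@dataclass(frozen=True)
class NeighborSet:
    """A focal cell and the ids of its nearest within-FOV neighbors."""

    cell_id: str
    fov: object
    neighbor_ids: tuple[str, ...]


@dataclass(frozen=True)
class NeighborProfile:
    """Neighbor cell-type counts for one focal cell."""

    cell_id: str
    fov: object
    neighbor_counts: dict[str, int]


def knn_within_fov(dataset: SpatialDataset, k: int) -> list[NeighborSet]:
    """Exact k-nearest neighbors per cell, restricted to the cell's FOV.

    Returns one :class:`NeighborSet` per cell, in dataset order. Each cell
    gets its ``min(k, n_fov - 1)`` nearest FOV-mates (self excluded); ties
    at the cut-off distance are broken by ascending cell id. A cell alone
    in its FOV gets an empty neighbor set and a logged warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: dict[str, NeighborSet] = {}
    for fov, group in dataset.cells.groupby("fov", sort=False):
        ids = group["cell_id"].to_numpy()
        coords = group[["x", "y"]].to_numpy(dtype=float)
        n = len(ids)
        if n == 1:
            logger.warning("FOV %r has a single cell; empty neighbor set", fov)
            out[ids[0]] = NeighborSet(ids[0], fov, ())
            continue
        # rank of each cell in ascending-id order, used as the tie-break key
        id_rank = np.empty(n, dtype=np.int64)
        id_rank[np.argsort(ids, kind="stable")] = np.arange(n)
        kk = min(k, n - 1)
        for start in range(0, n, _BLOCK):
            stop = min(start + _BLOCK, n)
            dists = cdist(coords[start:stop], coords)
            for i_local, i in enumerate(range(start, stop)):
                order = np.lexsort((id_rank, dists[i_local]))
                order = order[order != i][:kk]
                out[ids[i]] = NeighborSet(ids[i], fov, tuple(ids[order]))
    return [out[cid] for cid in dataset.cells["cell_id"]]


def tabulate_neighbor_types(
    neighbor_sets: Sequence[NeighborSet],
    labels: Mapping[str, str],
    unlabeled: str = "drop",
) -> list[NeighborProfile]:
    """Count neighbor labels per focal cell.

    ``labels`` maps cell id to cell-type label. Neighbors without a label
    are dropped with a warning by default (``unlabeled="drop"``); set
    ``unlabeled="error"`` to fail instead. Focal cells themselves need not
    be labelled here — sender filtering happens at matrix time.
    """
    if unlabeled not in ("drop", "error"):
        raise ValueError("unlabeled must be 'drop' or 'error'")
    n_dropped = 0
    profiles = []
    for ns in neighbor_sets:
        counts: dict[str, int] = {}
        for nid in ns.neighbor_ids:
            lab = labels.get(nid)
            if lab is None or pd.isna(lab):
                if unlabeled == "error":
                    raise ValueError(f"neighbor {nid!r} of {ns.cell_id!r} is unlabeled")
                n_dropped += 1
                continue
            counts[lab] = counts.get(lab, 0) + 1
        profiles.append(NeighborProfile(ns.cell_id, ns.fov, counts))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} unlabeled neighbor entries", stacklevel=2)
    return profiles


def _label_totals(labels: Mapping[str, str]) -> dict[str, int]:
    totals: dict[str, int] = {}
    for lab in labels.values():
        if lab is None or pd.isna(lab):
            continue
        totals[lab] = totals.get(lab, 0) + 1
    return totals


def enrichment_matrix(
    profiles: Sequence[NeighborProfile],
    labels: Mapping[str, str],
    params: NeighborhoodParams = NeighborhoodParams(),
    abundance_normalize: bool = True,
) -> pd.DataFrame:
    """Aggregate neighbor profiles into the sender x receiver percentage matrix.

    Rows are sender types, columns receiver types (identical, sorted label
    sets after the minimum-cells exclusion). Every row with any neighbor
    mass sums to 100.
    """
    totals = _label_totals(labels)
    retained = sorted(lab for lab, n in totals.items() if n >= params.min_cells_per_type)
    if not retained:
        raise AllTypesExcludedError(
            f"no cell type reaches min_cells_per_type={params.min_cells_per_type}"
        )
    index = {lab: i for i, lab in enumerate(retained)}

    raw = np.zeros((len(retained), len(retained)), dtype=float)
    for prof in profiles:
        sender = labels.get(prof.cell_id)
        if sender is None or pd.isna(sender) or sender not in index:
            continue
        s = index[sender]
        for lab, n in prof.neighbor_counts.items():
            r = index.get(lab)
            if r is not None:
                raw[s, r] += n

    if abundance_normalize:
        pool = np.array([totals[lab] for lab in retained], dtype=float)
        norm = raw / pool[np.newaxis, :]
    else:
        norm = raw
    row_sums = norm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_sums[:, None] > 0, norm / row_sums[:, None] * 100.0, 0.0)
    return pd.DataFrame(pct, index=pd.Index(retained, name="sender"), columns=retained)


def run_enrichment(
    dataset: SpatialDataset,
    labels: Mapping[str, str] | None = None,
    params: NeighborhoodParams = NeighborhoodParams(),
    abundance_normalize: bool = True,
) -> tuple[pd.DataFrame, list[NeighborProfile]]:
    """Convenience wrapper: k-NN, tabulation and matrix in one call."""
    if labels is None:
        labels = dataset.labels().dropna().to_dict()
    neighbor_sets = knn_within_fov(dataset, params.k)
    profiles = tabulate_neighbor_types(neighbor_sets, labels)
    matrix = enrichment_matrix(profiles, labels, params, abundance_normalize)
    return matrix, profiles


def profiles_to_frame(profiles: Sequence[NeighborProfile]) -> pd.DataFrame:
    """Long-format (cell_id, fov, neighbor_label, count) table."""
    rows = [
        (p.cell_id, p.fov, lab, n)
        for p in profiles
        for lab, n in sorted(p.neighbor_counts.items())
    ]
    return pd.DataFrame(rows, columns=["cell_id", "fov", "neighbor_label", "count"])


def permutation_pvalue(
    neighbor_sets: Sequence[NeighborSet],
    labels: Mapping[str, str],
    sender: str,
    receiver: str,
    params: NeighborhoodParams = NeighborhoodParams(),
    n_permutations: int = 99,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Label-permutation test for one enrichment-matrix entry.

    Cell-type labels are shuffled across all labelled cells (the spatial
    graph stays fixed), the ``sender -> receiver`` percentage is recomputed
    per shuffle, and the one-sided empirical p-value
    ``(1 + #{null >= observed}) / (1 + n_permutations)`` is returned along
    with the observed value and the null distribution.
    """
    rng = np.random.default_rng(rng)
    labelled_ids = [cid for cid, lab in labels.items() if lab is not None and not pd.isna(lab)]
    id_pos = {cid: i for i, cid in enumerate(labelled_ids)}
    label_arr = np.array([labels[cid] for cid in labelled_ids], dtype=object)

    # flatten the graph once: focal index / neighbor index pairs
    focal_idx, neigh_idx = [], []
    for ns in neighbor_sets:
        f = id_pos.get(ns.cell_id)
        if f is None:
            continue
        for nid in ns.neighbor_ids:
            nn = id_pos.get(nid)
            if nn is not None:
                focal_idx.append(f)
                neigh_idx.append(nn)
    focal_idx = np.array(focal_idx, dtype=np.int64)
    neigh_idx = np.array(neigh_idx, dtype=np.int64)

    uniq, codes = np.unique(label_arr, return_inverse=True)
    totals = np.bincount(codes, minlength=len(uniq))
    retained = totals >= params.min_cells_per_type
    if not retained.any():
        raise AllTypesExcludedError("no cell type reaches the minimum-cells threshold")
    name_to_code = {name: c for c, name in enumerate(uniq)}
    if sender not in name_to_code or receiver not in name_to_code:
        raise KeyError(f"sender/receiver {sender!r}/{receiver!r} not among labels")
    s_code, r_code = name_to_code[sender], name_to_code[receiver]
    if not (retained[s_code] and retained[r_code]):
        raise AllTypesExcludedError("sender or receiver excluded by the minimum-cells rule")

    n_types = len(uniq)
    pool = totals.astype(float)

    def entry(code_vec: np.ndarray) -> float:
        pair = code_vec[focal_idx] * n_types + code_vec[neigh_idx]
        raw = np.bincount(pair, minlength=n_types * n_types).reshape(n_types, n_types).astype(float)
        raw = raw[np.ix_(retained, retained)]
        norm = raw / pool[retained][np.newaxis, :]
        s_local = int(retained[:s_code].sum())
        r_local = int(retained[:r_code].sum())
        row = norm[s_local]
        return 0.0 if row.sum() == 0 else row[r_local] / row.sum() * 100.0

    observed = entry(codes)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = entry(rng.permutation(codes))
    pval = (1 + int((null >= observed).sum())) / (1 + n_permutations)
    return pval, observed, null
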