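"""Nearest-target proximity analysis.

For each immune cell the Euclidean distance to the nearest target cell
(by default the IL-36G+ keratinocyte subset) is computed, stratified at a
threshold into "Near" (< 20 um, strict) and "Far" (>= 20 um), summarised
per subset, and compared between subsets with the two-sided Wilcoxon
rank-sum (Mann-Whitney) test.

Scope: distances default to within-FOV (a query in a tile without any
target gets a missing distance and is excluded downstream); global scope
across stitched coordinates is available by flag. A query cell that is
itself a target reports its distance to the nearest *other* target.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import fisher_exact, mannwhitneyu

from .errors import EmptySubsetError, NoTargetCellsError
from .gating import IMMUNE_SUBSETS, TARGET_LABEL, GatingResult
from .io_cosmx import SpatialDataset

NEAR, FAR = "Near", "Far"


@dataclass(frozen=True)
class ProximityParams:
    near_threshold: float = 20.0  # um
    target_label: str = TARGET_LABEL

    def __post_init__(self):
        if self.near_threshold <= 0:
            raise ValueError("near_threshold must be positive")


def nearest_target_distance(
    dataset: SpatialDataset,
    query_ids: Sequence[str],
    target_ids: Iterable[str],
    scope: str = "within_fov",
) -> pd.Series:
    """Minimum Euclidean distance from each query cell to the target set.

    Returns a float Series indexed by query id, NaN where no in-scope
    target exists (e.g. a FOV without targets under within-FOV scope).
    Queries that are themselves targets are matched against the remaining
    targets only.
    """
    if scope not in ("within_fov", "global"):
        raise ValueError("scope must be 'within_fov' or 'global'")
    target_ids = list(dict.fromkeys(target_ids))
    if not target_ids:
        raise NoTargetCellsError("empty target set")

    cells = dataset.cells.set_index("cell_id")
    missing = [cid for cid in list(query_ids) + target_ids if cid not in cells.index]
    if missing:
        raise KeyError(f"unknown cell ids: {missing[:5]}")

    result = pd.Series(np.nan, index=pd.Index(query_ids, name="cell_id"), dtype=float)
    target_set = set(target_ids)

    if scope == "global":
        groups = [(None, list(query_ids), target_ids)]
    else:
        q_by_fov: dict[object, list[str]] = {}
        for cid in query_ids:
            q_by_fov.setdefault(cells.at[cid, "fov"], []).append(cid)
        t_by_fov: dict[object, list[str]] = {}
        for cid in target_ids:
            t_by_fov.setdefault(cells.at[cid, "fov"], []).append(cid)
        groups = [(fov, qs, t_by_fov.get(fov, [])) for fov, qs in q_by_fov.items()]

    n_missing = 0
    for _fov, qs, ts in groups:
        if not ts:
            n_missing += len(qs)
            continue
        t_arr = np.asarray(ts, dtype=object)
        t_xy = cells.loc[ts, ["x", "y"]].to_numpy(dtype=float)
        tree = cKDTree(t_xy)
        q_xy = cells.loc[qs, ["x", "y"]].to_numpy(dtype=float)
        k = min(2, len(ts))
        dists, idx = tree.query(q_xy, k=k)
        if k == 1:
            dists = dists[:, np.newaxis]
            idx = idx[:, np.newaxis]
        for row, qid in enumerate(qs):
            if qid in target_set:
                # skip the query's own entry in the target set
                choices = [
                    dists[row, j] for j in range(k) if t_arr[idx[row, j]] != qid
                ]
                if choices:
                    result[qid] = min(choices)
                else:
                    n_missing += 1
            else:
                result[qid] = dists[row, 0]
    if n_missing:
        warnings.warn(
            f"{n_missing} query cell(s) have no in-scope target; distance set to NaN",
            stacklevel=2,
        )
    return result


def stratify(table: pd.DataFrame, params: ProximityParams = ProximityParams()) -> pd.DataFrame:
    """Add the Near/Far stratum column (Near iff distance < threshold)."""
    out = table.copy()
    dist = out["distance_um"].to_numpy(dtype=float)
    strata = np.where(dist < params.near_threshold, NEAR, FAR)
    out["stratum"] = pd.array(
        [s if np.isfinite(d) else pd.NA for s, d in zip(strata, dist)], dtype="object"
    )
    return out


def proximity_table(
    dataset: SpatialDataset,
    gating: GatingResult,
    params: ProximityParams = ProximityParams(),
    scope: str = "within_fov",
    subsets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format proximity table: (cell_id, subset, distance_um, stratum).

    A multi-gated cell appears once per subset it belongs to. Cells gated
    into the target subset are valid queries for their immune subsets but
    are excluded from their own target search.
    """
    if subsets is None:
        subsets = [s for s in IMMUNE_SUBSETS if s in gating.rule_names]
    target_ids = gating.members(params.target_label)
    rows = [
        (cid, subset)
        for subset in subsets
        for cid in gating.members(subset)
    ]
    table = pd.DataFrame(rows, columns=["cell_id", "subset"])
    if table.empty:
        table["distance_um"] = pd.Series(dtype=float)
        return stratify(table, params)
    query_ids = list(dict.fromkeys(table["cell_id"]))
    dist = nearest_target_distance(dataset, query_ids, target_ids, scope=scope)
    table["distance_um"] = table["cell_id"].map(dist)
    return stratify(table, params)


def subset_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subset Near/Far proportions and counts (NaN distances excluded)."""
    rows = []
    for subset, grp in table.groupby("subset", sort=True):
        grp = grp.dropna(subset=["distance_um"])
        n = len(grp)
        if n == 0:
            warnings.warn(f"subset {subset!r} has no measurable cells; omitted", stacklevel=2)
            continue
        n_near = int((grp["stratum"] == NEAR).sum())
        rows.append((subset, n_near / n, (n - n_near) / n, n))
    return pd.DataFrame(rows, columns=["subset", "prop_near", "prop_far", "n"])


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U).

    Exact enumeration when both groups have at most 20 observations and
    the pooled sample is tie-free; tie-corrected normal approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if max(len(x), len(y)) <= 20 and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_subsets(table: pd.DataFrame, subset_a: str, subset_b: str) -> tuple[float, float]:
    """Rank-sum test between two subsets' nearest-target distances."""
    vals = {}
    for subset in (subset_a, subset_b):
        d = table.loc[table["subset"] == subset, "distance_um"].dropna().to_numpy()
        if d.size == 0:
            raise EmptySubsetError(subset)
        vals[subset] = d
    return rank_sum_test(vals[subset_a], vals[subset_b])


def pairwise_tests(
    table: pd.DataFrame,
    subsets: Sequence[str] | None = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """All pairwise subset comparisons.

    Per pair: the rank-sum test on distance distributions (primary) and a
    Fisher exact test on the 2x2 Near/Far counts (sensitivity output).
    ``adjust=True`` appends Benjamini-Hochberg adjusted distance p-values.
    """
    if subsets is None:
        subsets = sorted(table["subset"].dropna().unique())
    rows = []
    for a, b in itertools.combinations(subsets, 2):
        stat, p = compare_subsets(table, a, b)
        counts = []
        for subset in (a, b):
            grp = table.loc[table["subset"] == subset].dropna(subset=["distance_um"])
            counts.append(
                [int((grp["stratum"] == NEAR).sum()), int((grp["stratum"] == FAR).sum())]
            )
        _, p_counts = fisher_exact(counts)
        rows.append((a, b, stat, p, float(p_counts)))
    out = pd.DataFrame(
        rows, columns=["subset_a", "subset_b", "statistic", "p_distance", "p_near_far"]
    )
    if adjust and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_distance_bh"] = multipletests(out["p_distance"], method="fdr_bh")[1]
    return out
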