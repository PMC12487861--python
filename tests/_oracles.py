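"""Independently coded brute-force references used to cross-check the package.

Everything here is deliberately written in plain Python (explicit loops,
``sorted`` on tuples) so it shares no code path with the implementation.
"""

import math


def brute_knn(cells, k):
    """cells: list of (cell_id, fov, x, y). Returns {cell_id: [neighbor ids]}.

    All-pairs distances, sorted by (distance, cell id), self excluded,
    truncated at min(k, n_fov - 1).
    """
    by_fov = {}
    for cid, fov, x, y in cells:
        by_fov.setdefault(fov, []).append((cid, x, y))
    out = {}
    for members in by_fov.values():
        for cid, x, y in members:
            ranked = sorted(
                (math.dist((x, y), (ox, oy)), ocid)
                for ocid, ox, oy in members
                if ocid != cid
            )
            out[cid] = [ocid for _, ocid in ranked[:k]]
    return out


def brute_enrichment(cells, labels, k, min_cells, abundance_normalize=True):
    """Full reference pipeline: kNN -> tabulate -> normalize -> row rescale.

    Returns (retained_labels, matrix as nested lists).
    """
    totals = {}
    for lab in labels.values():
        totals[lab] = totals.get(lab, 0) + 1
    retained = sorted(lab for lab, n in totals.items() if n >= min_cells)
    pos = {lab: i for i, lab in enumerate(retained)}

    neigh = brute_knn(cells, k)
    raw = [[0.0] * len(retained) for _ in retained]
    for cid, neighbors in neigh.items():
        sender = labels.get(cid)
        if sender not in pos:
            continue
        for nid in neighbors:
            receiver = labels.get(nid)
            if receiver in pos:
                raw[pos[sender]][pos[receiver]] += 1
    norm = [
        [
            (raw[s][r] / totals[retained[r]]) if abundance_normalize else raw[s][r]
            for r in range(len(retained))
        ]
        for s in range(len(retained))
    ]
    matrix = []
    for row in norm:
        total = sum(row)
        matrix.append([v / total * 100.0 if total > 0 else 0.0 for v in row])
    return retained, matrix


def brute_nearest(queries, targets):
    """queries/targets: list of (cell_id, fov, x, y); within-FOV scope.

    Returns {query id: min distance or None}, queries excluded from their
    own target entry.
    """
    out = {}
    for qid, qfov, qx, qy in queries:
        best = None
        for tid, tfov, tx, ty in targets:
            if tid == qid or tfov != qfov:
                continue
            d = math.dist((qx, qy), (tx, ty))
            if best is None or d < best:
                best = d
        out[qid] = best
    return out
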