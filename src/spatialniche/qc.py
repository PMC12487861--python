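"""Cell-level quality-control filters.

Two filters are provided, matching the two assay types they were designed
for:

* :func:`filter_scrna_cells` — droplet scRNA-Seq style: a cell is dropped
  when it has fewer than 500 total transcripts, fewer than 100 detected
  genes, or more than 10% mitochondrial expression. All three bounds are
  strict, so a cell sitting exactly on a boundary (500 transcripts, 100
  genes, 10% mito) is retained.
* :func:`filter_cosmx_cells` — imaging-based panel style: control probes
  (feature names starting with "Neg" or "System") are removed first, then
  cells with fewer than 20 remaining counts are dropped. Probe removal
  precedes the count threshold because control probes are not biological
  signal; the order is fixed and the thresholds are configurable.

Both return a :class:`QcReport` that attributes every removed cell to each
rule it violates, so report counts always reconcile with the matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .errors import AllGenesRemovedError, EmptyMatrixError
from .io_cosmx import SpatialDataset

RULE_MIN_TRANSCRIPTS = "min_transcripts"
RULE_MIN_GENES = "min_genes"
RULE_MAX_MITO = "max_mito_fraction"
RULE_MIN_COSMX = "min_cosmx_counts"


@dataclass(frozen=True)
class QcThresholds:
    """Quality-control thresholds; defaults follow the strict readings above."""

    min_transcripts: int = 500
    min_genes: int = 100
    max_mito_fraction: float = 0.10
    min_cosmx_counts: int = 20
    control_prefixes: tuple[str, ...] = ("Neg", "System")

    def __post_init__(self):
        if self.min_transcripts < 0 or self.min_genes < 0 or self.min_cosmx_counts < 0:
            raise ValueError("count thresholds must be non-negative")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


@dataclass
class QcReport:
    """Book-keeping for one filtering pass."""

    n_input: int
    n_retained: int
    removed_ids: list[str]
    rule_violations: dict[str, tuple[str, ...]]  # removed cell id -> rules it violates
    n_genes_removed: int = 0
    removed_genes: list[str] = field(default_factory=list)

    @property
    def n_removed_by_rule(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rules in self.rule_violations.values():
            for rule in rules:
                counts[rule] = counts.get(rule, 0) + 1
        return counts

    def check(self) -> None:
        if self.n_retained + len(set(self.removed_ids)) != self.n_input:
            raise AssertionError("QC report does not reconcile with matrix shapes")

    def to_text(self) -> str:
        lines = [
            f"n_input = {self.n_input}",
            f"n_retained = {self.n_retained}",
            f"n_removed = {len(self.removed_ids)}",
            f"n_genes_removed = {self.n_genes_removed}",
        ]
        for rule, n in sorted(self.n_removed_by_rule.items()):
            lines.append(f"removed_by.{rule} = {n}")
        return "\n".join(lines) + "\n"


def default_mito_predicate(gene: str) -> bool:
    """Mitochondrial genes identified by the conventional ``MT-`` prefix."""
    return gene.upper().startswith("MT-")


def filter_scrna_cells(
    counts: pd.DataFrame,
    mito_genes: Callable[[str], bool] | Iterable[str] | None = None,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[pd.DataFrame, QcReport]:
    """Drop low-quality cells from a genes x cells scRNA-Seq count matrix.

    Parameters
    ----------
    counts:
        Genes x cells DataFrame of raw non-negative counts.
    mito_genes:
        Predicate on gene names, or an explicit collection of mitochondrial
        gene names; defaults to the ``MT-`` prefix convention.
    thresholds:
        See :class:`QcThresholds`.

    Returns
    -------
    (filtered, report):
        The retained columns (same gene order) and the per-rule audit.

    Notes
    -----
    A cell with zero total counts has an undefined mitochondrial fraction;
    it is removed under the transcript rule and the fraction is treated as
    zero, never as a division error.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise EmptyMatrixError("QC on an empty count matrix")
    if mito_genes is None:
        predicate = default_mito_predicate
    elif callable(mito_genes):
        predicate = mito_genes
    else:
        mito_set = set(mito_genes)
        predicate = mito_set.__contains__

    values = counts.to_numpy()
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    total = values.sum(axis=0)
    detected = (values > 0).sum(axis=0)
    mito_mask = np.fromiter((predicate(g) for g in counts.index), bool, count=len(counts.index))
    mito_total = values[mito_mask].sum(axis=0) if mito_mask.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1), 0.0)

    fails = {
        RULE_MIN_TRANSCRIPTS: total < thresholds.min_transcripts,
        RULE_MIN_GENES: detected < thresholds.min_genes,
        RULE_MAX_MITO: mito_frac > thresholds.max_mito_fraction,
    }
    removed_mask = fails[RULE_MIN_TRANSCRIPTS] | fails[RULE_MIN_GENES] | fails[RULE_MAX_MITO]

    cell_ids = [str(c) for c in counts.columns]
    violations = {
        cell_ids[i]: tuple(rule for rule, mask in fails.items() if mask[i])
        for i in np.flatnonzero(removed_mask)
    }
    filtered = counts.loc[:, ~removed_mask]
    report = QcReport(
        n_input=len(cell_ids),
        n_retained=filtered.shape[1],
        removed_ids=[cell_ids[i] for i in np.flatnonzero(removed_mask)],
        rule_violations=violations,
    )
    report.check()
    return filtered, report


def filter_cosmx_cells(
    dataset: SpatialDataset,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[SpatialDataset, QcReport]:
    """Remove control probes, then under-sampled cells, from a spatial run.

    Control probes (names starting with any of ``thresholds.control_prefixes``)
    are dropped first; cell totals are then recomputed on the biological
    panel and cells below ``thresholds.min_cosmx_counts`` are dropped
    (strictly fewer than the threshold).
    """
    dataset.validate()
    is_control = np.array(
        [any(g.startswith(p) for p in thresholds.control_prefixes) for g in dataset.gene_names]
    )
    if is_control.all():
        raise AllGenesRemovedError("control-probe removal would drop every feature")
    removed_genes = [g for g, c in zip(dataset.gene_names, is_control) if c]
    probe_free = dataset.subset_genes(~is_control)

    totals = probe_free.counts.sum(axis=0)
    keep = totals >= thresholds.min_cosmx_counts
    removed_ids = list(probe_free.cells.loc[~keep, "cell_id"])
    filtered = probe_free.subset_cells(keep)

    report = QcReport(
        n_input=dataset.n_cells,
        n_retained=filtered.n_cells,
        removed_ids=removed_ids,
        rule_violations={cid: (RULE_MIN_COSMX,) for cid in removed_ids},
        n_genes_removed=len(removed_genes),
        removed_genes=removed_genes,
    )
    report.check()
    return filtered, report
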