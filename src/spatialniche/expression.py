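"""Per-cell-type expression summaries for a gene panel.

Raw transcript counts (never normalised values) are summarised per
(gene, cell type) as the mean and median count per cell plus the total
count over all cells of that type. The default panel is the eight genes
used to verify the regTh17 / IL-36G axis in pustular skin: CD3E, CD4,
CTLA4, FOXP3, IL17A, IL17F, IL26, IL36G.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MissingPanelGeneError
from .gating import normalize_marker
from .io_cosmx import SpatialDataset

DEFAULT_PANEL = ("CD3E", "CD4", "CTLA4", "FOXP3", "IL17A", "IL17F", "IL26", "IL36G")


def summarize_panel(
    dataset: SpatialDataset,
    labels: Mapping[str, str] | None = None,
    panel: Sequence[str] = DEFAULT_PANEL,
) -> pd.DataFrame:
    """Tidy summary table: (gene, cell_type, mean_count, median_count, total_count, n_cells).

    ``labels`` maps cell id to cell type; defaults to the dataset's own
    annotations. Unlabelled cells are excluded with a warning. Panel gene
    names are matched after normalisation (case, hyphens), and a missing
    gene raises :class:`MissingPanelGeneError`.
    """
    if labels is None:
        labels = dataset.labels().dropna().to_dict()
    gene_index = {normalize_marker(g): i for i, g in enumerate(dataset.gene_names)}
    missing = [g for g in panel if normalize_marker(g) not in gene_index]
    if missing:
        raise MissingPanelGeneError(missing)

    cell_ids = dataset.cells["cell_id"]
    cell_labels = np.array([labels.get(cid) for cid in cell_ids], dtype=object)
    labelled = np.array([lab is not None and not pd.isna(lab) for lab in cell_labels])
    if not labelled.all():
        warnings.warn(
            f"{int((~labelled).sum())} unlabelled cell(s) excluded from the summary",
            stacklevel=2,
        )

    rows = []
    for gene in panel:
        g = gene_index[normalize_marker(gene)]
        counts = dataset.counts[g]
        for cell_type in sorted({lab for lab in cell_labels[labelled]}):
            mask = labelled & (cell_labels == cell_type)
            vals = counts[mask]
            rows.append(
                (
                    gene,
                    cell_type,
                    float(vals.mean()),
                    float(np.median(vals)),
                    int(vals.sum()),
                    int(mask.sum()),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "cell_type", "mean_count", "median_count", "total_count", "n_cells"],
    )
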