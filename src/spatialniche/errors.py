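"""Structured exceptions raised by the pipeline.

Every error a caller might want to branch on carries its payload as
attributes rather than only in the message.
"""

from __future__ import annotations


class SpatialNicheError(Exception):
    """Base class for all structured pipeline errors."""


class MissingFileError(SpatialNicheError):
    """A mandatory flat file is absent from the input directory."""

    def __init__(self, filename: str, directory: str):
        self.filename = filename
        self.directory = directory
        super().__init__(f"mandatory flat file {filename!r} not found in {directory}")


class OrphanCellsError(SpatialNicheError):
    """Cells present in one flat file but absent from its counterpart."""

    def __init__(self, orphan_ids, where: str):
        self.orphan_ids = sorted(orphan_ids)
        self.where = where
        shown = ", ".join(self.orphan_ids[:10])
        more = "" if len(self.orphan_ids) <= 10 else f" (+{len(self.orphan_ids) - 10} more)"
        super().__init__(f"{len(self.orphan_ids)} orphan cell(s) {where}: {shown}{more}")


class EmptyMatrixError(SpatialNicheError):
    """A count matrix with zero cells or zero genes where data is required."""


class AllGenesRemovedError(SpatialNicheError):
    """Control-probe removal left no genes in the panel."""


class MissingMarkersError(SpatialNicheError):
    """A gating rule references markers absent from the dataset panel."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"marker gene(s) not in panel: {', '.join(self.missing)}")


class MissingPanelGeneError(SpatialNicheError):
    """An expression-summary panel gene is absent from the dataset."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"panel gene(s) not in dataset: {', '.join(self.missing)}")


class AllTypesExcludedError(SpatialNicheError):
    """The minimum-cells rule excluded every cell type."""


class EmptySubsetError(SpatialNicheError):
    """A statistical comparison was requested on an empty subset."""

    def __init__(self, subset: str):
        self.subset = subset
        super().__init__(f"subset {subset!r} has no finite distances to compare")


class NoTargetCellsError(SpatialNicheError):
    """Proximity analysis requested with an empty target set."""


class ConfigError(SpatialNicheError):
    """Invalid or unknown configuration entry."""


class DensityError(SpatialNicheError):
    """Requested cell density exceeds what the field of view can hold."""
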