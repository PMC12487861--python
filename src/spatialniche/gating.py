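"""Marker-rule cell gating.

Cells are assigned to subsets by boolean coexpression rules: a cell carries
a subset label iff its raw count is at or above the positivity threshold
(default: at least one transcript) for *every* required marker of that
subset. Rules are independent gates, not a partition — a cell may satisfy
several rules and then belongs to each subset.

The built-in rules cover the populations of interest in pustular skin
disease: IL-36G+ keratinocytes (the inflammatory target population) and
four immune subsets — Treg (CD4+FOXP3+IL2RA+), Th17 (CD4+IL17A+RORC+),
regTh17 (IL17F+IL26+FOXP3+, the hybrid regulatory/Th17 phenotype) and
NKT (CD8A+NKG7+KLRD1+).

Marker names are normalised before matching (case folded, hyphens and dots
stripped), so "IL-17F" and "IL17F" refer to the same gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MissingMarkersError
from .io_cosmx import SpatialDataset

TARGET_LABEL = "IL36G_KC"
IMMUNE_SUBSETS = ("Treg", "Th17", "regTh17", "NKT")


def normalize_marker(name: str) -> str:
    """Canonical marker spelling: upper case, hyphens/dots removed."""
    return name.replace("-", "").replace(".", "").upper()


@dataclass(frozen=True)
class GatingRule:
    """A named conjunction of positive markers."""

    name: str
    required_markers: tuple[str, ...]
    positivity_min_count: int = 1

    def __post_init__(self):
        if not self.required_markers:
            raise ValueError("a gating rule needs at least one marker")
        normed = [normalize_marker(m) for m in self.required_markers]
        if len(set(normed)) != len(normed):
            raise ValueError(f"duplicate markers in rule {self.name!r}")
        if self.positivity_min_count < 1:
            raise ValueError("positivity_min_count must be >= 1")


@dataclass
class GatingResult:
    """Per-cell subset assignments (a cell may carry several labels)."""

    assignments: dict[str, frozenset[str]]  # cell id -> labels
    rule_names: tuple[str, ...]

    @property
    def per_subset_counts(self) -> dict[str, int]:
        counts = {name: 0 for name in self.rule_names}
        for labels in self.assignments.values():
            for lab in labels:
                counts[lab] += 1
        return counts

    def members(self, label: str) -> list[str]:
        return [cid for cid, labels in self.assignments.items() if label in labels]

    def to_frame(self) -> pd.DataFrame:
        """Long-format (cell_id, label) table, one row per assignment."""
        rows = [
            (cid, lab)
            for cid, labels in self.assignments.items()
            for lab in sorted(labels)
        ]
        return pd.DataFrame(rows, columns=["cell_id", "label"])


def builtin_rules(positivity_min_count: int = 1) -> list[GatingRule]:
    """The five marker rules used throughout the pipeline."""
    spec = [
        (TARGET_LABEL, ("IL36G",)),
        ("Treg", ("CD4", "FOXP3", "IL2RA")),
        ("Th17", ("CD4", "IL17A", "RORC")),
        ("regTh17", ("IL17F", "IL26", "FOXP3")),
        ("NKT", ("CD8A", "NKG7", "KLRD1")),
    ]
    return [GatingRule(name, markers, positivity_min_count) for name, markers in spec]


def gate_cells(dataset: SpatialDataset, rules: list[GatingRule] | None = None) -> GatingResult:
    """Apply gating rules to raw counts.

    Raises
    ------
    MissingMarkersError
        If any rule marker is absent from the dataset panel (after name
        normalisation).
    """
    if rules is None:
        rules = builtin_rules()
    gene_index = {normalize_marker(g): i for i, g in enumerate(dataset.gene_names)}
    missing = {
        m
        for rule in rules
        for m in rule.required_markers
        if normalize_marker(m) not in gene_index
    }
    if missing:
        raise MissingMarkersError(missing)

    cell_ids = list(dataset.cells["cell_id"])
    n = len(cell_ids)
    per_rule_pass = {}
    for rule in rules:
        rows = [gene_index[normalize_marker(m)] for m in rule.required_markers]
        passing = (dataset.counts[rows, :] >= rule.positivity_min_count).all(axis=0)
        per_rule_pass[rule.name] = passing if n else np.zeros(0, dtype=bool)

    assignments = {
        cid: frozenset(
            name for name, passing in per_rule_pass.items() if passing[i]
        )
        for i, cid in enumerate(cell_ids)
    }
    return GatingResult(assignments=assignments, rule_names=tuple(r.name for r in rules))


def load_rules(path) -> list[GatingRule]:
    """Read rules from plain text: ``label: M1,M2[,...] [>= threshold]`` per line."""
    rules = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        label, rest = line.split(":", 1)
        threshold = 1
        if ">=" in rest:
            rest, thr = rest.split(">=", 1)
            threshold = int(thr)
        markers = tuple(m.strip() for m in rest.split(",") if m.strip())
        rules.append(GatingRule(label.strip(), markers, threshold))
    return rules
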