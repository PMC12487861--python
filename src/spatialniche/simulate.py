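"""Synthetic multi-FOV spatial datasets with planted niche structure.

The generator emulates the statistical shape of an imaging-based spatial
run on inflamed skin so every pipeline stage is testable without patient
data:

* cells of several types are scattered over rectangular tiles (FOVs) by a
  homogeneous Poisson process (a Thomas-style clustered anchor process is
  available to stress the enrichment statistic);
* a *niche* plants co-localisation: for an (attracted, anchor, radius,
  fraction) spec, the given fraction of the attracted type's cells is
  placed uniformly inside a disc of the given radius around a random
  anchor cell of the same FOV, the rest uniformly;
* transcript counts are negative binomial per gene with type-specific
  means. Marker means are high enough (default 6 counts at dispersion 10)
  that a planted cell passes its own marker gate with probability >= 0.95,
  and background means low enough that off-type cells pass with
  probability <= 0.05. Housekeeping genes keep per-cell totals above the
  spatial QC floor, and negative/system control probes are included so the
  QC path is exercised end to end.

Identical configuration (including the seed) yields a bit-identical
dataset, and the exported flat files are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DensityError
from .gating import TARGET_LABEL, builtin_rules
from .io_cosmx import SpatialDataset, write_flat_files

#: markers set high (per type) by the default count model
_RULE_MARKERS = {rule.name: rule.required_markers for rule in builtin_rules()}

DEFAULT_ABUNDANCES: dict[str, float] = {
    TARGET_LABEL: 60,
    "Treg": 40,
    "Th17": 40,
    "regTh17": 40,
    "NKT": 40,
    "Keratinocyte": 90,
    "Fibroblast": 70,
}

#: flavour genes giving the structural types an identity of their own
_TYPE_GENES = {"Keratinocyte": "KRT14", "Fibroblast": "COL1A1"}


@dataclass(frozen=True)
class NicheSpec:
    """One planted co-localisation rule."""

    attracted: str
    anchor: str
    radius: float = 15.0  # um
    fraction: float = 0.8

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("attraction radius must be positive")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction attracted must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults define the standard study conditions."""

    seed: int = 0
    n_fovs: int = 2
    fov_size: tuple[float, float] = (500.0, 500.0)  # um
    abundances: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ABUNDANCES)
    )
    niches: tuple[NicheSpec, ...] = (NicheSpec("regTh17", TARGET_LABEL, 15.0, 0.8),)
    marker_mean: float = 6.0
    background_mean: float = 0.005
    housekeeping_genes: int = 10
    housekeeping_mean: float = 8.0
    n_neg_probes: int = 10
    n_system_probes: int = 5
    control_probe_mean: float = 0.05
    dispersion: float = 10.0  # NB size parameter; larger = closer to Poisson
    min_spacing: float = 2.0  # um; density sanity bound, not enforced per pair
    clustered_anchors: bool = False
    anchor_cluster_sd: float = 40.0  # Thomas-process spread when clustered

    def __post_init__(self):
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError("abundances must be non-negative")
        for niche in self.niches:
            if niche.attracted not in self.abundances or niche.anchor not in self.abundances:
                raise ValueError(f"niche {niche} references an unknown cell type")

    def null(self) -> "SimConfig":
        """Copy of this config with all planted attraction removed."""
        return replace(self, niches=tuple())


def _gene_panel(config: SimConfig) -> list[str]:
    markers = sorted({m for ms in _RULE_MARKERS.values() for m in ms} | {"CD3E", "CTLA4"})
    flavour = [g for t, g in sorted(_TYPE_GENES.items()) if t in config.abundances]
    housekeeping = [f"HK{i + 1:02d}" for i in range(config.housekeeping_genes)]
    neg = [f"NegPrb{i + 1}" for i in range(config.n_neg_probes)]
    system = [f"SystemControl{i + 1}" for i in range(config.n_system_probes)]
    return markers + flavour + housekeeping + neg + system


def _mean_table(config: SimConfig) -> pd.DataFrame:
    """Per-type per-gene NB mean matrix (genes x types)."""
    genes = _gene_panel(config)
    types = sorted(config.abundances)
    means = pd.DataFrame(config.background_mean, index=genes, columns=types, dtype=float)
    means.loc[[g for g in genes if g.startswith("HK")], :] = config.housekeeping_mean
    controls = [g for g in genes if g.startswith(("NegPrb", "SystemControl"))]
    means.loc[controls, :] = config.control_probe_mean
    for cell_type, markers in _RULE_MARKERS.items():
        if cell_type in means.columns:
            means.loc[list(markers), cell_type] = config.marker_mean
    t_cell_types = [t for t in ("Treg", "Th17", "regTh17", "NKT") if t in means.columns]
    if t_cell_types:
        means.loc["CD3E", t_cell_types] = 2.0
    for t in ("Treg", "regTh17"):
        if t in means.columns:
            means.loc["CTLA4", t] = 1.5
    if "regTh17" in means.columns:
        means.loc["CD4", "regTh17"] = 1.0
    for cell_type, gene in _TYPE_GENES.items():
        if cell_type in means.columns:
            means.loc[gene, cell_type] = config.marker_mean
    return means


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, size, dispersion: float):
    """Negative binomial with the given means and common dispersion."""
    mean = np.broadcast_to(mean, size)
    out = np.zeros(size, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = dispersion / (dispersion + mean[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def generate_spatial(config: SimConfig) -> tuple[SpatialDataset, pd.Series, pd.Series]:
    """Generate one dataset.

    Returns
    -------
    (dataset, truth_labels, niche_membership):
        The dataset (labels already attached to its cells), the
        ground-truth label per cell id, and a boolean Series marking cells
        placed by a niche attraction rather than uniformly.
    """
    rng = np.random.default_rng(config.seed)
    width, height = config.fov_size
    expected = sum(config.abundances.values())
    capacity = (width * height) / (config.min_spacing**2)
    if expected > capacity:
        raise DensityError(
            f"{expected:.0f} expected cells exceed FOV capacity {capacity:.0f} "
            f"at min spacing {config.min_spacing} um"
        )

    anchor_types = {niche.anchor for niche in config.niches}
    attracted = {niche.attracted: niche for niche in config.niches}
    types = sorted(config.abundances)

    records = []  # (fov, local_x, local_y, label, planted)
    for fov in range(1, config.n_fovs + 1):
        positions: dict[str, np.ndarray] = {}
        # anchors (and every non-attracted type) first
        for cell_type in types:
            if cell_type in attracted:
                continue
            n = rng.poisson(config.abundances[cell_type])
            if cell_type in anchor_types and config.clustered_anchors and n > 0:
                n_parents = max(1, n // 10)
                parents = rng.uniform((0, 0), (width, height), size=(n_parents, 2))
                pick = rng.integers(0, n_parents, size=n)
                xy = parents[pick] + rng.normal(0, config.anchor_cluster_sd, size=(n, 2))
                xy = np.clip(xy, 0, (width, height))
            else:
                xy = rng.uniform((0, 0), (width, height), size=(n, 2))
            positions[cell_type] = xy
            for x, y in xy:
                records.append((fov, x, y, cell_type, False))
        # attracted types: fraction near a random anchor, remainder uniform
        for cell_type in types:
            niche = attracted.get(cell_type)
            if niche is None:
                continue
            n = rng.poisson(config.abundances[cell_type])
            anchors = positions.get(niche.anchor, np.empty((0, 2)))
            n_attr = rng.binomial(n, niche.fraction) if len(anchors) else 0
            for i in range(n):
                if i < n_attr:
                    a = anchors[rng.integers(0, len(anchors))]
                    while True:  # uniform in the disc, rejected back into the tile
                        r = niche.radius * math.sqrt(rng.uniform())
                        theta = rng.uniform(0, 2 * math.pi)
                        x, y = a[0] + r * math.cos(theta), a[1] + r * math.sin(theta)
                        if 0 <= x <= width and 0 <= y <= height:
                            break
                    records.append((fov, x, y, cell_type, True))
                else:
                    x, y = rng.uniform((0, 0), (width, height))
                    records.append((fov, x, y, cell_type, False))

    fov_gap = 100.0
    offsets = pd.DataFrame(
        {
            "x": [(fov - 1) * (width + fov_gap) for fov in range(1, config.n_fovs + 1)],
            "y": [0.0] * config.n_fovs,
        },
        index=pd.Index(range(1, config.n_fovs + 1), name="fov"),
    )

    per_fov_counter: dict[int, int] = {}
    rows = []
    for fov, x, y, label, planted in records:
        per_fov_counter[fov] = per_fov_counter.get(fov, 0) + 1
        cid = f"{fov}_c{per_fov_counter[fov]:04d}"
        rows.append((cid, fov, x + offsets.at[fov, "x"], y + offsets.at[fov, "y"], label, planted))
    cells = pd.DataFrame(rows, columns=["cell_id", "fov", "x", "y", "label", "planted"])

    means = _mean_table(config)
    genes = list(means.index)
    counts = np.zeros((len(genes), len(cells)), dtype=np.int64)
    for cell_type in types:
        mask = (cells["label"] == cell_type).to_numpy()
        n_t = int(mask.sum())
        if n_t == 0:
            continue
        mu = means[cell_type].to_numpy()[:, np.newaxis]
        counts[:, mask] = _nb_sample(rng, mu, (len(genes), n_t), config.dispersion)

    dataset = SpatialDataset(
        cells=cells[["cell_id", "fov", "x", "y", "label"]].copy(),
        counts=counts,
        gene_names=genes,
        fov_offsets=offsets,
        extras={},
    )
    dataset.validate()
    truth = cells.set_index("cell_id")["label"]
    membership = cells.set_index("cell_id")["planted"].astype(bool)
    return dataset, truth, membership


def export_run(config: SimConfig, directory) -> SpatialDataset:
    """Generate a dataset, write its flat files plus a ground-truth CSV."""
    from pathlib import Path

    dataset, truth, membership = generate_spatial(config)
    directory = Path(directory)
    write_flat_files(dataset, directory)
    pd.DataFrame({"label": truth, "in_niche": membership}).to_csv(
        directory / "ground_truth.csv", index_label="cell_id"
    )
    return dataset


def generate_count_matrix(
    n_cells: int = 100,
    n_genes: int = 300,
    n_mito_genes: int = 10,
    n_low_transcript: int = 0,
    n_low_gene: int = 0,
    n_high_mito: int = 0,
    n_boundary: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Genes x cells scRNA-Seq-style matrix with planted QC violations.

    Ordinary cells comfortably satisfy the default QC thresholds (about
    600 transcripts over ~250 detected genes, ~2% mitochondrial). Planted
    cells violate exactly one rule each: low-transcript cells (~300 total,
    >=100 genes, low mito), low-gene cells (~900 total on 60 genes),
    high-mito cells (~20% mitochondrial, otherwise ordinary). Boundary
    cells sit exactly on every threshold (500 transcripts, 100 genes, 10%
    mito) and must survive filtering.

    Returns the matrix and a dict mapping violation class to cell ids.
    """
    if n_genes <= n_mito_genes or n_mito_genes < 1:
        raise ValueError("need at least one mitochondrial and one nuclear gene")
    n_planted = n_low_transcript + n_low_gene + n_high_mito + n_boundary
    if n_planted > n_cells:
        raise ValueError("more planted cells than cells")
    rng = np.random.default_rng(seed)
    mito = [f"MT-G{i + 1}" for i in range(n_mito_genes)]
    nuclear = [f"G{i + 1:04d}" for i in range(n_genes - n_mito_genes)]
    genes = mito + nuclear
    mat = np.zeros((n_genes, n_cells), dtype=np.int64)

    def fill(col, mito_total, nuclear_means):
        mat[:n_mito_genes, col] = rng.multinomial(
            mito_total, np.full(n_mito_genes, 1 / n_mito_genes)
        )
        mat[n_mito_genes:, col] = rng.poisson(nuclear_means)

    ordinary_means = np.zeros(len(nuclear))
    ordinary_means[:250] = 2.4  # ~600 transcripts on ~250 genes
    planted: dict[str, list[str]] = {
        "low_transcript": [],
        "low_gene": [],
        "high_mito": [],
        "boundary": [],
    }
    col = 0
    for _ in range(n_low_transcript):
        m = np.zeros(len(nuclear))
        m[:150] = 2.0  # ~300 total, ~130 genes detected
        fill(col, mito_total=6, nuclear_means=m)
        planted["low_transcript"].append(f"cell{col + 1:04d}")
        col += 1
    for _ in range(n_low_gene):
        m = np.zeros(len(nuclear))
        m[:60] = 15.0  # ~900 total on <=60 genes
        fill(col, mito_total=18, nuclear_means=m)
        planted["low_gene"].append(f"cell{col + 1:04d}")
        col += 1
    for _ in range(n_high_mito):
        fill(col, mito_total=150, nuclear_means=ordinary_means)  # ~20% mito
        planted["high_mito"].append(f"cell{col + 1:04d}")
        col += 1
    for _ in range(n_boundary):
        # deterministic: 50 mito + 450 nuclear transcripts on exactly 100 genes
        mat[:, col] = 0
        mat[0, col] = 50 - (n_mito_genes - 1)
        mat[1:n_mito_genes, col] = 1
        n_nuc_genes = 100 - n_mito_genes
        mat[n_mito_genes : n_mito_genes + n_nuc_genes, col] = 5
        mat[n_mito_genes, col] = 450 - 5 * (n_nuc_genes - 1)
        planted["boundary"].append(f"cell{col + 1:04d}")
        col += 1
    for _ in range(n_cells - col):
        fill(col, mito_total=12, nuclear_means=ordinary_means)
        col += 1

    frame = pd.DataFrame(
        mat, index=genes, columns=[f"cell{i + 1:04d}" for i in range(n_cells)]
    )
    return frame, planted
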