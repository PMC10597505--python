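"""Experiment orchestration: SNV-mode pipeline, parameter grids, heatmaps.

A grid experiment varies exactly one simulation variable over a list of
values while holding everything else at the defaults, and repeats each
cell several times with deterministically derived seeds.  Every dataset
directory is self-describing via a manifest JSON.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix, build_G
from .io import (
    write_flags,
    write_labels,
    write_manifest,
    write_matrix,
)
from .noise import NoiseParams, ObservedMatrix, error_category_matrix, inject_doublets, make_D
from .tree import assign_cells, assign_mutations, grow_tree, write_newick

__all__ = [
    "SimConfig",
    "ExperimentGrid",
    "SnvDataset",
    "simulate_snv_dataset",
    "run_grid",
    "derive_seed",
    "render_heatmap",
    "summarize",
]

#: Benchmark grid: variable name -> values, defaults marked by SimConfig.
TABLE_GRID = {
    "fp_rate": [0.001, 0.01, 0.05],
    "fn_rate": [0.1, 0.2, 0.3, 0.4],
    "missing_rate": [0.2, 0.3],
    "n_cells": [100, 500, 1000, 1500],
    "n_mutations": [50, 200, 500],
    "n_clusters": [4, 8, 16, 32],
    "doublet_rate": [0.0, 0.01, 0.05, 0.1],
    "beta_split": [0.05, 0.2, 0.5],
}


@dataclass
class SimConfig:
    """Defaults of the SNV-mode benchmark grid."""

    n_cells: int = 500
    n_mutations: int = 200
    n_clusters: int = 8
    fp_rate: float = 0.01
    fn_rate: float = 0.2
    missing_rate: float = 0.2
    doublet_rate: float = 0.0
    beta_split: float = 0.2
    repetitions: int = 5
    seed: int = 0
    mode: str = "snv"  # "snv" | "lowcov"
    coverages: tuple = (0.01, 0.03, 0.05)
    ado_rate: float = 0.2
    seq_error: float = 0.01

    def __post_init__(self):
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.mode not in ("snv", "lowcov"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coverages"] = list(self.coverages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "coverages" in d:
            d["coverages"] = tuple(d["coverages"])
        return cls(**d)


@dataclass
class ExperimentGrid:
    varying: str
    values: list
    defaults: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        if self.varying not in TABLE_GRID and not hasattr(self.defaults, self.varying):
            raise ValueError(f"unknown variable {self.varying!r}")


@dataclass
class SnvDataset:
    tree: "object"
    assignment: "object"
    G: GenotypeMatrix
    G_doublet: GenotypeMatrix
    doublet_flags: np.ndarray
    D: ObservedMatrix

    @property
    def labels(self) -> np.ndarray:
        return self.G.clone_labels


def simulate_snv_dataset(config: SimConfig, seed=None) -> SnvDataset:
    """Full SNV-mode pipeline: tree -> G -> doublets -> noisy D."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tree = grow_tree(config.n_clusters, config.beta_split, rng)
    assign_mutations(tree, config.n_mutations, rng)
    assignment = assign_cells(tree, config.n_cells, rng)
    G = build_G(tree, assignment)
    G_doublet, flags = inject_doublets(G, config.doublet_rate, seed=rng)
    params = NoiseParams(
        fp_rate=config.fp_rate,
        fn_rate=config.fn_rate,
        missing_rate=config.missing_rate,
        doublet_rate=config.doublet_rate,
        seed=int(rng.integers(2**31)),
    )
    D = make_D(G_doublet, params, doublet_flags=flags)
    return SnvDataset(
        tree=tree, assignment=assignment, G=G, G_doublet=G_doublet, doublet_flags=flags, D=D
    )


def derive_seed(base_seed: int, variable: str, value, replicate: int) -> int:
    """Deterministic, well-separated child seed below 2^31."""
    key = f"{base_seed}|{variable}|{value!r}|{replicate}".encode()
    return zlib.crc32(key) % (2**31)


def _write_dataset(ds: SnvDataset, out: Path, transpose: bool = False) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(ds.G.values, out / "G.tsv")
    write_matrix(ds.D.values, out / "D.tsv", transpose=transpose)
    write_labels(ds.labels, out / "labels.tsv")
    write_flags(ds.doublet_flags, out / "doublets.tsv")
    write_newick(ds.tree, out / "tree.nwk")


def run_grid(grid: ExperimentGrid, out_dir, force: bool = False, transpose: bool = False) -> list[Path]:
    """Simulate every (value, replicate) cell of a one-variable grid.

    Returns the list of dataset directories, each with a manifest recording
    the exact configuration and derived seed.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force=True)")
    dirs = []
    for value in grid.values:
        for rep in range(grid.defaults.repetitions):
            cfg = SimConfig.from_dict({**grid.defaults.to_dict(), grid.varying: value})
            seed = derive_seed(grid.defaults.seed, grid.varying, value, rep)
            ds = simulate_snv_dataset(cfg, seed=seed)
            d = out_dir / f"{grid.varying}_{value}" / f"rep{rep}"
            _write_dataset(ds, d, transpose=transpose)
            manifest = cfg.to_dict()
            manifest.update({"varying": grid.varying, "value": value, "replicate": rep, "derived_seed": seed})
            write_manifest(manifest, d / "manifest.json")
            dirs.append(d)
    return dirs


# five-category palette: TN grey, TP light blue, FP dark red, FN dark blue, missing white
HEATMAP_COLORS = ["#b0b0b0", "#9ecae1", "#8b0000", "#00008b", "#ffffff"]


def heatmap_index_matrix(G, D, labels):
    """Category matrix (mutations x cells) with cells sorted clone-blocked."""
    g = np.asarray(G.values if hasattr(G, "values") else G)
    d = np.asarray(D.values if hasattr(D, "values") else D)
    labels = np.asarray(labels)
    order = np.argsort(labels, kind="stable")
    cat = error_category_matrix(g[order], d[order])
    return cat.T, labels[order]


def render_heatmap(G, D, labels, path, dpi: int = 150):
    """Raster heatmap of observation errors with a clone color bar on top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    cat, sorted_labels = heatmap_index_matrix(G, D, labels)
    fig, (ax_bar, ax) = plt.subplots(
        2, 1, figsize=(8, 6), gridspec_kw={"height_ratios": [1, 24]}, sharex=True
    )
    cmap = ListedColormap(HEATMAP_COLORS)
    ax.imshow(cat, aspect="auto", cmap=cmap, vmin=0, vmax=4, interpolation="nearest")
    ax.set_xlabel("cells (clone-blocked)")
    ax.set_ylabel("mutations")
    clone_cmap = plt.get_cmap("tab20")
    ax_bar.imshow(
        sorted_labels[None, :],
        aspect="auto",
        cmap=clone_cmap,
        interpolation="nearest",
    )
    ax_bar.set_yticks([])
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return cat


def summarize(reports, index=None) -> pd.DataFrame:
    """Median of each metric over replicate evaluation reports.

    ``reports`` may be a flat collection (one grid cell) or a mapping of
    grid-cell key -> collection of reports.
    """
    def med(rs):
        df = pd.DataFrame([asdict(r) for r in rs])
        return df.median(numeric_only=True)

    if isinstance(reports, dict):
        return pd.DataFrame({k: med(v) for k, v in reports.items()}).T
    out = med(list(reports)).to_frame().T
    if index is not None:
        out.index = [index]
    return out
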