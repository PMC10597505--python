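"""Ultra-low-coverage read-count model.

For data sequenced at ~0.01-0.05x per cell, whether a variant can be seen
at all is governed by the per-entry read depth.  The model caps depth at
two reads: for coverage c, each cell-site draws x ~ Uniform[0, 1) and gets
t = 2 reads if x < c^2, t = 1 if c^2 <= x < c, else t = 0.  Variant-
supporting reads v then depend on the true genotype: at reference sites
each read is a variant read with probability equal to the sequencing-error
rate; at (heterozygous) variant sites an allele-dropout event occurs with
probability ``ado_rate`` and silences either the reference allele (all
reads variant) or the variant allele (no variant reads) with equal
probability, otherwise each read is a fair coin between alleles.

The observed matrix follows the conservative rule D = 1 where v >= 1 and
D = 3 (missing) everywhere else: zero variant reads cannot be
distinguished from lack of coverage, so no 0 is ever emitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype import GenotypeMatrix, build_G
from .noise import MISSING, ObservedMatrix
from .tree import CellAssignment, ClonalTree, assign_cells, assign_mutations, grow_tree

__all__ = [
    "LowCovParams",
    "ReadCountPair",
    "sample_total_reads",
    "sample_variant_reads",
    "reads_to_D",
    "simulate_lowcov_dataset",
    "LowCovDataset",
]


@dataclass
class LowCovParams:
    coverage: float = 0.05
    ado_rate: float = 0.2
    seq_error: float = 0.01
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 < self.coverage < 0.5):
            raise ValueError(f"coverage={self.coverage} must be in (0, 0.5)")
        if not (0.0 <= self.ado_rate <= 1.0):
            raise ValueError("ado_rate must be in [0, 1]")
        if not (0.0 <= self.seq_error <= 1.0):
            raise ValueError("seq_error must be in [0, 1]")


@dataclass
class ReadCountPair:
    t: np.ndarray  # total reads, int8 in {0, 1, 2}
    v: np.ndarray  # variant-supporting reads, 0 <= v <= t


def sample_total_reads(coverage: float, shape, seed=None) -> np.ndarray:
    """Total read depths in {0, 1, 2}: P(t=2) = c^2, P(t=1) = c - c^2."""
    if not (0.0 < coverage < 0.5):
        raise ValueError(f"coverage={coverage} must be in (0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.random(shape)
    t = np.zeros(shape, dtype=np.int8)
    t[x < coverage] = 1
    t[x < coverage * coverage] = 2
    return t


def sample_variant_reads(
    G: np.ndarray | GenotypeMatrix,
    t: np.ndarray,
    ado_rate: float = 0.2,
    seq_error: float = 0.01,
    seed=None,
) -> np.ndarray:
    """Variant-supporting read counts given genotypes and total depths.

    Reference sites: v ~ Binomial(t, seq_error).  Variant (heterozygous)
    sites: one ADO decision per entry; ref-allele dropout gives v = t,
    variant-allele dropout gives v = 0, no dropout gives v ~ Binomial(t, 0.5).
    """
    g = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)
    if g.shape != t.shape:
        raise ValueError(f"shape mismatch: G {g.shape} vs t {t.shape}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    v = np.zeros(g.shape, dtype=np.int8)
    ref = g == 0
    v[ref] = rng.binomial(t[ref], seq_error)

    var = ~ref
    n_var = int(var.sum())
    if n_var:
        ado = rng.random(n_var) < ado_rate
        ref_dropped = rng.random(n_var) < 0.5  # which allele is silenced
        tv = t[var]
        vv = rng.binomial(tv, 0.5).astype(np.int8)  # no-ADO branch
        vv[ado & ref_dropped] = tv[ado & ref_dropped]  # only variant allele left
        vv[ado & ~ref_dropped] = 0  # variant allele silenced
        v[var] = vv
    if (v > t).any():
        raise AssertionError("internal error: v exceeds t")
    return v


def reads_to_D(t: np.ndarray, v: np.ndarray) -> ObservedMatrix:
    """Observed matrix: 1 where v >= 1, missing (3) everywhere else."""
    if (np.asarray(v) > np.asarray(t)).any():
        raise ValueError("v exceeds t")
    values = np.where(np.asarray(v) >= 1, 1, MISSING).astype(np.int8)
    return ObservedMatrix(
        values=values,
        doublet_flags=np.zeros(values.shape[0], dtype=bool),
    )


@dataclass
class LowCovDataset:
    tree: ClonalTree
    assignment: CellAssignment
    G: GenotypeMatrix
    reads: ReadCountPair
    D: ObservedMatrix

    @property
    def missing_fraction(self) -> float:
        return float((self.D.values == MISSING).mean())


def simulate_lowcov_dataset(
    n_cells: int = 4000,
    n_mutations: int = 5000,
    n_clusters: int = 8,
    coverage: float = 0.05,
    ado_rate: float = 0.2,
    seq_error: float = 0.01,
    beta_split: float = 0.2,
    seed=None,
) -> LowCovDataset:
    """End-to-end ultra-low-coverage simulation.

    Tree growth, mutation and cell assignment, and the true genotype matrix
    are exactly as in the SNV-mode simulator; the observed matrix comes
    from the read model instead of direct FP/FN/missing injection.
    """
    rng = np.random.default_rng(seed)
    tree = grow_tree(n_clusters, beta_split, rng)
    assign_mutations(tree, n_mutations, rng)
    assignment = assign_cells(tree, n_cells, rng)
    G = build_G(tree, assignment)
    t = sample_total_reads(coverage, G.values.shape, rng)
    v = sample_variant_reads(G, t, ado_rate=ado_rate, seq_error=seq_error, seed=rng)
    D = reads_to_D(t, v)
    return LowCovDataset(tree=tree, assignment=assignment, G=G, reads=ReadCountPair(t, v), D=D)
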