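"""Observed-matrix construction: doublets, missing entries, FP/FN flips.

The observed matrix D is what a clustering tool sees: 0 (reference),
1 (variant) or 3 (missing).  Noise is injected with exact-count semantics —
for a requested rate r and a pool of eligible entries of size n, exactly
round(r * n) entries are altered, chosen uniformly without replacement —
so the achieved rates match the requested ones as closely as rounding
allows.  A per-entry Bernoulli alternative is available via
``bernoulli=True``.

Order of operations: doublets are formed on true genotypes first, then
missing entries are punched, then false positives/negatives are flipped
among the remaining (non-missing) zeros and ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype import GenotypeMatrix

__all__ = [
    "MISSING",
    "NoiseParams",
    "ObservedMatrix",
    "inject_doublets",
    "make_D",
    "error_category_matrix",
    "CATEGORY_NAMES",
]

MISSING = 3

# error_category_matrix codes
TN, TP, FP, FN, MISS = 0, 1, 2, 3, 4
CATEGORY_NAMES = {TN: "TN", TP: "TP", FP: "FP", FN: "FN", MISS: "MISSING"}


@dataclass
class NoiseParams:
    """Rates for the observed-matrix noise model.

    Defaults are the benchmark grid's default row: FP 0.01, FN 0.2,
    missing 0.2, no doublets.
    """

    fp_rate: float = 0.01
    fn_rate: float = 0.2
    missing_rate: float = 0.2
    doublet_rate: float = 0.0
    seed: int | None = None
    bernoulli: bool = False

    def __post_init__(self):
        for name in ("fp_rate", "fn_rate", "missing_rate", "doublet_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name}={v} must be in [0, 1)")


@dataclass
class ObservedMatrix:
    values: np.ndarray  # N' x M, int8 in {0, 1, 3}
    doublet_flags: np.ndarray  # length-N' bool
    missing_mask: np.ndarray = field(repr=False, default=None)
    fp_mask: np.ndarray = field(repr=False, default=None)  # flipped 0 -> 1
    fn_mask: np.ndarray = field(repr=False, default=None)  # flipped 1 -> 0

    @property
    def shape(self):
        return self.values.shape


def inject_doublets(
    G: GenotypeMatrix,
    doublet_rate: float,
    seed=None,
    partner_other_clone: bool = True,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Replace round(rate*N) rows by the OR of the row and a partner cell's.

    A doublet is two cells captured together; its apparent genotype carries
    the union of both cells' mutations.  The partner is drawn uniformly,
    from a different clone by default.  Flagged cells are excluded from all
    evaluation metrics downstream.
    """
    N = G.n_cells
    n_doublets = int(round(doublet_rate * N))
    flags = np.zeros(N, dtype=bool)
    values = G.values.copy()
    if n_doublets == 0:
        return (
            GenotypeMatrix(values, G.cell_ids.copy(), G.mutation_ids.copy(), G.clone_labels.copy()),
            flags,
        )
    if len(np.unique(G.clone_labels)) < 2 and partner_other_clone:
        raise ValueError("doublets with a different-clone partner need at least 2 clones")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(N, size=n_doublets, replace=False)
    for i in chosen:
        if partner_other_clone:
            pool = np.flatnonzero(G.clone_labels != G.clone_labels[i])
        else:
            pool = np.delete(np.arange(N), i)
        j = int(rng.choice(pool))
        values[i] = values[i] | G.values[j]
    flags[chosen] = True
    return (
        GenotypeMatrix(values, G.cell_ids.copy(), G.mutation_ids.copy(), G.clone_labels.copy()),
        flags,
    )


def _pick(rng: np.random.Generator, flat_idx: np.ndarray, count: int) -> np.ndarray:
    if count > flat_idx.size:
        raise ValueError(
            f"requested {count} flips but only {flat_idx.size} eligible entries"
        )
    return rng.choice(flat_idx, size=count, replace=False)


def make_D(
    G: GenotypeMatrix,
    params: NoiseParams,
    doublet_flags: np.ndarray | None = None,
) -> ObservedMatrix:
    """Build the ternary observed matrix from (possibly doublet-bearing) G.

    Stage 1: exactly round(missing_rate * N * M) entries become 3.
    Stage 2: among remaining 0s, round(fp_rate * #0) flip to 1; among
    remaining 1s, round(fn_rate * #1) flip to 0.
    """
    rng = np.random.default_rng(params.seed)
    values = G.values.astype(np.int8).copy()
    N, M = values.shape
    if doublet_flags is None:
        doublet_flags = np.zeros(N, dtype=bool)

    missing_mask = np.zeros((N, M), dtype=bool)
    fp_mask = np.zeros((N, M), dtype=bool)
    fn_mask = np.zeros((N, M), dtype=bool)
    flat = values.ravel()

    if params.bernoulli:
        miss = rng.random(N * M) < params.missing_rate
        zeros = (flat == 0) & ~miss
        ones = (flat == 1) & ~miss
        fp = zeros & (rng.random(N * M) < params.fp_rate)
        fn = ones & (rng.random(N * M) < params.fn_rate)
        missing_mask.ravel()[miss] = True
        fp_mask.ravel()[fp] = True
        fn_mask.ravel()[fn] = True
    else:
        n_missing = int(round(params.missing_rate * N * M))
        miss_idx = _pick(rng, np.arange(N * M), n_missing)
        missing_mask.ravel()[miss_idx] = True
        mflat = missing_mask.ravel()
        zero_idx = np.flatnonzero((flat == 0) & ~mflat)
        one_idx = np.flatnonzero((flat == 1) & ~mflat)
        fp_idx = _pick(rng, zero_idx, int(round(params.fp_rate * zero_idx.size)))
        fn_idx = _pick(rng, one_idx, int(round(params.fn_rate * one_idx.size)))
        fp_mask.ravel()[fp_idx] = True
        fn_mask.ravel()[fn_idx] = True

    values[fp_mask] = 1
    values[fn_mask] = 0
    values[missing_mask] = MISSING
    return ObservedMatrix(
        values=values,
        doublet_flags=doublet_flags.copy(),
        missing_mask=missing_mask,
        fp_mask=fp_mask,
        fn_mask=fn_mask,
    )


def error_category_matrix(G: np.ndarray | GenotypeMatrix, D: np.ndarray | ObservedMatrix) -> np.ndarray:
    """Per-entry comparison of D against G: TN/TP/FP/FN/MISSING codes."""
    g = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)
    d = D.values if isinstance(D, ObservedMatrix) else np.asarray(D)
    if g.shape != d.shape:
        raise ValueError(f"shape mismatch: G {g.shape} vs D {d.shape}")
    cat = np.empty(g.shape, dtype=np.int8)
    cat[(g == 0) & (d == 0)] = TN
    cat[(g == 1) & (d == 1)] = TP
    cat[(g == 0) & (d == 1)] = FP
    cat[(g == 1) & (d == 0)] = FN
    cat[d == MISSING] = MISS
    return cat
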