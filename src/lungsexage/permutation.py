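"""Label-permutation null for discovery counts.

The discovery scan reports how many genes pass FDR < 0.05; to calibrate
that count against chance, the variable of interest (sex or age) is
shuffled across samples many times and the full scan (OLS + BH) is re-run
on each shuffle.  Covariates stay attached to their samples — only the
variable of interest is permuted.  Two statistics are accumulated per
cycle: the total number of FDR-significant genes, and, for each candidate
gene, whether it was significant in that cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .association import AssociationConfig, bh_adjust, build_design, _scan
from .preprocess import GeneMatrix

__all__ = ["PermutationSummary", "permutation_null"]


@dataclass
class PermutationSummary:
    """Per-cycle significant-gene counts and candidate-level null rates."""

    n_permutations: int
    threshold: float
    counts: np.ndarray  # per-cycle number of FDR-significant genes
    per_gene_null_freq: pd.Series  # candidate gene -> cycles significant

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.size != self.n_permutations:
            raise ValueError("counts length must equal n_permutations")

    @property
    def expected_count(self) -> float:
        """Mean number of significant genes per permutation cycle."""
        return float(self.counts.mean())

    @property
    def n_zero(self) -> int:
        """Number of cycles with zero significant genes."""
        return int((self.counts == 0).sum())

    @property
    def fraction_zero(self) -> float:
        return self.n_zero / self.n_permutations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cycle": np.arange(1, self.n_permutations + 1), "n_significant": self.counts}
        )


def permutation_null(
    matrix: GeneMatrix,
    cfg: AssociationConfig,
    candidates: Sequence[str] = (),
    n_permutations: int = 1000,
    seed: int = 0,
    permuter: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> PermutationSummary:
    """Run the label-permutation null.

    ``permuter(rng, n)`` must return an index permutation of length n; the
    default draws uniform permutations.  Passing ``lambda rng, n:
    np.arange(n)`` forces identity permutations (test hook).  Deterministic
    for a fixed seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    candidates = list(candidates)
    unknown = [c for c in candidates if c not in matrix.expr.columns]
    if unknown:
        raise ValueError(f"candidates absent from the matrix: {unknown[:5]}")

    X, kept = build_design(matrix.samples, cfg)
    Y = matrix.expr.loc[kept].to_numpy(dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    draw = permuter or (lambda r, k: r.permutation(k))
    cand_pos = matrix.expr.columns.get_indexer(candidates)

    counts = np.empty(n_permutations, dtype=int)
    freq = np.zeros(len(candidates), dtype=int)
    Xp = X.copy()
    base_var = X[:, 1].copy()
    for cycle in range(n_permutations):
        Xp[:, 1] = base_var[draw(rng, n)]
        _, _, _, pvals, _ = _scan(Xp, Y)
        sig = bh_adjust(pvals) < cfg.fdr_threshold
        counts[cycle] = int(sig.sum())
        if len(candidates):
            freq += sig[cand_pos]

    return PermutationSummary(
        n_permutations=n_permutations,
        threshold=cfg.fdr_threshold,
        counts=counts,
        per_gene_null_freq=pd.Series(freq, index=pd.Index(candidates, name="gene")),
    )
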