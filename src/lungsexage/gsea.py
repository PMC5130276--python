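"""Gene set enrichment by a Kolmogorov-Smirnov running-sum statistic.

Genes are ranked by the t statistic of the per-gene association model; a
gene set's enrichment score (ES) is the signed extremum of a running sum
that increments at ranked positions of set members and decrements
elsewhere.  With weight exponent 0 (the default) the increment is uniform,
giving the classic KS form; weight 1 weights hits by |score| for parity
with common GSEA software.  Significance comes from phenotype permutation:
the variable of interest is shuffled, t statistics recomputed, genes
re-ranked and the ES recomputed under the null.  Significant sets are
connected into an enrichment map, a graph whose edges link sets with
overlap coefficient |A∩B| / min(|A|, |B|) at or above a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .association import AssociationConfig, bh_adjust, build_design, fit_associations, _scan
from .preprocess import GeneMatrix

__all__ = [
    "GeneSetCollection",
    "EnrichmentScore",
    "rank_genes",
    "filter_sets",
    "enrichment_score",
    "enrichment_significance",
    "build_enrichment_map",
    "overlap_coefficient",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (member lists deduplicated, order-preserving)."""

    sets: dict[str, tuple[str, ...]]
    source: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for name, members in self.sets.items():
            members = tuple(dict.fromkeys(members))
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = members
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def sizes(self) -> pd.Series:
        return pd.Series({k: len(v) for k, v in self.sets.items()}, name="size")


@dataclass
class EnrichmentScore:
    es: float
    running_sum: np.ndarray
    leading_edge: list[str]


def rank_genes(assoc: pd.DataFrame) -> pd.Series:
    """Genes ordered by descending t statistic, ties broken alphabetically.

    Returns the t statistics as a Series in ranked order.
    """
    t = assoc["t_stat"].to_numpy(dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("t statistics must be finite")
    genes = assoc.index.to_numpy()
    order = np.lexsort((genes, -t))
    return pd.Series(t[order], index=pd.Index(genes[order], name="gene"))


def filter_sets(
    collection: GeneSetCollection,
    universe: Sequence[str],
    min_size: int = 15,
    max_size: int = 500,
) -> GeneSetCollection:
    """Intersect each set with the analysis universe, then keep sets whose
    post-intersection size lies in [min_size, max_size] (inclusive)."""
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    uni = set(universe)
    kept = {}
    for name, members in collection.sets.items():
        inside = tuple(g for g in members if g in uni)
        if min_size <= len(inside) <= max_size:
            kept[name] = inside
    return GeneSetCollection(sets=kept, source=collection.source)


def _es_from_positions(
    positions: np.ndarray, n_total: int, hit_weights: np.ndarray | None = None
) -> tuple[float, int]:
    """ES and extremum position from sorted 0-based hit positions.

    With ``hit_weights`` None the classic KS increments 1/N_hit are used;
    otherwise increments are hit_weights / sum(hit_weights) (weights must be
    aligned with the sorted positions).  Returns (es, extremum_rank).
    """
    k = positions.size
    miss_step = 1.0 / (n_total - k)
    if hit_weights is None:
        cum_hit = np.arange(1, k + 1) / k
    else:
        cum_hit = np.cumsum(hit_weights) / hit_weights.sum()
    # running sum just after each hit, and just before each hit
    after = cum_hit - (positions + 1 - np.arange(1, k + 1)) * miss_step
    before = np.concatenate([[0.0], cum_hit[:-1]]) - (
        positions - np.arange(k)
    ) * miss_step
    imax = int(np.argmax(after))
    imin = int(np.argmin(before))
    hi, lo = after[imax], before[imin]
    if hi >= -lo:
        return float(hi), int(positions[imax])
    return float(lo), int(positions[imin])


def enrichment_score(
    ranked: pd.Series | Sequence[str],
    set_members: Sequence[str],
    weight: float = 0.0,
    scores: Sequence[float] | None = None,
) -> EnrichmentScore:
    """Running-sum enrichment score of one gene set against a ranking.

    ``ranked`` is either a Series (index = genes in rank order, values =
    scores) or a plain gene sequence with ``scores`` given separately
    (required when weight > 0).  Hits increment the running sum by
    |score|^weight normalized over in-set scores (uniform at weight 0);
    misses decrement by 1/(N - N_set).  The ES is the signed extremum;
    the leading edge collects the hits at or before a positive extremum
    (at or after a negative one).
    """
    if isinstance(ranked, pd.Series):
        genes = list(ranked.index)
        score_arr = ranked.to_numpy(dtype=float)
    else:
        genes = list(ranked)
        score_arr = None if scores is None else np.asarray(scores, dtype=float)
    n = len(genes)
    members = set(set_members)
    hit = np.array([g in members for g in genes], dtype=bool)
    k = int(hit.sum())
    if k == 0:
        raise ValueError("gene set has no members in the ranking")
    if k == n:
        raise ValueError("gene set equals the whole universe")

    if weight == 0:
        inc = np.full(n, 1.0 / k)
    else:
        if score_arr is None:
            raise ValueError("weighted enrichment requires ranking scores")
        w = np.abs(score_arr) ** weight
        inc = w / w[hit].sum()
    steps = np.where(hit, inc, -1.0 / (n - k))
    running = np.cumsum(steps)
    imax, imin = int(np.argmax(running)), int(np.argmin(running))
    if running[imax] >= -running[imin]:
        es, pivot = float(running[imax]), imax
        leading = [g for j, g in enumerate(genes) if hit[j] and j <= pivot]
    else:
        es, pivot = float(running[imin]), imin
        leading = [g for j, g in enumerate(genes) if hit[j] and j >= pivot]
    return EnrichmentScore(es=es, running_sum=running, leading_edge=leading)


def enrichment_significance(
    matrix: GeneMatrix,
    cfg: AssociationConfig,
    collection: GeneSetCollection,
    n_permutations: int = 1000,
    seed: int = 0,
    weight: float = 0.0,
) -> pd.DataFrame:
    """Permutation significance for every set in the collection.

    Sets are intersected with the matrix's gene universe (they should
    already be size-filtered via :func:`filter_sets`).  The null shuffles
    the variable of interest, recomputes t statistics and re-ranks;
    p = (1 + #{null |ES| >= |observed ES|}) / (n_permutations + 1), NES is
    the ES divided by the mean |null ES| of matching sign, and BH runs
    across all tested sets.

    Returns a set-indexed frame with columns es, nes, p_value, fdr,
    size_after_filter, leading_edge.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    genes = list(matrix.expr.columns)
    uni = set(genes)
    members_by_set = {
        name: tuple(g for g in mem if g in uni) for name, mem in collection.sets.items()
    }
    empty = [name for name, mem in members_by_set.items() if not mem]
    if empty:
        raise ValueError(f"sets with no genes in the universe: {empty[:5]}")

    observed = fit_associations(matrix, cfg)
    ranked = rank_genes(observed)
    obs: dict[str, EnrichmentScore] = {
        name: enrichment_score(ranked, mem, weight=weight)
        for name, mem in members_by_set.items()
    }

    X, kept = build_design(matrix.samples, cfg)
    Y = matrix.expr.loc[kept].to_numpy(dtype=float)
    n = X.shape[0]
    gene_arr = np.array(genes)
    set_names = list(members_by_set)
    pos_of = {g: i for i, g in enumerate(genes)}
    member_idx = {
        name: np.array([pos_of[g] for g in mem]) for name, mem in members_by_set.items()
    }

    rng = np.random.default_rng(seed)
    base_var = X[:, 1].copy()
    Xp = X.copy()
    null_es = np.empty((n_permutations, len(set_names)))
    n_genes = len(genes)
    for b in range(n_permutations):
        Xp[:, 1] = base_var[rng.permutation(n)]
        _, _, t, _, _ = _scan(Xp, Y)
        order = np.lexsort((gene_arr, -t))
        inv = np.empty(n_genes, dtype=int)
        inv[order] = np.arange(n_genes)
        if weight != 0:
            t_ranked_abs = np.abs(t[order]) ** weight
        for j, name in enumerate(set_names):
            pos = np.sort(inv[member_idx[name]])
            hw = t_ranked_abs[pos] if weight != 0 else None
            null_es[b, j], _ = _es_from_positions(pos, n_genes, hw)

    rows = []
    for j, name in enumerate(set_names):
        es = obs[name].es
        nulls = null_es[:, j]
        p = (1.0 + np.sum(np.abs(nulls) >= abs(es))) / (n_permutations + 1.0)
        matching = nulls[np.sign(nulls) == np.sign(es)] if es != 0 else nulls
        denom = np.abs(matching).mean() if matching.size else np.nan
        rows.append(
            {
                "set": name,
                "es": es,
                "nes": es / denom if denom and np.isfinite(denom) else np.nan,
                "p_value": p,
                "size_after_filter": len(members_by_set[name]),
                "leading_edge": ",".join(obs[name].leading_edge),
            }
        )
    result = pd.DataFrame(rows).set_index("set")
    result["fdr"] = bh_adjust(result["p_value"].to_numpy())
    result.attrs.update(
        variable=cfg.variable, n_permutations=n_permutations, weight=weight, seed=seed
    )
    return result[["es", "nes", "p_value", "fdr", "size_after_filter", "leading_edge"]]


def overlap_coefficient(a: Sequence[str], b: Sequence[str]) -> float:
    """|A ∩ B| / min(|A|, |B|)."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / min(len(sa), len(sb))


def build_enrichment_map(
    result: pd.DataFrame,
    collection: GeneSetCollection,
    fdr_cutoff: float = 0.05,
    overlap_cutoff: float = 0.5,
) -> nx.Graph:
    """Enrichment-map graph over significant sets.

    Nodes are sets with FDR < ``fdr_cutoff`` (attributes: size, es, fdr);
    an edge joins two sets whose overlap coefficient is at least
    ``overlap_cutoff`` (inclusive), weighted by the shared-gene count.
    """
    sig = [s for s in result.index if result.at[s, "fdr"] < fdr_cutoff]
    g = nx.Graph()
    for s in sig:
        if s not in collection.sets:
            raise KeyError(f"set {s!r} missing from the collection")
        g.add_node(
            s,
            size=len(collection.sets[s]),
            es=float(result.at[s, "es"]),
            fdr=float(result.at[s, "fdr"]),
        )
    for i, a in enumerate(sig):
        for b in sig[i + 1 :]:
            coef = overlap_coefficient(collection.sets[a], collection.sets[b])
            if coef >= overlap_cutoff:
                shared = len(set(collection.sets[a]) & set(collection.sets[b]))
                g.add_edge(a, b, weight=shared, overlap=coef)
    return g
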