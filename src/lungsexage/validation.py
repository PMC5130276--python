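"""Multi-cohort validation of discovery candidates.

Candidates found in the discovery cohort are re-tested in each validation
cohort; BH correction is applied within the candidate subset actually
present on the cohort's platform.  A gene is validated in a cohort when it
is significant there with the same direction of effect as in discovery.
Genes significant anywhere with the opposite direction are
"contra-regulated" and excluded from every validated list.  The common set
is the intersection of per-cohort validated lists; a Venn-style region
count over "significant in dataset d" membership is also produced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import AssociationConfig, fit_associations
from .preprocess import GeneMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CohortResult",
    "ValidationReport",
    "test_candidates",
    "intersect_concordant",
    "annotate_chromosomal",
]

_AUTOSOMES = {str(c) for c in range(1, 23)}


@dataclass
class CohortResult:
    cohort: str
    table: pd.DataFrame  # association table over tested candidates
    n_candidates_tested: int
    missing_candidates: list[str]


@dataclass
class ValidationReport:
    datasets: list[str]  # discovery first, then cohorts, fixes venn bit order
    validated: dict[str, list[str]]  # cohort -> validated gene list
    common_set: list[str]
    contra_regulated: list[str]
    venn_counts: dict[tuple[int, ...], int]

    def venn_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "".join(map(str, region)), "count": count}
            for region, count in sorted(self.venn_counts.items(), reverse=True)
        ]
        return pd.DataFrame(rows)


def test_candidates(
    matrix: GeneMatrix,
    cfg: AssociationConfig,
    candidates: Sequence[str],
    cohort: str | None = None,
) -> CohortResult:
    """Re-test discovery candidates in one cohort.

    The association model (with the cohort's covariates) is fit on the
    candidate genes present on the platform; BH runs across exactly that
    subset.  Candidates absent from the cohort are recorded as missing.
    """
    candidates = list(dict.fromkeys(candidates))
    if not candidates:
        raise ValueError("candidate list is empty")
    present = [g for g in candidates if g in matrix.expr.columns]
    missing = [g for g in candidates if g not in matrix.expr.columns]
    if not present:
        raise ValueError("no candidates present on this cohort's platform")
    sub = GeneMatrix(
        expr=matrix.expr.loc[:, present],
        samples=matrix.samples,
        genes=matrix.genes.loc[present],
    )
    table = fit_associations(sub, cfg)
    name = cohort or str(matrix.samples["cohort"].iloc[0])
    return CohortResult(
        cohort=name,
        table=table,
        n_candidates_tested=len(present),
        missing_candidates=missing,
    )


def intersect_concordant(
    discovery: pd.DataFrame,
    cohorts: Sequence[CohortResult],
    threshold: float = 0.05,
) -> ValidationReport:
    """Intersect per-cohort validated lists with direction concordance.

    ``discovery`` is the discovery association table restricted to (or at
    least covering) the candidate genes; its signs define the reference
    directions.  Venn membership is significance (FDR < threshold) per
    dataset, with discovery counted as significant for every candidate it
    deems significant.
    """
    candidates = list(discovery.index)
    disc_dir = np.sign(discovery["beta"])

    sig_by_dataset: dict[str, set[str]] = {
        "discovery": set(discovery.index[discovery["fdr"] < threshold])
    }
    validated: dict[str, list[str]] = {}
    contra: set[str] = set()
    for res in cohorts:
        tab = res.table
        sig = tab.index[tab["fdr"] < threshold]
        sig_by_dataset[res.cohort] = set(sig)
        same, opposite = [], []
        for g in sig:
            d_cohort = np.sign(tab.at[g, "beta"])
            d_disc = disc_dir.get(g, 0)
            if d_cohort == 0 or d_disc == 0:
                logger.warning("gene %s has undefined direction; treated as non-concordant", g)
                continue
            (same if d_cohort == d_disc else opposite).append(g)
        validated[res.cohort] = same
        contra.update(opposite)

    # contra-regulated genes are excluded from every validated list
    for name in validated:
        validated[name] = sorted(g for g in validated[name] if g not in contra)

    common: set[str] | None = None
    for name in validated:
        s = set(validated[name])
        common = s if common is None else (common & s)
    common_set = sorted(common or set())

    datasets = ["discovery"] + [res.cohort for res in cohorts]
    venn: dict[tuple[int, ...], int] = {}
    for g in candidates:
        region = tuple(int(g in sig_by_dataset[d]) for d in datasets)
        if any(region):
            venn[region] = venn.get(region, 0) + 1

    return ValidationReport(
        datasets=datasets,
        validated=validated,
        common_set=common_set,
        contra_regulated=sorted(contra),
        venn_counts=venn,
    )


def annotate_chromosomal(
    genes: Sequence[str],
    gene_annotation: Mapping[str, str] | pd.Series,
    directions: Mapping[str, float] | pd.Series | None = None,
) -> dict[str, int]:
    """Chromosomal bookkeeping for a validated gene set.

    Counts genes on autosomes (with the number of distinct autosomes
    involved), on non-pseudoautosomal X and Y, and in the pseudoautosomal
    regions (chromosome "X;Y").  If per-gene directions (sign of the
    discovery coefficient) are supplied, up/down counts are included.
    """
    genes = list(genes)
    ann = dict(gene_annotation.items()) if hasattr(gene_annotation, "items") else dict(gene_annotation)
    missing = [g for g in genes if g not in ann or str(ann[g]) == ""]
    if missing:
        raise ValueError(f"unannotated genes: {missing[:5]}")
    chroms = [str(ann[g]) for g in genes]
    auto = [c for c in chroms if c in _AUTOSOMES]
    out = {
        "n_genes": len(genes),
        "autosomal": len(auto),
        "distinct_autosomes": len(set(auto)),
        "x_linked": sum(c == "X" for c in chroms),
        "y_linked": sum(c == "Y" for c in chroms),
        "pseudoautosomal": sum(c == "X;Y" for c in chroms),
    }
    if directions is not None:
        d = dict(directions.items()) if hasattr(directions, "items") else dict(directions)
        out["up"] = sum(1 for g in genes if d.get(g, 0) > 0)
        out["down"] = sum(1 for g in genes if d.get(g, 0) < 0)
    return out
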