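"""TSV/GMT input-output, run configuration and pipeline orchestration.

All on-disk formats are plain text: probe-level studies as four TSV files
(expr.tsv and detection.tsv with probes as rows and samples as columns,
samples.tsv, probes.tsv), gene-level matrices as genes x samples TSV with a
one-line provenance comment header, gene sets as standard GMT.  The
``run_full_analysis`` entry point ties the stages together for the two
analysis arms (sex and age): preprocessing, discovery scans, the
permutation null, candidate validation in every validation cohort,
intersection with chromosomal bookkeeping, and gene set enrichment.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import AssociationConfig, fit_associations
from .gsea import (
    GeneSetCollection,
    build_enrichment_map,
    enrichment_significance,
    filter_sets,
)
from .permutation import permutation_null
from .preprocess import GeneMatrix, PreprocessConfig, preprocess_study
from .synthetic import EffectTruth, ExpressionStudy
from .validation import annotate_chromosomal, intersect_concordant, test_candidates

logger = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "write_study",
    "read_study",
    "write_truth",
    "write_gene_matrix",
    "read_gene_matrix",
    "CohortConfig",
    "RunConfig",
    "run_full_analysis",
]


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate member symbols within a set are dropped; a duplicate set name
    is an error; an empty file yields an empty collection with a warning.
    """
    path = Path(path)
    sets: dict[str, tuple[str, ...]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members = tuple(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = members
    if not sets:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
        return GeneSetCollection(sets={}, source=str(path))
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, collection.source or "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# study / matrix TSV formats


def write_study(study: ExpressionStudy, directory: str | Path) -> None:
    """Write a probe-level study as expr/detection/samples/probes TSVs
    (expression and detection with probes as rows, samples as columns)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study.expr.T.to_csv(directory / "expr.tsv", sep="\t", index_label="probe_id")
    study.detection_p.T.to_csv(directory / "detection.tsv", sep="\t", index_label="probe_id")
    study.samples.to_csv(directory / "samples.tsv", sep="\t")
    study.probes.to_csv(directory / "probes.tsv", sep="\t")


def read_study(directory: str | Path) -> ExpressionStudy:
    directory = Path(directory)
    expr = pd.read_csv(directory / "expr.tsv", sep="\t", index_col=0).T
    det = pd.read_csv(directory / "detection.tsv", sep="\t", index_col=0).T
    samples = pd.read_csv(directory / "samples.tsv", sep="\t", index_col=0)
    probes = pd.read_csv(
        directory / "probes.tsv", sep="\t", index_col=0, keep_default_na=False
    )
    expr = expr.rename_axis(index="sample_id", columns="probe_id")
    det = det.rename_axis(index="sample_id", columns="probe_id")
    return ExpressionStudy(expr=expr, detection_p=det, samples=samples, probes=probes)


def write_truth(truth: EffectTruth, path: str | Path) -> None:
    """Persist the planted-effect table for test harnesses."""
    truth.genes.to_csv(Path(path), sep="\t", index_label="symbol")


def _provenance(seed: int | None, config_repr: str = "") -> str:
    digest = hashlib.sha1(config_repr.encode()).hexdigest()[:12]
    return f"# lungsexage v{__version__} seed={seed} config={digest}"


def write_gene_matrix(
    matrix: GeneMatrix,
    directory: str | Path,
    seed: int | None = None,
    config_repr: str = "",
) -> None:
    """Write a gene-level matrix (genes x samples TSV with provenance
    header) plus its sample and gene annotation sheets."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with (directory / "matrix.tsv").open("w") as fh:
        fh.write(_provenance(seed, config_repr) + "\n")
        matrix.expr.T.to_csv(fh, sep="\t", index_label="gene_symbol")
    matrix.samples.to_csv(directory / "samples.tsv", sep="\t")
    matrix.genes.to_csv(directory / "genes.tsv", sep="\t", index_label="gene_symbol")


def read_gene_matrix(directory: str | Path) -> GeneMatrix:
    directory = Path(directory)
    expr = pd.read_csv(directory / "matrix.tsv", sep="\t", index_col=0, comment="#").T
    expr = expr.rename_axis(index="sample_id", columns="gene_symbol")
    samples = pd.read_csv(directory / "samples.tsv", sep="\t", index_col=0)
    genes_path = directory / "genes.tsv"
    if genes_path.exists():
        genes = pd.read_csv(genes_path, sep="\t", index_col=0, keep_default_na=False)
    else:
        genes = pd.DataFrame(index=expr.columns)
        genes["chromosome"] = ""
        genes["detection_rate"] = np.nan
        genes["probe_id"] = ""
    return GeneMatrix(expr=expr, samples=samples, genes=genes)


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None, config_repr: str = "") -> None:
    """TSV with a one-line provenance comment header."""
    with Path(path).open("w") as fh:
        fh.write(_provenance(seed, config_repr) + "\n")
        df.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# run configuration and orchestration


@dataclass
class CohortConfig:
    name: str
    role: str  # {"discovery", "validation"}
    level: str  # {"probe", "gene"}
    path: str
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ("discovery", "validation"):
            raise ValueError(f"unknown cohort role {self.role!r}")
        if self.level not in ("probe", "gene"):
            raise ValueError(f"unknown cohort level {self.level!r}")
        self.covariates = tuple(self.covariates)


@dataclass
class RunConfig:
    cohorts: list[CohortConfig]
    output_dir: str
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    fdr_threshold: float = 0.05
    n_permutations: int = 100
    gene_sets: str | None = None
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    gsea_n_permutations: int = 200
    gsea_fdr_cutoff: float = 0.05
    gsea_overlap_cutoff: float = 0.5
    gsea_weight: float = 0.0

    def __post_init__(self) -> None:
        n_disc = sum(1 for c in self.cohorts if c.role == "discovery")
        if n_disc != 1:
            raise ValueError(f"exactly one discovery cohort required, found {n_disc}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cohorts = [CohortConfig(**c) for c in raw.pop("cohorts")]
        pre = PreprocessConfig(**raw.pop("preprocess", {}))
        return cls(cohorts=cohorts, preprocess=pre, **raw)

    @property
    def discovery(self) -> CohortConfig:
        return next(c for c in self.cohorts if c.role == "discovery")

    @property
    def validations(self) -> list[CohortConfig]:
        return [c for c in self.cohorts if c.role == "validation"]


def _load_cohort(cohort: CohortConfig, pre: PreprocessConfig) -> GeneMatrix:
    if cohort.level == "probe":
        study = read_study(cohort.path)
        return preprocess_study(study, pre)
    return read_gene_matrix(cohort.path)


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full discovery-validation pipeline for both arms.

    Writes association, permutation, validation, intersection and
    enrichment tables plus a run log under ``config.output_dir``;
    deterministic for a fixed seed.  Returns a summary report dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_repr = repr(config)
    log_lines = [f"lungsexage v{__version__} seed={config.seed}"]

    matrices = {c.name: _load_cohort(c, config.preprocess) for c in config.cohorts}
    disc_cfgc = config.discovery
    disc = matrices[disc_cfgc.name]
    log_lines.append(
        f"discovery cohort {disc_cfgc.name}: {disc.expr.shape[0]} samples x "
        f"{disc.expr.shape[1]} genes"
    )

    collection = None
    if config.gene_sets:
        collection = read_gmt(config.gene_sets)

    children = iter(np.random.SeedSequence(config.seed).spawn(4 * 2))
    report: dict = {"seed": config.seed, "arms": {}}
    for arm in ("sex", "age"):
        arm_report: dict = {}
        disc_assoc_cfg = AssociationConfig(
            variable=arm, covariates=disc_cfgc.covariates, fdr_threshold=config.fdr_threshold
        )
        disc_table = fit_associations(disc, disc_assoc_cfg)
        candidates = list(disc_table.index[disc_table["fdr"] < config.fdr_threshold])
        write_table(disc_table.sort_values("fdr"), out / f"associations_{arm}.tsv", config.seed, cfg_repr)
        arm_report["n_candidates"] = len(candidates)
        log_lines.append(f"[{arm}] discovery: {len(candidates)} genes at FDR < {config.fdr_threshold}")

        perm = permutation_null(
            disc,
            disc_assoc_cfg,
            candidates=candidates,
            n_permutations=config.n_permutations,
            seed=next(children),
        )
        write_table(perm.to_frame().set_index("cycle"), out / f"permutations_{arm}.tsv", config.seed, cfg_repr)
        write_table(
            perm.per_gene_null_freq.rename("n_cycles_significant").to_frame(),
            out / f"null_freq_{arm}.tsv",
            config.seed,
            cfg_repr,
        )
        arm_report["permutation"] = {
            "n_zero": perm.n_zero,
            "expected_count": perm.expected_count,
        }
        log_lines.append(
            f"[{arm}] permutation null ({perm.n_permutations} cycles, unstratified shuffling): "
            f"{perm.n_zero} cycles with zero significant genes, "
            f"expected count {perm.expected_count:.3f}"
        )

        cohort_results = []
        if candidates:
            for vc in config.validations:
                vcfg = AssociationConfig(
                    variable=arm, covariates=vc.covariates, fdr_threshold=config.fdr_threshold
                )
                res = test_candidates(matrices[vc.name], vcfg, candidates, cohort=vc.name)
                cohort_results.append(res)
                write_table(
                    res.table.sort_values("fdr"),
                    out / f"validated_{vc.name}_{arm}.tsv",
                    config.seed,
                    cfg_repr,
                )
            rep = intersect_concordant(
                disc_table.loc[candidates], cohort_results, threshold=config.fdr_threshold
            )
            write_table(
                pd.DataFrame({"gene": rep.common_set}).set_index("gene"),
                out / f"common_set_{arm}.tsv",
                config.seed,
                cfg_repr,
            )
            write_table(
                pd.DataFrame({"gene": rep.contra_regulated}).set_index("gene"),
                out / f"contra_regulated_{arm}.tsv",
                config.seed,
                cfg_repr,
            )
            write_table(rep.venn_frame().set_index("region"), out / f"venn_counts_{arm}.tsv", config.seed, cfg_repr)
            arm_report["common_set"] = rep.common_set
            arm_report["validated"] = {k: len(v) for k, v in rep.validated.items()}
            annotation = disc.genes["chromosome"]
            if rep.common_set and all(
                g in annotation.index and str(annotation[g]) != "" for g in rep.common_set
            ):
                summary = annotate_chromosomal(
                    rep.common_set,
                    annotation,
                    directions=disc_table.loc[rep.common_set, "direction"],
                )
                write_table(
                    pd.Series(summary, name="count").to_frame(),
                    out / f"chromosome_summary_{arm}.tsv",
                    config.seed,
                    cfg_repr,
                )
                arm_report["chromosome_summary"] = summary
            log_lines.append(
                f"[{arm}] validation: common set of {len(rep.common_set)} genes; "
                f"{len(rep.contra_regulated)} contra-regulated"
            )
        else:
            log_lines.append(f"[{arm}] validation skipped: no discovery candidates")

        gsea_seed = next(children)
        if collection is not None and len(collection):
            filtered = filter_sets(
                collection,
                list(disc.expr.columns),
                min_size=config.gsea_min_size,
                max_size=config.gsea_max_size,
            )
            if len(filtered):
                enr = enrichment_significance(
                    disc,
                    disc_assoc_cfg,
                    filtered,
                    n_permutations=config.gsea_n_permutations,
                    seed=gsea_seed,
                    weight=config.gsea_weight,
                )
                write_table(enr.sort_values("fdr"), out / f"gsea_{arm}.tsv", config.seed, cfg_repr)
                graph = build_enrichment_map(
                    enr, filtered, config.gsea_fdr_cutoff, config.gsea_overlap_cutoff
                )
                edges = pd.DataFrame(
                    [
                        {"set_a": a, "set_b": b, "shared": d["weight"], "overlap": d["overlap"]}
                        for a, b, d in graph.edges(data=True)
                    ]
                )
                write_table(
                    edges.set_index("set_a") if len(edges) else pd.DataFrame(
                        columns=["set_a", "set_b", "shared", "overlap"]
                    ).set_index("set_a"),
                    out / f"enrichment_map_{arm}_edges.tsv",
                    config.seed,
                    cfg_repr,
                )
                arm_report["gsea"] = {
                    "n_sets_tested": len(filtered),
                    "n_significant": int((enr["fdr"] < config.gsea_fdr_cutoff).sum()),
                    "map_nodes": graph.number_of_nodes(),
                    "map_edges": graph.number_of_edges(),
                }
                log_lines.append(
                    f"[{arm}] gsea: {arm_report['gsea']['n_significant']} of "
                    f"{len(filtered)} sets at FDR < {config.gsea_fdr_cutoff}"
                )
        report["arms"][arm] = arm_report

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return report
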