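"""Synthetic multi-cohort expression studies with known planted effects.

This module generates probe-level log2-intensity matrices that emulate the
structure of a bead-array lung-tissue study: a discovery cohort processed in
two batches with a strong male excess, plus validation cohorts with more
balanced sex and smoking composition.  Every downstream stage of the
pipeline (probe filtering, probe-to-gene collapse, batch adjustment,
per-gene regression, permutation null, multi-cohort validation, enrichment)
can therefore be exercised against ground truth without any external data.

The generative model for a non-Y gene g in sample i is

    y_ig = baseline_g + beta_sex_g * male_i + beta_age_g * age_i
           + smoking_shift_g(level_i) + gamma_{b(i),g}
           + eps,   eps ~ N(0, (sigma_g * delta_{b(i),g})^2)

where gamma and delta are per-batch location and scale effects.  Y-linked
genes are special-cased: females do not carry the gene, so their probe
intensities are drawn from a low background-intensity distribution
independent of age and smoking; the planted male-minus-female difference is
then measured against that background, which is how fold changes such as
the ~49-fold male excess of an RPS4Y1-like gene arise.

Detection p-values are generated so that each probe is "detected"
(p < 0.01) in exactly ``expressed_fraction`` of samples in expectation:
detectable sample-probe pairs draw p ~ U(0, 0.01) and the rest draw
p ~ U(0.01, 1).

A single integer seed drives everything; multi-cohort generation derives
one child stream per cohort deterministically from it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import age_gene_table, sex_gene_table

SMOKING_LEVELS = ("never", "former", "current", "unknown")

__all__ = [
    "CohortSpec",
    "EffectTruth",
    "BatchEffect",
    "ExpressionStudy",
    "generate_study",
    "generate_multi_cohort",
    "default_truth_from_tables",
    "discovery_spec",
    "laval_spec",
    "ubc_spec",
    "groningen_spec",
    "validation_specs",
    "signed_fc_to_log2",
]


def signed_fc_to_log2(fc: float) -> float:
    """Convert a signed fold change (|fc| >= 1) to a log2 difference."""
    if fc >= 1:
        return float(np.log2(fc))
    if fc <= -1:
        return float(-np.log2(-fc))
    raise ValueError(f"signed fold change must lie outside (-1, 1), got {fc}")


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class CohortSpec:
    """Size and composition of one emulated cohort.

    ``smoking_levels`` maps category labels to sampling proportions (must sum
    to 1); ``batch_sizes`` lists processing-batch sizes summing to
    ``n_samples``.
    """

    name: str
    n_samples: int
    n_male: int
    age_range_male: tuple[float, float]
    age_range_female: tuple[float, float]
    smoking_levels: Mapping[str, float]
    batch_sizes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.batch_sizes:
            self.batch_sizes = (self.n_samples,)
        self.batch_sizes = tuple(int(b) for b in self.batch_sizes)
        if self.n_male > self.n_samples:
            raise ValueError(
                f"n_male ({self.n_male}) exceeds n_samples ({self.n_samples})"
            )
        if sum(self.batch_sizes) != self.n_samples:
            raise ValueError("batch_sizes must sum to n_samples")
        total = sum(self.smoking_levels.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"smoking proportions sum to {total}, expected 1")
        for lo, hi in (self.age_range_male, self.age_range_female):
            if not (0 < lo < hi):
                raise ValueError("age ranges must be positive with min < max")

    @property
    def batch_names(self) -> tuple[str, ...]:
        return tuple(f"{self.name}_b{i + 1}" for i in range(len(self.batch_sizes)))


@dataclass
class EffectTruth:
    """Per-gene generative parameters.

    ``genes`` is a symbol-indexed frame with columns ``baseline_log2``,
    ``sex_log2fc`` (male minus female), ``age_slope_log2_per_year``,
    ``residual_sd``, ``chromosome`` ("1".."22", "X", "Y", "X;Y"),
    ``n_probes`` and ``expressed_fraction``.  ``smoking_shifts`` optionally
    holds per-level additive log2 shifts (genes x levels; absent level = 0).
    ``background_mean``/``background_sd`` define the background-intensity
    distribution used for Y-linked genes in females.
    """

    genes: pd.DataFrame
    smoking_shifts: pd.DataFrame | None = None
    background_mean: float = 5.0
    background_sd: float = 0.5

    _REQUIRED = (
        "baseline_log2",
        "sex_log2fc",
        "age_slope_log2_per_year",
        "residual_sd",
        "chromosome",
        "n_probes",
        "expressed_fraction",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self._REQUIRED if c not in self.genes.columns]
        if missing:
            raise ValueError(f"truth table missing columns: {missing}")
        g = self.genes
        if (g["residual_sd"] <= 0).any():
            raise ValueError("residual_sd must be positive")
        if (g["n_probes"] < 1).any():
            raise ValueError("n_probes must be >= 1")
        ef = g["expressed_fraction"]
        if ((ef < 0) | (ef > 1)).any():
            raise ValueError("expressed_fraction must lie in [0, 1]")
        if self.background_sd <= 0:
            raise ValueError("background_sd must be positive")

    @property
    def symbols(self) -> pd.Index:
        return self.genes.index

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def copy(self) -> "EffectTruth":
        return EffectTruth(
            genes=self.genes.copy(),
            smoking_shifts=None if self.smoking_shifts is None else self.smoking_shifts.copy(),
            background_mean=self.background_mean,
            background_sd=self.background_sd,
        )

    def smoking_shift_matrix(self, levels: Sequence[str]) -> np.ndarray:
        """Genes x levels additive shifts, zero-filled for absent levels."""
        out = np.zeros((self.n_genes, len(levels)))
        if self.smoking_shifts is not None:
            for j, lev in enumerate(levels):
                if lev in self.smoking_shifts.columns:
                    out[:, j] = (
                        self.smoking_shifts[lev].reindex(self.symbols).fillna(0.0).to_numpy()
                    )
        return out


@dataclass
class BatchEffect:
    """Per-batch, per-gene location shifts and residual-scale factors.

    ``location`` and ``scale`` are batch x gene frames; scale factors must
    be positive.  These are the parameters an empirical-Bayes batch
    adjustment is expected to remove.
    """

    location: pd.DataFrame
    scale: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.location.index.equals(self.scale.index) or not self.location.columns.equals(
            self.scale.columns
        ):
            raise ValueError("location and scale must share batch and gene axes")
        if (self.scale.to_numpy() <= 0).any():
            raise ValueError("scale factors must be positive")

    @classmethod
    def none(cls, batch_names: Sequence[str], genes: Sequence[str]) -> "BatchEffect":
        shape = (len(batch_names), len(genes))
        return cls(
            location=pd.DataFrame(np.zeros(shape), index=batch_names, columns=genes),
            scale=pd.DataFrame(np.ones(shape), index=batch_names, columns=genes),
        )

    @classmethod
    def random(
        cls,
        batch_names: Sequence[str],
        genes: Sequence[str],
        seed: int | np.random.Generator = 0,
        location_sd: float = 0.3,
        scale_range: tuple[float, float] = (0.7, 1.4),
    ) -> "BatchEffect":
        """Independent per-batch/per-gene shifts, N(0, location_sd) locations
        and log-uniform scales."""
        rng = np.random.default_rng(seed)
        shape = (len(batch_names), len(genes))
        loc = rng.normal(0.0, location_sd, size=shape)
        scale = np.exp(rng.uniform(np.log(scale_range[0]), np.log(scale_range[1]), size=shape))
        return cls(
            location=pd.DataFrame(loc, index=batch_names, columns=genes),
            scale=pd.DataFrame(scale, index=batch_names, columns=genes),
        )


@dataclass
class ExpressionStudy:
    """Probe-level study: expression, detection p-values, annotations.

    ``expr`` and ``detection_p`` are samples x probes with identical axes;
    ``samples`` carries sex ("M"/"F"), age_years, smoking, batch and cohort;
    ``probes`` is probe-indexed with gene_symbol (empty string for
    unannotated probes) and chromosome.
    """

    expr: pd.DataFrame
    detection_p: pd.DataFrame
    samples: pd.DataFrame
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.expr.index.equals(self.detection_p.index) or not self.expr.columns.equals(
            self.detection_p.columns
        ):
            raise ValueError("expr and detection_p must share axes")
        if not self.expr.index.equals(self.samples.index):
            raise ValueError("expr rows must match the sample sheet")
        if not self.expr.columns.equals(self.probes.index):
            raise ValueError("expr columns must match the probe table")

    @property
    def gene_annotation(self) -> pd.Series:
        """Gene symbol -> chromosome, over annotated probes."""
        annotated = self.probes[self.probes["gene_symbol"] != ""]
        return annotated.drop_duplicates("gene_symbol").set_index("gene_symbol")["chromosome"]

    def detection_rate(self, cutoff: float = 0.01) -> pd.Series:
        """Fraction of samples with detection p < cutoff, per probe."""
        return (self.detection_p < cutoff).mean(axis=0)


# ---------------------------------------------------------------------------
# cohort presets (sizes, sex ratios, age ranges and smoking mix of the
# emulated study populations)


def discovery_spec() -> CohortSpec:
    """284-sample discovery cohort: 202 M / 82 F, two processing batches of
    206 and 78, nearly all ever-smokers, ages 36-85 (M) / 40-83 (F)."""
    return CohortSpec(
        name="discovery",
        n_samples=284,
        n_male=202,
        age_range_male=(36.0, 85.0),
        age_range_female=(40.0, 83.0),
        smoking_levels={"current": 283 / 284, "never": 1 / 284},
        batch_sizes=(206, 78),
    )


def laval_spec() -> CohortSpec:
    return CohortSpec(
        name="laval",
        n_samples=409,
        n_male=229,
        age_range_male=(30.0, 82.0),
        age_range_female=(33.0, 84.0),
        smoking_levels={"current": 0.220, "former": 0.692, "never": 0.088},
    )


def ubc_spec() -> CohortSpec:
    return CohortSpec(
        name="ubc",
        n_samples=339,
        n_male=182,
        age_range_male=(11.0, 85.0),
        age_range_female=(4.0, 82.0),
        smoking_levels={"current": 0.289, "former": 0.481, "never": 0.077, "unknown": 0.153},
    )


def groningen_spec() -> CohortSpec:
    return CohortSpec(
        name="groningen",
        n_samples=363,
        n_male=193,
        age_range_male=(6.0, 83.0),
        age_range_female=(8.0, 75.0),
        smoking_levels={"current": 0.157, "former": 0.510, "never": 0.275, "unknown": 0.058},
    )


def validation_specs() -> list[CohortSpec]:
    return [laval_spec(), ubc_spec(), groningen_spec()]


# ---------------------------------------------------------------------------
# generation


def _sample_sheet(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_samples
    sex = np.array(["M"] * spec.n_male + ["F"] * (n - spec.n_male), dtype=object)
    age = np.empty(n)
    age[: spec.n_male] = rng.uniform(*spec.age_range_male, size=spec.n_male)
    age[spec.n_male :] = rng.uniform(*spec.age_range_female, size=n - spec.n_male)
    levels = list(spec.smoking_levels)
    probs = np.array([spec.smoking_levels[l] for l in levels], dtype=float)
    probs = probs / probs.sum()
    smoking = rng.choice(levels, size=n, p=probs)
    # shuffle jointly before assigning batches so batch composition is not
    # confounded with sex by construction
    order = rng.permutation(n)
    sex, age, smoking = sex[order], age[order], smoking[order]
    batch = np.repeat(spec.batch_names, spec.batch_sizes)
    sample_ids = [f"{spec.name}_{i + 1:04d}" for i in range(n)]
    return pd.DataFrame(
        {
            "sex": sex,
            "age_years": np.round(age, 3),
            "smoking": smoking,
            "batch": batch,
            "cohort": spec.name,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


def _probe_table(truth: EffectTruth, rng: np.random.Generator) -> pd.DataFrame:
    """One row per probe: gene, chromosome, per-probe expressed fraction.

    The first probe of each gene carries the gene's expressed_fraction;
    additional probes get an independently degraded fraction so the
    highest-detection-rate collapse rule has something to choose between.
    """
    rows = []
    for sym, row in truth.genes.iterrows():
        k = int(row["n_probes"])
        for j in range(k):
            ef = float(row["expressed_fraction"])
            if j > 0:
                ef = ef * float(rng.uniform(0.3, 0.95))
            rows.append((f"{sym}_P{j + 1}", sym, row["chromosome"], ef))
    return pd.DataFrame(
        rows, columns=["probe_id", "gene_symbol", "chromosome", "expressed_fraction"]
    ).set_index("probe_id")


def generate_study(
    spec: CohortSpec,
    truth: EffectTruth,
    batches: BatchEffect | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    n_unannotated_probes: int = 0,
) -> ExpressionStudy:
    """Draw one probe-level study from the generative model.

    Identical seeds yield identical studies.  ``batches`` defaults to no
    batch effect; if given, its batch axis must match ``spec.batch_sizes``
    and its gene axis must match ``truth``.
    """
    rng = np.random.default_rng(seed)
    if batches is None:
        batches = BatchEffect.none(spec.batch_names, list(truth.symbols))
    if len(batches.location.index) != len(spec.batch_sizes):
        raise ValueError("batch effect count does not match spec.batch_sizes")
    if not batches.location.columns.equals(pd.Index(truth.symbols)):
        raise ValueError("batch effects and truth cover different gene universes")

    samples = _sample_sheet(spec, rng)
    probes = _probe_table(truth, rng)
    n = spec.n_samples
    g = truth.genes
    male = (samples["sex"] == "M").to_numpy(dtype=float)
    age = samples["age_years"].to_numpy()
    batch_idx = pd.Categorical(
        samples["batch"], categories=list(batches.location.index)
    ).codes

    levels = list(dict.fromkeys(samples["smoking"]))
    shift_gl = truth.smoking_shift_matrix(levels)  # genes x levels
    level_idx = np.array([levels.index(s) for s in samples["smoking"]])

    baseline = g["baseline_log2"].to_numpy()
    sex_fc = g["sex_log2fc"].to_numpy()
    slope = g["age_slope_log2_per_year"].to_numpy()
    sigma = g["residual_sd"].to_numpy()
    loc = batches.location.to_numpy()  # batches x genes
    scale = batches.scale.to_numpy()

    # gene-level mean and SD, samples x genes
    mean = (
        baseline[None, :]
        + sex_fc[None, :] * male[:, None]
        + slope[None, :] * age[:, None]
        + shift_gl.T[level_idx, :]
        + loc[batch_idx, :]
    )
    sd = sigma[None, :] * scale[batch_idx, :]

    # Y-linked genes: females do not carry the gene; background intensity
    y_cols = np.flatnonzero((g["chromosome"] == "Y").to_numpy())
    if y_cols.size:
        female = male == 0.0
        for c in y_cols:
            mean[female, c] = truth.background_mean + loc[batch_idx[female], c]
            sd[female, c] = truth.background_sd * scale[batch_idx[female], c]

    gene_pos = {sym: i for i, sym in enumerate(truth.symbols)}
    probe_gene_idx = np.array([gene_pos[s] for s in probes["gene_symbol"]])
    mean_p = mean[:, probe_gene_idx]
    sd_p = sd[:, probe_gene_idx]
    expr = mean_p + rng.normal(size=mean_p.shape) * sd_p

    ef = probes["expressed_fraction"].to_numpy()
    detectable = rng.random(expr.shape) < ef[None, :]
    detection_p = np.where(
        detectable,
        rng.uniform(0.0, 0.01, size=expr.shape),
        rng.uniform(0.01, 1.0, size=expr.shape),
    )

    probe_frame = probes.drop(columns=["expressed_fraction"])
    if n_unannotated_probes > 0:
        extra_ids = [f"UNANN_P{j + 1}" for j in range(n_unannotated_probes)]
        extra_expr = rng.normal(
            truth.background_mean, truth.background_sd, size=(n, n_unannotated_probes)
        )
        extra_det = rng.uniform(0.0, 0.01, size=(n, n_unannotated_probes))
        expr = np.hstack([expr, extra_expr])
        detection_p = np.hstack([detection_p, extra_det])
        probe_frame = pd.concat(
            [
                probe_frame,
                pd.DataFrame(
                    {"gene_symbol": "", "chromosome": ""},
                    index=pd.Index(extra_ids, name="probe_id"),
                ),
            ]
        )

    expr_df = pd.DataFrame(expr, index=samples.index, columns=probe_frame.index)
    det_df = pd.DataFrame(detection_p, index=samples.index, columns=probe_frame.index)
    return ExpressionStudy(expr=expr_df, detection_p=det_df, samples=samples, probes=probe_frame)


def generate_multi_cohort(
    specs: Iterable[CohortSpec],
    truths: Mapping[str, EffectTruth] | EffectTruth,
    seed: int = 0,
    batches: Mapping[str, BatchEffect] | None = None,
) -> dict[str, ExpressionStudy]:
    """Generate several cohorts from one global seed.

    ``truths`` may be a single truth shared by all cohorts or a mapping from
    cohort name to a cohort-specific truth (e.g. effects planted in the
    discovery cohort only).  Child random streams are derived
    deterministically from the global seed, one per cohort in order.
    """
    specs = list(specs)
    children = np.random.SeedSequence(seed).spawn(len(specs))
    out: dict[str, ExpressionStudy] = {}
    for spec, child in zip(specs, children):
        truth = truths if isinstance(truths, EffectTruth) else truths[spec.name]
        be = None if batches is None else batches.get(spec.name)
        out[spec.name] = generate_study(spec, truth, batches=be, seed=child)
    return out


# ---------------------------------------------------------------------------
# default truth built from the published catalogues


def default_truth_from_tables(
    n_background_genes: int,
    seed: int = 0,
    residual_sd: float = 0.15,
    background_mean: float = 5.0,
    background_sd: float = 0.5,
    expressed_fraction: float = 0.95,
    two_probe_fraction: float = 0.1,
) -> EffectTruth:
    """Truth object planting the 25 sex and 22 age catalogue genes among
    ``n_background_genes`` null genes.

    Published signed fold changes are converted to log2 differences; age
    estimates are used directly as log2-per-year slopes.  The planted genes
    share ``residual_sd`` (the catalogue's tiny discovery FDRs at modest
    effect sizes imply well-measured, low-noise genes); background genes get
    heterogeneous noise SDs in [0.1, 0.4] and zero effects.  The Y-linked
    gene's baseline equals the female background mean, so males (baseline +
    sex_log2fc) sit exactly the planted fold change above the female
    background intensity.
    """
    if n_background_genes < 0:
        raise ValueError("n_background_genes must be >= 0")
    rng = np.random.default_rng(seed)
    sex_tab = sex_gene_table()
    age_tab = age_gene_table()

    rows = []
    for sym, row in sex_tab.iterrows():
        fc = signed_fc_to_log2(row["fold_change"])
        if row["chromosome"] == "Y":
            # males: baseline + sex_log2fc; females: background. Baseline at
            # the background mean makes the M-vs-F contrast equal the
            # planted fold change.
            baseline = background_mean
        else:
            baseline = rng.uniform(6.0, 11.0)
        rows.append((sym, baseline, fc, 0.0, residual_sd, row["chromosome"]))
    for sym, row in age_tab.iterrows():
        rows.append(
            (sym, rng.uniform(6.0, 10.0), 0.0, row["estimate"], residual_sd, row["chromosome"])
        )

    # background baselines reach down to the background intensity itself:
    # filtered arrays still contain transcripts barely above background in
    # most samples, and without that low tail the Y-gene female draws would
    # be rank outliers that quantile normalization distorts
    autosomes = [str(c) for c in range(1, 23)]
    for i in range(n_background_genes):
        chrom = "X" if rng.random() < 0.04 else autosomes[rng.integers(0, 22)]
        rows.append(
            (
                f"BG{i + 1:05d}",
                rng.uniform(background_mean - 1.0, 11.0),
                0.0,
                0.0,
                float(rng.uniform(0.1, 0.4)),
                chrom,
            )
        )

    genes = pd.DataFrame(
        rows,
        columns=[
            "symbol",
            "baseline_log2",
            "sex_log2fc",
            "age_slope_log2_per_year",
            "residual_sd",
            "chromosome",
        ],
    ).set_index("symbol")
    genes["n_probes"] = np.where(rng.random(len(genes)) < two_probe_fraction, 2, 1)
    genes["expressed_fraction"] = expressed_fraction
    return EffectTruth(
        genes=genes,
        background_mean=background_mean,
        background_sd=background_sd,
    )
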