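import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import lungsexage as lx

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_study(expr, detection, sex=None, gene_of=None, chrom_of=None, cohort="test"):
    """Hand-rolled probe-level study from plain arrays.

    expr/detection: samples x probes arrays; gene_of maps probe id to gene
    symbol ("" = unannotated).
    """
    expr = np.asarray(expr, dtype=float)
    det = np.asarray(detection, dtype=float)
    n, p = expr.shape
    probe_ids = [f"P{j + 1:03d}" for j in range(p)]
    sample_ids = [f"{cohort}_{i + 1:03d}" for i in range(n)]
    gene_of = gene_of or {pid: f"G{j + 1}" for j, pid in enumerate(probe_ids)}
    chrom_of = chrom_of or {}
    sex = list(sex) if sex is not None else ["M" if i % 2 == 0 else "F" for i in range(n)]
    samples = pd.DataFrame(
        {
            "sex": sex,
            "age_years": np.linspace(40, 80, n),
            "smoking": "current",
            "batch": f"{cohort}_b1",
            "cohort": cohort,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    probes = pd.DataFrame(
        {
            "gene_symbol": [gene_of[pid] for pid in probe_ids],
            "chromosome": [chrom_of.get(pid, "1") for pid in probe_ids],
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return lx.ExpressionStudy(
        expr=pd.DataFrame(expr, index=sample_ids, columns=probe_ids),
        detection_p=pd.DataFrame(det, index=sample_ids, columns=probe_ids),
        samples=samples,
        probes=probes,
    )


def null_gene_matrix(n_samples=80, n_genes=500, seed=0, n_male=None, cohort="null"):
    """Gene-level matrix with no planted effects (pure noise)."""
    rng = np.random.default_rng(seed)
    n_male = n_male if n_male is not None else n_samples // 2
    genes = [f"G{j + 1:04d}" for j in range(n_genes)]
    sample_ids = [f"{cohort}_{i + 1:04d}" for i in range(n_samples)]
    sex = np.array(["M"] * n_male + ["F"] * (n_samples - n_male))
    rng.shuffle(sex)
    samples = pd.DataFrame(
        {
            "sex": sex,
            "age_years": rng.uniform(36, 85, n_samples),
            "smoking": rng.choice(["never", "former", "current"], n_samples),
            "batch": f"{cohort}_b1",
            "cohort": cohort,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    expr = pd.DataFrame(
        rng.normal(8.0, 0.5, size=(n_samples, n_genes)), index=sample_ids, columns=genes
    )
    gene_tab = pd.DataFrame(
        {"chromosome": "1", "detection_rate": 1.0, "probe_id": genes},
        index=pd.Index(genes, name="gene_symbol"),
    )
    return lx.GeneMatrix(expr=expr, samples=samples, genes=gene_tab)


def planted_gene_matrix(truth, spec=None, batches=None, seed=0):
    """Generate a study from truth (one probe per gene) and collapse it to a
    gene matrix without normalization, for tests that target the association
    stage directly."""
    spec = spec or lx.discovery_spec()
    study = lx.generate_study(spec, truth, batches=batches, seed=seed)
    from lungsexage.preprocess import collapse_probes

    return collapse_probes(study)


def simple_truth(genes: dict, residual_sd=0.15, **kwargs):
    """EffectTruth from {symbol: (baseline, sex_log2fc, age_slope, chromosome)}."""
    rows = {
        sym: dict(
            baseline_log2=v[0],
            sex_log2fc=v[1],
            age_slope_log2_per_year=v[2],
            residual_sd=residual_sd,
            chromosome=v[3],
            n_probes=1,
            expressed_fraction=1.0,
        )
        for sym, v in genes.items()
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "symbol"
    return lx.EffectTruth(genes=frame, **kwargs)


@pytest.fixture(scope="session")
def discovery_matrix():
    """Preprocessed discovery-like cohort with the planted catalogue and
    batch effects; shared across tests that only read from it."""
    truth = lx.default_truth_from_tables(1500, seed=7)
    spec = lx.discovery_spec()
    batches = lx.BatchEffect.random(
        spec.batch_names, list(truth.symbols), seed=8, location_sd=0.3
    )
    study = lx.generate_study(spec, truth, batches=batches, seed=9)
    return lx.preprocess_study(study)
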