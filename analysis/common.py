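"""Shared conventions for the analysis drivers: paths, the study truth and
the cohort roster.

The emulated study: a 284-sample discovery cohort (202 M / 82 F, two
processing batches of 206 and 78) and three validation cohorts (409, 339,
363 samples) with balanced sex and mixed smoking.  The discovery truth
plants the 25 validated sex genes and 22 validated age genes at their
published effect sizes, padded with extra discovery-only effects (190 sex,
195 age) that vanish in the validation cohorts — emulating candidates that
fail replication — plus null background genes.
"""

from pathlib import Path

import numpy as np

import lungsexage as lx

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results" / "analysis"

SEED = 20160
N_BACKGROUND = 3000  # null genes beyond the planted catalogue
N_EXTRA_SEX = 190  # discovery-only sex effects (215 candidates in total)
N_EXTRA_AGE = 195  # discovery-only age effects (217 candidates in total)

COHORTS = ["discovery", "laval", "ubc", "groningen"]


def study_truths(seed: int = SEED):
    """(discovery_truth, validation_truth) sharing one gene universe."""
    rng = np.random.default_rng(seed)
    disc = lx.default_truth_from_tables(N_BACKGROUND, seed=seed)
    bg = [g for g in disc.symbols if g.startswith("BG")]
    sex_extra = bg[:N_EXTRA_SEX]
    age_extra = bg[N_EXTRA_SEX : N_EXTRA_SEX + N_EXTRA_AGE]
    disc.genes.loc[sex_extra, "sex_log2fc"] = rng.choice(
        [-1.0, 1.0], N_EXTRA_SEX
    ) * rng.uniform(0.25, 0.5, N_EXTRA_SEX)
    disc.genes.loc[age_extra, "age_slope_log2_per_year"] = rng.choice(
        [-1.0, 1.0], N_EXTRA_AGE
    ) * rng.uniform(0.008, 0.02, N_EXTRA_AGE)
    disc.genes.loc[sex_extra + age_extra, "residual_sd"] = 0.15

    val = disc.copy()
    val.genes.loc[sex_extra, "sex_log2fc"] = 0.0
    val.genes.loc[age_extra, "age_slope_log2_per_year"] = 0.0
    return disc, val


def matrix_dir(cohort: str) -> Path:
    return SCRATCH / "matrices" / cohort


def study_dir(cohort: str) -> Path:
    return SCRATCH / "data" / cohort
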