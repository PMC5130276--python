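"""Generate the four emulated cohorts with known planted effects.

Writes probe-level studies (expression, detection p-values, sample and
probe sheets) under scratch/analysis/data/<cohort>/ plus the planted-truth
tables, and prints the cohort roster.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import lungsexage as lx
from lungsexage.io import write_study, write_truth

from common import SCRATCH, SEED, study_dir, study_truths


def main() -> None:
    disc_truth, val_truth = study_truths()
    specs = [lx.discovery_spec(), *lx.validation_specs()]
    truths = {spec.name: (disc_truth if spec.name == "discovery" else val_truth) for spec in specs}
    batches = {
        "discovery": lx.BatchEffect.random(
            lx.discovery_spec().batch_names,
            list(disc_truth.symbols),
            seed=SEED + 1,
            location_sd=0.3,
        )
    }
    studies = lx.generate_multi_cohort(specs, truths, seed=SEED, batches=batches)
    for name, study in studies.items():
        write_study(study, study_dir(name))
        n_m = int((study.samples["sex"] == "M").sum())
        print(
            f"{name:>10}: {study.expr.shape[0]:4d} samples ({n_m} M / "
            f"{study.expr.shape[0] - n_m} F), {study.expr.shape[1]} probes, "
            f"{study.samples['batch'].nunique()} batch(es)"
        )
    write_truth(disc_truth, SCRATCH / "truth_discovery.tsv")
    write_truth(val_truth, SCRATCH / "truth_validation.tsv")
    print(f"planted: {disc_truth.n_genes} genes "
          f"({(disc_truth.genes['sex_log2fc'] != 0).sum()} with sex effects, "
          f"{(disc_truth.genes['age_slope_log2_per_year'] != 0).sum()} with age effects)")


if __name__ == "__main__":
    main()
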