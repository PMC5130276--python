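"""Preprocess every cohort to a gene-level matrix.

Discovery: detection filter, probe-to-gene collapse, quantile
normalization, then empirical-Bayes combination of the two processing
batches.  Validation cohorts: same steps minus the batch adjustment (each
was generated as a single batch).  Writes matrices under
scratch/analysis/matrices/<cohort>/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import lungsexage as lx
from lungsexage.io import read_study, write_gene_matrix

from common import COHORTS, SEED, matrix_dir, study_dir


def main() -> None:
    for cohort in COHORTS:
        study = read_study(study_dir(cohort))
        n_probes_before = study.expr.shape[1]
        matrix = lx.preprocess_study(study)
        write_gene_matrix(matrix, matrix_dir(cohort), seed=SEED)
        print(
            f"{cohort:>10}: {n_probes_before} probes -> {matrix.expr.shape[1]} genes "
            f"({'ComBat over ' + str(matrix.samples['batch'].nunique()) + ' batches' if matrix.samples['batch'].nunique() > 1 else 'single batch'})"
        )


if __name__ == "__main__":
    main()
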