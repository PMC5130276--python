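"""Re-test discovery candidates in the three validation cohorts.

Candidate-subset BH per cohort (smoking as covariate), concordant-direction
validation, contra-regulation exclusion, four-way intersection with Venn
region counts, and chromosomal bookkeeping of the common sets.  Tables go
under results/analysis/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

import lungsexage as lx
from lungsexage.io import read_gene_matrix, write_table

from common import RESULTS, SEED, matrix_dir

VALIDATION = ["laval", "ubc", "groningen"]


def main() -> None:
    disc_matrix = read_gene_matrix(matrix_dir("discovery"))
    for arm in ("sex", "age"):
        disc = pd.read_csv(
            RESULTS / f"associations_{arm}.tsv", sep="\t", index_col=0, comment="#"
        )
        candidates = list(disc.index[disc["fdr"] < 0.05])
        results = []
        for name in VALIDATION:
            matrix = read_gene_matrix(matrix_dir(name))
            cfg = lx.AssociationConfig(variable=arm, covariates=("smoking",))
            res = lx.test_candidates(matrix, cfg, candidates, cohort=name)
            results.append(res)
            write_table(res.table.sort_values("fdr"),
                        RESULTS / f"validated_{name}_{arm}.tsv", seed=SEED)
        report = lx.intersect_concordant(disc.loc[candidates], results)
        write_table(pd.DataFrame({"gene": report.common_set}).set_index("gene"),
                    RESULTS / f"common_set_{arm}.tsv", seed=SEED)
        write_table(pd.DataFrame({"gene": report.contra_regulated}).set_index("gene"),
                    RESULTS / f"contra_regulated_{arm}.tsv", seed=SEED)
        write_table(report.venn_frame().set_index("region"),
                    RESULTS / f"venn_counts_{arm}.tsv", seed=SEED)

        per_cohort = ", ".join(f"{r.cohort}: {len(report.validated[r.cohort])}" for r in results)
        print(f"[{arm}] {len(candidates)} candidates; validated per cohort -> {per_cohort}")
        print(f"[{arm}] common set: {len(report.common_set)} genes; "
              f"contra-regulated: {len(report.contra_regulated)}")
        summary = lx.annotate_chromosomal(
            report.common_set,
            disc_matrix.genes["chromosome"],
            directions=disc.loc[report.common_set, "direction"],
        )
        write_table(pd.Series(summary, name="count").to_frame(),
                    RESULTS / f"chromosome_summary_{arm}.tsv", seed=SEED)
        print(f"[{arm}] chromosomes: {summary['x_linked']} X, {summary['y_linked']} Y, "
              f"{summary['pseudoautosomal']} PAR, {summary['autosomal']} autosomal "
              f"on {summary['distinct_autosomes']} autosomes; "
              f"{summary['up']} up / {summary['down']} down")


if __name__ == "__main__":
    main()
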