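"""Per-gene association scans of the discovery cohort for sex and age.

Writes the full association tables under results/analysis/ and prints the
discovery counts plus the headline extreme genes (the Y-linked ~49-fold
male excess and the X-inactivation transcript's female excess).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import lungsexage as lx
from lungsexage.io import read_gene_matrix, write_table

from common import RESULTS, SEED, matrix_dir


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    matrix = read_gene_matrix(matrix_dir("discovery"))
    m = matrix.expr.shape[1]
    for arm in ("sex", "age"):
        cfg = lx.AssociationConfig(variable=arm)
        table = lx.fit_associations(matrix, cfg)
        n_sig = int((table["fdr"] < 0.05).sum())
        up = int(((table["fdr"] < 0.05) & (table["beta"] > 0)).sum())
        write_table(table.sort_values("fdr"), RESULTS / f"associations_{arm}.tsv", seed=SEED)
        pct = 100 * n_sig / m
        print(f"[{arm}] {n_sig} of {m} genes at FDR < 0.05 ({pct:.0f}%): "
              f"{up} higher / {n_sig - up} lower with {'male sex' if arm == 'sex' else 'age'}")
        if arm == "sex":
            for g in ("RPS4Y1", "XIST"):
                row = table.loc[g]
                print(f"        {g}: signed fold change {row['signed_fc']:.3f}, FDR {row['fdr']:.2e}")
        else:
            row = table.loc["ITGBL1"]
            print(f"        ITGBL1: {row['beta']:.6f} log2/year, FDR {row['fdr']:.2e}")


if __name__ == "__main__":
    main()
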