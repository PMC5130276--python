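"""Published catalogues of validated sex- and age-associated lung genes.

These are the 25 genes whose lung-tissue expression differed between men and
women, and the 22 genes whose expression tracked age at surgery, in a
discovery cohort of 284 non-tumor lung samples and three independent
validation cohorts.  Fold changes follow the signed convention: values > 1
mean higher expression in males, values < -1 mean higher expression in
females (a fold change of -12.561 is 12.561-fold higher in females).  Age
estimates are log2-expression change per year of age.

Chromosome labels use "X;Y" for pseudoautosomal genes.
"""

from __future__ import annotations

import pandas as pd

# symbol, Entrez ID, chromosome, signed fold change (M vs F), discovery FDR
_SEX_GENES = [
    ("AOX1", 316, "2", 1.397, 2.81e-04),
    ("ARSD", 414, "X", -1.543, 5.78e-50),
    ("ATP6V1B1", 525, "2", -1.352, 3.30e-04),
    ("CD99", 4267, "X;Y", 1.342, 5.85e-22),
    ("CILP", 8483, "15", 1.397, 1.24e-02),
    ("DDX3X", 1654, "X", -1.215, 2.29e-04),
    ("EIF1AX", 1964, "X", -1.336, 1.34e-16),
    ("EIF2S3", 1968, "X", -1.231, 1.39e-16),
    ("GEMIN8", 54960, "X", -1.134, 1.20e-04),
    ("HDHD1", 8226, "X", -1.586, 1.75e-50),
    ("KAL1", 3730, "X", -1.982, 1.75e-30),
    ("KDM6A", 7403, "X", -1.514, 4.96e-39),
    ("OFD1", 8481, "X", -1.179, 5.06e-04),
    ("OLFML2A", 169611, "9", -1.287, 6.86e-03),
    ("PHGDH", 26227, "1", -1.170, 3.64e-02),
    ("PRKX", 5613, "X", -1.131, 2.38e-03),
    ("RPS4X", 6191, "X", -1.369, 1.83e-09),
    ("RPS4Y1", 6192, "Y", 48.948, 1.76e-249),
    ("TRAPPC2", 6399, "X", -1.171, 1.72e-07),
    ("TXLNG", 55787, "X", -1.184, 7.33e-07),
    ("USP9X", 8239, "X", -1.084, 2.15e-02),
    ("XIST", 7503, "X", -12.561, 1.14e-171),
    ("ZBED1", 9189, "X;Y", 1.108, 3.91e-05),
    ("ZFX", 7543, "X", -1.382, 3.14e-21),
    ("ZRSR2", 8233, "X", -1.362, 2.54e-16),
]

# symbol, Entrez ID, chromosome, log2 per-year estimate, discovery FDR
_AGE_GENES = [
    ("AGR2", 10551, "7", -0.01213, 2.95e-02),
    ("CRYAB", 1410, "11", 0.013824, 1.60e-03),
    ("CXCL17", 284340, "19", -0.00911, 4.85e-02),
    ("CXCL9", 4283, "4", 0.028698, 3.35e-02),
    ("DIRAS3", 9077, "1", 0.008936, 3.00e-03),
    ("FANCE", 2178, "6", -0.01075, 1.10e-03),
    ("FMO3", 2328, "1", 0.0131, 1.44e-02),
    ("GSTA4", 2941, "6", -0.01173, 4.80e-03),
    ("ITGB5", 3693, "3", 0.007076, 4.19e-02),
    ("ITGBL1", 9358, "13", 0.018297, 1.21e-05),
    ("LCN2", 3934, "9", -0.02576, 3.78e-02),
    ("MGP", 4256, "12", 0.00841, 4.97e-02),
    ("PGM5", 5239, "9", 0.009683, 4.80e-02),
    ("PLCD3", 113026, "17", 0.005974, 1.42e-02),
    ("PTCHD4", 442213, "6", 0.003035, 4.85e-02),
    ("RCAN2", 10231, "6", 0.015413, 1.56e-04),
    ("RERGL", 79785, "12", 0.022899, 6.70e-03),
    ("SCARF2", 91179, "22", 0.009692, 1.96e-02),
    ("TC2N", 123036, "14", -0.00923, 3.78e-02),
    ("WISP2", 8839, "20", 0.026326, 9.02e-05),
    ("ZMAT3", 64393, "3", 0.016636, 1.84e-04),
    ("ZNF518B", 85460, "4", -0.00626, 4.07e-02),
]


def sex_gene_table() -> pd.DataFrame:
    """Validated sex-associated genes (symbol-indexed).

    Columns: ``entrez_id``, ``chromosome``, ``fold_change`` (signed, M vs F)
    and ``fdr`` (discovery-series FDR).
    """
    df = pd.DataFrame(
        _SEX_GENES, columns=["symbol", "entrez_id", "chromosome", "fold_change", "fdr"]
    )
    return df.set_index("symbol")


def age_gene_table() -> pd.DataFrame:
    """Validated age-associated genes (symbol-indexed).

    Columns: ``entrez_id``, ``chromosome``, ``estimate`` (log2 units per
    year of age) and ``fdr`` (discovery-series FDR).
    """
    df = pd.DataFrame(
        _AGE_GENES, columns=["symbol", "entrez_id", "chromosome", "estimate", "fdr"]
    )
    return df.set_index("symbol")
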