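"""Probe-level preprocessing: detection filtering, probe-to-gene collapse,
quantile normalization and empirical-Bayes (ComBat-style) batch adjustment.

The pipeline mirrors common bead-array practice: probes without a gene
annotation or detected (detection p < 0.01) in fewer than 10% of samples
are dropped; when several probes map to the same gene only the one with the
highest detection rate is kept; sample distributions are equalized by
quantile normalization (a documented stand-in for spline-based
normalization); and processing batches are combined with a parametric
empirical-Bayes location/scale adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import ExpressionStudy

__all__ = [
    "PreprocessConfig",
    "GeneMatrix",
    "filter_probes",
    "collapse_probes",
    "quantile_normalize",
    "combat_adjust",
    "preprocess_study",
]


@dataclass
class PreprocessConfig:
    detection_p_cutoff: float = 0.01
    min_detected_fraction: float = 0.10
    normalization: str = "quantile"  # {"quantile", "none"}
    combat: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.detection_p_cutoff < 1:
            raise ValueError("detection_p_cutoff must lie in (0, 1)")
        if not 0 <= self.min_detected_fraction <= 1:
            raise ValueError("min_detected_fraction must lie in [0, 1]")
        if self.normalization not in ("quantile", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class GeneMatrix:
    """Gene-level study: samples x genes log2 matrix plus annotations.

    ``genes`` is symbol-indexed with columns ``chromosome``,
    ``detection_rate`` (of the retained probe) and ``probe_id``.
    """

    expr: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.expr.index.equals(self.samples.index):
            raise ValueError("expr rows must match the sample sheet")
        if not self.expr.columns.equals(self.genes.index):
            raise ValueError("expr columns must match the gene table")

    def copy(self) -> "GeneMatrix":
        return GeneMatrix(self.expr.copy(), self.samples.copy(), self.genes.copy())


def filter_probes(study: ExpressionStudy, cfg: PreprocessConfig | None = None) -> ExpressionStudy:
    """Drop unannotated probes and probes detected in too few samples.

    A probe is retained iff it maps to a gene symbol and its detection rate
    (fraction of samples with detection p < ``detection_p_cutoff``) is at
    least ``min_detected_fraction`` (boundary inclusive).  Probe order is
    preserved.
    """
    cfg = cfg or PreprocessConfig()
    rate = study.detection_rate(cfg.detection_p_cutoff)
    annotated = study.probes["gene_symbol"].astype(str) != ""
    keep = annotated & (rate >= cfg.min_detected_fraction)
    if not keep.any():
        warnings.warn("no probes survive filtering", stacklevel=2)
    kept = study.probes.index[keep]
    return ExpressionStudy(
        expr=study.expr.loc[:, kept],
        detection_p=study.detection_p.loc[:, kept],
        samples=study.samples,
        probes=study.probes.loc[kept],
    )


def collapse_probes(
    study: ExpressionStudy, detection_p_cutoff: float = 0.01
) -> GeneMatrix:
    """Keep one probe per gene: the one with the highest detection rate.

    Ties are broken by the lexicographically smallest probe identifier.  The
    winning probe's detection rate is recorded per gene.
    """
    rate = study.detection_rate(detection_p_cutoff)
    tab = study.probes.copy()
    tab["detection_rate"] = rate
    tab = tab[tab["gene_symbol"].astype(str) != ""]
    tab = tab.reset_index().sort_values(
        ["gene_symbol", "detection_rate", "probe_id"], ascending=[True, False, True]
    )
    winners = tab.groupby("gene_symbol", sort=True).head(1)
    genes = winners.set_index("gene_symbol")[["chromosome", "detection_rate", "probe_id"]]
    expr = study.expr.loc[:, winners["probe_id"]]
    expr.columns = genes.index
    return GeneMatrix(expr=expr, samples=study.samples, genes=genes)


def quantile_normalize(matrix: GeneMatrix) -> GeneMatrix:
    """Force every sample's value distribution to the mean order-statistic
    distribution across samples.

    Within-sample ranks are preserved; tied values receive the mean of the
    reference values at the tied positions.  A single-sample matrix is
    returned unchanged.
    """
    X = matrix.expr.to_numpy(dtype=float)
    n, m = X.shape
    if n < 2:
        return matrix.copy()
    if np.isnan(X).any():
        raise ValueError("quantile normalization requires complete data")
    ref = np.sort(X, axis=1).mean(axis=0)
    out = np.empty_like(X)
    for i in range(n):
        order = np.argsort(X[i], kind="stable")
        row_sorted = X[i][order]
        eq = np.diff(row_sorted) == 0
        if eq.any():
            # average reference values over runs of tied input values
            starts = np.flatnonzero(np.concatenate([[True], ~eq]))
            lens = np.diff(np.concatenate([starts, [m]]))
            means = np.add.reduceat(ref, starts) / lens
            assigned = np.repeat(means, lens)
        else:
            assigned = ref
        out[i, order] = assigned
    res = matrix.copy()
    res.expr = pd.DataFrame(out, index=matrix.expr.index, columns=matrix.expr.columns)
    return res


def _design_matrix(
    batch_labels: pd.Series, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    batches = list(pd.unique(batch_labels))
    B = np.column_stack([(batch_labels == b).to_numpy(dtype=float) for b in batches])
    if covariates is not None and covariates.shape[1] > 0:
        X = np.column_stack([B, covariates.to_numpy(dtype=float)])
    else:
        X = B
    return X, B, batches


def combat_adjust(
    matrix: GeneMatrix,
    batch_labels: pd.Series | None = None,
    covariates: pd.DataFrame | None = None,
    conv: float = 1e-4,
    max_iter: int = 100,
) -> GeneMatrix:
    """Parametric empirical-Bayes batch adjustment.

    Per gene, batch location shifts (gamma) and scale factors (delta) are
    estimated after standardizing out covariates and the weighted grand
    mean, shrunk across genes toward normal / inverse-gamma priors whose
    hyperparameters are set by method of moments, and removed.  Covariates
    (a numeric design frame, no intercept) are protected.  Defaults: batch
    labels from the sample sheet's ``batch`` column, no covariates.
    """
    if batch_labels is None:
        batch_labels = matrix.samples["batch"]
    X, B, batches = _design_matrix(batch_labels, covariates)
    if len(batches) < 2:
        raise ValueError("combat_adjust requires >= 2 batches")
    counts = B.sum(axis=0)
    if (counts < 2).any():
        raise ValueError("every batch needs >= 2 samples")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design is singular (covariates confounded with batch?)")

    Y = matrix.expr.to_numpy(dtype=float)  # samples x genes
    n, m = Y.shape
    n_batch = len(batches)

    beta = np.linalg.lstsq(X, Y, rcond=None)[0]  # design cols x genes
    grand_mean = (counts / n) @ beta[:n_batch, :]  # per gene
    resid = Y - X @ beta
    var_pooled = (resid**2).mean(axis=0)  # per gene, ddof 0
    stand_mean = np.tile(grand_mean, (n, 1))
    if X.shape[1] > n_batch:
        stand_mean = stand_mean + X[:, n_batch:] @ beta[n_batch:, :]
    sd = np.sqrt(var_pooled)
    Z = (Y - stand_mean) / sd[None, :]

    batch_masks = [B[:, i] == 1.0 for i in range(n_batch)]
    gamma_hat = np.vstack([Z[mask].mean(axis=0) for mask in batch_masks])
    delta_hat = np.vstack([Z[mask].var(axis=0, ddof=1) for mask in batch_masks])

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    d_mean = delta_hat.mean(axis=1)
    d_var = delta_hat.var(axis=1, ddof=1)
    a_prior = (2 * d_var + d_mean**2) / d_var
    b_prior = (d_mean * d_var + d_mean**3) / d_var

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i, mask in enumerate(batch_masks):
        ni = int(counts[i])
        g_old = gamma_hat[i].copy()
        d_old = delta_hat[i].copy()
        Zi = Z[mask]
        for _ in range(max_iter):
            g_new = (tau2[i] * ni * gamma_hat[i] + d_old * gamma_bar[i]) / (
                tau2[i] * ni + d_old
            )
            sum2 = ((Zi - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (0.5 * sum2 + b_prior[i]) / (ni / 2 + a_prior[i] - 1)
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
            )
            g_old, d_old = g_new, d_new
            if change < conv:
                break
        gamma_star[i] = g_old
        delta_star[i] = d_old

    adj = Z.copy()
    for i, mask in enumerate(batch_masks):
        adj[mask] = (Z[mask] - gamma_star[i][None, :]) / np.sqrt(delta_star[i])[None, :]
    adj = adj * sd[None, :] + stand_mean

    res = matrix.copy()
    res.expr = pd.DataFrame(adj, index=matrix.expr.index, columns=matrix.expr.columns)
    return res


def preprocess_study(study: ExpressionStudy, cfg: PreprocessConfig | None = None) -> GeneMatrix:
    """Full probe-level pipeline: filter -> collapse -> normalize -> combat.

    ComBat runs only when the sample sheet has >= 2 batches and the config
    enables it; with a single batch the step is a no-op.
    """
    cfg = cfg or PreprocessConfig()
    filtered = filter_probes(study, cfg)
    matrix = collapse_probes(filtered, cfg.detection_p_cutoff)
    if cfg.normalization == "quantile":
        matrix = quantile_normalize(matrix)
    if cfg.combat and matrix.samples["batch"].nunique() >= 2:
        matrix = combat_adjust(matrix)
    return matrix
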