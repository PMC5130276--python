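"""Per-gene linear-model association of expression with sex or age.

Each gene is fit by ordinary least squares on [intercept, variable,
covariates]; sex is coded female = 0, male = 1, so a positive coefficient
means higher expression in males.  Two-sided p-values use the t
distribution with residual degrees of freedom, and Benjamini-Hochberg FDR
is applied across all genes tested in the same analysis.  Sex effects are
additionally reported as signed fold changes (values > 1: male-higher;
values < -1: female-higher, |value|-fold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import GeneMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationConfig",
    "fit_associations",
    "signed_fold_change",
    "inverse_signed_fold_change",
    "bh_adjust",
]


@dataclass
class AssociationConfig:
    variable: str = "sex"  # {"sex", "age"}
    covariates: tuple[str, ...] = ()
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.variable not in ("sex", "age"):
            raise ValueError(f"variable must be 'sex' or 'age', got {self.variable!r}")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        self.covariates = tuple(self.covariates)


def signed_fold_change(beta_log2):
    """Map a log2 difference to the signed fold-change convention.

    2**beta for beta >= 0, -(2**-beta) otherwise; the image is
    (-inf, -1] U [1, inf) and the mapping is exactly invertible.
    """
    beta = np.asarray(beta_log2, dtype=float)
    out = np.where(beta >= 0, np.exp2(beta), -np.exp2(-beta))
    return float(out) if np.isscalar(beta_log2) else out


def inverse_signed_fold_change(fc):
    """Inverse of :func:`signed_fold_change`."""
    fc_arr = np.asarray(fc, dtype=float)
    if np.any((fc_arr > -1) & (fc_arr < 1)):
        raise ValueError("signed fold changes lie outside (-1, 1)")
    out = np.where(fc_arr >= 1, np.log2(np.abs(fc_arr)), -np.log2(np.abs(fc_arr)))
    return float(out) if np.isscalar(fc) else out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _encode_variable(samples: pd.DataFrame, variable: str) -> np.ndarray:
    if variable == "sex":
        sex = samples["sex"]
        bad = ~sex.isin(["M", "F"])
        if bad.any():
            raise ValueError(f"unrecognized sex labels: {sorted(sex[bad].unique())}")
        return (sex == "M").to_numpy(dtype=float)
    return samples["age_years"].to_numpy(dtype=float)


def _covariate_columns(
    samples: pd.DataFrame, covariates: tuple[str, ...]
) -> tuple[np.ndarray, pd.Index, list[str]]:
    """Build covariate design columns; returns (matrix, kept index, names).

    Categorical covariates become indicators against a reference level
    (never-smoker for smoking); samples with missing/unknown values are
    dropped.
    """
    keep = pd.Series(True, index=samples.index)
    cols: list[pd.Series] = []
    names: list[str] = []
    for cov in covariates:
        if cov not in samples.columns:
            raise ValueError(f"covariate column {cov!r} not in sample sheet")
        col = samples[cov]
        if cov == "smoking" or col.dtype == object:
            missing = col.isna() | (col.astype(str) == "unknown")
            keep &= ~missing
            levels = sorted(x for x in col[~missing].unique())
            reference = "never" if "never" in levels else levels[0]
            for lev in levels:
                if lev == reference:
                    continue
                cols.append((col == lev).astype(float).rename(f"{cov}[{lev}]"))
                names.append(f"{cov}[{lev}]")
        else:
            keep &= col.notna()
            cols.append(col.astype(float))
            names.append(cov)
    if cols:
        mat = pd.concat(cols, axis=1).loc[keep].to_numpy(dtype=float)
    else:
        mat = np.empty((int(keep.sum()), 0))
    return mat, samples.index[keep], names


def _scan(X: np.ndarray, Y: np.ndarray, coef_index: int = 1):
    """Vectorized OLS of each column of Y on X; returns stats for one
    coefficient.  Y is samples x genes."""
    n, p = X.shape
    if n <= p:
        raise ValueError("more design columns than samples")
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("rank-deficient design") from exc
    if np.linalg.matrix_rank(XtX) < p:
        raise ValueError("rank-deficient design")
    H = XtX_inv @ X.T
    beta_all = H @ Y
    resid = Y - X @ beta_all
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    beta = beta_all[coef_index]
    se = np.sqrt(sigma2 * XtX_inv[coef_index, coef_index])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, se, t, pvals, dof


def build_design(
    samples: pd.DataFrame, cfg: AssociationConfig
) -> tuple[np.ndarray, pd.Index]:
    """Design matrix [intercept, variable, covariates] and the retained
    sample index (samples with missing covariates dropped)."""
    cov_mat, kept, _ = _covariate_columns(samples, cfg.covariates)
    dropped = len(samples) - len(kept)
    if dropped:
        logger.info("dropping %d samples with missing covariate values", dropped)
    v = _encode_variable(samples.loc[kept], cfg.variable)
    if np.unique(v).size < 2:
        raise ValueError(f"variable {cfg.variable!r} is constant in this cohort")
    X = np.column_stack([np.ones(len(kept)), v, cov_mat])
    return X, kept


def fit_associations(matrix: GeneMatrix, cfg: AssociationConfig) -> pd.DataFrame:
    """Per-gene OLS association table.

    Returns a symbol-indexed frame with columns beta, se, t_stat, p_value,
    fdr, signed_fc (sex analyses only, NaN otherwise) and direction
    (sign of beta).  ``attrs`` records the variable, covariates, retained
    sample count and residual degrees of freedom.
    """
    X, kept = build_design(matrix.samples, cfg)
    Y = matrix.expr.loc[kept].to_numpy(dtype=float)
    beta, se, t, pvals, dof = _scan(X, Y)
    table = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "t_stat": t,
            "p_value": pvals,
            "fdr": bh_adjust(pvals),
            "signed_fc": signed_fold_change(beta) if cfg.variable == "sex" else np.nan,
            "direction": np.sign(beta).astype(int),
        },
        index=matrix.expr.columns.rename("gene"),
    )
    table.attrs.update(
        variable=cfg.variable,
        covariates=list(cfg.covariates),
        n_samples_used=int(len(kept)),
        dof=int(dof),
        fdr_threshold=cfg.fdr_threshold,
    )
    return table
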