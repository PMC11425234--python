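"""Library-size normalization, VST and nuisance-covariate residualization.

Size factors use the median-of-ratios estimator. The variance-stabilizing
transformation (VST) uses a single common negative-binomial dispersion with
the closed-form asinh integral; residualization removes additive nuisance
effects (batch, sex) on the VST scale for visualization and scoring only —
differential expression always models covariates explicitly on the counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LN2 = float(np.log(2.0))


def median_of_ratios_size_factors(counts: pd.DataFrame,
                                  pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Reference genes are those with nonzero counts in every sample (so the
    per-gene geometric mean is finite). ``factor_j = median_g(count_gj /
    geomean_g)`` over the reference genes. When no gene is expressed in all
    samples, pass ``pseudo_reference=True`` to compute geometric means on
    counts + 0.5 over all genes instead.
    """
    values = counts.to_numpy(dtype=float)
    if pseudo_reference:
        shifted = values + 0.5
        log_geomean = np.log(shifted).mean(axis=1)
        ratios = shifted / np.exp(log_geomean)[:, None]
    else:
        expressed = (values > 0).all(axis=1)
        if not expressed.any():
            raise ValueError(
                "no gene has nonzero counts in every sample; re-run with "
                "pseudo_reference=True to use a pseudo-reference geometric mean")
        ref = values[expressed]
        log_geomean = np.log(ref).mean(axis=1)
        ratios = ref / np.exp(log_geomean)[:, None]
    factors = np.median(ratios, axis=0)
    if np.any(factors <= 0):
        raise ValueError("a sample produced a non-positive size factor")
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def moment_dispersions(counts: pd.DataFrame, sf: pd.Series) -> pd.Series:
    """Per-gene method-of-moments NB dispersions on normalized counts.

    ``phi = max((var - mean) / mean^2, 0)`` with Var = mu + phi mu^2.
    Genes with zero mean yield NaN.
    """
    q = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    mean = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(mean > 0, np.maximum((var - mean) / mean**2, 0.0), np.nan)
    return pd.Series(phi, index=counts.index, name="phi_mom")


def vst_transform(counts: pd.DataFrame, sf: pd.Series,
                  phi_common: float | None = None) -> pd.DataFrame:
    """Closed-form VST for NB counts at a single common dispersion.

    ``value = (2 / (sqrt(phi) * ln 2)) * asinh(sqrt(phi * count / sf))``;
    zero counts map to zero and the transform is strictly increasing. As
    phi -> 0 it approaches ``2 * sqrt(count/sf) / ln 2`` (the Poisson
    square-root limit). ``phi_common`` defaults to the median of per-gene
    method-of-moments dispersions (floored at 1e-8).
    """
    if phi_common is None:
        phi = moment_dispersions(counts, sf).dropna()
        phi_common = float(max(np.median(phi) if len(phi) else 0.0, 1e-8))
    if phi_common <= 0:
        raise ValueError("phi_common must be > 0")
    q = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    values = (2.0 / (np.sqrt(phi_common) * LN2)) * np.arcsinh(
        np.sqrt(phi_common * q))
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def log_transform(counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    """log2(count/sf + 1) fallback transform."""
    q = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    return pd.DataFrame(np.log2(q + 1.0), index=counts.index,
                        columns=counts.columns)


def _covariate_columns(samples: pd.DataFrame,
                       covariate: str) -> tuple[np.ndarray, list[str]]:
    """Encode one covariate: categoricals as drop-first dummies, numerics as is."""
    col = samples[covariate]
    if covariate in ("nas", "fibrosis") or pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)[:, None], [covariate]
    levels = sorted(pd.unique(col.astype(str)))
    cols, names = [], []
    for level in levels[1:]:
        cols.append((col.astype(str) == level).to_numpy(dtype=float)[:, None])
        names.append(f"{covariate}[{level}]")
    if not cols:
        return np.empty((len(samples), 0)), []
    return np.hstack(cols), names


def residualize_covariates(expr: pd.DataFrame, samples: pd.DataFrame,
                           remove: list[str],
                           keep: list[str] | None = None) -> pd.DataFrame:
    """Remove additive nuisance covariate effects from an expression matrix.

    Per gene, an ordinary-least-squares fit on the full design (intercept +
    remove + keep covariates) is computed; the returned value is the
    observed value minus the mean-centred fitted contribution of the
    ``remove`` covariates, so gene means and the structure of ``keep``
    covariates are untouched. Idempotent. Raises if the design is
    rank-deficient, naming the aliased columns.
    """
    keep = keep or []
    samples = samples.loc[expr.columns]
    blocks, names, owner = [np.ones((len(samples), 1))], ["intercept"], [None]
    for cov in list(remove) + list(keep):
        block, block_names = _covariate_columns(samples, cov)
        blocks.append(block)
        names.extend(block_names)
        owner.extend([cov] * len(block_names))
    X = np.hstack(blocks)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by pivoted QR: small diagonal of R
        _, R, piv = _qr_pivot(X)
        aliased = [names[piv[i]] for i in range(rank, X.shape[1])]
        raise ValueError(f"design is rank-deficient; aliased columns: {aliased}")
    Y = expr.to_numpy(dtype=float).T          # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    remove_cols = [i for i, cov in enumerate(owner) if cov in set(remove)]
    if not remove_cols:
        return expr.copy()
    Xr = X[:, remove_cols]
    contribution = Xr @ beta[remove_cols]
    contribution -= contribution.mean(axis=0, keepdims=True)
    adjusted = (Y - contribution).T
    return pd.DataFrame(adjusted, index=expr.index, columns=expr.columns)


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr
    Q, R, piv = qr(X, pivoting=True)
    return Q, R, piv
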