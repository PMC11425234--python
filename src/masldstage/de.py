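"""Per-gene negative-binomial GLM with ordinal severity covariates.

NAS (0-8) and fibrosis stage (0-4) enter as numeric linear covariates — the
DEG thresholds are stated per unit change — alongside batch and sex
nuisance terms. Each gene is fit by IRLS with a log link and a log
size-factor offset, starting from a Poisson fit; the per-gene dispersion is
estimated by maximum likelihood with a bounded search on log-phi, and two
rounds of (beta | phi) updates are alternated. Coefficients are reported in
log2 units (natural-log estimates divided by ln 2), standard errors come
from the inverse observed information at the optimum, and Wald tests with
Benjamini-Hochberg adjustment drive DEG calling. No dispersion or LFC
shrinkage is applied: the model is exactly specifiable and testable, at the
cost of slightly noisier dispersion estimates than shrinkage frameworks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

LN2 = float(np.log(2.0))
_PHI_BOUNDS = (np.log(1e-8), np.log(10.0))
_MU_FLOOR = 1e-8
_ETA_CLIP = 30.0

DEG_UP = "up"
DEG_DOWN = "down"
DEG_NONE = "none"


@dataclass(frozen=True)
class DEGThresholds:
    """Effect-size and significance thresholds for DEG calling.

    ``lfc_nas``/``lfc_fib`` are log2 fold changes per unit of NAS and per
    fibrosis stage; ``mouse_lfc`` applies in two-group mode.
    """

    lfc_nas: float = 0.1
    lfc_fib: float = 0.2
    alpha: float = 0.05
    mouse_lfc: float = 1.0

    def __post_init__(self):
        if min(self.lfc_nas, self.lfc_fib, self.alpha, self.mouse_lfc) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class GeneFit:
    """Fitted NB GLM for one gene: log2-scale betas/SEs, dispersion, loglik."""

    beta_log2: dict[str, float]
    se_log2: dict[str, float]
    phi: float
    converged: bool
    loglik: float
    mu: np.ndarray = field(repr=False, default=None)


def build_design(samples: pd.DataFrame,
                 covariates: tuple[str, ...] = ("batch", "sex", "nas",
                                                "fibrosis"),
                 ) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, batch dummies (drop-first), sex, NAS, fibrosis.

    Categorical covariates with a single observed level contribute no
    columns. Raises on rank deficiency, naming aliased columns.
    """
    cols = [np.ones(len(samples))]
    names = ["intercept"]
    for cov in covariates:
        if cov in ("nas", "fibrosis"):
            values = samples[cov].to_numpy(dtype=float)
            if np.isnan(values).any():
                raise ValueError(f"covariate {cov!r} has missing values")
            cols.append(values)
            names.append(cov)
        else:
            levels = sorted(pd.unique(samples[cov].astype(str)))
            for level in levels[1:]:
                cols.append((samples[cov].astype(str) == level)
                            .to_numpy(dtype=float))
                names.append(f"{cov}[{level}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr
        _, _, piv = qr(X, pivoting=True)
        aliased = [names[piv[i]] for i in range(rank, X.shape[1])]
        raise ValueError(f"design is rank-deficient; aliased columns: {aliased}")
    return X, names


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """NB2 log-likelihood, Var = mu + phi mu^2."""
    if phi < 1e-10:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    inv = 1.0 / phi
    return float(np.sum(
        special.gammaln(y + inv) - special.gammaln(inv)
        - special.gammaln(y + 1)
        + y * np.log(phi * mu / (1.0 + phi * mu))
        - inv * np.log1p(phi * mu)))


def _irls(y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: float,
          beta0: np.ndarray | None = None, max_iter: int = 50,
          tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS for the log-link NB GLM at fixed dispersion (phi=0: Poisson).

    Returns (beta on the natural-log scale, fitted mu, converged).
    """
    n, p = X.shape
    if beta0 is None:
        beta = np.zeros(p)
        beta[0] = np.log(max(np.mean(y / np.exp(offset)), _MU_FLOOR))
    else:
        beta = beta0.copy()
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
        mu = np.maximum(np.exp(eta), _MU_FLOOR)
        W = mu / (1.0 + phi * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * W
        try:
            new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            break
        step = new - beta
        beta = new
        if np.max(np.abs(step)) < tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break
    eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
    return beta, np.maximum(np.exp(eta), _MU_FLOOR), converged


def fit_gene_model(counts_g: np.ndarray, X: np.ndarray, names: list[str],
                   sf: np.ndarray, n_rounds: int = 2) -> GeneFit | None:
    """Fit the NB GLM for one gene; ``None`` for an all-zero gene.

    Alternates ``n_rounds`` of dispersion ML (bounded line search on
    log-phi in [1e-8, 10] at fixed fitted means) and IRLS beta updates at
    the fixed dispersion, starting from a Poisson fit.
    """
    y = np.asarray(counts_g, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("counts length does not match design rows")
    sf = np.asarray(sf, dtype=float)
    if np.any(sf <= 0):
        raise ValueError("size factors must be positive")
    if not np.any(y > 0):
        return None
    offset = np.log(sf)

    beta, mu, ok = _irls(y, X, offset, phi=0.0)
    phi = 1e-8
    for _ in range(n_rounds):
        res = optimize.minimize_scalar(
            lambda lp: -_nb_loglik(y, mu, np.exp(lp)),
            bounds=_PHI_BOUNDS, method="bounded",
            options={"xatol": 1e-6})
        phi = float(np.exp(res.x))
        beta, mu, ok = _irls(y, X, offset, phi, beta0=beta)
    W = mu / (1.0 + phi * mu)
    info = (X.T * W) @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
        ok = False
    return GeneFit(
        beta_log2={n: b / LN2 for n, b in zip(names, beta)},
        se_log2={n: s / LN2 for n, s in zip(names, se)},
        phi=phi, converged=bool(ok),
        loglik=_nb_loglik(y, mu, phi), mu=mu)


def wald_test(fit: GeneFit, coef: str) -> tuple[float, float]:
    """Wald z and two-sided normal p for one coefficient.

    The ratio beta/se is scale-free, so the log2-reported values give the
    same statistic as the natural-log ones. Zero SE yields (nan, nan).
    """
    beta = fit.beta_log2[coef]
    se = fit.se_log2[coef]
    if not np.isfinite(se) or se == 0.0:
        return np.nan, np.nan
    z = beta / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def adjust_bh(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries stay NaN."""
    arr = np.asarray(p, dtype=float)
    mask = ~np.isnan(arr)
    if ((arr[mask] < 0) | (arr[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(arr, np.nan)
    if mask.any():
        out[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    return out


def fit_severity_de(counts: pd.DataFrame, samples: pd.DataFrame,
                    sf: pd.Series,
                    covariates: tuple[str, ...] = ("batch", "sex", "nas",
                                                   "fibrosis"),
                    thresholds: DEGThresholds | None = None) -> pd.DataFrame:
    """Fit the severity NB GLM for every gene and call DEGs.

    Returns a table with per-gene beta_nas/beta_fib (log2 per covariate
    unit), SEs, dispersion, base mean, Wald p-values, per-covariate BH
    adjusted p-values and a ``deg_call``. All-zero genes carry NaN
    statistics and deg_call ``none``. BH is applied separately per
    covariate (conservative; the two covariates are tested separately).
    """
    samples = samples.loc[counts.columns]
    X, names = build_design(samples, covariates)
    sf_arr = sf.loc[counts.columns].to_numpy()
    rows = []
    for gene in counts.index:
        fit = fit_gene_model(counts.loc[gene].to_numpy(), X, names, sf_arr)
        if fit is None:
            rows.append(dict(gene_id=gene, base_mean=0.0, converged=False,
                             beta_nas=np.nan, beta_fib=np.nan,
                             se_nas=np.nan, se_fib=np.nan, phi=np.nan,
                             p_nas=np.nan, p_fib=np.nan))
            continue
        _, p_nas = wald_test(fit, "nas")
        _, p_fib = wald_test(fit, "fibrosis")
        rows.append(dict(
            gene_id=gene,
            base_mean=float(np.mean(counts.loc[gene].to_numpy() / sf_arr)),
            converged=fit.converged,
            beta_nas=fit.beta_log2["nas"], beta_fib=fit.beta_log2["fibrosis"],
            se_nas=fit.se_log2["nas"], se_fib=fit.se_log2["fibrosis"],
            phi=fit.phi, p_nas=p_nas, p_fib=p_fib))
    table = pd.DataFrame(rows).set_index("gene_id")
    table["padj_nas"] = adjust_bh(table["p_nas"])
    table["padj_fib"] = adjust_bh(table["p_fib"])
    return call_severity_degs(table, thresholds or DEGThresholds())


def call_severity_degs(table: pd.DataFrame,
                       th: DEGThresholds | None = None) -> pd.DataFrame:
    """Fill ``deg_call``: up/down per the per-unit LFC and FDR thresholds.

    A gene is up if (beta_nas > lfc_nas and padj_nas < alpha) or
    (beta_fib > lfc_fib and padj_fib < alpha); down symmetrically with
    negative betas (strict inequalities). Genes qualifying in opposite
    directions on the two covariates are flagged ``ambiguous`` and called
    ``none`` — signature curation needs a single direction.
    """
    th = th or DEGThresholds()
    out = table.copy()
    up_nas = (out["beta_nas"] > th.lfc_nas) & (out["padj_nas"] < th.alpha)
    up_fib = (out["beta_fib"] > th.lfc_fib) & (out["padj_fib"] < th.alpha)
    dn_nas = (out["beta_nas"] < -th.lfc_nas) & (out["padj_nas"] < th.alpha)
    dn_fib = (out["beta_fib"] < -th.lfc_fib) & (out["padj_fib"] < th.alpha)
    up = (up_nas | up_fib).fillna(False)
    down = (dn_nas | dn_fib).fillna(False)
    ambiguous = up & down
    call = np.where(ambiguous, DEG_NONE,
                    np.where(up, DEG_UP, np.where(down, DEG_DOWN, DEG_NONE)))
    out["deg_call"] = call
    out["ambiguous"] = ambiguous
    return out


def cluster_deg_patterns(expr: pd.DataFrame, samples: pd.DataFrame,
                         k: int = 3) -> pd.Series:
    """Hierarchically cluster DEG severity profiles into ``k`` pattern groups.

    The per-gene profile is the mean z-scored expression per observed NAS
    level; Ward-linkage agglomerative clustering on Euclidean distances.
    Deterministic given input order.
    """
    from sklearn.cluster import AgglomerativeClustering

    if expr.shape[0] < k:
        raise ValueError(f"need at least k={k} genes, got {expr.shape[0]}")
    samples = samples.loc[expr.columns]
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    z = (values - values.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    nas = samples["nas"].to_numpy(dtype=float)
    levels = np.unique(nas[~np.isnan(nas)])
    profile = np.column_stack([z[:, nas == lv].mean(axis=1) for lv in levels])
    if k == 1:
        labels = np.zeros(expr.shape[0], dtype=int)
    else:
        model = AgglomerativeClustering(n_clusters=k, linkage="ward")
        labels = model.fit_predict(profile)
    return pd.Series(labels, index=expr.index, name="cluster")


def two_group_mouse_degs(counts: pd.DataFrame, samples: pd.DataFrame,
                         th: DEGThresholds | None = None,
                         group_col: str = "group") -> pd.DataFrame:
    """Two-group NB GLM DEG test (e.g. one diet timepoint vs control).

    The model has a single binary group covariate; DEG rule
    |log2FC| > ``mouse_lfc`` and BH-adjusted p < alpha. The log fold change
    is for the lexicographically later group relative to the earlier one.
    """
    th = th or DEGThresholds()
    samples = samples.loc[counts.columns]
    groups = sorted(pd.unique(samples[group_col].astype(str)))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    sizes = samples[group_col].value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"group(s) with fewer than 2 samples: "
                         f"{list(small.index)}")
    indicator = (samples[group_col].astype(str) == groups[1]).to_numpy(float)
    X = np.column_stack([np.ones(len(samples)), indicator])
    names = ["intercept", "group"]
    sf = median_of_ratios_size_factors_safe(counts)
    sf_arr = sf.to_numpy()
    rows = []
    for gene in counts.index:
        fit = fit_gene_model(counts.loc[gene].to_numpy(), X, names, sf_arr)
        if fit is None:
            rows.append(dict(gene_id=gene, lfc=np.nan, se=np.nan, phi=np.nan,
                             p=np.nan, converged=False))
            continue
        _, p = wald_test(fit, "group")
        rows.append(dict(gene_id=gene, lfc=fit.beta_log2["group"],
                         se=fit.se_log2["group"], phi=fit.phi, p=p,
                         converged=fit.converged))
    table = pd.DataFrame(rows).set_index("gene_id")
    table["padj"] = adjust_bh(table["p"])
    sig = (table["lfc"].abs() > th.mouse_lfc) & (table["padj"] < th.alpha)
    sig = sig.fillna(False)
    table["deg_call"] = np.where(
        sig & (table["lfc"] > 0), DEG_UP,
        np.where(sig & (table["lfc"] < 0), DEG_DOWN, DEG_NONE))
    return table


def median_of_ratios_size_factors_safe(counts: pd.DataFrame) -> pd.Series:
    """Size factors with automatic pseudo-reference fallback."""
    from masldstage.normalize import median_of_ratios_size_factors
    try:
        return median_of_ratios_size_factors(counts)
    except ValueError:
        return median_of_ratios_size_factors(counts, pseudo_reference=True)
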