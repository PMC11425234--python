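"""Boruta shadow-feature selection and signature curation.

Boruta is an all-relevant wrapper: each iteration appends a permuted
"shadow" copy of every surviving candidate column, fits a feature-importance
regressor on [real | shadow], and records a hit for each real feature whose
importance strictly exceeds the maximum shadow importance. Accumulated hits
are tested against Binomial(n, 1/2) with a two-sided binomial test at a
Bonferroni-corrected level; upward rejection confirms a feature, downward
rejection removes it from subsequent iterations, and anything undecided
when the iteration budget runs out stays tentative.

The selection logic is the point here and is independent of the estimator,
which is pluggable: the default is a random-forest regressor with
sqrt-feature subsampling (full-feature greedy forests starve correlated
relevant features of importance, which defeats all-relevant selection).

Curation then applies the two signature filters: keep only confirmed genes
that are positively associated with disease progression (deg_call ``up``)
and have a mouse ortholog; order by descending beta_nas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

STATUS_CONFIRMED = "confirmed"
STATUS_TENTATIVE = "tentative"
STATUS_REJECTED = "rejected"


@dataclass
class BorutaParams:
    n_iter: int = 100
    alpha: float = 0.05
    estimator: object | None = None   # sklearn-like, exposes feature_importances_
    seed: int = 0
    n_trees: int = 200                # for the default random forest
    correction: str = "bonferroni"

    def __post_init__(self):
        if self.n_iter < 10:
            raise ValueError("n_iter must be >= 10")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction != "bonferroni":
            raise ValueError("only bonferroni correction is supported")


@dataclass
class BorutaResult:
    """Per-feature selection outcome.

    ``table`` columns: status, hit_count, n_iter_seen, decision_iteration
    (NaN while tentative).
    """

    table: pd.DataFrame
    n_iter_run: int

    @property
    def confirmed(self) -> list[str]:
        return list(self.table.index[self.table["status"] == STATUS_CONFIRMED])

    @property
    def rejected(self) -> list[str]:
        return list(self.table.index[self.table["status"] == STATUS_REJECTED])

    @property
    def tentative(self) -> list[str]:
        return list(self.table.index[self.table["status"] == STATUS_TENTATIVE])


@dataclass
class GeneSignature:
    """Ordered severity signature: human genes, direction, mouse orthologs.

    Every member carries all four provenance flags (deg, boruta_confirmed,
    positive_assoc, has_ortholog) true; direction is ``up`` only.
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["human_gene", "direction", "mouse_gene", "deg",
                 "boruta_confirmed", "positive_assoc", "has_ortholog"]))
    name: str = "MASLD_UNIFIED"

    @property
    def human_genes(self) -> list[str]:
        return list(self.table["human_gene"])

    @property
    def mouse_genes(self) -> list[str]:
        return list(self.table["mouse_gene"])

    def __len__(self) -> int:
        return len(self.table)


def _default_estimator(n_trees: int, random_state: int):
    from sklearn.ensemble import RandomForestRegressor
    return RandomForestRegressor(n_estimators=n_trees, max_features="sqrt",
                                 random_state=random_state, n_jobs=1)


def _importances(estimator, X: np.ndarray, y: np.ndarray,
                 random_state: int, n_trees: int) -> np.ndarray:
    if estimator is None:
        model = _default_estimator(n_trees, random_state)
    else:
        from sklearn.base import clone
        model = clone(estimator)
        if "random_state" in model.get_params():
            model.set_params(random_state=random_state)
    model.fit(X, y)
    return np.asarray(model.feature_importances_, dtype=float)


def boruta_select(features: pd.DataFrame, target: np.ndarray | pd.Series,
                  params: BorutaParams | None = None) -> BorutaResult:
    """Run Boruta all-relevant selection of ``features`` against ``target``.

    ``features`` is samples x candidate genes; ``target`` a numeric
    severity vector (regression mode). Deterministic under ``params.seed``.
    """
    params = params or BorutaParams()
    y = np.asarray(target, dtype=float)
    if features.shape[0] < 20:
        raise ValueError("Boruta needs at least 20 samples")
    if features.shape[1] < 1:
        raise ValueError("no candidate features supplied")
    if y.shape[0] != features.shape[0]:
        raise ValueError("target length does not match feature rows")
    if np.std(y) == 0:
        raise ValueError("target has zero variance")

    names = list(features.columns)
    n_initial = len(names)
    alpha_corr = params.alpha / n_initial
    X_all = features.to_numpy(dtype=float)
    rng = np.random.default_rng(params.seed)
    seeds = rng.integers(0, 2**31 - 1, size=params.n_iter)

    hits = dict.fromkeys(names, 0)
    seen = dict.fromkeys(names, 0)
    status = dict.fromkeys(names, STATUS_TENTATIVE)
    decision_iter: dict[str, float] = dict.fromkeys(names, np.nan)
    active = list(names)

    for it in range(params.n_iter):
        if not active:
            break
        idx = [names.index(a) for a in active]
        X = X_all[:, idx]
        shadows = np.column_stack(
            [rng.permutation(X[:, j]) for j in range(X.shape[1])])
        imp = _importances(None if params.estimator is None else params.estimator,
                           np.hstack([X, shadows]), y,
                           random_state=int(seeds[it]),
                           n_trees=params.n_trees)
        real_imp = imp[:X.shape[1]]
        shadow_max = imp[X.shape[1]:].max()
        for a, im in zip(active, real_imp):
            seen[a] += 1
            if im > shadow_max:
                hits[a] += 1
        # binomial decisions on everything still active
        still = []
        for a in active:
            h, n = hits[a], seen[a]
            p_two = float(stats.binomtest(h, n, 0.5).pvalue)
            if p_two < alpha_corr and h > n / 2:
                status[a] = STATUS_CONFIRMED
                decision_iter[a] = it + 1
                still.append(a)     # confirmed features keep competing
            elif p_two < alpha_corr and h < n / 2:
                status[a] = STATUS_REJECTED
                decision_iter[a] = it + 1
            else:
                still.append(a)
        active = [a for a in still if status[a] != STATUS_REJECTED]
        if all(status[a] != STATUS_TENTATIVE for a in names):
            break

    table = pd.DataFrame({
        "status": [status[a] for a in names],
        "hit_count": [hits[a] for a in names],
        "n_iter_seen": [seen[a] for a in names],
        "decision_iteration": [decision_iter[a] for a in names],
    }, index=pd.Index(names, name="gene_id"))
    return BorutaResult(table=table, n_iter_run=min(params.n_iter,
                                                    int(max(seen.values(),
                                                            default=0))))


def _resolve_ortholog(human_gene: str, orth: pd.DataFrame) -> str | None:
    """Pick the mouse partner: the one_to_one entry, else the smallest symbol."""
    rows = orth[orth["human_gene"] == human_gene]
    if rows.empty:
        return None
    one = rows[rows["one_to_one"]]
    if len(one):
        return str(one["mouse_gene"].iloc[0])
    partners = sorted(rows["mouse_gene"])
    if len(partners) > 1:
        warnings.warn(
            f"human gene {human_gene!r} has {len(partners)} mouse partners; "
            f"using lexicographically smallest {partners[0]!r}")
    return partners[0]


def curate_signature(boruta: BorutaResult, de: pd.DataFrame,
                     orth: pd.DataFrame,
                     name: str = "MASLD_UNIFIED") -> GeneSignature:
    """Filter Boruta-confirmed genes into the unified severity signature.

    Retains genes that are confirmed, called ``up`` (positively associated
    with disease progression) and linked to a mouse ortholog; ordered by
    descending beta_nas. Empty results return an empty signature with a
    warning, not an error.
    """
    confirmed = set(boruta.confirmed)
    rows = []
    for gene in de.index:
        if gene not in confirmed:
            continue
        if de.loc[gene, "deg_call"] != "up":
            continue
        mouse = _resolve_ortholog(str(gene), orth)
        if mouse is None:
            continue
        rows.append(dict(human_gene=str(gene), direction="up",
                         mouse_gene=mouse, beta_nas=float(de.loc[gene, "beta_nas"]),
                         deg=True, boruta_confirmed=True, positive_assoc=True,
                         has_ortholog=True))
    if not rows:
        warnings.warn("signature curation produced an empty signature")
        return GeneSignature(name=name)
    table = (pd.DataFrame(rows)
             .sort_values("beta_nas", ascending=False, kind="mergesort")
             .drop(columns="beta_nas")
             .reset_index(drop=True))
    return GeneSignature(table=table, name=name)


def translate_signature(sig: GeneSignature, orth: pd.DataFrame,
                        to_species: str = "mouse") -> list[str]:
    """Map the signature into the target species namespace, order preserved."""
    if to_species == "human":
        return sig.human_genes
    if to_species != "mouse":
        raise ValueError(f"unknown target species {to_species!r}")
    out = []
    for gene in sig.human_genes:
        mouse = _resolve_ortholog(gene, orth)
        if mouse is None:
            raise ValueError(f"signature gene {gene!r} has no mouse ortholog")
        out.append(mouse)
    return out
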