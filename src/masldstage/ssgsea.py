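"""Single-sample gene-set enrichment (ssGSEA) scores.

For one sample, genes are ordered by descending expression (ties broken
deterministically by gene identifier) and assigned rank weights
``r_i = n - position + 1`` (the top gene gets weight n). With weight
exponent alpha, the enrichment score is the summed difference of two
cumulative distributions walked down the ranking:

    ES = sum_i [ P_in(i) - P_out(i) ]
    P_in(i)  = sum_{j<=i, g_j in S} r_j^alpha / sum_{g in S} r_g^alpha
    P_out(i) = |{j<=i, g_j not in S}| / (n - |S|)

The score depends only on the ordering of a sample's values, so any
strictly monotone transform of one sample's expression leaves its ES
unchanged. With alpha=0 it reduces to the summed difference of unweighted
ECDFs. Raw (unnormalized) ES is the default staging statistic — staging
uses within-analysis ranks, which range normalization cannot change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ScoringParams:
    alpha: float = 0.25
    normalize: str = "none"     # "none" or "range"

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.normalize not in ("none", "range"):
            raise ValueError("normalize must be 'none' or 'range'")


def ssgsea_sample(expr_values: pd.Series, gene_set: Iterable[str],
                  params: ScoringParams | None = None,
                  set_name: str = "gene_set") -> float:
    """Enrichment score of one gene set in one sample.

    ``expr_values`` is indexed by gene identifier. The set must intersect
    the measured genes but not cover all of them.
    """
    params = params or ScoringParams()
    genes = expr_values.index.to_numpy(dtype=object)
    n = len(genes)
    if n < 2:
        raise ValueError("need at least 2 genes to score a sample")
    members = set(gene_set)
    in_set = np.array([g in members for g in genes])
    k = int(in_set.sum())
    if k == 0:
        raise ValueError(f"gene set {set_name!r} shares no gene with the sample")
    if k == n:
        raise ValueError(f"gene set {set_name!r} covers every measured gene")

    values = expr_values.to_numpy(dtype=float)
    # descending expression, ties broken by ascending gene identifier
    order = np.lexsort((genes, -values))
    in_sorted = in_set[order]
    ranks = np.arange(n, 0, -1, dtype=float)    # position 1 -> weight n
    w = ranks ** params.alpha
    win = np.where(in_sorted, w, 0.0)
    p_in = np.cumsum(win) / win.sum()
    p_out = np.cumsum(~in_sorted) / (n - k)
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(expr: pd.DataFrame, gene_set: Sequence[str],
                  params: ScoringParams | None = None,
                  set_name: str = "gene_set",
                  min_fraction: float = 0.5) -> pd.DataFrame:
    """Per-sample enrichment scores for one signature over a matrix.

    Signature members absent from the matrix are dropped with a warning;
    more than half missing is an error listing the missing genes. Returns a
    table with raw ES, range-normalized ES (if enabled, else NaN) and ranks
    by descending ES with average-rank ties.
    """
    params = params or ScoringParams()
    members = list(dict.fromkeys(gene_set))
    present = [g for g in members if g in expr.index]
    missing = [g for g in members if g not in expr.index]
    if len(present) < min_fraction * len(members) or not present:
        raise ValueError(
            f"{len(missing)}/{len(members)} genes of set {set_name!r} absent "
            f"from the expression matrix: {missing}")
    if missing:
        import warnings
        warnings.warn(f"set {set_name!r}: dropping {len(missing)} missing "
                      f"gene(s): {missing}")
    es = np.array([
        ssgsea_sample(expr[col], present, params, set_name=set_name)
        for col in expr.columns])
    table = pd.DataFrame({"es": es}, index=pd.Index(expr.columns,
                                                    name="sample_id"))
    if params.normalize == "range":
        span = es.max() - es.min()
        table["es_normalized"] = ((es - es.min()) / span if span > 0
                                  else np.full_like(es, 0.5))
    else:
        table["es_normalized"] = np.nan
    table["rank"] = stats.rankdata(-es, method="average")
    return table
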