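"""Rank-based disease stratification and cross-species severity mapping.

Query samples (e.g. a mouse time-course) scored with the translated
signature are placed on the human severity scale by nearest-neighbour
matching in enrichment-score space: each query inherits the median NAS and
fibrosis stage of its k score-nearest graded human reference samples.
Enrichment-score magnitudes are cohort-dependent, so reference and query
must be scored with the same signature and scoring parameters; ranks over
the pooled score vector are the comparable quantity.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from masldstage.de import DEG_DOWN, DEG_NONE, DEG_UP


def spearman_validate(scores: pd.Series | np.ndarray,
                      severity: pd.Series | np.ndarray,
                      exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation between enrichment scores and histology.

    Average-rank tie handling; p-value from the large-sample t
    approximation, or by exhaustive permutation when ``exact`` is set
    (n <= 10 only).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(severity, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("scores and severity must be paired")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(y == y[0]):
        raise ValueError("severity is constant; correlation undefined")
    rho, p = stats.spearmanr(x, y)
    if exact:
        if x.shape[0] > 10:
            raise ValueError("exact permutation p available only for n <= 10")
        ry = stats.rankdata(y)
        count = 0
        total = 0
        for perm in permutations(stats.rankdata(x)):
            r = stats.pearsonr(np.asarray(perm), ry)[0]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        p = count / total
    return float(rho), float(p)


def rank_map_to_human(query: pd.DataFrame, reference: pd.DataFrame,
                      reference_samples: pd.DataFrame,
                      k: int = 5) -> pd.DataFrame:
    """Map query samples onto the human severity scale by score neighbours.

    ``query`` and ``reference`` are enrichment tables (with an ``es``
    column); ``reference_samples`` carries NAS/fibrosis for the reference.
    Each query sample's k nearest reference samples in absolute ES
    difference (ties broken by reference sample identifier) define its
    neighbours; mapped NAS/fibrosis are the medians of the neighbours'
    scores. Ranks are computed over the pooled reference+query ES vector.
    """
    ref = reference.join(reference_samples[["nas", "fibrosis"]], how="inner")
    ref = ref.dropna(subset=["nas", "fibrosis"])
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(ref) < k:
        raise ValueError(f"k={k} exceeds the {len(ref)} graded reference "
                         "samples")
    pooled = pd.concat([reference["es"], query["es"]])
    pooled_rank = pd.Series(stats.rankdata(-pooled.to_numpy(),
                                           method="average"),
                            index=pooled.index)
    ref_ids = ref.index.to_numpy(dtype=object)
    ref_es = ref["es"].to_numpy(dtype=float)
    rows = []
    for sid, es in query["es"].items():
        diff = np.abs(ref_es - es)
        order = np.lexsort((ref_ids, diff))[:k]
        neighbors = ref_ids[order]
        rows.append(dict(
            sample_id=sid, es=float(es),
            rank=float(pooled_rank.loc[sid]),
            mapped_nas=float(np.median(ref["nas"].to_numpy()[order])),
            mapped_fibrosis=float(np.median(ref["fibrosis"].to_numpy()[order])),
            neighbors=",".join(map(str, neighbors))))
    return pd.DataFrame(rows).set_index("sample_id")


def cross_species_deg_overlap(human_de: pd.DataFrame,
                              mouse_de_by_timepoint: dict[str, pd.DataFrame],
                              orth: pd.DataFrame) -> pd.DataFrame:
    """Count concordant/discordant DEG ortholog pairs per mouse timepoint.

    A common DEG is an ortholog pair called a DEG in both species;
    concordant-up when up in both, concordant-down when down in both, else
    discordant.
    """
    if orth is None or len(orth) == 0:
        raise ValueError("ortholog map is empty")
    human_calls = human_de["deg_call"]
    rows = []
    for label, mouse_de in mouse_de_by_timepoint.items():
        mouse_calls = mouse_de["deg_call"]
        n_up = n_down = n_disc = 0
        for hgene, mgene in zip(orth["human_gene"], orth["mouse_gene"]):
            hcall = human_calls.get(hgene, DEG_NONE)
            mcall = mouse_calls.get(mgene, DEG_NONE)
            if hcall == DEG_NONE or mcall == DEG_NONE:
                continue
            if hcall == DEG_UP and mcall == DEG_UP:
                n_up += 1
            elif hcall == DEG_DOWN and mcall == DEG_DOWN:
                n_down += 1
            else:
                n_disc += 1
        rows.append(dict(timepoint=label, n_common_up=n_up,
                         n_common_down=n_down, n_discordant=n_disc))
    return pd.DataFrame(rows).set_index("timepoint")
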