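"""Synthetic multi-cohort liver RNA-seq with planted severity structure.

Emulates the statistical structure a transcriptomic-staging meta-analysis
assumes: several human cohorts with batch and sex effects, negative-binomial
counts, a subset of genes whose log2-mean shifts per unit of NAS (0-8) and
fibrosis stage (0-4) in three pattern clusters (monotone-down, monotone-up,
up-then-down), correlated NAS/fibrosis annotations, and a mouse time-course
whose ortholog-linked genes carry increasing planted severity. Every planted
effect is recorded in a :class:`GroundTruth` so downstream stages can be
checked against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from masldstage.io import ortholog_map_from_frame

CLUSTER_NONE = "none"
CLUSTER_DOWN = "down"
CLUSTER_UP = "up"
CLUSTER_UP_THEN_DOWN = "up_then_down"

#: NAS level above which the up-then-down cluster's slope reverses sign.
UP_THEN_DOWN_BREAKPOINT = 5.0


@dataclass(frozen=True)
class GenConfig:
    """Generator configuration.

    Effect sizes are in log2 units per covariate unit so planted values are
    directly comparable to DEG-calling thresholds. Log-normal parameters are
    (location, scale) of the underlying normal on the natural-log scale.
    """

    n_genes: int = 2000
    n_cohorts: int = 2
    samples_per_cohort: int = 75
    frac_severity_genes: float = 0.10
    cluster_mix: tuple[float, float, float] = (0.3, 0.5, 0.2)  # down/up/up-then-down
    beta_nas_range: tuple[float, float] = (0.15, 0.40)   # log2 per NAS unit
    beta_fib_range: tuple[float, float] = (0.25, 0.50)   # log2 per fibrosis stage
    batch_sd: float = 0.30          # log2 units, per (gene, cohort)
    sex_effect_sd: float = 0.20     # log2 units, per gene
    baseline_logmean_params: tuple[float, float] = (3.5, 1.5)
    dispersion_params: tuple[float, float] = (-3.0, 0.5)   # median phi ~ 0.05
    libsize_params: tuple[float, float] = (0.0, 0.15)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_cohorts < 1 or self.samples_per_cohort < 1:
            raise ValueError("n_genes, n_cohorts and samples_per_cohort must be >= 1")
        if not 0.0 <= self.frac_severity_genes <= 1.0:
            raise ValueError("frac_severity_genes must lie in [0, 1]")
        if len(self.cluster_mix) != 3 or any(f < 0 for f in self.cluster_mix):
            raise ValueError("cluster_mix must be three non-negative fractions")
        if abs(sum(self.cluster_mix) - 1.0) > 1e-9:
            raise ValueError("cluster_mix must sum to 1 within 1e-9")
        for name in ("beta_nas_range", "beta_fib_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi")
        if self.batch_sd < 0 or self.sex_effect_sd < 0:
            raise ValueError("effect standard deviations must be >= 0")


@dataclass
class GroundTruth:
    """Planted parameters of one generated dataset.

    ``genes`` carries per-gene beta_nas/beta_fib (log2 per covariate unit),
    cluster_label, dispersion phi and sex effect; ``samples`` the true NAS,
    fibrosis and library size per sample; ``batch_offsets`` the per-cohort,
    per-gene log2 shifts.
    """

    genes: pd.DataFrame
    samples: pd.DataFrame
    batch_offsets: pd.DataFrame = field(default_factory=pd.DataFrame)


def fibrosis_from_nas(nas: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Fibrosis stage as a noisy deterministic function of NAS.

    ``clamp(round(NAS/2 + eps), 0, 4)`` — mimics the clinical correlation
    between the two ordinal severity scores.
    """
    nas = np.asarray(nas, dtype=float)
    eps = np.asarray(eps, dtype=float)
    return np.clip(np.rint(nas / 2.0 + eps), 0, 4).astype(int)


def sample_severity_pair(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw correlated (NAS, fibrosis) annotations for ``n`` samples.

    NAS is uniform on the integers 0..8; fibrosis follows
    :func:`fibrosis_from_nas` with eps ~ Normal(0, 0.5).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    nas = rng.integers(0, 9, size=n)
    eps = rng.normal(0.0, 0.5, size=n)
    return nas.astype(int), fibrosis_from_nas(nas, eps)


def _nas_contribution(beta_nas: np.ndarray, cluster: np.ndarray,
                      nas: np.ndarray) -> np.ndarray:
    """Per-gene x per-sample log2 contribution of the NAS covariate.

    Monotone clusters contribute ``beta * NAS``; the up-then-down cluster
    rises with slope ``beta`` up to the breakpoint and falls with slope
    ``-beta`` beyond it.
    """
    beta = beta_nas[:, None]
    nas = nas[None, :].astype(float)
    rising = beta * np.minimum(nas, UP_THEN_DOWN_BREAKPOINT)
    falling = -beta * np.maximum(nas - UP_THEN_DOWN_BREAKPOINT, 0.0)
    piecewise = rising + falling
    linear = beta * nas
    return np.where((cluster == CLUSTER_UP_THEN_DOWN)[:, None], piecewise, linear)


def _assign_clusters(rng: np.random.Generator, cfg: GenConfig,
                     gene_ids: np.ndarray) -> pd.DataFrame:
    n_sev = int(round(cfg.frac_severity_genes * cfg.n_genes))
    sev_idx = rng.choice(cfg.n_genes, size=n_sev, replace=False)
    labels = np.full(cfg.n_genes, CLUSTER_NONE, dtype=object)
    n_down = int(round(cfg.cluster_mix[0] * n_sev))
    n_up = int(round(cfg.cluster_mix[1] * n_sev))
    order = rng.permutation(sev_idx)
    labels[order[:n_down]] = CLUSTER_DOWN
    labels[order[n_down:n_down + n_up]] = CLUSTER_UP
    labels[order[n_down + n_up:]] = CLUSTER_UP_THEN_DOWN

    beta_nas = np.zeros(cfg.n_genes)
    beta_fib = np.zeros(cfg.n_genes)
    mag_nas = rng.uniform(*cfg.beta_nas_range, size=cfg.n_genes)
    mag_fib = rng.uniform(*cfg.beta_fib_range, size=cfg.n_genes)
    beta_nas[labels == CLUSTER_UP] = mag_nas[labels == CLUSTER_UP]
    beta_nas[labels == CLUSTER_DOWN] = -mag_nas[labels == CLUSTER_DOWN]
    beta_nas[labels == CLUSTER_UP_THEN_DOWN] = mag_nas[labels == CLUSTER_UP_THEN_DOWN]
    beta_fib[labels == CLUSTER_UP] = mag_fib[labels == CLUSTER_UP]
    beta_fib[labels == CLUSTER_DOWN] = -mag_fib[labels == CLUSTER_DOWN]
    # up-then-down genes carry no monotone fibrosis term: a linear fibrosis
    # effect would contradict the non-monotone pattern the cluster emulates
    return pd.DataFrame({
        "gene_id": gene_ids,
        "cluster_label": labels,
        "beta_nas": beta_nas,
        "beta_fib": beta_fib,
    }).set_index("gene_id")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             phi: np.ndarray) -> np.ndarray:
    """NB(mean mu, dispersion phi): Var = mu + phi mu^2 (gamma-Poisson)."""
    phi = np.broadcast_to(np.asarray(phi, dtype=float)[:, None], mu.shape)
    shape = 1.0 / np.maximum(phi, 1e-12)
    lam = rng.gamma(shape, phi * mu)
    # phi -> 0 limit: gamma mixing collapses to the mean
    lam = np.where(phi < 1e-10, mu, lam)
    return rng.poisson(lam)


def generate_human_cohorts(
        cfg: GenConfig,
        gene_truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a multi-cohort human-like count matrix with planted truth.

    Count for gene g, sample j is negative-binomial with
    ``log2 mean = baseline_g + f_g(NAS_j) + beta_fib_g * fib_j
    + batch_offset_{cohort(j), g} + sex_effect_g * sex_j + log2(libsize_j)``
    and per-gene dispersion phi_g. Deterministic under ``cfg.seed``.

    Pass ``gene_truth`` (from an earlier call) to reuse its per-gene
    parameters — the planted biology — and draw only new samples, batch
    offsets and counts: that is how a validation cohort of the same
    disease is generated.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_cohorts * cfg.samples_per_cohort
    sample_ids = np.array([f"HS{j:04d}" for j in range(n_samples)])

    if gene_truth is not None:
        genes = gene_truth.genes.copy()
        if len(genes) != cfg.n_genes:
            raise ValueError("gene_truth does not match cfg.n_genes")
        gene_ids = genes.index.to_numpy(dtype=object)
        baseline = genes["baseline_log2"].to_numpy()
    else:
        gene_ids = np.array([f"HG{i:05d}" for i in range(cfg.n_genes)])
        genes = _assign_clusters(rng, cfg, gene_ids)
        genes["phi"] = rng.lognormal(*cfg.dispersion_params, size=cfg.n_genes)
        genes["sex_effect"] = (
            rng.normal(0.0, cfg.sex_effect_sd, size=cfg.n_genes)
            if cfg.sex_effect_sd > 0 else np.zeros(cfg.n_genes))
        baseline = np.log2(rng.lognormal(*cfg.baseline_logmean_params,
                                         size=cfg.n_genes))
        genes["baseline_log2"] = baseline

    batch_labels = np.repeat(
        [f"cohort{c}" for c in range(cfg.n_cohorts)], cfg.samples_per_cohort)
    offsets = (rng.normal(0.0, cfg.batch_sd, size=(cfg.n_genes, cfg.n_cohorts))
               if cfg.batch_sd > 0 else np.zeros((cfg.n_genes, cfg.n_cohorts)))
    batch_offsets = pd.DataFrame(
        offsets, index=gene_ids,
        columns=[f"cohort{c}" for c in range(cfg.n_cohorts)])

    nas = rng.integers(0, 9, size=n_samples)
    fib = fibrosis_from_nas(nas, rng.normal(0.0, 0.5, size=n_samples))
    sex = rng.integers(0, 2, size=n_samples)
    libsize = rng.lognormal(*cfg.libsize_params, size=n_samples)

    cohort_index = np.repeat(np.arange(cfg.n_cohorts), cfg.samples_per_cohort)
    log2mu = (baseline[:, None]
              + _nas_contribution(genes["beta_nas"].to_numpy(),
                                  genes["cluster_label"].to_numpy(), nas)
              + genes["beta_fib"].to_numpy()[:, None] * fib[None, :]
              + offsets[:, cohort_index]
              + genes["sex_effect"].to_numpy()[:, None] * sex[None, :]
              + np.log2(libsize)[None, :])
    mu = np.exp2(log2mu)
    counts = pd.DataFrame(_nb_draw(rng, mu, genes["phi"].to_numpy()),
                          index=pd.Index(gene_ids, name="gene_id"),
                          columns=sample_ids)

    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "batch": batch_labels,
        "sex": np.where(sex == 1, "F", "M"),
        "species": "human",
        "nas": nas.astype(float),
        "fibrosis": fib.astype(float),
        "group": "clinical",
    }).set_index("sample_id", drop=False)

    truth_samples = pd.DataFrame({
        "sample_id": sample_ids, "nas": nas, "fibrosis": fib,
        "sex": sex, "libsize": libsize,
    }).set_index("sample_id")
    return counts, samples, GroundTruth(genes=genes, samples=truth_samples,
                                        batch_offsets=batch_offsets)


def make_ortholog_map(gene_ids: pd.Index | np.ndarray, coverage: float = 0.85,
                      seed: int = 0) -> pd.DataFrame:
    """Synthetic human->mouse ortholog table covering a random gene subset.

    Mouse symbols mirror the human ones with an ``m`` prefix; ``coverage``
    is the fraction of human genes that have a mouse ortholog.
    """
    rng = np.random.default_rng(seed)
    gene_ids = np.asarray(gene_ids, dtype=object)
    n_cov = int(round(coverage * len(gene_ids)))
    covered = np.sort(rng.choice(len(gene_ids), size=n_cov, replace=False))
    human = gene_ids[covered]
    mouse = np.array([f"m{g}" for g in human], dtype=object)
    return ortholog_map_from_frame(
        pd.DataFrame({"human_gene": human, "mouse_gene": mouse}))


def generate_mouse_timecourse(
        cfg: GenConfig,
        ortholog_map: pd.DataFrame,
        human_truth: GroundTruth,
        timepoints: tuple[int, ...] = (0, 4, 8, 12, 16),
        n_per_timepoint: int = 6,
        seed: int | None = None,
        nas_levels: tuple[int, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Mouse time-course counts whose ortholog genes inherit human effects.

    Planted severity rises with feeding duration: timepoint t of T is
    assigned NAS ``round(8 * t_index / (T - 1))`` and a correlated fibrosis
    stage. Genes orthologous to human severity genes inherit the human
    baseline and beta (direction and magnitude); dispersions are redrawn.
    Mouse samples carry no histology annotation in their sample table — the
    planted severity lives only in the returned :class:`GroundTruth`.
    """
    cfg.validate()
    if ortholog_map is None or len(ortholog_map) == 0:
        raise ValueError("ortholog map is empty: no gene links the two species")
    sig_eligible = set(
        human_truth.genes.index[human_truth.genes["cluster_label"] != CLUSTER_NONE])
    if not sig_eligible & set(ortholog_map["human_gene"]):
        raise ValueError(
            "ortholog map links no human severity gene to a mouse gene")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)

    # mouse gene space: one gene per mapped human gene, plus 10% background
    pairs = ortholog_map.drop_duplicates("human_gene")
    mouse_ids = pairs["mouse_gene"].to_numpy(dtype=object)
    human_of = dict(zip(pairs["mouse_gene"], pairs["human_gene"]))
    n_bg = max(1, len(mouse_ids) // 10)
    bg_ids = np.array([f"mBG{i:05d}" for i in range(n_bg)], dtype=object)
    all_ids = np.concatenate([mouse_ids, bg_ids])

    hgenes = human_truth.genes
    baseline = np.empty(len(all_ids))
    beta_nas = np.zeros(len(all_ids))
    beta_fib = np.zeros(len(all_ids))
    cluster = np.full(len(all_ids), CLUSTER_NONE, dtype=object)
    bg_baseline = np.log2(rng.lognormal(*cfg.baseline_logmean_params,
                                        size=len(all_ids)))
    for i, mg in enumerate(all_ids):
        hg = human_of.get(mg)
        if hg is not None and hg in hgenes.index:
            row = hgenes.loc[hg]
            baseline[i] = row["baseline_log2"]
            beta_nas[i] = row["beta_nas"]
            beta_fib[i] = row["beta_fib"]
            cluster[i] = row["cluster_label"]
        else:
            baseline[i] = bg_baseline[i]
    phi = rng.lognormal(*cfg.dispersion_params, size=len(all_ids))

    n_t = len(timepoints)
    if nas_levels is None:
        levels = (np.rint(8 * np.arange(n_t) / max(n_t - 1, 1)).astype(int)
                  if n_t > 1 else np.array([4]))
    else:
        if len(nas_levels) != n_t:
            raise ValueError("nas_levels must match the number of timepoints")
        levels = np.asarray(nas_levels, dtype=int)
    nas = np.repeat(levels, n_per_timepoint)
    fib = fibrosis_from_nas(nas, rng.normal(0.0, 0.5, size=nas.size))
    libsize = rng.lognormal(*cfg.libsize_params, size=nas.size)
    sample_ids = np.array([f"MS{j:04d}" for j in range(nas.size)])
    weeks = np.repeat(list(timepoints), n_per_timepoint)

    log2mu = (baseline[:, None]
              + _nas_contribution(beta_nas, cluster, nas)
              + beta_fib[:, None] * fib[None, :]
              + np.log2(libsize)[None, :])
    counts = pd.DataFrame(_nb_draw(rng, np.exp2(log2mu), phi),
                          index=pd.Index(all_ids, name="gene_id"),
                          columns=sample_ids)

    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "batch": "mouse0",
        "sex": "M",
        "species": "mouse",
        "nas": np.nan,
        "fibrosis": np.nan,
        "group": [f"week{w}" for w in weeks],
    }).set_index("sample_id", drop=False)

    genes = pd.DataFrame({
        "gene_id": all_ids, "cluster_label": cluster,
        "beta_nas": beta_nas, "beta_fib": beta_fib, "phi": phi,
        "sex_effect": 0.0, "baseline_log2": baseline,
    }).set_index("gene_id")
    truth_samples = pd.DataFrame({
        "sample_id": sample_ids, "nas": nas, "fibrosis": fib,
        "week": weeks, "libsize": libsize,
    }).set_index("sample_id")
    return counts, samples, GroundTruth(genes=genes, samples=truth_samples)


def null_config(n_genes: int = 1000, n_samples: int = 120,
                seed: int = 0) -> GenConfig:
    """Single-cohort configuration with no planted effects of any kind."""
    return GenConfig(n_genes=n_genes, n_cohorts=1, samples_per_cohort=n_samples,
                     frac_severity_genes=0.0, batch_sd=0.0, sex_effect_sd=0.0,
                     seed=seed)


def with_seed(cfg: GenConfig, seed: int) -> GenConfig:
    return replace(cfg, seed=seed)
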