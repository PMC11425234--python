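# masldstage

Transcriptomic staging of metabolic dysfunction-associated steatotic liver
disease (MASLD). The package derives a severity-associated gene signature
from multi-cohort liver RNA-seq annotated with histology scores, scores
individual samples by single-sample gene-set enrichment (ssGSEA), and maps
ungraded query samples — typically a diet-induced mouse model time-course —
onto the human severity scale. It is aimed at computational biologists who
want a fully testable, self-contained staging pipeline: a synthetic-data
generator with planted ground truth makes every stage verifiable without
downloading any cohort.

## The method

Severity is carried by two ordinal histology scores, the MASLD activity
score (NAS, 0–8) and fibrosis stage (F0–F4), entered as numeric covariates
in a per-gene negative-binomial GLM

&nbsp;&nbsp;&nbsp;&nbsp;log μ_gj = ln s_j + x_jᵀ β_g ,&nbsp;&nbsp;Var = μ + φ_g μ² ,

with batch and sex as nuisance terms and median-of-ratios size factors
s_j. A gene is a severity DEG when β_NAS > 0.1 log2/NAS-unit or β_fib >
0.2 log2/stage (strictly, either direction) with a Benjamini–Hochberg
adjusted Wald p < 0.05. The DEG set is distilled by Boruta shadow-feature
selection against the composite severity NAS + fibrosis, then curated to
genes positively associated with progression that have a mouse ortholog —
the unified human–mouse signature. Each sample's enrichment score is the
rank-weighted running-sum statistic

&nbsp;&nbsp;&nbsp;&nbsp;ES = Σ_i [P_in(i) − P_out(i)],&nbsp;&nbsp;P_in
weighting in-signature genes by (rank weight)^α, α = 0.25,

and query samples inherit the median NAS/fibrosis of their k = 5
score-nearest graded reference samples. See `docs/methods.md` for the full
model, defaults and limitations.

## Worked example

Run the full pipeline on synthetic cohorts (two training cohorts of 75
samples, a 60-sample hold-out cohort sharing the same planted biology, and
a 5-timepoint mouse course):

```sh
$ masldstage run --outdir demo --seed 0
n_severity_degs         183
n_boruta_confirmed      112
n_signature_genes       75
train_spearman_nas      0.9827158539632611
train_spearman_fibrosis 0.9631376610856797
holdout_spearman_nas    0.9754478939214162
holdout_spearman_fibrosis       0.9660142094813764
mouse_mapping_spearman  0.9840889362668186
```

Reading the output: 183 of 2,000 genes pass the severity DEG thresholds
(200 carry planted effects, of which the non-monotone fifth is largely
invisible to a linear model); Boruta confirms 112 of them and curation
keeps 75 up-regulated ortholog-bearing genes. Signature enrichment scores
track planted severity almost perfectly on the training cohorts and on the
held-out cohort (Spearman ρ ≈ 0.97 against both NAS and fibrosis), and
the mouse time-course maps onto the human scale in the right order
(ρ ≈ 0.98 between mapped NAS and feeding duration). Every intermediate
artifact — counts, size factors, adjusted expression, DE table, Boruta
table, signature GMT, enrichment tables, the mouse staging table and the
cross-species DEG overlap counts — is written into `demo/` as TSV/GMT.

Individual stages are also exposed (`simulate`, `normalize`, `de`,
`signature`, `score`, `stage`, `validate`), e.g.:

```sh
$ masldstage validate --scores demo/scores_holdout.tsv \
      --samples demo/holdout_samples.tsv --against nas
spearman_rho    0.9754
p_value         8.23e-40
```

The same operations are available as library functions
(`masldstage.fit_severity_de`, `masldstage.boruta_select`,
`masldstage.ssgsea_matrix`, `masldstage.rank_map_to_human`, ...).

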