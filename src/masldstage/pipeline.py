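"""End-to-end pipeline: simulate -> normalize -> DE -> signature -> score -> stage.

Every intermediate artifact is written as TSV/GMT into the output
directory, together with a deterministic ``run_log.json`` (seeds,
parameters, library versions and headline results). Timestamps go only to
the standard-error log so fixed-seed runs produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from masldstage import io
from masldstage.de import (DEGThresholds, cluster_deg_patterns,
                           fit_severity_de, two_group_mouse_degs)
from masldstage.errors import PipelineError
from masldstage.normalize import (median_of_ratios_size_factors,
                                  residualize_covariates, vst_transform)
from masldstage.signature import (BorutaParams, boruta_select,
                                  curate_signature, translate_signature)
from masldstage.simulate import (GenConfig, generate_human_cohorts,
                                 generate_mouse_timecourse, make_ortholog_map)
from masldstage.ssgsea import ScoringParams, ssgsea_matrix
from masldstage.staging import (cross_species_deg_overlap, rank_map_to_human,
                                spearman_validate)

log = logging.getLogger("masldstage")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "generator": {},            # GenConfig field overrides
    "holdout_samples": 60,
    "ortholog_coverage": 0.85,
    "mouse_timepoints": [0, 4, 8, 12, 16],
    "mouse_per_timepoint": 6,
    "lfc_nas": 0.1,
    "lfc_fib": 0.2,
    "alpha": 0.05,
    "mouse_lfc": 1.0,
    "boruta_n_iter": 100,
    "boruta_trees": 200,
    "ssgsea_alpha": 0.25,
    "k": 5,
}


def _setup_logging() -> None:
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(name)s: %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return result
        return inner
    return wrap


def run_pipeline(config: dict[str, Any] | None, outdir: str | Path) -> dict:
    """Execute the full synthetic staging pipeline and write all artifacts.

    ``config`` overrides :data:`DEFAULT_CONFIG`; unknown keys raise. The
    returned dict holds the headline results also recorded in
    ``run_log.json``.
    """
    _setup_logging()
    cfg = dict(DEFAULT_CONFIG)
    for key, value in (config or {}).items():
        if key not in cfg:
            raise PipelineError(f"unknown config key {key!r}")
        cfg[key] = value
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    seed = int(cfg["seed"])
    child = np.random.SeedSequence(seed).generate_state(6) % (2**31 - 1)
    gen = GenConfig(**cfg["generator"])

    # --- simulate -----------------------------------------------------------
    @_stage("simulate")
    def simulate():
        train_cfg = replace(gen, seed=int(child[0]))
        counts, samples, truth = generate_human_cohorts(train_cfg)
        hold_cfg = replace(gen, n_cohorts=1,
                           samples_per_cohort=int(cfg["holdout_samples"]),
                           seed=int(child[1]))
        h_counts, h_samples, h_truth = generate_human_cohorts(
            hold_cfg, gene_truth=truth)
        h_counts = h_counts.rename(columns=lambda s: "V" + s)
        h_samples = h_samples.assign(
            sample_id="V" + h_samples["sample_id"]).set_index("sample_id",
                                                              drop=False)
        orth = make_ortholog_map(counts.index,
                                 coverage=float(cfg["ortholog_coverage"]),
                                 seed=int(child[2]))
        m_counts, m_samples, m_truth = generate_mouse_timecourse(
            gen, orth, truth,
            timepoints=tuple(cfg["mouse_timepoints"]),
            n_per_timepoint=int(cfg["mouse_per_timepoint"]),
            seed=int(child[3]))
        return (counts, samples, truth, h_counts, h_samples, h_truth,
                orth, m_counts, m_samples, m_truth)

    (counts, samples, truth, h_counts, h_samples, h_truth, orth,
     m_counts, m_samples, m_truth) = simulate()
    io.write_counts(counts, outdir / "train_counts.tsv")
    io.write_sample_table(samples, outdir / "train_samples.tsv")
    io.write_counts(h_counts, outdir / "holdout_counts.tsv")
    io.write_sample_table(h_samples, outdir / "holdout_samples.tsv")
    io.write_counts(m_counts, outdir / "mouse_counts.tsv")
    io.write_sample_table(m_samples, outdir / "mouse_samples.tsv")
    io.write_ortholog_map(orth, outdir / "ortholog_map.tsv")
    io.write_table(truth.genes, outdir / "truth_train_genes.tsv")
    io.write_table(truth.samples, outdir / "truth_train_samples.tsv")
    io.write_table(m_truth.samples, outdir / "truth_mouse_samples.tsv")

    # --- normalize ----------------------------------------------------------
    @_stage("normalize")
    def normalize():
        sf = median_of_ratios_size_factors(counts)
        vst = vst_transform(counts, sf)
        adjusted = residualize_covariates(vst, samples,
                                          remove=["batch", "sex"],
                                          keep=["nas", "fibrosis"])
        h_sf = median_of_ratios_size_factors(h_counts)
        h_vst = vst_transform(h_counts, h_sf)
        m_sf = median_of_ratios_size_factors(m_counts)
        m_vst = vst_transform(m_counts, m_sf)
        return sf, vst, adjusted, h_vst, m_vst

    sf, vst, adjusted, h_vst, m_vst = normalize()
    io.write_table(sf.to_frame(), outdir / "size_factors.tsv")
    io.write_expression(adjusted, outdir / "train_vst_adjusted.tsv")

    # --- differential expression -------------------------------------------
    thresholds = DEGThresholds(lfc_nas=float(cfg["lfc_nas"]),
                               lfc_fib=float(cfg["lfc_fib"]),
                               alpha=float(cfg["alpha"]),
                               mouse_lfc=float(cfg["mouse_lfc"]))

    @_stage("de")
    def de_stage():
        table = fit_severity_de(counts, samples, sf, thresholds=thresholds)
        degs = table.index[table["deg_call"] != "none"]
        clusters = (cluster_deg_patterns(adjusted.loc[degs], samples, k=3)
                    if len(degs) >= 3 else pd.Series(dtype=int))
        return table, clusters

    de_table, deg_clusters = de_stage()
    io.write_table(de_table, outdir / "de_table.tsv")
    io.write_table(deg_clusters.to_frame(), outdir / "deg_clusters.tsv")

    # --- signature ----------------------------------------------------------
    @_stage("signature")
    def signature_stage():
        degs = de_table.index[de_table["deg_call"] != "none"]
        if len(degs) == 0:
            raise ValueError("no DEGs to select from")
        features = adjusted.loc[degs].T
        severity = (samples["nas"] + samples["fibrosis"]).to_numpy(float)
        params = BorutaParams(n_iter=int(cfg["boruta_n_iter"]),
                              n_trees=int(cfg["boruta_trees"]),
                              seed=int(child[4]))
        boruta = boruta_select(features, severity, params)
        sig = curate_signature(boruta, de_table, orth)
        return boruta, sig

    boruta, sig = signature_stage()
    io.write_table(boruta.table, outdir / "boruta.tsv")
    io.write_gmt({sig.name: sig.human_genes} if len(sig) else
                 {sig.name: ["EMPTY"]}, outdir / "signature.gmt")
    io.write_table(sig.table, outdir / "signature_provenance.tsv",
                   index=False)

    # --- score --------------------------------------------------------------
    sparams = ScoringParams(alpha=float(cfg["ssgsea_alpha"]))

    @_stage("score")
    def score_stage():
        if len(sig) == 0:
            raise ValueError("empty signature; cannot score")
        mouse_genes = translate_signature(sig, orth, "mouse")
        train_scores = ssgsea_matrix(adjusted, sig.human_genes, sparams,
                                     set_name=sig.name)
        hold_scores = ssgsea_matrix(h_vst, sig.human_genes, sparams,
                                    set_name=sig.name)
        mouse_scores = ssgsea_matrix(m_vst, mouse_genes, sparams,
                                     set_name=sig.name)
        return train_scores, hold_scores, mouse_scores

    train_scores, hold_scores, mouse_scores = score_stage()
    io.write_table(train_scores, outdir / "scores_train.tsv")
    io.write_table(hold_scores, outdir / "scores_holdout.tsv")
    io.write_table(mouse_scores, outdir / "scores_mouse.tsv")

    # --- stage / validate ---------------------------------------------------
    @_stage("stage")
    def stage_stage():
        rho_nas, p_nas = spearman_validate(
            train_scores["es"], samples.loc[train_scores.index, "nas"])
        rho_fib, p_fib = spearman_validate(
            train_scores["es"], samples.loc[train_scores.index, "fibrosis"])
        rho_nas_hold, _ = spearman_validate(
            hold_scores["es"], h_samples.loc[hold_scores.index, "nas"])
        rho_fib_hold, _ = spearman_validate(
            hold_scores["es"], h_samples.loc[hold_scores.index, "fibrosis"])
        mapping = rank_map_to_human(mouse_scores, hold_scores, h_samples,
                                    k=int(cfg["k"]))
        weeks = m_truth.samples.loc[mapping.index, "week"].to_numpy(float)
        rho_map, _ = spearman_validate(mapping["mapped_nas"], weeks)

        baseline = sorted(pd.unique(m_samples["group"]))[0]
        mouse_de = {}
        for group in sorted(pd.unique(m_samples["group"])):
            if group == baseline:
                continue
            mask = m_samples["group"].isin([baseline, group])
            mouse_de[group] = two_group_mouse_degs(
                m_counts.loc[:, mask.to_numpy()], m_samples[mask],
                thresholds)
        overlap = cross_species_deg_overlap(de_table, mouse_de, orth)
        return (rho_nas, p_nas, rho_fib, p_fib, rho_nas_hold, rho_fib_hold,
                mapping, rho_map, overlap)

    (rho_nas, p_nas, rho_fib, p_fib, rho_nas_hold, rho_fib_hold, mapping,
     rho_map, overlap) = stage_stage()
    io.write_table(mapping, outdir / "staging_mouse.tsv")
    io.write_table(overlap, outdir / "overlap_counts.tsv")

    results = {
        "n_severity_degs": int((de_table["deg_call"] != "none").sum()),
        "n_boruta_confirmed": len(boruta.confirmed),
        "n_signature_genes": len(sig),
        "train_spearman_nas": rho_nas,
        "train_spearman_fibrosis": rho_fib,
        "holdout_spearman_nas": rho_nas_hold,
        "holdout_spearman_fibrosis": rho_fib_hold,
        "mouse_mapping_spearman": rho_map,
    }
    run_log = {
        "seed": seed,
        "config": {k: v for k, v in cfg.items()},
        "generator": asdict(gen),
        "versions": {
            "masldstage": _version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "results": results,
    }
    (outdir / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True) + "\n")
    for key, value in results.items():
        log.info("result %s = %s", key, value)
    return {"results": results, "de_table": de_table, "signature": sig,
            "boruta": boruta, "mapping": mapping, "overlap": overlap,
            "truth": truth, "mouse_truth": m_truth, "orth": orth,
            "scores": {"train": train_scores, "holdout": hold_scores,
                       "mouse": mouse_scores}}


def _version() -> str:
    from masldstage import __version__
    return __version__
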