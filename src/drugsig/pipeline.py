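"""End-to-end pipeline: generate/load, normalize, screen, score, classify,
network extraction, enrichment and mechanism inference, driven by a flat
config with the study's printed thresholds as defaults."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression, drug_space, enrichment, io, scoring, screen, synthetic, targets

log = logging.getLogger("drugsig")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run.

    Threshold defaults are the study's printed values: Bonferroni family
    alpha 0.05, FDR 0.05, top 300 transcripts by score (score > 1.8 in
    threshold mode), per-drug regulation threshold 10, walk-length
    cutoff 4, top 50 sensitive transcripts per mechanism.
    """

    outdir: str = "drugsig_run"
    seed: int = 0
    # inputs: either synthetic generation or files
    generate: bool = True
    n_probes: int = 600
    network_sizes: tuple = (60, 30, 20)
    noise_sd: float = 0.3
    matrix_path: str | None = None
    sample_sheet_path: str | None = None
    # stage toggles
    stages: dict = field(
        default_factory=lambda: {
            "normalize": True,
            "screen": True,
            "score": True,
            "classify": True,
            "network": True,
            "enrich": True,
            "infer_targets": True,
        }
    )
    # normalization
    quantile: bool = False  # synthetic data is already on a common scale
    log2_input: bool = False
    batch_standardize: bool = False
    # thresholds (printed defaults)
    bonferroni_alpha: float = 0.05
    fdr: float = 0.05
    g2m_top_k: int = 300
    g2m_threshold: float = 1.8
    per_drug_threshold: float = 10.0
    walk_cutoff: int = 4
    min_network_size: int = 10
    top_k_sensitive: int = 50
    # enrichment inputs (GMT path; optional)
    gene_sets: str | None = None
    query_drug: str | None = None

    def __post_init__(self) -> None:
        self.network_sizes = tuple(self.network_sizes)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)

    def validate(self) -> None:
        for name in ("bonferroni_alpha", "fdr", "g2m_threshold", "per_drug_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("g2m_top_k", "walk_cutoff", "top_k_sensitive", "min_network_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.generate and (self.matrix_path is None or self.sample_sheet_path is None):
            raise ValueError("either enable synthetic generation or give input paths")


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the summary dict.

    Stage outputs are written as TSV into ``config.outdir``; the summary
    (counts at every threshold) goes to ``summary.json``.  Identical
    config and seed produce identical outputs.  Downstream stages fail
    fast with a stage-named error when a prerequisite stage is off.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    # --- input -----------------------------------------------------------
    truth = None
    if config.generate:
        cfg = synthetic.study_config(
            n_probes=config.n_probes,
            network_sizes=tuple(config.network_sizes),
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
        em, truth = synthetic.generate_experiment(cfg)
        io.write_expression(em, outdir / "expression.tsv", outdir / "samples.tsv")
        synthetic.write_truth(truth, outdir / "truth")
        synthetic.write_config(cfg, outdir / "synthetic_config.tsv")
        vehicle_map = truth.vehicle_map
        n_treat = len(cfg.treatment_drugs)
        per_drug_arrays = len(cfg.time_points) * cfg.replicates_per_timepoint
        summary["design"] = {
            "n_drugs": n_treat,
            "n_vehicles": len(cfg.vehicles),
            "time_points": list(cfg.time_points),
            "replicates_per_timepoint": cfg.replicates_per_timepoint,
            "arrays_per_drug": per_drug_arrays,
            "n_samples": em.n_samples,
            "n_probes": em.n_probes,
        }
    else:
        em = io.load_expression(config.matrix_path, config.sample_sheet_path)
        vehicle_map = None
        summary["design"] = {"n_samples": em.n_samples, "n_probes": em.n_probes}
    log.info("input: %d probes × %d samples", em.n_probes, em.n_samples)

    def stage_on(name: str) -> bool:
        return bool(config.stages.get(name, True))

    # --- normalize -------------------------------------------------------
    if stage_on("normalize"):
        try:
            em = io.normalize(
                em,
                quantile=config.quantile,
                log2=config.log2_input,
                batch_standardize=config.batch_standardize,
            )
        except Exception as err:
            raise StageError("normalize", err) from err
        io.write_expression(em, outdir / "normalized.tsv", outdir / "samples.tsv")

    # --- screen ----------------------------------------------------------
    if stage_on("screen"):
        try:
            res = screen.twoway_anova(em)
        except Exception as err:
            raise StageError("screen", err) from err
        res.write(outdir / "screen.tsv")
        tp_curve = screen.estimate_true_positives(res.table["p_drug"].to_numpy())
        tp_curve.to_csv(outdir / "true_positives.tsv", sep="\t", index=False)
        summary["screen"] = {
            "df": [res.df_drug, res.df_time, res.df_interaction],
            "n_bonferroni": int(len(res.significant("p_bonf", config.bonferroni_alpha))),
            "n_fdr": int(len(res.significant("p_bh", config.fdr))),
            "tp_plateau": tp_curve.attrs["plateau"],
        }
        log.info("screen: %s", summary["screen"])

    # --- score -----------------------------------------------------------
    fct = scores = selected = None
    if stage_on("score"):
        try:
            fct = scoring.fold_changes(em, vehicle_policy="matched", vehicle_map=vehicle_map)
            scores = scoring.g2m(fct)
        except Exception as err:
            raise StageError("score", err) from err
        scores.write(outdir / "g2m_scores.tsv")
        k = min(config.g2m_top_k, len(scores.global_score.dropna()))
        selected = scoring.select_transcripts(scores, "top_k", k)
        above = scoring.select_transcripts(scores, "threshold", config.g2m_threshold)
        counts = scoring.per_drug_counts(scores, config.per_drug_threshold)
        counts.rename("n_regulated").to_csv(outdir / "per_drug_counts.tsv", sep="\t")
        summary["score"] = {
            "n_selected": int(len(selected)),
            "n_above_threshold": int(len(above)),
            "per_drug_counts": {str(d): int(c) for d, c in counts.items()},
        }

    def need(name: str, obj):
        if obj is None:
            raise StageError(name, RuntimeError("requires the 'score' stage output"))

    # --- classify --------------------------------------------------------
    if stage_on("classify"):
        need("classify", fct)
        try:
            profiles = drug_space.build_drug_profiles(fct, selected)
            Z = drug_space.cluster_drugs(profiles)
            pca = drug_space.pca_drugs(profiles, n_components=3)
            comp_corr = drug_space.correlate_components(pca, fct, selected)
        except Exception as err:
            raise StageError("classify", err) from err
        (outdir / "dendrogram.nwk").write_text(
            drug_space.linkage_to_newick(Z, profiles.index), encoding="utf-8"
        )
        pca.scores.rename_axis("drug").to_csv(outdir / "pca_scores.tsv", sep="\t")
        comp_corr.rename_axis("probe_id").to_csv(outdir / "pca_correlations.tsv", sep="\t")
        summary["classify"] = {
            "explained_variance": [round(float(v), 6) for v in pca.explained_variance_ratio],
            "explained_variance_total": round(float(pca.explained_variance_ratio.sum()), 6),
        }

    # --- network ---------------------------------------------------------
    if stage_on("network"):
        need("network", fct)
        try:
            profiles_all = coexpression.expression_profiles(fct)
            dist = coexpression.spearman_distance(profiles_all)
            tree = coexpression.build_mst(dist)
            nets = coexpression.extract_networks(
                tree, selected, cutoff=config.walk_cutoff,
                min_network_size=config.min_network_size,
            )
        except Exception as err:
            raise StageError("network", err) from err
        coexpression.write_tree(tree, outdir / "mst_edges.tsv", outdir / "mst.graphml")
        nets.write(outdir / "networks.tsv")
        summary["network"] = {"sizes": nets.sizes}

    # --- enrich ----------------------------------------------------------
    if stage_on("enrich") and config.gene_sets is not None:
        need("enrich", selected)
        try:
            coll = enrichment.read_gmt(config.gene_sets)
            enr = enrichment.set_enrichment(set(selected), coll)
        except Exception as err:
            raise StageError("enrich", err) from err
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        summary["enrich"] = {"n_enriched_sets": int(len(enr))}

    # --- infer targets ---------------------------------------------------
    if stage_on("infer_targets") and truth is not None:
        need("infer_targets", fct)
        try:
            E = scoring.drug_response_summary(fct)
            query = config.query_drug or E.columns[0]
            train = [d for d in E.columns if d != query]
            B_train = truth.B_true.loc[train]
            A = targets.fit_sensitivity(E[train], B_train)
            top_k = min(config.top_k_sensitive, A.shape[1])
            _, A_red = targets.reduce_sensitive(A, top_k=top_k)
            pred = targets.predict_mechanisms(E[query], A_red)
        except Exception as err:
            raise StageError("infer_targets", err) from err
        pred.write(outdir / f"activation_{query}.tsv")
        summary["infer_targets"] = {
            "query_drug": str(query),
            "top_mechanism": str(pred.top_mechanism()),
            "residual_norm": round(pred.residual_norm, 6),
            "n_reduced_transcripts": int(A_red.shape[1]),
        }

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return summary


def config_to_yaml(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config)), encoding="utf-8")
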