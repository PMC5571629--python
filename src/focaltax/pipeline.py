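"""End-to-end orchestration of the focal-taxon analysis flow.

Sequences the analysis stages — screening, zero-inflated modelling,
diversity, network inference, resilience — on synthetic or user-supplied
data, writing per-stage TSV/JSON artifacts and a machine-readable
manifest.  All randomness flows through seeds derived from the single
configured seed.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import diversity as div
from . import netinfer, resilience, screening, synthetic, zinb
from .tables import CountTable, read_metadata, write_metadata

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

STAGES = ["screening", "zinb", "diversity", "netinfer", "resilience"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    With ``table_path`` unset, a synthetic cohort is generated with
    ``n_subjects`` subjects and ``n_species`` background species.
    """

    out_dir: str = "focaltax_run"
    seed: int = 0
    # inputs (optional; synthetic data generated when absent)
    table_path: str | None = None
    meta_path: str | None = None
    tree_path: str | None = None
    # synthetic cohort size
    n_subjects: int = 400
    n_species: int = 40
    # screening
    min_depth: int = 10_000
    site: str = "feces"
    focal_taxa: tuple = ("focalA", "focalB")
    detection_threshold: int = 1
    # zinb
    covariates: tuple = ("age", "sex", "race", "bmi_cat", "antibiotic_history", "country")
    baseline_covariates: tuple = ("age", "sex", "race")
    reference_levels: dict = field(default_factory=lambda: {
        "sex": "Female", "race": "Caucasian", "bmi_cat": "Normal",
        "antibiotic_history": ">365d", "country": "USA"})
    # diversity
    rarefaction_depth: int = 10_000
    permanova_permutations: int = 1000
    # network
    nlambda: int = 30
    min_ratio: float = 0.2
    rep_num: int = 20
    stars_beta: float = 0.05
    # resilience distribution stage (off by default: expensive)
    run_connectivity_distribution: bool = False
    distribution_iterations: int = 10
    distribution_subsample: int = 100

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        cfg = cls(**data)
        cfg.focal_taxa = tuple(cfg.focal_taxa)
        cfg.covariates = tuple(cfg.covariates)
        cfg.baseline_covariates = tuple(cfg.baseline_covariates)
        return cfg


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed in stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _jsonable(asdict(config)),
        "stages": {},
    }
    summary_lines = []

    # ---- inputs ----------------------------------------------------------
    if config.table_path:
        path = config.table_path
        table = (CountTable.from_biom_json(path) if str(path).endswith(".json")
                 else CountTable.from_tsv(path))
        meta = read_metadata(config.meta_path)
        tree_newick = Path(config.tree_path).read_text() if config.tree_path else None
    else:
        spec = synthetic.default_cohort_spec(config.n_subjects, seed=config.seed)
        truths = synthetic.default_focal_truths()
        truths = {k: truths[k] for k in list(truths)[: max(2, len(config.focal_taxa))]}
        truths = dict(zip(config.focal_taxa, truths.values()))
        community = synthetic.CommunityTruth(
            synthetic.chain_precision(config.n_species, 0.3))
        ds = synthetic.assemble_dataset(spec, truths, community)
        table, meta, tree_newick = ds.table, ds.meta, ds.tree_newick
        table.to_tsv(out / "table.tsv")
        write_metadata(meta, out / "metadata.tsv")
        (out / "tree.nwk").write_text(tree_newick)

    def _stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:  # halt with stage name, keep artifacts
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                with open(out / "manifest.json", "w") as fh:
                    json.dump(_jsonable(manifest), fh, indent=2)
                raise PipelineError(name, exc) from exc
            manifest["stages"][name] = {
                "status": "ok", "seconds": round(time.time() - t0, 2),
                **(result or {}),
            }
        return deco

    state: dict = {}

    @_stage("screening")
    def _screening():
        res = screening.filter_and_dedup(table, meta, config.min_depth, config.site)
        det = screening.detect_focal(res.table, list(config.focal_taxa),
                                     config.detection_threshold)
        summary = screening.summarize_focal(res.table, det)
        summary.to_csv(out / "focal_summary.tsv", sep="\t")
        a, b = config.focal_taxa[:2]
        overlap = screening.overlap_test(det, a, b)
        report = {"retention": res.retention,
                  "overlap": {"n_overlap": overlap.n_overlap,
                              "conditional_pct": overlap.conditional_pct,
                              "p_value": overlap.p_value}}
        try:
            shift = screening.codetection_shift(res.table, det, a, b)
            report["codetection_shift_p"] = shift["p_value"]
        except ValueError as exc:
            report["codetection_shift_p"] = None
            warnings.warn(str(exc))
        # longitudinal grouping on multi-sample subjects (pre-dedup)
        full_meta = meta.loc[[s for s in table.samples if s in meta.index]]
        multi = full_meta.groupby("subject_id")["collection_order"].transform("count") >= 2
        if multi.sum() >= 4:
            det_all = screening.detect_focal(table, list(config.focal_taxa),
                                             config.detection_threshold)
            sub_meta = full_meta.loc[multi]
            sub_tab = table.subset_samples(list(sub_meta.index))
            sub_det = screening.DetectionMatrix(
                det_all.df.loc[sub_meta.index], det_all.threshold)
            groups = screening.longitudinal_groups(sub_tab, sub_meta, sub_det)
            report["longitudinal_group_sizes"] = (
                groups.groups.value_counts().to_dict())
        state["filtered"] = res
        state["detection"] = det
        summary_lines.append(
            f"screening: kept {res.retention['dedup']} samples; "
            f"focal overlap p = {overlap.p_value:.3g}")
        with open(out / "screening.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2)
        return {"n_samples": res.retention["dedup"]}

    @_stage("zinb")
    def _zinb():
        res = state["filtered"]
        focal = config.focal_taxa[0]
        y = res.table.df[focal].to_numpy()
        candidates = [c for c in config.covariates
                      if c not in config.baseline_covariates]
        screen = zinb.univariate_screen(
            y, res.meta, res.table.depths, candidates,
            baseline=config.baseline_covariates)
        design = zinb.build_design(res.meta, res.table.depths,
                                   screen["selected"], config.reference_levels)
        idx = design.X.index
        yy = pd.Series(y, index=res.meta.index).loc[idx].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_zinb = zinb.fit_mixture(yy, design, "zinb")
            fit_zip = zinb.fit_mixture(yy, design, "zip")
        comp = zinb.compare_models(fit_zinb, fit_zip)
        fit_zinb.coef_table().to_csv(out / "zinb_coefficients.tsv", sep="\t")
        apv = {}
        for cov in screen["selected"]:
            if design.kinds.get(cov) == "categorical":
                apv[cov] = zinb.apv_proportions(fit_zinb, design, cov).proportions_pct.to_dict()
        with open(out / "zinb.json", "w") as fh:
            json.dump(_jsonable({
                "selected_covariates": screen["selected"],
                "screen": screen["table"].to_dict(orient="index"),
                "zinb": {"loglik": fit_zinb.loglik, "aic": fit_zinb.aic,
                         "bic": fit_zinb.bic, "df": fit_zinb.df},
                "zip": {"loglik": fit_zip.loglik, "aic": fit_zip.aic,
                        "bic": fit_zip.bic, "df": fit_zip.df},
                "comparison": comp, "apv_pct": apv,
            }), fh, indent=2)
        state["fit"] = fit_zinb
        summary_lines.append(
            f"zinb: AIC {fit_zinb.aic:.1f} vs ZIP {fit_zip.aic:.1f}; "
            f"LRT p = {comp['lrt_p']:.3g}")
        return {"aic_zinb": fit_zinb.aic, "aic_zip": fit_zip.aic}

    @_stage("diversity")
    def _diversity():
        res = state["filtered"]
        det = state["detection"]
        groups = det.n_detected().astype(int).astype(str)
        depth = min(config.rarefaction_depth, int(res.table.depths.min()))
        alpha = {}
        for metric in ("observed_otus", "chao1", "shannon"):
            alpha[metric] = div.alpha_diversity(
                res.table, metric, rarefaction_depth=depth, seed=config.seed)
        if tree_newick is not None:
            alpha["faith_pd"] = div.alpha_diversity(
                res.table, "faith_pd", tree=tree_newick,
                rarefaction_depth=depth, seed=config.seed)
        alpha_df = pd.DataFrame({m: a["value"] for m, a in alpha.items()})
        alpha_df["n_focal_detected"] = groups
        alpha_df.to_csv(out / "alpha_diversity.tsv", sep="\t")
        comp = div.alpha_compare(alpha_df[list(alpha)[0]], groups,
                                 seed=config.seed)
        comp.to_csv(out / "alpha_comparisons.tsv", sep="\t", index=False)
        dist = div.beta_distance(res.table, "bray_curtis")
        ord_res = div.pcoa(dist)
        ord_res["coordinates"].to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        perm = div.permanova(dist, groups, config.permanova_permutations,
                             seed=config.seed)
        gd = div.group_distance_compare(dist, groups)
        gd["summary"].to_csv(out / "group_distances.tsv", sep="\t", index=False)
        summary_lines.append(
            f"diversity: PERMANOVA pseudo-F {perm['pseudo_F']:.2f}, "
            f"p = {perm['p_value']:.3g}")
        return {"permanova_p": perm["p_value"], "rarefaction_depth": depth}

    @_stage("netinfer")
    def _netinfer():
        res = state["filtered"]
        background = res.table.df.drop(columns=[c for c in config.focal_taxa
                                                if c in res.table.df.columns])
        net, stars = netinfer.infer_network(
            CountTable(background), nlambda=config.nlambda,
            min_ratio=config.min_ratio, rep_num=config.rep_num,
            beta=config.stars_beta, seed=config.seed)
        net.write_tsv(out / "network_edges.tsv")
        state["network"] = net
        summary_lines.append(
            f"netinfer: {net.n_edges} edges at lambda = {stars.selected_lambda:.4f}")
        return {"n_edges": net.n_edges, "selected_lambda": stars.selected_lambda}

    @_stage("resilience")
    def _resilience():
        net = state["network"]
        report = {}
        if net.graph.number_of_nodes() >= 3:
            cent = pd.DataFrame({
                "degree": resilience.centrality(net, "degree"),
                "betweenness": resilience.centrality(net, "betweenness"),
            })
            cent.to_csv(out / "centrality.tsv", sep="\t")
            report["natural_connectivity"] = resilience.natural_connectivity(net)
            curves = {}
            for ordering in ("degree", "betweenness", "random"):
                att = resilience.attack_simulation(net, ordering, seed=config.seed)
                curves[ordering] = att.trajectory["natural_connectivity"].tolist()
                att.trajectory.to_csv(out / f"attack_{ordering}.tsv",
                                      sep="\t", index=False)
            report["attack_auc"] = {k: float(np.trapezoid(v[::-1]))
                                    for k, v in curves.items()}
        if config.run_connectivity_distribution:
            res = state["filtered"]
            det = state["detection"]
            dist = resilience.connectivity_distribution(
                res.table, det, config.focal_taxa[0],
                iterations=config.distribution_iterations,
                subsample=config.distribution_subsample, seed=config.seed,
                nlambda=config.nlambda, rep_num=max(2, config.rep_num // 2))
            report["connectivity_distribution_p"] = dist["p_one_sided"]
        with open(out / "resilience.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2)
        summary_lines.append(
            f"resilience: baseline connectivity "
            f"{report.get('natural_connectivity', float('nan')):.4f}")
        return {k: v for k, v in report.items() if not isinstance(v, dict)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2)
    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    return _jsonable(manifest)
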