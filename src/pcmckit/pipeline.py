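"""End-to-end orchestration: simulate -> validate -> label -> metrics -> stats -> models.

``run_all`` executes every analysis stage in order on a simulated (or
loaded) dataset and produces a JSON report that mirrors the structure of a
post-conflict study's results: occurrence of consolation and
reconciliation, latency of post-conflict affiliation, determinants of
consolation (GLMM with AIC selection and reduced robustness runs),
relationship dynamics (dyadic LMMs), victim stress proxies, and the
matched-control contact control.  A reproducibility manifest records the
seed, configuration hash, package versions, per-stage wall time and
SHA-256 checksums of every file written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ethogram_io import Dataset, load_dataset_dir, write_dataset
from .mixed_models import lmm_dyadic, enumerate_and_select, reduced_model_runs
from .pcmc import (
    CONSOLATION_ANY,
    RECONCILIATION,
    RelationshipSelector,
    consolation_index,
    focal_proportions,
    label_bystander_pairs,
    label_dataset,
    tendency_scores,
)
from .postconflict_stats import (
    logrank_compare,
    mc_contact_control,
    stress_rates,
    wilcoxon_paired,
)
from .social_metrics import affiliation_matrix, build_dyad_table, build_opportunity_table
from .synthetic_colony import ColonyConfig, ResponseModel, simulate_colony

logger = logging.getLogger(__name__)

DEFAULT_GLMM_POOL = (
    "prox_lt5m",
    "prox_5to10m",
    "bystander_juvenile",
    "bystander_mother_reared",
    "log_affiliation_bv",
    "kin_bystander_victim",
    "context_feed",
    "reconciliation",
)
DEFAULT_LMM_POOL = (
    "bystander_juvenile",
    "bystander_mother_reared",
    "bystander_sex_m",
    "kin",
    "log_affiliation",
)


@dataclass
class PipelineConfig:
    seed: int = 1
    hours: float = 453.0
    kin_boost: float = 1.5
    concentration: float = 40.0
    colony: ColonyConfig = field(default_factory=ColonyConfig)
    response: ResponseModel = field(default_factory=ResponseModel)
    input_dir: Optional[str] = None       # load instead of simulating
    glmm_pool: tuple[str, ...] = DEFAULT_GLMM_POOL
    lmm_pool: tuple[str, ...] = DEFAULT_LMM_POOL
    include_models: bool = True
    include_reduced_runs: bool = True
    figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("seed", "hours", "kin_boost", "concentration", "input_dir",
                    "include_models", "include_reduced_runs", "figures"):
            if key in raw:
                kwargs[key] = raw[key]
        for key in ("glmm_pool", "lmm_pool"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        if "response" in raw:
            kwargs["response"] = ResponseModel(**raw["response"])
        if "colony" in raw:
            kwargs["colony"] = ColonyConfig(**raw["colony"])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            d = dataclasses.asdict(o)
            return {str(k): v for k, v in d.items()}
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    def stringify(obj):
        if isinstance(obj, dict):
            return {str(k): stringify(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [stringify(v) for v in obj]
        return obj

    blob = json.dumps(stringify(dataclasses.asdict(config)), default=str,
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _fit_summary(fit) -> dict:
    return {
        "terms": list(fit.spec.term_names),
        "coefficients": _jsonable(fit.params),
        "se": _jsonable(fit.bse),
        "z": _jsonable(fit.zvalues),
        "loglik": _jsonable(fit.log_likelihood),
        "aic": _jsonable(fit.aic),
        "k": fit.k_params,
        "n_obs": fit.n_obs,
        "converged": bool(fit.converged),
        "random_effect_sd": _jsonable(fit.vc_sd),
    }


def _selection_summary(sel) -> dict:
    return {
        "n_models": int(len(sel.results)),
        "best": _fit_summary(sel.best),
        "null_loglik": _jsonable(sel.null.log_likelihood),
        "lrt_chi2": _jsonable(sel.lrt_chi2),
        "lrt_df": sel.lrt_df,
        "lrt_p": _jsonable(sel.lrt_p),
        "screened_pairs": [sorted(p) for p in sel.screened_pairs],
    }


def analyze_dataset(dataset: Dataset, config: PipelineConfig,
                    timings: Optional[dict] = None) -> dict:
    """Run the full analysis battery on a validated dataset."""
    timings = timings if timings is not None else {}
    report: dict = {
        "n_conflicts": len(dataset.conflicts),
        "n_pairs_analyzed": len(dataset.retained_pairs()),
        "n_excluded": len(dataset.excluded),
    }

    t0 = time.perf_counter()
    consol = label_dataset(dataset, RelationshipSelector(CONSOLATION_ANY))
    recon = label_dataset(dataset, RelationshipSelector(RECONCILIATION))
    by_records = label_bystander_pairs(dataset)
    timings["label"] = time.perf_counter() - t0

    def occurrence(records, tendency_name):
        props = focal_proportions(records)
        if props.empty:
            return {"n_pairs": 0}
        wil = wilcoxon_paired(props["prop_attracted"], props["prop_dispersed"])
        scores = tendency_scores(records, by="victim")
        return {
            "n_pairs": int(sum(r is not None for r in records) and len(records)),
            "n_focals": int(len(props)),
            "mean_prop_attracted_pct": float(100 * props["prop_attracted"].mean()),
            "sd_prop_attracted_pct": float(100 * props["prop_attracted"].std(ddof=1)),
            "mean_prop_dispersed_pct": float(100 * props["prop_dispersed"].mean()),
            "sd_prop_dispersed_pct": float(100 * props["prop_dispersed"].std(ddof=1)),
            "wilcoxon_z": wil.z,
            "wilcoxon_p": wil.p,
            "wilcoxon_n": wil.n_effective,
            f"mean_{tendency_name}_pct": float(scores["tct"].mean()),
            f"sd_{tendency_name}_pct": float(scores["tct"].std(ddof=1)),
        }

    t0 = time.perf_counter()
    report["occurrence"] = {
        "consolation": occurrence(consol, "tct"),
        "reconciliation": occurrence(recon, "cct"),
    }

    report["latency"] = {}
    for name, records in (("consolation", consol), ("reconciliation", recon)):
        try:
            lr = logrank_compare(records, fit_curves=False)
            report["latency"][name] = {
                "chi2": lr.chi2, "p": lr.p, "df": lr.df, "n_pairs": lr.n_pc,
            }
        except ValueError as exc:
            report["latency"][name] = {"undefined": str(exc)}

    stress = stress_rates(dataset, consol, recon)
    report["stress"] = {
        "outcome_counts": stress.outcome_counts,
        "alpha_corrected": stress.alpha_corrected,
        "condition_means": _jsonable(
            {c: dict(row) for c, row in stress.condition_means.iterrows()}
        ),
        "comparisons": stress.comparisons.to_dict(orient="records"),
    }
    mc_ctrl, _ = mc_contact_control(dataset)
    report["mc_contact_control"] = {
        "z": mc_ctrl.z, "p": mc_ctrl.p, "n": mc_ctrl.n_effective,
        "method": mc_ctrl.method,
    }
    timings["stats"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    ids = dataset.analysis_ids()
    affil = affiliation_matrix(dataset.scans, ids=ids)
    opportunities = build_opportunity_table(dataset, by_records, recon, affil)
    dyad_scores = tendency_scores(by_records, by="dyad")
    ci = consolation_index(dataset)
    dyads = (build_dyad_table(dataset, dyad_scores, ci, affil)
             if not dyad_scores.empty else pd.DataFrame())
    report["n_opportunities"] = int(len(opportunities))
    report["n_dyads"] = int(len(dyads))
    timings["metrics"] = time.perf_counter() - t0

    report["tables"] = {
        "affiliation": affil,
        "opportunities": opportunities,
        "dyads": dyads,
        "labels_consolation": consol,
        "labels_reconciliation": recon,
        "labels_bystander": by_records,
    }

    if config.include_models and len(opportunities) > 0:
        t0 = time.perf_counter()
        pool = [c for c in config.glmm_pool if c in opportunities.columns
                and opportunities[c].std() > 0]
        sel = enumerate_and_select(
            opportunities, "outcome", pool,
            random_effects=("victim_id", "aggressor_id", "bystander_id",
                            "group_id", "conflict_id"),
            reoptimize_theta=False,
        )
        report["determinants"] = {"glmm": _selection_summary(sel)}
        if config.include_reduced_runs:
            for exclusion in ("mother_reared_bystanders", "juvenile_bystanders"):
                try:
                    red = reduced_model_runs(
                        opportunities, exclusion, pool=pool,
                        random_effects=("victim_id", "bystander_id", "conflict_id"),
                        reoptimize_theta=False,
                    )
                    report["determinants"][exclusion] = {
                        "n_before": red["n_before"], "n_after": red["n_after"],
                        "n_bystanders_before": red["n_bystanders_before"],
                        "n_bystanders_after": red["n_bystanders_after"],
                        "selection": _selection_summary(red["selection"]),
                    }
                except ValueError as exc:
                    report["determinants"][exclusion] = {"skipped": str(exc)}
        timings["glmm"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        report["relationship_dynamics"] = {}
        if len(dyads) >= 10:
            for response in ("tct", "consolation_index_pct"):
                pool_l = [c for c in config.lmm_pool if dyads[c].std() > 0]
                sel_l, pvals = lmm_dyadic(
                    dyads, response, pool_l, seed=config.seed,
                )
                report["relationship_dynamics"][response] = {
                    **_selection_summary(sel_l),
                    "mcmc_p": _jsonable(pvals),
                }
        timings["lmm"] = time.perf_counter() - t0
    return report


def make_figures(report: dict, consol_records, outdir: Path) -> list[Path]:
    """Survival curves and summary bar charts for the report bundle."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    try:
        lr = logrank_compare(consol_records, fit_curves=True)
    except ValueError:
        lr = None
    if lr is not None and lr.km_pc is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.step(lr.km_pc.index, lr.km_pc["PC"], where="post", label="PC")
        ax.step(lr.km_mc.index, lr.km_mc["MC"], where="post", label="MC")
        ax.set_xlabel("latency to first bystander contact (s)")
        ax.set_ylabel("fraction without contact")
        ax.set_title(f"first-contact latency (log-rank chi2={lr.chi2:.1f})")
        ax.legend()
        path = outdir / "latency_survival.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

    occ = report.get("occurrence", {})
    if occ.get("consolation", {}).get("n_pairs"):
        fig, ax = plt.subplots(figsize=(6, 4))
        labels, att, disp = [], [], []
        for name in ("consolation", "reconciliation"):
            o = occ.get(name, {})
            if "mean_prop_attracted_pct" in o:
                labels.append(name)
                att.append(o["mean_prop_attracted_pct"])
                disp.append(o["mean_prop_dispersed_pct"])
        x = np.arange(len(labels))
        ax.bar(x - 0.18, att, width=0.36, label="attracted")
        ax.bar(x + 0.18, disp, width=0.36, label="dispersed")
        ax.set_xticks(x, labels)
        ax.set_ylabel("% of PC/MC pairs per focal")
        ax.legend()
        path = outdir / "attracted_dispersed.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

    means = report.get("stress", {}).get("condition_means", {})
    if means:
        order = [c for c in ("MC", "PC_no_affiliation", "PC_consolation") if c in means]
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(order, [means[c]["scratch_rate"] for c in order])
        ax.set_ylabel("self-scratch bouts / min")
        ax.set_title("victim self-scratching by outcome")
        path = outdir / "scratch_rates.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages, write the report bundle, return the report dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        if config.input_dir:
            dataset = load_dataset_dir(config.input_dir)
            truth = None
        else:
            dataset, _affinity, truth = simulate_colony(
                config.colony, config.response, hours=config.hours,
                kin_boost=config.kin_boost, concentration=config.concentration,
                seed=config.seed,
            )
        timings[stage] = time.perf_counter() - t0

        stage = "write_dataset"
        t0 = time.perf_counter()
        data_dir = out / "dataset"
        files = write_dataset(dataset, data_dir)
        if truth is not None:
            truth_path = data_dir / "ground_truth.json"
            truth_path.write_text(json.dumps(_jsonable(truth), indent=2))
            files.append(truth_path)
        timings[stage] = time.perf_counter() - t0

        stage = "analyze"
        report = analyze_dataset(dataset, config, timings)
        tables = report.pop("tables")

        stage = "write_tables"
        t0 = time.perf_counter()
        tables["affiliation"].to_csv(out / "affiliation.csv", index=False)
        tables["opportunities"].to_csv(out / "opportunities.csv", index=False)
        if len(tables["dyads"]):
            tables["dyads"].to_csv(out / "dyads.csv", index=False)
        labels = pd.DataFrame(
            [
                {"selector": sel, "conflict_id": r.conflict_id,
                 "victim_id": r.victim_id, "bystander_id": r.bystander_id,
                 "pc_latency": r.pc_latency, "mc_latency": r.mc_latency,
                 "label": r.label}
                for sel, recs in (
                    ("consolation", tables["labels_consolation"]),
                    ("reconciliation", tables["labels_reconciliation"]),
                    ("bystander", tables["labels_bystander"]),
                )
                for r in recs
            ]
        )
        labels.to_csv(out / "labels.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        if config.figures:
            stage = "figures"
            t0 = time.perf_counter()
            make_figures(report, tables["labels_consolation"], out / "figures")
            timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        manifest = {
            "failed_stage": stage,
            "error": str(exc),
            "completed_timings_s": timings,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    checksums = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            checksums[str(path.relative_to(out))] = _sha256(path)
    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "versions": {
            "pcmckit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "checksums": checksums,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    report_clean = _jsonable(report)
    (out / "report.json").write_text(json.dumps(report_clean, indent=2))
    report_clean["manifest"] = manifest
    return report_clean
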