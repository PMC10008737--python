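"""End-to-end study replica: simulate -> call chromothripsis -> train the
CPS model -> genomic covariates -> immune scores -> survival analysis.

A single YAML config drives every stage; all randomness flows from one
root seed through named substreams, so rerunning with the same config
reproduces every output table byte-identically (checksums are written
to ``manifest.json``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import immune, metrics, survival_analysis as surv
from .cn_profile import filter_profile, write_seg
from .detect import CTThresholds, call_chromothripsis, calls_to_frame
from .signatures import ChromothripsisScoreModel
from .simulate import SimConfig, simulate_cohort, simulate_gene_annotation, simulate_survival, substream

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

_KNOWN_BLOCKS = {"simulate", "chromothripsis", "cps", "survival", "immune", "seed"}


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    simulate: dict = dataclasses.field(default_factory=dict)
    chromothripsis: dict = dataclasses.field(default_factory=dict)
    cps: dict = dataclasses.field(default_factory=dict)
    immune: dict = dataclasses.field(default_factory=dict)
    survival: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_BLOCKS
        if unknown:
            raise ValueError(f"unknown config block(s): {sorted(unknown)}")
        return cls(
            seed=int(raw.get("seed", 0)),
            simulate=dict(raw.get("simulate", {})),
            chromothripsis=dict(raw.get("chromothripsis", {})),
            cps=dict(raw.get("cps", {})),
            immune=dict(raw.get("immune", {})),
            survival=dict(raw.get("survival", {})),
        )


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig | dict, outdir) -> dict:
    """Execute all stages in dependency order; returns paths and summary
    statistics. Fails fast with the stage name on any error."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    written: dict[str, Path] = {}
    summary: dict = {}

    def log(msg: str) -> None:
        log_lines.append(msg)

    def emit(name: str, path: Path) -> None:
        written[name] = path

    stage = "simulate"
    try:
        t0 = time.time()
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        cfg = SimConfig(**sim_kwargs)
        log(f"[simulate] config: {sim_kwargs}")
        cohort = simulate_cohort(cfg)
        write_seg(cohort["profiles"], outdir / "profiles.seg")
        emit("profiles", outdir / "profiles.seg")
        cohort["mutations"].to_csv(outdir / "mutations.tsv", sep="\t", index=False)
        emit("mutations", outdir / "mutations.tsv")
        cohort["expression"].to_csv(outdir / "expression.tsv", sep="\t")
        emit("expression", outdir / "expression.tsv")
        immune.write_gmt(cohort["gene_sets"], outdir / "gene_sets.gmt")
        emit("gene_sets", outdir / "gene_sets.gmt")
        cohort["labels"].astype(int).to_csv(outdir / "true_labels.tsv", sep="\t")
        emit("true_labels", outdir / "true_labels.tsv")
        genes = simulate_gene_annotation(cfg)
        genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
        emit("genes", outdir / "genes.tsv")
        log(f"[simulate] {cfg.n_samples} samples in {time.time() - t0:.1f}s")

        stage = "chromothripsis"
        t0 = time.time()
        thresholds = CTThresholds(**config.chromothripsis)
        log(f"[chromothripsis] thresholds: {dataclasses.asdict(thresholds)}")
        filtered = [filter_profile(p) for p in cohort["profiles"]]
        all_calls, flags = [], {}
        for p in filtered:
            calls, flag = call_chromothripsis(p, thresholds)
            all_calls.extend(calls)
            flags[p.sample_id] = flag
        calls_df = calls_to_frame(all_calls)
        calls_df.to_csv(outdir / "chromothripsis_calls.tsv", sep="\t", index=False)
        emit("calls", outdir / "chromothripsis_calls.tsv")
        labels = pd.Series(flags, name="called_chromothripsis")
        labels.astype(int).to_csv(outdir / "called_labels.tsv", sep="\t")
        emit("called_labels", outdir / "called_labels.tsv")
        truth = cohort["labels"]
        tp = int((labels & truth).sum())
        fp = int((labels & ~truth).sum())
        fn = int((~labels & truth).sum())
        tn = int((~labels & ~truth).sum())
        summary["detector"] = {
            "sensitivity": tp / max(tp + fn, 1),
            "specificity": tn / max(tn + fp, 1),
        }
        log(f"[chromothripsis] sens={summary['detector']['sensitivity']:.3f} "
            f"spec={summary['detector']['specificity']:.3f} in {time.time() - t0:.1f}s")

        stage = "cps"
        t0 = time.time()
        cps_kwargs = dict(config.cps)
        cps_kwargs.setdefault("seed", config.seed)
        model = ChromothripsisScoreModel(filtered, labels.loc[[p.sample_id for p in filtered]].values,
                                         **cps_kwargs)
        results = model.fit()
        results.save(outdir / "cps_model.json")
        emit("cps_model", outdir / "cps_model.json")
        cps_scores = results.predict_counts(results.counts)["cps"]
        cps_scores.to_csv(outdir / "cps_scores.tsv", sep="\t")
        emit("cps_scores", outdir / "cps_scores.tsv")
        summary["cps"] = {"cv_auc": results.cv_auc, "n_signatures": results.n_signatures}
        log(f"[cps] CV AUC={results.cv_auc:.3f} (K={results.n_signatures}) "
            f"in {time.time() - t0:.1f}s")

        stage = "covariates"
        t0 = time.time()
        covars = metrics.compute_covariates(
            filtered, metrics.filter_variants(cohort["mutations"]), genes,
            region_size_mb=cfg.exome_size_mb,
        )
        covars.to_csv(outdir / "covariates.tsv", sep="\t")
        emit("covariates", outdir / "covariates.tsv")
        log(f"[covariates] done in {time.time() - t0:.1f}s")

        stage = "immune"
        t0 = time.time()
        expr = cohort["expression"]
        ss = immune.ssgsea(expr, cohort["gene_sets"],
                           weight=config.immune.get("weight", 0.25))
        ss.to_csv(outdir / "ssgsea_scores.tsv", sep="\t")
        emit("ssgsea", outdir / "ssgsea_scores.tsv")
        cell_sets = {n: g for n, g in cohort["gene_sets"].items()
                     if cohort["gene_set_roles"][n] == "cell_type"}
        gm = immune.geometric_mean_scores(expr, cell_sets, expr_scale="log2")
        gm.to_csv(outdir / "geometric_mean_scores.tsv", sep="\t")
        emit("geomean", outdir / "geometric_mean_scores.tsv")
        ratios = immune.cell_ratios(gm)
        ratios["cytokine_ratio"] = immune.cytokine_ratio(expr, expr_scale="log2")
        ratios.to_csv(outdir / "cell_ratios.tsv", sep="\t")
        emit("ratios", outdir / "cell_ratios.tsv")
        diff = immune.pathway_differential(ss, labels)
        diff.to_csv(outdir / "pathway_differential.tsv", sep="\t")
        emit("pathway_differential", outdir / "pathway_differential.tsv")
        log(f"[immune] scored {len(cohort['gene_sets'])} sets in {time.time() - t0:.1f}s")

        stage = "survival"
        t0 = time.time()
        clinical = simulate_survival(cps_scores.values, cfg, substream(cfg, "survival"),
                                     sample_ids=list(cps_scores.index))
        clinical = clinical.set_index("sample")
        clinical["cps"] = cps_scores
        clinical["tmb"] = covars["tmb"]
        clinical["wgii"] = covars["wgii"]
        clinical["cna_burden"] = covars["cna_gain_burden"] + covars["cna_loss_burden"]
        clinical["cd8a"] = expr.loc["CD8A"]
        clinical["pdl1"] = expr.loc["CD274"]
        clinical.to_csv(outdir / "clinical.tsv", sep="\t")
        emit("clinical", outdir / "clinical.tsv")
        biomarkers = config.survival.get(
            "biomarkers", ["cps", "tmb", "wgii", "cna_burden", "cd8a", "pdl1"]
        )
        biotable = surv.biomarker_table(clinical, biomarkers)
        biotable.to_csv(outdir / "biomarker_survival.tsv", sep="\t")
        emit("biomarker_survival", outdir / "biomarker_survival.tsv")
        time_grid = config.survival.get("time_grid", [6, 12, 18, 24, 30, 36])
        auc_rows = []
        for name in biomarkers:
            auc = surv.time_dependent_auc(clinical["os_months"], clinical["os_event"],
                                          clinical[name], time_grid)
            auc["biomarker"] = name
            auc_rows.append(auc)
        auc_df = pd.concat(auc_rows, ignore_index=True)
        auc_df.to_csv(outdir / "time_dependent_auc.tsv", sep="\t", index=False)
        emit("auc_t", outdir / "time_dependent_auc.tsv")
        high = surv.median_groups(clinical["cps"])
        km = surv.km_logrank(clinical["os_months"], clinical["os_event"], high)
        resp = surv.response_rates(clinical["response"], clinical["sd_duration_months"], high)
        summary["survival"] = {
            "cps_logrank_p": km.logrank_p,
            "median_high": km.median_survival["high"],
            "median_low": km.median_survival["low"],
            "responder_fisher_p": resp["responder_p"],
            "objective_fisher_p": resp["objective_p"],
        }
        km_rows = []
        for grp, curve in km.curves.items():
            c = curve.copy()
            c["group"] = grp
            km_rows.append(c)
        pd.concat(km_rows, ignore_index=True).to_csv(outdir / "km_cps.tsv", sep="\t",
                                                     index=False)
        emit("km_cps", outdir / "km_cps.tsv")
        log(f"[survival] log-rank p={km.logrank_p:.3g} in {time.time() - t0:.1f}s")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {name: _sha256(path) for name, path in sorted(written.items())}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=float)
    )
    return {"outdir": outdir, "manifest": manifest, "summary": summary,
            "tables": {k: str(v) for k, v in written.items()}}
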