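"""End-to-end study workflow: match -> split -> diversity/ordination ->
screen -> feature-count selection -> POD/ROC -> external validation ->
clinical SparCC, driven by a single validated config.

Every stage persists its intermediate output under ``out_dir`` so later
stages (e.g. external validation) can rerun without recomputing earlier
ones, and the final report is recomputable from those intermediates.
Reports contain no timestamps: identical config + inputs give a
byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import micropod
from micropod import diversity, matching, ordination, rfcv, screen, sparcc, synth
from micropod.otu_io import (
    OtuTable,
    read_metadata,
    read_otu_table,
    read_tree,
    to_relative_abundance,
    write_otu_table,
    write_tree,
)


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 at the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3 at the CLI)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    case_label: str = "case"
    control_label: str = "control"
    distance: str = "bray-curtis"   # bray-curtis | unifrac-weighted | unifrac-unweighted
    synthetic: dict | None = None
    inputs: dict | None = None
    match: dict = field(default_factory=lambda: {"enabled": True, "caliper_sd": 0.2})
    split: dict = field(default_factory=lambda: {"ratio": [2, 1]})
    screen: dict = field(default_factory=dict)
    rfcv: dict = field(default_factory=lambda: {
        "folds": 5, "repeats": 3, "n_trees": 300, "rule": "min",
        "importance_floor": 0.001})
    sparcc: dict = field(default_factory=lambda: {
        "n_inner": 10, "n_boot": 50,
        "indicators": ["ALB", "Pro24h", "SCr"]})

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        if "seed" not in doc or doc["seed"] is None:
            raise ConfigError("config must declare a seed")
        if "out_dir" not in doc:
            raise ConfigError("config must declare out_dir")
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(doc) - known - {"version"}
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        cfg = cls(**{k: v for k, v in doc.items() if k in known})
        if cfg.synthetic is None and cfg.inputs is None:
            raise ConfigError("config needs either 'synthetic' or 'inputs'")
        if cfg.distance not in ("bray-curtis", "unifrac-weighted",
                                "unifrac-unweighted"):
            raise ConfigError(f"unknown distance {cfg.distance!r}")
        for path_key in ("otu_table", "metadata"):
            if cfg.inputs and path_key in cfg.inputs:
                if not Path(cfg.inputs[path_key]).exists():
                    raise ConfigError(f"input file missing: {cfg.inputs[path_key]}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigError("config must be a mapping")
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_cohorts(cfg: PipelineConfig, out: Path):
    """Returns (table, meta, tree, externals, truth) — externals is a list
    of (name, table, meta)."""
    if cfg.synthetic is not None:
        syn = dict(cfg.synthetic)
        n_external = int(syn.pop("external_cohorts", 1))
        batch_sigma = float(syn.pop("batch_sigma", 0.5))
        couplings = [synth.Coupling(**c) for c in syn.pop("couplings", [])]
        spec = synth.SyntheticSpec(couplings=couplings, **syn)
        cohorts, tree, truth = synth.generate_multicohort(
            spec, n_cohorts=1 + max(1, n_external), batch_sigma=batch_sigma,
            seed=cfg.seed)
        (table, meta) = cohorts[0]
        externals = [(f"external{i}", t, m)
                     for i, (t, m) in enumerate(cohorts[1:1 + n_external], 1)]
        truth.to_json(out / "synthetic_truth.json")
        return table, meta, tree, externals, truth
    inp = cfg.inputs
    table = read_otu_table(inp["otu_table"], fmt=inp.get("format", "tsv"),
                           orientation=inp.get("orientation", "otus-as-rows"))
    meta = read_metadata(inp["metadata"])
    tree = read_tree(inp["tree"]) if inp.get("tree") else None
    externals = []
    for i, ext in enumerate(inp.get("external", []), 1):
        et = read_otu_table(ext["otu_table"], fmt=ext.get("format", "tsv"),
                            orientation=ext.get("orientation", "otus-as-rows"))
        em = read_metadata(ext["metadata"])
        externals.append((ext.get("name", f"external{i}"), et, em))
    return table, meta, tree, externals, None


def _distance(cfg: PipelineConfig, table: OtuTable, tree):
    if cfg.distance == "bray-curtis":
        return diversity.bray_curtis(table)
    if tree is None:
        raise ConfigError("UniFrac distance requires a tree input")
    return diversity.unifrac(table, tree,
                             weighted=cfg.distance == "unifrac-weighted",
                             normalized=True)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the study report (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software_version": micropod.__version__,
        "config": cfg.to_dict(),
        "pod_definition": "fraction of forest trees voting the disease class"
        " (averaged over CV repeats in cross-validated mode)",
    }

    stage = "load"
    try:
        table, meta, tree, externals, truth = _load_cohorts(cfg, out)
        write_otu_table(table, out / "otu_table.tsv")
        meta.to_csv(out / "metadata.csv")
        if tree is not None:
            write_tree(tree, out / "tree.nwk")
    except ConfigError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    case, control = cfg.case_label, cfg.control_label
    try:
        stage = "match"
        if cfg.match.get("enabled", True):
            matched = matching.propensity_match(
                meta, case_label=case, control_label=control,
                caliper_sd=float(cfg.match.get("caliper_sd", 0.2)),
                seed=cfg.seed)
        else:
            cases = list(meta.index[meta["group"] == case])
            controls = list(meta.index[meta["group"] == control])
            n = min(len(cases), len(controls))
            matched = matching.MatchedCohort(
                pairs=list(zip(cases[:n], controls[:n])),
                coefficients={}, caliper=float("inf"))
        matched.to_dataframe().to_csv(out / "matched_pairs.csv", index=False)
        if not matched.pairs:
            raise RuntimeError("no matched case/control pairs")

        stage = "split"
        split = matching.split_discovery_validation(
            matched, ratio=tuple(cfg.split.get("ratio", (2, 1))), seed=cfg.seed)
        pd.DataFrame({
            "sample_id": split.discovery + split.validation,
            "cohort": ["discovery"] * len(split.discovery)
            + ["validation"] * len(split.validation),
        }).to_csv(out / "split.csv", index=False)
        disc = table.select_samples(split.discovery)
        disc_labels = meta.loc[split.discovery, "group"].to_numpy()
        val = table.select_samples(split.validation)
        val_labels = meta.loc[split.validation, "group"].to_numpy()

        stage = "diversity"
        alpha = diversity.alpha_diversity_table(disc)
        alpha["group"] = disc_labels
        alpha.to_csv(out / "alpha_diversity.csv")
        alpha_stats = {
            metric: diversity.compare_groups(alpha[metric].to_numpy(),
                                             disc_labels, mode="two-group")
            for metric in ("observed", "ace")
        }
        report["alpha"] = alpha_stats

        stage = "ordination"
        dm = _distance(cfg, disc, tree)
        dm.write_tsv(out / f"distance_{cfg.distance}.tsv")
        pc = ordination.pcoa(dm, k=2)
        pc.to_dataframe().to_csv(out / "pcoa.csv")
        nm = ordination.nmds(dm, k=2, seed=cfg.seed)
        nm.to_dataframe().to_csv(out / "nmds.csv")
        an = ordination.anosim(dm, disc_labels, n_perm=999, seed=cfg.seed)
        (out / "anosim.json").write_text(json.dumps(an.to_dict(), sort_keys=True))
        report["beta"] = {
            "distance": cfg.distance,
            "pcoa_proportion_explained": [
                round(float(x), 6) for x in pc.proportion_explained[:2]],
            "nmds_stress": round(float(nm.stress), 6),
            "anosim": an.to_dict(),
        }

        stage = "screen"
        rel_disc = to_relative_abundance(disc)
        scfg = screen.ScreenConfig(seed=cfg.seed, **cfg.screen)
        sres = screen.select_candidates(rel_disc, disc, disc_labels, scfg)
        sres.table.to_csv(out / "screen.csv")
        report["screen"] = {"n_candidates": len(sres.candidates),
                            "candidates": sres.candidates}
        if not sres.candidates:
            raise RuntimeError("screen produced no candidate OTUs")
        if len(sres.candidates) < 2:
            raise RuntimeError("screen produced fewer than 2 candidates")

        stage = "rfcv"
        rcfg = cfg.rfcv
        curve = rfcv.cv_error_curve(
            rel_disc, disc_labels, sres.candidates,
            folds=int(rcfg.get("folds", 5)), repeats=int(rcfg.get("repeats", 3)),
            n_trees=int(rcfg.get("n_trees", 300)), seed=cfg.seed)
        k = rfcv.choose_feature_count(curve, rule=rcfg.get("rule", "min"))
        curve.to_dataframe().to_csv(out / "rfcv_curve.csv", index=False)
        panel = sres.candidates[:k]
        model = rfcv.train_final(
            rel_disc, disc_labels, panel,
            importance_floor=float(rcfg.get("importance_floor", 0.001)),
            n_trees=int(rcfg.get("n_trees", 300)), seed=cfg.seed,
            positive_label=case)
        rfcv.save_model(model, out / "model.json")
        model.importances.to_csv(out / "model_importances.csv")
        report["model"] = {"chosen_k": k, "panel": panel,
                           "below_floor": model.below_floor,
                           "n_trees": model.n_trees, "seed": model.seed}
        if truth is not None:
            planted = set(truth.effect_otus)
            report["model"]["planted_in_panel"] = len(planted & set(panel))

        stage = "evaluate"
        cohort_summaries = {}
        pod_disc = rfcv.compute_pod(model, rel_disc, labels=disc_labels,
                                    mode="cross-validated",
                                    folds=int(rcfg.get("folds", 5)),
                                    repeats=int(rcfg.get("repeats", 3)))
        roc_disc = rfcv.roc_analysis(pod_disc, disc_labels, case)
        cohort_summaries["discovery"] = roc_disc.summary()
        _persist_cohort(out, "discovery", pod_disc, roc_disc)

        rel_val = to_relative_abundance(val)
        roc_val = rfcv.validate_external(model, rel_val, val_labels)
        pod_val = rfcv.compute_pod(model, rel_val, mode="external")
        cohort_summaries["validation"] = roc_val.summary()
        _persist_cohort(out, "validation", pod_val, roc_val)

        for name, et, em in externals:
            rel_ext = to_relative_abundance(et)
            ext_labels = em.loc[et.sample_ids, "group"].to_numpy()
            roc_ext = rfcv.validate_external(model, rel_ext, ext_labels)
            pod_ext = rfcv.compute_pod(model, rel_ext, mode="external")
            cohort_summaries[name] = roc_ext.summary()
            _persist_cohort(out, name, pod_ext, roc_ext)
        report["cohorts"] = cohort_summaries

        stage = "sparcc"
        spcfg = cfg.sparcc
        indicators = list(spcfg.get("indicators", ["ALB", "Pro24h", "SCr"]))
        case_ids = [s for s in table.sample_ids
                    if meta.loc[s, "group"] == case]
        panel_table = table.select_samples(case_ids).select_otus(panel)
        have = [c for c in indicators if c in meta.columns]
        if have and len(case_ids) >= 10:
            try:
                assoc = sparcc.clinical_association(
                    panel_table.counts, panel, meta.loc[case_ids],
                    indicators=have,
                    n_inner=int(spcfg.get("n_inner", 10)),
                    n_boot=int(spcfg.get("n_boot", 50)), seed=cfg.seed)
                assoc.to_csv(out / "sparcc_clinical.csv", index=False)
                report["sparcc"] = {
                    "n_pairs": len(assoc),
                    "significant": int((assoc["p"] < 0.05).sum()),
                }
            except ValueError as e:
                report["sparcc"] = {"skipped": str(e)}
        else:
            report["sparcc"] = {"skipped": "insufficient clinical data"}
    except (StageError, ConfigError):
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    report_json = json.dumps(report, sort_keys=True, indent=1, default=float)
    (out / "report.json").write_text(report_json)
    (out / "report.md").write_text(_render_markdown(report))
    return report


def _persist_cohort(out: Path, name: str, pod: rfcv.PodScores,
                    roc: rfcv.RocResult) -> None:
    pod.scores.to_csv(out / f"pod_{name}.csv", header=True)
    roc.curve.to_csv(out / f"roc_{name}.csv", index=False)
    (out / f"summary_{name}.json").write_text(
        json.dumps(roc.summary(), sort_keys=True, default=float))


def _render_markdown(report: dict) -> str:
    lines = ["# Study report", ""]
    lines.append(f"Software version: {report['software_version']}")
    lines.append(f"POD definition: {report['pod_definition']}")
    lines.append("")
    if "alpha" in report:
        lines.append("## Alpha diversity (discovery)")
        for metric, res in report["alpha"].items():
            lines.append(f"- {metric}: {res['method']} statistic="
                         f"{res['statistic']:.4g}, p={res['p']:.4g}")
        lines.append("")
    if "beta" in report:
        b = report["beta"]
        lines.append("## Beta diversity (discovery)")
        lines.append(f"- distance: {b['distance']}")
        lines.append(f"- ANOSIM R={b['anosim']['R']:.4f}, p={b['anosim']['p']:.4g} "
                     f"({b['anosim']['n_permutations']} permutations)")
        lines.append(f"- NMDS stress: {b['nmds_stress']}")
        lines.append("")
    if "screen" in report:
        lines.append("## Candidate screen")
        lines.append(f"- candidates ({report['screen']['n_candidates']}): "
                     + ", ".join(report["screen"]["candidates"]))
        lines.append("")
    if "model" in report:
        m = report["model"]
        lines.append("## Diagnostic model")
        lines.append(f"- chosen feature count: {m['chosen_k']}")
        lines.append(f"- panel: {', '.join(m['panel'])}")
        lines.append("")
    if "cohorts" in report:
        lines.append("## Cohort performance")
        lines.append("| cohort | AUC | cut-off | sensitivity | specificity "
                     "| n case | n control |")
        lines.append("|---|---|---|---|---|---|---|")
        for name, s in report["cohorts"].items():
            lines.append(
                f"| {name} | {s['auc']:.4f} | {s['cutoff']:.4f} "
                f"| {s['sensitivity']:.4f} | {s['specificity']:.4f} "
                f"| {s['n_case']} | {s['n_control']} |")
        lines.append("")
    if "sparcc" in report:
        lines.append("## OTU-clinical correlation")
        lines.append(f"- {json.dumps(report['sparcc'], sort_keys=True)}")
        lines.append("")
    return "\n".join(lines)
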