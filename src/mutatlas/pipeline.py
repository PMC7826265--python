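"""End-to-end orchestration with a config file, manifest, and report.

Stages: generate (optional synthetic bundle) -> merge (multi-caller
consensus) -> stats -> mirna -> isomir -> clinical -> report. Each stage
reads/writes plain TSV/JSON under the run directory; the manifest records
the seed, the effective configuration, content hashes, and per-stage row
counts, so reruns of deterministic stages are bit-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import clinical as clin
from . import consensus, isomir, mirna, stats, synthetic
from .types import MutatlasError, ValidationError, load_transcripts

log = logging.getLogger("mutatlas")

STAGES = ("generate", "merge", "stats", "mirna", "isomir", "clinical", "report")


@dataclasses.dataclass
class Thresholds:
    hypermutation: int = 10_000
    detectability_pan: float = 0.30
    detectability_single: float = 0.10
    alpha: float = 0.05
    overmutation_nominal: float = 0.00005
    min_rpm: float = 100.0
    hotspot_recurrence: int = 3
    pseudocount: float = 1.0

    def validate(self):
        if self.hypermutation <= 0:
            raise ValidationError("thresholds.hypermutation must be > 0")
        for nm in ("detectability_pan", "detectability_single", "alpha",
                   "overmutation_nominal"):
            v = getattr(self, nm)
            if not 0 < v <= 1:
                raise ValidationError(f"thresholds.{nm} must be in (0, 1]")
        if self.min_rpm < 0:
            raise ValidationError("thresholds.min_rpm must be >= 0")
        if self.hotspot_recurrence < 2:
            raise ValidationError("thresholds.hotspot_recurrence must be >= 2")


@dataclasses.dataclass
class RunConfig:
    out_dir: str = "mutatlas_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    thresholds: Thresholds = dataclasses.field(default_factory=Thresholds)
    #: gene and mutation class driving the group comparisons
    focus_gene: str = "DICER1"
    focus_class: str = "hotspot"
    survival_gene: str = "SMAD4"
    survival_class: str = "deleterious"
    cnv_gene: str = "SMAD4"
    #: inputs; filled automatically by the generate stage
    inputs: dict = dataclasses.field(default_factory=dict)
    synthetic: Optional[synthetic.CohortConfig] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = Thresholds(**kwargs["thresholds"])
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            syn = dict(kwargs["synthetic"])
            for key, typ in (("arm_effect", synthetic.ArmEffect),
                             ("survival_effect", synthetic.SurvivalEffect),
                             ("cnv_effect", synthetic.CnvEffect)):
                if key in syn:
                    syn[key] = typ(**syn[key])
            if "genes" in syn:
                syn["genes"] = tuple(synthetic.GeneSpec(**g) for g in syn["genes"])
            if "hotspot_spec" in syn:
                syn["hotspot_spec"] = tuple(
                    synthetic.HotspotSpec(
                        **{**h, "cancers": tuple(h["cancers"])
                           if h.get("cancers") else None})
                    for h in syn["hotspot_spec"])
            if "cancer_types" in syn:
                syn["cancer_types"] = tuple(syn["cancer_types"])
            kwargs["synthetic"] = synthetic.CohortConfig(**syn)
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def validate(self) -> None:
        self.thresholds.validate()
        for st in self.stages:
            if st not in STAGES:
                raise ValidationError(f"unknown stage {st!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(o):
    import numpy as np
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


class StageError(MutatlasError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Any stage error halts the run with the stage name and a
    machine-readable code. The manifest lists every output file with a
    content hash and per-stage row counts.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        filename=out_dir / "run.log", level=logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s %(message)s", force=True)
    manifest: dict = {"seed": config.seed, "config": config.to_dict(),
                      "stages": {}, "outputs": {}}
    inputs = dict(config.inputs)
    th = config.thresholds

    def _register(name: str, path: Path, n_rows: Optional[int] = None):
        manifest["outputs"][name] = {"path": str(path),
                                     "sha256": _sha256(path),
                                     "rows": n_rows}

    def _need(key: str, stage: str) -> Path:
        if key not in inputs:
            raise StageError(stage, "missing-input",
                             f"required input {key!r} not available; did an "
                             "upstream stage run?")
        p = Path(inputs[key])
        if not p.exists():
            raise StageError(stage, "missing-input", f"{p} does not exist")
        return p

    # ---- generate -------------------------------------------------------
    if "generate" in config.stages:
        syn = config.synthetic or synthetic.CohortConfig(seed=config.seed)
        syn = dataclasses.replace(syn, seed=config.seed)
        bundle, truth = synthetic.generate_cohort(syn, out_dir / "cohort")
        log.info("generate: %d planted mutations, %d samples",
                 len(truth.mutations),
                 len(syn.cancer_types) * syn.n_samples_per_cancer)
        for key, path in bundle.items():
            if key == "calls_dir":
                inputs["calls_dir"] = str(path)
            else:
                inputs[key] = str(path)
                _register(f"cohort/{key}", Path(path))
        manifest["stages"]["generate"] = {
            "planted_mutations": len(truth.mutations),
            "hypermutated": len(truth.hypermutated)}

    # ---- merge ----------------------------------------------------------
    muts_df = None
    if "merge" in config.stages:
        calls_dir = _need("calls_dir", "merge")
        regions = _need("regions", "merge")
        clinical_path = _need("clinical", "merge")
        clinical_df = pd.read_csv(clinical_path, sep="\t")
        transcripts = None
        if "transcripts" in inputs:
            transcripts = load_transcripts(inputs["transcripts"])
        muts = consensus.run_consensus(calls_dir, regions, clinical_df,
                                       transcripts)
        muts_path = out_dir / "mutations.tsv"
        muts_df = consensus.write_mutations_tsv(muts, muts_path)
        inputs["mutations"] = str(muts_path)
        _register("mutations", muts_path, len(muts_df))
        manifest["stages"]["merge"] = {"consensus_mutations": len(muts_df)}
        log.info("merge: %d consensus mutations", len(muts_df))

    # ---- shared tables --------------------------------------------------
    def _load_samples(stage):
        df = pd.read_csv(_need("clinical", stage), sep="\t")
        return stats.flag_hypermutated(df, th.hypermutation)

    def _load_muts(stage):
        nonlocal muts_df
        if muts_df is None:
            muts_df = consensus.read_mutations_tsv(_need("mutations", stage))
        return muts_df

    # ---- stats ----------------------------------------------------------
    if "stats" in config.stages:
        samples = _load_samples("stats")
        muts_all = _load_muts("stats")
        muts_kept, samples_kept = stats.exclude_hypermutated(muts_all, samples)
        summary = stats.classification_summary(muts_kept)
        summary["n_samples"] = len(samples_kept)
        summary["n_samples_excluded"] = int(samples["hypermutated"].sum())
        summary["n_mutations_excluded"] = len(muts_all) - len(muts_kept)
        p = out_dir / "classification_summary.json"
        p.write_text(json.dumps(summary, indent=1, default=_json_default) + "\n")
        _register("classification_summary", p)
        freq = stats.sample_mutation_frequency(muts_kept, samples_kept)
        p = out_dir / "mutation_frequency.tsv"
        freq.to_csv(p, sep="\t", float_format="%.4f")
        _register("mutation_frequency", p, len(freq))
        enrich = stats.overmutation_scan(muts_kept, samples_kept)
        p = out_dir / "overmutation.tsv"
        enrich.to_csv(p, sep="\t", index=False)
        _register("overmutation", p, len(enrich))
        hotspots = stats.detect_hotspots(muts_kept, th.hotspot_recurrence)
        p = out_dir / "hotspots.tsv"
        stats.hotspots_to_frame(hotspots).to_csv(p, sep="\t", index=False)
        _register("hotspots", p, len(hotspots))
        manifest["stages"]["stats"] = {
            "mutations_retained": len(muts_kept),
            "samples_retained": len(samples_kept),
            "hotspots": len(hotspots),
            "significant_overmutation": int(
                (enrich["p"] < th.overmutation_nominal).sum()),
        }

    # ---- mirna ----------------------------------------------------------
    if "mirna" in config.stages:
        samples = _load_samples("mirna")
        muts_all = _load_muts("mirna")
        muts_kept, samples_kept = stats.exclude_hypermutated(muts_all, samples)
        annotations = pd.read_csv(_need("mirna_annotations", "mirna"), sep="\t")
        em = mirna.load_expression(_need("expression_normalized", "mirna"),
                                   "batch_normalized", annotations)
        em = em.subset(em.values.index[
            (em.values == 0).mean(axis=1) <= th.detectability_pan])
        labels = samples_kept.set_index("sample_id")["cancer_type"]
        em = mirna.ExpressionMatrix(
            em.values[[s for s in em.samples if s in labels.index]],
            em.dialect, em.arm, em.high_confidence)
        em = mirna.pan_cancer_normalize(em, labels)
        hotspots = stats.detect_hotspots(muts_kept, th.hotspot_recurrence)
        residues = [h.aa_position for h in hotspots
                    if h.gene == config.focus_gene] or None
        mutated, reference = mirna.define_groups(
            samples_kept, muts_kept, config.focus_gene, config.focus_class,
            hotspot_residues=residues)
        results = mirna.diff_test(em, mutated, reference)
        p = out_dir / "diff_results.tsv"
        results.to_csv(p, sep="\t", index=False, float_format="%.6g")
        _register("diff_results", p, len(results))
        arm = mirna.arm_asymmetry(results, th.alpha)
        # RPM dialect re-normalized against the reference miRNA
        arm_ref = None
        if "expression_rpm" in inputs:
            em_rpm = mirna.load_expression(inputs["expression_rpm"], "rpm",
                                           annotations)
            em_rpm = mirna.filter_expressed(em_rpm, "pan_cancer")
            em_rpm = mirna.ExpressionMatrix(
                em_rpm.values[[s for s in em_rpm.samples if s in labels.index]],
                "rpm", em_rpm.arm, em_rpm.high_confidence)
            ref_id = (config.synthetic.reference_mirna_id if config.synthetic
                      else "hsa-miR-451a")
            if ref_id in em_rpm.values.index:
                em_ref = mirna.reference_normalize(em_rpm, ref_id,
                                                   th.pseudocount)
                res_ref = mirna.diff_test(em_ref, mutated, reference)
                p2 = out_dir / "diff_results_refnorm.tsv"
                res_ref.to_csv(p2, sep="\t", index=False, float_format="%.6g")
                _register("diff_results_refnorm", p2, len(res_ref))
                arm_ref = mirna.arm_asymmetry(res_ref, th.alpha)
        p = out_dir / "arm_asymmetry.json"
        p.write_text(json.dumps(
            {"pan_cancer_normalized": arm, "reference_normalized": arm_ref},
            indent=1, default=_json_default) + "\n")
        _register("arm_asymmetry", p)
        manifest["stages"]["mirna"] = {
            "n_mirnas_tested": len(results),
            "n_mutated": len(mutated), "n_reference": len(reference),
            "direction": mirna.direction_summary(results, th.alpha),
        }

    # ---- isomir ---------------------------------------------------------
    if "isomir" in config.stages:
        samples = _load_samples("isomir")
        muts_all = _load_muts("isomir")
        muts_kept, samples_kept = stats.exclude_hypermutated(muts_all, samples)
        iso = isomir.load_isomirs(_need("isomirs", "isomir"))
        annotations = pd.read_csv(_need("mirna_annotations", "isomir"), sep="\t")
        arm = annotations.set_index("mirna")["arm"]
        hotspots = stats.detect_hotspots(muts_kept, th.hotspot_recurrence)
        residues = [h.aa_position for h in hotspots
                    if h.gene == config.focus_gene] or None
        mutated, reference = mirna.define_groups(
            samples_kept, muts_kept, config.focus_gene, config.focus_class,
            hotspot_residues=residues)
        selected = isomir.select_high_expression_3p(iso, arm, th.min_rpm)
        fractions = [isomir.main_fraction(iso, m, reference) for m in selected]
        comp = isomir.compare_fractions(fractions, mutated, reference)
        p = out_dir / "isomir_comparison.tsv"
        comp.to_csv(p, sep="\t", index=False, float_format="%.6g")
        _register("isomir_comparison", p, len(comp))
        manifest["stages"]["isomir"] = {
            "n_mirnas_selected": len(selected),
            "pooled_p": (None if comp.empty else
                         comp.loc[comp["mirna"] == "pooled", "p"].iloc[0]),
        }

    # ---- clinical -------------------------------------------------------
    if "clinical" in config.stages:
        samples = _load_samples("clinical")
        muts_all = _load_muts("clinical")
        muts_kept, samples_kept = stats.exclude_hypermutated(muts_all, samples)
        hotspots = stats.detect_hotspots(muts_kept, th.hotspot_recurrence)
        residues = [h.aa_position for h in hotspots
                    if h.gene == config.survival_gene] or None
        mutated, reference = mirna.define_groups(
            samples_kept, muts_kept, config.survival_gene,
            config.survival_class, hotspot_residues=residues)
        surv = clin.km_logrank(samples_kept, mutated, reference,
                               label=f"{config.survival_gene}:"
                                     f"{config.survival_class}")
        p = out_dir / "survival.json"
        p.write_text(json.dumps(surv.to_dict(), indent=1,
                                default=_json_default) + "\n")
        _register("survival", p)
        any_mut, _ = mirna.define_groups(samples_kept, muts_kept,
                                         config.survival_gene, "any")
        stage_res = clin.cmh_stage_test(samples_kept, any_mut)
        p = out_dir / "stage_association.json"
        p.write_text(json.dumps({
            "n_strata": stage_res.n_strata,
            "cmh_statistic": stage_res.statistic,
            "cmh_p": stage_res.p,
            "per_stratum_fisher": stage_res.per_stratum_fisher,
        }, indent=1, default=_json_default) + "\n")
        _register("stage_association", p)
        cnv_stats = None
        if "copy_number" in inputs:
            cnv_df = pd.read_csv(inputs["copy_number"], sep="\t")
            if config.cnv_gene in cnv_df.columns:
                table, fisher_p = clin.cnv_cooccurrence(
                    samples_kept, cnv_df, muts_kept, config.cnv_gene,
                    hotspot_residues=residues)
                p = out_dir / "cnv_cooccurrence.tsv"
                table.to_csv(p, sep="\t", index=False, float_format="%.6g")
                _register("cnv_cooccurrence", p, len(table))
                cnv_stats = {"fisher_p": fisher_p}
        manifest["stages"]["clinical"] = {
            "logrank_p": surv.p, "hazard_ratio": surv.hazard_ratio,
            "cmh_p": stage_res.p, "cnv": cnv_stats,
        }

    # ---- report ---------------------------------------------------------
    if "report" in config.stages:
        report = render_report(out_dir, manifest)
        p = out_dir / "report.md"
        p.write_text(report)
        _register("report", p)

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True,
                                        default=_json_default) + "\n")
    return manifest


def render_report(out_dir, manifest: Optional[dict] = None) -> str:
    """Human-readable summary of whatever outputs are present; missing
    sections are reported as gaps rather than errors."""
    out_dir = Path(out_dir)
    lines = ["# mutatlas run report", ""]

    def _section(title, path, fmt):
        lines.append(f"## {title}")
        p = out_dir / path
        if not p.exists():
            lines.append("_not computed in this run_")
        else:
            fmt(p)
        lines.append("")

    def _json_block(p):
        lines.append("```json")
        lines.append(p.read_text().strip())
        lines.append("```")

    def _tsv_head(p, n=15):
        df = pd.read_csv(p, sep="\t")
        lines.append(f"{len(df)} rows; first {min(n, len(df))}:")
        lines.append("```")
        lines.append(df.head(n).to_string(index=False))
        lines.append("```")

    _section("Mutation classification", "classification_summary.json",
             _json_block)
    _section("Mutated-sample frequency (% by gene x cancer)",
             "mutation_frequency.tsv", _tsv_head)
    _section("Overmutation enrichment", "overmutation.tsv",
             lambda p: _tsv_head(p, 10))
    _section("Hotspots", "hotspots.tsv", _tsv_head)
    _section("Differential miRNA results", "diff_results.tsv",
             lambda p: _tsv_head(p, 10))
    _section("Arm asymmetry", "arm_asymmetry.json", _json_block)
    _section("isomiR main-fraction comparison", "isomir_comparison.tsv",
             lambda p: _tsv_head(p, 10))
    _section("Survival", "survival.json", lambda p: lines.append(
        json.dumps({k: v for k, v in json.loads(p.read_text()).items()
                    if k != "curves"}, indent=1)))
    _section("Stage association", "stage_association.json", _json_block)
    _section("Copy-number co-occurrence", "cnv_cooccurrence.tsv", _tsv_head)
    return "\n".join(lines)
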