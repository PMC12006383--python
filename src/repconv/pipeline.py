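"""End-to-end orchestration: simulate -> load -> clonotype -> share ->
derive -> enrich -> features -> report, under one validated config.

Every stage writes tidy TSV outputs into the run directory and records
its row counts in the run report; a stage failure leaves earlier
outputs in place and marks the failed stage.  Identical config + seed
gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import airr_io, clonotyping, convergence, features, synthetic

logger = logging.getLogger("repconv")


class ConfigError(ValueError):
    """Raised when a pipeline configuration fails validation."""


@dataclass
class PipelineConfig:
    """One pipeline run: simulation inputs, thresholds, and stage knobs.

    Defaults for the sharing/derivation stages follow the published
    protocol scale (8 patients x 1500 clones x 200 iterations for
    group-level sharing; 16 patients x 500 clones for isotype-level
    sharing; two case carriers minimum; top-3000 expansion refinement);
    the bundled demo (:func:`demo_config`) scales these to the demo
    cohort so it finishes in minutes.
    """

    simulation: synthetic.SimulationConfig = field(
        default_factory=synthetic.SimulationConfig
    )
    nt_threshold: float = 0.15
    aa_identity_threshold: float = 0.85
    sharing_n_patients: int = 8
    sharing_n_clones: int = 1500
    sharing_n_iter: int = 200
    min_case_carriers: int = 2
    top_n_expanded: int | None = 3000
    enrichment_weight: str = "clone"
    enrichment_sidedness: str = "greater"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.nt_threshold <= 1.0):
            raise ConfigError("nt_threshold must lie in (0, 1]")
        if not (0.0 < self.aa_identity_threshold <= 1.0):
            raise ConfigError("aa_identity_threshold must lie in (0, 1]")
        if self.min_case_carriers < 2:
            raise ConfigError(
                "min_case_carriers must be >= 2: a shared disease-associated "
                "clone requires at least two case carriers"
            )
        if self.sharing_n_patients < 2 or self.sharing_n_clones < 1 or self.sharing_n_iter < 1:
            raise ConfigError("sharing parameters must be positive (>= 2 patients)")
        if self.top_n_expanded is not None and self.top_n_expanded < 1:
            raise ConfigError("top_n_expanded must be positive or null")
        if self.enrichment_weight not in {"clone", "umi"}:
            raise ConfigError("enrichment_weight must be 'clone' or 'umi'")
        if self.seed is None:
            raise ConfigError("seed is required")
        self.simulation.validate()

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulation", {})
        if isinstance(sim, Mapping):
            sim_fields = {f.name for f in dataclasses.fields(synthetic.SimulationConfig)}
            unknown = set(sim) - sim_fields
            if unknown:
                raise ConfigError(f"unknown simulation fields: {sorted(unknown)}")
            sim_kwargs = dict(sim)
            if "cdr3_length_distribution" in sim_kwargs:
                sim_kwargs["cdr3_length_distribution"] = {
                    int(k): float(v)
                    for k, v in sim_kwargs["cdr3_length_distribution"].items()
                }
            sim = synthetic.SimulationConfig(**sim_kwargs)
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(simulation=sim, **data)
        # seed propagates to the simulation unless it sets its own
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls.from_dict(data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def demo_config(seed: int = 0) -> PipelineConfig:
    """The bundled demo: 16 cases, 8 controls, 50 planted public clones
    at penetrance 0.6, 500 clones per subject; sharing and refinement
    parameters scaled to that cohort."""
    return PipelineConfig(
        simulation=synthetic.SimulationConfig(
            n_case_subjects=16,
            n_control_subjects=8,
            clones_per_subject=500,
            public_clone_count=50,
            public_penetrance=0.6,
            seed=seed,
        ),
        sharing_n_patients=8,
        sharing_n_clones=400,
        sharing_n_iter=25,
        top_n_expanded=300,
        seed=seed,
    )


@dataclass
class RunReport:
    """Per-stage accounting for one pipeline run."""

    config: dict = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    manifest: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def record(self, stage: str, **counts) -> None:
        self.stages.append({"stage": stage, **counts})
        logger.info("stage %s: %s", stage, counts)

    def to_json_dict(self) -> dict:
        return {
            "config": self.config,
            "stages": self.stages,
            "manifest": self.manifest,
            "failed_stage": self.failed_stage,
        }


def clones_to_frame(clones_by_sample: Mapping[str, list[clonotyping.Clone]]) -> pd.DataFrame:
    rows = []
    for sample_id in sorted(clones_by_sample):
        for c in clones_by_sample[sample_id]:
            rows.append(
                {
                    "sample_id": c.sample_id,
                    "subject_id": c.subject_id,
                    "clone_id": c.clone_id,
                    "v_gene": c.v_gene,
                    "j_gene": c.j_gene,
                    "cdr3_length": c.cdr3_length,
                    "junction_aa": c.junction_aa,
                    "member_count": c.member_count,
                    "umi_total": c.umi_total,
                    "isotype": c.dominant_isotype,
                    "mean_shm_percent": (
                        "" if c.mean_shm_percent is None else round(c.mean_shm_percent, 6)
                    ),
                }
            )
    return pd.DataFrame(rows)


def clones_from_frame(df: pd.DataFrame) -> dict[str, list[clonotyping.Clone]]:
    """Rebuild key-level clones from a clone table TSV (no member
    rearrangements; sufficient for sharing/derivation/enrichment)."""
    from collections import Counter

    out: dict[str, list[clonotyping.Clone]] = {}
    for rec in df.to_dict("records"):
        shm = rec.get("mean_shm_percent")
        clone = clonotyping.Clone(
            clone_id=str(rec["clone_id"]),
            sample_id=str(rec["sample_id"]),
            subject_id=str(rec["subject_id"]),
            v_gene=str(rec["v_gene"]),
            j_gene=str(rec["j_gene"]),
            junction_aa=str(rec["junction_aa"]),
            member_count=int(rec["member_count"]),
            umi_total=int(rec["umi_total"]),
            isotypes=Counter({str(rec["isotype"]): int(rec["member_count"])}),
            mean_shm_percent=(
                None if shm in ("", None) or pd.isna(shm) else float(shm)
            ),
        )
        out.setdefault(clone.sample_id, []).append(clone)
    return out


def _write_tsv(df: pd.DataFrame, path: Path, report: RunReport) -> None:
    df.to_csv(path, sep="\t", index=False)
    report.manifest.append(path.name)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunReport:
    """Execute the full analysis on a simulated cohort.

    Stages: simulate, write/load round trip through the AIRR TSV layer,
    within-sample clone assignment, subsampled sharing (case group),
    disease-list derivation (cases vs controls), enrichment scoring of
    every sample against the derived list with a case/control rank-sum
    test, SHM and gene-usage feature tables, and a JSON run report.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict())
    t0 = time.time()
    stage = "simulate"
    try:
        samples, truth = synthetic.simulate_dataset(config.simulation)
        airr_path = outdir / "repertoire.tsv"
        airr_io.write_repertoire(samples, airr_path)
        report.manifest.append(airr_path.name)
        meta_path = outdir / "metadata.tsv"
        airr_io.write_metadata(samples, meta_path)
        report.manifest.append(meta_path.name)
        truth_path = outdir / "ground_truth.json"
        truth_path.write_text(json.dumps(truth.to_json_dict(), sort_keys=True))
        report.manifest.append(truth_path.name)
        report.record(
            stage,
            n_samples=len(samples),
            n_rearrangements=sum(len(s) for s in samples),
            n_planted_public=len(truth.planted_public),
        )

        stage = "load"
        metadata = airr_io.read_metadata(meta_path)
        samples, load_report = airr_io.read_repertoire(airr_path, metadata)
        report.record(stage, n_rows=load_report.n_rows, n_kept=load_report.n_kept,
                      n_dropped=load_report.n_dropped)

        stage = "clonotype"
        clones_by_sample = {
            s.sample_id: clonotyping.assign_clones(s, config.nt_threshold) for s in samples
        }
        for clones in clones_by_sample.values():
            features.annotate_clone_shm(clones)
        _write_tsv(clones_to_frame(clones_by_sample), outdir / "clones.tsv", report)
        report.record(stage, n_clones=sum(len(v) for v in clones_by_sample.values()))

        group_of_sample = {s.sample_id: s.group for s in samples}
        case_group = config.simulation.case_group
        control_group = config.simulation.control_group
        case_ids = sorted(s.sample_id for s in samples if s.group == case_group)
        control_ids = sorted(s.sample_id for s in samples if s.group == control_group)

        stage = "share"
        clones_by_patient = {}
        for sid in case_ids:
            for c in clones_by_sample[sid]:
                clones_by_patient.setdefault(c.subject_id, []).append(c)
        sharing = convergence.subsampled_sharing(
            clones_by_patient,
            n_patients=config.sharing_n_patients,
            n_clones=config.sharing_n_clones,
            n_iter=config.sharing_n_iter,
            seed=config.seed,
            threshold=config.aa_identity_threshold,
            group=case_group,
        )
        _write_tsv(sharing, outdir / "sharing.tsv", report)
        report.record(stage, n_iterations=len(sharing),
                      median_shared=float(sharing["shared_clone_count"].median()))

        stage = "derive"
        dlist = convergence.derive_disease_list(
            {sid: clones_by_sample[sid] for sid in case_ids},
            {sid: clones_by_sample[sid] for sid in control_ids},
            min_case_carriers=config.min_case_carriers,
            top_n=config.top_n_expanded,
            threshold=config.aa_identity_threshold,
            list_id="disease_list",
            case_group=case_group,
            control_groups=(control_group,),
        )
        dlist.to_tsv(outdir / "disease_list.tsv")
        report.manifest.append("disease_list.tsv")
        report.record(stage, n_clusters=len(dlist))

        stage = "enrich"
        enrichment = convergence.score_enrichment(
            dlist, clones_by_sample, weight=config.enrichment_weight
        )
        _write_tsv(enrichment, outdir / "enrichment.tsv", report)
        test = convergence.enrichment_group_test(
            enrichment,
            group_of_sample,
            case_group,
            control_group,
            sidedness=config.enrichment_sidedness,
        )
        _write_tsv(test, outdir / "enrichment_test.tsv", report)
        report.record(
            stage,
            n_samples=len(enrichment),
            pvalue=(float(test["pvalue"].iloc[0]) if len(test) else float("nan")),
        )

        stage = "shm"
        shm_clone = features.shm_records(clones_by_sample)
        _write_tsv(shm_clone, outdir / "shm_clones.tsv", report)
        shm_summary = features.shm_by_isotype(clones_by_sample)
        _write_tsv(shm_summary, outdir / "shm_by_isotype.tsv", report)
        report.record(stage, n_clone_records=len(shm_clone), n_strata=len(shm_summary))

        stage = "usage"
        for gene_field in ("v", "j"):
            usage = features.gene_usage(clones_by_sample, gene_field=gene_field)
            _write_tsv(usage, outdir / f"{gene_field}_usage.tsv", report)
        report.record(stage)

        stage = "report"
        report.record(stage, wall_seconds=round(time.time() - t0, 2))
        report_path = outdir / "run_report.json"
        report_path.write_text(json.dumps(report.to_json_dict(), indent=2, sort_keys=True))
        report.manifest.append(report_path.name)
        for name in report.manifest:
            assert (outdir / name).exists(), f"manifest entry missing: {name}"
    except Exception:
        report.failed_stage = stage
        (outdir / "run_report.json").write_text(
            json.dumps(report.to_json_dict(), indent=2, sort_keys=True)
        )
        logger.error("pipeline failed at stage %s", stage)
        raise
    return report


def output_checksums(outdir: str | Path) -> dict[str, str]:
    """SHA-256 of every data output in a run directory (determinism
    audit: identical config + seed must give identical checksums).

    The run report carries wall-clock timings, so it is excluded; all
    TSV outputs and the ground-truth JSON are covered.
    """
    outdir = Path(outdir)
    sums = {}
    for path in sorted(outdir.glob("*")):
        if path.is_file() and (path.suffix == ".tsv" or path.name == "ground_truth.json"):
            sums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return sums
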