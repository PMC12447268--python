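"""Stage orchestration: simulate -> ingest -> annotate -> dynamics ->
kinetics -> response -> report.

Each stage is a pure function of (inputs, config, seed): all randomness
lives in the simulate stage, analysis stages are deterministic, and a
manifest recording the configuration, package version, and seed is
written next to the outputs so every number in a report is regenerable.
Timings go to the log, never into output tables, which keeps reruns
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .dynamics import (build_trajectories, classify_kinetics, classify_longevity,
                       shared_clones, run_expansion_tests, trajectories_to_frame)
from .expression import (QCParams, cluster_mean_expression, normalize_log1p,
                         profiles_to_frame, qc_filter, read_expression,
                         score_signatures, assign_phenotypes)
from .kinetics import (MeasurementSeries, best_response_fold, count_responders,
                       summarize_folds)
from .repertoire import (read_bulk_repertoire, read_clone_table,
                         read_sc_clonotypes, write_clone_table)
from .response import BlastSeries, RecoveryFlags, change_from_baseline, classify_eln
from .signatures import default_signatures
from .simulate import SimulationParams, write_dataset
from .timepoints import Timepoint

logger = logging.getLogger(__name__)

STAGES = ("simulate", "repertoire", "annotate", "dynamics", "kinetics",
          "response", "report")


class PipelineError(RuntimeError):
    """A stage precondition failed; nothing was (or will be) written."""


@dataclass
class PipelineConfig:
    """Run configuration; YAML-serializable, CLI-overridable."""

    outdir: str = "clonaltrack_out"
    seed: int = 0
    alpha: float = 0.05
    test_mode: str = "pooled_null"
    classification_mode: str = "significance"
    early: str = "d14"
    late: str = "d42"
    responder_threshold: float = 1.5
    qc: Dict[str, object] = field(default_factory=dict)
    simulate: Dict[str, object] = field(default_factory=dict)
    inputs: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def qc_params(self) -> QCParams:
        return QCParams(**self.qc)

    def simulation_params(self) -> SimulationParams:
        return SimulationParams(seed=self.seed, **self.simulate)


def _check_inputs(config: PipelineConfig, keys: Sequence[str], stage: str) -> None:
    for key in keys:
        value = config.inputs.get(key)
        if value is None:
            raise PipelineError(
                f"stage {stage!r} needs input {key!r}; run simulate first or "
                "point the config at existing files")
        paths = value if isinstance(value, list) else [value]
        for p in paths:
            if not Path(p).exists():
                raise PipelineError(f"stage {stage!r}: input path {p} does not exist")


def _stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    params = config.simulation_params()
    synth = outdir / "synthetic"
    write_dataset(synth, params)
    rep = synth / "repertoire"
    config.inputs.setdefault("contigs", sorted(str(p) for p in rep.glob("bm_*_contigs.csv")))
    config.inputs.setdefault("bulk", sorted(str(p) for p in rep.glob("pb_*_bulk.tsv")))
    config.inputs.setdefault("expression_dir", str(synth / "expression"))
    config.inputs.setdefault("assays", str(synth / "assays.tsv"))
    config.inputs.setdefault("blast", str(synth / "blast.tsv"))
    config.inputs.setdefault("flags", str(synth / "flags.tsv"))


def _parse_sample_name(path: Path):
    # files are named <compartment>_<timepoint>_(contigs|bulk).<ext>
    parts = path.stem.split("_")
    if len(parts) < 2:
        raise PipelineError(f"cannot infer compartment/timepoint from {path.name}")
    return parts[0].upper(), parts[1]


def _load_samples(config: PipelineConfig, patient_id: str = "P001"):
    samples = []
    for p in config.inputs.get("contigs", []):
        path = Path(p)
        compartment, tp = _parse_sample_name(path)
        samples.append(read_sc_clonotypes(
            path, patient_id=patient_id, compartment=compartment, timepoint=tp))
    for p in config.inputs.get("bulk", []):
        path = Path(p)
        compartment, tp = _parse_sample_name(path)
        samples.append(read_bulk_repertoire(
            path, patient_id=patient_id, compartment=compartment, timepoint=tp))
    return samples


def _stage_repertoire(config: PipelineConfig, outdir: Path) -> None:
    _check_inputs(config, ["contigs", "bulk"], "repertoire")
    samples = _load_samples(config)
    write_clone_table(samples, outdir / "clone_table.tsv")


def _stage_annotate(config: PipelineConfig, outdir: Path) -> None:
    _check_inputs(config, ["expression_dir"], "annotate")
    exp = Path(config.inputs["expression_dir"])
    adata = read_expression(exp / "matrix.mtx", exp / "features.tsv",
                            exp / "barcodes.tsv", exp / "cell_meta.tsv")
    adata = qc_filter(adata, config.qc_params())
    normalize_log1p(adata)
    profiles = cluster_mean_expression(adata)
    signatures = default_signatures()
    score_signatures(profiles, signatures)
    assign_phenotypes(profiles)
    profiles_to_frame(profiles).to_csv(outdir / "cluster_profiles.tsv",
                                       sep="\t", index=False)


def _stage_dynamics(config: PipelineConfig, outdir: Path) -> None:
    clone_table = outdir / "clone_table.tsv"
    if not clone_table.exists():
        raise PipelineError("stage 'dynamics' needs clone_table.tsv; run the "
                            "repertoire stage first")
    samples = read_clone_table(clone_table)
    by_key: Dict[tuple, list] = {}
    for s in samples:
        by_key.setdefault((s.patient_id, s.compartment), []).append(s)
    frames = []
    for (patient, compartment), group in sorted(by_key.items()):
        trajectories = build_trajectories(group)
        run_expansion_tests(trajectories, early=config.early, late=config.late,
                          test_mode=config.test_mode)
        spans_m6 = max(tp.days for tp in trajectories[0].timepoints) >= Timepoint.M6.days
        for t in trajectories:
            classify_kinetics(t, alpha=config.alpha, early=config.early,
                              late=config.late,
                              classification_mode=config.classification_mode)
            if spans_m6 and t.last_detected is not None:
                classify_longevity(t)
        frame = trajectories_to_frame(trajectories)
        frame.insert(0, "patient", patient)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "trajectories.tsv", sep="\t", index=False)

    bm = [s for s in samples if s.compartment == "BM"]
    pb = [s for s in samples if s.compartment == "PB"]
    if bm and pb:
        report = shared_clones(bm, pb)
        payload = {"patient": report.patient_id,
                   "venn": report.venn_counts(),
                   "cumulative_bm_frequency": report.cumulative_bm_frequency}
        (outdir / "venn.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _stage_kinetics(config: PipelineConfig, outdir: Path) -> None:
    _check_inputs(config, ["assays"], "kinetics")
    df = pd.read_csv(config.inputs["assays"], sep="\t",
                     dtype={"patient": str})
    rows, folds_by_analyte = [], {}
    keys = ["patient", "compartment", "analyte", "unit"]
    for (patient, compartment, analyte, unit), grp in df.groupby(keys, sort=True):
        series = MeasurementSeries(
            patient_id=patient, compartment=compartment, analyte=analyte,
            unit=unit, values=dict(zip(grp["timepoint"], grp["value"])))
        tp, fold = best_response_fold(series)
        rows.append({"patient": patient, "compartment": compartment,
                     "analyte": analyte, "best_timepoint": tp.label,
                     "pre": series.pre, "best": series.values[tp],
                     "fold": fold})
        folds_by_analyte.setdefault((analyte, compartment), []).append(fold)
    per_patient = pd.DataFrame(rows)
    per_patient.to_csv(outdir / "fold_table.tsv", sep="\t", index=False)
    summary_rows = []
    for (analyte, compartment), folds in sorted(folds_by_analyte.items()):
        summary = summarize_folds(folds)
        summary_rows.append({
            "analyte": analyte, "compartment": compartment, "n": summary.n,
            "mean_fold": round(summary.mean, 2), "sem_fold": round(summary.sem, 2),
            "responders": count_responders(folds, config.responder_threshold)})
    pd.DataFrame(summary_rows).to_csv(outdir / "fold_summary.tsv",
                                      sep="\t", index=False)


def _stage_response(config: PipelineConfig, outdir: Path) -> None:
    _check_inputs(config, ["blast"], "response")
    blast = pd.read_csv(config.inputs["blast"], sep="\t", dtype={"patient": str})
    flags_path = config.inputs.get("flags")
    flag_map: Dict[str, RecoveryFlags] = {}
    if flags_path and Path(flags_path).exists():
        fdf = pd.read_csv(flags_path, sep="\t", dtype={"patient": str})
        for _, row in fdf.iterrows():
            flag_map[row["patient"]] = RecoveryFlags(
                anc_recovered=bool(row["anc_recovered"]),
                platelets_recovered=bool(row["platelets_recovered"]))
    rows = []
    for patient, grp in blast.groupby("patient", sort=True):
        series = BlastSeries(patient_id=patient,
                             values=dict(zip(grp["timepoint"],
                                             grp["blast_percent"])))
        changes = change_from_baseline(series)
        post = series.post()
        best_tp = min(post, key=lambda tp: post[tp])
        rows.append({
            "patient": patient,
            "baseline_blast": series.baseline,
            "best_timepoint": best_tp.label,
            "best_blast": post[best_tp],
            "change_from_baseline": changes[best_tp],
            "response": classify_eln(series, flag_map.get(patient))})
    pd.DataFrame(rows).to_csv(outdir / "response.tsv", sep="\t", index=False)


def _stage_report(config: PipelineConfig, outdir: Path) -> None:
    report: Dict[str, object] = {}
    traj_path = outdir / "trajectories.tsv"
    if traj_path.exists():
        df = pd.read_csv(traj_path, sep="\t")
        report["kinetic_class_counts"] = (
            df["kinetic_class"].value_counts().sort_index().to_dict())
    venn = outdir / "venn.json"
    if venn.exists():
        report["venn"] = json.loads(venn.read_text())
    resp = outdir / "response.tsv"
    if resp.exists():
        df = pd.read_csv(resp, sep="\t")
        report["responses"] = dict(zip(df["patient"], df["response"]))
    summary = outdir / "fold_summary.tsv"
    if summary.exists():
        df = pd.read_csv(summary, sep="\t")
        report["fold_summaries"] = df.to_dict(orient="records")
    profiles = outdir / "cluster_profiles.tsv"
    if profiles.exists():
        df = pd.read_csv(profiles, sep="\t")
        report["cluster_phenotypes"] = dict(zip(df["cluster"], df["phenotype"]))
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "repertoire": _stage_repertoire,
    "annotate": _stage_annotate,
    "dynamics": _stage_dynamics,
    "kinetics": _stage_kinetics,
    "response": _stage_response,
    "report": _stage_report,
}


def run_pipeline(config: PipelineConfig,
                 stages: Optional[Sequence[str]] = None) -> Dict[str, float]:
    """Run the requested stages in canonical order; returns stage timings.

    Raises :class:`PipelineError` before touching the output directory
    when a requested stage's inputs are missing.  The manifest
    (config + package version) is written on success.
    """
    requested = list(stages) if stages else list(STAGES)
    unknown = [s for s in requested if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stages {unknown}; choose from {STAGES}")
    ordered = [s for s in STAGES if s in requested]
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: Dict[str, float] = {}
    for stage in ordered:
        t0 = time.perf_counter()
        logger.info("stage %s: starting", stage)
        _STAGE_FUNCS[stage](config, outdir)
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %s: done in %.2fs", stage, timings[stage])
    manifest = {
        "package": "clonaltrack",
        "version": __version__,
        "seed": config.seed,
        "stages": ordered,
        "config": dataclasses.asdict(config),
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return timings
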