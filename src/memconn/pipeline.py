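"""Manifest handling, file dialects, and end-to-end orchestration.

Stages run in a fixed order — simulate (or load) -> per-run connectomes ->
QC -> generalized connectomes -> network summaries -> brain-behavior models
-> CBPM -> lesion analysis — and every tabular artifact is written in one
dialect: UTF-8, header row, '.' decimal, NA token "NA", numbers at 10
significant digits. A provenance record carries the configuration hash and
the master seed so identical inputs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, cbpm as cbpm_mod, networks
from .connectome import (
    ConfoundSet,
    Connectome,
    PipelineOptions,
    RoiTimeSeries,
    TaskEvents,
    average_connectomes,
    qc_filter,
    run_connectome,
)
from .networks import AtlasLabels
from .synthetic import SimulationConfig, write_cohort

log = logging.getLogger(__name__)

NA = "NA"
FLOAT_FORMAT = "%.10g"

__all__ = [
    "PipelineConfig",
    "load_manifest",
    "validate_inputs",
    "run_pipeline",
    "write_connectome",
    "read_connectome",
]


@dataclass
class PipelineConfig:
    """Declarative configuration for the full pipeline.

    All randomness flows from ``seed``; stage-specific seeds are derived
    from it, so a config + manifest pair pins every numeric output.
    """

    seed: int = 0
    options: PipelineOptions = field(default_factory=PipelineOptions)
    cbpm: cbpm_mod.CbpmConfig = field(default_factory=cbpm_mod.CbpmConfig)
    behavior_column: str = "behavior"
    cbpm_covariates: tuple = ("age", "sex", "fd")
    include_hipp_in_extra: bool = False
    include_hipp_internal: bool = False
    run_lesion: bool = True
    run_sweep: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        options = PipelineOptions(**raw.pop("options", {}))
        cfg = cbpm_mod.CbpmConfig(**raw.pop("cbpm", {}))
        if "cbpm_covariates" in raw:
            raw["cbpm_covariates"] = tuple(raw["cbpm_covariates"])
        return cls(options=options, cbpm=cfg, **raw)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_manifest(path) -> dict:
    """Load a manifest, resolve paths against its directory, and require
    every referenced file to exist before any compute happens."""
    path = Path(path)
    manifest = json.loads(path.read_text())
    base = path.parent
    resolved = dict(manifest)
    for key in ("atlas", "subjects"):
        resolved[key] = base / manifest[key]
    resolved["runs"] = {}
    for subject, runs in manifest["runs"].items():
        resolved["runs"][subject] = {}
        for run, entry in runs.items():
            entry = dict(entry)
            for file_key in ("timeseries", "confounds", "events"):
                if file_key in entry:
                    entry[file_key] = base / entry[file_key]
            resolved["runs"][subject][run] = entry
    missing = [
        str(p)
        for p in _manifest_paths(resolved)
        if not Path(p).exists()
    ]
    if missing:
        raise FileNotFoundError(f"manifest references missing files: {missing}")
    return resolved


def _manifest_paths(manifest: dict):
    yield manifest["atlas"]
    yield manifest["subjects"]
    for runs in manifest["runs"].values():
        for entry in runs.values():
            for key in ("timeseries", "confounds", "events"):
                if key in entry:
                    yield entry[key]


def _read_run(manifest: dict, subject: str, run: str) -> tuple:
    entry = manifest["runs"][subject][run]
    ts_frame = pd.read_csv(entry["timeseries"], sep="\t")
    conf_frame = pd.read_csv(entry["confounds"], sep="\t")
    ts = RoiTimeSeries(
        ts_frame.to_numpy(dtype=float),
        np.asarray(ts_frame.columns),
        manifest["sampling_interval"],
        entry.get("run_type", "rest"),
        subject,
    )
    events = None
    if "events" in entry:
        ev = pd.read_csv(entry["events"], sep="\t")
        events = TaskEvents(ev["onset"].to_numpy(dtype=float))
    return ts, ConfoundSet(conf_frame), events


def validate_inputs(manifest: dict, atlas: AtlasLabels | None = None) -> list:
    """Report-only consistency checks; returns a list of violations."""
    violations = []
    atlas = atlas or AtlasLabels.from_tsv(manifest["atlas"])
    subjects = pd.read_csv(manifest["subjects"], na_values=[NA])
    known = set(subjects["subject_id"])
    atlas_ids = list(map(str, atlas.roi_ids))
    for subject, runs in manifest["runs"].items():
        if subject not in known:
            violations.append(f"{subject}: missing from subjects table")
        for run, entry in runs.items():
            ts = pd.read_csv(entry["timeseries"], sep="\t", nrows=None)
            conf = pd.read_csv(entry["confounds"], sep="\t")
            if len(ts) != len(conf):
                violations.append(
                    f"{subject}/{run}: timeseries has {len(ts)} rows but "
                    f"confounds has {len(conf)}"
                )
            if list(map(str, ts.columns)) != atlas_ids:
                violations.append(
                    f"{subject}/{run}: ROI columns do not match the atlas"
                )
    return violations


def write_connectome(conn: Connectome, path, meta: dict | None = None) -> None:
    path = Path(path)
    frame = pd.DataFrame(conn.matrix, columns=conn.roi_ids)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT, na_rep=NA)
    sidecar = {"scale": conn.scale, "source": list(conn.source), **(meta or {})}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_connectome(path) -> Connectome:
    path = Path(path)
    frame = pd.read_csv(path, na_values=[NA])
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    matrix = frame.to_numpy(dtype=float)
    # symmetrize away text-roundtrip noise before the strict constructor
    matrix = (matrix + matrix.T) / 2.0
    if meta.get("scale", "pearson_r") == "pearson_r":
        np.fill_diagonal(matrix, 1.0)
    return Connectome(
        matrix,
        np.asarray(frame.columns),
        meta.get("scale", "pearson_r"),
        meta.get("source", []),
    )


def _derive_seed(seed: int, label: str) -> int:
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def build_generalized_connectomes(
    manifest: dict, config: PipelineConfig
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Per-run pipeline + QC + cross-run averaging for every subject.

    Returns (subject -> generalized Connectome, exclusion log, per-run FD
    table). Bad runs (mean FD above the run threshold) of retained subjects
    are dropped from the average when ``options.drop_bad_runs``.
    """
    options = config.options
    subjects = pd.read_csv(manifest["subjects"], na_values=[NA])
    age_col = (
        subjects["age"] if "age" in subjects else pd.Series(np.nan, index=subjects.index)
    )
    ages = dict(zip(subjects["subject_id"], age_col))

    run_conns: dict = {}
    run_fd_means: dict = {}
    fd_rows = []
    for subject, runs in manifest["runs"].items():
        run_conns[subject] = {}
        run_fd_means[subject] = {}
        for run in runs:
            ts, confounds, events = _read_run(manifest, subject, run)
            conn = run_connectome(ts, confounds, events, options)
            run_conns[subject][run] = conn
            fd_mean = float(confounds.fd.mean())
            run_fd_means[subject][run] = fd_mean
            fd_rows.append({"subject_id": subject, "run": run, "fd_mean": fd_mean})

    retained, exclusions = qc_filter(
        run_fd_means, ages, run_threshold=options.run_fd_threshold
    )
    generalized = {}
    bad = dict(zip(exclusions["subject_id"], exclusions["bad_runs"]))
    for subject in retained:
        drop = set(bad.get(subject, "").split(",")) if options.drop_bad_runs else set()
        keep = [c for run, c in run_conns[subject].items() if run not in drop]
        generalized[subject] = average_connectomes(keep, options.average)
    return generalized, exclusions, pd.DataFrame(fd_rows)


def run_pipeline(
    manifest_path,
    config: PipelineConfig | None = None,
    out_dir="pipeline_out",
    simulation: SimulationConfig | None = None,
) -> Path:
    """Execute every stage and write all artifacts plus a provenance record.

    With ``simulation`` given, a synthetic cohort is first materialized in
    ``out_dir/cohort`` and its manifest used in place of ``manifest_path``.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if simulation is not None:
        manifest_path = write_cohort(out / "cohort", simulation)
    manifest = load_manifest(manifest_path)
    atlas = AtlasLabels.from_tsv(manifest["atlas"])
    violations = validate_inputs(manifest, atlas)
    if violations:
        raise ValueError(f"invalid inputs: {violations}")

    stage = "connectome"
    try:
        generalized, exclusions, fd_table = build_generalized_connectomes(
            manifest, config
        )
        conn_dir = out / "connectomes"
        conn_dir.mkdir(exist_ok=True)
        for subject, conn in generalized.items():
            write_connectome(
                conn,
                conn_dir / f"{subject}_generalized.csv",
                {"config_hash": config.hash()},
            )
        exclusions.to_csv(out / "exclusions.csv", index=False, na_rep=NA)
        fd_table.to_csv(
            out / "run_fd.csv", index=False, na_rep=NA, float_format=FLOAT_FORMAT
        )

        stage = "summarize"
        summary_rows = []
        for subject, conn in generalized.items():
            summary = networks.summarize(
                conn,
                atlas,
                include_hipp_in_extra=config.include_hipp_in_extra,
                include_hipp_internal=config.include_hipp_internal,
            )
            summary_rows.append({"subject_id": subject, **summary.as_dict()})
        summaries = pd.DataFrame(summary_rows)
        summaries.to_csv(
            out / "summaries.csv", index=False, na_rep=NA, float_format=FLOAT_FORMAT
        )

        stage = "regress"
        subjects = pd.read_csv(manifest["subjects"], na_values=[NA])
        table = summaries.merge(subjects, on="subject_id", how="left")
        models = association.fit_model_table(table, y=config.behavior_column)
        models.to_csv(
            out / "models.csv", index=False, na_rep=NA, float_format=FLOAT_FORMAT
        )

        stage = "cbpm"
        order = list(generalized)
        x = np.stack([networks.vectorize(generalized[s]).values for s in order])
        table_indexed = table.set_index("subject_id").loc[order]
        y = table_indexed[config.behavior_column].to_numpy(dtype=float)
        cov = (
            table_indexed[list(config.cbpm_covariates)].to_numpy(dtype=float)
            if config.cbpm_covariates
            else None
        )
        cbpm_config = dataclasses.replace(
            config.cbpm, seed=_derive_seed(config.seed, "cbpm")
        )
        result = cbpm_mod.run_cbpm(x, y, cov, cbpm_config)
        _write_cbpm_outputs(result, atlas, order, out)

        if config.run_sweep:
            sweep = cbpm_mod.threshold_sweep(x, y, cov, cbpm_config)
            sweep.to_csv(
                out / "threshold_sweep.csv", index=False, na_rep=NA,
                float_format=FLOAT_FORMAT,
            )
        if config.run_lesion:
            stage = "lesion"
            lesion = cbpm_mod.lesion_analysis(x, y, cov, atlas, cbpm_config)
            lesion.to_csv(
                out / "lesion_table.csv", index=False, na_rep=NA,
                float_format=FLOAT_FORMAT,
            )
    except Exception as err:  # annotate failures with the stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    provenance = {
        "config_hash": config.hash(),
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "n_subjects_retained": len(generalized),
        "stages": ["connectome", "summarize", "regress", "cbpm"]
        + (["lesion"] if config.run_lesion else []),
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True, default=str)
    )
    return out


def _write_cbpm_outputs(result, atlas: AtlasLabels, order: list, out: Path) -> None:
    record = {
        "r_obs_pred": result.r_obs_pred,
        "p_perm": result.p_perm,
        "p_perm_add_one": result.p_perm_add_one,
        "status": result.status,
        "alpha": result.alpha,
        "n_fallback_folds": len(result.fallback_folds),
        "predicted": {s: float(v) for s, v in zip(order, result.predicted)},
        "observed": {s: float(v) for s, v in zip(order, result.observed)},
    }
    (out / "cbpm_result.json").write_text(json.dumps(record, indent=2, sort_keys=True))
    pd.DataFrame({"null_r": result.null_r}).to_csv(
        out / "null_distribution.csv", index=False, float_format=FLOAT_FORMAT
    )
    rows_idx, cols_idx = networks.edge_index_pairs(atlas.n_rois)
    freq = result.selection_frequency()
    any_selected = (freq["pos_frequency"] > 0) | (freq["neg_frequency"] > 0)
    consensus = pd.DataFrame(
        {
            "edge": np.flatnonzero(any_selected),
            "roi_i": atlas.roi_ids[rows_idx[any_selected]],
            "roi_j": atlas.roi_ids[cols_idx[any_selected]],
            "sign": np.where(
                freq.loc[any_selected, "pos_frequency"]
                >= freq.loc[any_selected, "neg_frequency"],
                "pos",
                "neg",
            ),
            "pos_frequency": freq.loc[any_selected, "pos_frequency"],
            "neg_frequency": freq.loc[any_selected, "neg_frequency"],
        }
    )
    consensus.to_csv(
        out / "consensus_edges.csv", index=False, float_format=FLOAT_FORMAT
    )
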