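"""Per-run denoising and connectome estimation.

One run of ROI time series is turned into an ROI-to-ROI Pearson correlation
matrix after nuisance regression (motion parameters and derivatives, aCompCor
components, framewise displacement, global signal, spike regressors, and —
for the sensorimotor task — an HRF-convolved stimulus regressor) followed by
zero-phase band-pass filtering. Per-run connectomes are then averaged on the
Fisher-z scale into a subject's "generalized" connectome, and subjects are
screened with motion- and age-based quality-control rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

log = logging.getLogger(__name__)

RUN_TYPES = ("rest", "movie", "sensorimotor")

__all__ = [
    "RoiTimeSeries",
    "ConfoundSet",
    "TaskEvents",
    "Connectome",
    "PipelineOptions",
    "build_spike_regressors",
    "build_task_regressor",
    "hrf_double_gamma",
    "regress_confounds",
    "bandpass",
    "correlation_connectome",
    "average_connectomes",
    "qc_filter",
    "run_connectome",
]


@dataclass
class RoiTimeSeries:
    """One run's T x R matrix of ROI signals."""

    values: np.ndarray
    roi_ids: np.ndarray
    sampling_interval: float  # seconds per sample (TR)
    run_type: str = "rest"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_ids = np.asarray(self.roi_ids)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x R) array")
        t, r = self.values.shape
        if t < 2 or r < 2:
            raise ValueError("need at least 2 timepoints and 2 ROIs")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite values")
        if len(self.roi_ids) != r:
            raise ValueError("roi_ids do not match the number of columns")
        if len(set(map(str, self.roi_ids))) != r:
            raise ValueError("roi_ids are not unique")
        if self.run_type not in RUN_TYPES:
            raise ValueError(f"run_type must be one of {RUN_TYPES}")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def replace_values(self, values: np.ndarray) -> "RoiTimeSeries":
        return RoiTimeSeries(
            values, self.roi_ids, self.sampling_interval, self.run_type, self.subject_id
        )


@dataclass
class ConfoundSet:
    """Nuisance time courses for one run, column-labelled.

    Columns follow the fMRIPrep-style vocabulary: six rigid-body motion
    parameters, their temporal derivatives and quadratics, up to six aCompCor
    components, framewise displacement (mm), standardized DVARS, and the
    global signal.
    """

    frame: pd.DataFrame

    MOTION = [f"motion_{i}" for i in range(6)]
    MOTION_DERIV = [f"motion_deriv_{i}" for i in range(6)]
    MOTION_QUAD = [f"motion_quad_{i}" for i in range(12)]
    COMPONENTS = [f"acompcor_{i}" for i in range(6)]

    def __post_init__(self) -> None:
        for col in ("fd", "dvars"):
            if col in self.frame:
                vals = self.frame[col].to_numpy(dtype=float)
                if (vals[np.isfinite(vals)] < 0).any():
                    raise ValueError(f"{col} must be non-negative")

    @property
    def n_timepoints(self) -> int:
        return len(self.frame)

    @property
    def fd(self) -> np.ndarray:
        return self.frame["fd"].to_numpy(dtype=float)

    @property
    def dvars(self) -> np.ndarray:
        return self.frame["dvars"].to_numpy(dtype=float)

    def nuisance_columns(
        self, include_global_signal: bool = True, max_components: int = 6
    ) -> tuple[np.ndarray, list]:
        """Assemble the regression design columns present in the table.

        Motion parameters + derivatives + quadratics, the first
        ``max_components`` aCompCor components, framewise displacement, and
        (optionally) the global signal; missing families are simply skipped.
        """
        names: list = []
        for family in (self.MOTION, self.MOTION_DERIV, self.MOTION_QUAD):
            names += [c for c in family if c in self.frame]
        comps = [c for c in self.COMPONENTS if c in self.frame]
        names += comps[:max_components]
        if "fd" in self.frame:
            names.append("fd")
        if include_global_signal and "global_signal" in self.frame:
            names.append("global_signal")
        if not names:
            return np.empty((len(self.frame), 0)), []
        return self.frame[names].to_numpy(dtype=float), names


@dataclass
class TaskEvents:
    """Stimulus onsets (seconds from run start) with optional labels."""

    onsets: np.ndarray
    conditions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if (self.onsets < 0).any():
            raise ValueError("onsets must be non-negative")
        if not np.all(np.diff(self.onsets) >= 0):
            raise ValueError("onsets must be sorted")


@dataclass
class Connectome:
    """Symmetric R x R connectivity matrix keyed to an atlas."""

    matrix: np.ndarray
    roi_ids: np.ndarray
    scale: str = "pearson_r"  # or "fisher_z"
    source: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.roi_ids = np.asarray(self.roi_ids)
        r = self.matrix.shape[0]
        if self.matrix.shape != (r, r):
            raise ValueError("connectome matrix must be square")
        if len(self.roi_ids) != r:
            raise ValueError("roi_ids do not match matrix size")
        if self.scale not in ("pearson_r", "fisher_z"):
            raise ValueError("scale must be 'pearson_r' or 'fisher_z'")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("connectome matrix is not symmetric within 1e-10")
        if self.scale == "pearson_r":
            off = self.matrix[~np.eye(r, dtype=bool)]
            if off.size and (np.abs(off) > 1 + 1e-12).any():
                raise ValueError("pearson_r entries must lie in [-1, 1]")
            if not np.allclose(np.diag(self.matrix), 1.0):
                raise ValueError("pearson_r diagonal must be exactly 1")

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PipelineOptions:
    """Per-run denoising options.

    Defaults reproduce the main pipeline: global signal regression on, spike
    flagging at FD > 0.6 mm or standardized DVARS > 2, band-pass
    0.008-0.1 Hz, at most six aCompCor components, Fisher-z cross-run
    averaging, and HRF task regression for sensorimotor runs only.
    """

    include_global_signal: bool = True
    fd_spike_threshold: float = 0.6
    dvars_spike_threshold: float = 2.0
    low_hz: float = 0.008
    high_hz: float = 0.1
    max_acompcor: int = 6
    average: str = "fisher_z"  # or "raw"
    drop_bad_runs: bool = True
    run_fd_threshold: float = 0.3


def build_spike_regressors(
    fd: np.ndarray,
    dvars: np.ndarray,
    fd_threshold: float = 0.6,
    dvars_threshold: float = 2.0,
) -> np.ndarray:
    """One-hot scrubbing regressors for motion-contaminated timepoints.

    A timepoint is flagged when FD strictly exceeds ``fd_threshold`` (mm)
    or standardized DVARS strictly exceeds ``dvars_threshold``; each flagged
    timepoint contributes one indicator column.
    """
    fd = np.asarray(fd, dtype=float)
    dvars = np.asarray(dvars, dtype=float)
    if fd.shape != dvars.shape:
        raise ValueError("fd and dvars must have the same length")
    if fd_threshold <= 0 or dvars_threshold <= 0:
        raise ValueError("spike thresholds must be positive")
    flagged = np.flatnonzero((fd > fd_threshold) | (dvars > dvars_threshold))
    spikes = np.zeros((fd.size, flagged.size))
    spikes[flagged, np.arange(flagged.size)] = 1.0
    return spikes


def hrf_double_gamma(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at times ``t``.

    Difference of two unit-scale gamma densities (shape ``peak_delay`` and
    ``undershoot_delay``, undershoot down-weighted by ``ratio``); the
    response peaks near 5 s with an undershoot near 15 s.
    """
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, peak_delay) - stats.gamma.pdf(t, undershoot_delay) / ratio
    h[t < 0] = 0.0
    return h


def build_task_regressor(
    events: TaskEvents, n_timepoints: int, sampling_interval: float
) -> np.ndarray:
    """Convolve stimulus-onset stick functions with the canonical HRF.

    Onsets are binned to the nearest acquisition sample; onsets beyond the
    run end are dropped with a warning. Returns a length-T vector.
    """
    sticks = np.zeros(n_timepoints)
    duration = n_timepoints * sampling_interval
    for onset in events.onsets:
        if onset >= duration:
            log.warning("dropping onset at %.2f s beyond run end (%.2f s)", onset, duration)
            continue
        sticks[int(round(onset / sampling_interval))] += 1.0
    if not sticks.any():
        return sticks
    t = np.arange(n_timepoints) * sampling_interval
    return np.convolve(sticks, hrf_double_gamma(t))[:n_timepoints]


def _prune_design(design: np.ndarray, names: list) -> tuple[np.ndarray, list]:
    """Drop constant columns and exact duplicates, warning about each."""
    keep, seen = [], []
    for k in range(design.shape[1]):
        col = design[:, k]
        if np.ptp(col) == 0:
            log.warning("dropping constant confound column %r", names[k])
            continue
        if any(np.array_equal(col, design[:, j]) for j in seen):
            log.warning("dropping duplicate confound column %r", names[k])
            continue
        seen.append(k)
        keep.append(k)
    return design[:, keep], [names[k] for k in keep]


def regress_confounds(
    ts: RoiTimeSeries,
    confounds: np.ndarray,
    confound_names: list | None = None,
) -> RoiTimeSeries:
    """OLS-residualize every ROI column against [intercept | confounds]."""
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    if confounds.shape[0] != ts.n_timepoints:
        raise ValueError("confound rows do not match the run length")
    names = confound_names or [f"c{k}" for k in range(confounds.shape[1])]
    confounds, names = _prune_design(confounds, list(names))
    design = np.column_stack([np.ones(ts.n_timepoints), confounds])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"confound design is rank deficient (rank {rank} < {design.shape[1]}); "
            f"columns: {names}"
        )
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    return ts.replace_values(ts.values - design @ beta)


def bandpass(
    ts: RoiTimeSeries, low_hz: float = 0.008, high_hz: float = 0.1
) -> RoiTimeSeries:
    """Zero-phase band-pass (order-2 Butterworth, forward-backward)."""
    nyquist = 0.5 / ts.sampling_interval
    if not 0 < low_hz < high_hz < nyquist:
        raise ValueError(
            f"need 0 < low ({low_hz}) < high ({high_hz}) < Nyquist ({nyquist:.4g}) Hz"
        )
    sos = sps.butter(2, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.sampling_interval, output="sos")
    filtered = sps.sosfiltfilt(sos, ts.values, axis=0)
    return ts.replace_values(filtered - filtered.mean(axis=0))


def correlation_connectome(ts: RoiTimeSeries) -> Connectome:
    """Pearson ROI-to-ROI correlation matrix for one denoised run."""
    sd = ts.values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance ROI columns: {list(np.asarray(ts.roi_ids)[dead])}"
        )
    m = np.corrcoef(ts.values, rowvar=False)
    m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return Connectome(m, ts.roi_ids, "pearson_r", source=[f"{ts.subject_id}:{ts.run_type}"])


def average_connectomes(runs: list, method: str = "fisher_z") -> Connectome:
    """Average per-run connectomes into a generalized connectome.

    Default combines edges on the Fisher-z scale (atanh, mean, tanh), which
    is the addition-friendly scale for correlations; ``method="raw"``
    averages Pearson r directly for sensitivity checks.
    """
    if not runs:
        raise ValueError("need at least one run to average")
    ref = runs[0]
    for run in runs[1:]:
        if run.matrix.shape != ref.matrix.shape or not np.array_equal(
            run.roi_ids, ref.roi_ids
        ):
            raise ValueError("runs have mismatched ROI sets or ordering")
    # sort per-edge values before reducing so the mean is exactly invariant
    # to run order (floating-point summation is otherwise order sensitive)
    stack = np.sort(np.stack([r.matrix for r in runs]), axis=0)
    if method == "fisher_z":
        # clip so |r|=1 (diagonal) stays finite through atanh
        z = np.arctanh(np.clip(stack, -1 + 1e-15, 1 - 1e-15))
        mean = np.tanh(z.mean(axis=0))
    elif method == "raw":
        mean = stack.mean(axis=0)
    else:
        raise ValueError("method must be 'fisher_z' or 'raw'")
    np.fill_diagonal(mean, 1.0)
    sources = [s for r in runs for s in r.source]
    return Connectome(mean, ref.roi_ids, "pearson_r", source=sources)


def qc_filter(
    run_fd_means: dict,
    ages: dict,
    run_threshold: float = 0.3,
    max_bad_runs: int = 1,
    age_range: tuple = (18.0, 50.0),
) -> tuple[list, pd.DataFrame]:
    """Motion/age subject screening with listwise deletion of missing data.

    A run is "bad" when its mean framewise displacement strictly exceeds
    ``run_threshold`` mm. A subject is excluded when more than
    ``max_bad_runs`` runs are bad, when age falls outside ``age_range``
    (strict comparisons: boundary ages pass), or when age is missing.
    Returns the retained subject ids plus a per-subject exclusion log with a
    ``bad_runs`` column naming the runs a retained subject should drop from
    averaging.
    """
    records = []
    retained = []
    for subject, fd_by_run in run_fd_means.items():
        if not fd_by_run:
            raise ValueError(f"subject {subject!r} has no run records")
        bad = [run for run, fd in fd_by_run.items() if fd > run_threshold]
        age = ages.get(subject)
        if age is None or (isinstance(age, float) and np.isnan(age)):
            reason = "missing_data"
        elif len(bad) > max_bad_runs:
            reason = "motion"
        elif age < age_range[0] or age > age_range[1]:
            reason = "age"
        else:
            reason = ""
            retained.append(subject)
        records.append(
            {
                "subject_id": subject,
                "retained": reason == "",
                "reason": reason,
                "n_bad_runs": len(bad),
                "bad_runs": ",".join(map(str, sorted(bad))),
            }
        )
    return retained, pd.DataFrame.from_records(records)


def run_connectome(
    ts: RoiTimeSeries,
    confounds: ConfoundSet,
    events: TaskEvents | None = None,
    options: PipelineOptions | None = None,
) -> Connectome:
    """Full per-run pipeline: confound + spike (+ task) regression, then
    band-pass, then Pearson correlation.

    The regression design concatenates nuisance columns, spike indicator
    columns, and — for sensorimotor runs only — the HRF-convolved stimulus
    regressor, all removed in a single OLS pass before filtering.
    """
    options = options or PipelineOptions()
    if confounds.n_timepoints != ts.n_timepoints:
        raise ValueError("confound table length does not match the run")
    design, names = confounds.nuisance_columns(
        include_global_signal=options.include_global_signal,
        max_components=options.max_acompcor,
    )
    spikes = build_spike_regressors(
        confounds.fd,
        confounds.dvars,
        options.fd_spike_threshold,
        options.dvars_spike_threshold,
    )
    columns = [design, spikes]
    names = names + [f"spike_{k}" for k in range(spikes.shape[1])]
    if ts.run_type == "sensorimotor" and events is not None:
        task = build_task_regressor(events, ts.n_timepoints, ts.sampling_interval)
        columns.append(task[:, None])
        names.append("task_hrf")
    full = np.column_stack(columns) if columns else np.empty((ts.n_timepoints, 0))
    log.info(
        "denoising %s:%s — %d confound columns, %d spikes, gsr=%s; order: "
        "regression -> band-pass -> correlation",
        ts.subject_id,
        ts.run_type,
        full.shape[1],
        spikes.shape[1],
        options.include_global_signal,
    )
    residual = regress_confounds(ts, full, names)
    filtered = bandpass(residual, options.low_hz, options.high_hz)
    return correlation_connectome(filtered)
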