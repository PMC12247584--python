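"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the data model of an individual-differences
connectomics study: a cortical atlas of 17 networks (400 parcels) plus six
hippocampal ROIs; per-subject connectomes built on the Fisher-z scale as a
group-mean block matrix plus planted edge-behavior effects, covariate
loadings, and subject noise; a behavior/covariate table (narrative-recall-
like score, age, sex, mean framewise displacement, fluid intelligence,
cognitive screen) whose covariates load on both behavior and edges; and,
when needed, multivariate-normal ROI time series whose population
correlation matches a target connectome, with additive motion-like confound
time courses.

Signal is planted on the Fisher-z scale and back-transformed with tanh, so
correlations stay inside (-1, 1) and the planted effect lives on the same
scale downstream averaging uses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import ConfoundSet, Connectome, RoiTimeSeries
from .networks import DEFAULT_ROLE_MAP, AtlasLabels, edge_index_pairs

log = logging.getLogger(__name__)

__all__ = [
    "CovariateSpec",
    "SimulationConfig",
    "default_confound_spec",
    "make_atlas",
    "default_atlas",
    "simulate_cohort",
    "nearest_psd",
    "simulate_timeseries",
    "write_cohort",
]

#: 17-network labels of the cortical parcellation, in table order.
NETWORK_LABELS_17 = (
    "VisCent", "VisPeri", "SomMotA", "SomMotB", "DorsAttnA", "DorsAttnB",
    "SalVentAttnA", "SalVentAttnB", "LimbicB", "LimbicA", "ContA", "ContB",
    "ContC", "DefaultA", "DefaultB", "DefaultC", "TempPar",
)


@dataclass
class CovariateSpec:
    """How one covariate is drawn and how it loads on behavior and edges.

    ``behavior_loading`` is the target Pearson correlation between the
    covariate and the latent behavior; ``edge_loading`` is the Fisher-z shift
    applied to every edge per SD of the covariate. ``kind`` selects the
    marginal: 'normal' (mean/sd), 'uniform' (low/high, Gaussian-copula
    coupled to behavior), or 'bernoulli' (p = mean, median-split coupling).
    """

    mean: float = 0.0
    sd: float = 1.0
    behavior_loading: float = 0.0
    edge_loading: float = 0.0
    kind: str = "normal"
    low: float = 0.0
    high: float = 1.0


def default_confound_spec() -> dict:
    """Default covariates with plausible cohort magnitudes.

    Means/SDs and behavior correlations echo the descriptive statistics of a
    young-adult cohort (ages 18-50, mean FD ~0.14 mm, fluid-intelligence and
    cognitive-screen totals on their native scales); edge loadings give
    motion and age a mild global effect on connectivity.
    """
    return {
        "age": CovariateSpec(kind="uniform", low=18.0, high=50.0,
                             behavior_loading=-0.13, edge_loading=-0.04),
        "sex": CovariateSpec(kind="bernoulli", mean=0.5,
                             behavior_loading=0.14, edge_loading=0.005),
        "fd": CovariateSpec(mean=0.14, sd=0.04,
                            behavior_loading=-0.10, edge_loading=-0.045),
        "cattell": CovariateSpec(mean=36.35, sd=4.23,
                                 behavior_loading=0.35, edge_loading=0.01),
        "acer": CovariateSpec(mean=96.54, sd=3.63,
                              behavior_loading=0.40, edge_loading=0.0),
    }


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator; identical config + seed reproduces
    byte-identical outputs."""

    n_subjects: int = 243
    network_sizes: dict | None = None  # network label -> parcel count
    hippocampus_size: int = 6
    n_runs: int = 3
    run_length: int = 200
    sampling_interval: float = 1.97
    signal_edges: list = field(default_factory=list)  # (roi_i, roi_j, beta_z)
    behavior_noise_sd: float = 0.0
    confound_spec: dict = field(default_factory=default_confound_spec)
    subject_noise_sd: float = 0.2
    within_network_z: float = 0.35
    between_network_z: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("n_subjects", self.n_subjects),
            ("hippocampus_size", self.hippocampus_size + 1),
            ("n_runs", self.n_runs),
            ("run_length", self.run_length),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.subject_noise_sd < 0 or self.behavior_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def atlas(self) -> AtlasLabels:
        if self.network_sizes is None:
            return default_atlas(self.hippocampus_size)
        return make_atlas(self.network_sizes, self.hippocampus_size)

    def validate_edges(self, n_rois: int) -> None:
        for i, j, _ in self.signal_edges:
            if i == j:
                raise ValueError("signal edges must reference distinct ROIs")
            if not (0 <= i < n_rois and 0 <= j < n_rois):
                raise ValueError(f"signal edge ({i},{j}) out of range for {n_rois} ROIs")


def make_atlas(network_sizes: dict | list, hippocampus_size: int = 6) -> AtlasLabels:
    """Build a label table from per-network parcel counts plus hippocampal
    ROIs (head/body/tail per hemisphere when the count allows).

    Cortical parcels alternate hemispheres within a network (extra parcel to
    the right, matching a 7-left/6-right style split for odd counts).
    """
    if isinstance(network_sizes, (list, tuple)):
        network_sizes = {f"Net{k + 1}": n for k, n in enumerate(network_sizes)}
    if len(network_sizes) < 2:
        raise ValueError("need at least two cortical networks")
    rows = []
    for network, size in network_sizes.items():
        if size <= 0:
            raise ValueError(f"network {network!r} has non-positive size {size}")
        n_left = size // 2 + (size % 2 if network == "DefaultC" else 0)
        for k in range(size):
            hemi = "L" if k < n_left else "R"
            rows.append(
                {
                    "roi_id": f"{network}_{k + 1}",
                    "roi_name": f"{hemi}H_{network}_{k + 1}",
                    "hemisphere": hemi,
                    "network": network,
                }
            )
    if hippocampus_size < 0:
        raise ValueError("hippocampus_size must be non-negative")
    parts = ("head", "body", "tail")
    for k in range(hippocampus_size):
        hemi = "LR"[k % 2]
        part = parts[(k // 2) % 3]
        rows.append(
            {
                "roi_id": f"Hipp_{k + 1}",
                "roi_name": f"{hemi}H_Hipp_{part}",
                "hemisphere": hemi,
                "network": "Hipp",
            }
        )
    return AtlasLabels(pd.DataFrame(rows), dict(DEFAULT_ROLE_MAP))


def default_atlas(hippocampus_size: int = 6) -> AtlasLabels:
    """The default 406-ROI preset: 400 cortical parcels in 17 networks
    (DMN-C 13, DMN-A 34, the remaining 353 spread over 15 networks) plus six
    hippocampal ROIs (head/body/tail, both hemispheres)."""
    sizes = {}
    other = [n for n in NETWORK_LABELS_17 if n not in ("DefaultA", "DefaultC")]
    base, extra = divmod(400 - 13 - 34, len(other))
    for k, network in enumerate(other):
        sizes[network] = base + (1 if k < extra else 0)
    sizes["DefaultA"] = 34
    sizes["DefaultC"] = 13
    sizes = {n: sizes[n] for n in NETWORK_LABELS_17}
    return make_atlas(sizes, hippocampus_size)


def _group_mean_z(atlas: AtlasLabels, within_z: float, between_z: float) -> np.ndarray:
    networks = atlas.networks
    same = networks[:, None] == networks[None, :]
    mean = np.where(same, within_z, between_z)
    np.fill_diagonal(mean, 0.0)
    return mean


def _draw_covariates(
    spec: dict, b_latent: np.ndarray, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw covariates coupled to behavior; returns (values, standardized).

    Each covariate is built from a Gaussian with the requested correlation to
    the latent behavior, then pushed through its marginal (identity, uniform
    quantile, or median split). The standardized frame carries the z-scored
    values used for edge loadings.
    """
    n = b_latent.size
    values, standardized = {}, {}
    for name, cov in spec.items():
        rho = float(np.clip(cov.behavior_loading, -0.999, 0.999))
        u = rho * b_latent + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        if cov.kind == "normal":
            x = cov.mean + cov.sd * u
        elif cov.kind == "uniform":
            x = cov.low + (cov.high - cov.low) * stats.norm.cdf(u)
        elif cov.kind == "bernoulli":
            x = (u > stats.norm.ppf(1.0 - cov.mean)).astype(float)
        else:
            raise ValueError(f"unknown covariate kind {cov.kind!r}")
        values[name] = x
        sd = x.std(ddof=1)
        standardized[name] = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
    return pd.DataFrame(values), pd.DataFrame(standardized)


def simulate_cohort(config: SimulationConfig) -> tuple[list, pd.DataFrame]:
    """Generate per-subject generalized connectomes and a subject table.

    Subject s's connectome on the Fisher-z scale is

        Z_s = M + sum_e beta_e * b_s * 1_e + (sum_j lambda_j * c_js) * 1 + eps_s

    with M the group-mean block matrix, b_s the standardized latent
    behavior, 1_e the planted-edge indicator, lambda_j the covariates' edge
    loadings on their standardized values c_js, and eps_s i.i.d.
    N(0, subject_noise_sd) edge noise. Entries are back-transformed with
    tanh, symmetrized, diagonal set to 1. The stored behavior score is
    b_s plus optional N(0, behavior_noise_sd) measurement noise.
    """
    atlas = config.atlas
    r = atlas.n_rois
    config.validate_edges(r)
    rng = np.random.default_rng(config.seed)

    b_latent = rng.standard_normal(config.n_subjects)
    cov_values, cov_std = _draw_covariates(config.confound_spec, b_latent, rng)
    behavior = b_latent + config.behavior_noise_sd * rng.standard_normal(config.n_subjects)

    mean_z = _group_mean_z(atlas, config.within_network_z, config.between_network_z)
    edge_loads = np.array(
        [config.confound_spec[c].edge_loading for c in cov_values.columns]
    )
    cov_std_mat = (
        cov_std.to_numpy(dtype=float)
        if len(cov_values.columns)
        else np.zeros((config.n_subjects, 0))
    )
    rows, cols = edge_index_pairs(r)

    connectomes = []
    n_extreme = 0
    for s in range(config.n_subjects):
        z = mean_z.copy()
        shift = float(cov_std_mat[s] @ edge_loads)
        noise = rng.normal(0.0, config.subject_noise_sd, size=rows.size)
        z[rows, cols] += shift + noise
        for i, j, beta in config.signal_edges:
            lo, hi = (j, i) if i > j else (i, j)
            z[hi, lo] += beta * b_latent[s]
        z[cols, rows] = z[rows, cols]
        m = np.tanh(z)
        if not np.isfinite(m).all():
            raise FloatingPointError("non-finite connectome entries generated")
        n_extreme += int((np.abs(m[rows, cols]) > 0.999).sum())
        np.fill_diagonal(m, 1.0)
        connectomes.append(
            Connectome(m, atlas.roi_ids, "pearson_r", source=[f"sim{s:04d}"])
        )
    frac = n_extreme / (config.n_subjects * rows.size)
    if frac > 0.01:
        log.warning(
            "%.1f%% of simulated edges are near saturation (|r| > 0.999); "
            "check effect sizes", 100 * frac
        )

    subjects = pd.DataFrame({"subject_id": [f"sub-{s + 1:04d}" for s in range(config.n_subjects)]})
    subjects["behavior"] = behavior
    for col in cov_values.columns:
        subjects[col] = cov_values[col]
    return connectomes, subjects


def nearest_psd(matrix: np.ndarray, floor: float = 1e-8) -> tuple[np.ndarray, float]:
    """Nearest-PSD repair by eigenvalue clipping at a small positive floor.

    Returns the repaired correlation matrix (rescaled to unit diagonal) and
    the Frobenius norm of the adjustment.
    """
    m = np.asarray(matrix, dtype=float)
    m = (m + m.T) / 2.0
    vals, vecs = np.linalg.eigh(m)
    if vals.min() >= floor:
        return m, 0.0
    repaired = (vecs * np.clip(vals, floor, None)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired, float(np.linalg.norm(repaired - m))


@dataclass
class ConfoundSignals:
    """Loadings of the additive confound time courses on the ROI signals."""

    motion_loading: float = 0.0
    global_loading: float = 0.0
    component_loading: float = 0.0


def _smooth_noise(rng: np.random.Generator, t: int, n: int, window: int = 10) -> np.ndarray:
    raw = rng.standard_normal((t + window, n))
    kernel = np.ones(window) / window
    out = np.empty((t, n))
    for k in range(n):
        out[:, k] = np.convolve(raw[:, k], kernel, mode="valid")[:t]
    return out


def simulate_timeseries(
    connectome: Connectome,
    run_length: int,
    sampling_interval: float,
    confound_signals: ConfoundSignals | None = None,
    seed: int = 0,
    run_type: str = "rest",
    subject_id: str = "",
) -> tuple[RoiTimeSeries, ConfoundSet]:
    """Multivariate-normal ROI time series with the target correlation.

    The target matrix is repaired to the nearest PSD correlation matrix
    first (eigenvalue clipping; the Frobenius adjustment is logged), then
    T draws are taken via its Cholesky factor. Confound time courses —
    smoothed random-walk motion traces, their derivatives/quadratics, six
    slow noise components, FD and DVARS derived from the motion traces, and
    the global signal — are returned in a matched table; nonzero loadings
    additively mix the motion/global/component traces into the ROI signals.
    """
    r = connectome.n_rois
    if run_length < r + 2:
        raise ValueError(
            f"run_length {run_length} too short for {r} ROIs (need >= {r + 2})"
        )
    confound_signals = confound_signals or ConfoundSignals()
    rng = np.random.default_rng(seed)

    target, frob = nearest_psd(connectome.matrix)
    if frob > 0:
        log.info("nearest-PSD repair applied; Frobenius adjustment %.3e", frob)
    chol = np.linalg.cholesky(target + 1e-10 * np.eye(r))
    signal = rng.standard_normal((run_length, r)) @ chol.T

    # step SD chosen so mean FD sits near 0.1 mm, typical of a calm scanner run
    motion = np.cumsum(rng.normal(0.0, 0.02, size=(run_length, 6)), axis=0)
    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    quad = np.column_stack([motion**2, deriv**2])
    components = _smooth_noise(rng, run_length, 6)
    fd = np.abs(deriv).sum(axis=1)
    global_noise = rng.standard_normal(run_length)

    mixed = signal.copy()
    if confound_signals.motion_loading:
        w = rng.standard_normal((6, r))
        mixed += confound_signals.motion_loading * (motion @ w)
    if confound_signals.component_loading:
        w = rng.standard_normal((6, r))
        mixed += confound_signals.component_loading * (components @ w)
    if confound_signals.global_loading:
        mixed += confound_signals.global_loading * global_noise[:, None]

    global_signal = mixed.mean(axis=1)
    diff = np.vstack([np.zeros((1, r)), np.diff(mixed, axis=0)])
    # standardized DVARS hovers near 1 in clean data; spikes exceed 2
    dvars_raw = np.sqrt((diff**2).mean(axis=1))
    scale = dvars_raw.mean()
    dvars = dvars_raw / scale if scale > 0 else dvars_raw

    frame = pd.DataFrame(
        {
            **{f"motion_{k}": motion[:, k] for k in range(6)},
            **{f"motion_deriv_{k}": deriv[:, k] for k in range(6)},
            **{f"motion_quad_{k}": quad[:, k] for k in range(12)},
            **{f"acompcor_{k}": components[:, k] for k in range(6)},
            "fd": fd,
            "dvars": dvars,
            "global_signal": global_signal,
        }
    )
    ts = RoiTimeSeries(mixed, connectome.roi_ids, sampling_interval, run_type, subject_id)
    return ts, ConfoundSet(frame)


def write_cohort(
    out_dir,
    config: SimulationConfig,
    confound_signals: ConfoundSignals | None = None,
) -> Path:
    """Materialize a cohort on disk in the package's delimited-text dialect.

    Writes one time-series and one confounds file per subject-run, the
    ``subjects.csv`` behavior/covariate table, the ``atlas.tsv`` label table,
    and a ``manifest.json`` index mapping subjects to runs and file paths.
    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = config.atlas
    connectomes, subjects = simulate_cohort(config)
    atlas.to_tsv(out / "atlas.tsv")
    subjects.to_csv(out / "subjects.csv", index=False, na_rep="NA",
                    float_format="%.10g")

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_subjects * config.n_runs)
    run_types = [RUN_ORDER[k % len(RUN_ORDER)] for k in range(config.n_runs)]
    manifest: dict = {
        "atlas": "atlas.tsv",
        "subjects": "subjects.csv",
        "sampling_interval": config.sampling_interval,
        "seed": config.seed,
        "runs": {},
    }
    for s, (conn, subject_id) in enumerate(zip(connectomes, subjects["subject_id"])):
        manifest["runs"][subject_id] = {}
        for k in range(config.n_runs):
            seed = int(seeds[s * config.n_runs + k].generate_state(1)[0] % (2**31))
            ts, conf = simulate_timeseries(
                conn,
                config.run_length,
                config.sampling_interval,
                confound_signals,
                seed=seed,
                run_type=run_types[k],
                subject_id=subject_id,
            )
            ts_path = f"{subject_id}_run-{k + 1}_timeseries.tsv"
            conf_path = f"{subject_id}_run-{k + 1}_confounds.tsv"
            pd.DataFrame(ts.values, columns=ts.roi_ids).to_csv(
                out / ts_path, sep="\t", index=False, float_format="%.10g"
            )
            conf.frame.to_csv(out / conf_path, sep="\t", index=False,
                              float_format="%.10g")
            entry = {"timeseries": ts_path, "confounds": conf_path,
                     "run_type": run_types[k]}
            if run_types[k] == "sensorimotor":
                onsets = np.arange(8.0, config.run_length * config.sampling_interval - 16.0, 16.0)
                events_path = f"{subject_id}_run-{k + 1}_events.tsv"
                pd.DataFrame({"onset": onsets}).to_csv(
                    out / events_path, sep="\t", index=False, float_format="%.10g"
                )
                entry["events"] = events_path
            manifest["runs"][subject_id][f"run-{k + 1}"] = entry
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


RUN_ORDER = ("movie", "rest", "sensorimotor")
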