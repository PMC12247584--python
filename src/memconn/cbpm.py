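"""Connectome-based predictive modeling (CBPM).

The procedure: for each left-out subject, correlate every edge of the
training subjects' connectomes with behavior (partial correlation given
nuisance covariates), keep edges with two-sided p below the selection
threshold split by correlation sign, sum each subject's selected edges into
positive and negative strength terms, fit an OLS of behavior on the two
terms in the training sample, and predict the held-out subject. Performance
is the Pearson correlation between observed and predicted scores across all
leave-one-out folds; significance comes from a permutation null that
re-pairs behavior with connectomes and reruns the entire procedure
(selection included). A computational lesion analysis repeats the whole
pipeline after removing every edge incident to one network at a time.

Implementation note: selection inside LOOCV is vectorized across folds.
For fold f the training-sample partial correlation numerator is
``X.T @ yres_f`` with ``yres_f`` the covariate-residualized behavior vector
padded with a zero at the held-out row, so all folds reduce to one matrix
product; per-fold residual norms of the edge matrix are precomputed from
per-fold QR factors of the covariate design and reused across permutations
(behavior is permuted, covariates stay attached to the connectome side).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .networks import AtlasLabels, edge_index_pairs

log = logging.getLogger(__name__)

__all__ = [
    "CbpmConfig",
    "CbpmResult",
    "select_edges",
    "summed_strengths",
    "loocv",
    "permutation_test",
    "run_cbpm",
    "threshold_sweep",
    "lesion_analysis",
]


@dataclass
class CbpmConfig:
    """Tunable parameters of the CBPM procedure."""

    selection_alpha: float = 0.01
    n_permutations: int = 100
    seed: int = 0
    threshold_sweep: tuple = (0.001, 0.005, 0.01, 0.05, 0.1)
    model_form: str = "combined_pos_neg"  # or "pos_only" / "neg_only"
    permute_covariates_with_y: bool = False
    normalize_strengths: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.selection_alpha <= 1:
            raise ValueError("selection_alpha must lie in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.model_form not in ("combined_pos_neg", "pos_only", "neg_only"):
            raise ValueError(f"unknown model_form {self.model_form!r}")


@dataclass
class CbpmResult:
    """Leave-one-out CBPM outcome for one dataset and configuration."""

    observed: np.ndarray
    predicted: np.ndarray
    r_obs_pred: float
    status: str                      # "ok" or "degenerate"
    alpha: float
    fold_pos_masks: np.ndarray       # (n_folds, E) bool
    fold_neg_masks: np.ndarray
    fold_coefs: list                 # per fold dict of fitted coefficients
    fallback_folds: list             # folds that predicted the training mean
    p_perm: float | None = None
    p_perm_add_one: float | None = None
    null_r: np.ndarray | None = None

    @property
    def consensus_pos(self) -> np.ndarray:
        """Edges selected with positive sign in every fold."""
        return self.fold_pos_masks.all(axis=0)

    @property
    def consensus_neg(self) -> np.ndarray:
        return self.fold_neg_masks.all(axis=0)

    def selection_frequency(self) -> pd.DataFrame:
        """Per-edge fold-selection frequency by sign."""
        n = self.fold_pos_masks.shape[0]
        return pd.DataFrame(
            {
                "pos_frequency": self.fold_pos_masks.sum(axis=0) / n,
                "neg_frequency": self.fold_neg_masks.sum(axis=0) / n,
            }
        )


def _partial_corr_stats(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, int]:
    """Columnwise (partial) correlation of edges with behavior.

    Residualizes both sides against [intercept | covariates] via a QR
    projection and correlates the residuals; p-values use the exact t
    transform with df = n - 2 - c. Zero-variance edge columns get r = 0,
    p = 1 (unselectable) with a logged count.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    c = 0 if covariates is None else np.atleast_2d(covariates).shape[1]
    design = np.ones((n, 1))
    if c:
        design = np.column_stack([design, covariates])
    q, _ = np.linalg.qr(design)
    xres = x - q @ (q.T @ x)
    yres = y - q @ (q.T @ y)
    df = n - 2 - c
    if df < 1:
        raise ValueError(f"not enough subjects (n={n}) for {c} covariates")
    xnorm = np.einsum("ij,ij->j", xres, xres)
    ynorm = float(yres @ yres)
    dead = xnorm <= 1e-12 * max(1.0, np.abs(x).max()) ** 2
    if dead.any():
        log.warning("%d constant edge columns are unselectable", int(dead.sum()))
    denom = np.sqrt(np.where(dead, 1.0, xnorm) * max(ynorm, 1e-300))
    r = np.clip((xres.T @ yres) / denom, -1.0, 1.0)
    r[dead] = 0.0
    p = _r_to_p(r, df)
    p[dead] = 1.0
    return r, p, df


def _r_to_p(r: np.ndarray, df: int) -> np.ndarray:
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df)


def select_edges(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    alpha: float = 0.01,
    return_stats: bool = False,
):
    """Threshold edge selection by (partial) correlation with behavior.

    Returns disjoint boolean masks (pos, neg): edges whose two-sided p is
    strictly below ``alpha``, split by correlation sign. With no covariates
    this is plain Pearson selection.
    """
    r, p, _ = _partial_corr_stats(x, y, covariates)
    pos = (p < alpha) & (r > 0)
    neg = (p < alpha) & (r < 0)
    if return_stats:
        return pos, neg, r, p
    return pos, neg


def summed_strengths(
    x_row: np.ndarray, pos_mask: np.ndarray, neg_mask: np.ndarray
) -> tuple[float, float]:
    """One subject's summed selected-edge strengths (empty mask -> 0)."""
    x_row = np.asarray(x_row, dtype=float)
    return float(x_row[pos_mask].sum()), float(x_row[neg_mask].sum())


class _LoocvEngine:
    """Precomputed per-fold projections for fast repeated LOOCV runs.

    Built once per (X, covariates) pair; :meth:`run` then evaluates a full
    leave-one-out CBPM for any behavior vector, which is what makes the
    permutation null (same connectomes, permuted behavior) cheap.
    """

    def __init__(self, x: np.ndarray, covariates: np.ndarray | None):
        x = np.asarray(x, dtype=float)
        self.x = x
        self.n, self.e = x.shape
        if self.n < 10:
            raise ValueError(f"need at least 10 subjects for LOOCV (got {self.n})")
        cov = None if covariates is None else np.atleast_2d(np.asarray(covariates, float))
        if cov is not None and cov.shape[0] != self.n:
            raise ValueError("covariate rows do not match the number of subjects")
        self.c = 0 if cov is None else cov.shape[1]
        design = np.ones((self.n, 1))
        if cov is not None:
            design = np.column_stack([design, cov])
        k = design.shape[1]
        self.df = (self.n - 1) - 2 - self.c
        if self.df < 1:
            raise ValueError("too few subjects for the covariate count")

        # Per-fold QR of the training covariate design, embedded at full
        # length with a zero row at the held-out index. All per-fold
        # quantities are computed strictly from training rows so a fold's
        # selection is bitwise independent of its held-out subject.
        self.q = np.zeros((self.n, self.n, k))
        self.xnorm2 = np.empty((self.n, self.e))
        self.dead = np.empty((self.n, self.e), dtype=bool)
        train_idx = np.arange(self.n)
        for f in range(self.n):
            rows = train_idx != f
            qf, _ = np.linalg.qr(design[rows])
            self.q[f, rows, :] = qf
            xt = x[rows]
            proj = qf.T @ xt
            norm2 = np.einsum("ij,ij->j", xt, xt) - np.einsum("ij,ij->j", proj, proj)
            self.xnorm2[f] = np.maximum(norm2, 0.0)
            scale = max(1.0, float(np.abs(xt).max()))
            self.dead[f] = self.xnorm2[f] <= 1e-12 * scale**2

    def _residualize_y(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-fold covariate-residualized behavior, zero-padded at the
        held-out row; returns (Yres (n, n_folds), ynorm2 (n_folds,))."""
        yres = np.repeat(y[:, None], self.n, axis=1)
        yres[np.diag_indices(self.n)] = 0.0
        for f in range(self.n):
            qf = self.q[f]
            yres[:, f] -= qf @ (qf.T @ yres[:, f])
            yres[f, f] = 0.0
        ynorm2 = np.einsum("ij,ij->j", yres, yres)
        return yres, ynorm2

    def run(self, y: np.ndarray, alpha: float, model_form: str,
            normalize: bool = False, keep_masks: bool = True) -> dict:
        y = np.asarray(y, dtype=float)
        yres, ynorm2 = self._residualize_y(y)
        numer = self.x.T @ yres                                   # (E, n_folds)
        denom = np.sqrt(
            np.where(self.dead.T, 1.0, self.xnorm2.T) * np.maximum(ynorm2, 1e-300)
        )
        r = np.clip(numer / denom, -1.0, 1.0)
        r[self.dead.T] = 0.0
        p = _r_to_p(r, self.df)
        p[self.dead.T] = 1.0
        pos = (p < alpha) & (r > 0)
        neg = (p < alpha) & (r < 0)
        # Strength sums for every subject under every fold's masks.
        s_pos = self.x @ pos.astype(float)
        s_neg = self.x @ neg.astype(float)
        if normalize:
            s_pos = s_pos / np.maximum(pos.sum(axis=0), 1)
            s_neg = s_neg / np.maximum(neg.sum(axis=0), 1)

        use_pos = model_form in ("combined_pos_neg", "pos_only")
        use_neg = model_form in ("combined_pos_neg", "neg_only")
        predicted = np.empty(self.n)
        coefs, fallback = [], []
        train_idx = np.arange(self.n)
        for f in range(self.n):
            rows = train_idx != f
            terms, names = [], []
            if use_pos and pos[:, f].any():
                terms.append(s_pos[:, f])
                names.append("pos_sum")
            if use_neg and neg[:, f].any():
                terms.append(s_neg[:, f])
                names.append("neg_sum")
            if not terms:
                predicted[f] = y[rows].mean()
                coefs.append({"intercept": predicted[f]})
                fallback.append(f)
                continue
            a = np.column_stack([np.ones(self.n)] + terms)
            coef, *_ = np.linalg.lstsq(a[rows], y[rows], rcond=None)
            predicted[f] = a[f] @ coef
            coefs.append(dict(zip(["intercept"] + names, map(float, coef))))
        return {
            "predicted": predicted,
            "pos": pos.T if keep_masks else None,   # (n_folds, E)
            "neg": neg.T if keep_masks else None,
            "coefs": coefs,
            "fallback": fallback,
        }


def _obs_pred_r(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, str]:
    if np.std(predicted) == 0 or np.std(observed) == 0:
        return float("nan"), "degenerate"
    return float(np.corrcoef(observed, predicted)[0, 1]), "ok"


def loocv(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    config: CbpmConfig | None = None,
) -> CbpmResult:
    """Leave-one-out CBPM on the observed pairing (no permutation p)."""
    config = config or CbpmConfig()
    engine = _LoocvEngine(x, covariates)
    out = engine.run(
        y, config.selection_alpha, config.model_form, config.normalize_strengths
    )
    r, status = _obs_pred_r(y, out["predicted"])
    if out["fallback"]:
        log.info("LOOCV fallback to training mean in folds %s", out["fallback"])
    return CbpmResult(
        observed=np.asarray(y, dtype=float),
        predicted=out["predicted"],
        r_obs_pred=r,
        status=status,
        alpha=config.selection_alpha,
        fold_pos_masks=out["pos"],
        fold_neg_masks=out["neg"],
        fold_coefs=out["coefs"],
        fallback_folds=out["fallback"],
    )


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    config: CbpmConfig | None = None,
    result: CbpmResult | None = None,
) -> tuple[float, np.ndarray, CbpmResult]:
    """Permutation null for the LOOCV prediction performance.

    Each of ``n_permutations`` draws re-pairs behavior with connectomes
    (covariates stay attached to the connectome side unless
    ``permute_covariates_with_y``) and reruns the full LOOCV, selection
    included. ``p_perm`` is the plain proportion of null runs whose r is at
    least the observed r (so 0.000 is attainable); the add-one estimator
    (b+1)/(m+1) is reported alongside.
    """
    config = config or CbpmConfig()
    y = np.asarray(y, dtype=float)
    result = result or loocv(x, y, covariates, config)
    rng = np.random.default_rng(config.seed)
    engine = None
    if not config.permute_covariates_with_y:
        engine = _LoocvEngine(x, covariates)
    null_r = np.empty(config.n_permutations)
    for b in range(config.n_permutations):
        perm = rng.permutation(len(y))
        if engine is not None:
            out = engine.run(
                y[perm], config.selection_alpha, config.model_form,
                config.normalize_strengths, keep_masks=False,
            )
        else:
            cov_b = None if covariates is None else np.asarray(covariates)[perm]
            out = _LoocvEngine(x, cov_b).run(
                y[perm], config.selection_alpha, config.model_form,
                config.normalize_strengths, keep_masks=False,
            )
        null_r[b], _ = _obs_pred_r(y[perm], out["predicted"])
    obs = result.r_obs_pred
    better = np.nansum(null_r >= obs) if np.isfinite(obs) else np.nan
    result.null_r = null_r
    result.p_perm = float(better / config.n_permutations) if np.isfinite(obs) else float("nan")
    result.p_perm_add_one = (
        float((better + 1) / (config.n_permutations + 1))
        if np.isfinite(obs)
        else float("nan")
    )
    return result.p_perm, null_r, result


def run_cbpm(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    config: CbpmConfig | None = None,
) -> CbpmResult:
    """LOOCV plus permutation inference in one call."""
    config = config or CbpmConfig()
    result = loocv(x, y, covariates, config)
    permutation_test(x, y, covariates, config, result)
    return result


def threshold_sweep(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    config: CbpmConfig | None = None,
) -> pd.DataFrame:
    """Rerun LOOCV + permutation at every selection threshold in the sweep."""
    config = config or CbpmConfig()
    rows = []
    for alpha in config.threshold_sweep:
        res = run_cbpm(x, y, covariates, replace(config, selection_alpha=alpha))
        rows.append(
            {
                "alpha": alpha,
                "r_obs_pred": res.r_obs_pred,
                "p_perm": res.p_perm,
                "p_perm_add_one": res.p_perm_add_one,
                "n_pos_consensus": int(res.consensus_pos.sum()),
                "n_neg_consensus": int(res.consensus_neg.sum()),
                "n_fallback_folds": len(res.fallback_folds),
            }
        )
    return pd.DataFrame(rows)


def lesion_analysis(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    atlas: AtlasLabels,
    config: CbpmConfig | None = None,
    extra_roles: tuple = ("DMN-C", "Hipp"),
) -> pd.DataFrame:
    """Computational lesion analysis over atlas networks.

    For each network (and each designated role set whose ROIs differ from
    every single network), every edge incident to any of its ROIs is removed
    and the full LOOCV + permutation analysis reruns on the reduced edge
    matrix. Edge columns must follow the canonical lower-triangle order for
    the atlas's ROI count.
    """
    config = config or CbpmConfig()
    r = atlas.n_rois
    rows_idx, cols_idx = edge_index_pairs(r)
    if x.shape[1] != rows_idx.size:
        raise ValueError(
            f"edge matrix has {x.shape[1]} columns; atlas implies {rows_idx.size}"
        )
    networks = atlas.networks
    roles = atlas.roles
    targets: list[tuple[str, np.ndarray]] = []
    seen = []
    for network in pd.unique(networks):
        roi_mask = networks == network
        targets.append((str(network), roi_mask))
        seen.append(frozenset(np.flatnonzero(roi_mask)))
    for role in extra_roles:
        roi_mask = roles == role
        if roi_mask.any() and frozenset(np.flatnonzero(roi_mask)) not in seen:
            targets.append((role, roi_mask))

    records = []
    for name, roi_mask in targets:
        keep = ~(roi_mask[rows_idx] | roi_mask[cols_idx])
        if not keep.any():
            raise ValueError(f"lesioning {name!r} removes every edge")
        res = run_cbpm(x[:, keep], y, covariates, config)
        records.append(
            {
                "network": name,
                "r": res.r_obs_pred,
                "p_perm": res.p_perm,
                "p_perm_add_one": res.p_perm_add_one,
                "n_edges_removed": int((~keep).sum()),
            }
        )
    return pd.DataFrame(records)
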