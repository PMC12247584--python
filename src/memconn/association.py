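"""Behavioral score construction and brain-behavior linear models.

Narrative recall is the mean of immediate and delayed story-detail counts;
an optional composite averages the z-scored narrative and emotional-memory
scores over subjects with both. Network summaries are related to behavior
with OLS under three nested covariate sets (none; age/sex/motion; plus
fluid intelligence and a cognitive screen), reporting standardized betas
with two-sided t tests and listwise deletion of incomplete rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "COVARIATE_SETS",
    "RegressionResult",
    "zscore",
    "build_scores",
    "fit_brain_behavior",
    "fit_model_table",
]

COVARIATE_SETS = {
    "none": (),
    "motion-demographic": ("age", "sex", "fd"),
    "full": ("age", "sex", "fd", "cattell", "acer"),
}


@dataclass
class RegressionResult:
    beta: float          # standardized coefficient of x
    se: float
    t: float
    df: int
    p: float
    n_used: int
    covariate_set: str
    beta_raw: float      # coefficient on the original scales

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize with the sample SD (n-1 denominator)."""
    x = np.asarray(x, dtype=float)
    sd = np.nanstd(x, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot standardize a zero-variance variable")
    return (x - np.nanmean(x)) / sd


def build_scores(
    immediate: np.ndarray,
    delayed: np.ndarray,
    emotional: np.ndarray | None = None,
) -> pd.DataFrame:
    """Derive memory scores from raw recall counts.

    ``mem_narr`` is the per-subject mean of immediate and delayed narrative
    recall counts. ``composite`` is the mean of z-scored ``mem_narr`` and
    z-scored emotional recall for subjects with both scores (NaN elsewhere);
    z-scores use the sample mean/SD of each score's complete cases.
    """
    immediate = np.asarray(immediate, dtype=float)
    delayed = np.asarray(delayed, dtype=float)
    if (immediate[np.isfinite(immediate)] < 0).any() or (
        delayed[np.isfinite(delayed)] < 0
    ).any():
        raise ValueError("recall counts must be non-negative")
    mem_narr = (immediate + delayed) / 2.0
    out = pd.DataFrame({"mem_narr": mem_narr})
    if emotional is not None:
        emotional = np.asarray(emotional, dtype=float)
        out["mem_emo"] = emotional
        both = np.isfinite(mem_narr) & np.isfinite(emotional)
        composite = np.full(mem_narr.shape, np.nan)
        if both.any():
            composite[both] = (
                zscore(mem_narr[both]) + zscore(emotional[both])
            ) / 2.0
        out["composite"] = composite
    return out


def fit_brain_behavior(
    table: pd.DataFrame,
    y: str,
    x: str,
    covariates: str = "none",
    zscore_sex: bool = True,
) -> RegressionResult:
    """OLS of behavior on one connectivity summary plus a covariate set.

    All variables are z-scored (sample SD) before fitting so the reported
    coefficient is a standardized beta; with no covariates it equals the
    Pearson correlation of y and x. ``zscore_sex=False`` leaves binary sex
    on its 0/1 coding. ``beta_raw`` is the same model fit on original
    scales. Rows with any missing model variable are dropped (listwise).
    """
    if covariates not in COVARIATE_SETS:
        raise ValueError(f"unknown covariate set {covariates!r}")
    cov_names = list(COVARIATE_SETS[covariates])
    cols = [y, x] + cov_names
    data = table[cols].dropna()
    n = len(data)
    if n < len(cols) + 1:
        raise ValueError(f"only {n} complete rows for model with {len(cols)} variables")

    def design(standardize: bool) -> tuple[np.ndarray, np.ndarray]:
        yv = data[y].to_numpy(dtype=float)
        xs = []
        for name in [x] + cov_names:
            v = data[name].to_numpy(dtype=float)
            if standardize and (name != "sex" or zscore_sex):
                v = zscore(v)
            xs.append(v)
        if standardize:
            yv = zscore(yv)
        return yv, np.column_stack(xs)

    yv, xmat = design(standardize=True)
    exog = sm.add_constant(xmat, has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        corr = np.corrcoef(xmat, rowvar=False)
        names = [x] + cov_names
        pairs = [
            f"{names[i]}~{names[j]}"
            for i in range(len(names))
            for j in range(i)
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"collinear predictors: {pairs or names}")
    fit = sm.OLS(yv, exog).fit()
    yr, xr = design(standardize=False)
    fit_raw = sm.OLS(yr, sm.add_constant(xr, has_constant="add")).fit()
    return RegressionResult(
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        t=float(fit.tvalues[1]),
        df=int(fit.df_resid),
        p=float(fit.pvalues[1]),
        n_used=n,
        covariate_set=covariates,
        beta_raw=float(fit_raw.params[1]),
    )


def fit_model_table(
    table: pd.DataFrame,
    y: str = "behavior",
    summaries: tuple = ("within", "between", "extra", "hipp"),
    covariate_sets: tuple = ("none", "motion-demographic", "full"),
) -> pd.DataFrame:
    """Tidy table of every summary x covariate-set model (one row each)."""
    rows = []
    for x in summaries:
        for cov in covariate_sets:
            res = fit_brain_behavior(table, y, x, cov)
            rows.append({"y": y, "x": x, **res.as_dict()})
    return pd.DataFrame(rows)
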