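"""Post-hoc resting-state cleaning, mPFC-PCC connectivity, and the
pre-registered mixed-effects analyses.

Cleaning regresses out 12 motion regressors (6 parameters + first
derivatives), the top-5 white-matter and top-5 CSF principal components
(aCompCor), linear drift, and optionally the mean gray-matter signal
(GSR); residuals are bandpass filtered (0.008-0.09 Hz, zero-phase
Butterworth order 4) and volumes with framewise displacement above the
censoring threshold are excluded from the correlation.

The primary outcome is the Fisher r-to-z transformed mPFC-PCC Pearson
correlation, modeled with linear mixed-effects regression:

    fisher_z ~ time + mean_fd + age            (+ (time | id))   Aim 1
    fisher_z ~ dose * time + mean_fd + age     (+ (time | id))   Aim 2

Random-intercept and random-slope structures are compared by AIC on
maximum-likelihood fits; the winner is refit by REML.  Robust (Huber
IRLS) estimation triggers when any outcome sits >= 3 SD from the outcome
mean.  Secondary-analysis p-values are corrected by the Benjamini-
Hochberg step-up within the pre-specified families, and an MNAR
sensitivity analysis refits the model with missing outcomes replaced
across a -2..+2 SD shift grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.decomposition import PCA
import statsmodels.formula.api as smf

R_CLIP = 1.0 - 1e-7


@dataclass
class CleaningParams:
    acompcor_components: int = 5
    linear_drift: bool = True
    gsr: bool = False
    bandpass_hz: Tuple[float, float] = (0.008, 0.09)
    fd_censor_threshold_mm: float = 0.3
    filter_order: int = 4

    def validate(self, tr_ms: float) -> None:
        lo, hi = self.bandpass_hz
        nyq = 1000.0 / (2.0 * tr_ms)
        if not (0.0 < lo < hi < nyq):
            raise ValueError("bandpass must satisfy 0 < low < high < Nyquist")


def _acompcor(data2d: np.ndarray, mask: np.ndarray, k: int) -> np.ndarray:
    """Top-k PCA component timecourses of the voxel series inside a tissue mask."""
    series = data2d[mask.ravel()]
    series = series - series.mean(axis=1, keepdims=True)
    sd = series.std(axis=1)
    series = series[sd > 0] / sd[sd > 0, None]
    if series.shape[0] == 0:  # constant tissue signal: nothing to regress
        return np.zeros((data2d.shape[1], 0))
    k = min(k, series.shape[0], series.shape[1] - 1)
    return PCA(n_components=k).fit_transform(series.T)  # (T, k)


def clean_run(run, wm_mask: np.ndarray, csf_mask: np.ndarray,
              whole_brain: np.ndarray,
              params: Optional[CleaningParams] = None):
    """Nuisance-regress, bandpass, and censor one resting run.

    Returns (cleaned Run4D, censor boolean array) where censored volumes
    are flagged True.  Filtering precedes censoring (filter-then-censor);
    censored volumes are dropped only at the correlation stage.
    """
    p = params or CleaningParams()
    p.validate(run.params.tr_ms)
    if not wm_mask.any() or not csf_mask.any():
        raise ValueError("WM and CSF masks must be nonempty")
    n = run.n_volumes

    motion = run.motion.params
    dmotion = np.diff(motion, axis=0, prepend=motion[:1])
    cols = [np.ones((n, 1)), motion, dmotion]
    if p.linear_drift:
        cols.append((np.arange(n, dtype=float) / max(n - 1, 1) - 0.5)[:, None])
    flat = run.data.reshape(-1, n)
    cols.append(_acompcor(flat, wm_mask, p.acompcor_components))
    cols.append(_acompcor(flat, csf_mask, p.acompcor_components))
    if p.gsr:
        gray = whole_brain & ~wm_mask & ~csf_mask
        gs = flat[gray.ravel()].mean(axis=0)
        cols.append((gs - gs.mean())[:, None])
    design = np.hstack(cols)
    if n <= design.shape[1]:
        raise ValueError(
            f"run has {n} volumes but the nuisance design has "
            f"{design.shape[1]} columns")

    # voxelwise projection onto the nuisance complement
    beta, *_ = np.linalg.lstsq(design, flat.T, rcond=None)
    resid = flat.T - design @ beta  # (T, V)

    fs = 1000.0 / run.params.tr_ms
    sos = signal.butter(p.filter_order, p.bandpass_hz, btype="bandpass",
                        fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, resid, axis=0).T.reshape(run.data.shape)

    censor = run.motion.framewise_displacement > p.fd_censor_threshold_mm
    return run.copy_with(filtered), censor


def fisher_z(r: float) -> float:
    """Variance-stabilizing r-to-z transform with clipping so z stays finite."""
    return float(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))


def roi_connectivity(run, roi_a: np.ndarray, roi_b: np.ndarray,
                     censor: Optional[np.ndarray] = None,
                     template_a: Optional[np.ndarray] = None,
                     template_b: Optional[np.ndarray] = None,
                     min_roi_voxels: int = 200,
                     min_uncensored: int = 10) -> Dict:
    """mPFC-PCC style connectivity: Pearson r of mean ROI timecourses.

    A personalized ROI with fewer than ``min_roi_voxels`` voxels is
    replaced by its template (flagged in the result).  Censored volumes
    are excluded before the correlation.
    """
    substituted = []
    if roi_a.sum() < min_roi_voxels and template_a is not None:
        roi_a, substituted = template_a, substituted + ["roi_a"]
    if roi_b.sum() < min_roi_voxels and template_b is not None:
        roi_b, substituted = template_b, substituted + ["roi_b"]
    if not roi_a.any() or not roi_b.any():
        raise ValueError("ROIs must be nonempty")
    keep = np.ones(run.n_volumes, dtype=bool) if censor is None else ~censor
    if keep.sum() < min_uncensored:
        raise ValueError(f"fewer than {min_uncensored} uncensored volumes")
    flat = run.data.reshape(-1, run.n_volumes)
    a = flat[roi_a.ravel()].mean(axis=0)[keep]
    b = flat[roi_b.ravel()].mean(axis=0)[keep]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant ROI timecourse; correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return {"r": r, "fisher_z": fisher_z(r), "substituted": substituted,
            "n_volumes_used": int(keep.sum())}


# ---------------------------------------------------------------------------
# Mixed-effects models


@dataclass
class ModelFit:
    formula: str
    random_structure: str            # "intercept" | "intercept+slope"
    params: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    aic_intercept: float
    aic_slope: float
    robust_used: bool = False
    fallback_used: bool = False
    notes: List[str] = field(default_factory=list)

    def coef(self, term: str) -> Dict[str, float]:
        lo, hi = self.conf_int.loc[term]
        return {"estimate": float(self.params[term]), "ci_low": float(lo),
                "ci_high": float(hi), "p": float(self.pvalues[term])}


def _fit_lmm(data: pd.DataFrame, fixed: str, slope: bool, reml: bool):
    re_formula = "~time" if slope else "~1"
    model = smf.mixedlm(fixed, data, groups=data["id"], re_formula=re_formula)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return model.fit(reml=reml, method="lbfgs", maxiter=300)
        except np.linalg.LinAlgError:
            return model.fit(reml=reml, method="bfgs", maxiter=300)


def _huber_weights(resid: np.ndarray, c: float = 1.345) -> np.ndarray:
    s = np.median(np.abs(resid)) / 0.6745
    if s <= 0:
        return np.ones_like(resid)
    u = np.abs(resid) / s
    return np.where(u <= c, 1.0, c / u)


def _fit_mixed(data: pd.DataFrame, fixed: str) -> ModelFit:
    """AIC model comparison (ML), REML refit, robust trigger, fallback."""
    notes: List[str] = []
    data = data.copy()
    fallback = False
    try:
        ml_int = _fit_lmm(data, fixed, slope=False, reml=False)
        ml_slope = _fit_lmm(data, fixed, slope=True, reml=False)
        aic_int, aic_slope = float(ml_int.aic), float(ml_slope.aic)
    except Exception as err:  # degenerate data: fall back to OLS
        notes.append(f"mixed-model fallback: {err}")
        return _ols_fallback(data, fixed, notes)
    slope = aic_slope < aic_int
    structure = "intercept+slope" if slope else "intercept"
    try:
        fit = _fit_lmm(data, fixed, slope=slope, reml=True)
        if not fit.converged:
            raise RuntimeError("REML fit did not converge")
    except Exception as err:
        notes.append(f"REML refit failed ({err}); reporting ML fit")
        fit = ml_slope if slope else ml_int
        fallback = True

    outcome = fixed.split("~")[0].strip()
    y = data[outcome].to_numpy(dtype=float)
    sd = y.std(ddof=1)
    robust = bool(sd > 0 and np.any(np.abs(y - y.mean()) >= 3 * sd))
    if robust:
        params, ci, pvals, irls_notes = _robust_refit(data, fixed, slope)
        notes.extend(irls_notes)
    else:
        params = fit.fe_params if hasattr(fit, "fe_params") else fit.params
        ci = fit.conf_int().loc[params.index]
        pvals = fit.pvalues.loc[params.index]
    return ModelFit(formula=fixed, random_structure=structure,
                    params=params, conf_int=ci, pvalues=pvals,
                    aic_intercept=aic_int, aic_slope=aic_slope,
                    robust_used=robust, fallback_used=fallback, notes=notes)


def _robust_refit(data: pd.DataFrame, fixed: str, slope: bool, n_iter: int = 5):
    """Huber IRLS: rows rescaled by sqrt(weight) between mixed-model fits.

    statsmodels' mixed model has no observation weights, so weighting is
    applied by scaling the outcome and the fixed-effect design row by the
    square-root Huber weight — an approximation adequate for bounding the
    influence of gross outcome outliers.
    """
    notes = [">=3 SD outcome outlier detected; Huber IRLS estimation used"]
    outcome = fixed.split("~")[0].strip()
    fit = _fit_lmm(data, fixed, slope=slope, reml=True)
    rename = lambda ix: ["Intercept" if i == "_w_intercept" else i for i in ix]
    # unweighted fixed-effect design, for marginal residuals each iteration
    # (BLUP prediction can fail on singular random-effect covariances, and
    # robust weighting targets gross marginal outliers anyway)
    exog0 = np.asarray(fit.model.exog)
    for _ in range(n_iter):
        marginal = exog0 @ np.asarray(fit.fe_params)
        resid = data[outcome].to_numpy() - marginal
        w = np.sqrt(_huber_weights(resid))
        work = data.copy()
        work[outcome] = data[outcome] * w
        for col in ("time", "dose", "mean_fd", "age_c"):
            if col in work.columns:
                work[col] = data[col] * w
        work["_w_intercept"] = w
        fixed_w = fixed.replace("~", "~ 0 + _w_intercept +", 1)
        fit = _fit_lmm(work, fixed_w, slope=slope, reml=True)
    fe = fit.fe_params
    params = pd.Series(fe.to_numpy(), index=rename(fe.index))
    ci = fit.conf_int().loc[fe.index]
    ci.index = rename(ci.index)
    pvals = pd.Series(fit.pvalues.loc[fe.index].to_numpy(), index=rename(fe.index))
    return params, ci, pvals, notes


def _ols_fallback(data: pd.DataFrame, fixed: str, notes: List[str]) -> ModelFit:
    try:
        fit = smf.ols(fixed, data).fit()
        return ModelFit(formula=fixed, random_structure="intercept",
                        params=fit.params, conf_int=fit.conf_int(),
                        pvalues=fit.pvalues, aic_intercept=float("nan"),
                        aic_slope=float("nan"), fallback_used=True, notes=notes)
    except Exception as err:
        raise ValueError(f"model could not be fit on degenerate data: {err}")


def _prepare(records: pd.DataFrame) -> pd.DataFrame:
    data = records.copy()
    required = {"id", "time", "fisher_z", "mean_fd", "age"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    data["age_c"] = data["age"] - data["age"].mean()
    return data


def fit_primary_model(records: pd.DataFrame) -> ModelFit:
    """Aim-1 model: fisher_z ~ time + mean_fd + age_c, random effects by id."""
    data = _prepare(records)
    if data.groupby("id")["time"].nunique().max() < 2 or data["id"].nunique() < 2:
        raise ValueError("need >= 2 participants with both pre and post records")
    return _fit_mixed(data, "fisher_z ~ time + mean_fd + age_c")


def fit_dose_model(records: pd.DataFrame,
                   include_dose_main: bool = True) -> ModelFit:
    """Aim-2 model with the dose x time interaction as the focal term.

    ``include_dose_main=False`` fits the sensitivity variant without the
    dose main effect.
    """
    data = _prepare(records)
    if "dose" not in data.columns:
        raise ValueError("records must include a dose column")
    if data["dose"].nunique() < 2:
        raise ValueError("dose x time interaction inestimable: only one dose "
                         "condition present")
    fixed = ("fisher_z ~ dose * time + mean_fd + age_c" if include_dose_main
             else "fisher_z ~ time + dose:time + mean_fd + age_c")
    return _fit_mixed(data, fixed)


# ---------------------------------------------------------------------------
# Multiplicity, missingness


def bh_adjust(p_values: Sequence[float], alpha: float = 0.05,
              families: Optional[Sequence[Sequence[int]]] = None) -> np.ndarray:
    """Benjamini-Hochberg step-up within each family; returns a reject mask.

    ``families`` partitions the p-value indices (default: one family).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if families is None:
        families = [list(range(p.size))]
    covered = sorted(i for fam in families for i in fam)
    if covered != list(range(p.size)):
        raise ValueError("families must partition the p-value indices")
    reject = np.zeros(p.size, dtype=bool)
    for fam in families:
        idx = np.asarray(list(fam))
        m = idx.size
        order = np.argsort(p[idx], kind="stable")
        sorted_p = p[idx][order]
        below = sorted_p <= alpha * (np.arange(1, m + 1) / m)
        if below.any():
            k = int(np.max(np.flatnonzero(below)))
            reject[idx[order[:k + 1]]] = True
    return reject


def mnar_sensitivity(records: pd.DataFrame, focal_term: str = "time",
                     model: str = "primary", shift_grid: Optional[np.ndarray] = None
                     ) -> pd.DataFrame:
    """Refit the model with missing outcomes replaced across a shift grid.

    Missing ``fisher_z`` values are replaced by observed mean + shift x
    observed SD for each shift in [-2, +2] SD; one row of focal-term
    results per shift.  With no missing outcomes a single identity row is
    returned.
    """
    fit_fn = fit_primary_model if model == "primary" else fit_dose_model
    observed = records["fisher_z"].dropna()
    if records["fisher_z"].notna().all():
        fit = fit_fn(records)
        c = fit.coef(focal_term)
        return pd.DataFrame([{"shift_sd": 0.0, "replaced": 0, **c}])
    if shift_grid is None:
        shift_grid = np.linspace(-2.0, 2.0, 9)
    mu, sd = observed.mean(), observed.std(ddof=1)
    n_missing = int(records["fisher_z"].isna().sum())
    rows = []
    for shift in shift_grid:
        filled = records.copy()
        filled.loc[filled["fisher_z"].isna(), "fisher_z"] = mu + shift * sd
        fit = fit_fn(filled)
        rows.append({"shift_sd": float(shift), "replaced": n_missing,
                     **fit.coef(focal_term)})
    return pd.DataFrame(rows)


def item_impute(items: pd.DataFrame, max_missing_frac: float = 0.10) -> pd.Series:
    """Person-mean item imputation for scale sums.

    Rows (respondents) with fewer than ``max_missing_frac`` of items
    missing have missing items replaced by that respondent's mean over
    answered items before summing; rows at or above the threshold score
    missing.
    """
    n_items = items.shape[1]
    frac = items.isna().sum(axis=1) / n_items
    person_mean = items.mean(axis=1)
    filled = items.apply(lambda col: col.fillna(person_mean))
    scores = filled.sum(axis=1)
    scores[frac >= max_missing_frac] = np.nan
    scores[frac == 1.0] = np.nan
    return scores


def records_from_sessions(sessions, phantom, params: Optional[CleaningParams] = None,
                          ages: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Build tidy connectivity records from simulated session logs.

    Each participant contributes 4 rows: 2 pre- and 2 post-feedback
    resting runs, with Fisher-z mPFC-PCC connectivity, mean framewise
    displacement, dose indicator, and age.
    """
    templates = phantom.template_masks()
    rows = []
    for i, log in enumerate(sessions):
        age = float(ages[i]) if ages is not None else 15.0
        dose = 1 if log.dose == "min30" else 0
        for time, runs in ((0, log.rest_runs_pre), (1, log.rest_runs_post)):
            for j, run in enumerate(runs):
                cleaned, censor = clean_run(run, templates["WM"],
                                            templates["CSF"],
                                            templates["whole_brain"], params)
                conn = roi_connectivity(cleaned, templates["mPFC"],
                                        templates["PCC"], censor=censor)
                rows.append({
                    "id": f"sub{i:03d}", "run": f"{'pre' if time == 0 else 'post'}{j+1}",
                    "time": time, "dose": dose, "r": conn["r"],
                    "fisher_z": conn["fisher_z"],
                    "mean_fd": float(run.motion.framewise_displacement.mean()),
                    "age": age,
                })
    return pd.DataFrame(rows)
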