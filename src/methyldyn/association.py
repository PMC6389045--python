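"""Per-site association models: cross-sectional EWAS and longitudinal LMMs.

The cross-sectional gate regresses technically adjusted M-values at
baseline on current-vs-never smoking status plus confounders, per site,
with Bonferroni control over all sites tested.  Sites passing the gate are
carried into random-intercept linear mixed models with smoking-category x
time interactions:

* the TSQ model (7 time-since-quitting categories vs never-smoker
  reference),
* the continued-smoking model (stable current smokers vs reference), and
* the intensity-vs-duration model (current smokers only).

In each longitudinal model, beta_C (the category main effect) is the
expected baseline methylation difference vs the reference, and beta_L
(the category x time interaction) is the expected difference in change in
methylation per year vs the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MethylationArraySet
from .lmm import fit_random_intercept_lmm, lmm_pvalues
from .phenotypes import CELL_PROPS, add_tsq_categories
from .preprocess import remove_outliers

CONFOUNDERS = ["sex", "alcohol_g_day", "bmi", "wbc_count", *CELL_PROPS]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive count")
    return alpha / m


# ---------------------------------------------------------------------------
# Cross-sectional EWAS
# ---------------------------------------------------------------------------

@dataclass
class EwasResult:
    """Per-site cross-sectional smoking effect (CS vs NS at baseline)."""

    table: pd.DataFrame  # columns: coef, se, p, significant, n
    alpha: float
    m_tested: int
    threshold: float

    @property
    def significant_sites(self) -> pd.Index:
        flag = self.table["significant"].fillna(False).astype(bool)
        return self.table.index[flag]


def _ols_site(y: np.ndarray, D: np.ndarray, coef_idx: int):
    """OLS fit of one site; returns (coef, se, p, n) or None if degenerate."""
    obs = ~np.isnan(y) & ~np.isnan(D).any(axis=1)
    n = int(obs.sum())
    p = D.shape[1]
    if n < p + 2:
        return None
    Do, yo = D[obs], y[obs]
    A = Do.T @ Do
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return None
    beta = Ainv @ (Do.T @ yo)
    resid = yo - Do @ beta
    s2 = resid @ resid / (n - p)
    se = np.sqrt(s2 * Ainv[coef_idx, coef_idx])
    t = beta[coef_idx] / se
    pval = 2.0 * stats.t.sf(abs(t), n - p)
    return beta[coef_idx], se, pval, n


def run_ewas(
    data: MethylationArraySet,
    sample_sheet: pd.DataFrame,
    alpha: float = 0.05,
    outlier_sd: float = 5.0,
    max_outliers: int = 5,
) -> EwasResult:
    """Baseline CS-vs-NS EWAS on technically adjusted M-values.

    Per site: 5-SD outliers are masked (at most 5, largest first), then an
    OLS model of M on smoking status plus age at interview and the
    standard confounders is fitted; the two-sided t-test p of the smoking
    coefficient is Bonferroni-flagged at alpha / (number of sites tested).
    Sites with fewer than 10 observations per smoking group are skipped.
    """
    if data.scale not in ("M", "M_adjusted"):
        raise ValueError("EWAS expects M-scale (technically adjusted) values")
    meta = sample_sheet.loc[data.sample_ids]
    base = meta[(meta["visit"] == "S4") & meta["smoking_status"].isin(["CS", "NS"])]
    samples = base.index
    smoking = (base["smoking_status"] == "CS").astype(float).to_numpy()
    D = np.column_stack([
        np.ones(len(base)),
        smoking,
        base["interview_age"].to_numpy(float),
        base[CONFOUNDERS].to_numpy(float),
    ])
    vals = data.values.loc[:, samples].to_numpy(float)

    rows = {}
    for i, site in enumerate(data.site_ids):
        y, _ = remove_outliers(vals[i], D, sd_threshold=outlier_sd, max_removed=max_outliers)
        obs = ~np.isnan(y)
        if min((smoking[obs] == 1).sum(), (smoking[obs] == 0).sum()) < 10:
            rows[site] = (np.nan, np.nan, np.nan, int(obs.sum()))
            continue
        res = _ols_site(y, D, coef_idx=1)
        rows[site] = res if res is not None else (np.nan, np.nan, np.nan, int(obs.sum()))

    table = pd.DataFrame.from_dict(rows, orient="index", columns=["coef", "se", "p", "n"])
    table.index.name = "site"
    m = int(table["p"].notna().sum())
    threshold = bonferroni_threshold(alpha, max(m, 1))
    table["significant"] = pd.array(table["p"] < threshold, dtype="boolean")
    table.loc[table["p"].isna(), "significant"] = pd.NA
    return EwasResult(table=table, alpha=alpha, m_tested=m, threshold=threshold)


# ---------------------------------------------------------------------------
# Longitudinal design construction
# ---------------------------------------------------------------------------

def _longitudinal_design(
    meta: pd.DataFrame, category: pd.Series, extra_cols: pd.DataFrame | None = None
) -> tuple[np.ndarray, list, np.ndarray, list]:
    """Fixed-effects design for the category-by-time longitudinal models.

    ``category`` maps individual_id -> category label; the reference label
    must be the first of its sorted unique values after placing the
    reference first (handled by the callers, which pass an ordered
    categorical).  Columns: intercept, category indicators, age at
    baseline, time passed, category x time interactions, confounders,
    plus any ``extra_cols`` (per-observation regressors).
    """
    iid = meta["individual_id"]
    cat = category.loc[iid].to_numpy()
    levels = [l for l in category.cat.categories if l != category.cat.categories[0]]
    ref = category.cat.categories[0]

    age = meta["interview_age"].to_numpy(float)
    is_base = (meta["visit"] == "S4").to_numpy()
    base_age = pd.Series(age[is_base], index=iid[is_base]).reindex(iid).to_numpy()
    time_passed = np.where(is_base, 0.0, age - base_age)

    cols, names = [np.ones(len(meta))], ["intercept"]
    for l in levels:
        cols.append((cat == l).astype(float))
        names.append(f"cat[{l}]")
    cols.append(base_age)
    names.append("age_baseline")
    cols.append(time_passed)
    names.append("time_passed")
    for l in levels:
        cols.append((cat == l).astype(float) * time_passed)
        names.append(f"cat[{l}]:time")
    if extra_cols is not None:
        for c in extra_cols.columns:
            cols.append(extra_cols[c].to_numpy(float))
            names.append(c)
    for c in CONFOUNDERS:
        cols.append(meta[c].to_numpy(float))
        names.append(c)
    D = np.column_stack(cols)
    return D, names, iid.to_numpy(), [str(l) for l in levels]


def _fit_sites(
    data: MethylationArraySet,
    samples: pd.Index,
    D: np.ndarray,
    names: list,
    groups: np.ndarray,
    sites,
    levels: list,
    alpha: float,
    df_method: str,
    outlier_sd: float = 5.0,
    max_outliers: int = 5,
    low_n_levels: dict | None = None,
) -> pd.DataFrame:
    """Fit the LMM for each site and tabulate per-category coefficients."""
    sites = list(data.site_ids if sites is None else sites)
    threshold = bonferroni_threshold(alpha, len(sites))
    vals = data.values.loc[sites, samples].to_numpy(float)

    records = []
    for i, site in enumerate(sites):
        y, n_out = remove_outliers(vals[i], D, sd_threshold=outlier_sd, max_removed=max_outliers)
        try:
            fit = fit_random_intercept_lmm(y, D, groups, param_names=names)
            pvals = lmm_pvalues(fit, df_method=df_method)
        except ValueError:
            for level in levels:
                records.append({"site": site, "category": level, "n_obs": 0,
                                "converged": False})
            continue
        par = pd.Series(fit.params, index=fit.param_names)
        se = pd.Series(fit.se, index=fit.param_names)
        pv = pd.Series(pvals, index=fit.param_names)
        beta_t = par.get("time_passed", np.nan)
        for level in levels:
            c, l = f"cat[{level}]", f"cat[{level}]:time"
            rec = {
                "site": site, "category": level,
                "beta_C": par.get(c, np.nan), "se_C": se.get(c, np.nan), "p_C": pv.get(c, np.nan),
                "beta_L": par.get(l, np.nan), "se_L": se.get(l, np.nan), "p_L": pv.get(l, np.nan),
                "beta_t": beta_t,
                "sigma2_mu": fit.sigma2_mu, "sigma2_eps": fit.sigma2_eps,
                "n_obs": fit.n_obs, "n_outliers_removed": n_out,
                "converged": fit.converged,
                "sig_L": bool(pv.get(l, np.nan) < threshold) if np.isfinite(pv.get(l, np.nan)) else np.nan,
                "low_n": bool(low_n_levels.get(level, False)) if low_n_levels else False,
            }
            records.append(rec)
    out = pd.DataFrame(records)
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["m_sites"] = len(sites)
    return out


def _attach_consistency(table: pd.DataFrame, ewas: "EwasResult | None") -> pd.DataFrame:
    """Direction consistency: beta_L opposite in sign to the EWAS effect."""
    if ewas is None:
        return table
    ew = ewas.table["coef"].reindex(table["site"]).to_numpy()
    table = table.copy()
    table["consistent_direction"] = np.sign(table["beta_L"].to_numpy()) == -np.sign(ew)
    return table


# ---------------------------------------------------------------------------
# The three longitudinal analyses
# ---------------------------------------------------------------------------

def run_tsq_model(
    data: MethylationArraySet,
    sample_sheet: pd.DataFrame,
    trajectories: pd.DataFrame,
    sites=None,
    alpha: float = 0.05,
    k: int = 7,
    mode: str = "matched",
    df_method: str = "satterthwaite",
    ewas: EwasResult | None = None,
) -> pd.DataFrame:
    """Time-since-quitting longitudinal model.

    Included individuals: never-smoker reference (NS-NS) plus included
    former-smoker trajectories (CS-FS, FS-FS) categorized into ``k``
    TSQ_L categories.  Per site, fits the random-intercept model with
    category indicators, a shared time trend for the reference, and
    category x time interactions, plus the standard confounders.
    """
    traj, edges = add_tsq_categories(trajectories, k=k, mode=mode)
    fs_ok = traj["included"] & traj["category"].isin(["CS-FS", "FS-FS"]) & traj["tsq_category"].notna()
    ns_ok = traj["included"] & (traj["category"] == "NS-NS")
    if fs_ok.sum() == 0:
        raise ValueError("no former-smoker trajectories: the TSQ model needs a non-reference category")
    label = pd.Series("NS-NS", index=traj.index, dtype=object)
    label[fs_ok] = [f"TSQ{int(c)}" for c in traj.loc[fs_ok, "tsq_category"]]
    keep_iids = traj.index[fs_ok | ns_ok]
    levels_order = ["NS-NS"] + [f"TSQ{i}" for i in range(1, k + 1)]
    category = pd.Series(
        pd.Categorical(label.loc[keep_iids], categories=levels_order), index=keep_iids
    )

    meta = sample_sheet.loc[data.sample_ids]
    meta = meta[meta["individual_id"].isin(keep_iids)]
    samples = meta.index
    counts = category.value_counts()
    low_n = {f"TSQ{i}": counts.get(f"TSQ{i}", 0) < 5 for i in range(1, k + 1)}
    for lev, flag in low_n.items():
        if flag:
            warnings.warn(f"TSQ category {lev} has fewer than 5 individuals")

    D, names, groups, levels = _longitudinal_design(meta, category)
    table = _fit_sites(data, samples, D, names, groups, sites, levels, alpha,
                       df_method, low_n_levels=low_n)
    table.attrs["tsq_breakpoints"] = list(np.asarray(edges, float))
    return _attach_consistency(table, ewas)


def run_continued_smoking_model(
    data: MethylationArraySet,
    sample_sheet: pd.DataFrame,
    trajectories: pd.DataFrame,
    sites=None,
    alpha: float = 0.05,
    df_method: str = "satterthwaite",
    ewas: EwasResult | None = None,
) -> pd.DataFrame:
    """Continued-smoking longitudinal model: CS-CS vs the NS-NS reference."""
    keep = trajectories["included"] & trajectories["category"].isin(["CS-CS", "NS-NS"])
    if (trajectories.loc[keep, "category"] == "CS-CS").sum() == 0:
        raise ValueError("no CS-CS individuals: the continued-smoking model needs a non-reference category")
    keep_iids = trajectories.index[keep]
    category = pd.Series(
        pd.Categorical(trajectories.loc[keep_iids, "category"], categories=["NS-NS", "CS-CS"]),
        index=keep_iids,
    )
    meta = sample_sheet.loc[data.sample_ids]
    meta = meta[meta["individual_id"].isin(keep_iids)]
    D, names, groups, levels = _longitudinal_design(meta, category)
    table = _fit_sites(data, meta.index, D, names, groups, sites, levels, alpha, df_method)
    return _attach_consistency(table, ewas)


def run_intensity_duration_model(
    data: MethylationArraySet,
    sample_sheet: pd.DataFrame,
    trajectories: pd.DataFrame,
    sites=None,
    alpha: float = 0.05,
    df_method: str = "satterthwaite",
) -> pd.DataFrame:
    """Intensity-vs-duration model among stable current smokers.

    Uses CS-CS individuals at both visits (2 rows each) with smoking
    intensity (cigarettes/day at interview) and duration (years at
    interview) as fixed effects alongside the longitudinal confounders,
    and an individual random intercept.  Returns one row per site with
    both coefficients and their p-values.
    """
    cs = trajectories.index[trajectories["included"] & (trajectories["category"] == "CS-CS")]
    if len(cs) == 0:
        raise ValueError("no CS-CS individuals for the intensity/duration model")
    meta = sample_sheet.loc[data.sample_ids]
    meta = meta[meta["individual_id"].isin(cs)]
    samples = meta.index

    dur = pd.concat([
        trajectories.loc[cs, "duration_S4"].rename("d").to_frame().assign(visit="S4"),
        trajectories.loc[cs, "duration_F4"].rename("d").to_frame().assign(visit="F4"),
    ])
    dur_lookup = dur.set_index([dur.index, "visit"])["d"]
    duration = np.array([
        dur_lookup.get((i, v), np.nan)
        for i, v in zip(meta["individual_id"], meta["visit"])
    ])
    extra = pd.DataFrame({
        "intensity": meta["cigs_per_day"].to_numpy(float),
        "duration": duration,
    }, index=samples)

    # Single-level category: no category/interactions, just the covariates.
    category = pd.Series(pd.Categorical(["CS-CS"] * len(cs), categories=["CS-CS"]), index=cs)
    D, names, groups, _ = _longitudinal_design(meta, category, extra_cols=extra)

    sites = list(data.site_ids if sites is None else sites)
    threshold = bonferroni_threshold(alpha, len(sites))
    vals = data.values.loc[sites, samples].to_numpy(float)
    records = []
    for i, site in enumerate(sites):
        y, n_out = remove_outliers(vals[i], D)
        try:
            fit = fit_random_intercept_lmm(y, D, groups, param_names=names)
            pvals = lmm_pvalues(fit, df_method=df_method)
        except ValueError:
            records.append({"site": site, "converged": False})
            continue
        par = pd.Series(fit.params, index=fit.param_names)
        se = pd.Series(fit.se, index=fit.param_names)
        pv = pd.Series(pvals, index=fit.param_names)
        records.append({
            "site": site,
            "beta_intensity": par.get("intensity", np.nan),
            "se_intensity": se.get("intensity", np.nan),
            "p_intensity": pv.get("intensity", np.nan),
            "beta_duration": par.get("duration", np.nan),
            "se_duration": se.get("duration", np.nan),
            "p_duration": pv.get("duration", np.nan),
            "sigma2_mu": fit.sigma2_mu, "sigma2_eps": fit.sigma2_eps,
            "n_obs": fit.n_obs, "n_outliers_removed": n_out,
            "sig_intensity": bool(pv.get("intensity", np.nan) < threshold),
            "sig_duration": bool(pv.get("duration", np.nan) < threshold),
            "converged": fit.converged,
        })
    out = pd.DataFrame(records)
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["m_sites"] = len(sites)
    return out
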