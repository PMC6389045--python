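"""Preprocessing of array-style methylation data.

Implements the standard quality-control and technical-adjustment chain for
450K-style data: entry-level detection/bead filters, sample and per-visit
site detection-rate filters, SNP-probe and sex-chromosome exclusion,
quantile normalization, the beta -> M logit transform, control-probe PCA
technical adjustment with a batch indicator, per-site 5-SD outlier removal,
and confounder residualization of beta values.

Pipeline order is fixed: SNP removal -> entry filters -> sample filter ->
per-visit site filters -> quantile normalization -> beta->M -> technical
adjustment.  The ``scale`` tag on :class:`MethylationArraySet` records the
stage and re-running on already-processed input is refused.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import FilterReport, MethylationArraySet

PIPELINE_ORDER = (
    "snp_removal", "entry_filters", "sample_filter", "site_filters",
    "quantile_normalization", "beta_to_m", "technical_adjustment",
)


# ---------------------------------------------------------------------------
# beta <-> M transforms
# ---------------------------------------------------------------------------

def beta_to_m(beta):
    """Binary logit transform, M = log2(beta / (1 - beta)).

    Accepts scalars, arrays or DataFrames; NaN entries pass through.  Values
    outside the open interval (0, 1) raise, naming an offending entry.
    """
    arr = np.asarray(beta, float) if not isinstance(beta, pd.DataFrame) else beta.to_numpy(float)
    bad = (arr <= 0.0) | (arr >= 1.0)
    bad &= ~np.isnan(arr)
    if bad.any():
        idx = tuple(np.argwhere(bad)[0]) if arr.ndim else ()
        raise ValueError(f"beta value {arr[idx] if arr.ndim else arr} at position {idx} "
                         "outside the open interval (0, 1)")
    with np.errstate(divide="ignore"):
        out = np.log2(arr / (1.0 - arr))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    return out if np.ndim(beta) else float(out)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 1 / (1 + 2**(-M))."""
    arr = np.asarray(m, float) if not isinstance(m, pd.DataFrame) else m.to_numpy(float)
    out = 1.0 / (1.0 + np.exp2(-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    return out if np.ndim(m) else float(out)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def remove_snp_probes(data: MethylationArraySet) -> tuple[MethylationArraySet, FilterReport]:
    """Drop sites flagged as SNP probes."""
    if data.annotation is None or "snp_probe" not in data.annotation:
        raise ValueError("annotation with a 'snp_probe' column is required")
    keep = ~data.annotation["snp_probe"].astype(bool)
    report = FilterReport(sites_removed_snp=int((~keep).sum()))
    return data.subset(sites=data.site_ids[keep]), report


def apply_entry_filters(
    data: MethylationArraySet,
    detection_threshold: float = 0.01,
    min_beads: int = 4,
    sample_detection_rate: float = 0.95,
) -> tuple[MethylationArraySet, FilterReport]:
    """Set unreliable entries missing and drop low-detection samples.

    Entries with detection p >= 0.01 (inclusive boundary) or bead count <= 3
    are set missing; samples whose fraction of non-missing entries is <= 0.95
    (inclusive) are dropped.
    """
    if data.detection_p is None or data.beads is None:
        raise ValueError("detection_p and beads companions are required")
    vals = data.values.to_numpy(float).copy()
    bad = (data.detection_p.to_numpy(float) >= detection_threshold) | \
          (data.beads.to_numpy(float) < min_beads)
    bad &= ~np.isnan(vals)
    vals[bad] = np.nan
    report = FilterReport(entries_set_missing=int(bad.sum()))

    detect_rate = 1.0 - np.isnan(vals).mean(axis=0)
    # inclusive boundary: a detection rate of exactly 0.95 drops the sample
    keep = detect_rate > sample_detection_rate + 1e-12
    dropped = data.sample_ids[~keep]
    report.samples_removed = int((~keep).sum())
    report.sample_removal_reasons = {
        s: f"detection rate {detect_rate[i]:.4f} <= {sample_detection_rate}"
        for i, s in zip(np.flatnonzero(~keep), dropped)
    }
    out = data.replace_values(pd.DataFrame(vals, index=data.site_ids, columns=data.sample_ids))
    out = out.subset(samples=data.sample_ids[keep])
    if out.n_samples == 0:
        warnings.warn("all samples removed by the detection-rate filter")
    return out, report


def apply_site_filters(
    data: MethylationArraySet, site_detection_rate: float = 0.95
) -> tuple[MethylationArraySet, FilterReport]:
    """Per-visit site detection filter plus sex-chromosome exclusion.

    A site is removed when its non-missing rate is below 95% within either
    visit, or when it lies on chromosome X or Y.
    """
    if data.annotation is None or "chromosome" not in data.annotation:
        raise ValueError("annotation with a 'chromosome' column is required")
    visit = data.visit.to_numpy()
    vals = data.values.to_numpy(float)
    ok = np.ones(data.n_sites, bool)
    for v in np.unique(visit):
        cols = visit == v
        rate = 1.0 - np.isnan(vals[:, cols]).mean(axis=1)
        # sites at exactly 95% detection are retained (rule is "below 95%")
        ok &= rate >= site_detection_rate - 1e-12
    sexchrom = data.annotation["chromosome"].astype(str).isin(["X", "Y"]).to_numpy()
    report = FilterReport(
        sites_removed_detection=int((~ok & ~sexchrom).sum()),
        sites_removed_sex_chrom=int(sexchrom.sum()),
    )
    keep = ok & ~sexchrom
    return data.subset(sites=data.site_ids[keep]), report


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns (samples) of a sites x samples matrix.

    After the call every complete sample shares the same sorted value
    vector: the across-sample mean of sorted vectors.  Ties share the mean
    reference value over their rank span.  Missing entries are excluded
    from the reference and restored as missing; samples with missing
    entries are mapped through interpolation of the reference quantile
    function at their within-sample rank positions.
    """
    X = values.to_numpy(float)
    n_sites, n_samples = X.shape
    if n_samples == 1:
        warnings.warn("single-sample input: quantile normalization is the identity")
        return values.copy()

    counts = (~np.isnan(X)).sum(axis=0)
    if (counts == 0).any():
        raise ValueError("cannot quantile-normalize a fully missing sample column")
    full = counts == counts.max()
    n_ref = int(counts.max())

    # Reference: mean of per-sample sorted vectors on a common grid.
    sorted_cols = np.empty((n_ref, n_samples))
    grid = (np.arange(n_ref) + 0.5) / n_ref
    for j in range(n_samples):
        col = np.sort(X[~np.isnan(X[:, j]), j])
        if col.size == n_ref:
            sorted_cols[:, j] = col
        else:
            pos = (np.arange(col.size) + 0.5) / col.size
            sorted_cols[:, j] = np.interp(grid, pos, col)
    ref = sorted_cols.mean(axis=1)

    out = np.full_like(X, np.nan)
    for j in range(n_samples):
        obs = ~np.isnan(X[:, j])
        col = X[obs, j]
        m = col.size
        order = np.argsort(col, kind="mergesort")
        if full[j] and m == n_ref:
            mapped = np.empty(m)
            mapped[order] = ref
        else:
            pos = ((np.arange(m) + 0.5) / m) * n_ref - 0.5
            vals_sorted = np.interp(pos, np.arange(n_ref), ref)
            mapped = np.empty(m)
            mapped[order] = vals_sorted
        # Ties share the mean reference value over their rank span.
        uniq, inv = np.unique(col, return_inverse=True)
        if uniq.size < m:
            sums = np.bincount(inv, weights=mapped)
            cnts = np.bincount(inv)
            mapped = (sums / cnts)[inv]
        out[obs, j] = mapped
    return pd.DataFrame(out, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# Technical adjustment (control-probe PCA)
# ---------------------------------------------------------------------------

def control_probe_pcs(control_probes: pd.DataFrame, n_pcs: int) -> np.ndarray:
    """Sample-wise principal components of the control-probe matrix.

    Probes are mean-centred (not variance-scaled); PCs are the right
    singular vectors over samples.  Each PC's sign is fixed by making its
    largest-magnitude probe loading positive, for reproducibility.
    """
    C = control_probes.to_numpy(float)
    n_samples = C.shape[1]
    if n_pcs >= n_samples:
        raise ValueError(f"n_pcs={n_pcs} must be smaller than the number of samples ({n_samples})")
    Cc = C - C.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Cc, full_matrices=False)
    # keep only directions with real variance (degenerate controls -> none)
    tol = max(Cc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    k = min(n_pcs, int((s > tol).sum()))
    if k == 0:
        return np.empty((n_samples, 0))
    flip = np.sign(U[np.abs(U[:, :k]).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    return Vt[:k].T * flip


def _residualize(values: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Per-row OLS residuals of ``values`` (rows x samples) on design D.

    Samples with an incomplete design row are left missing in the output;
    rows with missing methylation are handled casewise per site.
    """
    out = np.full_like(values, np.nan)
    ok_cols = ~np.isnan(D).any(axis=1)
    Dv = D[ok_cols]
    sub = values[:, ok_cols]
    res = np.full_like(sub, np.nan)
    complete = ~np.isnan(sub).any(axis=1)
    if complete.any():
        coef, *_ = np.linalg.lstsq(Dv, sub[complete].T, rcond=None)
        res[complete] = sub[complete] - (Dv @ coef).T
    for i in np.flatnonzero(~complete):
        obs = ~np.isnan(sub[i])
        if obs.sum() <= Dv.shape[1] + 1:
            continue  # too few observations: left missing
        coef, *_ = np.linalg.lstsq(Dv[obs], sub[i, obs], rcond=None)
        res[i, obs] = sub[i, obs] - Dv[obs] @ coef
    out[:, ok_cols] = res
    return out


def technical_adjust(
    m_values: pd.DataFrame,
    control_probes: pd.DataFrame,
    batch_indicator=None,
    n_pcs: int = 20,
) -> pd.DataFrame:
    """Regress out control-probe PCs and a batch indicator from M-values.

    For each site, M is modelled by least squares on an intercept, the
    first ``n_pcs`` control-probe principal components and batch indicator
    dummies; the residuals are the technically adjusted values.
    """
    if not control_probes.columns.equals(m_values.columns):
        control_probes = control_probes.loc[:, m_values.columns]
    pcs = control_probe_pcs(control_probes, n_pcs)
    n_samples = m_values.shape[1]
    cols = [np.ones((n_samples, 1)), pcs]
    if batch_indicator is not None:
        batch = pd.Series(np.asarray(batch_indicator), index=m_values.columns)
        dummies = pd.get_dummies(batch, drop_first=True).to_numpy(float)
        if dummies.size:
            cols.append(dummies)
    D = np.hstack(cols)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        if batch_indicator is not None and len(cols) == 3:
            warnings.warn("batch indicator collinear with control-probe PCs; dropping batch term")
            D = np.hstack(cols[:2])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError("technical-adjustment design is rank deficient")
    resid = _residualize(m_values.to_numpy(float), D)
    return pd.DataFrame(resid, index=m_values.index, columns=m_values.columns)


# ---------------------------------------------------------------------------
# Outlier removal and confounder residualization
# ---------------------------------------------------------------------------

def remove_outliers(
    values: np.ndarray,
    covariate_design: np.ndarray,
    sd_threshold: float = 5.0,
    max_removed: int = 5,
) -> tuple[np.ndarray, int]:
    """Mask regression outliers in one site's value vector.

    Fits OLS of ``values`` on ``covariate_design`` (casewise-complete rows),
    computes the residual SD with denominator (n - rank), marks entries with
    |residual| > ``sd_threshold`` * SD, and removes at most ``max_removed``
    of them, largest |residual| first.  Single pass, no refit.

    Returns the masked copy (outliers as NaN) and the removal count.
    """
    y = np.asarray(values, float).copy()
    D = np.asarray(covariate_design, float)
    obs = ~np.isnan(y) & ~np.isnan(D).any(axis=1)
    rank = np.linalg.matrix_rank(D[obs]) if obs.any() else 0
    if obs.sum() < rank + 2:
        warnings.warn("too few observations for outlier screening; skipping")
        return y, 0
    coef, *_ = np.linalg.lstsq(D[obs], y[obs], rcond=None)
    resid = y[obs] - D[obs] @ coef
    sd = np.sqrt(resid @ resid / (obs.sum() - rank))
    if sd == 0:
        return y, 0
    extreme = np.abs(resid) > sd_threshold * sd
    idx_obs = np.flatnonzero(obs)
    cand = idx_obs[extreme]
    if cand.size > max_removed:
        order = np.argsort(-np.abs(resid[extreme]), kind="mergesort")
        cand = cand[order[:max_removed]]
    y[cand] = np.nan
    return y, int(cand.size)


def residualize_confounders(
    beta_values: pd.DataFrame, covariate_design: np.ndarray
) -> pd.DataFrame:
    """Per-site OLS residuals of beta values on the full confounder design.

    The design should already contain an intercept column; rank-deficient
    designs have aliased columns dropped with a warning.  Residuals are
    orthogonal to every retained design column.
    """
    D = np.asarray(covariate_design, float)
    ok_rows = ~np.isnan(D).any(axis=1)
    if np.linalg.matrix_rank(D[ok_rows]) < D.shape[1]:
        warnings.warn("rank-deficient confounder design; dropping aliased columns")
        q, r = np.linalg.qr(D[ok_rows])
        keep = np.abs(np.diag(r)) > 1e-10 * np.abs(np.diag(r)).max()
        D = D[:, keep]
    resid = _residualize(beta_values.to_numpy(float), D)
    return pd.DataFrame(resid, index=beta_values.index, columns=beta_values.columns)


# ---------------------------------------------------------------------------
# The full chain
# ---------------------------------------------------------------------------

def preprocess_pipeline(
    data: MethylationArraySet, n_pcs: int = 20
) -> tuple[MethylationArraySet, FilterReport]:
    """Run the fixed preprocessing chain on a raw beta-scale array set.

    Returns the technically adjusted M-value array set and the combined
    filter report.  Refuses input that is not on the beta scale.
    """
    if data.scale != "beta":
        raise ValueError(
            f"preprocess_pipeline expects raw beta-scale input, got scale={data.scale!r}; "
            "re-running on processed data is refused"
        )
    data, report = remove_snp_probes(data)
    data, r2 = apply_entry_filters(data)
    report = report.merge(r2)
    data, r3 = apply_site_filters(data)
    report = report.merge(r3)
    normed = quantile_normalize(data.values)
    m_vals = beta_to_m(normed)
    batch = data.sample_meta["batch"] if (data.sample_meta is not None
                                          and "batch" in data.sample_meta) else None
    n_pcs_eff = min(n_pcs, data.n_samples - 2, data.control_probes.shape[0] - 1)
    adjusted = technical_adjust(m_vals, data.control_probes, batch, n_pcs=n_pcs_eff)
    out = data.replace_values(adjusted, scale="M_adjusted")
    return out, report
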