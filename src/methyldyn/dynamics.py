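"""Fine-scale reversion statistics on confounder-residualized beta values.

From per-individual baseline-to-follow-up changes in methylation, computes
per-TSQ-bin medians per site, the across-site interquartile range of those
medians (the "dynamism" of methylation in a bin), the proportion of sites
whose median change opposes the baseline smoking effect (reversion toward
never-smoker levels), cross-sectional vs longitudinal coefficient
correlations, and the diverging/converging classification of group medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MethylationArraySet
from .association import EwasResult

REFERENCE_BINS = ("NS-NS", "CS-CS")


@dataclass
class DynamicsSummary:
    """Per-bin median-change summaries.

    ``median_change`` is sites x bins (beta-value units); bins are ordered
    TSQ intervals followed by the NS-NS and CS-CS reference bins.
    """

    median_change: pd.DataFrame
    n_per_bin: pd.Series
    bin_edges: dict = field(default_factory=dict)
    iqr_per_bin: pd.Series | None = None
    consistency_per_bin: pd.Series | None = None


def per_individual_delta(beta_resid: MethylationArraySet) -> pd.DataFrame:
    """Follow-up minus baseline change per site per individual.

    Entries are missing when either endpoint is missing; individuals with
    only one visit are excluded.
    """
    if beta_resid.sample_meta is None:
        raise ValueError("sample metadata with visit labels is required")
    meta = beta_resid.sample_meta
    s4 = meta.index[meta["visit"] == "S4"]
    f4 = meta.index[meta["visit"] == "F4"]
    iid_s4 = meta.loc[s4, "individual_id"]
    iid_f4 = meta.loc[f4, "individual_id"]
    common = pd.Index(iid_s4).intersection(pd.Index(iid_f4))
    if len(common) < len(set(iid_s4)) or len(common) < len(set(iid_f4)):
        missing = (set(iid_s4) ^ set(iid_f4))
        if missing:
            import logging
            logging.getLogger(__name__).info(
                "excluding %d individuals with a single visit", len(missing))
    s4_by_iid = pd.Series(s4, index=iid_s4).loc[common]
    f4_by_iid = pd.Series(f4, index=iid_f4).loc[common]
    base = beta_resid.values.loc[:, s4_by_iid.to_numpy()].to_numpy(float)
    follow = beta_resid.values.loc[:, f4_by_iid.to_numpy()].to_numpy(float)
    delta = follow - base
    return pd.DataFrame(delta, index=beta_resid.site_ids, columns=common)


def _two_year_bins(tsq: pd.Series, width: float = 2.0) -> tuple[pd.Series, dict]:
    """Half-open (low, high] bins of the given width over observed TSQ."""
    top = float(np.ceil(tsq.max() / width) * width)
    edges = np.arange(0.0, top + width, width)
    labels = [f"({edges[i]:g},{edges[i + 1]:g}]" for i in range(len(edges) - 1)]
    idx = np.clip(np.searchsorted(edges[1:], tsq.to_numpy(), side="left"),
                  0, len(labels) - 1)
    assigned = pd.Series([labels[i] for i in idx], index=tsq.index)
    return assigned, {lab: (edges[i], edges[i + 1]) for i, lab in enumerate(labels)}


def median_change_by_bin(
    deltas: pd.DataFrame,
    trajectories: pd.DataFrame,
    binning: str = "two_year",
) -> DynamicsSummary:
    """Median per-site change within TSQ bins and the reference groups.

    Former smokers are binned by TSQ at follow-up in half-open 2-year
    intervals (``two_year``) or by their TSQ_L category (``tsq_l``, which
    requires a ``tsq_category`` column); NS-NS and CS-CS are computed as
    reference bins.  Empty bins keep a column of missing medians.
    """
    traj = trajectories[trajectories["included"]]
    fs = traj[traj["category"].str.endswith("FS") & (traj["tsq_at_followup"] > 0)]
    if binning == "two_year":
        assigned, edges = _two_year_bins(fs["tsq_at_followup"])
        bin_order = list(edges)
    elif binning == "tsq_l":
        if "tsq_category" not in traj.columns:
            raise ValueError("tsq_l binning requires a 'tsq_category' column")
        fs = fs[fs["tsq_category"].notna()]
        assigned = fs["tsq_category"].map(lambda c: f"TSQ{int(c)}")
        bin_order = sorted(assigned.unique(), key=lambda s: int(s[3:]))
        edges = {}
    else:
        raise ValueError("binning must be 'two_year' or 'tsq_l'")

    groups = {lab: assigned.index[assigned == lab] for lab in bin_order}
    for ref in REFERENCE_BINS:
        groups[ref] = traj.index[traj["category"] == ref]

    cols, ns = {}, {}
    avail = deltas.columns
    for lab, iids in groups.items():
        members = avail.intersection(iids)
        ns[lab] = len(members)
        if len(members) == 0:
            cols[lab] = pd.Series(np.nan, index=deltas.index)
        else:
            cols[lab] = deltas.loc[:, members].median(axis=1, skipna=True)
    order = bin_order + list(REFERENCE_BINS)
    return DynamicsSummary(
        median_change=pd.DataFrame(cols)[order],
        n_per_bin=pd.Series(ns)[order],
        bin_edges=edges,
    )


def dynamism_iqr(summary: DynamicsSummary, min_sites: int = 4,
                 min_individuals: int = 10) -> pd.Series:
    """Across-site IQR (Q3 - Q1, linear-interpolation quantiles) per bin.

    Bins with fewer than ``min_sites`` sites of data, or fewer than
    ``min_individuals`` contributing individuals, are reported missing: a
    "median change" over a handful of people is dominated by individual
    noise and would make the across-bin comparison meaningless.
    """
    out = {}
    for lab in summary.median_change.columns:
        col = summary.median_change[lab].dropna()
        if len(col) < min_sites or summary.n_per_bin.get(lab, 0) < min_individuals:
            out[lab] = np.nan
        else:
            q1, q3 = np.quantile(col.to_numpy(), [0.25, 0.75])
            out[lab] = q3 - q1
    iqr = pd.Series(out)[summary.median_change.columns]
    summary.iqr_per_bin = iqr
    return iqr


def consistency_proportion(summary: DynamicsSummary, ewas: EwasResult) -> pd.Series:
    """Fraction of sites per bin whose median change opposes the EWAS effect.

    Sites with a zero median change (or missing EWAS coefficient) are
    excluded from both numerator and denominator.
    """
    coef = ewas.table["coef"].reindex(summary.median_change.index)
    missing = coef.isna()
    if missing.any():
        raise ValueError(
            f"{int(missing.sum())} sites in the summary lack an EWAS coefficient")
    out = {}
    for lab in summary.median_change.columns:
        med = summary.median_change[lab]
        usable = med.notna() & (med != 0)
        if usable.sum() == 0:
            out[lab] = np.nan
        else:
            out[lab] = float(
                (np.sign(med[usable]) == -np.sign(coef[usable])).mean())
    cons = pd.Series(out)[summary.median_change.columns]
    summary.consistency_per_bin = cons
    return cons


def coefficient_correlation(cross, longitudinal, subset=None) -> tuple[float, float]:
    """Spearman correlation between cross-sectional and longitudinal effects.

    Mid-rank ties; two-sided p from the t approximation.  ``subset`` is an
    optional boolean mask or index selecting the site pairs to use.
    """
    cross = pd.Series(cross)
    longitudinal = pd.Series(longitudinal)
    if subset is not None:
        cross, longitudinal = cross[subset], longitudinal[subset]
    ok = cross.notna() & longitudinal.notna()
    x, y = cross[ok].to_numpy(), longitudinal[ok].to_numpy()
    if x.size < 4:
        raise ValueError(f"need at least 4 paired coefficients, got {x.size}")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def classify_divergence(
    median_group_baseline: float, median_group_followup: float,
    median_ref_baseline: float, median_ref_followup: float,
) -> tuple[str | None, bool]:
    """Classify a site as diverging or converging between two groups.

    ``Div`` when the absolute gap between group medians grows from
    baseline to follow-up, ``Con`` when it shrinks; exact ties are
    labelled ``Con`` with the tie flag set.  Missing medians give
    (None, False).
    """
    vals = [median_group_baseline, median_group_followup,
            median_ref_baseline, median_ref_followup]
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
        return None, False
    gap_b = abs(median_group_baseline - median_ref_baseline)
    gap_f = abs(median_group_followup - median_ref_followup)
    if gap_f > gap_b:
        return "Div", False
    return "Con", gap_f == gap_b


def divergence_table(
    beta_resid: MethylationArraySet,
    trajectories: pd.DataFrame,
    group: str = "CS-CS",
    reference: str = "NS-NS",
    sites=None,
) -> pd.DataFrame:
    """Per-site Div/Con classification of ``group`` vs ``reference`` medians."""
    meta = beta_resid.sample_meta
    traj = trajectories[trajectories["included"]]
    sites = beta_resid.site_ids if sites is None else pd.Index(sites)

    def visit_median(cat, visit):
        iids = traj.index[traj["category"] == cat]
        cols = meta.index[(meta["visit"] == visit) & meta["individual_id"].isin(iids)]
        return beta_resid.values.loc[sites, cols].median(axis=1, skipna=True)

    gb, gf = visit_median(group, "S4"), visit_median(group, "F4")
    rb, rf = visit_median(reference, "S4"), visit_median(reference, "F4")
    labels, ties = [], []
    for s in sites:
        lab, tie = classify_divergence(gb[s], gf[s], rb[s], rf[s])
        labels.append(lab)
        ties.append(tie)
    return pd.DataFrame({"classification": labels, "tie": ties}, index=sites)
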