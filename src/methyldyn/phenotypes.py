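"""Smoking phenotype derivation: status, trajectories, TSQ, duration, intensity.

Works on the two-visit sample sheet (one row per individual-visit) and
derives, per individual, the baseline-to-follow-up trajectory category
(e.g. ``CS-FS``), time since quitting (TSQ) at follow-up, its sample-size
matched categorization (TSQ_L), smoking duration and intensity, and the
inclusion/exclusion flags for former smokers with unreliable histories.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STATUSES = ("CS", "FS", "NS")
OCCASIONAL_INTENSITY = 0.5  # cigarettes/day assumed for occasional smokers
CELL_PROPS = ("prop_mono", "prop_b", "prop_nk", "prop_cd4", "prop_cd8")

#: Fixed-mode TSQ_L breakpoints.  The first four interval bounds
#: ((0,4], (4,14], (14,21], (21,27]) follow the published category labels;
#: the remaining bounds are package defaults and configurable.
DEFAULT_FIXED_BREAKS = (0.0, 4.0, 14.0, 21.0, 27.0, 35.0, 45.0, np.inf)


# ---------------------------------------------------------------------------
# Record-level derivations
# ---------------------------------------------------------------------------

def classify_status(currently_smokes: bool, ever_smoked: bool,
                    occasional: bool = False,
                    cessation_age: float | None = None) -> tuple[str, float | None]:
    """Classify a questionnaire record into CS/FS/NS.

    Regular and occasional current smokers are CS (occasional smokers get
    an assumed intensity of 0.5 cigarettes/day); never smokers are NS;
    previous smokers who no longer smoke are FS.

    Returns (status, assumed_intensity_or_None).
    """
    if currently_smokes and not ever_smoked:
        raise ValueError("contradictory record: currently smoking but never smoked")
    if currently_smokes:
        if cessation_age is not None and not np.isnan(cessation_age):
            raise ValueError(
                f"contradictory record: cessation age {cessation_age} given while currently smoking"
            )
        return "CS", (OCCASIONAL_INTENSITY if occasional else None)
    if not ever_smoked:
        return "NS", None
    return "FS", None


def compute_tsq(cessation_age: float, interview_age: float) -> float:
    """Time since quitting: interview age minus cessation age (years).

    A value of 0 is arithmetically valid but not categorizable (TSQ
    categories cover the strictly positive range).
    """
    tsq = interview_age - cessation_age
    if tsq < 0:
        raise ValueError(
            f"negative TSQ: cessation age {cessation_age} after interview age {interview_age}"
        )
    return tsq


def compute_duration(init_age: float, end_age: float) -> float:
    """Smoking duration: initiation to interview (CS) or cessation (FS)."""
    duration = end_age - init_age
    if duration < 0:
        raise ValueError(
            f"negative duration: initiation age {init_age} after end age {end_age}"
        )
    return duration


def validate_former_smokers(
    tsq_baseline: float | None,
    tsq_followup: float | None,
    gap_years: float,
    baseline_status: str,
    followup_status: str,
    followup_cessation_age: float | None = None,
    baseline_interview_age: float | None = None,
    rule: str = "conjunctive",
) -> tuple[bool, str | None]:
    """Inclusion check for trajectories containing a former smoker.

    Exclusion reasons:

    * ``missing TSQ`` — an FS visit without a usable cessation age;
    * ``restart-requit`` — FS at both visits but the follow-up cessation
      age postdates the baseline interview (quit, restarted, quit again);
    * ``inconsistent TSQ`` — for FS-FS, the follow-up TSQ deviates from
      (baseline TSQ + gap) by more than 5 years AND more than 20% of the
      expected value.  ``rule='disjunctive'`` turns the AND into OR for
      sensitivity analysis.

    Returns (included, reason).
    """
    def nanish(x):
        return x is None or (isinstance(x, float) and np.isnan(x))

    if followup_status == "FS" and nanish(tsq_followup):
        return False, "missing TSQ"
    if baseline_status == "FS" and nanish(tsq_baseline):
        return False, "missing TSQ"
    if (baseline_status == "FS" and followup_status == "FS"
            and followup_cessation_age is not None and baseline_interview_age is not None
            and not nanish(followup_cessation_age) and not nanish(baseline_interview_age)
            and followup_cessation_age > baseline_interview_age):
        return False, "restart-requit"
    if baseline_status == "FS" and followup_status == "FS":
        expected = tsq_baseline + gap_years
        deviation = abs(tsq_followup - expected)
        big_years = deviation > 5.0
        big_frac = deviation > 0.2 * expected
        inconsistent = (big_years and big_frac) if rule == "conjunctive" else (big_years or big_frac)
        if inconsistent:
            return False, "inconsistent TSQ"
    return True, None


# ---------------------------------------------------------------------------
# TSQ categorization
# ---------------------------------------------------------------------------

def assign_tsq_categories(
    tsq_values, k: int = 7, mode: str = "matched", breaks=None
) -> tuple[np.ndarray, np.ndarray]:
    """Categorize strictly positive TSQ values into k half-open bins.

    ``matched`` mode chooses integer-year breakpoints greedily so category
    counts are as equal as possible (ties resolved toward the earlier
    boundary); ``fixed`` mode uses supplied breakpoints (default
    :data:`DEFAULT_FIXED_BREAKS`).  TSQ values are rounded half-up to
    integer years before categorization, matching integer-reported
    questionnaire ages.  Intervals are (low, high].

    Returns (labels 1..k, breakpoints array of length k+1 starting at 0).
    """
    tsq = np.asarray(tsq_values, float)
    if np.any(np.isnan(tsq)) or np.any(tsq <= 0):
        raise ValueError("TSQ values must be strictly positive and non-missing")
    rounded = np.floor(tsq + 0.5)  # round half up

    if mode == "fixed":
        edges = np.asarray(DEFAULT_FIXED_BREAKS if breaks is None else breaks, float)
        if len(edges) < 3:
            raise ValueError("need at least two categories' worth of breakpoints")
    elif mode == "matched":
        uniq = np.unique(rounded)
        if uniq.size < k:
            raise ValueError(
                f"cannot form {k} categories from {uniq.size} distinct integer TSQ values"
            )
        counts = pd.Series(rounded).value_counts().sort_index()
        cum = counts.cumsum()
        n = rounded.size
        edges = [0.0]
        for i in range(1, k):
            target = i * n / k
            # candidate boundaries must leave room for the remaining categories
            avail = cum.index.to_numpy()
            lo_ok = avail > edges[-1]
            hi_ok = avail <= uniq[-(k - i)]
            cand = avail[lo_ok & hi_ok]
            dist = np.abs(cum.loc[cand].to_numpy() - target)
            edges.append(float(cand[int(np.argmin(dist))]))  # argmin: earliest tie
        edges.append(np.inf)
        edges = np.asarray(edges)
    else:
        raise ValueError("mode must be 'matched' or 'fixed'")

    labels = np.searchsorted(edges[1:-1], rounded, side="left") + 1
    if labels.max() > len(edges) - 1:
        raise ValueError("TSQ values exceed the final breakpoint")
    return labels.astype(int), edges


# ---------------------------------------------------------------------------
# Trajectory table
# ---------------------------------------------------------------------------

def derive_trajectories(sample_sheet: pd.DataFrame, rule: str = "conjunctive") -> pd.DataFrame:
    """Build the per-individual trajectory table from the sample sheet.

    Columns: ``category`` (e.g. ``CS-FS``), ``tsq_at_followup``,
    ``duration_S4``/``duration_F4``, ``intensity_S4``/``intensity_F4``,
    ``gap_years``, ``included`` and ``exclusion_reason``.  TSQ categories
    are assigned separately (see :func:`assign_tsq_categories`) because
    breakpoints depend on the included set.
    """
    s4 = sample_sheet[sample_sheet["visit"] == "S4"].set_index("individual_id")
    f4 = sample_sheet[sample_sheet["visit"] == "F4"].set_index("individual_id")
    common = s4.index.intersection(f4.index)
    s4, f4 = s4.loc[common], f4.loc[common]

    rows = []
    for iid in common:
        b, f = s4.loc[iid], f4.loc[iid]
        gap = f["interview_age"] - b["interview_age"]
        category = f"{b['smoking_status']}-{f['smoking_status']}"

        def tsq_of(rec):
            if rec["smoking_status"] != "FS" or pd.isna(rec["cessation_age"]):
                return np.nan
            return compute_tsq(rec["cessation_age"], rec["interview_age"])

        tsq_b, tsq_f = tsq_of(b), tsq_of(f)

        def duration_of(rec):
            if rec["smoking_status"] == "NS" or pd.isna(rec["init_age"]):
                return np.nan
            end = rec["interview_age"] if rec["smoking_status"] == "CS" else rec["cessation_age"]
            if pd.isna(end):
                return np.nan
            return compute_duration(rec["init_age"], end)

        included, reason = True, None
        if "FS" in (b["smoking_status"], f["smoking_status"]):
            included, reason = validate_former_smokers(
                tsq_b, tsq_f, gap, b["smoking_status"], f["smoking_status"],
                followup_cessation_age=f["cessation_age"],
                baseline_interview_age=b["interview_age"],
                rule=rule,
            )
        rows.append({
            "individual_id": iid,
            "category": category,
            "tsq_at_followup": tsq_f,
            "gap_years": gap,
            "duration_S4": duration_of(b),
            "duration_F4": duration_of(f),
            "intensity_S4": b["cigs_per_day"],
            "intensity_F4": f["cigs_per_day"],
            "included": included,
            "exclusion_reason": reason,
        })
    out = pd.DataFrame(rows).set_index("individual_id")
    return out


def add_tsq_categories(
    trajectories: pd.DataFrame, k: int = 7, mode: str = "matched", breaks=None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assign TSQ_L categories to included FS trajectories.

    Only included trajectories ending FS with a strictly positive TSQ are
    categorized; everyone else gets a missing category.  Returns the
    augmented table and the breakpoints used.
    """
    out = trajectories.copy()
    eligible = (
        out["included"]
        & out["category"].str.endswith("FS")
        & (out["tsq_at_followup"] > 0)
    )
    out["tsq_category"] = np.nan
    if eligible.sum() == 0:
        return out, np.array([])
    labels, edges = assign_tsq_categories(
        out.loc[eligible, "tsq_at_followup"].to_numpy(), k=k, mode=mode, breaks=breaks
    )
    out.loc[eligible, "tsq_category"] = labels
    return out, edges
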