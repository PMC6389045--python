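import numpy as np
import pandas as pd
import pytest

import methyldyn as md
from methyldyn.phenotypes import CELL_PROPS
from methyldyn.simulate import SHEET_COLUMNS


@pytest.fixture(scope="session")
def small_cfg():
    return md.SimulationConfig(n_individuals=150, n_sites=150,
                               n_affected_sites=12, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return md.simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def adjusted_cohort(small_cohort):
    """Preprocessed (technically adjusted M) version of the small cohort."""
    phenos, mars, effects = small_cohort
    adjusted, report = md.preprocess_pipeline(mars, n_pcs=10)
    return phenos, adjusted, effects, report


@pytest.fixture(scope="session")
def decay_cohort():
    """Cohort where every affected site reverts exponentially after quitting."""
    cfg = md.SimulationConfig(n_individuals=400, n_sites=120, n_affected_sites=60,
                              persistent_fraction=0.0, seed=29)
    return cfg, md.simulate_cohort(cfg)


def manual_sheet(statuses, tsq=None, seed=0, gap=7.0, age=55.0):
    """Hand-built two-visit sample sheet with identical covariates.

    ``statuses`` is a list of (baseline, followup) status pairs; ``tsq``
    optionally fixes the follow-up TSQ of every FS individual.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, (sb, sf) in enumerate(statuses):
        iid = f"I{i:05d}"
        for visit, status in (("S4", sb), ("F4", sf)):
            a = age if visit == "S4" else age + gap
            cess = np.nan
            if status == "FS":
                t = tsq if tsq is not None else 10.0
                t_here = t if visit == "F4" else max(t - gap, 0.5)
                cess = a - t_here
            row = {
                "individual_id": iid, "visit": visit, "interview_age": a,
                "sex": 0, "bmi": 27.0, "alcohol_g_day": 10.0, "wbc_count": 6.0,
                **{c: v for c, v in zip(CELL_PROPS, (0.08, 0.04, 0.06, 0.15, 0.10))},
                "smoking_status": status,
                "init_age": np.nan if status == "NS" else 18.0,
                "cessation_age": cess,
                "true_cessation_age": cess,
                "cigs_per_day": 15.0 if status == "CS" else np.nan,
                "batch": int(rng.integers(0, 2)),
            }
            rows.append(row)
    sheet = pd.DataFrame(rows)
    sheet.index = pd.Index(
        [f"{r['individual_id']}_{r['visit']}" for r in rows], name="sample_id")
    return sheet
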