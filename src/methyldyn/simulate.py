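"""Synthetic two-visit smoking/methylation cohort generator.

Generates a seeded cohort with the statistical structure a longitudinal
smoking EWAS assumes: two visits roughly seven years apart, current/former/
never smoker (CS/FS/NS) trajectories, site-level smoking effects on the
M-value scale that decay exponentially with time since quitting (TSQ) at
reversible sites, confounder effects, per-individual random intercepts,
batch structure expressed in control probes, and planted missingness and
outliers.  Everything downstream of the generator is testable without any
external data set.

The latent model per site ``s``, individual ``i``, visit ``j`` is::

    M_sij = baseline_s + covariate effects + mu_si + smoking term
            + batch shift + eps_sij

with the smoking term ``delta_s * (1 + slope * (cigs - 15))`` for current
smokers and ``delta_s * exp(-TSQ_ij / tau)`` for former smokers at
reversible sites (no decay at persistent sites).  Beta values are the
inverse logit (base 2) of M.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .containers import MethylationArraySet
from .phenotypes import CELL_PROPS

VISITS = ("S4", "F4")
SHEET_COLUMNS = [
    "individual_id", "visit", "interview_age", "sex", "bmi", "alcohol_g_day",
    "wbc_count", *CELL_PROPS, "smoking_status", "init_age", "cessation_age",
    "cigs_per_day", "batch",
]

_CELL_ALPHA = np.array([4.8, 2.4, 3.6, 9.0, 6.0, 34.2])  # mono,B,NK,CD4,CD8,rest
_CIG_REFERENCE = 15.0  # cigarettes/day at which the intensity modifier is 1
_CONTROL_NOISE_SD = 50.0
_CONTROL_BATCH_SD = 150.0
_TSQ_MAX = 70.0


@dataclass
class TrueEffects:
    """Ground truth planted by the generator.

    Attributes
    ----------
    delta
        Per-site smoking effect on the M scale (0 at unaffected sites).
    decay
        Per-site flag: ``reversible``, ``persistent`` or ``none``.
    mu0
        Sites x individuals matrix of random intercepts.  Intercepts are
        drawn independently per site so that per-site model fits are
        independent across sites, matching the per-site analysis model.
    batch
        Per-sample batch assignment.
    """

    delta: pd.Series
    decay: pd.Series
    mu0: pd.DataFrame
    batch: pd.Series

    def write(self, path: str | Path) -> None:
        truth = pd.DataFrame({"delta": self.delta, "decay_flag": self.decay})
        truth.index.name = "site"
        truth.to_csv(path, sep="\t")


def _draw_statuses(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    props = config.status_proportions
    counts = {}
    remaining = config.n_individuals
    for status in ("CS", "FS"):
        counts[status] = int(round(config.n_individuals * props.get(status, 0.0)))
        remaining -= counts[status]
    counts["NS"] = remaining
    for status, k in counts.items():
        if props.get(status, 0.0) > 0 and k < 2:
            raise ValueError(
                f"status_proportions give only {k} {status} individuals; need >= 2 per represented status"
            )
        if k < 0:
            raise ValueError("status_proportions are inconsistent with n_individuals")
    pool = np.repeat(["CS", "FS", "NS"], [counts["CS"], counts["FS"], counts["NS"]])
    return rng.permutation(pool)


def _cell_proportions(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.dirichlet(_CELL_ALPHA, size=n)[:, :5]


def simulate_smoking_histories(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the two-visit sample sheet (one row per individual-visit).

    Returns a DataFrame with the columns of :data:`SHEET_COLUMNS` plus a
    ``sample_id`` index and a ``true_cessation_age`` helper column (the
    uncorrupted history that drives the methylation model; the reported
    ``cessation_age`` may be corrupted for a small fraction of former
    smokers to exercise the exclusion rules).
    """
    rng = np.random.default_rng([config.seed, 11])
    n = config.n_individuals
    status_b = _draw_statuses(rng, config)
    iids = np.array([f"I{i:05d}" for i in range(n)])

    age_mean = np.where(status_b == "CS", 51.0, 55.0)
    age_b = np.clip(rng.normal(age_mean, 8.5), 30.0, 78.0)
    male_p = np.select([status_b == "CS", status_b == "FS"], [0.57, 0.64], default=0.35)
    sex = (rng.random(n) < male_p).astype(int)
    bmi_b = np.clip(rng.normal(27.5, 4.5), 16.0, 45.0)
    alcohol_b = np.abs(rng.normal(0.0, 20.0, n))
    wbc_b = np.clip(rng.normal(6.0, 1.5, n), 2.5, 15.0)
    cells_b = _cell_proportions(rng, n)

    gap = rng.uniform(config.visit_gap_years - config.visit_gap_jitter,
                      config.visit_gap_years + config.visit_gap_jitter, n)
    age_f = age_b + gap

    ever = status_b != "NS"
    init_age = np.where(ever, np.minimum(rng.uniform(15.0, 25.0, n), age_b - 6.0), np.nan)

    # Baseline TSQ for baseline former smokers; capped so follow-up TSQ <= 70.
    tsq_cap = np.minimum(age_b - init_age - 1.0, _TSQ_MAX - gap - 0.5)
    tsq_b = np.clip(np.abs(rng.normal(20.0, 12.0, n)), 0.5, np.maximum(tsq_cap, 0.5))
    cess_b = np.where(status_b == "FS", age_b - tsq_b, np.nan)

    cigs_b = np.clip(rng.gamma(2.0, 7.5, n), 1.0, 60.0)
    occasional = rng.random(n) < config.occasional_fraction
    cigs_b = np.where(occasional, 0.5, cigs_b)
    cigs_b = np.where(status_b == "CS", cigs_b, np.nan)

    # Follow-up transitions: a baseline CS quits before follow-up with
    # per-year probability quit_rate; FS and NS keep their status.
    status_f = status_b.copy()
    quit_p = 1.0 - (1.0 - config.quit_rate) ** gap
    quits = (status_b == "CS") & (rng.random(n) < quit_p)
    status_f[quits] = "FS"
    cess_true_f = np.where(status_f == "FS", cess_b, np.nan)
    new_cess = rng.uniform(age_b + 0.5, age_f - 0.25)
    cess_true_f = np.where(quits, new_cess, cess_true_f)

    cigs_f = np.clip(cigs_b + rng.normal(-1.5, 3.0, n), 0.5, 60.0)
    cigs_f = np.where(occasional, 0.5, cigs_f)
    cigs_f = np.where(status_f == "CS", cigs_f, np.nan)

    # Reported follow-up cessation age starts from the true history, then a
    # small fraction of stable FS-FS is corrupted (inconsistent TSQ) or given
    # a quit/restart/requit signature (cessation after the baseline visit).
    cess_rep_f = cess_true_f.copy()
    stable_fs = (status_b == "FS") & (status_f == "FS")
    u = rng.random(n)
    inconsistent = stable_fs & (u < config.inconsistent_fs_fraction)
    restart = stable_fs & ~inconsistent & (
        u < config.inconsistent_fs_fraction + config.restart_fraction
    )
    shift = np.maximum(6.0, 0.3 * (tsq_b + gap))
    cess_rep_f = np.where(
        inconsistent,
        np.maximum(init_age + 0.5, np.maximum(cess_true_f - shift, age_f - _TSQ_MAX)),
        cess_rep_f,
    )
    cess_rep_f = np.where(restart, rng.uniform(age_b + 0.5, age_f - 0.5), cess_rep_f)

    bmi_f = np.clip(bmi_b + rng.normal(0.35, 1.2, n), 16.0, 45.0)
    alcohol_f = np.abs(0.85 * alcohol_b + rng.normal(0.0, 6.0, n))
    wbc_f = np.clip(wbc_b + rng.normal(0.0, 0.8, n), 2.5, 15.0)
    cells_f = 0.7 * cells_b + 0.3 * _cell_proportions(rng, n)

    batch = rng.integers(0, config.n_batches, size=2 * n)

    def visit_frame(visit, age, bmi, alcohol, wbc, cells, status, cess_rep, cess_true, cigs):
        df = pd.DataFrame({
            "individual_id": iids,
            "visit": visit,
            "interview_age": age,
            "sex": sex,
            "bmi": bmi,
            "alcohol_g_day": alcohol,
            "wbc_count": wbc,
            **{c: cells[:, k] for k, c in enumerate(CELL_PROPS)},
            "smoking_status": status,
            "init_age": init_age,
            "cessation_age": cess_rep,
            "true_cessation_age": cess_true,
            "cigs_per_day": cigs,
        })
        df.index = pd.Index([f"{i}_{visit}" for i in iids], name="sample_id")
        return df

    s4 = visit_frame("S4", age_b, bmi_b, alcohol_b, wbc_b, cells_b,
                     status_b, cess_b, cess_b, cigs_b)
    f4 = visit_frame("F4", age_f, bmi_f, alcohol_f, wbc_f, cells_f,
                     status_f, cess_rep_f, cess_true_f, cigs_f)
    sheet = pd.concat([s4, f4])
    sheet["batch"] = batch
    return sheet


def _site_annotation(rng: np.random.Generator, config: SimulationConfig) -> pd.DataFrame:
    m = config.n_sites
    site_ids = [f"cg{i:08d}" for i in range(m)]
    chroms = rng.integers(1, 23, size=m).astype(object)
    n_sex = int(round(config.sex_chrom_fraction * m))
    n_snp = int(round(config.snp_probe_fraction * m))
    special = rng.choice(m, size=n_sex + n_snp, replace=False)
    sex_idx, snp_idx = special[:n_sex], special[n_sex:]
    chroms[sex_idx] = rng.choice(["X", "Y"], size=n_sex)
    snp = np.zeros(m, bool)
    snp[snp_idx] = True
    ann = pd.DataFrame(
        {"chromosome": [str(c) for c in chroms],
         "gene": [f"GENE{i % max(m // 3, 1):05d}" for i in range(m)],
         "snp_probe": snp},
        index=pd.Index(site_ids, name="site"),
    )
    return ann


def m_from_beta(beta):
    return np.log2(beta / (1.0 - beta))


def beta_from_m(m):
    return 1.0 / (1.0 + np.exp2(-np.asarray(m, float)))


def simulate_methylation(
    phenos: pd.DataFrame, config: SimulationConfig
) -> tuple[MethylationArraySet, TrueEffects]:
    """Simulate the methylation array set implied by a sample sheet.

    Returns the beta-scale :class:`MethylationArraySet` (with detection-p,
    bead-count and control-probe companions) and the planted
    :class:`TrueEffects`.
    """
    rng = np.random.default_rng([config.seed, 23])
    ann = _site_annotation(rng, config)
    m_sites = config.n_sites
    samples = phenos.index.to_numpy()
    n_samples = len(samples)
    iids = phenos["individual_id"].to_numpy()
    uniq_iids, indiv_idx = np.unique(iids, return_inverse=True)

    # Planted smoking effects, restricted to autosomal non-SNP sites so the
    # standard probe filters never discard them.
    eligible = np.flatnonzero(~ann["snp_probe"].to_numpy()
                              & ~ann["chromosome"].isin(["X", "Y"]).to_numpy())
    affected = rng.choice(eligible, size=min(config.n_affected_sites, eligible.size),
                          replace=False)
    delta = np.zeros(m_sites)
    raw = rng.normal(config.effect_size_loc, config.effect_size_scale, affected.size)
    sign = np.where(raw == 0, -1.0, np.sign(raw))
    delta[affected] = sign * np.maximum(np.abs(raw), config.effect_size_min_abs)
    decay = np.array(["none"] * m_sites, dtype=object)
    persistent = rng.random(affected.size) < config.persistent_fraction
    decay[affected] = np.where(persistent, "persistent", "reversible")

    # Bimodal baseline M-values, as on real arrays.
    u = rng.random(m_sites)
    baseline = np.where(u < 0.45, rng.normal(-3.0, 0.8, m_sites),
                        np.where(u < 0.9, rng.normal(3.0, 0.8, m_sites),
                                 rng.normal(0.0, 1.2, m_sites)))

    # Covariate effects on centred/scaled covariates.
    scales = config.confounder_effect_scales
    cov_cols = ["interview_age", "sex", "bmi", "alcohol_g_day", "wbc_count", *CELL_PROPS]
    cov_sd = [scales["age"], scales["sex"], scales["bmi"], scales["alcohol_g_day"],
              scales["wbc_count"]] + [scales["cellprop"]] * 5
    X = phenos[cov_cols].to_numpy(float)
    Xc = X - X.mean(axis=0)
    coef = rng.normal(0.0, 1.0, (m_sites, Xc.shape[1])) * np.asarray(cov_sd)

    # Smoking term factors per sample, for reversible and persistent sites.
    status = phenos["smoking_status"].to_numpy()
    cigs = phenos["cigs_per_day"].to_numpy(float)
    tsq = (phenos["interview_age"] - phenos["true_cessation_age"]).to_numpy(float)
    g_cs = 1.0 + config.intensity_slope * (np.nan_to_num(cigs, nan=_CIG_REFERENCE) - _CIG_REFERENCE)
    g_rev = np.zeros(n_samples)
    g_pers = np.zeros(n_samples)
    is_cs, is_fs = status == "CS", status == "FS"
    g_rev[is_cs] = g_cs[is_cs]
    g_pers[is_cs] = g_cs[is_cs]
    g_rev[is_fs] = np.exp(-np.clip(tsq[is_fs], 0.0, None) / config.decay_timescale)
    g_pers[is_fs] = 1.0
    G = np.where((decay == "persistent")[:, None], g_pers[None, :], g_rev[None, :])

    mu0 = rng.normal(0.0, config.sigma_mu, (m_sites, uniq_iids.size))
    batch = phenos["batch"].to_numpy()
    gamma = rng.normal(0.0, config.batch_m_sd * config.batch_shift_scale,
                       (m_sites, config.n_batches))
    eps = rng.normal(0.0, config.sigma_eps, (m_sites, n_samples))

    M = (baseline[:, None] + coef @ Xc.T + mu0[:, indiv_idx]
         + delta[:, None] * G + gamma[:, batch] + eps)

    # Planted gross outliers: displacement of at least 6 total SDs.
    total_sd = np.sqrt(config.sigma_mu**2 + config.sigma_eps**2)
    n_out = int(round(config.outlier_rate * M.size))
    if n_out and total_sd > 0:
        flat = rng.choice(M.size, size=n_out, replace=False)
        displ = rng.choice([-1.0, 1.0], n_out) * (6.0 + rng.exponential(2.0, n_out)) * total_sd
        M.flat[flat] += displ

    beta = beta_from_m(M)
    values = pd.DataFrame(beta, index=ann.index, columns=samples)

    detection_p = rng.uniform(0.0, 0.005, (m_sites, n_samples))
    fail = rng.random((m_sites, n_samples)) < config.missing_rate
    detection_p[fail] = rng.uniform(0.01, 1.0, int(fail.sum()))
    beads = rng.poisson(14.0, (m_sites, n_samples)) + 4
    bead_fail = rng.random((m_sites, n_samples)) < config.bead_fail_rate
    beads[bead_fail] = rng.integers(0, 4, int(bead_fail.sum()))

    probe_mean = rng.uniform(2000.0, 8000.0, config.n_control_probes)
    ctrl_shift = rng.normal(0.0, _CONTROL_BATCH_SD * config.batch_shift_scale,
                            (config.n_control_probes, config.n_batches))
    control = (probe_mean[:, None] + ctrl_shift[:, batch]
               + rng.normal(0.0, _CONTROL_NOISE_SD, (config.n_control_probes, n_samples)))
    control_df = pd.DataFrame(
        control, columns=samples,
        index=pd.Index([f"ctrl{i:04d}" for i in range(config.n_control_probes)], name="probe"),
    )

    meta = phenos[["individual_id", "visit", "batch"]].copy()
    mars = MethylationArraySet(
        values=values,
        scale="beta",
        detection_p=pd.DataFrame(detection_p, index=ann.index, columns=samples),
        beads=pd.DataFrame(beads, index=ann.index, columns=samples),
        sample_meta=meta,
        control_probes=control_df,
        annotation=ann,
    )
    effects = TrueEffects(
        delta=pd.Series(delta, index=ann.index, name="delta"),
        decay=pd.Series(decay, index=ann.index, name="decay_flag"),
        mu0=pd.DataFrame(mu0, index=ann.index, columns=uniq_iids),
        batch=pd.Series(batch, index=phenos.index, name="batch"),
    )
    return mars, effects


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, MethylationArraySet, TrueEffects]:
    """Convenience wrapper: sample sheet plus methylation in one call."""
    phenos = simulate_smoking_histories(config)
    mars, effects = simulate_methylation(phenos, config)
    return phenos, mars, effects


def write_cohort(outdir: str | Path, phenos: pd.DataFrame,
                 mars: MethylationArraySet, effects: TrueEffects) -> None:
    """Write the cohort as the delimited text layout shared by all stages."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phenos.to_csv(outdir / "sample_sheet.csv")
    mars.values.to_csv(outdir / "beta.tsv", sep="\t")
    mars.detection_p.to_csv(outdir / "detection_p.tsv", sep="\t")
    mars.beads.to_csv(outdir / "beads.tsv", sep="\t")
    mars.control_probes.to_csv(outdir / "control_probes.tsv", sep="\t")
    mars.annotation.to_csv(outdir / "annotation.csv")
    effects.write(outdir / "truth.tsv")


def read_cohort(indir: str | Path) -> tuple[pd.DataFrame, MethylationArraySet]:
    """Read a cohort previously written by :func:`write_cohort`."""
    indir = Path(indir)
    phenos = pd.read_csv(indir / "sample_sheet.csv", index_col=0)
    values = pd.read_csv(indir / "beta.tsv", sep="\t", index_col=0)
    detection = pd.read_csv(indir / "detection_p.tsv", sep="\t", index_col=0)
    beads = pd.read_csv(indir / "beads.tsv", sep="\t", index_col=0)
    control = pd.read_csv(indir / "control_probes.tsv", sep="\t", index_col=0)
    ann = pd.read_csv(indir / "annotation.csv", index_col=0)
    ann["chromosome"] = ann["chromosome"].astype(str)
    meta = phenos[["individual_id", "visit", "batch"]].copy()
    mars = MethylationArraySet(values=values, scale="beta", detection_p=detection,
                               beads=beads, sample_meta=meta,
                               control_probes=control, annotation=ann)
    return phenos, mars
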