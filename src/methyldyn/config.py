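"""Configuration objects for the synthetic cohort generator and pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


def _default_status_proportions() -> dict:
    # Baseline CS/FS/NS counts of 280/449/615 in a cohort of 1344.
    return {"CS": 280 / 1344, "FS": 449 / 1344, "NS": 615 / 1344}


def _default_confounder_scales() -> dict:
    # Per-covariate SD of the per-site regression coefficient, M-value units
    # per unit of the covariate.  Cell-type proportions dominate, as they do
    # in whole-blood methylation.
    return {
        "age": 0.005,
        "sex": 0.05,
        "bmi": 0.008,
        "alcohol_g_day": 0.002,
        "wbc_count": 0.02,
        "cellprop": 0.8,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-visit smoking/methylation cohort.

    Defaults emulate a population cohort of middle-aged adults genotyped on
    a 450K-style array at two visits roughly seven years apart, with
    current/former/never smoker (CS/FS/NS) baseline proportions of about
    21/33/46%.

    Attributes
    ----------
    n_individuals, n_sites, n_affected_sites
        Cohort and array sizes; ``n_affected_sites`` sites receive a nonzero
        smoking effect ``delta`` on the M-value scale.
    visit_gap_years, visit_gap_jitter
        Mean gap between visits and the half-width of its uniform jitter.
    status_proportions
        Baseline CS/FS/NS fractions (must sum to 1).
    quit_rate
        Per-year probability that a baseline current smoker quits before
        the follow-up visit.
    effect_size_loc, effect_size_scale
        Normal location/scale of the per-site smoker effect ``delta`` in
        M-value units (smoking predominantly lowers methylation, hence a
        negative default location).
    decay_timescale
        Exponential timescale tau (years) of post-cessation reversion of the
        smoking effect at reversible sites.
    persistent_fraction
        Fraction of affected sites whose effect does not decay.
    intensity_slope
        Relative modulation of the smoker effect per cigarette/day away
        from the 15/day reference.
    confounder_effect_scales
        SDs of per-site covariate coefficients (see module docs).
    sigma_mu, sigma_eps
        SD of the individual random intercept and of the residual, M units.
    n_batches, batch_shift_scale, batch_m_sd
        Technical batch structure: number of batches, the magnitude of the
        additive per-probe batch shift expressed in the control probes, and
        the SD of the per-(site, batch) shift on M-values.  Both shifts are
        scaled by ``batch_shift_scale`` so 0 switches batch effects off.
    missing_rate, bead_fail_rate, outlier_rate
        Rates of planted detection failures (p >= 0.01), low bead counts
        (<= 3 beads) and gross outliers (>= 6 SD displacement).
    occasional_fraction
        Fraction of current smokers who are occasional smokers (recorded
        as 0.5 cigarettes/day).
    inconsistent_fs_fraction, restart_fraction
        Fractions of stable former smokers given a corrupted follow-up
        cessation age, or a quit/restart/requit history, to exercise the
        exclusion rules.
    snp_probe_fraction, sex_chrom_fraction
        Fractions of sites flagged as SNP probes or placed on chrX/chrY
        (affected sites are always autosomal non-SNP).
    n_control_probes
        Number of quality-control probes.
    seed
        Seed of the single generator driving all randomness.
    """

    n_individuals: int = 600
    n_sites: int = 1000
    n_affected_sites: int = 50
    visit_gap_years: float = 7.0
    visit_gap_jitter: float = 0.5
    status_proportions: dict = field(default_factory=_default_status_proportions)
    quit_rate: float = 0.06
    effect_size_loc: float = -0.8
    effect_size_scale: float = 0.4
    effect_size_min_abs: float = 0.3
    decay_timescale: float = 10.0
    persistent_fraction: float = 0.2
    intensity_slope: float = 0.02
    confounder_effect_scales: dict = field(default_factory=_default_confounder_scales)
    sigma_mu: float = 0.25
    sigma_eps: float = 0.25
    n_batches: int = 2
    batch_shift_scale: float = 1.0
    batch_m_sd: float = 0.2
    missing_rate: float = 0.005
    bead_fail_rate: float = 0.002
    outlier_rate: float = 0.001
    occasional_fraction: float = 0.05
    inconsistent_fs_fraction: float = 0.02
    restart_fraction: float = 0.01
    snp_probe_fraction: float = 0.01
    sex_chrom_fraction: float = 0.03
    n_control_probes: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_sites", "n_control_probes", "n_batches"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.n_affected_sites <= self.n_sites:
            raise ValueError("n_affected_sites must lie in [0, n_sites]")
        total = sum(self.status_proportions.get(k, 0.0) for k in ("CS", "FS", "NS"))
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"status_proportions must sum to 1 (got {total})")
        if self.decay_timescale <= 0:
            raise ValueError("decay_timescale must be positive")
        if self.sigma_mu < 0 or self.sigma_eps < 0:
            raise ValueError("variance-component SDs must be non-negative")
        for name in (
            "quit_rate", "missing_rate", "bead_fail_rate", "outlier_rate",
            "occasional_fraction", "inconsistent_fs_fraction", "restart_fraction",
            "snp_probe_fraction", "sex_chrom_fraction", "persistent_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1] (got {v})")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (see the ``pipeline`` module)."""

    outdir: str = "methyldyn_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    alpha: float = 0.05
    n_pcs: int = 20
    outlier_sd: float = 5.0
    max_outliers_per_site: int = 5
    n_tsq_categories: int = 7
    tsq_category_mode: str = "matched"
    binning: str = "two_year"
    df_method: str = "satterthwaite"
    heatmap_threshold: float = 0.025
    threads: int = 1

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)
        elif isinstance(self.simulation, dict):
            self.simulation = SimulationConfig.from_dict(self.simulation)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.binning not in ("two_year", "tsq_l"):
            raise ValueError("binning must be 'two_year' or 'tsq_l'")
        if self.df_method not in ("satterthwaite", "normal"):
            raise ValueError("df_method must be 'satterthwaite' or 'normal'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
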