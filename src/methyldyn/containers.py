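"""In-memory containers for array-style methylation data.

The central object is :class:`MethylationArraySet`, a sites x samples value
matrix with its detection-p and bead-count companions, per-sample metadata
(visit, batch), a control-probe intensity matrix and a per-site annotation
table.  Every preprocessing stage consumes one and returns a transformed
copy; the ``scale`` tag records where in the pipeline the values stand.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Allowed value scales, in pipeline order.
SCALES = ("beta", "M", "M_adjusted", "beta_residualized")


@dataclass
class MethylationArraySet:
    """Sites x samples methylation values with companions.

    Parameters
    ----------
    values
        DataFrame indexed by site ID with one column per sample ID.
    scale
        One of ``beta``, ``M``, ``M_adjusted``, ``beta_residualized``.
    detection_p
        Same-shape detection p-values in [0, 1] (optional after filtering).
    beads
        Same-shape non-negative bead counts (optional after filtering).
    sample_meta
        One row per sample: at least ``individual_id``, ``visit`` and
        ``batch`` columns, indexed by sample ID.
    control_probes
        Control-probes x samples intensity matrix.
    annotation
        One row per site: ``chromosome``, ``gene`` and ``snp_probe`` columns.
    """

    values: pd.DataFrame
    scale: str = "beta"
    detection_p: pd.DataFrame | None = None
    beads: pd.DataFrame | None = None
    sample_meta: pd.DataFrame | None = None
    control_probes: pd.DataFrame | None = None
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale tag {self.scale!r}; expected one of {SCALES}")
        for name in ("detection_p", "beads"):
            companion = getattr(self, name)
            if companion is not None and companion.shape != self.values.shape:
                raise ValueError(f"{name} shape {companion.shape} != values shape {self.values.shape}")
        if self.scale == "beta":
            vals = self.values.to_numpy(float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() <= 0.0 or finite.max() >= 1.0):
                raise ValueError("beta values must lie strictly inside (0, 1)")

    # -- basic introspection -------------------------------------------------
    @property
    def site_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def visit(self) -> pd.Series:
        if self.sample_meta is None:
            raise ValueError("no sample metadata attached")
        return self.sample_meta.loc[self.sample_ids, "visit"]

    # -- transformation helpers ---------------------------------------------
    def replace_values(self, values: pd.DataFrame, scale: str | None = None) -> "MethylationArraySet":
        """Return a copy with a new value matrix (and optionally scale tag)."""
        return dataclasses.replace(self, values=values,
                                   scale=self.scale if scale is None else scale)

    def subset(self, sites=None, samples=None) -> "MethylationArraySet":
        """Restrict to the given site and/or sample IDs (order preserved)."""
        sites = self.site_ids if sites is None else pd.Index(sites)
        samples = self.sample_ids if samples is None else pd.Index(samples)

        def cut(df: pd.DataFrame | None) -> pd.DataFrame | None:
            return None if df is None else df.loc[sites, samples]

        return MethylationArraySet(
            values=self.values.loc[sites, samples],
            scale=self.scale,
            detection_p=cut(self.detection_p),
            beads=cut(self.beads),
            sample_meta=None if self.sample_meta is None else self.sample_meta.loc[samples],
            control_probes=None if self.control_probes is None else self.control_probes.loc[:, samples],
            annotation=None if self.annotation is None else self.annotation.loc[sites],
        )

    # -- I/O ------------------------------------------------------------------
    def write(self, outdir: str | Path, prefix: str = "methylation") -> None:
        """Write the matrices as TSV files sharing row/column order."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(outdir / f"{prefix}_{self.scale}.tsv", sep="\t")
        if self.detection_p is not None:
            self.detection_p.to_csv(outdir / f"{prefix}_detection_p.tsv", sep="\t")
        if self.beads is not None:
            self.beads.to_csv(outdir / f"{prefix}_beads.tsv", sep="\t")
        if self.control_probes is not None:
            self.control_probes.to_csv(outdir / f"{prefix}_control_probes.tsv", sep="\t")
        if self.sample_meta is not None:
            self.sample_meta.to_csv(outdir / f"{prefix}_samples.csv")
        if self.annotation is not None:
            self.annotation.to_csv(outdir / f"{prefix}_annotation.csv")


@dataclass
class FilterReport:
    """Audit of preprocessing filters: what was removed, and why."""

    sites_removed_snp: int = 0
    sites_removed_detection: int = 0
    sites_removed_sex_chrom: int = 0
    samples_removed: int = 0
    sample_removal_reasons: dict = field(default_factory=dict)
    entries_set_missing: int = 0
    outliers_removed: dict = field(default_factory=dict)

    def merge(self, other: "FilterReport") -> "FilterReport":
        merged = FilterReport(
            sites_removed_snp=self.sites_removed_snp + other.sites_removed_snp,
            sites_removed_detection=self.sites_removed_detection + other.sites_removed_detection,
            sites_removed_sex_chrom=self.sites_removed_sex_chrom + other.sites_removed_sex_chrom,
            samples_removed=self.samples_removed + other.samples_removed,
            entries_set_missing=self.entries_set_missing + other.entries_set_missing,
        )
        merged.sample_removal_reasons = {**self.sample_removal_reasons, **other.sample_removal_reasons}
        merged.outliers_removed = {**self.outliers_removed, **other.outliers_removed}
        return merged

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=int)
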