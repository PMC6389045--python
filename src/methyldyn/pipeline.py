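"""End-to-end orchestration: simulate -> preprocess -> phenotypes -> EWAS ->
longitudinal models -> dynamics -> report.

Each stage reads its inputs from, and writes its outputs to, the artifact
directory, so any stage can be rerun from disk.  A manifest records the
seed, filter counts, thresholds and parameters of every run; reruns with
the same configuration produce byte-identical numeric tables.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .association import (EwasResult, run_continued_smoking_model, run_ewas,
                          run_intensity_duration_model, run_tsq_model)
from .config import PipelineConfig, SimulationConfig
from .containers import MethylationArraySet
from .dynamics import (consistency_proportion, coefficient_correlation,
                       divergence_table, dynamism_iqr, median_change_by_bin,
                       per_individual_delta)
from .phenotypes import CELL_PROPS, derive_trajectories
from .preprocess import m_to_beta, preprocess_pipeline, residualize_confounders
from .simulate import read_cohort, simulate_cohort, write_cohort

_FLOAT_FMT = "%.10g"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def _confounder_design(meta: pd.DataFrame) -> np.ndarray:
    """Pooled-visit confounder design: intercept, confounders, age at
    baseline and the time-passed variable (0 at baseline)."""
    iid = meta["individual_id"]
    age = meta["interview_age"].to_numpy(float)
    is_base = (meta["visit"] == "S4").to_numpy()
    base_age = pd.Series(age[is_base], index=iid[is_base]).reindex(iid).to_numpy()
    time_passed = np.where(is_base, 0.0, age - base_age)
    cols = [np.ones(len(meta)), meta["sex"].to_numpy(float),
            meta["alcohol_g_day"].to_numpy(float), meta["bmi"].to_numpy(float),
            meta["wbc_count"].to_numpy(float)]
    cols += [meta[c].to_numpy(float) for c in CELL_PROPS]
    cols += [base_age, time_passed]
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    phenos, mars, effects = simulate_cohort(config.simulation)
    write_cohort(outdir, phenos, mars, effects)


def stage_preprocess(config: PipelineConfig, outdir: Path) -> dict:
    phenos, mars = read_cohort(outdir)
    adjusted, report = preprocess_pipeline(mars, n_pcs=config.n_pcs)
    _write_tsv(adjusted.values, outdir / "adjusted_m.tsv")
    report.to_json(outdir / "filter_report.json")
    # Adjusted values on the beta scale (site mean level restored before the
    # inverse logit) for the beta-value dynamics analyses.
    raw = mars.subset(sites=adjusted.site_ids, samples=adjusted.sample_ids)
    from .preprocess import beta_to_m  # local import to avoid cycle confusion
    site_mean = beta_to_m(raw.values).mean(axis=1)
    beta_adj = m_to_beta(adjusted.values.add(site_mean, axis=0))
    _write_tsv(beta_adj, outdir / "adjusted_beta.tsv")
    return {"filters": json.loads((outdir / "filter_report.json").read_text())}


def stage_phenotypes(config: PipelineConfig, outdir: Path) -> dict:
    phenos = pd.read_csv(outdir / "sample_sheet.csv", index_col=0)
    traj = derive_trajectories(phenos)
    traj.to_csv(outdir / "trajectories.csv")
    return {"n_individuals": len(traj),
            "n_included": int(traj["included"].sum()),
            "trajectory_counts": traj["category"].value_counts().to_dict()}


def _load_adjusted(outdir: Path, which: str = "adjusted_m.tsv") -> MethylationArraySet:
    phenos = pd.read_csv(outdir / "sample_sheet.csv", index_col=0)
    vals = pd.read_csv(outdir / which, sep="\t", index_col=0)
    ann = pd.read_csv(outdir / "annotation.csv", index_col=0)
    ann["chromosome"] = ann["chromosome"].astype(str)
    meta = phenos.loc[vals.columns, ["individual_id", "visit", "batch"]]
    scale = "M_adjusted" if which.startswith("adjusted_m") else "beta_residualized"
    return MethylationArraySet(values=vals, scale=scale, sample_meta=meta,
                               annotation=ann.loc[vals.index])


def stage_ewas(config: PipelineConfig, outdir: Path) -> dict:
    data = _load_adjusted(outdir)
    phenos = pd.read_csv(outdir / "sample_sheet.csv", index_col=0)
    ewas = run_ewas(data, phenos, alpha=config.alpha,
                    outlier_sd=config.outlier_sd,
                    max_outliers=config.max_outliers_per_site)
    _write_tsv(ewas.table, outdir / "ewas.tsv")
    (outdir / "ewas_meta.json").write_text(json.dumps({
        "alpha": ewas.alpha, "m_tested": ewas.m_tested,
        "threshold": ewas.threshold,
        "n_significant": int(ewas.table["significant"].fillna(False).sum()),
    }, indent=2))
    return {"ewas_threshold": ewas.threshold, "m_tested": ewas.m_tested,
            "n_significant": int(ewas.table["significant"].fillna(False).sum())}


def _load_ewas(outdir: Path) -> EwasResult:
    table = pd.read_csv(outdir / "ewas.tsv", sep="\t", index_col=0)
    meta = json.loads((outdir / "ewas_meta.json").read_text())
    return EwasResult(table=table, alpha=meta["alpha"], m_tested=meta["m_tested"],
                      threshold=meta["threshold"])


def _carry_forward_sites(outdir: Path) -> list:
    ewas = _load_ewas(outdir)
    sites = list(ewas.significant_sites)
    return sorted(sites)


def stage_tsq_model(config: PipelineConfig, outdir: Path) -> dict:
    data = _load_adjusted(outdir)
    phenos = pd.read_csv(outdir / "sample_sheet.csv", index_col=0)
    traj = pd.read_csv(outdir / "trajectories.csv", index_col=0)
    ewas = _load_ewas(outdir)
    sites = _carry_forward_sites(outdir)
    if not sites:
        raise RuntimeError("no EWAS-significant sites to carry forward")
    table = run_tsq_model(data, phenos, traj, sites=sites, alpha=config.alpha,
                          k=config.n_tsq_categories, mode=config.tsq_category_mode,
                          df_method=config.df_method, ewas=ewas)
    table = table.sort_values(["site", "category"]).reset_index(drop=True)
    _write_tsv(table, outdir / "tsq_model.tsv")
    breaks = [b if np.isfinite(b) else None
              for b in (table.attrs.get("tsq_breakpoints") or [])]
    return {"longitudinal_threshold": table.attrs["bonferroni_threshold"],
            "m_sites": table.attrs["m_sites"],
            "tsq_breakpoints": breaks,
            "n_significant_L": int(table["sig_L"].fillna(False).astype(bool).sum())}


def stage_continued(config: PipelineConfig, outdir: Path) -> dict:
    data = _load_adjusted(outdir)
    phenos = pd.read_csv(outdir / "sample_sheet.csv", index_col=0)
    traj = pd.read_csv(outdir / "trajectories.csv", index_col=0)
    ewas = _load_ewas(outdir)
    sites = _carry_forward_sites(outdir)
    table = run_continued_smoking_model(data, phenos, traj, sites=sites,
                                        alpha=config.alpha,
                                        df_method=config.df_method, ewas=ewas)
    threshold = table.attrs["bonferroni_threshold"]
    table = table.sort_values(["site", "category"]).reset_index(drop=True)

    beta_adj = _load_adjusted(outdir, "adjusted_beta.tsv")
    div = divergence_table(beta_adj.subset(sites=pd.Index(sites)), traj)
    table = table.merge(div["classification"].rename("div_con"),
                        left_on="site", right_index=True, how="left")
    _write_tsv(table, outdir / "continued_smoking.tsv")
    return {"longitudinal_threshold": threshold,
            "n_significant_L": int(table["sig_L"].fillna(False).astype(bool).sum())}


def stage_intensity_duration(config: PipelineConfig, outdir: Path) -> dict:
    data = _load_adjusted(outdir)
    phenos = pd.read_csv(outdir / "sample_sheet.csv", index_col=0)
    traj = pd.read_csv(outdir / "trajectories.csv", index_col=0)
    sites = _carry_forward_sites(outdir)
    table = run_intensity_duration_model(data, phenos, traj, sites=sites,
                                         alpha=config.alpha,
                                         df_method=config.df_method)
    table = table.sort_values("site").reset_index(drop=True)
    _write_tsv(table, outdir / "intensity_duration.tsv")
    return {"n_sig_intensity": int(table["sig_intensity"].sum()),
            "n_sig_duration": int(table["sig_duration"].sum())}


def stage_dynamics(config: PipelineConfig, outdir: Path) -> dict:
    phenos = pd.read_csv(outdir / "sample_sheet.csv", index_col=0)
    traj = pd.read_csv(outdir / "trajectories.csv", index_col=0)
    ewas = _load_ewas(outdir)
    sites = _carry_forward_sites(outdir)
    beta_adj = _load_adjusted(outdir, "adjusted_beta.tsv")
    meta = phenos.loc[beta_adj.sample_ids]
    D = _confounder_design(meta)
    resid = residualize_confounders(beta_adj.values, D)
    resid_set = beta_adj.replace_values(resid, scale="beta_residualized")

    deltas = per_individual_delta(resid_set.subset(sites=pd.Index(sites)))
    summary = median_change_by_bin(deltas, traj, binning=config.binning)
    iqr = dynamism_iqr(summary)
    cons = consistency_proportion(summary, ewas)
    _write_tsv(summary.median_change, outdir / "median_change.tsv")
    per_bin = pd.DataFrame({"n": summary.n_per_bin, "iqr": iqr, "consistency": cons})
    per_bin.index.name = "bin"
    _write_tsv(per_bin, outdir / "dynamics_per_bin.tsv")

    # Coefficient correlations per TSQ category, from the TSQ model table.
    correlations = {}
    tsq_path = outdir / "tsq_model.tsv"
    if tsq_path.exists():
        tsq = pd.read_csv(tsq_path, sep="\t", index_col=0)
        for cat, sub in tsq.groupby("category"):
            try:
                rho, p = coefficient_correlation(
                    sub.set_index("site")["beta_C"], sub.set_index("site")["beta_L"])
                correlations[cat] = {"rho": rho, "p": p, "n": len(sub)}
            except ValueError:
                correlations[cat] = {"rho": None, "p": None, "n": len(sub)}
        (outdir / "coefficient_correlations.json").write_text(
            json.dumps(correlations, indent=2))
    return {"bins": list(summary.median_change.columns),
            "correlations": correlations}


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def _cohort_table(phenos: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for visit in ("S4", "F4"):
        sub = phenos[phenos["visit"] == visit]
        for status, grp in sub.groupby("smoking_status"):
            rows.append({
                "visit": visit, "status": status, "n": len(grp),
                "male_frac": grp["sex"].mean(),
                "age": grp["interview_age"].mean(),
                "bmi": grp["bmi"].mean(),
                "alcohol_g_day": grp["alcohol_g_day"].mean(),
                "cigs_per_day": grp["cigs_per_day"].mean(),
            })
    return pd.DataFrame(rows)


def render_report(artifact_dir: str | Path, heatmap_threshold: float = 0.025) -> Path:
    """Render a markdown report (with PNG figures) from a completed run.

    Sections with missing stage outputs are omitted with a notice.
    """
    outdir = Path(artifact_dir)
    lines = ["# methyldyn run report", ""]

    def missing(name):
        lines.append(f"*Section '{name}' omitted: stage output not found.*\n")

    # 1. Cohort characteristics
    if (outdir / "sample_sheet.csv").exists():
        phenos = pd.read_csv(outdir / "sample_sheet.csv", index_col=0)
        lines += ["## Cohort characteristics", "",
                  _cohort_table(phenos).to_markdown(index=False, floatfmt=".2f"), ""]
    else:
        missing("cohort characteristics")

    # 2. Volcano-style panels per TSQ category
    tsq_path = outdir / "tsq_model.tsv"
    if tsq_path.exists():
        tsq = pd.read_csv(tsq_path, sep="\t", index_col=0)
        cats = sorted(tsq["category"].unique())
        fig, axes = plt.subplots(1, len(cats), figsize=(3 * len(cats), 3),
                                 squeeze=False, sharey=True)
        for ax, cat in zip(axes[0], cats):
            sub = tsq[tsq["category"] == cat]
            ax.scatter(sub["beta_L"], -np.log10(sub["p_L"].clip(lower=1e-300)), s=8)
            ax.set_title(cat)
            ax.set_xlabel("longitudinal coefficient")
        axes[0][0].set_ylabel("-log10 p")
        fig.tight_layout()
        fig.savefig(outdir / "fig_longitudinal_volcano.png", dpi=110)
        plt.close(fig)
        lines += ["## Longitudinal coefficients by TSQ category", "",
                  "![volcano](fig_longitudinal_volcano.png)", ""]
    else:
        missing("longitudinal coefficient panels")

    # 3. Median-change heat map
    med_path = outdir / "median_change.tsv"
    if med_path.exists():
        import seaborn as sns
        med = pd.read_csv(med_path, sep="\t", index_col=0)
        keep = med.abs().max(axis=1) > heatmap_threshold
        shown = med[keep]
        if len(shown):
            fig = plt.figure(figsize=(8, max(2, 0.2 * len(shown))))
            sns.heatmap(shown, cmap="coolwarm", center=0)
            fig.tight_layout()
            fig.savefig(outdir / "fig_median_change_heatmap.png", dpi=110)
            plt.close(fig)
            lines += ["## Median change heat map",
                      f"Sites with |median change| > {heatmap_threshold} in at least one bin "
                      f"({len(shown)} of {len(med)}).", "",
                      "![heatmap](fig_median_change_heatmap.png)", ""]
        else:
            lines += ["## Median change heat map",
                      f"No site exceeds the {heatmap_threshold} display threshold.", ""]
    else:
        missing("median change heat map")

    # 4. IQR / consistency curves
    per_bin_path = outdir / "dynamics_per_bin.tsv"
    if per_bin_path.exists():
        per_bin = pd.read_csv(per_bin_path, sep="\t", index_col=0)
        fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 5), sharex=True)
        x = np.arange(len(per_bin))
        ax1.plot(x, per_bin["iqr"], marker="o")
        ax1.set_ylabel("IQR of median change")
        ax2.plot(x, per_bin["consistency"], marker="o", color="tab:orange")
        ax2.set_ylabel("consistency proportion")
        ax2.set_xticks(x, per_bin.index, rotation=60)
        fig.tight_layout()
        fig.savefig(outdir / "fig_dynamism.png", dpi=110)
        plt.close(fig)
        lines += ["## Dynamism and reversion consistency", "",
                  "![dynamism](fig_dynamism.png)", ""]
    else:
        missing("dynamism curves")

    # 5. Cross-sectional vs longitudinal scatter
    if tsq_path.exists():
        tsq = pd.read_csv(tsq_path, sep="\t", index_col=0)
        cats = sorted(tsq["category"].unique())[:4]
        fig, axes = plt.subplots(1, len(cats), figsize=(3 * len(cats), 3), squeeze=False)
        for ax, cat in zip(axes[0], cats):
            sub = tsq[tsq["category"] == cat]
            ax.scatter(sub["beta_C"], sub["beta_L"], s=8)
            ax.axhline(0, lw=0.5, color="gray")
            ax.set_title(cat)
            ax.set_xlabel("cross-sectional")
        axes[0][0].set_ylabel("longitudinal")
        fig.tight_layout()
        fig.savefig(outdir / "fig_reversion_scatter.png", dpi=110)
        plt.close(fig)
        lines += ["## Reversion rate: cross-sectional vs longitudinal coefficients", "",
                  "![scatter](fig_reversion_scatter.png)", ""]
    else:
        missing("reversion scatter")

    # 6. Significant-site tables
    cont_path = outdir / "continued_smoking.tsv"
    int_path = outdir / "intensity_duration.tsv"
    if cont_path.exists() or int_path.exists():
        lines.append("## Significant sites")
        if cont_path.exists():
            cont = pd.read_csv(cont_path, sep="\t", index_col=0)
            sig = cont[cont["sig_L"].fillna(False).astype(bool)]
            lines += ["", "### Continued smoking (longitudinally significant)", "",
                      sig[["site", "beta_C", "beta_L", "p_L", "div_con"]]
                      .to_markdown(index=False) if len(sig) else "*none*", ""]
        if int_path.exists():
            intdur = pd.read_csv(int_path, sep="\t", index_col=0)
            sig = intdur[intdur["sig_intensity"] | intdur["sig_duration"]]
            lines += ["", "### Intensity / duration", "",
                      sig[["site", "beta_intensity", "p_intensity",
                           "beta_duration", "p_duration"]]
                      .to_markdown(index=False) if len(sig) else "*none*", ""]
    else:
        missing("significant-site tables")

    report_path = outdir / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

STAGES = ("simulate", "preprocess", "phenotypes", "ewas", "tsq-model",
          "continued", "intensity-duration", "dynamics", "report")


def run_pipeline(config: PipelineConfig, stages=None) -> Path:
    """Run the pipeline end to end; returns the artifact directory.

    Raises ``RuntimeError`` naming the failing stage on any error.  The
    resolved configuration and a manifest (versions, seed, filter counts,
    thresholds) are written next to the outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "resolved_config.yaml")
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": {},
    }
    runners = {
        "simulate": lambda: stage_simulate(config, outdir),
        "preprocess": lambda: stage_preprocess(config, outdir),
        "phenotypes": lambda: stage_phenotypes(config, outdir),
        "ewas": lambda: stage_ewas(config, outdir),
        "tsq-model": lambda: stage_tsq_model(config, outdir),
        "continued": lambda: stage_continued(config, outdir),
        "intensity-duration": lambda: stage_intensity_duration(config, outdir),
        "dynamics": lambda: stage_dynamics(config, outdir),
        "report": lambda: render_report(outdir, config.heatmap_threshold),
    }
    for stage in (STAGES if stages is None else stages):
        try:
            result = runners[stage]()
            manifest["stages"][stage] = result if isinstance(result, dict) else {"ok": True}
        except Exception as exc:  # noqa: BLE001 - stage name must surface
            manifest["stages"][stage] = {"error": str(exc)}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
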