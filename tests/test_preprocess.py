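"""Tests of filters, normalization, transforms and technical adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import methyldyn as md
from methyldyn.containers import MethylationArraySet
from methyldyn.preprocess import (apply_entry_filters, apply_site_filters,
                                  beta_to_m, control_probe_pcs, m_to_beta,
                                  quantile_normalize, remove_outliers,
                                  remove_snp_probes, residualize_confounders,
                                  technical_adjust)


def toy_set(values, detection=None, beads=None, visits=None, chroms=None, snp=None):
    values = np.asarray(values, float)
    n_sites, n_samples = values.shape
    sites = pd.Index([f"cg{i:04d}" for i in range(n_sites)], name="site")
    samples = pd.Index([f"s{j}" for j in range(n_samples)], name="sample_id")
    mk = lambda a: pd.DataFrame(np.asarray(a, float), index=sites, columns=samples)
    if visits is None:
        visits = ["S4"] * (n_samples // 2) + ["F4"] * (n_samples - n_samples // 2)
    meta = pd.DataFrame({"individual_id": [f"I{j}" for j in range(n_samples)],
                         "visit": visits, "batch": 0}, index=samples)
    ann = pd.DataFrame({
        "chromosome": chroms if chroms is not None else ["1"] * n_sites,
        "gene": "G", "snp_probe": snp if snp is not None else [False] * n_sites,
    }, index=sites)
    return MethylationArraySet(
        values=mk(values),
        detection_p=mk(detection) if detection is not None else mk(np.zeros_like(values)),
        beads=mk(beads) if beads is not None else mk(np.full_like(values, 10)),
        sample_meta=meta, annotation=ann,
        control_probes=pd.DataFrame(np.ones((3, n_samples)), columns=samples),
    )


class TestLogitTransform:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_reference_points(self, beta, m):
        assert beta_to_m(beta) == pytest.approx(m, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.3])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError, match="outside the open interval"):
            beta_to_m(bad)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=0.001, max_value=0.999))
    def test_round_trip(self, x):
        assert m_to_beta(beta_to_m(x)) == pytest.approx(x, abs=1e-12)

    def test_dataframe_round_trip_with_nan(self):
        df = pd.DataFrame([[0.2, np.nan], [0.9, 0.5]])
        back = m_to_beta(beta_to_m(df))
        assert back.iloc[0, 0] == pytest.approx(0.2, abs=1e-12)
        assert np.isnan(back.iloc[0, 1])


class TestEntryFilters:
    def test_detection_boundary_is_inclusive(self):
        det = np.zeros((30, 4))
        det[0, 0] = 0.01  # exactly at the threshold -> missing
        data = toy_set(np.full((30, 4), 0.5), detection=det)
        out, report = apply_entry_filters(data)
        assert np.isnan(out.values.iloc[0, 0])
        assert report.entries_set_missing == 1

    def test_low_bead_count_masked(self):
        beads = np.full((30, 4), 10.0)
        beads[1, 2] = 3  # <= 3 beads -> missing
        data = toy_set(np.full((30, 4), 0.5), beads=beads)
        out, report = apply_entry_filters(data)
        assert np.isnan(out.values.iloc[1, 2])
        assert report.entries_set_missing == 1

    def test_sample_at_exact_095_detection_dropped(self):
        det = np.zeros((20, 3))
        det[0, 1] = 0.5  # sample s1 detects 19/20 = 0.95 exactly -> dropped
        data = toy_set(np.full((20, 3), 0.5), detection=det)
        out, report = apply_entry_filters(data)
        assert "s1" not in out.sample_ids
        assert report.samples_removed == 1

    def test_clean_input_is_untouched(self):
        data = toy_set(np.full((3, 4), 0.5))
        out, report = apply_entry_filters(data)
        assert out.values.equals(data.values)
        assert report.entries_set_missing == 0 and report.samples_removed == 0


class TestSiteFilters:
    def test_either_visit_rule(self):
        # 50 samples per visit; site 0 misses 3/50 at F4 (94%) but 2/50 (96%) at S4
        vals = np.full((2, 100), 0.5)
        vals[0, :2] = np.nan      # S4: 96%
        vals[0, 50:53] = np.nan   # F4: 94% -> removed
        data = toy_set(vals, visits=["S4"] * 50 + ["F4"] * 50)
        out, report = apply_site_filters(data)
        assert "cg0000" not in out.site_ids
        assert "cg0001" in out.site_ids
        assert report.sites_removed_detection == 1

    def test_sex_chromosome_removed(self):
        data = toy_set(np.full((3, 4), 0.5), chroms=["1", "X", "Y"])
        out, report = apply_site_filters(data)
        assert list(out.site_ids) == ["cg0000"]
        assert report.sites_removed_sex_chrom == 2

    def test_snp_probe_removed(self):
        data = toy_set(np.full((3, 4), 0.5), snp=[False, True, False])
        out, report = remove_snp_probes(data)
        assert "cg0001" not in out.site_ids
        assert report.sites_removed_snp == 1

    def test_exact_95_percent_site_retained(self):
        vals = np.full((1, 40), 0.5)
        vals[0, 0] = np.nan  # 19/20 = 95% at S4 exactly -> retained
        data = toy_set(vals, visits=["S4"] * 20 + ["F4"] * 20)
        out, _ = apply_site_filters(data)
        assert "cg0000" in out.site_ids


class TestQuantileNormalize:
    def test_sorted_columns_identical(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(200, 5)))
        out = quantile_normalize(df)
        ref = np.sort(out.to_numpy(), axis=0)
        assert np.allclose(ref, ref[:, [0]])

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(100, 4)))
        out = quantile_normalize(df)
        for j in range(4):
            rho, _ = stats.spearmanr(df.iloc[:, j], out.iloc[:, j])
            assert rho == pytest.approx(1.0)

    def test_identical_distributions_unchanged(self):
        col = np.linspace(0.1, 0.9, 50)
        rng = np.random.default_rng(2)
        df = pd.DataFrame({f"s{j}": rng.permutation(col) for j in range(3)})
        out = quantile_normalize(df)
        assert np.allclose(out.to_numpy(), df.to_numpy(), atol=1e-12)

    def test_missing_entries_restored_as_missing(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 3))
        X[5, 1] = np.nan
        out = quantile_normalize(pd.DataFrame(X))
        assert np.isnan(out.iloc[5, 1])
        assert out.notna().sum().sum() == 180 - 1

    def test_single_sample_warns_identity(self):
        df = pd.DataFrame({"s0": [0.1, 0.2, 0.3]})
        with pytest.warns(UserWarning, match="single-sample"):
            out = quantile_normalize(df)
        assert out.equals(df)


class TestTechnicalAdjust:
    def test_default_n_pcs_is_20(self):
        import inspect
        assert inspect.signature(technical_adjust).parameters["n_pcs"].default == 20

    def test_degenerate_controls_give_mean_centering(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(5, 30)))
        controls = pd.DataFrame(np.ones((6, 30)), columns=m.columns)
        out = technical_adjust(m, controls, batch_indicator=None, n_pcs=2)
        expected = m.sub(m.mean(axis=1), axis=0)
        assert np.allclose(out.to_numpy(), expected.to_numpy(), atol=1e-8)

    def test_planted_batch_effect_removed(self):
        cfg = md.SimulationConfig(n_individuals=100, n_sites=40,
                                  n_affected_sites=0, batch_shift_scale=1.0,
                                  missing_rate=0.0, outlier_rate=0.0, seed=55)
        phenos, mars, _ = md.simulate_cohort(cfg)
        m = beta_to_m(mars.values)
        batch = mars.sample_meta["batch"]
        raw_cor = np.array([abs(np.corrcoef(m.iloc[i], batch)[0, 1])
                            for i in range(m.shape[0])])
        adj = technical_adjust(m, mars.control_probes, batch, n_pcs=10)
        adj_cor = np.array([abs(np.corrcoef(adj.iloc[i], batch)[0, 1])
                            for i in range(adj.shape[0])])
        assert raw_cor.max() > 0.1       # the effect was there
        assert adj_cor.max() <= 0.05     # and is gone

    def test_too_many_pcs_raises(self):
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 5)))
        controls = pd.DataFrame(np.random.default_rng(1).normal(size=(4, 5)),
                                columns=m.columns)
        with pytest.raises(ValueError, match="n_pcs"):
            technical_adjust(m, controls, n_pcs=5)

    def test_pc_sign_convention_deterministic(self):
        rng = np.random.default_rng(6)
        controls = pd.DataFrame(rng.normal(size=(8, 12)))
        a = control_probe_pcs(controls, 3)
        b = control_probe_pcs(controls.copy(), 3)
        assert np.allclose(a, b)


class TestOutlierRemoval:
    def setup_method(self):
        rng = np.random.default_rng(8)
        self.n = 1000
        self.D = np.column_stack([np.ones(self.n), rng.normal(size=self.n)])
        self.y = self.D @ np.array([1.0, 0.5]) + rng.normal(0, 1, self.n)

    def test_six_sd_point_removed(self):
        y = self.y.copy()
        y[7] += 8.0  # far beyond 5 residual SDs
        masked, count = remove_outliers(y, self.D)
        assert count == 1 and np.isnan(masked[7])

    def test_at_most_five_removed_largest_first(self):
        # all seven displacements exceed 5x the (single-pass, inflated)
        # residual SD; only the five most extreme may be removed
        y = self.y.copy()
        displ = [30.0, 29.0, 28.0, 27.0, 26.0, 25.0, 24.0]
        idx = [3, 10, 20, 30, 40, 50, 60]
        for i, d in zip(idx, displ):
            y[i] += d
        masked, count = remove_outliers(y, self.D)
        assert count == 5
        assert all(np.isnan(masked[i]) for i in idx[:5])
        assert all(~np.isnan(masked[i]) for i in idx[5:])

    def test_clean_gaussian_rarely_flagged(self):
        masked, count = remove_outliers(self.y[:100], self.D[:100])
        assert count == 0

    def test_short_input_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="too few"):
            masked, count = remove_outliers(np.array([1.0, 2.0]), np.ones((2, 1)))
        assert count == 0


class TestResidualizeConfounders:
    def test_orthogonality(self):
        rng = np.random.default_rng(9)
        D = np.column_stack([np.ones(120), rng.normal(size=(120, 3))])
        vals = pd.DataFrame(rng.normal(size=(6, 120)))
        out = residualize_confounders(vals, D)
        R = out.to_numpy()
        for j in range(D.shape[1]):
            dots = np.abs(R @ D[:, j]) / (np.linalg.norm(R, axis=1)
                                          * np.linalg.norm(D[:, j]))
            assert (dots < 1e-8).all()

    def test_intercept_only_mean_centers(self):
        vals = pd.DataFrame([[1.0, 2.0, 3.0], [4.0, 6.0, 8.0]])
        out = residualize_confounders(vals, np.ones((3, 1)))
        assert np.allclose(out.to_numpy().mean(axis=1), 0.0, atol=1e-12)

    def test_planted_sex_effect_removed(self):
        rng = np.random.default_rng(10)
        n = 400
        sex = rng.integers(0, 2, n).astype(float)
        D = np.column_stack([np.ones(n), sex])
        beta = 0.4 + 0.1 * sex + rng.normal(0, 0.02, n)
        out = residualize_confounders(pd.DataFrame(beta[None, :]), D)
        r = out.to_numpy()[0]
        assert abs(r[sex == 1].mean() - r[sex == 0].mean()) < 1e-3

    def test_rank_deficient_design_warns(self):
        D = np.column_stack([np.ones(50), np.ones(50)])
        vals = pd.DataFrame(np.random.default_rng(11).normal(size=(2, 50)))
        with pytest.warns(UserWarning, match="rank-deficient"):
            residualize_confounders(vals, D)


class TestPipelineChain:
    def test_refuses_processed_input(self, adjusted_cohort):
        _, adjusted, _, _ = adjusted_cohort
        with pytest.raises(ValueError, match="refused"):
            md.preprocess_pipeline(adjusted)

    def test_filter_report_reconciles(self, small_cohort, adjusted_cohort):
        _, mars, _ = small_cohort
        _, adjusted, _, report = adjusted_cohort
        removed = (report.sites_removed_snp + report.sites_removed_detection
                   + report.sites_removed_sex_chrom)
        assert mars.n_sites - removed == adjusted.n_sites

    def test_output_scale_and_centering(self, adjusted_cohort):
        _, adjusted, _, _ = adjusted_cohort
        assert adjusted.scale == "M_adjusted"
        row_means = np.nanmean(adjusted.values.to_numpy(), axis=1)
        assert np.abs(row_means).max() < 1e-8
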