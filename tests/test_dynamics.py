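"""Tests of the fine-scale reversion/dynamism statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methyldyn as md
from methyldyn.association import EwasResult
from methyldyn.containers import MethylationArraySet
from methyldyn.dynamics import (classify_divergence, coefficient_correlation,
                                consistency_proportion, dynamism_iqr,
                                median_change_by_bin, per_individual_delta)


def resid_set(values, individuals, visits):
    samples = pd.Index([f"{i}_{v}" for i, v in zip(individuals, visits)],
                       name="sample_id")
    meta = pd.DataFrame({"individual_id": individuals, "visit": visits,
                         "batch": 0}, index=samples)
    vals = pd.DataFrame(np.asarray(values, float),
                        index=[f"cg{i:03d}" for i in range(np.shape(values)[0])],
                        columns=samples)
    return MethylationArraySet(values=vals, scale="beta_residualized",
                               sample_meta=meta)


def toy_trajectories(categories, tsq=None, included=None):
    n = len(categories)
    return pd.DataFrame({
        "category": categories,
        "tsq_at_followup": tsq if tsq is not None else [np.nan] * n,
        "included": included if included is not None else [True] * n,
        "exclusion_reason": None,
    }, index=pd.Index([f"I{i:03d}" for i in range(n)], name="individual_id"))


def toy_ewas(sites, coefs):
    table = pd.DataFrame({"coef": coefs, "se": 0.1, "p": 1e-9,
                          "significant": True, "n": 100},
                         index=pd.Index(sites, name="site"))
    return EwasResult(table=table, alpha=0.05, m_tested=len(sites),
                      threshold=0.05 / len(sites))


class TestPerIndividualDelta:
    def test_simple_subtraction(self):
        data = resid_set([[0.30, 0.34]], ["I000", "I000"], ["S4", "F4"])
        deltas = per_individual_delta(data)
        assert deltas.iloc[0, 0] == pytest.approx(0.04)

    def test_identical_visits_give_zero(self):
        data = resid_set([[0.5, 0.5]], ["I000", "I000"], ["S4", "F4"])
        assert per_individual_delta(data).iloc[0, 0] == 0.0

    def test_missing_endpoint_gives_missing_delta_only(self):
        vals = np.array([[np.nan, 0.4, 0.2, 0.3],
                         [0.1, 0.2, 0.3, 0.35]])
        data = resid_set(vals, ["I000", "I000", "I001", "I001"],
                         ["S4", "F4", "S4", "F4"])
        deltas = per_individual_delta(data)
        assert np.isnan(deltas.loc["cg000", "I000"])
        assert deltas.loc["cg001", "I000"] == pytest.approx(0.1)

    def test_single_visit_individual_excluded(self):
        vals = np.array([[0.1, 0.2, 0.3]])
        data = resid_set(vals, ["I000", "I000", "I001"], ["S4", "F4", "S4"])
        deltas = per_individual_delta(data)
        assert list(deltas.columns) == ["I000"]


class TestMedianChangeByBin:
    def setup_method(self):
        rng = np.random.default_rng(50)
        inds = [f"I{i:03d}" for i in range(12)]
        individuals = np.repeat(inds, 2)
        visits = ["S4", "F4"] * 12
        base = rng.uniform(0.3, 0.7, (4, 12))
        follow = base + rng.normal(0, 0.01, (4, 12))
        vals = np.empty((4, 24))
        vals[:, ::2], vals[:, 1::2] = base, follow
        self.data = resid_set(vals, individuals, visits)
        cats = ["FS-FS"] * 8 + ["NS-NS"] * 2 + ["CS-CS"] * 2
        tsq = [1.5, 1.5, 3.0, 3.0, 5.0, 9.0, 21.0, 41.0] + [np.nan] * 4
        self.traj = toy_trajectories(cats, tsq=tsq)

    def test_bins_are_half_open_two_year_intervals(self):
        deltas = per_individual_delta(self.data)
        summary = median_change_by_bin(deltas, self.traj)
        assert "(0,2]" in summary.median_change.columns
        assert summary.n_per_bin["(0,2]"] == 2
        assert summary.n_per_bin["(2,4]"] == 2
        assert summary.n_per_bin["NS-NS"] == 2
        assert summary.n_per_bin["CS-CS"] == 2

    def test_single_member_bin_median_is_that_delta(self):
        deltas = per_individual_delta(self.data)
        summary = median_change_by_bin(deltas, self.traj)
        assert summary.n_per_bin["(8,10]"] == 1
        expected = deltas["I005"]
        got = summary.median_change["(8,10]"]
        np.testing.assert_allclose(got, expected)

    def test_all_zero_deltas_give_zero_medians_and_iqr(self):
        vals = np.tile(np.array([0.4, 0.4]), (3, 12))
        data = resid_set(vals, self.data.sample_meta["individual_id"],
                         self.data.sample_meta["visit"])
        deltas = per_individual_delta(data)
        summary = median_change_by_bin(deltas, self.traj)
        assert (summary.median_change.fillna(0) == 0).all().all()
        iqr = dynamism_iqr(summary, min_sites=3, min_individuals=1)
        assert (iqr.dropna() == 0).all()

    def test_permutation_invariance(self):
        deltas = per_individual_delta(self.data)
        shuffled = deltas[deltas.columns[::-1]]
        a = median_change_by_bin(deltas, self.traj).median_change
        b = median_change_by_bin(shuffled, self.traj).median_change
        pd.testing.assert_frame_equal(a, b)


class TestDynamismIqr:
    def test_brute_force_quartile_example(self):
        medians = pd.DataFrame({"bin": [0.0, 0.1, 0.2, 0.3]},
                               index=[f"cg{i}" for i in range(4)])
        summary = md.DynamicsSummary(median_change=medians,
                                     n_per_bin=pd.Series({"bin": 20}))
        iqr = dynamism_iqr(summary)
        assert iqr["bin"] == pytest.approx(0.15)

    def test_small_bins_are_missing(self):
        medians = pd.DataFrame({"bin": [0.0, 0.1, np.nan, np.nan]},
                               index=[f"cg{i}" for i in range(4)])
        summary = md.DynamicsSummary(median_change=medians,
                                     n_per_bin=pd.Series({"bin": 20}))
        assert np.isnan(dynamism_iqr(summary)["bin"])

    def test_sparse_individual_bins_are_missing(self):
        medians = pd.DataFrame({"bin": [0.0, 0.1, 0.2, 0.3]},
                               index=[f"cg{i}" for i in range(4)])
        summary = md.DynamicsSummary(median_change=medians,
                                     n_per_bin=pd.Series({"bin": 2}))
        assert np.isnan(dynamism_iqr(summary)["bin"])


class TestConsistencyProportion:
    def test_all_reverting_gives_one(self):
        sites = ["cg0", "cg1"]
        medians = pd.DataFrame({"bin": [0.02, 0.05]}, index=sites)
        summary = md.DynamicsSummary(median_change=medians,
                                     n_per_bin=pd.Series({"bin": 5}))
        cons = consistency_proportion(summary, toy_ewas(sites, [-1.0, -0.5]))
        assert cons["bin"] == 1.0

    def test_same_direction_gives_zero(self):
        sites = ["cg0"]
        medians = pd.DataFrame({"bin": [-0.02]}, index=sites)
        summary = md.DynamicsSummary(median_change=medians,
                                     n_per_bin=pd.Series({"bin": 1}))
        cons = consistency_proportion(summary, toy_ewas(sites, [-1.0]))
        assert cons["bin"] == 0.0

    def test_zero_medians_excluded(self):
        sites = ["cg0", "cg1", "cg2"]
        medians = pd.DataFrame({"bin": [0.0, 0.03, -0.03]}, index=sites)
        summary = md.DynamicsSummary(median_change=medians,
                                     n_per_bin=pd.Series({"bin": 3}))
        cons = consistency_proportion(summary, toy_ewas(sites, [-1.0, -1.0, -1.0]))
        assert cons["bin"] == pytest.approx(0.5)

    def test_sign_flip_complements(self):
        rng = np.random.default_rng(51)
        sites = [f"cg{i}" for i in range(40)]
        medians = pd.DataFrame({"bin": rng.normal(0, 0.02, 40)}, index=sites)
        coefs = rng.choice([-1.0, 1.0], 40)
        summary = md.DynamicsSummary(median_change=medians,
                                     n_per_bin=pd.Series({"bin": 40}))
        c1 = consistency_proportion(summary, toy_ewas(sites, coefs))
        c2 = consistency_proportion(summary, toy_ewas(sites, -coefs))
        assert c1["bin"] + c2["bin"] == pytest.approx(1.0)

    def test_random_signs_near_half(self):
        rng = np.random.default_rng(52)
        n = 590
        sites = [f"cg{i}" for i in range(n)]
        medians = pd.DataFrame({"bin": rng.normal(0, 0.02, n)}, index=sites)
        summary = md.DynamicsSummary(median_change=medians,
                                     n_per_bin=pd.Series({"bin": n}))
        cons = consistency_proportion(summary, toy_ewas(sites, np.full(n, -1.0)))
        assert abs(cons["bin"] - 0.5) < 3 * 0.5 / np.sqrt(n)


class TestCoefficientCorrelation:
    def test_identical_vectors(self):
        rho, _ = coefficient_correlation([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_reversed_ranks(self):
        rho, _ = coefficient_correlation([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0, abs=1e-12)

    def test_matches_rank_then_pearson_with_ties(self):
        rng = np.random.default_rng(53)
        x = np.round(rng.normal(size=60), 1)  # ties on purpose
        y = np.round(rng.normal(size=60), 1)
        rho, _ = coefficient_correlation(x, y)
        brute = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(brute, abs=1e-12)

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError, match="at least 4"):
            coefficient_correlation([1, 2, 3], [3, 2, 1])

    def test_decay_generator_negative_correlation(self, decay_cohort):
        """Under exponential reversion, larger baseline gaps revert faster:
        cross-sectional and longitudinal coefficients anticorrelate."""
        cfg, (phenos, mars, effects) = decay_cohort
        adjusted, _ = md.preprocess_pipeline(mars, n_pcs=10)
        traj = md.derive_trajectories(phenos)
        planted = [s for s in effects.delta.index[effects.delta != 0]
                   if s in adjusted.site_ids]
        table = md.run_tsq_model(adjusted, phenos, traj, sites=planted,
                                 k=4, df_method="normal")
        cat1 = table[table["category"] == "TSQ1"]
        rho, p = coefficient_correlation(cat1.set_index("site")["beta_C"],
                                         cat1.set_index("site")["beta_L"])
        assert rho < 0 and p < 0.01


class TestClassifyDivergence:
    def test_growing_gap_is_diverging(self):
        assert classify_divergence(0.10, 0.12, 0.0, 0.0) == ("Div", False)

    def test_shrinking_gap_is_converging(self):
        assert classify_divergence(0.10, 0.08, 0.0, 0.0) == ("Con", False)

    def test_same_sign_coefficients_can_still_converge(self):
        # both medians below reference at both visits, gap shrinking
        label, tie = classify_divergence(-0.30, -0.25, 0.0, 0.0)
        assert label == "Con"

    def test_tie_flagged_as_converging(self):
        label, tie = classify_divergence(0.10, -0.10, 0.0, 0.0)
        assert label == "Con" and tie

    def test_missing_median_gives_missing_label(self):
        label, tie = classify_divergence(np.nan, 0.1, 0.0, 0.0)
        assert label is None
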