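import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import cauchy, nct, norm
from scipy.stats import t as t_dist

from itasense.inference import (
    ComparisonResult,
    bf_category,
    compare_group_trialwise,
    compare_summary,
    funnel_coordinates,
    individual_ita_tests,
    jzs_bf_one_sided,
    jzs_bf_two_sided,
    proportion_ci,
)
from itasense.observer import (
    GroupSensitivity,
    TrialTable,
    direct_dprime_from_trials,
    indirect_dprime_from_trials,
)
from itasense.sdt import SensitivityEstimate
from itasense.simulate import SimulationConfig, simulate_experiment


def _group(dprimes, source="direct"):
    df = pd.DataFrame(
        {
            "dprime": dprimes,
            "se": 0.1,
            "hr": 0.6,
            "fa": 0.4,
            "hits": 6,
            "false_alarms": 4,
            "n_signal": 10,
            "n_noise": 10,
        },
        index=[f"p{i}" for i in range(len(dprimes))],
    )
    df.index.name = "participant"
    return GroupSensitivity(df, source)


class TestCompareGroupTrialwise:
    def test_identical_collections(self):
        g = _group([0.1, 0.2, 0.3, 0.15])
        res = compare_group_trialwise(g, _group([0.1, 0.2, 0.3, 0.15], "indirect_trials"))
        assert res.d_difference == 0.0
        assert res.t_stat == 0.0
        assert not res.ita_decision

    def test_participant_mismatch(self):
        a = _group([0.1, 0.2])
        b = _group([0.1, 0.2, 0.3], "indirect_trials")
        with pytest.raises(ValueError, match="mismatch"):
            compare_group_trialwise(a, b)

    def test_matches_manual_t_test(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.1, 0.3, 12)
        i = rng.normal(0.3, 0.3, 12)
        res = compare_group_trialwise(_group(d), _group(i, "indirect_trials"))
        diffs = i - d
        t_manual = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(12))
        assert res.t_stat == pytest.approx(t_manual)
        assert res.p_two_sided == pytest.approx(2 * t_dist.sf(abs(t_manual), 11))
        assert res.ci_low < diffs.mean() < res.ci_high

    def test_null_type_one_calibration(self):
        # shared latent sensitivity: ~5% two-sided rejections
        rng = np.random.default_rng(8)
        reps, n, rejects = 2000, 15, 0
        for _ in range(reps):
            shared = rng.normal(0.2, 0.1, n)
            d = shared + rng.normal(0, 0.3, n)
            i = shared + rng.normal(0, 0.3, n)
            diffs = i - d
            t = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(n))
            rejects += abs(t) > t_dist.ppf(0.975, n - 1)
        band = 2.58 * math.sqrt(0.05 * 0.95 / reps)
        assert rejects / reps == pytest.approx(0.05, abs=band)


class TestCompareSummary:
    def test_worked_example_difference(self):
        ind = SensitivityEstimate(0.24, 48, 48, "indirect_summary", se=0.11)
        dire = SensitivityEstimate(0.11, 12, 12, "direct", se=0.14)
        res = compare_summary(ind, dire, n_participants=14)
        assert res.d_difference == pytest.approx(0.13, abs=1e-9)
        assert res.df == 13

    def test_equal_inputs(self):
        e = SensitivityEstimate(0.2, 10, 10, "direct", se=0.1)
        res = compare_summary(e, e, n_participants=10)
        assert res.d_difference == 0.0

    def test_quadrature_se(self):
        ind = SensitivityEstimate(0.3, 48, 48, "indirect_summary", se=0.10)
        dire = SensitivityEstimate(0.1, 12, 12, "direct", se=0.14)
        res = compare_summary(ind, dire, n_participants=20)
        assert res.se == pytest.approx(0.172, abs=5e-4)

    def test_missing_se_errors(self):
        ind = SensitivityEstimate(0.3, 48, 48, "indirect_summary", se=None)
        dire = SensitivityEstimate(0.1, 12, 12, "direct", se=0.14)
        with pytest.raises(ValueError, match="no SE"):
            compare_summary(ind, dire, n_participants=20)


class TestJzsBayesFactor:
    def test_worked_example(self):
        assert round(jzs_bf_one_sided(0.66, 14), 2) == 0.47

    def test_one_sided_equals_two_sided_at_zero(self):
        assert jzs_bf_one_sided(0.0, 14) == pytest.approx(
            jzs_bf_two_sided(0.0, 14), rel=1e-6
        )

    def test_monotone_in_t(self):
        ts = np.linspace(0, 10, 21)
        bfs = [jzs_bf_one_sided(t, 14) for t in ts]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    @pytest.mark.parametrize("t,n", [(0.66, 14), (2.0, 20), (-1.0, 10)])
    def test_against_monte_carlo_prior_integration(self, t, n):
        # oracle: average the noncentral-t likelihood over truncated-Cauchy draws
        rng = np.random.default_rng(31)
        scale = 1 / math.sqrt(2)
        deltas = np.abs(cauchy.rvs(scale=scale, size=200_000, random_state=rng))
        like = nct.pdf(t, n - 1, deltas * math.sqrt(n))
        m1 = like.mean()
        mc_se = like.std(ddof=1) / math.sqrt(like.size)
        bf_mc = m1 / t_dist.pdf(t, n - 1)
        tol = 3 * mc_se / t_dist.pdf(t, n - 1)
        assert jzs_bf_one_sided(t, n) == pytest.approx(bf_mc, abs=tol)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            jzs_bf_one_sided(float("nan"), 14)
        with pytest.raises(ValueError):
            jzs_bf_one_sided(1.0, 1)


def test_bf_categories():
    assert bf_category(0.2) == "against"
    assert bf_category(0.47) == "inconclusive"
    assert bf_category(5.0) == "for"


class TestProportionCI:
    def test_large_sample_example(self):
        lo, hi = proportion_ci(48, 766)
        assert lo == pytest.approx(0.047, abs=5e-4)
        assert hi == pytest.approx(0.082, abs=5e-4)

    def test_zero_successes(self):
        lo, hi = proportion_ci(0, 50)
        assert lo == 0.0
        assert hi < 0.1

    def test_all_successes(self):
        lo, hi = proportion_ci(50, 50)
        assert hi == 1.0

    def test_wilson_brackets_similar_interval(self):
        cp = proportion_ci(48, 766, "clopper_pearson")
        wi = proportion_ci(48, 766, "wilson")
        assert wi[0] == pytest.approx(cp[0], abs=0.005)
        assert wi[1] == pytest.approx(cp[1], abs=0.005)

    def test_invalid(self):
        with pytest.raises(ValueError):
            proportion_ci(5, 4)


def _result(d, se):
    return ComparisonResult(
        d_difference=d, se=se, ci_low=d - 2 * se, ci_high=d + 2 * se,
        t_stat=d / se if se else 0.0, df=10, p_two_sided=0.5,
        bf10_one_sided=1.0, mode="summary",
    )


class TestFunnel:
    def test_zero_on_axis(self):
        funnel = funnel_coordinates([_result(0.0, 0.2)])
        assert funnel.points["d_difference"].iloc[0] == 0.0

    def test_boundary_point(self):
        se = 0.2
        z = float(norm.ppf(0.975))
        funnel = funnel_coordinates([_result(z * se, se)])
        lines = funnel.boundary_lines()
        five = lines[lines["alpha"] == 0.05]
        # the point x = 1.96 * se sits exactly on the interpolated 5% boundary
        assert np.interp(se, five["se"], five["upper"]) == pytest.approx(z * se, rel=1e-9)

    def test_null_ensemble_coverage(self):
        rng = np.random.default_rng(44)
        ses = rng.uniform(0.05, 0.3, 2000)
        ds = rng.normal(0, ses)
        funnel = funnel_coordinates([_result(d, s) for d, s in zip(ds, ses)])
        z = funnel.critical_z[0.05]
        inside = (np.abs(ds) < z * ses).mean()
        assert inside == pytest.approx(0.95, abs=0.02)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            funnel_coordinates([])


@pytest.fixture(scope="module")
def tables():
    cfg = SimulationConfig(
        n_participants=12, k_per_condition=40, k_direct_per_condition=12,
        delta=0.2, sigma_effect=0.1, seed=77,
    )
    search, recog, _ = simulate_experiment(cfg)
    return search, recog


class TestIndividualITA:
    def test_extreme_participant_flagged(self):
        # perfectly separated indirect trials, chance-level direct responses
        rng = np.random.default_rng(9)
        rows = []
        for rt in np.linspace(300, 399, 50):
            rows.append({"participant": "p1", "condition": "repeated", "rt_ms": rt})
        for rt in np.linspace(600, 699, 50):
            rows.append({"participant": "p1", "condition": "new", "rt_ms": rt})
        search = TrialTable(pd.DataFrame(rows))
        recog_rows = []
        for i in range(20):
            recog_rows.append({"participant": "p1", "condition": "repeated",
                               "response": "old" if i % 2 else "new"})
            recog_rows.append({"participant": "p1", "condition": "new",
                               "response": "old" if i % 2 else "new"})
        recog = TrialTable(pd.DataFrame(recog_rows), task="recognition")
        res = individual_ita_tests(search, recog, n_boot=500, seed=1, epochs="all")
        assert res.per_participant.loc["p1", "significant"]

    def test_bootstrap_stability(self, tables):
        search, recog = tables
        small = individual_ita_tests(search, recog, n_boot=200, seed=5, epochs="all")
        large = individual_ita_tests(search, recog, n_boot=2000, seed=5, epochs="all")
        ratio = (
            small.per_participant["se_boot"] / large.per_participant["se_boot"]
        ).to_numpy()
        assert np.all(np.abs(ratio - 1.0) < 0.15)

    def test_seed_reproducible(self, tables):
        search, recog = tables
        a = individual_ita_tests(search, recog, n_boot=300, seed=3, epochs="all")
        b = individual_ita_tests(search, recog, n_boot=300, seed=3, epochs="all")
        pd.testing.assert_frame_equal(a.per_participant, b.per_participant)

    def test_small_b_rejected(self, tables):
        search, recog = tables
        with pytest.raises(ValueError, match="n_boot"):
            individual_ita_tests(search, recog, n_boot=50, epochs="all")
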