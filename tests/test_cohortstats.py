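"""Normality testing, subgroup comparisons and log-age correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rvotshape import cohortstats as cs


def ad_statistic_oracle(x):
    """Textbook Anderson-Darling A^2 against the fitted normal."""
    x = np.sort(np.asarray(x, float))
    n = len(x)
    mu, sd = x.mean(), x.std(ddof=1)
    z = stats.norm.cdf((x - mu) / sd)
    i = np.arange(1, n + 1)
    return -n - np.mean((2 * i - 1) * (np.log(z) + np.log1p(-z[::-1])))


class TestNormality:
    def test_normal_draws_flagged_normal(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=500)
            hits += cs.normality(x).normal
        assert hits >= 90

    def test_exponential_draws_flagged_non_normal(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(size=200)
            hits += not cs.normality(x).normal
        assert hits >= 95

    def test_statistic_matches_textbook_formula(self):
        x = np.random.default_rng(42).normal(2.0, 3.0, size=60)
        res = cs.normality(x)
        assert res.statistic == pytest.approx(ad_statistic_oracle(x), abs=1e-8)

    def test_constant_input_flagged_with_warning(self):
        with pytest.warns(UserWarning):
            res = cs.normality(np.ones(20))
        assert not res.normal

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            cs.normality(np.arange(5.0))


def make_table(groups, rng):
    rows = []
    for name, values in groups.items():
        for v in values:
            rows.append(dict(group=name, y=v))
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_type_one_error_calibrated(self):
        """Null: all groups from one distribution; the omnibus rejects at
        about the nominal 5% level (3-8% band over 200 replicates)."""
        rejections = 0
        for rep in range(200):
            rng = np.random.default_rng(rep)
            tab = make_table(
                {g: rng.normal(0, 1, 20) for g in ("a", "b", "c")}, rng
            )
            res = cs.compare_groups(tab, "y", "group")
            rejections += res.omnibus_p < 0.05
        assert 0.03 <= rejections / 200 <= 0.08

    def test_large_shift_detected_with_high_power(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            tab = make_table(
                {"a": rng.normal(0, 1, 15), "b": rng.normal(2, 1, 15)}, rng
            )
            res = cs.compare_groups(tab, "y", "group")
            hits += res.omnibus_p < 0.05
        assert hits > 95

    def test_small_group_excluded_from_testing(self):
        rng = np.random.default_rng(0)
        tab = make_table(
            {
                "a": rng.normal(0, 1, 15),
                "b": rng.normal(3, 1, 15),
                "tiny": rng.normal(0, 1, 3),
            },
            rng,
        )
        res = cs.compare_groups(tab, "y", "group")
        assert "tiny" in res.excluded_groups
        assert all("tiny" not in (p[0], p[1]) for p in res.pairwise)
        assert "tiny" in res.descriptives  # still described

    def test_pairwise_only_when_omnibus_significant(self):
        rng = np.random.default_rng(3)
        tab = make_table({"a": rng.normal(0, 1, 20), "b": rng.normal(0, 1, 20)}, rng)
        res = cs.compare_groups(tab, "y", "group")
        if res.omnibus_p >= 0.05:
            assert res.pairwise == []

    def test_welch_t_and_wilcoxon_match_reference(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 25)
        b = rng.normal(3.0, 2, 25)
        tab = make_table({"a": a, "b": b}, rng)
        res = cs.compare_groups(tab, "y", "group")
        f_ref, p_ref = stats.f_oneway(a, b)
        assert res.omnibus_p == pytest.approx(p_ref, abs=1e-12)
        (ga, gb, test, p) = res.pairwise[0]
        if test == "welch-t":
            ref = stats.ttest_ind(a, b, equal_var=False).pvalue
        else:
            ref = stats.ranksums(a, b).pvalue
        assert p == pytest.approx(float(ref), abs=1e-12)

    def test_single_eligible_group_gives_descriptives_only(self):
        rng = np.random.default_rng(5)
        tab = make_table({"a": rng.normal(0, 1, 15), "b": rng.normal(0, 1, 2)}, rng)
        res = cs.compare_groups(tab, "y", "group")
        assert np.isnan(res.omnibus_p)
        assert res.pairwise == []
        assert set(res.descriptives) == {"a", "b"}


class TestCorrelateWithLogAge:
    def test_exact_linear_in_log_age(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(2, 40, 50)
        tab = pd.DataFrame(dict(age_years=age, y=3.0 * np.log(age)))
        r, p = cs.correlate_with_log_age(tab, "y")
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_null_calibration(self):
        small = 0
        for rep in range(500):
            rng = np.random.default_rng(rep)
            tab = pd.DataFrame(
                dict(age_years=rng.uniform(2, 40, 81), y=rng.normal(size=81))
            )
            r, _ = cs.correlate_with_log_age(tab, "y")
            small += abs(r) < 0.3
        assert small / 500 >= 0.95

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        age = rng.uniform(2, 40, 30)
        y = rng.normal(size=30)
        tab = pd.DataFrame(dict(age_years=age, y=y))
        r, _ = cs.correlate_with_log_age(tab, "y")
        la = np.log(age)
        oracle = ((y - y.mean()) * (la - la.mean())).sum() / np.sqrt(
            ((y - y.mean()) ** 2).sum() * ((la - la.mean()) ** 2).sum()
        )
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_nonpositive_age_rejected(self):
        tab = pd.DataFrame(dict(age_years=[1.0, -2.0, 3.0], y=[1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            cs.correlate_with_log_age(tab, "y")

    def test_zero_variance_flagged(self):
        tab = pd.DataFrame(dict(age_years=[1.0, 2.0, 3.0], y=[1.0, 1.0, 1.0]))
        with pytest.warns(UserWarning):
            r, p = cs.correlate_with_log_age(tab, "y")
        assert np.isnan(r)


class TestScoreGeometryCorrelations:
    def _frames(self, rng, size_factor=True):
        n = 40
        size = rng.normal(1.0, 0.2, n)
        scores = pd.DataFrame(
            dict(
                subject_id=[f"S{i}" for i in range(n)],
                mode1=(size - size.mean()) * 10 + rng.normal(0, 0.2, n),
                mode2=rng.normal(0, 1, n),
            )
        )
        summaries = pd.DataFrame(
            dict(
                subject_id=[f"S{i}" for i in range(n)],
                sa=6000 * size**2,
                l_rvot=55 * size,
                d_ave=25 * size,
            )
        )
        return scores, summaries

    def test_dominant_size_factor_detected(self):
        rng = np.random.default_rng(0)
        scores, summaries = self._frames(rng)
        out = cs.correlate_scores_with_geometry(scores, summaries)
        r = out[(out["mode"] == "mode1") & (out.variable == "sa")].r.iloc[0]
        assert abs(r) > 0.8

    def test_noise_mode_uncorrelated(self):
        rng = np.random.default_rng(1)
        scores, summaries = self._frames(rng)
        out = cs.correlate_scores_with_geometry(scores, summaries)
        r = out[(out["mode"] == "mode2") & (out.variable == "sa")].r.iloc[0]
        assert abs(r) < 0.3

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(2)
        scores, summaries = self._frames(rng)
        out0 = cs.correlate_scores_with_geometry(scores, summaries)
        summaries2 = summaries.copy()
        summaries2["sa"] = 3.7 * summaries2["sa"] + 100.0
        out1 = cs.correlate_scores_with_geometry(scores, summaries2)
        r0 = out0[(out0["mode"] == "mode1") & (out0.variable == "sa")].r.iloc[0]
        r1 = out1[(out1["mode"] == "mode1") & (out1.variable == "sa")].r.iloc[0]
        assert r0 == pytest.approx(r1, abs=1e-12)
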