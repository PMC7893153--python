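"""Statistical battery: gated paired tests, RM-ANOVA, sphericity, Dunnett."""

import numpy as np
import pandas as pd
import pytest

from revlearn.errors import UnbalancedDesignError
from revlearn.stats import (
    dunnett_sf,
    greenhouse_geisser_epsilon,
    mauchly_test,
    paired_compare,
    rm_anova_dunnett,
)


def long_format(Y, odor=None):
    n, k = Y.shape
    d = pd.DataFrame(
        {
            "fly_id": np.repeat(np.arange(n), k),
            "trial_index": np.tile(np.arange(1, k + 1), n),
            "value": Y.ravel(),
        }
    )
    if odor is not None:
        d["odor"] = odor
    return d


class TestPairedCompare:
    def test_identical_samples_degenerate(self):
        x = np.arange(5.0)
        res = paired_compare(x, x)
        assert res.degenerate and res.p_value == 1.0

    def test_t_statistic_matches_textbook_formula(self):
        """t = mean(d) / (sd(d)/sqrt(n)) on a small worked dataset."""
        x = np.array([2.3, 1.9, 2.8, 3.1, 2.0, 2.6, 2.2, 2.9, 2.4])
        y = np.array([2.0, 1.7, 2.9, 2.5, 1.8, 2.1, 2.3, 2.2, 2.0])
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        res = paired_compare(x, y)
        assert res.test_name == "paired_t"
        assert res.statistic == pytest.approx(t_hand)
        assert 0.0 <= res.p_value <= 1.0

    def test_heavy_tailed_data_routes_to_wilcoxon(self):
        rng = np.random.default_rng(3)
        d = rng.standard_cauchy(30) * 10
        x = rng.normal(size=30)
        res = paired_compare(x + d, x)
        assert res.test_name == "wilcoxon"
        assert res.normality_p < 0.05

    def test_small_n_uses_t_without_omnibus(self):
        res = paired_compare([1.0, 2.0, 3.5], [0.5, 2.2, 3.0])
        assert res.test_name == "paired_t"
        assert np.isnan(res.normality_p)

    def test_type_one_error_calibrated(self):
        """Null paired normal samples: rejection rate at alpha=0.05 stays in
        [0.04, 0.06] over 2000 replicates."""
        rng = np.random.default_rng(2024)
        rej = sum(
            paired_compare(rng.normal(size=9), rng.normal(size=9)).p_value < 0.05
            for _ in range(2000)
        )
        assert 0.04 <= rej / 2000 <= 0.06


class TestDunnett:
    def test_single_comparison_reduces_to_two_sided_t(self):
        from scipy import stats as ss

        for tval, df in [(1.0, 5), (2.5, 12), (4.0, 30)]:
            assert dunnett_sf(tval, 1, df) == pytest.approx(2 * ss.t.sf(tval, df))

    def test_matches_scipy_independent_groups_dunnett(self):
        """On a balanced independent-groups design (correlation exactly 0.5)
        the adjustment agrees with scipy's Dunnett test."""
        from scipy import stats as ss

        rng = np.random.default_rng(0)
        n = 20
        control = rng.normal(size=n)
        g1 = rng.normal(0.5, size=n)
        g2 = rng.normal(1.0, size=n)
        res = ss.dunnett(
            g1, g2, control=control, random_state=np.random.default_rng(1)
        )
        df = 3 * (n - 1)
        s2 = sum(((g - g.mean()) ** 2).sum() for g in (control, g1, g2)) / df
        for scipy_p, g in zip(res.pvalue, (g1, g2)):
            t = (g.mean() - control.mean()) / np.sqrt(2 * s2 / n)
            assert dunnett_sf(abs(t), 2, df) == pytest.approx(scipy_p, abs=2e-3)

    def test_monotone_in_t_and_k(self):
        assert dunnett_sf(3.0, 2, 10) < dunnett_sf(2.0, 2, 10)
        assert dunnett_sf(2.0, 2, 10) < dunnett_sf(2.0, 4, 10)


class TestSphericity:
    def test_epsilon_is_one_under_compound_symmetry(self):
        """Construct data whose sample covariance is exactly compound
        symmetric: epsilon must be exactly 1."""
        k = 5
        # orthogonal design achieving an exactly CS sample covariance
        rng = np.random.default_rng(1)
        n = 40
        Y = rng.normal(size=(n, k))
        # force the sample covariance to I + 0.5 J by whitening + recoloring
        Yc = Y - Y.mean(axis=0)
        S = np.cov(Yc, rowvar=False, ddof=1)
        L = np.linalg.cholesky(S)
        white = Yc @ np.linalg.inv(L).T
        target = np.eye(k) + 0.5
        Lt = np.linalg.cholesky(target)
        Ycs = white @ Lt.T
        assert greenhouse_geisser_epsilon(Ycs) == pytest.approx(1.0)

    def test_epsilon_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            Y = rng.normal(size=(8, 5)) * rng.uniform(0.2, 3.0, size=5)
            eps = greenhouse_geisser_epsilon(Y)
            assert 1.0 / 4.0 <= eps <= 1.0

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(10, 4)) + rng.normal(size=(10, 1))
        d = long_format(Y)
        eps_pg = pg.epsilon(d, dv="value", within="trial_index", subject="fly_id",
                            correction="gg")
        assert greenhouse_geisser_epsilon(Y) == pytest.approx(float(eps_pg), rel=1e-6)
        sph = pg.sphericity(d, dv="value", within="trial_index", subject="fly_id")
        W, p = mauchly_test(Y)
        assert W == pytest.approx(float(sph.W), rel=1e-6)
        assert p == pytest.approx(float(sph.pval), rel=1e-3, abs=1e-3)


class TestRmAnova:
    def test_f_matches_brute_force_sums_of_squares(self):
        """4 flies x 3 trials toy table against an explicit-loop oracle."""
        Y = np.array(
            [
                [0.5, 0.4, 0.2],
                [0.7, 0.5, 0.4],
                [0.6, 0.6, 0.3],
                [0.8, 0.5, 0.5],
            ]
        )
        n, k = Y.shape
        grand = Y.mean()
        ss_factor = sum(n * (Y[:, j].mean() - grand) ** 2 for j in range(k))
        ss_subject = sum(k * (Y[i, :].mean() - grand) ** 2 for i in range(n))
        ss_total = sum(
            (Y[i, j] - grand) ** 2 for i in range(n) for j in range(k)
        )
        ss_err = ss_total - ss_factor - ss_subject
        F_oracle = (ss_factor / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
        res = rm_anova_dunnett(long_format(Y), apply_gg=False)
        assert res.statistic == pytest.approx(F_oracle)

    def test_matches_pingouin_oneway(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        Y = rng.normal(size=(9, 5)) + np.linspace(0, 0.8, 5) + rng.normal(size=(9, 1))
        d = long_format(Y)
        res = rm_anova_dunnett(d, apply_gg=False)
        aov = pg.rm_anova(
            data=d, dv="value", within="trial_index", subject="fly_id",
            correction=True, detailed=True,
        )
        assert res.statistic == pytest.approx(float(aov.loc[0, "F"]), rel=1e-9)
        assert res.p_value == pytest.approx(float(aov.loc[0, "p_unc"]), rel=1e-9)
        assert rm_anova_dunnett(d, apply_gg=True).epsilon == pytest.approx(
            float(aov.loc[0, "eps"]), rel=1e-9
        )

    def test_matches_pingouin_twoway(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(21)
        n, a, b = 8, 5, 2
        cube = rng.normal(size=(n, a, b)) + rng.normal(size=(n, 1, 1))
        long = pd.DataFrame(
            {
                "fly_id": np.repeat(np.arange(n), a * b),
                "trial_index": np.tile(np.repeat(np.arange(a), b), n),
                "odor": np.tile(["CSplus", "CSminus"], n * a),
                "value": cube.ravel(),
            }
        )
        res = rm_anova_dunnett(long, apply_gg=False)
        aov = pg.rm_anova(
            data=long, dv="value", within=["trial_index", "odor"], subject="fly_id"
        ).set_index("Source")
        for mine, theirs in [
            ("trial", "trial_index"),
            ("odor", "odor"),
            ("trial_x_odor", "trial_index * odor"),
        ]:
            assert res.effects[mine].statistic == pytest.approx(
                float(aov.loc[theirs, "F"]), rel=1e-9
            )
            assert res.effects[mine].epsilon == pytest.approx(
                float(aov.loc[theirs, "eps"]), rel=1e-6
            )

    def test_posthoc_references_first_trial(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(8, 4))
        res = rm_anova_dunnett(long_format(Y))
        assert len(res.posthoc) == 3
        assert all("vs 1" in name for name, _ in res.posthoc)
        assert all(0 <= p <= 1 for _, p in res.posthoc)

    def test_unbalanced_design_rejected(self):
        d = long_format(np.random.default_rng(0).normal(size=(5, 4)))
        d = d.drop(index=d.index[3])
        with pytest.raises(UnbalancedDesignError):
            rm_anova_dunnett(d)

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(9)
        Y = rng.normal(scale=0.1, size=(9, 5)) + np.linspace(0, -1.0, 5)
        res = rm_anova_dunnett(long_format(Y))
        assert res.p_value < 1e-4
        # every later trial differs from trial 1 except possibly trial 2
        assert res.posthoc[-1][1] < 1e-3
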