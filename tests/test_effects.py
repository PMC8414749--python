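"""Mixed-model fitting, Wald contrasts, Holm correction and the
study's normalized effect measures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scapkin import effects
from scapkin.effects import (
    DESIGN_COLUMNS,
    borg_mean_difference,
    build_design,
    compensation_percent_change,
    fit_random_intercept_lmm,
    holm_adjust,
    normalize_by_baseline,
    normalized_trunk_compensation,
    posthoc_contrasts,
    relative_effect_vs_therapist,
    reml_criterion,
    wald_contrast,
)

SUPPORTS = ["none", "therapist", "orthosis"]
DIRECTIONS = ["flexion", "abduction"]


def simulate_obs(
    rng,
    n_participants=8,
    therapist=15.0,
    orthosis=6.0,
    sigma_b=10.0,
    sigma_e=2.0,
):
    """Balanced support x direction observations with random intercepts."""
    rows = []
    for i in range(n_participants):
        intercept = 100.0 + rng.normal(0, sigma_b)
        for support in SUPPORTS:
            gain = {"none": 0.0, "therapist": therapist, "orthosis": orthosis}[support]
            for direction in DIRECTIONS:
                rows.append(
                    {
                        "participant": f"P{i}",
                        "support": support,
                        "direction": direction,
                        "peak_theta": intercept + gain + rng.normal(0, sigma_e),
                    }
                )
    return pd.DataFrame(rows)


class TestLmmFit:
    def test_zero_between_variance_matches_ols(self):
        """No participant effect in the data: fixed effects equal OLS."""
        rng = np.random.default_rng(1)
        df = simulate_obs(rng, sigma_b=0.0, sigma_e=1.0)
        fit = fit_random_intercept_lmm(df)
        X = build_design(df)
        y = df["peak_theta"].to_numpy()
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.beta.to_numpy(), beta_ols, atol=1e-5)

    def test_grid_search_oracle_tiny_dataset(self):
        """2 participants x 2 supports x 2 directions: the profiled REML
        optimum matches a dense grid over the variance ratio."""
        rng = np.random.default_rng(7)
        rows = []
        for i, intercept in enumerate([95.0, 110.0]):
            for support in ["none", "therapist"]:
                for direction in DIRECTIONS:
                    rows.append(
                        {
                            "participant": f"P{i}",
                            "support": support,
                            "direction": direction,
                            "peak_theta": intercept
                            + (8.0 if support == "therapist" else 0.0)
                            + rng.normal(0, 1.0),
                        }
                    )
        df = pd.DataFrame(rows)
        # drop interaction/orthosis columns from the design by fitting the
        # full model anyway; the criterion comparison is what matters
        y = df["peak_theta"].to_numpy()
        X = np.column_stack(
            [
                np.ones(len(df)),
                (df["support"] == "therapist").to_numpy(float),
                (df["direction"] == "flexion").to_numpy(float),
            ]
        )
        groups = df["participant"].to_numpy()
        grid = np.concatenate([[0.0], np.geomspace(1e-4, 1e4, 4000)])
        crit = [reml_criterion(y, X, groups, lam) for lam in grid]
        lam_grid = grid[int(np.argmin(crit))]
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda l: reml_criterion(y, X, groups, l), bounds=(0, 1e4), method="bounded"
        )
        crit_opt = reml_criterion(y, X, groups, res.x)
        crit_grid = reml_criterion(y, X, groups, lam_grid)
        assert crit_opt <= crit_grid + 1e-9  # optimizer at least as good as grid
        assert crit_opt == pytest.approx(crit_grid, abs=1e-4)
        if lam_grid > 0:
            assert res.x == pytest.approx(lam_grid, rel=0.05)

    def test_matches_statsmodels_mixedlm(self):
        """Independent oracle: statsmodels MixedLM (REML) agrees on the
        fixed effects and variance components."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(42)
        df = simulate_obs(rng)
        fit = fit_random_intercept_lmm(df)
        sm_fit = smf.mixedlm(
            "peak_theta ~ C(support, Treatment('none')) * C(direction, Treatment('abduction'))",
            df,
            groups=df["participant"],
        ).fit(reml=True)
        ours = fit.beta.to_numpy()
        theirs = np.concatenate(
            [
                [sm_fit.params["Intercept"]],
                [
                    sm_fit.params["C(support, Treatment('none'))[T.therapist]"],
                    sm_fit.params["C(support, Treatment('none'))[T.orthosis]"],
                    sm_fit.params["C(direction, Treatment('abduction'))[T.flexion]"],
                    sm_fit.params[
                        "C(support, Treatment('none'))[T.therapist]:C(direction, Treatment('abduction'))[T.flexion]"
                    ],
                    sm_fit.params[
                        "C(support, Treatment('none'))[T.orthosis]:C(direction, Treatment('abduction'))[T.flexion]"
                    ],
                ],
            ]
        )
        np.testing.assert_allclose(ours, theirs, atol=1e-4)
        assert fit.sigma_b2 == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.sigma_e2 == pytest.approx(float(sm_fit.scale), rel=1e-3)

    def test_balanced_design_parameter_recovery(self):
        """Known effects and variance components are recovered within the
        Monte-Carlo standard error over 200 replicates."""
        rng = np.random.default_rng(3)
        ther, orth = [], []
        for _ in range(200):
            df = simulate_obs(rng, therapist=15.0, orthosis=6.0)
            fit = fit_random_intercept_lmm(df)
            est_t, _, _ = wald_contrast(fit, {"therapist": 1.0, "therapist:flexion": 1.0})
            est_o, _, _ = wald_contrast(fit, {"orthosis": 1.0, "orthosis:flexion": 1.0})
            ther.append(est_t)
            orth.append(est_o)
        for vals, truth in ((ther, 15.0), (orth, 6.0)):
            se = np.std(vals, ddof=1) / np.sqrt(len(vals))
            assert abs(np.mean(vals) - truth) < 2.5 * se

    def test_single_participant_falls_back_to_ols(self):
        rng = np.random.default_rng(0)
        df = simulate_obs(rng, n_participants=1, sigma_b=0.0)
        df = pd.concat([df, df], ignore_index=True)  # enough rows
        with pytest.warns(UserWarning, match="single participant"):
            fit = fit_random_intercept_lmm(df)
        assert fit.single_group_fallback
        assert fit.sigma_b2 == 0.0

    def test_deterministic_given_data(self):
        rng = np.random.default_rng(11)
        df = simulate_obs(rng)
        f1 = fit_random_intercept_lmm(df)
        f2 = fit_random_intercept_lmm(df)
        np.testing.assert_array_equal(f1.beta.to_numpy(), f2.beta.to_numpy())

    def test_unknown_levels_rejected(self):
        df = pd.DataFrame(
            {
                "participant": ["P1", "P2"],
                "support": ["none", "robot"],
                "direction": ["flexion", "flexion"],
                "peak_theta": [100.0, 110.0],
            }
        )
        with pytest.raises(ValueError, match="unknown support"):
            build_design(df)


class TestContrasts:
    @pytest.fixture()
    def fit(self):
        rng = np.random.default_rng(8)
        return fit_random_intercept_lmm(simulate_obs(rng))

    def test_identical_conditions_null_contrast(self, fit):
        est, se, p = wald_contrast(fit, {})
        assert est == 0.0 and p == 1.0

    def test_sign_flip_equivariance(self):
        rng = np.random.default_rng(9)
        df = simulate_obs(rng)
        flipped = df.assign(peak_theta=-df["peak_theta"])
        a = posthoc_contrasts(fit_random_intercept_lmm(df))
        b = posthoc_contrasts(fit_random_intercept_lmm(flipped))
        for ca, cb in zip(a, b):
            assert cb.mean == pytest.approx(-ca.mean, abs=1e-8)
            assert cb.p_raw == pytest.approx(ca.p_raw, abs=1e-10)

    def test_family_is_four_contrasts_with_holm(self, fit):
        rows = posthoc_contrasts(fit)
        assert len(rows) == 4
        assert {(r.contrast, r.direction) for r in rows} == {
            ("therapist-none", "flexion"),
            ("therapist-none", "abduction"),
            ("orthosis-none", "flexion"),
            ("orthosis-none", "abduction"),
        }
        for r in rows:
            assert r.p_holm >= r.p_raw
            assert r.ci_low <= r.mean <= r.ci_high

    def test_ci_coverage_near_nominal(self):
        """CI95 of a 15 deg therapist effect covers the truth ~95% of the
        time at study-like noise."""
        rng = np.random.default_rng(17)
        covered = 0
        n_rep = 250
        for _ in range(n_rep):
            df = simulate_obs(rng, therapist=15.0, sigma_b=10.0, sigma_e=2.0)
            fit = fit_random_intercept_lmm(df)
            for c in posthoc_contrasts(fit):
                if c.contrast == "therapist-none" and c.direction == "flexion":
                    covered += c.ci_low <= 15.0 <= c.ci_high
        assert 0.88 <= covered / n_rep <= 0.99

    def test_non_estimable_contrast_raises(self, fit):
        with pytest.raises(ValueError, match="non-estimable"):
            wald_contrast(fit, {"bogus": 1.0})

    def test_t_option_widens_ci(self, fit):
        zrows = posthoc_contrasts(fit, use_t=False)
        trows = posthoc_contrasts(fit, use_t=True)
        for zr, tr in zip(zrows, trows):
            assert (tr.ci_high - tr.ci_low) > (zr.ci_high - zr.ci_low)


class TestHolm:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.04]), [0.04])

    def test_step_down_worked_example(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(holm_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_order_restored(self):
        p = [0.03, 0.01, 0.02]
        np.testing.assert_allclose(holm_adjust(p), [0.04, 0.03, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            holm_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_dominates_raw_and_never_beats_bonferroni(self, p):
        """Holm >= raw everywhere and Bonferroni is never smaller."""
        from statsmodels.stats.multitest import multipletests

        adj = holm_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        bonf = np.minimum(np.asarray(p) * len(p), 1.0)
        assert np.all(adj <= bonf + 1e-12)
        # cross-check against the statsmodels implementation
        _, sm_adj, *_ = multipletests(p, method="holm")
        np.testing.assert_allclose(adj, sm_adj, atol=1e-12)


class TestNormalizedMeasures:
    def test_baseline_normalization(self):
        assert normalize_by_baseline(110.0, 100.0) == pytest.approx(0.10)
        assert normalize_by_baseline(100.0, 100.0) == 0.0
        with pytest.raises(ValueError, match="baseline"):
            normalize_by_baseline(110.0, 0.0)

    def test_relative_effect(self):
        assert relative_effect_vs_therapist(5.0, 5.0) == pytest.approx(1.0)
        assert relative_effect_vs_therapist(-1.0, 2.0) == pytest.approx(-0.5)
        assert relative_effect_vs_therapist(3.0, 0.0) is None  # exclusion rule
        assert relative_effect_vs_therapist(3.0, -2.0) is None

    def test_trunk_compensation_ratio(self):
        assert normalized_trunk_compensation(10.0, 100.0) == pytest.approx(0.10)
        with pytest.raises(ValueError, match="positive"):
            normalized_trunk_compensation(10.0, 0.0)

    def test_compensation_percent_change(self):
        assert compensation_percent_change(0.2, 0.2) == 0.0
        assert compensation_percent_change(0.2, 0.1) == pytest.approx(50.0)

    def test_borg_difference(self):
        assert borg_mean_difference([16.5], [15.25]) == pytest.approx(1.25)
        assert borg_mean_difference([15.0, 15.0], [15.0, 15.0]) == 0.0
        assert borg_mean_difference([17.0], [15.0]) == pytest.approx(2.0)
        with pytest.raises(ValueError, match="Borg"):
            borg_mean_difference([5.0], [15.0])
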