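import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from avdegrade import stats_models as sm


def simulate_lmm(
    seed=0,
    n_groups=24,
    n_per=8,
    effect=0.0,
    group_sd=0.4,
    noise_sd=0.5,
    intercept=1.0,
):
    """Two-condition within-participant data with known parameters."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, group_sd)
        for k in range(n_per):
            cond = "a" if k % 2 == 0 else "b"
            # sum coding: condition a at +effect/2, b at -effect/2
            shift = effect / 2 if cond == "a" else -effect / 2
            y = intercept + shift + u + rng.normal(0, noise_sd)
            rows.append((f"p{g:02d}", cond, y))
    return pd.DataFrame(rows, columns=["participant", "condition", "y"])


class TestModelSpec:
    def test_parses_fixed_and_random_terms(self):
        spec = sm.ModelSpec(
            "hu_asin ~ condition*age + emotion + (condition|participant) + (1|movie)"
        )
        assert spec.outcome == "hu_asin"
        assert spec.fixed_terms == ("condition*age", "emotion")
        assert spec.random_terms == (
            ("condition", "participant"),
            ("1", "movie"),
        )

    def test_referenced_columns(self):
        spec = sm.ModelSpec("y ~ condition*age + (1|participant)")
        assert spec.referenced_columns() == {"y", "condition", "age", "participant"}

    def test_requires_random_structure(self):
        with pytest.raises(ValueError, match="random"):
            sm.ModelSpec("y ~ condition")

    def test_requires_tilde(self):
        with pytest.raises(ValueError, match="~"):
            sm.ModelSpec("y + condition")


class TestFitMixedModel:
    def test_recovers_planted_effect_and_grand_mean(self):
        effect = 0.3
        data = simulate_lmm(seed=1, n_groups=40, n_per=10, effect=effect)
        fit = sm.fit_mixed_model("y ~ condition + (1|participant)", data)
        assert fit.usable
        # sum coding: intercept is the grand mean, the condition coefficient
        # is half the a-b difference
        assert fit.fe_params["Intercept"] == pytest.approx(1.0, abs=0.15)
        coef = fit.fe_params["C(condition, Sum)[S.a]"]
        assert coef == pytest.approx(effect / 2, abs=0.08)

    def test_missing_columns_rejected(self):
        data = simulate_lmm()
        with pytest.raises(ValueError, match="lacks columns"):
            sm.fit_mixed_model("y ~ nonexistent + (1|participant)", data)

    def test_single_group_rejected(self):
        data = simulate_lmm(n_groups=1)
        with pytest.raises(ValueError, match="at least 2 levels"):
            sm.fit_mixed_model("y ~ condition + (1|participant)", data)

    def test_missing_values_rejected(self):
        data = simulate_lmm()
        data.loc[0, "y"] = np.nan
        with pytest.raises(ValueError, match="missing values"):
            sm.fit_mixed_model("y ~ condition + (1|participant)", data)

    def test_extra_random_slope_term_rejected(self):
        data = simulate_lmm()
        data["movie"] = np.tile(["m1", "m2"], len(data) // 2)
        with pytest.raises(ValueError, match="intercept-only"):
            sm.fit_mixed_model(
                "y ~ condition + (1|participant) + (condition|movie)", data
            )

    def test_zero_group_variance_flagged_singular(self):
        """A random intercept fitted to data generated with no participant
        effect collapses to zero variance and must be flagged."""
        data = simulate_lmm(seed=1, n_groups=30, n_per=8, effect=0.3, group_sd=0.0)
        fit = sm.fit_mixed_model("y ~ condition + (1|participant)", data)
        assert fit.converged
        assert fit.singular
        assert not fit.usable

    def test_aic_matches_loglik_bookkeeping(self):
        data = simulate_lmm(seed=3)
        fit = sm.fit_mixed_model("y ~ condition + (1|participant)", data)
        assert fit.aic == pytest.approx(2 * fit.k_params - 2 * fit.llf)


class TestSingularDetection:
    class _Stub:
        def __init__(self, cov_re, vcomp=()):
            self.cov_re = np.asarray(cov_re)
            self.vcomp = np.asarray(vcomp)

    def test_tiny_variance_is_singular(self):
        assert sm._is_singular(self._Stub([[1e-12]]), outcome_sd=1.0)

    def test_healthy_fit_not_singular(self):
        assert not sm._is_singular(
            self._Stub([[0.25, 0.1], [0.1, 0.16]]), outcome_sd=1.0
        )

    def test_pinned_correlation_is_singular(self):
        cov = np.array([[0.25, 0.19999], [0.19999, 0.16]])  # corr 0.99995
        assert sm._is_singular(self._Stub(cov), outcome_sd=1.0)

    def test_collapsed_variance_component_is_singular(self):
        assert sm._is_singular(
            self._Stub([[0.25]], vcomp=[1e-12]), outcome_sd=1.0
        )


class TestAicLadder:
    def _stub_fit(self, aic, converged=True, singular=False):
        def factory(spec, data):
            if isinstance(spec, str):
                spec = sm.ModelSpec(spec)
            key = spec.formula
            a, conv, sing = table[key]
            return sm.FitResult(spec, conv, sing, a, -a / 2, 1)

        table = aic
        return factory

    def test_boundary_at_exactly_two(self, monkeypatch):
        """Delta AIC of exactly 2 is accepted ('at least two'); 1.9 is not."""
        table = {
            "y ~ 1 + (1|g)": (100.0, True, False),
            "y ~ a + (1|g)": (98.0, True, False),  # delta = 2.0 -> accept
            "y ~ a + b + (1|g)": (96.1, True, False),  # delta = 1.9 -> reject
        }
        monkeypatch.setattr(sm, "fit_mixed_model", self._stub_fit(table))
        best, trace = sm.aic_ladder(list(table), data=pd.DataFrame())
        assert best.spec.formula == "y ~ a + (1|g)"
        assert [t["decision"] for t in trace] == [
            "baseline",
            "accepted",
            "rejected: AIC improvement < 2",
        ]

    def test_singular_and_nonconverged_rejected_despite_aic(self, monkeypatch):
        table = {
            "y ~ 1 + (1|g)": (100.0, True, False),
            "y ~ a + (1|g)": (50.0, True, True),  # singular
            "y ~ b + (1|g)": (50.0, False, False),  # did not converge
        }
        monkeypatch.setattr(sm, "fit_mixed_model", self._stub_fit(table))
        best, trace = sm.aic_ladder(list(table), data=pd.DataFrame())
        assert best.spec.formula == "y ~ 1 + (1|g)"
        assert trace[1]["decision"] == "rejected: singular fit"
        assert trace[2]["decision"] == "rejected: did not converge"

    def test_real_ladder_prefers_true_model(self):
        """With a strong planted effect the ladder must climb; adding a pure
        noise predictor must not be accepted."""
        data = simulate_lmm(seed=4, n_groups=40, n_per=10, effect=0.8)
        rng = np.random.default_rng(5)
        data["noise"] = rng.choice(["u", "v"], size=len(data))
        best, trace = sm.aic_ladder(
            [
                "y ~ 1 + (1|participant)",
                "y ~ condition + (1|participant)",
                "y ~ condition + noise + (1|participant)",
            ],
            data,
        )
        assert best.spec.formula == "y ~ condition + (1|participant)"
        assert trace[1]["decision"] == "accepted"
        assert trace[2]["decision"].startswith("rejected")

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            sm.aic_ladder([], pd.DataFrame())


class TestWaldAnova:
    def test_single_df_term_equals_z_squared(self):
        data = simulate_lmm(seed=6, effect=0.4)
        fit = sm.fit_mixed_model("y ~ condition + (1|participant)", data)
        table = sm.wald_anova(fit)
        name = "C(condition, Sum)"
        z = fit.fe_params[f"{name}[S.a]"] / np.sqrt(
            fit.fe_cov.loc[f"{name}[S.a]", f"{name}[S.a]"]
        )
        assert table.loc[name, "df"] == 1
        assert table.loc[name, "chi2"] == pytest.approx(z**2)
        assert table.loc[name, "p"] == pytest.approx(
            sstats.chi2.sf(z**2, 1)
        )

    def test_multi_level_factor_df(self):
        data = simulate_lmm(seed=7, n_groups=30)
        rng = np.random.default_rng(8)
        data["emotion"] = rng.choice(["joy", "fear", "pride"], size=len(data))
        fit = sm.fit_mixed_model("y ~ condition + emotion + (1|participant)", data)
        table = sm.wald_anova(fit)
        assert table.loc["C(emotion, Sum)", "df"] == 2

    def test_aliased_term_detected(self):
        data = simulate_lmm(seed=9)
        data["condition_copy"] = data["condition"]
        with pytest.raises(ValueError, match="aliased|rank deficient"):
            sm.fit_mixed_model(
                "y ~ condition + condition_copy + (1|participant)", data
            )

    def test_type_one_error_rate_near_nominal(self):
        """Under the null, the Wald p for the condition term rejects at
        roughly the nominal 5 % level (80 simulations, binomial bound)."""
        rejections = 0
        n_sim = 80
        for s in range(n_sim):
            data = simulate_lmm(seed=1000 + s, n_groups=20, n_per=6, effect=0.0)
            fit = sm.fit_mixed_model("y ~ condition + (1|participant)", data)
            if not fit.converged:
                continue
            p = sm.wald_anova(fit).loc["C(condition, Sum)", "p"]
            rejections += p < 0.05
        # binomial(80, 0.05): P(X > 11) < 1e-3, P(X = 0) ~ 0.017
        assert 0 < rejections <= 11


@pytest.fixture(scope="module")
def fit3():
    data = simulate_lmm(seed=10, n_groups=40, n_per=9, effect=0.0)
    rng = np.random.default_rng(11)
    data["condition"] = rng.choice(["a", "b", "c"], size=len(data))
    data.loc[data.condition == "a", "y"] += 0.5
    return sm.fit_mixed_model("y ~ condition + (1|participant)", data)


class TestPosthocContrasts:
    def test_all_pairs_present(self, fit3):
        table = sm.posthoc_contrasts(fit3, "condition")
        assert list(table["contrast"]) == ["a - b", "a - c", "b - c"]

    def test_bonferroni_is_capped_multiple(self, fit3):
        table = sm.posthoc_contrasts(fit3, "condition", correction="bonferroni")
        expected = np.minimum(table["p"] * len(table), 1.0)
        assert np.allclose(table["p_corrected"], expected)

    def test_fdr_matches_independent_step_up(self, fit3):
        """Compare against a from-scratch Benjamini-Hochberg step-up."""
        table = sm.posthoc_contrasts(fit3, "condition", correction="fdr")
        p = table["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        adj = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj, 1.0)
        assert np.allclose(table["p_corrected"], expected)

    def test_planted_difference_detected(self, fit3):
        table = sm.posthoc_contrasts(fit3, "condition").set_index("contrast")
        assert table.loc["a - b", "estimate"] == pytest.approx(0.5, abs=0.15)
        assert table.loc["a - b", "p_corrected"] < 0.01
        assert table.loc["b - c", "p_corrected"] > 0.05

    def test_unknown_factor_rejected(self, fit3):
        with pytest.raises(KeyError):
            sm.posthoc_contrasts(fit3, "nonexistent")

    def test_invalid_correction_rejected(self, fit3):
        with pytest.raises(ValueError):
            sm.posthoc_contrasts(fit3, "condition", correction="holm")
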