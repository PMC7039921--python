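"""Mixed models, selection, variance partitioning, beta regression, PCA."""

import numpy as np
import pandas as pd
import pytest

from isoniche.core import InsufficientDataError
from isoniche.stats import (
    BetaFit,
    LmmSpec,
    ModelFit,
    backward_select,
    conditional_r2,
    fit_beta_proportions,
    fit_lmm,
    lr_test,
    morphometric_pca,
    shrink_proportions,
    wic_tnw,
)


def simulate_lmm(
    n_seals=20,
    n_obs=40,
    intercept=-21.61,
    slope=-0.30,
    sd_b0=0.45,
    sd_b1=0.03,
    noise=0.9,
    group_effects=None,
    interaction=None,
    seed=0,
):
    """Long-format segment data from a random-intercept/slope model."""
    rng = np.random.default_rng(seed)
    groups = list(group_effects) if group_effects else ["male"]
    rows = []
    for g in groups:
        for i in range(n_seals):
            b0 = rng.normal(0, sd_b0)
            b1 = rng.normal(0, sd_b1)
            ages = np.linspace(2.0, 8.5, n_obs)
            ge = group_effects[g] if group_effects else 0.0
            ia = (interaction or {}).get(g, 0.0)
            y = (intercept + ge + b0 + (slope + ia + b1) * ages
                 + rng.normal(0, noise, n_obs))
            for k, (a, v) in enumerate(zip(ages, y)):
                rows.append({"seal_id": f"{g}_{i}", "group": g, "age": a,
                             "y": v, "position_mm": 5.0 * k})
    df = pd.DataFrame(rows)
    if group_effects:
        df["group"] = pd.Categorical(df["group"], categories=groups)
    return df


def _stub_fit(between, within, fe_pred=None):
    return ModelFit(
        response="d13C", fixed_terms=(), fixed_effects={},
        variance_components=(between, within), log_likelihood=0.0, aic=0.0,
        reml=True, n_fixed_params=1,
        fe_predictions=np.zeros(10) if fe_pred is None else fe_pred,
    )


class TestFitLmm:
    def test_near_noiseless_slope_recovery(self):
        df = simulate_lmm(n_seals=6, n_obs=20, sd_b0=0.3, sd_b1=0.0,
                          noise=1e-7, seed=1)
        fit = fit_lmm(df, LmmSpec("y", fixed=("age",)))
        assert fit.fixed_effects["age"][0] == pytest.approx(-0.30, abs=1e-6)

    def test_variance_components_match_anova_oracle(self):
        # balanced random-intercept data: REML components agree with the
        # method-of-moments one-way ANOVA estimates
        rng = np.random.default_rng(4)
        rows = []
        for i in range(50):
            b = rng.normal(0, 0.7)
            for k in range(50):
                rows.append({"seal_id": f"s{i}", "age": 1.0 + 0.1 * k,
                             "y": b + rng.normal(0, 1.2),
                             "position_mm": 5.0 * k})
        df = pd.DataFrame(rows)
        fit = fit_lmm(df, LmmSpec("y", fixed=(), random_slope=False))
        g = df.groupby("seal_id")["y"]
        msw = g.var(ddof=1).mean()
        msb = g.mean().var(ddof=1) * 50
        between, within = fit.variance_components
        assert within == pytest.approx(msw, rel=0.02)
        assert between == pytest.approx((msb - msw) / 50, rel=0.02)

    def test_iid_data_gives_tiny_between_variance(self):
        rng = np.random.default_rng(5)
        rows = [
            {"seal_id": f"s{i}", "age": 1.0 + 0.2 * k,
             "y": rng.normal(0, 1.0), "position_mm": 5.0 * k}
            for i in range(25) for k in range(25)
        ]
        fit = fit_lmm(pd.DataFrame(rows),
                      LmmSpec("y", fixed=(), random_slope=False))
        between, within = fit.variance_components
        assert between < 0.05 * within

    def test_ar_whitening_recovers_phi(self):
        # residuals generated with AR(2) innovations along each whisker
        rng = np.random.default_rng(6)
        phi_true = np.array([0.45, -0.25])
        rows = []
        for i in range(25):
            b = rng.normal(0, 0.6)
            e = np.zeros(60)
            for t in range(60):
                e[t] = (phi_true[0] * e[t - 1] if t >= 1 else 0.0) \
                    + (phi_true[1] * e[t - 2] if t >= 2 else 0.0) \
                    + rng.normal(0, 0.5)
            ages = np.linspace(2, 8, 60)
            for k, a in enumerate(ages):
                rows.append({"seal_id": f"s{i}", "age": a,
                             "y": b - 0.3 * a + e[k], "position_mm": 5.0 * k})
        fit = fit_lmm(pd.DataFrame(rows),
                      LmmSpec("y", fixed=("age",), random_slope=False,
                              ar_order=2))
        assert not fit.ar_fallback
        np.testing.assert_allclose(fit.residual_correlation, phi_true,
                                   atol=0.12)

    def test_insufficient_data_errors(self):
        df = simulate_lmm(n_seals=1, n_obs=10)
        with pytest.raises(InsufficientDataError):
            fit_lmm(df, LmmSpec("y", fixed=("age",)))


class TestBackwardSelect:
    def test_strong_interaction_retained(self):
        df = simulate_lmm(
            n_seals=8, n_obs=25, noise=0.5, seed=7,
            group_effects={"male": 0.0, "female_g1": 1.7},
            interaction={"male": 0.0, "female_g1": 0.4},
        )
        fit, trace = backward_select(df, LmmSpec("y"))
        assert "group:age" in fit.fixed_terms
        assert not trace[0]["dropped"]

    def test_null_interaction_dropped(self):
        df = simulate_lmm(
            n_seals=8, n_obs=25, noise=0.9, seed=8,
            group_effects={"male": 0.0, "female_g1": 1.7, "female_g2": 3.6},
        )
        fit, trace = backward_select(df, LmmSpec("y"))
        assert trace[0]["term"] == "group:age"
        assert trace[0]["dropped"]
        assert set(fit.fixed_terms) == {"group", "age"}

    def test_never_drops_significant_terms(self):
        df = simulate_lmm(
            n_seals=8, n_obs=25, noise=0.9, seed=9,
            group_effects={"male": 0.0, "female_g1": 1.7},
        )
        _, trace = backward_select(df, LmmSpec("y"))
        for step in trace:
            if step["p"] < 0.05:
                assert not step["dropped"]

    def test_single_candidate_trace(self):
        df = simulate_lmm(n_seals=6, n_obs=20, seed=10)
        _, trace = backward_select(df, LmmSpec("y", fixed=("age",)))
        assert len(trace) <= 2  # age kept (step 1); nothing else to test

    def test_lr_requires_ml(self):
        df = simulate_lmm(n_seals=6, n_obs=20, seed=11)
        full = fit_lmm(df, LmmSpec("y", fixed=("age",)), reml=True)
        red = fit_lmm(df, LmmSpec("y", fixed=()), reml=True)
        with pytest.raises(ValueError):
            lr_test(full, red)


class TestConditionalR2:
    def test_noiseless_limit(self):
        fit = _stub_fit(between=1.0, within=0.0)
        assert conditional_r2(fit) == 1.0

    def test_equal_components_no_fixed(self):
        fit = _stub_fit(between=1.0, within=1.0)
        assert conditional_r2(fit) == 0.5

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            conditional_r2(_stub_fit(0.0, 0.0))


class TestWicTnw:
    def test_extremes(self):
        assert wic_tnw(_stub_fit(between=0.0, within=2.3)).index == 1.0
        assert wic_tnw(_stub_fit(between=2.3, within=0.0)).index == 0.0
        with pytest.raises(ValueError):
            wic_tnw(_stub_fit(0.0, 0.0))

    def test_location_and_scale_invariance(self):
        rng = np.random.default_rng(12)
        rows = []
        for i in range(20):
            b = rng.normal(0, 1.0)
            for k in range(20):
                rows.append({"seal_id": f"s{i}", "age": 1 + 0.3 * k,
                             "y": b + rng.normal(0, 1.0),
                             "position_mm": 5.0 * k})
        df = pd.DataFrame(rows)
        spec = LmmSpec("y", fixed=(), random_slope=False)
        base = wic_tnw(fit_lmm(df, spec)).index
        shifted = df.assign(y=df["y"] + 100.0)
        scaled = df.assign(y=df["y"] * 7.0)
        assert wic_tnw(fit_lmm(shifted, spec)).index == pytest.approx(base,
                                                                      abs=1e-3)
        assert wic_tnw(fit_lmm(scaled, spec)).index == pytest.approx(base,
                                                                     abs=1e-3)


class TestBetaProportions:
    def test_group_mean_recovery(self):
        rng = np.random.default_rng(13)
        phi = 12.0
        truth = {"female_g2": 0.858, "female_g1": 0.326, "male": 0.026}
        y, g = [], []
        for grp, n in (("female_g2", 6), ("female_g1", 14), ("male", 20)):
            m = truth[grp]
            y.extend(rng.beta(m * phi, (1 - m) * phi, n))
            g.extend([grp] * n)
        fit = fit_beta_proportions(np.array(y), np.array(g))
        for grp, m in truth.items():
            assert fit.group_means[grp] == pytest.approx(m, abs=0.1)
        assert fit.lr_p < 0.001

    def test_null_lr_pvalues_uniform(self):
        from scipy import stats as sps

        rng = np.random.default_rng(14)
        ps = []
        for _ in range(200):
            y = rng.beta(2, 4, 40)
            g = np.r_[["a"] * 20, ["b"] * 20]
            ps.append(fit_beta_proportions(y, g).lr_p)
        assert sps.kstest(ps, "uniform").pvalue > 0.005

    def test_single_group_intercept_near_mean(self):
        rng = np.random.default_rng(15)
        y = rng.beta(5, 5, 30)
        fit = fit_beta_proportions(y)
        assert isinstance(fit, BetaFit)
        assert fit.group_means["all"] == pytest.approx(float(np.mean(y)),
                                                       rel=0.05)

    def test_boundary_shrinkage_and_degenerate(self):
        y = shrink_proportions(np.array([0.0, 1.0, 0.5]), 3)
        assert 0.0 < y.min() and y.max() < 1.0
        with pytest.raises(ValueError):
            fit_beta_proportions(np.full(10, 0.4))


class TestMorphometricPca:
    def _records(self, offset=1.0, n1=14, n2=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for grp, n, f in (("female_g1", n1, 1.0), ("female_g2", n2, offset)):
            for i in range(n):
                rows.append({
                    "seal_id": f"{grp}_{i}", "group": grp,
                    "mass_kg": rng.normal(35 * f, 4),
                    "length_cm": rng.normal(125 * f, 6),
                    "span_cm": rng.normal(130 * f, 6),
                    "girth_cm": rng.normal(95 * f, 8),
                })
        return pd.DataFrame(rows)

    def test_orthonormal_loadings(self):
        res = morphometric_pca(self._records())
        l = res.loadings.to_numpy()
        np.testing.assert_allclose(l.T @ l, np.eye(l.shape[1]), atol=1e-10)

    def test_identical_groups_mostly_nonsignificant(self):
        ps = [morphometric_pca(self._records(offset=1.0, seed=s)).welch["PC1"][1]
              for s in range(10)]
        assert np.mean(ps) > 0.2

    def test_offset_groups_detected(self):
        hits = sum(
            morphometric_pca(self._records(offset=1.10, seed=s)).welch["PC1"][1]
            < 0.05
            for s in range(10)
        )
        assert hits >= 6

    def test_missing_records_excluded_with_warning(self):
        df = self._records()
        df.loc[0, "mass_kg"] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            res = morphometric_pca(df)
        assert len(res.scores) == len(df) - 1

    def test_too_few_records(self):
        df = self._records(n2=2)
        with pytest.raises(InsufficientDataError):
            morphometric_pca(df)
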