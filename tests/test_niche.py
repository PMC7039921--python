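"""Standard ellipse areas, Bayesian posteriors, and overlap geometry."""

import numpy as np
import pytest

from isoniche.core import DegenerateInputError
from isoniche.niche import (
    EllipseFit,
    age_windows,
    ellipse_overlap,
    ellipse_polygon,
    fit_ellipse,
    ontogenetic_ellipses,
    sea_bayesian,
)


def _unit_fit(label, mean):
    return EllipseFit(label, 10, np.asarray(mean, float), np.eye(2),
                      np.pi, np.pi * 9 / 8)


def mc_overlap_area(mean_a, cov_a, mean_b, cov_b, n=1_000_000, seed=0):
    """Monte-Carlo hit-counting oracle for the ellipse intersection area."""
    rng = np.random.default_rng(seed)
    ia, ib = np.linalg.inv(cov_a), np.linalg.inv(cov_b)

    def bbox(mean, cov):
        r = np.sqrt(np.diag(cov))
        return mean - 1.05 * np.sqrt(np.max(np.linalg.eigvalsh(cov))), \
            mean + 1.05 * np.sqrt(np.max(np.linalg.eigvalsh(cov)))

    lo = np.minimum(bbox(mean_a, cov_a)[0], bbox(mean_b, cov_b)[0])
    hi = np.maximum(bbox(mean_a, cov_a)[1], bbox(mean_b, cov_b)[1])
    pts = rng.uniform(lo, hi, size=(n, 2))
    da = np.einsum("ni,ij,nj->n", pts - mean_a, ia, pts - mean_a)
    db = np.einsum("ni,ij,nj->n", pts - mean_b, ib, pts - mean_b)
    frac = np.mean((da <= 1.0) & (db <= 1.0))
    return frac * np.prod(hi - lo)


class TestFitEllipse:
    def test_hand_computed_covariance(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
        fit = fit_ellipse(pts)
        np.testing.assert_allclose(fit.cov, np.diag([4 / 3, 4 / 3]))
        assert fit.sea == pytest.approx(np.pi * 4 / 3, abs=1e-12)
        assert fit.sea_c == pytest.approx(fit.sea * 3 / 2)

    def test_identity_covariance_gives_pi(self):
        a = np.sqrt(1.5)
        pts = np.array([[a, 0.0], [-a, 0.0], [0.0, a], [0.0, -a]])
        fit = fit_ellipse(pts)
        assert fit.sea == pytest.approx(np.pi, abs=1e-12)

    def test_sea_equals_eigenvalue_form(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pts = rng.multivariate_normal([0, 0], [[2.0, 0.8], [0.8, 1.0]], 50)
            fit = fit_ellipse(pts)
            lam = np.linalg.eigvalsh(fit.cov)
            assert fit.sea == pytest.approx(np.pi * np.sqrt(lam.prod()), abs=1e-10)

    def test_rotation_invariance_and_scaling(self):
        rng = np.random.default_rng(1)
        pts = rng.multivariate_normal([0, 0], [[3.0, 1.0], [1.0, 2.0]], 200)
        fit = fit_ellipse(pts)
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert fit_ellipse(pts @ rot.T).sea == pytest.approx(fit.sea, rel=1e-10)
        assert fit_ellipse(3.0 * pts).sea == pytest.approx(9.0 * fit.sea, rel=1e-10)

    def test_containment_fraction(self):
        # the standard ellipse holds 1 − e^{−1/2} ≈ 39.35% of a bivariate normal
        rng = np.random.default_rng(2)
        cov = np.array([[2.0, 0.7], [0.7, 1.0]])
        pts = rng.multivariate_normal([0, 0], cov, 100_000)
        d2 = np.einsum("ni,ij,nj->n", pts, np.linalg.inv(cov), pts)
        assert np.mean(d2 <= 1.0) == pytest.approx(1 - np.exp(-0.5), abs=0.005)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            fit_ellipse(np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(DegenerateInputError):
            fit_ellipse(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))


class TestSeaBayesian:
    def test_posterior_mode_near_ml_at_large_n(self):
        rng = np.random.default_rng(3)
        pts = rng.multivariate_normal([-20, 9], [[1.5, 0.3], [0.3, 1.0]], 500)
        fit = sea_bayesian(pts, n_draws=10_000, seed=1)
        assert abs(fit.sea_b_mode - fit.sea) / fit.sea < 0.05
        lo, hi = fit.sea_b_ci95
        assert lo <= fit.sea_b_mode <= hi
        assert np.all(fit.posterior_draws > 0)

    def test_interval_narrows_with_n(self):
        rng = np.random.default_rng(4)
        widths = {}
        for n in (50, 500, 5000):
            w = []
            for k in range(5):
                pts = rng.multivariate_normal([0, 0], [[2.0, 0.5], [0.5, 1.0]], n)
                fit = sea_bayesian(pts, n_draws=4000, seed=100 * n + k)
                w.append(fit.sea_b_ci95[1] - fit.sea_b_ci95[0])
            widths[n] = np.mean(w)
        assert widths[50] > widths[500] > widths[5000]

    def test_mode_converges_to_ml(self):
        rng = np.random.default_rng(5)
        pts = rng.multivariate_normal([0, 0], [[1.7, 0.4], [0.4, 1.2]], 5000)
        fit = sea_bayesian(pts, n_draws=10_000, seed=6)
        assert fit.sea_b_mode == pytest.approx(fit.sea, rel=0.02)

    def test_draw_floor(self):
        rng = np.random.default_rng(6)
        pts = rng.multivariate_normal([0, 0], np.eye(2), 30)
        with pytest.raises(ValueError):
            sea_bayesian(pts, n_draws=10)


class TestEllipseOverlap:
    def test_identical_ellipses(self):
        a = _unit_fit("a", [0, 0])
        ov = ellipse_overlap(a, _unit_fit("b", [0, 0]))
        assert ov.proportion == pytest.approx(1.0, abs=1e-3)

    def test_disjoint_ellipses(self):
        ov = ellipse_overlap(_unit_fit("a", [0, 0]), _unit_fit("b", [100, 0]))
        assert ov.area_overlap == 0.0 and ov.proportion == 0.0

    def test_unit_circle_lens_closed_form(self):
        # circles of radius 1 with centres 1 apart: lens area 2π/3 − √3/2
        ov = ellipse_overlap(_unit_fit("a", [0, 0]), _unit_fit("b", [1, 0]))
        lens = 2 * np.arccos(0.5) - 0.5 * np.sqrt(3)
        assert ov.area_overlap == pytest.approx(lens, rel=1e-4)
        union = 2 * np.pi - lens
        assert ov.proportion == pytest.approx(lens / union, rel=1e-3)

    def test_overlap_bounded_by_smaller_area(self):
        rng = np.random.default_rng(7)
        for k in range(10):
            a = fit_ellipse(rng.multivariate_normal([0, 0], [[2, 0.5], [0.5, 1]], 40))
            b = fit_ellipse(rng.multivariate_normal([0.5, 0.3], [[1, 0], [0, 1]], 40))
            ov = ellipse_overlap(a, b)
            assert ov.area_overlap <= min(a.sea, b.sea) + 1e-9

    def test_against_monte_carlo_oracle(self):
        rng = np.random.default_rng(8)
        for k in range(5):
            ca = np.array([[1.5, 0.4], [0.4, 0.8]]) * (0.5 + k * 0.3)
            cb = np.array([[0.9, -0.2], [-0.2, 1.4]])
            ma, mb = np.array([0.0, 0.0]), np.array([0.8, 0.4])
            a = EllipseFit("a", 9, ma, ca, np.pi * np.sqrt(np.linalg.det(ca)), 0)
            b = EllipseFit("b", 9, mb, cb, np.pi * np.sqrt(np.linalg.det(cb)), 0)
            ov = ellipse_overlap(a, b)
            oracle = mc_overlap_area(ma, ca, mb, cb, n=400_000, seed=k)
            assert ov.area_overlap == pytest.approx(oracle, rel=0.02)

    def test_proportion_definitions(self):
        a = _unit_fit("a", [0, 0])
        b = _unit_fit("b", [1, 0])
        union = ellipse_overlap(a, b, proportion_def="union")
        smaller = ellipse_overlap(a, b, proportion_def="smaller")
        assert smaller.proportion > union.proportion
        assert smaller.proportion_def == "smaller"

    def test_bayesian_overlap_fields(self):
        rng = np.random.default_rng(9)
        a = sea_bayesian(rng.multivariate_normal([0, 0], np.eye(2), 80),
                         "a", n_draws=2000, seed=1)
        b = sea_bayesian(rng.multivariate_normal([1, 0], np.eye(2), 80),
                         "b", n_draws=2000, seed=2)
        ov = ellipse_overlap(a, b, n_bayes_draws=200, seed=3)
        lo, hi = ov.bayes_ci95
        assert 0.0 <= lo <= hi <= 1.0
        assert ov.bayes_mode is not None


class TestOntogeneticEllipses:
    def _series_with_chronologies(self, slope=0.0, n_seals=6, seed=0):
        from isoniche.chronology import assign_ages
        from isoniche.core import WhiskerSeries

        rng = np.random.default_rng(seed)
        series, chron = [], []
        for i in range(n_seals):
            x = np.arange(50) * 5.0
            ages = 9.0 - x / (0.096 * 365.25)
            d13c = -21.0 + slope * ages + rng.normal(0, 0.4, 50)
            d15n = 9.0 + rng.normal(0, 0.4, 50)
            s = WhiskerSeries(f"m{i}", "male", x, d13c, d15n)
            series.append(s)
            chron.append(assign_ages(s, 0.096, age_at_collection=9.0))
        return series, chron

    def test_single_window_equals_global_fit(self):
        series, chron = self._series_with_chronologies()
        out = ontogenetic_ellipses(series, chron, window_years=20.0,
                                   group_filter="male")
        assert len(out) == 1
        _, fit, _ = out[0]
        pts = np.concatenate([np.column_stack([s.d13C, s.d15N]) for s in series])
        assert fit.sea == pytest.approx(fit_ellipse(pts).sea, rel=1e-12)

    def test_declining_d13c_across_windows(self):
        series, chron = self._series_with_chronologies(slope=-0.30)
        out = ontogenetic_ellipses(series, chron, group_filter="male")
        means = [fit.mean[0] for (_, fit, _) in out]
        # δ13C declines with age: later (older) windows have lower means
        assert all(b < a for a, b in zip(means, means[1:]))

    def test_sparse_window_skipped_with_warning(self):
        series, chron = self._series_with_chronologies(n_seals=1)
        with pytest.warns(UserWarning, match="skipped"):
            out = ontogenetic_ellipses(series, chron, group_filter="male")
        assert all(fit.n >= 3 for (_, fit, _) in out)

    def test_separated_reference_gives_zero_overlap(self):
        series, chron = self._series_with_chronologies()
        ref = {"far": _unit_fit("far", [50.0, 50.0])}
        out = ontogenetic_ellipses(series, chron, group_filter="male",
                                   reference_fits=ref)
        assert all(ovs["far"].proportion == 0.0 for (_, _, ovs) in out)


def test_age_windows_start_at_half_year():
    w = age_windows(3.2)
    assert w[0] == (0.5, 1.0)
    assert w[-1][1] >= 3.2


def test_ellipse_polygon_area():
    cov = np.array([[2.0, 0.3], [0.3, 0.9]])
    poly = ellipse_polygon(np.zeros(2), cov)
    assert poly.area == pytest.approx(np.pi * np.sqrt(np.linalg.det(cov)),
                                      rel=1e-4)
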