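"""Isotopic niche ellipses: SEA, SEA_c, Bayesian SEA_B, and overlaps.

The isotopic niche of a group is summarised by the standard ellipse of its
(δ13C, δ15N) point cloud: the contour at Mahalanobis radius 1, whose area is

    SEA = π·sqrt(det Σ̂)   (‰²),

containing 1 − e^(−1/2) ≈ 39.35% of a bivariate normal ("≈40% of the data").
SEA_c applies the small-sample correction (n−1)/(n−2).  SEA_B propagates
sampling uncertainty by drawing covariances from a conjugate normal–
inverse-Wishart posterior under a vague prior; the posterior mode and 95%
credibility interval are reported.  Overlaps between ellipses are computed
by polygon clipping, with the overlap proportion taken over the union area
by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from shapely.geometry import Polygon

from .core import DegenerateInputError


@dataclass
class EllipseFit:
    """Bivariate niche summary for one group of (δ13C, δ15N) points."""

    group_label: str
    n: int
    mean: np.ndarray  # (2,) ‰
    cov: np.ndarray  # (2, 2) ‰², unbiased sample covariance
    sea: float  # ‰², ML standard ellipse area
    sea_c: float  # ‰², small-sample corrected
    posterior_draws: np.ndarray | None = None  # SEA_B draws, ‰²
    sea_b_mode: float | None = None
    sea_b_ci95: tuple[float, float] | None = None
    posterior_mean_draws: np.ndarray | None = field(default=None, repr=False)
    posterior_cov_draws: np.ndarray | None = field(default=None, repr=False)


@dataclass
class OverlapResult:
    """Intersection of two standard ellipses."""

    area_overlap: float  # ‰²
    proportion: float  # in [0, 1]
    proportion_def: str  # "union" | "smaller"
    bayes_mode: float | None = None
    bayes_ci95: tuple[float, float] | None = None


def fit_ellipse(points: np.ndarray, label: str = "") -> EllipseFit:
    """ML standard-ellipse fit of an n×2 point cloud."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an n×2 array of (δ13C, δ15N)")
    n = pts.shape[0]
    if n < 3:
        raise DegenerateInputError(f"group {label!r}: need >= 3 points, got {n}")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    det = float(np.linalg.det(cov))
    if det <= 0 or np.linalg.matrix_rank(cov) < 2:
        raise DegenerateInputError(f"group {label!r}: singular covariance")
    sea = float(np.pi * np.sqrt(det))
    return EllipseFit(
        group_label=label,
        n=n,
        mean=mean,
        cov=cov,
        sea=sea,
        sea_c=sea * (n - 1) / (n - 2),
    )


def _kde_mode(draws: np.ndarray, grid_size: int = 512) -> float:
    kde = stats.gaussian_kde(draws, bw_method="silverman")
    grid = np.linspace(draws.min(), draws.max(), grid_size)
    return float(grid[np.argmax(kde(grid))])


def sea_bayesian(
    points: np.ndarray,
    label: str = "",
    n_draws: int = 100_000,
    kappa0: float = 1e-3,
    nu0: float = 3.0,
    psi0: np.ndarray | None = None,
    seed: int | None = 0,
) -> EllipseFit:
    """SEA_B via a conjugate normal–inverse-Wishart posterior.

    Vague prior: prior mean at the sample mean, precision kappa0 = 1e-3,
    scale matrix psi0 = identity, nu0 = 3 degrees of freedom.  One SEA is
    computed per posterior covariance draw; the mode comes from a Gaussian
    kernel density (Silverman bandwidth) over the draws, the interval from
    the 2.5/97.5 posterior percentiles.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    fit = fit_ellipse(points, label)
    pts = np.asarray(points, dtype=float)
    n = fit.n
    psi0 = np.eye(2) if psi0 is None else np.asarray(psi0, float)

    s = (n - 1) * fit.cov  # scatter about the sample mean
    kappa_n = kappa0 + n
    nu_n = nu0 + n
    psi_n = psi0 + s  # prior mean = sample mean, so no shrinkage term

    rng = np.random.default_rng(seed)
    cov_draws = stats.invwishart.rvs(df=nu_n, scale=psi_n, size=n_draws, random_state=rng)
    cov_draws = np.asarray(cov_draws).reshape(n_draws, 2, 2)
    dets = np.linalg.det(cov_draws)
    draws = np.pi * np.sqrt(np.clip(dets, 0.0, None))

    # mean | cov ~ N(sample mean, cov / kappa_n)
    z = rng.standard_normal((n_draws, 2))
    chol = np.linalg.cholesky(cov_draws / kappa_n)
    mean_draws = fit.mean + np.einsum("nij,nj->ni", chol, z)

    lo, hi = np.percentile(draws, [2.5, 97.5])
    fit.posterior_draws = draws
    fit.sea_b_mode = _kde_mode(draws)
    fit.sea_b_ci95 = (float(lo), float(hi))
    fit.posterior_mean_draws = mean_draws
    fit.posterior_cov_draws = cov_draws
    return fit


def ellipse_polygon(
    mean: np.ndarray, cov: np.ndarray, radius2: float = 1.0, n_vertices: int = 1024
) -> Polygon:
    """Polygonal approximation of the ellipse x: (x−μ)ᵀΣ⁻¹(x−μ) ≤ radius2.

    radius2 = 1 gives the standard ellipse; chi2(2).ppf(0.95) gives the 95%
    prediction ellipse used for plotting.
    """
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    chol = np.linalg.cholesky(np.asarray(cov, float) * radius2)
    return Polygon(np.asarray(mean, float) + circle @ chol.T)


def _overlap_area(mean_a, cov_a, mean_b, cov_b, n_vertices=1024) -> tuple[float, float, float]:
    pa = ellipse_polygon(mean_a, cov_a, n_vertices=n_vertices)
    pb = ellipse_polygon(mean_b, cov_b, n_vertices=n_vertices)
    return pa.intersection(pb).area, pa.area, pb.area


def _proportion(overlap: float, area_a: float, area_b: float, definition: str) -> float:
    if definition == "union":
        denom = area_a + area_b - overlap
    elif definition == "smaller":
        denom = min(area_a, area_b)
    else:
        raise ValueError(f"unknown proportion definition {definition!r}")
    return overlap / denom if denom > 0 else 0.0


def ellipse_overlap(
    a: EllipseFit,
    b: EllipseFit,
    proportion_def: str = "union",
    n_bayes_draws: int = 1000,
    n_vertices: int = 1024,
    seed: int | None = 0,
) -> OverlapResult:
    """Overlap of two ML standard ellipses, optionally with a Bayesian variant.

    The intersection area comes from polygon clipping of dense ellipse
    polygons (relative error well below 1e-3 at the default vertex count).
    When both fits carry posterior draws, the overlap proportion is
    recomputed for ``n_bayes_draws`` posterior (mean, cov) pairs and the
    posterior mode and 95% interval reported.
    """
    overlap, area_a, area_b = _overlap_area(a.mean, a.cov, b.mean, b.cov, n_vertices)
    result = OverlapResult(
        area_overlap=float(overlap),
        proportion=float(_proportion(overlap, area_a, area_b, proportion_def)),
        proportion_def=proportion_def,
    )
    if a.posterior_cov_draws is not None and b.posterior_cov_draws is not None:
        rng = np.random.default_rng(seed)
        na = len(a.posterior_cov_draws)
        nb = len(b.posterior_cov_draws)
        take = min(n_bayes_draws, na, nb)
        ia = rng.choice(na, take, replace=False)
        ib = rng.choice(nb, take, replace=False)
        props = np.empty(take)
        for k in range(take):
            ov, aa, ab = _overlap_area(
                a.posterior_mean_draws[ia[k]],
                a.posterior_cov_draws[ia[k]],
                b.posterior_mean_draws[ib[k]],
                b.posterior_cov_draws[ib[k]],
                n_vertices=256,
            )
            props[k] = _proportion(ov, aa, ab, proportion_def)
        lo, hi = np.percentile(props, [2.5, 97.5])
        if np.ptp(props) == 0.0:
            result.bayes_mode = float(props[0])
        else:
            result.bayes_mode = _kde_mode(props)
        result.bayes_ci95 = (float(lo), float(hi))
    return result


def age_windows(max_age: float, first: tuple[float, float] = (0.5, 1.0)) -> list[tuple[float, float]]:
    """Annual age windows starting with the late-suckling window (0.5-1 yr)."""
    windows = [first]
    hi = first[1]
    while hi < max_age:
        windows.append((hi, hi + 1.0))
        hi += 1.0
    return windows


def ontogenetic_ellipses(
    series_list,
    chronologies,
    window_years: float = 1.0,
    group_filter: str | None = "male",
    groups: dict[str, str] | None = None,
    reference_fits: dict[str, EllipseFit] | None = None,
    proportion_def: str = "union",
):
    """Age-windowed niche ellipses of one group, with overlaps vs references.

    Segments of every seal in ``group_filter`` are pooled by the estimated
    age of the segment into annual windows (first window 0.5-1 yr); an
    ellipse is fitted per window with at least 3 points (windows with fewer
    are skipped with a warning) and its overlap against each full-record
    reference ellipse is computed.

    Returns a list of (window, EllipseFit, {ref_label: OverlapResult}).
    """
    if window_years <= 0:
        raise ValueError("window_years must be positive")
    chron_by_id = {c.seal_id: c for c in chronologies}
    pts, ages = [], []
    for s in series_list:
        if s.seal_id not in chron_by_id:
            raise KeyError(f"no chronology for seal {s.seal_id}")
        label = groups.get(s.seal_id, s.sex) if groups else s.sex
        if group_filter is not None and label != group_filter:
            continue
        c = chron_by_id[s.seal_id]
        pts.append(np.column_stack([s.d13C, s.d15N]))
        ages.append(c.ages)
    if not pts:
        raise DegenerateInputError("no seals in the requested group")
    pts = np.concatenate(pts)
    ages = np.concatenate(ages)

    first = (0.5, min(1.0, 0.5 + window_years))
    if window_years != 1.0:
        windows = [(0.5 + k * window_years, 0.5 + (k + 1) * window_years)
                   for k in range(int(np.ceil((ages.max() - 0.5) / window_years)))]
    else:
        windows = age_windows(float(ages.max()), first)

    out = []
    for lo, hi in windows:
        in_win = (ages >= lo) & (ages < hi)
        if in_win.sum() < 3:
            warnings.warn(
                f"age window {lo:g}-{hi:g} yr: only {int(in_win.sum())} "
                "segments, skipped"
            )
            continue
        try:
            fit = fit_ellipse(pts[in_win], label=f"{group_filter}_{lo:g}-{hi:g}y")
        except DegenerateInputError:
            warnings.warn(f"age window {lo:g}-{hi:g} yr: degenerate cloud, skipped")
            continue
        overlaps = {}
        for ref_label, ref in (reference_fits or {}).items():
            overlaps[ref_label] = ellipse_overlap(fit, ref, proportion_def)
        out.append(((lo, hi), fit, overlaps))
    if not out:
        raise DegenerateInputError("no age window had sufficient data")
    return out
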