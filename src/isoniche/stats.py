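"""Ontogenetic mixed models, specialisation indices, and group comparisons.

Per-segment isotope values are modelled with linear mixed models: fixed
effects of foraging group, age and their interaction; random intercept and
age slope per seal; optionally AR(2)-correlated residuals along the whisker.
A global model is refined by backward-stepwise deletion with likelihood-ratio
tests (maximum-likelihood fits for the comparisons; the final model is refit
by REML).  Variance components from the best-fit model give the individual
specialisation index WIC/TNW (within-individual variance over total niche
width): 0 means complete individual specialists, 1 means every individual
spans the population's whole niche.  Per-seal proportions of time north of
the front are compared between groups with a logit-link beta regression, and
female morphometrics with a PCA followed by Welch's t-tests on the component
scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
from scipy.linalg import solve_toeplitz
from sklearn.decomposition import PCA
from statsmodels.othermod.betareg import BetaModel
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .core import InsufficientDataError, IsonicheError


class FitError(IsonicheError):
    """Mixed-model optimisation failed."""


@dataclass
class LmmSpec:
    """Mixed-model specification for one response."""

    response: str
    fixed: tuple = ("group", "age", "group:age")
    random_slope: bool = True
    ar_order: int = 0  # 0 = independent residuals; 2 = corAR(2) whitening


@dataclass
class ModelFit:
    """Fitted mixed model summary."""

    response: str
    fixed_terms: tuple
    fixed_effects: dict  # name -> (estimate, se, p)
    variance_components: tuple  # (between_individual, within_individual)
    log_likelihood: float
    aic: float
    reml: bool
    n_fixed_params: int
    fe_predictions: np.ndarray = field(repr=False, default=None)
    residual_correlation: tuple | None = None
    r2_conditional: float | None = None
    singular_re: bool = False
    ar_fallback: bool = False
    random_slope: bool = True
    confint: dict | None = None  # name -> (low, high), 95%


@dataclass
class SpecialisationIndex:
    response: str
    wic: float  # within-individual variance, ‰²
    tnw: float  # total niche width = within + between, ‰²
    index: float  # wic / tnw in [0, 1]


def _formula(response: str, terms: tuple) -> str:
    return f"{response} ~ {' + '.join(terms) if terms else '1'}"


def _pooled_ar_coefficients(resid: np.ndarray, groups: np.ndarray, order: int) -> np.ndarray:
    """Yule-Walker AR coefficients from residuals pooled within groups."""
    acov = np.zeros(order + 1)
    counts = np.zeros(order + 1)
    for g in pd.unique(groups):
        r = resid[groups == g]
        for k in range(order + 1):
            if r.size > k:
                acov[k] += np.dot(r[: r.size - k], r[k:])
                counts[k] += r.size - k
    acov = acov / np.maximum(counts, 1)
    if acov[0] <= 0:
        raise FitError("zero residual variance, cannot estimate AR structure")
    rho = acov / acov[0]
    return solve_toeplitz(rho[:order], rho[1 : order + 1])


def _ar_marginal_factor(phi: np.ndarray) -> float:
    """Ratio of marginal (stationary) AR variance to innovation variance,
    1 / (1 − Σ_k φ_k ρ_k), with autocorrelations ρ solved from the
    Yule-Walker relations ρ_j = Σ_k φ_k ρ_{|j−k|} (ρ_0 = 1)."""
    p = len(phi)
    a = np.eye(p)
    c = np.array(phi, float)  # contribution of the ρ_0 terms
    for j in range(1, p + 1):
        for k in range(1, p + 1):
            lag = abs(j - k)
            if lag > 0:
                a[j - 1, lag - 1] -= phi[k - 1]
    rho = np.linalg.solve(a, c)
    denom = 1.0 - float(np.dot(phi, rho))
    if denom <= 0:
        raise FitError("AR coefficients imply non-stationary residuals")
    return 1.0 / denom


def _whiten(mat: np.ndarray, groups: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Apply the AR filter v_t − Σ φ_k v_{t−k} within each group (conditional
    least-squares convention: the first ``order`` rows pass unchanged)."""
    order = len(phi)
    out = mat.astype(float).copy()
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        block = mat[idx].astype(float)
        w = block.copy()
        for k, p in enumerate(phi, start=1):
            w[k:] -= p * block[:-k]
        out[idx[order:]] = w[order:]
    return out


def _fit_arrays(y, x, groups, exog_re, names, reml):
    """Fit a MixedLM with a small multi-start over optimisers.

    Gradient optimisers routinely stall on variance-component boundaries, so
    lbfgs and powell are both run (nm as a last resort) and the best finite
    converged likelihood wins.
    """
    best = None
    errors = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for method in ("lbfgs", "powell", "nm"):
            model = MixedLM(y, x, groups=groups, exog_re=exog_re)
            try:
                res = model.fit(reml=reml, method=[method], maxiter=2000)
            except (np.linalg.LinAlgError, ValueError) as exc:
                errors.append(f"{method}: {exc}")
                continue
            ok = (res.converged and np.isfinite(res.llf)
                  and np.all(np.isfinite(res.fe_params)))
            if ok and (best is None or res.llf > best.llf):
                best = res
            if method == "powell" and best is not None:
                break  # nm only as a last resort
    if best is None:
        raise FitError(
            "mixed-model optimisation failed for every optimiser "
            f"({len(y)} rows, {x.shape[1]} fixed params; {'; '.join(errors) or 'no convergence'})"
        )
    return best


def fit_lmm(
    data: pd.DataFrame,
    spec: LmmSpec,
    reml: bool = True,
    position_col: str = "position_mm",
    group_col: str = "seal_id",
    fixed_phi: np.ndarray | None = None,
) -> ModelFit:
    """REML/ML fit of the segment-level mixed model.

    ``data`` is long-format with one row per segment, carrying the response,
    ``age``, ``group``, ``seal_id`` and (for AR structures) a position column
    ordering segments within the whisker.  With ``ar_order`` = 2, residual
    autocorrelation is handled by iterated feasible-GLS whitening: fit,
    estimate AR coefficients from within-whisker residuals by Yule-Walker,
    whiten response and design, refit.  If the AR stage fails, the
    independent-residual fit is returned with ``ar_fallback`` set.
    """
    if data[group_col].nunique() < 2:
        raise InsufficientDataError("need at least two individuals")
    counts = data.groupby(group_col).size()
    if (counts < 3).any():
        raise InsufficientDataError("every individual needs >= 3 observations")
    df = data.sort_values([group_col, position_col]).reset_index(drop=True)

    y_dm, x_dm = patsy.dmatrices(_formula(spec.response, spec.fixed), df,
                                 return_type="dataframe")
    y = np.asarray(y_dm).ravel()
    x = np.asarray(x_dm)
    names = list(x_dm.columns)
    groups = df[group_col].to_numpy()
    z_slope = np.column_stack([np.ones(len(df)), df["age"].to_numpy(float)])
    z_icpt = np.ones((len(df), 1))

    def _fit_best(yv, xv, zs, zi, want_slope):
        """Fit the requested RE structure; with a random slope, also fit the
        random-intercept submodel and keep whichever likelihood is higher —
        the slope variance often sits on the boundary, where gradient
        optimisers stall short of the (boundary) MLE."""
        if not want_slope:
            return _fit_arrays(yv, xv, groups, zi, names, reml), False
        ri = rs = None
        try:
            rs = _fit_arrays(yv, xv, groups, zs, names, reml)
        except FitError:
            pass
        try:
            ri = _fit_arrays(yv, xv, groups, zi, names, reml)
        except FitError:
            if rs is None:
                raise
        if rs is None:
            return ri, True
        if ri is not None and ri.llf > rs.llf + 1e-6:
            return ri, True
        return rs, False

    res, used_icpt = _fit_best(y, x, z_slope, z_icpt, spec.random_slope)
    z = z_icpt if used_icpt else (z_slope if spec.random_slope else z_icpt)
    phi = None
    ar_fallback = False
    if spec.ar_order > 0:
        try:
            if fixed_phi is not None:
                # caller-supplied filter (e.g. held fixed across nested fits
                # so their likelihoods stay comparable)
                phi = np.asarray(fixed_phi, float)
            else:
                try:
                    resid = np.asarray(res.resid)
                except (ValueError, np.linalg.LinAlgError):
                    # singular RE covariance blocks BLUPs; marginal residuals
                    resid = y - x @ np.asarray(res.fe_params)
                phi = _pooled_ar_coefficients(resid, groups, spec.ar_order)
            if np.any(np.abs(np.roots(np.r_[1, -phi])) > 0.95):
                # near-unit-root whitening would difference away the
                # between-individual signal; treat as non-stationary
                raise FitError("estimated AR process (near) non-stationary")
            res, used_icpt = _fit_best(
                _whiten(y[:, None], groups, phi).ravel(),
                _whiten(x, groups, phi),
                _whiten(z_slope, groups, phi),
                _whiten(z_icpt, groups, phi),
                spec.random_slope,
            )
        except (FitError, ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"AR({spec.ar_order}) stage failed ({exc}); "
                          "falling back to independent residuals")
            phi, ar_fallback = None, True

    has_slope = spec.random_slope and not used_icpt
    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    singular = used_icpt or bool(
        np.linalg.eigvalsh(cov_re).min() < 1e-10 * max(cov_re.max(), 1.0)
    )

    mean_age = float(df["age"].mean())
    if has_slope:
        w = np.array([1.0, mean_age])
        between = float(w @ cov_re @ w)
    else:
        between = float(cov_re[0, 0])
    within = float(res.scale)
    if phi is not None:
        # scale is the innovation variance of the whitened fit; report the
        # marginal (stationary) residual variance on the data scale
        within *= _ar_marginal_factor(phi)

    params = np.asarray(res.fe_params)
    bse = np.asarray(res.bse_fe)
    pvals = 2 * sps.norm.sf(np.abs(params / bse))
    # t-based intervals with between-individual df: Wald-normal intervals
    # undercover noticeably at a few dozen individuals
    df_t = max(data[group_col].nunique() - 1, 1)
    ci = {}
    for nm, est, se in zip(names, params, bse):
        half = sps.t.ppf(0.975, df_t) * se
        ci[nm] = (est - half, est + half)
    n_vc = cov_re.shape[0] * (cov_re.shape[0] + 1) // 2 + 1
    return ModelFit(
        response=spec.response,
        fixed_terms=tuple(spec.fixed),
        fixed_effects={nm: (float(e), float(s), float(p))
                       for nm, e, s, p in zip(names, params, bse, pvals)},
        variance_components=(between, within),
        log_likelihood=float(res.llf),
        aic=float(-2 * res.llf + 2 * (len(params) + n_vc)),
        reml=reml,
        n_fixed_params=len(params),
        fe_predictions=x @ params,
        residual_correlation=tuple(map(float, phi)) if phi is not None else None,
        singular_re=singular,
        ar_fallback=ar_fallback,
        random_slope=has_slope,
        confint=ci,
    )


def lr_test(full: ModelFit, reduced: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square test of nested ML fits."""
    if full.reml or reduced.reml:
        raise ValueError("LR tests on fixed effects require ML fits")
    stat = 2 * (full.log_likelihood - reduced.log_likelihood)
    dof = full.n_fixed_params - reduced.n_fixed_params
    if dof <= 0:
        raise ValueError("models are not properly nested")
    return float(max(stat, 0.0)), dof, float(sps.chi2.sf(max(stat, 0.0), dof))


def _droppable(terms: tuple) -> list[str]:
    interactions = [t for t in terms if ":" in t]
    if interactions:
        return interactions  # interactions are always tested first
    return list(terms)


def backward_select(
    data: pd.DataFrame,
    spec: LmmSpec,
    alpha: float = 0.05,
    **fit_kwargs,
) -> tuple[ModelFit, list[dict]]:
    """Backward-stepwise deletion of fixed effects by LR tests.

    At each step the droppable term with the largest LR p-value is removed
    when p >= alpha (ML fits for the comparisons); interaction terms are
    tested before their main effects.  With an AR structure, the whitening
    filter is estimated once under the global model and held fixed across
    nested fits so their likelihoods stay comparable.  Returns the final
    model refit by REML together with the selection trace.
    """
    terms = tuple(spec.fixed)
    phi = None
    if spec.ar_order > 0:
        prefit = fit_lmm(data, spec, reml=False, **fit_kwargs)
        if prefit.residual_correlation is not None:
            phi = np.asarray(prefit.residual_correlation)
    trace: list[dict] = []
    while terms:
        base = fit_lmm(data, LmmSpec(spec.response, terms, spec.random_slope,
                                     spec.ar_order), reml=False,
                       fixed_phi=phi, **fit_kwargs)
        best = None
        for term in _droppable(terms):
            reduced_terms = tuple(t for t in terms if t != term)
            red = fit_lmm(data, LmmSpec(spec.response, reduced_terms,
                                        spec.random_slope, spec.ar_order),
                          reml=False, fixed_phi=phi, **fit_kwargs)
            stat, dof, p = lr_test(base, red)
            if best is None or p > best[3]:
                best = (term, stat, dof, p)
        term, stat, dof, p = best
        dropped = p >= alpha
        trace.append({"term": term, "lr": stat, "df": dof, "p": p,
                      "dropped": dropped})
        if not dropped:
            break
        terms = tuple(t for t in terms if t != term)
    final = fit_lmm(data, LmmSpec(spec.response, terms, spec.random_slope,
                                  spec.ar_order), reml=True,
                    fixed_phi=phi, **fit_kwargs)
    final.r2_conditional = conditional_r2(final)
    return final, trace


def conditional_r2(fit: ModelFit) -> float:
    """Variance explained by fixed plus random effects (conditional R²):
    (var(Xβ) + σ²_between) / (var(Xβ) + σ²_between + σ²_within)."""
    between, within = fit.variance_components
    var_fixed = float(np.var(fit.fe_predictions))
    total = var_fixed + between + within
    if total <= 0:
        raise ValueError("zero total variance")
    return (var_fixed + between) / total


def wic_tnw(fit: ModelFit) -> SpecialisationIndex:
    """Individual specialisation index from the variance components.

    WIC is the within-individual variance, TNW = WIC + between-individual
    variance (evaluated at the mean age when a random slope is present);
    index = WIC/TNW.
    """
    between, within = fit.variance_components
    tnw = between + within
    if tnw <= 0:
        raise ValueError("total niche width is zero")
    return SpecialisationIndex(fit.response, wic=within, tnw=tnw,
                               index=within / tnw)


@dataclass
class BetaFit:
    """Beta regression of per-seal proportions on group."""

    params: dict
    group_means: dict  # group -> fitted mean proportion
    log_likelihood: float
    lr_stat: float | None = None
    lr_df: int | None = None
    lr_p: float | None = None


def shrink_proportions(p: np.ndarray, n: int) -> np.ndarray:
    """Pull 0/1 proportions off the boundary: (p·(n−1) + 0.5)/n."""
    return (np.asarray(p, float) * (n - 1) + 0.5) / n


def fit_beta_proportions(
    props, groups=None, lr_test_group: bool = True
) -> BetaFit:
    """Logit-link beta regression of proportions north on foraging group.

    Proportions are shrunk off {0, 1} first.  With more than one group, the
    group effect is tested by an LR test against the intercept-only model.
    One proportion exists per seal, so the model is a fixed-effects beta
    regression (an individual random effect would be unidentifiable).
    """
    y = shrink_proportions(np.asarray(props, float), len(np.asarray(props)))
    if np.ptp(y) == 0:
        raise ValueError("all proportions identical; beta fit is degenerate")
    df = pd.DataFrame({"prop": y})
    if groups is not None:
        df["group"] = np.asarray(groups)
    formula = "prop ~ group" if groups is not None and df["group"].nunique() > 1 else "prop ~ 1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = BetaModel.from_formula(formula, df).fit(disp=False)
    fit = BetaFit(
        params={k: float(v) for k, v in res.params.items()},
        group_means={},
        log_likelihood=float(res.llf),
    )
    if "group" in df.columns:
        for g in sorted(df["group"].unique()):
            fit.group_means[g] = float(
                np.mean(res.predict(pd.DataFrame({"group": [g]})))
            )
    else:
        fit.group_means["all"] = float(np.mean(res.predict(df.iloc[[0]])))
    if formula != "prop ~ 1" and lr_test_group:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null = BetaModel.from_formula("prop ~ 1", df).fit(disp=False)
        stat = 2 * (res.llf - null.llf)
        dof = len(res.params) - len(null.params)
        fit.lr_stat = float(max(stat, 0.0))
        fit.lr_df = dof
        fit.lr_p = float(sps.chi2.sf(max(stat, 0.0), dof))
    return fit


@dataclass
class PcaResult:
    loadings: pd.DataFrame  # variables × components, orthonormal columns
    scores: pd.DataFrame  # seal_id, group, PC1..PCk
    explained_variance_ratio: np.ndarray
    welch: dict  # component -> (t, p) between female groups


MORPHO_VARS = ("mass_kg", "length_cm", "span_cm", "girth_cm")


def morphometric_pca(
    records: pd.DataFrame,
    variables: tuple = MORPHO_VARS,
    compare_groups: tuple = ("female_g1", "female_g2"),
    n_welch_components: int = 2,
) -> PcaResult:
    """PCA of standardised morphometrics with Welch tests on the scores.

    Rows with missing morphometrics are excluded with a warning.  Welch's
    t-test compares the two female foraging groups on each of the first
    ``n_welch_components`` component scores.
    """
    cols = list(variables)
    complete = records.dropna(subset=cols)
    n_dropped = len(records) - len(complete)
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} records with missing morphometrics")
    for g in compare_groups:
        if (complete["group"] == g).sum() < 3:
            raise InsufficientDataError(f"fewer than 3 complete records in {g}")
    x = complete[cols].to_numpy(float)
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    k = min(len(cols), len(complete))
    pca = PCA(n_components=k)
    scores = pca.fit_transform(z)
    pc_names = [f"PC{i + 1}" for i in range(k)]
    score_df = complete[["seal_id", "group"]].reset_index(drop=True)
    score_df[pc_names] = scores
    welch = {}
    for pc in pc_names[:n_welch_components]:
        a = score_df.loc[score_df["group"] == compare_groups[0], pc]
        b = score_df.loc[score_df["group"] == compare_groups[1], pc]
        t, p = sps.ttest_ind(a, b, equal_var=False)
        welch[pc] = (float(t), float(p))
    return PcaResult(
        loadings=pd.DataFrame(pca.components_.T, index=cols, columns=pc_names),
        scores=score_df,
        explained_variance_ratio=pca.explained_variance_ratio_,
        welch=welch,
    )
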