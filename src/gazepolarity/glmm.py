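"""Binomial mixed models with crossed random effects, and the analysis
procedures built on them.

The estimator is a Laplace-approximation maximum-likelihood fit of a
logit-link Bernoulli GLMM with crossed grouping factors (participant or
session, and stimulus individual) and *uncorrelated* random intercepts and
slopes: the random-effect covariance is diagonal, with one standard
deviation shared across the dummy columns of a multi-level factor's slope.

For variance parameters θ = log σ and fixed effects β, the marginal
log-likelihood is approximated by

    ℓ(β, θ) = ℓ_cond(β, b̂) − ½ b̂ᵀD⁻¹b̂ − ½ log|D| − ½ log|ZᵀWZ + D⁻¹|

where b̂ is the conditional mode (found by a damped Newton iteration),
D = diag(σ²) and W the Bernoulli weights at the mode.  The outer problem
maximizes ℓ over (β, θ) jointly with L-BFGS-B; with no random terms the fit
reduces exactly to ordinary logistic regression.  Fixed-effect standard
errors come from the profiled information
X'WX − X'WZ (Z'WZ + D⁻¹)⁻¹ Z'WX at the optimum.

On top of the fitter sit the likelihood-ratio test for nested models, the
interaction-pruning testing procedure (drop nonsignificant higher-order
interactions before testing lower-order terms; stop and hand off to simple
effects when an interaction is significant), Bonferroni-corrected simple
effects, a Pearson-residual dispersion check, and nonparametric bootstrap
confidence intervals for proportions correct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "ModelSpec",
    "FitResult",
    "LrtResult",
    "BootstrapCI",
    "fit_glmm",
    "lrt",
    "prune_and_test",
    "simple_effects",
    "dispersion",
    "bootstrap_ci",
    "study1_exp1_spec",
    "study1_exp2_spec",
    "study2_spec",
    "build_design",
]

_GRAD_TOL = 1e-8
_THETA_BOUNDS = (np.log(1e-3), np.log(5.0))
_SEPARATION_BOUND = 15.0


# ---------------------------------------------------------------------------
# Model specification and design construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """A GLMM formula in structured form.

    ``fixed`` lists main-effect and interaction terms over the factor
    vocabulary {species, level, polarity, phase, block, trial}; interactions
    use ``:`` (e.g. ``"species:level"``).  ``random`` maps a grouping column
    to its slope terms, ``"1"`` meaning the intercept.  ``test_terms`` marks
    which fixed terms are hypothesis terms (the rest are controls).
    Treatment coding throughout: reference levels are the chimpanzee
    stimulus, the lowest stimulus level present, and normal polarity; block
    and within-block trial enter as centered numeric covariates.
    """

    fixed: tuple[str, ...]
    random: tuple[tuple[str, tuple[str, ...]], ...] = ()
    test_terms: tuple[str, ...] = ()
    response: str = "correct"

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(
            self, "random", tuple((g, tuple(ts)) for g, ts in self.random)
        )
        object.__setattr__(self, "test_terms", tuple(self.test_terms))

    def drop(self, term: str) -> "ModelSpec":
        """Remove one fixed term.  The random structure is kept unchanged so
        that nested fits differ only in their fixed parameters and the LRT
        df counts fixed effects (df = 3 for a four-level factor, etc.)."""
        if term not in self.fixed:
            raise ValueError(f"term {term!r} not in the model")
        return replace(
            self,
            fixed=tuple(t for t in self.fixed if t != term),
            test_terms=tuple(t for t in self.test_terms if t != term),
        )

    @property
    def n_variance_components(self) -> int:
        return sum(len(ts) for _, ts in self.random)


def study1_exp1_spec(maximal_slopes: bool = True) -> ModelSpec:
    """Keypress experiment 1: species x level, participant and stimulus
    random factors, all-slope (or intercept+species) participant structure."""
    fixed = ("species", "level", "species:level", "block", "trial")
    p_slopes = ("1", "species", "level", "species:level") if maximal_slopes else ("1", "species")
    return ModelSpec(
        fixed=fixed,
        random=(("participant_id", p_slopes), ("stimulus_id", ("1",))),
        test_terms=("species", "level", "species:level"),
    )


def study1_exp2_spec(maximal_slopes: bool = True) -> ModelSpec:
    """Keypress experiment 2: species x level x polarity."""
    fixed = (
        "species",
        "level",
        "polarity",
        "species:level",
        "species:polarity",
        "level:polarity",
        "species:level:polarity",
        "block",
        "trial",
    )
    p_slopes = (
        ("1", "species", "level", "polarity", "species:level", "species:polarity",
         "level:polarity", "species:level:polarity")
        if maximal_slopes
        else ("1", "species", "polarity")
    )
    return ModelSpec(
        fixed=fixed,
        random=(("participant_id", p_slopes), ("stimulus_id", ("1",))),
        test_terms=(
            "species",
            "level",
            "polarity",
            "species:level",
            "species:polarity",
            "level:polarity",
            "species:level:polarity",
        ),
    )


def study2_spec(with_phase: bool = False) -> ModelSpec:
    """Visual-search task, one participant: species as the test factor,
    session and stimulus individual as random factors, no level term (the
    adaptive staircase confounds level with session, which the session
    random factor absorbs)."""
    if with_phase:
        fixed = ("species", "phase", "species:phase", "block", "trial")
        test = ("species", "phase", "species:phase")
    else:
        fixed = ("species", "block", "trial")
        test = ("species",)
    return ModelSpec(
        fixed=fixed,
        random=(("session_id", ("1", "species")), ("stimulus_id", ("1",))),
        test_terms=test,
    )


def _component_columns(data: pd.DataFrame, comp: str) -> list[tuple[str, np.ndarray]]:
    if comp == "species":
        return [("species[human]", (data["species"] == "human").to_numpy(float))]
    if comp == "polarity":
        return [("polarity[reversed]", (data["polarity"] == "reversed").to_numpy(float))]
    if comp == "phase":
        vals = sorted(data["phase"].astype(str).unique())
        return [
            (f"phase[{v}]", (data["phase"].astype(str) == v).to_numpy(float))
            for v in vals[1:]
        ]
    if comp == "level":
        lev = data["level"].astype(float)
        vals = sorted(lev.unique())
        return [(f"level[{v:g}]", (lev == v).to_numpy(float)) for v in vals[1:]]
    if comp == "block":
        x = data["block"].to_numpy(float)
        return [("block", x - x.mean())]
    if comp == "trial":
        x = data["trial_in_block"].to_numpy(float)
        return [("trial", x - x.mean())]
    raise ValueError(f"unknown model component {comp!r}")


def _term_columns(data: pd.DataFrame, term: str) -> list[tuple[str, np.ndarray]]:
    if term == "1":
        return [("Intercept", np.ones(len(data)))]
    parts = [_component_columns(data, c) for c in term.split(":")]
    cols = parts[0]
    for nxt in parts[1:]:
        cols = [(f"{n1}:{n2}", v1 * v2) for n1, v1 in cols for n2, v2 in nxt]
    return cols


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str], sp.csr_matrix, np.ndarray, list[str]]:
    """Assemble the response, fixed design X and sparse random design Z.

    Returns ``(y, X, x_names, Z, comp_of_col, comp_names)`` where
    ``comp_of_col`` maps each Z column to its variance-component index.
    """
    y = data[spec.response].to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")

    x_cols: list[tuple[str, np.ndarray]] = [("Intercept", np.ones(len(data)))]
    for term in spec.fixed:
        x_cols.extend(_term_columns(data, term))
    x_names = [n for n, _ in x_cols]
    X = np.column_stack([v for _, v in x_cols])

    rows, cols, vals = [], [], []
    comp_of_col: list[int] = []
    comp_names: list[str] = []
    offset = 0
    n = len(data)
    for group_col, terms in spec.random:
        codes, uniques = pd.factorize(data[group_col], sort=True)
        if len(uniques) < 2:
            raise ValueError(f"random factor {group_col!r} needs >= 2 levels")
        g = len(uniques)
        for term in terms:
            tcols = _term_columns(data, term)
            k = len(tcols)
            comp_idx = len(comp_names)
            comp_names.append(f"{group_col}:{term}")
            for j, (_, v) in enumerate(tcols):
                nz = np.flatnonzero(v)
                rows.append(nz)
                cols.append(offset + codes[nz] * k + j)
                vals.append(v[nz])
            comp_of_col.extend([comp_idx] * (g * k))
            offset += g * k
    if comp_names:
        Z = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, offset),
        )
    else:
        Z = sp.csr_matrix((n, 0))
    return y, X, x_names, Z, np.asarray(comp_of_col, dtype=int), comp_names


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """A converged (or honestly flagged) GLMM fit."""

    params: pd.Series
    se: pd.Series
    sigma: dict[str, float]
    loglik: float
    converged: bool
    nobs: int
    spec: ModelSpec
    fitted: np.ndarray  # conditional response probabilities
    response: np.ndarray
    separation: bool = False
    message: str = ""

    @property
    def n_fixed(self) -> int:
        return len(self.params)

    @property
    def n_params(self) -> int:
        return len(self.params) + len(self.sigma)


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log p for y=1, log(1-p) for y=0, numerically stable
    return float(-np.sum(np.logaddexp(0.0, eta) - y * eta))


def _fit_logistic(
    y: np.ndarray, X: np.ndarray, beta0: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Damped-Newton logistic regression.  Returns (beta, cov, loglik, ok)."""
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    ll = _bernoulli_loglik(y, X @ beta)
    ok = False
    for _ in range(100):
        eta = X @ beta
        mu = expit(eta)
        g = X.T @ (y - mu)
        if np.max(np.abs(g)) < _GRAD_TOL:
            ok = True
            break
        w = mu * (1 - mu) + 1e-12
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new = _bernoulli_loglik(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta = beta + t * step
        ll = _bernoulli_loglik(y, X @ beta)
    mu = expit(X @ beta)
    w = mu * (1 - mu) + 1e-12
    H = (X * w[:, None]).T @ X
    cov = np.linalg.pinv(H)
    return beta, cov, ll, ok


class _LaplaceObjective:
    """Negative Laplace log-likelihood over (β, θ) with a warm-started
    inner Newton solve for the conditional random-effect mode."""

    def __init__(self, y, X, Z, comp_of_col):
        self.y, self.X = y, X
        self.Z = Z.tocsr()
        self.Zt = self.Z.T.tocsr()
        self.comp = comp_of_col
        self.p = X.shape[1]
        self.q = Z.shape[1]
        self.b = np.zeros(self.q)
        self.inner_ok = True
        # augmented design for the profiled-beta stage
        self.A = sp.hstack([sp.csr_matrix(X), self.Z]).tocsr()
        self.At = self.A.T.tocsr()
        self.ab = np.zeros(self.p + self.q)

    def _mode(self, eta_fixed: np.ndarray, prec: np.ndarray):
        """Damped Newton for the penalized Bernoulli log-likelihood."""
        b = self.b.copy()
        y, Z, Zt = self.y, self.Z, self.Zt

        def pll(bv):
            return _bernoulli_loglik(y, eta_fixed + Z @ bv) - 0.5 * np.sum(prec * bv**2)

        cur = pll(b)
        self.inner_ok = True
        for _ in range(100):
            eta = eta_fixed + Z @ b
            mu = expit(eta)
            g = Zt @ (y - mu) - prec * b
            if np.max(np.abs(g)) < 1e-9:
                break
            w = mu * (1 - mu) + 1e-12
            H = (Zt @ sp.diags(w) @ Z).toarray()
            H[np.diag_indices_from(H)] += prec
            try:
                c = cho_factor(H, lower=True)
                step = cho_solve(c, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            t = 1.0
            for _ in range(30):
                cand = b + t * step
                new = pll(cand)
                if new >= cur - 1e-12:
                    break
                t /= 2.0
            b = b + t * step
            cur = pll(b)
        else:
            self.inner_ok = False
        # final-state Hessian for the Laplace determinant
        eta = eta_fixed + Z @ b
        mu = expit(eta)
        w = mu * (1 - mu) + 1e-12
        H = (Zt @ sp.diags(w) @ Z).toarray()
        H[np.diag_indices_from(H)] += prec
        self.b = b
        return b, H, eta, mu

    def profiled(self, theta: np.ndarray) -> float:
        """Laplace criterion with β profiled out by joint (β, b) Newton.

        Used as a cheap first stage to locate good variance parameters and
        starting fixed effects before the joint L-BFGS refinement.
        """
        sigma2 = np.exp(2.0 * theta)[self.comp]
        prec_full = np.concatenate([np.zeros(self.p), 1.0 / sigma2])
        y, A, At = self.y, self.A, self.At
        x = self.ab.copy()

        def pll(v):
            return _bernoulli_loglik(y, A @ v) - 0.5 * np.sum(prec_full * v**2)

        cur = pll(x)
        for _ in range(100):
            eta = A @ x
            mu = expit(eta)
            g = At @ (y - mu) - prec_full * x
            if np.max(np.abs(g)) < 1e-9:
                break
            w = mu * (1 - mu) + 1e-12
            H = (At @ sp.diags(w) @ A).toarray()
            H[np.diag_indices_from(H)] += prec_full
            try:
                c = cho_factor(H, lower=True)
                step = cho_solve(c, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            t = 1.0
            for _ in range(30):
                if pll(x + t * step) >= cur - 1e-12:
                    break
                t /= 2.0
            x = x + t * step
            cur = pll(x)
        self.ab = x
        self.last_beta = x[: self.p]
        self.b = x[self.p :]
        return self.value(self.last_beta, theta)

    def value(self, beta: np.ndarray, theta: np.ndarray) -> float:
        sigma2 = np.exp(2.0 * theta)[self.comp]
        prec = 1.0 / sigma2
        eta_fixed = self.X @ beta
        b, H, eta, _ = self._mode(eta_fixed, prec)
        ll = _bernoulli_loglik(self.y, eta)
        pen = 0.5 * np.sum(prec * b**2)
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            return np.inf
        lap = ll - pen - 0.5 * np.sum(np.log(sigma2)) - 0.5 * logdet
        return -lap


def fit_glmm(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit a binomial GLMM by Laplace-approximate maximum likelihood.

    With no random terms in ``spec`` this is exactly ordinary logistic
    regression.  Non-convergence and (quasi-)separation are reported on the
    result, never masked.
    """
    y, X, x_names, Z, comp_of_col, comp_names = build_design(data, spec)
    n, p = X.shape

    beta0, cov0, ll0, ok0 = _fit_logistic(y, X)
    separation = bool(np.max(np.abs(beta0)) > _SEPARATION_BOUND)
    if separation:
        warnings.warn("possible separation: very large fixed-effect estimate")

    if Z.shape[1] == 0:
        mu = expit(X @ beta0)
        return FitResult(
            params=pd.Series(beta0, index=x_names),
            se=pd.Series(np.sqrt(np.diag(cov0)), index=x_names),
            sigma={},
            loglik=ll0,
            converged=ok0,
            nobs=n,
            spec=spec,
            fitted=mu,
            response=y,
            separation=separation,
        )

    K = len(comp_names)
    obj = _LaplaceObjective(y, X, Z, comp_of_col)

    def fun(x):
        return obj.value(x[:p], x[p:])

    x0 = np.concatenate([beta0, np.full(K, np.log(0.1))])
    bounds = [(-30.0, 30.0)] * p + [_THETA_BOUNDS] * K
    res = scipy.optimize.minimize(
        fun,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-6},
    )
    if not res.success:
        # restart from the profiled-beta optimum over theta alone; this
        # rescues line-search failures caused by the numerical-gradient
        # noise floor near the optimum
        alt = scipy.optimize.minimize(
            lambda th: obj.profiled(np.clip(th, *_THETA_BOUNDS)),
            res.x[p:],
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-8, "maxiter": 200 * K},
        )
        theta_alt = np.clip(alt.x, *_THETA_BOUNDS)
        val = obj.profiled(theta_alt)
        if val < res.fun:
            res = scipy.optimize.OptimizeResult(
                x=np.concatenate([obj.last_beta, theta_alt]),
                fun=val,
                success=True,
                message="profiled restart",
            )
    beta = res.x[:p]
    theta = res.x[p:]
    sigma = {name: float(np.exp(t)) for name, t in zip(comp_names, theta)}
    loglik = -float(res.fun)

    # SEs from the profiled fixed-effect information at the optimum.
    sigma2 = np.exp(2.0 * theta)[comp_of_col]
    prec = 1.0 / sigma2
    b, H, eta, mu = obj._mode(X @ beta, prec)
    w = mu * (1 - mu) + 1e-12
    XtW = X.T * w
    XtWX = XtW @ X
    XtWZ = (obj.Zt @ sp.diags(w) @ sp.csr_matrix(X)).toarray().T  # p x q
    try:
        c = cho_factor(H, lower=True)
        Finfo = XtWX - XtWZ @ cho_solve(c, XtWZ.T)
        cov = np.linalg.inv(Finfo)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(XtWX)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))

    return FitResult(
        params=pd.Series(beta, index=x_names),
        se=pd.Series(se, index=x_names),
        sigma=sigma,
        loglik=loglik,
        converged=bool(res.success and obj.inner_ok),
        nobs=n,
        spec=spec,
        fitted=mu,
        response=y,
        separation=separation,
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# Likelihood-ratio testing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LrtResult:
    """χ² test of a nested model comparison."""

    term: str
    chi2: float
    df: int
    p_value: float
    alpha: float = 0.05
    warning: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def lrt(full: FitResult, reduced: FitResult, term: str = "", alpha: float = 0.05) -> LrtResult:
    """Likelihood-ratio test: χ² = 2(ℓ_full − ℓ_reduced).

    ``df`` is the parameter-count difference.  A χ² more negative than the
    numerical tolerance is flagged (it indicates the full fit should be
    restarted) and clipped to zero.
    """
    df = full.n_params - reduced.n_params
    stat = 2.0 * (full.loglik - reduced.loglik)
    if df < 1:
        if abs(stat) < 1e-6:  # identical models: trivially chi2 = 0, p = 1
            return LrtResult(term=term, chi2=0.0, df=0, p_value=1.0, alpha=alpha)
        raise ValueError("models are not strictly nested (df < 1)")
    warning = ""
    if stat < -1e-4:
        warning = f"negative chi-square ({stat:.3g}); refit the full model"
        warnings.warn(warning)
    if not (full.converged and reduced.converged):
        warning = (warning + "; " if warning else "") + "a fit did not converge"
    stat = max(stat, 0.0)
    p = float(chi2_dist.sf(stat, df)) if stat > 0 else 1.0
    return LrtResult(term=term, chi2=stat, df=df, p_value=p, alpha=alpha, warning=warning)


def _term_order(term: str) -> int:
    return term.count(":") + 1


def prune_and_test(
    data: pd.DataFrame, spec: ModelSpec, alpha: float = 0.05
) -> tuple[list[LrtResult], bool, ModelSpec]:
    """Test hypothesis terms, pruning nonsignificant interactions first.

    Highest-order interactions are tested first; nonsignificant ones are
    dropped and lower-order terms are then tested in the reduced model.  As
    soon as a significant interaction is found the procedure stops testing
    the terms it contains and flags a simple-effects follow-up.  Returns the
    ordered test results, the follow-up flag, and the final model.
    """
    current = spec
    results: list[LrtResult] = []
    fits: dict[ModelSpec, FitResult] = {}

    def fit(s: ModelSpec) -> FitResult:
        if s not in fits:
            fits[s] = fit_glmm(data, s)
        return fits[s]

    orders = sorted({_term_order(t) for t in spec.test_terms}, reverse=True)
    for order in orders:
        terms = [t for t in current.test_terms if _term_order(t) == order]
        if not terms:
            continue
        significant = []
        for term in terms:
            res = lrt(fit(current), fit(current.drop(term)), term=term, alpha=alpha)
            results.append(res)
            if res.significant:
                significant.append(term)
        if significant and order > 1:
            return results, True, current
        for term in terms:
            if term not in significant and order > 1:
                current = current.drop(term)
    return results, False, current


def simple_effects(
    data: pd.DataFrame,
    spec: ModelSpec,
    focal: str,
    within: Mapping[str, Sequence],
    alpha: float = 0.05,
) -> list[tuple[dict, LrtResult]]:
    """Test ``focal`` inside every stratum of the conditioning factor(s).

    ``within`` maps conditioning column names to the values defining strata;
    all terms involving a conditioning factor are removed from the stratum
    model (they are constant there).  ``alpha`` is passed through so callers
    can supply a Bonferroni-corrected level such as 0.05/3.  Empty or
    single-outcome strata are skipped with a warning.
    """
    split_cols = list(within)
    combos: list[dict] = [{}]
    for col in split_cols:
        combos = [dict(c, **{col: v}) for c in combos for v in within[col]]

    def strip(s: ModelSpec) -> ModelSpec:
        fixed = tuple(
            t for t in s.fixed if not set(t.split(":")) & set(split_cols)
        )
        random = tuple(
            (g, tuple(t for t in ts if not set(t.split(":")) & set(split_cols)))
            for g, ts in s.random
        )
        test = tuple(t for t in s.test_terms if t in fixed)
        return replace(s, fixed=fixed, random=random, test_terms=test)

    base = strip(spec)
    out: list[tuple[dict, LrtResult]] = []
    for combo in combos:
        mask = np.ones(len(data), dtype=bool)
        for col, val in combo.items():
            mask &= (data[col] == val).to_numpy()
        sub = data.loc[mask]
        if sub.empty:
            warnings.warn(f"empty stratum {combo}; skipped")
            continue
        if sub[spec.response].nunique() < 2:
            warnings.warn(f"degenerate stratum {combo} (all outcomes equal); skipped")
            continue
        full = fit_glmm(sub, base)
        reduced = fit_glmm(sub, base.drop(focal))
        out.append((combo, lrt(full, reduced, term=focal, alpha=alpha)))
    return out


# ---------------------------------------------------------------------------
# Diagnostics and bootstrap
# ---------------------------------------------------------------------------


def dispersion(
    fit: FitResult,
    groupby: np.ndarray | pd.Series | None = None,
) -> float:
    """Pearson dispersion: Σ r² / residual df.

    By default residuals are per Bernoulli trial.  For binary data that
    statistic cannot exceed 1 in expectation even under strong latent
    heterogeneity, so ``groupby`` optionally aggregates trials into binomial
    clusters (e.g. sessions) first: r_c = (Σy − Σp̂)/sqrt(Σ p̂(1−p̂)), which
    does pick up beta-binomial-style extra variation.
    """
    y, mu = fit.response, np.clip(fit.fitted, 1e-10, 1 - 1e-10)
    if groupby is None:
        r2 = ((y - mu) ** 2 / (mu * (1 - mu))).sum()
        ddf = fit.nobs - fit.n_params
    else:
        g = pd.Series(np.asarray(groupby))
        df = pd.DataFrame({"y": y, "mu": mu, "v": mu * (1 - mu), "g": g.values})
        agg = df.groupby("g").sum()
        r2 = (((agg["y"] - agg["mu"]) ** 2) / agg["v"]).sum()
        ddf = len(agg) - fit.n_params
    if ddf < 1:
        raise ValueError("not enough residual degrees of freedom")
    return float(r2 / ddf)


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap CI for a proportion correct."""

    estimate: float
    lower: float
    upper: float
    n_resamples: int
    unit: str
    seed: int

    def __post_init__(self) -> None:
        if not self.lower <= self.estimate <= self.upper:
            raise ValueError("CI does not bracket the estimate")


def bootstrap_ci(
    data: pd.DataFrame,
    unit_col: str,
    value_col: str = "correct",
    n_resamples: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> BootstrapCI:
    """Nonparametric bootstrap over resampling units.

    Units (participants, or sessions for the chimpanzee task) are resampled
    with replacement; each replicate's statistic is the pooled proportion
    correct of the drawn units.  Percentile interval, reproducible per seed.
    """
    grouped = data.groupby(unit_col)[value_col].agg(["sum", "count"])
    if len(grouped) < 2:
        raise ValueError("need at least two resampling units")
    sums = grouped["sum"].to_numpy(float)
    counts = grouped["count"].to_numpy(float)
    estimate = float(sums.sum() / counts.sum())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(sums), size=(n_resamples, len(sums)))
    stats = sums[idx].sum(axis=1) / counts[idx].sum(axis=1)
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [tail, 1.0 - tail])
    lo, hi = min(lo, estimate), max(hi, estimate)
    return BootstrapCI(
        estimate=estimate,
        lower=float(lo),
        upper=float(hi),
        n_resamples=n_resamples,
        unit=unit_col,
        seed=seed,
    )
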