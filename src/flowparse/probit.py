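"""Hierarchical probit regression on binary 2IFC responses.

The response ("comparison faster", 0/1) is modelled as

    P(y = 1) = Phi( x' beta + z' b_g ),   b_g ~ N(0, D),  D diagonal,

with fixed effects ``beta`` (intercept, comparison speed, self-motion terms
and their interactions) and a random-effect vector per grouping level
(typically the participant: random intercept plus slopes for comparison
speed and motion profile).  The random effects are integrated out by a
Laplace approximation; for fixed variance parameters the fixed effects and
random modes are found by a joint penalized Newton solve (block elimination
of the random blocks), and the variance parameters are optimized on the
profiled Laplace log-likelihood.  Nested models are compared with
likelihood-ratio tests; confidence intervals come from a parametric
bootstrap.

The random-effect covariance is diagonal (no intercept-slope correlations):
with desk-scale group counts the correlations are poorly identified and the
model comparisons of interest do not involve them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

__all__ = [
    "ModelSpec",
    "ProbitFitResult",
    "LRTResult",
    "precision_test_spec",
    "precision_null_spec",
    "accuracy_test_spec",
    "accuracy_null_spec",
    "build_design",
    "fit_probit_mixed",
    "laplace_loglik",
    "likelihood_ratio_test",
    "bootstrap_ci",
    "compensation_percentage",
]

_LOG_SD_BOUNDS = (-5.0, 2.5)


# ---------------------------------------------------------------------------
# Model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Fixed and random structure of a hierarchical probit model.

    ``fixed_terms`` / ``random_terms`` use a small formula-like vocabulary:
    ``speed`` (comparison speed, m/s), ``subject_motion`` (binary: any
    visually simulated self-motion), ``motion_profile`` (3-level, treatment
    coded with "static" as reference), ``met_criterion`` (binary), and
    ``a:b`` interactions.  An intercept is always included; random terms
    always include a group intercept.
    """

    fixed_terms: tuple
    random_terms: tuple = ("speed", "motion_profile")
    group: str = "subject_id"
    name: str = "model"

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return (
            set(self.fixed_terms) <= set(other.fixed_terms)
            and set(self.random_terms) == set(other.random_terms)
            and self.group == other.group
        )


#: Fixed stratification by the standard (target) speed.  The study's model
#: formulas place the standard speed in a second random grouping factor;
#: with only two levels its variance components are unidentifiable, so the
#: per-standard-speed intercept and psychometric-slope differences (the two
#: standards have different PSEs) are absorbed as fixed effects shared by
#: every test/null pair (they cancel in the likelihood-ratio tests).
_STRATA = ("standard_speed", "standard_speed:speed")


def precision_test_spec() -> ModelSpec:
    """Self-motion x speed interaction (slope = precision channel)."""
    return ModelSpec(
        fixed_terms=("subject_motion", "speed", "subject_motion:speed") + _STRATA,
        name="precision_test",
    )


def precision_null_spec() -> ModelSpec:
    return ModelSpec(
        fixed_terms=("subject_motion", "speed") + _STRATA, name="precision_null"
    )


def accuracy_test_spec() -> ModelSpec:
    """Motion-profile main effect (intercept shift = PSE channel)."""
    return ModelSpec(
        fixed_terms=("motion_profile", "speed") + _STRATA, name="accuracy_test"
    )


def accuracy_null_spec() -> ModelSpec:
    return ModelSpec(fixed_terms=("speed",) + _STRATA, name="accuracy_null")


def _base_columns(trials: pd.DataFrame) -> dict:
    profile = trials["motion_profile"].to_numpy()
    cols = {
        "speed": trials["comparison_speed_mps"].to_numpy(dtype=float),
        "subject_motion": (profile != "static").astype(float),
        "motion_profile": {
            "motion_profile[same]": (profile == "same").astype(float),
            "motion_profile[opposite]": (profile == "opposite").astype(float),
        },
    }
    if "standard_speed_mps" in trials.columns:
        std = trials["standard_speed_mps"].abs().to_numpy(dtype=float)
        levels = np.unique(std)
        # treatment coding, slowest standard speed as reference
        cols["standard_speed"] = {
            f"standard_speed[{lv:g}]": (std == lv).astype(float)
            for lv in levels[1:]
        }
    if "met_criterion" in trials.columns:
        cols["met_criterion"] = trials["met_criterion"].to_numpy(dtype=float)
    return cols


def _term_columns(term: str, base: dict) -> dict:
    """Expand one term (possibly an interaction) to named columns."""
    cols = {"": None}
    for part in term.split(":"):
        if part not in base:
            raise ValueError(f"unknown model term {part!r}")
        col = base[part]
        sub = col if isinstance(col, dict) else {part: col}
        nxt = {}
        for n1, v1 in cols.items():
            for n2, v2 in sub.items():
                nxt[f"{n1}:{n2}" if n1 else n2] = v2 if v1 is None else v1 * v2
        cols = nxt
    return cols


def build_design(trials: pd.DataFrame, terms) -> tuple[np.ndarray, list]:
    """Design matrix (with leading intercept) for the given terms."""
    base = _base_columns(trials)
    names = ["(Intercept)"]
    cols = [np.ones(len(trials))]
    for term in terms:
        for name, col in _term_columns(term, base).items():
            names.append(name)
            cols.append(col)
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# Probit log-likelihood pieces (stable in the tails)
# ---------------------------------------------------------------------------

def _probit_l(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.where(y == 1, log_ndtr(eta), log_ndtr(-eta))


def _mills(z: np.ndarray) -> np.ndarray:
    """phi(z) / Phi(z), computed in log space."""
    return np.exp(norm.logpdf(z) - log_ndtr(z))


def _probit_deriv(eta: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(dl/deta, -d2l/deta2) of the Bernoulli-probit log-likelihood."""
    lam_pos = _mills(eta)
    lam_neg = _mills(-eta)
    grad = np.where(y == 1, lam_pos, -lam_neg)
    w = np.where(y == 1, lam_pos * (lam_pos + eta), lam_neg * (lam_neg - eta))
    return grad, np.maximum(w, 1e-12)


# ---------------------------------------------------------------------------
# Grouped (padded) data container
# ---------------------------------------------------------------------------

class _Grouped:
    """Responses and design matrices padded into (G, M, .) arrays."""

    def __init__(self, y, X, Z, groups):
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        self.levels, inverse = np.unique(groups, return_inverse=True)
        G = len(self.levels)
        sizes = np.bincount(inverse, minlength=G)
        M = int(sizes.max())
        p, q = X.shape[1], Z.shape[1]
        self.Y = np.zeros((G, M))
        self.X = np.zeros((G, M, p))
        self.Z = np.zeros((G, M, q))
        self.mask = np.zeros((G, M))
        order = np.argsort(inverse, kind="stable")
        g_sorted = inverse[order]
        starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
        pos = np.arange(len(y)) - starts[g_sorted]
        self.Y[g_sorted, pos] = y[order]
        self.X[g_sorted, pos] = X[order]
        self.Z[g_sorted, pos] = Z[order]
        self.mask[g_sorted, pos] = 1.0
        self.G, self.M, self.p, self.q = G, M, p, q
        self.n_obs = int(self.mask.sum())


def _inner_newton(
    gd: _Grouped,
    sigma: np.ndarray,
    beta: np.ndarray,
    b: np.ndarray,
    profile_beta: bool,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Joint penalized Newton over (beta, {b_g}) at fixed variances.

    With ``profile_beta=False`` only the random modes are updated (used when
    evaluating the Laplace likelihood at externally supplied coefficients).
    Returns (beta, b, penalized objective, H_bb at the mode).
    """
    d_inv = 1.0 / np.maximum(sigma**2, 1e-300)

    def objective(beta, b):
        eta = gd.X @ beta + np.einsum("gmq,gq->gm", gd.Z, b)
        ll = float(np.sum(_probit_l(eta, gd.Y) * gd.mask))
        pen = 0.5 * float(np.sum(b**2 * d_inv))
        return ll - pen, eta

    obj, eta = objective(beta, b)
    Hbb = None
    for _ in range(max_iter):
        grad_eta, w = _probit_deriv(eta, gd.Y)
        grad_eta = grad_eta * gd.mask
        w = w * gd.mask
        grad_b = np.einsum("gmq,gm->gq", gd.Z, grad_eta) - b * d_inv
        Hbb = np.einsum("gmq,gm,gmr->gqr", gd.Z, w, gd.Z) + np.diag(d_inv)[None, :, :]
        if profile_beta:
            grad_beta = np.einsum("gmp,gm->p", gd.X, grad_eta)
            Hxx = np.einsum("gmp,gm,gmr->pr", gd.X, w, gd.X)
            Hxz = np.einsum("gmp,gm,gmq->gpq", gd.X, w, gd.Z)
            Hbb_inv_gb = np.linalg.solve(Hbb, grad_b[..., None])[..., 0]
            Hbb_inv_Hzx = np.linalg.solve(Hbb, np.swapaxes(Hxz, 1, 2))
            S = Hxx - np.einsum("gpq,gqr->pr", Hxz, Hbb_inv_Hzx)
            rhs = grad_beta - np.einsum("gpq,gq->p", Hxz, Hbb_inv_gb)
            try:
                d_beta = np.linalg.solve(S, rhs)
            except np.linalg.LinAlgError:
                d_beta = np.linalg.pinv(S) @ rhs
            d_b = Hbb_inv_gb - np.einsum("gqp,p->gq", Hbb_inv_Hzx, d_beta)
        else:
            d_beta = np.zeros_like(beta)
            d_b = np.linalg.solve(Hbb, grad_b[..., None])[..., 0]

        gnorm = max(
            float(np.max(np.abs(grad_b))),
            float(np.max(np.abs(np.einsum("gmp,gm->p", gd.X, grad_eta))))
            if profile_beta
            else 0.0,
        )
        if gnorm < tol:
            break
        step = 1.0
        for _half in range(30):
            nb = beta + step * d_beta
            nbb = b + step * d_b
            nobj, neta = objective(nb, nbb)
            if nobj >= obj - 1e-12:
                beta, b, obj, eta = nb, nbb, nobj, neta
                break
            step *= 0.5
        else:
            break
    # recompute Hbb at the final mode for the Laplace determinant
    _, w = _probit_deriv(eta, gd.Y)
    w = w * gd.mask
    Hbb = np.einsum("gmq,gm,gmr->gqr", gd.Z, w, gd.Z) + np.diag(d_inv)[None, :, :]
    return beta, b, obj, Hbb


def _laplace_from_mode(obj: float, sigma: np.ndarray, Hbb: np.ndarray, G: int) -> float:
    """Laplace marginal log-likelihood given the penalized-objective value at
    the mode and the per-group negative Hessians of the random blocks."""
    logdet_D = 2.0 * float(np.sum(np.log(sigma)))
    sign, logdet_H = np.linalg.slogdet(Hbb)
    if np.any(sign <= 0):
        return -np.inf
    return obj - 0.5 * (G * logdet_D + float(np.sum(logdet_H)))


def laplace_loglik(y, X, Z, groups, beta, sigma) -> float:
    """Laplace-approximate marginal log-likelihood at given parameters.

    ``sigma`` holds the random-effect standard deviations (diagonal D).  The
    random-effect modes are found by Newton with the fixed effects held at
    ``beta``.  This is the quantity the Gauss-Hermite oracle cross-checks.
    """
    gd = _Grouped(np.asarray(y), np.asarray(X, dtype=float), np.asarray(Z, dtype=float), groups)
    sigma = np.asarray(sigma, dtype=float)
    beta = np.asarray(beta, dtype=float)
    b = np.zeros((gd.G, gd.q))
    _, b, obj, Hbb = _inner_newton(gd, sigma, beta, b, profile_beta=False)
    return _laplace_from_mode(obj, sigma, Hbb, gd.G)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbitFitResult:
    """Result of a hierarchical probit fit (probit-scale coefficients)."""

    spec: ModelSpec
    coefficients: dict
    standard_errors: dict
    random_sd: dict
    log_likelihood: float
    n_obs: int
    n_groups: int
    converged: bool
    boundary: bool
    coef_names: tuple = ()

    @property
    def n_parameters(self) -> int:
        return len(self.coefficients) + len(self.random_sd)

    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients[n] for n in self.coef_names])


def _matrices(trials: pd.DataFrame, spec: ModelSpec):
    X, xnames = build_design(trials, spec.fixed_terms)
    Z, znames = build_design(trials, spec.random_terms)
    y = trials["response"].to_numpy(dtype=int)
    groups = trials[spec.group].to_numpy()
    return y, X, xnames, Z, znames, groups


def fit_probit_mixed(
    trials: pd.DataFrame,
    spec: ModelSpec,
    theta0: np.ndarray | None = None,
    xatol: float = 2e-3,
    fatol: float = 2e-4,
) -> ProbitFitResult:
    """Fit a hierarchical probit model by Laplace-approximate ML.

    The variance parameters (log random-effect SDs) are optimized by
    Nelder-Mead on the profiled Laplace log-likelihood; at each candidate the
    fixed effects and random modes are re-solved by the penalized Newton
    step, warm-started from the previous candidate.  Variance components
    that hit the lower bound (SD ~ exp(-5)) are reported as boundary fits.
    """
    if trials[spec.group].nunique() < 2:
        raise ValueError("need at least 2 grouping levels")
    if not set(np.unique(trials["response"])) <= {0, 1}:
        raise ValueError("responses must be binary 0/1")

    y, X, xnames, Z, znames, groups = _matrices(trials, spec)
    gd = _Grouped(y, X, Z, groups)

    state = {"beta": np.zeros(gd.p), "b": np.zeros((gd.G, gd.q))}

    def profiled_negll(theta: np.ndarray) -> float:
        sigma = np.exp(np.clip(theta, *_LOG_SD_BOUNDS))
        beta, b, obj, Hbb = _inner_newton(
            gd, sigma, state["beta"].copy(), state["b"].copy(), profile_beta=True
        )
        state["beta"], state["b"] = beta, b
        ll = _laplace_from_mode(obj, sigma, Hbb, gd.G)
        return -ll if np.isfinite(ll) else 1e12

    theta0 = (
        np.asarray(theta0, dtype=float)
        if theta0 is not None
        else np.full(gd.q, np.log(0.3))
    )
    res = minimize(
        profiled_negll,
        theta0,
        method="Nelder-Mead",
        bounds=[_LOG_SD_BOUNDS] * gd.q,
        options={"xatol": xatol, "fatol": fatol, "maxiter": 200 * gd.q, "maxfev": 250 * gd.q},
    )
    theta = np.clip(res.x, *_LOG_SD_BOUNDS)
    sigma = np.exp(theta)
    beta, b, obj, Hbb = _inner_newton(
        gd, sigma, state["beta"].copy(), state["b"].copy(), profile_beta=True
    )
    ll = _laplace_from_mode(obj, sigma, Hbb, gd.G)

    # approximate fixed-effect SEs: inverse Schur complement at the mode
    eta = gd.X @ beta + np.einsum("gmq,gq->gm", gd.Z, b)
    _, w = _probit_deriv(eta, gd.Y)
    w = w * gd.mask
    Hxx = np.einsum("gmp,gm,gmr->pr", gd.X, w, gd.X)
    Hxz = np.einsum("gmp,gm,gmq->gpq", gd.X, w, gd.Z)
    S = Hxx - np.einsum(
        "gpq,gqr->pr", Hxz, np.linalg.solve(Hbb, np.swapaxes(Hxz, 1, 2))
    )
    try:
        cov = np.linalg.inv(S)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        ses = np.full(gd.p, np.nan)

    boundary = bool(np.any(theta <= _LOG_SD_BOUNDS[0] + 1e-6))
    return ProbitFitResult(
        spec=spec,
        coefficients=dict(zip(xnames, beta.tolist())),
        standard_errors=dict(zip(xnames, ses.tolist())),
        random_sd=dict(zip(znames, sigma.tolist())),
        log_likelihood=float(ll),
        n_obs=gd.n_obs,
        n_groups=gd.G,
        converged=bool(res.success) and np.isfinite(ll),
        boundary=boundary,
        coef_names=tuple(xnames),
    )


# ---------------------------------------------------------------------------
# Model comparison, bootstrap, compensation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p_value: float


def likelihood_ratio_test(fit_null: ProbitFitResult, fit_test: ProbitFitResult) -> LRTResult:
    """Chi-square LRT of nested hierarchical probit fits.

    ``chi2 = 2 (LL_test - LL_null)`` clamped at zero; degrees of freedom are
    the difference in parameter counts.
    """
    if not fit_null.spec.is_nested_in(fit_test.spec):
        raise ValueError("null model is not nested in the test model")
    if fit_null.n_obs != fit_test.n_obs:
        raise ValueError("fits use different data")
    df = fit_test.n_parameters - fit_null.n_parameters
    chi2 = max(0.0, 2.0 * (fit_test.log_likelihood - fit_null.log_likelihood))
    p = 1.0 if df == 0 else float(chi2_dist.sf(chi2, df))
    return LRTResult(chi2=chi2, df=df, p_value=p)


def simulate_from_fit(
    trials: pd.DataFrame, fit: ProbitFitResult, rng: np.random.Generator
) -> pd.DataFrame:
    """Parametric-bootstrap responses drawn from a fitted model."""
    y, X, xnames, Z, znames, groups = _matrices(trials, fit.spec)
    beta = fit.coef_vector()
    sigma = np.array([fit.random_sd[n] for n in znames])
    levels, inverse = np.unique(groups, return_inverse=True)
    b = rng.normal(0.0, 1.0, size=(len(levels), len(sigma))) * sigma
    eta = X @ beta + np.einsum("nq,nq->n", Z, b[inverse])
    out = trials.copy()
    out["response"] = (rng.random(len(out)) < ndtr(eta)).astype(int)
    return out


def bootstrap_ci(
    trials: pd.DataFrame,
    spec: ModelSpec,
    n_boot: int,
    rng: np.random.Generator,
    level: float = 0.95,
    max_fail_fraction: float = 0.2,
) -> pd.DataFrame:
    """Percentile parametric-bootstrap CIs for all fixed-effect coefficients.

    Responses are re-simulated from the fitted model, the model is refitted
    (warm-started at the fitted variance parameters), and per-coefficient
    percentile intervals are taken.  Aborts if more than 20% of the refits
    fail.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    fit = fit_probit_mixed(trials, spec)
    theta0 = np.log(np.maximum(list(fit.random_sd.values()), 1e-4))
    draws, failures = [], 0
    for _ in range(n_boot):
        sim = simulate_from_fit(trials, fit, rng)
        try:
            refit = fit_probit_mixed(sim, spec, theta0=theta0)
            if not np.isfinite(refit.log_likelihood):
                raise RuntimeError("non-finite refit likelihood")
            draws.append(refit.coef_vector())
        except Exception:
            failures += 1
    if failures > max_fail_fraction * n_boot:
        raise RuntimeError(
            f"bootstrap aborted: {failures}/{n_boot} refits failed"
        )
    draws = np.asarray(draws)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(draws, alpha, axis=0)
    hi = np.quantile(draws, 1.0 - alpha, axis=0)
    return pd.DataFrame(
        {
            "coefficient": list(fit.coef_names),
            "estimate": fit.coef_vector(),
            "ci_lower": lo,
            "ci_upper": hi,
        }
    )


def compensation_percentage(coef: float, direction: str) -> float:
    """Compensation for visually simulated self-motion implied by a
    motion-profile coefficient.

    A coefficient of -1 for same-direction self-motion (or +1 for
    opposite-direction) corresponds to no compensation; 0 to full (100%)
    compensation.  Returns ``100 * (1 - coef / coef_nocomp)``.
    """
    if direction == "same":
        nocomp = -1.0
    elif direction == "opposite":
        nocomp = 1.0
    else:
        raise ValueError(f"direction must be 'same' or 'opposite', got {direction!r}")
    return 100.0 * (1.0 - coef / nocomp)
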