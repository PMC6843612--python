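"""Exponential-family GLMs for life-table hazards.

The per-interval event count ``y_t`` is modelled through a distribution from
the exponential family with the interval time (or a transform of it) as the
only covariate:

* Poisson pathway — ``y_t ~ Poisson(lambda_t * tau_t)`` with a log link and
  ``log tau_t`` as offset; ``lambda_t`` is the per-interval hazard.  The
  exponential, Gompertz and Weibull models are this GLM with covariate
  none / ``t`` / ``log t``.
* Binomial pathway — cumulative failures among the initial cohort with a
  logit (log-logistic) or probit (lognormal) response.

Beyond the GLM forms, classical parametric hazard families (gamma,
generalized gamma, generalized F, lognormal, log-logistic) are fit by
maximizing the same Poisson life-table likelihood with ``lambda_t`` set to
the family's hazard function at the interval midpoint, so every model in the
comparison suite is scored on one likelihood scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, special, stats

from .lifetable import LifeTable

__all__ = [
    "FamilySpec",
    "DesignSpec",
    "FittedHazardModel",
    "poisson_loglik",
    "binomial_loglik",
    "aic",
    "standard_spec",
    "fit_glm",
    "fit_binomial_glm",
    "fit_parametric_hazard",
    "predict_hazard",
    "PARAMETRIC_FAMILIES",
]


def aic(loglik: float, k: float) -> float:
    """Akaike information criterion, ``-2 logL + 2 k`` (lower is better)."""
    if k < 0:
        raise ValueError("parameter count k must be nonnegative")
    return -2.0 * loglik + 2.0 * k


def poisson_loglik(y, lam, tau) -> float:
    """Poisson log-likelihood for interval counts with hazard and exposure.

    ``sum_t [ y_t log(lambda_t tau_t) - lambda_t tau_t - log(y_t!) ]``.
    Intervals with zero expected count contribute only when ``y_t = 0``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(lam, dtype=float) * np.asarray(tau, dtype=float)
    if np.any((y > 0) & (mu <= 0)):
        raise ValueError("observed events in an interval with zero expected count")
    out = -mu - special.gammaln(y + 1.0)
    pos = mu > 0
    out[pos] += y[pos] * np.log(mu[pos])
    return float(out.sum())


def binomial_loglik(y, pi, n) -> float:
    """Binomial log-likelihood including the binomial-coefficient term.

    ``sum_t [ y_t log(pi_t/(1-pi_t)) + n_t log(1-pi_t) + log C(n_t, y_t) ]``
    with real-valued ``n_t`` allowed (actuarial effective denominators).
    """
    y = np.asarray(y, dtype=float)
    pi = np.asarray(pi, dtype=float)
    n = np.asarray(n, dtype=float)
    interior = (y > 0) & (y < n)
    if np.any((pi <= 0) | (pi >= 1)) and np.any(interior & ((pi <= 0) | (pi >= 1))):
        raise ValueError("cumulative probability outside (0, 1) with non-boundary counts")
    pi = np.clip(pi, 1e-300, 1 - 1e-16)
    coef = special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1)
    return float(np.sum(y * np.log(pi / (1 - pi)) + n * np.log1p(-pi) + coef))


# ---------------------------------------------------------------------------
# Model specification


@dataclass(frozen=True)
class FamilySpec:
    """Distribution + response function of the GLM."""

    distribution: str  # "poisson" | "binomial"
    response: str  # "exponential" | "logistic" | "inverse-probit"

    def __post_init__(self) -> None:
        if self.distribution not in ("poisson", "binomial"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.response not in ("exponential", "logistic", "inverse-probit"):
            raise ValueError(f"unknown response {self.response!r}")

    def h(self, eta: np.ndarray) -> np.ndarray:
        """Response function mapping the linear predictor to the mean."""
        if self.response == "exponential":
            return np.exp(eta)
        if self.response == "logistic":
            return special.expit(eta)
        return stats.norm.cdf(eta)


@dataclass(frozen=True)
class DesignSpec:
    """Time covariate of the GLM, evaluated at interval midpoints.

    ``transform`` is one of ``none`` (intercept only), ``t``, ``log_t`` or
    ``basis`` with an explicit basis callable (fractional-polynomial,
    spline or penalized bases from :mod:`hazglm.flexible`).
    """

    transform: str = "none"
    basis: Callable[[np.ndarray], np.ndarray] | None = None
    label: str = ""

    def matrix(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        ones = np.ones_like(times)
        if self.transform == "none":
            return ones[:, None]
        if self.transform == "t":
            return np.column_stack([ones, times])
        if self.transform == "log_t":
            if np.any(times <= 0):
                raise ValueError("log-time design requires strictly positive times")
            return np.column_stack([ones, np.log(times)])
        if self.transform == "basis":
            if self.basis is None:
                raise ValueError("basis design without a basis callable")
            return np.column_stack([ones, self.basis(times)])
        raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class FittedHazardModel:
    """A fitted hazard model: coefficients, fit statistics and a predictor.

    ``k`` may be non-integer (penalized fits report effective degrees of
    freedom).  ``predict(times)`` returns the per-interval hazard at times
    given in years.
    """

    name: str
    family: FamilySpec
    design: DesignSpec
    beta: np.ndarray
    loglik: float
    k: float
    predict: Callable[[np.ndarray], np.ndarray]
    extra: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return aic(self.loglik, self.k)

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "distribution": self.family.distribution,
            "response": self.family.response,
            "design": self.design.label or self.design.transform,
            "beta": np.asarray(self.beta, dtype=float).tolist(),
            "loglik": self.loglik,
            "k": self.k,
            "aic": self.aic,
        }
        payload.update({k: v for k, v in self.extra.items() if _json_safe(v)})
        return json.dumps(payload, indent=2)


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


_STANDARD = {
    "exponential": ("poisson", "exponential", "none"),
    "gompertz": ("poisson", "exponential", "t"),
    "weibull": ("poisson", "exponential", "log_t"),
    "log-logistic": ("binomial", "logistic", "log_t"),
    "lognormal": ("binomial", "inverse-probit", "log_t"),
}


def standard_spec(name: str) -> tuple[FamilySpec, DesignSpec]:
    """Family/design pair for a named standard survival model.

    The classical models correspond to particular GLM triples: exponential
    (Poisson hazard, no covariate), Gompertz (time), Weibull (log time) on
    the hazard; log-logistic (logit) and lognormal (probit) on cumulative
    failure with log time.
    """
    try:
        dist, resp, transform = _STANDARD[name]
    except KeyError:
        raise KeyError(
            f"unknown standard model {name!r}; valid names: {sorted(_STANDARD)}"
        ) from None
    return FamilySpec(dist, resp), DesignSpec(transform, label=transform)


# ---------------------------------------------------------------------------
# Poisson life-table GLM fitting


def _poisson_data(lt: LifeTable):
    """Usable rows for Poisson fitting: positive exposure."""
    keep = lt.at_risk > 0
    return lt.events[keep], lt.at_risk[keep], lt.midpoints[keep]


def fit_glm(lt: LifeTable, family: FamilySpec, design: DesignSpec, name: str | None = None) -> FittedHazardModel:
    """Maximum-likelihood fit of a hazard GLM on a life table.

    The Poisson pathway fits ``log lambda_t = x_t' beta`` with exposure as
    offset via iteratively reweighted least squares (statsmodels).  The
    binomial pathway (cumulative failures) is dispatched to
    :func:`fit_binomial_glm`.
    """
    if len(lt) == 0:
        raise ValueError("empty life table")
    if family.distribution == "binomial":
        return fit_binomial_glm(lt, family, design, name=name)
    y, tau, mid = _poisson_data(lt)
    X = design.matrix(mid)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient on the fitted data")
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(tau))
    try:
        res = model.fit(maxiter=200, tol=1e-10)
    except Exception as exc:  # pragma: no cover - statsmodels failure path
        raise RuntimeError(f"GLM fit failed for {name or design.label}: {exc}") from exc
    if not res.converged:
        raise RuntimeError(f"GLM fit did not converge for {name or design.label}")
    beta = np.asarray(res.params, dtype=float)

    def predict(times, beta=beta, design=design):
        return np.exp(design.matrix(np.asarray(times, dtype=float)) @ beta)

    return FittedHazardModel(
        name=name or (design.label or design.transform),
        family=family,
        design=design,
        beta=beta,
        loglik=float(res.llf),
        k=float(len(beta)),
        predict=predict,
        extra={"beta_se": np.asarray(res.bse, dtype=float).tolist()},
    )


# ---------------------------------------------------------------------------
# Binomial cumulative-failure pathway


def _cumulative_data(lt: LifeTable):
    """Cumulative failures and actuarial effective denominators.

    The trials count for interval t is the at-risk exposure plus everyone
    who already failed: with no censoring this is the initial cohort size;
    censored subjects progressively leave the effective denominator.
    """
    y_cum = np.cumsum(lt.events)
    n_eff = lt.at_risk + y_cum
    keep = (lt.at_risk > 0) & (y_cum < n_eff)
    return y_cum[keep], n_eff[keep], lt.midpoints[keep]


def fit_binomial_glm(lt: LifeTable, family: FamilySpec, design: DesignSpec, name: str | None = None) -> FittedHazardModel:
    """Fit the binomial cumulative-failure GLM by direct ML.

    ``pi_t = h(x_t' beta)`` is the cumulative failure probability; the
    per-interval hazard is recovered as the discrete conditional failure
    probability ``(pi(t_end) - pi(t_start)) / (1 - pi(t_start))``.
    """
    if len(lt) == 0:
        raise ValueError("empty life table")
    y, n, mid = _cumulative_data(lt)
    X = design.matrix(mid)

    def negll(beta):
        pi = family.h(X @ beta)
        pi = np.clip(pi, 1e-12, 1 - 1e-12)
        return -binomial_loglik(y, pi, n)

    frac = np.clip(y.sum() / n.sum(), 1e-6, 1 - 1e-6)
    start = np.zeros(X.shape[1])
    start[0] = np.log(frac / (1 - frac)) if family.response == "logistic" else stats.norm.ppf(frac)
    res = optimize.minimize(negll, start, method="BFGS", options={"gtol": 1e-8, "maxiter": 500})
    if not np.isfinite(res.fun):
        raise RuntimeError(f"binomial GLM fit failed for {name or design.label}")
    beta = res.x

    def cumulative(times, beta=beta, design=design, family=family):
        return family.h(design.matrix(np.asarray(times, dtype=float)) @ beta)

    width = lt.width

    def predict(times, cumulative=cumulative, width=width):
        times = np.asarray(times, dtype=float)
        lo = np.maximum(times - width / 2.0, 1e-9)
        hi = times + width / 2.0
        p_lo, p_hi = cumulative(lo), cumulative(hi)
        return np.clip((p_hi - p_lo) / np.maximum(1.0 - p_lo, 1e-12), 0.0, 1.0)

    return FittedHazardModel(
        name=name or (design.label or design.transform),
        family=family,
        design=design,
        beta=beta,
        loglik=-float(res.fun),
        k=float(len(beta)),
        predict=predict,
        extra={"pathway": "binomial-cumulative"},
    )


# ---------------------------------------------------------------------------
# Parametric hazard families on the Poisson life-table likelihood


def _genf_logpdf_w(w, m1, m2):
    """Log-density of the log-F(m1, m2) variable underlying generalized F."""
    return (
        m1 * np.log(m1 / m2)
        + m1 * w
        - (m1 + m2) * np.log1p(m1 * np.exp(w) / m2)
        - special.betaln(m1, m2)
    )


def _genf_hazard(t, mu, sigma, m1, m2):
    """Hazard of the generalized F distribution (log-F representation).

    ``log T = mu + sigma W`` with ``W ~ log-F(m1, m2)``; the survival
    function follows from ``m1 e^W / (m2 + m1 e^W) ~ Beta(m1, m2)``.
    """
    t = np.asarray(t, dtype=float)
    w = (np.log(t) - mu) / sigma
    logpdf_t = _genf_logpdf_w(w, m1, m2) - np.log(sigma) - np.log(t)
    u = m1 * np.exp(w) / (m2 + m1 * np.exp(w))
    sf = np.clip(1.0 - special.betainc(m1, m2, u), 1e-300, 1.0)
    return np.exp(logpdf_t) / sf


def _hazard_from_frozen(dist):
    def hz(t):
        t = np.asarray(t, dtype=float)
        sf = np.clip(dist.sf(t), 1e-300, None)
        return dist.pdf(t) / sf
    return hz


#: family name -> (n params, unconstrained->hazard-function factory, start)
PARAMETRIC_FAMILIES: dict[str, tuple[int, Callable, np.ndarray]] = {
    # theta components are unconstrained; positive parameters enter as exp()
    "gamma": (
        2,
        lambda th: _hazard_from_frozen(stats.gamma(a=math.exp(th[0]), scale=math.exp(th[1]))),
        np.array([0.0, 1.0]),
    ),
    "generalized-gamma": (
        3,
        lambda th: _hazard_from_frozen(
            stats.gengamma(a=math.exp(th[0]), c=math.exp(th[1]), scale=math.exp(th[2]))
        ),
        np.array([0.0, 0.0, 1.0]),
    ),
    "generalized-F": (
        4,
        lambda th: (lambda t: _genf_hazard(t, th[0], math.exp(th[1]), math.exp(th[2]), math.exp(th[3]))),
        np.array([1.0, 0.0, 0.0, 0.0]),
    ),
    "lognormal-hazard": (
        2,
        lambda th: _hazard_from_frozen(stats.lognorm(s=math.exp(th[1]), scale=math.exp(th[0]))),
        np.array([1.0, 0.0]),
    ),
    "log-logistic-hazard": (
        2,
        lambda th: _hazard_from_frozen(stats.fisk(c=math.exp(th[0]), scale=math.exp(th[1]))),
        np.array([0.0, 1.0]),
    ),
}


def fit_parametric_hazard(
    lt: LifeTable,
    family_name: str,
    fixed: dict[int, float] | None = None,
) -> FittedHazardModel:
    """Fit a classical parametric hazard family on the life-table likelihood.

    The per-interval hazard is the family's continuous-time hazard at the
    interval midpoint times the interval width; parameters maximize the
    Poisson likelihood with the at-risk exposure as offset, via quasi-Newton
    search on log-transformed positive parameters.

    Parameters
    ----------
    fixed:
        Optional map from parameter index (on the unconstrained scale) to a
        frozen value — used e.g. to pin the generalized gamma to its Weibull
        special case.
    """
    if len(lt) == 0:
        raise ValueError("empty life table")
    if family_name not in PARAMETRIC_FAMILIES:
        raise KeyError(
            f"unknown parametric family {family_name!r}; valid: {sorted(PARAMETRIC_FAMILIES)}"
        )
    n_par, make_hazard, start = PARAMETRIC_FAMILIES[family_name]
    fixed = fixed or {}
    free = [i for i in range(n_par) if i not in fixed]
    y, tau, mid = _poisson_data(lt)
    width = lt.width

    def expand(theta_free):
        th = np.empty(n_par)
        th[free] = theta_free
        for i, v in fixed.items():
            th[i] = v
        return th

    def negll(theta_free):
        th = expand(theta_free)
        if np.any(np.abs(th) > 50):
            return 1e10
        hz = make_hazard(th)
        lam = hz(mid) * width
        if not np.all(np.isfinite(lam)) or np.any(lam < 0) or np.any((y > 0) & (lam <= 0)):
            return 1e10
        return -poisson_loglik(y, np.maximum(lam, 1e-300), tau)

    res = optimize.minimize(
        negll, start[free], method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 5000},
    )
    res = optimize.minimize(negll, res.x, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-11, "maxiter": 5000})
    if not np.isfinite(res.fun) or res.fun >= 1e10:
        raise RuntimeError(f"parametric hazard fit failed for {family_name}")
    theta = expand(res.x)
    hz = make_hazard(theta)

    def predict(times, hz=hz, width=width):
        return hz(np.asarray(times, dtype=float)) * width

    return FittedHazardModel(
        name=family_name,
        family=FamilySpec("poisson", "exponential"),
        design=DesignSpec("none", label=f"parametric:{family_name}"),
        beta=theta,
        loglik=-float(res.fun),
        k=float(len(free)),
        predict=predict,
        extra={"parameterization": "unconstrained (log for positive parameters)"},
    )


def predict_hazard(model: FittedHazardModel, times: Sequence[float]) -> np.ndarray:
    """Per-interval hazard at the given times (years)."""
    times = np.asarray(times, dtype=float)
    if model.design.transform in ("log_t", "basis") and np.any(times <= 0):
        raise ValueError("hazard at t <= 0 requested for a log-time design")
    return model.predict(times)
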