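"""Dynamic survival models: Poisson state-space filtering of the hazard.

The log hazard is a latent state evolving over life-table intervals,

* observation:  ``y_t ~ Poisson(lambda_t tau_t)``, ``log lambda_t`` = level state;
* transition:   ``state_t = F state_{t-1} + innovation``;
* initial:      ``state_0 ~ N(b0, Z0)``.

Three structures are provided: a local level (random-walk log hazard), a
local level with a fixed global drift, and a local level + local trend
model.  Filtering uses the conjugate-gamma dynamic-GLM update: the normal
state prior on the log hazard is moment-matched to a gamma prior on the
hazard (digamma/trigamma matching), conjugately updated by the Poisson
count, and matched back.  State innovation is parameterized by discount
factors.  Hyperparameters are chosen by minimizing one-step-ahead forecast
error, so parameter estimation directly targets extrapolation quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .glm_core import DesignSpec, FamilySpec, FittedHazardModel, aic
from .lifetable import LifeTable

__all__ = ["DSMSpec", "DSMFit", "dsm_filter", "fit_dsm", "dsm_forecast", "STRUCTURES"]

STRUCTURES = ("local_level", "level_with_drift", "local_trend")

#: optimized hyperparameters per structure (initial level / trend, prior
#: scale, discounts, drift) — also the AIC parameter count.
_N_HYPER = {"local_level": 3, "level_with_drift": 4, "local_trend": 5}


def _trigamma_inv(q: float) -> float:
    """Solve ``polygamma(1, a) = q`` for ``a`` by Newton."""
    a = (1.0 + np.sqrt(1.0 + 2.0 * q)) / (2.0 * q)  # from psi'(a) ~ 1/a + 1/(2a^2)
    for _ in range(50):
        f = special.polygamma(1, a) - q
        fp = special.polygamma(2, a)
        step = f / fp
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) < 1e-13 * a:
            a = a_new
            break
        a = a_new
    return float(a)


@dataclass(frozen=True)
class DSMSpec:
    """Structure + hyperparameters of a dynamic hazard model.

    ``delta`` discounts the level (and, for ``local_trend``, ``delta_trend``
    the trend): each step the state-prior variance is inflated by ``1/delta``,
    so ``delta = 1`` means a static coefficient.  ``drift`` is a fixed
    per-interval increment of the log hazard (``level_with_drift`` only).
    """

    structure: str
    b0: np.ndarray  # initial state mean
    z0: float  # initial state variance scale
    delta: float = 0.95
    delta_trend: float = 0.98
    drift: float = 0.0

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}; valid: {STRUCTURES}")
        if not (0.0 < self.delta <= 1.0) or not (0.0 < self.delta_trend <= 1.0):
            raise ValueError("discount factors must lie in (0, 1]")
        dim = 2 if self.structure == "local_trend" else 1
        if np.shape(np.atleast_1d(self.b0)) != (dim,):
            raise ValueError(f"b0 must have dimension {dim} for {self.structure}")

    @property
    def dim(self) -> int:
        return 2 if self.structure == "local_trend" else 1


@dataclass
class DSMFit:
    """Filter output: states, one-step forecasts and fit statistics."""

    spec: DSMSpec
    width: float
    m: np.ndarray = field(repr=False)  # filtered state means, T x dim
    C: np.ndarray = field(repr=False)  # filtered state covariances, T x dim x dim
    forecast: np.ndarray = field(repr=False)  # one-step-ahead hazards
    sse: float = 0.0
    pred_loglik: float = 0.0
    skipped: list[int] = field(default_factory=list)
    n_intervals: int = 0

    @property
    def k(self) -> float:
        return float(_N_HYPER[self.spec.structure])

    @property
    def aic(self) -> float:
        return aic(self.pred_loglik, self.k)

    def final_state(self) -> tuple[np.ndarray, np.ndarray]:
        return self.m[-1], self.C[-1]


def dsm_filter(lt: LifeTable, spec: DSMSpec) -> DSMFit:
    """Run the conjugate-gamma Poisson filter over a life table.

    Each interval: the state is propagated (drift added, variance discounted),
    the implied normal prior on the log hazard is matched to a gamma, updated
    with ``(y_t, tau_t)``, and the posterior moments are folded back into the
    state.  Intervals with zero exposure are skipped (no update).  Returns
    one-step hazard forecasts, their SSE against the empirical hazard, and
    the one-step predictive (negative-binomial) log-likelihood.
    """
    if len(lt) == 0:
        raise ValueError("empty life table")
    dim = spec.dim
    if spec.structure == "local_trend":
        G = np.array([[1.0, 1.0], [0.0, 1.0]])
        deltas = np.array([spec.delta, spec.delta_trend])
    else:
        G = np.eye(1)
        deltas = np.array([spec.delta])
    Fobs = np.zeros(dim)
    Fobs[0] = 1.0

    m = np.atleast_1d(np.asarray(spec.b0, dtype=float)).copy()
    C = np.eye(dim) * spec.z0
    T = len(lt)
    ms = np.empty((T, dim))
    Cs = np.empty((T, dim, dim))
    forecasts = np.empty(T)
    sse = 0.0
    pll = 0.0
    skipped: list[int] = []

    infl = 1.0 / np.sqrt(np.outer(deltas, deltas))
    for t in range(T):
        a = G @ m
        if spec.structure == "level_with_drift":
            a = a + np.array([spec.drift])
        R = (G @ C @ G.T) * infl
        f = float(Fobs @ a)
        qv = float(Fobs @ R @ Fobs)
        alpha = _trigamma_inv(qv)
        beta = np.exp(special.digamma(alpha) - f)
        lam_hat = alpha / beta  # one-step forecast of the hazard
        forecasts[t] = lam_hat

        y, tau = lt.events[t], lt.at_risk[t]
        if tau <= 0:
            skipped.append(t)
            m, C = a, R
            ms[t], Cs[t] = m, C
            continue
        sse += (lam_hat - lt.hazard[t]) ** 2
        # negative-binomial one-step predictive mass
        pll += float(
            special.gammaln(alpha + y) - special.gammaln(alpha) - special.gammaln(y + 1)
            + alpha * np.log(beta / (beta + tau))
            + y * np.log(tau / (beta + tau))
        )
        a_post = alpha + y
        b_post = beta + tau
        g = special.digamma(a_post) - np.log(b_post)
        p = special.polygamma(1, a_post)
        RF = R @ Fobs
        m = a + RF * (g - f) / qv
        C = R - np.outer(RF, RF) * (1.0 - p / qv) / qv
        ms[t], Cs[t] = m, C

    return DSMFit(
        spec=spec, width=lt.width, m=ms, C=Cs, forecast=forecasts,
        sse=float(sse), pred_loglik=float(pll), skipped=skipped, n_intervals=T,
    )


def dsm_forecast(fit: DSMFit, horizon_intervals: int) -> np.ndarray:
    """Extrapolated hazard for the next ``horizon_intervals`` intervals.

    Local level extrapolates flat at the last filtered level; the drift and
    trend structures continue the log hazard linearly.
    """
    if horizon_intervals <= 0:
        raise ValueError("horizon must be a positive number of intervals")
    m, _ = fit.final_state()
    h = np.arange(1, horizon_intervals + 1, dtype=float)
    if fit.spec.structure == "local_level":
        eta = np.full_like(h, m[0])
    elif fit.spec.structure == "level_with_drift":
        eta = m[0] + fit.spec.drift * h
    else:
        eta = m[0] + m[1] * h
    return np.exp(eta)


def _pack_bounds(structure: str, lt: LifeTable):
    crude = np.log(max(lt.events.sum(), 0.5) / lt.at_risk.sum())
    if structure == "local_level":
        x0 = [crude, 0.0, 0.95]
        bounds = [(crude - 6, crude + 4), (-6.0, 3.0), (0.8, 1.0)]
    elif structure == "level_with_drift":
        x0 = [crude, 0.0, 0.95, 0.0]
        bounds = [(crude - 6, crude + 4), (-6.0, 3.0), (0.8, 1.0), (-0.5, 0.5)]
    else:
        x0 = [crude, 0.0, 0.0, 0.95, 0.98]
        bounds = [(crude - 6, crude + 4), (-0.5, 0.5), (-6.0, 3.0), (0.8, 1.0), (0.8, 1.0)]
    return np.array(x0, dtype=float), bounds


def _unpack(structure: str, x) -> DSMSpec:
    if structure == "local_level":
        return DSMSpec(structure, b0=np.array([x[0]]), z0=float(np.exp(x[1])), delta=float(x[2]))
    if structure == "level_with_drift":
        return DSMSpec(structure, b0=np.array([x[0]]), z0=float(np.exp(x[1])),
                       delta=float(x[2]), drift=float(x[3]))
    return DSMSpec(structure, b0=np.array([x[0], x[1]]), z0=float(np.exp(x[2])),
                   delta=float(x[3]), delta_trend=float(x[4]))


def fit_dsm(lt: LifeTable, structure: str) -> DSMFit:
    """Tune DSM hyperparameters by one-step-ahead forecast error.

    Bounded Nelder–Mead search over (initial state, prior scale, discount
    factor(s), drift) minimizing the forecast SSE of :func:`dsm_filter`.
    The optimized hyperparameter count (3 / 4 / 5 by structure) is the
    model's AIC parameter count.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}; valid: {STRUCTURES}")
    if len(lt) < 10:
        raise ValueError("dynamic models need at least 10 life-table intervals")
    x0, bounds = _pack_bounds(structure, lt)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def objective(x):
        if np.any(x < lo) or np.any(x > hi):
            return 1e10
        try:
            return dsm_filter(lt, _unpack(structure, x)).sse
        except (ValueError, FloatingPointError, OverflowError):
            return 1e10

    best = None
    for start in (x0, (x0 + lo) / 2 + (hi - x0) / 4):
        res = optimize.minimize(objective, start, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 800})
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun) or best.fun >= 1e10:
        raise RuntimeError(f"DSM hyperparameter search failed for {structure}")
    return dsm_filter(lt, _unpack(structure, np.clip(best.x, lo, hi)))


def as_hazard_model(fit: DSMFit, name: str | None = None) -> FittedHazardModel:
    """Wrap a DSM fit as a hazard model for the comparison workflow.

    Within the fitted range the hazard is the filtered (posterior) level;
    beyond it the structure's extrapolation rule applies.  The reported
    log-likelihood is the one-step predictive log-likelihood.
    """
    width = fit.width
    T = fit.n_intervals
    level = fit.m[:, 0]

    def predict(times):
        t = np.asarray(times, dtype=float)
        idx = np.floor(t / width + 1e-12).astype(int)
        out = np.empty(t.shape)
        inside = idx < T
        out[inside] = np.exp(level[np.clip(idx[inside], 0, T - 1)])
        if np.any(~inside):
            horizon = int(idx.max()) - T + 1
            extr = dsm_forecast(fit, horizon)
            out[~inside] = extr[idx[~inside] - T]
        return out

    return FittedHazardModel(
        name=name or fit.spec.structure,
        family=FamilySpec("poisson", "exponential"),
        design=DesignSpec("none", label=f"dsm:{fit.spec.structure}"),
        beta=fit.m[-1],
        loglik=fit.pred_loglik,
        k=fit.k,
        predict=predict,
        extra={"dsm": {"structure": fit.spec.structure, "delta": fit.spec.delta,
                       "drift": fit.spec.drift, "sse_onestep": fit.sse}},
    )


def fit_log(fit: DSMFit):
    """Per-interval filter log (state, forecast, error) as a DataFrame."""
    import pandas as pd

    T = fit.n_intervals
    return pd.DataFrame(
        {
            "interval": np.arange(T),
            "level": fit.m[:, 0],
            "trend": fit.m[:, 1] if fit.spec.dim == 2 else np.zeros(T),
            "forecast_hazard": fit.forecast,
        }
    )
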