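"""Model comparison: AIC tables, split-sample extrapolation error, life expectancy.

The workflow mirrors a standard extrapolation assessment: every model is
fit on the full data (within-sample AIC) and refit on follow-up truncated
at a cutoff (default three years); the truncated fit's hazard predictions
are scored against the observed monthly hazard over a holdout window
(default months 37-88) by sum of squared errors; and mean life expectancy
is computed from the full-data fit by actuarial integration of the
extrapolated survival curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .glm_core import FittedHazardModel, aic
from .lifetable import LifeTable, SubjectRecord, build_lifetable, truncate_followup

__all__ = [
    "ComparisonRow",
    "extrapolation_sse",
    "life_expectancy",
    "compare_models",
    "comparison_frame",
    "hazard_curves",
    "DEFAULT_WINDOW",
]

#: Default holdout window: monthly intervals 37..88 (1-based months), i.e.
#: interval indices 36..87.
DEFAULT_WINDOW = range(36, 88)


def extrapolation_sse(predicted, lt: LifeTable, window: Sequence[int]) -> tuple[float, float]:
    """Sum of squared hazard errors over a holdout window.

    ``predicted`` is either a fitted model or a hazard vector aligned with
    ``window``.  The observed hazard is the life table's empirical monthly
    hazard.  Returns ``(raw, raw * 1e4)`` — comparison tables conventionally
    report the x10^4 scale.
    """
    window = np.asarray(list(window), dtype=int)
    if window.min() < 0 or window.max() >= len(lt):
        raise ValueError(
            f"window [{window.min()}, {window.max()}] outside the observed life table (0..{len(lt) - 1})"
        )
    if isinstance(predicted, FittedHazardModel):
        lam_hat = predicted.predict(lt.midpoints[window])
    else:
        lam_hat = np.asarray(predicted, dtype=float)
        if lam_hat.shape != window.shape:
            raise ValueError("predicted hazard vector must align with the window")
    sse = float(np.sum((lam_hat - lt.hazard[window]) ** 2))
    return sse, sse * 1e4


def life_expectancy(model, horizon: float = 100.0, width: float = 1.0 / 12.0) -> float:
    """Mean survival (years) by actuarial integration to ``horizon``.

    The per-interval hazard is evaluated at interval midpoints, clamped to
    [0, 1]; survival is the cumulative product of ``1 - hazard`` and the
    mean is ``width * sum_t S(t)``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    n = int(np.ceil(horizon / width))
    mids = (np.arange(n) + 0.5) * width
    lam = model.predict(mids) if hasattr(model, "predict") else np.asarray(model(mids), dtype=float)
    lam = np.asarray(lam, dtype=float)
    if not np.all(np.isfinite(lam)):
        raise ValueError("hazard predictions diverge over the life-expectancy horizon")
    lam = np.clip(lam, 0.0, 1.0)
    surv = np.cumprod(1.0 - lam)
    return float(width * surv.sum())


@dataclass
class ComparisonRow:
    """One model's record in the comparison table."""

    name: str
    loglik: float
    k: float
    aic_full: float
    aic_train: float
    sse: float  # x 1e4
    life_expectancy: float
    error: str = ""


def compare_models(
    records: list[SubjectRecord],
    registry: dict[str, Callable[..., FittedHazardModel]],
    split_cutoff: float = 3.0,
    window: Sequence[int] = DEFAULT_WINDOW,
    horizon: float = 100.0,
    width: float = 1.0 / 12.0,
) -> list[ComparisonRow]:
    """Fit every registered model on full and truncated data and score it.

    ``registry`` maps a display name to a fitting callable
    ``(LifeTable, records) -> FittedHazardModel`` (the records are supplied
    so that e.g. spline knots can be re-derived from the event times of the
    data actually being fit).  Per-model failures are recorded in the row
    rather than aborting the table.  The holdout empirical hazard always
    comes from the full-data life table; the split affects fitting only.
    """
    if not registry:
        raise ValueError("empty model registry")
    train_records = truncate_followup(records, split_cutoff)
    lt_full = build_lifetable(records, width)
    lt_train = build_lifetable(train_records, width)
    window = [i for i in window if i < len(lt_full)]
    rows = []
    for name, fitter in registry.items():
        try:
            full = fitter(lt_full, records)
            train = fitter(lt_train, train_records)
            sse_raw, sse_scaled = extrapolation_sse(train, lt_full, window)
            le = life_expectancy(full, horizon=horizon, width=width)
            rows.append(
                ComparisonRow(
                    name=name,
                    loglik=full.loglik,
                    k=full.k,
                    aic_full=full.aic,
                    aic_train=train.aic,
                    sse=sse_scaled,
                    life_expectancy=le,
                )
            )
        except Exception as exc:  # failures stay in-row
            rows.append(ComparisonRow(name, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, error=str(exc)))
    return rows


def comparison_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    """Comparison rows as a DataFrame sorted by full-data AIC."""
    df = pd.DataFrame(
        {
            "model": [r.name for r in rows],
            "loglik": [r.loglik for r in rows],
            "k": [r.k for r in rows],
            "aic_full": [r.aic_full for r in rows],
            "aic_train": [r.aic_train for r in rows],
            "sse_x1e4": [r.sse for r in rows],
            "life_expectancy": [r.life_expectancy for r in rows],
            "error": [r.error for r in rows],
        }
    )
    return df.sort_values("aic_full", kind="stable").reset_index(drop=True)


def hazard_curves(
    lt: LifeTable,
    models: dict[str, FittedHazardModel],
    horizon: float = 10.0,
) -> pd.DataFrame:
    """Tidy observed + fitted + extrapolated hazard curves for plotting."""
    frames = [
        pd.DataFrame(
            {"model": "observed", "time": lt.midpoints, "hazard": lt.hazard, "at_risk": lt.at_risk}
        )
    ]
    n = int(np.ceil(horizon / lt.width))
    mids = (np.arange(n) + 0.5) * lt.width
    for name, model in models.items():
        frames.append(
            pd.DataFrame({"model": name, "time": mids, "hazard": model.predict(mids), "at_risk": np.nan})
        )
    return pd.concat(frames, ignore_index=True)
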