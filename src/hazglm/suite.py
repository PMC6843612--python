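"""The eleven-model comparison suite.

Assembles the full registry used by the comparison workflow: three dynamic
models, two GAM variants, the AIC-selected restricted cubic spline, the
closed-test fractional polynomial with and without frailty, the generalized
gamma and generalized F, and the lognormal — every model scored on the
Poisson life-table likelihood scale.
"""

from __future__ import annotations

from .dynamic import as_hazard_model, fit_dsm
from .flexible import fit_fp, fit_gam, select_fp, select_rcs
from .frailty import fit_frailty
from .glm_core import FittedHazardModel, fit_parametric_hazard
from .lifetable import LifeTable, SubjectRecord

__all__ = ["default_registry"]


def _fp_with_frailty(lt: LifeTable, records: list[SubjectRecord]) -> FittedHazardModel:
    """Frailty on top of the best FP(2) design (AIC-chosen powers)."""
    fp = select_fp(lt)
    powers = tuple(fp.extra["best_fp2_powers"])
    base = fit_fp(lt, powers)
    fit = fit_frailty(lt, base.design, name=f"FP{powers}+frailty")
    return fit.model


def default_registry() -> dict:
    """Name -> ``(LifeTable, records) -> FittedHazardModel`` for all 11 models."""
    return {
        "local level": lambda lt, rec: as_hazard_model(fit_dsm(lt, "local_level"), "local level"),
        "local level with drift": lambda lt, rec: as_hazard_model(
            fit_dsm(lt, "level_with_drift"), "local level with drift"
        ),
        "local trend": lambda lt, rec: as_hazard_model(fit_dsm(lt, "local_trend"), "local trend"),
        "GAM v1": lambda lt, rec: fit_gam(lt, q=11, selection="fixed-q"),
        "GAM v2": lambda lt, rec: fit_gam(lt, selection="aic-q"),
        "RCS": lambda lt, rec: select_rcs(lt, rec),
        "FP": lambda lt, rec: select_fp(lt),
        "FP with random effects": _fp_with_frailty,
        "generalized gamma": lambda lt, rec: fit_parametric_hazard(lt, "generalized-gamma"),
        "generalized F": lambda lt, rec: fit_parametric_hazard(lt, "generalized-F"),
        "lognormal": lambda lt, rec: fit_parametric_hazard(lt, "lognormal-hazard"),
    }
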