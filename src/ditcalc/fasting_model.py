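"""Per-animal fasting regression of EE on transformed activity.

The method's core assumption is that under fasting conditions energy
expenditure is linear in a concave transform of the spontaneous-activity
count — by default its square root, which straightens the scatter because
the energetic cost of an extra beam break falls off at high activity.  For
animals that move very little, a log transform (realized as ln(1 + x) so
zero counts are in-domain) can fit better; :func:`select_transform` compares
candidates by R² and leaves the choice to the analyst.

The fit is ordinary least squares, one model per animal, never pooled:
between-animal differences in resting EE and activity cost are exactly what
the per-animal intercept and slope absorb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io import CalorimetryError
from .preprocess import BinnedTrace

__all__ = [
    "TRANSFORMS",
    "FastingModel",
    "ResidualDiagnostics",
    "transform_activity",
    "fit_fasting_model",
    "select_transform",
    "residual_diagnostics",
    "predict_ee",
]

TRANSFORMS = ("sqrt", "log1p", "identity")
# fixed preference order for R² ties in select_transform
_TRANSFORM_PREFERENCE = {"sqrt": 0, "log1p": 1, "identity": 2}


def transform_activity(counts, method: str = "sqrt"):
    """Apply the chosen activity transform to non-negative counts/min."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise CalorimetryError("activity counts must be non-negative")
    if method == "sqrt":
        out = np.sqrt(counts)
    elif method == "log1p":
        out = np.log1p(counts)
    elif method == "identity":
        out = counts
    else:
        raise CalorimetryError(f"unknown transform {method!r}; use one of {TRANSFORMS}")
    return float(out) if out.ndim == 0 else out


@dataclass
class FastingModel:
    """OLS fit of fasting EE on transformed activity for one animal.

    ``intercept`` is the model's EE at zero activity (kcal/min) — the
    resting reading; ``slope`` is kcal/min per transformed-activity unit.
    """

    intercept: float
    slope: float
    transform: str
    r2: float
    n_points: int
    residuals: np.ndarray
    fitted: np.ndarray
    animal_id: str = "unknown"

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "transform": self.transform,
            "r2": self.r2,
            "n_points": self.n_points,
            "animal_id": self.animal_id,
        }


@dataclass
class ResidualDiagnostics:
    """Homoscedasticity check for a fitted fasting model.

    ``homoscedasticity_pvalue`` comes from a Breusch–Pagan test of the
    squared residuals against the fitted values (LM statistic n·R², 1 df).
    It is advisory — the method inspects the residual plot, it never gates
    on the p-value.
    """

    homoscedasticity_pvalue: float
    residual_vs_fitted: np.ndarray  # shape (n, 2): fitted, residual
    degenerate: bool = False


def fit_fasting_model(fasting: BinnedTrace, transform: str = "sqrt") -> FastingModel:
    """Simple linear regression of binned fasting EE on transformed activity."""
    if fasting.n_bins < 3:
        raise CalorimetryError(
            f"need at least 3 bins to fit, got {fasting.n_bins}"
        )
    x = transform_activity(fasting.activity, transform)
    y = np.asarray(fasting.ee, dtype=float)
    if np.ptp(x) == 0:
        raise CalorimetryError(
            "transformed activity is constant; regression design is degenerate"
        )
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    resid = y - fitted
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst
    return FastingModel(
        intercept=float(res.intercept),
        slope=float(res.slope),
        transform=transform,
        r2=r2,
        n_points=fasting.n_bins,
        residuals=resid,
        fitted=fitted,
        animal_id=fasting.animal_id,
    )


def select_transform(
    fasting: BinnedTrace, candidates: Sequence[str] = TRANSFORMS
) -> tuple[str, dict[str, float]]:
    """Fit every candidate transform and pick the one with the highest R².

    Ties break by the fixed preference order sqrt > log1p > identity.
    Returns ``(best_transform, {transform: r2})``; candidates whose fit
    fails (degenerate design) are omitted from the table.
    """
    if not candidates:
        raise CalorimetryError("candidates must be non-empty")
    table: dict[str, float] = {}
    errors: list[str] = []
    for cand in candidates:
        try:
            table[cand] = fit_fasting_model(fasting, cand).r2
        except CalorimetryError as exc:
            errors.append(f"{cand}: {exc}")
    if not table:
        raise CalorimetryError(
            "every candidate transform failed to fit: " + "; ".join(errors)
        )
    best = max(table, key=lambda c: (table[c], -_TRANSFORM_PREFERENCE.get(c, 99)))
    return best, table


def residual_diagnostics(model: FastingModel) -> ResidualDiagnostics:
    """Breusch–Pagan homoscedasticity test plus residual-vs-fitted pairs."""
    pairs = np.column_stack([model.fitted, model.residuals])
    if np.allclose(model.residuals, 0) or np.ptp(model.fitted) == 0:
        # a perfect line (or flat fit) carries no variance information
        return ResidualDiagnostics(1.0, pairs, degenerate=True)
    from statsmodels.stats.diagnostic import het_breuschpagan

    exog = np.column_stack([np.ones_like(model.fitted), model.fitted])
    lm, lm_pvalue, _, _ = het_breuschpagan(model.residuals, exog)
    return ResidualDiagnostics(float(lm_pvalue), pairs)


def predict_ee(model: FastingModel, activity):
    """Activity-matched EE prediction: intercept + slope * transform(activity)."""
    x = transform_activity(activity, model.transform)
    out = model.intercept + model.slope * np.asarray(x, dtype=float)
    return float(out) if np.ndim(out) == 0 else out
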