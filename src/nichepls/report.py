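"""Interpretation of the fitted model: signaling calls, external validation, stepwise rebuild.

* :func:`classify_signaling` reads the autocrine/paracrine coefficient–VIP
  pattern off a (reduced) model: each retained ``auto_<factor>`` /
  ``para_<factor>`` column becomes a call with a mode, a direction
  (stimulatory if the scaled coefficient is positive) and a significance flag
  (VIP at or above the threshold). The condition-level columns (cellcell,
  adhesion, heparin) are reported separately as environment effects.

* :func:`external_validate` applies a frozen model to an independent
  condition set, regresses observed on predicted cell numbers, and reports
  R², slope, intercept and a classical prediction band of that regression.
  A slope far from 1 with high R² indicates a global rescaling of
  proliferation (e.g. a different cytokine background) rather than a failure
  of the mechanistic structure.

* :func:`stepwise_rebuild` re-applies the full model's scaled coefficients
  over growing variable sets (ordered by decreasing VIP) without refitting,
  showing how much of the prediction each signaling layer carries.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix
from .pls import PLSModel, predict

__all__ = [
    "SignalingMode",
    "Direction",
    "SignalingCall",
    "EnvironmentEffect",
    "ValidationReport",
    "classify_signaling",
    "external_validate",
    "stepwise_rebuild",
    "steps_from_vip_cutpoints",
]


class SignalingMode(str, enum.Enum):
    AUTOCRINE = "autocrine"
    PARACRINE = "paracrine"


class Direction(str, enum.Enum):
    STIMULATORY = "stimulatory"
    INHIBITORY = "inhibitory"
    NONE = "none"


@dataclass(frozen=True)
class SignalingCall:
    factor: str
    mode: SignalingMode
    vip: float
    coefficient: float  # scaled space
    direction: Direction
    significant: bool


@dataclass(frozen=True)
class EnvironmentEffect:
    name: str  # cellcell / adhesion / heparin
    vip: float
    coefficient: float
    direction: Direction
    significant: bool


def _direction(coef: float) -> Direction:
    if coef > 0:
        return Direction.STIMULATORY
    if coef < 0:
        return Direction.INHIBITORY
    return Direction.NONE


def classify_signaling(
    model: PLSModel, vip_threshold: float = 0.8
) -> tuple[list[SignalingCall], list[EnvironmentEffect]]:
    """One autocrine/paracrine call per retained factor column, plus environment effects.

    A coefficient of exactly zero carries no direction and is never
    significant, whatever its VIP.
    """
    calls: list[SignalingCall] = []
    env: list[EnvironmentEffect] = []
    for name, coef, vip in zip(model.column_names, model.coeff_scaled, model.vip):
        coef, vip = float(coef), float(vip)
        significant = bool(vip >= vip_threshold and coef != 0.0)
        if name.startswith("auto_") or name.startswith("para_"):
            mode = SignalingMode.AUTOCRINE if name.startswith("auto_") else SignalingMode.PARACRINE
            calls.append(
                SignalingCall(
                    factor=name.split("_", 1)[1],
                    mode=mode,
                    vip=vip,
                    coefficient=coef,
                    direction=_direction(coef),
                    significant=significant,
                )
            )
        else:
            env.append(
                EnvironmentEffect(
                    name=name, vip=vip, coefficient=coef,
                    direction=_direction(coef), significant=significant,
                )
            )
    return calls, env


def calls_to_frame(calls: Sequence[SignalingCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "factor": c.factor,
                "mode": c.mode.value,
                "vip": c.vip,
                "coefficient": c.coefficient,
                "direction": c.direction.value,
                "significant": c.significant,
            }
            for c in calls
        ]
    )


@dataclass
class ValidationReport:
    """Observed-vs-predicted regression of a frozen model on external samples."""

    r_squared: float
    slope: float
    intercept: float
    slope_ratio: float  # slope relative to the ideal 1 (global-rescaling diagnostic)
    prediction_band_level: float
    table: pd.DataFrame  # sample_id, predicted, observed, lower, upper, inside_band

    def to_dict(self) -> dict:
        d = {
            "r_squared": self.r_squared,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ratio": self.slope_ratio,
            "prediction_band_level": self.prediction_band_level,
            "samples": self.table.to_dict(orient="records"),
        }
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def external_validate(
    model: PLSModel,
    rows,
    observed: np.ndarray,
    sample_ids: Sequence[str] | None = None,
    column_names: Sequence[str] | None = None,
    band_level: float = 0.90,
) -> ValidationReport:
    """Validate a frozen model on an external condition set.

    ``rows`` carries raw-unit predictors (DataFrame or array +
    ``column_names``); ``observed`` the measured day-7 cell counts. The
    observed counts are regressed on the model predictions; the prediction
    band is the classical pointwise interval of that simple regression at
    ``band_level``.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.size < 3:
        raise ValueError(f"external validation needs >= 3 samples, got {observed.size}")
    pred = predict(model, rows, column_names=column_names)
    if pred.shape != observed.shape:
        raise ValueError("predictions and observations differ in length")
    if np.ptp(pred) == 0:
        raise ValueError("model predictions are constant on the external set; no regression possible")

    n = observed.size
    x, y = pred, observed
    xbar = x.mean()
    sxx = float(((x - xbar) ** 2).sum())
    slope = float(((x - xbar) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * xbar)
    fitted = intercept + slope * x
    sse = float(((y - fitted) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0

    dof = n - 2
    s = np.sqrt(sse / dof) if dof > 0 else 0.0
    tq = stats.t.ppf(0.5 + band_level / 2.0, dof) if dof > 0 else np.inf
    half = tq * s * np.sqrt(1.0 + 1.0 / n + (x - xbar) ** 2 / sxx)
    lower, upper = fitted - half, fitted + half
    inside = (y >= lower) & (y <= upper)

    if sample_ids is None and isinstance(rows, pd.DataFrame) and "sample_id" in rows.columns:
        sample_ids = rows["sample_id"].tolist()
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    table = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "predicted": x,
            "observed": y,
            "band_lower": lower,
            "band_upper": upper,
            "inside_band": inside,
        }
    )
    return ValidationReport(
        r_squared=float(r2),
        slope=slope,
        intercept=intercept,
        slope_ratio=slope / 1.0,
        prediction_band_level=band_level,
        table=table,
    )


def steps_from_vip_cutpoints(
    model: PLSModel, cutpoints: Sequence[float] = (1.6, 1.3, 1.1), include_rest: bool = True
) -> list[list[str]]:
    """Group model variables into rebuild steps by descending VIP cut points.

    The first step takes every variable with VIP above the first cut point,
    each following step the band between consecutive cut points; with
    ``include_rest`` a final step adds whatever remains so the rebuild
    telescopes to the full model. Empty bands are dropped.
    """
    cuts = sorted(cutpoints, reverse=True)
    order = np.argsort(-model.vip, kind="stable")
    names = [model.column_names[i] for i in order]
    vips = model.vip[order]
    steps: list[list[str]] = []
    upper = np.inf
    for c in cuts:
        band = [n for n, v in zip(names, vips) if c < v <= upper]
        if band:
            steps.append(band)
        upper = c
    if include_rest:
        rest = [n for n, v in zip(names, vips) if v <= upper]
        if rest:
            steps.append(rest)
    return steps


def stepwise_rebuild(
    model: PLSModel,
    dm: DesignMatrix,
    steps: Sequence[Sequence[str]],
) -> pd.DataFrame:
    """Partial predictions from cumulative variable sets at the full model's coefficients.

    For the cumulative set S after each step, the partial prediction is

        yhat_S = mean(y) + sd(y) * sum_{j in S} b_j * x_j(scaled)

    using the already-fitted scaled coefficients b_j — no refitting, so each
    step shows the contribution layer the added variables carry. The empty
    set (step 0) is the response mean; the full set reproduces the model's
    fitted values exactly.

    Returns a tidy frame: step, added variables, sample_id, condition group,
    observed and partial-predicted cell numbers.
    """
    known = set(model.column_names)
    flat = [v for s in steps for v in s]
    unknown = sorted(set(flat) - known)
    if unknown:
        raise ValueError(f"unknown variable name(s) in steps: {unknown}")
    if len(set(flat)) != len(flat):
        raise ValueError("a variable appears in more than one step")

    vip_by_name = dict(zip(model.column_names, model.vip))
    max_vips = [max(vip_by_name[v] for v in s) for s in steps]
    if any(b > a + 1e-12 for a, b in zip(max_vips, max_vips[1:])):
        warnings.warn("rebuild steps are not in decreasing VIP order", stacklevel=2)

    if dm.scaled:
        raise ValueError("pass the unscaled design; the model's own scaling is applied")
    idx_all = [dm.column_names.index(n) for n in model.column_names]
    Xs = (dm.X[:, idx_all] - model.column_means) / model.column_sds
    contrib = Xs * model.coeff_scaled  # per-variable scaled contributions

    col_pos = {n: i for i, n in enumerate(model.column_names)}
    rows = []
    partial = np.zeros(dm.n_samples)
    cumulative: list[str] = []
    step_sets = [[]] + [list(s) for s in steps]
    for step_no, added in enumerate(step_sets):
        if added:
            partial = partial + contrib[:, [col_pos[v] for v in added]].sum(axis=1)
            cumulative = cumulative + added
        yhat = model.y_mean + model.y_sd * partial
        for i, sid in enumerate(dm.sample_ids):
            rows.append(
                {
                    "step": step_no,
                    "added": "+".join(added) if added else "(baseline)",
                    "n_variables": len(cumulative),
                    "sample_id": sid,
                    "material": dm.groups[i][0],
                    "cavity": dm.groups[i][1],
                    "observed": float(dm.y[i]),
                    "predicted": float(yhat[i]),
                }
            )
    return pd.DataFrame(rows)


def stepwise_group_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-step per-condition-group means of the rebuild table (plot-ready)."""
    return (
        table.groupby(["step", "added", "material", "cavity"], sort=True)[["observed", "predicted"]]
        .mean()
        .reset_index()
    )
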