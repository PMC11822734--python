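"""Per-sample concentration-change prediction and model validation.

Prediction combines the pre- and postcentrifugation drift models of a
parameter: the expected percent change of a sample processed with
delays (t_pre, t_post) is

    pct_total = 100 * (beta1_pre * t_pre + beta1_post * t_post) / beta0

where the baseline beta0 is taken from the precentrifugation model by
default (it estimates the concentration at blood draw). Predictions are
flagged against a user-set tolerable error (default 15%).

Validation follows the held-out timecourse protocol: each validation
donor's time-0 observation anchors the model's slope, the remaining
time points are predicted, and the mean percentage error (MPE) over
donors is reported per parameter × time, signed and in absolute value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drift import DriftModel, ModelStore
from .preanalytics import SampleRecord

__all__ = [
    "PredictionEntry",
    "ValidationResult",
    "predict_pct_change",
    "flag_tolerable",
    "predict_cohort",
    "mpe_validation",
    "validation_frame",
]

DEFAULT_TOLERABLE_ERROR_PCT = 15.0


@dataclass(frozen=True)
class PredictionEntry:
    """Predicted percent change for one sample × parameter."""

    sample_id: str
    parameter: str
    pct_change_pre: float | None
    pct_change_post: float | None
    pct_change_total: float | None
    exceeds_tolerable: bool | None
    tolerable_error: float
    partial: bool = False
    note: str | None = None


@dataclass(frozen=True)
class ValidationResult:
    """Mean percentage error for one parameter × material × phase × time."""

    parameter: str
    material: str
    phase: str
    time_h: float
    mpe_pct: float
    abs_mpe_pct: float
    n_donors: int


def predict_pct_change(
    model_pre: DriftModel | None,
    model_post: DriftModel | None,
    t_pre: float,
    t_post: float,
    baseline: str = "pre",
) -> tuple[float | None, float | None, float | None]:
    """Percent change from the two phase models at the given delays.

    Returns ``(pct_pre, pct_post, pct_total)``. A missing phase model
    yields ``None`` for that component and a partial total equal to the
    available component. ``baseline`` selects which model's intercept
    normalizes the change ("pre" by default; "post" uses the
    postcentrifugation intercept when only that model exists).
    """
    if model_pre is None and model_post is None:
        raise ValueError("at least one phase model is required")
    if model_pre is not None and model_post is not None:
        if model_pre.parameter != model_post.parameter:
            raise ValueError(
                f"parameter mismatch: {model_pre.parameter!r} vs {model_post.parameter!r}"
            )
        if model_pre.material != model_post.material:
            raise ValueError(
                f"material mismatch: {model_pre.material!r} vs {model_post.material!r}"
            )
    if t_pre < 0 or t_post < 0:
        raise ValueError("delays must be non-negative")
    if baseline == "pre":
        base_model = model_pre if model_pre is not None else model_post
    elif baseline == "post":
        base_model = model_post if model_post is not None else model_pre
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    b0 = base_model.beta0
    if b0 <= 0:
        raise ValueError(f"non-positive baseline for {base_model.parameter}")
    pct_pre = 100.0 * model_pre.beta1 * t_pre / b0 if model_pre is not None else None
    pct_post = 100.0 * model_post.beta1 * t_post / b0 if model_post is not None else None
    pct_total = (pct_pre or 0.0) + (pct_post or 0.0)
    return pct_pre, pct_post, pct_total


def flag_tolerable(pct_total: float, tolerable_error: float = DEFAULT_TOLERABLE_ERROR_PCT) -> bool:
    """True iff |pct_total| strictly exceeds the tolerable error (percent)."""
    if tolerable_error <= 0:
        raise ValueError("tolerable_error must be positive")
    return abs(pct_total) > tolerable_error


def predict_cohort(
    records: list[SampleRecord],
    store: ModelStore,
    tolerable_error: float = DEFAULT_TOLERABLE_ERROR_PCT,
    baseline: str = "pre",
) -> pd.DataFrame:
    """Predicted percent change for every sample × parameter.

    For each record (which must carry its delays) and each parameter
    with a model in the record's material, the pre- and
    postcentrifugation components are combined; a parameter with a model
    in only one phase is reported with a partial total and flagged.
    Samples whose material has no models at all get a single
    unpredicted row with a reason.
    """
    entries: list[PredictionEntry] = []
    for rec in records:
        if rec.pre_delay_h is None or rec.post_delay_h is None:
            entries.append(
                PredictionEntry(
                    sample_id=rec.sample_id,
                    parameter="",
                    pct_change_pre=None,
                    pct_change_post=None,
                    pct_change_total=None,
                    exceeds_tolerable=None,
                    tolerable_error=tolerable_error,
                    partial=True,
                    note="record has no delays",
                )
            )
            continue
        material = rec.material.value
        mat_store = store.subset(material=material)
        if len(mat_store) == 0:
            entries.append(
                PredictionEntry(
                    sample_id=rec.sample_id,
                    parameter="",
                    pct_change_pre=None,
                    pct_change_post=None,
                    pct_change_total=None,
                    exceeds_tolerable=None,
                    tolerable_error=tolerable_error,
                    partial=True,
                    note=f"no models for material {material}",
                )
            )
            continue
        for parameter in mat_store.parameters:
            m_pre = mat_store.get(parameter, material, "pre")
            m_post = mat_store.get(parameter, material, "post")
            pct_pre, pct_post, pct_total = predict_pct_change(
                m_pre, m_post, rec.pre_delay_h, rec.post_delay_h, baseline=baseline
            )
            partial = m_pre is None or m_post is None
            entries.append(
                PredictionEntry(
                    sample_id=rec.sample_id,
                    parameter=parameter,
                    pct_change_pre=pct_pre,
                    pct_change_post=pct_post,
                    pct_change_total=pct_total,
                    exceeds_tolerable=flag_tolerable(pct_total, tolerable_error),
                    tolerable_error=tolerable_error,
                    partial=partial,
                    note="missing phase model" if partial else None,
                )
            )
    return pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "parameter": e.parameter,
                "pct_pre": e.pct_change_pre,
                "pct_post": e.pct_change_post,
                "pct_total": e.pct_change_total,
                "exceeds_tolerable": e.exceeds_tolerable,
                "tolerable_error": e.tolerable_error,
                "partial": e.partial,
                "note": e.note,
            }
            for e in entries
        ],
        columns=[
            "sample_id",
            "parameter",
            "pct_pre",
            "pct_post",
            "pct_total",
            "exceeds_tolerable",
            "tolerable_error",
            "partial",
            "note",
        ],
    )


def mpe_validation(store: ModelStore, validation: pd.DataFrame) -> list[ValidationResult]:
    """Mean percentage error of model predictions on held-out timecourses.

    For each stratum with a model, each validation donor's observation
    at time 0 anchors the prediction ``pred_i(t) = obs_i(0) + beta1·t``;
    the signed MPE at each later time point is

        mpe(t) = (100 / n) · Σ_i (pred_i(t) − obs_i(t)) / obs_i(t)

    over the n donors with both measurements. Donors lacking a time-0
    value, or with obs(t) = 0, are excluded from that cell with a
    warning. Returns one result per stratum × nonzero time point.
    """
    results: list[ValidationResult] = []
    grouped = validation.dropna(subset=["value"]).groupby(
        ["parameter", "material", "phase"], sort=True, observed=True
    )
    for (parameter, material, phase), sub in grouped:
        model = store.get(parameter, material, phase)
        if model is None:
            continue
        base = sub[sub["time_h"] == 0.0].set_index("donor_id")["value"]
        later = sub[sub["time_h"] > 0.0]
        for time_h, cell in later.groupby("time_h"):
            errors = []
            for _, row in cell.iterrows():
                donor = row["donor_id"]
                obs = row["value"]
                if donor not in base.index:
                    warnings.warn(
                        f"donor {donor} lacks time-0 value for {parameter} "
                        f"({material}, {phase}); excluded",
                        stacklevel=2,
                    )
                    continue
                if obs == 0:
                    warnings.warn(
                        f"zero observation for donor {donor}, {parameter} at t={time_h}; excluded",
                        stacklevel=2,
                    )
                    continue
                pred = float(base.loc[donor]) + model.beta1 * float(time_h)
                errors.append(100.0 * (pred - obs) / obs)
            if not errors:
                continue
            mpe = float(np.mean(errors))
            results.append(
                ValidationResult(
                    parameter=parameter,
                    material=material,
                    phase=phase,
                    time_h=float(time_h),
                    mpe_pct=mpe,
                    abs_mpe_pct=abs(mpe),
                    n_donors=len(errors),
                )
            )
    return results


def validation_frame(results: list[ValidationResult]) -> pd.DataFrame:
    """Flatten validation results for delimited-text output."""
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "material": r.material,
                "phase": r.phase,
                "time_h": r.time_h,
                "mpe_pct": r.mpe_pct,
                "abs_mpe_pct": r.abs_mpe_pct,
                "n": r.n_donors,
            }
            for r in results
        ],
        columns=["parameter", "material", "phase", "time_h", "mpe_pct", "abs_mpe_pct", "n"],
    )
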