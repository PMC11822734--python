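"""Stability time points derived from fitted drift models.

The stability time point t* of a parameter is the processing delay at
which its modeled concentration has changed by a threshold fraction
(default 20%) relative to the zero-delay value:

    t* = threshold * beta0 / |beta1|

The population (fixed-effect) intercept is used as the initial value,
and the sign of the drift is ignored — a 20% rise and a 20% fall are
equally disqualifying. Parameters whose slope is numerically zero, or
whose t* exceeds the reporting horizon, are censored rather than given
a finite time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .drift import DriftModel, ModelStore
from .preanalytics import SPRECLadder, PRE_LADDER, classify_delay

__all__ = [
    "StabilityResult",
    "stability_time_point",
    "timeline_table",
    "count_within",
    "timeline_frame",
]

#: slopes below this (model units per hour) count as "no drift"
SLOPE_EPS = 1e-12

#: default censoring horizon in hours
DEFAULT_HORIZON_H = 48.0


@dataclass(frozen=True)
class StabilityResult:
    """A parameter's stability time point at a given change threshold."""

    parameter: str
    material: str
    phase: str
    threshold: float
    t_star_h: float | None
    timeline_letter: str | None
    censored: bool


def stability_time_point(
    model: DriftModel,
    threshold: float = 0.20,
    horizon_h: float = DEFAULT_HORIZON_H,
    ladder: SPRECLadder | None = None,
) -> StabilityResult:
    """Compute t* = threshold · beta0 / |beta1| for one fitted model.

    Censors when |beta1| < 1e-12 (no measurable drift) or when t*
    exceeds ``horizon_h``. Raises for a non-positive fitted baseline,
    which signals an unusable model (e.g. a parameter near the limit of
    detection).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if model.beta0 <= 0:
        raise ValueError(
            f"non-positive baseline for {model.parameter} ({model.material}, {model.phase})"
        )
    if abs(model.beta1) < SLOPE_EPS:
        t_star, censored = None, True
    else:
        t_star = threshold * model.beta0 / abs(model.beta1)
        censored = t_star > horizon_h
        if censored:
            t_star = None
    letter = None
    if not censored and ladder is not None:
        letter = classify_delay(t_star, ladder)
    return StabilityResult(
        parameter=model.parameter,
        material=model.material,
        phase=model.phase,
        threshold=threshold,
        t_star_h=t_star,
        timeline_letter=letter,
        censored=censored,
    )


def timeline_table(
    store: ModelStore,
    threshold: float = 0.20,
    ladder: SPRECLadder = PRE_LADDER,
    horizon_h: float = DEFAULT_HORIZON_H,
) -> list[StabilityResult]:
    """Stability results for every model in a store, soonest first.

    Finite time points are sorted ascending (ties broken by parameter
    name); censored parameters come last. Each finite result carries
    the SPREC letter of the ladder bin containing its t*.
    """
    if len(store) == 0:
        raise ValueError("empty model store")
    results = [
        stability_time_point(m, threshold=threshold, horizon_h=horizon_h, ladder=ladder)
        for m in store
    ]
    results.sort(
        key=lambda r: (r.censored, r.t_star_h if r.t_star_h is not None else float("inf"), r.parameter)
    )
    return results


def count_within(results: list[StabilityResult], horizon_h: float) -> int:
    """Number of non-censored stability time points with t* ≤ horizon.

    The boundary is inclusive: a parameter whose t* falls exactly on the
    horizon counts as within it.
    """
    return sum(1 for r in results if not r.censored and r.t_star_h <= horizon_h)


def timeline_frame(results: list[StabilityResult]) -> pd.DataFrame:
    """Flatten stability results for delimited-text output."""
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "material": r.material,
                "phase": r.phase,
                "threshold": r.threshold,
                "t_star_h": r.t_star_h,
                "letter": r.timeline_letter,
                "censored": r.censored,
            }
            for r in results
        ]
    )
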