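"""Operating-point (threshold) analysis at three clinical levels.

For each marker three cut-offs are reported: a high-sensitivity point (the
lowest achievable sensitivity at or above a target, by default 90%), the
best balance of sensitivity and specificity (maximum Youden index J =
sens + spec - 1), and a high-specificity point (mirror of the first).
Achieved sensitivities and specificities are exact attainable fractions
m/n_pos and k/n_neg; with 54 cases the smallest sensitivity >= 0.90 is
49/54 = 90.7%, and with 48 cases it is 44/48 = 91.7%.

Reported thresholds are midpoints between adjacent distinct scores (on
the marker's original scale), so the cut-off is reproducible regardless
of strict-vs-weak inequality conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import ROCCurve, roc_curve

__all__ = [
    "OperatingPoint",
    "point_at_sensitivity",
    "point_at_specificity",
    "youden_point",
    "three_level_table",
    "LEVELS",
]

LEVELS = ("high_sensitivity", "balanced", "high_specificity")


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    level: str
    orientation: str  # "higher" | "lower"


def _report_threshold(roc: ROCCurve, i: int) -> float:
    """Midpoint cut-off on the marker's original scale.

    Internal thresholds are on the oriented scale (negated when the
    marker is lower-is-positive); the reported cut-off is the midpoint
    between the selected distinct score and the next higher one, mapped
    back to the original scale.
    """
    thr = roc.thresholds
    if np.isinf(thr[i]):
        # sentinel: place the cut just outside the observed range
        finite = thr[np.isfinite(thr)]
        val = finite.max() + 1.0 if thr[i] > 0 else finite.min() - 1.0
    else:
        # "score >= cut" is unchanged for any cut in (next lower distinct
        # value, thr[i]]; the midpoint of that gap is the reported cut
        nxt = thr[i + 1]
        val = (thr[i] + nxt) / 2.0 if np.isfinite(nxt) else thr[i] - 1.0
    return float(-val) if roc.orientation == "lower" else float(val)


def _make_point(roc: ROCCurve, i: int, level: str) -> OperatingPoint:
    return OperatingPoint(
        threshold=_report_threshold(roc, i),
        sensitivity=float(roc.sensitivity[i]),
        specificity=float(roc.specificity[i]),
        level=level,
        orientation=roc.orientation,
    )


def point_at_sensitivity(roc: ROCCurve, target: float) -> OperatingPoint:
    """Smallest achievable sensitivity >= target; ties favour specificity.

    Sensitivity can only take the values m/n_pos, so the achieved value is
    the least such fraction at or above the target; among thresholds
    achieving it, the one with the highest specificity is returned.
    """
    if not 0 < target <= 1:
        raise ValueError("target must lie in (0, 1]")
    ok = roc.sensitivity >= target - 1e-12
    best_sens = roc.sensitivity[ok].min()
    cand = np.flatnonzero(ok & np.isclose(roc.sensitivity, best_sens))
    i = cand[np.argmax(roc.specificity[cand])]
    return _make_point(roc, int(i), "high_sensitivity")


def point_at_specificity(roc: ROCCurve, target: float) -> OperatingPoint:
    """Smallest achievable specificity >= target; ties favour sensitivity."""
    if not 0 < target <= 1:
        raise ValueError("target must lie in (0, 1]")
    ok = roc.specificity >= target - 1e-12
    best_spec = roc.specificity[ok].min()
    cand = np.flatnonzero(ok & np.isclose(roc.specificity, best_spec))
    i = cand[np.argmax(roc.sensitivity[cand])]
    return _make_point(roc, int(i), "high_specificity")


def youden_point(roc: ROCCurve) -> OperatingPoint:
    """Maximize J = sensitivity + specificity - 1; ties favour sensitivity."""
    j = roc.youden()
    best = j.max()
    cand = np.flatnonzero(np.isclose(j, best))
    i = cand[np.argmax(roc.sensitivity[cand])]
    return _make_point(roc, int(i), "balanced")


def three_level_table(
    markers: dict[str, tuple[np.ndarray, bool]],
    labels: np.ndarray,
    sens_target: float = 0.90,
    spec_target: float = 0.90,
) -> pd.DataFrame:
    """One row per marker x level with threshold and achieved sens/spec.

    ``markers`` maps name -> (scores, lower_is_positive).  Percentages are
    reported to one decimal (half-up).
    """
    rows = []
    for name, (scores, lower) in markers.items():
        roc = roc_curve(scores, labels, lower_is_positive=lower)
        points = {
            "high_sensitivity": point_at_sensitivity(roc, sens_target),
            "balanced": youden_point(roc),
            "high_specificity": point_at_specificity(roc, spec_target),
        }
        for level in LEVELS:
            pt = points[level]
            rows.append(
                {
                    "marker": name,
                    "level": level,
                    "threshold": pt.threshold,
                    "sensitivity_pct": _pct1(pt.sensitivity),
                    "specificity_pct": _pct1(pt.specificity),
                    "orientation": pt.orientation,
                }
            )
    cols = [
        "marker",
        "level",
        "threshold",
        "sensitivity_pct",
        "specificity_pct",
        "orientation",
    ]
    return pd.DataFrame(rows, columns=cols)


def _pct1(fraction: float) -> float:
    """Percent to one decimal with half-up rounding."""
    return float(np.floor(fraction * 1000 + 0.5) / 10)
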