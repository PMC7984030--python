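"""Experiment 2 analysis: changes in relative density during boiling.

Immersed (hydrostatic) weight series are normalised to percent of the
time-0 weight; three curve features summarise the density loss over a
truncated boiling window — the area under the weight-change curve (AUWCC,
as a fraction of the full plot rectangle), the ordinary-least-squares
linear slope (LINEAR, percent/min), and the coefficients of a quadratic
fit (QUADRATIC).  Cooking time is then regressed on each feature, and
genotypes are screened by a slope threshold (default -1.25 %/min at the
30-min window: steeper density loss predicts short cooking time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import pearson

__all__ = [
    "DenCurve",
    "CurveFeatures",
    "normalize_weight_in_water",
    "auwcc",
    "linear_feature",
    "quadratic_feature",
    "ct_feature_regression",
    "classify_by_slope",
    "analyze_density_campaign",
    "SLOPE_THRESHOLD",
    "DEFAULT_WINDOWS",
]

logger = logging.getLogger(__name__)

#: Default screening threshold on the 30-min LINEAR slope (percent/min).
SLOPE_THRESHOLD = -1.25

#: Truncation windows (minutes) over which features are extracted.
DEFAULT_WINDOWS = (20.0, 30.0, 40.0, 50.0, 60.0)

_GRID_TOL = 1e-9


@dataclass
class DenCurve:
    """Normalized weight-in-water curve (percent of the time-0 weight)."""

    genotype_id: str
    times: np.ndarray
    w_pct: np.ndarray
    flagged: bool = False  # True if any point is negative (piece floating)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.w_pct = np.asarray(self.w_pct, dtype=float)
        if self.times.size == 0 or self.times[0] != 0.0:
            raise ValueError("curve must start at t = 0")
        if self.w_pct[0] != 100.0:
            raise ValueError("w_pct[0] must be exactly 100")
        if not np.all(np.isfinite(self.w_pct)):
            raise ValueError("w_pct must be finite")

    def window(self, window_end: float):
        """(t, w) restricted to [0, window_end]; window_end must be a grid
        point (no interpolation off the weighing grid)."""
        if not np.any(np.abs(self.times - window_end) < _GRID_TOL):
            raise ValueError(
                f"window_end={window_end:g} is not on the curve's time grid"
            )
        mask = self.times <= window_end + _GRID_TOL
        return self.times[mask], self.w_pct[mask]


@dataclass(frozen=True)
class CurveFeatures:
    genotype_id: str
    window_end: float
    auwcc: float        # fraction of the 100% x window rectangle
    linear_slope: float  # percent / min
    quad_b1: float       # percent / min
    quad_b2: float       # percent / min^2


def normalize_weight_in_water(
    times, weights_g, genotype_id: str = ""
) -> DenCurve:
    """Express an immersed-weight series as percent of its time-0 value.

    A non-positive initial weight means the sample floats (or the scale
    faulted) and is rejected.  Later non-positive values are kept and the
    curve flagged — fragmenting fast cookers can rise back through zero.
    """
    times = np.asarray(times, dtype=float)
    w = np.asarray(weights_g, dtype=float)
    if times.size == 0 or abs(times[0]) > _GRID_TOL:
        raise ValueError("series must start at t = 0")
    if w[0] <= 0:
        raise ValueError(
            f"{genotype_id or 'sample'}: non-positive initial weight in water "
            f"({w[0]:.2f} g) — root floating or scale fault"
        )
    w_pct = 100.0 * w / w[0]
    w_pct[0] = 100.0
    flagged = bool(np.any(w_pct < 0))
    if flagged:
        logger.warning("%s: negative weight-in-water points kept and flagged",
                       genotype_id or "sample")
    return DenCurve(genotype_id, times, w_pct, flagged=flagged)


def auwcc(curve: DenCurve, window_end: float) -> float:
    """Area under the normalized curve over [0, window_end] by the
    trapezoidal rule, as a fraction of the full 100% x window rectangle.
    A constant-100 curve gives exactly 1."""
    t, w = curve.window(window_end)
    if window_end <= 0:
        raise ValueError("window_end must be positive")
    return float(np.trapezoid(w, t) / (100.0 * window_end))


def linear_feature(curve: DenCurve, window_end: float) -> float:
    """OLS slope (percent/min) of w_pct on time over [0, window_end]."""
    t, w = curve.window(window_end)
    if t.size < 3:
        raise ValueError("need at least 3 grid points in the window")
    slope, _ = np.polyfit(t, w, 1)
    return float(slope)


def quadratic_feature(curve: DenCurve, window_end: float):
    """OLS fit w_pct = b0 + b1 t + b2 t^2 over [0, window_end]; returns
    (b1, b2).  The screening feature is b1, the coefficient on time."""
    t, w = curve.window(window_end)
    if t.size < 4:
        raise ValueError("need at least 4 grid points in the window")
    if np.unique(t).size < 4:
        raise ValueError("rank-deficient design: need >= 4 distinct times")
    b2, b1, _ = np.polyfit(t, w, 2)
    return float(b1), float(b2)


def extract_features(curve: DenCurve, window_end: float) -> CurveFeatures:
    b1, b2 = quadratic_feature(curve, window_end)
    return CurveFeatures(
        genotype_id=curve.genotype_id,
        window_end=window_end,
        auwcc=auwcc(curve, window_end),
        linear_slope=linear_feature(curve, window_end),
        quad_b1=b1,
        quad_b2=b2,
    )


def ct_feature_regression(
    features: pd.DataFrame,
    cts: Mapping,
    windows: Sequence[float] = DEFAULT_WINDOWS,
) -> dict:
    """r-squared of the CT-on-feature simple regressions per window.

    ``features`` is tidy with columns genotype, window_end, auwcc,
    linear_slope, quad_b1.  r^2 is the squared Pearson correlation of CT
    with the feature (identical to simple-OLS r^2).  Cells with fewer than
    3 genotypes or degenerate variance are undefined (NaN).  Returns the
    grid and the argmax cell.
    """
    feature_cols = {"AUWCC": "auwcc", "LINEAR": "linear_slope",
                    "QUADRATIC": "quad_b1"}
    rows = []
    for w in windows:
        sub = features[np.abs(features["window_end"] - w) < 1e-9]
        row = {"window": w}
        for name, col in feature_cols.items():
            pairs = [
                (cts[g], v)
                for g, v in zip(sub["genotype"], sub[col])
                if g in cts and np.isfinite(v) and np.isfinite(cts[g])
            ]
            if len(pairs) < 3:
                row[name] = np.nan
                continue
            x = np.array([p[0] for p in pairs])
            y = np.array([p[1] for p in pairs])
            entry = pearson(x, y, "CT", name)
            row[name] = entry.r ** 2 if np.isfinite(entry.r) else np.nan
        rows.append(row)
    grid = pd.DataFrame(rows).set_index("window")
    if grid.notna().to_numpy().any():
        stacked = grid.stack()
        best = stacked.idxmax()
        argmax = {"window": float(best[0]), "feature": best[1],
                  "r2": float(stacked.max())}
    else:
        argmax = {"window": np.nan, "feature": None, "r2": np.nan}
    return {"grid": grid, "argmax": argmax}


def classify_by_slope(slope: float, threshold: float = SLOPE_THRESHOLD) -> str:
    """Screen a genotype by its density-loss slope.

    Slopes at or below the threshold (faster density loss) predict a short
    cooking time; the boundary is assigned to predicted_short, favouring
    false positives over rejecting good cookers in pre-selection.
    """
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    return "predicted_short" if slope <= threshold else "predicted_long"


def analyze_density_campaign(
    density: pd.DataFrame,
    cts: Optional[Mapping] = None,
    windows: Sequence[float] = DEFAULT_WINDOWS,
    threshold: float = SLOPE_THRESHOLD,
    classify_window: float = 30.0,
) -> dict:
    """Full Experiment-2 pipeline on a tidy immersed-weight table.

    ``density`` has columns genotype, t_min, weight_in_water_g.  Returns
    normalized curves, the per-genotype feature table, the r^2 grid (when
    CTs are supplied) and the per-genotype classification table at
    ``classify_window``.
    """
    curves = []
    for g, sub in density.groupby("genotype"):
        sub = sub.sort_values("t_min")
        curves.append(
            normalize_weight_in_water(
                sub["t_min"].to_numpy(), sub["weight_in_water_g"].to_numpy(), g
            )
        )
    feat_rows = []
    for c in curves:
        for w in windows:
            f = extract_features(c, w)
            feat_rows.append(
                (f.genotype_id, f.window_end, f.auwcc, f.linear_slope,
                 f.quad_b1, f.quad_b2)
            )
    features = pd.DataFrame(
        feat_rows,
        columns=["genotype", "window_end", "auwcc", "linear_slope",
                 "quad_b1", "quad_b2"],
    )

    cls = features[np.abs(features["window_end"] - classify_window) < 1e-9]
    class_rows = []
    for g, slope in zip(cls["genotype"], cls["linear_slope"]):
        class_rows.append(
            {
                "genotype": g,
                "linear_slope": slope,
                "ct": cts.get(g, np.nan) if cts else np.nan,
                "predicted": classify_by_slope(slope, threshold),
            }
        )
    classification = pd.DataFrame(class_rows)

    regression = ct_feature_regression(features, cts, windows) if cts else None
    return {
        "curves": curves,
        "features": features,
        "regression": regression,
        "classification": classification,
        "threshold": threshold,
        "classify_window": classify_window,
    }
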