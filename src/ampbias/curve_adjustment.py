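"""Curve Adjustment (CA): positional reweighting of PM intensities.

A deliberately simple comparator to the model-based correction: smooth the
mean PM intensity as a function of probe position (lowess), normalize the
smoothed curve to unit mean over the window, and multiply every probe's PM
by the reciprocal of the normalized value at its position.  CA flattens the
positional trend of the *mean* profile by construction, but unlike the
model-based correction it carries no per-probe-set notion of ideal
intensity, so it does not reduce within-set dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["PositionWeightTable", "compute_position_weights", "apply_ca"]

DEFAULT_WINDOW = (12.0, 588.0)
_WEIGHT_EPS = 1e-6


@dataclass
class PositionWeightTable:
    """Per-position multiplicative weights derived from the mean PM profile."""

    z: np.ndarray
    mean_pm: np.ndarray
    smoothed: np.ndarray
    normalized: np.ndarray
    weight: np.ndarray
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if abs(float(np.mean(self.normalized)) - 1.0) > 1e-9:
            raise ValueError("normalized smoothed profile must have unit mean")
        if np.any(self.weight <= 0):
            raise ValueError("weights must be strictly positive")

    def lookup(self, z) -> np.ndarray:
        """Weight at the nearest tabulated position."""
        idx = np.searchsorted(self.z, np.asarray(z, dtype=float))
        idx = np.clip(idx, 1, len(self.z) - 1)
        left = self.z[idx - 1]
        right = self.z[idx]
        idx -= np.asarray(z) - left < right - np.asarray(z)
        return self.weight[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z": self.z,
                "mean_pm": self.mean_pm,
                "smoothed": self.smoothed,
                "normalized": self.normalized,
                "weight": self.weight,
            }
        )


def compute_position_weights(
    df: pd.DataFrame,
    window: tuple[float, float] = DEFAULT_WINDOW,
    lowess_fraction: float = 0.3,
    present_only: bool = True,
) -> PositionWeightTable:
    """Mean PM per position -> lowess smooth -> unit-mean normalize -> invert.

    Positions are rounded to integer bp before averaging; probes are pooled
    across all samples in ``df``.  Smoothed values are floored at a tiny
    positive value so the reciprocal stays finite.
    """
    sub = df
    if present_only and "present" in df.columns:
        sub = df[df["present"] == 1]
    pos = sub["z"].round().astype(int)
    mask = (pos >= window[0]) & (pos <= window[1])
    if not mask.any():
        raise ValueError(f"no probes inside the position window {window}")
    prof = sub.loc[mask, "pm"].groupby(pos[mask]).mean().sort_index()
    z = prof.index.to_numpy(dtype=float)
    mean_pm = prof.to_numpy(dtype=float)
    smoothed = sm.nonparametric.lowess(
        mean_pm, z, frac=lowess_fraction, return_sorted=False
    )
    smoothed = np.maximum(smoothed, _WEIGHT_EPS * max(mean_pm.mean(), 1.0))
    normalized = smoothed / smoothed.mean()
    return PositionWeightTable(
        z=z,
        mean_pm=mean_pm,
        smoothed=smoothed,
        normalized=normalized,
        weight=1.0 / normalized,
        window=window,
    )


def apply_ca(df: pd.DataFrame, weights: PositionWeightTable) -> pd.DataFrame:
    """Multiply each probe's PM by the weight at its (nearest) position.

    Probes outside the weight window pass through unweighted and are flagged
    in the ``ca_flag`` column.  Output adds ``pm_ca`` (and ``mm_ca`` when MM
    is present); input columns are untouched.
    """
    out = df.copy()
    z = out["z"].to_numpy(dtype=float)
    inside = (z >= weights.window[0]) & (z <= weights.window[1])
    w = np.ones(len(out))
    w[inside] = weights.lookup(z[inside])
    out["pm_ca"] = out["pm"].to_numpy() * w
    if "mm" in out.columns:
        out["mm_ca"] = out["mm"].to_numpy() * w
    out["ca_flag"] = np.where(inside, "", "outside_window")
    return out
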