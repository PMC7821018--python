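"""Angle-wise pooling of voxel metrics into fiber-orientation curves.

Voxels from across the whole white matter are pooled into 18 intervals
of 5 degrees between 0 (parallel to B0) and 90 (perpendicular), which
suppresses tract-specific differences and yields curves such as apparent
MWF as a function of fiber angle.  Group curves across subjects carry a
t-distribution 95% confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AngleBins", "AngleCurve", "bin_angles", "pooled_curve", "group_curve"]


@dataclass(frozen=True)
class AngleBins:
    """Uniform angle bins over [0, 90] degrees; half-open except the last.

    With the defaults: [0,5), [5,10), ..., [85,90]; theta = 90 falls in
    the last bin.
    """

    width_deg: float = 5.0
    max_deg: float = 90.0

    def __post_init__(self) -> None:
        n = self.max_deg / self.width_deg
        if self.width_deg <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("bin width must evenly divide the angle range")

    @property
    def n_bins(self) -> int:
        return int(round(self.max_deg / self.width_deg))

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, self.max_deg, self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.edges[:-1] + self.width_deg / 2.0


@dataclass
class AngleCurve:
    """A per-bin statistic with voxel counts and optional CI band."""

    bin_centers_deg: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None
    label: str = ""

    @property
    def missing(self) -> np.ndarray:
        return self.counts == 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bin_center_deg": self.bin_centers_deg,
                "value": self.values,
                "count": self.counts,
            }
        )
        if self.ci_lo is not None:
            df["ci_lo"] = self.ci_lo
            df["ci_hi"] = self.ci_hi
        return df


def bin_angles(theta_deg: np.ndarray, bins: AngleBins | None = None) -> np.ndarray:
    """Bin index per angle; NaN angles map to -1 (unassigned).

    Raises if any finite angle lies outside [0, 90].
    """
    bins = bins or AngleBins()
    theta = np.asarray(theta_deg, dtype=float)
    finite = np.isfinite(theta)
    if np.any((theta[finite] < 0) | (theta[finite] > bins.max_deg)):
        raise ValueError(f"angles must lie in [0, {bins.max_deg}] degrees")
    idx = np.full(theta.shape, -1, dtype=int)
    idx[finite] = np.minimum(
        (theta[finite] / bins.width_deg).astype(int), bins.n_bins - 1
    )
    return idx


def pooled_curve(
    metric: np.ndarray,
    theta_deg: np.ndarray,
    mask: np.ndarray | None = None,
    bins: AngleBins | None = None,
    label: str = "",
) -> AngleCurve:
    """Per-bin arithmetic mean of ``metric`` over masked voxels.

    Voxels with NaN metric or undefined angle are dropped; empty bins are
    NaN-valued with count 0.
    """
    bins = bins or AngleBins()
    metric = np.asarray(metric, dtype=float).ravel()
    theta = np.asarray(theta_deg, dtype=float).ravel()
    if metric.shape != theta.shape:
        raise ValueError("metric and theta maps must share a grid")
    if mask is not None:
        sel = np.asarray(mask).astype(bool).ravel()
        if sel.shape != metric.shape:
            raise ValueError("mask must share the metric grid")
        if not sel.any():
            raise ValueError("empty mask: nothing to pool")
        metric, theta = metric[sel], theta[sel]
    keep = np.isfinite(metric) & np.isfinite(theta)
    metric, theta = metric[keep], theta[keep]

    idx = bin_angles(theta, bins)
    counts = np.bincount(idx, minlength=bins.n_bins)
    sums = np.bincount(idx, weights=metric, minlength=bins.n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    return AngleCurve(bins.centers.copy(), means, counts, label=label)


def group_curve(curves: list[AngleCurve], confidence: float = 0.95, label: str = "") -> AngleCurve:
    """Across-subject mean curve with a t-distribution confidence band.

    Bins missing in a subject are ignored for that subject.  With a
    single subject the band is undefined (NaN).
    """
    if not curves:
        raise ValueError("need at least one subject curve")
    centers = curves[0].bin_centers_deg
    for c in curves[1:]:
        if not np.allclose(c.bin_centers_deg, centers):
            raise ValueError("subject curves must share bins")
    vals = np.vstack([c.values for c in curves])  # (n_subj, n_bins)
    n = np.sum(np.isfinite(vals), axis=0)
    mean = np.full(vals.shape[1], np.nan)
    has = n > 0
    if has.any():
        mean[has] = np.nanmean(vals[:, has], axis=0)
    ci_lo = np.full_like(mean, np.nan)
    ci_hi = np.full_like(mean, np.nan)
    have_ci = n >= 2
    if np.any(have_ci):
        sd = np.full(vals.shape[1], np.nan)
        sd[have_ci] = np.nanstd(vals[:, have_ci], axis=0, ddof=1)
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=np.maximum(n - 1, 1))
        with np.errstate(invalid="ignore"):
            half = tcrit * sd / np.sqrt(np.maximum(n, 1))
        ci_lo = np.where(have_ci, mean - half, np.nan)
        ci_hi = np.where(have_ci, mean + half, np.nan)
    counts = np.sum(np.vstack([c.counts for c in curves]), axis=0)
    return AngleCurve(centers.copy(), mean, counts, ci_lo=ci_lo, ci_hi=ci_hi, label=label)
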