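"""Pool partitioning of T2 spectra: apparent MWF and per-pool T2 statistics.

The T2 spectrum of white matter separates into a short-T2 myelin-water
pool and a longer intra/extracellular-water pool.  Following the 25 ms
boundary convention, the apparent myelin water fraction is the spectrum
mass at T2 <= cutoff divided by the total mass (CSF-range amplitudes
included in the denominator).  Per-pool T2 is summarized by the
amplitude-weighted geometric mean, the usual statistic of multi-echo
relaxometry; R2 values are reported as 1000/T2[ms] in 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nnls import T2Spectrum

__all__ = [
    "PoolSummary",
    "apparent_mwf",
    "pool_geometric_mean_t2",
    "cumulative_spectrum",
    "summarize_pools",
    "mwf_from_amplitudes",
    "pool_gm_t2_from_amplitudes",
]

DEFAULT_CUTOFF_MS = 25.0
DEFAULT_CSF_CUTOFF_MS = 1000.0


@dataclass(frozen=True)
class PoolSummary:
    """Per-voxel (or per-bin) pool metrics.

    ``gm_t2_*`` are amplitude-weighted geometric means in ms (NaN for an
    empty pool); ``r2_*`` their reciprocals in 1/s.  Amplitudes above the
    CSF cutoff count in the MWF denominator but are excluded from the
    intra/extracellular geometric mean.
    """

    mwf: float
    gm_t2_mw_ms: float
    gm_t2_ie_ms: float
    cutoff_ms: float = DEFAULT_CUTOFF_MS
    csf_cutoff_ms: float = DEFAULT_CSF_CUTOFF_MS

    @property
    def r2_mw_per_s(self) -> float:
        return 1000.0 / self.gm_t2_mw_ms

    @property
    def r2_ie_per_s(self) -> float:
        return 1000.0 / self.gm_t2_ie_ms


def _check(t2: np.ndarray, amp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t2 = np.asarray(t2, dtype=float)
    amp = np.asarray(amp, dtype=float)
    if t2.shape != amp.shape or t2.ndim != 1:
        raise ValueError("grid and amplitudes must be 1-D arrays of equal length")
    if np.any(amp < 0):
        raise ValueError("spectrum amplitudes must be nonnegative")
    return t2, amp


def mwf_from_amplitudes(
    amplitudes: np.ndarray, t2_ms: np.ndarray, cutoff_ms: float = DEFAULT_CUTOFF_MS
) -> np.ndarray:
    """Apparent MWF for amplitude arrays of shape (..., n_t2) (vectorized)."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    t2_ms = np.asarray(t2_ms, dtype=float)
    total = amplitudes.sum(axis=-1)
    mw = amplitudes[..., t2_ms <= cutoff_ms].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, mw / np.where(total > 0, total, 1.0), np.nan)


def apparent_mwf(spec: T2Spectrum, cutoff_ms: float = DEFAULT_CUTOFF_MS) -> float:
    """Spectrum mass at T2 <= cutoff over total mass (CSF included in total)."""
    t2, amp = _check(spec.grid.t2_ms, spec.amplitudes)
    total = amp.sum()
    if total <= 0:
        raise ValueError("zero total spectrum amplitude: MWF undefined")
    return float(amp[t2 <= cutoff_ms].sum() / total)


def pool_gm_t2_from_amplitudes(
    amplitudes: np.ndarray,
    t2_ms: np.ndarray,
    cutoff_ms: float = DEFAULT_CUTOFF_MS,
    csf_cutoff_ms: float | None = DEFAULT_CSF_CUTOFF_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pool geometric-mean T2 for (..., n_t2) amplitude arrays.

    Returns (gm_t2_mw, gm_t2_ie) in ms with NaN where a pool is empty.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    t2_ms = np.asarray(t2_ms, dtype=float)
    log_t2 = np.log(t2_ms)
    mw_sel = t2_ms <= cutoff_ms
    ie_sel = t2_ms > cutoff_ms
    if csf_cutoff_ms is not None:
        ie_sel &= t2_ms <= csf_cutoff_ms

    def gm(sel: np.ndarray) -> np.ndarray:
        w = amplitudes[..., sel]
        tot = w.sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            val = np.exp((w * log_t2[sel]).sum(axis=-1) / np.where(tot > 0, tot, 1.0))
        return np.where(tot > 0, val, np.nan)

    return gm(mw_sel), gm(ie_sel)


def pool_geometric_mean_t2(
    spec: T2Spectrum,
    cutoff_ms: float = DEFAULT_CUTOFF_MS,
    csf_cutoff_ms: float | None = DEFAULT_CSF_CUTOFF_MS,
) -> tuple[float, float]:
    """Amplitude-weighted geometric-mean T2 of each pool (ms; NaN if empty)."""
    t2, amp = _check(spec.grid.t2_ms, spec.amplitudes)
    gm_mw, gm_ie = pool_gm_t2_from_amplitudes(amp, t2, cutoff_ms, csf_cutoff_ms)
    if np.isnan(gm_mw) and np.isnan(gm_ie):
        raise ValueError("both pools empty: pool T2 undefined")
    return float(gm_mw), float(gm_ie)


def cumulative_spectrum(spec: T2Spectrum) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cumulative spectrum: (t2_ms, cumulative fraction).

    The curve is non-decreasing and reaches exactly 1 at the last grid
    point; evaluated at the pool cutoff it equals the apparent MWF.
    """
    t2, amp = _check(spec.grid.t2_ms, spec.amplitudes)
    total = amp.sum()
    if total <= 0:
        raise ValueError("zero total spectrum amplitude")
    cum = np.cumsum(amp) / total
    cum[-1] = 1.0  # guard against round-off
    return t2, cum


def summarize_pools(
    spec: T2Spectrum,
    cutoff_ms: float = DEFAULT_CUTOFF_MS,
    csf_cutoff_ms: float | None = DEFAULT_CSF_CUTOFF_MS,
) -> PoolSummary:
    gm_mw, gm_ie = pool_geometric_mean_t2(spec, cutoff_ms, csf_cutoff_ms)
    return PoolSummary(
        mwf=apparent_mwf(spec, cutoff_ms),
        gm_t2_mw_ms=gm_mw,
        gm_t2_ie_ms=gm_ie,
        cutoff_ms=cutoff_ms,
        csf_cutoff_ms=csf_cutoff_ms if csf_cutoff_ms is not None else np.inf,
    )
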