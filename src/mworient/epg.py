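"""Extended phase graph (EPG) simulation of CPMG echo trains.

Multi-echo spin-echo sequences acquired with imperfect (< 180 deg)
refocusing pulses generate stimulated-echo pathways that mix T1 into the
echo decay and raise late echoes above the pure ``exp(-t/T2)`` envelope.
The EPG algorithm tracks the configuration states of the magnetization
through the pulse train and computes the resulting echo amplitudes
exactly (for ideal hard pulses and crusher-ideal gradients).  These
amplitudes serve both as the decay basis for stimulated-echo-corrected
T2 spectrum inversion and as the forward model of the synthetic phantom.

Conventions: excitation is a 90 deg pulse applied in quadrature with the
refocusing pulses (CPMG condition); relaxation acts over each TE/2
interval; longitudinal recovery within the train is neglected (TE << T1);
returned amplitudes are magnitudes for unit initial magnetization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SequenceParams",
    "RelaxParams",
    "epg_echo_amplitudes",
    "epg_echo_amplitudes_multi",
]


@dataclass(frozen=True)
class SequenceParams:
    """Multi-echo spin-echo (CPMG) acquisition parameters.

    Parameters
    ----------
    n_echoes : int
        Number of recorded echoes.
    te_ms : float
        Echo spacing in ms; the first echo occurs at ``te_ms``.
    tr_ms : float
        Repetition time in ms.  Not used inside the echo train, but
        carried along because it controls the T1 weighting of the pools.
    excitation_deg : float
        Excitation flip angle in degrees (90 for a standard acquisition).
    refocus_deg : float
        Nominal refocusing flip angle in degrees.  The effective angle in
        tissue is often lower due to B1 inhomogeneity; 0 is allowed as a
        degenerate value and yields zero signal.
    """

    n_echoes: int = 48
    te_ms: float = 8.0
    tr_ms: float = 1073.0
    excitation_deg: float = 90.0
    refocus_deg: float = 180.0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_echoes, (int, np.integer)) and self.n_echoes >= 1):
            raise ValueError(f"n_echoes must be a positive integer, got {self.n_echoes}")
        if not (np.isfinite(self.te_ms) and self.te_ms > 0):
            raise ValueError(f"te_ms must be positive and finite, got {self.te_ms}")
        if not (np.isfinite(self.tr_ms) and self.tr_ms > self.n_echoes * self.te_ms):
            raise ValueError(
                f"tr_ms ({self.tr_ms}) must exceed the last echo time "
                f"({self.n_echoes * self.te_ms} ms)"
            )
        if not (np.isfinite(self.refocus_deg) and 0.0 <= self.refocus_deg <= 180.0):
            raise ValueError(f"refocus_deg must lie in [0, 180], got {self.refocus_deg}")
        if not (np.isfinite(self.excitation_deg) and 0.0 < self.excitation_deg <= 90.0):
            raise ValueError(f"excitation_deg must lie in (0, 90], got {self.excitation_deg}")

    @property
    def echo_times_ms(self) -> np.ndarray:
        """Echo times ``te, 2*te, ..., n*te`` in ms."""
        return self.te_ms * np.arange(1, self.n_echoes + 1)


@dataclass(frozen=True)
class RelaxParams:
    """Single-pool relaxation times in ms (requires ``t1_ms >= t2_ms``)."""

    t2_ms: float
    t1_ms: float = 1000.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t2_ms) and self.t2_ms > 0):
            raise ValueError(f"t2_ms must be positive and finite, got {self.t2_ms}")
        if not (np.isfinite(self.t1_ms) and self.t1_ms >= self.t2_ms):
            raise ValueError(f"t1_ms must be finite and >= t2_ms, got {self.t1_ms}")


def epg_echo_amplitudes_multi(
    seq: SequenceParams,
    t2_ms: np.ndarray,
    t1_ms: float = 1000.0,
    alpha_deg: float | None = None,
) -> np.ndarray:
    """EPG echo amplitudes for several T2 values at once.

    Parameters
    ----------
    seq : SequenceParams
        Sequence timing and flip angles.  ``alpha_deg`` overrides
        ``seq.refocus_deg`` when given (used by the flip-angle search).
    t2_ms : array-like, shape (m,)
        Transverse relaxation times in ms.
    t1_ms : float
        Longitudinal relaxation time in ms shared by all columns.

    Returns
    -------
    ndarray, shape (n_echoes, m)
        Nonnegative echo magnitudes for unit initial magnetization;
        column ``j`` is the decay curve for ``t2_ms[j]``.
    """
    t2 = np.atleast_1d(np.asarray(t2_ms, dtype=float))
    if t2.ndim != 1 or t2.size == 0:
        raise ValueError("t2_ms must be a non-empty 1-D array")
    if not np.all(np.isfinite(t2) & (t2 > 0)):
        raise ValueError("all t2_ms values must be positive and finite")
    if not (np.isfinite(t1_ms) and t1_ms > 0):
        raise ValueError(f"t1_ms must be positive and finite, got {t1_ms}")
    alpha = seq.refocus_deg if alpha_deg is None else float(alpha_deg)
    if not (np.isfinite(alpha) and 0.0 <= alpha <= 180.0):
        raise ValueError(f"refocusing angle must lie in [0, 180], got {alpha}")

    n = seq.n_echoes
    m = t2.size
    half = seq.te_ms / 2.0
    e2 = np.exp(-half / t2)  # per-half-interval transverse decay, shape (m,)
    e1 = np.exp(-half / t1_ms)

    # Configuration orders -K..K for transverse states, 0..K longitudinal.
    # Orders beyond n_echoes+1 cannot rephase before the last recorded echo.
    K = n + 1
    F = np.zeros((2 * K + 1, m), dtype=complex)  # F[K + k] = F(k)
    Z = np.zeros((K + 1, m), dtype=complex)

    # Ideal excitation about y (quadrature with refocusing pulses about x):
    # thermal Z0 = 1 tips to F(0) = sin(exc), Z(0) = cos(exc).
    exc = np.deg2rad(seq.excitation_deg)
    F[K] = np.sin(exc)
    Z[0] = np.cos(exc)

    a = np.deg2rad(alpha)
    c2, s2, sa, ca = np.cos(a / 2) ** 2, np.sin(a / 2) ** 2, np.sin(a), np.cos(a)

    echoes = np.empty((n, m))
    for i in range(n):
        # TE/2 relaxation, then dephasing shift F(k) -> F(k+1)
        F *= e2
        Z *= e1
        F[1:] = F[:-1]
        F[0] = 0.0

        # Refocusing pulse about x (phase 0):
        #   F'(k) = cos^2(a/2) F(k) + sin^2(a/2) conj(F(-k)) - i sin(a) Z(k)
        #   Z'(k) = -(i/2) sin(a) [F(k) - conj(F(-k))] + cos(a) Z(k)
        # with Z(-k) = conj(Z(k)).
        Frev = np.conj(F[::-1])
        Zfull = np.concatenate([np.conj(Z[K:0:-1]), Z], axis=0)
        Fnew = c2 * F + s2 * Frev - 1j * sa * Zfull
        Znew = -0.5j * sa * (F[K:] - Frev[K:]) + ca * Z
        F, Z = Fnew, Znew

        # second TE/2 relaxation and shift; echo forms at order 0
        F *= e2
        Z *= e1
        F[1:] = F[:-1]
        F[0] = 0.0
        echoes[i] = np.abs(F[K])

    return echoes


def epg_echo_amplitudes(seq: SequenceParams, relax: RelaxParams) -> np.ndarray:
    """Echo-train magnitudes for one pool (unit initial magnetization).

    With a perfect 180 deg refocusing train this reduces to the
    mono-exponential ``exp(-t/T2)``; at lower flip angles stimulated-echo
    pathways redistribute signal towards later echoes.

    Returns
    -------
    ndarray, shape (n_echoes,)
        Values in [0, 1], decaying to 0 with echo index.
    """
    return epg_echo_amplitudes_multi(seq, np.array([relax.t2_ms]), relax.t1_ms)[:, 0]
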