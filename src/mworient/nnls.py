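"""Regularized-NNLS T2 spectrum inversion with stimulated-echo correction.

A multi-echo decay is modeled as a nonnegative mixture of EPG decay
curves over a log-spaced T2 grid (8 ms to 2 s by default).  The
effective refocusing flip angle alpha is estimated per voxel by
minimizing the unregularized NNLS misfit, which corrects for the
stimulated echoes produced by imperfect refocusing pulses.  The spectrum
is then stabilized with minimum-energy Tikhonov regularization, with the
penalty weight chosen so the regularized misfit equals a fixed multiple
of the minimal misfit (chi-square targeting).  The default target of
1.005 keeps the myelin water fraction effectively unbiased at realistic
SNR; the stronger 1.02 inflation used by several relaxometry packages is
available via ``reg_factor`` and trades a smoother spectrum for a small
negative MWF bias (the smoothed myelin peak leaks across the pool
cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls as _nnls
from scipy.special import i0e, i1e

from .epg import SequenceParams, epg_echo_amplitudes_multi

__all__ = [
    "T2Grid",
    "T2Spectrum",
    "build_basis",
    "fit_spectrum",
    "T2SpectrumNNLS",
]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class T2Grid:
    """Strictly increasing log-spaced T2 grid (ms)."""

    t2_ms: np.ndarray

    def __post_init__(self) -> None:
        t2 = np.asarray(self.t2_ms, dtype=float)
        if t2.ndim != 1 or t2.size < 2:
            raise ValueError("T2 grid needs at least two points")
        if not np.all(np.diff(t2) > 0) or not np.all(t2 > 0):
            raise ValueError("T2 grid must be positive and strictly increasing")
        object.__setattr__(self, "t2_ms", t2)

    @classmethod
    def log_spaced(cls, t2_min_ms: float = 8.0, t2_max_ms: float = 2000.0, n_points: int = 40) -> "T2Grid":
        return cls(np.geomspace(t2_min_ms, t2_max_ms, n_points))

    @property
    def n_points(self) -> int:
        return self.t2_ms.size


@dataclass
class T2Spectrum:
    """Result of one voxel's spectrum inversion.

    ``amplitudes`` are nonnegative weights over ``grid``;
    ``chosen_alpha_deg`` is the estimated effective refocusing angle;
    ``residual_norm`` is the regularized data misfit ||A x - y||;
    ``mu`` the Tikhonov weight that achieved the chi-square target.
    """

    grid: T2Grid
    amplitudes: np.ndarray
    chosen_alpha_deg: float
    residual_norm: float
    mu: float = 0.0
    noise_sigma: float = 0.0

    @property
    def total(self) -> float:
        return float(self.amplitudes.sum())


def build_basis(
    seq: SequenceParams,
    grid: T2Grid,
    alpha_deg: float,
    t1_ms: float = 1000.0,
) -> np.ndarray:
    """EPG decay basis: column ``j`` is the echo train for ``grid.t2_ms[j]``.

    T1 inside the train defaults to 1000 ms; at TE << T1 the inversion is
    insensitive to the exact value.
    """
    return epg_echo_amplitudes_multi(seq, grid.t2_ms, t1_ms=t1_ms, alpha_deg=alpha_deg)


def _chi2_nnls(basis: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    x, rnorm = _nnls(basis, y)
    return x, rnorm * rnorm


def _rician_mean(s: np.ndarray, sigma: float) -> np.ndarray:
    """Expected Rician magnitude E[m | s, sigma] (exact, via Bessel I0/I1)."""
    t = s * s / (4.0 * sigma * sigma)
    return sigma * np.sqrt(np.pi / 2.0) * ((1.0 + 2.0 * t) * i0e(t) + 2.0 * t * i1e(t))


def _regularized_nnls(
    basis: np.ndarray,
    y: np.ndarray,
    chi2_min: float,
    target_factor: float,
    rtol: float = 5e-3,
    max_iter: int = 60,
) -> tuple[np.ndarray, float, float]:
    """Minimum-energy Tikhonov NNLS hitting chi2 = target_factor * chi2_min.

    Solves ``min ||A x - y||^2 + mu ||x||^2, x >= 0`` via the augmented
    system and bisects log(mu) until the data misfit reaches the target
    within ``rtol``.  Returns (amplitudes, chi2, mu).
    """
    n_echoes, n_t2 = basis.shape
    target = target_factor * chi2_min
    if chi2_min <= 1e-12 * float(y @ y):
        # (near-)perfect fit: any mu > 0 overshoots a zero target
        x, chi2 = _chi2_nnls(basis, y)
        return x, chi2, 0.0

    aug = np.zeros((n_echoes + n_t2, n_t2))
    aug[:n_echoes] = basis
    y_aug = np.concatenate([y, np.zeros(n_t2)])
    diag = np.arange(n_t2)

    def chi2_of(mu: float) -> tuple[np.ndarray, float]:
        aug[n_echoes + diag, diag] = np.sqrt(mu)
        x, _ = _nnls(aug, y_aug)
        r = basis @ x - y
        return x, float(r @ r)

    # bracket: chi2(mu) is nondecreasing in mu
    scale = float(np.trace(basis.T @ basis)) / n_t2
    lo, hi = 1e-8 * scale, 1e2 * scale
    x_hi, chi2_hi = chi2_of(hi)
    while chi2_hi < target and hi < 1e12 * scale:
        hi *= 10.0
        x_hi, chi2_hi = chi2_of(hi)
    x_lo, chi2_lo = chi2_of(lo)
    while chi2_lo > target and lo > 1e-16 * scale:
        lo /= 10.0
        x_lo, chi2_lo = chi2_of(lo)

    best_x, best_chi2, best_mu = x_hi, chi2_hi, hi
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        x_mid, chi2_mid = chi2_of(mid)
        if chi2_mid >= target:
            # prefer the larger mu among admissible solutions (smoother)
            best_x, best_chi2, best_mu = x_mid, chi2_mid, mid
            hi = mid
        else:
            lo = mid
        if abs(chi2_mid / target - 1.0) < rtol:
            return x_mid, chi2_mid, mid
    return best_x, best_chi2, best_mu


def _golden_section_alpha(
    objective, lo: float, hi: float, tol: float
) -> tuple[float, float]:
    """Golden-section minimization of a unimodal objective on [lo, hi]."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = objective(c), objective(d)
    while (b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = objective(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = objective(d)
    return (c, fc) if fc <= fd else (d, fd)


def _parabolic_refine(alphas: np.ndarray, chi2s: np.ndarray) -> float:
    """Vertex of the parabola through the grid minimum and its neighbors."""
    i = int(np.argmin(chi2s))
    if i == 0 or i == alphas.size - 1:
        return float(alphas[i])
    x0, x1, x2 = alphas[i - 1 : i + 2]
    f0, f1, f2 = chi2s[i - 1 : i + 2]
    denom = (x0 - x1) * (f1 - f2) - (x2 - x1) * (f1 - f0)
    if denom == 0:
        return float(alphas[i])
    vertex = x1 + 0.5 * (
        (x0 - x1) ** 2 * (f1 - f2) - (x2 - x1) ** 2 * (f1 - f0)
    ) / denom
    return float(np.clip(vertex, alphas[i - 1], alphas[i + 1]))


class T2SpectrumNNLS:
    """T2 spectrum inversion for a stack of echo trains (sklearn style).

    Transforms arrays of shape ``(n_voxels, n_echoes)`` into nonnegative
    T2 spectra of shape ``(n_voxels, n_t2)``, estimating the effective
    refocusing flip angle per voxel.

    Parameters
    ----------
    te_ms : float
        Echo spacing in ms.
    tr_ms : float
        Repetition time carried into ``SequenceParams`` (train-internal
        physics does not depend on it).
    t2_min_ms, t2_max_ms, n_t2 : grid of T2 values (log-spaced).
    reg_factor : float
        Chi-square inflation target of the Tikhonov regularization.
    alpha_bounds_deg : (float, float)
        Search interval for the effective refocusing angle.
    alpha_search : {"grid", "golden"}
        "grid" evaluates the misfit on a fixed angle grid whose EPG bases
        are precomputed once and shared across voxels, then refines the
        minimum parabolically; "golden" runs a per-voxel golden-section
        search (slower: every probe rebuilds a basis).
    alpha_grid_deg : float
        Spacing of the fixed angle grid.
    alpha_tol_deg : float
        Convergence tolerance of the golden-section search.
    t1_ms : float
        T1 assumed when generating the basis.
    rician_correction : bool
        If True, subtract the Rician noise floor in the second-moment
        sense before the final solve: ``s = sqrt(max(m^2 - 2 sigma^2, 0))``
        with ``sigma^2`` estimated from the minimal misfit.  Useful when
        late echoes decay below the noise floor of magnitude images.

    Attributes (after :meth:`fit`)
    ------------------------------
    grid_ : T2Grid
    amplitudes_ : ndarray (n_voxels, n_t2)
    alpha_deg_ : ndarray (n_voxels,)
    residual_norm_ : ndarray (n_voxels,)
    mu_ : ndarray (n_voxels,)
    """

    def __init__(
        self,
        te_ms: float = 8.0,
        tr_ms: float = 1073.0,
        n_echoes: int | None = None,
        t2_min_ms: float = 8.0,
        t2_max_ms: float = 2000.0,
        n_t2: int = 40,
        reg_factor: float = 1.005,
        alpha_bounds_deg: tuple[float, float] = (90.0, 180.0),
        alpha_search: str = "grid",
        alpha_grid_deg: float = 3.0,
        alpha_tol_deg: float = 0.5,
        t1_ms: float = 1000.0,
        rician_correction: bool = False,
        noise_sigma: float | None = None,
    ) -> None:
        self.te_ms = te_ms
        self.tr_ms = tr_ms
        self.n_echoes = n_echoes
        self.t2_min_ms = t2_min_ms
        self.t2_max_ms = t2_max_ms
        self.n_t2 = n_t2
        self.reg_factor = reg_factor
        self.alpha_bounds_deg = alpha_bounds_deg
        self.alpha_search = alpha_search
        self.alpha_grid_deg = alpha_grid_deg
        self.alpha_tol_deg = alpha_tol_deg
        self.t1_ms = t1_ms
        self.rician_correction = rician_correction
        self.noise_sigma = noise_sigma

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "te_ms", "tr_ms", "n_echoes", "t2_min_ms", "t2_max_ms", "n_t2",
                "reg_factor", "alpha_bounds_deg", "alpha_search",
                "alpha_grid_deg", "alpha_tol_deg", "t1_ms", "rician_correction",
                "noise_sigma",
            )
        }

    def set_params(self, **params) -> "T2SpectrumNNLS":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals ---------------------------------------------------------
    def _seq(self, n_echoes: int) -> SequenceParams:
        return SequenceParams(n_echoes=n_echoes, te_ms=self.te_ms, tr_ms=self.tr_ms)

    def _alpha_grid(self) -> np.ndarray:
        lo, hi = self.alpha_bounds_deg
        n = max(int(round((hi - lo) / self.alpha_grid_deg)) + 1, 3)
        return np.linspace(lo, hi, n)

    def _fit_one(
        self,
        y: np.ndarray,
        seq: SequenceParams,
        grid: T2Grid,
        bases: dict[float, np.ndarray],
        alpha_nodes: np.ndarray | None,
    ) -> T2Spectrum:
        if not np.any(y > 0):
            raise ValueError("all-zero decay: spectrum is undefined")

        def chi2_min_at(alpha: float) -> float:
            basis = bases.get(alpha)
            if basis is None:
                basis = build_basis(seq, grid, alpha, self.t1_ms)
                bases[alpha] = basis
            return _chi2_nnls(basis, y)[1]

        lo, hi = self.alpha_bounds_deg
        if self.alpha_search == "golden":
            alpha, _ = _golden_section_alpha(chi2_min_at, lo, hi, self.alpha_tol_deg)
        elif self.alpha_search == "grid":
            chi2s = np.array([chi2_min_at(a) for a in alpha_nodes])
            alpha = _parabolic_refine(alpha_nodes, chi2s)
        else:
            raise ValueError(f"unknown alpha_search {self.alpha_search!r}")

        basis = bases.get(alpha)
        if basis is None:
            basis = build_basis(seq, grid, alpha, self.t1_ms)
            bases[alpha] = basis
        x0, chi2_min = _chi2_nnls(basis, y)
        sigma = self.noise_sigma
        if self.rician_correction:
            estimate_sigma = sigma is None
            if estimate_sigma:
                dof = max(seq.n_echoes - int(np.count_nonzero(x0)), 1)
                sigma = float(np.sqrt(chi2_min / dof))
            s = basis @ x0
            yc = y
            for _ in range(3):
                yc = y - (_rician_mean(s, sigma) - s)
                x0, chi2_min = _chi2_nnls(basis, yc)
                s = basis @ x0
                if estimate_sigma:
                    # refine sigma on echoes safely above the floor,
                    # where the magnitude noise is effectively Gaussian
                    hi = s > 3.0 * sigma
                    if hi.sum() > seq.n_echoes // 4:
                        r = (yc - s)[hi]
                        sigma = float(
                            np.sqrt((r @ r) / max(int(hi.sum()) - int(np.count_nonzero(x0)), 1))
                        )
            y = yc
        x, chi2, mu = _regularized_nnls(basis, y, chi2_min, self.reg_factor)
        return T2Spectrum(
            grid=grid,
            amplitudes=x,
            chosen_alpha_deg=float(alpha),
            residual_norm=float(np.sqrt(chi2)),
            mu=float(mu),
            noise_sigma=float(sigma or 0.0),
        )

    # -- public API ---------------------------------------------------------
    def fit(self, X: np.ndarray, y=None) -> "T2SpectrumNNLS":
        """Invert every row of ``X`` (n_voxels, n_echoes) into a spectrum."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_voxels, n_echoes)")
        if np.any(X < 0) or not np.all(np.isfinite(X)):
            raise ValueError("echo decays must be finite and nonnegative")
        n_echoes = self.n_echoes or X.shape[1]
        if X.shape[1] != n_echoes:
            raise ValueError(f"expected {n_echoes} echoes, got {X.shape[1]}")

        seq = self._seq(n_echoes)
        grid = T2Grid.log_spaced(self.t2_min_ms, self.t2_max_ms, self.n_t2)
        alpha_nodes = self._alpha_grid() if self.alpha_search == "grid" else None
        bases: dict[float, np.ndarray] = {}
        if alpha_nodes is not None:
            for a in alpha_nodes:
                bases[a] = build_basis(seq, grid, a, self.t1_ms)

        specs = [self._fit_one(row, seq, grid, bases, alpha_nodes) for row in X]
        self.grid_ = grid
        self.n_features_in_ = n_echoes
        self.amplitudes_ = np.stack([s.amplitudes for s in specs])
        self.alpha_deg_ = np.array([s.chosen_alpha_deg for s in specs])
        self.residual_norm_ = np.array([s.residual_norm for s in specs])
        self.mu_ = np.array([s.mu for s in specs])
        self.sigma_ = np.array([s.noise_sigma for s in specs])
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Return spectra (n_voxels, n_t2) for ``X`` without storing state."""
        est = T2SpectrumNNLS(**self.get_params()).fit(X)
        return est.amplitudes_

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).amplitudes_


def fit_spectrum(
    decay: np.ndarray,
    seq: SequenceParams,
    grid: T2Grid | None = None,
    reg_factor: float = 1.005,
    alpha_search: str = "grid",
    alpha_bounds_deg: tuple[float, float] = (90.0, 180.0),
    alpha_tol_deg: float = 0.5,
    t1_ms: float = 1000.0,
) -> T2Spectrum:
    """Invert a single echo train into a regularized T2 spectrum.

    Thin functional wrapper over :class:`T2SpectrumNNLS` for one voxel.
    """
    decay = np.asarray(decay, dtype=float)
    if decay.ndim != 1 or decay.size != seq.n_echoes:
        raise ValueError(f"decay must have length {seq.n_echoes}")
    grid = grid or T2Grid.log_spaced()
    est = T2SpectrumNNLS(
        te_ms=seq.te_ms,
        tr_ms=seq.tr_ms,
        n_echoes=seq.n_echoes,
        t2_min_ms=grid.t2_ms[0],
        t2_max_ms=grid.t2_ms[-1],
        n_t2=grid.n_points,
        reg_factor=reg_factor,
        alpha_bounds_deg=alpha_bounds_deg,
        alpha_search=alpha_search,
        alpha_tol_deg=alpha_tol_deg,
        t1_ms=t1_ms,
    )
    est.fit(decay[None, :])
    return T2Spectrum(
        grid=est.grid_,
        amplitudes=est.amplitudes_[0],
        chosen_alpha_deg=float(est.alpha_deg_[0]),
        residual_norm=float(est.residual_norm_[0]),
        mu=float(est.mu_[0]),
    )
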