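"""Diffusion tensor fitting and fiber-to-B0 angle mapping.

The local white-matter fiber direction is taken as the principal
eigenvector of the single diffusion tensor fitted per voxel by
log-linear least squares.  The orientation statistic theta is the angle
between that eigenvector and the main field B0 (the volume z-axis for an
axial acquisition without angulation), folded into [0, 90] degrees since
fiber direction is sign-ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "DiffusionScheme",
    "DiffusionTensorModel",
    "fit_tensor",
    "angle_to_b0",
    "erode_mask",
    "fractional_anisotropy",
]


@dataclass(frozen=True)
class DiffusionScheme:
    """Diffusion gradient table: unit directions and b-values (s/mm^2)."""

    bvecs: np.ndarray  # (n, 3)
    bvals: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        bvecs = np.asarray(self.bvecs, dtype=float)
        bvals = np.asarray(self.bvals, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3 or bvals.shape != (bvecs.shape[0],):
            raise ValueError("bvecs must be (n, 3) and bvals (n,)")
        if not np.any(bvals == 0):
            raise ValueError("at least one b=0 volume is required")
        dwi = bvals > 0
        if dwi.sum() >= 1:
            norms = np.linalg.norm(bvecs[dwi], axis=1)
            if np.any(norms == 0):
                raise ValueError("b>0 directions must be non-zero")
            bvecs = bvecs.copy()
            bvecs[dwi] /= norms[:, None]
        # rank of the quadratic-form design decides identifiability
        g = bvecs[dwi]
        quad = np.column_stack(
            [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
             2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]]
        )
        if np.linalg.matrix_rank(quad) < 6:
            raise ValueError("need >= 6 non-collinear b>0 directions for a tensor fit")
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "bvals", bvals)

    @classmethod
    def from_fsl(cls, bvecs_path: str | Path, bvals_path: str | Path) -> "DiffusionScheme":
        """Read FSL-style plain-text b-tables (3 x n or n x 3 bvecs)."""
        bvecs = np.loadtxt(bvecs_path, dtype=float)
        bvals = np.atleast_1d(np.loadtxt(bvals_path, dtype=float))
        if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
            bvecs = bvecs.T
        return cls(bvecs=bvecs, bvals=bvals)

    def to_fsl(self, bvecs_path: str | Path, bvals_path: str | Path) -> None:
        np.savetxt(bvecs_path, self.bvecs.T, fmt="%.8f")
        np.savetxt(bvals_path, self.bvals[None, :], fmt="%.1f")


def fractional_anisotropy(evals: np.ndarray) -> np.ndarray:
    """FA from eigenvalue arrays of shape (..., 3)."""
    evals = np.asarray(evals, dtype=float)
    md = evals.mean(axis=-1, keepdims=True)
    num = ((evals - md) ** 2).sum(axis=-1)
    den = (evals**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / np.where(den > 0, den, 1.0))
    return np.where(den > 0, fa, 0.0)


class DiffusionTensorModel:
    """Per-voxel log-linear diffusion tensor fit (sklearn style).

    Parameters
    ----------
    scheme : DiffusionScheme
        Gradient table matching the columns of the signal matrix.
    b0_dir : 3-vector
        Direction of the main magnetic field; z-axis by default.
    fa_threshold : float
        Voxels with FA below this are flagged orientation-undefined
        (orientation is meaningless for an isotropic tensor).

    Attributes (after :meth:`fit` on X of shape (n_voxels, n_meas))
    ----------------------------------------------------------------
    tensors_ : (n_voxels, 3, 3) symmetric diffusion tensors
    evals_ : (n_voxels, 3) eigenvalues, descending
    evecs_ : (n_voxels, 3, 3) eigenvectors in columns, evecs_[:, :, 0]
        is the principal direction (unit norm, sign-arbitrary)
    fa_ : (n_voxels,) fractional anisotropy
    theta_deg_ : (n_voxels,) fiber-to-B0 angle in [0, 90], NaN if invalid
    valid_mask_ : (n_voxels,) True where the fit and orientation are defined
    """

    def __init__(
        self,
        scheme: DiffusionScheme,
        b0_dir: tuple[float, float, float] = (0.0, 0.0, 1.0),
        fa_threshold: float = 0.2,
    ) -> None:
        self.scheme = scheme
        self.b0_dir = b0_dir
        self.fa_threshold = fa_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {"scheme": self.scheme, "b0_dir": self.b0_dir, "fa_threshold": self.fa_threshold}

    def set_params(self, **params) -> "DiffusionTensorModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y=None) -> "DiffusionTensorModel":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        b = self.scheme.bvals
        g = self.scheme.bvecs
        if X.shape[1] != b.size:
            raise ValueError(f"expected {b.size} measurements per voxel, got {X.shape[1]}")

        # design for log S = log S0 - b g^T D g
        design = np.column_stack(
            [np.ones_like(b),
             -b * g[:, 0] ** 2, -b * g[:, 1] ** 2, -b * g[:, 2] ** 2,
             -2 * b * g[:, 0] * g[:, 1], -2 * b * g[:, 0] * g[:, 2],
             -2 * b * g[:, 1] * g[:, 2]]
        )
        n = X.shape[0]
        valid = np.all(X > 0, axis=1)
        coeffs = np.full((n, 7), np.nan)
        if valid.any():
            sol, *_ = np.linalg.lstsq(design, np.log(X[valid]).T, rcond=None)
            coeffs[valid] = sol.T

        D = np.full((n, 3, 3), np.nan)
        dxx, dyy, dzz, dxy, dxz, dyz = (coeffs[:, i] for i in range(1, 7))
        D[:, 0, 0], D[:, 1, 1], D[:, 2, 2] = dxx, dyy, dzz
        D[:, 0, 1] = D[:, 1, 0] = dxy
        D[:, 0, 2] = D[:, 2, 0] = dxz
        D[:, 1, 2] = D[:, 2, 1] = dyz

        evals = np.full((n, 3), np.nan)
        evecs = np.full((n, 3, 3), np.nan)
        if valid.any():
            w, v = np.linalg.eigh(D[valid])  # ascending
            evals[valid] = w[:, ::-1]
            evecs[valid] = v[:, :, ::-1]

        fa = np.where(valid, fractional_anisotropy(np.nan_to_num(evals)), np.nan)
        ok = valid & (np.nan_to_num(fa, nan=0.0) >= self.fa_threshold)
        theta = np.full(n, np.nan)
        if ok.any():
            theta[ok] = angle_to_b0(evecs[ok][:, :, 0], np.asarray(self.b0_dir, dtype=float))

        self.tensors_ = D
        self.evals_ = evals
        self.evecs_ = evecs
        self.fa_ = fa
        self.theta_deg_ = theta
        self.valid_mask_ = ok
        self.n_features_in_ = b.size
        return self


def fit_tensor(signals: np.ndarray, scheme: DiffusionScheme, **kwargs) -> DiffusionTensorModel:
    """Fit diffusion tensors to (n_voxels, n_meas) signals; returns the fitted model."""
    return DiffusionTensorModel(scheme, **kwargs).fit(signals)


def angle_to_b0(eigvec: np.ndarray, b0_dir: np.ndarray) -> np.ndarray:
    """Angle (degrees, in [0, 90]) between fiber direction(s) and B0.

    Sign-invariant: v and -v give the same angle.  Accepts a single
    3-vector or an (n, 3) stack.
    """
    v = np.asarray(eigvec, dtype=float)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    b0 = np.asarray(b0_dir, dtype=float)
    nb = np.linalg.norm(b0)
    nv = np.linalg.norm(v, axis=1)
    if nb == 0 or np.any(nv == 0):
        raise ValueError("zero vector has no direction")
    cosang = np.abs(v @ (b0 / nb)) / nv
    theta = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
    return float(theta[0]) if single else theta


def erode_mask(mask: np.ndarray, kernel_size: int = 3) -> np.ndarray:
    """Binary erosion with a full cubic structuring element (3x3x3 default)."""
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be a 3-D volume")
    structure = np.ones((kernel_size,) * 3, dtype=bool)
    return ndimage.binary_erosion(mask, structure=structure)
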