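"""Orientation models for R2(theta) and the TR/T1 attenuation of MWF.

Three models from the white-matter relaxation literature describe how R2
depends on the fiber-to-B0 angle theta:

* ``dipole``:          R2 = a + b (3 cos^2 theta - 1)      (dipolar z-field)
* ``dipole_squared``:  R2 = a + b (3 cos^2 theta - 1)^2    (extended dipolar)
* ``knight``:          R2 = a + b sin^2 theta + c sin^4 theta
                       (susceptibility: gradient-interaction sin^2 term,
                       diffusion-mediated sin^4 term)

plus the single-term ``sin2_only`` and ``sin4_only`` reductions.  After
expanding cos^2 = 1 - sin^2, every model is linear in {1, sin^2, sin^4},
so fits are exact weighted linear least squares and the models obey
algebraic identities: the dipole model equals ``a + 2b - 3b sin^2`` and
the squared dipole model equals ``a + 4b - 12b sin^2 + 9b sin^4``.

A separate one-compartment-per-pool saturation-recovery model explains
why the *apparent* MWF depends on TR: myelin water (T1 ~ 200 ms) is
almost fully relaxed at any practical TR while intra/extracellular water
(T1 ~ 1100 ms) is attenuated at short TR, inflating the measured ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MODEL_IDS",
    "ModelCoefficients",
    "OrientationR2Model",
    "fit_orientation_model",
    "model_identity_transform",
    "magic_angle",
    "apparent_mwf_vs_tr",
    "true_mwf_from_apparent",
    "TrAttenuationParams",
]

MODEL_IDS = ("dipole", "dipole_squared", "knight", "sin2_only", "sin4_only")


@dataclass(frozen=True)
class ModelCoefficients:
    """Fitted coefficients (1/s) and goodness of fit of one model."""

    model_id: str
    a: float
    b: float
    c: float | None
    rss: float
    n_points: int

    def predict(self, theta_deg: np.ndarray) -> np.ndarray:
        return _evaluate(self.model_id, self.a, self.b, self.c, np.asarray(theta_deg, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"model": self.model_id, "a": self.a, "b": self.b,
              "c": self.c if self.c is not None else np.nan,
              "rss": self.rss, "n_points": self.n_points}]
        )


def _design(model_id: str, theta_deg: np.ndarray) -> np.ndarray:
    s2 = np.sin(np.deg2rad(theta_deg)) ** 2
    c2 = np.cos(np.deg2rad(theta_deg)) ** 2
    one = np.ones_like(s2)
    if model_id == "dipole":
        return np.column_stack([one, 3 * c2 - 1])
    if model_id == "dipole_squared":
        return np.column_stack([one, (3 * c2 - 1) ** 2])
    if model_id == "knight":
        return np.column_stack([one, s2, s2**2])
    if model_id == "sin2_only":
        return np.column_stack([one, s2])
    if model_id == "sin4_only":
        return np.column_stack([one, s2**2])
    raise ValueError(f"unknown model {model_id!r}; choose from {MODEL_IDS}")


def _evaluate(model_id: str, a: float, b: float, c: float | None, theta_deg: np.ndarray) -> np.ndarray:
    coefs = np.array([a, b] + ([c] if model_id == "knight" else []))
    return _design(model_id, theta_deg) @ coefs


class OrientationR2Model:
    """Weighted linear least-squares fit of an orientation model (sklearn style).

    Parameters
    ----------
    model : one of ``MODEL_IDS``.
    weighted : bool
        If True (default) and sample weights are provided to :meth:`fit`,
        points are weighted (e.g. by bin voxel counts; bins near 0 deg
        hold few voxels in real white matter).

    Attributes (after :meth:`fit`)
    ------------------------------
    a_, b_, c_ : coefficients (``c_`` is None except for "knight")
    rss_ : unweighted residual sum of squares
    n_points_ : number of non-missing points used
    """

    def __init__(self, model: str = "knight", weighted: bool = True) -> None:
        self.model = model
        self.weighted = weighted

    def get_params(self, deep: bool = True) -> dict:
        return {"model": self.model, "weighted": self.weighted}

    def set_params(self, **params) -> "OrientationR2Model":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None) -> "OrientationR2Model":
        theta = np.asarray(X, dtype=float).ravel()
        r2 = np.asarray(y, dtype=float).ravel()
        if theta.shape != r2.shape:
            raise ValueError("theta and R2 must have equal length")
        w = None
        if sample_weight is not None and self.weighted:
            w = np.asarray(sample_weight, dtype=float).ravel()
            if w.shape != theta.shape:
                raise ValueError("sample_weight must match data length")
        keep = np.isfinite(theta) & np.isfinite(r2)
        if w is not None:
            keep &= np.isfinite(w) & (w > 0)
            w = w[keep]
        theta, r2 = theta[keep], r2[keep]

        design = _design(self.model, theta)
        if theta.size < design.shape[1]:
            raise ValueError(
                f"{self.model} needs >= {design.shape[1]} points, got {theta.size}"
            )
        if w is not None:
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(design * sw[:, None], r2 * sw, rcond=None)
        else:
            coef, *_ = np.linalg.lstsq(design, r2, rcond=None)
        resid = r2 - design @ coef
        self.a_ = float(coef[0])
        self.b_ = float(coef[1])
        self.c_ = float(coef[2]) if self.model == "knight" else None
        self.rss_ = float(resid @ resid)
        self.n_points_ = int(theta.size)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _evaluate(self.model, self.a_, self.b_, self.c_, np.asarray(X, dtype=float).ravel())

    @property
    def coefficients_(self) -> ModelCoefficients:
        return ModelCoefficients(
            model_id=self.model, a=self.a_, b=self.b_, c=self.c_,
            rss=self.rss_, n_points=self.n_points_,
        )


def fit_orientation_model(
    theta_deg: np.ndarray,
    r2_per_s: np.ndarray,
    model_id: str = "knight",
    weights: np.ndarray | None = None,
) -> ModelCoefficients:
    """Fit one orientation model to an R2(theta) curve; returns coefficients."""
    est = OrientationR2Model(model=model_id, weighted=weights is not None)
    est.fit(theta_deg, r2_per_s, sample_weight=weights)
    return est.coefficients_


def model_identity_transform(coeffs: ModelCoefficients) -> ModelCoefficients:
    """Rewrite a dipolar model in the {1, sin^2, sin^4} basis.

    dipole (a, b)          -> (a + 2b, -3b, 0)
    dipole_squared (a, b)  -> (a + 4b, -12b, 9b)
    knight                 -> unchanged

    The transformed model evaluates identically at every angle.
    """
    if coeffs.model_id == "dipole":
        a, b, c = coeffs.a + 2 * coeffs.b, -3 * coeffs.b, 0.0
    elif coeffs.model_id == "dipole_squared":
        a, b, c = coeffs.a + 4 * coeffs.b, -12 * coeffs.b, 9 * coeffs.b
    elif coeffs.model_id == "knight":
        return coeffs
    else:
        raise ValueError(f"no knight-basis identity for {coeffs.model_id!r}")
    return ModelCoefficients(
        model_id="knight", a=a, b=b, c=c, rss=coeffs.rss, n_points=coeffs.n_points
    )


def magic_angle() -> float:
    """The angle (degrees) at which 3 cos^2 theta - 1 vanishes: ~54.7356."""
    return float(np.degrees(np.arccos(1.0 / np.sqrt(3.0))))


@dataclass(frozen=True)
class TrAttenuationParams:
    """Two-pool T1 values (ms) and the underlying myelin water fraction."""

    true_mwf: float
    t1_mw_ms: float = 200.0
    t1_ie_ms: float = 1100.0

    def __post_init__(self) -> None:
        if not (0.0 < self.true_mwf < 1.0):
            raise ValueError("true_mwf must lie in (0, 1)")
        if not (0.0 < self.t1_mw_ms < self.t1_ie_ms):
            raise ValueError("require 0 < t1_mw_ms < t1_ie_ms")


def apparent_mwf_vs_tr(params: TrAttenuationParams, tr_ms: float) -> float:
    """Apparent MWF after saturation-recovery weighting of the two pools.

    Each pool recovers by E = 1 - exp(-TR/T1) between excitations, so the
    measured fraction is ``f E_mw / (f E_mw + (1 - f) E_ie)``.  Since
    T1 of myelin water is short, E_mw ~ 1 at practical TR while E_ie < 1,
    so the apparent MWF exceeds the true one and decreases with TR.
    """
    if not (np.isfinite(tr_ms) and tr_ms > 0):
        raise ValueError("tr_ms must be positive")
    f = params.true_mwf
    e_mw = 1.0 - np.exp(-tr_ms / params.t1_mw_ms)
    e_ie = 1.0 - np.exp(-tr_ms / params.t1_ie_ms)
    return float(f * e_mw / (f * e_mw + (1.0 - f) * e_ie))


def true_mwf_from_apparent(
    apparent_mwf: float,
    tr_ms: float,
    t1_mw_ms: float = 200.0,
    t1_ie_ms: float = 1100.0,
) -> float:
    """Invert the TR-attenuation model for the underlying fraction."""
    if not (0.0 < apparent_mwf < 1.0):
        raise ValueError("apparent_mwf must lie in (0, 1)")
    e_mw = 1.0 - np.exp(-tr_ms / t1_mw_ms)
    e_ie = 1.0 - np.exp(-tr_ms / t1_ie_ms)
    a = apparent_mwf
    return float(a * e_ie / (a * e_ie + (1.0 - a) * e_mw))
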