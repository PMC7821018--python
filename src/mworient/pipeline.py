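"""End-to-end analysis pipeline: volumes in, orientation curves and fits out.

Stages: (optional) phantom simulation -> voxelwise T2 spectrum inversion
-> pool metrics -> diffusion tensor orientation -> white-matter mask
erosion -> angle-wise pooling -> orientation-model fits.  All stages are
deterministic given the configuration and seed, and results do not
depend on the voxel chunking used for the inversion.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dti import DiffusionScheme, DiffusionTensorModel, erode_mask
from .models import MODEL_IDS, ModelCoefficients, fit_orientation_model
from .nnls import T2SpectrumNNLS
from .phantom import PhantomDataset, PhantomSpec, generate_dataset, simulate_cohort
from .pooling import AngleBins, AngleCurve, group_curve, pooled_curve
from .pools import mwf_from_amplitudes, pool_gm_t2_from_amplitudes

logger = logging.getLogger("mworient")

__all__ = [
    "PipelineConfig",
    "SubjectResult",
    "fit_t2_volume",
    "orientation_from_dwi",
    "analyze_subject",
    "analyze_cohort",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline in one place (YAML-serializable)."""

    cutoff_ms: float = 25.0
    csf_cutoff_ms: float = 1000.0
    t2_min_ms: float = 8.0
    t2_max_ms: float = 2000.0
    n_t2: int = 40
    reg_factor: float = 1.005
    rician_correction: bool = True
    alpha_search: str = "grid"
    alpha_bounds_deg: tuple[float, float] = (90.0, 180.0)
    alpha_grid_deg: float = 3.0
    basis_t1_ms: float = 1000.0
    b0_dir: tuple[float, float, float] = (0.0, 0.0, 1.0)
    fa_threshold: float = 0.2
    erode_kernel: int = 3
    bin_width_deg: float = 5.0
    chunk_size: int = 4096
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self._as_plain_dict(), fh, sort_keys=False)

    def _as_plain_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self._as_plain_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def bins(self) -> AngleBins:
        return AngleBins(width_deg=self.bin_width_deg)


def fit_t2_volume(
    volume: np.ndarray,
    mask: np.ndarray,
    te_ms: float,
    tr_ms: float,
    config: PipelineConfig | None = None,
) -> dict[str, np.ndarray]:
    """Voxelwise spectrum inversion of a 4-D (x, y, z, echo) volume.

    Returns maps: ``mwf``, ``alpha_deg``, ``t2_mw_ms``, ``t2_ie_ms`` plus
    the spectra as ``amplitudes`` (x, y, z, n_t2) with ``t2_grid_ms``.
    Voxels outside the mask are NaN.
    """
    config = config or PipelineConfig()
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4:
        raise ValueError("t2 fitting stage: volume must be 4-D (x, y, z, echo)")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != volume.shape[:3]:
        raise ValueError("t2 fitting stage: mask and volume grids differ")

    est = T2SpectrumNNLS(
        te_ms=te_ms,
        tr_ms=tr_ms,
        n_echoes=volume.shape[3],
        t2_min_ms=config.t2_min_ms,
        t2_max_ms=config.t2_max_ms,
        n_t2=config.n_t2,
        reg_factor=config.reg_factor,
        rician_correction=config.rician_correction,
        alpha_bounds_deg=config.alpha_bounds_deg,
        alpha_search=config.alpha_search,
        alpha_grid_deg=config.alpha_grid_deg,
        t1_ms=config.basis_t1_ms,
    )
    voxels = volume[mask]  # (n_masked, n_echoes)
    n = voxels.shape[0]
    if config.rician_correction and n >= 32:
        # noise is spatially uniform: estimate sigma once on an evenly
        # spaced voxel subsample, then correct all voxels with it
        sub = voxels[np.linspace(0, n - 1, min(256, n)).astype(int)]
        pre = T2SpectrumNNLS(**{**est.get_params(), "noise_sigma": None}).fit(sub)
        est.set_params(noise_sigma=float(np.median(pre.sigma_)))
    amps = None
    alphas = np.empty(n)
    for start in range(0, n, config.chunk_size):  # chunk order does not affect results
        stop = min(start + config.chunk_size, n)
        est.fit(voxels[start:stop])
        if amps is None:
            amps = np.empty((n, est.grid_.n_points))
        amps[start:stop] = est.amplitudes_
        alphas[start:stop] = est.alpha_deg_

    t2_grid = est.grid_.t2_ms
    mwf = mwf_from_amplitudes(amps, t2_grid, config.cutoff_ms)
    gm_mw, gm_ie = pool_gm_t2_from_amplitudes(amps, t2_grid, config.cutoff_ms, config.csf_cutoff_ms)

    def to_map(vals: np.ndarray, extra: tuple[int, ...] = ()) -> np.ndarray:
        out = np.full(mask.shape + extra, np.nan)
        out[mask] = vals
        return out

    return {
        "mwf": to_map(mwf),
        "alpha_deg": to_map(alphas),
        "t2_mw_ms": to_map(gm_mw),
        "t2_ie_ms": to_map(gm_ie),
        "amplitudes": to_map(amps, (t2_grid.size,)),
        "t2_grid_ms": t2_grid,
    }


def orientation_from_dwi(
    dwi: np.ndarray,
    scheme: DiffusionScheme,
    mask: np.ndarray,
    config: PipelineConfig | None = None,
) -> dict[str, np.ndarray]:
    """Tensor fit inside the mask; returns theta map and eroded mask."""
    config = config or PipelineConfig()
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4:
        raise ValueError("orientation stage: DWI must be 4-D (x, y, z, meas)")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != dwi.shape[:3]:
        raise ValueError("orientation stage: mask and DWI grids differ")

    model = DiffusionTensorModel(scheme, b0_dir=config.b0_dir, fa_threshold=config.fa_threshold)
    model.fit(dwi[mask])
    theta = np.full(mask.shape, np.nan)
    theta[mask] = model.theta_deg_
    fa = np.full(mask.shape, np.nan)
    fa[mask] = model.fa_
    return {
        "theta_deg": theta,
        "fa": fa,
        "eroded_mask": erode_mask(mask, config.erode_kernel),
    }


@dataclass
class SubjectResult:
    """Per-subject maps and angle curves, keyed by TR."""

    maps: dict[float, dict[str, np.ndarray]]
    theta_deg: np.ndarray
    eroded_mask: np.ndarray
    curves: dict[float, dict[str, AngleCurve]]  # tr -> metric -> curve

    def global_mean(self, tr_ms: float, metric: str = "mwf") -> float:
        vals = self.maps[tr_ms][metric][self.eroded_mask]
        return float(np.nanmean(vals))


_METRICS = ("mwf", "t2_mw_ms", "t2_ie_ms", "r2_mw_per_s", "r2_ie_per_s")


def analyze_subject(dataset: PhantomDataset, config: PipelineConfig | None = None) -> SubjectResult:
    """Full single-subject pipeline on an in-memory bundle."""
    config = config or PipelineConfig()
    orient = orientation_from_dwi(dataset.dwi, dataset.scheme, dataset.mask, config)
    theta, eroded = orient["theta_deg"], orient["eroded_mask"]
    bins = config.bins()

    maps: dict[float, dict[str, np.ndarray]] = {}
    curves: dict[float, dict[str, AngleCurve]] = {}
    for tr, vol in dataset.echo_volumes.items():
        logger.info("T2 inversion at TR=%s ms (%d voxels)", tr, int(eroded.sum()))
        m = fit_t2_volume(vol, eroded, dataset.spec.te_ms, tr, config)
        with np.errstate(invalid="ignore", divide="ignore"):
            m["r2_mw_per_s"] = 1000.0 / m["t2_mw_ms"]
            m["r2_ie_per_s"] = 1000.0 / m["t2_ie_ms"]
        maps[tr] = m
        curves[tr] = {
            name: pooled_curve(m[name], theta, eroded, bins, label=f"{name}@TR{int(tr)}")
            for name in _METRICS
        }
    return SubjectResult(maps=maps, theta_deg=theta, eroded_mask=eroded, curves=curves)


def analyze_cohort(
    results: list[SubjectResult], config: PipelineConfig | None = None
) -> dict[float, dict[str, AngleCurve]]:
    """Group mean curves with 95% CI across subjects, per TR and metric."""
    if not results:
        raise ValueError("no subjects")
    trs = results[0].curves.keys()
    out: dict[float, dict[str, AngleCurve]] = {}
    for tr in trs:
        out[tr] = {
            name: group_curve([r.curves[tr][name] for r in results], label=f"{name}@TR{int(tr)}")
            for name in _METRICS
        }
    return out


def fit_models_to_curves(
    curves: dict[str, AngleCurve], weighted: bool = True
) -> pd.DataFrame:
    """Fit all five orientation models to the R2 curves of both pools."""
    rows = []
    for pool, key in (("mw", "r2_mw_per_s"), ("ie", "r2_ie_per_s")):
        curve = curves[key]
        w = curve.counts.astype(float) if weighted else None
        for model_id in MODEL_IDS:
            coeff = fit_orientation_model(curve.bin_centers_deg, curve.values, model_id, weights=w)
            rows.append(
                {
                    "pool": pool,
                    "model": model_id,
                    "a": coeff.a,
                    "b": coeff.b,
                    "c": coeff.c if coeff.c is not None else np.nan,
                    "rss": coeff.rss,
                    "n_points": coeff.n_points,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file-based driver


def _save_nifti(path: Path, arr: np.ndarray, config_hash: str) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), np.eye(4))
    img.header["descrip"] = f"mworient cfg={config_hash}".encode()[:80]
    nib.save(img, path)


def _save_table(path: Path, df: pd.DataFrame, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mworient config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    dataset: PhantomDataset | None = None,
    phantom_spec: PhantomSpec | None = None,
    n_subjects: int = 1,
) -> dict:
    """Run simulate/ingest -> inversion -> orientation -> pooling -> fits.

    Either an existing ``dataset`` is analyzed, or ``n_subjects`` phantoms
    are generated from ``phantom_spec`` (seeded by ``config.seed``).
    Writes NIfTI maps, CSV curves/fits and a JSON report; every output
    carries the configuration hash.  Returns the report dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    logging.basicConfig(level=logging.INFO)

    if dataset is not None:
        cohort = [dataset]
    else:
        spec = phantom_spec or PhantomSpec(seed=config.seed)
        logger.info("simulating %d phantom subject(s), seed=%d", n_subjects, config.seed)
        cohort = simulate_cohort(spec, n_subjects, seed=config.seed)

    results = [analyze_subject(ds, config) for ds in cohort]

    # per-subject outputs
    for i, (ds, res) in enumerate(zip(cohort, results)):
        sdir = out / f"subject{i:02d}"
        sdir.mkdir(exist_ok=True)
        _save_nifti(sdir / "theta_deg.nii.gz", res.theta_deg, h)
        _save_nifti(sdir / "eroded_mask.nii.gz", res.eroded_mask.astype(np.float32), h)
        for tr, m in res.maps.items():
            for name in ("mwf", "alpha_deg", "t2_mw_ms", "t2_ie_ms"):
                _save_nifti(sdir / f"{name}_tr{int(tr)}.nii.gz", m[name], h)
            np.savez_compressed(
                sdir / f"spectra_tr{int(tr)}.npz",
                amplitudes=m["amplitudes"],
                t2_grid_ms=m["t2_grid_ms"],
            )
            for name, curve in res.curves[tr].items():
                _save_table(sdir / f"curve_{name}_tr{int(tr)}.csv", curve.to_frame(), h)

    group = analyze_cohort(results, config)
    fits = {}
    for tr, curves in group.items():
        for name, curve in curves.items():
            _save_table(out / f"group_curve_{name}_tr{int(tr)}.csv", curve.to_frame(), h)
        fit_df = fit_models_to_curves(curves)
        _save_table(out / f"model_fits_tr{int(tr)}.csv", fit_df, h)
        fits[tr] = fit_df

    report = {
        "config_hash": h,
        "config": config._as_plain_dict(),
        "n_subjects": len(cohort),
        "tr_list_ms": sorted(float(tr) for tr in group),
        "global_mwf_by_tr": {
            str(int(tr)): float(np.mean([r.global_mean(tr, "mwf") for r in results]))
            for tr in group
        },
        "outputs": sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    config.to_yaml(out / "config.yaml")
    return report
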