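"""Reconstruction-quality metrics, volume/curve I/O and run manifests.

The two image-quality figures compare a reconstruction ("tom") with its
reference model ("src") over all I voxels:

* ``kcor`` — the Pearson correlation coefficient
  Σ(x_tom − x̄_tom)(x_src − x̄_src) / ((I−1) Δx_tom Δx_src); close to 1
  means high structural agreement.
* ``kdev`` — the RMS voxel difference normalized by the reference standard
  deviation, √(Σ(x_tom − x_src)²/I) / Δx_src; close to 0 means high
  amplitude agreement.

Δx is the (I−1)-denominator sample standard deviation throughout.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .curves import TimeCurve
from .mc import SensitivityVolume
from .optics import DomainError
from .phantom import VoxelGrid


class UndefinedMetricError(ValueError):
    """Metric undefined (zero variance in an input image)."""


@dataclass
class ImagePair:
    """A reconstructed volume and its reference model on congruent grids."""

    tom: np.ndarray
    src: np.ndarray

    def __post_init__(self) -> None:
        self.tom = np.asarray(self.tom, float)
        self.src = np.asarray(self.src, float)
        if self.tom.shape != self.src.shape:
            raise DomainError("tom and src must have congruent shapes")


def kcor(pair: ImagePair) -> float:
    """Pearson correlation coefficient between reconstruction and model."""
    t = pair.tom.ravel()
    s = pair.src.ravel()
    dt = t.std(ddof=1)
    ds = s.std(ddof=1)
    if dt <= 0.0 or ds <= 0.0:
        raise UndefinedMetricError("kcor undefined for zero-variance image")
    n = len(t)
    return float(((t - t.mean()) @ (s - s.mean())) / ((n - 1) * dt * ds))


def kdev(pair: ImagePair) -> float:
    """RMS voxel difference divided by the reference standard deviation."""
    s = pair.src.ravel()
    ds = s.std(ddof=1)
    if ds <= 0.0:
        raise UndefinedMetricError("kdev undefined for zero-variance model")
    t = pair.tom.ravel()
    return float(np.sqrt(np.mean((t - s) ** 2)) / ds)


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def save_volume(path, values: np.ndarray, grid: VoxelGrid, **attrs) -> None:
    """Write a volume to an HDF5 container (datasets ``values`` plus grid
    metadata; axis order x, y, z)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=np.asarray(values, float))
        f.attrs["voxel_size"] = grid.voxel_size
        f.attrs["origin"] = np.asarray(grid.origin, float)
        f.attrs["shape"] = np.asarray(grid.shape, int)
        f.attrs["axes"] = "xyz"
        for k, v in attrs.items():
            f.attrs[k] = v


def load_volume(path) -> tuple[np.ndarray, VoxelGrid, dict]:
    with h5py.File(path, "r") as f:
        values = f["values"][()]
        grid = VoxelGrid(tuple(int(s) for s in f.attrs["shape"]),
                         float(f.attrs["voxel_size"]),
                         tuple(float(o) for o in f.attrs["origin"]))
        attrs = {k: f.attrs[k] for k in f.attrs
                 if k not in ("voxel_size", "origin", "shape", "axes")}
    return values, grid, attrs


def save_sensitivity(path, vol: SensitivityVolume) -> None:
    save_volume(path, vol.values, vol.grid, gate=vol.gate,
                n_histories=vol.n_histories, seed=vol.seed,
                link=np.asarray(vol.link.key, float))


def save_system(path, system) -> None:
    """Persist an assembled W f = g system (W chunked, g, row metadata)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=system.W, chunks=True)
        f.create_dataset("g", data=system.g)
        f.attrs["voxel_size"] = system.grid.voxel_size
        f.attrs["origin"] = np.asarray(system.grid.origin, float)
        f.attrs["shape"] = np.asarray(system.grid.shape, int)
        f.attrs["rows"] = json.dumps(system.rows)
        f.attrs["meta"] = json.dumps(
            {k: v for k, v in system.meta.items()
             if isinstance(v, (int, float, str, bool, type(None)))})
        if system.meta.get("roi_shape"):
            f.attrs["roi_shape"] = np.asarray(system.meta["roi_shape"], int)


def load_system(path):
    from .assembly import LinearSystem

    with h5py.File(path, "r") as f:
        W = f["W"][()]
        g = f["g"][()]
        grid = VoxelGrid(tuple(int(s) for s in f.attrs["shape"]),
                         float(f.attrs["voxel_size"]),
                         tuple(float(o) for o in f.attrs["origin"]))
        meta = json.loads(f.attrs["meta"])
        if "roi_shape" in f.attrs:
            meta["roi_shape"] = tuple(int(s) for s in f.attrs["roi_shape"])
        rows = json.loads(f.attrs["rows"])
    return LinearSystem(W=W, g=g, grid=grid, rows=rows, meta=meta)


def export_nifti(path, values: np.ndarray, grid: VoxelGrid) -> None:
    """NIfTI export for external viewers (mm voxel spacing in the affine)."""
    import nibabel as nib

    affine = np.diag([grid.voxel_size] * 3 + [1.0])
    affine[:3, 3] = grid.origin
    nib.save(nib.Nifti1Image(np.asarray(values, float), affine), str(path))


# ---------------------------------------------------------------------------
# Time curves
# ---------------------------------------------------------------------------

def write_timecurve(path, curve: TimeCurve) -> None:
    """Two-column TSV (time_ps at bin centers, value); kind and metadata
    as '#'-prefixed header lines."""
    with open(path, "w") as fh:
        fh.write(f"# kind\t{curve.kind}\n")
        fh.write(f"# bin_width_ps\t{curve.bin_width!r}\n")
        for k, v in sorted(curve.meta.items()):
            fh.write(f"# {k}\t{v!r}\n")
        fh.write("time_ps\tvalue\n")
        for t, v in zip(curve.centers, curve.values):
            fh.write(f"{float(t)!r}\t{float(v)!r}\n")


def read_timecurve(path) -> TimeCurve:
    kind = "FTPSF"
    with open(path) as fh:
        header = []
        for line in fh:
            if line.startswith("#"):
                header.append(line[1:].strip())
            else:
                break
    for h in header:
        if h.startswith("kind"):
            kind = h.split("\t", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#")
    t = df["time_ps"].to_numpy(float)
    width = t[1] - t[0] if len(t) > 1 else 1.0
    edges = np.concatenate([t - width / 2.0, [t[-1] + width / 2.0]])
    return TimeCurve(edges, df["value"].to_numpy(float), kind=kind)


# ---------------------------------------------------------------------------
# Config and run manifests
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load and schema-check the structured JSON configuration."""
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise DomainError("config must be a JSON object")
    unknown = set(cfg) - set(default_config())
    if unknown:
        raise DomainError(f"unknown config sections: {sorted(unknown)}")
    merged = default_config()
    for key, val in cfg.items():
        if isinstance(merged[key], dict) and isinstance(val, dict):
            bad = set(val) - set(merged[key])
            if bad:
                raise DomainError(f"unknown keys in [{key}]: {sorted(bad)}")
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def default_config() -> dict:
    """Package-wide default configuration (reference phantom geometry)."""
    return dict(
        phantom=dict(grid_shape=[200, 200, 150], voxel_size=0.1,
                     grid_origin=[-10.0, -10.0, 0.0],
                     mua=0.01, mus=2.63, g=0.62, n=1.521,
                     muaf=0.01, gamma=0.2, tau=900.0,
                     shape="cylinder", center=[0.0, 0.0, 4.2], radius=1.0),
        probe=dict(fiber_diameter=0.4, numerical_aperture=0.2,
                   critical_angle=8.2, sr_offsets=[3.3, 2.2, 1.1]),
        scan=dict(n_rows=19, n_cols=19, step=0.5, origin=[-4.5, -4.5]),
        mc=dict(n_histories=1000000, bin_width=2.0, max_time=1000.0,
                diffusion_denominator="scattering_only"),
        strategy=dict(kind=2, base_gate=200.0),
        preprocess=dict(sg_window=11, sg_order=3, rl_iterations=20,
                        edge_threshold=0.02),
        recon=dict(lam=0.9, alpha=0.001, s_artfist=100, s_tv=3,
                   beta0=0.005, beta_decay=0.997, tol=1e-4, max_outer=30),
        separation=dict(omega=1e-3, f_threshold=0.05),
        calibration=dict(scalar=1.0),
    )


def write_manifest(path, seed: int, config: dict, extra: dict | None = None
                   ) -> None:
    """Log parameters, seed and versions for a run."""
    import earlyflt

    manifest = dict(timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
                    seed=seed, python=sys.version.split()[0],
                    earlyflt=earlyflt.__version__,
                    numpy=np.__version__, config=config)
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
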