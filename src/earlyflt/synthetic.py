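"""Synthetic instrument responses and noisy fluorescence temporal
responses, so the whole pipeline is exercisable without measured data.

A synthetic FTR is built exactly the way a TCSPC chain produces one:
the modeled FTPSF is scaled by a coupling factor, convolved with an IRF
whose time origin carries a stochastic shift, rescaled to a target peak
count, and Poisson shot noise is applied per bin.  The IRF stand-in is a
unit-area Gaussian (the real detection chain's IRF shape is
instrument-specific); its default FWHM is 50 ps, a typical value for a
photomultiplier-based single-photon-counting chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import h5py
import numpy as np

from .curves import TimeCurve, uniform_grid
from .mc import compute_sensitivity_multi, simulate_ftpsf
from .optics import DomainError, fpdf_value
from .phantom import (Phantom, PhantomConfig, ProbeGeometry, ScanPattern,
                      make_phantom, scan_links)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SyntheticFTRParams:
    """Coupling factor C, IRF width/center (ps), stochastic time-origin
    shift window (± ps, drawn per curve), target FTR peak counts, seed."""

    coupling: float = 1.0
    irf_fwhm: float = 50.0
    irf_t0: float = 100.0
    t_shift_window: float = 20.0
    peak_counts: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling <= 0.0:
            raise DomainError("coupling must be > 0")
        if self.irf_fwhm <= 0.0:
            raise DomainError("irf_fwhm must be > 0")
        if self.peak_counts < 1:
            raise DomainError("peak_counts must be >= 1")


def make_irf(params: SyntheticFTRParams, bin_edges: np.ndarray) -> TimeCurve:
    """Unit-area Gaussian IRF of the given FWHM centered at ``irf_t0``."""
    edges = np.asarray(bin_edges, float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    sigma = params.irf_fwhm * _FWHM_TO_SIGMA
    vals = np.exp(-0.5 * ((centers - params.irf_t0) / sigma) ** 2)
    total = vals.sum() * width
    if total <= 0.0:  # FWHM far below the bin width: single-bin impulse
        vals = np.zeros_like(vals)
        vals[int(np.argmin(np.abs(centers - params.irf_t0)))] = 1.0 / width
        total = 1.0
        return TimeCurve(edges, vals, kind="IRF")
    return TimeCurve(edges, vals / total, kind="IRF",
                     meta=dict(fwhm=params.irf_fwhm, t0=params.irf_t0))


def synthesize_ftr(ftpsf: TimeCurve, irf: TimeCurve,
                   params: SyntheticFTRParams, rng: np.random.Generator,
                   noise: bool = True) -> TimeCurve:
    """Noisy FTR from an FTPSF: C·FTPSF ⊗ IRF(t − t_shift), rescaled to
    ``peak_counts`` at its maximum, then per-bin Poisson counts.

    ``t_shift`` is drawn uniformly in ±``t_shift_window`` and rounded to
    whole bins; it is recorded in the output metadata.  Deterministic for
    a given ``rng`` state.
    """
    if not np.array_equal(ftpsf.bin_edges, irf.bin_edges):
        raise DomainError("FTPSF and IRF must share one time grid")
    n = len(ftpsf.values)
    width = ftpsf.bin_width
    shift = 0.0
    if params.t_shift_window > 0.0:
        shift = float(rng.uniform(-params.t_shift_window,
                                  params.t_shift_window))
    nbins = int(round(shift / width))
    irf_shifted = np.zeros(n)
    if nbins >= 0:
        irf_shifted[nbins:] = irf.values[:n - nbins] if nbins < n else 0.0
    else:
        irf_shifted[:nbins] = irf.values[-nbins:]
    signal = np.convolve(params.coupling * ftpsf.values, irf_shifted)[:n]
    peak = signal.max()
    if peak > 0.0:
        signal = signal * (params.peak_counts / peak)
    if noise:
        values = rng.poisson(signal).astype(float)
    else:
        values = signal
    return TimeCurve(ftpsf.bin_edges.copy(), values, kind="FTR",
                     meta=dict(t_shift_ps=nbins * width,
                               coupling=params.coupling,
                               peak_counts=params.peak_counts))


def make_fixture(out_dir, phantom_cfg: PhantomConfig, pattern: ScanPattern,
                 probe: ProbeGeometry, gates, n_histories: int, seed: int,
                 ftr_params: SyntheticFTRParams | None = None,
                 bin_width: float = 2.0, max_time: float = 400.0) -> dict:
    """Generate a reduced synthetic scan: phantom, per-link FTPSFs and
    FTRs, an IRF, sensitivity volumes and a JSON manifest of every seed
    and parameter.  Re-running with the same manifest reproduces every
    array bitwise.

    Returns the manifest dict; arrays are written under ``out_dir`` (TSV
    curves, .npy volumes) and also returned in memory under ``"data"``.
    """
    from .metrics_io import write_timecurve  # local import: avoid cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ftr_params = ftr_params or SyntheticFTRParams(seed=seed)
    phantom = make_phantom(phantom_cfg)
    links = scan_links(pattern, probe)
    edges = uniform_grid(max_time, bin_width)
    irf = make_irf(ftr_params, edges)
    write_timecurve(out / "irf.tsv", irf)

    rng = np.random.default_rng(seed)
    data = dict(phantom=phantom, links=links, irf=irf, ftpsf={}, ftr={},
                sensitivity={})
    manifest = dict(seed=seed, n_histories=int(n_histories),
                    bin_width=bin_width, max_time=max_time,
                    gates=[float(g) for g in gates],
                    ftr_params=asdict(ftr_params),
                    pattern=asdict(pattern), probe=asdict(probe),
                    links=[])
    for i, link in enumerate(links):
        link_seed = seed + 1000 + i
        curve = simulate_ftpsf(phantom, link, probe, n_histories, link_seed,
                               bin_width=bin_width, max_time=max_time)
        ftr = synthesize_ftr(curve, irf, ftr_params, rng)
        tag = f"r{link.row_index}_c{link.col_index}_R{link.sr_distance:g}"
        write_timecurve(out / f"ftpsf_{tag}.tsv", curve)
        write_timecurve(out / f"ftr_{tag}.tsv", ftr)
        vols = compute_sensitivity_multi(phantom, link, probe, gates,
                                         n_histories, link_seed + 500000)
        with h5py.File(out / f"sens_{tag}.h5", "w") as hf:
            hf.create_dataset("values",
                              data=np.stack([v.values for v in vols]))
            hf.attrs["gates"] = np.asarray([v.gate for v in vols])
            hf.attrs["seed"] = link_seed + 500000
        data["ftpsf"][link.key] = curve
        data["ftr"][link.key] = ftr
        data["sensitivity"][link.key] = vols
        manifest["links"].append(dict(key=list(link.key), seed=link_seed,
                                      sens_seed=link_seed + 500000))
    # FPDF ground truth per gate velocity is a closed-form map of the
    # phantom parameters; consumers recompute it with fpdf_value
    manifest["fpdf_truth_note"] = (
        "fpdf_value(medium, fluor, v) applied to muaf_map/tau_map")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    manifest["data"] = data
    return manifest


def fpdf_truth(phantom: Phantom, v: float) -> np.ndarray:
    """Closed-form FPDF volume for a phantom at one average velocity."""
    f_in = fpdf_value(phantom.medium, phantom.fluor, v)
    return np.where(phantom.fluoro_mask, f_in, 0.0)
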