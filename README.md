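# earlyflt

Early-photon mesoscopic time-domain fluorescence molecular lifetime
tomography (FMLT) on synthetic digital phantoms.

Fluorescence lifetime is the most environment-sensitive parameter a
fluorescent probe reports, but reconstructing its 3D distribution from
time-resolved surface measurements is hard: the fluorescence source term
depends nonlinearly on the lifetime. For photons on the *leading edge* of
the fluorescence temporal point-spread function (FTPSF), the problem
linearizes: a gated measurement at source–detector distance R and delay t
becomes a linear functional of the **fluorescence parameter distribution
function**

    f(r) = 4Dcγ μaf(r) / (v² τ(r) + 4Dc),      v = R/t,

where D and c are the diffusion coefficient and light speed of the
background medium, γ the quantum yield, μaf the fluorophore absorption
coefficient and τ the lifetime. Reconstructing f at three distinct
average photon velocities v and solving the per-voxel overdetermined
system separates μaf(r) and τ(r) directly in the time domain.

The package is aimed at people developing or evaluating mesoscopic
diffuse/fluorescence tomography methods. It provides, as testable
library code plus a thin CLI:

* a voxelized digital phantom and raster-scan geometry (`phantom`);
* a time-resolved fluorescence Monte Carlo with voxel path tracking,
  Henyey–Greenstein scattering, Fresnel boundaries and shadow-ray
  detection scoring, producing FTPSFs and per-voxel sensitivity volumes
  (`mc`);
* synthetic TCSPC responses — IRF convolution, origin shift, Poisson
  counts (`synthetic`) — and the inverse preprocessing chain:
  Savitzky–Golay smoothing, Richardson–Lucy deconvolution, leading-edge
  alignment, gate extraction (`preprocess`);
* the single-gate and constant-velocity measurement strategies,
  calibration and system assembly (`assembly`);
* the ART-FIST-TV reconstruction solver — relaxed Kaczmarz sweeps with
  soft-thresholding and FISTA momentum alternating with total-variation
  descent (`recon`);
* per-voxel damped least-squares parameter separation (`separation`);
* image-quality metrics (Pearson `kcor`, normalized RMS `kdev`), HDF5 /
  NIfTI / TSV / JSON I/O (`metrics_io`), and an end-to-end synthetic
  experiment driver (`pipeline`).

## Worked example

Closed-form FPDF values for the reference phantom (μa = 0.01 mm⁻¹,
μs = 2.63 mm⁻¹, g = 0.62, n = 1.521; fluorophore μaf = 0.01 mm⁻¹,
γ = 0.2, τ = 900 ps) at the constant-velocity strategy's velocities, and
the lifetime recovered from them:

```python
import numpy as np
from earlyflt import (OpticalMedium, FluorophoreProps, VelocitySet,
                      SeparationParams, build_strategy2, fpdf_value,
                      separate_voxel)

medium = OpticalMedium(mua=0.01, mus=2.63, g=0.62, n=1.521)
fluor = FluorophoreProps(muaf=0.01, gamma=0.2, tau=900.0)

strategy = build_strategy2((3.3, 2.2, 1.1), base_gate=200.0)
for entry in strategy.entries:
    print(entry.used_sr_distances, entry.gate_per_distance,
          round(entry.velocity, 4),
          f"f = {fpdf_value(medium, fluor, entry.velocity):.4e}")

v = VelocitySet(strategy.velocities)
f = np.array([fpdf_value(medium, fluor, x) for x in v.v])
muaf, tau, ok = separate_voxel(f, v, medium, fluor.gamma,
                               SeparationParams(omega=0.0))
print(f"recovered muaf = {muaf:.6f} mm^-1, tau = {tau:.3f} ps")
```

prints

```
(3.3, 2.2, 1.1) {3.3: 200, 2.2: 133, 1.1: 66} 0.0165 f = 1.0353e-03
(2.2, 1.1) {2.2: 200, 1.1: 100} 0.011 f = 1.4143e-03
(3.3, 2.2) {3.3: 100, 2.2: 66} 0.033 f = 4.2309e-04
recovered muaf = 0.010000 mm^-1, tau = 900.000 ps
```

— the three gated-velocity FPDF values (1.0e−3, 1.4e−3, 4.2e−4 mm⁻¹ at
quoted precision) and the exact noiseless round trip back to the
fluorophore parameters.

A Monte Carlo FTPSF for the shortest link on a reduced grid:

```python
import numpy as np
from earlyflt import (PhantomConfig, ProbeGeometry, SRLink, make_phantom,
                      simulate_ftpsf)

ph = make_phantom(PhantomConfig(grid_shape=(60, 60, 45), voxel_size=0.25,
                                grid_origin=(-7.5, -7.5, 0.0)))
link = SRLink((-0.55, 0, 0), (0.55, 0, 0), 1.1, 0, 0)
c = simulate_ftpsf(ph, link, ProbeGeometry(), n_histories=100_000, seed=2,
                   max_time=400.0)
nz = np.nonzero(c.values)[0]
print("leading edge at", c.centers[nz[0]], "ps")
```

prints `leading edge at 33.0 ps` — the pulse rises a few tens of
picoseconds after the excitation flash, the two-leg flight time to a
fluorophore a few millimetres deep, and then decays on the scale of the
900-ps lifetime.

The full synthetic experiment (simulate → assemble → reconstruct →
separate) is `earlyflt.run_experiment`, or from the shell
`earlyflt pipeline --config cfg.json --out-dir out/`.

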