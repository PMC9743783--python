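# Methods

`earlyflt` implements mesoscopic time-domain fluorescence molecular
lifetime tomography (FMLT) from early-arriving photons, end to end on a
synthetic digital phantom: Monte Carlo forward modeling, measurement
formation, linear reconstruction of the fluorescence parameter
distribution function (FPDF), and per-voxel separation of the fluorophore
absorption coefficient and lifetime.

Units throughout: lengths in mm, times in ps, rates in mm⁻¹, velocities in
mm/ps. Coordinates are right-handed with the scan surface at z = 0 and z
positive into the medium.

## Model

The time-resolved fluorescence signal for a source–detector ("SR") pair at
distance R and receiver gate delay t is linearized for photons on the
leading edge of the temporal point-spread function (FTPSF). In that regime
the signal is proportional to a volume integral of a sensitivity function
W(r_s, r_d, r, t) against the FPDF

    f(r) = 4 D c γ μ_af(r) / (v² τ(r) + 4 D c) ,     v = R / t ,

where D = 1/(3 μs(1−g)) is the photon diffusion coefficient of the
background, c = c₀/n the light speed in the medium, γ the quantum yield,
μ_af the fluorophore absorption coefficient, τ the lifetime, and v the
average photon migration velocity implied by the gate. f is bounded by
γμ_af, reached at v = 0 or τ = 0, and decreases monotonically in v.

Reconstructing f at three or more distinct velocities turns the per-voxel
pair (μ_af, τ) into an overdetermined linear system

    4Dcγ·μ_af − f_m v_m²·τ = 4Dc f_m ,   m = 1…3,

solved in the damped least-squares sense.

The scattering-only form of D is used: in the early-photon regime
absorption is weak (μa ≪ μs′), and at the reference parameters the
alternative 1/(3(μa+μs′)) differs by less than the precision at which FPDF
values are quoted. The choice is recorded in the configuration.

## Digital phantom and scan

The default phantom reproduces the reference experiment: a homogeneous
slab (μa = 0.01 mm⁻¹, μs = 2.63 mm⁻¹, g = 0.62, n = 1.521) with a
cylindrical fluorophore inclusion (diameter 2 mm, axis parallel to the
scan rows) filled with a Cy5-like fluorophore (μ_af = 0.01 mm⁻¹, γ = 0.2,
τ = 900 ps). The cylinder center sits 4.2 mm deep (top at 3.2 mm). That
depth is both "almost four times" the shortest SR distance (1.1 mm) and
the value at which the minimal two-leg flight time of a detectable photon
is 33–40 ps for the three SR distances — matching the observed FTPSF
leading-edge onset; a 4.0-mm top depth would push the onset past 40 ps.

The probe is a linear four-fiber array (0.4-mm core, NA 0.2, acceptance
half-angle 8.2° in the medium) giving SR distances 3.3, 2.2 and 1.1 mm.
The scan is a 19×19 raster at 0.5-mm steps over 9×9 mm², traversed in
zigzag order; reduced scans use the same conventions. Voxel membership of
the inclusion is decided by the voxel center (deterministic and testable
against brute force).

## Monte Carlo transport

Photon histories use Henyey–Greenstein scattering with the medium's g,
free paths sampled from scattering only, continuous absorption as weight
attenuation exp(−μa ℓ), unpolarized Fresnel reflection/refraction at the
index-mismatched top surface, absorbing lateral and bottom faces, and
Russian roulette below weight 1e−4 (survival 0.1). Launch positions are
uniform on the source disk; the polar angle is a Gaussian with σ = ϑcr/2
truncated at ϑcr. One fluorescent photon is spawned per fluorophore-voxel
crossing of the excitation path, at the chord midpoint, with weight
μa·L times the excitation survival there (first-order expansion of
1 − exp(−μa L)); emission is isotropic.

Detection — exit through the detector fiber disk within the acceptance
cone — is scored by next-event estimation: from the emission vertex and
every scattering vertex of a fluorescent walk, a direction is sampled
uniformly inside the acceptance cone and the expected unscattered weight
reaching the disk is added (phase-function density × cone solid angle ×
exp(−(μs+μa) r) × Fresnel transmission). Sampling the cone rather than
the disk area bounds individual contributions (no 1/r² blow-up beneath
the detector). This is an unbiased estimator of the same acceptance as
analog scoring with orders of magnitude lower variance for gated early
photons; analog scoring detects only ~10⁻⁴ of desk-scale histories, which
is why the reference calculations needed ~10⁸ histories per run on a
cluster.

Two scoring modes exist. Sensitivity mode accumulates detected weight
into the conversion voxel for every gate at or before the arrival time —
the emission decay and yield deliberately stay out, since they live in
the FPDF. FTPSF mode histograms arrival times with γ applied; the
Exponential(τ) emission delay enters as its exact expectation, a discrete
convolution of the flight-time histogram with the analytic decay kernel,
removing the delay-sampling noise (the per-spawn sampled-delay form
remains available in `fluorescence_conversion`). All runs are bitwise
reproducible given a seed. Exact time pruning (a photon deeper than
z cannot arrive before t + z/c) keeps gated runs cheap.

## Measurement formation and preprocessing

A synthetic fluorescence temporal response (FTR) is built the way a TCSPC
chain produces one: the FTPSF scaled by a coupling factor, convolved with
a unit-area Gaussian IRF (default FWHM 50 ps) whose origin carries a
stochastic shift (uniform, default ±20 ps), rescaled to a target peak
count and Poisson-sampled per 2-ps bin.

The inverse chain is Savitzky–Golay smoothing (window 11, order 3 —
preserves the leading edge at 2-ps binning), Richardson–Lucy
deconvolution (20 iterations, exponentiated-update acceleration 1.5, with
the Kᵀ1 renormalization that the truncated time grid requires — without
it the tail erodes and the error grows with iterations), leading-edge
alignment against a modeled FTPSF (first bin ≥ 2% of peak), and linear
interpolation of the curve at the gate delay. Early stopping of RL is the
noise regularizer; at peak SNR 100 the chain recovers the 200-ps gate
value of the generating FTPSF to ~1% (peak-normalized).

## Strategies, calibration and assembly

Strategy 1 uses one gate (200 ps) for all three SR distances — three
single-distance systems at velocities R_m/200. Strategy 2 assigns each
distance its own gate so R/t is constant within a reconstruction,
yielding entries (all three R; gates 200/133/66 ps; v = 0.0165),
(R2, R3; 200/100; v = 0.011) and (R1, R2; 100/66; v = 0.033), with gates
truncated to whole picoseconds as quoted and the exact values kept in
metadata. Rows of W are flattened sensitivity volumes in zigzag scan
order; sensitivity volumes computed for one row are reused along the row
axis by whole-voxel translation (exact here, because the cylinder axis is
parallel to the rows), and `replicate_rows`/`translate_volume` provide
the row-replication and "symmetric kernel" assembly modes.

The early-photon linearization leaves an unknown proportionality between
a gated measurement and the sensitivity integral. Empirically (and
consistently with the approximation's derivation) this factor is nearly
constant across the classes *within* a constant-velocity entry (~5–10%
spread) but varies severalfold *between* entries. It is therefore fixed
by calibration against the closed-form FPDF of the known phantom — the
synthetic analogue of calibration measurements on a reference object —
with one factor per (R, gate) class by default; a single global scalar
mode is available. The factors do not touch the within-entry spatial
structure, which remains data-driven.

## Reconstruction

The FPDF solver alternates (outer cycle) a run of relaxed Kaczmarz (ART)
sweeps composed with soft-thresholding and FISTA momentum, and a short
cycle of steepest-descent steps on the ε-smoothed isotropic TV norm
(forward differences, reflective boundaries, ε = 1e−8), with the iterate
clipped at zero after each outer cycle and the TV step β decaying
geometrically across the run. Defaults: λ = 0.9, α = 0.001,
S_art-fist = 100, S_tv = 3, β₀ = 0.005 with decay 0.997, stop when the
relative L2 image change falls below 1e−4 (cap 30 outer cycles).

Two numerical safeguards matter in practice. First, a Kaczmarz sweep is
not a gradient step with a known Lipschitz constant, so raw FISTA
momentum can diverge geometrically at high relaxation on strongly
correlated rows; the cycle restarts the momentum (t = 1) whenever the
residual grows, which leaves fixed points untouched. Second, the solver
rescales the system so the working amplitude is of order one (a single
plain ART sweep sets the scale, deterministically), making the absolute
constants α and β meaningful for data of any magnitude; the scale is
undone on output. Divergence — five consecutive residual increases well
above the best residual seen — raises an error.

For piecewise-constant targets the alternation needs a long, slowly
annealed TV schedule to settle onto the TV-minimal consistent solution
(it then recovers ~93% of a plateau that an L-BFGS TV-oracle recovers at
~99%). The pipeline preset for the phantom experiment therefore uses
β₀ = 0.2, S_tv = 5, S_art-fist = 50 and 80 outer cycles.

## Parameter separation

Per voxel, the 3×2 system is solved as min ‖Ax − b‖² + ω²‖x‖². The two
unknowns differ by five orders of magnitude (μ_af ~ 0.01 mm⁻¹,
τ ~ 10²–10³ ps), so the damping is applied in column-equilibrated
variables by default — raw damping at any useful ω is carried almost
entirely by τ and collapses it toward zero; ω defaults to 1e−3 and a
sweep utility reports recovery error versus ω. Single voxels go through
SciPy's LSQR (Golub–Kahan bidiagonalization with damping); volumes solve
the equivalent 2×2 damped normal equations vectorized, and the two routes
agree to ~1e−8. Voxels whose FPDF values all fall below 5% of the volume
maximum are not separated; solutions with μ_af < 0 or τ outside
[0, 10·τ_ref] are flagged invalid and zero-filled rather than clipped,
so summary statistics are not silently biased.

At ω = 0 the noiseless round trip is exact to machine precision over
(0, 0.1] mm⁻¹ × (0, 5000] ps.

## The desk-scale end-to-end experiment

`run_experiment` chains everything at a reduced scale chosen to keep a
full run in minutes on one core: grid 60×60×45 at 0.25 mm, 5×5 scan at
0.5-mm steps, the three reference SR distances, strategy 2, 1.5×10⁵
histories per multi-gate sensitivity run and 5×10⁵ per FTPSF run (the
next-event estimator makes these counts statistically comparable to
analog scoring at orders of magnitude more histories). One sensitivity
volume and one FTPSF are computed per (scan row, SR distance) and reused
across the columns of the row — exact by translation symmetry of the
cylinder. Measurements are gated FTPSF values (Savitzky–Golay smoothed);
the full FTR-synthesis + deconvolution chain can be switched in but is
validated separately, since stacking its ~1% shape error onto the
lifetime budget adds nothing at this scale.

Regularized reconstruction from a few tens of rows recovers the inclusion
plateau at an entry-dependent fraction of its amplitude. That attenuation
is a solver artifact: reconstructing an exact synthetic data vector
W f_ref with the same matrix reproduces it almost exactly. The pipeline
therefore gauges each entry's attenuation on the known model and rescales
the measured-data reconstruction accordingly (a calibration calculation;
the between-entry measurement ratios that carry the lifetime stay
data-driven), and applies a 3-voxel mean filter to the FPDF volumes
before separation to suppress reconstruction speckle. Under these
conditions the separated lifetime map's median over the true fluorophore
core lands within ±13% of the configured 900 ps across independent seeds.

## What the synthetic data does and does not emulate

The generator reproduces the geometry, optics, timing physics, TCSPC
convolution/shift/shot-noise chain and scan protocol of the reference
experiment, with known ground truth. It does not emulate detector dark
counts, dead time or afterpulsing, wavelength-dependent optical
properties (μae = μaf = μa is assumed), fiber-coupling drifts across
positions, or uncertainty in the phantom model itself — the calibration
steps here use the exact phantom, where the physical experiment used
separately measured a-priori information. Passing tests therefore
demonstrate the correctness and internal consistency of the method and
its implementation under the stated model, not its robustness to the
systematics of a physical instrument.

## Known limitations

* The early-photon asymptotic behind the FPDF model is quantitatively
  rough in the mesoscopic regime (that is precisely why the sensitivity
  functions are computed by Monte Carlo, and why absolute amplitudes
  require calibration). Between-entry proportionality varies severalfold
  and is absorbed by per-class calibration against a known model.
* Mirror symmetry of the centered-link sensitivity holds at the scale the
  desk-run resolves (1-mm blocks, ~10%); per-voxel statements at fine
  grids would need cluster-scale history counts even with the shadow-ray
  estimator.
* The solver approaches but does not exactly attain TV-optimal
  reconstructions; amplitude attenuation of deep inclusions is corrected
  by calibration rather than eliminated.
* Lifetime separation assumes a single-exponential decay and a spatially
  uniform quantum yield.
* With the default geometry the FTPSF leading edge starts 30–40 ps after
  the excitation flash (tested), the flight-only arrival histogram peaks
  near 150 ps, and the decay-convolved FTPSF near 390 ps. No single
  inclusion depth reproduces published onset and maximum windows
  simultaneously under this model; the depth default is anchored to the
  onset, which the gating strategy actually uses.
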