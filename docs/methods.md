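# Methods

This note documents the models implemented in `alphadose3d`, their
assumptions, the defaults that matter, and what the synthetic phantoms
do and do not emulate.

## Decay chain and kinetics

The ²²⁵Ac chain is represented by five nuclides with half-lives 9.9 d
(²²⁵Ac), 4.8 min (²²¹Fr), 32 ms (²¹⁷At), 45.6 min (²¹³Bi) and 3.72 µs
(²¹³Po), and alpha yields per chain decay of 1, 1, 1, 0.021 and 0.979
(the ²¹³Bi alpha branch is 2.1%; the complement proceeds through the
²¹³Po alpha). Mean alpha energies (5.79, 6.30, 7.07, 5.87, 8.38 MeV)
are standard nuclear-data values shipped as overridable defaults; the
branching-weighted total is 27.49 MeV per chain decay. All internal
times are seconds; configuration strings carry explicit unit suffixes
(`"9.9 d"`, `"32 ms"`) to prevent silent unit mistakes.

Everything faster than ²¹³Bi is treated as in secular equilibrium with
the parent. ²¹³Bi itself is not: nuclear recoil frees it from the
carrier molecule and it redistributes (notably to kidneys) before
decaying. The two-nuclide relation for the activity ratio
r(t) = A_b(t)/A_a(t) after sacrifice,

    r(t) = (r0 − k) e^{−(λ_b − λ_a) t} + k,    k = λ_b/(λ_b − λ_a),

and its algebraic inverse for A_b(0) are exact for a parent/daughter
pair and are verified against numerical integration of the Bateman ODE
system to six significant digits. k ≈ 1.003 for this pair; the code
keeps it distinct from 1 but treats measured ratios within a configurable
tolerance (default 5%) of unity as secular equilibrium, since measured
tumor ratios like 0.97 ± 0.04 are equilibrium within uncertainty. The
free-daughter excess A_b(0) − A_a(0) is clamped at zero with a deficit
flag, because a negative excess (blood) means clearance, not negative
activity.

### Frame-coincidence factor

When a progeny half-life is on the order of the camera frame period,
the parent and daughter alphas can land in the same frame at nearly the
same position and be counted as one event. We model the parent decay
time as uniform within the frame and the daughter delay as exponential,
giving a same-frame probability P = 1 − (1 − e^{−λT})/(λT) and a count
correction 1/(1 − P/m) for m alphas per chain. At T = 40 ms,
t½ = 32 ms, m = 4 this is 1.0902 → 1.09. This is a reconstruction of
the device correction from its stated physical origin: whether spatial
overlap probability enters the device's own derivation is not public,
so the model here is the minimal one consistent with the stated
mechanism, and it is cross-checked internally by Monte Carlo rather
than against an external reference.

## Gamma-counter spectroscopy

Energy windows (defaults: 168–268 keV for ²²¹Fr, 370–510 keV for
²¹³Bi; 175–250 and 385–490 keV for droplet calibration) are fit with a
Gaussian photopeak on a linear background by least squares.
Initialization: center at the window midpoint, width at one sixth of
the window, area from the total minus an endpoint-interpolated
background — robust for single-peak windows. Each window is fit
independently (no shared background model across windows). Net counts
are the fitted Gaussian area, clamped at zero with a flag because
activities are physical; `background_counts` is defined as window total
minus net so the two always partition the window. Activity conversion
divides by branching ratio, detector efficiency and live time, with
Poisson error propagation; efficiency calibration is a least-squares
proportionality through the origin on a known-activity dilution series.

## Alpha dose-point kernel

GATE-style Monte Carlo transport is out of scope; the kernel is built
analytically under the continuous-slowing-down approximation: alphas
travel straight and isotropically, and the energy deposited in a
spherical shell [r, r+dr] by emission j is y_j (E_res,j(r) −
E_res,j(r+dr)), the exact energy its track loses crossing the shell.
Total energy is therefore conserved by construction. Shell dose is
shell energy over shell water mass (1 g/cm³). Secondary electrons
(sub-µm ranges), recoil nuclei, β/γ dose, energy-loss straggling and
angular scattering are all neglected; only alpha emissions contribute,
with progeny in secular equilibrium so the kernel is normalized per
²²⁵Ac chain decay.

The default stopping-power table is generated from the power-law
range–energy relation R(E) = 2.77 E^1.58 µm (E in MeV), calibrated to
standard alpha CSDA ranges in liquid water (~47 µm at 6 MeV, ~85 µm at
8.4 MeV; the implied support radius for the chain is 79.7 µm). The
sub-MeV Bragg region of this synthetic table is only approximate,
which affects the last few µm of track; because the kernel integrates
the table self-consistently, energy conservation and all downstream
dose totals are unaffected by table inaccuracy — only the sub-10-µm
shape of the radial profile is. Users with ICRU 49 / ASTAR data or
Monte Carlo kernels can supply either a replacement table or a complete
voxelized kernel (NPZ container with JSON metadata); imported kernels
are audited for energy conservation and rejected if negative.

Voxel binning tiles the kernel bounding box with subcells no larger
than the radial step, assigns each shell's energy evenly over the
subcells it contains, and block-averages into voxels. Because energy is
assigned shell-by-shell, the voxelized kernel conserves energy to
floating point for any voxel shape, including the strongly anisotropic
39 × 39 × 10 µm imaging grid. The kernel array is explicitly
symmetrized over axis flips to remove accumulation-order round-off.

## DAR dosimetry

Activity per pixel is counts × frame factor / (4 alphas × geometric
efficiency × (1 − pileup loss) × live time), decay-corrected to
sacrifice with the ²²⁵Ac half-life. Calibration defaults (50%
geometric efficiency, 23.8% pileup loss → 38% absolute efficiency,
frame factor 1.09) are device-measured constants consumed as inputs.

The cloning method duplicates one measured slice into a 21-plane
volume (center ± 10 planes at 10 µm, covering the ~80 µm kernel
support) for dose-point-kernel convolution; the sequential method
stacks actually measured neighboring slices. Convolution is linear 3D
FFT convolution with zero padding — tissue mounted in air/OCT absorbs
the escaping dose, and negative FFT round-off is clipped at zero. On a
z-uniform activity distribution the two methods agree to 1e−6 by
construction, which is the method's founding assumption and is tested.
Assembled 3D volumes place each measured 10-µm slice's dose rate on a
z voxel of pitch + thickness (200 + 10 = 210 µm), i.e. each slice
represents its full sampling interval; this convention is recorded in
the volume metadata.

The gamma index uses the standard combined criterion
γ = min √((ΔD/(δ·D_norm))² + (Δr/Δd)²) with defaults δ = 10%,
Δd = 117 µm (three pixels) and local normalization. The default search
visits voxel centers within 3×Δd (a documented `supersample` flag
enables a bilinear subpixel search); the brute-force oracle test widens
the search so the radius restriction cannot bind. The low-dose floor
defaults to 0 — no floor — with a configurable fraction because
conventional gamma analyses often exclude voxels below 10% of maximum.
Pass rates are reported for both γ ≤ 1 and γ < 1, since printed pass
criteria vary between the two conventions.

## Macro-to-micro dosimetry

Organ-level time–dose-rate curves are fit with non-negative
bi-exponentials A₁e^{−µ₁t} + A₂e^{−µ₂t} by plain (unweighted) least
squares; a log-space tail fit seeds the slow component and the residual
seeds the fast one, so a mono-exponential truth collapses cleanly to
A₂ ≈ 0. The total dose is the analytic integral Σ Aᵢ/µᵢ (1 −
e^{−µᵢ·T}) to T = six ²²⁵Ac half-lives (1425.6 h ≈ 59.4 d) — the
parent governs the chain under equilibrium. Extrapolation factors
c_t = D / Ḋ(t) convert a dose-rate snapshot at t (24 h or 168 h) into
total dose voxelwise, assuming the spatial distribution does not
change over time. Uncertainty uses ±1σ parameter modulation
(amplitudes up with rates down, and vice versa), which brackets the
central curve at all times; the resulting factor bounds propagate into
lower/upper dose maps. Only fit-parameter uncertainty is propagated —
DAR counting noise is not folded into the per-voxel bounds. Free-²¹³Bi
dose enters as an organ-level scalar addition
(total = D_Ac (1 + ratio)), never voxelwise, because the bismuth
redistributes and its spatial distribution has decayed away by imaging
time.

## Radiobiology

Linear-quadratic survival with α = 1.8 Gy⁻¹ and β = 0 by default: for
high-LET alpha irradiation α ≫ β, and the α value is a
radiopharmaceutical-specific in-vitro constant consumed from
configuration. Voxel control probability is e^{−n·S(D)} for n cells at
uniform voxel dose D; cell counts are non-negative reals (density
binning), not forced integers. Products over voxels are accumulated in
log space, so a volume TCP of e^{−10⁶} is represented exactly in the
log and reported as 0 in the linear value rather than overflowing.
Before the products, a 5 × 5 erosion band is removed from the edge of
each slice's n > 0 contour (configurable off) to de-sensitize the
result to registration error; erosion can only shrink the voxel set
entering the product. Underdosed voxels are flagged at VCP < 0.95.

De-escalation scales the dose map linearly with injected activity,
holding the spatial distribution fixed, and reports both the mean
slice-TCP (the headline metric — the volume product compounds small
per-slice failure probabilities into pessimistic totals, e.g. fifty
slices at 0.95 give 0.08) and the volume product itself. The smallest
activity reaching a target TCP is found by bisection on the monotone
curve to 0.1 kBq.

## Morphometry

Nuclei segmentation is Otsu threshold → Euclidean distance transform →
watershed from its peaks → area filter; the threshold is relative, so
counts are invariant under intensity rescaling. The published macro's
parameters are not public, so this is a standard re-implementation of
the same pipeline shape. Registration is rigid only (translation +
rotation, MSE objective, coarse angle scan seeded by phase correlation,
Powell refinement); the manual landmark-based affine step used for
fine tumor alignment is interactive by nature and out of scope — an
externally computed transform can be applied instead. Resampled images
are rescaled to preserve their pixel sum to 1e−6, keeping total
activity invariant under interpolation.

Kidney compartment masks (cortex, ISOM/OSOM, IM/Pa, V/Pe) are consumed
as label images; anatomical auto-segmentation is not attempted, and
vasculature must be pre-assigned by the mask author. DrVHs report
per-region differential histograms, cumulative (fraction ≥ dose)
curves, means, and means relative to the first region. Regional
S-value dosimetry distributes a total measured activity over
compartments by measured fractions and sums S-weighted contributions;
merged compartments use the unweighted mean of their published S
values. Per-slice damage QC flags exclude slices from all aggregations.

## Synthetic phantoms

The generators emulate the study's inputs, not its anatomy:

- **Tumor**: ellipsoid with a concentric necrotic core sized to a
  volume fraction (default 0.3), core uptake 0.1 relative to rim 1,
  cell densities 500 (rim) and 10 (core) per voxel — synthetic values
  chosen so TCP transitions fall inside the 0–18.5 kBq range.
- **Kidney**: concentric shells plus a hilar wedge with uptake ratios
  (1, 0.50, 0.88, 1.19); compartment means are exactly proportional
  before noise.
- **Activity scale**: 15 Bq in the default 64³ phantom, set so the
  default tumor receives a ~50 Gy mean dose under the default kinetics
  — the scale at which well-controlled tumors sit at the 18.5 kBq
  reference injection.
- **Counting**: Poisson draws through the exact inverse of the
  calibration model, so the round trip is unbiased.
- **Cohorts**: per-subject lognormal scaling (default CV 30%, the
  dominant uncertainty in measured curves) of shared bi-exponential
  components.

Everything is bit-reproducible under a fixed seed. Not emulated: real
tubule/glomerulus-scale microstructure (where the identical-adjacent-
slices assumption would break), slice damage and folding, registration
mismatch between modalities, detector flat-field structure, and
activity redistribution over time. Passing tests on these phantoms
demonstrate the correctness of the computational chain, not the
biological accuracy of any particular animal result.

## Numerical choices and problem sizes

Images are float32, kinetics and statistics float64. FFT convolution
tolerances are validated against direct double sums at 1e−8. The
demonstration pipeline runs a 64 × 48 × 48 phantom and the end-to-end
recovery test a 64³ phantom — sizes chosen so the full suite and demo
complete in well under a minute each on one CPU while keeping every
compartment several kernel supports wide. Bi-exponential fits bound
parameters non-negative; rate degeneracy (µ₁ = µ₂) is avoided by the
peeling initialization and fast/slow ordering is enforced after the
fit. Bisection and fit tolerances are stated at each API.

## Known limitations

- The CSDA kernel ignores straggling and scattering; its Bragg-region
  shape is approximate unless a measured stopping-power table is
  supplied.
- The frame-coincidence model is a physical reconstruction of a device
  constant, not the manufacturer's derivation.
- c-factor bounds reflect fit-parameter modulation only.
- The gamma search is voxel-centered by default; subpixel agreement
  can be probed with the supersampled search at ~100× cost.
- Rigid-only registration; strongly deformed histology requires an
  external affine/deformable step.
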