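# Methods

This note documents the models, defaults and numerical choices behind
puffsense, and what the synthetic study does and does not demonstrate.

## Forward optics

Droplets are treated as homogeneous non-absorbing spheres. The Mie
partial-wave series is evaluated with the standard stable scheme: the
logarithmic derivative D_n(mx) by downward recurrence (start order
max(n_max, |mx|) + 16), the Riccati–Bessel functions ψ_n(x), χ_n(x) by
upward recurrence, and the series truncated at the Wiscombe order
n_max = x + 4.05 x^{1/3} + 2, which converges the efficiency sums to
better than 1e−9 relative. Tests cross-check against an independent
brute-force implementation built on scipy's spherical Bessel functions with
doubled truncation, against the Rayleigh closed form for x ≤ 0.1, and
against the geometric-optics limit Q_ext → 2.

Key optical parameters:

| parameter | default | unit | rationale |
|---|---|---|---|
| refractive index m | 1.45 + 0i | — | typical 70/30 VG/PG e-liquid; never measured for the study liquid, exposed in config |
| droplet density ρ_p | 1.12 | g/mL | e-liquid density |
| LED bands (center, FWHM) | 370/10, 640/17, 940/50 | nm | the three LEDs of the photometric module |
| band averaging | 21 uniform points across the FWHM | — | only the FWHM is known, so a rectangular line shape is assumed |
| size bins | 100–300–600–1000 | nm | transition points of the three scattering spectra |

The bin-by-wavelength extinction matrix f[i][j] (base-10 attenuation per
(mg/L) per mm of path) is the mass-weighted mean of the per-mass extinction
1.5 Q_ext/(D ρ_p) over each bin; the default within-bin weights come from a
lognormal number distribution with CMD 250 nm, GSD 1.6. With the default
optics the matrix is

    f = [[3.37e-3, 7.38e-4, 2.01e-4],
         [4.73e-3, 2.09e-3, 7.94e-4],
         [2.52e-3, 2.81e-3, 1.67e-3]]   (condition number ≈ 68)

Its rows/columns are strongly correlated — a property of Mie physics at
these bands and bins that matters below.

## Size distributions and reference masses

SMPS-style reduction follows the standard discrete conventions: dN/dlogDp
on a geometric grid (64 channels per decade, 60–1170 nm scan by default),
channel-wise conversion dC = (π/6) D³ ρ_p dN, and bin masses as channel
sums × Δlog10 D × V_box with V_box = 94.6 L, reported in mg. A channel
belongs to bin [lo, hi) by its center (half-open upward). Mass outside
100–1000 nm is carried in the distributions but excluded from binned
masses. Lognormal generators are Hatch–Choate consistent: the mass
distribution of a lognormal number distribution has the same GSD and median
CMD·exp(3 ln² GSD).

## The synthetic puff generator

The generator is the package's stand-in for the vaping machine, sensor and
SMPS reference. Per puff:

1. **Conditions → pressure and flow.** The dilution-box pump produces a
   plateau inhalation pressure ΔP = 2200·(1 − e^{−t_p/100}) Pa from the
   pressurization time t_p (7–150 s → ≈150–1700 Pa). Flow follows an
   orifice law Q = 0.062·ΔP^{1/2} L/min (≈2 L/min at 1 kPa); a linear law is
   configurable. Pressure is constant during the puff plateau.
2. **Conditions → aerosol.** Emission is a two-mode mixture: a main
   accumulation mode (count median 230 nm at 20 W, +6 nm/W, GSD 1.9) and a
   coalescence-grown coarse mode at 1.6× the main mass-median diameter
   (GSD 1.4) holding a varying mass fraction (0.2 ± 0.15). Total emitted
   mass is 5.5 mg at reference conditions, scaling as power^1.5, linearly
   with button duration and as √ΔP. Puff-to-puff jitter: CMD ± 20 nm,
   GSD ± 0.2, mass ± 10% lognormal. The number concentration peaks in the
   100–300 nm range while the mass distribution peaks at several hundred
   nm, and mean bin masses increase M1 < M2 < M3.

   A single lognormal was deliberately rejected: its two shape parameters
   make the aerosol family two-dimensional, in which case two wavelengths
   plus pressure already identify the bin masses and the third wavelength
   is informationless — contradicting the premise of a multi-spectral
   sensor. Real fresh vapour aerosols at these concentrations coagulate
   within seconds, producing exactly the kind of variable coarse-mode
   structure modelled here.
3. **Aerosol → signals.** Bin concentrations follow a smooth trapezoidal
   pulse (0.3 s rise/fall around the button duration), normalized so that
   ∫c_i Q dt equals the drawn bin masses. Attenuations are exactly linear,
   A_j = Σ_i f_ij c_i L with L = 10 mm (differential-path-length factor
   fixed to 1, geometry offset 0), and intensities are I0·10^{−A} with
   0.3% relative Gaussian noise (I0 = 30 000 counts); pressure carries 2 Pa
   Gaussian noise. Optical samples every 44 ms, pressure every 338 ms; the
   first and last 2 s of every record are aerosol-free baseline.
4. **Reference truth.** The attached ground truth is the *measured* truth:
   the true bin masses times lognormal measurement error with an 8% common
   component (dilution-volume uncertainty shared by all bins) and a 6%
   per-bin component (scan and bin-reduction error). This matches the error
   budget of a dilution-box + SMPS reference chain and sets the ~10%
   irreducible floor that dominates the study-scale regression errors. The
   `NOISELESS` spec zeroes all four noise sources, which the exact
   forward/inverse round-trip tests rely on.

**Condition schedules.** The 100 training puffs cycle the three parameters
as triangles with periods 8 (power 15–25 W), 6 (duration 1.5–3 s) and 10
puffs (pressurization 7–150 s, log-ramped), so each parameter sweeps its
full range and the combinations oscillate. The 10 held-out puffs use a
half-step phase shift: every individual parameter stays strictly inside the
training range but no combination repeats.

All randomness flows from one seed through `numpy.random.SeedSequence`
substreams (one per puff, one per pipeline stage), so every artifact is
bit-reproducible.

## Signal processing

Baseline intensities are the first-2 s means; ambient pressure is the
final-2 s mean. Intensities are floored at 1e−6·I0 before the log so noise
cannot produce non-finite attenuation. Pressure is linearly interpolated
onto the 44 ms optical grid (no extrapolation outside the recorded span).
The effective window is bounded by the first upward and last downward
crossing of 0.1× the red-channel maximum, located by linear interpolation
between samples; extra crossings from noisy shoulders are logged and
subsumed. AUCs are trapezoidal integrals with interpolated window
endpoints; ΔP̄ is the arithmetic mean of the samples inside the window.
The window channel, threshold and noise floor (0.02 attenuation) are
configurable.

## The regressor

A 4 → H → 3 feedforward network, tanh hidden layer (logistic selectable)
and linear output; H = 8 by default, giving 8·4 + 8 + 3·8 + 3 = 67
parameters. Inputs and outputs are min–max normalized to [−1, 1] on the
training split. Training minimizes the summed squared normalized residual
with Levenberg–Marquardt: exact per-sample backprop Jacobian,
(JᵀJ + μI)δ = −Jᵀr with μ starting at 1e−3, ×10 on rejection, ×0.1 on
acceptance, stop on μ > 1e10, gradient < 1e−10, 6 non-improving validation
epochs, or the epoch cap (300 by default); the returned parameters are
those of the best validation epoch. The 85/15 split is a seeded
permutation. Initialization is Nguyen–Widrow-style on the normalized range.

At study scale (85 training puffs for 67 parameters) a single LM run is
multistart-sensitive, so `SizeBinnedMassModel.fit` runs 5 restarts over a
common split and keeps the lowest-validation-MSE run. `train_lm` itself
remains a single documented LM run.

## Evaluation conventions

Per-bin statistics over n puffs: MSE (mg²), MRE (fraction, zero-target
samples excluded with a warning), MBE (mg) with the residual defined as
**target minus prediction** — a positive MBE means the model
underpredicts — and the bias ratio 100·MBE/mean(target) in percent.
Accuracy is reported as 100·(1 − MRE). The identity
MSE = MBE² + Var(residual) is asserted in tests.

## What the synthetic study shows — and what it cannot

With the default generator, ten replicated 100 + 10-puff studies give
median held-out MREs of roughly 16%/10%/8% for M1/M2/M3 — the intended
operating regime of the method, dominated by the simulated reference
uncertainty, with M1 additionally limited by the conditioning of the
optical inversion (the smallest masses ride on the largest extinction-matrix
amplification). Single-wavelength models degrade their test MSE by factors
of 5–6, confirming that wavelength contrast carries the size information.

One caveat is intrinsic to the reduced linear attenuation model used
throughout (A = Σ f_ij c_i L): at these three bands and bins the extinction
matrix is so strongly correlated that the red channel contributes only a
few percent of signal not already present in UV + IR. Within this model a
UV+IR two-wavelength configuration is therefore informationally almost
equivalent to the full three-wavelength sensor, and simulated ablations
cannot reproduce a systematic three-versus-two-wavelength advantage; any
such advantage observed on hardware must involve effects outside the
reduced model (path-length modification by multiple scattering,
wavelength-dependent absorption of the liquid, geometry factors), which are
deliberately out of scope here. Other non-goals: coagulation/evaporation
dynamics during transit, channel-flow CFD, polarization-resolved
scattering, multiply-charged-particle SMPS corrections, and hardware
timing/dark-signal emulation.

Problem sizes throughout (100 + 10 puffs per study, 10 study replicates,
64-channel decade grids, 21-point band quadrature) are the package's
defaults and reproduce in seconds on a laptop.
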