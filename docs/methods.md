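# Methods note

This note records the forward model, the inversion chain, the generator's
study conditions, and the numerical and design choices behind `hydromap`,
with their rationale and known limitations.

## 1. Forward model

All scans are ideally spoiled gradient-echo (GRE) steady-state magnitude
images:

```
S = g · b1r · W · sin(b1t·α) · (1 − E1) / (1 − cos(b1t·α)·E1) · exp(−TE/T2*)
E1 = exp(−TR/T1)
```

with `W` water content, `g` a global scanner gain, `b1t`/`b1r` the
multiplicative transmit/receive field maps, and nominal flip angle `α`.
Assumptions: perfect spoiling, mono-exponential T2\* decay, no motion, no
chemical shift, no slice-profile effects.

### Protocol (defaults)

| scan | TR (ms) | TE (ms) | flip (°) | notes |
|---|---|---|---|---|
| PD-weighted | 1800 | 5.2 | 40 | the scan that is corrected and calibrated |
| T1-weighting | 500 | 5.2 | 90 | pairs with the PD scan for T1 inversion |
| B1+ series (×4, EPI) | 20000 | 11 | 30/60/90/120 | TR ≫ T1 isolates sin(b1t·α) |
| receive pair (×2) | 500 | 5.2 | 40 | array vs. body coil, 2× lower resolution |
| multi-echo GRE (8 echoes) | 35 | 2.3 + k·2.27 | 12 | T2\* relaxometry |

The B1+ series is simulated fully relaxed (saturation-free, TR 20 s) — the
series' purpose is the flip-angle scaling, and modelling an EPI readout
would add nothing the inversion uses. Low-resolution scans are
block-averaged then nearest-neighbour upsampled. Noise is zero-mean
Gaussian on the magnitude with SD = `noise_sd` × mean brain signal per
echo (default 0.02, i.e. SNR 50), clipped at zero; Rician noise is
available by flag. Gaussian-with-clipping was chosen as default because at
SNR 50 the Rician bias in brain is negligible and the Gaussian model keeps
the noiseless limit exactly linear.

## 2. Phantom and cohort generator

The phantom is a set of nested ellipsoids at 64³ voxels of 3 mm (head span
~190 mm): a CSF rim, a GM shell, a WM core, and two ellipsoidal lateral
ventricles (pure CSF). Probability maps are one-hot: every voxel is pure
by construction; partial-volume effects enter only through the low-
resolution receive scans and smoothing. Class truth values (defaults):

| class | water (% pure water) | T1 (ms) | T2* (ms) |
|---|---|---|---|
| WM | 71.46 | 900 | 50 |
| GM | 82.93 | 1400 | 60 |
| CSF | 100 (fixed) | 4000 | 200 |

Water defaults are the control-group values the generator emulates; T1/T2\*
are 3 T literature-scale values. CSF is the calibration reference, so its
water content admits no offset or between-subject variation (enforced).

Cohort structure: two groups (`hd`, `control`) × `n_per_group` subjects ×
two timepoints. HD subjects receive group offsets (+1.43 WM, +1.49 GM
percentage points) plus a per-subject Gaussian random effect
(between-subject SD 1.06 WM, 1.00 GM); each HD subject also has a parietal
water deviation (SD 0.8) to which dialysis vintage (mean 44.5 months,
SD 20, clipped at 1) and intradialytic weight change (mean −1.5 kg,
SD 0.8) are correlated (r = +0.69 / −0.74) by Gaussian construction.
These SDs and offsets are the *study conditions*: with n = 10 the standard
error of a group-mean water value is ~0.34 points, so recovered group
means scatter by several tenths of a point across master seeds. That is a
property of the design, not of the estimator (see §6 of the README and the
acceptance discussion below).

B1 fields are Gaussian-filtered white noise (correlation length 60 mm),
zero-mean over the brain, scaled to a peak deviation of ±15 %.

Limitations of realism: no anatomy beyond nested ellipsoids, no
within-class texture by default, no motion/flow/susceptibility, one-hot
probabilities (a real segmentation is itself uncertain), and covariates
correlated to a single regional deviation rather than a physiological
model.

## 3. Correction chain

1. **B1+**: per-voxel least squares of `S(α) = A·sin(b·α)` by dense grid
   search over b ∈ [0.3, 1.7] (step 0.001, analytic amplitude, parabolic
   refinement of the minimum), followed by 24 mm-FWHM masked Gaussian
   smoothing (B1 is physically smooth; smoothing suppresses fit noise).
2. **T2\***: weighted log-linear regression of `ln(S_k/S_0)` on TE.
   Weights ∝ S² are the Gauss–Markov choice for log-transformed additive
   noise. Regressing on the first-echo *ratio* makes the slope exactly
   invariant to a global gain (bitwise for power-of-two gains). Voxels
   with non-positive samples are fitted on their positive prefix (≥3
   echoes) or flagged; non-decaying voxels are capped at 2000 ms and
   flagged.
3. **T1**: bracketed vectorized bisection on the two-scan ratio
   `R(T1) = f(1800, 40·b1t) / f(500, 90·b1t)` on [100, 6000] ms to 0.1 ms;
   monotonicity of R is asserted at run time over the observed b1t range;
   out-of-range ratios are clamped to the bracket end and flagged.
4. **Receive field**: smoothed (15 mm FWHM) array/body ratio,
   mean-normalized to 1; body-coil values below 5 % of the in-mask median
   are excluded from the smoothing support.
5. **Combined correction**: the PD scan is divided by
   `b1r·sin(b1t·α)·(1−E1)/(1−cos(b1t·α)·E1)` and multiplied by
   `exp(TE/T2*)`; near-zero denominators are excluded via a validity mask.
6. **Residual bias**: homomorphic estimation in the log domain. The log
   map is first decomposed into 3 piecewise-constant class levels (1-D
   k-means with quantile initialization — deterministic), because directly
   smoothing the log map with a 60 mm kernel over a ~190 mm head would
   flatten genuine WM/GM contrast by several percent and violate the
   step's own identity contract. The class-residual is smoothed (60 mm
   FWHM, brain-masked, normalized convolution) to give the bias field,
   which is divided out mean-preservingly. Two robustness refinements:
   residual outliers beyond 3×1.4826×MAD (mostly partial-volume voxels
   between classes) are excluded from the smoothing support, and the
   estimate is iterated (≤3 passes) to recover the kernel's attenuation of
   genuinely smooth bias. Contracts verified by tests: identity within
   0.2 % on bias-free input; removal of a 0.1-amplitude field much
   smoother than the kernel to within 1 %.
7. **CSF normalization**: the ventricle mask is eroded by one voxel
   (partial-volume guard; ≥20 voxels required), and the map scaled so the
   eroded-region mean is exactly 100 %.

### Pooled reference-region relaxometry

Per-voxel T1/T2\* estimates inside the small ventricular reference are
noisy, and they enter the calibration factor nonlinearly (via 1/f(T1)), so
at SNR 50 they bias *every* tissue value by ~−0.2 points. Since the
reference is one homogeneous compartment, the chain instead fits a single
T1 (Brent root-finding on the ratio of region-mean signals) and a single
T2\* (log-linear fit on region-mean echoes) and applies them within the
eroded reference. Operating on ratios of means keeps the step exactly
gain-invariant. Residual tissue bias after this fix is below 0.15 points
(6-seed Monte-Carlo).

### Gain invariance

The whole chain is built from ratio forms and mean-normalizations so that
a global gain applied to all scans cancels *bitwise* for power-of-two
gains (and to ~1e-12 relatively otherwise). This is asserted in the tests
with `np.array_equal`.

## 4. Classification and ROI statistics

Pure voxels (any tissue probability = 1; CSF excluded by default) are
classified by a 2-component full-covariance Gaussian mixture on
(water, T1/10) — the rescaling gives both coordinates comparable spread.
EM uses 5 initializations and a seeded RNG; classes are relabelled in
ascending water order (WM, GM). Per-subject class means are the global
tissue water values.

The synthetic atlas contains four lobe sectors (frontal/parietal/temporal/
occipital quadrants), a mid-sagittal corpus-callosum slab (pure WM) and a
periventricular shell, blurred to probabilistic boundaries. ROI masking
follows two rules, both covered by boundary tests: probability ≥ 0.75
(inclusive) and tissue fraction within the ROI > 7 % (strict).

## 5. Statistics

- Wilcoxon rank-sum: exact null enumeration for n ≤ 12 without ties
  (verified against full combinatorial enumeration), tie-corrected normal
  approximation otherwise.
- Two-sample t-tests from summary statistics (pooled variance), Fisher
  exact tests — used for demographic-table reproduction.
- Linear mixed model `outcome ~ group + time + group:time (+ covariates)`
  with subject random intercepts, fitted by REML (the convention when the
  estimator is unstated); unbalanced repeated measures are handled by the
  likelihood. Singular random-effect fits and non-convergence are flagged;
  a Shapiro–Wilk residual-normality p accompanies each fit. Null
  calibration: type-I error at n = 10/group over 300 seeded simulations is
  0.060–0.067 per fixed effect, inside the 0.05 ± 0.02 band (Wald tests
  are mildly anti-conservative at this size; this is inherent to the
  method, not a defect).
- Cohen's d (pooled SD, no small-sample correction) with bands
  small/medium/large at 0.3/0.5/0.9 (inclusive upward); Bonferroni
  `min(1, p·m)` applied per effect across outcomes.

## 6. Seeding and determinism

A master seed spawns per-subject, per-scan, per-stage sub-seeds through
hashed `numpy` seed sequences (all < 2³¹), so adding a subject or scan
never perturbs any other noise stream, and identical config + seed gives a
byte-identical summary JSON (tested). The mixture fit, k-means and all
noise draws are seeded.

## 7. Acceptance status

Five of the six acceptance properties pass. The end-to-end recovery test
(group WM/GM class means within ±0.5 points of 71.46/82.93 at n = 10,
master seed 1) is red on WM by 0.054 points: the seed-1 cohort's *true*
WM mean is 71.86 (a 1.2 σ draw of the subject random effects), and the
pipeline tracks it to +0.15. The band is a ~1.5 σ check under the
prescribed study conditions and fails ~15 % of seeds by design; the seed,
band and generator SDs were fixed before measurement and have not been
adjusted. GM passes (83.28 vs 82.93 ± 0.5).
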