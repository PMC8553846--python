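# Methods

This note records the models implemented in spinflex, the conventions
and defaults behind them, what the synthetic generators do and do not
emulate, and the numerical choices a maintainer would want to know.

## Units and conventions

Delays and relaxation periods are seconds; rates and ν_CPMG are s⁻¹;
chemical shifts are ppm; static fields are quoted as the ¹H frequency in
MHz; spin-lock fields and offsets are Hz. Conversions happen only at the
I/O boundary. Residue numbering always follows the input file. Shift
differences are converted ppm → rad/s as
Δω = Δδ × 10⁻⁶ × |γ_X/γ_H| × (2π × ν_H), with |γ_C/γ_H| = 0.25145 and
|γ_N/γ_H| = 0.10133 (these truncate to the CSP weights 0.251 and 0.101).

## Relaxation fitting

The decay model is strictly mono-exponential, I(t) = I₀e^(−Rt); no
multi-exponential alternative is offered. Start values are analytic and
deterministic: I₀ from the maximum intensity, R from a log-linear
regression over the positive intensities. Peak-height errors carry a 2%
floor — an error smaller than 2% of the height is replaced by it.

Rate uncertainties are Monte Carlo: each of n_mc = 500 replicates (both
the count and the floor are configurable) resamples every intensity from
a Gaussian centred on the **measured** value with width equal to its
error, and the SD of the replicate estimates is the reported error.
Resampling around the measured points rather than the fitted curve is a
deliberate convention choice; the two differ slightly and the tests
calibrate the implemented one against a brute-force re-simulation
(fresh noise around the true curve, refit, repeat), agreeing within 15%
when the comparison is averaged over measured datasets — the error
conditional on a single dataset scatters by roughly ±8% around that.

R₁ρ → R₂ uses R₂ = R₁ρ/sin²θ − R₁/tan²θ with θ = tan⁻¹(ω/Ω), errors by
first-order propagation with R₁ρ and R₁ independent. One
`SpinLockSettings` per experiment is used; the run summary records
whether the offset was global or per-residue. The helical-baseline flag
("enhanced ps–ns dynamics") requires R₁ > mean + k·SD **and**
NOE < mean − k·SD over the annotated helical residues (k defaults to 2,
at least five helical residues required); it is invariant under constant
shifts of either profile.

## Chemical-shift perturbations

CSP = √(Δδ_H² + (W·Δδ_X)²), with the weight chosen by the atom-label
class (amide → W_N, methyl → W_C), never guessed from shift ranges.
Unweighted Δδ values are kept signed (condition 2 − condition 1);
thresholding uses magnitudes. The significance threshold is

  trimmed_mean + sigma_factor × SD(trimmed set)

where the trim removes ⌊n × trim_fraction⌋ values from **each** tail and
the SD is the sample SD of the trimmed set. "10% trimmed" is ambiguous
in common usage (per-tail vs total, σ of full vs trimmed set); the
per-tail/trimmed-σ convention implemented here is recorded in every
output so alternates can be compared. With trim_fraction = 0 the rule
reduces exactly to mean + sigma_factor·SD. On pure-noise profiles the
rule flags a small nominal tail (empirically ≈ 5–15% of residues at the
1.5σ default); significance calls are therefore meaningful only for
perturbations well above the noise scale, which is how they are used.

Peaks present in only one condition are reported "not comparable",
never as CSP = 0. When a probe has several resonances in one condition,
the major state (largest |height|) defines its position; minor states
remain listed in the input table.

## Multi-state populations

Clusters are fit as sums of separable 2D Lorentzians
A / [(1+((x−x₀)/w_x)²)(1+((y−y₀)/w_y)²)] with per-component position,
HWHM linewidths and amplitude, by bounded least squares from
user-supplied (or generator-supplied) initial positions. The default
population measure is the analytic component volume A·π²·w_x·w_y over
the total — heights are biased for overlapped components — with a
height mode behind a flag. Populations are sorted descending, sum to
one by construction, and are invariant under uniform intensity scaling.
Vanishing fitted amplitudes or non-convergence raise with diagnostics.

## CPMG dispersion

R₂,eff(ν) = −ln(I(ν)/I₀)/T_relax. Replicated ν points are pooled: value
= mean, error = SD of the replicate R₂,eff values **floored at the
pooled (RMS) replicate SD**; non-replicated points get the pooled SD.
The pooled-variance estimator is used for the floor because the median
of a handful of 1-degree-of-freedom pair SDs is biased low and a single
near-zero pair SD would otherwise dominate a weighted fit. Non-positive
intensities are dropped with a warning. Rex defaults to the R₂,eff
endpoint difference (lowest minus highest ν) with quadrature error and
an explicit metadata caveat that endpoint subtraction underestimates
the Rex error; the literal intensity-difference reading is available
behind a flag.

The two-state models propagate the coherence exactly. Each CPMG cycle is
τ–180°–2τ–180°–τ with τ = T_relax/(4n) and n = ν·T_relax cycles (n must
be integral within tolerance; each cycle holds two refocusing pulses).
Evolution blocks are 2×2 complex matrices combining exchange
(k_AB = p_b·k_ex, k_BA = (1−p_b)·k_ex) with the minor-state precession
offset; matrix exponentials use the closed 2×2 form written in terms of
the eigenvalue exponentials so strongly damped blocks cannot overflow.
For MQ coherence the offset is Δω_H + Δω_C in one branch and
Δω_H − Δω_C in the other, and each ¹³C 180° pulse conjugates only the
carbon part, i.e. swaps the branches; the detected signal is the
major-state coherence from an equilibrium start, normalized by its
initial value and averaged over the two starting branches (an HMQC
creates both). For SQ coherence the pulses conjugate the full phase.
R₂,eff adds the exchange-free baseline R₂,₀ analytically.

Two consequences of exact propagation are worth noting. First, R₂,eff
carries a finite-cycle contribution from the projection of the initial
condition onto the decaying modes; it scales as 1/T_relax, so R₂,eff is
invariant to the choice of T_relax only asymptotically (differences of
a few tenths of s⁻¹ between T = 20 and 40 ms at identical ν are real).
Second, the Carver–Richards closed form is the asymptotic
(dominant-eigenvalue) rate: it matches propagation to < 0.05 s⁻¹ only
once the cycle count is large (tests pin this in the many-cycle
regime), and deviates by up to ~1 s⁻¹ at one or two cycles in slow
exchange. Both the MQ and SQ production models therefore use numerical
propagation; Carver–Richards and its Luz–Meiboom fast-exchange limit
serve as independent analytic cross-checks.

### Global fitting

Curves are grouped with shared k_ex and p_b; Δω is shared per probe
(Δω_C ≥ 0 because its sign is unidentifiable from CPMG alone — the
model is invariant under a simultaneous sign flip of (Δω_C, Δω_H) — and
the relative sign of Δω_H is left free for MQ probes); R₂,₀ is per
probe × field. Weights are 1/σ²(R₂,eff). The baselines enter the model
additively and are profiled out analytically at every objective
evaluation (variable projection); the remaining nonlinear parameters
are minimized at each point of a 9-point log-spaced k_ex grid (default
span 100–1600 s⁻¹), warm-starting each inner fit from the previous grid
point while always retaining two fresh starts so one bad basin cannot
poison the profile, and the profile minimum is refined parabolically in
log k_ex. This profile-likelihood construction was chosen after joint
descent over all parameters proved unreliable: the (k_ex, p_b, Δω)
valley is long, curved and — in deep slow exchange — multimodal.

The k_ex uncertainty is read from the curvature of the χ² profile
(Δχ² = 1), inflated by √(reduced χ²) when that exceeds one (the
replicate-derived weights are themselves noisy); other parameter errors
come from the full finite-difference covariance at the optimum. A fit
driven to the p_b bound or with negligible model dispersion is flagged
"no detectable exchange" rather than reported as a rate. Failure to fit
a group jointly is a reportable outcome, not an exception: with real
multistate exchange a shared two-state (k_ex, p_b) simply may not exist,
and the reduced χ² carries that evidence.

## Synthetic generators and presets

Each generator draws from an independent substream keyed on
(seed, stream label), so adding a generator or reordering calls never
perturbs other fixtures, and fixed seeds are bit-reproducible.

The generators emulate the statistical structure the analysis assumes:
Gaussian intensity noise proportional to the reference intensity (2%
default, matching the error floor), independent noise on replicate ν
points, Lorentzian lineshapes with volumes proportional to populations,
and Gaussian shift noise in the paired-condition tables. They do **not**
emulate raw FIDs, truncation/apodization artifacts, baseline distortion,
peak-picking errors, ¹H–¹H cross-relaxation during the CPMG period, or
temperature/field drift — so passing recovery tests demonstrates the
correctness and calibration of the estimators under the assumed noise
model, not robustness to every pathology of real spectra.

Preset generating truths are literature-printed values: k_ex = 390 s⁻¹
(two MQ methyl probes, two fields), k_ex = 356 s⁻¹ (one MQ + one SQ
probe), L48a populations 86/7/7 (K⁺) and 47/37/16 (Na⁺), N68 NOE 0.43
(K⁺). The ν_CPMG grids and constant-time periods are the experimental
designs (K⁺ MQ: T = 20 ms, 50–1000 Hz with duplicates at 200 and
600 Hz; Na⁺ MQ: T = 30 ms, 33.33–1000 Hz with three duplicated points;
Na⁺ ¹H SQ: T = 20 ms, 50–1000 Hz), as are the R₁ delay grids and the
1923 Hz spin lock. Everything else is assumed and labelled as such in
the preset metadata: p_b = 0.05, R₂,₀ = 20 s⁻¹, and per-probe shift
differences Δω_C = 1.0 / 0.35 ppm and Δω_H = 0.01–0.02 ppm for the MQ
probes and Δω_H = 0.15 ppm for the SQ probe. These assumed values were
chosen once, on two grounds: (i) realism — the V64-like probe's
endpoint Rex at 18.8 T is ≈ 15 s⁻¹ and the V59-like probe's ≈ 7 s⁻¹,
matching the observed exchange contributions; a much larger methyl
Δω_H would add a non-refocusable static broadening to the MQ curves
that the observed deep dispersions exclude; and (ii) identifiability —
with 2% noise the exchange must sit in the slow-to-intermediate regime
(k_ex within a factor of a few of Δω_C) for a pairwise fit to determine
k_ex with a standard error of the order the literature reports (±47 and
±67 s⁻¹); the presets yield calibrated standard errors of ~50–100 s⁻¹.
Assumed parameters are never used as recovery targets.

## Problem sizes

Recovery checks run at the experimental design sizes: 19–22 unique ν
points per curve, two probes × two fields per exchange fit, 96×96
cluster grids, 5-delay decays, and Monte Carlo calibration with 500
package replicates against a 10,000-replicate brute-force reference.

## Known limitations

- Two-state exchange only; evidence for more states surfaces as poor
  reduced χ², not as a multistate fit.
- Exchange-free R₂,₀ is assumed equal for both exchanging states.
- The MQ model treats the methyl as an isolated ¹H–¹³C pair coherence;
  relaxation interference within the methyl group is absorbed into
  R₂,₀.
- Per-residue spin-lock offsets are supported only through a global
  `SpinLockSettings` per experiment run.
- The population deconvolution requires user-supplied component counts
  and starting positions; it does not pick peaks.
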