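# Methods

## Scope and rationale

The package implements, against synthetic data, the analysis chain of an
MEG study of implicit suicidal associations: S-IAT D-score scoring,
dynamic-causal-model (DCM) inversion of cross-spectral densities (CSDs)
under a canonical-microcircuit (CMC) neural mass model over early visual
cortex (EV, −2 −92 −4), amygdala (AM, −20 −10 −30) and insula (IN, −50 10
2; MNI mm), fixed-effects model selection over four architectures,
parametric empirical Bayes (PEB) at the group level, and a Gaussian
non-overlap classifier. Sensor-level MEG processing (filtering, artifact
rejection, source localization) is out of scope; the analysis boundary is
the region-by-region CSD.

## Behavioral model

Each synthetic run has eight blocks: four single-category blocks (24
trials each) and four critical blocks (28 trials each) in which the
life/death and me/not-me categories are pooled, giving exactly 56 self-life
and 56 self-death critical trials. RTs are lognormal around a median of
800 ms with log-SD 0.25 — the standard positively skewed RT family; the
study reports no RT distributions, so these are generic values for a
word-categorization task. Inter-trial intervals (uniform 1.5–2.5 s) are
recorded but unused downstream. Accuracy is Bernoulli(0.95) independent of
condition; error trials are retained in scoring by default (a
`correct_only` flag restricts to correct trials), since the emulated
scoring procedure defines no error penalty.

Each subject's true D is drawn from the group Normal (HV: −0.297, SD 0.44;
SC: −0.083, SD 0.32). The generator then pins the realized condition means
to grand ± Δ/2 with Δ² = D²·SSw/(n−1−nD²/4) (SSw the pooled
within-condition sum of squares), which makes the empirical D equal the
drawn D exactly rather than only in expectation. Draws are clamped at
|D| = 1.9 where the construction becomes singular (≈3.6 SD events at the
HV defaults). The D-score sign convention is: positive D ⇔ faster
self-death responses, i.e. D = (mean RT self-life − mean RT
self-death)/SD(critical), with the SD using denominator n−1.

The one-sample Wilcoxon signed-rank test drops exact zeros, uses
average-rank ties with the tie-corrected normal-approximation Z (no
continuity correction), and computes two-sided p by exact enumeration of
all 2^n sign assignments for n ≤ 12.

## CMC forward model

Each region contains SS, SP, II and DP populations. Population p obeys a
second-order kernel, v̈ₚ = κₚ(uₚ − 2v̇ₚ/κₚ... written in first-order form
v̇ = i, i̇ = κ(u − 2i) − κ²v, with κ = 1/τ and synaptic time constants
τ = 4, 4, 16, 28 ms for SS, SP, II, DP. Presynaptic drive passes through
the sigmoid S(v) = 1/(1+e^(−ρv)) − 1/2 with slope ρ = 2/3 (zero output,
slope ρ/4, at rest). The ten intrinsic connections (a fast SS↔SP loop, a
slower II/DP loop, inhibitory self-connections on every population) ship
as a versioned `IntrinsicWiring` table. The default weights were
calibrated once so that, at prior means, the three-region system is stable
(slowest eigenvalue real part ≈ −27 s⁻¹; ~1% instability under 0.35-SD
log-parameter perturbations), and exhibits an alpha-range (~8 Hz) and a
gamma-range (~45 Hz) resonance inside the fitted 1–58 Hz band — the band
of interest for the task effects being emulated.

Extrinsic connections follow the laminar rule: forward = source SP →
target SS (base scale 1600 s⁻¹) and target DP (800); backward = source DP
→ target SP (−1600) and target II (−800). All strengths are base ×
exp(log-scaling parameter), hence positive; trial modulation multiplies an
edge's strengths by exp(B) on self-death trials. The extrinsic base scale
was set so that connected regions show non-trivial coherence
(~0.05–0.15 at prior means) against equal-amplitude independent
per-region innovations; an order of magnitude lower and extrinsic and
modulatory parameters are practically unidentifiable from CSDs.

Four architectures over {EV, AM, IN}: Model 1 forward EV→AM, EV→IN, AM→IN;
Model 2 EV→AM, EV→IN, IN→AM; Model 3 EV→AM, AM→IN; Model 4 EV→IN, IN→AM —
each fully reciprocated by backward edges. EV receives the exogenous
stimulus (a Gaussian bump, default latency 80 ms, width 16 ms), used by
the time-domain simulator only.

Spectral prediction linearizes at the quiescent fixed point (exact here:
the sigmoid output and the mean stochastic drive are both zero at rest)
and returns CSD(f) = H G_u H* + G_n, where H(f) = L(2πif·I − A)⁻¹C maps
per-region innovations entering SS to gain-scaled SP depolarizations.
Innovations and channel noise have power-law-plus-floor spectra
a(f^(−b) + c) with shared parameters across regions; the channel floor is
calibrated to ~1% of mean neuronal power at prior means. Predictions are
Hermitian and positive semidefinite by construction; an eigenvalue with
positive real part raises a stability error. The time-domain integrator
(Heun, dt ≤ 1 ms; innovations colored by FFT to match G_u one-sided PSD)
agrees with the transfer-function auto-spectra within 10% across the band,
which is the main correctness oracle tying the two routes together.

## Inversion

Real and imaginary parts of the upper-triangular CSD entries for both
conditions form the prediction-error vector (1044 elements at 58
frequencies, 3 regions, 2 conditions). Observation precision has one
estimated log-precision per region applied to a fixed within-component
envelope 1/(S_ii S_jj) — the scaling of cross-spectral sampling error — so
the residual is effectively relative rather than absolute. Priors: zero
mean log-scalings with variance 1/16 (extrinsic, modulatory, amplitudes,
gains), 1/64 (intrinsic gain, spectral exponents), 1/128 (rate constants).
Gauss–Newton steps on the Laplace free energy F with Levenberg–Marquardt
damping; steps are accepted only when F increases, log-precisions are
updated by bounded Newton steps within each iteration, and convergence is
declared when ΔF < 0.01 nats over 4 consecutive accepted steps (cap 128
iterations). Initialization is at the prior mean; `restarts=N` adds seeded
jittered starts with best-F selection. Unstable candidate parameters are
rejected by the damping loop rather than terminating the fit.

The per-region fit metric is the Pearson correlation between predicted and
observed auto-spectral magnitudes stacked across conditions.

## Group level

Fixed-effects model selection sums per-subject F per architecture and
reports the argmax, with exact ties reported rather than broken. PEB
models first-level parameters (extrinsic + modulatory subset by default)
as θᵢ = (xᵢ⊗I)β + εᵢ with design columns [1, group]; first-level posterior
covariances propagate into the marginal likelihood, the scalar
between-subject variance is optimized by bounded scalar search on the
exact Gaussian marginal evidence, and β carries an independent N(0, 1)
prior per entry — weakly informative on the sub-unity log-scaling effects
of interest. A tighter (first-level-style, 1/16) prior would shrink a
4-subject group contrast by ~20%, which is why the wider prior is the
default. Per-entry posterior probabilities come from Bayesian model
reduction: the log-evidence change from pinning one β entry to zero
(prior variance 10⁻¹⁰), mapped through a softmax under equal model priors;
Pp > 0.95 is the reporting threshold.

## Classifier

For a chosen parameter, the control density is N(HV sample mean, HV
sample variance, n−1 denominator); each case contributes its own
first-level posterior density for that parameter. The distance is
non-overlap = 1 − ∫min(pdf₁, pdf₂), computed in closed form from the
intersection points of the two Gaussians (validated against adaptive
quadrature to 10⁻⁶). Per-case "sensitivity" is reported as the continuous
non-overlap percentage — four cases yield four values and their mean,
rounded half away from zero — because the reported per-connection values
behave like continuous percentages rather than binary rates over four
cases; a thresholded binary reading is available via a flag. Specificity
is exact leave-one-out fold arithmetic in controls: a held-out control's
posterior density (symmetric with the case treatment) is compared to the
control density of the remaining n−1 at the same 0.95 non-overlap
threshold.

## Synthetic second-level truths

The built-in `default_group_truth()` fixes per-connection group-average
effects (forward EV→AM SP–SS −0.3035 and SP–DP −0.2287, their trial
modulation −0.4451, plus four sub-threshold effects of magnitude
0.07–0.14) and group differences (forward EV→IN SP–SS −0.5904, backward
AM→EV DP–SP +0.5477), with between-subject SD 0.1 and first-level
posterior variance 0.05 — values at which the strong effects exceed
Pp 0.95 at the 21+4 cohort size while the sub-threshold ones do not.
Cross-spectral observation noise defaults to 0.1 of the local spectral
scale √(S_ii S_jj), the sampling error of an estimate averaged over ~100
trials — commensurate with the 112 critical trials of a run.

## Problem sizes

The test suite and the acceptance script run at the study's native sizes
where cheap (50 × 21-subject behavioral cohorts; 20 × 25-subject PEB
cohorts) and at deliberately reduced sizes where inversion cost dominates:
six subjects for the full modulation-recovery loop and five single-subject
replicates per generating architecture for selection consistency. These
sizes give comfortable statistical margins for the properties checked
(selection log-evidence gaps are hundreds of nats; modulation recovery
scatter is ~0.05 per subject).

## What passing does and does not show

The generators share the forward model with the estimators, so recovery
results demonstrate internal consistency of the inference chain —
identifiability at realistic noise, absence of systematic bias beyond
prior shrinkage, calibration of Pp thresholding — not robustness to the
mismatch between a neural mass model and real MEG. Real cross-spectra
carry non-Gaussian, frequency-correlated estimation error, head-model and
source-leakage confounds, and between-subject heterogeneity in intrinsic
dynamics, none of which the noise model emulates. Group-level numbers
built into the truths are recovered by construction up to shrinkage and
sampling error; matching them validates the estimator, not the science of
any particular dataset.

## Known limitations

* Convolution-based CMC only; no conductance-based (receptor-channel)
  variant, and no evoked-response fitting beyond the bump-driven
  simulator.
* One DCM per subject with condition modulations; separate per-condition
  inversions are not supported.
* The classifier is univariate per parameter by design; no joint densities.
* Fixed-effects model selection only (no random-effects exceedance
  probabilities).
* LOOCV specificity at n = 21 is quantized to multiples of 1/21; reported
  values are exact fold arithmetic.
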