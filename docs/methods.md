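# Methods

## Signal model

The simulated experiment is a 2D inversion-recovery MRF-FISP acquisition:
an adiabatic inversion (modeled as instantaneous, efficiency 1.0 by
default), a delay TI = 20 ms, then a train of T = 400 excitations with
TR = 10 ms and TE = 5 ms. RF phase is constant (FISP convention — no
quadratic RF spoiling), so every rotation is about a fixed transverse axis.
Time is in seconds everywhere inside the library; milliseconds appear only
at CLI/config boundaries. The recorded fingerprint is the complex
isochromat-average transverse magnetization at each echo time, scaled by the
complex proton density M0; linearity in M0 is exact and exploited for the
analytic M0 columns of the Jacobian.

**Flip-angle train.** The published sequence's flip schedule is not
reproduced in print, so the default is a documented stand-in: two smooth
sinusoidal lobes with 70° maximum flip (`make_flip_schedule`, kind
`sinusoidal`). Any explicit schedule can be supplied instead. Absolute CRB
levels and steady-state contrast therefore differ from the published
sequence; all comparisons in this package are internal to one schedule, so
every conclusion is about the estimation strategy, not the sequence.

**Spoiling and slice profile.** Intravoxel spoiling is modeled by an
isochromat ensemble whose spoiler phase per TR is linear in slice position
with 14.6π span across the slice-profile FWHM (and proportionally more in
the tails — the linear-extension reading). The excitation profile is the
small-flip-angle approximation: the magnitude-normalized Fourier transform
of the Hamming-apodized sinc envelope (time-bandwidth 4, 1 ms), sampled at
the isochromat positions; the reference configuration places 600 of 1324
isochromats uniformly between the FWHM points, tails extending 2 FWHM per
side. Desk-scale runs use a 264-isochromat ensemble (120 in the FWHM),
which matches the 1324-isochromat reference to ~1% relative RMS and is 5×
cheaper; dense CSF sampling (5300 isochromats) is available via the
`n_total` override for T2 > 1 s.

**EPG oracle.** An independent extended-phase-graph recursion (ideal
unbalanced spoiling, no slice profile) serves as cross-check: with uniform
2π dephasing and more isochromats than populated dephasing orders the two
simulators agree to machine precision, and the constant-flip limit
reproduces the Freeman–Hill SSFP-FID steady state analytically.

## Noise and CRB conventions

Measurement noise is additive white complex Gaussian with i.i.d. real and
imaginary parts of standard deviation σ per channel, and SNR := |M0|/σ. One
convention is used everywhere (simulation, CRB, losses, evaluation) and a
unit test locks it. Fisher information for real parameters of the complex
model is I = Re(JᴴJ)/σ²; the complex scale enters as two nuisance
parameters (Re M0, Im M0) — the magnitude/phase parameterization is avoided
because of its singularity at M0 → 0 — and CRBs are diagonal elements of
the full inverse with nuisance rows masked out. T1/T2 Jacobian columns are
central finite differences with relative step 1e-4 (Richardson-checked);
M0 columns are analytic. CRBs are computed once at σ = 1 and rescaled as σ²
when the SNR is randomized, which is exact because b ∝ σ².

CRBs are computed **post-compression** (from UᴴJ), i.e. for the measurement
the network actually sees; the full-signal alternative is available via
`crb` on the uncompressed Jacobian. Orthonormality of U keeps white noise
white with the same per-channel σ in coefficient space, so noise may be
added post-compression (statistically identical to pre-compression).

## Dictionary, subspace, training data

The default grids are the published three tissue blocks (ranges in ms,
min:step:max, cartesian product per block): grey/white matter T1
500:2:1500 × T2 10:0.38:200, fat 250:2.4:550 × 60:0.65:140, CSF
3000:16:5000 × 1500:8.1:2500 — 282,249 atoms by that arithmetic. The
temporal basis is the SVD of the noiseless dictionary, rank 10, with each
singular vector's phase fixed (largest-magnitude entry real-positive) for
cross-platform reproducibility. Desk-scale runs coarsen the grey/white
matter block to 25 ms × 5 ms steps (1,599 atoms).

Training batches hold Nr noise realizations per sample at a per-sample σ
drawn via SNR ~ Uniform(10, 50) — the published open interval with the
least-informative bounded distribution — re-randomized every epoch and
shared across that sample's realizations. The train/test split is a random
80/20 by sample with the split seed recorded.

## Loss family and gradients

See the README for the WVCB definition. Numerical choices: the sample
covariance/variance is uncorrected (divide by Nr), matching the
decomposition identity and the evaluation convention; δ = 1 by default
(δ = 1.01 is exposed to compensate the sample-variance noise at Nr = 200
but is not default); gradients flow through both the sample mean and the
variance term (no stop-gradient); the variance hinge takes subgradient 0 at
its kink. The δ = 0 equivalence with the bias-constrained loss carries an
overall factor λ; the per-parameter form is matched literally and the
factor is documented and tested rather than absorbed. Off-diagonal
covariance penalties are not implemented (per-parameter form only); a
full-matrix weighting path exists for the weighted-MSE/bias-constrained
losses.

## Network and training

Architecture: inputs are the real and imaginary parts of the r = 10
subspace coefficients (20 features, raw — no input normalization by
default; a documented knob exists), two fully connected hidden layers with
ReLU and affine batch normalization, and two outputs constrained by ReLUs
clamped above at 5 s (lower bound 0 from the rectifier). At width 300 this
is 98,402 trainable parameters. Batch statistics are used during training
and exponentially-averaged running statistics at inference, so inference is
deterministic and batch-size independent. Because no deep-learning
framework is assumed, forward, backward (through batch norm and the hinged
loss) and ADAM are implemented in numpy and gradient-checked against finite
differences.

Protocol: stage-0 trains with λ = 0, Nr = 1 until the validation loss
improves < 0.1% over a patience window (the "to convergence" criterion),
capped; both branches start from identical stage-0 weights. Published
branch settings: Bias-Reduced Nr = 200, λ = 1, δ = 1, 500 epochs, batch
256; MSE-CRB Nr = 1, 500 epochs, batch 51,200; ADAM, learning rate 1e-4.
Note that with Nr = 1 the sample variance is identically zero, so the
MSE-CRB branch optimizes the CRB-weighted squared error regardless of λ.
Training data use M0 = 1 (real); an optional phase-alignment preprocessing
(largest coefficient rotated real-positive) exists and is off by default.

**Desk scale** (`DeskScaleConfig`): width 64, Nr = 50, 100 branch epochs,
MSE-CRB batch 2,048, stage-0 cap 1,200 epochs, learning rate 1e-3. The
published rate (1e-4) suits a 300-wide network taking ~450k optimizer
steps; at desk scale the step budget is ~100× smaller and 1e-3 reaches the
same convergence regime within it (chosen while tuning stage-0 convergence,
before any bias/variance comparison was run). The output-layer bias is
initialized at min(0.5, cap/2) so the capped output ReLUs start inside
their active range.

## Reference estimators

Dictionary matching maximizes |⟨d_i, y⟩|/‖d_i‖ over the (compressed)
dictionary — the discretized maximum-likelihood estimator — with
m0 = ⟨d_i, y⟩/‖d_i‖² and ties broken to the lowest index. NLLS minimizes
the compressed-domain residual over (T1, T2) with Levenberg-Marquardt,
solving the complex scale in closed form per iterate (variable projection);
bounded fits fall back to the trust-region reflective solver.

## Evaluation

Monte-Carlo reports use the uncorrected sample variance so evaluation and
loss agree. Each test point draws its noise from a substream keyed by
(master seed, point index): adding points never perturbs existing rows.
Population summaries use log-spaced bins (edges recorded), medians, the
fraction of points with variance ≤ δ·CRB, Wilcoxon signed-rank between
paired CRB-weighted squared-bias vectors and Welch's t-test per sweep
point. Identical estimators are reported as p = 1 (no detectable
difference) rather than passed to the rank test, which is undefined at
all-zero differences.

## What the synthetic world does and does not establish

The generator emulates the published simulation study: noiseless
model-generated fingerprints plus white complex Gaussian noise, uniform
B1+, no B0 dynamics, no reconstruction artifacts, training and test data
from the same grid family. A green desk-scale run establishes that the
WVCB-trained network reduces parameter bias relative to MSE-CRB training at
variance at or below the CRB *under the model's own assumptions*. It does
not establish robustness to model mismatch (unmodeled compartments,
non-Gaussian residuals after regularized reconstruction, B0/B1 deviations),
absolute performance of the published sequence (the flip train is a
stand-in), or full-scale behaviour (281k-atom dictionary, width-300
network, Nr = 200).

## Known limitations

* Single-compartment relaxometry only; no magnetization-transfer/qMT
  two-pool model, no B0 off-resonance, no finite RF duration inside the TR
  loop, no k-space/image reconstruction.
* Finite-difference Jacobians cost four extra dictionary passes; fine for
  desk scale, the dominant cost at full scale.
* The numpy trainer is single-threaded; full-scale (width 300, Nr = 200,
  500 epochs, 225k samples) is out of desk-scale reach by design.
* Dictionary matching at desk scale benefits from the coarse grid matching
  the evaluation grid exactly; its near-zero on-grid bias is a property of
  that alignment, not of the estimator off-grid (see the off-grid T2
  report in the acceptance suite).
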