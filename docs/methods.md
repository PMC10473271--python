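# Methods

## Model and assumptions

`arrowtime` treats nonreversibility of a multivariate time series as a
classification problem: if a classifier can tell a window of the signal
from its time-reversed copy on *held-out participants*, the underlying
dynamics break detailed balance. The approach assumes (i) the series is
approximately stationary within a recording after band-pass filtering and
per-region z-scoring, (ii) direction information, if present, is
expressed within windows of the chosen length, and (iii) participants are
exchangeable draws from a condition, so that participant-disjoint splits
measure generalisable direction information rather than memorised
idiosyncrasy.

The reversibility index of a window combines the classifier's two margins,

    R(t) = [(o_f(2) − o_f(1)) + (o_b(1) − o_b(2))] / 2 ,

clipped to zero when either pattern is misclassified, so R ∈ [0, 1] and is
antitone under blurring of the outputs toward indifference. Per
participant we report the mean of R over windows (nonreversibility) and
its population (n-denominator) standard deviation over windows
(second-order nonstationarity). Condition-level values average the
per-participant means; group contrasts are pairwise two-sided Wilcoxon
rank-sum tests with Benjamini–Hochberg FDR over the explicit pair family,
with the rank-biserial correlation r = 2U/(n₁n₂) − 1 as effect size (no
canonical effect-size choice exists for this statistic; ours is stated and
configurable).

## Direction classifier

Input *N·w* (flattened region-major), ten fully connected layers of
2048, 1024, 512, 256, 128, 64, 32, 16, 8, 4 units — each linear map
followed by batch normalization (ε = 10⁻⁵) then ReLU — and a final linear
pair with softmax. Class coding: output 1 backward, output 2 forward.
Training: Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸), learning rate 10⁻³, L2
weight decay 10⁻⁴ on weights only, minibatch 128, exactly 10 epochs, one
dataset shuffle before the first epoch, Glorot-uniform initialization.
There is no early stopping; validation metrics are recorded but never
acted on. After the last step, batch-norm statistics are finalized as
population moments from a layer-by-layer pass over the training set, so
evaluation does not depend on the lag of running averages. Everything is
float32 numpy, single-threaded, and bit-deterministic given the seed.

Two behaviours of this estimator at small sample sizes matter for
interpretation. First, softmax *margins* saturate with optimizer steps:
with ~150 minibatch updates (a 20-participant cohort) a perfectly
classified separable cohort reaches mean R ≈ 0.85 rather than 1.0, even
though held-out accuracy is 1.0; the saturated R → 1 regime needs the
step counts of study-scale cohorts (hundreds of participants). Second,
nets trained on data with little or no direction signal still produce
confidently random outputs on held-out windows, and the clipping makes
their contribution positive: the mean R of an exactly reversible process
is a small positive floor (~0.1 at this scale), not zero. Both effects
are properties of the margin-based statistic, which is why reversible
baselines should always be compared against the label-randomization null
band rather than against literal zero, and why weak irreversibility
levels adjacent in ground truth may not be resolved in rank order at
desk-scale cohort sizes.

## Synthetic testbed

The generator is a multivariate Ornstein–Uhlenbeck process
dx = −Ax dt + √2 dW with A = S + κK, where S = QᵀQ/n + I (Q standard
normal) is symmetric positive definite and K is a random antisymmetric
matrix of unit spectral norm. Eigenvalues of A have real part ≥
λ_min(S) > 0 for every κ, so stability holds by construction, and with
isotropic noise the process satisfies detailed balance iff κ = 0 — κ is a
continuous ground-truth irreversibility knob with comparable scale across
seeds. Oracles: the stationary covariance Σ solves AΣ + ΣAᵀ = 2D; the
lagged covariance is C(τ) with C_ij(τ) = E[x_i(t)x_j(t+τ)], equal to
(e^{−Aτ}Σ)ᵀ; its normalized asymmetry is the population value of the
empirical lagged-FC asymmetry; and the exact Gaussian KL divergence
between a forward window and its reversal (block-Toeplitz construction,
`window_direction_kl`) upper-bounds what any direction classifier can
achieve at a given window size.

Sampling uses the exact Gaussian transition of the OU process at the
recording interval (x_{t+1} = e^{−A·dt} x_t + η with
Cov(η) = Σ − e^{−A·dt} Σ e^{−Aᵀ·dt}, stationary start), rather than
Euler–Maruyama substepping: the Euler scheme's stationary covariance
carries an O(dt‖A‖) bias that would contaminate covariance- and
asymmetry-convergence checks at the few-percent level, while the exact
transition is unbiased at any recording rate. The recording interval
defaults to dt = 0.2, giving lag-1 autocorrelations of roughly 0.4–0.8
across modes — smooth, TR-sampled-looking series for which a lag of ~3
samples shows clear but incomplete autocorrelation decay.

Degenerate fixtures bracket the R scale: `make_ramp_series` (strictly
monotone drift, random slope per region, optional white noise in units of
the mean per-step drift) is linearly separable at zero noise — the
maximal-irreversibility limit; `make_noise_series` (iid Gaussian) has
exactly exchangeable forward/reversed windows — the reversible null.
Cohorts built from GroupSpec lists share one (S, K) pair across groups of
equal dimension, so the between-group ordering of ground-truth
irreversibility is exactly the ordering of κ. Discrete entropy production
H_P = Σ_ij P_ij log(P_ij/P_ji) is computed on the pair-frequency (joint)
distribution of transitions with a strictly positive pseudocount: under
joint normalization it is a true KL divergence between forward and
reversed transition statistics — nonnegative, zero for detailed-balanced
chains, finite always — whereas a row-conditional normalization admits
negative values. Continuous signals are discretized by equal-occupancy
(quantile) binning per region, which is invariant to monotone amplitude
changes.

What the generator does *not* emulate: hemodynamic convolution, spatial
parcel geometry, physiological noise structure, non-Gaussian or
non-stationary dynamics, and head-motion artefacts. Passing tests on this
testbed therefore validate the estimators' statistical machinery (window
bookkeeping, split hygiene, calibration against analytic ground truth),
not the physiological interpretation of R on real BOLD data.

## Preprocessing

Band-pass filtering uses a second-order Butterworth (default
0.008–0.08 Hz) applied forward–backward (`sosfiltfilt`, odd-reflection
padding up to three slow-edge settling lengths, capped by series length).
Zero-phase application is deliberate: one-directional filtering imposes a
phase lag that is itself a temporal asymmetry, which a direction
classifier could exploit as a preprocessing artefact. The squared
magnitude response (relative to a single pass) is accepted in exchange.
Filtering then time-reversing agrees with reversing then filtering up to
boundary transients of order 10⁻³ of the signal scale. Series are
z-scored per region over the whole recording (not per window) before
windowing, so the classifier sees temporal structure rather than
amplitude differences; windows are flattened region-major, and the order
is serialized with every trained model and enforced at prediction time.

## Windowing and splits

Windows start at 0, s, 2s, … while start + w ≤ T, giving
⌊(T − w)/s⌋ + 1 windows; every window contributes exactly one forward and
one backward pattern, so direction labels are balanced by construction.
All series of a dataset are truncated to a common length from timepoint 0,
and conditions must contribute equal participant counts (balance is
enforced at build time). Splits are at the participant level — no window
of an evaluation participant is ever seen in training — with the
evaluation set ⌊n·fraction⌋ (minimum 1) participants; for cohorts whose
conditions contain different participants (case/control designs) the
split stratifies by condition. For small cohorts the recommended
estimator (`pipeline.condition_mean_R`) repeats the
split–train–evaluate cycle over several shuffles and averages, since a
single 10% hold-out of 20 participants is two people.

## Analysis presets

Two acquisition presets bundle defaults: `hcp` (TR 0.72 s, truncation to
176 samples, global/system w = 20 shift 3, node w = 150 shift 2, lagged-FC
delay τ = 3 TRs) and `ucla` (TR 2 s, 152 samples, global w = 10 shift 1,
node w = 20 shift 1, τ chosen at run time). When τ is not fixed it is the
smallest lag at which the mean regional autocorrelation drops below 0.5,
capped (with a warning) at a configurable maximum. Window-level lagged FC
uses the valid overlap of length w − τ with per-window standardization;
windows shorter than τ + 3 are rejected.

## Detailed-balance functionals

The literal mean of FC(τ) − FC(τ)ᵀ is identically zero for any matrix
(the difference is antisymmetric), so the global asymmetry is defined as
the mean *absolute* off-diagonal difference, with mean-of-squares as an
option — only nonnegative functionals of the antisymmetric part are
informative. Node flows are F_in(i) = Σ_j FC_ij(τ) (row sum) and
F_out(i) = Σ_j FC_ji(τ) (column sum); their totals cancel exactly in every
window, and the node asymmetry |F_out − F_in| is transpose- and
permutation-consistent. Conditioning on reversibility takes windows below
the 0.25 and above the 0.75 R-quantiles (thresholds configurable), requires
a minimum of 10 windows per set, and compares the low/high asymmetry
distributions by rank-sum.

## Condition classification

Features are one row per (participant, condition) — e.g. per-network mean
R — and the classifier is a one-vs-one ensemble of K(K−1)/2 RBF-kernel
SVMs with per-feature standardization fit on the training fold only
(kernel scale and box constraint at library defaults; no canonical values
exist for this feature family and both are exposed). Evaluation uses
stratified 90/10 splits repeated 100 times — stratification guarantees
every class in every fold at these row counts — and reports the averaged
row-normalized confusion matrix; the headline number is the mean of its
diagonal (the mean per-repeat accuracy is also recorded). Chance level is
estimated by permuting labels across rows and rerunning the repeated
evaluation; the permutation-averaged null mean and a 95% percentile
interval are reported, with an empirical p-value for an observed accuracy.

## Problem sizes and numerical choices

Synthetic validations run at desk scale on one CPU: cohorts of 20
participants per condition with 10 regions and 176 timepoints (window 20,
shift 3) for classifier-based checks; 2·10⁵ recorded samples for
covariance/asymmetry convergence against the closed-form oracles; 100 × 8
feature rows with 100 repeated splits (and 20 permutations) for the
condition classifier; 500 replicates for type-I-error calibration of the
group statistics. Lyapunov solutions are symmetrized and verified by
residual; transition-noise Cholesky factors get a 10⁻¹² jitter; simplex
inputs to R are validated to 10⁻⁶; rank-sum tests use the normal
approximation. Degenerate inputs (windows longer than the series,
zero-variance regions, constant R traces, classes with fewer than two
rows, participants appearing on both sides of a split) raise errors that
name the offending unit rather than degrading silently.

## Known limitations

Mean R is not an absolute physical quantity: it depends on window size,
cohort size and optimizer budget through margin saturation and the
overfit floor described above, so comparisons are only meaningful within
a matched pipeline configuration, against the label-randomization null.
Very weak irreversibility (asymmetries of order 0.02 in normalized lagged
covariance) is detectable in principle at these window sizes (the exact
window KL is ~0.45 nats) but not reliably recovered by the classifier at
20-participant scale. The discrete entropy-production estimate depends on
the binning resolution and pseudocount and should be read as a relative,
not absolute, rate. The condition classifier's accuracy reflects the
separability of the supplied feature table; it performs no feature
selection.
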