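# Methods

## Model and assumptions

Activity behavior is modeled at two levels. At the *motor sentence* level a
first-order Markov chain over Q activity primitives governs which activity
is performed when: prior vector π (π_i = Pr(X(t₀) = S_i)) and row-stochastic
transition matrix **A** (a_ij = Pr(X(t_n)=S_j | X(t_{n-1})=S_i)). At the
*emission* level each state produces one feature vector per data frame
through a Gaussian mixture p(**x** | S_i) = Σ_m c_im N(**x**; μ_im, Σ_im)
with full covariances and Σ_m c_im = 1. Together these form a
continuous-emission HMM. The first-order assumption means activity duration
is implicitly geometric; no semi-Markov duration modeling is attempted.

The single-frame baseline (GMM classifier) uses the identical emission
densities and assigns each frame to the class with the highest
class-conditional density — no prior weighting, so the comparison between
the sequential and single-frame classifiers isolates exactly the value of
the chain.

## Windowing and features

Recordings are segmented into frames of constant width with
step = round(width·(1−overlap)); trailing samples that do not fill a frame
are dropped, and no padding is ever introduced. Defaults follow the study
conditions the package emulates: 512-sample frames at 76.25 Hz (≈6.7 s) for
the seven-activity setting and 64-sample frames at 250 Hz (≈256 ms) for the
sit-stand-walk setting — both rounded to powers of two for FFT convenience.
When per-sample annotations are present a frame takes the majority label;
any frame that touches an annotated transition zone (or whose majority vote
ties) is labeled `transition` and excluded from supervised estimation,
since its true state is genuinely mixed.

Per frame and channel: DC = sample mean; energy = Σ_{k≥1}|X_k|²/N over the
non-DC bins of the frame's N-point transform (so sum(x²) = N·DC² + energy
exactly, by Parseval); spectral entropy = differential Shannon entropy of a
Gaussian KDE fitted to the unit-sum-normalized non-DC magnitude
coefficients. Correlation features are the entries of the frame covariance
matrix (mean-removed channel dot products / width), self-pairs included —
this is what makes the counts 55 (10 channels) and 6 (3 channels) come out.

KDE details: Silverman bandwidth 0.9·min(sd, IQR/1.34)·n^{-1/5}, floored at
1e-4 on the unit-sum coefficient scale. The floor keeps near-degenerate
spectra (a pure tone concentrates all mass in one bin, driving the plug-in
bandwidth to zero) at a finite, strongly negative entropy instead of
producing unbounded values; the integration grid is refined to at least four
points per bandwidth so the trapezoidal entropy integral is accurate. The
unit-sum normalization makes the feature invariant to amplitude scaling of
the frame. Energy is normalized by frame width; this affects only the scale
of the feature, not any classification decision.

## Feature selection

The floating search (SFFS-SFBS) adds, at each step, the feature that
maximizes same-class compactness — the negative mean Euclidean distance
between same-class feature vectors, computed on standardized features — and
conditionally removes features whenever the reduced subset beats the best
subset previously recorded at that size. The search runs until every feature
has entered the candidate set, so the recorded trace covers sizes 1..d.
A k-NN cross-validated accuracy (k = 5, 10 stratified folds by default;
the criterion's constants are configurable and not load-bearing) then
arbitrates: the minimal-size subset maximizing accuracy wins, ties going to
the smaller size and then lexicographic order. Features are standardized
before distances and PCA because the families live on incommensurate scales
(g, g², nats). PCA is an eigendecomposition of the standardized sample
covariance; kept components are the smallest count reaching the requested
variance fraction, enabling either pure rotation (keep all) or reduction.

## Two-level training

Level 1 (supervised): with labeled sequences, (π, **A**) are counting
estimates (â_ij = N_{i→j}/N_{i→·}, pooled over sequences) and each state's
mixture is fitted on that state's frames — closed form for M = 1, EM with
k-means++ seeding otherwise (200 iterations max, relative tolerance 1e-8).
Covariance eigenvalues are floored at 1e-6 to survive small per-state frame
counts. States with no outgoing transitions get a one-hot self-loop and a
warning. Frames labeled `transition`/`garbage`/`unknown` or flagged
spurious are excluded from counts and fits; removing them concatenates
their neighbors in the transition counting, a second-order effect at the
contamination rates considered.

Level 2 (Baum-Welch): EM re-estimation initialized at the level-1
parameters, pooled over the training sequences, in the log domain with
log-sum-exp throughout (64-sample frames with 13-15 densities underflow
linear-domain arithmetic). By default only (π, **A**) are updated and the
emissions stay frozen — the refinement the two-level design aims at — with
`update="all"` available to re-estimate emissions too. Iteration stops at
max_iter or when the total log-likelihood improves by less than tol
(relative); a decrease beyond round-off raises, and the per-iteration
history is returned for inspection.

Decoding is standard log-domain Viterbi; exact score ties resolve to the
lowest state index. Rejected frames are skipped (no emission term,
transition structure unchanged) and then filled with the previous retained
frame's decoded label — "skip-and-stitch" as the computation, carry-forward
only for the output labels; leading rejected frames take the first retained
label.

## Rejection

The rejection statistic is max_i log p(**x** | S_i); a frame is spurious
when the statistic falls below Th (thresholding log densities is
monotone-equivalent to thresholding raw densities). The ROC uses spurious
as the positive class: Se = fraction of truly spurious frames rejected,
Sp = fraction of genuine frames retained, evaluated on the sorted unique
statistic values. The selected threshold is the largest grid value at which
Sp ≥ Se — the point just before the Se/Sp crossing, where specificity is
slightly greater than sensitivity. In leave-one-subject-out evaluation the
threshold is selected per fold from the training subjects only. Accuracy
"after rejection" excludes rejected frames from the denominator by default;
a strict mode that keeps rejected genuine frames as errors is available.

## Synthetic data

The generator exists because the recordings behind the original studies are
not redistributable; it reproduces the *statistical structure* the pipeline
needs, not biomechanics. Each activity has an emission spec: per-channel
gravity-projection DC baseline, gait harmonics (e.g. walking 2 Hz + 4 Hz,
running 2.8 Hz + 5.6 Hz) with random phase, and cross-correlated Gaussian
noise. The seven default specs are separable with a deliberate overlap
between climbing stairs (1.8/3.6 Hz) and walking (2/4 Hz), so the dominant
synthetic confusion mirrors the stairs-vs-walking confusion real systems
show. Garbage frames come from a distinct "unknown activity" spec
(0.7/3.3 Hz), not pure noise, because real spurious data are unmodeled
activities, not sensor noise.

Virtual experiments sample a state path of T = 300 frames from the
benchmark seven-activity chain and emit, per state, frames drawn with
replacement from per-subject pools of N ∈ [18, 58] frames; 20 experiments
per subject is the default. Garbage is interspersed at uniformly random
positions at 1 garbage : 3 genuine frames (25 % of the total). Because the
two natural readings of a "1 : 3 proportion" differ, `garbage_mode`
switches to the one-third-of-total reading (50 % more garbage) when wanted.
Per-subject style factors (DC scale ~ N(1, 0.05), harmonic amplitude scale
~ N(1, 0.08)) create between-subject variability; for low-noise postures
this shift is many within-state standard deviations, so cross-subject
generalization is genuinely hard in the synthetic world too — rejection
thresholds tuned on other subjects can over-reject a held-out subject,
which is the synthetic analogue of the anomalous-subject effect seen in
real data.

The sit-stand-walk generator produces a continuous 15 s, 250 Hz, 3-channel
recording: the gravity projection rotates smoothly (logistic blend, ≈0.8 s,
jittered) from the sitting to the standing orientation, then gait harmonics
ramp in; annotations mark sit / transition / stand / transition / walk.

The benchmark transition matrix ships with a known defect: its first row
sums to 1.20 as printed. The default repair zeroes the implausible
lying→cycling entry (0.20), restoring an exact sum of 1.00 with a single
minimal correction; full row renormalization is available as an alternative.
Priors are not specified by the benchmark and default to uniform.

What passing the synthetic tests does **not** show: robustness to real
sensor artifacts (drift, saturation, placement variation), realistic gait
spectra, or realistic transition dynamics. The generator validates the
algorithmic pipeline, no more.

## Evaluation protocol and problem sizes

Leave-one-subject-out throughout: models, and the rejection threshold, are
computed from the training subjects only. Without rejection every frame
counts and garbage frames are necessarily errors. Reported per-subject
accuracies aggregate that subject's test frames; mean ± sd is across
subjects.

The automated checks scale the simulations to desk size as the package's
own choice of problem size: transition-matrix recovery uses 20 sequences of
T = 300 (the virtual-experiment setting); the sequential-vs-single-frame
comparison uses 20 replicates of 4 subjects × 2 sequences × 150 frames with
state means 1.5σ apart and a 0.85-diagonal chain; the rejection-benefit
check uses 20 replicates of the full signal pipeline with 128-sample frames
at 32 Hz, pools of 30 frames, 3 training experiments and 1 test experiment
of T = 200 at 1:3 contamination. Tolerances for stochastic recoveries are
derived from binomial standard errors at the expected state occupancies
(rarely visited states — stationary mass ≈ 0.02 — carry proportionally
wider bounds); spot checks on well-occupied entries use absolute bounds.

## Known limitations

* Geometric state durations (first-order chain); no duration modeling.
* The floating search's two criteria (distance compactness inside the
  search, k-NN accuracy across subset sizes) are one defensible split of an
  under-specified procedure; other splits are possible.
* Level-2 Baum-Welch runs pooled across training subjects; per-subject
  adaptation is out of scope.
* No automated outlier-subject exclusion.
* The synthetic emission specs are declared stand-ins; no acceptance
  property depends on their physiological realism.
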