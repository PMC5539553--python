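# Methods

## Signals and data model

The unit of analysis is a fixed-length multi-channel epoch: by default 3 s
at 500 Hz (N = 1500 samples) on a 30-electrode 10–20 montage (mastoid
references and ground excluded). A session is a balanced two-class
collection of epochs — 40 resting epochs segmented from a 90-s baseline
with 3-s windows and 1-s overlap (44 candidate windows; the earliest 40
are kept, a deterministic convention since which 40 are used is otherwise
arbitrary), and 40 task epochs. Continuous recordings are zero-phase
band-pass filtered 0.5–100 Hz (order-4 Butterworth, applied forward and
backward) before segmentation. The native storage format is one delimited
matrix per trial plus a JSON sidecar (sampling rate, channel names,
labels, task); EDF is read-only convenience via `mne` when present.
Sample indexing is 0-based internally; 1-based formulas are translated at
the API boundary.

## Grassberger–Procaccia fractal dimension (GPFD)

The epoch is delay-embedded with delay τ (samples) and embedding dimension
M; `Np = N − (M−1)τ` reconstructed vectors result. The correlation
integral C(r) is the fraction of *unordered* vector pairs at Euclidean
distance strictly below r (Heaviside H(0) = 0, so a pair at distance
exactly r is excluded). Normalizing by `Np(Np−1)/2` keeps C in [0, 1]; a
printed normalization that double-counts ordered pairs differs only by a
constant factor and would leave the fitted slope unchanged. The
correlation dimension `d_c(M)` is the least-squares slope of log C(r)
against log r over a scaling region.

**Scaling region.** The region where log C(r) is approximately linear in
log r is not defined by the estimator itself; the default grid is 24
log-spaced radii between the 5th and 50th percentiles of the pairwise
distance distribution. The lower bound avoids the noise- and
discreteness-dominated small-r tail, the upper bound the plateau where
C → 1. Both percentiles, the grid size, or a fully explicit grid are
configurable (`RadiusSpec`). Radii with C(r) = 0 are dropped from the fit
and at least five contributing radii are required.

**Saturation loop.** `d_c(M)` is computed at M = 2 and then for
M = 3, 4, … until `|d_c(M) − d_c(M−1)| < ε` (first comparison at M = 3),
with defaults ε = 0.001 and a cap `M_max = 50`; with τ = 50 and N = 1500
the embedding itself becomes infeasible at M = 31, so the cap guarantees
termination in all cases. The reported FD is `d_c` at stopping; hitting
the cap (typical for stochastic, noise-like signals whose d_c grows with
M) flags the result `saturated=False` rather than raising.

**Numerics.** Distances are recomputed per M as condensed squared
Euclidean distances (`scipy pdist`); the same helper serves the public
fixed-M estimator and the saturation loop, so both produce bitwise
identical values. C(r) is counted in a single-precision histogram pass
(only bin membership is evaluated in float32; the fit uses float64), with
a float64 fallback when the radius grid is too narrow for single
precision. For pipeline-scale runs an optional `max_vectors` cap takes an
evenly strided deterministic subsample of the reconstructed vectors; the
pair-count fraction from a subsample estimates the same C(r) without
bias, at slightly higher variance. The cap is off by default.

**Parameter choices.** τ is a free parameter; the analysis default τ = 50
(0.1 s at 500 Hz) suits broadband EEG-like epochs, and a grid search over
τ ∈ {20, 30, 40, 50, 60, 70} by LOO-CV is provided. For the Lorenz
validation signal τ = 20 integration steps is used instead, near the
point where the x-autocorrelation has decayed to ~0.6 — a τ at a
multiple of a dominant oscillation period collapses the embedding onto a
diagonal line and must be avoided (the validation sinusoid is 7.3 Hz for
exactly this reason).

## Higuchi fractal dimension (HFD)

For interval size k and start offset m (1 ≤ m ≤ k), the curve length
`L_m(k)` sums the absolute lag-k differences along the subsampled curve,
normalized by `(N−1)/(n·k)` with `n = int((N−m)/k)` and a leading `1/k`;
`L(k)` is the mean of the k offset curves. The FD is the least-squares
slope of log L(k) against log(1/k) for k = 1..kmax (default kmax = 100 —
the stated fit orientation yields a positive FD, whereas reading the
proportionality `L(k) ∝ k^FD` literally would flip its sign). For a
noiseless ramp `L(k) = a(N−1)/k` exactly, so FD = 1 to machine precision;
white noise sits at FD ≈ 2; fractional Brownian motion at FD ≈ 2 − H.
The batch implementation computes, per k, all lag-k differences at once
and reduces the k start offsets as residue-class sums; it is
numerically identical (to ~1e-12 relative) to averaging the per-offset
curve lengths.

## Fisher-criterion channel selection

Per feature column f, the within-class scatter diagonal is
`S_w(f) = Σ_i P_i · (1/n_i) Σ_j (x_ijf − m_if)²` (population variances,
priors `P_i = n_i/n`) and the between-class diagonal
`S_b(f) = Σ_i P_i (m_if − m_f)²` — the standard Fisher form; only the
diagonals are needed for scoring. The score `F(f) = S_b(f)/S_w(f)` is
translation invariant and invariant to per-column affine rescaling. A
configurable floor (default 1e-12) guards a vanishing within-class
scatter instead of emitting infinities. Rankings sort by descending
score with ties broken by ascending column index (determinism). Features
that span several columns per channel (AR coefficients) are ranked by
the mean of their column scores; classes with fewer than two trials are
refused (their variance is undefined under the 1/n convention in any
useful sense).

## Baseline features

*Band power*: mean squared amplitude of the zero-phase order-3
Butterworth band-passed epoch (the same filter family used for CSP);
Welch-periodogram integration is available behind a flag, and powers are
linear by default with an optional log transform. The five comparison
sub-bands are 8–12, 12–16, 16–20, 20–24, 24–28 Hz. *AR*: ordinary least
squares on lagged regressors (covariance method, no intercept), order
grid 2–7; rank-deficient designs are flagged. *CSP*: per-trial spatial
covariances are trace-normalized and averaged per class; the transform W
solves the generalized eigenproblem of the class-A covariance against
the composite covariance, rows ordered by descending eigenvalue, with
diagonal shrinkage applied (and logged) when the composite is rank
deficient. Features are the log of the (sum-normalized) variances of the
first p and last p projected rows — 2p features, invariant to epoch-wide
scaling; CSP structurally requires at least two channels.

## Classification and cross-validation

Accuracy is estimated by leave-one-out cross-validation: one fold per
trial. K-NN uses Euclidean distance with default K = 1 (odd K
recommended); voting ties break by smaller mean neighbor distance, then
lower class index. LDA uses a pooled covariance with equal priors
(classes are balanced by design) and falls back to auto-shrinkage when
the pooled covariance is ill-conditioned (more features than trials).
Features are z-scored with training-fold statistics by default — feature
scales differ by orders of magnitude across methods — with a flag to
disable. Channel selection has two placements: *nested* (default), where
the Fisher ranking is recomputed on every training fold so the held-out
trial never influences its own channel configuration, and
*paper-faithful*, where channels are ranked once on all trials before
cross-validation. The global variant leaks selection information and
measurably inflates accuracy on null data; both are exposed because the
global protocol is what per-channel score tables in the field typically
report. Grid search returns the accuracy-maximizing parameter with ties
toward the smaller value and retains the full table.

## Synthetic sessions

The generator targets the statistical property the FD features exploit —
class-dependent signal complexity — rather than cortical physiology.
Each epoch/channel is an independent fractional Brownian motion
(exact-covariance circulant embedding of fractional Gaussian noise),
standardized per epoch, plus optional class-dependent band-limited
sinusoid and white measurement noise (`noise_sd`, default 0.1 of the
unit-variance backbone). Imagery epochs on the informative channels get
Hurst exponent `H0 + ΔH`; defaults H0 = 0.3 (resting HFD ≈ 1.7, in the
range of raw EEG) and ΔH = +0.2 (imagery smoother, lower FD — the
direction seen in imagery-vs-resting recordings). Sessions are fully
determined by spec + seed.

What this emulates: per-channel complexity differences, balanced classes,
the session's trial structure. What it does not: spatial correlation
between channels, volume conduction, 1/f-plus-rhythm spectra, artifacts,
non-stationarity within epochs. Passing tests on these sessions
therefore validate the estimators and the selection/evaluation machinery
— not classification performance on clinical EEG.

Reference signals: line and sinusoid (dimension 1), white noise (Higuchi
FD 2), fBm (Higuchi FD 2 − H), and the Lorenz system at the classical
parameters (σ = 10, ρ = 28, β = 8/3), integrated with fixed-step RK4 at
dt = 0.01 with 10⁴ transient steps discarded; its correlation dimension
(~2.05) is validated against a brute-force correlation sum computed
directly on the 3-D states.

## Validation problem sizes

The test battery uses 1500-sample epochs throughout. Stochastic checks
average 20 seeds (estimator bias), 50 seeds (planted-channel recovery, on
10-channel sessions), or 100 seeds (chance-level calibration, on
5-channel null sessions). The chance calibration runs K-NN with K = 5:
the interval it checks is a binomial band at 80 trials, and single-
neighbor LOO accuracy has noticeably super-binomial spread, so the
smoother 5-neighbor vote is the configuration whose sampling distribution
the band describes. The large-effect pipeline check uses 8-channel
sessions (3 informative, ΔH = 0.45 from H0 = 0.25) with the GPFD
`max_vectors=400` cap. These sizes are the package's validation choices;
all estimator defaults remain as stated above.

## Known limitations

* The scaling-region percentiles are a heuristic; strongly multiscale
  signals may need manual radius bounds.
* GPFD on short epochs is biased low for high-dimensional dynamics
  (Np shrinks as M grows); results with `saturated=False` should be read
  as lower bounds, not converged dimensions.
* The Fisher score is univariate: channels that are only jointly
  informative rank poorly by construction.
* The synthetic generator's independence across channels makes channel
  selection easier than on real, spatially correlated EEG.
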