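# Methods

## Model

A trial is a 9 s block of 30-channel EEG at 250 Hz (2250 samples), assumed
zero-mean per channel; the per-channel empirical mean is subtracted before
every covariance estimate so the assumption holds by construction.  All
covariance matrices are eigenvalue-floored (`λ ↦ max(λ, ε)` with
`ε = 1e−8`), which keeps them on the SPD cone without changing eigenvectors.

Three feature blocks are computed per trial and concatenated in the fixed
order (temporal, spatial, distance):

**Temporal branch.**  Seven overlapping 3 s segments (1 s step) give seven
segment covariances, each half-vectorized (diagonal + lower triangle,
row-major) to a 465-vector.  The ordering convention is recorded in every
checkpoint manifest, because a consistent bijection between matrices and
vectors is all that matters.  The 7-step sequence feeds a 2-layer LSTM
(standard input/forget/cell/output gates, forget bias initialized to +1,
other weights uniform in ±1/√H); the final hidden state of the top layer is
the temporal feature.  Sequence vectors are standardized per feature with
training-set statistics before the LSTM (toggleable): raw covariance entries
span orders of magnitude and would otherwise saturate the gates.

**Spatial branch.**  The whole-trial covariance passes through
BiMap(30→24) → ReEig → BiMap(24→16) → LogEig, then half-vectorization
(136 features at the defaults).  The layer sizes shrink gradually and are
configurable; the layer order is the standard SPD-network stacking in which
the rectification sits between the two maps so it acts as a genuine
nonlinearity.  The rectification threshold is `1e−4` — deliberately larger
than the input regularization floor `1e−8`, since a threshold the data never
reaches would make the layer an identity.  The maps are kept
column-orthonormal by QR retraction after each gradient step (a flag
disables the constraint for a plain full-rank reading); semi-orthogonal maps
make LogEig well-posed and bound the layer's conditioning.

**Distance features.**  The Stein (S-)divergence
`S(A,B) = log det((A+B)/2) − ½ log det(AB)` is computed with Cholesky
log-determinants for stability near singularity.  A variant without the ½
exponent on the product term exists behind `form="literal"` for comparison;
it is neither nonnegative nor scale-consistent and is not used by the
pipeline.  Class barycenters minimize the summed squared divergence and are
found by the fixed-point iteration from the arithmetic-mean start, stopping
when the Frobenius step drops below `1e−9` or after 50 iterations; the
stationarity residual `‖Σᵢ((C+Cᵢ)/2)⁻¹ − M C⁻¹‖_F` is the convergence
diagnostic.  Centers are computed from training-fold trials only.

**Head and optimizer.**  The fused vector feeds a linear layer with softmax;
the loss is mean cross-entropy.  Training alternates per iteration: odd
iterations step only the LSTM, even iterations only the SPD network, and the
head steps every iteration, all with plain full-batch gradient steps.
Early stopping monitors a stratified 10 % split of the training fold
(patience 10) and restores the best parameters; the stop is global — it ends
both branches at once rather than pausing one.  Default step sizes are
`η_L = 3e−2` (LSTM), `η_S = 1e−2` (SPD maps), `η_F = 0.25` (head).  They are
larger than typical minibatch-SGD rates because the gradients here are
full-batch averages on standardized, order-one features; with rates around
`1e−3` the plain (momentum-free) schedule moves the loss negligibly within
the 50-iteration budget.  All rates, the iteration cap (`Maxite = 50`) and
the schedule are configurable.

**Gradients.**  Both branches are differentiated by hand in NumPy.  The two
eigenvalue layers use the Daleckii–Krein first-divided-difference form
`∂L/∂X = U (P ∘ UᵀGU) Uᵀ`, with the divided differences replaced by the
scalar derivative whenever an eigenvalue pair is closer than `1e−12`
(degenerate spectra otherwise produce 0/0).  Gradients on the half-vectorized
output are lifted to symmetric matrix gradients by halving the off-diagonal
entries.  The LSTM uses standard backpropagation through time.  Finite
non-finiteness of any gradient aborts training with a diagnostic rather than
silently corrupting parameters.

## Evaluation

Leave-one-subject-out: one fold per subject, the model retrained from
scratch per fold with a fold-derived seed, drowsy as the positive class.
Accuracy, sensitivity, specificity and F1 are reported in percent per fold
with mean and sample variance (ddof 1) across folds; ratios with empty
denominators (single-class test folds) are NaN and excluded from aggregates.
Ablation variants restrict the fused layout only: TRDC (temporal features
alone), SDTR (temporal + distances), SNTR (temporal + SPD network), full.

## Reaction-time labeling

The global RT of trial *l* is the centered moving average of the local RTs
over indices *l−n..l+n* with *n = 2*; at series boundaries the window is
truncated to the available trials and divided by the actual count, so edge
trials are not discarded.  Labels: vigilant iff both RTs ≤ 0.62 s, drowsy iff
both ≥ 1.5 s, excluded otherwise; excluded trials are dropped before
training.  The trial window is anchored at the response offset (−1 s to
+8 s, half-open sample intervals, 0-based); the anchor is configurable.

## Preprocessing

Recordings are bandpass filtered 1–50 Hz (Butterworth order 10 in
second-order sections) and decimated 500 → 250 Hz with an anti-aliasing FIR.
Zero phase is obtained by forward-backward filtering per biquad section with
Gustafsson initial conditions rather than signal-extension padding: the
1 Hz band edge gives the IIR a multi-second impulse response, and padding
methods leave edge transients that dominate short blocks, while the
Gustafsson method chooses initial states that minimize them.  Band edges
must lie strictly inside (0, Nyquist of the output rate).

## Synthetic benchmark

The generator reproduces the statistical structure the method exploits and
nothing more.  Each class is defined by seven SPD covariance targets
`Σ_{c,t} = B^{1/2} exp(α_t T + s·β_t S_c) B^{1/2}`: a shared random base
`B`, a shared temporal drift `T` (amplitude 0.3), class-specific symmetric
directions `S_c`, separation scale `s`, and ramps `α_t, β_t` increasing over
the seven segments (classes differ at every segment, increasingly so).  At
`s = 0` the classes are one process.  Per-trial variability is a Wishart
draw around the class targets (default 400 degrees of freedom) sharing one
random matrix across segments so trial trajectories stay smooth.  A trial's
signal is nine 1 s zero-mean Gaussian blocks whose covariances linearly
interpolate the trial targets — the simplest process whose sliding-window
covariances recover the trajectory.

Reaction times are lognormal with class-conditional medians 0.45 s
(vigilant) and 2.0 s (drowsy) and log-scale spreads 0.12 and 0.15 — positive
and right-skewed, with dead-zone probabilities of a few percent at most.
Subjects hold two contiguous same-state runs (uniform trial counts in the
configured range, classes split per the balance target), and the global-RT
smoother runs within each run with truncated windows: the smoother assumes
slowly varying state, and averaging across an abrupt synthetic state switch
would manufacture dead-zone trials that say nothing about the method.
Trials the rule still excludes have their RT redrawn (up to 5 sweeps);
stubborn ones stay excluded.  Everything is deterministic given the seed.

The generator makes no attempt at realistic EEG spectra, electrode geometry,
artifacts, volume conduction or nonstationarity within a second.  Passing
tests therefore demonstrate that the pipeline recovers class structure that
is *present in the covariance trajectories*; they say nothing about how much
such structure real driving EEG carries.

## Zeta statistic and source analysis

ζ = (Γ+Θ)/(Φ+Υ) over a chosen set of trajectory-matrix columns, with
Pearson correlations φ and strong-correlation offset ω = 0.9.  The defining
sums do not fix pair multiplicity, so both conventions are implemented:
intra-class pairs counted once (unordered; default) and the cross-class sum
over all ordered pairs including matched columns (default; both
switchable).  Υ (squared correlation differences) is summed into the same
denominator as Φ (exponentiated correlations) exactly as defined, despite
the scale mismatch.  Zero-variance columns get φ = 0 with a warning.
Combinations are enumerated exhaustively when C(pool, k) ≤ 10⁴ and sampled
without replacement otherwise.

The source analysis treats the inverse-solution transform W as an input; a
random semi-orthogonal stand-in (labelled synthetic) is generated when no
real head-model solution is available.  Source variances are the diagonal of
`WᵀΣxW` (independent-sources assumption; the off-diagonals are discarded —
this is also why Σs must be read as a diagonal matrix for `Σs⁻¹` to exist).
Forward weights `A = Σx W Σs⁻¹` satisfy `Σx W = A Σs` to machine precision
by construction.  Per-source weight columns get maximum-likelihood
location-scale t fits; the discrete KL divergence uses natural log on a
shared 512-point grid spanning both fits' ±6 scale ranges, and per-source
values are min-max normalized.

## Problem sizes

Training tests and the acceptance script use deliberately modest sizes
chosen as the smallest that exercise every code path with clear separation:
6 subjects with 18–22 trials each (≈120 trials) at separation 2 for the
main LOSO run, 4 subjects with 8–12 trials at reduced network sizes
(hidden 16, maps 30→16→8, 20 iterations) for the 20-seed variant
comparison, and 364 synthetic sources for the KL analysis.  Gradient checks
run on 6×6 covariances, where finite differences are trustworthy.

## Known limitations

* Full-batch training limits datasets to what fits in memory; a minibatch
  mode is not the default because the alternating schedule is defined
  per-iteration.
* The eigendecomposition backward is stable under the difference floor but
  still loses accuracy for nearly defective spectra far beyond it.
* Sensitivity/specificity are undefined on single-class test subjects and
  excluded from aggregates rather than imputed.
* The synthetic RT model draws trial RTs independently within a run; real
  RT series are autocorrelated, so the global-RT smoother is less binding
  here than on real data.
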