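# Methods

`crossmi` implements a cross-subject motor-imagery (MI) BCI pipeline in
which EEG source localization drives channel selection: wavelet-domain
maximum-entropy-on-the-mean (wMEM) estimates the cortical sources that two
subjects express *jointly*, the electrodes above those sources become the
montage, and a (regularized) common-spatial-pattern classifier trained on
one subject is scored on the other.  This note records the models, the
defaults, and the design choices that were genuinely open.

## 1. Forward model and synthetic world

The forward model is the standard distributed-dipole linear model
`M = G J + E`: `M` (q channels x tau samples) are scalp potentials, `J`
(r sources x tau) dipolar current densities along a source shell, `E`
Gaussian sensor noise, and `G` the q x r lead field.  Realistic boundary-
element lead fields are out of scope; `build_toy_headmodel` uses a fixed
analytic kernel

    g(c, s) = (o_s . u_cs) / (||p_c - p_s||^2 + 0.01),

with electrodes on the unit upper hemisphere (Fibonacci lattice), sources
on an inner shell of radius 0.8 with radial-plus-jitter unit orientations
`o_s`, and `u_cs` the unit vector from source to electrode.  The kernel
keeps the two properties the inverse problem needs: smooth, correlated
columns for neighboring sources, and r > q under-determinedness.  Default
geometry is 118 electrodes / 600 sources; tests and the acceptance script
use 32 / 200 for speed — every algorithmic path is identical.

The synthetic generator emulates a two-class (e.g. right-hand vs right-foot
MI), two-subject recording: 140 trials per class per subject, 3.5 s trials
at 100 Hz with a 0.5 s signal-free pre-cue baseline.  Each (class, subject)
has a compact active source patch (8 sources by default) carrying one
coherent amplitude-modulated (Hann) sinusoid per trial with random frequency
in 10-13 Hz and random phase; sensor noise is iid Gaussian (sd 1 uV).
`shared_fraction` sets how much of the two subjects' class patches coincide
— the generative notion of inter-subject associativity.  Two deliberate
idealizations:

- **Power equalization.** Each patch's summed scalp topography is rescaled
  to a common norm (`equalize_power=True`).  Without it, whichever class
  happens to produce the stronger scalp signal is classifiable from
  amplitude alone — a cue that transfers across subjects even with fully
  disjoint sources and would contaminate the associativity contrast.  The
  linearity of the forward map can still be exercised with the flag off.
- **Stated SNR.** `target_snr` rescales the source amplitude so that mean
  signal power / noise power over the post-cue window equals the requested
  value; recovery experiments are specified at SNR 10.

What the generator does *not* emulate: 1/f background spectra, spatially
correlated noise, artifacts (EOG/EMG), non-stationarity across trials, or
individual head geometry.  A green recovery test therefore establishes that
the pipeline works when its modelling assumptions hold, not that it works
on recorded EEG.

The sampling rate of the emulated public dataset's downsampled distribution
is not documented; the synthetic default is 100 Hz (250-sample analysis
windows) and is configurable.

## 2. Preprocessing and the cross-subject protocol

Trials are band-pass filtered at 8-40 Hz with an order-10 Butterworth
design, realized as cascaded second-order sections and applied
forward-backward (zero phase).  The zero-phase choice avoids group delay
shifting the 0.5 s cue alignment; the SOS realization avoids the numerical
fragility of a direct-form order-10 filter at fs = 100 Hz.  The contract is
the magnitude response, not coefficient values.  The analysis window is the
2.5 s following the first 0.5 s after cue onset; the pipeline order is
fixed as filter-then-window (windowing first would smear edge transients
into the epoch).

Each subject's 280 trials are split into 10 contiguous, equal subsets in
recorded order; subset i of the training subject (28 trials) is paired with
subset i of the test subject (28 trials).  A directed pair "X-Y" trains on
X and tests on Y; the reversed direction is a separate experiment.
Accuracies are reported per set and aggregated as mean +/- SD with the n-1
denominator (the convention is not externally fixed; it is documented
here).  The grand summary is the mean of per-pair means, its SD, and the
median.

## 3. wMEM source localization

Class trials (and their baselines) are ensemble-averaged, and the average
is transformed with an orthogonal periodized Daubechies-4 DWT (the wavelet
with four vanishing moments; depth defaults to floor(log2 tau) - 2).
Because neither PyWavelets nor MNE is a dependency, the transform is built
in-package as explicit orthogonal filter-bank matrices; Parseval and
perfect reconstruction hold to 1e-10 and are tested.

**Noise model.**  The q x q baseline covariance is estimated from the
pooled pre-cue segments and inverted to a whitener via eigendecomposition
with a relative eigenvalue floor of 1e-8 (degenerate baselines must not
crash).  Since the analyzed data is an n-trial average, the whitener is
scaled by sqrt(n).  Per-channel shrinkage thresholds follow universal-
threshold practice: tau_ch = c * sd_ch * sqrt(2 ln N) with c = 1, where
sd_ch = 1.4826 * median(|d1|) is the median-estimator noise scale of the
channel's finest-scale coefficients of the *averaged data* (already on the
averaged scale; the baseline is the documented fallback).  Each coefficient
is soft-shrunk, delta_tau(w) = (1 - tau/|w|)+ w, then whitened; boxes whose
shrunk coefficients vanish on all channels are skipped.

**Reference law.**  The source space is clustered once per localization:
multivariate pre-localization scores m_s in [0, 1] (squared projection of
the whitened, normalized lead-field column onto the whitened data's
dominant SVD subspace at 95% energy), then region growing around the top
K = 20 local maxima of m_s on a 6-nearest-neighbor source graph
(best-first accretion, lowest-index tie-break).  Parcel k gets a Bernoulli
activation probability alpha_k (mean member score, clipped to
[0.05, 0.95]) and an active-state zero-mean Gaussian with covariance
sigma^2 (I + 0.5 A_k), A_k the within-parcel adjacency, eigenvalue-clipped
at 0.05 because a degree-6 node at correlation 0.5 is not otherwise
positive definite.  The prior scale sigma^2 is set from the data:
mean squared shrunk coefficient over mean whitened lead-field column
energy.  alpha posteriors are recorded per box but not fed back
(single-pass inference).

**Dual solve.**  For each retained box, the maximum-entropy posterior mean
solves the concave dual

    D(lambda) = lambda' d* - F*(G_w' lambda) - 1/2 lambda' eta lambda,
    F*(xi)    = sum_k ln[(1 - alpha_k) + alpha_k exp(xi_k' Sigma_k xi_k / 2)],

by BFGS with the analytic gradient (init 0, gradient tolerance 1e-6, at
most 500 iterations; non-convergence is flagged per box, never silent),
and w*_k = p_k Sigma_k xi_k with p_k the posterior activation.  eta is the
identity in whitened coordinates.  With all alpha_k = 1 the law is purely
Gaussian and w* reduces to Sigma_J G'(G Sigma_J G' + eta)^-1 d*, which the
tests use as a closed-form oracle.  The per-source energy map sums w*^2
over all boxes (per-scale maps are kept for inspection); boxes are solved
independently — cross-scale coupling is out of scope.

## 4. Channel selection

Manual inspection of source maps is replaced by an explicit criterion:
sources in the top 5% of the nonzero energy distribution (deterministic
lowest-index tie-break) are projected radially to the electrode shell, and
electrodes within 0.25 head-radius units of any projection are selected;
if the radius captures nothing, each source's nearest electrode is taken.
The per-class channel sets are unioned.  Lowering the energy quantile can
only grow the selection, and |union| is bounded by max and sum of the
per-class counts — both tested.  The quantile/radius defaults are an
explicit stand-in for visual inspection, not an inference of anyone's
intent; on the synthetic world they select compact clusters above the true
patches (of order 10 of 32 electrodes at test geometry).

In the evaluation protocol, channel selection is computed per protocol set
on the *combined* class-specific trials of both subjects.  This is the
deliberate, protocol-defining exception to train/test separation: joint
localization is what operationalizes associativity.  It is label-aware and
subject-joint, but spatial filters, the beta/gamma choice and classifier
weights never see test trials (asserted by test).  A fast mode reuses the
set-1 selection with a warning.

## 5. CSP / RCSP

Per-trial covariances are normalized to unit trace, S = EE'/tr(EE').
RCSP shrinks the class covariance twice: beta mixes in "generic" trials,

    Omega_c(beta) = [(1-beta) S_c + beta S^_c] / [(1-beta) M + beta M^],

and gamma shrinks toward the scaled identity,
Sigma_c(beta,gamma) = (1-gamma) Omega_c + (gamma/N) tr(Omega_c) I.  Which
trials are "generic" is not externally fixed; the default is the training
subject's trials from the other nine protocol sets (configurable).  The
filters come from the two-step factorization: eigendecompose the composite
Sigma_1 + Sigma_2 = U L U' (descending), whiten, eigendecompose the
whitened class-1 covariance, W = B' L^-1/2 U'.  Then W Sigma_1 W' and
W Sigma_2 W' are diagonal and sum to the identity; beta = gamma = 0
reproduces plain CSP bit-for-bit.  Eigenvector signs are fixed by making
each vector's largest-magnitude entry positive, and degenerate eigenvalues
are tie-broken by original index, for bit-reproducibility.  Four
components are retained: the first two and last two rows of W (two per
class).  Note that although the projection is often printed as W'E, with
W = B' L^-1/2 U' it is the *rows* of W that are the spatial filters; the
implementation projects X = W E, the form for which the diagonalization
identities hold.

When beta/gamma are searched rather than fixed, the grids are

    beta  in {0, 0.001, 0.01, 0.1, 0.2, ..., 0.9}   (12 values)
    gamma in {0, 0.01, 0.1, 0.2, ..., 0.9}          (11 values)

and the choice maximizes mean accuracy over internal stratified 2-fold
splits of the training half only, ties toward less regularization.

## 6. Features and classifier

Each retained component is decomposed with a level-3 Daubechies-3 DWT into
A3/D3/D2/D1, and each subband contributes the Shannon entropy of its
normalized squared coefficients (natural log, 0 ln 0 := 0): a 16-vector
per trial.  The features are invariant to component sign and scale; each
entry lies in [0, ln n_subband].  A log-energy entropy variant sits behind
a flag.  One property worth stating precisely: within-subband entropy over
translations measures *temporal* energy spread.  A persistent oscillation
fills its subband uniformly and scores near ln n — *higher* than white
noise; it is temporally localized (envelope-modulated) activity that scores
low.  The generator's Hann-windowed bursts are of the latter kind, which is
what makes the features discriminative here.

The classifier is a two-layer feed-forward network — 10 logistic hidden
units (unspecified externally; configurable), softmax output, cross-entropy
loss — trained by L-BFGS for at most 500 epochs with a 1e-6 plateau stop,
deterministic given its seed.  No feature normalization is applied by
default; optional z-scoring uses training-set statistics only.

## 7. Numerical choices and degenerate inputs

- Whitener/composite-covariance eigenvalue floors: 1e-8 (noise model) and
  1e-10 (CSP composite) relative to the top eigenvalue; all-zero
  covariances raise.
- Zero data: pre-localization returns all-zero scores with a warning;
  localization of all-zero trials returns a zero energy map with every box
  skipped; all-zero subbands contribute entropy 0 by convention.
- Free-energy evaluation uses logaddexp, so alpha in {0, 1} and large
  exponents are safe.
- DWT lengths not divisible by 2^levels are zero-padded on the right; the
  inverse truncates.  Levels are rejected when the periodized length would
  fall below the filter length.
- Per-set sub-seeds are derived from the experiment seed by a fixed affine
  map mod 2^31 - 1; every stochastic stage (inner splits, classifier init)
  draws from them.

## 8. Known limitations

- The toy lead field is not a BEM model; absolute source amplitudes and
  depth biases are not physiological.
- The wMEM solver is a self-consistent Bernoulli-Gaussian implementation,
  not a numerical replica of any external solver; alpha is not iterated.
- Channel-selection defaults were chosen on synthetic recovery; on real
  montages the quantile/radius would need recalibration.
- The dissociative (shared_fraction = 0) chance-level result is a
  statement about this generator (equalized power, disjoint patches), not
  a guarantee for arbitrary subject pairs.
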