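# Methods

## Model and procedure

`holssa` treats a single EEG channel as a sum of a few structured
sources (narrow-band rhythms, transients, periodic interference) plus
broadband noise, and recovers that structure geometrically rather than
statistically: consecutive non-overlapping windows of the series form
the rows of an embedding matrix, overlapping row-blocks of that matrix
form an order-3 trajectory tensor that is Hankel in its first two
modes, and a truncated higher-order SVD of the tensor concentrates any
low-rank temporal structure into a small core.  Because the map from
series to tensor is linear and injective on its image, every linear
operation on the tensor (truncation, grouping, component selection) is
pulled back to the time domain by diagonal averaging — the least-squares
inverse that averages all tensor entries sharing an original sample
index.  Two exactness properties anchor the implementation and are
enforced by tests at 1e-8 relative error or tighter:

* full-rank decomposition followed by reconstruction is the identity
  on the first `L·i` samples (the `l mod i` remainder is zero-padded);
* the truncated reconstruction error never exceeds
  `sqrt(Σ_m Σ_{k>r_m} σ(m)_k²)`, the discarded-spectrum bound.

**Component ranking and grouping.**  Each kept core entry `(p,q,r)`
defines a rank-1 component whose time-domain contribution has a closed
form: with `c[m]` the anti-diagonal multiplicities,
`series[m·i + b] = (conv(u,v)[m] / c[m]) · w[b]` for factor columns
`u, v, w` — identical to diagonal-averaging the explicit outer product
but O(L) per component.  Components are ordered by the L-scale λ₂ of
these series.  L-moments are linear in the data and weight
observations by rank, so λ₂ measures dispersion like a standard
deviation but grows only linearly (not quadratically) with stray
transient amplitudes, making the ranking stable in the presence of the
very artifacts the pipeline exists to remove.  The sample estimators
are the standard unbiased probability-weighted-moment forms; tests
verify they equal exhaustive enumeration of order statistics over all
subsets exactly.  Grouping thresholds the normalized cumulative-λ₂
profile: group 0 holds the leading components reaching 90 % of total
λ₂ (the "signal" subseries), group 1 the remainder.  Group
reconstruction masks the core and applies the multilinear product —
algebraically equal to summing member outer products, but without
enumerating them (a full-rank enumeration would cost O(L·w·i)
components; grouping "all" therefore skips per-component scoring
entirely).

**Source separation.**  The stacked subseries of all channels are
separated by a streaming algorithm: a recursive mean/covariance
estimate whose inverse square root whitens each sample, and the
multiplicative demixing update `S⁻¹ ← S⁻¹ + l_r (I − f(y) yᵀ) S⁻¹`
with `y = S⁻¹ a` the current source estimate.  Its fixed point is the
nonlinear decorrelation condition E[f(y) yᵀ] = I; `f = tanh` matches
super-Gaussian sources (EEG rhythms, blinks, spikes), `f(y) = y³` is
provided for sub-Gaussian ones — note that `tanh` cannot separate
uniform-type sources, which is a property of this family of rules, not
an implementation limit.  The update is applied exactly as stated; the
equivalent propagation of the mixing estimate is a Sherman–Morrison
rank-1 inverse update, and tests verify the recursion against direct
dense inversion over random update sequences.

Numerical choices for the offline case (`separate`, `ORICA`):

* **Averaged whitening.**  The covariance rate decays as 1/(n+2), so
  the whitener converges to the record-wide estimate.  The forgetting
  mode (`whiten_mode="forget"`, EWMA with factor `l_r`) is kept for
  genuinely streaming use, but a forgetting whitener's final snapshot
  reflects only the last ~1/l_r samples — applied retroactively to a
  bursty record it is systematically wrong.
* **Polyak averaging.**  With a constant learning rate the demixing
  recursion fluctuates around the separating solution; the transform
  applied to the record is the average of `S⁻¹` over the final pass
  rather than its end-of-stream value.  On 2-source Laplace mixtures
  this lifts matched source correlations from ~0.93–0.99 (snapshot) to
  ≈ 1.0, and it removes the sensitivity of artifact cleaning to
  whatever burst happens to end the record.
* **Outlier clipping.**  `‖y‖` is capped at `4·√r` inside the update
  (whitened data satisfies E‖y‖² = r), since a single blink-scale
  sample otherwise multiplies `S⁻¹` by a large factor and can make the
  recursion diverge; typical samples are unaffected.  A step that
  still produces non-finite values is rejected and the rate halved.
* Defaults: `l_r = 0.005`, 3 passes over offline data, no annealing
  (an optional `l_r/n^γ` schedule exists; with Polyak averaging it was
  not needed and slows adaptation early on).
* Inputs whose excess kurtosis is all within ±0.1 trigger a logged
  warning: rotation is unidentifiable for Gaussian sources.

**Artifact labelling.**  Each independent component gets a PSD-based
fingerprint (Welch, 2 s segments): power fractions in 1–4 Hz, 8–13 Hz,
20–60 Hz and 49–51 Hz bands, Pearson kurtosis, and a cardiac
periodicity score — the autocorrelation of the <8 Hz-smoothed energy
envelope at its best lag in 0.6–1.5 s *minus the minimum at shorter
lags*.  The prominence form matters: a waxing-waning alpha envelope
decays smoothly and scores near zero, while a spike train dips between
beats and rebounds.  Labels come from a first-match decision list —
line (ratio > 0.5), muscle (> 0.5), eye (low-freq > 0.4 **and**
kurtosis > 5), heart (prominence > 0.3 at a cardiac lag **and**
kurtosis > 5, since heartbeat artifacts are impulsive), brain
(8–13 Hz > 0.3), else other.  All thresholds are configuration fields.
Cleaning keeps brain components, back-projects through the estimated
mixing, and sums each channel's cleaned subseries.  If *no* component
is labelled brain the pipeline keeps the one with the largest alpha-band
fraction (with a warning) instead of returning silence; the low-level
`remove_and_backproject` refuses an empty keep set outright.

**Preprocessing** follows common motor-imagery practice: keep channels
whose name contains "C" (the central strip, including FC*/CP*),
polyphase anti-aliased downsampling (500→250 Hz), zero-phase 4th-order
Butterworth filters (1 Hz high-pass before decomposition; 4–38 Hz
band-pass available for rhythm-band analysis), and amplitude-threshold
segment flagging with boundary events recorded where data was excised.
The pipeline applies the 1 Hz high-pass before decomposition: slow
drift otherwise consumes the tensor's rank budget without carrying
artifact-discriminative structure.

**Features and classification.**  CSP solves `C₁w = λ(C₁+C₂)w` on
trace-normalised average covariances via whitening of the pooled
covariance followed by symmetric diagonalisation (ridge 1e-8 of the
trace if rank-deficient); features are `log` normalised variances of
the first/last 3 filter pairs, one-vs-rest across the four classes.
Phase 1 is an MLP (one hidden layer of 64, early stopping on a 20 %
validation split, 25-iteration patience — small feature sets plateau
slowly).  Phase 2 concatenates the features with *out-of-fold* phase-1
probabilities (5-fold, so phase 2 never sees optimistic in-sample
probabilities) and fits an RBF SVM, C selected from {0.1, 1, 10} by
stratified CV, with per-sample weights realising session adaptation:
trials flagged as new-session get weight `adaptation_rate`, everything
else 1.  Metrics use the standard definitions; κ = (p_o − p_e)/(1 − p_e)
with marginal-product chance agreement.

## Synthetic data: what it emulates, and what it does not

The generator produces the signal classes that dominate practical EEG
cleaning work, each seeded and bit-reproducible:

| element | form | default |
|---|---|---|
| rhythm | random-phase sinusoid, optional low-pass AM envelope | 10 Hz, amp 1, 2 Hz bandwidth |
| background | 1/f-amplitude (pink) noise, unit RMS scaled | amp 0.5 |
| EOG blink | 0.3 s squared-sine unipolar pulse, Poisson events | 0.2 /s, amp 8 |
| EMG burst | 20–60 Hz band-passed noise under 0.5 s Hanning gates | 0.5 /s, amp 2.5 |
| ECG | biphasic (Gaussian-derivative, σ = 20 ms) spikes, ~2 % jitter | 1.2 /s, amp 1.5 |
| mains | fixed 50 Hz sinusoid (configurable frequency) | amp 1.5 |
| sensor noise | i.i.d. Gaussian per channel | sd 0.1 |

Contaminated recordings are 30 s, 4 channels at 250 Hz, mixed by a
random-sign matrix with unit-scale entries; the EOG column decays
toward "posterior" channels, mimicking frontal dominance.  Blink
amplitude 8× the rhythm reflects the order-of-magnitude gap between
ocular potentials and cortical rhythms at frontal sites.  MI epoch
sets are 2 s × 8 channels at 250 Hz: every channel carries the 10 Hz
rhythm over pink + white noise, and each class attenuates the rhythm
by `1 − erd_depth` (default 0.8) on a fixed quarter of the channels
(left hand → first quarter, right hand → second, feet → third, rest →
none) — a deliberately clean ERD topography.

Not emulated: volume conduction from a head model (mixing is an
arbitrary matrix, not a leadfield), nonstationary mixing, channel
drift/popping, inter-subject variability, or realistic ERD time
courses.  Consequently, passing tests demonstrate the *algorithmic*
properties — exact reconstruction, correct update algebra, artifact
RMSE reduction under linear instantaneous mixing, class separation
when class information is variance-coded — not clinical-grade
performance on recorded EEG; the near-ceiling benchmark accuracy says
the pipeline extracts a strong planted effect, not that real
four-class MI is this easy.

## Problem sizes and defaults

Embedding window `i` defaults to 0.1 s of samples (25 at 250 Hz), slab
depth `w = ⌊L/2⌋`; per-mode truncation keeps 99 % spectral energy
capped at rank 8 (the cap bounds the component enumeration at 512 and,
on broadband noise, acts as an additional denoiser — pink noise and
EMG do not compress, which is intrinsic to low-rank trajectory
methods).  Acceptance-style runs use: 20 series of 300–3000 samples
for reconstruction exactness, 50 random tensors for the HOSVD checks,
200 draws of n ≤ 8 for L-moment enumeration, 2×50 000-sample mixtures
for separation, five 30 s recordings for cleaning, and five
100-trial-per-class epoch sets for classification — sizes at which
every quantity is stable yet the full suite completes in a couple of
minutes on one core.

## Degenerate inputs and tie-breaks

Constant series have λ₂ = 0 (tiny negative round-off is clamped);
zero-variance CSP projections are floored at 1e-30 before the log;
near-singular running covariances are eigenvalue-floored with a logged
warning; component ordering uses a stable sort so equal-λ₂ components
keep enumeration order; sign indeterminacy of SVD factors, CSP filters
and ICA components is inherent and all comparisons in tests are made
up to sign/permutation.

## Known limitations

* Single-channel decomposition treats channels independently; joint
  spatio-temporal embedding is out of scope.
* The labelling rules are transparent thresholds, not a trained
  classifier; on real data they would need threshold calibration and
  ideally scalp-topography evidence, which requires electrode geometry
  this package does not model.
* EDF files can be read (via `mne`) but not written; the native format
  is provenance-headed CSV.
* The streaming separator's `forget` mode tracks nonstationarity but
  its end-of-stream state should not be applied retroactively to a
  whole record — use the offline defaults for that.
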