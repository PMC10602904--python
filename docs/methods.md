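# Methods

## The analysis model

The package treats neural entrainment as lagged linear tracking of a
stimulus timeseries. The stimulus side is the global optical-flow
magnitude series of a video (summed per-pixel velocity magnitude per frame
transition, in pixels/frame); the response side is multichannel scalp EEG.
Coherence is defined per frequency bin as the maximal lagged Pearson
correlation between the two signals after both are passed through the same
narrowband zero-phase filter:

    r_{c,f} = max_{τ ∈ W} | corr( F_f s (t), F_f x_c (t + τ) ) |

with `F_f` a second-order IIR resonator at center `f` and 0.2 Hz −3 dB
bandwidth applied forward–backward (zero phase, so τ is interpretable as a
physiological delay), `W = [0, 1000]` ms (positive lags only: the brain
follows the stimulus), and both the maximising amplitude and its lag kept.
For univariate narrowband pairs this is exactly the rank-1 case of
delay-embedded canonical correlation; `entrainment.cca_correlation`
provides the embedded-CCA variant for sensitivity analysis.

Assumptions: tracking is linear and time-invariant within a trial;
delays are constant per (region, frequency); trials are exchangeable
within a participant × condition cell (per-trial spectra are averaged —
the mean was chosen over the median for variance reduction; a median mode
exists).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| frequency grid | 0.2–12.4 Hz, 0.2 steps (62 bins) | Hz | spans the delta–alpha range resolvable from ~5 s of video-locked data; the top is bounded by the video Nyquist |
| filter bandwidth | 0.2 | Hz | matches the bin spacing; forward–backward application narrows the effective band further |
| lag window | 0–1000 | ms | visual tracking latencies; configurable |
| epoch window | 0–5 | s | the shortest stimulus duration, so every trial contributes equally |
| band-pass | 0.1–30 Hz, 8th order | Hz | 48 dB/oct each side at 6 dB/oct/pole; cascaded second-order sections for stability at 0.1 Hz/500 Hz |
| amplitude review | ±75 | μV | the only review criterion on by default; gradient/flatline checks exist but are off |
| regions | 5 electrodes × 4 regions | — | anterior {F3,F4,Fz,FC1,FC2}, posterior {P7,P8,P3,P4,Pz}, left {C3,FC5,T7,CP1,CP5}, right {C4,FC6,T8,CP2,CP6} |
| UFS discretization | equal-frequency, ⌈√n⌉ bins | — | monotone-transform invariance; ≈ 9 bins at n = 88 |
| ensembles | RF 100, ET 100, AB 50, GBM 100 | trees | fixed battery design |
| hold-out | 20 % of participants per group | — | drawn before any fitting; both condition rows of a participant travel together |

## The synthetic generator

`synth.make_cohort` emulates the study design: two populations (24 and 20
participants), two conditions per participant (direct and time-reversed
stimuli), the *same* stimulus videos shown to everyone. EEG channels carry
1/f background noise (exponent 1.0, std 8 μV — realistic scalp scale with
a few percent of trials exceeding the ±75 μV review bound) plus, for each
*entrainment cell* `(group, region, frequency, lag, snr)`, a delayed
narrowband copy of the stimulus flow added to all five channels of the
region. `snr` is the amplitude ratio of the injected component to the
channel's noise within the cell's 0.2 Hz band. The reversed condition
attenuates each group's cells by a factor (defaults: 0.3 for group a,
whose entrainment models comprehension; 0.6 for group b, whose entrainment
models biological-motion tracking) — this condition-dependence is what the
classifiers detect; it is a modeling choice of the generator, not an
empirical claim.

Two deliberate realism choices:

* **Circular delay.** The injected copy is delayed by circular shift of
  the (stationary) narrowband segment rather than zero-padding: at 0.2 Hz
  bandwidth a filter rings for ~5 s, so a hard onset edge would smear
  across the entire trial and dominate every correlation.
* **Shared stimuli.** Because all participants see the same videos (as in
  the real design), the per-bin *spurious* coherence structure of a video
  is shared across participants and differs between a video and its
  reversal. Condition contrasts therefore contain a genuine
  stimulus-driven component on top of the injected neural effects — a
  property of the paradigm itself, mitigated (as in the real study) by
  averaging across videos.

Scaled-down problem sizes: the generator defaults to 2 videos per
condition and 5 s videos (the real study used 40 videos of 5–7 s);
videos-per-condition affects only trial-averaging variance, never the
design shape (88 instances × 496 features is preserved). The pipeline and
all tests run on these sizes in minutes on one CPU.

What the generator does **not** emulate: volume conduction between
regions, non-stationary artifacts (blinks propagate to scalp channels only
if explicitly mixed in), oscillatory alpha with eyes-closed dynamics,
between-participant latency variability within a cell, and real
sign-language motion statistics. Passing tests therefore demonstrate that
the *machinery* recovers what it assumes; they do not validate the
linear-tracking model on real EEG.

## Parameter recovery and its limits

A pooled localization diagnostic (`entrainment.localize_cells`) averages
*signed* correlation curves over a region's five channels before
peak-picking: background noise is independent across channels while an
embedded copy is shared, so pooling suppresses the high spurious peaks
(|r| ≈ 0.9) that single 0.2 Hz-band channels show under a free lag search.

Two resolution limits are intrinsic to the prescribed analysis and bound
what any recovery can achieve on 5 s trials:

* **Frequency.** 5 s of data has 0.2 Hz Fourier resolution — exactly the
  bin spacing — and second-order resonators have Lorentzian tails that
  genuinely entrain adjacent bins. Pooled localization finds the exact
  embedded bin in roughly half to two-thirds of single trials and the
  embedded bin ±1 in the large majority (the acceptance script measures
  both rates at run time); no injection scheme consistent with the
  generative model does materially better.
* **Lag.** Delay-estimation precision scales as
  `1/(2π · bandwidth · √(2 · snr · BT))`; with 0.2 Hz bandwidth and
  BT ≈ 1 the correlation surface is flat over ±100 ms around its peak, so
  single-trial lag estimates scatter by tens of milliseconds *independent
  of snr*. Lags are recovered to the right 100–300 ms range, not to the
  sample.

The acceptance suite states the per-trial recovery targets in their strict
form (exact bin, ±1 sample lag, 95 % of trials); the lag clause fails for
the reasons above and is reported honestly rather than loosened.

## Numerical choices

* Narrowband filtering uses `scipy.signal.iirpeak` coefficients applied
  with `filtfilt` and a pad length of min(n−1, 3·rate/bandwidth); the
  forward–backward pass squares the magnitude response (halving the
  effective bandwidth), which is immaterial because every signal passes
  the identical filter.
* Lagged Pearson correlations use exact per-lag overlap means and
  variances (prefix sums) with one FFT cross-correlation per
  channel × bin; lags may be negative (used by the mirrored-lag symmetry
  test). Zero-variance overlaps return r = 0; fully flat inputs return
  amplitude 0 with the peak time flagged missing (NaN), never fabricated.
* Flow resampling (≈30 → 500 Hz) is polyphase with an exact rational rate
  ratio; passband ripple bounds the error at ~0.1 %.
* Peak-picking rectifies (|r|) by default, with the sign preserved in a
  side field; the pooled localization diagnostic uses signed curves, which
  halves the carrier-phase ambiguity for positively-injected effects.
* Equal-frequency discretization falls back to the raw values as
  categories when a feature has no more distinct values than bins, so a
  binary feature equal to a balanced binary label scores exactly
  H = 1 bit. Plug-in MI has a positive bias of ≈ (B−1)²/(2N ln 2) bits
  for independent pairs; the leave-one-out entropy scores inherit it
  (documented, not corrected — rankings compare features under the same
  bias).
* The leave-one-out dataset entropy uses the pairwise approximation
  H(D) ≈ Σ H(X_j) − Σ_{j<k} I(X_j; X_k); a feature's score is the unique
  information H(X_f) − Σ_{k≠f} I(X_f; X_k), so removing a duplicated
  column scores ≈ 0 and a unique high-entropy column scores highest.
* Ranking ties break deterministically: lower frequency bin, then region
  order anterior < posterior < left < right, then amplitude before time.
* Cross-validation folds are stratified by class and grouped by
  participant; a class missing from any training fold raises rather than
  silently degrading. Scaling parameters (per-fold means/SDs and the
  fit-row ids) are recorded in the report as leakage instrumentation.
* "Linear regression" in the battery is realised as logistic regression —
  the standard reading in a classification battery, since least squares
  has no native class output.
* Every stochastic stage derives its seed from the top-level seed plus
  the stage name (SHA-256), so stages rerun independently yet
  reproducibly; rerunning a pipeline with an identical config recomputes
  nothing (content-hash manifest).

## Design choices where the field offers options

* **Gratton–Coles variant:** whole-recording raw regression rather than
  the ERP-subtraction original, because single-trial coherence (not ERPs)
  is the downstream target.
* **Scaling scope:** z-scaling is fit within training folds in every
  classification context (leakage-free); a global-scaling mode exists
  behind a flag for replication of the classical workflow.
* **Trial aggregation:** per-trial spectra averaged per
  participant × condition; an alternative would concatenate trials before
  correlation — both are implemented at the module level (average is the
  pipeline default).
* **Lowest bins:** the 0.2–0.4 Hz bins complete only 1–2 cycles in 5 s;
  they are flagged `low_confidence` in every spectrum but retained, since
  low-delta features are scientifically central to the paradigm.
* **All-rejected instances:** if every trial of a participant × condition
  fails amplitude review, the pipeline falls back to the flagged trials
  (loudly logged in `rejections.json`) rather than producing an incomplete
  design matrix.

## Known limitations

* Real stimulus videos and EEG were not available; absolute coherence
  levels, spurious-peak magnitudes and classifier accuracies on synthetic
  data should not be read as predictions for real recordings.
* The narrowband + free-lag-search design saturates peak correlation near
  1 for low bins regardless of true coherence; *contrasts* between
  conditions carry the information, absolute amplitudes do not.
* EDF files are read but not written; video decoding covers frame
  directories and array archives (no codec-backed container reading).
* The leave-one-out entropy estimator is pairwise; it cannot see
  higher-order redundancy (e.g., a feature reconstructible only from two
  others jointly).
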