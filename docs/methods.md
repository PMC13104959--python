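# Methods

`respshape` quantifies whether the *shape* of each breath is coupled to the
shape of the corresponding cycle of a respiration-entrained neural
oscillation. This note records the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic-data studies do and
do not demonstrate.

## Pipeline overview

1. **Preprocessing** — downsample (anti-aliased polyphase) to a common rate;
   bipolar re-reference adjacent depth-electrode contacts (channel *i* −
   channel *i+1*); low-pass respiration at 2 Hz (windowed-sinc FIR, Hamming,
   ~1 Hz transition, applied forward–backward). For all time-domain stages
   both signals are band-passed 0.01–2 Hz with a fifth-order Bessel filter
   applied forward–backward (zero phase, maximally flat group delay inside
   the band — waveform shape is the measurand, so phase linearity matters
   more than rolloff) and z-scored over the whole recording.
2. **Breathing band** — the respiration PSD (Welch, 40 s Hanning windows,
   20 s overlap, 0.025 Hz grid) is parameterized into an aperiodic 1/f-like
   component plus Gaussian periodic peaks; the highest-amplitude peak in
   0.05–1 Hz is the breathing frequency `f_resp`, with a fixed ±0.1 Hz
   analysis band and period `tau = 1/f_resp`. No periodic peak ⇒ the
   participant is excluded (`NoBreathingPeakError`).
3. **Coherence screen** — magnitude-squared coherence
   `C(f) = |Pxy|² / (Pxx·Pyy)` on 32 s segments with 27 s overlap (1/32 ≈
   0.03 Hz grid). A channel passes when its maximum in-band coherence
   exceeds the 99th percentile of the same max-in-band statistic over 1,000
   phase-randomized surrogates of the neural signal (amplitude spectrum
   preserved, phases uniform, DC/Nyquist untouched), **and** its own PSD has
   a parameterized periodic peak inside the band. The dual criterion rejects
   channels whose coherence is carried by harmonics of a nonsinusoidal
   rhythm with no fundamental neural peak. The surrogate statistic is the
   max-in-band value — matching the selection statistic controls the
   selection-level error.
4. **Cross-correlation screen** — signals are epoched on respiration peaks
   with a centered window of one mean breath period (`tau`), so inhale peak
   and exhale trough both fall inside. Per epoch, the Pearson-normalized
   cross-correlation (demeaned, divided by the product of epoch norms, hence
   bounded in [−1, 1]); the epoch-averaged CCF is restricted to |lag| ≤
   tau/2 and its maximum absolute value compared against the 99th percentile
   of 500 permutations in which the respiration epochs are paired with
   random neural segments drawn outside a 10 s margin around each epoch's
   own window. A negative extremal mean CCF flips the channel polarity
   (sign is arbitrary after bipolar referencing).
5. **Phase monotonicity index** — per respiration cycle, the neural signal
   is split at the respiration extrema into rising (trough→peak) and
   falling (peak→trough) phases; per phase the fraction of consecutive
   sample differences that are directionally consistent is computed (ties
   count as inconsistent in both directions — conservative); the cycle PMI
   is the unweighted mean of the two fractions (both are also reported
   separately), the channel PMI the median over cycles. The null circularly
   shifts the neural signal by an offset drawn uniformly from
   [10 s, duration − 10 s], preserving the sample multiset and
   autocorrelation while destroying alignment. PMI depends only on
   difference signs, so it is invariant under strictly increasing transforms
   of the neural signal.
6. **Cycle extraction and matching** — two-stage extrema detection
   (`find_peaks` with a base height at the signal median and a minimum
   spacing of 1.5 s; a second pass removes extrema below 0.3× the median
   extremum amplitude; alternation is enforced by keeping the more extreme
   of consecutive same-kind extrema). Cycles whose amplitude or within-cycle
   RMS exceeds median + 5·MAD are dropped. Extrema within 10 s of the
   recording edges are excluded (filter transients). Respiration peaks are
   then greedily matched, in time order, each to the temporally closest
   unmatched neural peak; a pair is kept when |Δt| < tau and both cycles
   have bounding troughs. Ties go to the earlier neural peak; a rejected
   candidate is not consumed. Greedy order — not global optimality — is the
   contract: on well-separated peaks the two coincide.
7. **Waveform features** (identical for both signals of a matched pair):
   rise time, decay time, duration (= rise + decay), amplitude (peak minus
   the mean of the bounding troughs), rise–decay symmetry (= rise/duration),
   inhale-peak and exhale-trough sharpness (mean |first difference| × fs in
   the contiguous window where the signal is on the extremum's side of the
   half-amplitude level, normalized by the cycle's peak-to-trough
   amplitude), inhale-peak and exhale-trough AUC (trapezoidal integral of
   the signal's excursion beyond the within-cycle median, over the
   contiguous super-/sub-median region around the extremum). Exhale-trough
   windows may extend past the bounding trough into the inter-breath pause,
   capped at one cycle length. Per channel and per feature, rows with a
   value above median + 3 SD are flagged and the whole row dropped (one-
   sided rule; amplitude itself is not outlier-filtered), keeping
   respiration and neural features paired.
8. **Coupling model** — for one feature, the respiration predictor is split
   into a subject-mean-centered within component (scaled by the pooled SD of
   the centered values) and a grand-mean-centered between component of
   subject means (scaled by their SD); the neural outcome is standardized by
   its pooled SD. The model is

       y_i ~ StudentT(nu, mu_i, sigma)
       mu_i = alpha + beta_within·xw_i + beta_between·xb_i
              + u_subject[s_i] + u_channel[c_i] + w_subject[s_i]·xw_i

   with priors beta ~ Normal(0, 1), alpha ~ Normal(0, 2), every scale
   (sigma and the three random-effect SDs) ~ Exponential(1), and
   nu ~ Gamma(2, 0.1). Random effects: intercepts for subject and channel-
   within-subject plus a by-subject random within-slope, dropped by default
   below 5 subjects (weak identification). Reported: the posterior median
   of `beta_within`, its equal-tailed 95% credible interval (2.5/97.5
   percentiles of pooled draws), and P(β > 0). Null models permute `xw`
   across cycles within each subject and refit with identical settings.
   Posterior-predictive adequacy is summarized as the coverage of the
   central 50% and 90% predictive intervals of the observed outcomes.
   Airflow-vs-belt morphology is compared per feature by participant-level
   medians with the two-sided Wilcoxon signed-rank test (exact null for
   n ≤ 25; all-zero differences flagged degenerate with p = 1).

## Posterior sampling

Posteriors are drawn with an ensemble MCMC sampler (`emcee`, 80%
differential-evolution + 20% snooker moves) on a non-centered
parameterization, positive parameters on the log scale (priors transformed
with their Jacobians). The walker count is `2·ndim + 2`; `chains`
independent ensembles are run for `iterations` steps with `warmup`
discarded, so each retained step contributes one draw per walker (an
ensemble run of 800 steps with ~100 walkers yields ~40,000 post-warmup
draws). Convergence is judged *between* independent ensembles: the Rhat
diagnostic compares each ensemble's pooled draw sequence (a single ensemble
is split in half). Individual walker trajectories are strongly
autocorrelated, so a cross-walker Rhat would report ~1.5 even when
independent ensembles agree on the posterior median to ±0.005; the
between-ensemble Rhat at the settings used here is ≤ ~1.07, with the
largest values on weakly identified latent offsets under near-zero
random-effect SDs. Results carry a non-fatal convergence warning whenever
any Rhat ≥ 1.01. Walkers start in a small ball around a data-informed point
(OLS slope, residual SD, nu = 10).

## Synthetic data: what it emulates

Breaths are rendered from half-period raised-cosine segments — smooth,
monotone, with an analytically known single extremum per cycle — with
per-cycle rise, decay, post-expiratory pause and amplitude drawn
independently (Gaussian jitter around template means, truncated at 0.2 s
segments). Defaults describe resting adult breathing near 0.25 Hz: rise
1.4 s, decay 1.8 s, pause 0.8 s, with jitter SDs 0.2/0.25/0.3 s and 15%
amplitude jitter. The *belt* modality renders the same drawn breaths with
the pause absorbed into a slower decay plus a 1 Hz zero-phase smooth: belts
measure chest displacement, miss the post-expiratory pause, and blunt
sharpness, while breath timing stays identical to the airflow trace —
which is what makes paired-cycle modality comparisons meaningful.

Coupled neural channels render one oscillation cycle per breath, peak
delayed `lag_s` (default 0.3 s — a free simulation parameter; typical
respiration–LFP lags are not prescribed) after the respiration peak, as a
*continuous* oscillation: the trough after cycle *i* is the trough before
cycle *i+1*. Standardized rise and amplitude of each neural cycle equal
`beta_true · z_resp + StudentT(noise_df=5) · s`; by default `s` is set so
the standardized neural feature has unit variance, which makes `beta_true`
exactly the standardized within-subject slope the coupling model estimates.
Decay and duration inherit coupling through breath timing rather than
carrying an independent slope (in a gapless oscillation rise and decay
cannot both be free and still tile the breath period). The oscillation is
summed with 1/f aperiodic background noise at a configurable relative
amplitude (default 0.2 of the oscillation SD). Uncoupled control channels
are pure aperiodic background — statistically independent of respiration —
and must fail the screens; respiration-locked channels with no *shape*
coupling are generated with `beta_true = 0`.

One global seed drives named per-(subject, stream) substreams, so adding
channels to a configuration does not perturb existing ones.

**What the generator does not emulate:** cardiac and movement artifacts,
apneas/sighs, nonstationary breathing rate, volume conduction, line noise,
and genuinely flow-shaped airflow (the template is a nonnegative
pressure-like trace). Passing tests therefore demonstrate the pipeline's
internal correctness and calibration, not robustness to every artifact of
clinical recordings.

## Validation studies and their problem sizes

The calibration module regenerates everything from scratch (sizes chosen to
keep a complete run on one CPU in the tens of minutes; all simulations at
fs = 100 Hz, the generator's minimum, ample for a < 2 Hz band):

- **Screen calibration**: 200 independent respiration/neural pairs (300 s
  each), every screen at alpha = 0.01 with 200 surrogates/permutations;
  each screen's false-positive rate must stay within 2× nominal.
- **Oracle equivalence**: greedy matching vs exhaustive enumeration on 100
  random ≤ 5-peak instances with separated peaks (where the optimum is
  unique and greedy provably attains it) plus a contended-peak
  counterexample asserting the documented greedy order; PMI vs a direct
  counting loop on 100 random cycles.
- **Feature fidelity**: on noiseless pause-free breaths, extracted
  rise/decay/duration match generator truth within 2 samples and a
  symmetric template yields symmetry exactly 0.5. Pause-free because a flat
  pause makes the trough location inside the pause non-unique; with pauses
  the per-cycle durations are instead checked to tile the recording within
  one sample.
- **Parameter recovery**: 20 replicates per level of
  `beta_true ∈ {0, 0.3}`, each 10 subjects × 2 coupled channels × ~150
  cycles (600 s), background amplitude 0.05, on the **amplitude** feature;
  the 95% CrI must cover the truth in ≥ 18/20 replicates and the
  cycle-shuffled null posterior must sit nearer zero than the real one in
  ≥ 18/20 at beta = 0.3. Sampler: 1–2 ensembles × 800 steps (400 warmup).

### Why recovery uses amplitude at low background

Cycle-feature measurement is an errors-in-variables problem: the measured
standardized slope is attenuated by the product of the truth–measurement
correlations on the two sides. Temporal features are intrinsically noisy to
measure — the respiration trough sits somewhere inside the post-expiratory
pause, and neural troughs of a shallow (cosine-flat) cycle shift by
~`sqrt(2·sigma_noise/curvature)` under background noise — so their measured
slope is systematically below `beta_true` at any realistic noise level
(roughly 0.6× at the defaults; the acceptance script reports this
attenuated rise-time slope as its own quantity). Amplitude extraction is
near-exact (truth–measurement correlation > 0.99 at low background), so for
amplitude the pipeline's estimand *is* `beta_true` and ground-truth
recovery is well-posed. This mirrors analysis of real recordings: published
coupling estimates for temporal features should be read as attenuated
lower bounds, not unbiased shape-coupling strengths.

## Numerical choices and edge cases

- Percentiles (surrogate/permutation thresholds, CrIs) use linear
  interpolation between order statistics.
- Welch/coherence segments are constant-detrended before the Hann taper;
  coherence values are clipped to [0, 1] against round-off. The surrogate
  loop evaluates coherence from precomputed respiration segment spectra —
  verified identical to `scipy.signal.coherence` to machine precision.
- The Bessel band-pass is applied with reflection padding of three time
  constants of the 0.01 Hz corner; its edge transient (~16 s time constant)
  otherwise bleeds deep into the recording. The first/last 10 s are
  additionally excluded from cycle extraction.
- MAD thresholds use the raw (unscaled) MAD with a strict `>` comparison,
  so homogeneous cycles (MAD = 0) reject nothing.
- Degenerate cycles (peak not above both troughs) are skipped with a
  warning; constant signals raise `DegenerateSignalError` at z-scoring;
  PMI skips phases with fewer than 3 samples.
- Sample-index convention: times in seconds from recording start, windows
  half-open [start, end); extrema quantized to the sample grid (sub-sample
  interpolation is out of scope).

## Known limitations

- Temporal-feature coupling estimates are attenuated by measurement noise
  (see above); the package measures, but does not de-attenuate, them.
- The belt emulation is phenomenological (smoothed pause-free airflow), not
  a mechanical model of chest-wall displacement.
- The ensemble sampler's Rhat can exceed 1.01 on weakly identified latent
  offsets when true random-effect spreads are ~0; results then carry a
  convergence warning even though `beta_within` is stable.
- Harmonically driven coherence without a fundamental peak is failed, not
  reported separately; the PSD-peak flag is retained in the output.
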