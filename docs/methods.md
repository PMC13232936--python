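# Methods notes

This note documents the models, defaults, and design decisions behind
`erpdecode`, and what the synthetic studies can and cannot show about real
recordings.

## What the generator emulates

Each simulated participant is an epoched tensor (epochs × channels ×
samples, μV) built from four additive components:

1. **Ongoing noise.** Per-epoch AR(1) source time series (coefficient
   `noise_ar`, default 0.97; stationary unit variance) are mixed through a
   random channels × sources matrix that is smooth over the montage
   (Gaussian kernel on unit-sphere electrode positions, width 0.6, plus a
   small rough component), with rows scaled so every channel's stationary
   SD equals `noise_sd` (default 10 μV). At 250–256 Hz an AR coefficient
   of 0.97 concentrates power below ~5 Hz, mimicking the strong
   low-frequency autocorrelation and inter-channel correlation of EEG.
2. **Class signal.** A Gaussian time course centered in the paradigm's
   measurement window (SD = window/4) carried on posterior channels.
   Binary designs use two opposite-sign topographies whose peak difference
   is `effect_amplitude`; multiclass designs assign posterior channels
   evenly spaced preferred angles and use circular-Gaussian
   (von-Mises-style) tuning `exp(κ(cos(θ_class − θ_ch) − 1))`, so κ = 0
   removes all class information — convenient for null studies.
3. **Blinks.** Raised-cosine pulses (default 300 ms, amplitude
   N(150, 30²) μV at the frontopolar peak) with a fixed frontal topography
   (Gaussian fall-off from Fp2, gain −0.8 below the eye) on a Bernoulli
   subset of trials. The per-class probability vector makes the
   ocular-confound scenario (blinks more likely in one class) a one-line
   config change. Blink peak latency is N(400, 100²) ms post-stimulus —
   stimulus-locked blinking that lands inside typical measurement windows.
4. **Gross artifacts.** On a Bernoulli(`artifact_prob`, default 0.05)
   subset of trials, a step at a random onset or a linear drift, amplitude
   uniform in 150–500 μV with random sign, on a random subset of 1–3 scalp
   channels. These have no consistent topography, so ICA should *not*
   remove them — they are the detectors' job.

Montage positions come from a standard 10-20 layout projected to the unit
sphere, with channel name sets matching the three paradigm families (28,
27, and 59 scalp channels) plus one infra-orbital EOG channel; only
inter-channel smoothness matters to the simulation, not anatomical
fidelity. Paradigm presets fix epoch/baseline/measurement windows, class
counts, and sampling rates (256 Hz for the binary paradigms, 250 Hz for
the orientation paradigms; the orientation presets default to the
perception window 100–500 ms, with the memory window reachable through
window arguments).

All randomness derives from `(master_seed, participant_index)`, so a study
is a pure function of its config.

**What it does not emulate:** continuous recordings (data are born
epoched, so segment-level cleaning is represented as epoch-level
plausibility screening), saccades/HEOG, realistic head-model forward
physics, bad channels, behavioral errors, and recording-chain
antialiasing/resampling. Passing tests therefore demonstrate the
*pipeline's* correctness and its behavior under the assumed artifact
structure, not performance claims about any particular real dataset.

## Preprocessing

The "12 dB/oct noncausal Butterworth" family is realized as order-2
Butterworth filters applied forward–backward (`filtfilt`), so the
effective magnitude response is the squared one-pass response:
|H(f)|² = 1/(1 + (f/f_c)⁴) for the lowpass. At a 30 Hz cutoff this leaves
1 Hz essentially untouched and passes ~6 % of a 60 Hz component's
amplitude.

ICA follows the parallel-dataset recipe: copy → 1–30 Hz bandpass →
polyphase resampling to 100 Hz → drop epochs whose global peak-to-peak
exceeds a plausibility limit (default 500 μV; typical per-dataset choices
span 350–750 μV, and no selection rule beyond that range exists, so a
fixed default with an override is used) → fit a full-rank FastICA on the
concatenated kept epochs → transfer weights to the minimally filtered
data. FastICA was chosen as the decomposition because the contract only
requires a convergent, deterministic linear unmixing that separates
independent sources; the fit refuses to run with fewer than `10·n_ch²`
samples (the usual ICA data-quantity heuristic). Blink components are
selected automatically by |Pearson r| ≥ 0.8 between component activation
and the VEOG-bipolar trace — an automated version of the common
visual-alignment criterion; trained IC classifiers are deliberately out of
scope. Correction zeroes the flagged component rows and remixes, a linear
projection on channel space (`mixing @ unmixing ≈ I` to 1e−6), so
correcting a sum equals the sum of corrections.

The 0.1 Hz highpass leg is implemented (as the bandpass lower edge) but is
a near-no-op on zero-mean synthetic noise; only spectral tests exercise
it.

## Rejection conventions

Fixed, testable conventions where the field's tools differ: strict
inequality at the threshold (equality does not flag); rejection-window
endpoints inclusive, ms mapped to the nearest sample; the moving window
defaults to 200 ms with step 1 sample (exhaustive placements); "any
channel" means all scalp channels and excludes the infra-orbital EOG
channel by default (configurable) so corrected blink residue at the eye is
not trivially re-flagged. The statistical threshold pools kept epochs of
*all* participants (empirical mean, population SD) per study and per
preprocessing variant, since the pooled SD depends on what preprocessing
preceded it. Detection never deletes data; masks only clear the keep-flag,
which keeps every decision auditable in the epoch log.

## Decoding

Averaged-ERP leave-one-out 3-fold CV with equated bin sizes
(`floor(min/3)`; leftover trials sit out that iteration and are eligible
again at the next random assignment). Iteration streams derive from
`(seed, iteration)`, making iterations reproducible and independent.
Optional normalization z-scores each (channel, timepoint) feature using
training-fold statistics only, mapping zero-variance features to 0.

The linear SVM (C = 1) is solved by a batched SMO on the dual, vectorized
across (timepoint × fold × class-pair) subproblems — in this design every
binary subproblem has exactly two training averages per class, so hundreds
of thousands of tiny, identically-shaped QPs arise per study and
per-problem library calls would dominate runtime by orders of magnitude.
The solver sweeps all multiplier pairs until the largest update falls
below 1e−8·C; the bias uses free support vectors when any exist and the
margin midpoint otherwise. The test suite pins it against a reference SVM
implementation on random problems (decision values to ~1e−3, identical
labels away from the boundary). Multiclass uses one-vs-one coding with
hinge-loss decoding (score of class k = summed hinge losses of its
codeword; ties to the lowest class index). Shrinkage LDA uses the pooled
within-class covariance shrunk toward its diagonal —
Σ_γ = (1 − γ)Σ + γ·diag(Σ) — inverted by pseudo-inverse so tiny-sample
fits stay defined; γ = 1 reduces to the diagonal (naive-Bayes-like)
discriminant, which the tests verify in closed form.

Accuracy is averaged over iterations first, then over window samples
(immaterial for the mean; fixed for reproducibility of intermediates).
Decoding can be restricted to a time window and decimated; chance-level
and window-mean results are insensitive to decimation, and the shipped
study scenarios decode the measurement window at every sample for binary
designs and every 4th sample for the 16/12-class designs (problem sizes
chosen to keep a full study in minutes on one core).

## Statistics

Cohen's d_z = (mean − chance) / SD across participants with the n−1
sample SD (the convention is not universal; it is fixed here and tested).
The bootstrap SE resamples participants (not iterations) 10,000 times;
degenerate zero-variance resamples are skipped rather than yielding
infinities. Paired comparisons use the standard paired t-test; no
multiple-testing correction is applied across approaches/thresholds, since
rows are reported per comparison. The RMS-of-SEM noise metric is the root
mean square over (condition, channel, timepoint) of SD/√n across kept
trials; for white noise of SD σ and n trials it equals σ/√n, which anchors
the tests.

## Study orchestration

Pipeline order is fixed and logged per participant: (optional 30 Hz
lowpass) → baseline correction → ICA correction (all non-baseline
approaches) → rejection → decoding. The random-removal control reruns a
matched rejection setting, then removes exactly that per-participant
number of trials at random from the same corrected data. Participants
whose surviving class counts cannot fill three folds are reported as
infeasible with their count, never silently dropped. Threshold grids
default to the standard printed sets (50–400 μV for the binary family,
70–400 μV and 150–500 μV for the orientation families; k = 2–6 SD) and
are config-driven.

There is no shell CLI: the package is a library; its functions plus
`scripts/acceptance.py` are the execution surface, and configs/epochs
round-trip through YAML/HDF5 for scripted use.

## Known limitations

- FastICA occasionally reports non-convergence on hard mixtures; the
  decomposition is still returned with `converged=False` rather than
  failing the pipeline.
- The blink topography is exactly rank-1 and fixed within participant, so
  ICA correction is easier here than for real blinks, whose topography
  drifts; the ≥70 % attenuation property should be read in that light.
- Per-participant decoding accuracy has high variance (few test averages
  per iteration and temporally correlated noise); group-level claims are
  the intended use, as in the underlying experimental literature.
- The statistical threshold assumes a roughly unimodal pooled voltage
  distribution; with pathological artifact rates the pooled SD inflates
  and the detector becomes conservative — visible in the masks'
  diagnostics.
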