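# Methods

This note records the models, the numerical choices, and the limits of what
the synthetic experiments show.  It is the design rationale behind the code;
all quantitative statements here are computed by the test suite or by
`scripts/acceptance.py`, not asserted from memory.

## Synthetic trial model

The generator emulates a cue-driven acquisition: `n_movements` classes
(default 17) plus rest (class 0), `n_repetitions` repetitions in sequential
or random order, 12 channels at 2 kHz.  Stock layouts: assay A/B = 6/10
sequential repetitions, C/D the same counts in random order.  Burst and rest
durations are protocol parameters (defaults 5 s and 3 s — typical values for
cue-driven protocols; they are stand-ins, not measured quantities, and do not
affect algorithm correctness).

The signal is amplitude-modulated zero-mean Gaussian noise, the standard
sEMG surrogate.  During a burst of class c, channel k records

    baseline_noise(sd = baseline_noise_sd)
      + snr · activation[c,k] · envelope(t) · white_noise

`activation` is a per-class × per-channel nonnegative gain matrix; the stock
subject draws 4–9 active channels per class with gains in [0.3, 1.0], so
classes differ in both pattern and level.  `snr` (default 3) scales movement
modulation relative to baseline and is the single separability dial.

**Envelope.**  The amplitude profile is a Gaussian bump spanning the burst
(motor-unit recruitment waxes and wanes), truncated at the burst support with
σ = duration/2, leaving ≈61% of peak modulation at the edges.  The truncation
is deliberate: muscle activation switches on and off abruptly at the ~100 ms
scale, and an envelope decaying smoothly to zero would make the true onset
statistically unidentifiable — no boundary estimator could recover it, so
"ground-truth onset" would be meaningless for evaluating relabeling.

**Label streams.**  `true_labels` mark the envelope support.  `stim_labels`
shift each burst later by a per-burst reaction-time delay drawn uniformly
from `reaction_delay_range_ms` (default 60–300 ms), giving the relabeler a
meaningful but recoverable misalignment.  Repetition ids attach each rest gap
to the following burst's repetition so that repetition-based splits keep rest
windows in every fold.

**What the generator does not model:** motor-unit action-potential trains,
inter-channel correlation, fatigue, electrode shift, cross-day drift.  The
synthetic classes are more separable than real inter-subject sEMG —
accuracies here sit near the ceiling, so passing tests demonstrate pipeline
correctness and the *relative* behavior of the variants (rejection helps,
regularization stabilizes), not absolute real-data accuracy levels.

## AVT filter

Per channel, independently (channels are separate electrodes).  The signal is
rectified first (the filter is defined on rectified amplitude).  The first
200 ms window is processed with unweighted whole-window statistics; each
subsequent 10 ms slide computes

    MSA = ff1 · mean(trailing 95%) + ff2 · mean(incoming 5%)
    MSD = ff1 · sd(trailing 95%)   + ff2 · sd(incoming 5%)

from the *already filtered* buffer (a single causal streaming pass), and
replaces only the incoming stride's samples outside [MSA − MSD, MSA + MSD]
with MSA.  Only the incoming stride is ever mutated, so no sample is touched
twice.  SD is the population form everywhere (segments are treated as
complete populations; fixed for cross-implementation determinism).  The band
test carries a 1e-12 relative slack so that constant signals are exact fixed
points despite rounding in the segment mean.  Samples after the last complete
window pass through unchanged; output length always equals input length.

## GLR relabeling

For each stimulation burst, an analysis window extends `search_margin_ms`
(default 500 ms) beyond the stimulation boundaries, clamped to midpoints
between neighbouring bursts.  Candidate onsets t0 sweep a 30 ms grid around
the stimulation onset; candidate offsets t1 sweep the same grid around the
stimulation offset, subject to t1 − t0 ≥ `min_movement_ms` (default 100 ms —
shorter than any plausible cued movement, long enough to exclude degenerate
one-step bursts).  The score is the log-likelihood of the three-segment
Gaussian model (rest | movement | rest, each segment with its own ML mean and
population variance of the rectified amplitude, summed over channels) minus
the constant single-segment term; the maximizing pair wins, ties going to the
earliest pair in scan order.  Segment variances are floored at
1e-12·(amplitude range)² so constant segments contribute finite likelihood.
Cumulative sums give O(1) segment statistics, so the exhaustive search over
~35 × 35 grid pairs per burst costs milliseconds.

The likelihood model (Gaussian mean+variance change on rectified amplitude)
is a design choice: amplitude modulation is exactly how the generator — and
to first order real sEMG — encodes muscle activity.

## Features

Window count is floor((n − W)/S) + 1; the trailing partial window is
dropped.  RMS, VAR, MAV, SD per channel per window, population forms, so
SD² = VAR and RMS² = VAR + mean² hold window-wise.  Windows are labeled by
majority vote of the chosen label stream; ties go to rest (conservative
toward no actuation).  Features default to the AVT-filtered rectified signal
(the pipeline order); raw mode is available.  The implementation reduces
numpy sliding-window views along the contiguous axis, which reproduces a
naive per-window loop bit-identically (verified in tests).

## ELM / RELM

Features are z-scored with training-set statistics (SDs floored at 1e-12)
before the kernel — with weights in [−1, 1] and biases in [−1.5, 1.5], raw
feature scales would saturate φ(z) = exp(−z²).  Targets are one-hot {0, 1};
argmax semantics are unchanged by the coding.  A single seeded generator
draws W (L × d, row-major) before b, making cross-run reproducibility
testable.

ELM solves Hβ = T by minimum-norm least squares (LAPACK gelsd, an SVD
solver).  RELM uses the ridge normal equations, primal
(HᵀH + I/C)⁻¹HᵀT when L ≤ N and the algebraically equivalent dual
Hᵀ(HHᵀ + I/C)⁻¹T otherwise.  Larger C means weaker regularization; C → ∞
recovers the ELM solution on well-conditioned problems (tested at C = 1e12
to 1e-4 relative).  Default C = 1, exposed as a flag; the default hidden
layer size L = 200 sits in the lower part of the conventional 50–1000 sweep
range and is a good accuracy/cost point for the synthetic task —
`select_hidden_neurons` performs the full validation sweep when wanted
(argmax of validation accuracy, ties to the smallest L).

Prediction ties at the argmax break to the lowest class id.

## Reliability rejection

r_i = max_c output_i,c on the raw (unnormalized) outputs — the rejection
heuristic operates on the argmax values directly, not on calibrated
probabilities.  Threshold th = μ(r) − σ(r) (population SD), computed by
default over the evaluated test block, matching offline evaluation; a
deployment would freeze the threshold from training outputs instead, and the
profile object supports that.  Windows with r < th receive the abstain
marker (−1) and are excluded from reliable metrics, with the abstained
fraction reported separately as the non-reliable-data rate.  A soft sanity
band of 2–25% discard triggers a warning (not an error) outside it.

## Metrics and splits

Overall accuracy = correct/total × 100.  Weighted accuracy = unweighted mean
of per-class recalls × 100; classes with zero test samples are excluded from
the mean with a logged notice.  Confusion matrices are plain count matrices
(rows = true class); tests recompute both metrics from an independently
built confusion matrix.  The default split for 6-repetition assays is
repetitions {1,3,4,6} train / {2,5} test; other repetition counts use the
first ~66% of repetition ids for training.

## Problem sizes in the test suite

Unit tests run on miniature protocols (3–4 movements, ≤3 repetitions,
~1 s bursts) — structurally identical to the full assays, seconds to run.
The end-to-end property tests use full assay A (17 × 6 bursts, ~1.6M samples
× 12 channels): 20 seeded trials for the rejection-improvement property and
5 seeds × 5 window lengths (100–500 ms) for the segmentation-robustness
property, sizes chosen to keep the whole suite in the tens of minutes on one
core while still exercising study-scale data.

## Known limitations

- Synthetic separability sits near the ceiling; absolute accuracies are not
  comparable to recorded-data benchmarks, and the weighted metric can exceed
  the overall metric here (errors concentrate in rest windows at
  transitions), unlike on real data where movement classes are the hard part.
- The GLR model assumes a single contiguous burst per stimulation run; it
  refines boundaries but never splits or merges bursts.
- The reliability threshold is a global statistic of the evaluated block; a
  per-class or adaptive threshold is out of scope.
- MAT-file support covers v5/v7 (scipy.io); v7.3 (HDF5) files are not read.
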