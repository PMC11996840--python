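# Methods

This note records the models implemented in `emgmeo`, the conventions chosen
where the underlying methods leave room, and what the synthetic benchmark
does and does not establish.

## Energy operators and conditioning

The lag-k energy operator Ψₖ(xₙ) = xₙ² − xₙ₊ₖ·xₙ₋ₖ is computed for every
interior sample; the k samples at each array end, where xₙ₊ₖ or xₙ₋ₖ does
not exist, are set to 0. The multi-resolution operator takes the pointwise
maximum over lags 1..k_max, and near the edges each sample pools only the
lags defined there. This "no fabricated samples" convention means array
boundaries can never carry spurious energy; its cost is that the first and
last samples are always 0, which is irrelevant for recordings that begin in
rest. The pooled lag set is all integers 1..k_max by default; a
`scales="odd"` switch restricts it to odd lags for consistency with
parameter sweeps quoted in odd steps (pooling every lag is the literal
multi-resolution definition and the default).

Conditioning is a hop-1 centred sliding median of length L (odd). At the
edges the window shrinks symmetrically (always odd) rather than padding —
again no invented values. A frame-hop variant (non-overlapping frames of
length L, constant within each frame) is available behind `mode="frame"`
and coincides with the sliding filter at frame centres; the sliding form is
the default because per-sample change-point detection needs a sample-aligned
series.

## MEOTD

Baseline estimation frames the first `baseline_ms` (default 1000 ms) of the
conditioned energy with window `frame_len` = 128 samples and hop `step` =
64 samples — at 1024 Hz that yields 15 frames, enough for a stable mean of
frame means and sds. These three values are conventions of this package
(the method itself only requires "an activity-free prefix, framed"); they
are exposed in `DoubleThresholdConfig`. Population (ddof = 0) sds are used.
The threshold is Th1 = mean(frame means) + j·mean(frame sds).

The double-threshold scan implements strict inequalities: onset requires
`ton` consecutive samples strictly above Th1, offset `toff` consecutive
samples strictly below; a sample exactly at Th1 therefore blocks an onset
run and blocks an offset run too. Millisecond parameters convert to samples
as round(ms·fs/1000) in exactly one utility (`ms_to_samples`). An activity
still open at the end of the recording is closed at the final sample so the
alternation invariant always holds; an onset that would fall *on* the final
sample is dropped rather than paired degenerately.

The defaults Ton = 100 ms and Toff = 30 ms come from contraction
physiology: a voluntary contraction lasts at least about 100 ms, and
switching from rest to the next activation takes at least 25–30 ms.

## MEONND

The convolution layer is evaluated literally from the neuron expression
(term by term, with the frozen weights W1=W2=W3=1, W4=−1, w11=w14=2, w22=1,
w33=w34=1/4), not by calling the energy operator — the algebraic identity
C_k ≡ Ψₖ is then a genuine machine-precision cross-check in the test suite
rather than a tautology. Non-canonical weights are rejected at
construction: the layer is fixed by design, not trainable.

The median filter runs once on the pooled series by default, mirroring the
threshold pipeline's order; a per-channel pre-pooling variant sits behind
`median_stage="per_channel"` for experiments.

**Sampling-layer normalization window.** The sampling layer maps the pooled,
conditioned energy into [0, 1] by min-max normalization, y = (x − min)/(max
− min), with the degenerate max = min case mapping to 0. Three window
choices are implemented:

* `"global"` (default) — extremes over the whole series;
* `"running"` — causal extremes over all samples seen so far;
* `"trailing"` — extremes over the 2·k_max samples ending at the current
  one, truncated at the start of the series.

The default is a deliberate design decision. A trailing window of 2·k_max
samples (≈ 29 ms at the default k = 15 and 1024 Hz) makes the layer
scale-invariant *locally*: inside any statistically stationary stretch —
rest or contraction alike — y is distributed the same way, so thresholding
y detects transitions rather than sustained activity, and on a 20 dB
synthetic recording the trailing variant fragments 30 contractions into
~1500 activations. Whole-series normalization preserves the properties the
architecture is meant to deliver (output in [0, 1], no baseline prior,
invariance to global amplitude rescaling) while making y small during rest
and large during contractions, which is what a burst detector needs. The
price is that the detector is no longer causal/streaming and presumes at
least one contraction is present in the analyzed window; `"running"` is the
causal compromise (it converges to the global behaviour once the first
burst has been seen). All three are exposed so the choice is auditable.

The classifier is sigmoid + hard limiter: active iff 1/(1+e^(−y)) ≥ T, with
ties activating. Since y ∈ [0, 1], the sigmoid output lives in
[0.5, 0.731]; thresholds at or below 0.5 mark everything active, which is
why the tuning grid's only effective values sit just above 0.5 (default
0.506). Post-processing removes activation runs shorter than 30 ms; short
*gaps* between runs are deliberately not merged (removal is the only
documented rule). Onsets are the first sample of each surviving run,
offsets the first inactive sample after it, and a run still open at the end
closes at the final sample.

## Evaluation

Each true change-point owns a valid interval [t − 300 ms, t + 200 ms]: EMG
activity can lead measurable movement by up to ~260 ms (electromechanical
delay, rounded up to 300 ms for equipment latency), and a control response
more than ~200 ms late is perceptible. The intervals partition the
recording into baseline / onset-segment / activity / offset-segment
regions. For a contraction shorter than 500 ms the onset and offset
intervals would overlap; they are abutted at the midpoint of the overlap,
leaving an empty activity region — the partition stays a tiling, which the
`RegionPartition` constructor enforces. Overlapping intervals of *distinct*
contractions are refused with an error: such truth sets have no unambiguous
region assignment (the synthetic generator's 600 ms minimum gap guarantees
they never arise there).

Counting granularity is region-level: one TP *or* FN per onset/offset
segment (a segment holding multiple events or a wrong-kind event scores a
single FP and no TP), one TN per empty baseline/activity region, one FP per
stray event. Region-level TNs keep the class sizes balanced; per-sample
TNs would swamp every other count. Timing bias is the RMS deviation (ms)
over matched TP pairs only, reported as missing when there are none —
scores requiring it then fail loudly rather than silently defaulting.
Detected events outside the recording span are ignored with a warning.

## AHP tuning

Weights come from row geometric means of the judgment matrix, normalized to
sum 1; λmax is the mean of (A·w)ᵢ/wᵢ, CI = (λmax − n)/(n − 1), CR = CI/RI.
This eigen-recipe (rather than the principal power-iteration eigenvector)
is pinned because it reproduces the published weight table exactly at
4 decimals, e.g. the 18^(1/5) = 1.7826 eigenvector entry. Two further
pinned conventions, both verified numerically: the canonical matrix carries
exact reciprocals (1/3, not the 4-decimal 0.3333, which would shift λmax
from 5.0133 to 5.0132), and RI(5) = 1.11 (some published RI tables say
1.12), which yields CR = 0.003. Reproducing the published composite scores
requires using the weights *rounded to 4 decimals*, as printed; the
full-precision weights shift the fourth decimal of some scores. The
composite score consumes TPRs and F1 as fractions and biases in ms divided
by 10⁵ — the scaling that makes the published score arithmetic consistent.

The tuning grids are k odd in 1..41, L odd in 3..83 (L = 2k+1 pairs a
median window to a lag), j integer in 1..10, and T from 0.406 in steps of
0.02. The quoted upper endpoint 0.514 is unreachable with that step and is
excluded, so the T axis ends at 0.506. Grid cells are scored on counts
micro-averaged over all recordings with bias pairs pooled; cells whose
detector raises, or whose metrics cannot be scored (no TPs → no bias), are
recorded as missing and skipped; ties break toward the lexicographically
smallest (k, L, third parameter).

## Synthetic benchmark

The generator emulates a wrist-muscle surface-EMG acquisition: 1024 Hz,
120 s, Gaussian baseline noise, and 30 voluntary contractions of 0.5–2 s
modeled as band-limited (20–450 Hz, 4th-order zero-phase Butterworth)
Gaussian noise scaled to σₐ = σ_b·10^(SNR/20) — default SNR 20 dB — under a
trapezoidal envelope with 50 ms linear ramps. The ramp start *is* the
ground-truth onset, which makes timing-bias assertions exact. Bursts keep
≥ 600 ms separation (disjoint evaluation regions) and start no earlier than
2 s (an activity-free prefix for threshold estimation). Everything is
drawn from one seeded generator: identical seeds give bit-identical
recordings.

What this surrogate does **not** capture: motor-unit action-potential
structure (no MUAP trains, no recruitment/firing-rate modulation within a
contraction), amplitude non-stationarity and fatigue, movement artefacts,
powerline interference, electrode-contact drift, and inter-subject
variability. Passing the synthetic recovery suite therefore shows the
pipeline is implemented correctly and behaves as designed under its own
stated noise model at a favourable SNR — it is not evidence about detection
rates on recorded human EMG, whose reference metrics here derive from a
20-subject dataset that is not publicly available.

Problem sizes in the test and acceptance suites (20 recordings × 30 bursts
× 120 s for the recovery property; 200 random instances per brute-force
oracle) were chosen as the smallest sets that exercise burst-count and
duration variability while keeping the full suite comfortably fast.

## Known limitations

* MEOTD's baseline estimate is a fixed prefix; there is no adaptive or
  rolling re-estimation, so slow noise-floor drift degrades Th1.
* MEONND's default normalization is whole-series (see above); for streaming
  use choose `"running"` and expect degraded behaviour before the first
  contraction.
* Multi-channel fusion, EDF/WFDB readers and figure-style plotting are out
  of scope; the CSV formats are the integration surface.
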