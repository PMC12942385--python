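# Methods

## Chart model and letter scoring

The default chart carries the lines 6/120, 6/60, 6/36, 6/24, 6/18, 6/12,
6/9, 6/6 — the conventional clinical progression between the stated
endpoints; intermediate lines are configurable through `ChartSpec` because
different clinics thin or extend this set. logMAR is log10(denominator/6),
and the per-letter increment is fixed at 0.02 logMAR: five-optotype rows on
a 0.1-per-line progression give 0.1/5 per letter. The sign convention is
clinical: "−m" means m optotypes missed on the recorded line (worse, +0.02·m),
"+k" means k optotypes read on the next smaller line beyond a fully read
row (better, −0.02·k).

The default letter vocabulary is the Sloan optotype set minus "O" (nine
symbols); "O" is dropped because it is indistinguishable from "zero" in
spoken responses. Digit charts use 0–9. Rows never repeat a symbol within
a presentation: with spoken input, a repeated symbol makes the
transcript-to-position assignment ill-posed.

`logmar_to_snellen` picks the chart line minimising |Δ logMAR| and clamps
the adjustment to ±2. Because adjacent default lines are ≥ 0.125 logMAR
apart and adjustments reach only ±0.04, the inverse is exact on everything
the forward map can produce; values more than two letters beyond the
largest line return a `WORSE_THAN_CHART` sentinel whose logMAR is +inf so
that ordering comparisons (the pinhole trigger, monotonicity checks)
remain defined.

## Examination protocol

Each phase descends in SINGLE mode (first optotype of each line) until a
miss, then anchors ROW mode at the last single-optotype pass. A row passes
iff strictly more than half its optotypes are read (≥ 3 of 5). Passing
advances to the next smaller line; a fail ends the phase once any row has
passed. If the anchor row itself fails before any pass, the engine backs
up one larger line at a time — the recorded acuity must be a *passed row*,
and without the back-up a patient whose single-optotype descent overshot
(one lucky single) could end with no row-confirmed score at all. A miss on
the very first single optotype, with nothing passed before it, scores the
phase worse-than-chart.

Adjustments at finalisation: misses on the recorded row give −m
(necessarily m ∈ {1,2}, since a pass allows at most two); only a 5/5
recorded row can earn +k from k ∈ {1,2} correct on the next smaller row
(k ≥ 3 would have passed that row instead, so +k is structurally capped at
+2). Misses take precedence over extras because "+k" is meaningful only
relative to a fully read line.

The pinhole branch triggers when the unaided score, adjustments included,
is strictly worse than 6/9 (logMAR > log10(9/6) ≈ 0.176): exactly 6/9 does
not trigger. Pinhole phases rerun the complete single-then-row protocol
starting two lines above the eye's unaided score (clamped to the chart
top) — the standard clinical shortcut, since pinhole acuity is almost
never worse than unaided and starting at 6/120 would waste presentations.
BLURRED and SKIP both mean "cannot read this stimulus"; REPEAT re-presents
the identical stimulus without affecting tallies. Phase order is right
unaided, left unaided, right pinhole (if triggered), left pinhole (if
triggered).

Timestamps come from an injectable clock (default: a fixed-step counter),
so event logs and phase durations are fully deterministic and sessions
replay byte-for-byte. Row contents derive from the session seed, the
phase, the line and a per-line attempt counter, so the second eye and any
row retest get fresh rows while REPEATs do not.

## Pose engine

Marker-set classification is a pure function of the detected id set; the
two singleton pinhole ids map to their base pose ({3}→Left like {4}→Right),
and any mix of left-family {1,3} and right-family {2,4} ids is Invalid
(impossible with one occluder). Pose labels name the eye under test, so
the "Right" pose means the left eye is covered. The iris check requires the
covered eye's iris inside the occluder bounding box (union of detected
marker boxes, inflated by 10% of its diagonal) and the tested eye's iris
outside it; a missing covered-eye landmark counts as covered, because full
occlusion removes the landmark — without that rule every properly occluded
pose would fail. Coordinates are image pixels, origin top-left.

The half-lowered-pinhole poses classify as valid base poses by design:
once the flap hides one marker, the remaining id is indistinguishable from
a legitimate base pose, a documented limitation of marker-only sensing
that the synthetic fixtures reproduce rather than patch.

Stream stabilisation: a valid label must persist for k consecutive frames
(default k = 5, roughly 150–250 ms at webcam rates) before it is emitted,
while any Invalid frame is emitted immediately — a safety asymmetry: the
exam pauses fast and resumes deliberately. `debounce` returns
(frame, label) emission events because downstream consumers need to know
*when* a pose established. The moving-average smoother is the trailing
window mean used for camera-control signals.

An image-based detection backend can be injected behind the
`detect(image) -> PoseObservation` contract; the shipped engine and all
tests consume synthetic observation streams only.

## Response interpretation and WER

Transcripts are uppercased, punctuation-stripped, and passed through an
editable homophone table (package data, `data/homophones.yml`) mapping
spoken forms ("bee"→B, "zero"/"oh"→0 in digit mode) onto symbols;
normalisation is idempotent. Parsing is conservative: command words alone
form a command; vocabulary symbols (unknown tokens dropped) form a symbol
response; a command mixed with symbols, or no usable content, resolves to
REPEAT so the stimulus is simply shown again. Row marking is positional
after dropping unknowns; short responses leave trailing positions wrong.

WER uses the unit-cost edit-distance alignment with a diagonal-first
backtrace, so ties between a substitution and an insertion+deletion pair
resolve to the substitution; the S+I+D total is the Levenshtein distance
regardless, which is what the independent oracle (edlib) verifies
exhaustively in tests. The real VAD+ASR pipeline is deliberately out of
scope: it is represented only by the backend contract
`utterance → Transcript`, with `MockRecognizer` as the deterministic,
seedable implementation used everywhere.

## Patient simulator

The response model is a logistic psychometric function with a guessing
floor: P(correct) = g + (1−g)·σ((x−L)/s) for optotype size x, threshold L
and slope s in logMAR units; s = 0 degenerates to the deterministic
threshold reader used for exact parameter-recovery tests. The guessing
floor defaults to 1/9 (letter charts) or 1/10 (digits) — chance for
forced-choice naming from the vocabulary. Wrong answers are uniform over
the other vocabulary symbols; when an entire stimulus fails, the patient
says "blurred" with probability 0.3 (people at threshold usually offer
guesses, but not always — the value only shapes event traffic, not
scores, since BLURRED and an all-wrong row are equivalent to the engine).
A slope of 0.03–0.06 logMAR is a realistic psychometric spread for letter
charts; 0 is the default because exactness, not realism, is what most
tests need. Pinhole acuity is a second per-eye threshold constrained to be
no worse than unaided.

The cohort generator emulates the *structure* of a paired-methods
validation study, not any particular clinic: manual acuities from a
truncated Normal on [0, 1.1] logMAR (mean 0.2, SD 0.25, a plausible
tertiary-clinic mix), automated = manual + bias + Normal noise, both
snapped to the 0.02 letter grid, pinhole columns only for eyes worse than
6/9, and an optional fraction of planted outlier eyes shifted by a
uniform 0.4–0.7 logMAR with random sign (flagged in a `planted_outlier`
column so filter tests can compare against ground truth). Bias and noise
default to zero so the generator is neutral unless a scenario sets them.
What it does **not** emulate: fatigue and learning effects, accent- or
age-dependent recognition failure, correlated eyes, or the acuity
distribution of any real cohort — so passing statistics here demonstrate
correctness of the estimators, not clinical performance.

## Agreement statistics

Bland–Altman uses the sample SD (n−1) and the fixed 1.96 Normal quantile
for the limits of agreement — the original convention — rather than a
t-quantile. The ICC is ICC(2,1): two-way random effects, absolute
agreement, single measurement, computed from the two-way ANOVA mean
squares with the F-based Shrout–Fleiss/McGraw–Wong confidence interval;
absolute agreement is the right form for an inter-method question because
a systematic offset between methods must count against agreement.
ICC(3,1) (consistency) is available via `model=`; the result carries a
model tag so the choice is auditable. Tests cross-check both forms against
an independent reference implementation (pingouin) to 1e−6.

Eyes are analysed as independent units (n = 2 × participants, no
clustering correction), matching the design convention of paired-eye VA
validation; the outlier filter alone is participant-level: one eye at
|manual − automated| ≥ 0.4 logMAR removes both of that participant's eyes.
The boundary is inclusive and carries a 1e−9 tolerance because grid-valued
differences can land at 0.4 minus one ulp. Wilcoxon, Shapiro–Wilk and
Spearman delegate to scipy behind this module's interface (zero
differences dropped; exact Wilcoxon null for n ≤ 25 without ties, else the
tie-corrected normal approximation; Shapiro–Wilk valid for 3 ≤ n ≤ 5000;
Spearman as mid-ranks then Pearson). Repeated-measures covariate modelling
(e.g. age on test duration) is out of scope: it is a routine off-the-shelf
model with nothing system-specific in it.

## Problem sizes and numerical choices

The shipped property checks use sizes at which their statistics are
decisive: 100 jitter seeds × 9 poses for the golden table, all 8 chart
lines exhaustively for threshold recovery, all token pairs of length ≤ 5
over a 3-symbol alphabet (132,132 pairs) for the WER oracle, 10,000
simulated differences for limits-of-agreement coverage, and 200 seeds ×
n = 500 per true-ICC point for estimator recovery. All randomness flows
through `numpy.random.default_rng` seeded from a single session or CLI
seed; derived seeds stay below 2^31.

Known limitations: no audio or image processing is performed anywhere (the
recognizer and detector are contracts with deterministic stand-ins);
illumination robustness of marker detection is not modelled; the engine is
a single-threaded pure transition function, so concurrency, camera
control and UI transport are host concerns; and simulated cohorts cannot
reproduce the clinical agreement values of any real study — they validate
the machinery that would compute them.
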