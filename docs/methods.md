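# Methods

## The model

Speech articulation is treated as a rapid human movement: the articulatory
apparatus (the end effector) responds to a sequence of time-spaced neuromotor
commands, and each command produces a simple movement — a *stroke* — whose
speed profile is lognormal in time,

    |v_j(t)| = D_j * Λ(t; t0_j, μ_j, σ_j)
             = D_j / (σ_j √(2π) (t − t0_j)) · exp(−(ln(t − t0_j) − μ_j)² / (2σ_j²)),

where `D_j` (mm) is the movement extent, `t0_j` (s) the command time, `μ_j`
the log time delay of the neuromuscular response, and `σ_j` its log response
time.  Each stroke travels along an arc of a circle whose direction sweeps
from `θs_j` to `θe_j` following the lognormal's cumulative weight; the
velocity of a complex movement is the vector sum of its time-overlapped
strokes, and the trajectory is a sum of overlapped circle arcs linking
*virtual target points* (VTPs) — the positions each stroke aims at but need
not reach.  Reconstruction quality is reported as

    SNR = 20 log10( Σ v_o²(t) / Σ |v_o(t) − v_r(t)|² )  dB,

computed on the shared sampling grid (the sampling step cancels in the
ratio).  Reconstructions below 15 dB are conventionally inadequate.

The value of the lognormal at `t = t0` is defined as 0 (its left limit).
Strokes with `|θe − θs| < 1e−8` rad use the analytic straight-stroke limit
(the arc formulas divide by `θe − θs`).

## From formants to kinematics

The first two formant tracks map linearly onto a planar kinematic space:
`y = c1·F1`, `x = c2·F2` with `c1 = k(1−α)`, `c2 = kα`.  The proportion
parameter `α ∈ [0,1]` comes from the speaker's vowel triangle: fitting the
/a/–/i/–/u/ extremes with an equilateral triangle and requiring the /i/–/a/
and /i/–/u/ sides to be equal gives

    α = (F1a − F1i) / [ (F1a − F1i) + (√3/2)(F2i − F2u) ],

which is scale-free in the anchors.  The scale constant `k = L2 / (α (F2i −
F2u))` (mm/Hz) fixes physical units from a reference articulatory excursion
`L2`; it does not affect the decomposition.  Defaults are `α = 0.3` and
`k = 0.04` mm/Hz, which keep peak speeds near measured articulator speeds
(~200 mm/s).  The y axis grows with F1 as the map is printed; no vowel-chart
flip is applied, since sign conventions affect neither speeds nor any derived
parameter.

Unvoiced gaps carry no formants; interior gaps are linearly interpolated
(treating the gap as a movement between the flanking voiced positions) and
edge gaps are trimmed.  Tracks are resampled to a uniform 10 ms step.
Velocity is obtained by central differences (one-sided at the edges); an
optional zero-phase 4th-order low-pass at 15 Hz (the articulatory band) can
be applied before differentiation but is off by default, keeping the default
path literal differencing.

The shipped vowel anchors: the American-English sets are the published adult
means of a large acoustic study of English vowels (they yield α = 0.27 for
males, 0.258 for females).  The German sets are approximate long-vowel means
recalled from secondary literature on the Kiel Corpus of Read Speech and are
marked as such; they yield α ≈ 0.22/0.24, and users with speaker-specific
anchors should supply their own.

## The inverse problem (stroke extraction)

Decomposing an observed velocity into lognormal strokes is a nonconvex
fitting problem with many near-equivalent minima.  The extractor is greedy
with a global refinement and three safeguards:

1. **Candidate detection.**  Local maxima of the unexplained speed (the norm
   of the residual planar velocity) above `peak_floor` (1%) of the global
   maximum, strongest first; equal heights resolve to the earlier peak.
2. **Characteristic-point initialization.**  The peak's sub-sample mode is
   located by a local quartic fit (the left/right asymmetry that encodes σ
   is only a few milliseconds, well below the 10 ms sampling step).
   Crossing times of an adaptive level (half maximum when the flanking
   valleys descend that far; raised just above the deeper valley fraction
   under overlap) invert the lognormal's closed forms for σ, μ, t0 and D.
   Angles are initialized straight along the velocity direction at the peak,
   where the stroke dominates its neighbours; curvature is left to the
   refinement.
3. **Local fit, then joint refinement.**  The new stroke is fitted to the
   residual inside its own bump (between the flanking valleys) with its mode
   anchored to the candidate peak, then all strokes are refined jointly by
   bounded trust-region least squares on the planar velocity, with an
   analytic block-sparse Jacobian.  A refinement step that would lower the
   SNR is rejected.

Bounds: σ ∈ [0.01, 1.5]; μ ∈ [−2.25, −0.85] (the fluent-speech range
widened twofold about its centre — this is what blocks degenerate spike
fits, where t0 drifts far into the past with μ compensating); t0 inside the
observation span and within ±0.15 s of its well-initialized value; each
amplitude capped at 4× its own seeding estimate (unbounded amplitudes admit
pairs of huge mutually-cancelling strokes that reconstruct the signal with
meaningless parameters); angles within ±π/2 of their initialization (strokes
are mild arcs; larger sweeps mimic unrelated stroke sums).

Iteration stops at the SNR target (default 25 dB), on candidate exhaustion,
or at the stroke budget.  Three post-passes then run:

* **Pruning** (backward elimination): the weakest-amplitude stroke is
  removed if the re-refined reconstruction loses less than 3 dB of SNR —
  capped at an 80 dB ceiling beyond which fidelity differences have no
  physical meaning — which absorbs redundant split strokes into their
  neighbours and yields a minimal stroke count.
* **Deep polish**: one tight final joint fit (ftol 1e−13); the incremental
  refinements routinely stop short in the narrow curved valley around a
  solution.
* **Seeded restarts**: if the result stays below both the target and a
  100 dB ceiling (on model-generated signals that usually indicates a wrong
  local basin), up to 2 retries re-run the greedy pass drawing each next
  candidate at random among the strong peaks (≥50% of the current maximum),
  so the cascade unfolds in a different order; the best SNR wins.  All
  randomness derives from the configuration seed, so results are
  reproducible bit-for-bit.

When only a scalar speed profile is given, angles are fixed at zero and only
the speed residual is minimized.

## Derived parameters and evaluation

From a time-ordered stroke sequence the package reports the mean
inter-command time Δt̄0, mean per-stroke peak speed V̄p, and means of μ, σ
and |D| — the quantities sensitive to neuromotor aging.  The inter-command
and peak-speed means are implemented literally as printed in the source
model — sums starting at the second stroke divided by NbLog, not NbLog−1 — 
with a `conventional_means` flag for the conventional estimators; the two
differ by the factor NbLog/(NbLog−1).

Lognormal–phoneme matching takes each stroke's support at 5% of its own
peak (by bracketed root finding on each side of the mode) and counts, per
phoneme interval: one true positive if any support overlaps (the assigned
stroke is the overlapping one whose peak is nearest the phoneme midpoint — 
the choice of assignee does not affect TPR), overlapping-minus-one false
positives, non-overlapping strokes as true negatives, and a false negative
when nothing overlaps.  TPR divides by the phoneme count; TNR uses the
literal NbLog−1 denominator and can exceed 1 — the report flags that rather
than clipping, and flags TNR as undefined when NbLog = 1.  The timing error
ε_t is the RMS difference between each phoneme transition and its nearest
speed-peak time; transitions default to the N_p−1 interior interval
boundaries, and ε_t is taken over the pairs actually formed.

Group comparison (e.g. young vs middle vs older speakers) is a one-way
ANOVA plus pairwise tests with Bonferroni correction (raw p × number of
pairs, capped at 1) at the 0.05 threshold — standard statistics via scipy,
with the exact-equal-means corner (F numerically ≈ −0, p undefined) clamped
to F = 0, p = 1.

## The synthetic generator

Because the corpora the method targets are external, every stage is
exercised on synthetic data built from the model's own forward picture:

* a **sound map** — a triangular lattice inside the equilateral vowel
  triangle (side L2 = 16 mm, a representative /i/–/u/ tongue excursion;
  spacing L2/4, giving several sites per edge);
* an **action plan** — a random walk over adjacent sites, one straight
  stroke per hop (D = hop distance, angles along the hop), with
  inter-command gaps drawn from [60, 120] ms and per-stroke μ ∈ [−1.9, −1.2],
  σ ∈ [0.05, 0.3] — the ranges observed in fluent adult speech;
* a **formant track** via the inverse acoustic map (F1 = y/c1, F2 = x/c2,
  offset so the minima sit at 300/800 Hz), with optional additive white
  Gaussian noise at a stated SNR (relative to each track's excursion power)
  and an optional contiguous interior unvoiced gap;
* an aligned **segmentation** whose interior boundaries sit exactly at the
  stroke peak times (in temporal order), so ground-truth matching gives
  TPR = 1 and ε_t = 0 by construction.

What this emulates — and what it does not.  The generator produces exactly
lognormal, mildly overlapping, straight strokes with clean formant tracks;
real speech adds co-articulation, curvature, formant-tracker errors and
model misfit.  Passing recovery tests therefore demonstrates that the
inverse machinery is correct and well-conditioned under the model's own
assumptions, not that real speech is lognormal — that question is empirical
and needs corpora.

## Benchmark conditions and numerical choices

The parameter-recovery study runs 100 seeded plans of 3–8 strokes under the
generator conditions above, with the extractor in full-reconstruction mode
(SNR target 200 dB, so stopping is governed by the candidate floor; the
15 dB adequacy bound is what gets scored, not the stopping rule).  True
strokes are paired with the extracted stroke of nearest peak time.  Under
heavy overlap the decomposition is not unique — distinct stroke sets can
reproduce the same velocity to 90+ dB — which is why the pruning, polish
and restart passes exist; the residual failure mode (a small fraction of
plans settling in an alternative basin) is visible as recovery errors
concentrated on plans whose final SNR stays in the 80–100 dB range.

Other defaults: sampling step 10 ms everywhere; stroke support level 5%;
SNR cap for exact reconstructions reported as +∞ unless a cap is requested;
phoneme intervals are half-open `[t_start, t_end)`.

## Known limitations

* Only F1/F2 are used; higher formants are out of scope.
* Formant estimation from audio is delegated to external tools (Praat
  files are read, audio is not).
* The TNR definition can exceed 1 by construction; it is reported flagged,
  never clipped.
* The German vowel anchors are approximate stand-ins (see above).
* Extraction runtime grows roughly linearly in stroke count times restart
  count; a 3–8 stroke utterance takes a few seconds single-threaded.
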