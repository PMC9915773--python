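# Methods notes

## Task model

The simulator is a discrete event loop over stay/leave decisions. Entry into
a patch delivers the entry reward at the moment of the entry poke; after
every reward the policy is consulted once. "Stay" schedules the next reward
one inter-reward interval (4 s) later at the next position of the geometric
schedule `150 · 0.8^(pos−1)` µL; "leave" records the changeover poke,
imposes the session's changeover delay (COD) with no reward anywhere, and
re-enters the alternative patch with the schedule reset. Volumes are
continuous µL (the schedule's printed values 150, 120, 96 are exact under
pure geometric decay); nothing is rounded.

Conventions chosen where the procedure leaves room:

- **Stay topography collapsed.** The apparatus allows a stay either as a
  re-poke after the 4-s interval or by holding the snout in the receptacle;
  both produce the same reward timing, so the simulator models a single
  decision point per interval.
- **Timing.** Internal time is integer milliseconds (the apparatus
  resolution), so the 3-decimal `time_s` column of the event-log CSV
  round-trips bit-exactly. Response latencies default to zero; the cohort
  generator can draw exponential per-poke latencies so time-based measures
  are not degenerate. With zero latency a leave-after-first-reward policy at
  COD 0 legitimately yields zero-duration visits; the validator therefore
  requires `exit_time ≥ entry_time`, not strict inequality. Reward delivery
  is instantaneous (pump duration ignored).
- **Caps.** The session ends the instant either cap is reached. A reward
  that would overshoot the 5000-µL cumulative cap is truncated to exactly
  fill it (the final patch is excluded from all measures, so truncation
  never contaminates an analyzed visit). A reward or poke scheduled exactly
  at the 600-s mark does not occur; if a leave's COD extends past the time
  cap the session ends mid-changeover with no further visit.
- **Patch identity** starts at A in every session; the first visit has no
  preceding changeover. A leave is honored at any decision point.

## MVT benchmarks and the two rejection-volume conventions

The cumulative rate of return `R(c, n) = Σ volumes / (c + 4(n−1))` is
maximized by enumeration (geometric decay guarantees eventual decline; a
rising rate at the search bound raises an assertion). At COD 0 the first
reward is instantaneous, so `R(0, 1) = ∞` and the optimal policy is
leave-after-first-reward with optimal time in patch 0.

Two conventions for "rejection volume" coexist and are deliberately kept
apart:

- the **optimal rejection volume** is the scheduled volume at the
  rate-maximizing position n\* (120 µL at COD 6) — the value the benchmark
  table and figures report;
- the **observed** rejection volume of a subject that leaves after n rewards
  is the *next* scheduled volume (position n + 1): a rat that left after
  earning 120 µL rejected 96 µL.

An optimal agent's observed rejection volume is therefore
`scheduled_volume(n* + 1)`, exposed as `optimal_observed_rejection` and used
as the reference in the percent-volume-deviation so that the rate-maximizing
agent scores exactly zero deviation. Scoring observed values against the
other convention would brand the optimal policy a 20% overharvester at
COD 6 — an off-by-one the field's verbal definitions invite, which is why
both numbers are printed side by side rather than harmonized.

Percent deviations follow the stated sign conventions: volume deviation
`(optimal − observed)/optimal × 100` is positive for overharvesting; time
deviation uses the same form, so *negative* values mean staying longer than
optimal. At COD 0 the optimal time in patch is zero and the time deviation
is emitted as missing rather than invented; consequently the composite time
deviation sums the four positive delays only. (Published plots of this task
show a time-deviation value at 0 s; under the conventions implemented here
that quantity is undefined, and the tension is surfaced rather than
resolved.)

The reinforcement-rate denominator spans the first included visit's entry to
the last included visit's exit, *including* interior CODs — the
overall-intake-rate framing under which MVT optimality is defined. A
documented toggle (`rate_includes_cod=False`) counts in-patch time only.
Sessions with ≤ 2 visits have nothing left after the first/final-patch
exclusion and yield missing measures, never zeros.

## Synthetic cohort

The generative agent inverts the hyperbolic discounting model rather than
maximizing rate: with bias b and discount rate k it values the fresh patch
at `v*(D) = bA/(1 + kD)` and leaves once the next scheduled volume no longer
exceeds v\* (non-strict, so the observed rejection volume equals the
indifference point whenever v\* lies on the volume grid). This makes the
discounting fit the matched estimator: parameter recovery is well-posed, and
the residual recovery error is exactly the quantization of indifference
points to the geometric volume grid (bounded in tests by refitting the
exactly-quantized profile; it is the dominant error term, not hidden).
The rate-maximizing agent is provided separately as the optimal reference
and as the pipeline's null configuration (zero deviation at every positive
delay).

Population structure: k is lognormal per sex (positive, right-skewed, as
discount rates typically are) with default medians 0.06 s⁻¹ (males) and
0.09 s⁻¹ (females), geometric SD 2.0 — a modest offset in the direction the
task has been reported to expose (the higher-k sex stays longer, switches
less, earns less water). b ~ N(0.8, 0.08) truncated to (0, 1]; 0.8 makes the
zero-delay indifference point coincide with the 120-µL second position.
Choice noise is logistic in volume (temperature 5 µL by default; a modeling
choice, no trial-level noise structure being published for this task), and
per-poke latencies are exponential with mean 0.5 s. Default cohort size is
100 per sex for speed; the study-scale 896/898 is a config change.

What the generator does *not* emulate: estrous cycles, motivation drifts
within a session, learning, batch/site effects, or realistic absolute
response-time distributions (a single 0.5-s latency scale makes simulated
intake rates higher than real animals'; direction checks, not absolute
rates, are what passing tests establish). At COD 0 the threshold rule is
k-independent, so the generator predicts no sex difference there — real
animals showed differences even at 0 s, a discrepancy this generative model
cannot reproduce. Per-subject random substreams are keyed by (cohort seed,
CRC32 of subject id), so a subject's data never depend on roster order.

## Discounting fits

b is fixed from the 0-s point (`b = v0/A`); k is fit by least squares on the
positive delays over k ∈ [0, 100] s⁻¹ — a log-spaced coarse grid (plus k = 0)
followed by bounded scalar minimization with `xatol = 1e-10`, which is robust
to the near-flat objectives five-point profiles can produce; exactly flat
profiles return k = 0. Delays are the schedule actually run
({0, 6, 12, 18, 24} s). Normalized AUC is the trapezoid over
(delay/max delay, volume/A); normalizing by the subject's own v0 instead is a
documented toggle (`auc_normalize_by="v0"`). Normalizing by A keeps AUC
comparable across subjects with different biases.

## Correlation comparison

Composites sum each delay-varying measure across the tested delays (time
deviation: positive delays only, see above); k, b and AUC pass through.
Subjects missing any non-structural value are listwise-deleted with a log
line. Pearson matrices and two-tailed p-values are computed per sex over the
seven composite variables. The Meng–Rosenthal–Rubin z-test compares two
overlapping correlations sharing a common variable, with the f statistic
capped at 1 as originally recommended; positive z means the first (here:
discounting) correlation is stronger in the signed Fisher-z sense. Its
type-I error under a simulated trivariate-normal null is verified at
5% ± 1% (N = 200, 10⁴ replicates), and its z agrees with a Monte-Carlo
estimate of the Fisher-z-difference sampling distribution within 10%.
No multiplicity correction is applied to the matrices.

## Problem sizes and determinism

Test and verification runs use: 50 optimal agents for the end-to-end null;
200 noiseless threshold agents with k log-spaced over [0.01, 1] for recovery
(Spearman ρ ≥ 0.95 against ground truth; observed ≈ 0.999); a 15-point k
grid × 4 delays for rate dominance; 10⁴ replicates for test calibration; and
100 subjects per sex for the qualitative sex-pattern checks — sizes at which
every stochastic check is stable across seeds while the full suite runs in
seconds. All randomness flows from explicit integer seeds through numpy
Generators; identical configs reproduce every output file byte for byte.

## Known limitations

- The hyperbolic-threshold agent is myopic: it ignores session caps and
  future patch values beyond the next fresh patch. It is a generative
  stand-in with the right indifference structure, not a process model of
  rat decision-making.
- Indifference points inherit the coarse geometric volume grid; k estimates
  for extreme discounters (threshold below a few µL) saturate.
- Event logs carry no termination column; the reader infers time-cap vs
  volume-cap from the configured 5000-µL cap.
- The percent-deviation measures are undefined at COD 0 (time) and
  convention-sensitive (volume); cross-study comparisons should state which
  convention they use.
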