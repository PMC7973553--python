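# Methods

This note documents the models, conventions and numerical choices behind
`osrt`, and what the synthetic-data tests do and do not establish about
recorded data.

## Task structures

A second-order conditional (SOC) sequence is 12 location codes over the
alphabet {1-down, 2-left, 3-right, 4-up}, read cyclically, with three
constraints: each location appears exactly three times, no element equals
its cyclic successor, and each of the 12 ordered pairs of distinct
locations occurs exactly once per cycle. The validator reports each broken
rule separately; malformed input (wrong length, out-of-alphabet codes) is
an input error, not a validation failure.

The fixed-sequence (FS) stream concatenates nine cycles per block (108
targets), eight blocks, each block starting at its own 1-based offset
within the cycle (defaults 1, 5, 10, 8, 4, 12, 1, 2); blocks 1–6 and 8
follow the Main sequence, block 7 the Interference sequence. Two
consequences of this construction are worth noting:

- **One boundary repeat.** Block 1 ends on location 1 and block 2 begins on
  it. We keep the stream exactly as constructed and flag block-boundary
  transitions; the usability filter excludes the affected prefix from
  four-way labeling, since a repeated pair belongs to neither sequence's
  grammar.
- **Reversal content.** Each sequence contains exactly one cyclic reversal
  triplet (1–2–1 in sequence A; 3–2–3 across sequence B's wrap). Exhaustive
  counting over all 862 triplets of the full stream gives a reversal share
  of 77/862 = 8.93% (summaries of this design typically round to 8.8%; the
  difference is a counting convention — within-block counting that skips
  boundary triplets gives slightly lower values).

### Prefix semantics

For each prefix (x, y): Main location = Main-sequence successor,
Interference location = Interference-sequence successor, Stuck location =
y, Alternative location = the remaining code. Enumeration over the two
task sequences confirms the four are a permutation of {1,2,3,4} for all 12
prefixes. The Alternative location equals the before-previous target x —
i.e. entails a gaze reversal — for **10 of the 12 prefixes**: the two
prefixes hosting the sequences' own reversal triplets, (1,2) and (3,2),
are the exceptions. Published prose for this design states 11 of 12, a
count reproduced only if one sequence's cyclic wrap triplet is ignored; we
report the strict enumeration and expose it as
`PrefixTable.alternative_reversal_count()` rather than hard-coding either
number. By the same enumeration, the Main label is ungrammatical for
exactly one prefix ((1,2)) and the Interference label for exactly one
((3,2)); Stuck is ungrammatical always.

## RS stream generation

The generator targets the conditional continuation law implied by the
published frequency profile: given the last two targets (x, y), the next
target is never y, is x (a reversal) with probability 0.117, and is either
remaining location with probability (1 − 0.117)/2. Sampling is sequential
with exponential deficit weighting — each candidate's base probability is
multiplied by `exp(gain · (location deficit + transition deficit) +
gain_soc · continuation deficit)`, where a deficit is the target frequency
minus the running empirical frequency. Defaults gain = 12 and gain_soc = 30
bring every family's spread inside the published SDs (0.3, 0.9, 0.1, 1.4
percentage points for locations, first-order transitions, reversal
triplets, and non-reversal second-order transitions).

"No repeating sequence" is operationalized as: no period p ≤ 24 for which
any window of length ≥ 3p is exactly p-periodic (equivalently, no run of
2p consecutive positions matching the position p earlier). Candidates that
would complete such a window are vetoed during sampling, and the whole
stream is re-audited after generation; a failed audit triggers a fresh
draw under an incremented sub-seed (default 50 attempts), and final
failure raises an error carrying the best-achieved statistics. Acceptance
bounds default to twice the published family SDs and a combined reversal
share of 11.7 ± 1.5%.

Whether the original study drew one RS stream for all participants or one
per participant is not stated; the cohort simulator defaults to one shared
stream per cohort seed (`shared_stream=False` gives one per participant).

## Gaze pipeline

Fixations are detected with the dispersion-threshold (I-DT) algorithm:
maximal windows whose dispersion (x-range + y-range) stays within the
threshold and whose duration reaches the minimum. Defaults are 1.0° and
80 ms — common I-DT settings, configurable, since the vendor detector's
parameters are unknown. The angular threshold converts to cm as
`2·d·tan(θ/2)` at viewing distance d (60 cm).

Regions are assigned by nearest target center. For the centered diamond
layout (eccentricity 8.8° → 9.29 cm at 60 cm) this is identical to
dividing the screen into four triangular sectors; exact ties resolve to
the smallest location code.

Each ISI window is (previous target offset, next target onset]. A fixation
belongs to an ISI if it **overlaps** the window — it ends after the window
opens and begins before it closes. We deliberately do not assign
fixations by onset time: a participant whose gaze simply stays in place
produces one long fixation that begins during the previous trial, and
onset-assignment would discard it, making Stuck anticipation — by
definition "leaving gaze in place" — invisible and contradicting the
near-universal presence of ISI fixations in recorded data. When several
fixations fall in one ISI, the last by offset time is the anticipation
(earlier ones are overwhelmingly carryover from the previous target).

Usability: four-way labeling needs a full two-target prefix inside the
task grammar, which excludes the experiment's first ISI and the flagged
boundary repeat; such ISIs remain eligible for Stuck-only labeling
(previous target suffices). ISIs without any overlapping fixation are
excluded with reason `no-fixation`.

## Statistics

The ANOVA core implements the classical sums-of-squares decompositions on
numpy arrays: one-way within, two-way fully within (each effect tested
against its own subject-interaction error term), and mixed one-between ×
one-within with unbalanced groups. Partial η² = SS_effect /(SS_effect +
SS_error-of-that-effect). Sphericity is assessed per within effect with
Mauchly's test on the orthonormal-contrast-transformed covariance (Helmert
contrasts; Kronecker products for interactions); when Mauchly's p < 0.05
the reported p and degrees of freedom are Greenhouse–Geisser corrected
(ε = tr(CSC′)² / (d · tr((CSC′)²)), clipped to [1/d, 1]), which is why
reported denominator dfs can be fractional. For the mixed design the
covariance is pooled within groups with N − G error df. Mauchly's p uses
the first-order chi-square approximation; reference implementations that
add the higher-order term differ in the third decimal, which can only
matter when p sits exactly at the 0.05 gate. F, p, and η² agree with
pingouin to floating-point precision across all three designs (covered in
the test suite); zero-variance degenerate inputs return F = 0 rather than
an indeterminate ratio.

Paired t (two-tailed, df = n−1) and Pearson r (df = n−2) delegate to
scipy; identical paired vectors return t = 0, p = 1, and zero-variance
correlation input raises.

The partition test takes, per participant, the per-block rates of
fixations matching sequence A's successors and sequence B's successors.
Each of the N random partitions assigns half the participants A-as-Main
(main = A-series) and half the reverse, runs the two-way within ANOVA
(anticipation type × block) and tests the type main effect and the
type × block interaction at α (default 0.05), GG-corrected per the rule
above. The in-package ANOVA makes 10,000 partitions run in seconds.
Rates for the two-level type factor make its sphericity vacuous (ε = 1).

RT: cleaning removes wrong/absent keypresses; block RT is the mean of
per-12-trial-window medians (the window equals one sequence cycle, and the
same convention is applied to RS data for comparability). Within
anticipation groups the default aggregator is the median (configurable to
the mean — the original figure convention is unstated). Correctness
grouping maps labels per block: correct = Main outside the interference
block and Interference inside it; no-attempt = Stuck; incorrect = the
rest.

## Synthetic-data generator

The latent factorization (attempt → grammar → sequence) is a modeling
choice, not an empirical claim: it maps one-to-one onto the three learning
processes the anticipation labels dissociate, making each separately
recoverable from block rates. Per ISI: no attempt ⇒ gaze stays on the
previous target (Stuck); an attempt is grammatical with p_grammar(b); a
grammatical attempt fixates the governing sequence's successor with
p_sequence(b) (in the interference block the governing successor *is* the
Interference location, which produces the block-7 spike without any extra
mechanism) and the other grammatical location otherwise; an ungrammatical
attempt splits between the previous location and the Alternative location
(default ratio 0.7, reflecting the low Alternative rates typical of this
task — the second-order rule is learned early).

Noise defaults follow the observed data rates: 54.8% multi-region ISIs,
91.6% of them opening with a carryover fixation on the previous target,
1.2% of ISIs without fixations, 0.8% response errors. Fixations are
emitted as samples at 250 Hz around the region center with a per-fixation
Gaussian centroid offset (SD 0.3 cm) plus per-sample uniform jitter
(±0.15 cm) — calibrated so that default classification accuracy is ≈ 100%;
gaze noise is a stress-test knob, not a realism claim. RT = base −
practice·(block−1) − advantage·[correct anticipation] +
penalty·[incorrect attempt] + Gaussian noise, clipped to [180, 3000] ms.
Default curves: the `fs-learner` preset rises from p_attempt 0.60 /
p_grammar 0.60 / p_sequence 0.52 in block 1 to 0.80/0.85/0.75 by block 6,
with p_sequence dipping to 0.62 in the interference block; the
`rs-grammar-only` preset keeps p_sequence at 0.5 (chance) with grammar
rising; the `null` preset holds all curves flat. Cohorts add one Gaussian
offset per process per participant (default SD 0.04), yielding
attempt-driven as well as accuracy-driven learners.

What passing tests show — and do not. Round-trip identity and curve
recovery establish that the pipeline is label-faithful and unbiased *under
this generative model*: fixations at region centers, ideal timing, no
drift. They do not establish robustness to calibration drift, smooth
pursuit, blinks, or covert (non-oculomotor) anticipation, none of which
the generator emulates.

## Problem sizes and determinism

The test suite runs single participants and 6–8-participant cohorts for
qualitative pattern checks, a 30-participant null cohort with 1,000
partitions for calibration, and full 10,000-partition runs in the
acceptance script — sizes chosen so the whole battery stays fast while the
Monte-Carlo tolerances stated in each test hold. All randomness flows
through numpy Generators seeded explicitly; cohort members draw
independent seeds from a master `SeedSequence`, so identical seeds
reproduce identical datasets bit-for-bit.

## Known limitations

- Saccade kinematics, pupil metrics, smooth pursuit and vendor file
  formats are out of scope; gaze input is a plain table in pixels or cm.
- The mixed ANOVA assumes listwise-complete within-profiles per subject;
  missing cells drop the participant from that analysis (logged).
- The RS generator matches the published summary statistics; it does not
  reconstruct the original streams, whose generator is unpublished.
- Mauchly's p uses the first-order chi-square approximation (see above).
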