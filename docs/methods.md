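# Methods

`ethoflow` analyses the mating behaviour of the mason bee *Osmia cornuta* as
a sequence of discrete, stereotyped behavioural units (action modules), and
provides a matching generative model. This note documents the model, the
conventions and the numerical choices, and what the synthetic data can and
cannot show.

## The behavioural model

### Unit catalogue

The male repertoire is a catalogue of 14 units, each with a token, an
observed duration range, and a stage:

| stage | units |
|---|---|
| precopulatory | pounce (1–2 s), sound (30–35 s), ant (30–50 s), buzz (2 s), abdom (3–28 s), back (40–60 s), rot (60–120 s) |
| copulation | long (60–120 s), short (1–2 s), end_cop (0–1 s) |
| postcopulatory | scratch (120–360 s), inact (600–1200 s), groom (120–180 s) |
| terminal | bye_bye (0–1 s) |

Conventions: all durations are stored in seconds (a single time base avoids
unit errors); `buzz`, reported as a point value, is a degenerate 2–2 s range;
`end_cop` and `bye_bye` are boundary markers with no reported duration and
are assigned 0–1 s; the `back` range is the module-level 40–60 s (the 1/24 s
figure describes the antenna posture *within* the module, which is not
modelled). The long-copulation range is stored as 1–2 min; a 40 s–2 min
variant appears in secondary accounts and is accepted on input but is not the
simulator default. Female behaviour is passive in the observations and is not
modelled.

### Sequence grammar

Observed sequences follow a stereotyped structure, encoded as explicit rules
(R1–R6 plus a strict-mode terminal rule) by the validator:

- R1 the mating begins with `pounce`; R2 `pounce` is immediately followed by
  `sound`; R3 every `long` is immediately preceded by `rot`; R4 `scratch`
  occurs only after an `end_cop` terminating a long copulation; R5 after a
  short copulation's `end_cop` the sequence resumes with `abdom` (or ends
  with `bye_bye`); R6 a single-long mating contains at most four structural
  antenna episodes.

Violations are reported with rule id, event position and message — never
auto-repaired: analysis must not silently alter observed data. An unknown
unit token is a hard error (malformed data, not ungrammatical behaviour).

**Antenna-episode counting.** The source observations label the antenna
episodes inconsistently (the first episode is called bare *ant*, the
subsequent ones *ant1…ant4*, yet the module is said to repeat "four times").
Our convention: every occurrence of a unit gets a strictly increasing
episode index; in indexed mode the first episode keeps the bare token as its
state label and episode *k* ≥ 2 is labelled `<token><k>`. Rule R6 counts
only *structural* episodes — the pre-copula exit episode (an `ant`
immediately followed by `abdom`/`back`/`rot`) and every `ant` at or after the
first copulation — so courtship-loop repeats (followed by `buzz` or `sound`)
do not count, and the canonical single-long sequence has exactly four.

### First-order transition model

The analysis of "which unit follows which" is the embedded discrete-time
chain: adjacent-pair counts across a corpus, row-normalised into a
row-stochastic matrix. Dwell times play no role in estimation (they live in
the simulator). Choices:

- **No smoothing.** Unobserved transitions are exactly 0, so the flow
  ethogram shows only observed arrows.
- **State order** is first appearance across the corpus — deterministic
  without imposing meaning.
- **Indexed mode** (repeated units distinct by episode) is the default for
  ethogram rendering, where the figure-style distinction between antenna
  episodes matters; bare-token mode is the default for summary statistics.
  Both are exposed.
- **Absorbing states** (`bye_bye`) have all-zero probability rows.
- Sequence probability is the product of step probabilities, 0 as soon as a
  step was never observed.
- **Percentage classes** for arrow thickness: 1 = (0, 0.05], 2 = (0.05,
  0.25], 3 = (0.25, 0.75], 4 = (0.75, 1.0), 5 = exactly 1.0. The source
  figures never print their bin edges; these were chosen once so the observed
  branch values 2, 4, 11, 85, 96, 98 and 100% land in visually distinct
  classes.

Note the distinction between the forward transition P(long | rot) and the
predecessor conditional P(rot precedes | long). The observed "100%" is the
latter: every long copulation is immediately preceded by `rot`. The forward
probability equals 1 only in corpora of single-long matings; in a mixed
corpus `rot` also precedes short copulations (≈ 0.83 under the natural-time
mixture). Both quantities are computable; tests and the acceptance script
check each in its own corpus.

### Copulation composition and group statistics

Each mating event's composition is its temporal string over {S, L}. A long
copulation always terminates the mating, so at most one L may occur and only
terminally. The inter-copula loop count is the number of short copulations
after which the sequence *resumes* (a final short followed only by `end_cop`
and departure does not count — "SSSS" has 3 loops). Group statistics are the
copulation counts, the long/short ratio (an infinity sentinel plus flag when
no short occurred, not an exception), copulation-type frequencies in percent
of all copulations, the percent of events ending with a long copulation, the
composition histogram, and per-pattern mean durations when timings exist.

"Reproductive failure" is operationalised as exactly 100 − (percent of
events ending long); the group comparison reports the difference of failures
(natural-time group: 0%; aged group: 31.25%). No fertility claim beyond this
arithmetic is encoded, and no inferential test is attached (none was
performed in the source observations).

**Rounding.** All statistics are stored at full precision; rounding happens
only at the report layer, as decimal half-up at a configurable precision.
Half-up reproduces the printed headline values where the source rounded
consistently (4.86, 31.3); the source's own rounding is in places
inconsistent (82/18 where the counts give 82.93/17.07; 68.7 where the count
gives 68.75), and those stored values are deliberately left at full
precision.

## The synthetic-data generator

The generator emulates the recorded mating sequences: per-group composition
mixtures, the courtship branch structure at the observed percentages, and
uniform dwell times on the catalogue ranges.

- **Composition-first generation.** The pattern (e.g. "SSL") is drawn from
  the group mixture, then realised as a sequence. The inter-copula loops are
  not memoryless — the observed compositions cap at four shorts — so a
  free-running first-order chain could not reproduce the composition
  histogram. The courtship interior *is* simulated as a genuine stochastic
  branch process.
- **Mixtures** are the observed event counts: natural-time group
  {L: 27, SL: 7}; aged group {L: 5, SL: 7, SSL: 10, SSS: 5, SSSS: 5}.
- **Branch probabilities**: pounce→sound 1.0; sound→{ant 0.96, buzz 0.04};
  ant→{buzz 0.98, sound 0.02}; buzz→{sound 0.11, ant 0.04, exit 0.85}; the
  exit antenna episode leads to abdom→back→rot. Rare observed variants (the
  exit bypassing `abdom` to `back` or `rot`; the recovery `abdom` leading
  directly to a long copulation) are exposed as optional branch
  probabilities defaulting to 0. Enabling the abdom→long variant produces
  sequences that violate rule R3, mirroring an inconsistency in the source
  description; it is off by default.
- **Structure per copulation**: the first copulation is preceded by
  pounce→sound→courtship→rot; subsequent ones re-enter at `sound`. After a
  non-final short: `end_cop → abdom → inact → ant`, then back to `sound`.
  After the final long: `ant → end_cop → scratch → ant → inact → ant → groom
  → bye_bye`, which makes the antenna module recur four times in a
  single-long mating. After a final short the male departs immediately
  (`end_cop → bye_bye`): the observations do not state what, if anything,
  precedes departure there, and this explicit convention is recorded in the
  batch metadata.
- **Dwell times** are uniform on each unit's range — the maximum-entropy
  choice given that only ranges were observed. Events are contiguous from
  time 0.
- **Determinism**: one RNG stream (`numpy` PCG64) per batch, seed recorded in
  the output; identical profile + seed give byte-identical event logs.

### What the generator does and does not emulate

It reproduces: the stereotyped unit order and grammar, the branch
percentages, the composition mixtures (hence all the headline group
statistics in expectation), and durations *within* the observed per-unit
ranges. It does not emulate: inter-individual heterogeneity beyond the
mixture, within-unit temporal structure, partially overlapping units (the
observations mention `ant` overlapping `sound` ends; events here are strictly
sequential), or any dependence of dwell time on context. Consequently,
passing tests show the pipeline recovers the parameters of *this* generative
process; they cannot show that real matings satisfy uniform dwell times.

A concrete limitation: the observed mean mating durations (31.5, 46.5, 68.5,
93 min for 1, 2, 3-short, 4-short-copulation matings) are monotone in the
number of copulations *across* terminal types, but under uniform dwell times
on the printed ranges an all-short mating is shorter in expectation than a
short-then-long one (it lacks the ~25 min postcopulatory tail). The duration
properties are therefore tested structurally — adding a loop to a pattern
lengthens the mating (L < SL < SSL; SSS < SSSS), and the simulated
single-long mean lies in the interval obtained by summing the backbone
units' range endpoints, which also contains the observed 31 min 30 s — and
the per-pattern means are not asserted as exact targets (the underlying
per-event timings were never published).

## Problem sizes

Simulation-based checks use 5000 sequences for transition-parameter recovery
(inside 99% binomial confidence intervals: half-width ≈ 0.7 percentage
points at p = 0.96), 1000 mixed-group sequences for the
long-preceded-by-rot percentage, 10 000 draws for mixture sampling checks,
and 200 events per pattern for duration structure. These sizes make the
Monte-Carlo error small relative to every tolerance used while keeping the
whole suite inside a few seconds.

## I/O conventions

Event logs are delimited text (CSV default) with columns subject, group,
unit, start_s, end_s, episode; times are 0-based seconds from mating onset,
half-open intervals `[start, end)` so adjacent events may touch; written
with three decimals (1 ms). A `frames_24fps` time unit converts by exact
division by 24, matching the frame-stepped video source. Ethograms export to
DOT (hand-emitted; edge pen width = percentage class) and GraphML (via
networkx). The catalogue, transition models, metrics and comparisons
serialise to JSON; group sequences with no label default to OTHER, and
episode indices auto-number when the column is absent.
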