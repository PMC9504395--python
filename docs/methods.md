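# Methods

This note documents the models implemented in `opinionpulse`, the
parameters that matter, the synthetic data the tests rely on, and the
numerical choices made where the design was genuinely open.

## Engagement: PES

Daily post volume in a region scales sublinearly with its population,
so raw counts overstate engagement in populous regions.  The Public
Engagement Score divides the daily count by a power of population,

    PES(d, r) = N(d, r) / pop_r^β.

* **β** (dimensionless, default 0.725): the volume–population scaling
  exponent, taken from the empirically reported range 0.67–0.78.  It is
  a fixed input, never estimated from the corpus.
* **Populations** are input data (`region,population` CSV).  The shipped
  defaults are 2010 census resident populations for the 48 contiguous
  states plus DC, and 2010 national totals per race group.  Census
  vintages differ across published sources (some use "latest" estimates,
  some 2010); the pipeline is agnostic — whatever table is supplied is
  used consistently, and the shipped fixtures use 2010 throughout.
* **Stratifications.**  State PES uses state populations; race PES uses
  national race populations; the `unknown` race stratum has no
  population denominator and is excluded from PES (it is still reported
  in counts).  Topic PES uses the national total population, since no
  "topic population" exists; this is recorded in output metadata via the
  `pop` column.

When the corpus is generated with the same exponent used for scoring,
per-region mean PES is equal up to Poisson noise — the test suite checks
exactly this, plus the scale law (pop → k·pop, N → k^β·N leaves PES
invariant).

## Sentiment: Dirichlet–multinomial PSS

Each post has a polarity in {positive, neutral, negative}.  For a day
and stratum with counts (n₁, n₂, n₃), N = Σnᵢ, the proportions are
θᵢ = nᵢ/N and the net sentiment is PSS = θ₁ − θ₃ ∈ [−1, 1].

The sampled posts are a small window on the underlying population, so
θ is estimated, not observed.  The model is the conjugate
Dirichlet–multinomial:

* **Prior.**  αᵢ = base + w · (sum of counts over the preceding
  window).  Defaults: base = 1, w = 1/7, window = trailing 7 days
  (strictly before the target day).  With no history this is the
  balanced non-informative prior (1, 1, 1).  The weight 1/7 makes a full
  week of history worth about one average day of data: enough to
  stabilize thin days, too little to dominate busy ones.  "Preceding
  week" is read as the trailing 7 days rather than the calendar week;
  the window length is a parameter.
* **Posterior.**  αᵢ′ = αᵢ + nᵢ.
* **Point estimate.**  The closed-form posterior mean
  (α₁′ − α₃′)/Σα′ — deterministic, independent of the Monte-Carlo step.
* **Interval.**  Equal-tailed quantiles of θ₁ − θ₃ over `n_mc`
  Dirichlet draws (default 20,000 at the function level; the pipeline
  default is 2,000, which puts the Monte-Carlo jitter of a 95% bound
  near ±0.01 interval width at typical posteriors — adequate for the
  plotted bands while keeping full multi-strata runs fast).  Equal-tailed
  rather than highest-density: simpler, deterministic given a seed, and
  the downstream use is an uncertainty band.
* **Degenerate days.**  N = 0 yields the prior-only estimate, flagged
  (`prior_only`), never silently interpolated.  θ on an N = 0 day is
  undefined and raising is left to the caller (`polarity_proportions`
  errors; the daily series falls back to the prior).

Whether the underlying literature models PSS directly or the three
proportions is ambiguous; modelling the proportions is implemented
here, as PSS is a deterministic functional of them and inherits its
posterior.

Seeding: one `numpy` stream is spawned per stratum (sorted order) from
the top-level seed, so per-stratum series are reproducible and adding a
stratum does not perturb the draws of existing ones beyond the spawn
indices.

## Polarity classification

A multinomial Naïve Bayes over unigram bags-of-words:
P(polarity | tokens) ∝ P(polarity) · Π P(token | polarity), priors from
label frequencies, token likelihoods Laplace-smoothed (default
pseudo-count 1).  Tokenization: lowercase, split on non-alphanumeric
runs, keep tokens of length ≥ 2.  Out-of-vocabulary tokens are skipped
at classification time (smoothing already reserved mass at training); a
post with no known tokens falls back to the priors.  Ties resolve in
the fixed order positive > neutral > negative.  With smoothing 0, zero
likelihoods are floored at log-probability −745 so classification stays
total.

Published analyses of this kind typically use a pretrained
off-the-shelf classifier whose weights are not part of the method; this
package instead trains its own model, and — the recommended route when
labels exist — accepts a `polarity` column that bypasses the classifier
entirely.  How an external tool's continuous polarity score was
thresholded into three classes is generally unstated, so no threshold is
guessed here.

## Topic tagging

Three vaccine aspects — `vaccine_type`, `phased_vaccination`,
`health_concern` — are tagged by whole-token phrase matching against a
lexicon (shipped default transcribed from the published keyword table;
user-replaceable YAML).  Token matching, not substring matching: "old"
must not fire inside "golden".  Notes on the shipped lexicon: "johnson
amp johnson" is the HTML-escaped form of "Johnson & Johnson" and both
token forms are included ("&" is dropped by the tokenizer, yielding
"johnson johnson"); the table's duplicated "fever" is stored once.  A
post may receive 0–3 topics.  Ranked within-post bigrams/trigrams (a
small built-in stop list applied to n-gram extraction only, never to
matching) serve as the lexicon-validation diagnostic.

## Race imputation

Race labels come from the census surname table: percentages per surname
over white, black, API, AIAN, two-or-more-races, Hispanic.  Rows are
renormalized to sum to exactly 100; rows deviating from 100 by more
than 0.5 before renormalization are rejected with a warning (the
shipped example table's *Beyale* row sums to 98.48 because of census
suppression zeros, and is therefore rejected — it stays in the file as
a realistic specimen of the published data).

Assignment draws one label per post from the surname's distribution via
a single uniform draw against the cumulative ordering white, black,
api, aian, two_prace, hispanic — making runs exactly replayable given
the seed.  Posts with absent or unmatched surnames are `unknown`,
reported separately and excluded from race-frequency denominators.
Assignment is deliberately per post, matching the published procedure;
an optional per-surname mode (one draw per distinct surname) is
available, keyed on the surname because no user identifier travels with
the records.

## Sub-periods and summaries

The study window (default 2020-10-01 .. 2021-05-21) is split into four
regimes at three milestone dates: 2020-11-09 (first efficacy
announcement), 2020-12-14 (first administered dose), 2021-03-12
(100 million doses; the exact published date for this milestone is only
given as "around 12 March", and the boundary is a config key).  A
boundary day starts the new regime.  Weekly PSS is the arithmetic mean
of daily point estimates over consecutive 7-day blocks anchored at the
series start; empty blocks are omitted.  Five-number summaries use
`np.quantile` with the inclusive-median linear-interpolation rule
(R type 7 / Excel QUARTILE.INC), switchable to any other `np.quantile`
method via config.

## Synthetic data: what it emulates, what it does not

The generator draws per-region daily counts from a Poisson around
`base_rate · (pop_r/pop_ref)^β_true · multiplier(day)` — Poisson being
the minimal count model consistent with sublinear volume growth — with
multipliers ≥ 1 on event days; per-post polarity from a per-day θ
schedule (constant or piecewise-linear between anchors); topic keywords
injected independently per topic (so multi-topic posts occur) into
neutral templates that contain no lexicon keyword, making tagging
precision and recall exactly measurable; and surnames from a weighted
pool, so race composition follows from the pool weights and the table
rows by the law of total probability.

Default study conditions: 49 regions (48 contiguous states + DC, 2010
populations), 233 days (2020-10-01 .. 2021-05-21), base rate 242 per
reference (national) population — about 660 posts/day nationally and
~155k posts overall, the scale of a real geo-located vaccine corpus —
five event-day spikes at the milestone dates above, a θ schedule
tracing modest early positivity, a jump at the efficacy announcement, a
winter dip, a spring climb and a mid-April dip, and a surname pool with
52% of its mass on matchable surnames (the classification rate reported
for census-matched corpora).

What the generator does **not** emulate: real language (templates are
fixed sentences; the polarity label is drawn, not expressed in the
text, so classifier quality on real prose is out of reach of these
tests), user networks, bots, platform sampling bias (urban and younger
users over-represented), or spatial correlation between neighboring
states.  Passing tests therefore demonstrate correctness of the scoring
and inference machinery under a known law, not validity of any
linguistic step on real posts.

## Numerical and design choices

* PES is computed in double precision; `N / pop**beta` agrees with
  30-digit arithmetic to 12 significant digits (tested on a randomized
  grid).
* Score CSVs are written with 12-significant-digit floats and a
  deterministic column order, so write-then-read round-trips and reruns
  are byte-identical.
* Dates are UTC calendar days throughout (no timezone is stated for
  such archives; one consistent convention suffices).
* Surnames are NFKD-normalized (diacritics stripped) and uppercased
  before lookup; the census table is ASCII uppercase.
* Retweet exclusion and geolocation-to-state mapping are upstream
  concerns: records arrive with a state code, and a sentinel `NA` state
  is accepted and excluded from state strata.
* The pipeline writes into a `.partial` directory renamed on success;
  any stage failure removes partial outputs.

## Known limitations

* The race imputation reproduces the published *procedure*; per-post
  sampling means a prolific user's posts can carry different labels,
  and surname-based inference is itself a coarse proxy with well-known
  biases (it is retained because it is the method under study).
* Credible intervals account for sampling of posts, not for classifier
  error or platform selection bias.
* The trailing-week informative prior assumes slow drift; across sharp
  regime changes (e.g. a major announcement) it biases the first day or
  two toward the old regime, bounded by the prior weight (~one day of
  data).
* Topic tags are keyword matches: synonyms or misspellings outside the
  lexicon are missed, and negated mentions still count.
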