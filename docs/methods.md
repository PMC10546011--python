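# Methods

## Graph model

A transcript is an ordered list of utterances of lowercase word tokens.
Utterance boundaries encode interruptions in spontaneous speech: the
transcriber places post-interruption speech on a new line, and the graph
builder never draws an edge across a line break.  The word-trajectory
graph is a directed multigraph — one node per word *type*, one edge per
consecutive within-utterance token pair, self-loops from immediate
repetitions and parallel edges from repeated pairs.  Component sizes are
insensitive to edge multiplicity, but multiplicity is kept in the
representation for attributes that would need it.

Connectedness attributes are node counts: **LCC** of the largest weakly
connected component (reachability ignoring direction) and **LSC** of the
largest strongly connected component (mutual directed reachability,
Tarjan-class algorithm via networkx).  A single node is trivially
strongly connected, so LSC ≥ 1 on any non-empty graph; an empty graph is
a pipeline error, not a size-0 result, because sub-window transcripts are
excluded upstream.

### Token normalization

The graph tool the measures originate from treats words as
whitespace-separated strings, so normalization is deliberately light and
every choice is explicit rather than inferred: case-folding on (distinct
case would inflate node counts), punctuation stripped from token edges
with apostrophes kept ("boy's" stays one type), filled pauses kept by
default (they are produced words; `drop_fillers` removes them), no
lemmatization by default (an optional hook exists).  CHAT markup is
removed but retraced/repeated words are *kept* — repetition is exactly
what LSC measures.  Normalization is idempotent and total.

## Moving-window verbosity control

Raw component sizes grow with transcript length, so attributes are
computed on a moving window of `window_length = 30` tokens with
`step = 3` (90% token overlap between consecutive windows) over the
concatenated token sequence, and averaged with a plain unweighted mean.
Windows may span several utterances; edges inside a window still respect
utterance boundaries — the window is defined on word count while the
interruption rule governs edges, the only reading consistent with
utterances shorter than the window.  Trailing partial windows are dropped
rather than padded, since padding would change graph sizes.  Grand means
are kept at full precision.  Transcripts with fewer than 30 tokens raise
a typed error carrying the participant id and token count; batch analysis
turns these into a machine-readable exclusion log.

A scale caveat: grand means over 30-word windows are bounded by 30,
whereas whole-narrative LCC in the cohort this package emulates ranges up
to 151.  The cohort generator therefore offers both scales — direct draws
on the published whole-narrative scale (default) and transcript-derived
windowed grand means (`from_transcripts=True`).  Analyses mixing the two
scales rescale the connectedness coefficient accordingly; variance
explained is scale-invariant.

## Statistical model

For each severity outcome (MMSE 0–30, MDRS 0–144, BDS 0–28) and each
connectedness measure, ordinary least squares of

    outcome ~ 1 + hdrs + onset_age + education + fluency_z + connectedness

on complete cases for the outcome (outcome missingness is handled per
outcome, so residual df may differ across outcomes).  `fluency_z` is the
sum of the semantic- and phonemic-fluency z-scores computed against the
analysis sample's own mean and SD (ddof = 1), *after* imputation and
within the per-outcome analysis set.  Two-sided p-values from the t
distribution; no multiple-testing correction.  Rank-deficient designs
raise an error naming the dependent columns.

### Imputation

Missingness is confined to the two fluency counts.  Chained equations:
each incomplete variable is regressed on the fully observed covariates
plus the other fluency variable at its current working values, over
originally observed rows; regression parameters are drawn from their
posterior (σ² from a scaled inverse-χ² draw, β from its normal); type-1
predictive-mean matching then copies an observed value from one of the 5
nearest donors by predicted value.  10 sweeps per chain, m = 5 chains
with independent spawned RNG streams — output is bit-reproducible from
the seed.  PMM is the default engine because fluency counts are
non-negative integers and matching preserves their support; a
normal-model engine is available (`engine="norm"`).  Variables entirely
missing, or with fewer than 3 observed values, are an error.

### Pooling

Rubin's rules over the m fits: pooled estimate is the mean, total
variance `W + (1 + 1/m) B`, per-coefficient degrees of freedom by the
Barnard–Rubin small-sample adjustment (reducing to the complete-data df
when the between-imputation variance is zero, hence exactly the single
fit at m = 1).  The published analysis reports single coefficient sets
after chained-equation imputation without stating a pooling rule; Rubin
pooling over m = 5 is standard practice and is the default here.  R² and
the overall F have no exact pooled analogue and are reported as means
across completed tables (exact at m = 1).

## Synthetic data

The generator exists so the full pipeline is testable without the
restricted corpus; it makes no claim of linguistic realism.

**Transcripts** follow a return-probability process: the next token
revisits a uniformly chosen earlier *token* with probability `p_return`,
otherwise it is a fresh/uniform vocabulary draw (`without_replacement`
makes fresh draws never repeat a type); after each token a new utterance
starts with probability `p_break`.  Defaults (`vocab_size = 60`,
`n_tokens = 120`, `p_return = 0.5`, `p_break = 0.1`) give
picture-description-sized narratives whose windowed attributes sit inside
the plausible range, and parameter settings exist whose whole-transcript
attributes reach the observed corpus extremes (LCC 14–151, LSC 1–117).

The LSC response to `p_return` is *hump-shaped*, not monotone: returns
create reciprocal paths (raising the fraction of nodes in the giant SCC,
roughly quadratically at first) but also shrink the distinct-type
inventory, whose expectation falls like `1 + (n − 1)(1 − p_return)` in
the fresh-draw regime.  Since LSC is a node count, the inventory cap
always wins at high return rates — between `p_return` 0.8 and 0.9 the cap
halves while the SCC fraction cannot double — so mean LSC rises with
`p_return` only on the low-return limb and falls thereafter; with a small
vocabulary relative to length (the defaults), uniform re-draws already
supply reciprocity and the curve is monotone decreasing.  Tests assert
the mechanism on its rising limb.

**Cohorts** draw covariates from truncated normals at the published
means/SDs/ranges of the baseline dementia sample (age 71.93 ± 8.70 in
[50, 88]; education 12.37 ± 2.95; HDRS 5.93 ± 3.55; semantic fluency
9.11 ± 4.66; phonemic fluency 6.74 ± 4.23; whole-narrative LCC
57.07 ± 22.85, LSC 35.78 ± 21.91).  Onset age is generated as age minus a
truncated-normal onset-to-assessment lag (mean 3.67 y, SD 2 y, ≥ 0) so
`onset_age ≤ age` holds row-wise; its marginal SD then tracks the age SD
rather than being set independently.  Directly drawn LSC is capped at the
drawn LCC to respect the attribute ordering.  Severity scores come from
the generating linear model (default coefficients follow the published
LCC-model estimates) plus Gaussian noise; when no noise SD is given it is
derived from a target R² as `sd(lp) · sqrt((1 − R²)/R²)` with targets
0.44 (MMSE), 0.61 (MDRS) and — since no value was reported for the
non-significant BDS model — a modest 0.15 chosen once.  Scores are left
unclipped and continuous by default because clipping and rounding bias
coefficient-recovery tests; instrument-range clipping is opt-in.
Fluency missingness is MCAR per cell at rate 0.25 by default (the
emulated sample reports 25% missingness; its cell count and participant
count do not reconcile exactly, so the summary reports both).

What passing tests do *not* show: the generator has no topic structure,
no syntax, no Zipfian word frequencies, and MCAR missingness only — real
corpora may miss fluency scores informatively, and real narratives
violate the stationarity of the return process.  Calibration results
(coverage, type-I error) therefore validate the statistical machinery,
not robustness to those real-data features.

## Numerical choices

- OLS via statsmodels; results verified against the normal equations to
  1e−8 relative tolerance.  Constant outcomes report R² = F = 0 rather
  than NaN.
- 95% CIs are `estimate ± t(df, 0.975) · SE` with df from Barnard–Rubin
  (complete-data df at m = 1).
- Component sizes tie-break trivially (only the size is reported).
- Simulation sizes in tests (500 calibration replicates at n = 128, 200
  imputation replicates, 1000 oracle graphs ≤ 12 nodes) were chosen to
  make binomial acceptance bands informative while keeping the suite
  fast on one CPU.

## Known limitations

- The CHAT reader covers main-tier selection and the common markup of
  picture-description transcripts; it is not a full CHAT parser (no
  dependent-tier semantics, no header validation).
- Windowed and whole-narrative connectedness scales differ (see above);
  per-unit coefficients are only comparable within one scale.
- Pooled R²/F are means across imputations, a pragmatic summary without
  Rubin-style theory behind it.
- Only the two connectedness attributes are implemented; other speech
  graph attributes (density, diameter, clustering) are out of scope.
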