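# Methods

## The simulation model

`screensim` simulates pool-based active learning for screening
prioritization. The pool is a fully labeled corpus of N candidate
publications (id, title, abstract, binary relevance). A trial is a complete
screening: steps 1–2 label the prior records (one relevant, one irrelevant,
drawn uniformly from their classes), and every later step (i) rebalances the
labeled set by dynamic resampling, (ii) refits the classifier, (iii) queries
the unlabeled record with the highest relevance score, and (iv) reveals its
recorded label. The loop runs to pool exhaustion, so final recall is always
exactly 1 and every metric is computed from a complete labeling order.

Assumptions built into this design:

- **Oracle labels are correct and instantaneous.** No label noise, no
  reviewer fatigue, no disagreement between reviewers.
- **Batch size 1.** The model retrains after every single label. A `batch`
  larger than 1 would be a straightforward extension but is deliberately not
  the default.
- **Pure exploitation.** The query rule is certainty-based (highest
  predicted relevance), which is the right objective for screening
  prioritization; uncertainty sampling is out of scope.
- **Transductive features.** TF-IDF statistics and paragraph-vector
  embeddings are computed once over the full corpus before simulation and
  held fixed. Refitting features at every step would change the feature
  space across steps and make rankings incomparable; since features use text
  only (never labels), this leaks no label information.

## Dynamic resampling

With n = n₁ + n₀ labeled records (n₁ relevant) in a pool of N, DR resamples
the training set to the target relevant fraction

    ρ = w₁·n₁ / (w₁·n₁ + w₀·n₀),   w₁ = a·(n/N)^(−α),   w₀ = b,

with defaults a = 2.155, α = 0.94, b = 0.789. The relevant target count is
round(ρ·n) (half away from zero), clamped to [1, n−1] so both classes always
survive; the irrelevant count is the complement, so the training-set size is
exactly preserved. Relevant indices are drawn with replacement
(oversampling); irrelevant indices without replacement whenever the target
does not exceed the available count (undersampling), with replacement
otherwise.

Properties that follow (and are tested): with the default parameters
w₁ ≥ a > b, so whenever the relevant class is the minority its fraction
never decreases; and at a fixed class ratio ρ is non-increasing in n/N, so
the rebalancing correction relaxes as screening progresses and decays toward
the constant ratio a : b at n = N.

The functional form is deliberately isolated behind `DRParams`: any other
monotone law with the same dependencies (n, N, n₁/n₀) can be dropped in
without interface changes. Whether relevant oversampling should be i.i.d.
with replacement or deterministic duplication is interface-agnostic; the
i.i.d. choice was made for simplicity and is fixed by the seeded stream.

## Classifiers and features

- `nb` — multinomial naive Bayes, Laplace smoothing 1.0. Requires
  non-negative features, hence infeasible with paragraph vectors (the 7-model
  grid).
- `lr` — L2-regularized logistic regression, C = 1.
- `svm` — linear-kernel SVC; its signed decision value is used directly for
  ranking (no probability calibration — only the ordering matters).
- `rf` — random forest, 100 trees, seeded.

Hyperparameters are conventional defaults, configurable per run; per-dataset
hyperparameter search is explicitly out of scope.

TF-IDF uses the smoothed inverse document frequency
idf(t) = ln((1+N)/(1+df(t))) + 1 with L2-normalized rows, lexicographic
vocabulary, and a tokenizer that lowercases, splits on non-alphanumerics and
drops single-character tokens (unigrams, unlimited vocabulary by default).

Paragraph vectors are trained by this package's own PV-DBOW trainer:
each document owns a dense vector optimized by SGD with negative sampling
(5 noise words per target, noise ∝ unigram^0.75, linearly decaying learning
rate from 0.05) to score its own words above noise words. Defaults:
dim = 40, epochs = 20, min_count = 2. Training is single-threaded and fully
seeded, so matrices are bit-identical across runs; the training-time
document vectors are used directly (no re-inference). The `window` parameter
exists for interface symmetry with distributed-memory training and is unused
by the bag-of-words variant. Embedding matrices contain negative entries,
which is what makes the nb + d2v cell infeasible.

## Metric conventions

Several conventions are not forced by the definitions and are fixed here:

- **Priors count as screened steps** (they are labeling decisions), and the
  relevant prior counts toward the recall numerator, so recall curves start
  above zero. A record contributes no TD in trials where it was a prior;
  records that were priors in *every* trial are excluded from the record-ATD
  with a warning.
- **Step functions, no interpolation**: WSS uses the first step whose recall
  reaches the level; RRF uses ⌊X/100·N⌋ (at least 1). Interpolating would
  fabricate fractional records.
- **Denominators include the priors** (WSS and recall are relative to the
  full N). Logs produced outside the engine (e.g. random-order baselines)
  may carry no prior structure (`prior_ids = ()`); all metrics then apply
  with no exclusions.
- At small R, WSS@95 is positively biased even for random orders: with
  R = 5, recall ≥ 0.95 requires all five relevant records, so s* is the
  maximum of five uniform order statistics and E[WSS@95] = +10 at N = 50.
  The bias vanishes as R grows (≈ +1.9 at R = 40, N = 200); the calibration
  tests check the near-zero asymptotic at large R and document the small-R
  offset.
- Record-level and trial-level ATD averages use plain sequential sums, so
  results are reproducible bit-for-bit and agree exactly with naive
  recomputation from the event lists.

## Synthetic corpora

The generator emulates the composition of real screening pools: N records
(default 2000) with a small exact relevant fraction (default 5%; realized
count is round(prevalence·N) deterministically). Each record's tokens are
drawn from its class signal vocabulary with probability `separability`, else
from a shared vocabulary; titles are the first 5 tokens, abstracts the rest.
Defaults: vocabularies of 300 (relevant-signal) / 1000 (irrelevant-signal) /
2000 (shared) types, token counts ~ Normal(60, 15) truncated at 10 —
magnitudes chosen to resemble title+abstract token counts and vocabulary
richness of bibliographic records. Record order is shuffled after label
assignment so the engine's index tie-breaking cannot leak labels.

What the generator does *not* emulate: topical drift, near-duplicate
records, Zipfian token frequencies, hard borderline cases, and the
heterogeneous "hard-to-find" relevant records seen in real reviews. Passing
tests on synthetic pools therefore demonstrate that the machinery is correct
and that separable classes are found early — not that any particular
performance level transfers to a given real review.

## Determinism and seeds

A master seed fans out through named `SeedSequence` substreams: (0, trial)
for prior sampling, (1, trial) for each trial's run stream (resampling draws
and classifier seeding), (2,) for embedding training. Consequences: priors
depend only on corpus and seed (so all models on a corpus share them),
and increasing `n_trials` extends the trial list without perturbing earlier
trials. Identical configuration and seed reproduce screening logs
byte-for-byte. Score ties are broken toward the lowest record index.

## Problem sizes in tests

The test suite simulates at the sizes the checks need rather than at survey
scale: the end-to-end performance floor runs naive Bayes + TF-IDF on the
reference pool (N = 2000, 5% prevalence, separability 0.8, 15 trials), the
recall-dominance check runs all 7 models at N = 500 with 2 trials, and the
separability-monotonicity check averages 10 seeds at N = 150. Metric
calibrations use direct random permutations (500 draws), which are exact
stand-ins for a random-scoring classifier by exchangeability.

## Known limitations

- The DR law is one concrete monotone instantiation of dynamic resampling;
  alternatives with the same qualitative behavior exist.
- The PV-DBOW trainer is minimal by design (no hierarchical softmax, no
  distributed-memory mode, no subsampling of frequent words); it is adequate
  for corpus-internal embeddings at these scales but not a general-purpose
  embedding library.
- RIS input carries no inclusion decision, so labels must come from an
  inclusion-id list or a custom tag; CSV is the canonical labeled format.
- Deduplication is exact after normalization (lowercasing, whitespace
  collapsing of title+abstract); fuzzy or DOI-based deduplication is out of
  scope.
- Simulations always run to pool exhaustion; stopping rules are not modeled.
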