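# Methods

## Setting and model

`survcat` treats free-text survey coding as closed-set classification: every
response must receive exactly one index from an ordered category scheme
(original questionnaire options first, researcher-added categories after,
1-based because the prompts ask the model to "return the number associated
with the chosen label"). Categorization is performed per *unique string* —
responses are normalized (Unicode NFC + whitespace trim by default, optional
case-folding), collapsed with multiplicities, categorized once, and expanded
back. For any categorizer that is a deterministic function of the text, the
collapse/expand round trip is exact; this is asserted as a property test and
is what makes per-unique-call cost projections valid.

All completion requests are issued at temperature 0 (the config rejects
anything else): categorization should be as reproducible as the backend
allows. Replies are parsed defensively — a bare in-range integer, or the
first integer after the last `ANSWER:` marker for reasoning prompts; an
out-of-range or missing index yields `parse_status="failed"`, which the
evaluator counts as discordant (never silently dropped).

## Strategies

- **Direct prompting** (zero-shot, few-shot(k), chain of thought): one
  completion per unique text. Few-shot examples are a seeded uniform sample
  without replacement, presented in the training set's original order; the
  selection is a function of (examples, k, seed) only, so every call in a
  run shares one example block and per-call prompt tokens grow strictly
  with k.
- **Cluster-then-label**: embed unique texts, cluster, then issue exactly
  one labeling completion per non-empty cluster using a seeded sample of at
  most 25 exemplar member texts (per-cluster seeds spawned from one seed
  sequence). The parsed label propagates to all members; an unparseable
  cluster reply fails all of them. Empty mixture components are dropped and
  cluster ids renumbered densely. k-means uses 10 restarts under the run
  seed; the Gaussian mixture uses full covariance with a diagonal retry on
  singular fits; hierarchical clustering is Ward linkage on Euclidean
  distance. At k equal to the number of texts, each cluster holds exactly
  its own text and the strategy provably coincides with zero-shot for any
  backend that depends only on the presented text.
- **Fine-tune export** writes the chat-format JSON-lines file (system /
  user / assistant) with the bare index as the assistant turn and reports
  total training tokens; running the remote training job is out of scope.

## Offline backends and token accounting

The mock completion backend is an ordered keyword-rule categorizer with a
declared fallback index. Default prompt templates fence the classification
payload (the response, or the exemplar list) in triple quotes; the mock
extracts only that payload, so its decision never depends on the category
list or instructions around it — the property the k = n convergence result
requires. A fallback decision is declared in-band (`[fallback]` marker) so
the parser can record it honestly.

The mock embedding backend hashes character 3-grams into a signed
256-dimensional vector (configurable; production embedding models are
wider) and L2-normalizes. Token counting defaults to whitespace tokens; any
tokenizer can be registered. Costs are linear functionals of counts, so the
cost model is exact under whichever counter produced the counts.

## Synthetic corpus generator

The generator emulates the structure of a vaccination-barriers free-text
channel, not its linguistic richness: short French noun phrases composed as
`prefix + template core + suffix` from a 12-category scheme, with three
response kinds —

- **clean** (one category's core; the matched rule backend always gets it),
- **vague** (a phrase embedding the cores of ≥ 2 categories; the coded truth
  is uniform over that acceptable set while the first-match rule
  deterministically returns its lowest index),
- **compound** (cores of two categories a, b joined by "et"; truth is a,
  either is acceptable; the rule returns min(a, b)).

Duplication is per unique phrase: repeat counts are Zipf with tail parameter
1 + `duplication_exponent`, so a smaller exponent gives a heavier tail and a
smaller unique fraction, matching the empirical regime where roughly half of
a large free-text corpus collapses to unique strings. Defaults —
vague_rate 0.10, compound_rate 0.05, duplication_exponent 1.2 — were chosen
once as a realistic register for this kind of corpus; calibration tests use
vague_rate 0.2 as their stated condition.

The closed-form expected accuracy of the matched rule backend is

    E[acc] = 1 − vague_rate · (1 − mean(1/|acceptable set|)) − compound_rate/2,

using the exact mean of reciprocals (identical to 1/mean size when all sets
have size 2, as the defaults do). Calibration is asserted at the
unique-string level with binomial standard errors: phrase kinds are i.i.d.
across unique phrases, whereas duplication makes raw-response accuracy
super-binomial. Scoring the backend with acceptable-set-aware adjudication
(a discordance is acceptable iff the model's index lies in the acceptable
set) reproduces the accuracy-vs-ceiling gap mechanism: the ceiling is 1.0
for the matched backend because every vague/compound miss is, by
construction, defensible.

What passing these tests shows — and does not. They demonstrate the
machinery is correct: call counts, dedup identities, parsing, propagation,
the analytic accuracy contract. They say nothing about how a live LLM
performs on real multilingual survey text, where vagueness is not
template-shaped and context (e.g. local rumor knowledge) changes the right
answer; measuring that requires a human-coded benchmark and live backend.

## Evaluation choices

- Train/test splitting is a seeded uniform sample without replacement.
- Failed parses count as discordant (conservative).
- Unreviewed or missing adjudications count as not acceptable, so a partial
  review can only lower the ceiling, never inflate it; an adjudication
  record attached to a concordant pair is rejected outright.
- Per-category accuracy is computed but flagged `underpowered` below a
  configurable minimum cell size (default 10): dozens of categories over a
  200-item test set cannot support category-level claims.
- Margin of error is the normal-approximation half-width z·√(p(1−p)/n);
  required sample size is its ceiling inverse, cross-checked by brute-force
  search in the tests.

## Cost model choices

Campaign totals always use the unrounded per-call cost; rounding (4 decimals
per-call, 2 decimals upfront/total) happens only at display. The shipped
campaign configuration carries the measured per-method token averages and
call volumes of the DRC vaccination-survey categorization campaign (9865
unique strings, 200 clusters) as *inputs* — the package projects costs from
them rather than re-deriving a proprietary tokenizer's counts. The
fine-tuned method's projected total uses its recorded $13 upfront training
cost plus base inference pricing; provider-specific fine-tuned inference
surcharges, if any, belong in a user-supplied pricing config. The embedding
pass upfront ($0.0003) is likewise configuration, since the source campaign
records no embedding token count.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale chosen as the package's
own verification sizes: corpora of 2,000–10,000 responses, benchmarks of
400–999 unique strings, clustering up to k = 200 on ~5,500 texts and
k = n on ~900. The k = n regime is the parameter-recovery condition for
cluster-then-label; at intermediate k the hashed-n-gram embeddings do not
guarantee pure clusters, and no such guarantee is claimed. Determinism
throughout comes from explicit seeds (numpy `default_rng` / `SeedSequence`
spawning per cluster); no global random state is touched.

## Known limitations

- The remote-API adapter is a minimal shim (3 fixed retries, no backoff
  tuning, no streaming); nothing in the package depends on it.
- The generator does not model dialect, interviewer bias, translation error
  or genuinely novel categories; it is a correctness harness, not a
  simulator of respondents.
- Ceilings are computed per method; pooling adjudications across methods is
  left to the analyst.
- The default 43-category scheme is a best-effort reconstruction shipped as
  editable configuration; exact label strings should come from the survey
  instrument being analyzed.
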