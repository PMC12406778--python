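# survcat

Closed-set categorization of open-ended survey free-text responses, with
LLM-assisted strategies, benchmark evaluation, and a token-based cost model.

## The problem

Large household surveys — vaccination-coverage surveys in particular — ask
closed-choice questions ("Why has the child not received all the recommended
vaccines?") with an *Other: free text* escape hatch. The free-text channel
holds the reasons the questionnaire designers did not anticipate (a health
worker strike, displacement by conflict, a pandemic lockdown), but coding
tens of thousands of short French phrases by hand is prohibitively slow.
`survcat` is a toolkit for researchers who want to assign each free-text
response to one category of a closed, numbered scheme (the original options
plus researcher-added categories) using a language model, and to know how
accurate and how expensive each way of doing that is.

## What it implements

**Strategies** (all issue prompts that end with a bare category index):

- *zero-shot* — one completion per response with the full category list;
- *few-shot(k)* — the prompt additionally embeds a seeded, order-stable
  sample of k labeled example pairs;
- *chain of thought* — the model reasons first, then ends its reply with
  `ANSWER: <index>`;
- *cluster-then-label* — embed every unique response, cluster the vectors
  (k-means / Gaussian mixture / Ward hierarchical), and issue **one**
  labeling completion per cluster over ≤ 25 sampled exemplars; at k = n this
  converges on zero-shot, at k ≪ n it is dramatically cheaper;
- *fine-tune export* — writes the chat-format JSON-lines training file
  (system / user / assistant messages) a remote fine-tuning job consumes.

**Unique-string deduplication.** Free-text answers repeat heavily, so every
strategy runs once per unique string and the result is expanded back across
all duplicates — an exact identity for any categorizer that is a function of
the text alone.

**Evaluation.** Seeded benchmark splits, strict accuracy against a human
coder, a discordance worksheet for human review, and the adjudicated
*accuracy ceiling* (concordant + acceptable)/n ≥ accuracy. Test-set sizing
uses the normal-approximation margin of error z·√(p(1−p)/n): at p = 0.85,
n = 200, z = 1.96 the margin is 0.0495, and n = 196 already achieves a 5%
margin.

**Cost model.** Cost is linear in exact token counts: per-call cost =
prompt_tokens·(input $/M)/10⁶ + completion_tokens·(output $/M)/10⁶; campaign
total = upfront + per-call × n_calls, computed from the *unrounded* per-call
cost. Upfront costs cover the embedding pass (cluster-then-label) and the
fine-tune training run.

**Offline backends.** A deterministic keyword-rule completion backend and a
hashed-n-gram embedding backend make every strategy testable end-to-end with
*knowable* accuracy, because the synthetic-corpus generator and the rule
backend are compiled from the same phrase templates.

## Worked example

```bash
survcat simulate --n 2000 --vague-rate 0 --compound-rate 0 --seed 5 --out-dir demo
survcat categorize --responses demo/responses.csv --scheme demo/scheme.csv \
    --method zero_shot --seed 5 --out demo/assignments.csv
survcat cost
```

The `categorize` run log reports one completion call per unique string:

```json
{
  "command": "categorize",
  "method": "zero_shot",
  "seed": 5,
  "backend_id": "mock-rule",
  "n_responses": 2000,
  "n_unique": 863,
  "completion_calls": 863,
  "cache_hits": 0,
  "cache_misses": 863,
  "measured_cost_usd": 0.3347975000000009
}
```

and `survcat cost` projects the campaign table from measured token averages
(9865 unique strings; 200 clusters):

```
               method  n_calls  avg_prompt_tokens  avg_completion_tokens  upfront_usd  per_call_usd  total_usd
cluster_label_gmm_200      200              605.0                    1.0          0.0        0.0015       0.30
            zero_shot     9865              398.0                    1.0          0.0        0.0010       9.91
     chain_of_thought     9865              472.0                   52.0          0.0        0.0017      16.77
          few_shot_20     9865              621.0                    1.0          0.0        0.0016      15.41
          few_shot_50     9865              943.0                    1.0          0.0        0.0024      23.36
         few_shot_400     9865             4486.0                    1.0          0.0        0.0112     110.73
         few_shot_799     9865             8464.0                    1.0          0.0        0.0212     208.84
       fine_tuned_799     9865              398.0                    1.0         13.0        0.0010      22.91
```

Reading the table: cluster-then-label is cheapest because it pays per
cluster, not per response; few-shot cost grows with k because every example
pair adds prompt tokens to every call; the fine-tuned model matches few-shot
accuracy at a fraction of the campaign cost because its prompts drop the
examples after a one-time $13 training investment.

In Python the same workflow is three calls:

```python
import survcat as sc

config = sc.default_generator_config(n_responses=2000, vague_rate=0.0,
                                     compound_rate=0.0, seed=5)
responses, truths = sc.generate(config)
table = sc.deduplicate(responses)

from survcat.strategies import categorize_texts
backend = sc.mock_backend_for(config)          # or a remote adapter
by_text = categorize_texts(table.unique_texts, config.scheme, backend)
assignments = sc.expand_assignments(table, by_text)   # one per response
```

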