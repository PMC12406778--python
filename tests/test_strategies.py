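"""Strategies: prompt rendering, parsing, the five categorization paths."""

import json

import numpy as np
import pytest

from survcat import (
    BackendConfig,
    CountingBackend,
    HashEmbeddingBackend,
    MockRuleBackend,
    SurveyResponse,
    default_scheme,
    deduplicate,
)
from survcat.core import ConfigurationError, ValidationError
from survcat.strategies import (
    COT_TEMPLATE,
    FEW_SHOT_TEMPLATE,
    ZERO_SHOT_TEMPLATE,
    categorize_texts,
    chain_of_thought,
    cluster_label,
    export_finetune_dataset,
    few_shot,
    fit_clusters,
    parse_category_reply,
    read_finetune_dataset,
    render_category_list,
    render_examples,
    select_examples,
    zero_shot,
)
from survcat.synthetic import (
    default_generator_config,
    generate,
    mock_backend_for,
    truth_by_text,
)

CFG = BackendConfig()


# ---------------------------------------------------------------------------
# Rendering and parsing
# ---------------------------------------------------------------------------


def test_render_category_list(small_scheme):
    assert render_category_list(small_scheme) == "1. Travel; 2. Strike; 3. Distance"
    assert render_category_list(small_scheme) == render_category_list(small_scheme)


def test_render_category_list_43_items():
    rendered = render_category_list(default_scheme())
    assert len(rendered.split("; ")) == 43
    assert rendered.startswith("1. ")


@pytest.mark.parametrize(
    "raw,fmt,expected",
    [
        ("24", "bare_index", (24, "ok")),
        ("  7 \n", "bare_index", (7, "ok")),
        ("44", "bare_index", (None, "failed")),
        ("not a number", "bare_index", (None, "failed")),
        ("I think… ANSWER: 7", "reasoning_then_index", (7, "ok")),
        ("rambling with no marker 9", "reasoning_then_index", (None, "failed")),
        ("5 [fallback]", "bare_index", (5, "fallback")),
    ],
)
def test_parse_category_reply(raw, fmt, expected):
    assert parse_category_reply(raw, default_scheme(), fmt) == expected


# ---------------------------------------------------------------------------
# Direct strategies
# ---------------------------------------------------------------------------


def _response(text="voyage", rid="r1"):
    return SurveyResponse(response_id=rid, survey_round=2021, text=text)


def test_zero_shot_mock_rule(small_scheme):
    backend = MockRuleBackend(rules=[("voyage", 3)], fallback_index=1)
    a = zero_shot(_response("parti en voyage"), small_scheme, backend=backend)
    assert (a.category_index, a.parse_status) == (3, "ok")
    assert a.method == "zero_shot"


def test_zero_shot_fallback_contract(small_scheme):
    backend = MockRuleBackend(rules=[], fallback_index=2)
    a = zero_shot(_response("anything"), small_scheme, backend=backend)
    assert (a.category_index, a.parse_status) == (2, "fallback")


def test_zero_shot_clean_corpus_full_recovery(clean_corpus, clean_config, mock_backend):
    """On a clean corpus the matched rule backend recovers every category."""
    responses, truths = clean_corpus
    table = deduplicate(responses)
    tm = truth_by_text(responses, truths)
    assigned = categorize_texts(table.unique_texts, clean_config.scheme, mock_backend)
    assert all(
        assigned[t].category_index == tm[t].true_category for t in table.unique_texts
    )


def test_few_shot_exhaustive_keeps_input_order():
    examples = [("a", 1), ("b", 2), ("c", 3)]
    assert select_examples(examples, 3, seed=9) == examples


def test_few_shot_sample_deterministic_and_order_stable():
    examples = [(f"t{i}", (i % 3) + 1) for i in range(50)]
    s1 = select_examples(examples, 10, seed=4)
    s2 = select_examples(examples, 10, seed=4)
    assert s1 == s2
    positions = [examples.index(e) for e in s1]
    assert positions == sorted(positions)


def test_few_shot_k_exceeds_examples(small_scheme):
    with pytest.raises(ConfigurationError):
        few_shot(
            _response(), small_scheme,
            backend=MockRuleBackend(rules=[], fallback_index=1),
            examples=[("a", 1)], k=5,
        )


def test_few_shot_prompt_tokens_strictly_increase_with_k(small_scheme):
    """More examples mean strictly more prompt tokens on a fixed corpus."""
    examples = [(f"exemple numero {i} assez long", (i % 3) + 1) for i in range(60)]
    backend = CountingBackend(inner=MockRuleBackend(rules=[], fallback_index=1))
    tokens = []
    for k in (5, 20, 40, 60):
        few_shot(
            _response(), small_scheme, backend=backend,
            examples=examples, k=k, seed=1,
        )
        tokens.append(backend.log[-1].prompt_tokens)
    assert tokens == sorted(tokens)
    assert len(set(tokens)) == len(tokens)


def test_chain_of_thought_parses_answer_marker(small_scheme):
    backend = MockRuleBackend(
        rules=[("voyage", 1)], fallback_index=3, reply_style="reasoning"
    )
    counting = CountingBackend(inner=backend)
    a = chain_of_thought(_response("en voyage"), small_scheme, backend=counting)
    assert (a.category_index, a.parse_status) == (1, "ok")
    assert counting.log[-1].completion_tokens > 1


def test_chain_of_thought_requires_reasoning_template(small_scheme):
    with pytest.raises(ConfigurationError):
        chain_of_thought(
            _response(), small_scheme, template=ZERO_SHOT_TEMPLATE,
            backend=MockRuleBackend(rules=[], fallback_index=1),
        )


def test_reasoning_without_marker_fails(small_scheme):
    class Rambler:
        backend_id = "ramble"

        def complete(self, system_role, prompt, config):
            from survcat.backends import CompletionResult

            return CompletionResult(
                text="thoughts with no final marker", prompt_tokens=1,
                completion_tokens=5, backend_id=self.backend_id,
            )

    a = chain_of_thought(_response(), small_scheme, backend=Rambler())
    assert (a.category_index, a.parse_status) == (None, "failed")


def test_backend_exception_becomes_failed_assignment(small_scheme):
    class Exploder:
        def complete(self, system_role, prompt, config):
            raise RuntimeError("transport down")

    a = zero_shot(_response(), small_scheme, backend=Exploder())
    assert a.parse_status == "failed"
    assert "transport down" in a.raw_output


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def _embed(texts):
    return HashEmbeddingBackend().embed(texts)


def test_fit_clusters_singleton_limit():
    texts = ["alpha beta", "gamma delta", "epsilon zeta"]
    model = fit_clusters(_embed(texts), "kmeans", k=3, seed=0, texts=texts)
    assert sorted(model.assignments.values()) == [0, 1, 2]


@pytest.mark.parametrize("algorithm", ["kmeans", "gmm", "hierarchical"])
def test_two_separated_families_perfect_purity(algorithm):
    """Two well-separated template families split cleanly at k=2."""
    rng = np.random.default_rng(2)
    fill = ["vraiment", "souvent", "encore", "cette fois"]
    fam_a = [f"grève des infirmiers {fill[rng.integers(4)]} {i}" for i in range(12)]
    fam_b = [f"rupture de stock de vaccins {fill[rng.integers(4)]} {i}" for i in range(12)]
    texts = fam_a + fam_b
    model = fit_clusters(_embed(texts), algorithm, k=2, seed=0, texts=texts)
    a_ids = {model.assignments[t] for t in fam_a}
    b_ids = {model.assignments[t] for t in fam_b}
    assert len(a_ids) == len(b_ids) == 1
    assert a_ids != b_ids


def test_fit_clusters_deterministic_under_seed():
    texts = [f"texte numero {i} {'grève' if i % 2 else 'voyage'}" for i in range(30)]
    m1 = fit_clusters(_embed(texts), "kmeans", k=5, seed=7, texts=texts)
    m2 = fit_clusters(_embed(texts), "kmeans", k=5, seed=7, texts=texts)
    assert m1.assignments == m2.assignments


def test_fit_clusters_k_out_of_range():
    texts = ["a b", "c d"]
    with pytest.raises(ConfigurationError):
        fit_clusters(_embed(texts), "kmeans", k=3, seed=0, texts=texts)


# ---------------------------------------------------------------------------
# Cluster labeling
# ---------------------------------------------------------------------------


def test_cluster_label_one_call_per_cluster_and_propagation():
    config = default_generator_config(n_responses=400, vague_rate=0, compound_rate=0, seed=2)
    responses, _ = generate(config)
    texts = deduplicate(responses).unique_texts
    backend = CountingBackend(inner=mock_backend_for(config))
    k = 10
    out = cluster_label(
        texts, config.scheme, HashEmbeddingBackend(), backend,
        algorithm="kmeans", k=k, seed=0,
    )
    assert backend.calls == k
    assert set(out) == set(texts)
    # all members of a cluster share the cluster's label
    by_raw: dict[str, set] = {}
    for t, a in out.items():
        by_raw.setdefault(a.raw_output, set()).add(a.category_index)
    assert all(len(v) == 1 for v in by_raw.values())


def test_cluster_label_at_k_equals_n_matches_zero_shot():
    config = default_generator_config(n_responses=300, seed=8)
    responses, _ = generate(config)
    texts = deduplicate(responses).unique_texts
    backend = mock_backend_for(config)
    clustered = cluster_label(
        texts, config.scheme, HashEmbeddingBackend(), backend,
        algorithm="kmeans", k=len(texts), seed=0,
    )
    direct = categorize_texts(texts, config.scheme, backend)
    assert all(
        clustered[t].category_index == direct[t].category_index for t in texts
    )


def test_cluster_label_unparseable_reply_fails_all_members(small_scheme):
    class Gibberish:
        backend_id = "gibberish"

        def complete(self, system_role, prompt, config):
            from survcat.backends import CompletionResult

            return CompletionResult(
                text="no index here", prompt_tokens=1, completion_tokens=2,
                backend_id=self.backend_id,
            )

    texts = ["aaa bbb", "aab bba", "zzz yyy"]
    out = cluster_label(
        texts, small_scheme, HashEmbeddingBackend(), Gibberish(),
        algorithm="kmeans", k=1, seed=0,
    )
    assert all(a.parse_status == "failed" and a.category_index is None for a in out.values())


# ---------------------------------------------------------------------------
# Fine-tune export
# ---------------------------------------------------------------------------


def test_finetune_export_record_count_and_round_trip(tmp_path, small_scheme):
    examples = [(f"réponse {i}", (i % 3) + 1) for i in range(799)]
    path = tmp_path / "ft.jsonl"
    summary = export_finetune_dataset(examples, small_scheme, "system role", path)
    assert summary["n_records"] == 799
    assert read_finetune_dataset(path) == examples


def test_finetune_export_token_accounting(tmp_path, small_scheme):
    examples = [("deux mots", 1)]
    path = tmp_path / "ft.jsonl"
    summary = export_finetune_dataset(examples, small_scheme, "un role", path)
    rec = json.loads(path.read_text(encoding="utf-8"))
    expected = sum(len(m["content"].split()) for m in rec["messages"])
    assert summary["total_tokens"] == expected


def test_finetune_export_rejects_out_of_range_before_writing(tmp_path, small_scheme):
    path = tmp_path / "ft.jsonl"
    with pytest.raises(ValidationError):
        export_finetune_dataset([("ok", 1), ("bad", 9)], small_scheme, "role", path)
    assert not path.exists()


def test_finetune_record_shape(tmp_path, small_scheme):
    path = tmp_path / "ft.jsonl"
    export_finetune_dataset([("texte", 2)], small_scheme, "role", path)
    rec = json.loads(path.read_text(encoding="utf-8"))
    assert [m["role"] for m in rec["messages"]] == ["system", "user", "assistant"]
    assert rec["messages"][2]["content"] == "2"
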