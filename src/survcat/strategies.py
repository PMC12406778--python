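"""Categorization strategies over a closed category scheme.

Five ways to turn free-text responses into category indices:

* :func:`zero_shot` — one completion per response, category list only.
* :func:`few_shot` — like zero-shot but the prompt embeds k labeled
  example pairs (a seeded, order-stable sample of the training set).
* :func:`chain_of_thought` — the model reasons first and ends its reply
  with ``ANSWER: <index>``.
* :func:`cluster_label` — embed every unique response, cluster the vectors
  (k-means / Gaussian mixture / Ward hierarchical), then issue **one**
  labeling completion per cluster using up to 25 sampled exemplar responses;
  the parsed category propagates to all cluster members.  At k equal to the
  number of responses this converges on zero-shot.
* :func:`export_finetune_dataset` — writes the chat-format JSON-lines file a
  remote fine-tuning job consumes (running that job is out of scope).

All prompts present the category list as ``1. label; 2. label; ...`` and ask
for the bare index back, so replies parse with :func:`parse_category_reply`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .backends import (
    BackendConfig,
    CompletionBackend,
    CompletionResult,
    EmbeddingVector,
    count_tokens,
    embedding_matrix,
)
from .core import (
    CategoryScheme,
    ConfigurationError,
    SurveyResponse,
    ValidationError,
)

FALLBACK_MARKER = "[fallback]"
ANSWER_MARKER = "ANSWER:"


# ---------------------------------------------------------------------------
# Prompt templates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PromptTemplate:
    """A system role plus a body with {response}, {category_list} and
    {examples} placeholders.  ``answer_format`` decides how the reply is
    parsed: a bare index, or free reasoning ending in ``ANSWER: <index>``."""

    system_role: str
    body_template: str
    answer_format: str = "bare_index"  # or "reasoning_then_index"

    def render(
        self, response: str, category_list: str, examples: str = ""
    ) -> str:
        text = self.body_template.format(
            response=response, category_list=category_list, examples=examples
        )
        if not text.strip():
            raise ValidationError("rendered prompt is empty")
        return text


_DIRECT_SYSTEM_ROLE = (
    "You are an assistant who looks at a response to a survey question and "
    "assigns it the best-fitting thematic label.\n\n"
    "The survey was conducted in DRC and asked parents why their child did "
    "not receive all their recommended vaccines.\n\n"
    "I will provide you with a survey response and a comprehensive list of "
    "thematic labels. You can only choose from one of these. You will only "
    "return the number associated with the chosen label, nothing else."
)

ZERO_SHOT_TEMPLATE = PromptTemplate(
    system_role=_DIRECT_SYSTEM_ROLE,
    body_template=(
        'Here is the survey response:\n"""{response}"""\n\n'
        "Here is a list of possible labels separated by semicolons:\n"
        "{category_list}"
    ),
)

FEW_SHOT_TEMPLATE = PromptTemplate(
    system_role=_DIRECT_SYSTEM_ROLE,
    body_template=(
        "Here are example responses with the number of their correct label, "
        "one per line:\n{examples}\n\n"
        'Here is the survey response to categorize:\n"""{response}"""\n\n'
        "Here is a list of possible labels separated by semicolons:\n"
        "{category_list}"
    ),
)

COT_TEMPLATE = PromptTemplate(
    system_role=(
        "You are an assistant who looks at a response to a survey question "
        "and assigns it the best-fitting thematic label.\n\n"
        "The survey was conducted in DRC and asked parents why their child "
        "did not receive all their recommended vaccines.\n\n"
        "I will provide you with a survey response and a comprehensive list "
        "of thematic labels. You can only choose from one of these. Think "
        "step by step about which label fits best, then end your reply with "
        "'ANSWER:' followed by the number of the chosen label."
    ),
    body_template=ZERO_SHOT_TEMPLATE.body_template,
    answer_format="reasoning_then_index",
)

CLUSTER_TEMPLATE = PromptTemplate(
    system_role=(
        "You are an assistant who looks at example responses to a survey "
        "question and describes their common thematic meaning.\n\n"
        "The survey was conducted in DRC and asked parents why their child "
        "did not receive all their recommended vaccines.\n\n"
        "I will provide you with a list of survey responses and a "
        "comprehensive list of thematic labels. You can only choose from one "
        "of these. You will only return the number associated with the "
        "chosen label, nothing else."
    ),
    body_template=(
        "Responses have been pre-screened and should all fit under one "
        "cohesive theme.\n\n"
        "Here are the example responses, separated by semicolons:\n"
        '"""{response}"""\n\n'
        "Here is a list of possible labels separated by semicolons:\n"
        "{category_list}"
    ),
)


def render_category_list(scheme: CategoryScheme) -> str:
    """Render the closed label list as ``1. label1; 2. label2; ...``."""
    return "; ".join(f"{c.index}. {c.label}" for c in scheme)


def render_examples(pairs: Sequence[tuple[str, int]]) -> str:
    """Render labeled example pairs as ``text -> index`` lines."""
    return "\n".join(f"{text} -> {index}" for text, index in pairs)


# ---------------------------------------------------------------------------
# Assignments and reply parsing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategoryAssignment:
    """One (response, category) decision with full provenance: the method
    that produced it, the raw model output and how parsing went."""

    response_id: str
    category_index: int | None
    method: str
    raw_output: str
    parse_status: str  # ok | fallback | failed

    def __post_init__(self) -> None:
        if self.parse_status not in ("ok", "fallback", "failed"):
            raise ValidationError(f"bad parse_status {self.parse_status!r}")
        if self.parse_status == "ok" and self.category_index is None:
            raise ValidationError("parse_status ok requires a category_index")


def parse_category_reply(
    raw: str, scheme: CategoryScheme, answer_format: str = "bare_index"
) -> tuple[int | None, str]:
    """Parse a backend reply into (category_index, parse_status).

    ``bare_index`` expects a single integer (whitespace tolerated);
    ``reasoning_then_index`` takes the first integer after the last
    ``ANSWER:`` marker.  A reply carrying the backend's ``[fallback]``
    marker parses with status ``fallback``.  Out-of-range or absent
    integers give (None, "failed").
    """
    status = "ok"
    text = raw
    if FALLBACK_MARKER in text:
        status = "fallback"
        text = text.replace(FALLBACK_MARKER, " ")
    if answer_format == "reasoning_then_index":
        pos = text.rfind(ANSWER_MARKER)
        if pos < 0:
            return None, "failed"
        text = text[pos + len(ANSWER_MARKER):]
        match = re.search(r"-?\d+", text)
        if match is None:
            return None, "failed"
        candidate = match.group()
    elif answer_format == "bare_index":
        candidate = text.strip()
        if not re.fullmatch(r"-?\d+", candidate):
            return None, "failed"
    else:
        raise ConfigurationError(f"unknown answer_format {answer_format!r}")
    index = int(candidate)
    if not scheme.in_range(index):
        return None, "failed"
    return index, status


# ---------------------------------------------------------------------------
# Direct strategies (one completion per response)
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = BackendConfig()


def _direct_call(
    response_id: str,
    text: str,
    scheme: CategoryScheme,
    template: PromptTemplate,
    backend: CompletionBackend,
    method: str,
    examples_block: str = "",
    config: BackendConfig | None = None,
) -> CategoryAssignment:
    config = config or _DEFAULT_CONFIG
    prompt = template.render(
        response=text,
        category_list=render_category_list(scheme),
        examples=examples_block,
    )
    try:
        result = backend.complete(template.system_role, prompt, config)
    except Exception as exc:  # declared backend failure -> failed assignment
        return CategoryAssignment(
            response_id=response_id,
            category_index=None,
            method=method,
            raw_output=f"<backend error: {exc}>",
            parse_status="failed",
        )
    index, status = parse_category_reply(result.text, scheme, template.answer_format)
    return CategoryAssignment(
        response_id=response_id,
        category_index=index,
        method=method,
        raw_output=result.text,
        parse_status=status,
    )


def zero_shot(
    response: SurveyResponse,
    scheme: CategoryScheme,
    template: PromptTemplate = ZERO_SHOT_TEMPLATE,
    backend: CompletionBackend = None,  # type: ignore[assignment]
    config: BackendConfig | None = None,
) -> CategoryAssignment:
    """Categorize one response with no examples: one completion call."""
    return _direct_call(
        response.response_id, response.text, scheme, template, backend,
        method="zero_shot", config=config,
    )


def select_examples(
    examples: Sequence[tuple[str, int]], k: int, seed: int
) -> list[tuple[str, int]]:
    """Seeded uniform sample of k example pairs, order-stable (input order)."""
    if k > len(examples):
        raise ConfigurationError(
            f"k={k} exceeds the {len(examples)} available examples"
        )
    if k == len(examples):
        return list(examples)
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(examples), size=k, replace=False).tolist())
    return [examples[i] for i in idx]


def few_shot(
    response: SurveyResponse,
    scheme: CategoryScheme,
    template: PromptTemplate = FEW_SHOT_TEMPLATE,
    backend: CompletionBackend = None,  # type: ignore[assignment]
    examples: Sequence[tuple[str, int]] = (),
    k: int = 20,
    seed: int = 0,
    config: BackendConfig | None = None,
) -> CategoryAssignment:
    """Categorize one response with k labeled examples embedded in the prompt.

    The example sample is a function of (examples, k, seed) only, so every
    response in a run sees the same example block.
    """
    block = render_examples(select_examples(examples, k, seed))
    return _direct_call(
        response.response_id, response.text, scheme, template, backend,
        method=f"few_shot_{k}", examples_block=block, config=config,
    )


def chain_of_thought(
    response: SurveyResponse,
    scheme: CategoryScheme,
    template: PromptTemplate = COT_TEMPLATE,
    backend: CompletionBackend = None,  # type: ignore[assignment]
    config: BackendConfig | None = None,
) -> CategoryAssignment:
    """Categorize with elicited reasoning; the reply is parsed at its
    ``ANSWER:`` marker."""
    if template.answer_format != "reasoning_then_index":
        raise ConfigurationError(
            "chain_of_thought requires a reasoning_then_index template"
        )
    return _direct_call(
        response.response_id, response.text, scheme, template, backend,
        method="chain_of_thought", config=config,
    )


def categorize_texts(
    texts: Sequence[str],
    scheme: CategoryScheme,
    backend: CompletionBackend,
    method: str = "zero_shot",
    examples: Sequence[tuple[str, int]] = (),
    k: int = 20,
    seed: int = 0,
    config: BackendConfig | None = None,
) -> dict[str, CategoryAssignment]:
    """Run a direct strategy over unique texts: one call per text.

    Returns a map text -> assignment with ``response_id`` set to the text
    itself; use :func:`survcat.core.expand_assignments` to restore response
    ids over the full corpus.
    """
    if method == "zero_shot":
        template, block = ZERO_SHOT_TEMPLATE, ""
        label = "zero_shot"
    elif method == "few_shot":
        template = FEW_SHOT_TEMPLATE
        block = render_examples(select_examples(examples, k, seed))
        label = f"few_shot_{k}"
    elif method == "chain_of_thought":
        template, block = COT_TEMPLATE, ""
        label = "chain_of_thought"
    else:
        raise ConfigurationError(f"unknown direct method {method!r}")
    return {
        t: _direct_call(t, t, scheme, template, backend, method=label,
                        examples_block=block, config=config)
        for t in texts
    }


# ---------------------------------------------------------------------------
# Clustering + cluster labeling
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    algorithm: str
    k: int
    assignments: dict[str, int]  # text -> dense cluster id in [0, k)
    seed: int

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))

    def members(self) -> dict[int, list[str]]:
        """Cluster id -> member texts, preserving input text order."""
        out: dict[int, list[str]] = {}
        for text, cid in self.assignments.items():
            out.setdefault(cid, []).append(text)
        return out


def fit_clusters(
    vectors: Sequence[EmbeddingVector],
    algorithm: str,
    k: int,
    seed: int,
    texts: Sequence[str] | None = None,
) -> ClusterModel:
    """Cluster embedding vectors with k-means, a Gaussian mixture, or Ward
    hierarchical clustering.

    ``texts`` must align with ``vectors``; cluster ids are renumbered densely
    in order of first appearance, dropping any empty components a mixture
    fit leaves behind.  Deterministic under a fixed seed.
    """
    n = len(vectors)
    if texts is None or len(texts) != n:
        raise ConfigurationError("texts must align one-to-one with vectors")
    if not 1 <= k <= n:
        raise ConfigurationError(f"k={k} must be in [1, {n}]")
    X = embedding_matrix(vectors)
    if algorithm == "kmeans":
        from sklearn.cluster import KMeans

        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)
    elif algorithm == "gmm":
        from sklearn.mixture import GaussianMixture

        try:
            gm = GaussianMixture(
                n_components=k, covariance_type="full", random_state=seed
            ).fit(X)
        except Exception:
            # singular full-covariance fit: retreat to diagonal covariance
            gm = GaussianMixture(
                n_components=k, covariance_type="diag", random_state=seed
            ).fit(X)
        labels = gm.predict(X)
    elif algorithm == "hierarchical":
        from sklearn.cluster import AgglomerativeClustering

        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    else:
        raise ConfigurationError(
            f"unknown algorithm {algorithm!r}; expected kmeans|gmm|hierarchical"
        )
    dense: dict[int, int] = {}
    assignments: dict[str, int] = {}
    for text, raw in zip(texts, labels):
        cid = dense.setdefault(int(raw), len(dense))
        assignments[text] = cid
    return ClusterModel(algorithm=algorithm, k=k, assignments=assignments, seed=seed)


def cluster_label(
    texts: Sequence[str],
    scheme: CategoryScheme,
    embed_backend,
    llm_backend: CompletionBackend,
    algorithm: str = "kmeans",
    k: int = 200,
    exemplars_per_cluster: int = 25,
    seed: int = 0,
    template: PromptTemplate = CLUSTER_TEMPLATE,
    config: BackendConfig | None = None,
) -> dict[str, CategoryAssignment]:
    """Embed, cluster, then label each cluster with a single completion call.

    Exactly one completion is issued per (non-empty) cluster — the cost
    advantage of this strategy — using a seeded sample of at most
    ``exemplars_per_cluster`` member texts rendered semicolon-separated into
    the labeling prompt.  The parsed category propagates to every member;
    an unparseable cluster reply marks all its members ``failed``.
    """
    config = config or _DEFAULT_CONFIG
    texts = list(texts)
    vectors = embed_backend.embed(texts, config)
    model = fit_clusters(vectors, algorithm, k, seed, texts=texts)
    method = f"cluster_label[{algorithm},k={k}]"
    category_list = render_category_list(scheme)
    out: dict[str, CategoryAssignment] = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(model.n_clusters)
    for cid, members in sorted(model.members().items()):
        rng = np.random.default_rng(children[cid])
        n_ex = min(len(members), exemplars_per_cluster)
        if n_ex == len(members):
            exemplars = members
        else:
            idx = sorted(rng.choice(len(members), size=n_ex, replace=False).tolist())
            exemplars = [members[i] for i in idx]
        prompt = template.render(
            response="; ".join(exemplars), category_list=category_list
        )
        result = llm_backend.complete(template.system_role, prompt, config)
        index, status = parse_category_reply(
            result.text, scheme, template.answer_format
        )
        for text in members:
            out[text] = CategoryAssignment(
                response_id=text,
                category_index=index,
                method=method,
                raw_output=result.text,
                parse_status=status,
            )
    return out


# ---------------------------------------------------------------------------
# Fine-tune dataset export
# ---------------------------------------------------------------------------


def export_finetune_dataset(
    examples: Sequence[tuple[str, int]],
    scheme: CategoryScheme,
    system_role: str,
    path: str | Path,
    token_counter: str = "whitespace",
) -> dict:
    """Write a chat-format JSON-lines training file for a fine-tuning job.

    One record per example: system message = ``system_role``, user message =
    the rendered zero-shot prompt for the example text, assistant message =
    the bare category index.  Indices are validated before anything is
    written.  Returns {"n_records", "total_tokens"} where total_tokens is the
    token count summed over all messages of all records (the quantity a
    per-million-token training price applies to).
    """
    if not examples:
        raise ConfigurationError("no examples to export")
    for pos, (_, index) in enumerate(examples):
        if not scheme.in_range(index):
            raise ValidationError(
                f"example {pos}: category index {index} outside scheme range "
                f"1..{len(scheme)}"
            )
    category_list = render_category_list(scheme)
    total_tokens = 0
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for text, index in examples:
            user = ZERO_SHOT_TEMPLATE.render(
                response=text, category_list=category_list
            )
            assistant = str(index)
            record = {
                "messages": [
                    {"role": "system", "content": system_role},
                    {"role": "user", "content": user},
                    {"role": "assistant", "content": assistant},
                ]
            }
            total_tokens += sum(
                count_tokens(m["content"], token_counter)
                for m in record["messages"]
            )
            fh.write(json.dumps(record, ensure_ascii=False, sort_keys=False) + "\n")
    return {"n_records": len(examples), "total_tokens": total_tokens}


def read_finetune_dataset(path: str | Path) -> list[tuple[str, int]]:
    """Read back an exported fine-tune file as (response text, index) pairs."""
    pairs: list[tuple[str, int]] = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            user = next(m["content"] for m in rec["messages"] if m["role"] == "user")
            assistant = next(
                m["content"] for m in rec["messages"] if m["role"] == "assistant"
            )
            fenced = user.split('"""')
            text = fenced[1] if len(fenced) >= 3 else user
            pairs.append((text, int(assistant.strip())))
    return pairs
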