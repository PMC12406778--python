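"""Completion and embedding backends with exact token accounting.

All categorization strategies talk to a backend through two calls —
``complete(system_role, prompt, config)`` and ``embed(texts, config)`` — and
every reply carries its exact prompt/completion token counts, which are the
currency of the cost model.  Two deterministic offline backends make the whole
pipeline testable without network access:

* :class:`MockRuleBackend` — a keyword-rule categorizer.  It extracts the
  classification payload (the response text, or a cluster's exemplar list)
  from between triple-quote fences in the prompt and fires the first matching
  (pattern, category) rule, so its behaviour depends only on the text
  presented, never on the surrounding prompt scaffolding.
* :class:`HashEmbeddingBackend` — deterministic semantic-embedding stand-in
  built from hashed character n-grams, L2-normalized.

A thin adapter for remote GPT-class APIs exists behind the same contract but
nothing in the package depends on it.  Completion temperature is pinned to 0:
categorization must be maximally reproducible.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np

from .core import ConfigurationError, SurvcatError, ValidationError

# Fences used by the default prompt templates to mark the text a rule-based
# backend should classify; see strategies.py.
PAYLOAD_FENCE = '"""'


class BackendError(SurvcatError):
    """A backend call failed after its retry budget (remote backends only)."""

    def __init__(self, message: str, attempts: int = 1):
        super().__init__(message)
        self.attempts = attempts


# ---------------------------------------------------------------------------
# Token counting
# ---------------------------------------------------------------------------


def whitespace_tokens(text: str) -> int:
    """Whitespace token count: the offline default.

    Costs are linear functions of counts, so the cost model is exact under
    any counter; a model tokenizer can be plugged in for realistic counts.
    """
    return len(text.split())


TOKEN_COUNTERS: dict[str, Callable[[str], int]] = {"whitespace": whitespace_tokens}


def register_token_counter(name: str, fn: Callable[[str], int]) -> None:
    """Register a tokenizer (e.g. a model tokenizer) under ``name``."""
    TOKEN_COUNTERS[name] = fn


def count_tokens(text: str, counter: str = "whitespace") -> int:
    try:
        return TOKEN_COUNTERS[counter](text)
    except KeyError:
        raise ConfigurationError(
            f"no token counter {counter!r} registered; known: {sorted(TOKEN_COUNTERS)}"
        ) from None


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompletionResult:
    text: str
    prompt_tokens: int
    completion_tokens: int
    backend_id: str

    def __post_init__(self) -> None:
        if self.prompt_tokens < 0 or self.completion_tokens < 0:
            raise ValidationError("token counts must be >= 0")


@dataclass(frozen=True)
class EmbeddingVector:
    values: tuple[float, ...]
    dim: int

    def __post_init__(self) -> None:
        if len(self.values) != self.dim:
            raise ValidationError(
                f"embedding has {len(self.values)} values but dim={self.dim}"
            )

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class BackendConfig:
    backend_id: str = "mock"
    temperature: float = 0.0
    seed: int = 0
    token_counter: str = "whitespace"

    def __post_init__(self) -> None:
        if self.temperature != 0.0:
            raise ValidationError(
                "temperature is pinned to 0 for reproducible categorization"
            )


class CompletionBackend(Protocol):  # pragma: no cover - typing only
    def complete(
        self, system_role: str, prompt: str, config: BackendConfig
    ) -> CompletionResult: ...


# ---------------------------------------------------------------------------
# Mock rule backend
# ---------------------------------------------------------------------------


def extract_payload(prompt: str) -> str:
    """Return the fenced classification payload of a prompt.

    The default templates wrap the response text (or cluster exemplar list)
    in triple-quote fences; everything else in the prompt — instructions and
    the full category list — is scaffolding a text-only backend must ignore.
    Falls back to the whole prompt when no fence is present.
    """
    parts = prompt.split(PAYLOAD_FENCE)
    if len(parts) >= 3:
        return parts[1]
    return prompt


@dataclass
class MockRuleBackend:
    """Deterministic keyword-rule categorizer standing in for an LLM.

    ``rules`` is an ordered list of (pattern, category_index); the first
    pattern found as a substring of the casefolded payload wins.  When no
    rule fires the declared ``fallback_index`` is returned.  ``reply_style``
    'bare' emits just the index; 'reasoning' emits a short reasoning sentence
    ending in ``ANSWER: <index>`` for chain-of-thought parsing.
    """

    rules: list[tuple[str, int]]
    fallback_index: int
    backend_id: str = "mock-rule"
    reply_style: str = "bare"

    def classify_text(self, text: str) -> tuple[int, str | None]:
        """Apply the first-match rule to raw text; returns (index, pattern)."""
        hay = text.casefold()
        for pattern, index in self.rules:
            if pattern.casefold() in hay:
                return index, pattern
        return self.fallback_index, None

    def complete(
        self, system_role: str, prompt: str, config: BackendConfig
    ) -> CompletionResult:
        if not prompt:
            raise ConfigurationError("empty prompt")
        payload = extract_payload(prompt)
        index, pattern = self.classify_text(payload)
        # no rule fired: declare the fallback in-band so parsers can record it
        marker = "" if pattern is not None else " [fallback]"
        if self.reply_style == "reasoning":
            cue = pattern if pattern is not None else "no clear cue"
            text = f"The response mentions {cue}. ANSWER: {index}{marker}"
        else:
            text = f"{index}{marker}"
        counter = config.token_counter
        return CompletionResult(
            text=text,
            prompt_tokens=count_tokens(system_role + " " + prompt, counter),
            completion_tokens=count_tokens(text, counter),
            backend_id=self.backend_id,
        )


# ---------------------------------------------------------------------------
# Mock embedding backend
# ---------------------------------------------------------------------------


@dataclass
class HashEmbeddingBackend:
    """Deterministic embedding from hashed character 3-grams, L2-normalized.

    Strings sharing most of their characters land close in cosine distance,
    which is enough structure for clustering tests; the default dimension is
    256 (configurable) rather than the 1536 of production embedding models,
    purely for speed.
    """

    dim: int = 256
    ngram: int = 3
    backend_id: str = "mock-embed"

    def _embed_one(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=float)
        s = f" {text.casefold()} "
        n = self.ngram
        if len(s) < n:
            s = s.ljust(n)
        for i in range(len(s) - n + 1):
            gram = s[i : i + n]
            h = hashlib.blake2b(gram.encode("utf-8"), digest_size=8).digest()
            bucket = int.from_bytes(h[:4], "little") % self.dim
            sign = 1.0 if h[4] % 2 == 0 else -1.0
            vec[bucket] += sign
        norm = np.linalg.norm(vec)
        if norm == 0:
            vec[0] = 1.0
            norm = 1.0
        return vec / norm

    def embed(
        self, texts: Sequence[str], config: BackendConfig | None = None
    ) -> list[EmbeddingVector]:
        if not texts:
            raise ConfigurationError("embed requires at least one text")
        for pos, t in enumerate(texts):
            if not t or not t.strip():
                raise ConfigurationError(f"empty text at position {pos}")
        return [
            EmbeddingVector(values=tuple(self._embed_one(t)), dim=self.dim)
            for t in texts
        ]


def embedding_matrix(vectors: Sequence[EmbeddingVector]) -> np.ndarray:
    return np.vstack([v.as_array() for v in vectors])


# ---------------------------------------------------------------------------
# Response cache
# ---------------------------------------------------------------------------


def _cache_key(backend_id: str, system_role: str, prompt: str) -> str:
    digest = hashlib.sha256(
        (system_role + "\x00" + prompt).encode("utf-8")
    ).hexdigest()
    return f"{backend_id}:{digest}"


@dataclass
class CachedBackend:
    """Transparent completion cache: identical calls are served from memory.

    The cache can be persisted as JSON-lines of (key, system_role, prompt,
    result) records; a corrupted entry is skipped with a warning rather than
    failing the run.
    """

    inner: CompletionBackend
    store: dict[str, CompletionResult] = field(default_factory=dict)
    hits: int = 0
    misses: int = 0

    def complete(
        self, system_role: str, prompt: str, config: BackendConfig
    ) -> CompletionResult:
        key = _cache_key(
            getattr(self.inner, "backend_id", config.backend_id), system_role, prompt
        )
        if key in self.store:
            self.hits += 1
            return self.store[key]
        self.misses += 1
        result = self.inner.complete(system_role, prompt, config)
        self.store[key] = result
        return result

    def embed(self, texts, config=None):
        # embeddings pass straight through; only completions are cached
        return self.inner.embed(texts, config)  # type: ignore[attr-defined]

    def save(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for key, result in self.store.items():
                fh.write(
                    json.dumps(
                        {
                            "key": key,
                            "result": {
                                "text": result.text,
                                "prompt_tokens": result.prompt_tokens,
                                "completion_tokens": result.completion_tokens,
                                "backend_id": result.backend_id,
                            },
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )

    def load(self, path: str | Path) -> int:
        """Load persisted entries; returns the number loaded. Bad lines warn."""
        loaded = 0
        with Path(path).open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                    result = CompletionResult(**rec["result"])
                    self.store[rec["key"]] = result
                    loaded += 1
                except (json.JSONDecodeError, KeyError, TypeError, ValidationError):
                    warnings.warn(
                        f"skipping corrupted cache entry at line {lineno}",
                        stacklevel=2,
                    )
        return loaded


@dataclass
class CountingBackend:
    """Pass-through wrapper that counts completion calls and accumulates a
    run log of :class:`CompletionResult` (for call-count contracts and
    measured-cost accounting)."""

    inner: CompletionBackend
    calls: int = 0
    log: list[CompletionResult] = field(default_factory=list)

    def complete(
        self, system_role: str, prompt: str, config: BackendConfig
    ) -> CompletionResult:
        self.calls += 1
        result = self.inner.complete(system_role, prompt, config)
        self.log.append(result)
        return result

    def embed(self, texts, config=None):
        return self.inner.embed(texts, config)  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# Remote adapter (optional shim; nothing in the package depends on it)
# ---------------------------------------------------------------------------


class RemoteChatBackend:
    """Adapter for an OpenAI-compatible chat-completion API.

    Requires the ``openai`` client package and network access; calls retry up
    to 3 times before raising :class:`BackendError`.  Kept behind the same
    ``complete`` contract as the offline backends.
    """

    def __init__(self, model: str, backend_id: str | None = None):
        self.model = model
        self.backend_id = backend_id or f"remote:{model}"

    def complete(
        self, system_role: str, prompt: str, config: BackendConfig
    ) -> CompletionResult:  # pragma: no cover - needs network
        try:
            import openai  # type: ignore
        except ImportError as exc:
            raise BackendError(
                "remote backend requires the 'openai' package", attempts=0
            ) from exc
        client = openai.OpenAI()
        last_exc: Exception | None = None
        for attempt in range(1, 4):
            try:
                reply = client.chat.completions.create(
                    model=self.model,
                    temperature=config.temperature,
                    messages=[
                        {"role": "system", "content": system_role},
                        {"role": "user", "content": prompt},
                    ],
                )
                choice = reply.choices[0].message.content or ""
                usage = reply.usage
                return CompletionResult(
                    text=choice,
                    prompt_tokens=usage.prompt_tokens,
                    completion_tokens=usage.completion_tokens,
                    backend_id=self.backend_id,
                )
            except Exception as exc:  # noqa: BLE001 - transport errors vary
                last_exc = exc
        raise BackendError(f"remote call failed: {last_exc}", attempts=3)
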