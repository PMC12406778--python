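"""Benchmark evaluation: splits, accuracy, adjudication, power calculation.

A benchmark is a set of (response, human category) pairs coded by a human
expert.  Accuracy is strict agreement with that coder.  Because short
free-text answers are often vague or compound, a discordant model category
can still be defensible; the *accuracy ceiling* re-scores after a human
review of all discordances, counting "acceptable" model categorizations in
the numerator.  The ceiling therefore always dominates plain accuracy.

The margin-of-error helpers implement the normal-approximation half-width
z*sqrt(p(1-p)/n) used to size the test set.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    AlignmentError,
    CategoryScheme,
    ConfigurationError,
    SurveyResponse,
    ValidationError,
)
from .strategies import CategoryAssignment


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BenchmarkExample:
    response: SurveyResponse
    human_category: int

    def __post_init__(self) -> None:
        if self.human_category < 1:
            raise ValidationError("human_category must be a positive index")


@dataclass
class BenchmarkSplit:
    train: list[BenchmarkExample]
    test: list[BenchmarkExample]
    seed: int

    def __post_init__(self) -> None:
        train_ids = {e.response.response_id for e in self.train}
        test_ids = {e.response.response_id for e in self.test}
        if train_ids & test_ids:
            raise ValidationError("train and test sets share response ids")


VERDICTS = ("acceptable", "not_acceptable", "unreviewed")


@dataclass(frozen=True)
class AdjudicationRecord:
    """A human verdict on one human-vs-model discordance."""

    response_id: str
    human_category: int
    model_category: int
    verdict: str = "unreviewed"

    def __post_init__(self) -> None:
        if self.human_category == self.model_category:
            raise ValidationError(
                f"{self.response_id}: adjudication requires a discordant pair"
            )
        if self.verdict not in VERDICTS:
            raise ValidationError(f"bad verdict {self.verdict!r}")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def split_benchmark(
    examples: Sequence[BenchmarkExample], n_test: int, seed: int
) -> BenchmarkSplit:
    """Seeded train/test partition: a uniform sample without replacement of
    ``n_test`` examples forms the test set, the remainder the training set."""
    n = len(examples)
    if not 0 < n_test < n:
        raise ConfigurationError(f"n_test={n_test} must be in (0, {n})")
    rng = np.random.default_rng(seed)
    test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
    train = [e for i, e in enumerate(examples) if i not in test_idx]
    test = [e for i, e in enumerate(examples) if i in test_idx]
    return BenchmarkSplit(train=train, test=test, seed=seed)


# ---------------------------------------------------------------------------
# Accuracy and the adjudicated ceiling
# ---------------------------------------------------------------------------


def _align(
    assignments: Sequence[CategoryAssignment], truths: Sequence[BenchmarkExample]
) -> list[tuple[CategoryAssignment, BenchmarkExample]]:
    by_id = {a.response_id: a for a in assignments}
    if len(by_id) != len(assignments):
        raise AlignmentError("duplicate response_id among assignments")
    missing = [t.response.response_id for t in truths if t.response.response_id not in by_id]
    if missing:
        raise AlignmentError(
            f"{len(missing)} benchmark ids lack assignments, e.g. {missing[0]!r}"
        )
    return [(by_id[t.response.response_id], t) for t in truths]


def accuracy(
    assignments: Sequence[CategoryAssignment], truths: Sequence[BenchmarkExample]
) -> float:
    """Strict agreement rate with the human coder: concordant / n.

    A failed parse can never be concordant, so it counts against accuracy.
    """
    pairs = _align(assignments, truths)
    if not pairs:
        raise ConfigurationError("empty benchmark")
    concordant = sum(
        1 for a, t in pairs
        if a.category_index is not None and a.category_index == t.human_category
    )
    return concordant / len(pairs)


def accuracy_ceiling(
    assignments: Sequence[CategoryAssignment],
    truths: Sequence[BenchmarkExample],
    adjudications: Sequence[AdjudicationRecord],
) -> float:
    """Accuracy after adjudication: (concordant + acceptable) / n.

    Discordances with no record, or an ``unreviewed`` verdict, count as not
    acceptable, so partial review can only lower the ceiling.  A record for
    a concordant pair is a validation error (there is nothing to adjudicate).
    """
    pairs = _align(assignments, truths)
    verdict_by_id = {}
    for rec in adjudications:
        if rec.response_id in verdict_by_id:
            raise ValidationError(f"duplicate adjudication for {rec.response_id}")
        verdict_by_id[rec.response_id] = rec
    concordant = 0
    acceptable = 0
    for a, t in pairs:
        is_concordant = (
            a.category_index is not None and a.category_index == t.human_category
        )
        rec = verdict_by_id.get(a.response_id)
        if is_concordant:
            if rec is not None:
                raise ValidationError(
                    f"{a.response_id}: adjudication record for a concordant pair"
                )
            concordant += 1
        elif rec is not None and rec.verdict == "acceptable":
            acceptable += 1
    return (concordant + acceptable) / len(pairs)


def export_discordances(
    assignments: Sequence[CategoryAssignment],
    truths: Sequence[BenchmarkExample],
    path: str | Path | None = None,
) -> list[AdjudicationRecord]:
    """List every human-vs-model discordance as an unreviewed adjudication
    record; optionally write the human-review worksheet (CSV) to ``path``.

    The worksheet columns are (response_id, text, human_category,
    model_category, verdict) and re-import via :func:`load_adjudications`.
    Failed parses are exported with model_category 0 (no valid index).
    """
    pairs = _align(assignments, truths)
    records: list[AdjudicationRecord] = []
    texts: dict[str, str] = {}
    for a, t in pairs:
        model = a.category_index if a.category_index is not None else 0
        if model == t.human_category:
            continue
        records.append(
            AdjudicationRecord(
                response_id=a.response_id,
                human_category=t.human_category,
                model_category=model,
            )
        )
        texts[a.response_id] = t.response.text
    if path is not None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["response_id", "text", "human_category", "model_category", "verdict"]
            )
            for rec in records:
                writer.writerow(
                    [
                        rec.response_id,
                        texts[rec.response_id],
                        rec.human_category,
                        rec.model_category,
                        rec.verdict,
                    ]
                )
    return records


def load_adjudications(path: str | Path) -> list[AdjudicationRecord]:
    """Read a (possibly partially) filled adjudication worksheet back in."""
    records = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            records.append(
                AdjudicationRecord(
                    response_id=rec["response_id"],
                    human_category=int(rec["human_category"]),
                    model_category=int(rec["model_category"]),
                    verdict=rec.get("verdict") or "unreviewed",
                )
            )
    return records


def per_category_accuracy(
    assignments: Sequence[CategoryAssignment],
    truths: Sequence[BenchmarkExample],
    scheme: CategoryScheme,
    min_n: int = 10,
) -> pd.DataFrame:
    """Accuracy by human category, with an ``underpowered`` flag below
    ``min_n`` test examples.

    With dozens of categories on a small test set, most per-category cells
    are too thin for category-level claims; the flag makes that explicit.
    """
    pairs = _align(assignments, truths)
    rows = []
    for cat in scheme:
        sub = [(a, t) for a, t in pairs if t.human_category == cat.index]
        n = len(sub)
        correct = sum(1 for a, t in sub if a.category_index == t.human_category)
        rows.append(
            {
                "category_index": cat.index,
                "label": cat.label,
                "n": n,
                "accuracy": correct / n if n else float("nan"),
                "underpowered": n < min_n,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Power calculation
# ---------------------------------------------------------------------------


def margin_of_error(p: float, n: int, z: float = 1.96) -> float:
    """Half-width of the normal-approximation CI for a proportion:
    z*sqrt(p(1-p)/n)."""
    if not 0 < p < 1:
        raise ConfigurationError(f"p={p} must be in (0, 1)")
    if n < 1:
        raise ConfigurationError(f"n={n} must be >= 1")
    return z * math.sqrt(p * (1 - p) / n)


def required_sample_size(p: float, target_margin: float, z: float = 1.96) -> int:
    """Smallest n with margin_of_error(p, n, z) <= target_margin:
    ceil(z^2 p(1-p) / m^2)."""
    if not 0 < p < 1:
        raise ConfigurationError(f"p={p} must be in (0, 1)")
    if target_margin <= 0:
        raise ConfigurationError("target_margin must be > 0")
    n = math.ceil(z * z * p * (1 - p) / (target_margin * target_margin))
    return max(n, 1)


# ---------------------------------------------------------------------------
# Benchmark file IO
# ---------------------------------------------------------------------------


def write_benchmark(
    examples: Iterable[BenchmarkExample], path: str | Path
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["response_id", "text", "human_category"])
        for e in examples:
            writer.writerow(
                [e.response.response_id, e.response.text, e.human_category]
            )


def load_benchmark(path: str | Path, survey_round: int = 0) -> list[BenchmarkExample]:
    examples = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            examples.append(
                BenchmarkExample(
                    response=SurveyResponse(
                        response_id=rec["response_id"],
                        survey_round=survey_round,
                        text=rec["text"],
                    ),
                    human_category=int(rec["human_category"]),
                )
            )
    return examples
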