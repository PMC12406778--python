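"""Seeded generator of survey-like free-text corpora with known truth.

The generator emulates the structure of the free-text "Other" channel of a
vaccination-coverage household survey: short French noun phrases, a few
dominant repeated strings over a heavy duplicated tail, and a mix of

* **clean** responses instantiating one category's phrase template,
* **vague** responses that arguably fit two or more categories (the
  ``acceptable_set`` records all defensible choices), and
* **compound** responses concatenating two categories' phrases (the first
  mentioned is the coded truth; either is defensible).

Duplication is drawn per unique phrase from a Zipf distribution over repeat
counts with tail parameter ``1 + duplication_exponent``; a smaller exponent
means a heavier tail, more duplication, and a smaller unique-string fraction.

The same templates compile into the keyword rules of the offline
:class:`~survcat.backends.MockRuleBackend` (first matching phrase core wins,
scanning categories in index order), which makes the accuracy of every
strategy on generated data *knowable*: :func:`expected_mock_accuracy` gives
the closed-form expectation that tests calibrate against.  Scoring the mock
backend with acceptable-set-aware adjudication reproduces the mechanism of
the accuracy-vs-ceiling gap: vague and compound misses are discordant but
acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backends import MockRuleBackend
from .core import (
    Category,
    CategoryOrigin,
    CategoryScheme,
    ConfigurationError,
    SurveyResponse,
    Stratum,
    ValidationError,
    deduplicate,
    normalize_text,
)
from .evaluation import AdjudicationRecord, BenchmarkExample, BenchmarkSplit, split_benchmark
from .strategies import CategoryAssignment


# ---------------------------------------------------------------------------
# Default scheme and phrase templates
# ---------------------------------------------------------------------------

_DEFAULT_CATEGORIES = [
    (1, "Travel, move, displacement", "access", "added_category"),
    (2, "Negligence", "caregiver", "added_category"),
    (3, "Health worker strike", "supply", "added_category"),
    (4, "Vaccine schedule in progress", "other", "added_category"),
    (5, "Vaccination site too far", "access", "original_option"),
    (6, "Mother too busy", "caregiver", "original_option"),
    (7, "Fear of side effects", "demand", "original_option"),
    (8, "Child was sick", "caregiver", "original_option"),
    (9, "War, armed conflict, ethnic conflict", "access", "added_category"),
    (10, "Working in the field / agricultural work", "caregiver", "added_category"),
    (11, "Fear of Covid-19", "demand", "added_category"),
    (12, "Vaccine stockout", "supply", "original_option"),
]

# One rule-bearing phrase core per template; cores are mutually
# non-substrings across categories so first-match rules are unambiguous.
DEFAULT_TEMPLATES: dict[int, list[str]] = {
    1: ["voyage", "déplacement de la famille"],
    2: ["négligence de la mère", "paresse"],
    3: ["grève des infirmiers", "grève du personnel"],
    4: ["calendrier vaccinal en cours", "vaccination en cours"],
    5: ["centre de santé trop loin", "distance trop longue"],
    6: ["maman trop occupée", "manque de temps"],
    7: ["peur des effets secondaires", "crainte de la fièvre"],
    8: ["enfant malade", "maladie de l'enfant"],
    9: ["guerre dans la zone", "conflit armé"],
    10: ["travaux champêtres", "parti au champ"],
    11: ["peur du covid", "confinement covid"],
    12: ["rupture de stock de vaccins", "absence de vaccins"],
}

# A vague phrase embeds the cores of every category it arguably fits, so the
# first-match rule deterministically picks the lowest acceptable index.
DEFAULT_VAGUE_TEMPLATES: list[tuple[str, tuple[int, ...]]] = [
    ("parti en voyage, distance trop longue", (1, 5)),
    ("négligence de la mère par manque de temps", (2, 6)),
    ("enfant malade, peur des effets secondaires", (7, 8)),
    ("peur du covid et crainte de la fièvre", (7, 11)),
]

_PREFIXES = [
    "", "c'est à cause de", "parce que", "on dit que", "selon la maman",
    "depuis longtemps", "cette fois", "vraiment", "souvent", "le problème est",
]
_SUFFIXES = [
    "", "du village", "depuis des mois", "cette année", "pour le moment",
    "chez nous", "encore", "malheureusement", "dit-elle", "après la pluie",
]
_PROVINCES = ["Kinshasa", "Nord-Kivu", "Sud-Kivu", "Kasaï", "Équateur", "Tanganyika"]
_ROUNDS = (2021, 2022, 2023)


def default_synthetic_scheme() -> CategoryScheme:
    return CategoryScheme(
        categories=tuple(
            Category(index=i, label=label, domain_tag=tag, origin=CategoryOrigin(origin))
            for i, label, tag, origin in _DEFAULT_CATEGORIES
        ),
        name="synthetic-barriers",
        version="1",
    )


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    scheme: CategoryScheme
    templates: dict[int, list[str]]
    n_responses: int = 2000
    vague_rate: float = 0.10
    compound_rate: float = 0.05
    duplication_exponent: float = 1.2
    seed: int = 0
    vague_templates: list[tuple[str, tuple[int, ...]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_responses < 1:
            raise ConfigurationError("n_responses must be >= 1")
        if self.duplication_exponent <= 0:
            raise ConfigurationError("duplication_exponent must be > 0")
        for rate in (self.vague_rate, self.compound_rate):
            if not 0 <= rate <= 1:
                raise ConfigurationError("rates must lie in [0, 1]")
        if self.vague_rate + self.compound_rate > 1:
            raise ConfigurationError("vague_rate + compound_rate must be <= 1")
        for cat in self.scheme:
            if not self.templates.get(cat.index):
                raise ConfigurationError(
                    f"category {cat.index} ({cat.label!r}) has no phrase template"
                )
        if self.vague_rate > 0 and not self.vague_templates:
            raise ConfigurationError("vague_rate > 0 requires vague_templates")
        for text, acceptable in self.vague_templates:
            if len(acceptable) < 2:
                raise ConfigurationError(
                    f"vague template {text!r} needs an acceptable set of >= 2"
                )
            for idx in acceptable:
                if not self.scheme.in_range(idx):
                    raise ConfigurationError(
                        f"vague template {text!r}: index {idx} outside scheme"
                    )


def default_generator_config(
    n_responses: int = 2000,
    vague_rate: float = 0.10,
    compound_rate: float = 0.05,
    duplication_exponent: float = 1.2,
    seed: int = 0,
) -> GeneratorConfig:
    return GeneratorConfig(
        scheme=default_synthetic_scheme(),
        templates={k: list(v) for k, v in DEFAULT_TEMPLATES.items()},
        n_responses=n_responses,
        vague_rate=vague_rate,
        compound_rate=compound_rate,
        duplication_exponent=duplication_exponent,
        seed=seed,
        vague_templates=list(DEFAULT_VAGUE_TEMPLATES),
    )


@dataclass(frozen=True)
class SyntheticTruth:
    response_id: str
    true_category: int
    acceptable_set: tuple[int, ...]
    kind: str  # clean | vague | compound

    def __post_init__(self) -> None:
        if self.true_category not in self.acceptable_set:
            raise ValidationError("acceptable_set must contain true_category")
        if self.kind not in ("clean", "vague", "compound"):
            raise ValidationError(f"bad kind {self.kind!r}")
        if self.kind in ("vague", "compound") and len(self.acceptable_set) < 2:
            raise ValidationError(f"{self.kind} truth needs >= 2 acceptable categories")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _compose(rng: np.random.Generator, core: str) -> str:
    prefix = _PREFIXES[rng.integers(len(_PREFIXES))]
    suffix = _SUFFIXES[rng.integers(len(_SUFFIXES))]
    return " ".join(p for p in (prefix, core, suffix) if p)


def _new_candidate(
    config: GeneratorConfig, rng: np.random.Generator, seen: set[str]
) -> tuple[str, int, tuple[int, ...], str]:
    """One unique (text, true_category, acceptable_set, kind) phrase."""
    indices = [c.index for c in config.scheme]
    u = rng.random()
    if u < config.vague_rate:
        kind = "vague"
        text_core, acceptable = config.vague_templates[
            rng.integers(len(config.vague_templates))
        ]
        true = int(acceptable[rng.integers(len(acceptable))])
        acceptable = tuple(sorted(acceptable))
        text = _compose(rng, text_core)
    elif u < config.vague_rate + config.compound_rate:
        kind = "compound"
        a, b = rng.choice(indices, size=2, replace=False).tolist()
        core_a = config.templates[a][rng.integers(len(config.templates[a]))]
        core_b = config.templates[b][rng.integers(len(config.templates[b]))]
        true, acceptable = int(a), tuple(sorted((int(a), int(b))))
        text = _compose(rng, f"{core_a} et {core_b}")
    else:
        kind = "clean"
        cat = int(indices[rng.integers(len(indices))])
        core = config.templates[cat][rng.integers(len(config.templates[cat]))]
        true, acceptable = cat, (cat,)
        text = _compose(rng, core)
    counter = 2
    base = text
    while normalize_text(text) in seen:
        text = f"{base} numero {counter}"
        counter += 1
    seen.add(normalize_text(text))
    return text, true, acceptable, kind


def generate(config: GeneratorConfig) -> tuple[list[SurveyResponse], list[SyntheticTruth]]:
    """Generate a corpus of ``n_responses`` with per-response ground truth.

    Unique phrases are drawn one at a time, each repeated Zipf(1 +
    duplication_exponent) times until the corpus is full (the last phrase is
    truncated to fit); the response order is then shuffled.  Truth is a
    function of the text alone, so deduplicating and re-expanding never
    changes it.  Fully reproducible under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    seen: set[str] = set()
    entries: list[tuple[str, int, tuple[int, ...], str]] = []
    total = 0
    while total < config.n_responses:
        text, true, acceptable, kind = _new_candidate(config, rng, seen)
        count = int(rng.zipf(1.0 + config.duplication_exponent))
        count = min(count, config.n_responses - total)
        entries.extend([(text, true, acceptable, kind)] * count)
        total += count
    order = rng.permutation(len(entries))
    responses: list[SurveyResponse] = []
    truths: list[SyntheticTruth] = []
    width = len(str(config.n_responses))
    for i, pos in enumerate(order):
        text, true, acceptable, kind = entries[pos]
        rid = f"r{i:0{width}d}"
        responses.append(
            SurveyResponse(
                response_id=rid,
                survey_round=int(_ROUNDS[rng.integers(len(_ROUNDS))]),
                text=text,
                weight=1.0,
                stratum=Stratum.ZERO_DOSE if rng.random() < 0.7 else Stratum.UNDER_VACCINATED,
                admin_unit=_PROVINCES[rng.integers(len(_PROVINCES))],
            )
        )
        truths.append(
            SyntheticTruth(
                response_id=rid,
                true_category=true,
                acceptable_set=acceptable,
                kind=kind,
            )
        )
    return responses, truths


def truth_by_text(
    responses: list[SurveyResponse],
    truths: list[SyntheticTruth],
    normalization: str = "exact",
) -> dict[str, SyntheticTruth]:
    """Map normalized unique text -> truth (truth is a function of text)."""
    by_id = {t.response_id: t for t in truths}
    out: dict[str, SyntheticTruth] = {}
    for r in responses:
        out.setdefault(normalize_text(r.text, normalization), by_id[r.response_id])
    return out


# ---------------------------------------------------------------------------
# Mock backend compilation
# ---------------------------------------------------------------------------


def compile_mock_rules(templates: dict[int, list[str]]) -> list[tuple[str, int]]:
    """Ordered (phrase core, category) rules: categories in index order."""
    rules: list[tuple[str, int]] = []
    for index in sorted(templates):
        for core in templates[index]:
            rules.append((core, index))
    return rules


def mock_backend_for(
    config: GeneratorConfig, reply_style: str = "bare"
) -> MockRuleBackend:
    """The rule categorizer matched to this generator's templates.

    Fallback is the scheme's last category (fires only on texts carrying no
    template core, which the generator never emits).
    """
    return MockRuleBackend(
        rules=compile_mock_rules(config.templates),
        fallback_index=len(config.scheme),
        reply_style=reply_style,
    )


# ---------------------------------------------------------------------------
# Benchmark construction and truth-aware adjudication
# ---------------------------------------------------------------------------


def generate_benchmark(
    config: GeneratorConfig, n_benchmark: int, n_test: int, seed: int
) -> tuple[BenchmarkSplit, dict[str, SyntheticTruth]]:
    """Draw a benchmark of unique strings with the generator as human coder.

    ``human_category`` is set to the generated true category; returns the
    train/test split plus the text-keyed truth map (which carries the
    acceptable sets an adjudicator would use).
    """
    responses, truths = generate(config)
    table = deduplicate(responses)
    if table.n_unique < n_benchmark:
        raise ConfigurationError(
            f"only {table.n_unique} unique strings available, need {n_benchmark}"
        )
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(table.n_unique, size=n_benchmark, replace=False).tolist())
    by_id = {r.response_id: r for r in responses}
    truth_map = truth_by_text(responses, truths)
    examples = []
    for i in idx:
        text = table.unique_texts[i]
        rep = by_id[table.representative[text]]
        examples.append(
            BenchmarkExample(
                response=rep, human_category=truth_map[text].true_category
            )
        )
    return split_benchmark(examples, n_test=n_test, seed=seed), truth_map


def synthetic_adjudications(
    assignments: list[CategoryAssignment],
    examples: list[BenchmarkExample],
    truth_map: dict[str, SyntheticTruth],
) -> list[AdjudicationRecord]:
    """Adjudicate discordances against the generator's acceptable sets:
    a discordant model category is ``acceptable`` iff it lies in the truth's
    acceptable set (the generator plays the human reviewer)."""
    by_id = {a.response_id: a for a in assignments}
    records = []
    for ex in examples:
        a = by_id[ex.response.response_id]
        model = a.category_index if a.category_index is not None else 0
        if model == ex.human_category:
            continue
        truth = truth_map[normalize_text(ex.response.text)]
        verdict = (
            "acceptable" if model in truth.acceptable_set else "not_acceptable"
        )
        records.append(
            AdjudicationRecord(
                response_id=ex.response.response_id,
                human_category=ex.human_category,
                model_category=model,
                verdict=verdict,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Analytic accuracy of the matched mock backend
# ---------------------------------------------------------------------------


def expected_mock_accuracy(config: GeneratorConfig) -> float:
    """Closed-form expected unique-string accuracy of the matched rule backend.

    Clean phrases always classify correctly (their own core fires).  A vague
    phrase embeds every acceptable category's core, so the first-match rule
    deterministically returns the lowest acceptable index while the coded
    truth is uniform over the set: correct with probability mean(1/|set|).
    A compound phrase (cores of a then b, truth = a) returns min(a, b):
    correct exactly when a < b, probability 1/2 under uniform ordered
    distinct pairs.  Hence

        E[acc] = 1 - vague_rate * (1 - mean(1/|set|)) - compound_rate / 2.
    """
    if config.vague_templates:
        p_vague = float(
            np.mean([1.0 / len(acc) for _, acc in config.vague_templates])
        )
    else:
        p_vague = 1.0
    return 1.0 - config.vague_rate * (1.0 - p_vague) - config.compound_rate * 0.5


def observed_unique_accuracy(
    assignments_by_text: dict[str, CategoryAssignment],
    truth_map: dict[str, SyntheticTruth],
) -> tuple[float, int]:
    """Fraction of unique strings categorized to their true category, with n.

    Computed at the unique-string level because phrase kinds are independent
    across unique phrases (duplication makes raw-response accuracy
    super-binomial)."""
    n = len(assignments_by_text)
    if n == 0:
        raise ConfigurationError("no assignments")
    correct = sum(
        1
        for text, a in assignments_by_text.items()
        if a.category_index == truth_map[normalize_text(text)].true_category
    )
    return correct / n, n
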