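"""Domain types and data plumbing for free-text survey categorization.

The objects here model the "Other: free text" channel of a closed-choice
survey question: each :class:`SurveyResponse` is one caregiver's free-text
answer, and a :class:`CategoryScheme` is the closed, numbered list of reason
categories an assignment must come from (the original questionnaire options
plus researcher-added categories).

Because free-text answers repeat heavily (the same short phrase is typed by
many respondents), categorization is run once per *unique string* and the
result propagated to every duplicate.  :func:`deduplicate` builds the
:class:`DedupTable` that makes this exact, and :func:`expand_assignments`
undoes it.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .strategies import CategoryAssignment


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class SurvcatError(Exception):
    """Base class for all package errors."""


class SchemaError(SurvcatError):
    """A record or file violates the expected schema."""


class ValidationError(SurvcatError):
    """An object violates its invariants."""


class ConfigurationError(SurvcatError):
    """A parameter combination is not usable."""


class AlignmentError(SurvcatError):
    """Two id-aligned inputs do not align."""


class IncompleteAssignmentError(SurvcatError):
    """A unique text is missing its assignment during expansion."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class Stratum(str, Enum):
    ZERO_DOSE = "zero_dose"
    UNDER_VACCINATED = "under_vaccinated"
    UNKNOWN = "unknown"


class CategoryOrigin(str, Enum):
    ORIGINAL_OPTION = "original_option"
    ADDED_CATEGORY = "added_category"


@dataclass(frozen=True)
class SurveyResponse:
    """One free-text survey answer with its survey metadata.

    ``weight`` is a sampling weight carried through to reporting; the
    categorization strategies themselves ignore it.
    """

    response_id: str
    survey_round: int
    text: str
    translated_text: str | None = None
    weight: float = 1.0
    stratum: Stratum = Stratum.UNKNOWN
    admin_unit: str | None = None

    def __post_init__(self) -> None:
        if not self.response_id:
            raise ValidationError("response_id must be non-empty")
        if not self.text or not self.text.strip():
            raise ValidationError(
                f"response {self.response_id!r}: text is empty after trimming"
            )
        if self.weight < 0:
            raise ValidationError(
                f"response {self.response_id!r}: weight must be >= 0, got {self.weight}"
            )


@dataclass(frozen=True)
class Category:
    """One entry of the closed category scheme; indices are 1-based because
    the classification prompt asks for "the number associated with the chosen
    label"."""

    index: int
    label: str
    domain_tag: str | None = None
    origin: CategoryOrigin = CategoryOrigin.ORIGINAL_OPTION

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValidationError(f"category index must be >= 1, got {self.index}")
        if not self.label or not self.label.strip():
            raise ValidationError(f"category {self.index}: label is empty")


@dataclass(frozen=True)
class CategoryScheme:
    """The closed, ordered set of candidate reason categories."""

    categories: tuple[Category, ...]
    name: str = "scheme"
    version: str = "1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", tuple(self.categories))
        if len(self.categories) < 2:
            raise ValidationError("a scheme needs at least 2 categories")
        indices = [c.index for c in self.categories]
        if indices != list(range(1, len(indices) + 1)):
            raise ValidationError(
                f"category indices must be contiguous from 1, got {indices}"
            )
        labels = [c.label for c in self.categories]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate category labels: {dupes}")

    def __len__(self) -> int:
        return len(self.categories)

    def __iter__(self):
        return iter(self.categories)

    def __getitem__(self, index: int) -> Category:
        """Look up a category by its 1-based index."""
        if not 1 <= index <= len(self.categories):
            raise KeyError(index)
        return self.categories[index - 1]

    def in_range(self, index: int) -> bool:
        return 1 <= index <= len(self.categories)


@dataclass
class DedupTable:
    """Unique-string table over a response list.

    ``unique_texts`` is in first-appearance order.  ``response_keys`` keeps
    (response_id, unique_text) for every input response, in input order, so
    per-unique results can be expanded back to the full set losslessly.
    """

    unique_texts: list[str]
    multiplicity: dict[str, int]
    representative: dict[str, str]
    response_keys: list[tuple[str, str]] = field(default_factory=list)
    normalization: str = "exact"

    @property
    def n_unique(self) -> int:
        return len(self.unique_texts)

    @property
    def n_responses(self) -> int:
        return len(self.response_keys)


# ---------------------------------------------------------------------------
# Normalization & deduplication
# ---------------------------------------------------------------------------

NORMALIZATIONS = ("exact", "trim_casefold")


def normalize_text(text: str, normalization: str = "exact") -> str:
    """Normalize a response string for unique-string matching.

    ``exact`` is Unicode NFC plus whitespace trim (a conservative reading of
    "unique strings" that still survives encoding round-trips of French
    diacritics); ``trim_casefold`` additionally case-folds.
    """
    if normalization not in NORMALIZATIONS:
        raise ConfigurationError(
            f"unknown normalization {normalization!r}; expected one of {NORMALIZATIONS}"
        )
    out = unicodedata.normalize("NFC", text).strip()
    if normalization == "trim_casefold":
        out = out.casefold()
    return out


def deduplicate(
    responses: Sequence[SurveyResponse], normalization: str = "exact"
) -> DedupTable:
    """Collapse responses to unique strings with multiplicities.

    Sum of multiplicities always equals ``len(responses)``; unique texts are
    kept in first-appearance order, and the representative of each unique
    string is the first response that carried it.
    """
    if not responses:
        raise ConfigurationError("cannot deduplicate an empty response list")
    unique_texts: list[str] = []
    multiplicity: dict[str, int] = {}
    representative: dict[str, str] = {}
    response_keys: list[tuple[str, str]] = []
    for r in responses:
        key = normalize_text(r.text, normalization)
        if key not in multiplicity:
            unique_texts.append(key)
            multiplicity[key] = 0
            representative[key] = r.response_id
        multiplicity[key] += 1
        response_keys.append((r.response_id, key))
    return DedupTable(
        unique_texts=unique_texts,
        multiplicity=multiplicity,
        representative=representative,
        response_keys=response_keys,
        normalization=normalization,
    )


def expand_assignments(
    table: DedupTable, unique_assignments: dict[str, "CategoryAssignment"]
) -> list["CategoryAssignment"]:
    """Propagate per-unique-string assignments back to every original response.

    Each expanded assignment is a copy of its unique string's assignment with
    the original response_id restored; output is in the dedup input order.
    """
    missing = [t for t in table.unique_texts if t not in unique_assignments]
    if missing:
        raise IncompleteAssignmentError(
            f"{len(missing)} unique texts lack assignments, e.g. {missing[0]!r}"
        )
    out = []
    for response_id, key in table.response_keys:
        out.append(dataclasses.replace(unique_assignments[key], response_id=response_id))
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

RESPONSE_COLUMNS = (
    "response_id",
    "survey_round",
    "text",
    "translated_text",
    "weight",
    "stratum",
    "admin_unit",
)
_REQUIRED_RESPONSE_KEYS = ("response_id", "survey_round", "text")


def _response_from_record(rec: dict, lineno: int) -> SurveyResponse:
    for key in _REQUIRED_RESPONSE_KEYS:
        if key not in rec or rec[key] is None or str(rec[key]).strip() == "":
            if key == "text" and key in rec:
                raise SchemaError(f"record {lineno}: field 'text' is empty")
            raise SchemaError(f"record {lineno}: missing required field {key!r}")
    try:
        survey_round = int(rec["survey_round"])
    except (TypeError, ValueError) as exc:
        raise SchemaError(
            f"record {lineno}: survey_round {rec['survey_round']!r} is not an integer"
        ) from exc
    weight_raw = rec.get("weight")
    weight = 1.0 if weight_raw in (None, "") else float(weight_raw)
    stratum_raw = rec.get("stratum")
    stratum = Stratum(stratum_raw) if stratum_raw not in (None, "") else Stratum.UNKNOWN
    translated = rec.get("translated_text") or None
    admin_unit = rec.get("admin_unit") or None
    try:
        return SurveyResponse(
            response_id=str(rec["response_id"]),
            survey_round=survey_round,
            text=str(rec["text"]),
            translated_text=translated,
            weight=weight,
            stratum=stratum,
            admin_unit=admin_unit,
        )
    except ValidationError as exc:
        raise SchemaError(f"record {lineno}: {exc}") from exc


def load_responses(path: str | Path, format: str = "delimited") -> list[SurveyResponse]:
    """Load survey responses from a delimited (CSV) or JSON-lines file.

    Missing weight defaults to 1; missing stratum defaults to ``unknown``.
    Raises :class:`SchemaError` naming the offending field and record number,
    and :class:`SchemaError` on an empty file.
    """
    path = Path(path)
    responses: list[SurveyResponse] = []
    if format == "delimited":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise SchemaError(f"{path}: empty file")
            for key in _REQUIRED_RESPONSE_KEYS:
                if key not in reader.fieldnames:
                    raise SchemaError(f"{path}: missing required column {key!r}")
            for lineno, rec in enumerate(reader, start=1):
                responses.append(_response_from_record(rec, lineno))
    elif format == "json_lines":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(
                (l for l in fh if l.strip()), start=1
            ):
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"record {lineno}: invalid JSON") from exc
                responses.append(_response_from_record(rec, lineno))
    else:
        raise ConfigurationError(
            f"unknown format {format!r}; expected 'delimited' or 'json_lines'"
        )
    if not responses:
        raise SchemaError(f"{path}: no records found")
    ids = [r.response_id for r in responses]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})[:3]
        raise SchemaError(f"duplicate response_id values, e.g. {dupes}")
    return responses


def write_responses(
    responses: Iterable[SurveyResponse], path: str | Path, format: str = "delimited"
) -> None:
    """Write responses; UTF-8 throughout so French diacritics round-trip."""
    path = Path(path)
    if format == "delimited":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(RESPONSE_COLUMNS)
            for r in responses:
                writer.writerow(
                    [
                        r.response_id,
                        r.survey_round,
                        r.text,
                        r.translated_text or "",
                        repr(r.weight) if r.weight != 1.0 else "1",
                        r.stratum.value,
                        r.admin_unit or "",
                    ]
                )
    elif format == "json_lines":
        with path.open("w", encoding="utf-8") as fh:
            for r in responses:
                fh.write(
                    json.dumps(
                        {
                            "response_id": r.response_id,
                            "survey_round": r.survey_round,
                            "text": r.text,
                            "translated_text": r.translated_text,
                            "weight": r.weight,
                            "stratum": r.stratum.value,
                            "admin_unit": r.admin_unit,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    else:
        raise ConfigurationError(f"unknown format {format!r}")


def load_category_scheme(path: str | Path) -> CategoryScheme:
    """Load a category scheme from CSV (index,label[,domain_tag,origin]) or JSON."""
    path = Path(path)
    rows: list[dict] = []
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        name = payload.get("name", path.stem)
        version = str(payload.get("version", "1"))
        rows = payload["categories"]
    else:
        name, version = path.stem, "1"
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "index" not in reader.fieldnames:
                raise SchemaError(f"{path}: expected columns index,label[,domain_tag,origin]")
            rows = list(reader)
    categories = []
    seen_indices: set[int] = set()
    for lineno, rec in enumerate(rows, start=1):
        try:
            index = int(rec["index"])
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"scheme row {lineno}: bad or missing index") from exc
        if index in seen_indices:
            raise ValidationError(f"duplicate category index {index}")
        seen_indices.add(index)
        origin_raw = rec.get("origin") or CategoryOrigin.ORIGINAL_OPTION.value
        categories.append(
            Category(
                index=index,
                label=str(rec["label"]),
                domain_tag=rec.get("domain_tag") or None,
                origin=CategoryOrigin(origin_raw),
            )
        )
    categories.sort(key=lambda c: c.index)
    return CategoryScheme(categories=tuple(categories), name=name, version=version)


def write_category_scheme(scheme: CategoryScheme, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "label", "domain_tag", "origin"])
        for c in scheme:
            writer.writerow([c.index, c.label, c.domain_tag or "", c.origin.value])


def default_scheme() -> CategoryScheme:
    """The package's best-effort default 43-category reason scheme.

    The original questionnaire options come first (origin ``original_option``),
    the researcher-added categories follow (origin ``added_category``).  Exact
    label strings are configuration, not ground truth: supply your own scheme
    file to match a specific survey instrument.
    """
    from importlib.resources import files

    return load_category_scheme(files("survcat.data").joinpath("default_scheme.csv"))
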