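"""Evaluation: splits, accuracy, adjudicated ceiling, power calculation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from survcat import (
    AdjudicationRecord,
    BenchmarkExample,
    SurveyResponse,
    accuracy,
    accuracy_ceiling,
    export_discordances,
    margin_of_error,
    required_sample_size,
    split_benchmark,
)
from survcat.core import AlignmentError, ConfigurationError, ValidationError
from survcat.evaluation import load_adjudications
from survcat.strategies import CategoryAssignment


def _example(rid, category, text="texte"):
    return BenchmarkExample(
        response=SurveyResponse(response_id=rid, survey_round=2021, text=text),
        human_category=category,
    )


def _assignment(rid, index, status="ok"):
    return CategoryAssignment(
        response_id=rid,
        category_index=index,
        method="m",
        raw_output=str(index),
        parse_status=status,
    )


def _benchmark(model_indices, human_indices):
    truths = [_example(f"r{i}", h) for i, h in enumerate(human_indices)]
    assignments = [
        _assignment(f"r{i}", m) if m is not None else _assignment(f"r{i}", None, "failed")
        for i, m in enumerate(model_indices)
    ]
    return assignments, truths


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def test_split_999_into_799_train_200_test():
    examples = [_example(f"r{i}", (i % 5) + 1) for i in range(999)]
    split = split_benchmark(examples, n_test=200, seed=3)
    assert (len(split.train), len(split.test)) == (799, 200)
    train_ids = {e.response.response_id for e in split.train}
    test_ids = {e.response.response_id for e in split.test}
    assert not train_ids & test_ids
    assert train_ids | test_ids == {f"r{i}" for i in range(999)}


def test_split_deterministic_under_seed():
    examples = [_example(f"r{i}", 1) for i in range(50)]
    s1 = split_benchmark(examples, n_test=10, seed=9)
    s2 = split_benchmark(examples, n_test=10, seed=9)
    assert [e.response.response_id for e in s1.test] == [
        e.response.response_id for e in s2.test
    ]


def test_split_n_test_out_of_range():
    examples = [_example(f"r{i}", 1) for i in range(5)]
    for bad in (0, 5, 9):
        with pytest.raises(ConfigurationError):
            split_benchmark(examples, n_test=bad, seed=0)


# ---------------------------------------------------------------------------
# Accuracy
# ---------------------------------------------------------------------------


def test_accuracy_167_of_200():
    model = [1] * 167 + [2] * 33
    human = [1] * 200
    assignments, truths = _benchmark(model, human)
    assert accuracy(assignments, truths) == pytest.approx(0.835)


def test_accuracy_all_concordant_and_failed_counts_against():
    assignments, truths = _benchmark([1, 1], [1, 1])
    assert accuracy(assignments, truths) == 1.0
    assignments, truths = _benchmark([1, None], [1, 1])
    assert accuracy(assignments, truths) == 0.5


def test_accuracy_matches_brute_force_count():
    """Direct enumeration oracle on random assignment vectors."""
    rng = np.random.default_rng(17)
    for _ in range(5):
        model = rng.integers(1, 6, size=40).tolist()
        human = rng.integers(1, 6, size=40).tolist()
        assignments, truths = _benchmark(model, human)
        expected = sum(1 for m, h in zip(model, human) if m == h) / 40
        assert accuracy(assignments, truths) == pytest.approx(expected)


def test_accuracy_permutation_invariant():
    rng = np.random.default_rng(4)
    model = rng.integers(1, 4, size=30).tolist()
    human = rng.integers(1, 4, size=30).tolist()
    assignments, truths = _benchmark(model, human)
    base = accuracy(assignments, truths)
    order = rng.permutation(30)
    assert accuracy([assignments[i] for i in order], truths) == pytest.approx(base)


def test_accuracy_alignment_error():
    assignments, truths = _benchmark([1], [1])
    with pytest.raises(AlignmentError):
        accuracy(assignments, [_example("zz", 1)])


# ---------------------------------------------------------------------------
# Accuracy ceiling
# ---------------------------------------------------------------------------


def test_ceiling_with_25_acceptable_of_33_discordant():
    """167 concordant + 25 adjudicated acceptable of 200 gives 0.96."""
    model = [1] * 167 + [2] * 33
    human = [1] * 200
    assignments, truths = _benchmark(model, human)
    records = [
        AdjudicationRecord(
            response_id=f"r{i}",
            human_category=1,
            model_category=2,
            verdict="acceptable" if i < 167 + 25 else "not_acceptable",
        )
        for i in range(167, 200)
    ]
    assert accuracy_ceiling(assignments, truths, records) == pytest.approx(0.96)


def test_ceiling_bounds():
    model = [1, 2, 3]
    human = [1, 1, 1]
    assignments, truths = _benchmark(model, human)
    none_ok = [
        AdjudicationRecord(f"r{i}", 1, m, "not_acceptable")
        for i, m in [(1, 2), (2, 3)]
    ]
    all_ok = [
        AdjudicationRecord(f"r{i}", 1, m, "acceptable") for i, m in [(1, 2), (2, 3)]
    ]
    assert accuracy_ceiling(assignments, truths, none_ok) == accuracy(assignments, truths)
    assert accuracy_ceiling(assignments, truths, all_ok) == 1.0


def test_ceiling_unreviewed_counts_as_not_acceptable():
    assignments, truths = _benchmark([2], [1])
    records = [AdjudicationRecord("r0", 1, 2, "unreviewed")]
    assert accuracy_ceiling(assignments, truths, records) == 0.0


def test_adjudication_of_concordant_pair_rejected():
    assignments, truths = _benchmark([1, 2], [1, 1])
    with pytest.raises(ValidationError, match="concordant"):
        accuracy_ceiling(
            assignments, truths, [AdjudicationRecord("r0", 1, 2, "acceptable")]
        )
    with pytest.raises(ValidationError):
        AdjudicationRecord("x", 3, 3, "acceptable")


@settings(derandomize=True, max_examples=60)
@given(
    model=st.lists(st.integers(1, 4), min_size=5, max_size=30),
    verdict_bits=st.lists(st.booleans(), min_size=30, max_size=30),
    human_seed=st.integers(0, 10_000),
)
def test_ceiling_dominates_accuracy(model, verdict_bits, human_seed):
    """accuracy_ceiling >= accuracy for every adjudication configuration,
    strictly greater when at least one verdict is acceptable."""
    rng = np.random.default_rng(human_seed)
    human = rng.integers(1, 5, size=len(model)).tolist()
    assignments, truths = _benchmark(model, human)
    records = []
    any_acceptable = False
    for i, (m, h) in enumerate(zip(model, human)):
        if m != h:
            ok = verdict_bits[i % len(verdict_bits)]
            any_acceptable = any_acceptable or ok
            records.append(
                AdjudicationRecord(
                    f"r{i}", h, m, "acceptable" if ok else "not_acceptable"
                )
            )
    acc = accuracy(assignments, truths)
    ceiling = accuracy_ceiling(assignments, truths, records)
    assert ceiling >= acc
    if any_acceptable:
        assert ceiling > acc


# ---------------------------------------------------------------------------
# Discordance export
# ---------------------------------------------------------------------------


def test_export_discordances_counts(tmp_path):
    model = [1] * 167 + [2] * 33
    human = [1] * 200
    assignments, truths = _benchmark(model, human)
    path = tmp_path / "worksheet.csv"
    records = export_discordances(assignments, truths, path=path)
    assert len(records) == 33
    assert all(r.verdict == "unreviewed" for r in records)
    assert load_adjudications(path) == records


def test_export_discordances_empty_when_all_concordant(tmp_path):
    assignments, truths = _benchmark([1, 2], [1, 2])
    path = tmp_path / "worksheet.csv"
    assert export_discordances(assignments, truths, path=path) == []
    assert load_adjudications(path) == []


# ---------------------------------------------------------------------------
# Power calculation
# ---------------------------------------------------------------------------


def test_margin_of_error_reference_values():
    assert margin_of_error(0.85, 200, 1.96) == pytest.approx(0.0495, abs=5e-5)
    assert margin_of_error(0.5, 100, 1.96) == pytest.approx(0.098)


def test_margin_quadruple_n_halves_margin():
    assert margin_of_error(0.3, 400) == pytest.approx(margin_of_error(0.3, 100) / 2)


def test_margin_monotone_in_n_and_maximized_at_half():
    margins = [margin_of_error(0.85, n) for n in (50, 100, 200, 400)]
    assert margins == sorted(margins, reverse=True)
    assert margin_of_error(0.5, 200) > margin_of_error(0.3, 200)
    assert margin_of_error(0.5, 200) > margin_of_error(0.9, 200)


def test_margin_domain_errors():
    for bad_p in (0, 1, -0.2, 1.5):
        with pytest.raises(ConfigurationError):
            margin_of_error(bad_p, 100)
    with pytest.raises(ConfigurationError):
        margin_of_error(0.5, 0)


def test_required_sample_size_closed_form_and_brute_force():
    assert required_sample_size(0.85, 0.05, 1.96) == 196
    assert required_sample_size(0.5, 0.5, 1.96) == 4
    # brute-force confirmation: smallest n whose margin is within target
    for p, m in [(0.85, 0.05), (0.5, 0.5), (0.7, 0.03)]:
        n = required_sample_size(p, m)
        assert margin_of_error(p, n) <= m
        if n > 1:
            assert margin_of_error(p, n - 1) > m


@settings(derandomize=True, max_examples=40)
@given(
    p=st.floats(0.05, 0.95),
    m=st.floats(0.01, 0.5),
)
def test_required_sample_size_defining_property(p, m):
    n = required_sample_size(p, m)
    assert margin_of_error(p, n) <= m + 1e-12


def test_required_sample_size_domain_errors():
    with pytest.raises(ConfigurationError):
        required_sample_size(0.5, 0)
    with pytest.raises(ConfigurationError):
        required_sample_size(1.2, 0.05)
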