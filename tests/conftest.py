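import pytest

from survcat import (
    Category,
    CategoryOrigin,
    CategoryScheme,
    SurveyResponse,
    default_generator_config,
    generate,
    mock_backend_for,
)


@pytest.fixture(scope="session")
def small_scheme() -> CategoryScheme:
    return CategoryScheme(
        categories=(
            Category(index=1, label="Travel"),
            Category(index=2, label="Strike"),
            Category(index=3, label="Distance", origin=CategoryOrigin.ADDED_CATEGORY),
        ),
        name="mini",
    )


@pytest.fixture(scope="session")
def clean_config():
    """Clean study conditions: no vague or compound responses."""
    return default_generator_config(
        n_responses=600, vague_rate=0.0, compound_rate=0.0, seed=11
    )


@pytest.fixture(scope="session")
def clean_corpus(clean_config):
    return generate(clean_config)


@pytest.fixture(scope="session")
def mock_backend(clean_config):
    return mock_backend_for(clean_config)


@pytest.fixture
def responses3() -> list[SurveyResponse]:
    return [
        SurveyResponse(response_id="a", survey_round=2021, text="Voyage"),
        SurveyResponse(response_id="b", survey_round=2022, text="Voyage"),
        SurveyResponse(response_id="c", survey_round=2022, text="Négligence"),
    ]
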