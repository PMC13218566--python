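from pathlib import Path

import pytest

from themecast import ArticleRecord, SyntheticSpec, gen_corpus

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture
def toy_records() -> list[ArticleRecord]:
    """Three hand-written articles with two clean topics."""
    return [
        ArticleRecord(id="a1", title="Dementia care at home",
                      abstract="Dementia care. Dementia support for older adults.",
                      author_keywords=["dementia", "care"],
                      keywords_plus=["DEMENTIA", "OLDER ADULTS"],
                      year=2021, citations=10, countries=["USA"],
                      institutions=["Uni A"], document_type="Article",
                      authors=["Smith, J"]),
        ArticleRecord(id="a2", title="Telehealth for dementia",
                      abstract="Telehealth and dementia care delivery.",
                      author_keywords=["dementia", "telehealth"],
                      keywords_plus=["DEMENTIA", "TELEHEALTH"],
                      year=2022, citations=5, countries=["Canada"],
                      institutions=["Uni B"], document_type="Article",
                      authors=["Lee, K"]),
        ArticleRecord(id="a3", title="Robotics in elder care",
                      abstract="Robotics platforms for elder care facilities.",
                      author_keywords=["robotics", "elder care"],
                      keywords_plus=["ROBOTICS", "CARE"],
                      year=2022, citations=0, countries=["USA"],
                      institutions=["Uni A"], document_type="Review",
                      authors=["Smith, J"]),
    ]


@pytest.fixture(scope="session")
def clean_corpus():
    """Zero-noise synthetic corpus with its planted themes."""
    spec = SyntheticSpec(seed=11, noise=0.0, n_articles=120, n_themes=4)
    records, planted = gen_corpus(spec)
    return spec, records, planted
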