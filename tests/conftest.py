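import pytest
from hypothesis import HealthCheck, settings

from reportriage.corpus_io import ReportRecord
from reportriage.lexicon import default_keyword_lexicon, default_stop_phrase_lexicon

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def keywords():
    return default_keyword_lexicon()


@pytest.fixture(scope="session")
def stop_phrases():
    return default_stop_phrase_lexicon()


def make_record(body="", conclusion="normal study", study_id="S1", age=40, **kwargs):
    defaults = dict(sex="female", study_date="2020-06-01", facility="Clinic A")
    defaults.update(kwargs)
    return ReportRecord(study_id=study_id, age=age, body=body, conclusion=conclusion, **defaults)


@pytest.fixture
def record_factory():
    return make_record
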