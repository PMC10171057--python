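"""Template-based generator of pseudo-report corpora with gold labels.

The generator emulates the statistical structure a hemorrhage-triage
pipeline assumes, so every stage can be exercised without any clinical
data.  Each record draws a scenario:

* ``plain_positive`` — an affirmative hemorrhage finding with >= 1 keyword;
* ``conflict_positive`` — a true hemorrhage whose report *also* contains a
  negation stop-phrase (the rule-based labeler's false-negative mode);
* ``negated_negative`` — no hemorrhage, report carries a stop-phrase
  verbatim from the lexicon;
* ``distractor_negative`` — no intracranial hemorrhage, but an extracranial
  one (scalp, facial soft tissues) described with a keyword; when such a
  record carries no stop-phrase it is the labeler's false-positive mode;
* ``keyword_free_negative`` — unremarkable report without any keyword;
* ``invalid`` — violates exactly one record-level exclusion criterion
  (blank text, underage, missing or abnormal age, complete duplicate).

Scenario draws are independent Bernoulli draws per record with the
configured rates; generation is a pure function of the seed.  Valid
records get ages uniform on [18, 99].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import ReportRecord, write_corpus
from .errors import ConfigError, DataError
from .evaluation import ConfusionMatrix, confusion
from .lexicon import default_stop_phrase_lexicon

SCENARIOS = (
    "plain_positive",
    "conflict_positive",
    "negated_negative",
    "distractor_negative",
    "keyword_free_negative",
    "invalid",
)

_INVALID_REASONS = ("empty_text", "underage", "missing_age", "abnormal_age", "duplicate")

_TEMPLATE_KEYS = (
    "facilities",
    "boilerplate",
    "neutral_findings",
    "positive_findings",
    "positive_conclusions",
    "distractor_findings",
    "distractor_conclusions",
    "negative_conclusions",
)


def load_template_bank(name_or_path: str = "en") -> dict:
    """Load a named packaged template bank or a JSON file path."""
    path = Path(name_or_path)
    if path.suffix == ".json" and path.exists():
        bank = json.loads(path.read_text(encoding="utf-8"))
    else:
        ref = resources.files("reportriage.data").joinpath(f"templates_{name_or_path}.json")
        try:
            bank = json.loads(ref.read_text(encoding="utf-8"))
        except FileNotFoundError:
            raise ConfigError(f"unknown template bank {name_or_path!r}")
    missing = [k for k in _TEMPLATE_KEYS if not bank.get(k)]
    if missing:
        raise DataError(f"template bank is missing or empty for: {', '.join(missing)}")
    return bank


@dataclass(frozen=True)
class GeneratorConfig:
    """Rates and sizes of the generated corpus.

    ``prevalence`` is the fraction of valid records with true hemorrhage;
    ``negation_rate`` the fraction of true negatives carrying a
    stop-phrase; ``distractor_rate`` the fraction of true negatives also
    describing an extracranial hemorrhage; ``conflict_rate`` the fraction
    of true positives whose report also contains a stop-phrase;
    ``invalid_record_rate`` the fraction of records violating an
    exclusion criterion.
    """

    n_records: int = 4000
    prevalence: float = 0.25
    negation_rate: float = 0.6
    distractor_rate: float = 0.05
    conflict_rate: float = 0.05
    invalid_record_rate: float = 0.05
    seed: int = 0
    template_bank: str = "en"

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        for name in (
            "prevalence",
            "negation_rate",
            "distractor_rate",
            "conflict_rate",
            "invalid_record_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class GoldRecord:
    record: ReportRecord
    true_class: str  # ICH | no_ICH
    scenario: str  # one of SCENARIOS
    expected_exclusion: str | None = None  # set only for invalid records


def _pick(rng: np.random.Generator, items: Sequence[str]) -> str:
    return items[int(rng.integers(len(items)))]


def _sentence(phrase: str) -> str:
    text = phrase.strip().rstrip(".")
    return text[:1].upper() + text[1:] + "."


def _metadata(rng: np.random.Generator, bank: dict, idx: int):
    age = int(rng.integers(18, 100))
    sex = "female" if rng.random() < 0.5 else "male"
    day = int(rng.integers(0, 366))
    date = (pd.Timestamp("2020-01-01") + pd.Timedelta(days=day)).strftime("%Y-%m-%d")
    facility = _pick(rng, bank["facilities"])
    return f"CT-2020-{idx:06d}", age, sex, date, facility


def _body(rng: np.random.Generator, bank: dict, findings: Sequence[str]) -> str:
    parts = [_pick(rng, bank["boilerplate"])]
    if rng.random() < 0.5:
        parts.append(_pick(rng, bank["neutral_findings"]))
    parts.extend(findings)
    return " ".join(parts)


def generate(config: GeneratorConfig) -> list[GoldRecord]:
    """Generate a gold-labeled pseudo-report corpus (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    bank = load_template_bank(config.template_bank)
    stop_raw = default_stop_phrase_lexicon().raw

    out: list[GoldRecord] = []
    valid_so_far: list[GoldRecord] = []
    for idx in range(config.n_records):
        study_id, age, sex, date, facility = _metadata(rng, bank, idx)
        if rng.random() < config.invalid_record_rate:
            gold = _invalid_record(
                rng, bank, stop_raw, study_id, age, sex, date, facility, valid_so_far
            )
            out.append(gold)
            continue
        if rng.random() < config.prevalence:
            scenario = (
                "conflict_positive"
                if rng.random() < config.conflict_rate
                else "plain_positive"
            )
            findings = []
            if scenario == "conflict_positive":
                findings.append(_sentence(_pick(rng, stop_raw)))
            findings.append(_pick(rng, bank["positive_findings"]))
            body = _body(rng, bank, findings)
            conclusion = _pick(rng, bank["positive_conclusions"])
            true_class = "ICH"
        else:
            true_class = "no_ICH"
            if rng.random() < config.distractor_rate:
                scenario = "distractor_negative"
                findings = [_pick(rng, bank["distractor_findings"])]
                if rng.random() < config.negation_rate:
                    findings.insert(0, _sentence(_pick(rng, stop_raw)))
                    conclusion = _pick(rng, bank["negative_conclusions"])
                else:
                    conclusion = _pick(rng, bank["distractor_conclusions"])
                body = _body(rng, bank, findings)
            elif rng.random() < config.negation_rate:
                scenario = "negated_negative"
                body = _body(rng, bank, [_sentence(_pick(rng, stop_raw))])
                conclusion = _pick(rng, bank["negative_conclusions"])
            else:
                scenario = "keyword_free_negative"
                body = _body(rng, bank, [_pick(rng, bank["neutral_findings"])])
                conclusion = _pick(rng, bank["negative_conclusions"])
        record = ReportRecord(study_id, age, sex, date, facility, body, conclusion)
        gold = GoldRecord(record, true_class, scenario)
        out.append(gold)
        valid_so_far.append(gold)
    return out


def _invalid_record(
    rng, bank, stop_raw, study_id, age, sex, date, facility, valid_so_far
) -> GoldRecord:
    reasons = list(_INVALID_REASONS)
    if not valid_so_far:
        reasons.remove("duplicate")
    reason = _pick(rng, reasons)
    if reason == "duplicate":
        source = valid_so_far[int(rng.integers(len(valid_so_far)))]
        return GoldRecord(source.record, source.true_class, "invalid", "duplicate")
    body = _body(rng, bank, [_pick(rng, bank["neutral_findings"])])
    conclusion = _pick(rng, bank["negative_conclusions"])
    if reason == "empty_text":
        if rng.random() < 0.5:
            body = ""
        else:
            conclusion = "   "
    elif reason == "underage":
        age = int(rng.integers(1, 18))
    elif reason == "missing_age":
        age = None
    elif reason == "abnormal_age":
        age = int(_pick(rng, ["976", "1000"]))
    return GoldRecord(
        ReportRecord(study_id, age, sex, date, facility, body, conclusion),
        "no_ICH",
        "invalid",
        reason,
    )


def gold_confusion(gold: Sequence[GoldRecord], predicted: Sequence[int]) -> ConfusionMatrix:
    """Confusion matrix of predictions against true classes.

    Invalid records must have been excluded before prediction; passing
    them here raises.
    """
    if any(g.scenario == "invalid" for g in gold):
        raise DataError("invalid records must be excluded before scoring")
    truth = [1 if g.true_class == "ICH" else 0 for g in gold]
    return confusion(truth, predicted)


def write_gold(gold: Sequence[GoldRecord], path) -> None:
    """Write the gold table (study_id, true_class, scenario, expected_exclusion)."""
    pd.DataFrame(
        {
            "study_id": [g.record.study_id for g in gold],
            "true_class": [g.true_class for g in gold],
            "scenario": [g.scenario for g in gold],
            "expected_exclusion": [g.expected_exclusion or "" for g in gold],
        }
    ).to_csv(path, index=False)


def read_gold(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def write_gold_corpus(gold: Sequence[GoldRecord], corpus_path, gold_path, dialect="csv") -> None:
    write_corpus([g.record for g in gold], corpus_path, dialect=dialect)
    write_gold(gold, gold_path)
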