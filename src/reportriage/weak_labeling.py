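"""Rule-based weak labels from keyword and stop-phrase evidence.

The weak-supervision rule table:

* no keyword hit anywhere                  -> ``NO_KEYWORD`` (not a candidate)
* keyword hit(s), no stop-phrase           -> ``ICH_POSITIVE``
* keyword hit(s) and any stop-phrase       -> ``ICH_NEGATIVE``

A stop-phrase always dominates (it is the negative marker), but when a
keyword hit lies *outside* every stop-phrase span the record is flagged
as a **conflict**: the text simultaneously negates hemorrhage in one
sentence and affirms a hemorrhage-related finding elsewhere.  Conflicts
are the rule's intrinsic false-negative mechanism and the prime target
for expert review, which is why labels carry full match provenance and
an override table can replace them with expert-adjudicated classes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus_io import ReportRecord
from .errors import DataError
from .lexicon import (
    KeywordHit,
    KeywordLexicon,
    MatchAnnotation,
    StopPhraseLexicon,
    annotate,
    find_keywords,
)


class Label(str, Enum):
    ICH_POSITIVE = "ICH_POSITIVE"
    ICH_NEGATIVE = "ICH_NEGATIVE"
    NO_KEYWORD = "NO_KEYWORD"


_LABEL_ALIASES = {
    "ich_positive": Label.ICH_POSITIVE,
    "positive": Label.ICH_POSITIVE,
    "ich": Label.ICH_POSITIVE,
    "ich_negative": Label.ICH_NEGATIVE,
    "negative": Label.ICH_NEGATIVE,
    "no_ich": Label.ICH_NEGATIVE,
}


def parse_class(value: str) -> Label:
    """Parse an override class name (accepts a few common aliases)."""
    try:
        return _LABEL_ALIASES[value.strip().lower()]
    except KeyError:
        raise DataError(f"unknown class {value!r}; expected ICH_POSITIVE or ICH_NEGATIVE")


@dataclass(frozen=True)
class WeakLabel:
    label: Label
    conflict: bool
    provenance: MatchAnnotation
    source: str = "rule"  # rule | expert


def _covered(hit: KeywordHit, stop_hits) -> bool:
    return any(
        s.field == hit.field and s.start <= hit.start and hit.end <= s.end
        for s in stop_hits
    )


def assign_weak_label(
    record: ReportRecord,
    keywords: KeywordLexicon,
    stop_phrases: StopPhraseLexicon,
) -> WeakLabel:
    """Apply the rule table to one record."""
    ann = annotate(record, keywords, stop_phrases)
    if not ann.keyword_hits:
        return WeakLabel(Label.NO_KEYWORD, False, ann)
    if not ann.stop_phrase_hits:
        return WeakLabel(Label.ICH_POSITIVE, False, ann)
    conflict = any(not _covered(h, ann.stop_phrase_hits) for h in ann.keyword_hits)
    return WeakLabel(Label.ICH_NEGATIVE, conflict, ann)


def select_candidates(
    records: Sequence[ReportRecord], keywords: KeywordLexicon
) -> list[ReportRecord]:
    """Records with at least one keyword hit in body or conclusion."""
    return [r for r in records if find_keywords(r, keywords).keyword_hits]


@dataclass
class LabeledCorpus:
    """Records paired index-by-index with their weak labels."""

    records: list[ReportRecord]
    labels: list[WeakLabel]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise DataError("records and labels must have equal length")

    def __len__(self) -> int:
        return len(self.records)

    def class_counts(self) -> dict[str, int]:
        counts = Counter(wl.label.value for wl in self.labels)
        return {label.value: counts.get(label.value, 0) for label in Label}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "study_id": [r.study_id for r in self.records],
                "label": [wl.label.value for wl in self.labels],
                "conflict": [wl.conflict for wl in self.labels],
                "n_keyword_hits": [len(wl.provenance.keyword_hits) for wl in self.labels],
                "n_stop_phrase_hits": [
                    len(wl.provenance.stop_phrase_hits) for wl in self.labels
                ],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def label_corpus(
    records: Sequence[ReportRecord],
    keywords: KeywordLexicon,
    stop_phrases: StopPhraseLexicon,
) -> LabeledCorpus:
    labels = [assign_weak_label(r, keywords, stop_phrases) for r in records]
    return LabeledCorpus(list(records), labels)


def apply_overrides(
    labeled: LabeledCorpus, overrides: Mapping[str, Label | str]
) -> LabeledCorpus:
    """Replace weak labels with expert-adjudicated classes by study id."""
    index: dict[str, list[int]] = {}
    for i, r in enumerate(labeled.records):
        index.setdefault(r.study_id, []).append(i)
    unknown = sorted(set(overrides) - set(index))
    if unknown:
        raise DataError(f"override study_ids not in corpus: {', '.join(unknown)}")
    labels = list(labeled.labels)
    for study_id, cls in overrides.items():
        label = cls if isinstance(cls, Label) else parse_class(cls)
        for i in index[study_id]:
            labels[i] = replace(labels[i], label=label, conflict=False, source="expert")
    return LabeledCorpus(list(labeled.records), labels)


def read_overrides(path) -> dict[str, Label]:
    """Read a ``study_id,class`` override table."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if tuple(df.columns) != ("study_id", "class"):
        raise DataError(
            f"override table must have columns (study_id, class), got {tuple(df.columns)}"
        )
    return {sid: parse_class(cls) for sid, cls in zip(df["study_id"], df["class"])}


def keyword_frequencies(
    records: Iterable[ReportRecord], keywords: KeywordLexicon
) -> dict[str, int]:
    """Per lexicon entry, the number of records with at least one hit.

    A record counts once per entry however many times the entry fires in
    it, and may count toward several entries.
    """
    counts = {entry.stem: 0 for entry in keywords.entries}
    for record in records:
        hit_stems = {h.stem for h in find_keywords(record, keywords).keyword_hits}
        for stem in hit_stems:
            counts[stem] += 1
    return counts
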