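"""Keyword and negation stop-phrase lexicons and their text matchers.

Two lexicons drive the weak-supervision rules:

* a **keyword lexicon** of hemorrhage-related word stems (``hemorrhage``,
  ``hematoma``, ``subdural`` ...) and abbreviations (``SAH``, ``SDH``,
  ``EDH``, ``ICH``).  Word stems match as prefixes of normalized tokens,
  which captures plural and inflected variants without a lemmatizer;
  abbreviations match only as whole tokens, so ``sah`` never fires inside
  ``sahara``.
* a **stop-phrase lexicon** of formulaic negation sentences ("signs of
  intracranial hemorrhage are not found") whose presence in a report
  implies absence of the pathology.  A phrase matches when its normalized
  token sequence occurs contiguously in the normalized field text.

Matching is "mechanical": it considers only the presence of a stem or
phrase, never the surrounding words.  Both matchers run over a shared
normalization (case folding, punctuation and whitespace collapsing) that
keeps an offset map, so every hit is reported as a span into the
*original* field text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .errors import LexiconError

KEYWORD_KINDS = ("word_stem", "abbreviation")

#: Tokens that mark a phrase as a negation even without a lexicon keyword.
NEGATION_TOKENS = frozenset({"no", "not", "without", "absence", "absent"})

#: The two report text fields that are searched.
FIELDS = ("body", "conclusion")

_TOKEN_RE = re.compile(r"[^ ]+")


# ---------------------------------------------------------------------------
# normalization

@dataclass(frozen=True)
class NormalizedText:
    """Normalized text plus a per-character map back to the original string.

    ``offsets[i]`` is the index in the original string of the character
    that produced ``text[i]``.
    """

    text: str
    offsets: tuple[int, ...]

    def to_original(self, start: int, end: int) -> tuple[int, int]:
        """Map a half-open normalized span to a half-open original span."""
        if not (0 <= start < end <= len(self.text)):
            raise ValueError(f"span [{start}, {end}) out of range")
        return self.offsets[start], self.offsets[end - 1] + 1


def normalize(text: str) -> NormalizedText:
    """Case-fold, map punctuation to spaces and collapse whitespace.

    Hyphens between two alphanumeric characters survive (intra-token
    hyphens); every other non-alphanumeric character becomes a space and
    space runs collapse to one.  The result is idempotent and carries the
    offset map needed to recover original spans.
    """
    produced: list[tuple[str, int]] = []
    for i, ch in enumerate(text):
        for c in ch.lower():
            produced.append((c, i))
    mapped: list[tuple[str, int]] = []
    for j, (c, i) in enumerate(produced):
        if c.isalnum():
            mapped.append((c, i))
        elif (
            c == "-"
            and 0 < j < len(produced) - 1
            and produced[j - 1][0].isalnum()
            and produced[j + 1][0].isalnum()
        ):
            mapped.append((c, i))
        else:
            mapped.append((" ", i))
    out: list[str] = []
    offs: list[int] = []
    for c, i in mapped:
        if c == " ":
            if out and out[-1] != " ":
                out.append(" ")
                offs.append(i)
        else:
            out.append(c)
            offs.append(i)
    while out and out[-1] == " ":
        out.pop()
        offs.pop()
    return NormalizedText("".join(out), tuple(offs))


def tokens(text: str) -> list[str]:
    """Normalized tokens of a raw text."""
    norm = normalize(text)
    return norm.text.split(" ") if norm.text else []


# ---------------------------------------------------------------------------
# lexicon types and loaders

@dataclass(frozen=True)
class KeywordEntry:
    stem: str  # normalized, single token
    kind: str  # word_stem | abbreviation


@dataclass(frozen=True)
class KeywordLexicon:
    entries: tuple[KeywordEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def stems(self) -> tuple[str, ...]:
        return tuple(e.stem for e in self.entries)


@dataclass(frozen=True)
class StopPhraseLexicon:
    phrases: tuple[str, ...]  # normalized token sequences joined by single spaces
    raw: tuple[str, ...]  # the phrases as written in the source file

    def __len__(self) -> int:
        return len(self.phrases)


def _content_lines(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        lines = [line.rstrip("\r\n") for line in fh]
    return [line for line in lines if line.strip() and not line.lstrip().startswith("#")]


def load_keyword_lexicon(path) -> KeywordLexicon:
    """Load a ``stem<TAB>kind`` keyword lexicon file.

    Rejects empty files, unknown kinds, multi-token stems and duplicate
    stems after normalization.
    """
    entries: list[KeywordEntry] = []
    seen: set[str] = set()
    for line in _content_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise LexiconError(f"malformed keyword line {line!r}: expected stem<TAB>kind")
        stem_raw, kind = parts[0].strip(), parts[1].strip()
        if kind not in KEYWORD_KINDS:
            raise LexiconError(f"unknown keyword kind {kind!r} in line {line!r}")
        stem = normalize(stem_raw).text
        if not stem or " " in stem:
            raise LexiconError(f"keyword stem must be one non-empty token, got {stem_raw!r}")
        if stem in seen:
            raise LexiconError(f"duplicate keyword stem {stem!r}")
        seen.add(stem)
        entries.append(KeywordEntry(stem, kind))
    if not entries:
        raise LexiconError(f"keyword lexicon {path} contains no entries")
    return KeywordLexicon(tuple(entries))


def _is_negation_like(phrase_tokens: list[str], keywords: KeywordLexicon | None) -> bool:
    if NEGATION_TOKENS.intersection(phrase_tokens):
        return True
    if keywords is not None:
        for tok in phrase_tokens:
            for entry in keywords.entries:
                if _token_matches(tok, entry):
                    return True
    return False


def load_stop_phrase_lexicon(path, keywords: KeywordLexicon | None = None) -> StopPhraseLexicon:
    """Load a one-phrase-per-line stop-phrase lexicon file.

    Every phrase must be multi-word, unique after normalization, and
    carry at least one negation token or keyword-bearing token (checked
    against ``keywords``, defaulting to the packaged keyword lexicon).
    """
    if keywords is None:
        keywords = default_keyword_lexicon()
    phrases: list[str] = []
    raws: list[str] = []
    seen: set[str] = set()
    for line in _content_lines(path):
        norm = normalize(line).text
        if not norm:
            continue
        toks = norm.split(" ")
        if len(toks) < 2:
            raise LexiconError(f"stop-phrase must be multi-word, got {line!r}")
        if norm in seen:
            raise LexiconError(f"duplicate stop-phrase after normalization: {line!r}")
        if not _is_negation_like(toks, keywords):
            raise LexiconError(
                f"stop-phrase {line!r} contains neither a negation token nor a keyword"
            )
        seen.add(norm)
        phrases.append(norm)
        raws.append(line.strip())
    if not phrases:
        raise LexiconError(f"stop-phrase lexicon {path} contains no entries")
    return StopPhraseLexicon(tuple(phrases), tuple(raws))


def _data_path(name: str):
    return resources.files("reportriage.data").joinpath(name)


@lru_cache(maxsize=1)
def default_keyword_lexicon() -> KeywordLexicon:
    """The packaged 14-entry hemorrhage keyword lexicon."""
    with resources.as_file(_data_path("ich_keywords.tsv")) as p:
        return load_keyword_lexicon(p)


@lru_cache(maxsize=1)
def default_stop_phrase_lexicon() -> StopPhraseLexicon:
    """The packaged 33-entry negation stop-phrase lexicon."""
    with resources.as_file(_data_path("ich_stop_phrases.txt")) as p:
        return load_stop_phrase_lexicon(p, default_keyword_lexicon())


# ---------------------------------------------------------------------------
# matching

@dataclass(frozen=True)
class KeywordHit:
    stem: str
    kind: str
    field: str  # body | conclusion
    start: int  # half-open span into the ORIGINAL field text
    end: int


@dataclass(frozen=True)
class StopPhraseHit:
    phrase: str  # normalized phrase
    field: str
    start: int
    end: int


@dataclass(frozen=True)
class MatchAnnotation:
    keyword_hits: tuple[KeywordHit, ...]
    stop_phrase_hits: tuple[StopPhraseHit, ...]

    def merge(self, other: "MatchAnnotation") -> "MatchAnnotation":
        return MatchAnnotation(
            self.keyword_hits + other.keyword_hits,
            self.stop_phrase_hits + other.stop_phrase_hits,
        )


def _token_matches(token: str, entry: KeywordEntry) -> bool:
    if entry.kind == "abbreviation":
        return token == entry.stem
    return token.startswith(entry.stem)


def _field_texts(record) -> list[tuple[str, str]]:
    return [(f, getattr(record, f)) for f in FIELDS]


def find_keywords(record, lexicon: KeywordLexicon) -> MatchAnnotation:
    """All keyword hits in a record's body and conclusion."""
    hits: list[KeywordHit] = []
    for field, text in _field_texts(record):
        norm = normalize(text)
        for m in _TOKEN_RE.finditer(norm.text):
            token = m.group()
            for entry in lexicon.entries:
                if _token_matches(token, entry):
                    start, end = norm.to_original(m.start(), m.end())
                    hits.append(KeywordHit(entry.stem, entry.kind, field, start, end))
    return MatchAnnotation(tuple(hits), ())


def find_stop_phrases(record, lexicon: StopPhraseLexicon) -> MatchAnnotation:
    """All stop-phrase occurrences in a record's body and conclusion."""
    hits: list[StopPhraseHit] = []
    for field, text in _field_texts(record):
        norm = normalize(text)
        for phrase in lexicon.phrases:
            pos = 0
            while True:
                i = norm.text.find(phrase, pos)
                if i < 0:
                    break
                j = i + len(phrase)
                at_start = i == 0 or norm.text[i - 1] == " "
                at_end = j == len(norm.text) or norm.text[j] == " "
                if at_start and at_end:
                    start, end = norm.to_original(i, j)
                    hits.append(StopPhraseHit(phrase, field, start, end))
                pos = i + 1
    return MatchAnnotation((), tuple(hits))


def annotate(record, keywords: KeywordLexicon, stop_phrases: StopPhraseLexicon) -> MatchAnnotation:
    """Combined keyword and stop-phrase annotation of one record."""
    return find_keywords(record, keywords).merge(find_stop_phrases(record, stop_phrases))
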