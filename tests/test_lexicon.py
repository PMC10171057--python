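"""Lexicon loading, text normalization and keyword/stop-phrase matching."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from reportriage.errors import LexiconError
from reportriage.lexicon import (
    find_keywords,
    find_stop_phrases,
    load_keyword_lexicon,
    load_stop_phrase_lexicon,
    normalize,
)

from conftest import make_record


# ---------------------------------------------------------------------------
# loaders

def test_single_entry_keyword_file(tmp_path):
    path = tmp_path / "kw.tsv"
    path.write_text("hematoma\tword_stem\n", encoding="utf-8")
    lex = load_keyword_lexicon(path)
    assert len(lex) == 1
    assert lex.entries[0].stem == "hematoma"


@pytest.mark.parametrize(
    "content",
    [
        "",  # empty file
        "hematoma\tword_stem\nhematoma\tabbreviation\n",  # duplicate stem
        "hematoma\tverb\n",  # unknown kind
        "two words\tword_stem\n",  # multi-token stem
    ],
)
def test_keyword_lexicon_validation_errors(tmp_path, content):
    path = tmp_path / "kw.tsv"
    path.write_text(content, encoding="utf-8")
    with pytest.raises(LexiconError):
        load_keyword_lexicon(path)


def test_single_phrase_file(tmp_path, keywords):
    path = tmp_path / "sp.txt"
    path.write_text("no signs of bleeding are seen\n", encoding="utf-8")
    lex = load_stop_phrase_lexicon(path, keywords)
    assert len(lex) == 1


def test_duplicate_phrase_after_normalization_rejected(tmp_path, keywords):
    path = tmp_path / "sp.txt"
    path.write_text("No signs   of ICH\nno signs of ich\n", encoding="utf-8")
    with pytest.raises(LexiconError):
        load_stop_phrase_lexicon(path, keywords)


def test_phrase_without_negation_or_keyword_rejected(tmp_path, keywords):
    path = tmp_path / "sp.txt"
    path.write_text("the brain appears unremarkable\n", encoding="utf-8")
    with pytest.raises(LexiconError):
        load_stop_phrase_lexicon(path, keywords)


# ---------------------------------------------------------------------------
# normalization

@pytest.mark.parametrize(
    "raw,expected",
    [
        ("SAH.  Not found", "sah not found"),
        ("", ""),
        ("already normalized", "already normalized"),
        ("cross-check T2-weighted", "cross-check t2-weighted"),
        ("- leading, trailing -", "leading trailing"),
    ],
)
def test_normalize_examples(raw, expected):
    assert normalize(raw).text == expected


@given(st.text(max_size=80))
def test_normalize_idempotent(text):
    once = normalize(text).text
    assert normalize(once).text == once


@given(st.text(max_size=80))
def test_offset_map_spans_lie_in_source(text):
    norm = normalize(text)
    assert len(norm.offsets) == len(norm.text)
    if norm.text:
        start, end = norm.to_original(0, len(norm.text))
        assert 0 <= start < end <= len(text)


# ---------------------------------------------------------------------------
# keyword matching

def test_finds_stems_in_conclusion(keywords):
    record = make_record(conclusion="acute subdural hematoma on the right")
    hits = find_keywords(record, keywords).keyword_hits
    assert {h.stem for h in hits} == {"subdural", "hematoma"}
    assert all(h.field == "conclusion" for h in hits)


def test_stem_prefix_matches_plural(keywords):
    record = make_record(body="multiple hemorrhages noted")
    assert {h.stem for h in find_keywords(record, keywords).keyword_hits} == {"hemorrhage"}


def test_abbreviation_requires_whole_token(keywords):
    record = make_record(body="patient history of sahara travel")
    assert find_keywords(record, keywords).keyword_hits == ()
    record = make_record(body="CT picture of SAH")
    assert {h.stem for h in find_keywords(record, keywords).keyword_hits} == {"sah"}


def test_empty_fields_have_no_hits(keywords):
    record = make_record(body="", conclusion="   ")
    assert find_keywords(record, keywords).keyword_hits == ()


def test_single_stem_text_yields_single_hit(keywords):
    for entry in keywords.entries:
        record = make_record(body=entry.stem, conclusion="clear")
        hits = find_keywords(record, keywords).keyword_hits
        assert len(hits) == 1 and hits[0].stem == entry.stem


def test_keyword_spans_index_original_text(keywords):
    body = "Dense EPIDURAL   hematoma."
    record = make_record(body=body)
    for hit in find_keywords(record, keywords).keyword_hits:
        token = body[hit.start:hit.end]
        assert normalize(token).text.startswith(hit.stem)


@given(
    text=st.sampled_from(["subdural hematoma", "SAH in cisterns", "epidural collection"]),
    rnd=st.randoms(use_true_random=False),
)
def test_matching_invariant_under_case_and_whitespace(keywords, text, rnd):
    mangled = "".join(
        (c.upper() if rnd.random() < 0.5 else c.lower()) + (" " if c == " " and rnd.random() < 0.5 else "")
        for c in text
    )
    base = {h.stem for h in find_keywords(make_record(body=text), keywords).keyword_hits}
    assert {h.stem for h in find_keywords(make_record(body=mangled), keywords).keyword_hits} == base


# ---------------------------------------------------------------------------
# stop-phrase matching

def test_printed_stop_phrase_matches(stop_phrases):
    record = make_record(body="Study done. Signs of intracranial hemorrhage are not found.")
    hits = find_stop_phrases(record, stop_phrases).stop_phrase_hits
    assert len(hits) == 1
    assert hits[0].phrase == "signs of intracranial hemorrhage are not found"


def test_phrase_split_across_line_break_still_matches(stop_phrases):
    record = make_record(body="signs of intracranial\nhemorrhage are not   found")
    assert len(find_stop_phrases(record, stop_phrases).stop_phrase_hits) == 1


def test_no_phrase_no_hits(stop_phrases):
    record = make_record(body="acute subdural hematoma on the left")
    assert find_stop_phrases(record, stop_phrases).stop_phrase_hits == ()


def test_phrase_span_roundtrips_through_offset_map(stop_phrases):
    body = "Noted:  SIGNS of intracranial hemorrhage are NOT found; follow-up advised."
    record = make_record(body=body)
    (hit,) = find_stop_phrases(record, stop_phrases).stop_phrase_hits
    assert normalize(body[hit.start:hit.end]).text == hit.phrase


def test_every_packaged_phrase_matches_itself(stop_phrases):
    for raw in stop_phrases.raw:
        record = make_record(body=f"Header. {raw}. Footer text.")
        hits = find_stop_phrases(record, stop_phrases).stop_phrase_hits
        assert normalize(raw).text in {h.phrase for h in hits}
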