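"""Bag-of-words featurization of report texts.

Reports are represented as raw token counts over a vocabulary frozen at
training time: body and conclusion are concatenated, normalized with the
same rules the lexicon matchers use, and tokenized on spaces.  Tokens
seen in fewer than ``min_document_frequency`` training documents are
dropped; tokens unseen at training time are ignored at prediction time.
An optional bigram switch adds adjacent token pairs to the vocabulary.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .corpus_io import ReportRecord
from .lexicon import tokens as _tokens

log = logging.getLogger(__name__)


def document_text(record: ReportRecord) -> str:
    """The text a record contributes to featurization (body + conclusion)."""
    return record.body + "\n" + record.conclusion


def _terms(text: str, bigrams: bool) -> list[str]:
    toks = _tokens(text)
    if not bigrams:
        return toks
    return toks + [f"{a} {b}" for a, b in zip(toks, toks[1:])]


@dataclass(frozen=True)
class Vocabulary:
    """Bijective token -> contiguous 0-based column index map."""

    token_to_index: Mapping[str, int]
    min_document_frequency: int = 1
    bigrams: bool = False

    def __len__(self) -> int:
        return len(self.token_to_index)

    @property
    def tokens(self) -> list[str]:
        return sorted(self.token_to_index, key=self.token_to_index.__getitem__)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"token": self.tokens, "index": range(len(self))})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_vocabulary(path) -> Vocabulary:
    df = pd.read_csv(path, sep="\t", dtype={"token": str, "index": int})
    mapping = dict(zip(df["token"], df["index"]))
    bigrams = any(" " in t for t in mapping)
    return Vocabulary(mapping, bigrams=bigrams)


def build_vocabulary(
    train_texts: Sequence[str],
    min_document_frequency: int = 2,
    bigrams: bool = False,
) -> Vocabulary:
    """Vocabulary of tokens occurring in >= ``min_document_frequency`` docs.

    Retained tokens are sorted lexicographically and indexed 0..V-1.
    """
    if len(train_texts) == 0:
        raise ValueError("cannot build a vocabulary from an empty training set")
    if min_document_frequency < 1:
        raise ValueError("min_document_frequency must be >= 1")
    doc_freq: Counter[str] = Counter()
    for text in train_texts:
        doc_freq.update(set(_terms(text, bigrams)))
    retained = sorted(t for t, c in doc_freq.items() if c >= min_document_frequency)
    if not retained:
        log.warning(
            "empty vocabulary: no token appears in >= %d of %d documents",
            min_document_frequency,
            len(train_texts),
        )
    return Vocabulary(
        {t: i for i, t in enumerate(retained)},
        min_document_frequency=min_document_frequency,
        bigrams=bigrams,
    )


def vectorize(texts: Sequence[str], vocabulary: Vocabulary) -> sp.csr_matrix:
    """Token-count document-term matrix; rows follow text order.

    Out-of-vocabulary tokens are dropped.
    """
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    lookup = vocabulary.token_to_index
    for text in texts:
        counts = Counter(_terms(text, vocabulary.bigrams))
        for token, count in sorted(counts.items()):
            col = lookup.get(token)
            if col is not None:
                indices.append(col)
                data.append(count)
        indptr.append(len(indices))
    return sp.csr_matrix(
        (data, indices, indptr),
        shape=(len(texts), len(vocabulary)),
        dtype="int64",
    )


def vectorize_records(records: Sequence[ReportRecord], vocabulary: Vocabulary) -> sp.csr_matrix:
    return vectorize([document_text(r) for r in records], vocabulary)


def export_matrix(matrix: sp.spmatrix, path) -> None:
    """Write a document-term matrix in Matrix Market (MTX) format."""
    scipy.io.mmwrite(path, matrix)
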