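"""End-to-end orchestration: filter -> label -> split -> featurize -> train -> evaluate.

The full flow mirrors how a weak-supervision triage study is run:

1. read the corpus and apply the record-level exclusion rules;
2. keep the keyword-bearing candidates and assign weak labels
   (optionally replaced by expert overrides);
3. split candidates 7:3, build a vocabulary on the training texts only,
   train the depth-bounded CART tree on the weak labels;
4. score the held-out test set and report diagnostic-accuracy metrics —
   against the operating (weak/overridden) labels, and additionally
   against gold classes when a gold table is supplied.

Every stage logs its input/output record counts; the run manifest
records the count funnel, the seeds and the lexicon checksums so a run
is reproducible from its manifest plus the original inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import corpus_io, features, tree, weak_labeling
from .errors import ConfigError, DataError
from .evaluation import MetricsReport, SplitSpec, confusion, metrics, split_indices
from .lexicon import (
    KeywordLexicon,
    StopPhraseLexicon,
    default_keyword_lexicon,
    default_stop_phrase_lexicon,
    load_keyword_lexicon,
    load_stop_phrase_lexicon,
)
from .synthetic import GoldRecord
from .weak_labeling import Label

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    corpus: str
    output_dir: str
    dialect: str = "csv"
    keyword_lexicon: str | None = None  # None -> packaged default
    stop_phrase_lexicon: str | None = None
    overrides: str | None = None
    gold: str | None = None
    train_fraction: float = 0.7
    split_seed: int = 0
    max_depth: int = tree.DEFAULT_MAX_DEPTH
    min_samples_split: int = 2
    tree_seed: int = 0
    min_document_frequency: int = 2
    bigrams: bool = False

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        try:
            obj = json.loads(Path(path).read_text(encoding="utf-8"))
        except FileNotFoundError:
            raise ConfigError(f"config file not found: {path}")
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config file {path} is not valid JSON: {exc}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(obj) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**obj)

    def validate_paths(self) -> None:
        required = {"corpus": self.corpus}
        for name in ("keyword_lexicon", "stop_phrase_lexicon", "overrides", "gold"):
            value = getattr(self, name)
            if value is not None:
                required[name] = value
        for name, path in required.items():
            if not Path(path).exists():
                raise ConfigError(f"{name} path does not exist: {path}")


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_lexicons(config: RunConfig) -> tuple[KeywordLexicon, StopPhraseLexicon, dict]:
    checksums = {}
    if config.keyword_lexicon is None:
        keywords = default_keyword_lexicon()
        checksums["keyword_lexicon"] = "packaged:ich_keywords.tsv"
    else:
        keywords = load_keyword_lexicon(config.keyword_lexicon)
        checksums["keyword_lexicon"] = _sha256(config.keyword_lexicon)
    if config.stop_phrase_lexicon is None:
        stop_phrases = default_stop_phrase_lexicon()
        checksums["stop_phrase_lexicon"] = "packaged:ich_stop_phrases.txt"
    else:
        stop_phrases = load_stop_phrase_lexicon(config.stop_phrase_lexicon, keywords)
        checksums["stop_phrase_lexicon"] = _sha256(config.stop_phrase_lexicon)
    return keywords, stop_phrases, checksums


def _binary_labels(labels: Sequence[weak_labeling.WeakLabel]) -> np.ndarray:
    return np.array(
        [1 if wl.label is Label.ICH_POSITIVE else 0 for wl in labels], dtype=np.int64
    )


@dataclass
class FitResult:
    """Everything the train/evaluate core produces for one split."""

    model: tree.DecisionTreeModel
    vocabulary: features.Vocabulary
    train_idx: np.ndarray
    test_idx: np.ndarray
    test_predictions: np.ndarray
    report: MetricsReport


def fit_and_evaluate(
    records: Sequence[corpus_io.ReportRecord],
    labels01: np.ndarray,
    split_spec: SplitSpec,
    train_config: tree.TrainConfig,
    min_document_frequency: int = 2,
    bigrams: bool = False,
    gold01: np.ndarray | None = None,
) -> FitResult:
    """Split, featurize on training texts, train the tree and score the test set.

    Metrics are computed against ``gold01`` when given, otherwise
    against ``labels01`` (the training-label convention).
    """
    train_idx, test_idx = split_indices(len(records), split_spec)
    texts = [features.document_text(r) for r in records]
    vocabulary = features.build_vocabulary(
        [texts[i] for i in train_idx], min_document_frequency, bigrams
    )
    X_train = features.vectorize([texts[i] for i in train_idx], vocabulary)
    X_test = features.vectorize([texts[i] for i in test_idx], vocabulary)
    model = tree.train(X_train, labels01[train_idx], train_config)
    predictions = tree.predict(model, X_test)
    reference = gold01 if gold01 is not None else labels01
    report = metrics(confusion(reference[test_idx], predictions))
    return FitResult(model, vocabulary, train_idx, test_idx, predictions, report)


def evaluate_on_gold(
    gold: Sequence[GoldRecord],
    split_spec: SplitSpec,
    train_config: tree.TrainConfig | None = None,
    min_document_frequency: int = 2,
) -> tuple[FitResult, dict]:
    """Run the whole pipeline on a generated corpus, scoring against gold.

    The tree is trained on *weak* labels; the held-out metrics compare
    its predictions with the generator's true classes, so label noise
    from conflict and distractor records flows through to the metrics
    exactly as it would in a real weak-supervision study.
    """
    if train_config is None:
        train_config = tree.TrainConfig()
    records = [g.record for g in gold]
    kept, exclusion_log = corpus_io.apply_exclusions(records)
    keywords = default_keyword_lexicon()
    stop_phrases = default_stop_phrase_lexicon()
    truth = {}
    for g in gold:
        truth.setdefault(g.record.study_id, 1 if g.true_class == "ICH" else 0)
    labeled = weak_labeling.label_corpus(kept, keywords, stop_phrases)
    cand = [
        (r, wl)
        for r, wl in zip(labeled.records, labeled.labels)
        if wl.label is not Label.NO_KEYWORD
    ]
    cand_records = [r for r, _ in cand]
    weak01 = _binary_labels([wl for _, wl in cand])
    gold01 = np.array([truth[r.study_id] for r in cand_records], dtype=np.int64)
    result = fit_and_evaluate(
        cand_records,
        weak01,
        split_spec,
        train_config,
        min_document_frequency,
        gold01=gold01,
    )
    counts = {
        "n_input": len(records),
        "n_kept": len(kept),
        "n_excluded": exclusion_log.n_excluded,
        "n_candidates": len(cand_records),
        "n_train": len(result.train_idx),
        "n_test": len(result.test_idx),
    }
    return result, counts


def run(config: RunConfig) -> tuple[dict, MetricsReport]:
    """Execute the full pipeline from a run configuration.

    Writes the exclusion log, labeled corpus, vocabulary, model, metrics
    and manifest into ``config.output_dir`` and returns the manifest and
    the metrics report.  Any stage failure propagates with the stage
    named in the exception message.
    """
    config.validate_paths()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "stages": [],
        "seeds": {"split": config.split_seed, "tree": config.tree_seed},
        "config": {
            "train_fraction": config.train_fraction,
            "max_depth": config.max_depth,
            "min_samples_split": config.min_samples_split,
            "min_document_frequency": config.min_document_frequency,
            "bigrams": config.bigrams,
        },
    }

    def stage(name: str, fn):
        start = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise type(exc)(f"stage {name!r} failed: {exc}") from exc
        elapsed = time.perf_counter() - start
        return result, elapsed

    def record_stage(name, n_in, n_out, elapsed):
        log.info("stage %-12s in=%-6d out=%-6d %.2fs", name, n_in, n_out, elapsed)
        manifest["stages"].append(
            {"stage": name, "n_in": n_in, "n_out": n_out, "seconds": round(elapsed, 3)}
        )

    records, t = stage("read", lambda: corpus_io.read_corpus(config.corpus, config.dialect))
    record_stage("read", len(records), len(records), t)

    (kept, exclusion_log), t = stage("filter", lambda: corpus_io.apply_exclusions(records))
    exclusion_log.write(out_dir / "exclusion_log.csv")
    record_stage("filter", len(records), len(kept), t)
    manifest["exclusion_reasons"] = exclusion_log.reason_counts()

    (keywords, stop_phrases, checksums), t = stage("lexicon", lambda: _load_lexicons(config))
    manifest["lexicons"] = checksums
    record_stage("lexicon", len(keywords), len(stop_phrases), t)

    labeled, t = stage(
        "label", lambda: weak_labeling.label_corpus(kept, keywords, stop_phrases)
    )
    if config.overrides is not None:
        overrides = weak_labeling.read_overrides(config.overrides)
        labeled = weak_labeling.apply_overrides(labeled, overrides)
        manifest["n_overrides"] = len(overrides)
    labeled.write(out_dir / "labeled.csv")
    manifest["class_counts"] = labeled.class_counts()
    record_stage("label", len(kept), len(labeled), t)

    cand = [
        (r, wl)
        for r, wl in zip(labeled.records, labeled.labels)
        if wl.label is not Label.NO_KEYWORD
    ]
    cand_records = [r for r, _ in cand]
    weak01 = _binary_labels([wl for _, wl in cand])
    record_stage("candidates", len(labeled), len(cand_records), 0.0)

    gold01 = None
    if config.gold is not None:
        from .synthetic import read_gold

        table = read_gold(config.gold)
        truth: dict[str, int] = {}
        for sid, cls in zip(table["study_id"], table["true_class"]):
            truth.setdefault(sid, 1 if cls == "ICH" else 0)
        missing = [r.study_id for r in cand_records if r.study_id not in truth]
        if missing:
            raise DataError(f"gold table lacks {len(missing)} candidate study_ids")
        gold01 = np.array([truth[r.study_id] for r in cand_records], dtype=np.int64)

    result, t = stage(
        "train_evaluate",
        lambda: fit_and_evaluate(
            cand_records,
            weak01,
            SplitSpec(config.train_fraction, config.split_seed),
            tree.TrainConfig(config.max_depth, config.min_samples_split, config.tree_seed),
            config.min_document_frequency,
            config.bigrams,
            gold01=gold01,
        ),
    )
    record_stage("train_evaluate", len(cand_records), len(result.test_idx), t)

    result.vocabulary.write(out_dir / "vocabulary.tsv")
    tree.save_model(result.model, out_dir / "model.json")
    (out_dir / "metrics.json").write_text(result.report.to_json(), encoding="utf-8")
    manifest["vocabulary_size"] = len(result.vocabulary)
    manifest["tree_depth"] = result.model.depth
    manifest["metrics"] = result.report.to_dict()
    manifest["scored_against"] = "gold" if gold01 is not None else "weak_labels"
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8"
    )
    return manifest, result.report
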