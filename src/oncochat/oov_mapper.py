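"""Out-of-vocabulary mapping of noisy speech transcriptions to supported terms.

A general-purpose speech recognizer transcribes domain terms — gene
symbols above all — unreliably ("MICK" for *MYC*, "kay rass" for *KRAS*).
This module resolves such transcriptions to a supported attribute value
(a GENE, CANCER_TYPE, or DATA_TYPE) through a chain of pipelines, each
invoked only if the previous one failed to resolve:

1. **personal** — per-user pronunciation overrides;
2. **exact** — normalized lookup against the lexicon of canonical values
   and their synonyms;
3. **crowdsourced** — lookup against a corpus of human pronunciation
   transcriptions, resolving only when all matching records agree on a
   single target;
4. **predicted** — a random-forest classifier over character n-gram
   TF-IDF, phonetic, syllable and length features, with majority vote
   across trees and seeded random tie-breaking.

Stages 1-3 are lookups and return confidence 1; the predicted stage
reports the (tie-adjusted) vote fraction.
"""

from __future__ import annotations

import json
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import HashingVectorizer, TfidfVectorizer

from .phonetics import phonetic_code
from .textnorm import EMPTY, normalize_text, syllable_count

MODEL_FORMAT_VERSION = 1


class AttributeType(str, Enum):
    GENE = "GENE"
    CANCER_TYPE = "CANCER_TYPE"
    DATA_TYPE = "DATA_TYPE"


class MatchStage(str, Enum):
    PERSONAL = "PERSONAL"
    EXACT = "EXACT"
    CROWDSOURCED = "CROWDSOURCED"
    PREDICTED = "PREDICTED"
    UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class TermEntry:
    """A canonical attribute value with optional synonyms."""

    value: str
    attribute_type: AttributeType
    synonyms: tuple[str, ...] = ()


@dataclass(frozen=True)
class UtteranceRecord:
    """One pronunciation transcription linked to its target term."""

    transcription: str
    target_value: str
    attribute_type: AttributeType
    speaker_id: str | None = None


@dataclass(frozen=True)
class MatchResult:
    value: str | None
    attribute_type: AttributeType | None
    stage: MatchStage
    confidence: float

    @property
    def resolved(self) -> bool:
        return self.stage is not MatchStage.UNRESOLVED


UNRESOLVED = MatchResult(None, None, MatchStage.UNRESOLVED, 0.0)


class LexiconError(ValueError):
    """Raised on malformed or colliding lexicon input."""


class Lexicon:
    """Collision-checked lookup from normalized term to canonical entry.

    Canonical values must be unique within their attribute type after
    normalization, and no synonym may collide with a different entry; both
    violations are load errors, since a silent overwrite would make the
    exact-match pipeline nondeterministic.
    """

    def __init__(self, entries: Iterable[TermEntry]):
        self.entries: list[TermEntry] = list(entries)
        self._by_norm: dict[str, TermEntry] = {}
        seen_values: set[tuple[str, AttributeType]] = set()
        for entry in self.entries:
            key = normalize_text(entry.value)
            if key == EMPTY:
                raise LexiconError(f"lexicon value normalizes to nothing: {entry.value!r}")
            if (key, entry.attribute_type) in seen_values:
                raise LexiconError(
                    f"duplicate canonical value after normalization: {entry.value!r}"
                )
            seen_values.add((key, entry.attribute_type))
            for alias in (entry.value, *entry.synonyms):
                akey = normalize_text(alias)
                if akey == EMPTY:
                    raise LexiconError(f"synonym normalizes to nothing: {alias!r}")
                prior = self._by_norm.get(akey)
                if prior is not None and (prior.value, prior.attribute_type) != (
                    entry.value,
                    entry.attribute_type,
                ):
                    raise LexiconError(
                        f"term {alias!r} collides between {prior.value!r} and {entry.value!r}"
                    )
                self._by_norm[akey] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, value: str) -> bool:
        return any(e.value == value for e in self.entries)

    def lookup(self, normalized: str) -> TermEntry | None:
        return self._by_norm.get(normalized)

    def values(self, attribute_type: AttributeType | None = None) -> list[str]:
        return [
            e.value
            for e in self.entries
            if attribute_type is None or e.attribute_type is attribute_type
        ]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        """Load a lexicon TSV with columns value / attribute_type / synonyms
        (pipe-separated, may be empty)."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"value", "attribute_type", "synonyms"}
        missing = required - set(df.columns)
        if missing:
            raise LexiconError(f"lexicon TSV missing columns: {sorted(missing)}")
        entries = []
        for row in df.itertuples(index=False):
            syns = tuple(s for s in str(row.synonyms).split("|") if s)
            entries.append(TermEntry(row.value, AttributeType(row.attribute_type), syns))
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "value": e.value,
                "attribute_type": e.attribute_type.value,
                "synonyms": "|".join(e.synonyms),
            }
            for e in self.entries
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_corpus_tsv(path: str | Path, lexicon: Lexicon | None = None) -> list[UtteranceRecord]:
    """Load an utterance-corpus TSV (transcription / target_value /
    attribute_type / optional speaker_id), validating targets against the
    lexicon when one is given."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"transcription", "target_value", "attribute_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"corpus TSV missing columns: {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        if not row.transcription.strip():
            raise ValueError(f"row {i}: empty transcription")
        if lexicon is not None and row.target_value not in lexicon:
            raise ValueError(f"row {i}: target {row.target_value!r} not in lexicon")
        records.append(
            UtteranceRecord(
                row.transcription,
                row.target_value,
                AttributeType(row.attribute_type),
                getattr(row, "speaker_id", None) or None,
            )
        )
    return records


def save_corpus_tsv(records: Sequence[UtteranceRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "transcription": r.transcription,
                "target_value": r.target_value,
                "attribute_type": r.attribute_type.value,
                "speaker_id": r.speaker_id or "",
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Matching pipelines


def exact_match(normalized: str, lexicon: Lexicon) -> MatchResult:
    """Stage-2 lookup of a normalized utterance against the lexicon."""
    if normalized == EMPTY:
        return UNRESOLVED
    entry = lexicon.lookup(normalized)
    if entry is None:
        return UNRESOLVED
    return MatchResult(entry.value, entry.attribute_type, MatchStage.EXACT, 1.0)


def build_corpus_index(
    corpus: Iterable[UtteranceRecord],
) -> dict[str, set[tuple[str, AttributeType]]]:
    """Index crowdsourced records by normalized transcription."""
    index: dict[str, set[tuple[str, AttributeType]]] = defaultdict(set)
    for rec in corpus:
        key = normalize_text(rec.transcription)
        if key != EMPTY:
            index[key].add((rec.target_value, rec.attribute_type))
    return dict(index)


def crowdsourced_match(
    normalized: str,
    corpus: Iterable[UtteranceRecord] | Mapping[str, set[tuple[str, AttributeType]]],
) -> MatchResult:
    """Stage-3 lookup in the crowdsourced corpus.

    Resolves only when every matching record points at one target; an
    ambiguous transcription falls through to the predicted stage.
    """
    if normalized == EMPTY:
        return UNRESOLVED
    index = corpus if isinstance(corpus, Mapping) else build_corpus_index(corpus)
    targets = index.get(normalized)
    if not targets or len(targets) > 1:
        return UNRESOLVED
    value, attr = next(iter(targets))
    return MatchResult(value, attr, MatchStage.CROWDSOURCED, 1.0)


# ---------------------------------------------------------------------------
# Personal pronunciations


class PersonalStore:
    """Per-user pronunciation overrides, persisted as a JSON file.

    Keyed by (user_id, normalized transcription); re-adding a key
    overwrites (upsert).  Lookups for one user never see another user's
    records.
    """

    def __init__(self) -> None:
        self._data: dict[str, dict[str, tuple[str, AttributeType]]] = {}

    def add(
        self,
        user_id: str,
        transcription: str,
        target_value: str,
        attribute_type: AttributeType,
        lexicon: Lexicon | None = None,
        custom: bool = False,
    ) -> None:
        key = normalize_text(transcription)
        if key == EMPTY:
            raise ValueError("empty transcription")
        if lexicon is not None and not custom and target_value not in lexicon:
            raise ValueError(f"target {target_value!r} not in lexicon (pass custom=True to allow)")
        self._data.setdefault(user_id, {})[key] = (target_value, AttributeType(attribute_type))

    def remove(self, user_id: str, transcription: str) -> bool:
        key = normalize_text(transcription)
        return self._data.get(user_id, {}).pop(key, None) is not None

    def list_user(self, user_id: str) -> dict[str, tuple[str, AttributeType]]:
        return dict(self._data.get(user_id, {}))

    def lookup(self, user_id: str | None, normalized: str) -> MatchResult:
        if user_id is None or normalized == EMPTY:
            return UNRESOLVED
        hit = self._data.get(user_id, {}).get(normalized)
        if hit is None:
            return UNRESOLVED
        return MatchResult(hit[0], hit[1], MatchStage.PERSONAL, 1.0)

    def save(self, path: str | Path) -> None:
        payload = {
            user: {k: [v[0], v[1].value] for k, v in recs.items()}
            for user, recs in self._data.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PersonalStore":
        store = cls()
        payload = json.loads(Path(path).read_text())
        for user, recs in payload.items():
            for key, (value, attr) in recs.items():
                store._data.setdefault(user, {})[key] = (value, AttributeType(attr))
        return store


# ---------------------------------------------------------------------------
# Features and the learned matcher


@dataclass
class UtteranceFeatures:
    """Flat features of one normalized transcription."""

    char_ngram_counts: dict[str, int]
    tfidf_weights: sp.csr_matrix
    phonetic_codes: list[str]
    syllable_count: int
    length_features: tuple[int, int]  # (characters, tokens)
    embedding: np.ndarray | None = None
    degenerate: bool = False


@dataclass
class MatcherConfig:
    """Hyperparameters of the learned matcher; fixed here, not tuned per run."""

    n_estimators: int = 200
    ngram_range: tuple[int, int] = (2, 4)
    phonetic_ngram_range: tuple[int, int] = (1, 3)
    use_embedding: bool = False
    embedding_dim: int = 64


class UtteranceFeaturizer:
    """Fits TF-IDF vocabularies on the training partition only, then maps
    normalized transcriptions to sparse feature matrices.

    Feature blocks: character n-grams (with word-boundary padding) of the
    text; character n-grams of the per-token Metaphone keys; syllable,
    character and token counts; an optional hashed character embedding
    (off by default)."""

    def __init__(self, config: MatcherConfig | None = None):
        self.config = config or MatcherConfig()
        self._char_vec = TfidfVectorizer(
            analyzer="char_wb", ngram_range=self.config.ngram_range, lowercase=False
        )
        self._phon_vec = TfidfVectorizer(
            analyzer="char_wb", ngram_range=self.config.phonetic_ngram_range, lowercase=False
        )
        self._embed_vec = (
            HashingVectorizer(
                analyzer="char_wb",
                ngram_range=(1, 2),
                n_features=self.config.embedding_dim,
                alternate_sign=False,
                norm="l2",
            )
            if self.config.use_embedding
            else None
        )
        self.fitted = False

    def fit(self, normalized_texts: Sequence[str]) -> "UtteranceFeaturizer":
        phon = [phonetic_code(t) for t in normalized_texts]
        self._char_vec.fit(normalized_texts)
        self._phon_vec.fit([p if p else " " for p in phon])
        self.fitted = True
        return self

    def _numeric_block(self, texts: Sequence[str]) -> sp.csr_matrix:
        rows = [
            (len(t), len(t.split()), syllable_count(t) if t else 0)
            for t in texts
        ]
        return sp.csr_matrix(np.asarray(rows, dtype=float))

    def transform(self, normalized_texts: Sequence[str]) -> sp.csr_matrix:
        if not self.fitted:
            raise RuntimeError("featurizer not fitted")
        phon = [phonetic_code(t) or " " for t in normalized_texts]
        blocks = [
            self._char_vec.transform(normalized_texts),
            self._phon_vec.transform(phon),
            self._numeric_block(normalized_texts),
        ]
        if self._embed_vec is not None:
            blocks.append(self._embed_vec.transform(normalized_texts))
        return sp.hstack(blocks, format="csr")

    def featurize(self, normalized: str) -> UtteranceFeatures:
        """Inspectable feature record for one transcription."""
        n = self.config.ngram_range
        padded = f" {normalized} " if normalized else ""
        counts: Counter[str] = Counter(
            padded[i : i + k]
            for k in range(n[0], n[1] + 1)
            for i in range(max(0, len(padded) - k + 1))
        )
        row = self.transform([normalized])
        emb = None
        if self._embed_vec is not None:
            emb = self._embed_vec.transform([normalized]).toarray()[0]
        return UtteranceFeatures(
            char_ngram_counts=dict(counts),
            tfidf_weights=row,
            phonetic_codes=phonetic_code(normalized).split(),
            syllable_count=syllable_count(normalized) if normalized else 0,
            length_features=(len(normalized), len(normalized.split())),
            embedding=emb,
            degenerate=(normalized == EMPTY),
        )


@dataclass
class MatcherModel:
    """A trained random-forest matcher plus everything needed to replay it."""

    classifier: RandomForestClassifier
    featurizer: UtteranceFeaturizer
    labels: list[tuple[str, str]]  # class id -> (value, attribute_type)
    training_seed: int
    format_version: int = MODEL_FORMAT_VERSION

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": self.format_version,
                "classifier": self.classifier,
                "featurizer": self.featurizer,
                "labels": self.labels,
                "training_seed": self.training_seed,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "MatcherModel":
        payload = joblib.load(path)
        version = payload.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model format version {version!r} unsupported (expected {MODEL_FORMAT_VERSION})"
            )
        return cls(
            classifier=payload["classifier"],
            featurizer=payload["featurizer"],
            labels=payload["labels"],
            training_seed=payload["training_seed"],
        )


def split_corpus(
    corpus: Sequence[UtteranceRecord], train_fraction: float, seed: int
) -> tuple[list[UtteranceRecord], list[UtteranceRecord]]:
    """Seeded shuffle split; |train| = floor(train_fraction * N)."""
    if not corpus:
        raise ValueError("empty corpus")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    n_train = math.floor(train_fraction * len(corpus))
    train = [corpus[i] for i in order[:n_train]]
    test = [corpus[i] for i in order[n_train:]]
    return train, test


def train_matcher(
    corpus: Sequence[UtteranceRecord],
    train_fraction: float = 0.9,
    seed: int = 0,
    config: MatcherConfig | None = None,
) -> tuple[MatcherModel, list[UtteranceRecord]]:
    """Split the corpus, fit the featurizer and forest on the training
    partition only, and return (model, held-out records)."""
    config = config or MatcherConfig()
    train, test = split_corpus(corpus, train_fraction, seed)
    if not train:
        raise ValueError("training partition is empty")
    texts = [normalize_text(r.transcription) for r in train]
    label_keys = sorted({(r.target_value, r.attribute_type.value) for r in train})
    label_to_id = {k: i for i, k in enumerate(label_keys)}
    y = np.array([label_to_id[(r.target_value, r.attribute_type.value)] for r in train])
    featurizer = UtteranceFeaturizer(config).fit(texts)
    X = featurizer.transform(texts)
    clf = RandomForestClassifier(
        n_estimators=config.n_estimators, random_state=int(seed) % (2**31)
    )
    clf.fit(X, y)
    return MatcherModel(clf, featurizer, list(label_keys), int(seed)), test


def predict_match(model: MatcherModel, normalized: str, seed: int = 0) -> MatchResult:
    """Majority vote over the forest's trees, ties split by a seeded draw.

    Confidence is the winning class's share of tree votes; with a k-way
    tie each tied class holds that same share and one is drawn uniformly.
    """
    if normalized == EMPTY:
        return UNRESOLVED
    X = model.featurizer.transform([normalized])
    class_ids = model.classifier.classes_
    votes = Counter()
    for tree in model.classifier.estimators_:
        proba = tree.predict_proba(X)[0]
        votes[class_ids[int(np.argmax(proba))]] += 1
    top = max(votes.values())
    winners = sorted(cid for cid, v in votes.items() if v == top)
    rng = np.random.default_rng(seed)
    winner = winners[int(rng.integers(len(winners)))] if len(winners) > 1 else winners[0]
    value, attr = model.labels[int(winner)]
    confidence = top / len(model.classifier.estimators_)
    return MatchResult(value, AttributeType(attr), MatchStage.PREDICTED, confidence)


# ---------------------------------------------------------------------------
# Full chain


def map_utterance(
    raw: str,
    lexicon: Lexicon,
    corpus: Iterable[UtteranceRecord] | Mapping[str, set] | None = None,
    model: MatcherModel | None = None,
    personal_store: PersonalStore | None = None,
    user_id: str | None = None,
    seed: int = 0,
) -> MatchResult:
    """Run the full resolution chain on a raw transcription.

    Stage order: personal overrides (for `user_id` only), exact lexicon
    match, crowdsourced corpus match, model prediction.  The first stage
    that resolves wins; when the least disambiguation is needed the exact
    stage answers and later pipelines never run.
    """
    normalized = normalize_text(raw)
    if normalized == EMPTY:
        return UNRESOLVED
    if personal_store is not None:
        result = personal_store.lookup(user_id, normalized)
        if result.resolved:
            return result
    result = exact_match(normalized, lexicon)
    if result.resolved:
        return result
    if corpus is not None:
        result = crowdsourced_match(normalized, corpus)
        if result.resolved:
            return result
    if model is not None:
        return predict_match(model, normalized, seed=seed)
    return UNRESOLVED


@dataclass
class EvalReport:
    """Held-out accuracy of the full chain versus the exact-only baseline."""

    n: int
    n_train: int
    full_chain_accuracy: float
    exact_only_accuracy: float
    per_type: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def improvement(self) -> float:
        """Relative improvement of the chain over the exact-only baseline."""
        if self.exact_only_accuracy == 0:
            return float("inf") if self.full_chain_accuracy > 0 else 0.0
        return (self.full_chain_accuracy - self.exact_only_accuracy) / self.exact_only_accuracy


def evaluate_matcher(
    model: MatcherModel | None,
    held_out: Sequence[UtteranceRecord],
    lexicon: Lexicon,
    corpus: Iterable[UtteranceRecord] | Mapping[str, set] | None = None,
    seed: int = 0,
    n_train: int = 0,
) -> EvalReport:
    """Fraction of held-out records the chain maps to their true target,
    with an exact-only baseline and a per-attribute-type breakdown."""
    if not held_out:
        raise ValueError("empty held-out set")
    index = (
        corpus
        if corpus is None or isinstance(corpus, Mapping)
        else build_corpus_index(corpus)
    )
    total = Counter()
    chain_ok = Counter()
    exact_ok = Counter()
    for rec in held_out:
        attr = rec.attribute_type.value
        total[attr] += 1
        result = map_utterance(
            rec.transcription, lexicon, index, model, seed=seed
        )
        if result.value == rec.target_value and result.attribute_type is rec.attribute_type:
            chain_ok[attr] += 1
        base = exact_match(normalize_text(rec.transcription), lexicon)
        if base.value == rec.target_value and base.attribute_type is rec.attribute_type:
            exact_ok[attr] += 1
    n = sum(total.values())
    per_type = {
        attr: {
            "n": total[attr],
            "full_chain_accuracy": chain_ok[attr] / total[attr],
            "exact_only_accuracy": exact_ok[attr] / total[attr],
        }
        for attr in total
    }
    return EvalReport(
        n=n,
        n_train=n_train,
        full_chain_accuracy=sum(chain_ok.values()) / n,
        exact_only_accuracy=sum(exact_ok.values()) / n,
        per_type=per_type,
    )
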