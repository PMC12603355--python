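"""RDP-style naive Bayes k-mer classifier with bootstrap confidence.

The reference classifier follows the Wang et al. word-presence model: each
training sequence is reduced to its set of distinct k-mers (default k=8,
words containing ambiguity codes are skipped); a class is one distinct
full lineage.  Word priors and class conditionals use the classical
pseudocounts

    P(w)   = (n(w) + 0.5) / (N + 1)
    P(w|c) = (m(w, c) + P(w)) / (M(c) + 1)

with N the corpus size, n(w) the number of sequences containing w, M(c)
the class size and m(w, c) the number of class-c sequences containing w.
A query scores each class by the sum of log conditionals over its distinct
words; confidence comes from bootstrap resampling ceil(V/8) of the query's
V words (100 draws by default), and the per-rank confidence is the
fraction of draws whose winning class agrees with the full-query winner on
the whole label prefix down to that rank — which makes confidence monotone
non-increasing with depth by construction.  Labels below the deepest rank
meeting the confidence cutoff (default 0.8) are blanked in the reported
lineage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .schema import Lineage, Provenance, RankSchema, ReferenceDatabase

__all__ = ["KmerModel", "Assignment", "train", "classify", "classify_many"]

_ACGT = frozenset("ACGT")


def _distinct_words(seq: str, k: int) -> List[str]:
    """Distinct unambiguous k-mers in order of first appearance."""
    seen = set()
    out: List[str] = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if w not in seen and set(w) <= _ACGT:
            seen.add(w)
            out.append(w)
    return out


@dataclass
class KmerModel:
    """Trained word-presence naive Bayes model.

    ``log_cond`` has one row per training-corpus word plus a final row for
    words never seen in training; columns are classes in lexicographic
    lineage order (so the first argmax is the documented tie-break).
    """

    k: int
    schema: RankSchema
    class_labels: List[Tuple[str, ...]]
    class_sizes: np.ndarray
    word_index: Dict[str, int]
    log_cond: np.ndarray
    n_sequences: int
    training_hash: Optional[str] = None

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def save(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "ranks": list(self.schema.ranks),
            "prefixes": list(self.schema.prefixes) if self.schema.prefixes else None,
            "class_labels": [list(c) for c in self.class_labels],
            "class_sizes": self.class_sizes.tolist(),
            "words": list(self.word_index),
            "log_cond": self.log_cond.tolist(),
            "n_sequences": self.n_sequences,
            "training_hash": self.training_hash,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "KmerModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        schema = RankSchema(
            tuple(d["ranks"]),
            tuple(d["prefixes"]) if d["prefixes"] else None,
        )
        return cls(
            k=d["k"],
            schema=schema,
            class_labels=[tuple(c) for c in d["class_labels"]],
            class_sizes=np.asarray(d["class_sizes"], dtype=np.int64),
            word_index={w: i for i, w in enumerate(d["words"])},
            log_cond=np.asarray(d["log_cond"], dtype=np.float64),
            n_sequences=d["n_sequences"],
            training_hash=d["training_hash"],
        )


@dataclass(frozen=True)
class Assignment:
    """One query's predicted lineage with per-rank bootstrap confidence."""

    query_id: str
    lineage: Lineage
    confidence: Tuple[float, ...]
    full_lineage: Lineage


def train(
    db: ReferenceDatabase, k: int = 8, training_hash: Optional[str] = None
) -> KmerModel:
    """Fit the word-presence model on a processed reference database."""
    records = db.sorted_records()
    if not records:
        raise ValueError("cannot train on an empty database")
    shortest = min(len(r.sequence) for r in records)
    if k > shortest:
        raise ValueError(
            f"k={k} exceeds the shortest training sequence ({shortest} nt)"
        )

    class_labels = sorted({r.lineage.labels for r in records})
    class_of = {lab: i for i, lab in enumerate(class_labels)}
    n_classes = len(class_labels)
    n_seqs = len(records)

    word_index: Dict[str, int] = {}
    rows: List[Tuple[int, int]] = []  # (word row, class column) per containing seq
    doc_freq: List[int] = []
    class_sizes = np.zeros(n_classes, dtype=np.int64)
    for rec in records:
        ci = class_of[rec.lineage.labels]
        class_sizes[ci] += 1
        for w in _distinct_words(rec.sequence, k):
            wi = word_index.setdefault(w, len(word_index))
            if wi == len(doc_freq):
                doc_freq.append(0)
            doc_freq[wi] += 1
            rows.append((wi, ci))

    n_words = len(word_index)
    m = np.zeros((n_words, n_classes), dtype=np.float64)
    for wi, ci in rows:
        m[wi, ci] += 1.0

    prior = (np.asarray(doc_freq, dtype=np.float64) + 0.5) / (n_seqs + 1.0)
    unseen_prior = 0.5 / (n_seqs + 1.0)
    denom = class_sizes.astype(np.float64) + 1.0
    log_cond = np.empty((n_words + 1, n_classes), dtype=np.float64)
    log_cond[:n_words] = np.log((m + prior[:, None]) / denom[None, :])
    log_cond[n_words] = np.log(unseen_prior / denom)

    return KmerModel(
        k=k,
        schema=db.schema,
        class_labels=class_labels,
        class_sizes=class_sizes,
        word_index=word_index,
        log_cond=log_cond,
        n_sequences=n_seqs,
        training_hash=training_hash,
    )


def classify(
    model: KmerModel,
    query: str,
    query_id: str = "query",
    n_bootstrap: int = 100,
    subsample: Optional[int] = None,
    confidence_threshold: float = 0.8,
    rng: Optional[np.random.Generator] = None,
) -> Assignment:
    """Assign a taxonomy to one query with bootstrap confidence.

    ``subsample`` defaults to ceil(V/8) where V is the query's distinct
    word count.  Ties in the class score break to the lexicographically
    smallest lineage.
    """
    if len(query) < model.k:
        raise ValueError(
            f"query {query_id!r} is shorter ({len(query)} nt) than k={model.k}"
        )
    words = _distinct_words(query.upper().replace("U", "T"), model.k)
    if not words:
        raise ValueError(f"query {query_id!r} has no unambiguous {model.k}-mers")
    unseen_row = model.log_cond.shape[0] - 1
    idx = np.asarray(
        [model.word_index.get(w, unseen_row) for w in words], dtype=np.int64
    )
    scores = model.log_cond[idx].sum(axis=0)
    winner = int(np.argmax(scores))  # first max = lexicographic tie-break

    n_ranks = len(model.schema)
    labels = np.asarray(model.class_labels, dtype=object)  # (n_classes, n_ranks)
    # agree[c, r]: class c matches the winner's whole label prefix through rank r
    eq = labels == labels[winner]
    agree = np.logical_and.accumulate(eq, axis=1)

    V = len(words)
    m = subsample if subsample is not None else max(1, math.ceil(V / 8))
    rng = rng or np.random.default_rng()
    draws = rng.integers(0, V, size=(n_bootstrap, m))
    boot_scores = model.log_cond[idx[draws]].sum(axis=1)  # (n_bootstrap, n_classes)
    boot_winners = np.argmax(boot_scores, axis=1)
    confidence = tuple(float(x) for x in agree[boot_winners].mean(axis=0))

    full = Lineage(tuple(model.class_labels[winner]))
    out_labels = list(full.labels)
    for r in range(n_ranks):
        if confidence[r] < confidence_threshold:
            out_labels[r] = ""
    reported = Lineage(tuple(out_labels))
    return Assignment(
        query_id=query_id, lineage=reported, confidence=confidence, full_lineage=full
    )


def classify_many(
    model: KmerModel,
    queries: Dict[str, str],
    n_bootstrap: int = 100,
    subsample: Optional[int] = None,
    confidence_threshold: float = 0.8,
    seed: int = 0,
) -> List[Assignment]:
    """Classify a batch of queries with one seeded random stream."""
    rng = np.random.default_rng(seed)
    return [
        classify(
            model,
            seq,
            query_id=qid,
            n_bootstrap=n_bootstrap,
            subsample=subsample,
            confidence_threshold=confidence_threshold,
            rng=rng,
        )
        for qid, seq in sorted(queries.items())
    ]
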