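"""Word-based naive Bayes genus classifier with bootstrap confidence.

Model
-----
A query is decomposed into all overlapping ``word_size``-mers containing only
unambiguous bases (A/C/G/T).  Training records word *presence* per reference
sequence (a word counts at most once per sequence).  With ``N`` training
sequences of which ``n(w)`` contain word ``w``, the corpus prior is

    P(w) = (n(w) + 0.5) / (N + 1)

and with ``M_g`` sequences in genus ``g`` of which ``m_g(w)`` contain ``w``,
the genus conditional is

    P(w | g) = (m_g(w) + P(w)) / (M_g + 1).

A read is assigned to the genus maximising the joint log score over its
*distinct* valid words (taxon priors assumed equiprobable, so the maximum
likelihood and maximum posterior solutions coincide).  Ties break toward the
earlier genus in model order (reference insertion order), making runs
reproducible.

The bootstrap confidence resamples a fraction (default 1/8) of the query's
word occurrences per trial, re-classifies the subsample, and reports per rank
the fraction of trials agreeing with the full-query assignment's ancestor at
that rank.  A fixed-word variant (``bootstrap_fixed_words``) decouples the
score from read length; it refuses queries shorter than twice the fixed span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import (
    ConfigurationError,
    EmptyDatabaseError,
    InputError,
    NoValidWordsError,
    TooShortReadError,
)
from .taxonomy import RANKS, TaxonomyTree
from .reference import ReferenceDB

MAX_WORD_SIZE = 12  # 4**12 word indices still fit comfortably in memory

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def encode_words(sequence: str, word_size: int) -> np.ndarray:
    """Indices (base-4 encoding) of all valid overlapping words, in order.

    Words overlapping any non-ACGT character are dropped; duplicates are kept.
    """
    if word_size < 1 or word_size > MAX_WORD_SIZE:
        raise ConfigurationError(f"word_size must be in [1, {MAX_WORD_SIZE}]")
    if len(sequence) < word_size:
        raise InputError(
            f"sequence of length {len(sequence)} shorter than word size {word_size}"
        )
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(codes, word_size)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(word_size - 1, -1, -1, dtype=np.int64)
    return (windows[valid] * powers).sum(axis=1)


def decode_word(index: int, word_size: int) -> str:
    letters = []
    for _ in range(word_size):
        letters.append("ACGT"[index % 4])
        index //= 4
    return "".join(reversed(letters))


def extract_words(sequence: str, word_size: int = 8) -> List[str]:
    """All overlapping unambiguous words of ``sequence``, order preserved."""
    return [decode_word(int(i), word_size) for i in encode_words(sequence, word_size)]


@dataclass
class ScoredRead:
    """A classified read: lineage, likelihood scores, bootstrap confidences."""

    read_id: str
    genus_id: int
    #: rank -> taxon id in the classifier's training tree
    assigned_lineage: Dict[str, int]
    #: kingdom..genus names of the assignment (tree-independent key)
    assigned_path: Tuple[str, ...]
    #: joint natural-log score of the best genus over distinct words
    log_likelihood: float
    #: log_likelihood / number of distinct valid words (length-comparable)
    norm_log_likelihood: float
    #: rank -> bootstrap confidence in [0, 1]; empty if not computed
    bootstrap: Dict[str, float] = field(default_factory=dict)

    def detector_score(self, score_kind: str, rank: str) -> float:
        if score_kind == "likelihood":
            return self.norm_log_likelihood
        if score_kind == "bootstrap":
            try:
                return self.bootstrap[rank]
            except KeyError:
                raise InputError(
                    f"read {self.read_id!r} has no bootstrap confidence at rank {rank!r}"
                ) from None
        raise InputError(f"unknown score kind {score_kind!r}")


class WordNaiveBayesClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style word naive Bayes classifier over genus labels.

    Parameters
    ----------
    word_size : int, default 8
        Length of the overlapping words the model is built on.
    bootstrap_trials : int, default 100
        Number of resampling trials per query.
    bootstrap_fraction : float, default 0.125
        Fraction of the query's word occurrences drawn per trial.
    bootstrap_fixed_words : int or None
        If set, each trial draws exactly this many words regardless of read
        length (read must supply at least twice as many valid words).
    bootstrap_replace : bool, default False
        Whether trial words are drawn with replacement.
    random_state : int, default 0
        Seed for the bootstrap resampler.

    Fitted attributes
    -----------------
    classes_ : ndarray of genus labels, in first-appearance order.
    class_count_ : ndarray, training sequences per genus.
    word_prior_ : ndarray of shape (4**word_size,), smoothed corpus priors.
    feature_counts_ : sparse matrix (n_classes, 4**word_size) of per-genus
        sequence-presence counts.
    taxonomy_ : TaxonomyTree or None, set when fitted from a ReferenceDB.
    """

    def __init__(
        self,
        word_size: int = 8,
        bootstrap_trials: int = 100,
        bootstrap_fraction: float = 0.125,
        bootstrap_fixed_words: Optional[int] = None,
        bootstrap_replace: bool = False,
        random_state: int = 0,
    ):
        self.word_size = word_size
        self.bootstrap_trials = bootstrap_trials
        self.bootstrap_fraction = bootstrap_fraction
        self.bootstrap_fixed_words = bootstrap_fixed_words
        self.bootstrap_replace = bootstrap_replace
        self.random_state = random_state

    # ------------------------------------------------------------------- fit
    def _validate_params_(self) -> None:
        if not (1 <= self.word_size <= MAX_WORD_SIZE):
            raise ConfigurationError(f"word_size must be in [1, {MAX_WORD_SIZE}]")
        if self.bootstrap_trials < 1:
            raise ConfigurationError("bootstrap_trials must be >= 1")
        if not (0.0 < self.bootstrap_fraction <= 1.0):
            raise ConfigurationError("bootstrap_fraction must be in (0, 1]")
        if self.bootstrap_fixed_words is not None and self.bootstrap_fixed_words < 1:
            raise ConfigurationError("bootstrap_fixed_words must be >= 1 when set")

    def fit(self, X: Sequence[str], y: Sequence) -> "WordNaiveBayesClassifier":
        """Fit on sequences ``X`` with genus labels ``y``.

        Labels keep first-appearance order (not sorted): downstream tie-breaks
        are defined by reference insertion order.
        """
        self._validate_params_()
        X = list(X)
        y = list(y)
        if len(X) != len(y):
            raise InputError(f"X and y length mismatch: {len(X)} vs {len(y)}")
        if not X:
            raise EmptyDatabaseError("cannot fit on an empty training set")
        class_index: Dict = {}
        for label in y:
            class_index.setdefault(label, len(class_index))
        n_classes = len(class_index)
        n_words = 4 ** self.word_size

        doc_freq = np.zeros(n_words, dtype=np.int64)
        rows: List[np.ndarray] = []
        cols: List[np.ndarray] = []
        class_count = np.zeros(n_classes, dtype=np.int64)
        for seq, label in zip(X, y):
            ci = class_index[label]
            class_count[ci] += 1
            distinct = np.unique(encode_words(seq, self.word_size))
            if distinct.size == 0:
                raise InputError("training sequence yields no valid words")
            doc_freq[distinct] += 1
            rows.append(np.full(distinct.size, ci, dtype=np.int64))
            cols.append(distinct)
        n_seqs = len(X)
        data = np.ones(sum(c.size for c in cols), dtype=np.float64)
        counts = sparse.coo_matrix(
            (data, (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_classes, n_words),
        ).tocsc()

        self.classes_ = np.asarray(list(class_index), dtype=object)
        self.class_count_ = class_count
        self.word_prior_ = (doc_freq + 0.5) / (n_seqs + 1.0)
        self.feature_counts_ = counts
        self.n_train_sequences_ = n_seqs
        self.taxonomy_: Optional[TaxonomyTree] = None
        self._lineage_cache: Dict[int, Dict[str, int]] = {}
        return self

    def fit_reference_db(self, db: ReferenceDB) -> "WordNaiveBayesClassifier":
        """Fit from a ReferenceDB, attaching its taxonomy for lineage lookup."""
        if len(db) == 0:
            raise EmptyDatabaseError("reference database has no sequences")
        self.fit([s.sequence for s in db.sequences], [s.genus_id for s in db.sequences])
        self.taxonomy_ = db.tree
        return self

    # --------------------------------------------------------------- scoring
    def _check_fitted(self) -> None:
        if not hasattr(self, "feature_counts_"):
            raise InputError("classifier is not fitted")

    def _class_log_scores(self, distinct_words: np.ndarray) -> np.ndarray:
        """Joint log score of each genus over the given distinct word indices."""
        m = np.asarray(self.feature_counts_[:, distinct_words].todense())
        p = (m + self.word_prior_[distinct_words][None, :]) / (
            self.class_count_[:, None] + 1.0
        )
        return np.log(p).sum(axis=1)

    def _distinct_words(self, sequence: str) -> np.ndarray:
        words = encode_words(sequence, self.word_size)
        if words.size == 0:
            raise NoValidWordsError("query contains no unambiguous words")
        return np.unique(words)

    def decision_function(self, X: Sequence[str]) -> np.ndarray:
        """Per-class joint log scores, shape (n_queries, n_classes)."""
        self._check_fitted()
        return np.vstack([self._class_log_scores(self._distinct_words(x)) for x in X])

    def predict(self, X: Sequence[str]) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def _lineage_of(self, genus_id: int) -> Dict[str, int]:
        if genus_id not in self._lineage_cache:
            assert self.taxonomy_ is not None
            self._lineage_cache[genus_id] = self.taxonomy_.lineage_ids(genus_id)
        return self._lineage_cache[genus_id]

    def classify(self, sequence: str, read_id: str = "query") -> ScoredRead:
        """Assign a single read; bootstrap field left empty."""
        self._check_fitted()
        distinct = self._distinct_words(sequence)
        scores = self._class_log_scores(distinct)
        best = int(np.argmax(scores))  # first max wins -> model-order tie-break
        genus = self.classes_[best]
        if self.taxonomy_ is not None:
            lineage = dict(self._lineage_of(genus))
            path = self.taxonomy_.genus_name_lineage(genus)
        else:
            lineage = {"genus": genus}
            path = (str(genus),)
        loglik = float(scores[best])
        return ScoredRead(
            read_id=read_id,
            genus_id=genus,
            assigned_lineage=lineage,
            assigned_path=path,
            log_likelihood=loglik,
            norm_log_likelihood=loglik / distinct.size,
        )

    def likelihood_score(self, sequence: str) -> float:
        """Length-normalised best-genus log score (detector score)."""
        return self.classify(sequence).norm_log_likelihood

    # ------------------------------------------------------------- bootstrap
    def _trial_words(self, occurrences: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        W = occurrences.size
        if self.bootstrap_fixed_words is not None:
            k = self.bootstrap_fixed_words
            if W < 2 * k:
                raise TooShortReadError(
                    f"fixed-word bootstrap needs >= {2 * k} valid words, got {W}"
                )
        else:
            if W < 8:
                raise TooShortReadError(
                    f"bootstrap needs >= 8 valid words, got {W}"
                )
            k = int(np.ceil(W * self.bootstrap_fraction))
        idx = rng.choice(W, size=k, replace=self.bootstrap_replace)
        return np.unique(occurrences[idx])

    def bootstrap_confidence(
        self,
        sequence: str,
        seed: Optional[int] = None,
        full_genus=None,
    ) -> Dict[str, float]:
        """Per-rank agreement fraction of resampled classifications.

        ``full_genus`` (the full-query assignment) is recomputed when not
        supplied.  Deterministic for a given seed (defaults to
        ``random_state``).
        """
        self._check_fitted()
        occurrences = encode_words(sequence, self.word_size)
        if occurrences.size == 0:
            raise NoValidWordsError("query contains no unambiguous words")
        if full_genus is None:
            full_genus = self.classify(sequence).genus_id
        rng = np.random.default_rng(self.random_state if seed is None else seed)
        trial_hits = np.zeros(len(RANKS), dtype=np.int64)
        if self.taxonomy_ is not None:
            full_anc = {r: self.taxonomy_.ancestor_at(full_genus, r) for r in RANKS}
        for _ in range(self.bootstrap_trials):
            distinct = self._trial_words(occurrences, rng)
            g = self.classes_[int(np.argmax(self._class_log_scores(distinct)))]
            if self.taxonomy_ is not None:
                for i, r in enumerate(RANKS):
                    if self.taxonomy_.ancestor_at(g, r) == full_anc[r]:
                        trial_hits[i] += 1
            elif g == full_genus:
                trial_hits += 1
        conf = trial_hits / self.bootstrap_trials
        if self.taxonomy_ is not None:
            return {r: float(conf[i]) for i, r in enumerate(RANKS)}
        return {"genus": float(conf[RANKS.index("genus")])}

    # ----------------------------------------------------------------- batch
    def score_reads(
        self,
        reads: Iterable,
        with_bootstrap: bool = True,
    ) -> Tuple[List[ScoredRead], List[str]]:
        """Classify a batch of reads (objects with .read_id/.sequence or
        (id, sequence) pairs).

        Returns (scored, unclassifiable_ids); reads with no valid words are
        reported rather than raised, and per-read bootstrap seeds are spawned
        deterministically from ``random_state``.
        """
        self._check_fitted()
        items: List[Tuple[str, str]] = []
        for r in reads:
            if hasattr(r, "read_id"):
                items.append((r.read_id, r.sequence))
            else:
                items.append((r[0], r[1]))
        seeds = np.random.SeedSequence(self.random_state).generate_state(
            max(len(items), 1)
        ) % (2**31)
        scored: List[ScoredRead] = []
        skipped: List[str] = []
        for (rid, seq), s in zip(items, seeds):
            try:
                sr = self.classify(seq, read_id=rid)
                if with_bootstrap:
                    sr.bootstrap = self.bootstrap_confidence(
                        seq, seed=int(s), full_genus=sr.genus_id
                    )
            except (NoValidWordsError, TooShortReadError):
                skipped.append(rid)
                continue
            scored.append(sr)
        return scored, skipped


# ------------------------------------------------------- module-level wrappers

def train_model(db: ReferenceDB, **params) -> WordNaiveBayesClassifier:
    """Train a classifier on a reference database (thin estimator wrapper)."""
    return WordNaiveBayesClassifier(**params).fit_reference_db(db)


def classify(read: str, model: WordNaiveBayesClassifier, read_id: str = "query") -> ScoredRead:
    return model.classify(read, read_id=read_id)


def bootstrap_confidence(
    read: str, model: WordNaiveBayesClassifier, seed: Optional[int] = None
) -> Dict[str, float]:
    return model.bootstrap_confidence(read, seed=seed)


def likelihood_score(read: str, model: WordNaiveBayesClassifier) -> float:
    return model.likelihood_score(read)
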