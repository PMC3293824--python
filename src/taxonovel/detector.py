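"""Open-set novelty detection: threshold training, ROC, f-measure.

The detector is a single score cutoff: a read whose score (bootstrap
confidence at a rank, or length-normalised log likelihood) is at or above the
threshold is called *known*, below it *novel*.  Low scores indicate novelty.

Training follows a half-fold + 5-fold design: a random half of the reference
sequences is the detector-training half; its genera are partitioned into five
near-equal groups; fold *i* trains the classifier on group *i* only (so reads
from the other 4/5 of genera are novel to it), scores reads simulated from the
whole training half, builds an ROC, and picks the threshold maximising the
f-measure (harmonic mean of sensitivity and specificity).  The final
threshold is the unweighted mean over the five folds.  The held-out half is
reserved for testing.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .classifier import ScoredRead, WordNaiveBayesClassifier
from .errors import (
    ConfigurationError,
    DegenerateScoresError,
    InputError,
)
from .readsim import KNOWN, NOVEL, fragment_sequences, label_reads
from .reference import ReferenceDB
from .taxonomy import RANK_INDEX

#: reads simulated per sequence at the standard read lengths
DEFAULT_READS_PER_SEQ = {100: 5, 250: 2, 500: 2}


def reads_per_seq_for(L: int) -> int:
    return DEFAULT_READS_PER_SEQ.get(L, max(1, round(500 / L)))


# ------------------------------------------------------------------ split plan

@dataclass(frozen=True)
class SplitPlan:
    """Half split plus 5-fold known/novel genus partitions of the train half."""

    train_half: Tuple[str, ...]
    test_half: Tuple[str, ...]
    #: list of (known_genera, novel_genera) frozensets partitioning the
    #: training-half genera
    folds: Tuple[Tuple[frozenset, frozenset], ...]
    rng_seed: int
    rank: str = "genus"


def make_split_plan(
    db: ReferenceDB, rng_seed: int, n_folds: int = 5, rank: str = "genus"
) -> SplitPlan:
    """Random half split by sequence, then an n-fold genus partition.

    The half split is *not* stratified by genus, so some genera fall entirely
    into the test half and become genuinely novel test taxa.  For detectors at
    ranks above genus, the fold partition groups genera by their ancestor at
    ``rank`` so a fold's known set never splits a higher taxon.
    """
    if rank not in RANK_INDEX:
        raise ConfigurationError(f"unknown rank {rank!r}")
    rng = np.random.default_rng(rng_seed)
    ids = np.array(db.seq_ids, dtype=object)
    perm = rng.permutation(len(ids))
    half = len(ids) // 2
    train_half = tuple(ids[perm[:half]])
    test_half = tuple(ids[perm[half:]])

    train_genera: Dict[int, None] = {}
    for sid in train_half:
        train_genera.setdefault(db.sequence(sid).genus_id, None)
    genera = list(train_genera)
    # group genera by their ancestor at the stratification rank
    groups: Dict[int, List[int]] = {}
    for g in genera:
        anc = db.tree.ancestor_at(g, rank)
        groups.setdefault(anc, []).append(g)
    group_keys = list(groups)
    if len(group_keys) < n_folds:
        raise ConfigurationError(
            f"training half has only {len(group_keys)} taxa at rank {rank!r}; "
            f"need >= {n_folds} for {n_folds}-fold detector training"
        )
    order = rng.permutation(len(group_keys))
    folds_known: List[List[int]] = [[] for _ in range(n_folds)]
    for i, gi in enumerate(order):
        folds_known[i % n_folds].extend(groups[group_keys[gi]])
    all_genera = frozenset(genera)
    folds = tuple(
        (frozenset(k), all_genera - frozenset(k)) for k in folds_known
    )
    return SplitPlan(train_half, test_half, folds, rng_seed, rank)


# ------------------------------------------------------------------------- ROC

@dataclass(frozen=True)
class RocCurve:
    """ROC points sorted by FPR, with thresholds and trapezoidal AUC.

    The decision rule is ``score >= threshold => known``; the (0, 0) endpoint
    carries threshold +inf and the sweep visits every distinct score.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    @property
    def points(self) -> List[Tuple[float, float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist(), self.thresholds.tolist()))


def _as_bool_known(label) -> bool:
    if isinstance(label, str):
        if label == KNOWN:
            return True
        if label == NOVEL:
            return False
        raise InputError(f"label must be 'known' or 'novel', got {label!r}")
    return bool(label)


def roc_from_scores(scores: Iterable[Tuple[float, object]]) -> RocCurve:
    """Build an ROC curve from (score, known/novel-label) pairs."""
    pairs = [(float(s), _as_bool_known(lab)) for s, lab in scores]
    if not pairs:
        raise InputError("empty score set")
    y = np.array([p[1] for p in pairs], dtype=bool)
    s = np.array([p[0] for p in pairs], dtype=float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateScoresError(
            f"need both classes to build an ROC (known={n_pos}, novel={n_neg})"
        )
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # cumulative counts at each position, collapsed to the last index of each
    # distinct score (threshold = that score; rule score >= t)
    distinct_last = np.nonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])[0]
    cum_tp = np.cumsum(y_sorted)[distinct_last]
    cum_fp = np.cumsum(~y_sorted)[distinct_last]
    tpr = np.r_[0.0, cum_tp / n_pos]
    fpr = np.r_[0.0, cum_fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct_last]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def f_measure(sensitivity: float, specificity: float) -> float:
    """Harmonic mean of sensitivity and specificity (0 when both are 0)."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not (0.0 <= v <= 1.0):
            raise InputError(f"{name} must be in [0, 1], got {v}")
    if sensitivity == 0.0 and specificity == 0.0:
        return 0.0
    return 2.0 * sensitivity * specificity / (sensitivity + specificity)


def select_threshold(roc: RocCurve) -> float:
    """Threshold maximising f_measure(TPR, 1-FPR); ties -> smallest threshold.

    Only actual distinct scores qualify (the +inf all-novel endpoint never
    does).  Favouring the smaller threshold among ties avoids losing further
    sensitivity, as the bootstrap detector is already conservative.
    """
    best_f = -1.0
    best_t = None
    for fpr, tpr, t in zip(roc.fpr, roc.tpr, roc.thresholds):
        if not math.isfinite(t):
            continue
        f = f_measure(tpr, 1.0 - fpr)
        if f > best_f or (f == best_f and t < best_t):
            best_f, best_t = f, t
    assert best_t is not None
    return float(best_t)


# ------------------------------------------------------------------- detector

@dataclass
class DetectorThreshold:
    """A trained per-(rank, read length) cutoff with its provenance."""

    rank: str
    read_length: int
    score_kind: str  # "bootstrap" | "likelihood"
    threshold: float
    fold_thresholds: List[float]
    rng_seed: int
    config_hash: str

    def to_json(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "rank": self.rank,
                    "read_length": self.read_length,
                    "score_kind": self.score_kind,
                    "threshold": self.threshold,
                    "fold_thresholds": self.fold_thresholds,
                    "rng_seed": self.rng_seed,
                    "config_hash": self.config_hash,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: Path | str) -> "DetectorThreshold":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


class NoveltyDetector(BaseEstimator, ClassifierMixin):
    """Single-shot threshold fit on (scores, known/novel labels).

    ``fit`` builds the ROC and selects the f-measure-maximising cutoff;
    ``predict`` applies ``score >= threshold_ => known``.  The fold-averaged
    training protocol lives in :func:`train_detector`, which composes five of
    these fits.
    """

    def __init__(self) -> None:
        pass

    def fit(self, X: Sequence[float], y: Sequence) -> "NoveltyDetector":
        self.roc_ = roc_from_scores(zip(np.asarray(X, dtype=float), y))
        self.threshold_ = select_threshold(self.roc_)
        return self

    def predict(self, X: Sequence[float]) -> np.ndarray:
        if not hasattr(self, "threshold_"):
            raise InputError("detector is not fitted")
        X = np.asarray(X, dtype=float)
        return np.where(X >= self.threshold_, KNOWN, NOVEL)


def _config_hash(params: Mapping) -> str:
    blob = json.dumps({k: params[k] for k in sorted(params)}, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def train_detector(
    db: ReferenceDB,
    plan: SplitPlan,
    rank: str,
    read_length: int,
    score_kind: str = "bootstrap",
    reads_per_seq: Optional[int] = None,
    classifier_params: Optional[Mapping] = None,
) -> DetectorThreshold:
    """Train the fold-averaged novelty threshold for one (rank, read length).

    For each of the plan's folds: fit the classifier on the fold's known
    sequences, simulate reads from the whole training half, score them
    (bootstrap confidence at ``rank`` or normalised log likelihood), label
    them known/novel at ``rank`` against the fold's known taxa, build an ROC
    and select the f-measure-optimal threshold.  The returned threshold is
    the mean of the five fold thresholds.
    """
    if score_kind not in ("bootstrap", "likelihood"):
        raise ConfigurationError(f"unknown score kind {score_kind!r}")
    params = dict(classifier_params or {})
    if reads_per_seq is None:
        reads_per_seq = reads_per_seq_for(read_length)
    train_seqs = [db.sequence(sid) for sid in plan.train_half]
    fold_seeds = np.random.SeedSequence(plan.rng_seed).generate_state(
        2 * len(plan.folds)
    ) % (2**31)
    fold_thresholds: List[float] = []
    for i, (known_genera, _novel) in enumerate(plan.folds):
        known_ids = [s.seq_id for s in train_seqs if s.genus_id in known_genera]
        fold_db = db.subset(known_ids)
        clf = WordNaiveBayesClassifier(
            **params, random_state=int(fold_seeds[2 * i])
        ).fit_reference_db(fold_db)
        reads = fragment_sequences(
            train_seqs, read_length, reads_per_seq, int(fold_seeds[2 * i + 1])
        )
        labeled = label_reads(reads, fold_db, db.tree)
        scored, _ = clf.score_reads(reads, with_bootstrap=score_kind == "bootstrap")
        by_id = {sr.read_id: sr for sr in scored}
        pairs = [
            (by_id[lr.read.read_id].detector_score(score_kind, rank), lr.label_at_rank[rank])
            for lr in labeled
            if lr.read.read_id in by_id
        ]
        try:
            roc = roc_from_scores(pairs)
        except DegenerateScoresError as exc:
            raise DegenerateScoresError(f"fold {i}: {exc}") from exc
        fold_thresholds.append(select_threshold(roc))
    return DetectorThreshold(
        rank=rank,
        read_length=read_length,
        score_kind=score_kind,
        threshold=float(np.mean(fold_thresholds)),
        fold_thresholds=fold_thresholds,
        rng_seed=plan.rng_seed,
        config_hash=_config_hash({**params, "reads_per_seq": reads_per_seq}),
    )


def apply_detector(
    scored: Iterable[ScoredRead], det: DetectorThreshold
) -> Dict[str, str]:
    """read_id -> known/novel call under the trained threshold."""
    calls: Dict[str, str] = {}
    for sr in scored:
        s = sr.detector_score(det.score_kind, det.rank)
        calls[sr.read_id] = KNOWN if s >= det.threshold else NOVEL
    return calls


def apply_threshold(
    scores: Mapping[str, float], det: DetectorThreshold
) -> Dict[str, str]:
    """Threshold an external (read_id -> score) table the same way."""
    return {
        rid: (KNOWN if float(s) >= det.threshold else NOVEL)
        for rid, s in scores.items()
    }
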