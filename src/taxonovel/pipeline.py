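"""End-to-end half-fold experiment: split, train detector, evaluate on the
held-out half.

This wires the modules into the standard workflow: a random half of the
reference sequences trains the detector threshold (via the 5-fold known/novel
design), the classifier is then retrained on the whole training half, reads
simulated from the *test* half are scored and labelled known/novel relative
to the training half, the trained threshold is applied, and confusion
metrics, ROC/AUC and known-read assignment accuracy are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional

import numpy as np

from .classifier import ScoredRead, WordNaiveBayesClassifier
from .detector import (
    DetectorThreshold,
    RocCurve,
    SplitPlan,
    apply_detector,
    make_split_plan,
    reads_per_seq_for,
    roc_from_scores,
    train_detector,
)
from .errors import ConfigurationError, UndefinedMetricError
from .evaluation import EvalReport, assignment_accuracy
from .readsim import KNOWN, LabeledRead, fragment_sequences, label_reads
from .reference import ReferenceDB
from .taxonomy import RANK_INDEX


@dataclass
class BenchmarkResult:
    """Everything produced by one half-fold experiment."""

    report: EvalReport
    detector: DetectorThreshold
    roc: RocCurve
    plan: SplitPlan
    scored: List[ScoredRead]
    labels: Dict[str, str]
    calls: Dict[str, str]


def _rebalance(
    labeled: List[LabeledRead],
    rank: str,
    known_fraction: float,
    rng: np.random.Generator,
) -> List[LabeledRead]:
    """Subsample the majority side to reach the requested known-read mix."""
    known = [lr for lr in labeled if lr.label_at_rank[rank] == KNOWN]
    novel = [lr for lr in labeled if lr.label_at_rank[rank] != KNOWN]
    if not known or not novel:
        return labeled
    # target n_known / (n_known + n_novel) = known_fraction
    want_known = known_fraction * len(novel) / (1.0 - known_fraction)
    if len(known) > want_known:
        keep = max(1, int(round(want_known)))
        idx = rng.choice(len(known), size=keep, replace=False)
        known = [known[i] for i in sorted(idx)]
    else:
        want_novel = len(known) * (1.0 - known_fraction) / known_fraction
        keep = max(1, min(len(novel), int(round(want_novel))))
        idx = rng.choice(len(novel), size=keep, replace=False)
        novel = [novel[i] for i in sorted(idx)]
    return known + novel


def half_fold_experiment(
    db: ReferenceDB,
    rank: str = "genus",
    read_length: int = 500,
    score_kind: str = "bootstrap",
    seed: int = 0,
    reads_per_seq: Optional[int] = None,
    known_read_fraction: Optional[float] = None,
    classifier_params: Optional[Mapping] = None,
    n_folds: int = 5,
) -> BenchmarkResult:
    """Run the full detector development + testing workflow on one database.

    ``known_read_fraction`` optionally subsamples the test reads to a target
    known/novel mix (e.g. 0.2 to emulate a diverse environmental sample);
    ``None`` keeps whatever mix the random half split produced.
    """
    if rank not in RANK_INDEX:
        raise ConfigurationError(f"unknown rank {rank!r}")
    if reads_per_seq is None:
        reads_per_seq = reads_per_seq_for(read_length)
    params = dict(classifier_params or {})

    ss = np.random.SeedSequence(seed)
    s_plan, s_reads, s_clf, s_mix = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4))

    plan = make_split_plan(db, s_plan, n_folds=n_folds, rank=rank)
    det = train_detector(
        db, plan, rank, read_length, score_kind,
        reads_per_seq=reads_per_seq, classifier_params=params,
    )

    # test phase: classifier trained on the whole training half
    train_db = db.subset(plan.train_half)
    clf = WordNaiveBayesClassifier(**params, random_state=s_clf).fit_reference_db(train_db)
    test_seqs = [db.sequence(sid) for sid in plan.test_half]
    reads = fragment_sequences(test_seqs, read_length, reads_per_seq, s_reads)
    labeled = label_reads(reads, train_db, db.tree)
    if known_read_fraction is not None:
        labeled = _rebalance(
            labeled, rank, known_read_fraction, np.random.default_rng(s_mix)
        )
    kept_reads = [lr.read for lr in labeled]
    scored, skipped = clf.score_reads(kept_reads, with_bootstrap=score_kind == "bootstrap")
    labels = {
        lr.read.read_id: lr.label_at_rank[rank]
        for lr in labeled
        if lr.read.read_id not in set(skipped)
    }
    roc = roc_from_scores(
        (sr.detector_score(score_kind, rank), labels[sr.read_id]) for sr in scored
    )
    calls = apply_detector(scored, det)

    truth = {
        lr.read.read_id: db.tree.genus_name_lineage(lr.read.source_genus_id)
        for lr in labeled
    }
    training_paths = train_db.tree.name_paths_at_rank(rank)
    known_scored = [sr for sr in scored if labels[sr.read_id] == KNOWN]
    try:
        acc = assignment_accuracy(known_scored, truth, rank, training_paths)
    except UndefinedMetricError:
        acc = None

    report = EvalReport.build(
        rank=rank,
        read_length=read_length,
        score_kind=score_kind,
        calls=calls,
        labels=labels,
        auc=roc.auc,
        assignment_accuracy=acc,
        threshold=det.threshold,
    )
    return BenchmarkResult(
        report=report, detector=det, roc=roc, plan=plan,
        scored=scored, labels=labels, calls=calls,
    )
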