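"""Confusion metrics, assignment accuracy, and database-growth correlation.

Positive class = *known* throughout: sensitivity = TP/(TP+FN) is the fraction
of known-origin reads called known; specificity = TN/(TN+FP) is the fraction
of novel-origin reads called novel.  Metrics with an empty denominator class
are reported as absent (None), never coerced to 0 — phylum-level test sets can
contain almost no novel reads.

The defection analysis correlates, per taxon, the novelty fraction predicted
by the detector under a half-size database (x = 1 - passed/assigned) with the
relative drop in reads the taxon retains once the full database is used
(y = (half - full)/half).  Reads from truly novel organisms should "defect"
to better-matching taxa added by the database growth, so a working detector
yields a positive Pearson correlation, strongest for abundant taxa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .classifier import ScoredRead
from .detector import f_measure
from .errors import InputError, UndefinedMetricError
from .readsim import KNOWN, NOVEL
from .taxonomy import RANK_INDEX


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n_known(self) -> int:
        return self.tp + self.fn

    @property
    def n_novel(self) -> int:
        return self.tn + self.fp


def confusion(calls: Mapping[str, str], labels: Mapping[str, str]) -> ConfusionCounts:
    """Tally TP/FN/TN/FP over identical read key sets (positive = known)."""
    if set(calls) != set(labels):
        missing = set(labels) ^ set(calls)
        raise InputError(f"calls and labels key mismatch ({len(missing)} differing ids)")
    tp = fn = tn = fp = 0
    for rid, lab in labels.items():
        call = calls[rid]
        if lab == KNOWN:
            if call == KNOWN:
                tp += 1
            else:
                fn += 1
        elif lab == NOVEL:
            if call == NOVEL:
                tn += 1
            else:
                fp += 1
        else:
            raise InputError(f"label must be known/novel, got {lab!r}")
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def metrics(c: ConfusionCounts) -> Tuple[float, float, float]:
    """(sensitivity, specificity, f_measure); raises if either class is empty."""
    if c.n_known == 0:
        raise UndefinedMetricError("no known-labelled reads: sensitivity undefined")
    if c.n_novel == 0:
        raise UndefinedMetricError("no novel-labelled reads: specificity undefined")
    sens = c.tp / c.n_known
    spec = c.tn / c.n_novel
    return sens, spec, f_measure(sens, spec)


def assignment_accuracy(
    scored: Iterable[ScoredRead],
    truth: Mapping[str, Tuple[str, ...]],
    rank: str,
    training_paths: Optional[set] = None,
) -> float:
    """Fraction of correctly assigned reads at ``rank``, known reads only.

    ``truth`` maps read_id -> the read's true kingdom..genus name lineage;
    ``training_paths`` (name paths at ``rank`` present in the training set)
    restricts evaluation to reads whose true taxon is actually trainable —
    accuracy is undefined for novel reads.
    """
    if rank not in RANK_INDEX:
        raise InputError(f"unknown rank {rank!r}")
    depth = RANK_INDEX[rank] + 1
    n = correct = 0
    for sr in scored:
        if sr.read_id not in truth:
            raise InputError(f"no truth lineage for read {sr.read_id!r}")
        true_path = tuple(truth[sr.read_id])[:depth]
        if training_paths is not None and true_path not in training_paths:
            continue
        n += 1
        if tuple(sr.assigned_path[:depth]) == true_path:
            correct += 1
    if n == 0:
        raise UndefinedMetricError(f"no eligible known reads at rank {rank!r}")
    return correct / n


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation with domain validation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise InputError("need at least 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


# --------------------------------------------------------------- eval report

@dataclass
class EvalReport:
    """Per-(rank, read length) detector evaluation summary."""

    rank: str
    read_length: int
    score_kind: str
    counts: ConfusionCounts
    sensitivity: Optional[float]
    specificity: Optional[float]
    f_measure: Optional[float]
    auc: Optional[float] = None
    assignment_accuracy: Optional[float] = None
    threshold: Optional[float] = None

    @classmethod
    def build(
        cls,
        rank: str,
        read_length: int,
        score_kind: str,
        calls: Mapping[str, str],
        labels: Mapping[str, str],
        auc: Optional[float] = None,
        assignment_accuracy: Optional[float] = None,
        threshold: Optional[float] = None,
    ) -> "EvalReport":
        c = confusion(calls, labels)
        sens = c.tp / c.n_known if c.n_known else None
        spec = c.tn / c.n_novel if c.n_novel else None
        f = f_measure(sens, spec) if sens is not None and spec is not None else None
        return cls(
            rank=rank,
            read_length=read_length,
            score_kind=score_kind,
            counts=c,
            sensitivity=sens,
            specificity=spec,
            f_measure=f,
            auc=auc,
            assignment_accuracy=assignment_accuracy,
            threshold=threshold,
        )

    def known_fraction(self) -> float:
        total = self.counts.n_known + self.counts.n_novel
        if total == 0:
            raise UndefinedMetricError("empty report")
        return self.counts.n_known / total

    def novel_pool_fraction(self) -> float:
        """Fraction of reads passed on to the candidate-novel pool.

        With known fraction k and sensitivity s, the detector removes k*s of
        the reads (known and called known), leaving 1 - k*s for downstream
        novelty analysis — the search-space-reduction identity.
        """
        if self.sensitivity is None:
            raise UndefinedMetricError("sensitivity undefined: no known reads")
        return 1.0 - self.known_fraction() * self.sensitivity

    def to_dict(self) -> Dict:
        return {
            "rank": self.rank,
            "read_length": self.read_length,
            "score_kind": self.score_kind,
            "tp": self.counts.tp,
            "fn": self.counts.fn,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f_measure": self.f_measure,
            "auc": self.auc,
            "assignment_accuracy": self.assignment_accuracy,
            "threshold": self.threshold,
        }

    def to_json(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ------------------------------------------------------- defection correlation

@dataclass(frozen=True)
class TaxonAbundanceRecord:
    """Per-taxon read counts under half DB, half DB + detector, and full DB."""

    taxon_id: str
    rank: str
    n_half: int
    n_passed: int
    n_full: int

    def __post_init__(self):
        if not (0 <= self.n_passed <= self.n_half):
            raise InputError(
                f"{self.taxon_id}: n_passed={self.n_passed} outside [0, n_half={self.n_half}]"
            )


#: abundance floors mirroring the over-50/over-100/over-500 stratification
DEFAULT_ABUNDANCE_FLOORS = (0, 50, 100, 500)


def defection_correlation(
    records: Iterable[TaxonAbundanceRecord],
    min_abundance: int = 0,
    include_vanished: bool = True,
) -> Tuple[float, int]:
    """Pearson r between predicted novelty fraction and observed relative drop.

    x = 1 - n_passed/n_half (detector's predicted novel fraction) against
    y = (n_half - n_full)/n_half (relative decrease under the full database),
    over taxa with n_half >= min_abundance.  Negative decreases (taxa that
    grow) are retained; taxa absent from the full-database output (n_full=0,
    y=1) are included unless ``include_vanished`` is False.  Returns (r, n).
    """
    xs: List[float] = []
    ys: List[float] = []
    n_eligible = 0
    for rec in records:
        if rec.n_half < min_abundance or rec.n_half == 0:
            continue
        if rec.n_full == 0 and not include_vanished:
            continue
        n_eligible += 1
        xs.append(1.0 - rec.n_passed / rec.n_half)
        ys.append((rec.n_half - rec.n_full) / rec.n_half)
    if n_eligible < 3:
        raise InputError(
            f"only {n_eligible} taxa with n_half >= {min_abundance}; need >= 3"
        )
    return pearson(xs, ys), n_eligible


def read_abundance_tsv(path: Path | str) -> List[TaxonAbundanceRecord]:
    """TSV with header taxon_id, rank, n_half, n_passed, n_full."""
    out: List[TaxonAbundanceRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["taxon_id", "rank", "n_half", "n_passed", "n_full"]
        if header != expected:
            raise InputError(f"{path}: expected header {expected}, got {header}")
        for line in fh:
            if not line.strip():
                continue
            tid, rank, h, p, f = line.rstrip("\n").split("\t")
            out.append(TaxonAbundanceRecord(tid, rank, int(h), int(p), int(f)))
    return out
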