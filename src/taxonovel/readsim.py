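"""Fixed-length read simulation and known/novel labelling.

Reads are error-free windows drawn at uniformly random start positions from
reference sequences (random placement avoids frame artifacts; no sequencing
error or quality model is applied).  Each read is labelled ``known`` or
``novel`` at every rank relative to a training database: known at rank *r*
iff the read's true taxon at *r* has at least one representative in the
training set.  Novelty is nested — novel at family implies novel at genus —
which the name-path membership test guarantees by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import numpy as np

from .errors import EmptyDatabaseError, InputError, LinkageError
from .reference import ReferenceDB, ReferenceSequence
from .taxonomy import RANKS, TaxonomyTree

logger = logging.getLogger(__name__)

_AMBIGUOUS = set("ACGT")

KNOWN = "known"
NOVEL = "novel"


@dataclass(frozen=True)
class Read:
    """A simulated read with provenance back to its source sequence."""

    read_id: str
    sequence: str
    source_seq_id: str
    source_genus_id: int
    start: int


@dataclass(frozen=True)
class LabeledRead:
    read: Read
    #: rank -> "known" | "novel"
    label_at_rank: Dict[str, str]


def _ambiguous_fraction(seq: str) -> float:
    return sum(1 for c in seq if c not in _AMBIGUOUS) / len(seq)


def fragment_sequences(
    seqs: Iterable[ReferenceSequence],
    L: int,
    reads_per_seq: int,
    rng_seed: int,
    max_ambiguous_frac: float = 0.2,
    max_retries: int = 5,
) -> List[Read]:
    """Draw ``reads_per_seq`` random L-bp windows from each eligible sequence.

    Sequences shorter than L are skipped (count logged).  Windows with more
    than ``max_ambiguous_frac`` ambiguity codes are redrawn up to
    ``max_retries`` times, then skipped.
    """
    if L < 1:
        raise InputError("read length must be >= 1")
    if reads_per_seq < 1:
        raise InputError("reads_per_seq must be >= 1")
    rng = np.random.default_rng(rng_seed)
    reads: List[Read] = []
    n_short = 0
    for s in seqs:
        if len(s.sequence) < L:
            n_short += 1
            continue
        top = len(s.sequence) - L  # inclusive upper bound for start
        for i in range(reads_per_seq):
            window = None
            for _ in range(max_retries + 1):
                start = int(rng.integers(0, top + 1))
                cand = s.sequence[start : start + L]
                if _ambiguous_fraction(cand) <= max_ambiguous_frac:
                    window = (start, cand)
                    break
            if window is None:
                continue
            start, seq = window
            reads.append(
                Read(
                    read_id=f"{s.seq_id}_r{i}",
                    sequence=seq,
                    source_seq_id=s.seq_id,
                    source_genus_id=s.genus_id,
                    start=start,
                )
            )
    if n_short:
        logger.info("fragment_sequences: skipped %d sequences shorter than %d bp", n_short, L)
    if not reads:
        raise EmptyDatabaseError(f"no sequence eligible for {L} bp reads")
    return reads


def label_reads(
    reads: Iterable[Read],
    training_db: ReferenceDB,
    full_tree: TaxonomyTree,
) -> List[LabeledRead]:
    """Label each read known/novel at every rank relative to ``training_db``.

    Taxa are matched by their kingdom..rank name path, so the training
    database need not share taxon ids with ``full_tree``.
    """
    present = {r: training_db.tree.name_paths_at_rank(r) for r in RANKS}
    out: List[LabeledRead] = []
    for read in reads:
        if read.source_genus_id not in full_tree:
            raise LinkageError(
                f"read {read.read_id!r} references genus {read.source_genus_id} "
                "absent from the full tree"
            )
        path = full_tree.genus_name_lineage(read.source_genus_id)
        labels: Dict[str, str] = {}
        for i, rank in enumerate(RANKS):
            labels[rank] = KNOWN if path[: i + 1] in present[rank] else NOVEL
        out.append(LabeledRead(read=read, label_at_rank=labels))
    return out


# ------------------------------------------------------------------------ I/O

def write_reads_fasta(reads: Sequence[Read], path: Path | str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(
                f">{r.read_id} source={r.source_seq_id} "
                f"genus={r.source_genus_id} start={r.start}\n{r.sequence}\n"
            )


def write_labels_tsv(labeled: Sequence[LabeledRead], path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\t" + "\t".join(RANKS) + "\n")
        for lr in labeled:
            fh.write(
                lr.read.read_id
                + "\t"
                + "\t".join(lr.label_at_rank[r] for r in RANKS)
                + "\n"
            )


def read_labels_tsv(path: Path | str) -> Dict[str, Dict[str, str]]:
    """read_id -> {rank: label} from the TSV written by write_labels_tsv."""
    out: Dict[str, Dict[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "read_id":
            raise InputError(f"{path}: not a label table (header {header!r})")
        ranks = header[1:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            out[parts[0]] = dict(zip(ranks, parts[1:]))
    return out
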