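"""Reference 16S collections: parsing, validation, filtering, serialisation.

File dialects
-------------
* FASTA with lineage-bearing headers: ``>seqid<TAB>Root;phylum;...;genus``.
  The six ';'-separated fields map onto kingdom..genus (the leading ``Root``
  token occupies the kingdom slot, as in RDP-style training FASTA).  Empty
  fields are filled with ``<child>_incertae_sedis`` placeholders.
* Taxonomy file, one node per line: ``taxid*name*parentid*depth*rank``
  (the RDP trainset convention).  The root sentinel line uses rank
  ``rootrank``.
* Cluster tables: two-column TSV ``seq_id<TAB>cluster_id`` (the post-processed
  form of CD-HIT ``.clstr`` output).

Sequences are uppercased on load and U is mapped to T (rRNA convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import EmptyDatabaseError, FormatError, LinkageError
from .taxonomy import RANKS, ROOT_ID, ROOT_PARENT, TaxonomyTree, fill_placeholders

_TRANS = str.maketrans({"u": "T", "U": "T"})


def normalize_sequence(seq: str) -> str:
    return seq.translate(_TRANS).upper()


@dataclass(frozen=True)
class ReferenceSequence:
    """A reference 16S sequence attached to a genus node."""

    seq_id: str
    sequence: str
    genus_id: int


class ReferenceDB:
    """A taxonomy tree plus the reference sequences hanging off its genera."""

    def __init__(self, tree: TaxonomyTree, sequences: Iterable[ReferenceSequence]):
        self.tree = tree
        self.sequences: List[ReferenceSequence] = []
        self._by_id: Dict[str, ReferenceSequence] = {}
        for rec in sequences:
            self.add_sequence(rec)

    def add_sequence(self, rec: ReferenceSequence) -> None:
        if rec.seq_id in self._by_id:
            raise FormatError(f"duplicate sequence id {rec.seq_id!r}")
        node = self.tree.node(rec.genus_id)  # raises LinkageError if absent
        if node.rank != "genus":
            raise LinkageError(
                f"sequence {rec.seq_id!r} references taxon {rec.genus_id} "
                f"at rank {node.rank!r}, not a genus"
            )
        self.sequences.append(rec)
        self._by_id[rec.seq_id] = rec

    # ------------------------------------------------------------------ access
    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def sequence(self, seq_id: str) -> ReferenceSequence:
        try:
            return self._by_id[seq_id]
        except KeyError:
            raise LinkageError(f"unknown sequence id {seq_id!r}") from None

    @property
    def seq_ids(self) -> List[str]:
        return [s.seq_id for s in self.sequences]

    def genus_sizes(self) -> Dict[int, int]:
        """Number of sequences per genus (genera with 0 are not listed)."""
        sizes: Dict[int, int] = {}
        for s in self.sequences:
            sizes[s.genus_id] = sizes.get(s.genus_id, 0) + 1
        return sizes

    def genera(self) -> List[int]:
        """Genus ids that own at least one sequence, in first-seen order."""
        seen: Dict[int, None] = {}
        for s in self.sequences:
            seen.setdefault(s.genus_id, None)
        return list(seen)

    def rank_counts(self) -> Dict[str, int]:
        return self.tree.rank_counts()

    def subset(self, seq_ids: Iterable[str]) -> "ReferenceDB":
        """Restrict to the given sequences; prune taxa left without sequences."""
        wanted = [self.sequence(sid) for sid in seq_ids]
        if not wanted:
            raise EmptyDatabaseError("subset selects no sequences")
        tree = self.tree.pruned_to({s.genus_id for s in wanted})
        return ReferenceDB(tree, wanted)


@dataclass
class ClusterTable:
    """Externally computed sequence -> similarity-cluster assignment."""

    assignments: Dict[str, str] = field(default_factory=dict)

    def cluster_of(self, seq_id: str) -> str:
        try:
            return self.assignments[seq_id]
        except KeyError:
            raise LinkageError(f"no cluster assignment for sequence {seq_id!r}") from None


# --------------------------------------------------------------------- parsing

def _parse_lineage(text: str) -> List[str]:
    parts = [p.strip() for p in text.split(";")]
    if len(parts) == len(RANKS) + 1 and parts[0].lower() == "root":
        parts = parts[1:]
    if len(parts) != len(RANKS):
        raise FormatError(
            f"lineage {text!r} must have {len(RANKS)} fields (kingdom..genus)"
        )
    return fill_placeholders(parts)


def _lineage_from_description(description: str) -> str:
    # header is ">seqid<TAB>lineage"; Biopython folds the tab into description
    fields = description.split(None, 1)
    if len(fields) < 2 or ";" not in fields[1]:
        raise FormatError(f"header {description!r} carries no ';'-separated lineage")
    return fields[1].strip()


def read_taxonomy_file(path: Path | str) -> TaxonomyTree:
    """Parse the ``taxid*name*parentid*depth*rank`` dialect into a tree."""
    tree = TaxonomyTree()
    rows: List[Tuple[int, str, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("*")
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 '*'-fields, got {len(parts)}")
            taxid_s, name, parent_s, _depth, rank = parts
            try:
                taxid, parent = int(taxid_s), int(parent_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer taxon/parent id") from exc
            if rank == "rootrank":
                if taxid != ROOT_ID or parent != ROOT_PARENT:
                    raise FormatError(f"{path}:{lineno}: root line must be '0*...*-1*0*rootrank'")
                continue
            if rank not in RANKS:
                raise FormatError(f"{path}:{lineno}: unknown rank label {rank!r}")
            rows.append((taxid, name, parent, rank))
    # parents may appear after children in the file; insert in rank order
    order = {r: i for i, r in enumerate(RANKS)}
    for taxid, name, parent, rank in sorted(rows, key=lambda r: order[r[3]]):
        tree.add_node(name, rank, parent, taxon_id=taxid)
    return tree


def load_reference_db(
    fasta_path: Path | str, taxonomy_path: Optional[Path | str] = None
) -> ReferenceDB:
    """Load a reference collection from FASTA (+ optional taxonomy file).

    With a taxonomy file, header lineages must resolve against it (a missing
    node is a linkage error).  Without one, the tree is grown from the header
    lineages themselves.
    """
    if taxonomy_path is not None:
        tree = read_taxonomy_file(taxonomy_path)
    else:
        tree = TaxonomyTree()
    sequences: List[ReferenceSequence] = []
    seen: Set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {fasta_path}")
        seen.add(rec.id)
        names = _parse_lineage(_lineage_from_description(rec.description))
        if taxonomy_path is not None:
            parent = ROOT_ID
            for rank, name in zip(RANKS, names):
                nid = tree.find_child(parent, rank, name)  # resolve, never create
                if nid is None:
                    raise LinkageError(
                        f"sequence {rec.id!r}: taxon {name!r} at rank {rank!r} "
                        f"not present in {taxonomy_path}"
                    )
                parent = nid
            genus_id = parent
        else:
            genus_id = tree.add_lineage(names)
        sequences.append(
            ReferenceSequence(rec.id, normalize_sequence(str(rec.seq)), genus_id)
        )
    if not sequences:
        raise EmptyDatabaseError(f"no sequences in {fasta_path}")
    return ReferenceDB(tree, sequences)


def write_reference_db(
    db: ReferenceDB, fasta_path: Path | str, taxonomy_path: Optional[Path | str] = None
) -> None:
    """Write FASTA (+ taxonomy file) in the dialects read by this module."""
    records = []
    for s in db.sequences:
        lineage = ";".join(db.tree.genus_name_lineage(s.genus_id))
        records.append(
            SeqRecord(Seq(s.sequence), id=s.seq_id, description=lineage)
        )
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\t{rec.description}\n{rec.seq}\n")
    if taxonomy_path is not None:
        with open(taxonomy_path, "w") as fh:
            fh.write(f"{ROOT_ID}*Root*{ROOT_PARENT}*0*rootrank\n")
            for depth, rank in enumerate(RANKS, start=1):
                for tid in db.tree.taxa_at_rank(rank):
                    n = db.tree.node(tid)
                    fh.write(f"{n.taxon_id}*{n.name}*{n.parent_id}*{depth}*{n.rank}\n")


def read_cluster_table(path: Path | str) -> ClusterTable:
    table = ClusterTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            table.assignments[parts[0]] = parts[1]
    return table


# -------------------------------------------------------------------- filters

def filter_well_represented(db: ReferenceDB, min_seqs: int) -> ReferenceDB:
    """Keep only genera with at least ``min_seqs`` sequences.

    The "well-represented genera" filter: poorly sampled genera (half of real
    reference sets are singletons) are the main source of misassignment, and
    restricting training to genera with >= 10 sequences markedly improves
    detector sensitivity.
    """
    if min_seqs < 1:
        raise FormatError("min_seqs must be >= 1")
    sizes = db.genus_sizes()
    keep = {g for g, n in sizes.items() if n >= min_seqs}
    if not keep:
        raise EmptyDatabaseError(
            f"no genus has >= {min_seqs} sequences; filter empties the database"
        )
    return db.subset([s.seq_id for s in db.sequences if s.genus_id in keep])


def filter_by_cluster_count(
    db: ReferenceDB, clusters: ClusterTable, max_clusters: int
) -> ReferenceDB:
    """Keep genera whose sequences span <= ``max_clusters`` similarity clusters."""
    if max_clusters < 1:
        raise FormatError("max_clusters must be >= 1")
    per_genus: Dict[int, Set[str]] = {}
    for s in db.sequences:
        per_genus.setdefault(s.genus_id, set()).add(clusters.cluster_of(s.seq_id))
    keep = {g for g, cl in per_genus.items() if len(cl) <= max_clusters}
    if not keep:
        raise EmptyDatabaseError("cluster-count filter empties the database")
    return db.subset([s.seq_id for s in db.sequences if s.genus_id in keep])
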