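"""Rank-labelled taxonomy trees (kingdom -> genus).

The tree is rooted at a sentinel node (id 0).  Every path from the root to a
genus visits exactly the six canonical ranks in order, so each reference
sequence carries a complete lineage.  Nodes are identified by small integer
ids; names are unique within a (parent, rank) pair, which makes the tuple of
names from kingdom down to a node a globally unique key — used to compare taxa
across independently constructed trees (e.g. a training subset vs. the full
database).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

from .errors import FormatError, LinkageError

#: Canonical ranks from coarsest to finest.
RANKS: Tuple[str, ...] = ("kingdom", "phylum", "class", "order", "family", "genus")
RANK_INDEX: Dict[str, int] = {r: i for i, r in enumerate(RANKS)}

ROOT_ID = 0
ROOT_PARENT = -1

#: Suffix used for placeholder nodes filling unlabelled intermediate ranks.
PLACEHOLDER_SUFFIX = "_incertae_sedis"


def fill_placeholders(names: Sequence[str]) -> List[str]:
    """Replace empty lineage fields with ``<child>_incertae_sedis`` placeholders.

    ``names`` must have one entry per canonical rank; the placeholder name is
    derived from the nearest labelled descendant so it is deterministic.
    """
    if len(names) != len(RANKS):
        raise FormatError(
            f"lineage must have {len(RANKS)} fields (kingdom..genus), "
            f"got {len(names)}: {names!r}"
        )
    filled = list(names)
    for i in range(len(filled) - 1, -1, -1):
        if not filled[i]:
            child = next((filled[j] for j in range(i + 1, len(filled)) if filled[j]), None)
            if child is None:
                raise FormatError(f"lineage {names!r} has no labelled genus")
            filled[i] = child + PLACEHOLDER_SUFFIX
    return filled


@dataclass(frozen=True)
class TaxonNode:
    """A single taxon: id, name, rank and parent id."""

    taxon_id: int
    name: str
    rank: str
    parent_id: int


class TaxonomyTree:
    """Mutable rooted taxonomy with per-rank node indexing."""

    def __init__(self) -> None:
        self._nodes: Dict[int, TaxonNode] = {}
        # (parent_id, rank, name) -> taxon_id ; enforces name uniqueness per parent
        self._key: Dict[Tuple[int, str, str], int] = {}
        # insertion-ordered ids per rank
        self._by_rank: Dict[str, List[int]] = {r: [] for r in RANKS}
        self._next_id = 1

    # ------------------------------------------------------------------ basics
    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, taxon_id: int) -> TaxonNode:
        try:
            return self._nodes[taxon_id]
        except KeyError:
            raise LinkageError(f"unknown taxon id {taxon_id}") from None

    def name(self, taxon_id: int) -> str:
        return self.node(taxon_id).name

    def taxa_at_rank(self, rank: str) -> List[int]:
        """Taxon ids at ``rank`` in insertion order."""
        self._check_rank(rank)
        return list(self._by_rank[rank])

    def rank_counts(self) -> Dict[str, int]:
        return {r: len(ids) for r, ids in self._by_rank.items()}

    @staticmethod
    def _check_rank(rank: str) -> None:
        if rank not in RANK_INDEX:
            raise FormatError(f"unknown rank label {rank!r}; expected one of {RANKS}")

    # ------------------------------------------------------------ construction
    def add_node(
        self, name: str, rank: str, parent_id: int, taxon_id: int | None = None
    ) -> int:
        """Add (or retrieve) a node; idempotent on (parent, rank, name).

        The parent must sit at the immediately coarser rank (or be the root
        for a kingdom node), so rank order along any path is enforced at
        insertion time.
        """
        self._check_rank(rank)
        ridx = RANK_INDEX[rank]
        if ridx == 0:
            if parent_id != ROOT_ID:
                raise FormatError("kingdom nodes must attach to the root sentinel")
        else:
            parent = self.node(parent_id)
            if RANK_INDEX[parent.rank] != ridx - 1:
                raise FormatError(
                    f"node {name!r} at rank {rank!r} cannot attach to parent "
                    f"{parent.name!r} at rank {parent.rank!r}"
                )
        key = (parent_id, rank, name)
        if key in self._key:
            existing = self._key[key]
            if taxon_id is not None and taxon_id != existing:
                raise FormatError(
                    f"duplicate taxon {name!r} under parent {parent_id} with "
                    f"conflicting ids {existing} and {taxon_id}"
                )
            return existing
        if taxon_id is None:
            taxon_id = self._next_id
        if taxon_id in self._nodes:
            raise FormatError(f"duplicate taxon id {taxon_id}")
        self._next_id = max(self._next_id, taxon_id) + 1
        self._nodes[taxon_id] = TaxonNode(taxon_id, name, rank, parent_id)
        self._key[key] = taxon_id
        self._by_rank[rank].append(taxon_id)
        return taxon_id

    def add_lineage(self, names: Sequence[str]) -> int:
        """Insert a full kingdom..genus lineage; return the genus id.

        ``names`` has one entry per canonical rank.  Empty entries are filled
        with a ``<child>_incertae_sedis`` placeholder derived from the nearest
        labelled descendant, so every sequence ends up with a complete 6-rank
        lineage.
        """
        filled = fill_placeholders(names)
        parent = ROOT_ID
        for rank, name in zip(RANKS, filled):
            parent = self.add_node(name, rank, parent)
        return parent

    # ------------------------------------------------------------------ lookup
    def find_child(self, parent_id: int, rank: str, name: str) -> int | None:
        """Id of the child of ``parent_id`` with this rank and name, or None."""
        return self._key.get((parent_id, rank, name))

    def ancestor_at(self, taxon_id: int, rank: str) -> int:
        """Id of the ancestor of ``taxon_id`` at ``rank`` (may be itself)."""
        self._check_rank(rank)
        node = self.node(taxon_id)
        target = RANK_INDEX[rank]
        while RANK_INDEX[node.rank] > target:
            node = self.node(node.parent_id)
        if RANK_INDEX[node.rank] != target:
            raise LinkageError(
                f"taxon {taxon_id} at rank {node.rank!r} has no ancestor at {rank!r}"
            )
        return node.taxon_id

    def lineage_ids(self, genus_id: int) -> Dict[str, int]:
        """Map rank -> taxon id along the path root..genus."""
        node = self.node(genus_id)
        if node.rank != "genus":
            raise LinkageError(f"taxon {genus_id} is a {node.rank}, not a genus")
        out: Dict[str, int] = {}
        while node.parent_id != ROOT_PARENT:
            out[node.rank] = node.taxon_id
            if node.parent_id == ROOT_ID:
                break
            node = self.node(node.parent_id)
        return out

    def name_path(self, taxon_id: int) -> Tuple[str, ...]:
        """Names from kingdom down to ``taxon_id`` — a tree-independent key."""
        names: List[str] = []
        node = self.node(taxon_id)
        while True:
            names.append(node.name)
            if node.parent_id == ROOT_ID:
                break
            node = self.node(node.parent_id)
        return tuple(reversed(names))

    def name_paths_at_rank(self, rank: str) -> set:
        return {self.name_path(t) for t in self.taxa_at_rank(rank)}

    def genus_name_lineage(self, genus_id: int) -> Tuple[str, ...]:
        """Kingdom..genus names for a genus (length 6)."""
        path = self.name_path(genus_id)
        if len(path) != len(RANKS):
            raise LinkageError(f"incomplete lineage for genus {genus_id}: {path!r}")
        return path

    # ----------------------------------------------------------------- pruning
    def pruned_to(self, genus_ids: Iterable[int]) -> "TaxonomyTree":
        """New tree containing only the given genera and their ancestors.

        Taxon ids are preserved, so membership checks by id remain valid
        between the original tree and the pruned copy.
        """
        keep: set = set()
        for g in genus_ids:
            node = self.node(g)
            while True:
                keep.add(node.taxon_id)
                if node.parent_id == ROOT_ID:
                    break
                node = self.node(node.parent_id)
        out = TaxonomyTree()
        for rank in RANKS:
            for tid in self._by_rank[rank]:
                if tid in keep:
                    n = self._nodes[tid]
                    out.add_node(n.name, n.rank, n.parent_id, taxon_id=tid)
        return out
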