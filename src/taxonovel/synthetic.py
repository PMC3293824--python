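"""Synthetic taxonomies, divergence-structured sequences, and benchmarks.

The generator emulates the structure of a 16S reference collection without
any download: a six-rank taxonomy, per-rank sequence divergence (one random
root ancestral sequence, i.i.d. substitutions applied down each rank edge —
the phylum edge is near-saturating by default, so phyla are almost mutually
random; substitution-only, no indels, so read windows stay aligned), and the
heavily imbalanced genus-size distribution of real reference sets (about half
the genera are singletons, with a geometric heavy tail capped at 50, so a few
genera are very well represented).

It deliberately does *not* mimic real 16S base composition, the conserved /
variable region architecture, or chimeras; what it preserves is the
*hierarchical divergence structure* that the classifier and detector exploit.

Presets
-------
``SynthConfig.easy()``
    Strong structure: sister genera ~15% diverged per genus edge, ~1%
    within-genus divergence.  Known and novel reads are well separated, so a
    correct detector implementation should approach perfect discrimination.
``SynthConfig.null()``
    Zero divergence everywhere — every sequence identical, so scores carry no
    information and any discrimination metric must sit at chance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError
from .evaluation import TaxonAbundanceRecord
from .readsim import LabeledRead, Read, label_reads
from .reference import ReferenceDB, ReferenceSequence
from .taxonomy import RANKS, ROOT_ID, TaxonomyTree

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: ranks that have their own edge divergence below the root ancestor
_EDGE_RANKS = ("phylum", "class", "order", "family", "genus")


@dataclass
class SynthConfig:
    """Study conditions for one synthetic benchmark."""

    n_kingdoms: int = 1
    n_phyla: int = 3
    n_classes: int = 4
    n_orders: int = 5
    n_families: int = 8
    n_genera: int = 20

    #: P(genus has exactly one sequence) — the imbalance of real references
    singleton_fraction: float = 0.5
    #: geometric tail parameter for multi-sequence genera
    tail_geom_p: float = 0.35
    max_seqs_per_genus: int = 50

    seq_length: int = 1200

    #: substitution probability applied when descending each rank edge, plus
    #: the per-sequence ("intra-genus") rate
    divergence: Dict[str, float] = field(
        default_factory=lambda: {
            "phylum": 0.35,
            "class": 0.10,
            "order": 0.08,
            "family": 0.06,
            "genus": 0.08,
            "sequence": 0.02,
        }
    )

    #: fraction of taxa withheld from the reference at each rank (nested)
    novel_fraction_per_rank: Dict[str, float] = field(
        default_factory=lambda: {
            "phylum": 0.0,
            "class": 0.0,
            "order": 0.0,
            "family": 0.1,
            "genus": 0.3,
        }
    )

    #: benchmark read set
    read_length: int = 250
    n_reads: int = 500
    known_read_fraction: float = 0.2

    rng_seed: int = 0

    def __post_init__(self):
        counts = [
            self.n_kingdoms,
            self.n_phyla,
            self.n_classes,
            self.n_orders,
            self.n_families,
            self.n_genera,
        ]
        if any(c < 1 for c in counts):
            raise ConfigurationError("all per-rank counts must be >= 1")
        for parent, child in zip(counts, counts[1:]):
            if child < parent:
                raise ConfigurationError(
                    f"infeasible taxonomy: child count {child} < parent count {parent}"
                )
        for rank, d in self.divergence.items():
            if rank not in _EDGE_RANKS + ("sequence",):
                raise ConfigurationError(f"unknown divergence key {rank!r}")
            if not (0.0 <= d < 0.5):
                raise ConfigurationError(f"divergence[{rank!r}]={d} outside [0, 0.5)")
        for rank, f in self.novel_fraction_per_rank.items():
            if not (0.0 <= f < 1.0):
                raise ConfigurationError(f"novel fraction at {rank!r} outside [0, 1)")
        if not (0.0 < self.known_read_fraction < 1.0):
            raise ConfigurationError("known_read_fraction must be in (0, 1)")

    def rank_count(self, rank: str) -> int:
        return {
            "kingdom": self.n_kingdoms,
            "phylum": self.n_phyla,
            "class": self.n_classes,
            "order": self.n_orders,
            "family": self.n_families,
            "genus": self.n_genera,
        }[rank]

    # ------------------------------------------------------------- presets
    @classmethod
    def easy(cls, rng_seed: int = 0, read_length: int = 500) -> "SynthConfig":
        """Strong divergence structure (20 genera, 15% genus edges, 1% intra)."""
        return cls(
            divergence={
                "phylum": 0.35,
                "class": 0.10,
                "order": 0.08,
                "family": 0.06,
                "genus": 0.15,
                "sequence": 0.01,
            },
            read_length=read_length,
            rng_seed=rng_seed,
        )

    @classmethod
    def null(cls, rng_seed: int = 0, read_length: int = 500) -> "SynthConfig":
        """No divergence structure: all sequences identical, scores uninformative."""
        return cls(
            divergence={r: 0.0 for r in _EDGE_RANKS + ("sequence",)},
            read_length=read_length,
            rng_seed=rng_seed,
        )


@dataclass
class SynthManifest:
    """Everything needed to recompute downstream known/novel labels."""

    config: Dict
    rank_counts: Dict[str, int]
    #: rank -> list of name paths designated novel (withheld from reference)
    novel_taxa: Dict[str, List[List[str]]]
    #: seq_id -> kingdom..genus name lineage
    sequence_lineages: Dict[str, List[str]]
    rng_seed: int

    def to_json(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: Path | str) -> "SynthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


# ----------------------------------------------------------------- generation

def generate_taxonomy(config: SynthConfig, rng: Optional[np.random.Generator] = None) -> TaxonomyTree:
    """Random tree with exactly the requested per-rank node counts.

    Every parent receives at least one child; remaining children attach to
    uniformly random parents.  Deterministic under the config seed.
    """
    rng = rng or np.random.default_rng(config.rng_seed)
    tree = TaxonomyTree()
    prefix = {"kingdom": "K", "phylum": "P", "class": "C", "order": "O", "family": "F", "genus": "G"}
    prev: List[int] = [ROOT_ID]
    for rank in RANKS:
        n = config.rank_count(rank)
        if rank == "kingdom":
            parents = [ROOT_ID] * n
        else:
            if n < len(prev):
                raise ConfigurationError(
                    f"{rank}: {n} children for {len(prev)} parents"
                )
            # one child per parent, extras uniformly random
            extra = rng.integers(0, len(prev), size=n - len(prev))
            parents = list(prev) + [prev[i] for i in extra]
        ids = [
            tree.add_node(f"{prefix[rank]}{i + 1}", rank, parent)
            for i, parent in enumerate(parents)
        ]
        prev = ids
    return tree


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position with probability ``rate`` (to a random other base)."""
    if rate <= 0.0:
        return seq.copy()
    hit = rng.random(seq.size) < rate
    out = seq.copy()
    # shift by 1..3 in base space guarantees a different base
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def generate_sequences(
    tree: TaxonomyTree,
    config: SynthConfig,
    rng: Optional[np.random.Generator] = None,
) -> ReferenceDB:
    """Evolve sequences down the tree and emit per-genus reference sets."""
    rng = rng or np.random.default_rng(config.rng_seed + 1)
    div = config.divergence
    seqs: List[ReferenceSequence] = []

    # single root ancestral state; kingdoms share it (they carry no edge rate)
    root = rng.integers(0, 4, size=config.seq_length).astype(np.int8)
    node_seq: Dict[int, np.ndarray] = {
        kid: root for kid in tree.taxa_at_rank("kingdom")
    }
    for rank in _EDGE_RANKS:
        rate = div.get(rank, 0.0)
        for tid in tree.taxa_at_rank(rank):
            parent = tree.node(tid).parent_id
            node_seq[tid] = _mutate(node_seq[parent], rate, rng)
    intra = div.get("sequence", 0.0)
    for gid in tree.taxa_at_rank("genus"):
        gname = tree.name(gid)
        if rng.random() < config.singleton_fraction:
            n = 1
        else:
            n = min(1 + int(rng.geometric(config.tail_geom_p)), config.max_seqs_per_genus)
        for i in range(n):
            arr = _mutate(node_seq[gid], intra, rng)
            seqs.append(
                ReferenceSequence(
                    seq_id=f"{gname}_s{i + 1}",
                    sequence=_BASES[arr].tobytes().decode("ascii"),
                    genus_id=gid,
                )
            )
    return ReferenceDB(tree, seqs)


def generate_synthetic_db(config: SynthConfig) -> ReferenceDB:
    """Taxonomy + sequences in one call, fully determined by the config seed."""
    ss = np.random.SeedSequence(config.rng_seed)
    r_tree, r_seq = (np.random.default_rng(s) for s in ss.spawn(2))
    tree = generate_taxonomy(config, r_tree)
    return generate_sequences(tree, config, r_seq)


# ------------------------------------------------------------------ benchmark

def _designate_novel(
    tree: TaxonomyTree, config: SynthConfig, rng: np.random.Generator
) -> Dict[str, set]:
    """Pick the taxa withheld from the reference, nested top-down."""
    novel: Dict[str, set] = {r: set() for r in RANKS}
    for i, rank in enumerate(RANKS):
        frac = config.novel_fraction_per_rank.get(rank, 0.0)
        taxa = tree.taxa_at_rank(rank)
        inherited = set()
        if i > 0:
            parent_novel = novel[RANKS[i - 1]]
            inherited = {t for t in taxa if tree.node(t).parent_id in parent_novel}
        need = int(np.ceil(frac * len(taxa)))
        chosen = set(inherited)
        candidates = [t for t in taxa if t not in chosen]
        if need > len(chosen):
            extra = need - len(chosen)
            if extra > len(candidates):
                raise ConfigurationError(
                    f"cannot withhold {need} taxa at rank {rank!r}: only "
                    f"{len(taxa)} exist"
                )
            chosen |= set(rng.choice(candidates, size=extra, replace=False).tolist())
        novel[rank] = chosen
    if len(novel["genus"]) >= len(tree.taxa_at_rank("genus")):
        raise ConfigurationError("every genus designated novel; no reference left")
    return novel


def _sample_reads(
    pool: Sequence[ReferenceSequence],
    n: int,
    L: int,
    rng: np.random.Generator,
    tag: str,
) -> List[Read]:
    eligible = [s for s in pool if len(s.sequence) >= L]
    if not eligible and n > 0:
        raise ConfigurationError(f"no {tag} sequence long enough for {L} bp reads")
    reads = []
    for i in range(n):
        s = eligible[int(rng.integers(0, len(eligible)))]
        start = int(rng.integers(0, len(s.sequence) - L + 1))
        reads.append(
            Read(
                read_id=f"{tag}_{i}",
                sequence=s.sequence[start : start + L],
                source_seq_id=s.seq_id,
                source_genus_id=s.genus_id,
                start=start,
            )
        )
    return reads


def generate_benchmark(
    config: SynthConfig,
) -> Tuple[ReferenceDB, List[Read], List[LabeledRead], SynthManifest]:
    """Reference DB (novel taxa withheld), reads at the configured known/novel
    mix, per-rank labels, and a manifest sufficient to recompute the labels."""
    ss = np.random.SeedSequence(config.rng_seed)
    r_tree, r_seq, r_novel, r_reads = (np.random.default_rng(s) for s in ss.spawn(4))
    tree = generate_taxonomy(config, r_tree)
    full_db = generate_sequences(tree, config, r_seq)
    novel = _designate_novel(tree, config, r_novel)

    known_seqs = [s for s in full_db.sequences if s.genus_id not in novel["genus"]]
    novel_seqs = [s for s in full_db.sequences if s.genus_id in novel["genus"]]
    reference = full_db.subset([s.seq_id for s in known_seqs])

    n_known = int(round(config.n_reads * config.known_read_fraction))
    n_novel = config.n_reads - n_known
    if novel_seqs:
        reads = _sample_reads(known_seqs, n_known, config.read_length, r_reads, "known") + \
            _sample_reads(novel_seqs, n_novel, config.read_length, r_reads, "novel")
    else:
        reads = _sample_reads(known_seqs, config.n_reads, config.read_length, r_reads, "known")
    labeled = label_reads(reads, reference, tree)

    manifest = SynthManifest(
        config={
            **{k: v for k, v in asdict(config).items()},
        },
        rank_counts=tree.rank_counts(),
        novel_taxa={
            r: sorted(list(tree.name_path(t)) for t in novel[r]) for r in RANKS
        },
        sequence_lineages={
            s.seq_id: list(tree.genus_name_lineage(s.genus_id))
            for s in full_db.sequences
        },
        rng_seed=config.rng_seed,
    )
    return reference, reads, labeled, manifest


# ----------------------------------------------------------- defection cohort

def simulate_defection_cohort(
    n_taxa: int = 300,
    seed: int = 0,
    defection_prob: float = 0.8,
    detector_sensitivity: float = 0.95,
    detector_false_pass: float = 0.05,
    rank: str = "genus",
) -> List[TaxonAbundanceRecord]:
    """Simulate per-taxon abundances across a database doubling.

    Each taxon receives a log-normal read abundance under the half database;
    a uniform fraction of those reads are of novel origin.  The detector
    passes known-origin reads with ``detector_sensitivity`` and novel-origin
    reads with ``detector_false_pass``; when the database doubles, each
    novel-origin read defects to a better-matching new taxon with
    ``defection_prob``.  Low-abundance taxa give noisy relative decreases, so
    the predicted/observed correlation strengthens as the abundance floor
    rises.
    """
    rng = np.random.default_rng(seed)
    records: List[TaxonAbundanceRecord] = []
    for i in range(n_taxa):
        n_half = int(np.clip(np.round(rng.lognormal(mean=3.3, sigma=1.2)), 3, 5000))
        p_novel = rng.uniform(0.0, 1.0)
        v = int(rng.binomial(n_half, p_novel))
        k = n_half - v
        n_passed = int(rng.binomial(k, detector_sensitivity) + rng.binomial(v, detector_false_pass))
        n_full = int(k + rng.binomial(v, 1.0 - defection_prob))
        records.append(
            TaxonAbundanceRecord(
                taxon_id=f"T{i}", rank=rank, n_half=n_half,
                n_passed=min(n_passed, n_half), n_full=n_full,
            )
        )
    return records
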