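import numpy as np
import pytest

from taxonovel.reference import ReferenceDB, ReferenceSequence
from taxonovel.synthetic import SynthConfig, generate_synthetic_db
from taxonovel.taxonomy import TaxonomyTree


def make_db(genus_seqs, lineages=None):
    """Small ReferenceDB from {genus_name: [sequences]}.

    ``lineages`` optionally maps genus name -> full 6-name lineage; by default
    every genus gets its own phylum..family chain.
    """
    tree = TaxonomyTree()
    seqs = []
    for gname, sequences in genus_seqs.items():
        if lineages and gname in lineages:
            lineage = lineages[gname]
        else:
            lineage = ["Root", f"P_{gname}", f"C_{gname}", f"O_{gname}", f"F_{gname}", gname]
        gid = tree.add_lineage(lineage)
        for i, s in enumerate(sequences):
            seqs.append(ReferenceSequence(f"{gname}_s{i}", s, gid))
    return ReferenceDB(tree, seqs)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def easy_db():
    """Session-wide easy synthetic database (strong divergence structure)."""
    return generate_synthetic_db(SynthConfig.easy(rng_seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
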