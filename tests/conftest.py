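import numpy as np
import pytest

from rdase_scout.genome_model import GeneFeature, Genome
from rdase_scout.synthetic_data import (
    GenomeSpec, OperonSpec, back_translate, gen_genome,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_genome():
    """Hand-built two-contig genome with three CDS features."""
    # contig1: gene at 101..109 on '+' (MK + stop), gene at 201..209 on '-'
    mk = "ATGAAATAA"
    c1 = ("A" * 100) + mk + ("C" * 91) + _rc(mk) + ("G" * 91)
    c2 = ("T" * 50) + "GTGAAATAA" + ("A" * 41)
    feats = [
        GeneFeature("c1", 101, 109, "+", "g1", "hypothetical protein"),
        GeneFeature("c1", 201, 209, "-", "g2", "hypothetical protein"),
        GeneFeature("c2", 51, 59, "+", "g3", "hypothetical protein"),
    ]
    return Genome("tiny", {"c1": c1, "c2": c2}, feats)


def _rc(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@pytest.fixture(scope="session")
def planted_genome():
    """One deterministic synthetic genome with a rich operon complement."""
    spec = GenomeSpec(
        genome_id="fix",
        operons=[
            OperonSpec(include_tat=True, rdase_b="downstream",
                       bebp="adjacent"),
            OperonSpec(include_tat=False, rdase_b="upstream",
                       bebp="within_window"),
        ],
        n_background=30,
        n_decoys=5,
        seed=7,
    )
    return gen_genome(7, spec)


@pytest.fixture
def protein_genome():
    """Build a single-contig genome from a list of (tag, protein, product)."""

    def build(genes, gap=200):
        seq = ""
        feats = []
        for tag, protein, product in genes:
            seq += "A" * gap
            dna = back_translate(protein)
            feats.append(GeneFeature("c", len(seq) + 1, len(seq) + len(dna),
                                     "+", tag, product, protein))
            seq += dna
        seq += "A" * gap
        return Genome("built", {"c": seq}, feats)

    return build
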