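"""Seeded generators of ground-truth substrates for the screening pipeline.

Three generators are provided:

* annotated genomes with planted reductive-dehalogenase operons (RDase A
  carrying the Tat and Fe-S motifs, the small hydrophobic RDase B, a nearby
  sigma-54-dependent activator gene, and a concrete sigma-54 −24/−12 element
  planted upstream of the operon), plus decoy genes with broken or partial
  motifs and a motif-free gene background;
* sequential first-order debromination kinetics (parent -> mono-bromophenol
  -> phenol) with optional Gaussian measurement noise;
* qPCR runs (standards on an exact line, samples with Cq noise) with a known
  true fold change.

Every generator is deterministic under a fixed numpy seed, and each genome
ships with a truth table naming the planted elements, so screening
sensitivity and precision can be scored exactly. Backgrounds are i.i.d.
uniform with rejection sampling against every registry motif; no attempt is
made to mimic real GC content or codon usage.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from Bio.Data import CodonTable

from .genome_model import (
    Genome, GeneFeature, revcomp, write_genbank, write_gff3_fasta,
)
from .motif_engine import REGISTRY, scan

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"

# deterministic back-translation: lexicographically smallest codon per
# residue under the bacterial code (table 11)
_T11 = CodonTable.unambiguous_dna_by_id[11]
BACK_CODON: dict[str, str] = {}
for codon, aa in sorted(_T11.forward_table.items()):
    BACK_CODON.setdefault(aa, codon)

#: proteins of the motif-free background are kept above the RDase B size
#: gate (130 aa) so the membrane-anchor heuristic can never fire on them
BACKGROUND_LEN = (150, 400)
RDHB_LEN = (70, 110)
BEBP_LEN = (420, 480)

_SAFE_PRODUCTS = (
    "hypothetical protein",
    "ABC transporter ATP-binding protein",
    "DNA polymerase III subunit delta",
    "elongation factor Tu",
    "ribosomal protein L2",
    "aspartate aminotransferase",
    "phosphoglycerate kinase",
)

BEBP_PRODUCT = "sigma-54 dependent transcriptional regulator"
RDHB_PRODUCTS = ("reductive dehalogenase anchoring protein RdhB",
                 "hypothetical protein")
RDASE_A_PRODUCT = "reductive dehalogenase catalytic subunit"


@dataclass
class OperonSpec:
    include_tat: bool = True
    include_fes: str = "both"  # both | long_only | short_only | none
    rdase_b: str = "downstream"  # downstream | upstream | absent
    bebp: str = "adjacent"  # adjacent | within_window | absent
    sigma54_site_offset: int | None = 120  # bp upstream of first gene start
    rdase_length: int = 450

    def __post_init__(self) -> None:
        if self.include_fes not in ("both", "long_only", "short_only",
                                    "none"):
            raise ValueError(f"bad include_fes {self.include_fes!r}")
        if self.rdase_b not in ("downstream", "upstream", "absent"):
            raise ValueError(f"bad rdase_b {self.rdase_b!r}")
        if self.bebp not in ("adjacent", "within_window", "absent"):
            raise ValueError(f"bad bebp {self.bebp!r}")
        if self.sigma54_site_offset is not None:
            if self.sigma54_site_offset < 16:
                raise ValueError("sigma54_site_offset must be >= 16")
        if not 200 <= self.rdase_length <= 800:
            raise ValueError("rdase_length outside generator bounds 200-800")


@dataclass
class GenomeSpec:
    genome_id: str = "synthetic"
    n_contigs: int = 2
    n_background: int = 50
    n_decoys: int = 5
    operons: list[OperonSpec] | None = None  # None -> 1-3 drawn at random
    intergenic_bp: tuple[int, int] = (150, 400)
    operon_gap_bp: tuple[int, int] = (10, 60)
    seed: int = 0


@dataclass
class TruthTable:
    genome_id: str
    operons: list[dict] = field(default_factory=list)
    decoys: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# proteins


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


def _protein_motif_free(protein: str) -> bool:
    return (
        not scan(protein, REGISTRY["tat"])
        and not scan(protein, REGISTRY["fes_long"])
        and not scan(protein, REGISTRY["fes_short"])
        and "GAFTGA" not in protein
    )


def gen_background_protein(rng: np.random.Generator,
                           length: int | None = None) -> str:
    """Motif-free background protein (no Tat, no Fe-S motifs, no GAFTGA)."""
    if length is None:
        length = int(rng.integers(*BACKGROUND_LEN))
    while True:
        p = "M" + _random_protein(rng, length - 1)
        if _protein_motif_free(p):
            return p


def _tat_instance(rng: np.random.Generator) -> str:
    return "RR" + rng.choice(list(_AA20)) + "F" + rng.choice(list(_AA20)) + "K"


def _fes_instance(rng: np.random.Generator, long: bool) -> str:
    x = lambda: rng.choice(list(_AA20))
    if long:
        return "C" + x() + x() + "C" + x() + x() + "C" + x() + x() + x() + "CP"
    return "C" + x() + x() + "C" + x() + x() + x() + "CP"


def gen_rdase_protein(rng: np.random.Generator, spec: OperonSpec) -> str:
    """An RDase A-like protein with the requested motif complement planted.

    Motifs are planted verbatim at non-overlapping positions (Tat inside the
    first 45 residues, Fe-S motifs in the C-terminal half) on a motif-free
    background; the result is re-scanned and resampled until exactly the
    requested motifs are present. Note a planted long Fe-S motif always
    contains a short-motif match (C positions 3/6/10 + P at 11), so
    include_fes='long_only' proteins still carry a short hit.
    """
    L = spec.rdase_length
    while True:
        p = list("M" + _random_protein(rng, L - 1))
        if spec.include_tat:
            off = int(rng.integers(2, 39))
            p[off:off + 6] = _tat_instance(rng)
        half = L // 2
        if spec.include_fes in ("both", "long_only"):
            off_l = int(rng.integers(half, L - 12))
            p[off_l:off_l + 12] = _fes_instance(rng, long=True)
        if spec.include_fes in ("both", "short_only"):
            while True:
                off_s = int(rng.integers(half, L - 9))
                if spec.include_fes != "both" or abs(off_s - off_l) >= 25:
                    break
            p[off_s:off_s + 9] = _fes_instance(rng, long=False)
        protein = "".join(p)

        tat_hits = [h for h in scan(protein, REGISTRY["tat"])
                    if h.offset < 45]
        long_hits = scan(protein, REGISTRY["fes_long"])
        short_hits = scan(protein, REGISTRY["fes_short"])
        if spec.include_tat != bool(tat_hits):
            continue
        if not spec.include_tat and scan(protein, REGISTRY["tat"]):
            continue
        want_long = spec.include_fes in ("both", "long_only")
        want_short = spec.include_fes != "none"  # long implies short
        if spec.include_fes == "short_only" and long_hits:
            continue
        if spec.include_fes == "none" and (long_hits or short_hits):
            continue
        if want_long and not long_hits:
            continue
        if spec.include_fes in ("both", "short_only") and not short_hits:
            continue
        if want_short and not short_hits:
            continue
        if "GAFTGA" in protein:
            continue
        return protein


def gen_rdhb_protein(rng: np.random.Generator) -> str:
    """Small membrane-anchor-like protein: <=130 aa with a hydrophobic core."""
    length = int(rng.integers(*RDHB_LEN))
    core_len = 30
    core_at = int(rng.integers(10, length - core_len - 5))
    while True:
        p = list("M" + _random_protein(rng, length - 1))
        core = rng.choice(list("ILVAF"), size=core_len)
        p[core_at:core_at + core_len] = core
        protein = "".join(p)
        if _protein_motif_free(protein):
            return protein


def gen_bebp_protein(rng: np.random.Generator,
                     plant_gaftga: bool = False) -> str:
    length = int(rng.integers(*BEBP_LEN))
    while True:
        p = list("M" + _random_protein(rng, length - 1))
        if plant_gaftga:
            off = int(rng.integers(length // 3, 2 * length // 3))
            p[off:off + 6] = "GAFTGA"
        protein = "".join(p)
        ok = (not scan(protein, REGISTRY["tat"])
              and not scan(protein, REGISTRY["fes_long"])
              and not scan(protein, REGISTRY["fes_short"]))
        if ok and (plant_gaftga == ("GAFTGA" in protein)):
            return protein


def gen_decoy_protein(rng: np.random.Generator, kind: int) -> tuple[str, str]:
    """Decoy gene content: (protein, product). Never a valid candidate.

    Kinds cycle through: short-Fe-S-only with/without Tat, Tat-only, and
    fully broken motifs. (A long-only decoy is impossible: the long Fe-S
    motif contains a short match.)
    """
    variants = [
        OperonSpec(include_tat=True, include_fes="short_only",
                   rdase_length=int(rng.integers(300, 600))),
        OperonSpec(include_tat=False, include_fes="short_only",
                   rdase_length=int(rng.integers(300, 600))),
        OperonSpec(include_tat=True, include_fes="none",
                   rdase_length=int(rng.integers(300, 600))),
        OperonSpec(include_tat=False, include_fes="none",
                   rdase_length=int(rng.integers(300, 600))),
        OperonSpec(include_tat=False, include_fes="short_only",
                   rdase_length=int(rng.integers(300, 600))),
    ]
    spec = variants[kind % len(variants)]
    return gen_rdase_protein(rng, spec), "putative oxidoreductase"


# ---------------------------------------------------------------------------
# DNA assembly


def back_translate(protein: str) -> str:
    """Deterministic codon choice (first codon per residue, table 11)."""
    return "".join(BACK_CODON[aa] for aa in protein) + "TAA"


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _sigma54_instance(rng: np.random.Generator) -> str:
    y = rng.choice(list("CT"))
    r = rng.choice(list("AG"))
    nnn = _random_dna(rng, 3)
    return y + "TGGCACG" + r + nnn + "TTGC"


@dataclass
class _Segment:
    """A stretch of DNA with locally-placed (1-based, forward) features."""

    seq: str
    feats: list[dict] = field(default_factory=list)
    sites: list[dict] = field(default_factory=list)

    def flip(self) -> "_Segment":
        L = len(self.seq)
        feats = [
            {**f, "start": L - f["end"] + 1, "end": L - f["start"] + 1,
             "strand": "-" if f["strand"] == "+" else "+"}
            for f in self.feats
        ]
        sites = [
            {**s, "start": L - s["end"] + 1, "end": L - s["start"] + 1,
             "strand": "-" if s["strand"] == "+" else "+"}
            for s in self.sites
        ]
        return _Segment(revcomp(self.seq), feats, sites)


def _gene_segment(protein: str, product: str, role: str,
                  op_idx: int | None = None) -> _Segment:
    dna = back_translate(protein)
    return _Segment(dna, [{
        "start": 1, "end": len(dna), "strand": "+", "product": product,
        "translation": protein, "role": role, "op_idx": op_idx,
    }])


def _operon_segment(rng: np.random.Generator, spec: OperonSpec,
                    gap_bp: tuple[int, int],
                    intergenic_bp: tuple[int, int],
                    op_idx: int = 0) -> _Segment:
    """Operon in local forward orientation: promoter pad, genes, activator."""
    parts: list[_Segment] = []

    def _gap(lo: int, hi: int) -> None:
        parts.append(_Segment(_random_dna(rng, int(rng.integers(lo, hi)))))

    a = _gene_segment(gen_rdase_protein(rng, spec), RDASE_A_PRODUCT,
                      "rdase_a", op_idx)
    b = None
    if spec.rdase_b != "absent":
        b = _gene_segment(
            gen_rdhb_protein(rng),
            RDHB_PRODUCTS[int(rng.integers(0, len(RDHB_PRODUCTS)))],
            "rdase_b", op_idx,
        )
    # promoter pad with the sigma-54 element at the stated offset
    extra = int(rng.integers(40, 150))
    if spec.sigma54_site_offset is not None:
        off = spec.sigma54_site_offset
        pad_len = off + extra
        pad = list(_random_dna(rng, pad_len))
        inst = _sigma54_instance(rng)
        pad[pad_len - off:pad_len - off + 16] = inst
        parts.append(_Segment("".join(pad), sites=[{
            "start": pad_len - off + 1, "end": pad_len - off + 16,
            "strand": "+", "matched": inst, "relative_offset": -off,
            "op_idx": op_idx,
        }]))
    else:
        parts.append(_Segment(_random_dna(rng, 120 + extra)))

    if spec.rdase_b == "upstream":
        parts.append(b)
        _gap(*gap_bp)
        parts.append(a)
    else:
        parts.append(a)
        if b is not None:
            _gap(*gap_bp)
            parts.append(b)

    if spec.bebp != "absent":
        bebp = _gene_segment(gen_bebp_protein(rng), BEBP_PRODUCT, "bebp",
                         op_idx)
        n_between = 0 if spec.bebp == "adjacent" else 2
        for _ in range(n_between):
            _gap(*intergenic_bp)
            parts.append(_gene_segment(
                gen_background_protein(rng),
                _SAFE_PRODUCTS[int(rng.integers(0, len(_SAFE_PRODUCTS)))],
                "background"))
        _gap(*intergenic_bp)
        parts.append(bebp)

    seq = ""
    feats: list[dict] = []
    sites: list[dict] = []
    for part in parts:
        off = len(seq)
        seq += part.seq
        for f in part.feats:
            feats.append({**f, "start": f["start"] + off,
                          "end": f["end"] + off})
        for s in part.sites:
            sites.append({**s, "start": s["start"] + off,
                          "end": s["end"] + off})
    return _Segment(seq, feats, sites)


def default_operon_specs(rng: np.random.Generator) -> list[OperonSpec]:
    """1-3 operons spanning the architectures seen in real clusters."""
    archetypes = [
        OperonSpec(include_tat=True, rdase_b="downstream", bebp="adjacent"),
        OperonSpec(include_tat=False, rdase_b="upstream",
                   bebp="within_window"),
        OperonSpec(include_tat=True, rdase_b="downstream",
                   bebp="within_window"),
    ]
    n = int(rng.integers(1, 4))
    out = []
    for i in range(n):
        proto = archetypes[i % len(archetypes)]
        out.append(OperonSpec(
            include_tat=proto.include_tat,
            rdase_b=proto.rdase_b,
            bebp=proto.bebp,
            sigma54_site_offset=120,
            rdase_length=int(rng.integers(350, 551)),
        ))
    return out


def _assemble(rng: np.random.Generator, spec: GenomeSpec
              ) -> tuple[Genome, TruthTable]:
    operon_specs = (spec.operons if spec.operons is not None
                    else default_operon_specs(rng))
    singles: list[_Segment] = []
    for i in range(spec.n_decoys):
        protein, product = gen_decoy_protein(rng, i)
        singles.append(_gene_segment(protein, product, "decoy"))
    for _ in range(spec.n_background):
        singles.append(_gene_segment(
            gen_background_protein(rng),
            _SAFE_PRODUCTS[int(rng.integers(0, len(_SAFE_PRODUCTS)))],
            "background"))
    order = rng.permutation(len(singles))
    singles = [singles[i] for i in order]

    operon_segs = [
        _operon_segment(rng, osp, spec.operon_gap_bp, spec.intergenic_bp,
                        op_idx=i)
        for i, osp in enumerate(operon_specs)
    ]

    # interleave: operon blocks separated by >=5 single-gene units so
    # neighboring clusters never bleed into each other's search windows
    blocks: list[tuple[str, _Segment]] = []
    n_op = len(operon_segs)
    cutpoints = [round((i + 1) * len(singles) / (n_op + 1))
                 for i in range(n_op)]
    si = 0
    for oi, seg in enumerate(operon_segs):
        while si < cutpoints[oi]:
            blocks.append(("single", singles[si]))
            si += 1
        blocks.append(("operon", seg))
    blocks.extend(("single", s) for s in singles[si:])

    # random strand per block
    blocks = [
        (kind, seg.flip() if rng.random() < 0.5 else seg)
        for kind, seg in blocks
    ]

    # split across contigs without separating a block
    n_contigs = max(1, spec.n_contigs)
    per = -(-len(blocks) // n_contigs)
    contig_blocks = [blocks[i * per:(i + 1) * per]
                     for i in range(n_contigs)]
    contig_blocks = [cb for cb in contig_blocks if cb]

    contigs: dict[str, str] = {}
    features: list[GeneFeature] = []
    placed_feats: list[dict] = []
    placed_sites: list[dict] = []
    tag_no = 0
    lo_ig, hi_ig = spec.intergenic_bp
    for ci, cb in enumerate(contig_blocks):
        cid = f"{spec.genome_id}_c{ci + 1}"
        seq = _random_dna(rng, int(rng.integers(lo_ig, hi_ig)))
        for kind, seg in cb:
            off = len(seq)
            seq += seg.seq
            for f in seg.feats:
                placed_feats.append({**f, "contig_id": cid,
                                     "start": f["start"] + off,
                                     "end": f["end"] + off})
            for s in seg.sites:
                placed_sites.append({**s, "contig_id": cid,
                                     "start": s["start"] + off,
                                     "end": s["end"] + off})
            seq += _random_dna(rng, int(rng.integers(lo_ig, hi_ig)))
        contigs[cid] = seq

    # locus tags in coordinate order
    placed_feats.sort(key=lambda f: (f["contig_id"], f["start"]))
    for f in placed_feats:
        tag_no += 1
        f["locus_tag"] = f"{spec.genome_id}_{tag_no:04d}"
        features.append(GeneFeature(
            f["contig_id"], f["start"], f["end"], f["strand"],
            f["locus_tag"], f["product"], f["translation"],
        ))
    genome = Genome(spec.genome_id, contigs, features)

    # truth straight from the planted operon indices
    truth = TruthTable(spec.genome_id)
    truth.decoys = [f["locus_tag"] for f in placed_feats
                    if f["role"] == "decoy"]
    for oi, osp in enumerate(operon_specs):
        mine = [f for f in placed_feats if f.get("op_idx") == oi]
        fa = next(f for f in mine if f["role"] == "rdase_a")
        fb = next((f for f in mine if f["role"] == "rdase_b"), None)
        bebp = sorted(f["locus_tag"] for f in mine if f["role"] == "bebp")
        sites = [s for s in placed_sites if s.get("op_idx") == oi]
        truth.operons.append({
            "rdase_a_locus": fa["locus_tag"],
            "expected_candidate": (
                osp.include_fes in ("both", "long_only")
                and 250 <= osp.rdase_length <= 750),
            "tat_expected": osp.include_tat,
            "rdase_b_class": osp.rdase_b,
            "rdase_b_locus": fb["locus_tag"] if fb else None,
            "bebp_loci": bebp,
            "sigma54_sites": [
                {"contig_id": s["contig_id"], "start": s["start"],
                 "end": s["end"], "strand": s["strand"],
                 "relative_offset": s["relative_offset"],
                 "matched": s["matched"]}
                for s in sorted(sites, key=lambda s: s["start"])
            ],
        })
    truth.operons.sort(key=lambda o: o["rdase_a_locus"])
    return genome, truth


def _genome_is_pure(genome: Genome, truth: TruthTable) -> bool:
    """Verify planted elements are the only registry-motif signals.

    Contig-wide both-strand sigma-54 scans must find exactly the planted
    sites, and no non-planted protein may combine both Fe-S motifs at a
    callable length.
    """
    planted = {
        (s["contig_id"], s["start"], s["strand"])
        for op in truth.operons for s in op["sigma54_sites"]
    }
    found = set()
    for cid, seq in genome.contigs.items():
        for hit in scan(seq, REGISTRY["sigma54_core"], both_strands=True):
            found.add((cid, hit.offset + 1, hit.strand))
    if found != planted:
        return False
    rdase_tags = {op["rdase_a_locus"] for op in truth.operons}
    for f in genome.features:
        if f.locus_tag in rdase_tags:
            continue
        p = f.translation or ""
        if (scan(p, REGISTRY["fes_long"]) and scan(p, REGISTRY["fes_short"])
                and 250 <= len(p) <= 750):
            return False
    return True


def gen_genome(rng_or_seed, spec: GenomeSpec | None = None
               ) -> tuple[Genome, TruthTable]:
    """Generate an annotated genome plus its planted-element truth table.

    Accepts a numpy Generator or an integer seed; with an integer seed the
    output is byte-identical across runs. Assembly is retried (deterministic
    continuation of the stream) in the rare case a random background
    accidentally recreates a registry motif.
    """
    if isinstance(rng_or_seed, (int, np.integer)):
        rng = np.random.default_rng(int(rng_or_seed))
    else:
        rng = rng_or_seed
    spec = spec or GenomeSpec()
    for _ in range(50):
        genome, truth = _assemble(rng, spec)
        if _genome_is_pure(genome, truth):
            return genome, truth
    raise RuntimeError("could not assemble a motif-pure genome in 50 tries")


def write_genome_files(genome: Genome, truth: TruthTable,
                       outdir: str) -> dict[str, str]:
    """Emit GFF3 + FASTA + GenBank + truth-table files; returns paths."""
    os.makedirs(outdir, exist_ok=True)
    base = os.path.join(outdir, genome.genome_id)
    paths = {
        "gff3": base + ".gff3",
        "fasta": base + ".fna",
        "genbank": base + ".gbk",
        "truth": base + ".truth.json",
    }
    write_gff3_fasta(genome, paths["gff3"], paths["fasta"])
    write_genbank(genome, paths["genbank"])
    with open(paths["truth"], "w") as fh:
        json.dump(asdict(truth), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# kinetics and qPCR


def gen_timeseries(
    rng_or_seed,
    k1: float = 0.15,
    k2: float = 0.05,
    c0: float = 200.0,
    times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    parent: str = "2,6-DBP",
    volume_l: float = 0.1,
):
    """Sequential first-order debromination kinetics parent -> 2-BP -> phenol.

    Closed form: parent = c0 e^(-k1 t); intermediate =
    c0 k1/(k2-k1) (e^(-k1 t) - e^(-k2 t)); phenol = c0 - parent -
    intermediate (exact ring conservation before noise). Gaussian noise of
    sd ``noise_sd`` µM is added per point, then clipped at zero.
    """
    from .physiology import DehalTimeSeries

    if isinstance(rng_or_seed, (int, np.integer)):
        rng = np.random.default_rng(int(rng_or_seed))
    else:
        rng = rng_or_seed
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rate constants must be positive")
    if k1 == k2:
        raise ValueError("k1 == k2 degenerate case not supported")
    t = (np.asarray(times, dtype=float) if times is not None
         else np.linspace(0.0, 48.0, 13))
    parent_c = c0 * np.exp(-k1 * t)
    inter = c0 * k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    phenol = c0 - parent_c - inter
    species = {parent: parent_c, "2-BP": inter, "phenol": phenol}
    if noise_sd > 0:
        species = {
            name: np.clip(v + rng.normal(0.0, noise_sd, size=v.shape),
                          0.0, None)
            for name, v in species.items()
        }
    return DehalTimeSeries(t, species, volume_l=volume_l, parent=parent)


def gen_qpcr(
    rng_or_seed,
    true_fold: float = 400.0,
    slope: float = -3.4,
    intercept: float = 32.0,
    cq_noise_sd: float = 0.1,
    n_bio: int = 3,
    n_tech: int = 2,
    target_gene: str = "rdaseA",
    reference_gene: str = "16S",
):
    """A qPCR run with known truth: 3 bio x 2 tech replicates by default.

    Standards lie exactly on Cq = slope*log10(q) + intercept over a 5-point
    tenfold dilution. Sample Cqs are generated from true quantities (target
    induced ``true_fold`` above control; reference equal across conditions)
    with Gaussian Cq noise.
    """
    from .physiology import QpcrRun

    if isinstance(rng_or_seed, (int, np.integer)):
        rng = np.random.default_rng(int(rng_or_seed))
    else:
        rng = rng_or_seed
    if slope >= 0:
        raise ValueError("slope must be negative")
    logqs = [0.0, -1.0, -2.0, -3.0, -4.0]
    standards = {
        g: [(lq, slope * lq + intercept) for lq in logqs]
        for g in (target_gene, reference_gene)
    }
    true_q = {
        (target_gene, "control"): 1e-3,
        (target_gene, "induced"): 1e-3 * true_fold,
        (reference_gene, "control"): 1.0,
        (reference_gene, "induced"): 1.0,
    }
    samples = []
    for (gene, condition), q in sorted(true_q.items()):
        cq_true = slope * np.log10(q) + intercept
        for bio in range(1, n_bio + 1):
            for tech in range(1, n_tech + 1):
                noise = (rng.normal(0.0, cq_noise_sd)
                         if cq_noise_sd > 0 else 0.0)
                samples.append({
                    "gene": gene, "condition": condition,
                    "bio_rep": bio, "tech_rep": tech,
                    "cq": cq_true + noise,
                })
    return QpcrRun(standards, samples), true_fold
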