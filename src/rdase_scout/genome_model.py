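"""Annotated-genome container and coordinate-aware slicing.

Genomes are represented as plain contig sequences plus a sorted list of CDS
features. All coordinates are 1-based inclusive (GenBank/GFF3 native) on the
forward strand; strand only affects the reading orientation of extraction
operations (:func:`translate_cds`, :func:`upstream_region`).

Nucleotide alphabet is restricted to A, C, G, T, N. ``N`` is tolerated in
contigs but never matches any motif position downstream; any other ambiguity
code is rejected at read time.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import gffutils
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_VALID_AA = frozenset(_AA20 + "X")

#: NCBI translation table 11 (bacterial); fixed, not configurable.
TRANSLATION_TABLE = 11
_TABLE11 = CodonTable.unambiguous_dna_by_id[TRANSLATION_TABLE]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeError(ValueError):
    """Raised on malformed or inconsistent genome input."""


@dataclass(frozen=True)
class GeneFeature:
    """A single CDS feature, 1-based inclusive, stranded."""

    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    locus_tag: str
    product: str = ""
    translation: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise GenomeError(
                f"{self.locus_tag}: invalid extent {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise GenomeError(f"{self.locus_tag}: strand must be '+' or '-'")
        if self.translation is not None:
            bad = set(self.translation) - _VALID_AA
            if bad:
                raise GenomeError(
                    f"{self.locus_tag}: illegal residues in translation: "
                    f"{sorted(bad)}"
                )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class Genome:
    """Contigs plus CDS features sorted by (contig_id, start)."""

    genome_id: str
    contigs: dict[str, str]
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            bad = set(seq) - _VALID_BASES
            if bad:
                raise GenomeError(
                    f"contig {cid}: ambiguous bases other than N not "
                    f"supported: {sorted(bad)}"
                )
        tags = [f.locus_tag for f in self.features]
        if len(tags) != len(set(tags)):
            dupes = sorted({t for t in tags if tags.count(t) > 1})
            raise GenomeError(f"duplicate locus_tags: {dupes}")
        for f in self.features:
            if f.contig_id not in self.contigs:
                raise GenomeError(
                    f"{f.locus_tag}: unknown contig {f.contig_id!r}"
                )
            if f.end > len(self.contigs[f.contig_id]):
                raise GenomeError(
                    f"{f.locus_tag}: end {f.end} outside contig "
                    f"{f.contig_id} (length {len(self.contigs[f.contig_id])})"
                )
        self.features.sort(key=lambda f: (f.contig_id, f.start, f.end))

    def feature_by_tag(self, locus_tag: str) -> GeneFeature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(locus_tag)

    def contig_features(self, contig_id: str) -> list[GeneFeature]:
        return [f for f in self.features if f.contig_id == contig_id]


def _clean_seq(raw: str, where: str) -> str:
    seq = str(raw).upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise GenomeError(
            f"{where}: ambiguous bases other than N not supported: "
            f"{sorted(bad)}"
        )
    return seq


def read_genbank(path: str, genome_id: str | None = None) -> Genome:
    """Read a (possibly multi-record) GenBank flat file into a Genome.

    One :class:`GeneFeature` is created per CDS feature; ``/translation``
    and ``/product`` qualifiers are captured when present.
    """
    contigs: dict[str, str] = {}
    features: list[GeneFeature] = []
    try:
        records = list(SeqIO.parse(path, "genbank"))
    except ValueError as exc:
        raise GenomeError(f"malformed GenBank file {path}: {exc}") from exc
    if not records:
        raise GenomeError(f"no GenBank records in {path}")
    for rec in records:
        contigs[rec.id] = _clean_seq(rec.seq, f"{path}:{rec.id}")
        for i, feat in enumerate(rec.features):
            if feat.type != "CDS":
                continue
            start = int(feat.location.start) + 1  # Biopython is 0-based
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            tag = feat.qualifiers.get(
                "locus_tag", feat.qualifiers.get("gene", [f"{rec.id}_cds{i}"])
            )[0]
            product = feat.qualifiers.get("product", [""])[0]
            translation = feat.qualifiers.get("translation", [None])[0]
            if end > len(rec.seq):
                raise GenomeError(
                    f"{tag}: CDS {start}..{end} outside contig {rec.id}"
                )
            features.append(
                GeneFeature(rec.id, start, end, strand, tag, product,
                            translation)
            )
    if not features:
        logger.warning("no CDS features found in %s", path)
    return Genome(genome_id or os.path.basename(path), contigs, features)


def read_gff3_fasta(gff: str, fasta: str,
                    genome_id: str | None = None) -> Genome:
    """Read a GFF3 + FASTA pair into a Genome.

    GFF3 1-based inclusive coordinates are preserved unchanged; the
    ``locus_tag`` attribute is used when present, else ``ID``. CDS phase is
    ignored for gene extent.
    """
    contigs = {
        rec.id: _clean_seq(rec.seq, f"{fasta}:{rec.id}")
        for rec in SeqIO.parse(fasta, "fasta")
    }
    db = gffutils.create_db(
        gff, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[GeneFeature] = []
    missing: set[str] = set()
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        if feat.seqid not in contigs:
            missing.add(feat.seqid)
            continue
        tag = (feat.attributes.get("locus_tag") or feat.attributes.get("ID")
               or [f"{feat.seqid}_{feat.start}"])[0]
        product = (feat.attributes.get("product") or [""])[0]
        translation = (feat.attributes.get("translation") or [None])[0]
        features.append(
            GeneFeature(feat.seqid, feat.start, feat.end,
                        "-" if feat.strand == "-" else "+",
                        tag, product, translation)
        )
    if missing:
        raise GenomeError(
            f"GFF3 seqids absent from FASTA: {sorted(missing)}"
        )
    if not features:
        logger.warning("no CDS features found in %s", gff)
    return Genome(genome_id or os.path.basename(gff), contigs, features)


def extract_cds(genome: Genome, feature: GeneFeature) -> str:
    """Coding-strand nucleotide sequence of a feature (5'->3')."""
    seq = genome.contigs[feature.contig_id][feature.start - 1:feature.end]
    return revcomp(seq) if feature.strand == "-" else seq


def translate_cds(genome: Genome, feature: GeneFeature) -> str:
    """Translate a CDS under the bacterial code (table 11).

    The stored ``/translation`` is returned verbatim when present. Otherwise
    the coding-strand sequence is translated; a trailing stop is removed, an
    internal stop raises, and any table-11 start codon in position 1 is
    rendered as M.
    """
    if feature.translation is not None:
        return feature.translation
    nt = extract_cds(genome, feature)
    if len(nt) % 3:
        raise GenomeError(
            f"{feature.locus_tag}: CDS length {len(nt)} not divisible by 3"
        )
    aa = str(Seq(nt).translate(table=TRANSLATION_TABLE))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise GenomeError(
            f"{feature.locus_tag}: internal stop at codon {aa.index('*') + 1}"
        )
    if aa and nt[:3] in _TABLE11.start_codons:
        aa = "M" + aa[1:]
    return aa


def upstream_region(
    genome: Genome, feature: GeneFeature, max_bp: int
) -> tuple[str, tuple[int, int] | None]:
    """Up to ``max_bp`` of sequence immediately 5' of the start codon.

    Returned in the gene's reading orientation (reverse-complemented for
    '-' strand genes), truncated at the contig edge. The second element
    gives the window's forward-frame 1-based inclusive coordinates, or
    ``None`` when the window is empty.
    """
    if max_bp < 1:
        raise ValueError("max_bp must be >= 1")
    contig = genome.contigs[feature.contig_id]
    if feature.strand == "+":
        lo = max(1, feature.start - max_bp)
        hi = feature.start - 1
    else:
        lo = feature.end + 1
        hi = min(len(contig), feature.end + max_bp)
    if hi < lo:
        return "", None
    seq = contig[lo - 1:hi]
    if feature.strand == "-":
        seq = revcomp(seq)
    return seq, (lo, hi)


# --- writers (used by the synthetic-genome generator and round-trip tests) ---

def _to_seqrecords(genome: Genome) -> list[SeqRecord]:
    recs = []
    for cid in genome.contigs:
        rec = SeqRecord(Seq(genome.contigs[cid]), id=cid, name=cid[:16],
                        description="")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["date"] = "01-JAN-2020"  # fixed for byte determinism
        for f in genome.contig_features(cid):
            qual = {"locus_tag": [f.locus_tag]}
            if f.product:
                qual["product"] = [f.product]
            if f.translation is not None:
                qual["translation"] = [f.translation]
            qual["transl_table"] = [str(TRANSLATION_TABLE)]
            rec.features.append(
                SeqFeature(
                    FeatureLocation(f.start - 1, f.end,
                                    strand=-1 if f.strand == "-" else 1),
                    type="CDS", qualifiers=qual,
                )
            )
        recs.append(rec)
    return recs


def write_genbank(genome: Genome, path: str) -> None:
    SeqIO.write(_to_seqrecords(genome), path, "genbank")


def write_gff3_fasta(genome: Genome, gff: str, fasta: str) -> None:
    with open(fasta, "w") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, seq in genome.contigs.items():
            fh.write(f"##sequence-region {cid} 1 {len(seq)}\n")
        for f in genome.features:
            attrs = [f"ID={f.locus_tag}", f"locus_tag={f.locus_tag}"]
            if f.product:
                attrs.append(f"product={f.product}")
            if f.translation is not None:
                attrs.append(f"translation={f.translation}")
            fh.write(
                "\t".join([
                    f.contig_id, "rdase_scout", "CDS", str(f.start),
                    str(f.end), ".", f.strand, "0", ";".join(attrs),
                ]) + "\n"
            )


def genome_to_json(genome: Genome) -> dict:
    """Plain-dict form of a genome (the CLI's internal JSON representation)."""
    return {
        "genome_id": genome.genome_id,
        "contigs": dict(genome.contigs),
        "features": [
            {
                "contig_id": f.contig_id, "start": f.start, "end": f.end,
                "strand": f.strand, "locus_tag": f.locus_tag,
                "product": f.product, "translation": f.translation,
            }
            for f in genome.features
        ],
    }


def genome_from_json(obj: dict) -> Genome:
    return Genome(
        obj["genome_id"], dict(obj["contigs"]),
        [GeneFeature(**f) for f in obj["features"]],
    )


def mirror_genome(genome: Genome) -> Genome:
    """Reverse-complement every contig and mirror all feature coordinates.

    Used for strand-invariance checks: screening results on the mirrored
    genome must equal the original up to coordinate mirroring.
    """
    contigs = {cid: revcomp(seq) for cid, seq in genome.contigs.items()}
    feats = []
    for f in genome.features:
        n = len(genome.contigs[f.contig_id])
        feats.append(
            replace(f, start=n - f.end + 1, end=n - f.start + 1,
                    strand="-" if f.strand == "+" else "+")
        )
    return Genome(genome.genome_id, contigs, feats)
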