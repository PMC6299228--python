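"""Degenerate sequence-motif compilation and scanning.

Two motif alphabets are supported:

* protein — the 20 standard residues plus ``X`` as a "any residue" wildcard,
  as in the twin-arginine export signal RRXFXK and the Fe-S cluster binding
  motifs CXXCXXCXXXCP / CXXCXXXCP of reductive dehalogenases;
* nucleotide — full IUPAC degeneracy codes, as in the sigma-54 −24/−12
  promoter element YTGGCACGRNNNTTGC.

Semantics are deliberately conservative: an ambiguous symbol in the *scanned*
sequence (N in DNA, X in protein) matches no motif position, including motif
N/X, so a low-quality sequence can never certify a motif. All overlapping
occurrences are reported. A brute-force expansion (:func:`expand_motif`)
serves as the independent oracle for the scanner.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

from .genome_model import revcomp

#: IUPAC nucleotide degeneracy codes -> concrete base sets.
IUPAC_NT: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_CODES: dict[str, str] = {aa: aa for aa in _AA20}
PROTEIN_CODES["X"] = _AA20  # wildcard over the 20 standard residues

_SEQ_ALPHABET = {"nucleotide": frozenset("ACGTN"),
                 "protein": frozenset(_AA20 + "X")}


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class MotifPattern:
    name: str
    alphabet: str  # 'protein' | 'nucleotide'
    pattern: str
    degeneracy: int
    _regex: re.Pattern = field(repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    """A concrete match; ``offset`` is 0-based in the scanned string.

    For strand='-' hits, ``offset`` is the forward-strand coordinate of the
    match start and ``matched`` is the reverse-strand (matching) sequence.
    """

    sequence_id: str
    offset: int
    matched: str
    strand: str = "+"


def _codes(alphabet: str) -> dict[str, str]:
    if alphabet == "nucleotide":
        return IUPAC_NT
    if alphabet == "protein":
        return PROTEIN_CODES
    raise MotifError(f"unknown alphabet {alphabet!r}")


def compile_motif(name: str, pattern: str, alphabet: str) -> MotifPattern:
    """Validate a degenerate pattern and precompile its scanner.

    The stored degeneracy is the product of per-position option counts.
    """
    codes = _codes(alphabet)
    if not pattern:
        raise MotifError("empty pattern")
    degeneracy = 1
    parts = []
    for i, sym in enumerate(pattern.upper(), start=1):
        if sym not in codes:
            raise MotifError(
                f"illegal {alphabet} symbol {sym!r} at position {i} "
                f"of pattern {pattern!r}"
            )
        opts = codes[sym]
        degeneracy *= len(opts)
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    # lookahead group -> overlapping matches
    rx = re.compile("(?=(" + "".join(parts) + "))")
    return MotifPattern(name, alphabet, pattern.upper(), degeneracy, rx)


def _check_sequence(seq: str, alphabet: str) -> None:
    bad = set(seq) - _SEQ_ALPHABET[alphabet]
    if bad:
        raise MotifError(
            f"sequence contains symbols outside the {alphabet} alphabet: "
            f"{sorted(bad)}"
        )


def scan(
    sequence: str,
    motif: MotifPattern,
    both_strands: bool = False,
    sequence_id: str = "",
) -> list[MotifHit]:
    """All overlapping matches of ``motif`` in ``sequence``, ascending offset.

    With ``both_strands`` (nucleotide only), reverse-complement matches are
    reported with strand='-' and offsets mapped to forward coordinates of
    the match start (the leftmost forward-strand base of the matched span).
    """
    sequence = sequence.upper()
    _check_sequence(sequence, motif.alphabet)
    hits = [
        MotifHit(sequence_id, m.start(), m.group(1), "+")
        for m in motif._regex.finditer(sequence)
    ]
    if both_strands:
        if motif.alphabet != "nucleotide":
            raise MotifError("both_strands applies to nucleotide motifs only")
        n, k = len(sequence), len(motif)
        rc = revcomp(sequence)
        hits += [
            MotifHit(sequence_id, n - m.start() - k, m.group(1), "-")
            for m in motif._regex.finditer(rc)
        ]
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def expand_motif(motif: MotifPattern, limit: int = 10_000) -> set[str]:
    """The full set of concrete strings the motif denotes (test oracle)."""
    if motif.degeneracy > limit:
        raise MotifError(
            f"motif {motif.name!r} denotes {motif.degeneracy} strings, "
            f"over the limit of {limit}"
        )
    codes = _codes(motif.alphabet)
    return {
        "".join(tup)
        for tup in itertools.product(*(codes[s] for s in motif.pattern))
    }


def _registry() -> dict[str, MotifPattern]:
    return {
        # Tat export signal, N-terminal region of periplasmic RDase A
        "tat": compile_motif("tat", "RRXFXK", "protein"),
        # twin Fe-S cluster binding motifs of the catalytic subunit
        "fes_long": compile_motif("fes_long", "CXXCXXCXXXCP", "protein"),
        "fes_short": compile_motif("fes_short", "CXXCXXXCP", "protein"),
        # sigma-54 holoenzyme −24/−12 element; 16-mer core is the default,
        # the 17-mer with the degenerate trailing W is also provided
        "sigma54_core": compile_motif(
            "sigma54_core", "YTGGCACGRNNNTTGC", "nucleotide"),
        "sigma54_extended": compile_motif(
            "sigma54_extended", "YTGGCACGRNNNTTGCW", "nucleotide"),
    }


#: Built-in motifs used by the screening pipeline.
REGISTRY: dict[str, MotifPattern] = _registry()


def load_motif_config(path: str) -> dict[str, MotifPattern]:
    """User motifs from a YAML/TOML-ish mapping file: name -> {alphabet, pattern}."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        name: compile_motif(name, spec["pattern"], spec["alphabet"])
        for name, spec in raw.items()
    }
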