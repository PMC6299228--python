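# Methods

This note records the models, conventions and heuristics behind
`rdase-scout`, the defaults and why they were chosen, and what the synthetic
ground truth does and does not establish.

## Coordinates and sequence conventions

All coordinates are 1-based inclusive on the forward strand, the native
convention of both GenBank and GFF3; no internal conversion ever happens
(0-based half-open forms would exist only at a serialization boundary, and
none is needed). Strand affects only reading-orientation operations:
translation and upstream-window extraction reverse-complement on the minus
strand. The nucleotide alphabet is A/C/G/T/N; any other IUPAC ambiguity
code in a *genome* is rejected at read time so motif semantics stay
predictable. Translation uses the bacterial code (table 11), not
configurable — every intended input organism is bacterial. Alternative
start codons in position 1 are rendered as M; internal stops are errors.

## Motif semantics

Motifs come in two alphabets: protein patterns over the 20 standard
residues with X as "any residue" (Tat signal `RRXFXK`, Fe–S binding motifs
`CXXCXXCXXXCP` and `CXXCXXXCP`), and nucleotide patterns over the full
IUPAC degeneracy codes (sigma-54 element `YTGGCACGRNNNTTGC`). Scanning is
deliberately conservative: an ambiguous symbol in the *scanned* sequence
(N in DNA, X in a translation) matches no motif position, including motif
N/X — an unreadable residue can never certify a motif, which avoids false
Tat/Fe–S calls on low-quality translations. All overlapping occurrences
are reported (no skip-ahead); completeness is cheap at these motif lengths.
Reverse-strand hits are mapped to forward coordinates of the match start.

Two registry variants of the sigma-54 element exist: the 16-mer core
(`sigma54_core`, the default actually used by the promoter scan) and the
17-mer with the degenerate trailing W (`sigma54_extended`). Promoter scans
run on the coding strand only by default — the −24/−12 element is oriented
with transcription — with a flag for both strands.

A structural fact worth knowing: every concrete instance of the long Fe–S
motif contains a short-motif match starting three residues in (cysteines at
relative positions 3, 6, 10 and the proline at 11 satisfy `CXXCXXXCP`). A
protein can therefore carry the short motif alone, but never the long motif
alone.

## Candidate-calling policy

Motif-based calls require *both* Fe–S motifs plus a protein length inside
250–750 aa; the bounds bracket typical respiratory RDase A sizes and
exclude decoy fusions. The Tat signal is never required — in real genomes
only roughly half of candidate RDase As carry it — it only sets the
periplasmic/cytoplasmic localization label (first `RRXFXK` match starting
within the N-terminal 45 residues). A `require_both_fes=False` policy is
available for sensitivity studies. Externally produced domain-hit tables
(TSV: locus_tag, domain_id, score; `pfam13486`/`PF13486` rows count) add
calls with basis `external`; profile-HMM search itself is out of scope.

## Neighborhood heuristics

"Close association" has no standard operational definition, so windows are
explicit parameters echoed into every report: 3 genes each side for RDase
B, 5 for regulators, 500 bp for the promoter. RDase B qualification
requires a small protein (≤130 aa) and either an annotation keyword
("reductive dehalogenase", "anchoring", "RdhB", "membrane") or the
hydropathy heuristic: at least two 19-residue windows of mean
Kyte–Doolittle hydropathy ≥1.6, a proxy for a membrane anchor when
annotation is silent. Ties between qualifying genes: nearest wins, and at
equal distance downstream wins, because downstream is the common
architecture and upstream the documented exception. bEBPs are recognized by
sigma-54-activator keywords or by the GAFTGA hexapeptide of the AAA+
domain; the latter is an auxiliary sequence heuristic and is labelled
`gaftga` in output so it can be audited separately from annotation-based
calls.

The promoter is scanned once per cluster, upstream of the operon's first
gene, not per gene — the sigma-54 element controls the transcription unit.
The first gene is found by walking 5′ from the candidate over same-strand
neighbors separated by ≤100 bp of intergenic sequence (operon continuation
threshold); sites are reported in genome coordinates and as negative
offsets relative to the start codon.

## Identity, grouping, distances, trees

Percent identity comes from Needleman–Wunsch global alignment under
BLOSUM62 with gap open 10 and extension 0.5 (a gap of length L costs
10 + 0.5·(L−1)), with identity = 100 · matches / alignment columns — gap
columns and terminal overhangs stay in the denominator, a conservative
choice for length-divergent dehalogenases, and the convention is stated in
output metadata. Because co-optimal alignments can disagree on matches and
columns, identity is defined as the maximum over score-optimal alignments
(enumeration capped at 256), which makes the value well defined and
reproducible.

Ortholog groups at a cutoff are single-linkage: connected components of the
graph with edges at ≥cutoff identity, matching the additive semantics of
"assign a sequence to a group when it clears the cutoff to any member".
Group ids are dense integers ordered by each component's smallest label.

Column filtering retains columns whose fraction of unambiguous, non-gap
residues is ≥ the coverage threshold (default 0.60); X counts as ambiguous.
Distances are p-distances over columns where both rows are unambiguous,
optionally Poisson-corrected (−ln(1−p)). Maximum-likelihood JTT distances
are deliberately out of scope; the Poisson correction is the labelled
substitute, so clade assignment against real reference sets should be
treated as approximate.

Neighbor joining is the standard Saitou–Nei algorithm with the Q criterion,
made bit-deterministic: ties in Q are broken by the lexicographically
lowest pair of minimum leaf labels, and a negative branch-length estimate
is clamped to zero with the deficit added to the sister branch so the
pair's summed length — and hence all patristic distances — is preserved.
The result is an unrooted tree (trifurcation at the seed node) carried as a
dendropy object, so Newick I/O and patristic distances follow dendropy
semantics. Clade assignment gives each query leaf the clade of its nearest
reference leaf by patristic distance; ties within 1e-9 yield "ambiguous".
Monophyly of each reference clade (existence of an edge whose reference
leaves are exactly that clade, queries disregarded) is checked and
reported, and a violation logs a warning without blocking assignment.

## Physiology

The bromine ledger fixes substituent counts (2,4,6-TBP = 3; 2,6-DBP =
2,4-DBP = 2; 2-BP = 4-BP = 1; phenol = 0); each bromine removed consumes
two electrons, so e⁻ (mmol) = 2 · Σ products (Br_parent − Br_product) ·
c (µM) · V (L) / 1000. Electrons routed to sulfate/sulfur reduction are
deliberately not booked — the yield computation describes growth on a
donor plus the bromophenol acceptor only. Protein yield is the quotient
mg / mmol e⁻, reported as mean ± sample sd over biological replicates.
Mass balance compares the phenol-ring molar total at each timepoint to
time zero; the default tolerance of 0.15 reflects typical HPLC scatter and
is configurable.

qPCR uses the relative standard-curve method: least squares of
Cq = m·log10(q) + b per gene, quantity(Cq) = 10^((Cq−b)/m), amplification
efficiency 10^(−1/m) − 1. Technical replicates are averaged on the Cq
scale before interpolation (common practice; averaging quantities instead
would bias upward under noise). Per biological replicate the target
quantity is divided by the 16S quantity; the fold change is the mean
normalized induced value over the mean normalized control, with sd across
biological replicates of the per-replicate induced fold. The whole statistic
is invariant to rescaling all quantities by a constant.

## Synthetic ground truth

The genome generator emulates annotated contigs containing complete RDase
operons — an RDase A with the requested motif complement, RDase B
downstream or upstream, a sigma-54 activator gene adjacent or within the
regulator window, and a concrete sigma-54 element planted at a stated
offset (default −120 bp) — plus decoys (exactly one Fe–S motif, or broken
motifs) and a motif-free background. Defaults are 2 contigs, 1–3 operons,
5 decoys and 50 background genes per genome. Background proteins are
150–400 aa, above the 130-aa RDase B gate so the hydropathy heuristic
cannot fire on them; RDase B proteins are 70–110 aa with a 30-residue
hydrophobic core; activators are 420–480 aa. Within-operon intergenic gaps
are 10–60 bp versus 150–400 bp between transcription units, a clean margin
around the 100-bp operon-continuation threshold; operon blocks are
separated by at least five single-gene units so neighboring clusters never
bleed into each other's search windows.

Backgrounds are i.i.d. uniform residues/bases with rejection sampling
against every registry motif, and each assembled genome is verified —
contig-wide both-strand sigma-54 scans must find exactly the planted
elements, and no non-planted protein may combine both Fe–S motifs at a
callable length — with deterministic retries from the same seeded stream.
DNA is produced by deterministic back-translation (lexicographically first
codon per residue, table 11), so genomes are DNA↔protein consistent and
byte-identical under a fixed seed. The generator makes no attempt to mimic
real GC content, codon usage, annotation noise or partial operons: a green
recovery test establishes that the screen's logic is exact on clean planted
structure, not that its heuristics are well calibrated on real genomes.

Kinetics are sequential first-order debromination (parent → mono-bromophenol
→ phenol, closed form; defaults k1 = 0.15 /h, k2 = 0.05 /h, c0 = 200 µM
over 48 h, matching the concentration and time scale of typical induction
experiments), with Gaussian noise clipped at zero; this rate law is a
fixture-realism choice, not an inference about enzyme kinetics. qPCR runs
follow a 3 biological × 2 technical design with standards exactly on a
line (slope −3.4, intercept 32) and Cq noise sd 0.1.

## Numerical choices and edge cases

- Regex scanning uses lookahead groups for overlapping matches; hits are
  sorted by offset with '+' before '−' at equal offset.
- `expand_motif` refuses above a degeneracy limit (default 10⁴) rather
  than silently enumerating millions of strings.
- Poisson correction is undefined at p = 1 and errors, as does a sequence
  pair with no comparable columns (the pair is named).
- The 2-taxon NJ case returns a single edge split evenly; the 3-taxon case
  uses the closed-form star lengths.
- An empty upstream window (gene at a contig edge) returns an empty string
  with no coordinates rather than an error.
- Fold-change computation errors when the control normalized quantity is
  zero; standard-curve fitting requires ≥2 distinct quantities.

## Known limitations

- Heuristic windows (3/5 genes, 500 bp) and the hydropathy rule are
  operational stand-ins for qualitative descriptions; on real genomes they
  need auditing via the rule labels in the reports.
- No ML/Bayesian phylogenetics, no bootstrap support, no alignment
  construction (alignments are consumed, not built).
- The survey's aggregate fractions are properties of whatever genome set is
  supplied; they are not comparable across annotation pipelines with
  different product vocabularies.
- No gene calling: unannotated contigs cannot be screened.
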