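"""Identity matrices, ortholog grouping, distance trees, clade assignment.

Operations mirror the community workflow for classifying reductive
dehalogenase catalytic subunits: pairwise percent identity from global
alignments, single-linkage ortholog groups at a 90% identity cutoff,
alignment-column filtering at 60% site coverage, p/Poisson distances, and
neighbor-joining trees from which query sequences are assigned to clades by
their nearest reference leaf.

Maximum-likelihood JTT distances are out of scope; the Poisson correction
-ln(1-p) is the provided substitute and is labelled as such in output.
Trees are dendropy objects, so Newick I/O and patristic distances follow
dendropy semantics; the NJ algorithm itself is implemented here with
deterministic tie-breaking (lowest leaf-label pair) and negative branch
lengths clamped to zero with the deficit moved to the sister branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import networkx as nx
import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

GAP = "-"
_AMBIG = "X"

#: scoring used for percent identity: Needleman-Wunsch global alignment,
#: BLOSUM62, gap of length L costs 10 + 0.5*(L-1)
GAP_OPEN = 10.0
GAP_EXTEND = 0.5


@dataclass
class Msa:
    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in alignment")
        if self.rows and len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows are not equal length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class IdentityMatrix:
    labels: list[str]
    values: np.ndarray  # percent, symmetric, diagonal 100

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("identity matrix not symmetric")
        self.values = v


@dataclass
class OrthologGroups:
    cutoff: float
    assignment: dict[str, int]  # label -> dense group id


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -GAP_OPEN
    al.extend_gap_score = -GAP_EXTEND
    return al


def _identity_of(a_row: str, b_row: str) -> float:
    matches = sum(1 for x, y in zip(a_row, b_row)
                  if x == y and x != GAP)
    return 100.0 * matches / len(a_row)


def pairwise_identity(a: str, b: str, max_alignments: int = 256) -> float:
    """Global-alignment percent identity between two protein sequences.

    Identity = 100 x matches / alignment length, counting gap columns and
    terminal overhangs in the denominator. Among score-optimal alignments
    (which may disagree on matches and length) the maximum identity is
    taken, making the value well defined; enumeration is capped at
    ``max_alignments`` co-optimal alignments.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 100.0
    alignments = _aligner().align(a, b)
    best = 0.0
    for i, aln in enumerate(alignments):
        if i >= max_alignments:
            break
        best = max(best, _identity_of(aln[0], aln[1]))
    return best


def identity_matrix(labels: list[str], seqs: list[str]) -> IdentityMatrix:
    n = len(labels)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pairwise_identity(seqs[i], seqs[j])
    return IdentityMatrix(labels, vals)


def ortholog_groups(m: IdentityMatrix, cutoff: float = 90.0) -> OrthologGroups:
    """Single-linkage groups: connected components of the >=cutoff graph.

    Group ids are dense integers, numbered by the lexicographically smallest
    member label of each component.
    """
    g = nx.Graph()
    g.add_nodes_from(m.labels)
    n = len(m.labels)
    for i in range(n):
        for j in range(i + 1, n):
            if m.values[i, j] >= cutoff:
                g.add_edge(m.labels[i], m.labels[j])
    comps = sorted(nx.connected_components(g), key=lambda c: min(c))
    assignment = {lab: gid for gid, comp in enumerate(comps)
                  for lab in sorted(comp)}
    return OrthologGroups(cutoff, assignment)


def filter_columns(msa: Msa, min_coverage: float = 0.60) -> Msa:
    """Drop alignment columns below the site-coverage threshold.

    Coverage of a column is the fraction of rows with an unambiguous,
    non-gap residue (X counts as ambiguous). Columns with coverage >=
    ``min_coverage`` are retained; row order and labels are preserved.
    """
    if msa.n_rows == 0:
        return Msa(list(msa.labels), list(msa.rows))
    arr = np.array([list(r) for r in msa.rows])
    good = (arr != GAP) & (arr != _AMBIG)
    keep = good.sum(axis=0) / msa.n_rows >= min_coverage - 1e-12
    if not keep.any():
        logger.warning("all %d columns removed by coverage filter",
                       msa.n_cols)
    rows = ["".join(row) for row in arr[:, keep]]
    return Msa(list(msa.labels), rows)


def distance_matrix(msa: Msa, correction: str = "p") -> np.ndarray:
    """Pairwise distances over columns where both rows are unambiguous.

    correction='p': proportion of differing comparable columns;
    correction='poisson': -ln(1-p). A pair with no comparable columns is an
    error naming the pair.
    """
    if correction not in ("p", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    arr = np.array([list(r) for r in msa.rows])
    ok = (arr != GAP) & (arr != _AMBIG)
    n = msa.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {msa.labels[i]!r} "
                    f"and {msa.labels[j]!r}"
                )
            p = np.sum(arr[i, both] != arr[j, both]) / m
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"Poisson correction undefined at p=1 for pair "
                        f"({msa.labels[i]!r}, {msa.labels[j]!r})"
                    )
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return d


# ---------------------------------------------------------------------------
# neighbor joining


def _min_leaf(node: dendropy.Node) -> str:
    return min(lf.taxon.label for lf in node.leaf_iter())


def nj_tree(d: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q criterion is joined at each step; ties are
    broken by the lexicographically lowest (min-leaf-label, min-leaf-label)
    pair. Branch lengths come from the standard two-point formulas; a
    negative estimate is clamped to zero and the deficit added to the
    sister branch so the pair's summed length is preserved. The returned
    tree is unrooted (root trifurcation for >=3 taxa).
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix not symmetric")
    if n < 2:
        raise ValueError("need at least 2 taxa")

    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes.append(node)

    if n == 2:
        half = d[0, 1] / 2.0
        for node in nodes:
            tree.seed_node.add_child(node)
            node.edge.length = half
        tree.is_rooted = False
        return tree

    dist = d.copy()
    active = list(range(n))  # indices into dist
    node_of = {i: nodes[i] for i in active}

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(dist[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for bi in range(ai + 1, r):
                i, j = active[ai], active[bi]
                q = (r - 2) * dist[i, j] - sums[i] - sums[j]
                key = tuple(sorted((_min_leaf(node_of[i]),
                                    _min_leaf(node_of[j]))))
                cand = (q, key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * dist[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = dist[i, j] - li
        # clamp negatives, preserving li + lj
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(node_of[i])
        node_of[i].edge.length = li
        parent.add_child(node_of[j])
        node_of[j].edge.length = lj
        # distances from the new node
        for k in active:
            if k in (i, j):
                continue
            dist[i, k] = dist[k, i] = 0.5 * (
                dist[i, k] + dist[j, k] - dist[i, j])
        node_of[i] = parent
        active.remove(j)

    # join the last three at the root trifurcation
    i, j, k = active
    li = 0.5 * (dist[i, j] + dist[i, k] - dist[j, k])
    lj = 0.5 * (dist[i, j] + dist[j, k] - dist[i, k])
    lk = 0.5 * (dist[i, k] + dist[j, k] - dist[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        tree.seed_node.add_child(node_of[idx])
        node_of[idx].edge.length = max(ln, 0.0)
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def patristic_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths, keyed by sorted label pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    for a in range(len(taxa)):
        for b in range(a + 1, len(taxa)):
            key = tuple(sorted((taxa[a].label, taxa[b].label)))
            out[key] = pdm.patristic_distance(taxa[a], taxa[b])
    return out


def _reference_monophyly(
    tree: dendropy.Tree, reference_clades: dict[str, str]
) -> dict[str, bool]:
    """Whether each clade's reference leaves sit on one side of some edge
    with no other reference leaf (query leaves are ignored)."""
    ref_labels = set(reference_clades)
    clades = {}
    for lab, clade in reference_clades.items():
        clades.setdefault(clade, set()).add(lab)
    all_leaf_sets = []
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        leaves = {lf.taxon.label for lf in head.leaf_iter()}
        all_leaf_sets.append(leaves & ref_labels)
    result = {}
    all_refs = ref_labels
    for clade, members in clades.items():
        result[clade] = any(
            s == members or s == all_refs - members for s in all_leaf_sets
        )
    return result


def assign_clades(
    tree: dendropy.Tree, reference_clades: dict[str, str],
    tol: float = 1e-9,
) -> tuple[dict[str, str], dict[str, bool]]:
    """Assign each non-reference leaf the clade of its nearest reference.

    Nearness is patristic distance; a tie within ``tol`` between different
    clades yields "ambiguous". Also reports, per clade, whether its
    reference leaves are monophyletic on the tree (a warning is logged when
    they are not; assignment proceeds regardless).
    """
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = sorted(set(reference_clades) - leaf_labels)
    if missing:
        raise ValueError(f"reference labels absent from tree: {missing}")
    pd = patristic_distances(tree)

    def dist(a: str, b: str) -> float:
        return pd[tuple(sorted((a, b)))]

    assignment = {}
    for lab in sorted(leaf_labels - set(reference_clades)):
        ranked = sorted(
            (dist(lab, ref), clade) for ref, clade in
            reference_clades.items()
        )
        best_d, best_clade = ranked[0]
        tied = {clade for dd, clade in ranked if dd <= best_d + tol}
        assignment[lab] = best_clade if len(tied) == 1 else "ambiguous"
    monophyly = _reference_monophyly(tree, reference_clades)
    for clade, ok in monophyly.items():
        if not ok:
            logger.warning("reference clade %r is not monophyletic", clade)
    return assignment, monophyly


# ---------------------------------------------------------------------------
# I/O


def read_aligned_fasta(path: str) -> Msa:
    labels, rows = [], []
    length = None
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper()
        if length is not None and len(seq) != length:
            raise ValueError(
                f"ragged alignment: record {rec.id!r} has length "
                f"{len(seq)}, expected {length}"
            )
        length = len(seq)
        labels.append(rec.id)
        rows.append(seq)
    return Msa(labels, rows)


def write_newick(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick", suppress_rooting=True,
               real_value_format_specifier=".12g")


def read_newick(path_or_str: str, from_string: bool = False) -> dendropy.Tree:
    if from_string:
        return dendropy.Tree.get(data=path_or_str, schema="newick")
    return dendropy.Tree.get(path=path_or_str, schema="newick")
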