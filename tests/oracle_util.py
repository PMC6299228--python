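"""Independent brute-force oracles used across the test suite.

These deliberately avoid the code paths they check: plain substring search
instead of compiled regex scanning, recursive enumeration of alignments
instead of DP, union-find instead of graph components, and a
networkx-edge-walk tree construction instead of neighbor joining.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
_OPEN, _EXT = 10.0, 0.5


def substring_hits(sequence: str, words: set[str]) -> set[tuple[int, str]]:
    """All (offset, matched) positions of any word via plain str.find."""
    out = set()
    for w in words:
        at = sequence.find(w)
        while at != -1:
            out.add((at, w))
            at = sequence.find(w, at + 1)
    return out


def alignment_identity_oracle(a: str, b: str) -> tuple[float, float]:
    """(optimal score, max identity among optimal alignments).

    Enumerates every global alignment under BLOSUM62 with affine gaps
    (first gap residue 10, each further residue 0.5). Exponential: keep
    sequences short (<=10 aa).
    """
    best = {"score": None, "ident": 0.0}

    def rec(i, j, score, matches, length, last):
        if i == len(a) and j == len(b):
            if best["score"] is None or score > best["score"] + 1e-9:
                best["score"] = score
                best["ident"] = 100.0 * matches / length
            elif abs(score - best["score"]) <= 1e-9:
                best["ident"] = max(best["ident"],
                                    100.0 * matches / length)
            return
        if i < len(a) and j < len(b):
            s = _B62[a[i]][b[j]]
            rec(i + 1, j + 1, score + s, matches + (a[i] == b[j]),
                length + 1, "M")
        if i < len(a):
            rec(i + 1, j, score - (_EXT if last == "A" else _OPEN),
                matches, length + 1, "A")
        if j < len(b):
            rec(i, j + 1, score - (_EXT if last == "B" else _OPEN),
                matches, length + 1, "B")

    rec(0, 0, 0.0, 0, 0, "")
    return best["score"], best["ident"]


def union_find_groups(labels: list[str], values: np.ndarray,
                      cutoff: float) -> dict[str, int]:
    """Exhaustive pairwise union-find; dense ids by smallest member label."""
    parent = {lab: lab for lab in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in combinations(range(len(labels)), 2):
        if values[i, j] >= cutoff:
            ri, rj = find(labels[i]), find(labels[j])
            if ri != rj:
                parent[ri] = rj
    roots: dict[str, list[str]] = {}
    for lab in labels:
        roots.setdefault(find(lab), []).append(lab)
    comps = sorted(roots.values(), key=min)
    return {lab: gid for gid, comp in enumerate(comps) for lab in comp}


def column_coverage_tally(rows: list[str], min_coverage: float) -> list[int]:
    """Independent per-column recount of retained column indices."""
    keep = []
    n = len(rows)
    for c in range(len(rows[0])):
        good = sum(1 for r in rows if r[c] not in "-X")
        if good / n >= min_coverage - 1e-12:
            keep.append(c)
    return keep


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random unrooted binary tree with positive branch lengths.

    Returns (graph, labels): a networkx Graph with 'length' edge weights,
    leaves labelled t0..t{n-1}. Built by attaching each new leaf to a
    random existing edge — no neighbor-joining involved.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    g = nx.Graph()
    nid = [0]

    def inner():
        nid[0] += 1
        return f"x{nid[0]}"

    def blen():
        return float(rng.uniform(0.05, 1.0))

    center = inner()
    for lab in labels[:3]:
        g.add_edge(center, lab, length=blen())
    for lab in labels[3:]:
        u, v = list(g.edges())[rng.integers(0, g.number_of_edges())]
        length = g[u][v]["length"]
        g.remove_edge(u, v)
        mid = inner()
        split = float(rng.uniform(0.2, 0.8)) * length
        g.add_edge(u, mid, length=split)
        g.add_edge(mid, v, length=length - split)
        g.add_edge(mid, lab, length=blen())
    return g, labels


def additive_distances(g: nx.Graph, labels: list[str]) -> np.ndarray:
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        lengths = nx.single_source_dijkstra_path_length(
            g, labels[i], weight="length")
        for j in range(n):
            d[i, j] = lengths[labels[j]]
    return d


def tree_splits(g: nx.Graph, labels: list[str]) -> set[frozenset]:
    """Non-trivial leaf bipartitions, normalized to the side without t0."""
    label_set = set(labels)
    splits = set()
    for u, v in list(g.edges()):
        length = g[u][v]["length"]
        g.remove_edge(u, v)
        side = nx.node_connected_component(g, u) & label_set
        g.add_edge(u, v, length=length)
        if labels[0] in side:
            side = label_set - side
        if 1 < len(side) < len(labels) - 1:
            splits.add(frozenset(side))
    return splits


def dendropy_splits(tree, labels: list[str]) -> set[frozenset]:
    label_set = set(labels)
    splits = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        side = {lf.taxon.label for lf in edge.head_node.leaf_iter()}
        if labels[0] in side:
            side = label_set - side
        if 1 < len(side) < len(labels) - 1:
            splits.add(frozenset(side))
    return splits
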