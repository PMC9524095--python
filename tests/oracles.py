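"""Independent brute-force oracles used to validate the implementation.

Each oracle deliberately uses a different algorithmic route from the code
under test: exhaustive path enumeration for affine alignment, exhaustive
topology enumeration with least-squares branch fitting for tree building,
set-based recursive evaluation for rule expressions, and repeated max-pick
selection for overlap resolution.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Sequence, Tuple

import numpy as np

from sodnox import architecture as arch
from sodnox.motif_map import load_matrix


# ---------------------------------------------------------------------------
# Affine alignment: enumerate every monotone alignment path


def brute_affine_score(
    a: str, b: str, matrix: str, gap_open: float, gap_extend: float
) -> float:
    """Optimal global affine score by exhaustive enumeration of all paths.

    A gap of length k costs gap_open + (k-1) * gap_extend. Exponential in
    the input lengths; intended for len <= 8.
    """
    sub, idx = load_matrix(matrix)
    best = [-np.inf]

    def rec(i: int, j: int, score: float, last: str) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + sub[idx[a[i]], idx[b[j]]], "M")
        if i < len(a):
            rec(i + 1, j, score + (gap_extend if last == "X" else gap_open), "X")
        if j < len(b):
            rec(i, j + 1, score + (gap_extend if last == "Y" else gap_open), "Y")

    rec(0, 0, 0.0, "M")
    return float(best[0])


# ---------------------------------------------------------------------------
# Rule expressions: independent set-based recursive evaluator


def brute_rule_eval(node, ann, rules) -> bool:
    cls_of = {
        i: rules.class_of(acc) for i, (_, acc, _, _, _) in enumerate(ann.domains)
    }

    def members(cls: str) -> List[int]:
        rules.accessions(cls)  # raise on unknown
        return [i for i, c in cls_of.items() if c == cls]

    if isinstance(node, arch.Has):
        return len(members(node.cls)) > 0
    if isinstance(node, arch.Count):
        n = len(members(node.cls))
        return {"<=": n <= node.k, ">=": n >= node.k, "==": n == node.k}[node.op]
    if isinstance(node, arch.Order):
        return any(
            ann.domains[i][3] < ann.domains[j][2]
            for i in members(node.first)
            for j in members(node.second)
        )
    if isinstance(node, arch.Region):
        return any(
            node.start <= ann.domains[i][2] and ann.domains[i][3] <= node.end
            for i in members(node.cls)
        )
    if isinstance(node, arch.Not):
        return not brute_rule_eval(node.child, ann, rules)
    if isinstance(node, arch.And):
        return all(brute_rule_eval(c, ann, rules) for c in node.children)
    if isinstance(node, arch.Or):
        return any(brute_rule_eval(c, ann, rules) for c in node.children)
    raise TypeError(node)


# ---------------------------------------------------------------------------
# Overlap resolution: repeated max-pick under the dominance order


def brute_select_hits(hits, tolerance: int):
    """Greedy-by-repeated-max selection (independent of sort-based code)."""

    def overlap(h, k):
        return max(0, min(h.env_end, k.env_end) - max(h.env_start, k.env_start) + 1)

    remaining = list(hits)
    kept = []
    while remaining:
        best = min(remaining, key=lambda h: (-h.score, h.i_evalue, h.env_start))
        kept.append(best)
        remaining = [
            h for h in remaining if h is not best and overlap(h, best) <= tolerance
        ]
    return sorted(kept, key=lambda h: (h.env_start, h.env_end))


# ---------------------------------------------------------------------------
# Trees: random additive matrices, and exhaustive least-squares topology search


def random_additive_tree(
    rng: np.random.Generator, n: int
) -> Tuple[Dict[frozenset, float], np.ndarray]:
    """Random binary tree on taxa 0..n-1 with positive branch lengths.

    Returns (bipartition -> internal branch length map, n x n additive
    distance matrix computed by summing path lengths).
    """
    nodes = {i: [i] for i in range(n)}  # node id -> leaf list
    lengths: Dict[Tuple[int, int], float] = {}
    parent: Dict[int, int] = {}
    nxt = n
    active = list(range(n))
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        for child in (a, b):
            parent[child] = nxt
            lengths[(child, nxt)] = float(rng.uniform(0.05, 1.0))
        nodes[nxt] = nodes[a] + nodes[b]
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    a, b = active
    parent[a] = b
    lengths[(a, b)] = float(rng.uniform(0.05, 1.0))

    def path_to_root(x):
        out = []
        while x in parent:
            out.append((x, parent[x]))
            x = parent[x]
        return out

    D = np.zeros((n, n))
    for p in range(n):
        for q in range(p + 1, n):
            ep, eq = path_to_root(p), path_to_root(q)
            shared = set(ep) & set(eq)
            d = sum(lengths[e] for e in ep if e not in shared) + sum(
                lengths[e] for e in eq if e not in shared
            )
            D[p, q] = D[q, p] = d
    bips = {
        frozenset(nodes[x]): lengths[(x, px)]
        for (x, px) in lengths
        if x >= n
    }
    return bips, D


def five_taxon_topologies() -> List[List[frozenset]]:
    """All 15 unrooted 5-taxon topologies as pairs of nontrivial bipartitions."""
    taxa = set(range(5))
    tops = []
    for pair in itertools.combinations(range(5), 2):
        rest = sorted(taxa - set(pair))
        for other in itertools.combinations(rest, 2):
            b1, b2 = frozenset(pair), frozenset(other)
            key = frozenset([b1, b2])
            if key not in [frozenset(t) for t in tops]:
                tops.append([b1, b2])
    return tops


def _edges_for_topology(bips: List[frozenset], n: int):
    """Edge list (as leaf-set of one side) for an unrooted binary topology."""
    edges = [frozenset([i]) for i in range(n)]
    edges.extend(bips)
    return edges


def ls_fit_sse(D: np.ndarray, bips: List[frozenset]) -> float:
    """Least-squares branch lengths for a topology; returns the SSE."""
    n = D.shape[0]
    edges = _edges_for_topology(bips, n)
    pairs = list(itertools.combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([D[p, q] for p, q in pairs])
    for r, (p, q) in enumerate(pairs):
        for c, side in enumerate(edges):
            if (p in side) != (q in side):
                A[r, c] = 1.0
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = A @ x - y
    return float(resid @ resid)


def best_ls_topology(D: np.ndarray) -> List[frozenset]:
    """Exhaustive least-squares winner over all 15 5-taxon topologies."""
    tops = five_taxon_topologies()
    sses = [ls_fit_sse(D, t) for t in tops]
    return tops[int(np.argmin(sses))]


def tree_bipartitions(tree, names: Sequence[str]) -> set:
    """Nontrivial bipartitions of an skbio tree as frozensets of indices."""
    index = {str(nm): i for i, nm in enumerate(names)}
    n = len(names)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(index[t.name] for t in node.tips())
        if 2 <= len(side) <= n - 2:
            comp = frozenset(range(n)) - side
            out.add(min(side, comp, key=lambda s: (len(s), sorted(s))))
    return out


def normalize_bips(bips, n: int) -> set:
    out = set()
    for side in bips:
        comp = frozenset(range(n)) - side
        out.add(min(side, comp, key=lambda s: (len(s), sorted(s))))
    return out
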