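"""Distance-based phylogenetic placement of candidate sequences.

Queries are aligned together with labelled reference exemplars
(progressive profile alignment over an average-linkage guide tree),
gappy columns are trimmed (columns with more than the configured gap
fraction removed), a neighbor-joining tree is built from pairwise
distances, bipartition supports are estimated by nonparametric bootstrap
(column resampling), and each query receives the label of the smallest
well-supported clade that contains it together with references of exactly
one label. This distance pipeline is the package's documented substitute
for maximum-likelihood inference with model selection.

Determinism: NJ picks the pair with the smallest Q value, ties broken by
lexicographic index order; bootstrap replication is driven by a single
seed; guide-tree construction uses edit distances and average linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import edlib
import numpy as np
import skbio
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .config import PipelineConfig
from .motif_map import _affine_dp, encode, load_matrix
from .seqio import SequenceRecord

__all__ = [
    "MultipleAlignment",
    "PhyloPlacement",
    "build_msa",
    "trim_alignment",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "assign_by_placement",
    "place_queries",
]


@dataclass
class MultipleAlignment:
    """Rows of equal-length gapped sequences, in input order."""

    ids: List[str]
    rows: List[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


def _codes(rows: Sequence[str], idx: Dict[str, int]) -> np.ndarray:
    """Encode gapped rows; gaps become -1."""
    x = idx.get("X", 0)
    lut = np.full(128, x, dtype=np.int16)
    for ch, i in idx.items():
        lut[ord(ch)] = i
    lut[ord("-")] = -1
    arr = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    return lut[arr].reshape(len(rows), -1)


def _profile_freqs(codes: np.ndarray, n_letters: int) -> np.ndarray:
    """Per-column residue frequencies (L, n_letters); gaps contribute zero."""
    n, L = codes.shape
    out = np.zeros((L, n_letters), dtype=np.float64)
    for r in range(n):
        row = codes[r]
        ok = row >= 0
        out[np.nonzero(ok)[0], row[ok]] += 1.0
    return out / n


def _merge_profiles(
    rows_a: List[str],
    rows_b: List[str],
    sub: np.ndarray,
    idx: Dict[str, int],
    gap_open: float,
    gap_extend: float,
) -> List[str]:
    ca = _codes(rows_a, idx)
    cb = _codes(rows_b, idx)
    fa = _profile_freqs(ca, sub.shape[0])
    fb = _profile_freqs(cb, sub.shape[0])
    smat = np.ascontiguousarray((fa @ sub) @ fb.T)
    _, cols_a, cols_b = _affine_dp(smat, gap_open, gap_extend, True)
    out: List[str] = []
    for row in rows_a:
        out.append("".join(row[i] if i >= 0 else "-" for i in cols_a))
    for row in rows_b:
        out.append("".join(row[j] if j >= 0 else "-" for j in cols_b))
    return out


def build_msa(
    seqs: Sequence[SequenceRecord], config: Optional[PipelineConfig] = None
) -> MultipleAlignment:
    """Progressive multiple alignment over an average-linkage guide tree.

    Guide distances are normalised edit distances; profiles are merged by
    the same affine dynamic programme as pairwise alignment (free end
    gaps). Deterministic for a given input order. Degapping any output row
    reproduces the corresponding input sequence.
    """
    config = config or PipelineConfig()
    ids = [r.id for r in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in alignment input")
    if len(seqs) == 0:
        raise ValueError("need at least one sequence")
    if len(seqs) == 1:
        return MultipleAlignment(ids, [seqs[0].residues])
    sub, idx = load_matrix(config.matrix)

    n = len(seqs)
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(seqs[i].residues, seqs[j].residues, task="distance")[
                "editDistance"
            ]
            cond.append(d / max(len(seqs[i]), len(seqs[j])))
    Z = linkage(np.array(cond), method="average")

    clusters: Dict[int, Tuple[List[int], List[str]]] = {
        i: ([i], [seqs[i].residues]) for i in range(n)
    }
    nxt = n
    for a, b, _, _ in Z:
        ia, rows_a = clusters.pop(int(a))
        ib, rows_b = clusters.pop(int(b))
        clusters[nxt] = (
            ia + ib,
            _merge_profiles(rows_a, rows_b, sub, idx, config.gap_open, config.gap_extend),
        )
        nxt += 1
    order, rows = clusters.popitem()[1]
    by_input = {orig: row for orig, row in zip(order, rows)}
    return MultipleAlignment(ids, [by_input[i] for i in range(n)])


def trim_alignment(msa: MultipleAlignment, config: PipelineConfig) -> MultipleAlignment:
    """Drop columns whose gap fraction exceeds ``trim_max_gap_fraction``.

    Strictly "more than": a column at exactly the threshold is retained.
    Column order is preserved and the operation is idempotent.
    """
    n = len(msa.rows)
    keep = [
        c
        for c in range(msa.n_cols)
        if sum(row[c] == "-" for row in msa.rows) / n <= config.trim_max_gap_fraction
    ]
    if not keep:
        raise ValueError(
            "trimming removed every column; raise trim_max_gap_fraction or "
            "inspect the alignment"
        )
    rows = ["".join(row[c] for c in keep) for row in msa.rows]
    return MultipleAlignment(list(msa.ids), rows)


def distance_matrix(
    msa: MultipleAlignment, model: str = "poisson"
) -> np.ndarray:
    """Pairwise distances with pairwise deletion of gapped columns.

    ``p``: proportion of differing comparable sites. ``poisson``:
    -ln(1 - p) correction (p is capped at 0.99 to keep it finite).
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model: {model!r}")
    _, idx = load_matrix("BLOSUM62")
    codes = _codes(msa.rows, idx)
    n, L = codes.shape
    n_letters = 25
    onehot = np.zeros((n, L, n_letters), dtype=np.float32)
    valid = codes >= 0
    rr, cc = np.nonzero(valid)
    onehot[rr, cc, codes[valid]] = 1.0
    flat = onehot.reshape(n, -1)
    matches = flat @ flat.T
    v = valid.astype(np.float32)
    comparable = v @ v.T
    if n > 1 and (comparable + np.eye(n) * 1.0 == 0).any():
        bad = np.argwhere(comparable == 0)
        bad = [tuple(x) for x in bad if x[0] != x[1]]
        if bad:
            i, j = bad[0]
            raise ValueError(
                f"no comparable columns between {msa.ids[i]} and {msa.ids[j]}"
            )
    with np.errstate(invalid="ignore"):
        p = 1.0 - matches / np.maximum(comparable, 1.0)
    np.fill_diagonal(p, 0.0)
    p = np.clip((p + p.T) / 2.0, 0.0, 0.99)
    if model == "p":
        return p.astype(np.float64)
    return (-np.log1p(-p)).astype(np.float64)


# ---------------------------------------------------------------------------
# Neighbor joining


def _nj_core(dist: np.ndarray):
    """NJ agglomeration; returns joins and the final unresolved trio.

    joins: list of (left node, right node, left length, right length,
    new node id, merged leaf index set). Leaf ids are 0..n-1; internal
    nodes are numbered from n upward. Tie-break: smallest Q, then
    lexicographic (row, column) in the current active matrix.
    """
    n = dist.shape[0]
    D = dist.astype(np.float64).copy()
    active = list(range(n))  # node ids per matrix index
    leafsets: Dict[int, FrozenSet[int]] = {i: frozenset([i]) for i in range(n)}
    joins = []
    nxt = n
    while len(active) > 3:
        m = D.shape[0]
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        k = int(np.argmin(Q))  # row-major first minimum = lexicographic tie-break
        i, j = divmod(k, m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        ni, nj = active[i], active[j]
        leafsets[nxt] = leafsets[ni] | leafsets[nj]
        joins.append((ni, nj, li, lj, nxt, leafsets[nxt]))
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = new_row[keep]
        D2[:-1, -1] = new_row[keep]
        D2[-1, -1] = 0.0
        D = D2
        active = [active[x] for x in keep] + [nxt]
        nxt += 1
    # final trio joined at an (unrooted) central node
    (a, b, c) = active
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    return joins, (a, b, c), (la, lb, lc), leafsets


def nj_tree(dist: np.ndarray, ids: Sequence[str]) -> skbio.TreeNode:
    """Neighbor-joining tree (unrooted; trifurcating root node).

    Exact on additive matrices: the tree's path lengths reproduce the
    input distances. Negative branch-length estimates (possible on
    non-additive input) are clamped to zero.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n != dist.shape[1] or not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if np.abs(np.diag(dist)).max() > 1e-12:
        raise ValueError("distance matrix diagonal must be zero")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if len(ids) != n:
        raise ValueError("ids length must match matrix size")

    joins, trio, trio_len, _ = _nj_core(dist)
    nodes: Dict[int, skbio.TreeNode] = {
        i: skbio.TreeNode(name=str(ids[i])) for i in range(n)
    }
    for ni, nj, li, lj, new, _ in joins:
        a, b = nodes.pop(ni), nodes.pop(nj)
        a.length = max(float(li), 0.0)
        b.length = max(float(lj), 0.0)
        nodes[new] = skbio.TreeNode(children=[a, b])
    children = []
    for node_id, ln in zip(trio, trio_len):
        ch = nodes.pop(node_id)
        ch.length = max(float(ln), 0.0)
        children.append(ch)
    return skbio.TreeNode(children=children)


def _canonical(bip: FrozenSet[str], all_leaves: FrozenSet[str], anchor: str) -> FrozenSet[str]:
    """Canonical side of a bipartition: the side not holding the anchor."""
    return (all_leaves - bip) if anchor in bip else bip


def _bipartitions_from_core(dist: np.ndarray, names: Sequence[str]):
    joins = _nj_core(dist)[0]
    n = dist.shape[0]
    out = set()
    for *_, leafset in joins:
        if 2 <= len(leafset) <= n - 2:
            out.add(frozenset(names[i] for i in leafset))
    return out


def bootstrap_support(
    msa: MultipleAlignment,
    reps: int,
    seed: int,
    config: Optional[PipelineConfig] = None,
) -> Dict[FrozenSet[str], int]:
    """Nonparametric bootstrap supports for the NJ tree of an alignment.

    Columns are resampled with replacement ``reps`` times; each replicate
    alignment is rebuilt into an NJ tree and the recovery of every
    bipartition of the full-data tree is counted. Supports are integer
    percentages keyed by the canonical bipartition (the side not containing
    the lexicographically smallest leaf). Deterministic per seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    config = config or PipelineConfig()
    names = list(msa.ids)
    all_leaves = frozenset(names)
    anchor = min(names)
    full = distance_matrix(msa, config.distance_model)
    main = {
        _canonical(b, all_leaves, anchor)
        for b in _bipartitions_from_core(full, names)
    }
    counts = {b: 0 for b in main}
    rng = np.random.default_rng(seed)
    L = msa.n_cols
    rows_arr = np.frombuffer("".join(msa.rows).encode("ascii"), dtype=np.uint8).reshape(
        len(names), L
    )
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        rep_rows = ["".join(map(chr, rows_arr[i, cols])) for i in range(len(names))]
        rep = MultipleAlignment(names, rep_rows)
        try:
            d = distance_matrix(rep, config.distance_model)
        except ValueError:
            continue  # replicate with an incomparable pair is skipped
        bips = {
            _canonical(b, all_leaves, anchor)
            for b in _bipartitions_from_core(d, names)
        }
        for b in main:
            if b in bips:
                counts[b] += 1
    return {b: int(round(100.0 * c / reps)) for b, c in counts.items()}


@dataclass
class PhyloPlacement:
    """A placement tree with supports and per-query clade assignments."""

    tree: Optional[skbio.TreeNode]
    supports: Dict[FrozenSet[str], int] = field(default_factory=dict)
    # query id -> (assigned label or None, support of the defining clade)
    assignments: Dict[str, Tuple[Optional[str], int]] = field(default_factory=dict)

    def label_of(self, seq_id: str) -> Optional[str]:
        return self.assignments.get(seq_id, (None, 0))[0]


def assign_by_placement(
    tree: skbio.TreeNode,
    supports: Dict[FrozenSet[str], int],
    query_ids: Sequence[str],
    ref_labels: Dict[str, str],
    min_support: int,
) -> Dict[str, Tuple[Optional[str], int]]:
    """Label queries from the reference clades they nest within.

    The tree is midpoint rooted (placement trees are unrooted; a root is a
    reading convention only). For each query, ancestors are walked from the
    leaf towards the root; nodes without references or with support below
    ``min_support`` are skipped; the first remaining node decides - a single
    reference label assigns it, mixed labels leave the query unclassified.
    Never returns a label absent from the reference panel.
    """
    rooted = tree.copy()
    try:
        rooted = rooted.root_at_midpoint()
    except Exception:
        pass  # degenerate (e.g. all-zero lengths): keep original rooting
    leaves = {leaf.name for leaf in rooted.tips()}
    for q in query_ids:
        if q not in leaves:
            raise KeyError(f"query {q!r} absent from placement tree")
    anchor = min(leaves)
    all_leaves = frozenset(leaves)

    leafset: Dict[int, FrozenSet[str]] = {}
    for node in rooted.postorder(include_self=True):
        if node.is_tip():
            leafset[id(node)] = frozenset([node.name])
        else:
            s: FrozenSet[str] = frozenset()
            for ch in node.children:
                s |= leafset[id(ch)]
            leafset[id(node)] = s

    tip_by_name = {leaf.name: leaf for leaf in rooted.tips()}
    out: Dict[str, Tuple[Optional[str], int]] = {}
    for q in query_ids:
        node = tip_by_name[q].parent
        verdict: Tuple[Optional[str], int] = (None, 0)
        while node is not None:
            ls = leafset[id(node)]
            labels = {ref_labels[x] for x in ls if x in ref_labels}
            if labels:
                if node.parent is None:
                    sup = 100  # whole-tree "clade": trivially present
                else:
                    key = _canonical(ls, all_leaves, anchor)
                    sup = supports.get(key, 0)
                if sup >= min_support:
                    verdict = (labels.pop(), sup) if len(labels) == 1 else (None, sup)
                    break
            node = node.parent
        out[q] = verdict
    return out


def place_queries(
    queries: Sequence[SequenceRecord],
    references: Sequence[Tuple[SequenceRecord, str]],
    config: PipelineConfig,
    seed: int,
) -> PhyloPlacement:
    """End-to-end placement: MSA -> trim -> distances -> NJ -> bootstrap -> labels."""
    if not queries:
        return PhyloPlacement(tree=None)
    if len({lbl for _, lbl in references}) < 1:
        raise ValueError("reference panel must carry at least one label")
    ref_labels = {rec.id: lbl for rec, lbl in references}
    seqs = list(queries) + [rec for rec, _ in references]

    if len(seqs) < 4:  # too few taxa for NJ + bootstrap: nearest reference
        assignments = {}
        for q in queries:
            best = min(
                references,
                key=lambda r: edlib.align(q.residues, r[0].residues, task="distance")[
                    "editDistance"
                ],
            )
            assignments[q.id] = (best[1], 100)
        return PhyloPlacement(tree=None, assignments=assignments)

    msa = trim_alignment(build_msa(seqs, config), config)
    dist = distance_matrix(msa, config.distance_model)
    tree = nj_tree(dist, msa.ids)
    supports = bootstrap_support(msa, config.bootstrap_reps, seed, config)
    assignments = assign_by_placement(
        tree, supports, [q.id for q in queries], ref_labels, config.min_support
    )

    # novelty guard: keep a clade label only when the query is closer to
    # that label's exemplars than to every other label's by a clear margin;
    # queries roughly equidistant from all subfamilies (novel or
    # paraphyletic lineages) must not inherit the nearest panel label.
    col = {sid: k for k, sid in enumerate(msa.ids)}
    by_label: Dict[str, List[int]] = {}
    for rid, lbl in ref_labels.items():
        by_label.setdefault(lbl, []).append(col[rid])
    if len(by_label) > 1:
        for q in queries:
            label, sup = assignments[q.id]
            if label is None:
                continue
            d_own = min(dist[col[q.id], i] for i in by_label[label])
            d_other = min(
                dist[col[q.id], i]
                for lbl, cols in by_label.items()
                if lbl != label
                for i in cols
            )
            if d_own > config.placement_margin_ratio * d_other:
                assignments[q.id] = (None, sup)
    return PhyloPlacement(tree=tree, supports=supports, assignments=assignments)
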