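"""Neighbor-joining trees over CSR fingerprints, with column bootstrap.

The evolutionary analysis of the family rests on the alignment of the five
CSRs only: pairwise distances are p-distances (mismatch fraction) over the 36
concatenated fingerprint columns, trees are built with the Saitou-Nei
neighbor-joining agglomeration, and edge supports come from Felsenstein's
bootstrap, resampling the 36 columns with replacement (1000 trials by
default).  The distance metric is the simplest faithful choice given that the
source analysis specifies only "alignment of the CSRs + neighbor joining";
any other symmetric matrix can be supplied directly.

Determinism: ties in the Q-matrix are broken toward the smallest (i, j) index
pair; negative branch lengths are clamped to zero with the deficit moved to
the sibling edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode

from .detect import encode_sequence
from .schema import FINGERPRINT_LENGTH

_UNKNOWN = 20


class PhyloError(ValueError):
    """Invalid distance matrix or fingerprint input."""


def p_distance(fp_a: str, fp_b: str) -> float:
    """Mismatch fraction between two equal-length fingerprints.

    Positions where either residue is outside the 20-letter alphabet are
    excluded from both numerator and denominator.
    """
    if len(fp_a) != len(fp_b):
        raise PhyloError(f"length mismatch: {len(fp_a)} vs {len(fp_b)}")
    a = encode_sequence(fp_a)
    b = encode_sequence(fp_b)
    valid = (a < _UNKNOWN) & (b < _UNKNOWN)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise PhyloError("no comparable standard-residue positions")
    return float(((a != b) & valid).sum() / n_valid)


def pdistance_matrix(fingerprints: Sequence[str], ids: Sequence[str] | None = None) -> DistanceMatrix:
    """Symmetric p-distance matrix over a set of fingerprints."""
    n = len(fingerprints)
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    if len(ids) != n:
        raise PhyloError("ids must match fingerprints")
    enc = np.array([encode_sequence(fp) for fp in fingerprints])
    valid = enc < _UNKNOWN
    pair_valid = valid[:, None, :] & valid[None, :, :]
    mism = (enc[:, None, :] != enc[None, :, :]) & pair_valid
    denom = pair_valid.sum(axis=2)
    if (denom == 0).any():
        raise PhyloError("some fingerprint pair has no comparable positions")
    D = mism.sum(axis=2) / denom
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, ids)


def _as_matrix(dm, ids=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(dm, DistanceMatrix):
        return np.array(dm.data, dtype=float), list(dm.ids)
    D = np.asarray(dm, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise PhyloError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise PhyloError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise PhyloError("distance matrix must have a zero diagonal")
    if ids is None:
        ids = [str(i) for i in range(D.shape[0])]
    return D, list(ids)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # negative branch length: clamp to 0, move the deficit to the sibling
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def _nj_agglomerate(D: np.ndarray):
    """Run NJ merges on a copy of ``D``.

    Returns ``(merges, star)`` where each merge is ``(node_a, node_b, la, lb,
    new_node)`` over a node numbering in which 0..n-1 are the leaves and new
    internal nodes are numbered consecutively, and ``star`` is the final
    three-way join ``[(node, length), ...]``.
    """
    n = D.shape[0]
    if n < 3:
        raise PhyloError("neighbor joining requires at least 3 taxa")
    D = D.copy()
    active = list(range(n))
    next_node = n
    merges = []
    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = Q[iu]
        k = int(np.argmin(flat))  # first occurrence = smallest (i, j) pair
        i, j = int(iu[0][k]), int(iu[1][k])
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2 * (m - 2))
        lj = d_ij - li
        li, lj = _clamp_pair(float(li), float(lj))
        merges.append((active[i], active[j], li, lj, next_node))

        new_row = 0.5 * (D[i] + D[j] - d_ij)
        keep = [x for x in range(m) if x not in (i, j)]
        D_new = np.empty((m - 1, m - 1))
        D_new[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D_new[: m - 2, m - 2] = new_row[keep]
        D_new[m - 2, : m - 2] = new_row[keep]
        D_new[m - 2, m - 2] = 0.0
        D = D_new
        active = [active[x] for x in keep] + [next_node]
        next_node += 1

    (a, b, c) = active
    d_ab, d_ac, d_bc = D[0, 1], D[0, 2], D[1, 2]
    la = max(0.5 * (d_ab + d_ac - d_bc), 0.0)
    lb = max(0.5 * (d_ab + d_bc - d_ac), 0.0)
    lc = max(0.5 * (d_ac + d_bc - d_ab), 0.0)
    star = [(a, float(la)), (b, float(lb)), (c, float(lc))]
    return merges, star


def _build_tree(ids: Sequence[str], merges, star) -> tuple[TreeNode, dict[int, int]]:
    """Materialise the merge list as an unrooted tree (degree-3 root).

    Also returns the leaf bitmask of every created internal node, keyed by
    node number; each such mask corresponds to one internal edge.
    """
    n = len(ids)
    nodes: dict[int, TreeNode] = {i: TreeNode(name=ids[i]) for i in range(n)}
    masks: dict[int, int] = {i: 1 << i for i in range(n)}
    internal_masks: dict[int, int] = {}
    for a, b, la, lb, new in merges:
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length = la
        nb.length = lb
        parent = TreeNode(children=[na, nb])
        nodes[new] = parent
        masks[new] = masks[a] | masks[b]
        internal_masks[new] = masks[new]
    children = []
    for node_id, length in star:
        child = nodes.pop(node_id)
        child.length = length
        children.append(child)
    root = TreeNode(children=children)
    root.length = None
    return root, internal_masks


def neighbor_joining(dm, ids: Sequence[str] | None = None) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree (trifurcating root).

    Accepts a ``skbio.DistanceMatrix`` or any square symmetric array with an
    optional ``ids`` sequence.
    """
    D, ids = _as_matrix(dm, ids)
    merges, star = _nj_agglomerate(D)
    tree, _ = _build_tree(ids, merges, star)
    return tree


def _split_keys(masks, n_leaves: int) -> set[int]:
    full = (1 << n_leaves) - 1
    keys = set()
    for mask in masks:
        keys.add(min(mask, full ^ mask))
    return keys


def tree_splits(tree: TreeNode, ids: Sequence[str]) -> set[int]:
    """Non-trivial bipartitions of a tree as canonical leaf bitmasks."""
    index = {name: i for i, name in enumerate(ids)}
    full = (1 << len(ids)) - 1
    keys = set()
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            node._mask = 1 << index[node.name]
        else:
            node._mask = 0
            for child in node.children:
                node._mask |= child._mask
            if node._mask not in (0, full):
                keys.add(min(node._mask, full ^ node._mask))
    return keys


def bootstrap_support(
    fingerprints: Sequence[str],
    ids: Sequence[str] | None = None,
    n_trials: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """NJ tree with column-bootstrap supports on its internal edges.

    Each trial resamples the 36 fingerprint columns with replacement,
    recomputes the p-distance matrix and the NJ tree; the support of an edge
    is the fraction of trials whose tree contains the same bipartition.
    Supports are stored on internal nodes as ``node.support`` and mirrored
    into ``node.name``.
    """
    if n_trials < 1:
        raise PhyloError("n_trials must be >= 1")
    n = len(fingerprints)
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    enc = np.array([encode_sequence(fp) for fp in fingerprints])
    if enc.shape[1] != FINGERPRINT_LENGTH:
        raise PhyloError("fingerprints must have length 36")
    valid = enc < _UNKNOWN
    pair_valid = valid[:, None, :] & valid[None, :, :]
    mism = (enc[:, None, :] != enc[None, :, :]) & pair_valid

    def matrix(cols: np.ndarray) -> np.ndarray:
        num = mism[:, :, cols].sum(axis=2)
        den = pair_valid[:, :, cols].sum(axis=2)
        den = np.where(den == 0, 1, den)
        D = num / den
        np.fill_diagonal(D, 0.0)
        return D

    all_cols = np.arange(FINGERPRINT_LENGTH)
    merges, star = _nj_agglomerate(matrix(all_cols))
    tree, internal_masks = _build_tree(ids, merges, star)
    ref_keys = _split_keys(internal_masks.values(), n)

    rng = np.random.default_rng(seed)
    full = (1 << n) - 1
    counts = {key: 0 for key in ref_keys}
    for _ in range(n_trials):
        cols = rng.integers(0, FINGERPRINT_LENGTH, FINGERPRINT_LENGTH)
        trial_merges, _ = _nj_agglomerate(matrix(cols))
        mask_of = {i: 1 << i for i in range(n)}
        trial_keys = set()
        for a, b, _la, _lb, new in trial_merges:
            mask_of[new] = mask_of[a] | mask_of[b]
            trial_keys.add(min(mask_of[new], full ^ mask_of[new]))
        for key in counts:
            if key in trial_keys:
                counts[key] += 1

    tree_splits(tree, ids)  # annotates node._mask
    for node in tree.non_tips(include_self=False):
        key = min(node._mask, full ^ node._mask)
        if key in counts:
            node.support = counts[key] / n_trials
            node.name = f"{node.support:g}"
    return tree


def monophyly_fraction(tree: TreeNode, labels: Mapping[str, str]) -> dict[str, float]:
    """How cleanly each labeled group forms a single clade of the tree.

    For each group the score is 1.0 if some edge of the (unrooted) tree
    induces exactly that group's leaf set, and otherwise the best Jaccard
    overlap between the group and any edge-induced leaf set (either side of
    the edge).  Leaf edges count, so singleton groups always score 1.
    """
    leaf_names = [tip.name for tip in tree.tips()]
    missing = [name for name in leaf_names if name not in labels]
    if missing:
        raise PhyloError(f"labels missing for leaves: {missing[:5]}")
    all_leaves = frozenset(leaf_names)
    clades: list[frozenset] = []
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            node._clade = frozenset([node.name])
        else:
            acc: set = set()
            for child in node.children:
                acc |= child._clade
            node._clade = frozenset(acc)
        clades.append(node._clade)

    groups: dict[str, set] = {}
    for leaf in leaf_names:
        groups.setdefault(labels[leaf], set()).add(leaf)

    scores = {}
    for group, members in groups.items():
        best = 0.0
        for clade in clades:
            for side in (clade, all_leaves - clade):
                inter = len(members & side)
                union = len(members | side)
                if union:
                    best = max(best, inter / union)
            if best == 1.0:
                break
        scores[group] = best
    return scores
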