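"""Max-tree construction and the hyperconnected openings codified on it.

The max-tree of a grayscale volume f is the rooted tree of peak components of
the upper threshold sets of f; its leaves are the regional maxima Max(f).
Each regional maximum Mi defines a hyperconnected function

    gMi = R(f, hMi),   hMi = f on Mi and 0 elsewhere,

the geodesic reconstruction of f from that maximum alone. gMi has exactly one
regional maximum, and the family W(f) = {gMi} covers f (their supremum is f).
On the tree, gMi evaluates at voxel p to the gray level of the lowest common
ancestor of p's node and the leaf Mi, which makes both the reconstructions and
their volumes Vol(gMi) = sum_p gMi(p) computable without materialising each
gMi.

The hyperconnected opening keeps the supremum of the gMi whose volume meets an
increasing criterion (a volume threshold mu_v, or the extreme criterion: the
largest volume attained). Sandwiching that selection between an erosion and a
dilation at size lam yields the viscous hyperconnected opening, the operator
the skull-stripping pipelines are built on.

Tree construction is union-find by descending gray level over an arbitrary
neighbour-offset adjacency, so the tree can be built on the graph induced by
the structuring element itself (the default here: for the 11-neighbour
element, 10 neighbours in 3D, plain 8-connectivity in 2D) as well as on the
standard 6/18/26 and 4/8 connectivities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np

from .morphology import (
    StructuringElement,
    as_volume,
    connectivity_footprint,
    dilate,
    erode,
    get_se,
)

__all__ = [
    "MaxTree",
    "MaximumRecord",
    "build_maxtree",
    "reconstruct_from_maximum",
    "maxima_volumes",
    "hyperconnected_opening",
    "extreme_hyperconnected",
    "viscous_hyperconnected_opening",
]


# --------------------------------------------------------------------------
# adjacency resolution
# --------------------------------------------------------------------------

def _neighbor_offsets(connectivity, se) -> np.ndarray:
    """(k, 3) array of neighbour offsets for the flat-zone adjacency.

    ``connectivity=None`` selects the graph induced by the structuring
    element ``se`` (default: the 11-neighbour element).
    """
    if connectivity is None:
        return get_se(se).neighbor_offsets()
    if isinstance(connectivity, StructuringElement):
        return connectivity.neighbor_offsets()
    fp = connectivity_footprint(connectivity)
    c = np.array(fp.shape) // 2
    offs = np.argwhere(fp) - c
    offs = offs[np.any(offs != 0, axis=1)]
    return np.ascontiguousarray(offs, dtype=np.int64)


# --------------------------------------------------------------------------
# numba kernels (flat index arithmetic over a 3D grid)
# --------------------------------------------------------------------------

@numba.njit(cache=False)
def _find_root(zpar, p):
    r = p
    while zpar[r] != r:
        r = zpar[r]
    # path compression
    while zpar[p] != r:
        q = zpar[p]
        zpar[p] = r
        p = q
    return r


@numba.njit(cache=False)
def _union_find_parents(values, order, nz, ny, nx, offs):
    """Berger-style union-find max-tree: process voxels by descending value,
    merging with already-processed neighbours. Returns the raw pixel parent
    array (root self-parented)."""
    n = values.size
    parent = np.full(n, -1, np.int64)
    zpar = np.full(n, -1, np.int64)
    k = offs.shape[0]
    for i in range(n):
        p = order[i]
        parent[p] = p
        zpar[p] = p
        z = p // (ny * nx)
        rem = p - z * ny * nx
        y = rem // nx
        x = rem - y * nx
        for j in range(k):
            zz = z + offs[j, 0]
            yy = y + offs[j, 1]
            xx = x + offs[j, 2]
            if zz < 0 or zz >= nz or yy < 0 or yy >= ny or xx < 0 or xx >= nx:
                continue
            q = (zz * ny + yy) * nx + xx
            if zpar[q] == -1:
                continue  # not processed yet (strictly lower value)
            r = _find_root(zpar, q)
            if r != p:
                parent[r] = p
                zpar[r] = p
    return parent


@numba.njit(cache=False)
def _canonize(values, parent, order):
    """Make every voxel point to the canonical voxel of its parent node
    (or of its own node, for non-canonical voxels). Voxels are visited by
    ascending value so that ancestors are canonical first."""
    n = order.size
    for i in range(n - 1, -1, -1):
        p = order[i]
        q = parent[p]
        if values[parent[q]] == values[q]:
            parent[p] = parent[q]


@numba.njit(cache=False)
def _accumulate_areas(node_parent, counts):
    """In-place: add each node's count into its parent, children first
    (node ids ascend from root to leaves)."""
    for i in range(counts.size - 1, 0, -1):
        counts[node_parent[i]] += counts[i]


@numba.njit(cache=False)
def _leaf_volumes(node_level, node_parent, node_area, leaves):
    """Vol(gMi) for each leaf via its root path: the voxels whose LCA with the
    leaf is an ancestor a contribute level(a) times the area exclusive to a
    (area(a) minus the area of a's child on the path)."""
    out = np.zeros(leaves.size, np.int64)
    for i in range(leaves.size):
        leaf = leaves[i]
        v = np.int64(node_level[leaf]) * node_area[leaf]
        c = leaf
        a = node_parent[c]
        while a != c:
            v += np.int64(node_level[a]) * (node_area[a] - node_area[c])
            c = a
            a = node_parent[c]
        out[i] = v
    return out


@numba.njit(cache=False)
def _selection_values(node_level, node_parent, selected_nodes):
    """Per-node value of sup{gMi : Mi in selection}: a node whose subtree
    holds a selected leaf evaluates to its own level, any other node inherits
    its parent's value; an empty selection gives the all-zero bottom."""
    n = node_level.size
    contains = np.zeros(n, np.bool_)
    for j in range(selected_nodes.size):
        contains[selected_nodes[j]] = True
    for i in range(n - 1, 0, -1):
        if contains[i]:
            contains[node_parent[i]] = True
    val = np.zeros(n, np.int64)
    for i in range(n):
        if contains[i]:
            val[i] = node_level[i]
        elif i != node_parent[i]:
            val[i] = val[node_parent[i]]
    return val


# --------------------------------------------------------------------------
# tree structure
# --------------------------------------------------------------------------

@dataclass
class MaxTree:
    """Canonical max-tree of a grayscale volume.

    Node ids ascend from the root (id 0) toward the leaves, so a node's parent
    always has a smaller id and a strictly lower gray level.

    Attributes
    ----------
    node_level : (n_nodes,) gray level of each node's peak component.
    parent : (n_nodes,) parent node id; the root is self-parented.
    pixel_node : canonical node id per voxel, shaped like the input.
    node_area : voxel count of each node's peak component (itself plus all
        descendants).
    leaves : node ids with no children — the regional maxima Max(f).
    """

    node_level: np.ndarray
    parent: np.ndarray
    pixel_node: np.ndarray
    node_area: np.ndarray
    leaves: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.node_level.size

    def reconstruct(self) -> np.ndarray:
        """Tree reconstruction identity: each voxel takes its node's level,
        recovering the input exactly."""
        return self.node_level[self.pixel_node].astype(np.uint8)

    def leaf_plateau(self, leaf_id: int) -> np.ndarray:
        """Boolean mask of the regional-maximum plateau of one leaf."""
        self._check_leaf(leaf_id)
        return self.pixel_node == leaf_id

    def _check_leaf(self, leaf_id: int):
        if leaf_id not in set(self.leaves.tolist()):
            raise ValueError(f"node {leaf_id} is not a leaf of this max-tree")


def build_maxtree(f, connectivity=None, se=None) -> MaxTree:
    """Build the canonical max-tree of ``f``.

    ``connectivity`` may be 6/18/26 (3D), 4/8 (2D) or a StructuringElement;
    ``None`` uses the adjacency induced by ``se`` (default 11-neighbour
    element, i.e. 8-connectivity for 2D inputs).
    """
    vol, was_2d = as_volume(f)
    offs = _neighbor_offsets(connectivity, se)
    nz, ny, nx = vol.shape
    values = vol.ravel().astype(np.int64)
    n = values.size
    # descending value, ties by ascending index (deterministic)
    order = np.lexsort((np.arange(n), -values))
    parent = _union_find_parents(values, order, nz, ny, nx, offs)
    _canonize(values, parent, order)

    idx = np.arange(n)
    canonical = (values != values[parent]) | (idx == parent)
    canon_idx = np.flatnonzero(canonical)
    # ids ascend root -> leaves: sort canonical voxels by (value, index)
    sort = np.lexsort((canon_idx, values[canon_idx]))
    canon_sorted = canon_idx[sort]
    node_id = np.full(n, -1, np.int64)
    node_id[canon_sorted] = np.arange(canon_sorted.size)

    pixel_node = np.where(canonical, node_id, node_id[parent])
    node_parent = node_id[parent[canon_sorted]]
    # non-canonical voxel's parent is its own canonical voxel; for canonical
    # voxels, parent is the canonical voxel of the parent node (root: itself)
    node_level = values[canon_sorted]

    counts = np.bincount(pixel_node, minlength=canon_sorted.size).astype(np.int64)
    node_area = counts.copy()
    _accumulate_areas(node_parent, node_area)

    has_child = np.zeros(canon_sorted.size, dtype=bool)
    nonroot = np.arange(canon_sorted.size) != node_parent
    has_child[node_parent[nonroot]] = True
    leaves = np.flatnonzero(~has_child)

    shape = vol.shape[1:] if was_2d else vol.shape
    return MaxTree(
        node_level=node_level,
        parent=node_parent,
        pixel_node=pixel_node.reshape(shape),
        node_area=node_area,
        leaves=leaves,
    )


# --------------------------------------------------------------------------
# hyperconnected functions and openings
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MaximumRecord:
    """One regional maximum Mi with its reconstruction volume Vol(gMi)."""

    leaf_id: int
    level: int
    area: int
    volume: int


def _selection_image(tree: MaxTree, selected: np.ndarray) -> np.ndarray:
    val = _selection_values(tree.node_level, tree.parent,
                            np.asarray(selected, dtype=np.int64))
    return val[tree.pixel_node].astype(np.uint8)


def reconstruct_from_maximum(tree: MaxTree, f, leaf_id: int) -> np.ndarray:
    """The hyperconnected function gMi = R(f, hMi) for one regional maximum,
    evaluated on the tree: voxel p takes the level of the lowest common
    ancestor of p's node and the leaf."""
    tree._check_leaf(int(leaf_id))
    return _selection_image(tree, np.array([int(leaf_id)]))


def maxima_volumes(tree: MaxTree, f=None) -> list[MaximumRecord]:
    """One record per regional maximum, with Vol(gMi) computed tree-side from
    the leaf's root path (no gMi is materialised)."""
    vols = _leaf_volumes(tree.node_level, tree.parent, tree.node_area,
                         tree.leaves)
    return [
        MaximumRecord(
            leaf_id=int(leaf),
            level=int(tree.node_level[leaf]),
            area=int(tree.node_area[leaf]),
            volume=int(v),
        )
        for leaf, v in zip(tree.leaves, vols)
    ]


def _select_leaves(tree: MaxTree, criterion: str, mu_v) -> np.ndarray:
    """Leaf ids passing the increasing criterion.

    'threshold': Vol(gMi) >= mu_v. 'extreme': the leaves attaining the
    greatest volume (ties kept — their supremum is still a single
    hyperconnected selection, consistent with the opening's supremum).
    """
    vols = _leaf_volumes(tree.node_level, tree.parent, tree.node_area,
                         tree.leaves)
    if criterion == "extreme":
        best = vols.max()
        return tree.leaves[vols == best]
    if criterion == "threshold":
        if mu_v is None:
            raise ValueError("criterion 'threshold' requires mu_v")
        if mu_v < 0:
            raise ValueError(f"mu_v must be >= 0, got {mu_v}")
        return tree.leaves[vols >= mu_v]
    raise ValueError(f"unknown criterion {criterion!r}")


def hyperconnected_opening(f, mu_v, connectivity=None, se=None,
                           tree: MaxTree | None = None) -> np.ndarray:
    """Volume-criterion hyperconnected opening: the supremum of the gMi with
    Vol(gMi) >= mu_v; an empty selection yields the all-zero volume."""
    if mu_v < 0:
        raise ValueError(f"mu_v must be >= 0, got {mu_v}")
    if tree is None:
        tree = build_maxtree(f, connectivity=connectivity, se=se)
    selected = _select_leaves(tree, "threshold", mu_v)
    return _selection_image(tree, selected)


def extreme_hyperconnected(f, connectivity=None, se=None,
                           tree: MaxTree | None = None) -> np.ndarray:
    """Extreme hyperconnectivity: the supremum of the gMi attaining the
    greatest volume (all tied argmax maxima are kept)."""
    if tree is None:
        tree = build_maxtree(f, connectivity=connectivity, se=se)
    selected = _select_leaves(tree, "extreme", None)
    return _selection_image(tree, selected)


def viscous_hyperconnected_opening(f, lam: int, mode: str = "extreme",
                                   mu_v=None, se=None,
                                   connectivity=None) -> np.ndarray:
    """Viscous hyperconnected opening: dilation after hyperconnected selection
    after erosion, all at viscosity ``lam``.

    ``mode='extreme'`` keeps the greatest-volume maximum; ``mode='threshold'``
    keeps every maximum with Vol(gMi) >= mu_v. The result is bounded above by
    the morphological opening at the same size.
    """
    se = get_se(se)
    eroded = erode(f, se, lam)
    tree = build_maxtree(eroded, connectivity=connectivity, se=se)
    if mode == "extreme":
        g = extreme_hyperconnected(eroded, tree=tree)
    elif mode == "threshold":
        g = hyperconnected_opening(eroded, mu_v, tree=tree)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return dilate(g, se, lam)
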