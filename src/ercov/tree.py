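"""Unrooted, leaf-labelled phylogenies with bipartition-stable branch identity.

Every branch of an unrooted tree induces a bipartition of the leaf set.  We
identify a branch by the frozenset of leaf names on the side *not* containing
the lexicographically smallest leaf, which makes branch identity stable across
re-reads, re-orderings and prunings of the same topology.  All downstream
rate vectors and projections index branches by these ids, never by node
numbers, so tables written by one run resolve unambiguously in another.

Conventions: trees are unrooted throughout (a rooted Newick is unrooted by
suppressing the degree-2 root, summing its two incident branch lengths);
branch lengths are in substitutions per site and may be absent (``None``)
for topology-only trees.
"""

from __future__ import annotations

from collections import deque
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Tuple

import dendropy
import numpy as np

BranchId = FrozenSet[str]

__all__ = [
    "BranchId",
    "Phylogeny",
    "PruneCache",
    "TreeError",
    "NewickParseError",
    "TooFewSpeciesError",
]


class TreeError(ValueError):
    """Malformed or unusable tree input."""


class NewickParseError(TreeError):
    """The Newick string could not be parsed into a valid phylogeny."""


class TooFewSpeciesError(TreeError):
    """An operation needs more leaves than the tree (or subset) provides."""


def _other_end(edge, node):
    return edge[1] if edge[0] == node else edge[0]


def _splice_clean(edges: dict, labels: dict, keep: Optional[frozenset]) -> None:
    """In place: delete leaves outside ``keep``, drop dangling unlabelled
    nodes and splice out unlabelled degree-2 nodes, summing lengths and
    unioning origin-branch sets.

    ``edges`` maps edge id -> [u, v, length, origin_set]; ``labels`` maps
    leaf node -> name.  ``keep=None`` keeps every labelled leaf.
    """
    adj: dict = {}
    for eid, e in edges.items():
        adj.setdefault(e[0], set()).add(eid)
        adj.setdefault(e[1], set()).add(eid)
    for node in labels:
        adj.setdefault(node, set())

    def drop_edge(eid):
        e = edges.pop(eid)
        adj[e[0]].discard(eid)
        adj[e[1]].discard(eid)

    next_eid = (max(edges) + 1) if edges else 0
    queue = deque(sorted(adj, key=repr))
    while queue:
        n = queue.popleft()
        if n not in adj:
            continue
        lab = labels.get(n)
        if lab is not None and (keep is None or lab in keep):
            continue
        deg = len(adj[n])
        if lab is not None:
            for eid in list(adj[n]):
                m = _other_end(edges[eid], n)
                drop_edge(eid)
                queue.append(m)
            del adj[n]
            del labels[n]
        elif deg == 0:
            del adj[n]
        elif deg == 1:
            eid = next(iter(adj[n]))
            m = _other_end(edges[eid], n)
            drop_edge(eid)
            del adj[n]
            queue.append(m)
        elif deg == 2:
            e1, e2 = sorted(adj[n])
            u = _other_end(edges[e1], n)
            v = _other_end(edges[e2], n)
            l1, l2 = edges[e1][2], edges[e2][2]
            length = None if (l1 is None or l2 is None) else l1 + l2
            origin = edges[e1][3] | edges[e2][3]
            drop_edge(e1)
            drop_edge(e2)
            edges[next_eid] = [u, v, length, origin]
            adj[u].add(next_eid)
            adj[v].add(next_eid)
            next_eid += 1
            del adj[n]
            queue.append(u)
            queue.append(v)


class Phylogeny:
    """Immutable unrooted tree; branches carry bipartition ids.

    Parameters
    ----------
    edges:
        Iterable of ``(u, v, length)`` with hashable node ids; ``length``
        may be ``None``.
    leaf_labels:
        Mapping from node id to species name for every degree-1 node.
    """

    def __init__(self, edges: Iterable[tuple], leaf_labels: Mapping):
        self._edges: Tuple[tuple, ...] = tuple((u, v, l) for u, v, l in edges)
        self._labels: Dict = dict(leaf_labels)
        self._adj: Dict = {}
        for i, (u, v, _l) in enumerate(self._edges):
            if u == v:
                raise TreeError("self-loop edge")
            self._adj.setdefault(u, []).append(i)
            self._adj.setdefault(v, []).append(i)
        for node in self._labels:
            self._adj.setdefault(node, [])

        names = list(self._labels.values())
        if len(names) < 2:
            raise TreeError("a phylogeny needs at least two labelled leaves")
        if len(set(names)) != len(names):
            raise TreeError("duplicate leaf names")
        nodes = set(self._adj)
        if set(self._labels) - nodes:
            raise TreeError("labelled node not attached to the tree")
        for n in nodes:
            deg = len(self._adj[n])
            if deg <= 1 and n not in self._labels:
                raise TreeError("unlabelled terminal node")
            if deg >= 2 and n in self._labels:
                raise TreeError("labelled node with degree >= 2")
        if len(self._edges) != len(nodes) - 1:
            raise TreeError("edge count inconsistent with a tree")
        # connectivity
        seen = set()
        stack = [next(iter(nodes))]
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            for eid in self._adj[n]:
                stack.append(_other_end(self._edges[eid], n))
        if seen != nodes:
            raise TreeError("tree is not connected")

        self.leaf_names: frozenset = frozenset(names)
        self._node_of = {lab: n for n, lab in self._labels.items()}
        ref = min(self.leaf_names)
        bips = []
        for i, (u, v, _l) in enumerate(self._edges):
            side = self._side_leaves(i, v)
            if ref in side:
                side = self.leaf_names - side
            bips.append(frozenset(side))
        if len(set(bips)) != len(bips):
            raise TreeError("duplicate bipartition (unsuppressed degree-2 node?)")
        self._edge_bip: Tuple[BranchId, ...] = tuple(bips)
        order = sorted(
            range(len(bips)), key=lambda i: (len(bips[i]), tuple(sorted(bips[i])))
        )
        self.branch_ids: Tuple[BranchId, ...] = tuple(bips[i] for i in order)
        self._bip_to_edge = {b: i for i, b in enumerate(bips)}

    # -- basic accessors -------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def n_branches(self) -> int:
        return len(self._edges)

    @property
    def branch_lengths(self) -> Dict[BranchId, Optional[float]]:
        return {b: self._edges[i][2] for b, i in self._bip_to_edge.items()}

    @property
    def has_lengths(self) -> bool:
        return all(e[2] is not None for e in self._edges)

    def lengths_array(self) -> np.ndarray:
        """Branch lengths in ``branch_ids`` order (NaN where absent)."""
        lens = self.branch_lengths
        return np.array(
            [np.nan if lens[b] is None else float(lens[b]) for b in self.branch_ids]
        )

    def leaf_label(self, node) -> Optional[str]:
        return self._labels.get(node)

    def _side_leaves(self, eid: int, start) -> set:
        """Leaf names on the ``start`` side of edge ``eid``."""
        out = set()
        stack = [start]
        seen = {start}
        while stack:
            n = stack.pop()
            if n in self._labels:
                out.add(self._labels[n])
            for e2 in self._adj[n]:
                if e2 == eid:
                    continue
                m = _other_end(self._edges[e2], n)
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return out

    # -- construction ----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        """Parse a Newick string; rooted inputs are unrooted."""
        if not newick or not newick.strip():
            raise NewickParseError("empty Newick string")
        try:
            t = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(str(exc)) from None
        ids: Dict[int, int] = {}

        def nid(nd):
            return ids.setdefault(id(nd), len(ids))

        edges: dict = {}
        labels: dict = {}
        eid = 0
        for nd in t.preorder_node_iter():
            if nd.parent_node is not None:
                edges[eid] = [nid(nd.parent_node), nid(nd), nd.edge.length, set()]
                eid += 1
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise NewickParseError("unlabelled leaf")
                labels[nid(nd)] = nd.taxon.label
        if len(set(labels.values())) != len(labels):
            raise NewickParseError("duplicate leaf labels")
        if len(labels) < 2:
            raise NewickParseError("fewer than two leaves")
        _splice_clean(edges, labels, None)
        try:
            return cls(
                [(e[0], e[1], e[2]) for _k, e in sorted(edges.items())], labels
            )
        except TreeError as exc:
            raise NewickParseError(str(exc)) from None

    def to_newick(self, precision: int = 17) -> str:
        """Serialize; ``from_newick`` of the result reproduces topology,
        branch ids and lengths exactly."""
        fmt = ":{:.%dg}" % precision

        if self.n_leaves == 2:
            u, v, l = self._edges[0]
            a, b = sorted([self._labels[u], self._labels[v]])
            lt = fmt.format(l) if l is not None else ""
            zt = ":0" if l is not None else ""
            return f"({a}{zt},{b}{lt});"

        root = sorted(self._adj, key=lambda n: (-len(self._adj[n]), repr(n)))[0]

        def build(n, in_eid):
            if n in self._labels:
                return self._labels[n]
            parts = []
            for eid in sorted(self._adj[n]):
                if eid == in_eid:
                    continue
                child = _other_end(self._edges[eid], n)
                s = build(child, eid)
                l = self._edges[eid][2]
                if l is not None:
                    s += fmt.format(l)
                parts.append(s)
            return "(" + ",".join(parts) + ")"

        return build(root, None) + ";"

    def with_lengths(self, lengths: Mapping[BranchId, float]) -> "Phylogeny":
        """Same topology, branch lengths replaced (keyed by branch id)."""
        new_edges = [
            (u, v, float(lengths[self._edge_bip[i]]))
            for i, (u, v, _l) in enumerate(self._edges)
        ]
        return Phylogeny(new_edges, self._labels)

    # -- structure operations --------------------------------------------

    def prune(
        self, keep: Iterable[str]
    ) -> Tuple["Phylogeny", Dict[BranchId, FrozenSet[BranchId]]]:
        """Restrict to a leaf subset.

        Suppressed degree-2 nodes have their incident branch lengths summed.
        Returns the pruned tree and a mapping from each pruned branch id to
        the frozenset of original branch ids merged into it (the identity
        mapping when ``keep`` is the full leaf set).
        """
        keep = frozenset(keep)
        if not keep <= self.leaf_names:
            raise TreeError("keep must be a subset of the leaf names")
        if len(keep) < 3:
            raise TooFewSpeciesError(
                f"cannot prune to {len(keep)} < 3 species"
            )
        if keep == self.leaf_names:
            return self, {b: frozenset([b]) for b in self.branch_ids}
        edges = {
            i: [u, v, l, {self._edge_bip[i]}]
            for i, (u, v, l) in enumerate(self._edges)
        }
        labels = dict(self._labels)
        _splice_clean(edges, labels, keep)
        order = sorted(edges)
        sub = Phylogeny(
            [(edges[k][0], edges[k][1], edges[k][2]) for k in order], labels
        )
        mapping = {
            sub._edge_bip[i]: frozenset(edges[order[i]][3])
            for i in range(len(order))
        }
        return sub, mapping

    def path_branches(self, a: str, b: str) -> Tuple[BranchId, ...]:
        """Branch ids on the path between two leaves."""
        if a == b:
            return ()
        start, goal = self._node_of[a], self._node_of[b]
        prev: Dict = {start: None}
        queue = deque([start])
        while queue:
            n = queue.popleft()
            if n == goal:
                break
            for eid in self._adj[n]:
                m = _other_end(self._edges[eid], n)
                if m not in prev:
                    prev[m] = (n, eid)
                    queue.append(m)
        path = []
        n = goal
        while prev[n] is not None:
            n, eid = prev[n]
            path.append(self._edge_bip[eid])
        return tuple(reversed(path))

    def leaf_distances(self) -> Tuple[Tuple[str, ...], np.ndarray]:
        """Path-length (patristic) distance matrix over sorted leaves."""
        if not self.has_lengths:
            raise TreeError("tree has no branch lengths")
        sp = tuple(sorted(self.leaf_names))
        lens = self.branch_lengths
        d = np.zeros((len(sp), len(sp)))
        for i in range(len(sp)):
            for j in range(i + 1, len(sp)):
                d[i, j] = d[j, i] = sum(
                    lens[b] for b in self.path_branches(sp[i], sp[j])
                )
        return sp, d

    def traversal(self):
        """Deterministic preorder edge walk from an internal root.

        Returns ``(root_node, [(parent, child, branch_id), ...])``.
        """
        root = sorted(self._adj, key=lambda n: (-len(self._adj[n]), repr(n)))[0]
        out = []
        stack = [(root, None)]
        while stack:
            n, in_eid = stack.pop()
            for eid in sorted(self._adj[n], reverse=True):
                if eid == in_eid:
                    continue
                child = _other_end(self._edges[eid], n)
                out.append((n, child, self._edge_bip[eid]))
                stack.append((child, eid))
        return root, out

    # -- comparison -------------------------------------------------------

    def same_topology(self, other: "Phylogeny") -> bool:
        return (
            self.leaf_names == other.leaf_names
            and set(self.branch_ids) == set(other.branch_ids)
        )

    def equals(self, other: "Phylogeny", rtol: float = 0.0) -> bool:
        """Topology and branch lengths equal (lengths compared with rtol)."""
        if not self.same_topology(other):
            return False
        la, lb = self.branch_lengths, other.branch_lengths
        for b in self.branch_ids:
            x, y = la[b], lb[b]
            if (x is None) != (y is None):
                return False
            if x is not None and not np.isclose(x, y, rtol=rtol, atol=0.0):
                return False
        return True

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Phylogeny {self.n_leaves} leaves, {self.n_branches} branches>"


class PruneCache:
    """Caches prunings of a master topology and branch-restriction maps.

    ``restriction(S, T)`` gives, for each branch of the topology pruned to
    ``T``, the index array of branches of the topology pruned to ``S`` whose
    lengths sum to it; this is how a gene's branch-rate vector on its own
    species set is restricted to a pair's shared species set.
    """

    def __init__(self, tree: Phylogeny):
        self.tree = tree
        self._pruned: Dict[frozenset, Phylogeny] = {tree.leaf_names: tree}
        self._restr: Dict = {}

    def pruned(self, species: Iterable[str]) -> Phylogeny:
        S = frozenset(species)
        if S not in self._pruned:
            self._pruned[S] = self.tree.prune(S)[0]
        return self._pruned[S]

    def restriction(self, source: Iterable[str], target: Iterable[str]):
        key = (frozenset(source), frozenset(target))
        if key not in self._restr:
            base = self.pruned(key[0])
            if key[1] == key[0]:
                branch_ids = base.branch_ids
                idx = [np.array([i], dtype=np.intp) for i in range(len(branch_ids))]
            else:
                sub, mapping = base.prune(key[1])
                pos = {b: i for i, b in enumerate(base.branch_ids)}
                branch_ids = sub.branch_ids
                idx = [
                    np.array(sorted(pos[o] for o in mapping[b]), dtype=np.intp)
                    for b in branch_ids
                ]
            self._restr[key] = (branch_ids, idx)
        return self._restr[key]
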