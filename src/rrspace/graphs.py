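"""Protomolecules: connected loop-free multigraphs with typed vertices.

A protomolecule is the element-agnostic skeleton of a molecule: vertices carry
an atom-type *slot* (valence plus positional element slot) and edges carry a
bond order (multiplicity).  Every vertex is valence-saturated: the sum of
incident bond orders equals its valence.

Canonical forms are computed with BLISS (via igraph) on an auxiliary simple
graph in which every bonded pair is subdivided by one extra vertex colored by
the bond order; vertex colors encode the atom-type slots.  Two protomolecules
are isomorphic (respecting slots and bond orders) iff their canonical keys are
equal.  The automorphism group order, needed for class-level sampling
corrections, comes from VF2 on the same auxiliary graph.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import igraph
import numpy as np

Color = tuple[int, int]  # (valence, element slot)


class Protomolecule:
    """Immutable typed multigraph with a dense bond-order matrix."""

    __slots__ = ("colors", "adj", "_key", "_aut")

    def __init__(self, colors: Sequence[Color], adj: np.ndarray, validate: bool = True):
        self.colors: tuple[Color, ...] = tuple((int(v), int(s)) for v, s in colors)
        a = np.asarray(adj, dtype=np.int64)
        a.setflags(write=False)
        self.adj = a
        self._key: str | None = None
        self._aut: int | None = None
        if validate:
            self._check()

    def _check(self) -> None:
        n = len(self.colors)
        if self.adj.shape != (n, n):
            raise ValueError("adjacency shape mismatch")
        if not np.array_equal(self.adj, self.adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adj) != 0):
            raise ValueError("self-loops are not allowed")
        if np.any(self.adj < 0):
            raise ValueError("negative bond order")
        degrees = self.adj.sum(axis=1)
        valences = np.array([v for v, _ in self.colors])
        if not np.array_equal(degrees, valences):
            raise ValueError("vertex degree must equal its valence")
        if not self.is_connected():
            raise ValueError("protomolecule must be connected")

    # -- basic structure ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.colors)

    @property
    def n_bonds(self) -> int:
        """Total bond count including multiplicity (M / 2)."""
        return int(self.adj.sum()) // 2

    def edges(self) -> list[tuple[int, int, int]]:
        """Sorted list of (i, j, multiplicity), i < j."""
        iu, ju = np.nonzero(np.triu(self.adj))
        return [(int(i), int(j), int(self.adj[i, j])) for i, j in zip(iu, ju)]

    def is_connected(self) -> bool:
        n = self.n
        if n == 0:
            return False
        seen = np.zeros(n, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            i = stack.pop()
            for j in np.nonzero(self.adj[i])[0]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(int(j))
        return bool(seen.all())

    # -- canonical form ----------------------------------------------------
    def _aux_graph(self) -> tuple[igraph.Graph, list[int]]:
        """Simple graph with bond orders encoded as colored midpoint vertices."""
        palette = {c: i for i, c in enumerate(sorted(set(self.colors)))}
        base = len(palette)
        colors = [palette[c] for c in self.colors]
        edges = []
        for i, j, m in self.edges():
            mid = len(colors)
            colors.append(base + m)  # color class per bond order
            edges.extend([(i, mid), (mid, j)])
        g = igraph.Graph(n=len(colors), edges=edges)
        return g, colors

    @property
    def canonical_key(self) -> str:
        """Text key equal across (and only across) isomorphic protomolecules."""
        if self._key is None:
            g, colors = self._aux_graph()
            perm = g.canonical_permutation(color=colors)
            gp = g.permute_vertices(perm)
            cp = [0] * len(colors)
            for old, new in enumerate(perm):
                cp[new] = colors[old]
            edgelist = sorted(tuple(sorted(e)) for e in gp.get_edgelist())
            self._key = json.dumps([cp, edgelist], separators=(",", ":"))
        return self._key

    @property
    def automorphism_count(self) -> int:
        """Order of the slot- and bond-order-preserving automorphism group."""
        if self._aut is None:
            g, colors = self._aux_graph()
            self._aut = int(g.count_automorphisms_vf2(color=colors))
        return self._aut

    # -- equality / hashing ------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Protomolecule):
            return NotImplemented
        return self.canonical_key == other.canonical_key

    def __hash__(self) -> int:
        return hash(self.canonical_key)

    def __repr__(self) -> str:
        return f"Protomolecule(n={self.n}, bonds={self.n_bonds})"

    # -- construction / exchange -------------------------------------------
    @classmethod
    def from_edges(
        cls,
        colors: Sequence[Color],
        edges: Iterable[tuple[int, int, int]],
        validate: bool = True,
    ) -> "Protomolecule":
        n = len(colors)
        adj = np.zeros((n, n), dtype=np.int64)
        for i, j, m in edges:
            adj[i, j] += m
            adj[j, i] += m
        return cls(colors, adj, validate=validate)

    def to_json(self, elements: Sequence[str] | None = None) -> str:
        """Graph exchange JSON: vertices with slot/valence (and optionally a
        concrete element label), edges as [i, j, multiplicity]."""
        vertices = []
        for idx, (v, s) in enumerate(self.colors):
            rec: dict[str, object] = {"valence": v, "slot": s}
            if elements is not None:
                rec["element"] = elements[idx]
            vertices.append(rec)
        return json.dumps(
            {"vertices": vertices, "edges": [list(e) for e in self.edges()]}
        )

    @classmethod
    def from_json(cls, text: str) -> tuple["Protomolecule", list[str] | None]:
        data = json.loads(text)
        colors = [(v["valence"], v["slot"]) for v in data["vertices"]]
        elements = [v["element"] for v in data["vertices"]] if all(
            "element" in v for v in data["vertices"]
        ) else None
        g = cls.from_edges(colors, [tuple(e) for e in data["edges"]])
        return g, elements


def canonical_form(g: Protomolecule) -> str:
    """Module-level alias of :attr:`Protomolecule.canonical_key`."""
    return g.canonical_key
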