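"""Exact enumeration of protomolecules for small degree sequences.

This is the correctness oracle of the package: every count estimator and the
sampler's uniformity tests are validated against it.  The strategy is simple
rather than clever — recursive construction of connected multigraphs vertex by
vertex with symmetry-light pruning, followed by canonical-form deduplication —
because at desk scale correctness matters and speed does not.

The recursion keeps a single growing connected component: the lowest-indexed
touched vertex with residual valence is fully saturated by distributing its
remaining stubs over (a) touched vertices with residual valence and (b)
so-far-untouched vertices, which thereby join the component.  Untouched
vertices of equal color are interchangeable, so stub allocations to them are
required to be non-increasing within a color class; remaining duplicates are
removed by canonical keys.
"""

from __future__ import annotations

import numpy as np

from .graphs import Protomolecule
from .formulas import is_realizable
from .space import LabeledDegreeSequence

DEFAULT_ATOM_CAP = 10


class EnumerationCapExceeded(RuntimeError):
    """Raised when a degree sequence is too large for exact enumeration."""


def enumerate_protomolecules(
    d: LabeledDegreeSequence,
    cap: int = DEFAULT_ATOM_CAP,
    max_multiplicity: int | None = None,
) -> list[Protomolecule]:
    """All protomolecules of degree sequence ``d``, up to isomorphism.

    Raises :class:`EnumerationCapExceeded` above ``cap`` atoms; callers should
    fall back to the count estimators there.  ``max_multiplicity`` optionally
    caps bond orders (off by default: any order the valences allow).
    """
    if d.natoms > cap:
        raise EnumerationCapExceeded(
            f"{d.natoms} atoms exceeds the exact-enumeration cap of {cap}; "
            "use the count estimators instead"
        )
    if not is_realizable(d.degrees):
        return []

    colors = d.vertex_colors()
    valences = [v for v, _ in colors]
    n = len(colors)
    adj = np.zeros((n, n), dtype=np.int64)
    residual = list(valences)
    touched = [False] * n
    touched[0] = True
    found: dict[str, Protomolecule] = {}
    mmax = max_multiplicity if max_multiplicity is not None else max(valences)

    def emit() -> None:
        g = Protomolecule(colors, adj.copy(), validate=False)
        if g.is_connected():  # defensive; construction keeps one component
            found.setdefault(g.canonical_key, g)

    def next_vertex() -> int | None:
        for i in range(n):
            if touched[i] and residual[i] > 0:
                return i
        return None

    def saturate(v: int) -> None:
        # Distribute residual[v] stubs over candidate partners.
        touched_cands = [u for u in range(n) if u != v and touched[u] and residual[u] > 0]
        untouched_cands = [u for u in range(n) if not touched[u] and residual[u] > 0]
        cands = touched_cands + untouched_cands

        def place(idx: int, remaining: int, prev_untouched: dict[object, int]) -> None:
            if remaining == 0:
                advance()
                return
            if idx == len(cands):
                return
            u = cands[idx]
            hi = min(remaining, residual[u], mmax)
            is_untouched = not touched[u]
            if is_untouched:
                # symmetry cut: equal-color untouched vertices get
                # non-increasing stub allocations
                limit = prev_untouched.get(colors[u])
                if limit is not None:
                    hi = min(hi, limit)
            for m in range(hi, -1, -1):
                if m > 0:
                    adj[v, u] += m
                    adj[u, v] += m
                    residual[u] -= m
                    if is_untouched:
                        touched[u] = True
                newprev = prev_untouched
                if is_untouched:
                    newprev = dict(prev_untouched)
                    newprev[colors[u]] = m if m > 0 else 0
                place(idx + 1, remaining - m, newprev)
                if m > 0:
                    adj[v, u] -= m
                    adj[u, v] -= m
                    residual[u] += m
                    if is_untouched:
                        touched[u] = False

        saved = residual[v]
        residual[v] = 0
        place(0, saved, {})
        residual[v] = saved

    def advance() -> None:
        v = next_vertex()
        if v is None:
            if all(touched) and all(r == 0 for r in residual):
                emit()
            return  # saturated component before covering all atoms: dead end
        saturate(v)

    advance()
    return sorted(found.values(), key=lambda g: g.canonical_key)


def count_exact(
    d: LabeledDegreeSequence,
    cap: int = DEFAULT_ATOM_CAP,
    max_multiplicity: int | None = None,
) -> int:
    """Number of distinct protomolecules of ``d`` (0 if unrealizable)."""
    return len(enumerate_protomolecules(d, cap=cap, max_multiplicity=max_multiplicity))
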