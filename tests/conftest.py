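import numpy as np
import pytest

from rrspace.fixtures import make_fixtures
from rrspace.graphs import Protomolecule


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(seed=0)


def swap_neighbors(g: Protomolecule, max_multiplicity=None):
    """All protomolecules one accepted double edge swap away from ``g``.

    Deterministic enumeration of the chain's move set: every unordered pair
    of unit-bond instances on four distinct vertices, both rewirings,
    connectivity-filtered.  Used for ergodicity (closure) checks.
    """
    out = []
    edges = []
    for i, j, m in g.edges():
        edges.append((i, j, m))
    for a_idx in range(len(edges)):
        for b_idx in range(a_idx, len(edges)):
            a, b, m1 = edges[a_idx]
            c, d, m2 = edges[b_idx]
            if a_idx == b_idx and m1 < 2:
                continue
            if len({a, b, c, d}) < 4:
                continue
            for (p, q, r, s) in (((a, c, b, d)), ((a, d, b, c))):
                adj = g.adj.copy()
                adj[a, b] -= 1
                adj[b, a] -= 1
                adj[c, d] -= 1
                adj[d, c] -= 1
                adj[p, q] += 1
                adj[q, p] += 1
                adj[r, s] += 1
                adj[s, r] += 1
                if max_multiplicity is not None and (
                    adj[p, q] > max_multiplicity or adj[r, s] > max_multiplicity
                ):
                    continue
                cand = Protomolecule(g.colors, adj, validate=False)
                if cand.is_connected():
                    out.append(cand)
    return out


def swap_closure(start: Protomolecule) -> dict[str, Protomolecule]:
    """Transitive closure of the double-edge-swap move set from ``start``."""
    seen = {start.canonical_key: start}
    frontier = [start]
    while frontier:
        g = frontier.pop()
        for nb in swap_neighbors(g):
            key = nb.canonical_key
            if key not in seen:
                seen[key] = nb
                frontier.append(nb)
    return seen
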