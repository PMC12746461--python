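"""Approximately uniform random sampling of molecules from a chemical space.

Sampling is two-level: a stoichiometry is drawn with probability proportional
to its (estimated) number of molecular graphs, then a protomolecule of the
corresponding degree sequence is drawn by a degree-preserving Markov chain.

The chain starts from a stub-seeded realization and proposes double edge
swaps: two unit bonds a-b and c-d on four distinct atoms are rewired to
a-c/b-d or a-d/b-c.  Proposals that disconnect the graph are rejected.  A
Hastings factor accounts for parallel-bond proposal asymmetry, making the
stationary law uniform over vertex-labeled realizations (bond matrices).
Uniformity over *isomorphism classes* — what the diagnostics test — then
requires reweighting by the automorphism-group order, since a class with
automorphisms owns proportionally fewer labeled realizations.  This class
correction is an extra Metropolis factor |Aut(g')| / |Aut(g)|, on by default;
it can be switched off for large molecules, where nontrivial automorphisms
are rare and the two laws practically coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .formulas import all_constitutions, is_realizable
from .graphs import Color, Protomolecule
from .space import (
    AtomType,
    ChemicalSpace,
    LabeledDegreeSequence,
    Stoichiometry,
    degree_sequence_of,
    slot_element_map,
)


@dataclass(frozen=True)
class SamplerConfig:
    """Chain schedule and stationary-law options.

    ``burn_in``/``thinning`` default to 10·E and E steps (E = bond count).
    ``max_multiplicity`` optionally caps bond orders (off by default: any
    order the endpoint valences allow).
    """

    burn_in: int | None = None
    thinning: int | None = None
    seed: int = 0
    automorphism_correction: bool = True
    max_multiplicity: int | None = None

    def __post_init__(self) -> None:
        if self.burn_in is not None and self.burn_in < 1:
            raise ValueError("burn_in must be >= 1")
        if self.thinning is not None and self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass(frozen=True)
class MoleculeSample:
    """A sampled protomolecule, optionally with concrete element labels."""

    graph: Protomolecule
    elements: tuple[str, ...] | None = None
    stoichiometry: Stoichiometry | None = None
    seed: int = 0
    burn_in: int = 0
    thinning: int = 0
    step: int = 0


# ---------------------------------------------------------------------------
# initial realization
# ---------------------------------------------------------------------------

def initial_graph(d: LabeledDegreeSequence, seed: int = 0) -> Protomolecule:
    """A valid (possibly biased) starting realization of ``d``.

    Random stub matching is attempted first; degree sequences dominated by
    trees rarely yield a connected loop-free pairing, so a deterministic
    greedy construction (spanning tree, then max-residual stub pairing) is
    the fallback.  Any start bias is removed by the chain's burn-in.
    """
    if not is_realizable(d.degrees):
        raise ValueError(f"degree sequence {d.key} is not realizable")
    colors = d.vertex_colors()
    degrees = [v for v, _ in colors]
    rng = np.random.default_rng(seed)
    for _ in range(50):
        g = _stub_matching(colors, degrees, rng)
        if g is not None:
            return g
    return _greedy_realization(colors, degrees)


def _stub_matching(colors, degrees, rng) -> Protomolecule | None:
    stubs = np.repeat(np.arange(len(degrees)), degrees)
    rng.shuffle(stubs)
    n = len(degrees)
    adj = np.zeros((n, n), dtype=np.int64)
    for a, b in zip(stubs[0::2], stubs[1::2]):
        if a == b:
            return None
        adj[a, b] += 1
        adj[b, a] += 1
    g = Protomolecule(colors, adj, validate=False)
    return g if g.is_connected() else None


def _greedy_realization(colors, degrees) -> Protomolecule:
    n = len(degrees)
    order = sorted(range(n), key=lambda i: -degrees[i])
    residual = list(degrees)
    adj = np.zeros((n, n), dtype=np.int64)
    # spanning tree first: every vertex attaches to the earlier vertex with
    # the largest residual, guaranteeing connectivity
    for pos in range(1, n):
        i = order[pos]
        prev = max(
            (order[p] for p in range(pos) if residual[order[p]] > 0),
            key=lambda j: residual[j],
            default=None,
        )
        if prev is None:
            raise ValueError("greedy realization failed (unrealizable input?)")
        adj[i, prev] += 1
        adj[prev, i] += 1
        residual[i] -= 1
        residual[prev] -= 1
    # pair remaining stubs between the two fullest distinct vertices
    while True:
        live = [i for i in range(n) if residual[i] > 0]
        if not live:
            break
        if len(live) < 2:
            raise ValueError("greedy realization failed (stranded stubs)")
        live.sort(key=lambda i: -residual[i])
        a, b = live[0], live[1]
        adj[a, b] += 1
        adj[b, a] += 1
        residual[a] -= 1
        residual[b] -= 1
    return Protomolecule(colors, adj)


# ---------------------------------------------------------------------------
# the chain
# ---------------------------------------------------------------------------

class _Chain:
    """Mutable double-edge-swap chain over realizations of one sequence."""

    def __init__(self, g: Protomolecule, config: SamplerConfig, seed: int):
        self.colors = g.colors
        self.adj = g.adj.copy()
        self.config = config
        self.rng = np.random.default_rng(seed)
        self._aut_cache: dict[bytes, int] = {}

    def _aut(self, adj: np.ndarray) -> int:
        # keyed by canonical form: one VF2 count per isomorphism class
        g = Protomolecule(self.colors, adj.copy(), validate=False)
        key = g.canonical_key
        cached = self._aut_cache.get(key)
        if cached is None:
            cached = g.automorphism_count
            self._aut_cache[key] = cached
        return cached

    def step(self) -> bool:
        """One proposal; returns True if the move was accepted."""
        adj = self.adj
        iu, ju = np.nonzero(np.triu(adj))
        mults = adj[iu, ju]
        k = int(mults.sum())
        if k < 2:
            return False
        # two distinct unit-bond instances, multiplicity-weighted
        probs = mults / k
        e1 = int(self.rng.choice(len(iu), p=probs))
        w = mults.astype(float).copy()
        w[e1] -= 1
        if w.sum() <= 0:
            return False
        e2 = int(self.rng.choice(len(iu), p=w / w.sum()))
        a, b = int(iu[e1]), int(ju[e1])
        c, d = int(iu[e2]), int(ju[e2])
        if len({a, b, c, d}) < 4:
            return False
        if self.rng.integers(2):
            c, d = d, c
        # rewire a-b, c-d  ->  a-c, b-d
        cap = self.config.max_multiplicity
        if cap is not None and (adj[a, c] + 1 > cap or adj[b, d] + 1 > cap):
            return False
        ratio = ((adj[a, c] + 1) * (adj[b, d] + 1)) / (adj[a, b] * adj[c, d])
        new = adj.copy()
        new[a, b] -= 1
        new[b, a] -= 1
        new[c, d] -= 1
        new[d, c] -= 1
        new[a, c] += 1
        new[c, a] += 1
        new[b, d] += 1
        new[d, b] += 1
        if not Protomolecule(self.colors, new, validate=False).is_connected():
            return False
        if self.config.automorphism_correction:
            ratio *= self._aut(new) / self._aut(adj)
        if ratio >= 1.0 or self.rng.random() < ratio:
            self.adj = new
            return True
        return False

    def current(self) -> Protomolecule:
        return Protomolecule(self.colors, self.adj.copy(), validate=False)


def mcmc_step(
    g: Protomolecule, rng_or_seed=0, config: SamplerConfig | None = None
) -> Protomolecule:
    """One swap proposal applied to ``g`` (returns ``g`` itself on rejection)."""
    config = config or SamplerConfig()
    seed = (
        int(rng_or_seed.integers(2**31))
        if isinstance(rng_or_seed, np.random.Generator)
        else int(rng_or_seed)
    )
    chain = _Chain(g, config, seed)
    return chain.current() if chain.step() else g


def sample_graphs(
    d: LabeledDegreeSequence, n: int, config: SamplerConfig | None = None
) -> list[MoleculeSample]:
    """``n`` protomolecules of ``d`` from one chain (burn-in, then thinning)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    config = config or SamplerConfig()
    g0 = initial_graph(d, seed=config.seed)
    e = max(1, g0.n_bonds)
    burn_in = config.burn_in if config.burn_in is not None else 10 * e
    if config.thinning is not None:
        thinning = config.thinning
    else:
        # the class correction deepens wells at symmetric graphs, which
        # lengthens the correlation time; thin harder in that mode
        thinning = 5 * e if config.automorphism_correction else e
    chain = _Chain(g0, config, seed=config.seed)
    for _ in range(burn_in):
        chain.step()
    out = []
    for i in range(n):
        if i > 0:
            for _ in range(thinning):
                chain.step()
        out.append(
            MoleculeSample(
                graph=chain.current(),
                seed=config.seed,
                burn_in=burn_in,
                thinning=thinning,
                step=burn_in + i * thinning,
            )
        )
    return out


# ---------------------------------------------------------------------------
# element assignment and space-level sampling
# ---------------------------------------------------------------------------

def assign_elements(
    g: Protomolecule, s: Stoichiometry, rng_or_seed=0
) -> MoleculeSample:
    """Attach concrete element labels to a protomolecule's slots.

    Atom types of equal valence and count are interchangeable placeholders;
    the bijection between them and the slots is drawn uniformly at random.
    """
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(int(rng_or_seed))
    )
    d = degree_sequence_of(s)
    if sorted(d.vertex_colors()) != sorted(g.colors):
        raise ValueError("stoichiometry is incompatible with this protomolecule")
    slot_map = slot_element_map(s)
    assignment: dict[Color, str] = {}
    for v, group in d.per_valence().items():
        slots = [(v, i) for i in range(len(group))]
        # permute interchangeable (equal-count) candidates uniformly
        by_candidates: dict[tuple[str, ...], list[Color]] = {}
        for slot in slots:
            cands = tuple(at.element for at in slot_map[slot])
            by_candidates.setdefault(cands, []).append(slot)
        for cands, slot_group in by_candidates.items():
            perm = rng.permutation(len(cands))
            for slot, pi in zip(slot_group, perm[: len(slot_group)]):
                assignment[slot] = cands[pi]
    elements = tuple(assignment[c] for c in g.colors)
    return MoleculeSample(graph=g, elements=elements, stoichiometry=s)


def sample_space(
    space: ChemicalSpace,
    n: int,
    db: "dict | None" = None,
    config: SamplerConfig | None = None,
    cal=None,
    counts: "dict[str, float] | None" = None,
) -> list[MoleculeSample]:
    """``n`` approximately uniform molecules from a chemical space.

    Stoichiometries are drawn with probability proportional to their
    (estimated) graph counts; graphs within a stoichiometry come from
    :func:`sample_graphs`.  ``counts`` may supply precomputed per-stoichiometry
    weights (keyed by :attr:`Stoichiometry.key`) to skip estimation.
    """
    from .counting import DEFAULT_CALIBRATION, estimate_count

    config = config or SamplerConfig()
    cal = cal or DEFAULT_CALIBRATION
    stoichs = all_constitutions(space)
    if not stoichs:
        raise ValueError("chemical space admits no feasible formulas")
    weights = []
    for s in stoichs:
        if counts is not None and s.key in counts:
            weights.append(float(counts[s.key]))
        else:
            d = degree_sequence_of(s)
            weights.append(float(estimate_count(d, db=db, cal=cal).count))
    weights = np.array(weights)
    if weights.sum() <= 0:
        raise ValueError("all stoichiometries have zero estimated count")
    rng = np.random.default_rng(config.seed)
    draws = rng.choice(len(stoichs), size=n, p=weights / weights.sum())
    out: list[MoleculeSample] = [None] * n  # type: ignore[list-item]
    for si in np.unique(draws):
        positions = np.nonzero(draws == si)[0]
        s = stoichs[int(si)]
        d = degree_sequence_of(s)
        sub = replace(config, seed=config.seed + 7919 * (int(si) + 1))
        graphs = sample_graphs(d, len(positions), sub)
        for pos, gs in zip(positions, graphs):
            ms = assign_elements(gs.graph, s, rng)
            out[int(pos)] = replace(
                ms,
                seed=sub.seed,
                burn_in=gs.burn_in,
                thinning=gs.thinning,
                step=gs.step,
            )
    return out
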