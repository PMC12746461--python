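"""Enumeration of all feasible sum formulas of a chemical space.

Formulas are found in two nested stages rather than by one direct partition:
first the atom count is partitioned over the *valence types* (keeping only
compositions whose degree sum is even and realizable as a connected loop-free
multigraph), then each valence's share is partitioned over the elements of
that valence.  The result is identical to the direct one-stage partition but
avoids generating valence-equivalent duplicates (CH4 and CF4 share the same
valence composition and only split when elements are assigned).
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Sequence

from .space import AtomType, ChemicalSpace, Stoichiometry, degree_sequence_of


def integer_partitions(n: int, k: int) -> list[tuple[int, ...]]:
    """All ordered k-tuples of nonnegative integers summing to n.

    These are compositions over an ordered set of k parts (weak compositions);
    there are C(n + k - 1, k - 1) of them.  Deterministic lexicographic order.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if k < 1:
        if n == 0 and k == 0:
            return [()]
        raise ValueError("k must be >= 1 for n > 0")
    return list(_compositions(n, k))


def _compositions(n: int, k: int) -> Iterator[tuple[int, ...]]:
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


def is_realizable(degrees: Sequence[int]) -> bool:
    """Can a connected loop-free multigraph have exactly these vertex degrees?

    The saturation condition: the degree sum M must be even, the maximum
    degree must not exceed the sum of the remaining degrees (loop-free
    multigraph realizability), and there must be at least n - 1 edges
    (M / 2 >= n - 1) so the graph can be connected.
    """
    degs = sorted((int(d) for d in degrees), reverse=True)
    if len(degs) < 2 or any(d < 1 for d in degs):
        return False
    m = sum(degs)
    if m % 2 != 0:
        return False
    if degs[0] > m - degs[0]:
        return False
    return m // 2 >= len(degs) - 1


def valence_compositions(
    n_atoms: int, space: ChemicalSpace
) -> list[tuple[int, ...]]:
    """All compositions q of ``n_atoms`` over the space's valence types whose
    degree multiset is realizable (even degree sum + saturation)."""
    if not (space.natoms_min <= n_atoms <= space.natoms_max):
        raise ValueError(
            f"n_atoms={n_atoms} outside space range "
            f"[{space.natoms_min}, {space.natoms_max}]"
        )
    valences = space.valence_types
    out = []
    for q in _compositions(n_atoms, len(valences)):
        degrees = [v for v, cnt in zip(valences, q) for _ in range(cnt)]
        if is_realizable(degrees):
            out.append(q)
    return out


def constitutions(n_atoms: int, space: ChemicalSpace) -> list[Stoichiometry]:
    """All constitutions (sum formulas with valences) of ``n_atoms`` atoms.

    For each feasible valence composition, the count of each valence type is
    partitioned over the elements of that valence; the Cartesian product over
    valences gives the constitutions.  Deterministic order, duplicate-free.
    """
    valences = space.valence_types
    result: list[Stoichiometry] = []
    seen: set[str] = set()
    for q in valence_compositions(n_atoms, space):
        per_valence_options: list[list[tuple[tuple[AtomType, int], ...]]] = []
        for v, cnt in zip(valences, q):
            elements = space.elements_of_valence(v)
            options = []
            for y in _compositions(cnt, len(elements)):
                options.append(
                    tuple((at, c) for at, c in zip(elements, y) if c > 0)
                )
            per_valence_options.append(options)
        for combo in itertools.product(*per_valence_options):
            counts = {at: c for part in combo for at, c in part}
            if not counts:
                continue
            s = Stoichiometry.from_mapping(counts)
            if s.key not in seen:
                seen.add(s.key)
                result.append(s)
    result.sort(key=lambda s: s.key)
    return result


def constitutions_brute_force(
    n_atoms: int, space: ChemicalSpace
) -> list[Stoichiometry]:
    """One-stage oracle: partition ``n_atoms`` directly over all atom types,
    then filter by parity and realizability.  Equivalent to
    :func:`constitutions`; exponentially slower, kept as a cross-check."""
    atom_types = sorted(space.atom_types, key=lambda at: (at.element, at.valence))
    result = []
    for y in _compositions(n_atoms, len(atom_types)):
        counts = {at: c for at, c in zip(atom_types, y) if c > 0}
        if not counts:
            continue
        degrees = [at.valence for at, c in counts.items() for _ in range(c)]
        if is_realizable(degrees):
            result.append(Stoichiometry.from_mapping(counts))
    result.sort(key=lambda s: s.key)
    return result


def all_constitutions(space: ChemicalSpace) -> list[Stoichiometry]:
    """Constitutions over the space's full atom-count range."""
    out: list[Stoichiometry] = []
    for n in range(space.natoms_min, space.natoms_max + 1):
        out.extend(constitutions(n, space))
    return out


def formula_table(space: ChemicalSpace) -> "list[dict[str, object]]":
    """Rows (formula, degree-sequence key, atom count) for CSV export."""
    rows = []
    for s in all_constitutions(space):
        rows.append(
            {
                "formula": s.formula,
                "degree_sequence": degree_sequence_of(s).key,
                "natoms": s.natoms,
            }
        )
    return rows
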