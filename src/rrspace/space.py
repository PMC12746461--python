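"""Chemical-space definitions: atom types, stoichiometries, degree sequences.

A chemical space is spanned by a set of *atom types* — pairs ``(element,
valence)`` — together with a molecular size range.  The same element with two
different valences counts as two distinct atom types (e.g. trivalent and
pentavalent phosphorus).  Element labels are opaque: two elements of equal
valence are interchangeable placeholders as far as graph counting goes, which
is why most of the machinery works on *labeled degree sequences* rather than
concrete formulas.

A labeled degree sequence records, per valence, how many atoms belong to each
element "slot" of that valence.  Slots are positional (first, second element
of a valence), not chemical symbols.  A sequence is *pure* when every valence
is served by a single slot; the pure counterpart of a nonpure sequence merges
all slots of a valence into one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple


class AtomType(NamedTuple):
    """An element label together with its (fixed) valence."""

    element: str
    valence: int

    def __str__(self) -> str:  # e.g. "C4"
        return f"{self.element}{self.valence}"


@dataclass(frozen=True)
class ChemicalSpace:
    """A set of atom types plus a molecular size range (atom counts).

    ``valence_types`` is the ordered (descending) tuple of distinct valences
    and ``multiplicity(v)`` counts the elements sharing valence ``v``.
    """

    atom_types: frozenset[AtomType]
    natoms_min: int
    natoms_max: int

    def __post_init__(self) -> None:
        if not self.atom_types:
            raise ValueError("a chemical space needs at least one atom type")
        for at in self.atom_types:
            if at.valence < 1:
                raise ValueError(f"invalid valence {at.valence} for {at.element!r}")
        if self.natoms_min < 2:
            raise ValueError("natoms_min must be >= 2 (a lone atom has no bonds)")
        if self.natoms_min > self.natoms_max:
            raise ValueError("natoms_min must not exceed natoms_max")

    @property
    def valence_types(self) -> tuple[int, ...]:
        return tuple(sorted({at.valence for at in self.atom_types}, reverse=True))

    def multiplicity(self, valence: int) -> int:
        return sum(1 for at in self.atom_types if at.valence == valence)

    def elements_of_valence(self, valence: int) -> tuple[AtomType, ...]:
        return tuple(
            sorted(
                (at for at in self.atom_types if at.valence == valence),
                key=lambda at: at.element,
            )
        )


@dataclass(frozen=True)
class Stoichiometry:
    """A constitution: a multiset of atom types (sum formula with valences)."""

    counts: tuple[tuple[AtomType, int], ...]

    @classmethod
    def from_mapping(cls, counts: Mapping[AtomType, int]) -> "Stoichiometry":
        items = []
        for at, c in counts.items():
            if c <= 0:
                raise ValueError(f"count for {at} must be positive")
            items.append((AtomType(*at), int(c)))
        if not items:
            raise ValueError("empty stoichiometry")
        items.sort(key=lambda p: (-p[0].valence, p[0].element))
        return cls(counts=tuple(items))

    def as_dict(self) -> dict[AtomType, int]:
        return dict(self.counts)

    @property
    def natoms(self) -> int:
        return sum(c for _, c in self.counts)

    @property
    def degree_sum(self) -> int:
        return sum(at.valence * c for at, c in self.counts)

    @property
    def formula(self) -> str:
        """Hill-like text key, e.g. ``C1H2F2`` (valences implicit)."""
        return "".join(f"{at.element}{c}" for at, c in self.counts)

    @property
    def key(self) -> str:
        """Unambiguous key including valences, e.g. ``C4:1,H1:2,F1:2``."""
        return ",".join(f"{at}:{c}" for at, c in self.counts)

    def __str__(self) -> str:
        return self.formula


@dataclass(frozen=True)
class LabeledDegreeSequence:
    """Per-valence slot counts of a candidate molecule.

    ``entries`` is a canonically ordered tuple of ``(valence, slot, count)``:
    valences descending, slots within a valence numbered 0, 1, ... in order of
    descending count.  Slot labels are positional placeholders, so two
    stoichiometries that differ only by renaming equal-valence elements map to
    the same sequence.
    """

    entries: tuple[tuple[int, int, int], ...]

    @classmethod
    def from_valence_counts(
        cls, per_valence: Mapping[int, Iterable[int]]
    ) -> "LabeledDegreeSequence":
        """Build from {valence: [count per element slot]}."""
        entries = []
        for v in sorted(per_valence, reverse=True):
            counts = sorted((int(c) for c in per_valence[v]), reverse=True)
            if v < 1:
                raise ValueError("valences must be positive")
            if any(c <= 0 for c in counts):
                raise ValueError("slot counts must be positive")
            entries.extend((v, slot, c) for slot, c in enumerate(counts))
        if not entries:
            raise ValueError("empty degree sequence")
        return cls(entries=tuple(entries))

    @property
    def natoms(self) -> int:
        return sum(c for _, _, c in self.entries)

    @property
    def degree_sum(self) -> int:
        return sum(v * c for v, _, c in self.entries)

    @property
    def pure(self) -> bool:
        valences = [v for v, _, _ in self.entries]
        return len(valences) == len(set(valences))

    def per_valence(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for v, _, c in self.entries:
            out.setdefault(v, []).append(c)
        return out

    def pure_counterpart(self) -> "LabeledDegreeSequence":
        """Merge all element slots of each valence into one (idempotent)."""
        merged = {v: [sum(cs)] for v, cs in self.per_valence().items()}
        return LabeledDegreeSequence.from_valence_counts(merged)

    @property
    def degrees(self) -> tuple[int, ...]:
        """The flat vertex-degree multiset, descending."""
        out: list[int] = []
        for v, _, c in self.entries:
            out.extend([v] * c)
        return tuple(sorted(out, reverse=True))

    def vertex_colors(self) -> tuple[tuple[int, int], ...]:
        """One ``(valence, slot)`` color per atom, in canonical vertex order."""
        out: list[tuple[int, int]] = []
        for v, slot, c in self.entries:
            out.extend([(v, slot)] * c)
        return tuple(out)

    @property
    def key(self) -> str:
        """Stable text key, e.g. ``4:1|1:2,2`` for the CH2F2 family."""
        parts = []
        for v, cs in sorted(self.per_valence().items(), reverse=True):
            parts.append(f"{v}:" + ",".join(str(c) for c in cs))
        return "|".join(parts)

    def __str__(self) -> str:
        return self.key


def make_space(config: Mapping[str, object]) -> ChemicalSpace:
    """Build a :class:`ChemicalSpace` from a parsed config mapping.

    The mapping holds one ``element: valence`` pair per atom type plus the
    reserved key ``natoms: [min, max]``.  Element labels are arbitrary; the
    same chemical element at two valences needs two distinct labels.
    """
    if "natoms" not in config:
        raise ValueError("config must define 'natoms: [min, max]'")
    natoms = config["natoms"]
    if not (isinstance(natoms, (list, tuple)) and len(natoms) == 2):
        raise ValueError("'natoms' must be a [min, max] pair")
    nmin, nmax = int(natoms[0]), int(natoms[1])

    atom_types: set[AtomType] = set()
    for element, valence in config.items():
        if element == "natoms":
            continue
        if not isinstance(valence, int) or isinstance(valence, bool):
            raise ValueError(f"valence of {element!r} must be an integer")
        at = AtomType(str(element), valence)
        if any(existing == at for existing in atom_types):
            raise ValueError(f"duplicate atom type {at}")
        atom_types.add(at)
    return ChemicalSpace(frozenset(atom_types), nmin, nmax)


def degree_sequence_of(s: Stoichiometry) -> LabeledDegreeSequence:
    """Canonical labeled degree sequence of a stoichiometry."""
    per_valence: dict[int, list[int]] = {}
    for at, c in s.counts:
        per_valence.setdefault(at.valence, []).append(c)
    return LabeledDegreeSequence.from_valence_counts(per_valence)


def slot_element_map(
    s: Stoichiometry,
) -> dict[tuple[int, int], list[AtomType]]:
    """Map each ``(valence, slot)`` color of ``degree_sequence_of(s)`` to the
    atom types that may occupy it.

    Slots within a valence are ordered by descending count; atom types with
    equal counts are interchangeable, so each slot maps to the list of
    equal-count candidates (element assignment picks a bijection).
    """
    per_valence: dict[int, list[tuple[AtomType, int]]] = {}
    for at, c in s.counts:
        per_valence.setdefault(at.valence, []).append((at, c))
    out: dict[tuple[int, int], list[AtomType]] = {}
    for v, pairs in per_valence.items():
        pairs.sort(key=lambda p: (-p[1], p[0].element))
        for slot, (at, c) in enumerate(pairs):
            out[(v, slot)] = [a for a, cc in pairs if cc == c]
    return out


def pure_counterpart(d: LabeledDegreeSequence) -> LabeledDegreeSequence:
    """Module-level alias of :meth:`LabeledDegreeSequence.pure_counterpart`."""
    return d.pure_counterpart()
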