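"""Built-in fixture spaces whose universes are exactly enumerable.

These small chemical spaces anchor every estimator and the sampler to ground
truth: each fixture's protomolecule universes can be enumerated exhaustively,
so uniformity, reachability and count-estimation claims are testable without
any external data.  Element labels follow chemical convention but are, as
everywhere in this package, placeholders for "an element of this valence".

The ``joint_sampling`` fixture mirrors the scale of the joint-sampling uniformity
test (a handful of stoichiometries, low hundreds of graphs in total: here 6
stoichiometries with 131 protomolecules).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .exact import enumerate_protomolecules
from .formulas import all_constitutions
from .graphs import Protomolecule
from .space import ChemicalSpace, Stoichiometry, degree_sequence_of, make_space


@dataclass(frozen=True)
class Fixture:
    name: str
    space: ChemicalSpace
    description: str
    enumeration_cap: int = 10

    def constitutions(self) -> list[Stoichiometry]:
        return all_constitutions(self.space)

    def universes(self) -> dict[str, list[Protomolecule]]:
        """Stoichiometry key -> exhaustively enumerated protomolecules."""
        return _universes(self)

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.universes().items()}

    def total_graphs(self) -> int:
        return sum(self.counts().values())


@lru_cache(maxsize=32)
def _universes_cached(fixture_id: tuple) -> dict[str, list[Protomolecule]]:
    name, cfg_items, cap = fixture_id
    space = make_space(dict(cfg_items))
    out: dict[str, list[Protomolecule]] = {}
    for s in all_constitutions(space):
        out[s.key] = enumerate_protomolecules(degree_sequence_of(s), cap=cap)
    return out


def _universes(fx: Fixture) -> dict[str, list[Protomolecule]]:
    cfg = {str(at.element): at.valence for at in fx.space.atom_types}
    cfg["natoms"] = (fx.space.natoms_min, fx.space.natoms_max)
    key = (fx.name, tuple(sorted(cfg.items(), key=str)), fx.enumeration_cap)
    return _universes_cached(key)


_DEFINITIONS: list[tuple[str, dict, str, int]] = [
    (
        "monovalent_pair",
        {"X": 1, "Y": 1, "natoms": [2, 2]},
        "two monovalent elements, two atoms: the 1-vs-3 protomolecule "
        "worked example",
        10,
    ),
    (
        "alkane",
        {"C": 4, "H": 1, "natoms": [2, 8]},
        "carbon/hydrogen up to 8 atoms: tree-dominated universes",
        10,
    ),
    (
        "divalent_chain",
        {"O": 2, "H": 1, "natoms": [2, 7]},
        "divalent chains and rings with monovalent caps",
        10,
    ),
    (
        "halogenated",
        {"C": 4, "H": 1, "F": 1, "natoms": [2, 6]},
        "two monovalent elements: nonpure degree sequences throughout",
        10,
    ),
    (
        "mixed_valence",
        {"C": 4, "N": 3, "O": 2, "natoms": [2, 5]},
        "three distinct valences: pure sequences with multiple bond orders",
        10,
    ),
    (
        "small_world",
        {"C": 4, "S": 6, "natoms": [4, 7]},
        "26 degree sequences with 3 to ~4400 graphs each: calibration-refit "
        "scale",
        10,
    ),
    (
        "joint_sampling",
        {"C": 4, "S": 6, "natoms": [5, 5]},
        "6 stoichiometries, 131 protomolecules: joint-sampling uniformity "
        "test scale",
        10,
    ),
]


def make_fixtures(seed: int = 0) -> dict[str, Fixture]:
    """The built-in fixtures (deterministic; ``seed`` kept for API symmetry)."""
    out = {}
    for name, cfg, desc, cap in _DEFINITIONS:
        out[name] = Fixture(
            name=name,
            space=make_space(dict(cfg)),
            description=desc,
            enumeration_cap=cap,
        )
    return out
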