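"""Scoring how representative a molecule database is of its chemical space.

Molecules are grouped by stoichiometry (sum formula with realized valences).
The database's stoichiometry frequencies and the space's estimated
per-stoichiometry graph counts are normalized to probability distributions
over the same support, ordered by the stoichiometry's size in the reference
space (ties broken by canonical key), and turned into CDFs.  Two scores are
reported: the Kolmogorov-Smirnov statistic (max absolute CDF difference, in
[0, 1]) and the Kullback-Leibler divergence KL(P||Q) = sum P ln(P/Q) with P
the space and Q the database.  Stoichiometries absent from the database make
KL terms undefined; Q is floored at a vanishingly small eps there, and the
result is flagged because such terms inflate the metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .space import AtomType, Stoichiometry


class MoleculeParseError(ValueError):
    pass


def stoichiometry_of(smiles: str) -> Stoichiometry:
    """Stoichiometry of a SMILES record, with valences realized from bonds.

    Hydrogens are made explicit; each atom's valence is the sum of its bond
    orders, so e.g. trivalent and pentavalent nitrogen map to distinct atom
    types.  Raises :class:`MoleculeParseError` on unparseable input (callers
    typically count and skip those).
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"unparseable SMILES: {smiles!r}")
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    except Exception as exc:  # pragma: no cover - rdkit-specific failure
        raise MoleculeParseError(f"cannot kekulize: {smiles!r}") from exc
    mol = Chem.AddHs(mol)
    counts: dict[AtomType, int] = {}
    for atom in mol.GetAtoms():
        valence = int(
            round(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))
        )
        if valence < 1:
            raise MoleculeParseError(
                f"atom {atom.GetSymbol()} without bonds in {smiles!r}"
            )
        at = AtomType(atom.GetSymbol(), valence)
        counts[at] = counts.get(at, 0) + 1
    return Stoichiometry.from_mapping(counts)


@dataclass(frozen=True)
class PairedDistributions:
    """Space (P) and database (Q) probabilities over a shared ordered support."""

    support: tuple[str, ...]  # stoichiometry keys, size-sorted
    p_space: np.ndarray
    q_db: np.ndarray
    space_total: float = 0.0  # raw molecule count of the space (sets KL eps)

    def __post_init__(self) -> None:
        for arr in (self.p_space, self.q_db):
            if abs(float(arr.sum()) - 1.0) > 1e-12:
                raise ValueError("probabilities must sum to 1")


def build_cdfs(
    db_counts: "dict[str, float]", space_counts: "dict[str, float]"
) -> PairedDistributions:
    """Align database and space counts on the space's support and normalize.

    The support is every stoichiometry of the space, sorted by ascending size
    in the reference space (canonical key breaks ties); database entries
    outside the space's support are rejected, missing ones get probability 0.
    """
    if not space_counts:
        raise ValueError("empty chemical space")
    unknown = set(db_counts) - set(space_counts)
    if unknown:
        raise ValueError(
            f"database stoichiometries outside the space: {sorted(unknown)[:5]}"
        )
    support = tuple(
        sorted(space_counts, key=lambda k: (space_counts[k], k))
    )
    p = np.array([space_counts[k] for k in support], dtype=float)
    q = np.array([db_counts.get(k, 0.0) for k in support], dtype=float)
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("distributions must have positive total mass")
    return PairedDistributions(
        support, p / p.sum(), q / q.sum(), space_total=float(p.sum())
    )


def ks_statistic(pq: PairedDistributions) -> float:
    """Max absolute difference between the paired CDFs; 0 iff identical."""
    return float(np.max(np.abs(np.cumsum(pq.p_space) - np.cumsum(pq.q_db))))


@dataclass(frozen=True)
class KLResult:
    value: float
    eps: float
    eps_bins: int  # bins where Q had to be floored


def kl_divergence(
    pq: PairedDistributions, eps: float | None = None
) -> KLResult:
    """KL(P||Q) = sum P ln(P / max(Q, eps)), natural log.

    ``eps`` defaults to 1/(10 * total space molecule count) — a vanishingly
    small probability below a single space molecule's share; bins where the
    floor was used are counted, since zero-support terms inflate the metric.
    """
    p, q = pq.p_space, pq.q_db
    if eps is None:
        total = pq.space_total if pq.space_total > 0 else float(len(p))
        eps = 1.0 / (10.0 * total)
    hit = int(np.sum((p > 0) & (q < eps)))
    qf = np.maximum(q, eps)
    mask = p > 0
    value = float(np.sum(p[mask] * np.log(p[mask] / qf[mask])))
    if hit == 0:
        value = max(value, 0.0)  # Gibbs: nonnegative when no flooring occurred
    return KLResult(value=value, eps=eps, eps_bins=hit)


def subsample_curve(
    db_keys: Sequence[str],
    space_counts: "dict[str, float]",
    fractions: Iterable[float],
    reps: int = 5,
    seed: int = 0,
) -> list[dict[str, float]]:
    """Mean KS of random database subsets vs the full space, per fraction.

    ``db_keys`` lists one stoichiometry key per database molecule; subsets are
    drawn without replacement.  Rows: fraction, mean_ks, sd_ks, n_molecules.
    """
    keys = list(db_keys)
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        if not (0 < frac <= 1):
            raise ValueError("fractions must lie in (0, 1]")
        m = max(1, int(round(frac * len(keys))))
        ks_vals = []
        for _ in range(reps):
            idx = rng.choice(len(keys), size=m, replace=False)
            counts: dict[str, float] = {}
            for i in idx:
                counts[keys[i]] = counts.get(keys[i], 0.0) + 1.0
            ks_vals.append(ks_statistic(build_cdfs(counts, space_counts)))
        rows.append(
            {
                "fraction": float(frac),
                "mean_ks": float(np.mean(ks_vals)),
                "sd_ks": float(np.std(ks_vals)),
                "n_molecules": m,
            }
        )
    return rows
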