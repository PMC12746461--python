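"""File formats: space configs, the counts database, molecule output.

The counts database is an append-only CSV keyed by degree-sequence key with a
JSON sidecar holding the calibration constants; both are diff-friendly plain
text.  Molecules are written as SMILES lines or SDF (V2000, bond order =
multiplicity) when the element labels are real element symbols, with a graph
JSON fallback for abstract labels or valences SMILES cannot express.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import __version__
from .counting import CalibrationConstants, CountRecord, DEFAULT_CALIBRATION
from .sampler import MoleculeSample
from .space import ChemicalSpace, make_space


# ---------------------------------------------------------------------------
# space configs
# ---------------------------------------------------------------------------

def load_space(path: str | Path) -> ChemicalSpace:
    """Read a space config: one ``element: valence`` per line plus
    ``natoms: [min, max]``."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: expected a mapping of element: valence")
    return make_space(config)


def space_config_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# counts database
# ---------------------------------------------------------------------------

_DB_COLUMNS = ["key", "tier", "count", "l_G", "n_pairs", "seed", "note", "version"]


def load_counts_db(path: str | Path) -> dict[str, CountRecord]:
    path = Path(path)
    if not path.exists():
        return {}
    df = pd.read_csv(path)
    out: dict[str, CountRecord] = {}
    for row in df.itertuples(index=False):
        out[str(row.key)] = CountRecord(
            key=str(row.key),
            tier=str(row.tier),
            count=float(row.count),
            l_G=None if pd.isna(row.l_G) else float(row.l_G),
            n_pairs=0 if pd.isna(row.n_pairs) else int(row.n_pairs),
            seed=None if pd.isna(row.seed) else int(row.seed),
            note="" if pd.isna(row.note) else str(row.note),
        )
    return out


def save_counts_db(
    db: "dict[str, CountRecord]",
    path: str | Path,
    cal: CalibrationConstants = DEFAULT_CALIBRATION,
) -> None:
    """Write the whole database (sorted by key) plus the calibration sidecar."""
    rows = []
    for key in sorted(db):
        rec = db[key]
        count = rec.count
        if float(count).is_integer():
            count = int(count)  # stable text form across load/save cycles
        rows.append(
            {
                "key": rec.key,
                "tier": rec.tier,
                "count": count,
                "l_G": rec.l_G,
                "n_pairs": rec.n_pairs,
                "seed": rec.seed,
                "note": rec.note,
                "version": __version__,
            }
        )
    pd.DataFrame(rows, columns=_DB_COLUMNS).to_csv(path, index=False)
    sidecar = Path(str(path) + ".calibration.json")
    sidecar.write_text(json.dumps(dataclasses.asdict(cal), indent=2) + "\n")


def load_calibration(path: str | Path) -> CalibrationConstants:
    sidecar = Path(str(path) + ".calibration.json")
    if not sidecar.exists():
        return DEFAULT_CALIBRATION
    return CalibrationConstants(**json.loads(sidecar.read_text()))


def merge_counts(
    db: "dict[str, CountRecord]", new: Iterable[CountRecord]
) -> "dict[str, CountRecord]":
    """Append-with-dedup: existing keys win (append-only semantics)."""
    out = dict(db)
    for rec in new:
        out.setdefault(rec.key, rec)
    return out


# ---------------------------------------------------------------------------
# molecule output
# ---------------------------------------------------------------------------

def _bond_type(order: int):
    from rdkit import Chem

    table = {
        1: Chem.BondType.SINGLE,
        2: Chem.BondType.DOUBLE,
        3: Chem.BondType.TRIPLE,
        4: Chem.BondType.QUADRUPLE,
        5: Chem.BondType.QUINTUPLE,
        6: Chem.BondType.HEXTUPLE,
    }
    if order not in table:
        raise ValueError(f"bond order {order} not expressible")
    return table[order]


def sample_to_mol(sample: MoleculeSample):
    """RDKit molecule with explicit atoms and bond orders; raises ValueError
    when the element labels are not real element symbols."""
    from rdkit import Chem

    if sample.elements is None:
        raise ValueError("sample carries no element assignment")
    mol = Chem.RWMol()
    for el in sample.elements:
        try:
            atom = Chem.Atom(el)
        except Exception as exc:
            raise ValueError(f"{el!r} is not an element symbol") from exc
        if atom.GetAtomicNum() == 0:
            raise ValueError(f"{el!r} is not an element symbol")
        atom.SetNoImplicit(True)
        mol.AddAtom(atom)
    for i, j, m in sample.graph.edges():
        mol.AddBond(i, j, _bond_type(m))
    out = mol.GetMol()
    Chem.FastFindRings(out)
    return out


def sample_to_smiles(sample: MoleculeSample) -> str:
    from rdkit import Chem

    return Chem.MolToSmiles(sample_to_mol(sample))


def write_smiles(samples: Sequence[MoleculeSample], path: str | Path) -> int:
    """One SMILES per line; falls back to graph JSON lines (prefixed with
    ``JSON``) for samples SMILES cannot express.  Returns lines written."""
    lines = []
    for s in samples:
        try:
            lines.append(sample_to_smiles(s))
        except ValueError:
            lines.append("JSON " + s.graph.to_json(elements=s.elements))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    return len(lines)


def write_sdf(samples: Sequence[MoleculeSample], path: str | Path) -> int:
    from rdkit import Chem

    blocks = []
    for s in samples:
        mol = sample_to_mol(s)
        blocks.append(Chem.MolToMolBlock(mol, kekulize=False) + "$$$$\n")
    Path(path).write_text("".join(blocks))
    return len(blocks)


def read_smiles_file(path: str | Path) -> tuple[list[str], int]:
    """SMILES lines (comments/blank skipped); returns (records, n_skipped)."""
    records = []
    skipped = 0
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        records.append(line.split()[0])
    return records, skipped


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

def write_manifest(
    path: str | Path,
    command: str,
    seed: int | None = None,
    space_hash: str | None = None,
    tiers: "dict[str, int] | None" = None,
) -> None:
    manifest = {
        "tool": "rrspace",
        "version": __version__,
        "command": command,
        "seed": seed,
        "space_hash": space_hash,
        "tiers": tiers or {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
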