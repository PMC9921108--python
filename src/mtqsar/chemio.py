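"""SMILES parsing, tabular input formats, and dataset curation.

Molecules are handled as hydrogen-suppressed graphs: only heavy atoms are
vertices, bonds are undirected edges annotated with bond order.  Parsing and
canonicalization delegate to RDKit; the graph container itself is a plain
dataclass so descriptor code stays independent of the toolkit.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import (
    ConflictError,
    FormatError,
    MalformedSmilesError,
    RowError,
    TruncationWarning,
)

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")

#: Maximum number of data rows retained from a batch file.
BATCH_ROW_CAP = 100

#: Dotted two-level Enzyme Commission subclass label, e.g. "1.1" or "2.7".
EC_PATTERN = re.compile(r"^\d+\.\d+$")


@dataclass(frozen=True)
class MolecularGraph:
    """Hydrogen-suppressed molecular graph.

    atoms
        ``(element symbol, aromatic flag)`` per heavy atom; indices are
        0-based and contiguous.
    bonds
        ``(i, j, order)`` with ``i < j``; aromatic bonds carry order 1.5.
    """

    atoms: tuple[tuple[str, bool], ...]
    bonds: tuple[tuple[int, int, float], ...]

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) outside atom range 0..{n - 1}")
            if i == j:
                raise ValueError(f"self-loop on atom {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def degrees(self) -> list[int]:
        d = [0] * self.n_atoms
        for i, j, _ in self.bonds:
            d[i] += 1
            d[j] += 1
        return d


@dataclass(frozen=True)
class PairRecord:
    """One (drug, enzyme subclass, interaction label) observation."""

    drug_id: str
    smiles: str
    ec_family: str
    label: int  # 1 = interacting, 0 = non-interacting

    def __post_init__(self):
        if not EC_PATTERN.match(self.ec_family):
            raise ValueError(f"bad EC subclass label {self.ec_family!r}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class SmilesBatch:
    """Ordered batch of (row id, SMILES) pairs, capped at 100 rows."""

    rows: list[tuple[str, str]]
    source: str = ""
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)


def parse_smiles(text: str) -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-suppressed :class:`MolecularGraph`.

    Raises :class:`MalformedSmilesError` on unparsable input.  Aromaticity
    perception is RDKit's; aromatic bonds are recorded with order 1.5.
    """
    if text is None or not text.strip():
        raise MalformedSmilesError(str(text), "empty string")
    mol = Chem.MolFromSmiles(text.strip())
    if mol is None:
        raise MalformedSmilesError(text, "RDKit could not parse")
    return mol_to_graph(mol)


def mol_to_graph(mol: Chem.Mol) -> MolecularGraph:
    atoms = tuple((a.GetSymbol(), a.GetIsAromatic()) for a in mol.GetAtoms())
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if b.GetIsAromatic():
            order = 1.5
        else:
            order = float(b.GetBondTypeAsDouble())
        bonds.append((min(i, j), max(i, j), order))
    return MolecularGraph(atoms=atoms, bonds=tuple(sorted(bonds)))


_uncharger = rdMolStandardize.Uncharger()


def canonical_smiles(text: str) -> str:
    """Canonical SMILES after salt stripping and charge neutralization.

    The largest covalent fragment is kept and simple charges are neutralized;
    two inputs that are alternative forms of the same compound map to the
    same string.
    """
    mol = Chem.MolFromSmiles(text.strip()) if text and text.strip() else None
    if mol is None:
        raise MalformedSmilesError(text, "RDKit could not parse")
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    mol = _uncharger.uncharge(mol)
    return Chem.MolToSmiles(mol)


def _check_extension(path: Path, force_format: bool) -> None:
    if path.suffix.lower() not in {".txt", ".tsv"} and not force_format:
        raise FormatError(
            f"{path.name}: expected a .txt or .tsv file (use force_format to override)"
        )


def read_smiles_batch(path: str | Path, force_format: bool = False) -> SmilesBatch:
    """Read a tab-separated SMILES batch with header columns ``id`` and ``SMILE``.

    Rows beyond the first 100 data rows are dropped and a truncation warning
    is recorded on the batch (and emitted as a :class:`TruncationWarning`).
    Column names are matched case-insensitively; ``SMILES`` is accepted as an
    alias of ``SMILE``.
    """
    path = Path(path)
    _check_extension(path, force_format)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        batch = SmilesBatch(rows=[], source=str(path))
        batch.warnings.append("empty file")
        return batch
    cols = {c.lower(): c for c in df.columns}
    id_col = cols.get("id")
    smi_col = cols.get("smile") or cols.get("smiles")
    if id_col is None or smi_col is None:
        raise FormatError(
            f"{path.name}: need 'id' and 'SMILE' columns, found {list(df.columns)}"
        )
    batch = SmilesBatch(
        rows=[(str(r), str(s)) for r, s in zip(df[id_col], df[smi_col])],
        source=str(path),
    )
    if len(batch.rows) > BATCH_ROW_CAP:
        msg = (
            f"{path.name}: {len(batch.rows)} rows exceed the cap; "
            f"only the first {BATCH_ROW_CAP} rows will be analyzed"
        )
        batch.rows = batch.rows[:BATCH_ROW_CAP]
        batch.warnings.append(msg)
        warnings.warn(msg, TruncationWarning, stacklevel=2)
    if not batch.rows:
        batch.warnings.append("no data rows")
    return batch


#: Default column-name mapping for pair tables.
DEFAULT_PAIR_COLUMNS = {
    "drug_id": ("drug_id", "id", "drug", "chembl_id"),
    "smiles": ("smiles", "smile", "canonical_smiles"),
    "ec_family": ("ec_family", "ec", "subclass", "ec_subclass", "family"),
    "label": ("label", "interaction", "interacting", "class", "activity"),
}

_LABEL_MAP = {
    "1": 1, "0": 0, "active": 1, "inactive": 0,
    "interacting": 1, "non-interacting": 0, "true": 1, "false": 0,
}


def read_pair_table(
    path: str | Path,
    columns: dict[str, str] | None = None,
    label_map: dict[str, int] | None = None,
    sep: str | None = None,
) -> tuple[list[PairRecord], list[RowError]]:
    """Load a drug-enzyme pair table (TSV or CSV).

    Returns ``(records, row_errors)``; rows with an invalid EC subclass label
    or label encoding are collected as :class:`RowError`, not fatal.  Raises
    :class:`FormatError` when a required column cannot be mapped.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path.name}: empty pair table", stacklevel=2)
        return [], []
    lower = {c.lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for field_name, aliases in DEFAULT_PAIR_COLUMNS.items():
        if columns and field_name in columns:
            if columns[field_name] not in df.columns:
                raise FormatError(f"{path.name}: mapped column {columns[field_name]!r} absent")
            resolved[field_name] = columns[field_name]
            continue
        for alias in aliases:
            if alias in lower:
                resolved[field_name] = lower[alias]
                break
        else:
            raise FormatError(f"{path.name}: no column mappable to {field_name!r}")
    lmap = {**_LABEL_MAP, **(label_map or {})}
    records: list[PairRecord] = []
    errors: list[RowError] = []
    for idx, row in df.iterrows():
        ec = str(row[resolved["ec_family"]]).strip()
        raw_label = str(row[resolved["label"]]).strip().lower()
        if not EC_PATTERN.match(ec):
            errors.append(RowError(int(idx), f"invalid EC subclass {ec!r}"))
            continue
        if raw_label not in lmap:
            errors.append(RowError(int(idx), f"unrecognized label {raw_label!r}"))
            continue
        records.append(
            PairRecord(
                drug_id=str(row[resolved["drug_id"]]),
                smiles=str(row[resolved["smiles"]]),
                ec_family=ec,
                label=lmap[raw_label],
            )
        )
    if not records:
        warnings.warn(f"{path.name}: no valid pair records", stacklevel=2)
    return records, errors


def curate_pairs(records: Sequence[PairRecord]) -> list[PairRecord]:
    """Apply the dataset curation rules.

    Exact duplicates of (canonical SMILES, EC subclass) collapse to one
    record; the same compound under a *different* subclass is retained — the
    multi-target structure depends on it.  Contradictory labels for one
    (compound, subclass) key raise :class:`ConflictError`.  Records whose
    SMILES cannot be parsed are dropped with a logged count.
    """
    kept: dict[tuple[str, str], PairRecord] = {}
    conflicts: list[tuple[str, str]] = []
    n_malformed = 0
    for rec in records:
        try:
            canon = canonical_smiles(rec.smiles)
        except MalformedSmilesError:
            n_malformed += 1
            continue
        key = (canon, rec.ec_family)
        prev = kept.get(key)
        if prev is None:
            kept[key] = rec
        elif prev.label != rec.label:
            conflicts.append(key)
    if conflicts:
        raise ConflictError(sorted(set(conflicts)))
    if n_malformed:
        logger.warning("curate_pairs dropped %d malformed-SMILES records", n_malformed)
    return list(kept.values())


def records_to_frame(records: Iterable[PairRecord]) -> pd.DataFrame:
    """Pair records as a DataFrame with columns drug_id, smiles, ec_family, label."""
    return pd.DataFrame(
        [(r.drug_id, r.smiles, r.ec_family, r.label) for r in records],
        columns=["drug_id", "smiles", "ec_family", "label"],
    )


def dataset_composition(records: Sequence[PairRecord]) -> dict[str, int]:
    """Total / interacting / non-interacting counts of a pair table."""
    n_pos = sum(r.label for r in records)
    return {
        "total": len(records),
        "interacting": n_pos,
        "non_interacting": len(records) - n_pos,
    }
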