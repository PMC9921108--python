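"""Batch and single-SMILES prediction tables.

Output contract: one row per input SMILES in input order; a malformed SMILES
flags its row (``status="malformed"``) instead of aborting the batch; valid
rows carry one interacting-confidence value in [0, 1] per enzyme subclass in
the model bundle, columns in numeric EC order (1.1 < 1.2 < ... < 7.2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd

from .chemio import SmilesBatch
from .errors import MalformedSmilesError, UnknownColumnError
from .pipeline import MultiTargetQSAR, _ec_sort_key

EXPORT_DECIMALS = 6


@dataclass
class PredictionTable:
    """Per-row prediction outcomes against every enzyme subclass."""

    families: list[str]
    rows: list[dict] = field(default_factory=list)
    bundle_topology: str = ""

    def to_frame(self) -> pd.DataFrame:
        cols = ["id", "smiles", "status"] + self.families
        recs = []
        for row in self.rows:
            rec = {"id": row["id"], "smiles": row["smiles"], "status": row["status"]}
            for fam in self.families:
                rec[fam] = row["confidences"].get(fam)
            recs.append(rec)
        return pd.DataFrame(recs, columns=cols)

    def __len__(self) -> int:
        return len(self.rows)


def predict_one(smiles: str, model: MultiTargetQSAR, row_id: str = "") -> dict[str, float]:
    """Interacting confidence of one drug against each subclass of the bundle.

    Propagates :class:`MalformedSmilesError` (with row context) for
    unparsable input.
    """
    try:
        return model.predict_profile(smiles)
    except MalformedSmilesError as err:
        raise MalformedSmilesError(smiles, err.detail, row_id=row_id or None) from None


def predict_batch(batch: SmilesBatch, model: MultiTargetQSAR) -> PredictionTable:
    """One output row per (capped) input row, order preserved; malformed rows
    are flagged, never fatal."""
    families = sorted(model.families_, key=_ec_sort_key)
    table = PredictionTable(
        families=families, bundle_topology=getattr(model, "topology_", "")
    )
    for row_id, smiles in batch.rows:
        try:
            conf = model.predict_profile(smiles)
            table.rows.append(
                {"id": row_id, "smiles": smiles, "status": "ok",
                 "confidences": conf, "error": ""}
            )
        except MalformedSmilesError as err:
            table.rows.append(
                {"id": row_id, "smiles": smiles, "status": "malformed",
                 "confidences": {}, "error": str(err)}
            )
    return table


def export_table(
    table: PredictionTable, path: str | Path, format: Literal["tsv", "csv"] = "csv"
) -> Path:
    """Write the prediction table; confidences rounded to 6 decimals.

    Header: ``id, smiles, status`` then one column per subclass in numeric EC
    order.  Malformed rows leave their confidence cells empty.
    """
    if format not in ("tsv", "csv"):
        raise ValueError(f"format must be 'tsv' or 'csv', got {format!r}")
    path = Path(path)
    df = table.to_frame()
    for fam in table.families:
        df[fam] = df[fam].map(
            lambda v: "" if pd.isna(v) else f"{v:.{EXPORT_DECIMALS}f}"
        )
    df.to_csv(path, sep="\t" if format == "tsv" else ",", index=False)
    return path


def read_exported_table(path: str | Path) -> pd.DataFrame:
    """Re-import an exported prediction table (confidences as floats)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str, "smiles": str, "status": str})
    return df


def sort_filter(
    table: PredictionTable,
    by: str | None = None,
    ascending: bool = False,
    query: str | None = None,
) -> pd.DataFrame:
    """Non-destructive sorted/filtered view of the prediction table.

    ``by`` names a column (a subclass label or id/smiles/status); ``query``
    keeps rows whose SMILES or id contains the substring.  The underlying
    table is never modified.
    """
    df = table.to_frame()
    if query:
        mask = df["smiles"].str.contains(query, regex=False) | df["id"].str.contains(
            query, regex=False
        )
        df = df[mask]
    if by is not None:
        if by not in df.columns:
            raise UnknownColumnError(f"no column {by!r}")
        df = df.sort_values(by=by, ascending=ascending, kind="stable", na_position="last")
    return df.reset_index(drop=True)
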