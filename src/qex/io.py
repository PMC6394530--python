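"""File I/O: SDF readers, activity-label CSVs, and JSON model artifacts."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterator, Optional, Union

import pandas as pd
from rdkit import Chem

from .errors import MoleculeError, SchemaError
from .scoring import QEXModel

logger = logging.getLogger(__name__)

__all__ = ["read_sdf", "read_labels", "save_model", "load_model"]


def read_sdf(path: Union[str, Path], id_prop: str = "PUBCHEM_CID",
             on_error: str = "skip") -> Iterator[tuple[str, Chem.Mol]]:
    """Lazily yield ``(id, molecule)`` from a V2000/V3000 SDF file.

    The id comes from the molecule title line, falling back to the
    ``id_prop`` SD tag (PubChem exports carry PUBCHEM_CID) and finally the
    1-based record index. Duplicate ids are disambiguated by appending the
    record index. Unparsable records honour the skip-vs-abort policy.
    """
    path = Path(path)
    if not path.is_file():
        raise OSError(f"SDF file not found: {path}")
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    seen: set[str] = set()
    for index, mol in enumerate(supplier, start=1):
        if mol is None:
            if on_error == "raise":
                raise MoleculeError(f"record-{index}", f"unparsable SDF record in {path}")
            logger.warning("read_sdf: skipping unparsable record %d of %s", index, path)
            continue
        cid = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        if not cid and mol.HasProp(id_prop):
            cid = mol.GetProp(id_prop).strip()
        if not cid:
            cid = str(index)
        if cid in seen:
            cid = f"{cid}_{index}"
        seen.add(cid)
        yield cid, mol


_ACTIVE_TOKENS = {"1", "active", "true", "yes"}
_INACTIVE_TOKENS = {"0", "inactive", "false", "no"}


def _normalize_label(raw) -> str:
    token = str(raw).strip().lower()
    if token in _ACTIVE_TOKENS:
        return "active"
    if token in _INACTIVE_TOKENS:
        return "inactive"
    raise SchemaError(f"unrecognized activity label {raw!r}")


def read_labels(path: Union[str, Path]) -> dict[str, str]:
    """Read an id→label map from a CSV with id and label columns.

    Column names are sniffed case-insensitively (``id``/``cid``/
    ``pubchem_cid`` and ``label``/``activity``/``outcome``); anything else
    is a schema error — we fail loudly rather than guess. Labels accept
    {1, 0} or {active, inactive} in any case. Duplicate rows with agreeing
    labels are deduplicated; conflicting duplicates are a data error.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    id_col = next((cols[k] for k in ("id", "cid", "pubchem_cid", "compound_id")
                   if k in cols), None)
    label_col = next((cols[k] for k in ("label", "activity", "outcome", "active")
                      if k in cols), None)
    if id_col is None or label_col is None:
        raise SchemaError(
            f"label file {path}: could not identify id/label columns "
            f"among {list(df.columns)}"
        )
    labels: dict[str, str] = {}
    for rid, raw in zip(df[id_col], df[label_col]):
        rid = str(rid).strip()
        lab = _normalize_label(raw)
        if rid in labels and labels[rid] != lab:
            raise SchemaError(f"conflicting labels for id {rid!r}")
        labels[rid] = lab
    return labels


def save_model(model: QEXModel, path: Union[str, Path]) -> None:
    """Serialize a model to schema-versioned JSON (includes its hash)."""
    doc = model.to_dict()
    doc["model_hash"] = model.model_hash
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def load_model(path: Union[str, Path]) -> QEXModel:
    """Load a model JSON; truncated or wrong-version files fail cleanly."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"model file {path} is not valid JSON: {exc}") from exc
    return QEXModel.from_dict(doc)
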