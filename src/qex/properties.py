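"""Physicochemical descriptors underlying druglikeness scores.

Eight properties are computed per compound, always in the same canonical
order: molecular weight (MW, g/mol), Ghose-Crippen octanol-water logP
(ALOGP), hydrogen-bond donor and acceptor counts (HBD, HBA, Lipinski-style
definitions), topological polar surface area (PSA, A^2), rotatable-bond
count (ROTB), aromatic-ring count (AROM), and the number of structural-alert
patterns matched (ALERTS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, MolSurf, rdMolDescriptors
from rdkit.Chem import FilterCatalog

from .errors import AlertSetError, MoleculeError, SchemaError

logger = logging.getLogger(__name__)

#: Canonical property order used everywhere a vector of eight values appears.
PROPERTY_NAMES = ("MW", "ALOGP", "HBD", "HBA", "PSA", "ROTB", "AROM", "ALERTS")

#: Count-valued properties (unit-width histogram bins, integer storage).
INTEGER_PROPERTIES = frozenset({"HBD", "HBA", "ROTB", "AROM", "ALERTS"})

#: Property-table CSV header, fixed across versions.
TABLE_COLUMNS = ("id",) + PROPERTY_NAMES


@dataclass(frozen=True)
class PropertyVector:
    """The eight per-compound physicochemical properties, canonically ordered."""

    mw: float
    alogp: float
    hbd: int
    hba: int
    psa: float
    rotb: int
    arom: int
    alerts: int

    def __post_init__(self):
        if not self.mw > 0:
            raise ValueError(f"mw must be positive, got {self.mw}")
        if self.psa < 0:
            raise ValueError(f"psa must be non-negative, got {self.psa}")
        for name in ("hbd", "hba", "rotb", "arom", "alerts"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    def as_array(self) -> np.ndarray:
        """Return the vector as a float array in canonical order."""
        return np.array(
            [self.mw, self.alogp, self.hbd, self.hba,
             self.psa, self.rotb, self.arom, self.alerts],
            dtype=float,
        )

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "PropertyVector":
        v = np.asarray(values, dtype=float)
        if v.shape != (8,):
            raise ValueError(f"expected 8 values, got shape {v.shape}")
        return cls(
            mw=float(v[0]), alogp=float(v[1]), hbd=int(round(v[2])),
            hba=int(round(v[3])), psa=float(v[4]), rotb=int(round(v[5])),
            arom=int(round(v[6])), alerts=int(round(v[7])),
        )


@dataclass(frozen=True)
class CompoundRecord:
    """A compound id, its property vector, and an optional activity label."""

    id: str
    properties: PropertyVector
    label: Optional[str] = None  # "active" | "inactive" | None


class AlertSet:
    """A named collection of structural-alert substructure patterns.

    Built either from a two-column text file of (name, SMARTS) pairs or from
    RDKit's bundled Brenk filter catalog (the alert collection used by the
    original QED lineage).
    """

    def __init__(self, patterns: Sequence[tuple[str, str]]):
        self.patterns = list(patterns)
        self._mols = []
        for name, smarts in self.patterns:
            q = Chem.MolFromSmarts(smarts)
            if q is None:
                raise AlertSetError(f"invalid SMARTS for alert {name!r}: {smarts}")
            self._mols.append(q)
        self._catalog = None
        self.source = "file"

    def __len__(self) -> int:
        if self._catalog is not None:
            return self._catalog.GetNumEntries()
        return len(self.patterns)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "AlertSet":
        """Load (name, SMARTS) pairs from whitespace-separated two-column text.

        Lines starting with '#' and blank lines are ignored.
        """
        pairs = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise AlertSetError(f"{path}:{lineno}: expected 'name SMARTS'")
            pairs.append((parts[0], parts[1].strip()))
        return cls(pairs)

    @classmethod
    def default(cls) -> "AlertSet":
        """The Brenk alert collection from RDKit's filter catalogs (105 patterns)."""
        params = FilterCatalog.FilterCatalogParams()
        params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.BRENK)
        catalog = FilterCatalog.FilterCatalog(params)
        obj = cls([])
        obj._catalog = catalog
        obj.source = "rdkit-brenk"
        return obj

    def count_matches(self, mol: Chem.Mol) -> int:
        """Number of patterns with at least one substructure match (patterns, not hits)."""
        if self._catalog is not None:
            return len(self._catalog.GetMatches(mol))
        return sum(1 for q in self._mols if mol.HasSubstructMatch(q))


def count_alerts(mol: Chem.Mol, alerts: AlertSet) -> int:
    """Count alert patterns matched by ``mol`` (each pattern counts at most once)."""
    return alerts.count_matches(mol)


# Textbook Lipinski donor definition: one count per N or O bearing >= 1 H.
# (RDKit's NumHDonors SMARTS excludes e.g. water's O; the per-atom count is
# the conventional rule-of-five reading and is what we record in metadata.)
_HBD_PATTERN = Chem.MolFromSmarts("[#7,#8;!H0]")

HBD_DEFINITION = "count of N/O atoms bearing >=1 H (SMARTS [#7,#8;!H0])"
HBA_DEFINITION = "rdkit Lipinski.NumHAcceptors"


def largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the fragment with the most heavy atoms (strips counter-ions/salts)."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol
    return max(frags, key=lambda f: (f.GetNumHeavyAtoms(), f.GetNumAtoms()))


def compute_properties(mol: Chem.Mol, alerts: AlertSet,
                       compound_id: str = "?") -> PropertyVector:
    """Compute the eight-property vector for a sanitized molecule.

    Multi-fragment inputs are reduced to the largest fragment first. Raises
    :class:`MoleculeError` carrying ``compound_id`` if the structure cannot
    be processed.
    """
    if mol is None:
        raise MoleculeError(compound_id, "molecule is None (parse failure)")
    try:
        mol = largest_fragment(mol)
        Chem.SanitizeMol(mol)
        return PropertyVector(
            mw=Descriptors.MolWt(mol),
            alogp=Crippen.MolLogP(mol),
            hbd=len(mol.GetSubstructMatches(_HBD_PATTERN)),
            hba=Lipinski.NumHAcceptors(mol),
            psa=MolSurf.TPSA(mol),
            rotb=Lipinski.NumRotatableBonds(mol),
            arom=rdMolDescriptors.CalcNumAromaticRings(mol),
            alerts=count_alerts(mol, alerts),
        )
    except MoleculeError:
        raise
    except Exception as exc:  # rdkit raises plain Exceptions on sanitize failure
        raise MoleculeError(compound_id, str(exc)) from exc


def records_to_frame(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Property table as a DataFrame with columns ``id,MW,...,ALERTS``."""
    rows = [(r.id, *r.properties.as_array()) for r in records]
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    for name in PROPERTY_NAMES:
        if name in INTEGER_PROPERTIES:
            df[name] = df[name].astype(int)
    return df


def frame_to_records(df: pd.DataFrame,
                     labels: Optional[dict] = None) -> list[CompoundRecord]:
    """Build CompoundRecords from a property-table DataFrame (schema-checked)."""
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"property table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        rid = str(getattr(row, "id"))
        vec = PropertyVector.from_array([getattr(row, n) for n in PROPERTY_NAMES])
        out.append(CompoundRecord(rid, vec, labels.get(rid) if labels else None))
    return out


def properties_table(
    source: Union[str, Path, Iterable[tuple[str, Chem.Mol]], pd.DataFrame],
    alerts: Optional[AlertSet] = None,
    on_error: str = "skip",
    dedupe: bool = False,
) -> list[CompoundRecord]:
    """Build a property table from molecules, an SDF path, or a property CSV.

    Parameters
    ----------
    source
        Either a path to a property CSV (header ``id,MW,...,ALERTS``), a path
        to an SDF file, an iterable of ``(id, mol)`` pairs, or a DataFrame
        already in table layout.
    alerts
        Alert set for structure input; defaults to :meth:`AlertSet.default`.
    on_error
        ``"skip"`` logs per-molecule failures and continues; ``"raise"``
        propagates the first :class:`MoleculeError`.
    dedupe
        Drop duplicate structures (by canonical SMILES), keeping the first
        occurrence. Only applies to structure input.
    """
    if isinstance(source, pd.DataFrame):
        return frame_to_records(source)
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix.lower() in {".csv", ".tsv", ".txt"}:
            sep = "\t" if path.suffix.lower() == ".tsv" else ","
            return frame_to_records(pd.read_csv(path, sep=sep))
        from .io import read_sdf  # late import: io depends on this module
        source = read_sdf(path, on_error=on_error)

    if alerts is None:
        alerts = AlertSet.default()
    records: list[CompoundRecord] = []
    seen_smiles: set[str] = set()
    n_failed = 0
    n_dupes = 0
    for cid, mol in source:
        try:
            if mol is None:
                raise MoleculeError(str(cid), "unparseable structure")
            if dedupe:
                smi = Chem.MolToSmiles(largest_fragment(mol))
                if smi in seen_smiles:
                    n_dupes += 1
                    continue
                seen_smiles.add(smi)
            records.append(CompoundRecord(str(cid), compute_properties(mol, alerts, str(cid))))
        except MoleculeError as exc:
            if on_error == "raise":
                raise
            n_failed += 1
            logger.warning("skipping %s", exc)
    if n_failed:
        logger.info("properties_table: %d compounds skipped", n_failed)
    if n_dupes:
        logger.info("properties_table: %d duplicate structures removed", n_dupes)
    return records


def write_property_table(records: Sequence[CompoundRecord],
                         path: Union[str, Path]) -> None:
    """Write records as the canonical property CSV."""
    records_to_frame(records).to_csv(path, index=False)


def property_matrix(records: Sequence[CompoundRecord]) -> np.ndarray:
    """Stack records into an (n, 8) float matrix in canonical property order."""
    return np.vstack([r.properties.as_array() for r in records])
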