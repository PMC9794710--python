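"""Study-compound registry: structures, activity table, selectivity arithmetic.

The fifteen benzyloxy chalcones B1-B15 share the chalcone core
Ar-C(=O)-CH=CH-Ar' with a benzyloxy group at the ortho or para position of
the B-ring (Ar') and a variable A-ring (Ar).  Activity data are residual
enzyme activities at 10 µM and IC50 values against the two human monoamine
oxidase isoforms; hMAO-A IC50s above the assay ceiling are censored
("> 40 µM") and that censoring is carried as data, never dropped.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
from rdkit import Chem

from .errors import CensoringError, DomainError, SchemaError, StructureError

__all__ = [
    "Censor",
    "BenzyloxyPosition",
    "CensoredValue",
    "Compound",
    "ActivityRecord",
    "SelectivityIndex",
    "COMPOUND_SMILES",
    "A_RING_LABELS",
    "BENZYLOXY_POSITIONS",
    "load_registry",
    "selectivity_index",
    "pic50",
    "fold_ratio",
    "fixture_path",
]


class Censor(str, enum.Enum):
    EXACT = "exact"
    GREATER_THAN = "greater_than"


class BenzyloxyPosition(str, enum.Enum):
    ORTHO = "ortho"
    PARA = "para"
    NONE = "none"


# Single source of truth for the reconstructed structures.  The B-ring
# carries the benzyloxy ether; the A-ring (acyl side) varies per compound.
_BN_PARA = "/C=C/c1ccc(OCc2ccccc2)cc1"
_BN_ORTHO = "/C=C/c1ccccc1OCc1ccccc1"

COMPOUND_SMILES: dict[str, str] = {
    "B1": "O=C(c1ccc2OCOc2c1)" + _BN_ORTHO,
    "B2": "O=C(c1ccc2OCOc2c1)" + _BN_PARA,
    "B3": "O=C(c1ccc2OCCOc2c1)" + _BN_PARA,
    "B4": "O=C(c1ccc(S(C)(=O)=O)cc1)" + _BN_ORTHO,
    "B5": "O=C(c1ccc(S(C)(=O)=O)cc1)" + _BN_PARA,
    "B6": "O=C(c1ccc(SC)cc1)" + _BN_ORTHO,
    "B7": "O=C(c1ccc(SC)cc1)" + _BN_PARA,
    "B8": "O=C(c1ccc(Br)s1)" + _BN_PARA,
    "B9": "O=C(c1ccc(Br)s1)" + _BN_ORTHO,
    "B10": "O=C(c1cccs1)" + _BN_PARA,
    "B11": "O=C(c1cccs1)" + _BN_ORTHO,
    "B12": "O=C(c1ccc(C(F)(F)F)cc1)" + _BN_ORTHO,
    "B13": "O=C(c1ccc(C(F)(F)F)cc1)" + _BN_PARA,
    "B14": "O=C(c1ccc(OCC)cc1)" + _BN_ORTHO,
    "B15": "O=C(c1ccc(OCC)cc1)" + _BN_PARA,
}

A_RING_LABELS: dict[str, str] = {
    "B1": "methylenedioxyphenyl",
    "B2": "methylenedioxyphenyl",
    "B3": "benzodioxanyl",
    "B4": "methylsulfonylphenyl",
    "B5": "methylsulfonylphenyl",
    "B6": "thiomethylphenyl",
    "B7": "thiomethylphenyl",
    "B8": "bromothiophenyl",
    "B9": "bromothiophenyl",
    "B10": "thiophenyl",
    "B11": "thiophenyl",
    "B12": "trifluoromethylphenyl",
    "B13": "trifluoromethylphenyl",
    "B14": "ethoxyphenyl",
    "B15": "ethoxyphenyl",
}

BENZYLOXY_POSITIONS: dict[str, BenzyloxyPosition] = {
    cid: (BenzyloxyPosition.ORTHO if smi.endswith(_BN_ORTHO) else BenzyloxyPosition.PARA)
    for cid, smi in COMPOUND_SMILES.items()
}

# Substructure checks: chalcone core and positional benzyloxy patterns.
_CORE = Chem.MolFromSmarts("[c,C]C(=O)C=C[c]")
_OBN_PARA = Chem.MolFromSmarts("C(=O)C=Cc1ccc(OCc2ccccc2)cc1")
_OBN_ORTHO = Chem.MolFromSmarts("C(=O)C=Cc1ccccc1OCc1ccccc1")


@dataclass(frozen=True)
class CensoredValue:
    """A concentration (µM) that is either exact or a lower bound ("> x")."""

    value: float
    censor: Censor = Censor.EXACT
    stderr: Optional[float] = None

    def __post_init__(self):
        if not self.value > 0:
            raise DomainError(f"censored value must be positive, got {self.value}")
        if self.stderr is not None and self.stderr < 0:
            raise DomainError(f"stderr must be non-negative, got {self.stderr}")

    @property
    def is_exact(self) -> bool:
        return self.censor is Censor.EXACT


@dataclass(frozen=True)
class Compound:
    id: str
    smiles: str
    a_ring: str = "other"
    benzyloxy_position: BenzyloxyPosition = BenzyloxyPosition.NONE

    def __post_init__(self):
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise StructureError(f"{self.id}: SMILES does not parse: {self.smiles!r}")
        if len(Chem.GetMolFrags(mol)) != 1:
            raise StructureError(f"{self.id}: molecule is disconnected")
        if self.id in COMPOUND_SMILES:
            if not mol.HasSubstructMatch(_CORE):
                raise StructureError(f"{self.id}: chalcone core Ar-C(=O)-CH=CH-Ar' missing")
            expected = {
                BenzyloxyPosition.PARA: _OBN_PARA,
                BenzyloxyPosition.ORTHO: _OBN_ORTHO,
            }.get(self.benzyloxy_position)
            if expected is not None and not mol.HasSubstructMatch(expected):
                raise StructureError(
                    f"{self.id}: benzyloxy position {self.benzyloxy_position.value} "
                    "inconsistent with structure"
                )

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


@dataclass(frozen=True)
class ActivityRecord:
    compound_id: str
    residual_A: float
    residual_A_se: Optional[float]
    residual_B: float
    residual_B_se: Optional[float]
    ic50_A: CensoredValue
    ic50_B: CensoredValue

    def __post_init__(self):
        for name, v in (("residual_A", self.residual_A), ("residual_B", self.residual_B)):
            if not 0 <= v <= 120:
                raise DomainError(f"{self.compound_id}: {name}={v} outside [0, 120]%")


@dataclass(frozen=True)
class SelectivityIndex:
    """IC50(hMAO-A) / IC50(hMAO-B); larger means more MAO-B selective."""

    value: float
    censor: Censor = Censor.EXACT


def selectivity_index(ic50_a: CensoredValue, ic50_b: CensoredValue) -> SelectivityIndex:
    """SI = IC50(hMAO-A)/IC50(hMAO-B), propagating numerator censoring.

    A censored denominator is rejected: "> 40 / > 40" carries no usable
    bound in either direction.
    """
    if not ic50_b.is_exact:
        raise CensoringError("selectivity index undefined for censored denominator")
    return SelectivityIndex(value=ic50_a.value / ic50_b.value, censor=ic50_a.censor)


def pic50(ic50: CensoredValue | float) -> float:
    """pIC50 = -log10(IC50 in molar) = 6 - log10(IC50 in µM)."""
    if isinstance(ic50, CensoredValue):
        if not ic50.is_exact:
            raise CensoringError("pIC50 undefined for censored IC50")
        value = ic50.value
    else:
        value = float(ic50)
    if not value > 0:
        raise DomainError(f"IC50 must be positive, got {value}")
    return 6.0 - math.log10(value)


def fold_ratio(x: float, y: float) -> float:
    """Symmetric fold difference max(x, y)/min(x, y) >= 1."""
    if not (x > 0 and y > 0):
        raise DomainError(f"fold ratio needs positive inputs, got ({x}, {y})")
    return max(x, y) / min(x, y)


_ACTIVITY_COLUMNS = [
    "id",
    "residual_A",
    "residual_A_se",
    "residual_B",
    "residual_B_se",
    "ic50_A",
    "ic50_A_censor",
    "ic50_A_se",
    "ic50_B",
    "ic50_B_censor",
    "ic50_B_se",
]


def fixture_path() -> Path:
    """Directory holding the packaged compounds.sdf + activity.csv fixture."""
    return Path(resources.files("chalqsar").joinpath("data"))


def _censored(row, prefix: str, rowid: str) -> CensoredValue:
    raw_censor = str(row[f"{prefix}_censor"]).strip()
    try:
        censor = Censor(raw_censor)
    except ValueError:
        raise SchemaError(f"row {rowid}: bad {prefix}_censor value {raw_censor!r}")
    se = row[f"{prefix}_se"]
    se = None if pd.isna(se) else float(se)
    try:
        return CensoredValue(float(row[prefix]), censor, se)
    except (TypeError, ValueError, DomainError) as exc:
        raise SchemaError(f"row {rowid}: field {prefix}: {exc}") from exc


def load_registry(path: str | Path | None = None) -> list[tuple[Compound, ActivityRecord]]:
    """Load compounds (SDF V2000) and activity records (CSV) from a fixture dir.

    Defaults to the packaged B1-B15 fixture.  Raises :class:`SchemaError`
    naming the offending row/field on any violation.
    """
    base = Path(path) if path is not None else fixture_path()
    sdf, csv = base / "compounds.sdf", base / "activity.csv"
    if not sdf.exists() or not csv.exists():
        raise SchemaError(f"fixture incomplete under {base}: need compounds.sdf + activity.csv")

    table = pd.read_csv(csv)
    missing = set(_ACTIVITY_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"activity.csv missing columns: {sorted(missing)}")
    if table.empty:
        raise SchemaError("activity.csv contains no data rows")

    mols: dict[str, Chem.Mol] = {}
    for mol in Chem.SDMolSupplier(str(sdf)):
        if mol is None:
            raise StructureError(f"unparseable record in {sdf}")
        mols[mol.GetProp("_Name")] = mol

    out: list[tuple[Compound, ActivityRecord]] = []
    for _, row in table.iterrows():
        cid = str(row["id"])
        if cid not in mols:
            raise SchemaError(f"row {cid}: no matching structure in compounds.sdf")
        compound = Compound(
            id=cid,
            smiles=Chem.MolToSmiles(mols[cid]),
            a_ring=A_RING_LABELS.get(cid, "other"),
            benzyloxy_position=BENZYLOXY_POSITIONS.get(cid, BenzyloxyPosition.NONE),
        )
        try:
            record = ActivityRecord(
                compound_id=cid,
                residual_A=float(row["residual_A"]),
                residual_A_se=None if pd.isna(row["residual_A_se"]) else float(row["residual_A_se"]),
                residual_B=float(row["residual_B"]),
                residual_B_se=None if pd.isna(row["residual_B_se"]) else float(row["residual_B_se"]),
                ic50_A=_censored(row, "ic50_A", cid),
                ic50_B=_censored(row, "ic50_B", cid),
            )
        except (TypeError, ValueError, DomainError) as exc:
            raise SchemaError(f"row {cid}: {exc}") from exc
        out.append((compound, record))
    return out
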