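"""Compound library: the 26-analogue TRPA1 agonist dataset.

The series shares a tricyclic core — two benzo rings fused to a central
seven-membered ring that carries an azomethine (C=N) and a variable bridge
atom A at the 11-position (O for the dibenz[b,f][1,4]oxazepines, CH2 for the
11H-dibenz[b,e]azepines, S for the thio analogue). Each analogue is defined
by the bridge atom plus at most one ring substituent, so the whole dataset is
encoded as a small CSV and structures are built programmatically by grafting
substituent fragments onto the mapped parent scaffold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
from rdkit import Chem

__all__ = [
    "ScaffoldSpec",
    "CompoundRecord",
    "SCAFFOLDS",
    "SUBSTITUENTS",
    "TEST_SET_IDS",
    "pec50_from_ec50",
    "ec50_from_pec50",
    "build_structure",
    "load_compound_table",
    "load_activity_table",
    "load_reference_stats",
    "ALIGNMENT_FRAGMENT_SMARTS",
]

#: (Z)-N-benzylidenebenzenamine: the 14-heavy-atom common fragment
#: (two phenyl rings joined by CH=N) every analogue shares; used for
#: template alignment. The azomethine geometry is fixed by the ring.
ALIGNMENT_FRAGMENT_SMARTS = "c1ccc(C=Nc2ccccc2)cc1"

# Parent scaffold written atom-by-atom so indices are stable:
#   0 N5, 1 C6 (azomethine CH), 2 C6a, 3 C7, 4 C8, 5 C9, 6 C10, 7 C10a,
#   8 bridge (11-position), 9 C11a, 10 C1, 11 C2, 12 C3, 13 C4, 14 C4a.
_PARENT_SMILES = "N1=Cc2ccccc2{bridge}c2ccccc21"

_POSITION_MAP = {
    1: 10, 2: 11, 3: 12, 4: 13,
    6: 1,                       # azomethine carbon; never substituted
    7: 3, 8: 4, 9: 5, 10: 6,
    11: 8,                      # the bridge (A) position
}


@dataclass(frozen=True)
class ScaffoldSpec:
    """Parent tricyclic scaffold for one bridge-atom variant."""

    name: str
    bridge_atom: str            # "O", "CH2" or "S"
    parent_smiles: str
    position_map: Mapping[int, int] = field(default_factory=lambda: dict(_POSITION_MAP))

    def parent_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.parent_smiles)
        if mol is None:  # pragma: no cover - smiles are fixed constants
            raise ValueError(f"bad parent SMILES for {self.name}")
        return mol


SCAFFOLDS: dict[str, ScaffoldSpec] = {
    "O": ScaffoldSpec("dibenz[b,f][1,4]oxazepine", "O", _PARENT_SMILES.format(bridge="O")),
    "CH2": ScaffoldSpec("11H-dibenz[b,e]azepine", "CH2", _PARENT_SMILES.format(bridge="C")),
    "S": ScaffoldSpec("dibenz[b,f][1,4]thiazepine", "S", _PARENT_SMILES.format(bridge="S")),
}

#: Substituent token -> fragment SMILES; the first atom is the attachment
#: point. H means "no substituent".
SUBSTITUENTS: dict[str, str] = {
    "H": "",
    "COOMe": "C(=O)OC",
    "COOiPr": "C(=O)OC(C)C",
    "COOnBu": "C(=O)OCCCC",
    "CONH2": "C(=O)N",
    "CONEt2": "C(=O)N(CC)CC",
    "CONH(CH2)3OMe": "C(=O)NCCCOC",
    "CN": "C#N",
    "Br": "Br",
    "OMe": "OC",
    "OH": "O",
}

TEST_SET_IDS = frozenset({7, 13, 15, 16, 25})

PEC50_MIN, PEC50_MAX = 6.030, 10.301


@dataclass(frozen=True)
class CompoundRecord:
    """One analogue of the series."""

    compound_id: int
    substituent_position: int | None
    substituent_group: str
    bridge_atom: str
    pec50_actual: float
    subset: str                 # "train" or "test"

    def __post_init__(self) -> None:
        if self.bridge_atom not in SCAFFOLDS:
            raise ValueError(f"unknown bridge atom {self.bridge_atom!r}")
        if self.subset not in ("train", "test"):
            raise ValueError(f"subset must be train/test, got {self.subset!r}")


def pec50_from_ec50(ec50: float) -> float:
    """Convert a molar EC50 into pEC50 = log10(1/EC50).

    Raises ``ValueError`` for non-positive concentrations.
    """
    if ec50 <= 0:
        raise ValueError(f"EC50 must be positive (got {ec50!r})")
    return math.log10(1.0 / ec50)


def ec50_from_pec50(pec50: float) -> float:
    """Inverse of :func:`pec50_from_ec50`: EC50 in mol/L."""
    return 10.0 ** (-pec50)


def _parse_error(token: str) -> ValueError:
    supported = ", ".join(sorted(SUBSTITUENTS))
    return ValueError(f"unknown substituent token {token!r}; supported: {supported}")


def build_structure(record: CompoundRecord, scaffold: ScaffoldSpec | None = None) -> Chem.Mol:
    """Build the molecular graph for one compound record.

    The parent tricycle (with the record's bridge atom at the 11-position) is
    taken from ``scaffold`` (default: the packaged scaffold for the record's
    bridge atom) and the substituent fragment is grafted at the mapped ring
    position. Returns a sanitized, neutral RDKit molecule.
    """
    if scaffold is None:
        scaffold = SCAFFOLDS[record.bridge_atom]
    token = record.substituent_group
    if token not in SUBSTITUENTS:
        raise _parse_error(token)
    parent = scaffold.parent_mol()
    frag_smiles = SUBSTITUENTS[token]
    if not frag_smiles:
        mol = parent
    else:
        pos = record.substituent_position
        if pos is None or pos not in scaffold.position_map:
            raise KeyError(
                f"compound {record.compound_id}: position {pos!r} not in scaffold map"
            )
        anchor = scaffold.position_map[pos]
        frag = Chem.MolFromSmiles(frag_smiles)
        combined = Chem.RWMol(Chem.CombineMols(parent, frag))
        combined.AddBond(anchor, parent.GetNumAtoms(), Chem.BondType.SINGLE)
        mol = combined.GetMol()
    Chem.SanitizeMol(mol)
    if Chem.GetFormalCharge(mol) != 0:  # pragma: no cover - fragments are neutral
        raise ValueError(f"compound {record.compound_id} is not neutral")
    mol.SetProp("_Name", f"compound_{record.compound_id}")
    mol.SetIntProp("compound_id", record.compound_id)
    return mol


def _data_path(name: str) -> Path:
    return Path(str(resources.files("trpa1_qsar").joinpath("data", name)))


def load_compound_table(source: str | Path | None = None) -> list[CompoundRecord]:
    """Load the 26-compound table (packaged CSV by default)."""
    path = Path(source) if source is not None else _data_path("compounds.csv")
    df = pd.read_csv(path, comment="#")
    records = []
    for row in df.itertuples(index=False):
        pos = None if pd.isna(row.substituent_position) else int(row.substituent_position)
        records.append(
            CompoundRecord(
                compound_id=int(row.compound_id),
                substituent_position=pos,
                substituent_group=str(row.substituent_group),
                bridge_atom=str(row.bridge_atom),
                pec50_actual=float(row.pec50_actual),
                subset=str(row.subset),
            )
        )
    _check_library(records)
    return records


def _check_library(records: list[CompoundRecord]) -> None:
    if len(records) != 26:
        raise ValueError(f"expected 26 compounds, got {len(records)}")
    test_ids = {r.compound_id for r in records if r.subset == "test"}
    if test_ids != set(TEST_SET_IDS):
        raise ValueError(f"test-set ids {sorted(test_ids)} != {sorted(TEST_SET_IDS)}")
    for r in records:
        if not (PEC50_MIN <= r.pec50_actual <= PEC50_MAX):
            raise ValueError(f"compound {r.compound_id}: pEC50 {r.pec50_actual} out of range")


#: |actual - predicted - printed residual| allowed by 3-decimal table rounding
RESIDUAL_ROUNDING_TOL = 0.0015


def load_activity_table(source: str | Path | None = None) -> pd.DataFrame:
    """Load the actual/predicted pEC50 table and check its integrity.

    Validates: 26 rows, the published activity extremes (min 6.030 at
    compound 20, max 10.301 at compound 10), 21 training rows, and that every
    printed residual equals actual − predicted within table rounding.
    """
    path = Path(source) if source is not None else _data_path("predictions_table2.csv")
    df = pd.read_csv(path, comment="#")
    if len(df) != 26:
        raise ValueError(f"activity table must have 26 rows, found {len(df)}")
    for model in ("comfa", "comsia"):
        resid = df["pec50_actual"] - df[f"pec50_pred_{model}"]
        bad = (resid - df[f"residual_{model}"]).abs() > RESIDUAL_ROUNDING_TOL
        if bad.any():
            row = df.loc[bad.idxmax()]
            raise ValueError(
                f"residual inconsistency for compound {int(row.compound_id)} ({model})"
            )
    if (df["subset"] == "train").sum() != 21:
        raise ValueError("expected 21 training rows")
    lo, hi = df["pec50_actual"].idxmin(), df["pec50_actual"].idxmax()
    if (df.loc[lo, "compound_id"], round(df.loc[lo, "pec50_actual"], 3)) != (20, PEC50_MIN):
        raise ValueError("activity minimum does not match the published table")
    if (df.loc[hi, "compound_id"], round(df.loc[hi, "pec50_actual"], 3)) != (10, PEC50_MAX):
        raise ValueError("activity maximum does not match the published table")
    return df


def load_reference_stats() -> dict:
    """Printed PLS / external-validation reference constants for both models."""
    with open(_data_path("reference_stats.json")) as fh:
        return json.load(fh)
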