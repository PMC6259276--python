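"""Structure preparation: 3D embedding, minimization, charges, alignment.

One conformer per compound is generated (sketch-and-minimize style), charged
with Gasteiger charges, and rigidly superimposed onto the template compound
(the most active analogue, compound 10) through the shared
(Z)-N-benzylidenebenzenamine fragment using a Kabsch least-squares fit.

The original study used the proprietary Tripos force field with
Gasteiger-Huckel charges; this package substitutes MMFF94 (UFF fallback) and
plain Gasteiger charges, so downstream field values and model statistics are
close to, but not bit-identical with, the published SYBYL ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors

from .compounds import ALIGNMENT_FRAGMENT_SMARTS

__all__ = [
    "Conformer",
    "AlignmentResult",
    "VDW_TABLE",
    "embed_and_minimize",
    "assign_charges",
    "conformer_from_mol",
    "align_to_template",
    "kabsch",
    "write_sdf",
    "read_sdf",
    "write_alignment_sidecar",
]

CHANNEL_WEIGHT_KEYS = ("steric", "electrostatic", "hydrophobic", "donor", "acceptor")

MINIMIZE_ENERGY_TOL = 1e-6   # kcal/mol
MINIMIZE_MAX_ITERS = 2000
EMBED_RETRIES = 5


def _load_vdw_table() -> pd.DataFrame:
    path = resources.files("trpa1_qsar").joinpath("data", "vdw_params.csv")
    return pd.read_csv(str(path), comment="#").set_index("element")


#: element -> (r_star [A], epsilon [kcal/mol]) Lennard-Jones parameters
VDW_TABLE = _load_vdw_table()


@dataclass(frozen=True)
class Conformer:
    """A charged 3D conformer with per-atom field-property weights.

    ``weights`` maps CoMSIA channel names (steric, electrostatic,
    hydrophobic, donor, acceptor) to per-atom weight arrays.
    """

    compound_id: int
    elements: tuple[str, ...]
    coords: np.ndarray              # (n_atoms, 3), Angstrom
    charges: np.ndarray             # (n_atoms,), e
    radii: np.ndarray               # (n_atoms,), Angstrom (LJ r_star)
    epsilons: np.ndarray            # (n_atoms,), kcal/mol
    weights: dict[str, np.ndarray]
    mol: Chem.Mol | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.elements) if e != "H"], dtype=int)

    def translated(self, shift: np.ndarray) -> "Conformer":
        return replace(self, coords=self.coords + np.asarray(shift, float))


def embed_and_minimize(mol: Chem.Mol, seed: int = 0) -> Chem.Mol:
    """Embed one 3D conformer (ETKDG) and minimize it with MMFF94.

    Deterministic for a fixed seed. Falls back to UFF when MMFF parameters
    are missing. Raises ``RuntimeError`` (tagged with the compound id when
    present) if embedding fails after a few re-seeded retries.
    """
    molh = Chem.AddHs(mol)
    conf_id = -1
    for attempt in range(EMBED_RETRIES):
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) + 1000 * attempt
        conf_id = AllChem.EmbedMolecule(molh, params)
        if conf_id == 0:
            break
    if conf_id != 0:
        cid = mol.GetIntProp("compound_id") if mol.HasProp("compound_id") else "?"
        raise RuntimeError(f"3D embedding failed for compound {cid}")
    if AllChem.MMFFHasAllMoleculeParams(molh):
        AllChem.MMFFOptimizeMolecule(
            molh, maxIters=MINIMIZE_MAX_ITERS, nonBondedThresh=100.0
        )
    else:  # pragma: no cover - full set is MMFF-parameterized
        AllChem.UFFOptimizeMolecule(molh, maxIters=MINIMIZE_MAX_ITERS)
    return molh


def assign_charges(mol: Chem.Mol) -> np.ndarray:
    """Gasteiger partial charges per atom (e); neutral molecules sum to ~0."""
    supported = set(VDW_TABLE.index)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in supported:
            raise ValueError(f"unsupported element {atom.GetSymbol()!r} for charge/vdW model")
    Chem.rdPartialCharges.ComputeGasteigerCharges(mol)
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()])
    if not np.all(np.isfinite(q)):  # pragma: no cover
        raise ValueError("Gasteiger charges did not converge")
    return q


def _donor_acceptor_flags(mol: Chem.Mol) -> tuple[np.ndarray, np.ndarray]:
    # donors: O-H / N-H heavy atoms; acceptors: N or O with an available
    # lone pair (excludes the amide-type N which is flagged only as donor).
    n = mol.GetNumAtoms()
    donor = np.zeros(n)
    acceptor = np.zeros(n)
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym in ("N", "O") and atom.GetTotalNumHs(includeNeighbors=True) > 0:
            donor[atom.GetIdx()] = 1.0
        if sym == "O":
            acceptor[atom.GetIdx()] = 1.0
        elif sym == "N" and atom.GetTotalValence() <= 3 and not _is_amide_n(atom):
            acceptor[atom.GetIdx()] = 1.0
    return donor, acceptor


def _is_amide_n(atom: Chem.Atom) -> bool:
    for nbr in atom.GetNeighbors():
        if nbr.GetSymbol() == "C":
            for bond in nbr.GetBonds():
                other = bond.GetOtherAtom(nbr)
                if other.GetSymbol() == "O" and bond.GetBondTypeAsDouble() == 2.0:
                    return True
    return False


def conformer_from_mol(mol: Chem.Mol, compound_id: int | None = None) -> Conformer:
    """Package an embedded, hydrogen-complete RDKit mol as a :class:`Conformer`.

    Populates charges, LJ parameters and the five CoMSIA property weights
    (steric r_vdw^3, electrostatic charge, Crippen logP increments, 0/1
    donor/acceptor flags).
    """
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D conformer")
    if compound_id is None:
        compound_id = mol.GetIntProp("compound_id") if mol.HasProp("compound_id") else -1
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    coords = mol.GetConformer().GetPositions().astype(float)
    charges = assign_charges(mol)
    radii = VDW_TABLE["r_star"].loc[list(elements)].to_numpy(float)
    epsilons = VDW_TABLE["epsilon"].loc[list(elements)].to_numpy(float)
    logp = np.array([c[0] for c in rdMolDescriptors._CalcCrippenContribs(mol)])
    donor, acceptor = _donor_acceptor_flags(mol)
    weights = {
        "steric": radii**3,
        "electrostatic": charges.copy(),
        "hydrophobic": logp,
        "donor": donor,
        "acceptor": acceptor,
    }
    return Conformer(
        compound_id=int(compound_id),
        elements=elements,
        coords=coords,
        charges=charges,
        radii=radii,
        epsilons=epsilons,
        weights=weights,
        mol=mol,
    )


@dataclass(frozen=True)
class AlignmentResult:
    """Rigid-body superposition of a target onto the template frame."""

    rotation: np.ndarray            # (3, 3), proper orthonormal
    translation: np.ndarray         # (3,), Angstrom
    rmsd: float                     # Angstrom, over matched atoms
    matched_pairs: tuple[tuple[int, int], ...]

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns (rotation, translation, rmsd) with a proper rotation
    (determinant +1); ``rotation @ x + translation`` maps moving points into
    the fixed frame.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    mu_m, mu_f = moving.mean(axis=0), fixed.mean(axis=0)
    H = (moving - mu_m).T @ (fixed - mu_f)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = mu_f - R @ mu_m
    diff = moving @ R.T + t - fixed
    rmsd = float(np.sqrt((diff**2).sum() / len(moving)))
    return R, t, rmsd


def _fragment_matches(mol: Chem.Mol, fragment: Chem.Mol) -> list[tuple[int, ...]]:
    matches = mol.GetSubstructMatches(fragment, uniquify=False, maxMatches=64)
    if not matches:
        raise ValueError("alignment fragment does not match molecule")
    return list(matches)


def align_to_template(
    target: Conformer,
    template: Conformer,
    fragment: str | Chem.Mol = ALIGNMENT_FRAGMENT_SMARTS,
) -> tuple[AlignmentResult, Conformer]:
    """Superimpose ``target`` onto ``template`` over the common fragment.

    Heavy atoms of the fragment are matched in both molecules; among all
    substructure-match pairings the one with the lowest post-superposition
    RMSD is kept (ties broken by lowest atom-index order). Returns the
    alignment and the transformed conformer.
    """
    if isinstance(fragment, str):
        fragment = Chem.MolFromSmarts(fragment)
    if target.mol is None or template.mol is None:
        raise ValueError("alignment requires conformers with attached molecules")
    # fragment SMARTS atoms are all heavy, so matching the H-complete mol
    # directly yields heavy-atom indices valid for ``coords``
    t_matches = _fragment_matches(target.mol, fragment)
    p_matches = _fragment_matches(template.mol, fragment)
    best: tuple[float, tuple, tuple, AlignmentResult] | None = None
    for pm in p_matches:
        fixed = template.coords[list(pm)]
        for tm in t_matches:
            R, t, rmsd = kabsch(target.coords[list(tm)], fixed)
            key = (round(rmsd, 9), tm, pm)
            if best is None or key < (best[0], best[1], best[2]):
                res = AlignmentResult(
                    rotation=R,
                    translation=t,
                    rmsd=rmsd,
                    matched_pairs=tuple(zip(pm, tm)),
                )
                best = (key[0], tm, pm, res)
    assert best is not None
    result = best[3]
    aligned = replace(target, coords=result.apply(target.coords))
    return result, aligned


def write_sdf(conformers: Sequence[Conformer], path: str | Path) -> None:
    """Write conformers as SDF V2000 with partial charges as atom properties."""
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    try:
        for conf in conformers:
            if conf.mol is None:
                raise ValueError("conformer has no molecule attached")
            mol = Chem.Mol(conf.mol)
            mconf = mol.GetConformer()
            for i in range(mol.GetNumAtoms()):
                mconf.SetAtomPosition(i, conf.coords[i].tolist())
                mol.GetAtomWithIdx(i).SetDoubleProp("partial_charge", float(conf.charges[i]))
            Chem.CreateAtomDoublePropertyList(mol, "partial_charge")
            mol.SetIntProp("compound_id", conf.compound_id)
            writer.write(mol)
    finally:
        writer.close()


def read_sdf(path: str | Path) -> list[Conformer]:
    """Read an SDF written by :func:`write_sdf` back into conformers."""
    out = []
    for mol in Chem.SDMolSupplier(str(path), removeHs=False):
        if mol is None:  # pragma: no cover
            raise ValueError(f"unparseable SDF record in {path}")
        out.append(conformer_from_mol(mol))
    return out


def write_alignment_sidecar(results: dict[int, AlignmentResult], path: str | Path) -> None:
    """Dump alignment matrices to a JSON sidecar keyed by compound id."""
    payload = {
        str(cid): {
            "rotation": res.rotation.tolist(),
            "translation": res.translation.tolist(),
            "rmsd": res.rmsd,
            "matched_pairs": [list(p) for p in res.matched_pairs],
        }
        for cid, res in results.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))
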