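"""Structure input, canonical atom numbering, 3D embedding, and proton equivalence.

Assignment tables in public NMR libraries number atoms however the depositor's
drawing tool happened to number them.  Everything downstream therefore runs on
a canonical numbering: heavy atoms first in canonical-rank order, then
hydrogens ordered by the rank of the heavy atom they sit on.  The numbering is
a pure function of the molecular graph, so the same molecule always gets the
same indices regardless of input atom order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors

LABILE_NEIGHBORS = frozenset({"O", "N", "S"})
MIN_ATOM_SEPARATION = 0.5  # Angstrom; closer atoms indicate a broken embedding


class StructureError(ValueError):
    """Raised for unparsable, multi-fragment, or un-embeddable structures."""


@dataclass
class MoleculeRecord:
    """A hydrogen-complete molecule with canonical 1-based numbering and 3D coords."""

    id: str
    smiles: str
    atoms: list[tuple[int, str, int]]          # (canonical_index, element, formal_charge)
    bonds: list[tuple[int, int, float]]        # 1-based endpoints, bond order
    coords: np.ndarray                         # (N, 3) in Angstrom
    provenance: str                            # "input" | "embedded"
    rdmol: Chem.Mol = field(repr=False, compare=False, default=None)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def hydrogen_indices(self) -> list[int]:
        return [i for i, el, _ in self.atoms if el == "H"]

    def molecular_weight(self) -> float:
        return Descriptors.MolWt(self.rdmol)


@dataclass(frozen=True)
class HydrogenGroup:
    """Topologically equivalent hydrogens sharing one observed chemical shift."""

    member_indices: frozenset[int]             # canonical 1-based indices
    labile: bool
    heavy_neighbor_element: str

    @property
    def representative(self) -> int:
        return min(self.member_indices)


def _canonical_order(mol: Chem.Mol) -> list[int]:
    """New-position list: old index of the atom placed at each canonical slot."""
    # chirality excluded: stereo annotations (e.g. perceived from 3D coords
    # on an SDF round trip) must not change the numbering
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True, includeChirality=False))
    heavy = sorted((i for i, a in enumerate(mol.GetAtoms()) if a.GetAtomicNum() != 1),
                   key=lambda i: ranks[i])
    new_pos = {old: pos for pos, old in enumerate(heavy)}
    # hydrogens follow their heavy neighbor's slot; H bonded to H (H2) by rank
    hydros = sorted((i for i, a in enumerate(mol.GetAtoms()) if a.GetAtomicNum() == 1),
                    key=lambda i: (new_pos.get(
                        mol.GetAtomWithIdx(i).GetNeighbors()[0].GetIdx(), -1),
                        ranks[i]))
    return heavy + hydros


def _renumber(mol: Chem.Mol) -> Chem.Mol:
    return Chem.RenumberAtoms(mol, _canonical_order(mol))


def _looks_like_sdf(text: str) -> bool:
    return "V2000" in text or "M  END" in text


def _normalize_molblock(text: str) -> str:
    """Pin the V2000 counts line to line 4 (molblocks split from an SDF
    stream often gain or lose leading blank lines) and drop the $$$$ fence."""
    lines = [ln for ln in text.splitlines() if ln.strip() != "$$$$"]
    counts = next((i for i, ln in enumerate(lines) if ln.rstrip().endswith("V2000")), None)
    if counts is None:
        return text
    if counts > 3:
        lines = lines[counts - 3:]
    elif counts < 3:
        lines = [""] * (3 - counts) + lines
    return "\n".join(lines)


def parse_structure(text: str, id: str) -> MoleculeRecord:
    """Parse a SMILES string or a single V2000 SDF block into a MoleculeRecord.

    Hydrogens are made explicit and the canonical numbering is applied.  If the
    input carried no 3D coordinates, a conformer is embedded deterministically
    (seed 0); pass the record through :func:`embed_3d` to control the seed.

    Raises :class:`StructureError` for unparsable text or multi-fragment input
    (salts and mixtures are unsupported).
    """
    had_coords = False
    if _looks_like_sdf(text):
        mol = Chem.MolFromMolBlock(_normalize_molblock(text),
                                   removeHs=False, sanitize=True)
        if mol is None:
            raise StructureError(f"{id}: could not parse SDF block")
        if mol.GetNumConformers() > 0:
            conf = mol.GetConformer()
            pos = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                             conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())])
            had_coords = conf.Is3D() and not np.allclose(pos[:, 2], 0.0)
    else:
        mol = Chem.MolFromSmiles(text.strip())
        if mol is None:
            raise StructureError(f"{id}: could not parse SMILES {text.strip()!r}")
    if len(Chem.GetMolFrags(mol)) > 1:
        raise StructureError(f"{id}: multi-fragment input (salts/mixtures unsupported)")
    mol = Chem.AddHs(mol, addCoords=had_coords)
    mol = _renumber(mol)
    rec = _record_from_rdmol(mol, id, provenance="input" if had_coords else "embedded")
    if not had_coords:
        rec = embed_3d(rec, seed=0)
    else:
        _check_geometry(rec)
    return rec


def _record_from_rdmol(mol: Chem.Mol, id: str, provenance: str) -> MoleculeRecord:
    atoms = [(i + 1, a.GetSymbol(), a.GetFormalCharge())
             for i, a in enumerate(mol.GetAtoms())]
    bonds = sorted((min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) + 1,
                    max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) + 1,
                    b.GetBondTypeAsDouble()) for b in mol.GetBonds())
    if mol.GetNumConformers() > 0:
        conf = mol.GetConformer()
        coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                            conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())])
    else:
        coords = np.full((mol.GetNumAtoms(), 3), np.nan)
    smiles = Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(mol)))
    mol.SetProp("_Name", id)   # SDF title; survives write/read round trips
    return MoleculeRecord(id=id, smiles=smiles, atoms=atoms, bonds=bonds,
                          coords=coords, provenance=provenance, rdmol=mol)


def _check_geometry(rec: MoleculeRecord) -> None:
    if not np.isfinite(rec.coords).all():
        raise StructureError(f"{rec.id}: non-finite coordinates")
    if rec.n_atoms >= 2:
        d = np.linalg.norm(rec.coords[:, None, :] - rec.coords[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < MIN_ATOM_SEPARATION:
            raise StructureError(
                f"{rec.id}: atoms closer than {MIN_ATOM_SEPARATION} A (min {d.min():.3f})")


N_CONFORMER_ENSEMBLE = 5


def embed_3d(mol: MoleculeRecord, seed: int) -> MoleculeRecord:
    """Deterministic distance-geometry embedding with force-field relaxation.

    Embeds a small ensemble of conformers (ETKDG, fixed seed), relaxes each
    with MMFF94 (UFF fallback), and keeps the lowest-energy one.  Determinism:
    fixed (structure, seed) gives byte-identical coordinates.
    """
    rd = Chem.Mol(mol.rdmol)
    rd.RemoveAllConformers()
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    cids = AllChem.EmbedMultipleConfs(rd, numConfs=N_CONFORMER_ENSEMBLE, params=params)
    if len(cids) == 0:
        raise StructureError(f"{mol.id}: 3D embedding failed")
    try:
        results = AllChem.MMFFOptimizeMoleculeConfs(rd, maxIters=500)
        if any(code < 0 for code, _ in results):  # no MMFF parameters
            raise ValueError
    except ValueError:
        results = AllChem.UFFOptimizeMoleculeConfs(rd, maxIters=500)
    energies = [e for _, e in results]
    best = int(np.argmin(energies))
    keep = rd.GetConformer(cids[best])
    out = Chem.Mol(rd)
    out.RemoveAllConformers()
    out.AddConformer(keep, assignId=True)
    rec = _record_from_rdmol(out, mol.id, provenance="embedded")
    _check_geometry(rec)
    return rec


def find_equivalent_hydrogens(mol: MoleculeRecord) -> list[HydrogenGroup]:
    """Partition the hydrogens into topological symmetry classes.

    Two hydrogens are grouped when they share a canonical rank computed without
    tie-breaking (graph automorphism classes); a group is labile when its heavy
    neighbor is O, N, or S.  Groups are returned sorted by lowest member index.
    """
    rd = mol.rdmol
    ranks = list(Chem.CanonicalRankAtoms(rd, breakTies=False, includeChirality=False))
    by_rank: dict[int, list[int]] = {}
    for atom in rd.GetAtoms():
        if atom.GetAtomicNum() == 1:
            by_rank.setdefault(ranks[atom.GetIdx()], []).append(atom.GetIdx())
    groups = []
    for members in by_rank.values():
        heavy = rd.GetAtomWithIdx(members[0]).GetNeighbors()[0].GetSymbol()
        groups.append(HydrogenGroup(
            member_indices=frozenset(i + 1 for i in members),
            labile=heavy in LABILE_NEIGHBORS,
            heavy_neighbor_element=heavy,
        ))
    return sorted(groups, key=lambda g: g.representative)


@dataclass
class PredictionResult:
    """Per-equivalence-group predicted shifts for one molecule."""

    molecule_id: str
    groups: list[HydrogenGroup]
    shifts_ppm: list[float]
    solvent: str
    reference: str


def write_predictions_csv(result: PredictionResult, path) -> None:
    """Write one row per hydrogen group: member indices, shift (2 dp), solvent, reference."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["atom_indices", "shift_ppm", "solvent", "reference"])
        for group, shift in zip(result.groups, result.shifts_ppm):
            idx = ";".join(str(i) for i in sorted(group.member_indices))
            writer.writerow([idx, f"{shift:.2f}", result.solvent, result.reference])


def write_sdf(mol: MoleculeRecord, path) -> None:
    with Chem.SDWriter(str(path)) as w:
        w.write(mol.rdmol)


def write_sdf_many(mols: list[MoleculeRecord], path) -> None:
    with Chem.SDWriter(str(path)) as w:
        for mol in mols:
            w.write(mol.rdmol)


def parse_sdf_file(path) -> list[MoleculeRecord]:
    """Parse every record of a (multi-)SDF file; the molblock title is the
    molecule id (``mol-<k>`` when blank)."""
    from pathlib import Path

    blocks = [b for b in Path(path).read_text().split("$$$$") if b.strip()]
    out = []
    for k, block in enumerate(blocks):
        title = block.lstrip("\n").splitlines()[0].strip() if block.lstrip("\n") else ""
        out.append(parse_structure(block, id=title or f"mol-{k:04d}"))
    return out
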