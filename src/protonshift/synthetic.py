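"""Synthetic molecules and oracle shift labels for end-to-end testing.

Real training data for a shift predictor is curated experimental assignments;
none ship with this package.  Instead, a deterministic grammar emits small
C/H/N/O molecules (chains, rings, carbonyls, hydroxyls, amines) in the 31-566
Da range typical of metabolites, and an additive topological oracle labels
every hydrogen equivalence group with a shift in ppm:

    shift(group) = base(heavy-neighbor class)
                   + sum over heavy atoms within topological distance 1..3
                     of increment(element, distance)
                   + Gaussian noise drawn once per group

The oracle is exact and brute-force checkable, which makes learnability,
transfer, and curation behaviour testable without any downloads.  A second,
systematically perturbed oracle (global slope/offset plus per-class deltas)
emulates the computed-vs-experimental domain gap that fine-tuning bridges.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem

from .chem_io import MoleculeRecord, parse_structure, embed_3d, find_equivalent_hydrogens
from .curation import AssignmentRecord

# base shift per hydrogen environment class (heavy-neighbor element x hybridization)
DEFAULT_BASE_SHIFT = {
    "C-sp3": 1.0,
    "C-sp2": 5.6,
    "C-ar": 7.2,
    "C-sp": 2.4,
    "N": 3.2,
    "O": 3.6,
    "S": 1.6,
}

# ppm contribution of a heavy atom of given element at topological distance 1-3
# from the hydrogen's heavy neighbor
DEFAULT_NEIGHBOR_INCREMENT = {
    ("C", 1): 0.12, ("C", 2): 0.05, ("C", 3): 0.02,
    ("N", 1): 0.55, ("N", 2): 0.25, ("N", 3): 0.08,
    ("O", 1): 0.85, ("O", 2): 0.35, ("O", 3): 0.12,
}


@dataclass(frozen=True)
class OracleParams:
    base_shift: dict = field(default_factory=lambda: dict(DEFAULT_BASE_SHIFT))
    neighbor_increment: dict = field(default_factory=lambda: dict(DEFAULT_NEIGHBOR_INCREMENT))
    noise_sd: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class PerturbationSpec:
    """Systematic label perturbation: delta_B = slope * delta_A + offset + class_delta."""

    global_slope: float = 1.0
    global_offset: float = 0.0
    class_deltas: dict = field(default_factory=dict)


def transfer_gap_spec() -> PerturbationSpec:
    """The canonical source->target domain gap for transfer studies:
    a mild global rescaling plus per-class shifts of at most 0.3 ppm."""
    return PerturbationSpec(
        global_slope=0.95, global_offset=0.2,
        class_deltas={"C-sp3": 0.05, "C-sp2": -0.10, "C-ar": 0.30,
                      "O": -0.20, "N": 0.15})


def environment_class(mol: MoleculeRecord, h_index: int) -> str:
    """Classify a hydrogen by its heavy neighbor's element and hybridization."""
    atom = mol.rdmol.GetAtomWithIdx(h_index - 1)
    heavy = atom.GetNeighbors()[0]
    el = heavy.GetSymbol()
    if el != "C":
        return el
    if heavy.GetIsAromatic():
        return "C-ar"
    hyb = heavy.GetHybridization()
    if hyb == Chem.HybridizationType.SP3:
        return "C-sp3"
    if hyb == Chem.HybridizationType.SP2:
        return "C-sp2"
    return "C-sp"


def oracle_shifts(mol: MoleculeRecord, params: OracleParams) -> dict[frozenset, float]:
    """Label every hydrogen equivalence group with an oracle shift in ppm.

    Deterministic for fixed (structure, params, seed); noise is drawn once per
    group so equivalent protons share a label, matching how experimental
    tables report shifts.  Raises KeyError naming any environment class the
    parameterization does not cover.
    """
    groups = find_equivalent_hydrogens(mol)
    dmat = Chem.GetDistanceMatrix(mol.rdmol)
    rng = np.random.default_rng([params.seed & 0x7FFFFFFF,
                                 zlib.crc32(mol.smiles.encode())])
    heavy_idx = [i for i in range(mol.n_atoms)
                 if mol.rdmol.GetAtomWithIdx(i).GetAtomicNum() != 1]
    out: dict[frozenset, float] = {}
    for group in groups:
        h = group.representative
        cls = environment_class(mol, h)
        if cls not in params.base_shift:
            raise KeyError(f"oracle has no base shift for environment class {cls!r}")
        anchor = mol.rdmol.GetAtomWithIdx(h - 1).GetNeighbors()[0].GetIdx()
        shift = params.base_shift[cls]
        for j in heavy_idx:
            if j == anchor:
                continue
            dist = int(dmat[anchor, j])
            if 1 <= dist <= 3:
                el = mol.rdmol.GetAtomWithIdx(j).GetSymbol()
                shift += params.neighbor_increment.get((el, dist), 0.0)
        if params.noise_sd > 0:
            shift += rng.normal(0.0, params.noise_sd)
        out[group.member_indices] = float(shift)
    return out


def perturb_oracle(params: OracleParams, spec: PerturbationSpec) -> OracleParams:
    """Build the perturbed oracle B from A so that, noise aside,
    delta_B = slope * delta_A + offset + class_delta(class) exactly."""
    base = {cls: spec.global_slope * v + spec.global_offset
                 + spec.class_deltas.get(cls, 0.0)
            for cls, v in params.base_shift.items()}
    inc = {k: spec.global_slope * v for k, v in params.neighbor_increment.items()}
    return replace(params, base_shift=base, neighbor_increment=inc)


# ---------------------------------------------------------------------------
# molecule grammar

_SCAFFOLDS = (
    "C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC",
    "C1CCCC1", "C1CCCCC1", "C1CCOC1", "C1CCNC1",
    "c1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1",
)

# substituent builders: (name, atoms-as-(symbol, bond-order-to-previous) chain
# rooted at the attachment site, free valence needed at the site)
_SUBSTITUENTS = (
    ("hydroxyl", (("O", 1),), 1),
    ("amine", (("N", 1),), 1),
    ("methyl", (("C", 1),), 1),
    ("ethyl", (("C", 1), ("C", 1)), 1),
    ("methoxy", (("O", 1), ("C", 1)), 1),
    ("carboxyl", (("C", 1), ("O", 2), ("O", 1)), 1),
    ("acetyl", (("C", 1), ("O", 2), ("C", 1)), 1),
    ("formyl", (("C", 1), ("O", 2)), 1),
    ("oxo", (("O", 2),), 2),
)


def _attach(rw: Chem.RWMol, site: int, chain) -> None:
    prev = site
    branch_root = None
    for k, (symbol, order) in enumerate(chain):
        idx = rw.AddAtom(Chem.Atom(symbol))
        bond = Chem.BondType.DOUBLE if order == 2 else Chem.BondType.SINGLE
        rw.AddBond(prev, idx, bond)
        if k == 0:
            branch_root = idx
        # double-bonded O is a branch off the root, not a chain extension
        prev = branch_root if order == 2 else idx


def _free_valence(atom: Chem.Atom) -> int:
    return atom.GetTotalNumHs()


def _grow_molecule(rng: np.random.Generator, max_heavy_atoms: int) -> str | None:
    scaffold = _SCAFFOLDS[rng.integers(len(_SCAFFOLDS))]
    rw = Chem.RWMol(Chem.MolFromSmiles(scaffold))
    n_subs = int(rng.integers(0, 4))
    for _ in range(n_subs):
        name, chain, need = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
        Chem.SanitizeMol(rw)
        sites = [a.GetIdx() for a in rw.GetAtoms()
                 if a.GetSymbol() == "C" and _free_valence(a) >= need
                 and (name != "oxo" or not a.GetIsAromatic())]
        if not sites or rw.GetNumAtoms() + len(chain) > max_heavy_atoms:
            continue
        _attach(rw, int(sites[rng.integers(len(sites))]), chain)
    try:
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    if mol.GetNumAtoms() > max_heavy_atoms:
        return None
    return Chem.MolToSmiles(mol)


MW_RANGE = (31.0, 566.0)  # Da; the metabolite-like mass window emulated


def generate_molecules(n: int, seed: int, max_heavy_atoms: int = 12) -> list[MoleculeRecord]:
    """Sample n valence-correct C/H/N/O molecules from the deterministic grammar.

    All outputs parse and embed via chem_io and fall inside the 31-566 Da
    molecular-weight window.  Fixed (n, seed) gives an identical list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[MoleculeRecord] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("molecule grammar failed to produce enough candidates")
        smiles = _grow_molecule(rng, max_heavy_atoms)
        if smiles is None:
            continue
        embed_seed = int(rng.integers(1, 2**31 - 1))
        try:
            rec = parse_structure(smiles, id=f"syn-{seed}-{len(out):04d}")
            rec = embed_3d(rec, embed_seed)
        except Exception:
            continue
        if not (MW_RANGE[0] <= rec.molecular_weight() <= MW_RANGE[1]):
            continue
        if not rec.hydrogen_indices():
            continue
        out.append(rec)
    return out


def make_dataset(n: int, oracle: OracleParams, noise_sd: float, seed: int,
                 max_heavy_atoms: int = 12):
    """Generate molecules plus one AssignmentRecord per hydrogen group.

    Records are stamped water/DSS (the training condition) and pass
    curation.validate_dataset cleanly by construction.
    """
    molecules = generate_molecules(n, seed, max_heavy_atoms=max_heavy_atoms)
    params = replace(oracle, noise_sd=noise_sd, seed=seed)
    records: list[AssignmentRecord] = []
    for mol in molecules:
        labels = oracle_shifts(mol, params)
        for members in sorted(labels, key=min):
            records.append(AssignmentRecord(
                molecule_id=mol.id, atom_index=min(members),
                observed_shift=labels[members], solvent="water",
                reference="DSS", source="synthetic-oracle"))
    return molecules, records
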