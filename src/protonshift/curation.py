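"""Dataset cleaning: assignment remapping, validation, and outlier flagging.

Published assignment tables arrive numbered by whatever tool drew the
structure.  Curation remaps them onto the canonical numbering, machine-checks
the obvious error classes (assignments to non-hydrogens, physically
implausible shifts, duplicates, equivalent protons reported with conflicting
shifts), and flags predictor-vs-observed disagreements above 1.0 ppm for
human review.  The tools flag; they never auto-correct — reassignment is an
expert decision.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace

from .chem_io import MoleculeRecord, find_equivalent_hydrogens

SHIFT_RANGE = (-2.0, 20.0)          # plausible 1H range, ppm
GROUP_CONFLICT_TOLERANCE = 0.02     # ppm; typical peak-picking precision
OUTLIER_THRESHOLD = 1.0             # ppm; strict ">" at the boundary


@dataclass(frozen=True)
class AssignmentRecord:
    """One observed shift bound to one canonical hydrogen index."""

    molecule_id: str
    atom_index: int                 # canonical 1-based H index (group representative)
    observed_shift: float           # ppm
    solvent: str
    reference: str
    source: str = ""


def remap_assignments(records: list[AssignmentRecord],
                      mapping: dict[int, int]):
    """Rewrite atom indices through an old->canonical mapping.

    The mapping must be a bijection.  Records citing an index absent from the
    mapping are returned in a rejects list, never silently dropped.
    Returns (remapped_records, rejects).
    """
    if len(set(mapping.values())) != len(mapping):
        raise ValueError("mapping is not a bijection (duplicate targets)")
    remapped, rejects = [], []
    for rec in records:
        if rec.atom_index in mapping:
            remapped.append(replace(rec, atom_index=mapping[rec.atom_index]))
        else:
            rejects.append(rec)
    return remapped, rejects


@dataclass
class ValidationReport:
    non_hydrogen: list[AssignmentRecord]
    out_of_range: list[AssignmentRecord]
    duplicates: list[AssignmentRecord]
    group_conflicts: list[tuple[str, frozenset, float]]   # (mol id, group, spread ppm)
    unknown_molecule: list[AssignmentRecord]

    @property
    def is_clean(self) -> bool:
        return not (self.non_hydrogen or self.out_of_range or self.duplicates
                    or self.group_conflicts or self.unknown_molecule)

    def summary(self) -> str:
        return ("validation: {} non-H, {} out-of-range, {} duplicate, "
                "{} group-conflict, {} unknown-molecule".format(
                    len(self.non_hydrogen), len(self.out_of_range),
                    len(self.duplicates), len(self.group_conflicts),
                    len(self.unknown_molecule)))


def validate_dataset(records: list[AssignmentRecord],
                     molecules: dict[str, MoleculeRecord]) -> ValidationReport:
    """Machine-check a set of assignments against their structures."""
    report = ValidationReport([], [], [], [], [])
    seen: set[tuple[str, int]] = set()
    group_shifts: dict[tuple[str, frozenset], list[float]] = {}
    for rec in records:
        mol = molecules.get(rec.molecule_id)
        if mol is None:
            report.unknown_molecule.append(rec)
            continue
        if not (SHIFT_RANGE[0] <= rec.observed_shift <= SHIFT_RANGE[1]):
            report.out_of_range.append(rec)
        h_set = set(mol.hydrogen_indices())
        if rec.atom_index not in h_set:
            report.non_hydrogen.append(rec)
            continue
        key = (rec.molecule_id, rec.atom_index)
        if key in seen:
            report.duplicates.append(rec)
        seen.add(key)
        for group in find_equivalent_hydrogens(mol):
            if rec.atom_index in group.member_indices:
                group_shifts.setdefault((rec.molecule_id, group.member_indices),
                                        []).append(rec.observed_shift)
                break
    for (mol_id, members), shifts in group_shifts.items():
        spread = max(shifts) - min(shifts)
        if spread > GROUP_CONFLICT_TOLERANCE:
            report.group_conflicts.append((mol_id, members, spread))
    return report


@dataclass(frozen=True)
class OutlierEntry:
    record: AssignmentRecord
    predicted: float
    abs_diff: float
    flagged: bool


@dataclass
class OutlierReport:
    entries: list[OutlierEntry]
    unevaluated: list[AssignmentRecord]
    threshold: float

    @property
    def flagged(self) -> list[OutlierEntry]:
        return [e for e in self.entries if e.flagged]


def flag_outliers(molecules: dict[str, MoleculeRecord],
                  records: list[AssignmentRecord],
                  predictor,
                  threshold: float = OUTLIER_THRESHOLD) -> OutlierReport:
    """Flag assignments whose |predicted - observed| exceeds the threshold.

    ``predictor(mol)`` must return a mapping canonical-H-index -> predicted
    ppm covering the molecule's hydrogens (equivalent protons may share a
    value).  The boundary is strict: |diff| exactly equal to the threshold is
    not flagged.  Molecules whose prediction raises are reported as
    unevaluated rather than failing the run.
    """
    predictions: dict[str, dict[int, float] | None] = {}
    report = OutlierReport(entries=[], unevaluated=[], threshold=threshold)
    for rec in records:
        mol = molecules.get(rec.molecule_id)
        if mol is None:
            report.unevaluated.append(rec)
            continue
        if rec.molecule_id not in predictions:
            try:
                predictions[rec.molecule_id] = predictor(mol)
            except Exception:
                predictions[rec.molecule_id] = None
        pred_map = predictions[rec.molecule_id]
        if pred_map is None or rec.atom_index not in pred_map:
            report.unevaluated.append(rec)
            continue
        pred = float(pred_map[rec.atom_index])
        diff = abs(pred - rec.observed_shift)
        report.entries.append(OutlierEntry(
            record=rec, predicted=pred, abs_diff=diff, flagged=diff > threshold))
    return report


# ---------------------------------------------------------------------------
# CSV interchange

ASSIGNMENT_COLUMNS = ("molecule_id", "atom_index", "observed_shift",
                      "solvent", "reference", "source")


def read_assignments_csv(path) -> list[AssignmentRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        return [AssignmentRecord(
            molecule_id=row["molecule_id"],
            atom_index=int(row["atom_index"]),
            observed_shift=float(row["observed_shift"]),
            solvent=row["solvent"], reference=row["reference"],
            source=row.get("source", "")) for row in reader]


def write_assignments_csv(records: list[AssignmentRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ASSIGNMENT_COLUMNS)
        for r in records:
            writer.writerow([r.molecule_id, r.atom_index, f"{r.observed_shift:.4f}",
                             r.solvent, r.reference, r.source])
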