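"""Linear solvent maps and reference-standard offsets.

Moving a compound from water into methanol, chloroform, or DMSO shifts its
proton resonances systematically; over matched compound sets the relation is
well described by a line, delta_solvent = a * delta_water + b.  Changing the
internal 0-ppm standard (DSS, TMS, TSP) adds a small constant offset.  The
model predicts on the water/DSS scale; these maps convert its output to the
requested condition.

Maps ship as identity placeholders plus a calibration routine: fit them from
any paired-shift table before relying on non-water output.  DSS is the
internal canonical scale (offset 0 by construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from scipy import stats

SOLVENTS = ("water", "methanol", "chloroform", "dmso")
REFERENCES = ("DSS", "TMS", "TSP")


@dataclass(frozen=True)
class LinearSolventMap:
    """delta_solvent = a * delta_water + b (a dimensionless, b in ppm)."""

    solvent: str
    a: float = 1.0
    b: float = 0.0
    fit_r2: float = 1.0
    n_pairs: int = 0

    def __post_init__(self):
        if self.a == 0.0:
            raise ValueError("solvent map slope must be nonzero (invertible)")


def fit_solvent_map(pairs, solvent: str) -> LinearSolventMap:
    """Ordinary least squares fit of (delta_water, delta_solvent) pairs.

    Requires >= 3 pairs and non-degenerate water shifts.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 3:
        raise ValueError("need at least 3 (delta_water, delta_solvent) pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.allclose(x, x[0]):
        raise ValueError("degenerate fit: all water shifts identical")
    res = stats.linregress(x, y)
    return LinearSolventMap(solvent=solvent, a=float(res.slope),
                            b=float(res.intercept), fit_r2=float(res.rvalue ** 2),
                            n_pairs=len(x))


def apply_solvent_map(delta: float, smap: LinearSolventMap) -> float:
    return smap.a * delta + smap.b


def invert_solvent_map(smap: LinearSolventMap) -> LinearSolventMap:
    return LinearSolventMap(solvent=smap.solvent, a=1.0 / smap.a, b=-smap.b / smap.a,
                            fit_r2=smap.fit_r2, n_pairs=smap.n_pairs)


def apply_reference_correction(delta: float, from_ref: str, to_ref: str,
                               table: dict[str, float]) -> float:
    """Convert between reference standards via DSS-anchored offsets.

    ``table[ref]`` is the ppm added to a ref-referenced shift to land on the
    DSS scale; DSS itself has offset 0.
    """
    for ref in (from_ref, to_ref):
        if ref not in table:
            raise KeyError(f"unknown reference {ref!r}; table has {sorted(table)}")
    return delta + table[from_ref] - table[to_ref]


@dataclass
class CorrectionCalibration:
    """Per-solvent linear maps and per-reference DSS-anchored offsets."""

    solvent_maps: dict[str, LinearSolventMap]
    reference_offsets: dict[str, float]

    @staticmethod
    def identity() -> "CorrectionCalibration":
        """Placeholder calibration: every map identity, every offset zero."""
        return CorrectionCalibration(
            solvent_maps={s: LinearSolventMap(solvent=s) for s in SOLVENTS},
            reference_offsets={r: 0.0 for r in REFERENCES},
        )

    def __post_init__(self):
        water = self.solvent_maps.get("water")
        if water is not None and (water.a != 1.0 or water.b != 0.0):
            raise ValueError("the water map must be the identity")
        if self.reference_offsets.get("DSS", 0.0) != 0.0:
            raise ValueError("DSS is the canonical scale; its offset must be 0")

    def correct(self, delta_water_dss: float, solvent: str, reference: str) -> float:
        """Water/DSS model output -> requested solvent and reference."""
        out = apply_solvent_map(delta_water_dss, self.solvent_maps[solvent])
        return apply_reference_correction(out, "DSS", reference, self.reference_offsets)

    # -- persistence (YAML calibration file) --------------------------------

    def save(self, path) -> None:
        doc = {
            "solvent_maps": {
                s: {"a": m.a, "b": m.b, "r2": m.fit_r2, "n": m.n_pairs}
                for s, m in self.solvent_maps.items()},
            "reference_offsets": dict(self.reference_offsets),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @staticmethod
    def load(path) -> "CorrectionCalibration":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        maps = {s: LinearSolventMap(solvent=s, a=d["a"], b=d["b"],
                                    fit_r2=d.get("r2", 1.0), n_pairs=d.get("n", 0))
                for s, d in doc["solvent_maps"].items()}
        return CorrectionCalibration(solvent_maps=maps,
                                     reference_offsets=doc["reference_offsets"])
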