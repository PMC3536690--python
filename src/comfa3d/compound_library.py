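"""Structure/activity table handling and molecular-formula arithmetic.

The packaged dataset is a 46-compound congeneric series (30 training
compounds D1-D30, 16 external test compounds F1-F16) shipped as a CSV of
SMILES + IC50 values, together with two companion tables transcribed from
the source publication: per-compound characterization constants (molecular
formula, protonated-ion m/z, calculated elemental percentages) and the
published PLS observed/predicted activity table.

Formula arithmetic deliberately keeps two embedded mass tables: standard
average atomic weights for percent composition and monoisotopic masses for
[M+H]+ m/z.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from rdkit import Chem

__all__ = [
    "MolecularFormula",
    "CompoundRecord",
    "ValidationError",
    "FormulaParseError",
    "load_activity_table",
    "load_characterization_table",
    "load_pls_reference_table",
    "pic50_from_ic50",
    "ic50_from_pic50",
    "formula_of",
    "percent_composition",
    "protonated_monoisotopic_mz",
]

# standard average atomic weights (IUPAC 2021 abridged)
AVERAGE_MASS: dict[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "F": 18.998403163,
    "Cl": 35.45,
    "Br": 79.904,
}

# most-abundant-isotope masses
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "F": 18.99840316273,
    "Cl": 34.968852682,
    "Br": 78.9183376,
}

PROTON_MASS = 1.00727646688

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ValidationError(ValueError):
    """A record in an activity table violates the dataset contract."""


class FormulaParseError(ValueError):
    """A connectivity string or formula string could not be parsed."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element->count map with a net charge in elementary charges."""

    counts: Mapping[str, int]
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValidationError("empty molecular formula")
        for element, n in self.counts.items():
            if n < 0:
                raise ValidationError(f"negative count for element {element}")

    @classmethod
    def from_string(cls, text: str, charge: int = 0) -> "MolecularFormula":
        """Parse a Hill-style formula string such as ``C18H18FN3S``."""
        stripped = text.strip()
        if not stripped or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", stripped):
            raise FormulaParseError(f"cannot parse formula {text!r}")
        counts: dict[str, int] = {}
        for element, digits in _FORMULA_TOKEN.findall(stripped):
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        return cls(counts=counts, charge=charge)

    def to_string(self) -> str:
        """Hill order: C, H, then remaining elements alphabetically."""
        parts = []
        for element in ["C", "H"] + sorted(e for e in self.counts if e not in ("C", "H")):
            n = self.counts.get(element, 0)
            if n:
                parts.append(element + (str(n) if n > 1 else ""))
        return "".join(parts)

    def average_mass(self) -> float:
        return sum(_mass(AVERAGE_MASS, e) * n for e, n in self.counts.items())

    def monoisotopic_mass(self) -> float:
        return sum(_mass(MONOISOTOPIC_MASS, e) * n for e, n in self.counts.items())

    def __eq__(self, other: object) -> bool:
        if isinstance(other, MolecularFormula):
            return dict(self.counts) == dict(other.counts) and self.charge == other.charge
        return NotImplemented

    def __hash__(self) -> int:
        return hash((frozenset(self.counts.items()), self.charge))


def _mass(table: Mapping[str, float], element: str) -> float:
    try:
        return table[element]
    except KeyError:
        from .params import ParameterTableError

        raise ParameterTableError(f"no mass tabulated for element {element!r}") from None


@dataclass
class CompoundRecord:
    """One molecule of the series with activity and formula metadata."""

    id: str
    role: str  # "train" | "test"
    smiles: str
    ic50_uM: float
    pic50_computed: float
    pic50_reported: float | None = None
    formula: MolecularFormula | None = field(default=None, repr=False)


def pic50_from_ic50(ic50_uM: float) -> float:
    """Negative base-10 logarithm of IC50 expressed in micromolar."""
    if not ic50_uM > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_uM}")
    return -math.log10(ic50_uM)


def ic50_from_pic50(pic50: float) -> float:
    """Inverse of :func:`pic50_from_ic50`."""
    return 10.0 ** (-pic50)


def formula_of(smiles: str) -> MolecularFormula:
    """Molecular formula (with implicit hydrogens) of a SMILES string."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FormulaParseError(f"unparsable SMILES: {smiles!r}")
    counts: dict[str, int] = {}
    charge = 0
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        h = atom.GetTotalNumHs()
        if h:
            counts["H"] = counts.get("H", 0) + h
        charge += atom.GetFormalCharge()
    return MolecularFormula(counts=counts, charge=charge)


def percent_composition(formula: MolecularFormula) -> dict[str, float]:
    """Mass percent per element using standard average atomic weights."""
    total = formula.average_mass()
    if total <= 0:
        raise ValidationError("formula has zero mass")
    return {
        e: 100.0 * _mass(AVERAGE_MASS, e) * n / total for e, n in formula.counts.items()
    }


def protonated_monoisotopic_mz(formula: MolecularFormula) -> float:
    """[M+H]+ m/z of a neutral formula using monoisotopic masses."""
    if formula.charge != 0:
        raise ValidationError("protonation expects a neutral formula")
    return formula.monoisotopic_mass() + PROTON_MASS


def _packaged_path(name: str) -> Path:
    return Path(str(resources.files("comfa3d").joinpath("data", name)))


def load_activity_table(source: str | Path | None = None) -> list[CompoundRecord]:
    """Load and validate an ``id,role,smiles,ic50_uM[,pic50_reported]`` CSV.

    With ``source=None`` the packaged 46-compound table is loaded, for which
    the full dataset contract (30 train / 16 test, unique ids) is enforced.
    """
    packaged = source is None
    path = _packaged_path("compounds.csv") if packaged else Path(source)
    frame = pd.read_csv(path, dtype={"id": str, "role": str})
    required = {"id", "role", "smiles", "ic50_uM"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    if len(frame) == 0:
        raise ValidationError("no records")

    seen: set[str] = set()
    records: list[CompoundRecord] = []
    for row in frame.itertuples(index=False):
        cid = str(row.id)
        if cid in seen:
            raise ValidationError(f"duplicate compound id {cid!r}")
        seen.add(cid)
        if row.role not in ("train", "test"):
            raise ValidationError(f"compound {cid!r}: role must be train|test")
        ic50 = float(row.ic50_uM)
        if not ic50 > 0 or not math.isfinite(ic50):
            raise ValidationError(f"compound {cid!r}: non-positive IC50 {ic50}")
        reported = getattr(row, "pic50_reported", None)
        records.append(
            CompoundRecord(
                id=cid,
                role=row.role,
                smiles=row.smiles,
                ic50_uM=ic50,
                pic50_computed=pic50_from_ic50(ic50),
                pic50_reported=float(reported) if reported is not None else None,
                formula=formula_of(row.smiles),
            )
        )

    if packaged:
        n_train = sum(1 for r in records if r.role == "train")
        n_test = sum(1 for r in records if r.role == "test")
        if (n_train, n_test) != (30, 16):
            raise ValidationError(
                f"packaged table must hold 30 train + 16 test records, got {n_train}+{n_test}"
            )
    return records


def load_characterization_table() -> pd.DataFrame:
    """Printed characterization constants for the packaged series.

    Columns: id, formula, mz_mh (printed [M+H]+ value), calcd_pct_C/H/N
    (printed calculated elemental percentages). These are transcription
    constants used as the validation gate for the packaged structures.
    """
    return pd.read_csv(_packaged_path("characterization.csv"), dtype={"id": str})


def load_pls_reference_table() -> pd.DataFrame:
    """Published per-compound PLS table (observed, predicted, residual).

    ``pic50``/``pre_pic50``/``residual`` are kept as strings to preserve the
    printed decimal places; ``comfa`` is an integer column of undefined
    meaning transcribed verbatim and never used by the pipeline.
    """
    return pd.read_csv(
        _packaged_path("pls_reference.csv"),
        dtype={"id": str, "pic50": str, "pre_pic50": str, "residual": str, "comfa": int},
    )


def validate_packaged_series(records: Iterable[CompoundRecord] | None = None) -> pd.DataFrame:
    """Cross-check packaged SMILES against the printed characterization data.

    Returns a frame with one row per compound and boolean columns
    ``formula_ok`` (exact string match), ``mz_ok`` (|calc - printed| <= 0.1)
    and ``pct_ok`` (all of %C/%H/%N within 0.01 of the printed values).
    """
    if records is None:
        records = load_activity_table()
    by_id = {r.id: r for r in records}
    char = load_characterization_table()
    rows = []
    for row in char.itertuples(index=False):
        rec = by_id[row.id]
        printed = MolecularFormula.from_string(row.formula)
        mz = protonated_monoisotopic_mz(printed)
        pct = percent_composition(printed)
        rows.append(
            {
                "id": row.id,
                "formula_ok": rec.formula.to_string() == row.formula,
                "mz_calc": mz,
                "mz_printed": row.mz_mh,
                "mz_ok": abs(mz - row.mz_mh) <= 0.1,
                "pct_ok": (
                    abs(pct["C"] - row.calcd_pct_C) <= 0.01 + 5e-13
                    and abs(pct["H"] - row.calcd_pct_H) <= 0.01 + 5e-13
                    and abs(pct["N"] - row.calcd_pct_N) <= 0.01 + 5e-13
                ),
            }
        )
    return pd.DataFrame(rows)
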