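"""Per-residue binding-energy table algebra and the key-residue filter.

Per-residue MM-GBSA energy decompositions arrive as five-column tables:
van der Waals (E_VDW) and electrostatic (E_ELE) terms in vacuum, polar
(E_GB) and non-polar (E_GBSUR) solvation terms, and the total E_TOT, all in
kJ/mol with "value ± sd" cells.  This module parses those tables, recomputes
totals as the component sum, and filters the key residues whose total
binding energy falls below a threshold (default −1.00 kJ/mol, strict).

The energy computation itself (force field, GB model) is upstream and out
of scope; a transcription of the reference key-residue table for the three
AABP–substrate complexes ships with the package
(:func:`load_reference_energy_table`).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

COMPONENTS = ("E_VDW", "E_ELE", "E_GB", "E_GBSUR")
_CELL_RE = re.compile(
    r"^\s*(?P<value>-?\d+(?:\.\d+)?)\s*(?:±\s*(?P<sd>-?\d+(?:\.\d+)?))?\s*$"
)


@dataclass
class EnergyRecord:
    """One residue's energy decomposition (kJ/mol)."""

    residue: int                     # consensus residue number
    native: str                      # native label, e.g. "K115"
    e_vdw: float
    e_ele: float
    e_gb: float
    e_gbsur: float
    e_tot: float
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        vals = (self.e_vdw, self.e_ele, self.e_gb, self.e_gbsur, self.e_tot)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"residue {self.residue}: non-finite energy")
        if not re.match(r"^[A-Z]\d+$", self.native):
            raise ValueError(f"unparseable native label {self.native!r}")


@dataclass
class EnergyTable:
    """Ordered energy records for one system (unique residue numbers)."""

    system: str
    records: list[EnergyRecord]

    def __post_init__(self):
        nums = [r.residue for r in self.records]
        if len(set(nums)) != len(nums):
            raise ValueError(f"{self.system}: duplicate residue numbers")

    def __len__(self):
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "system": self.system, "residue": r.residue,
                    "native": r.native, "E_VDW": r.e_vdw, "E_ELE": r.e_ele,
                    "E_GB": r.e_gb, "E_GBSUR": r.e_gbsur, "E_TOT": r.e_tot,
                }
                for r in self.records
            ]
        )


def _parse_cell(cell: str, path, line_no: int) -> tuple[float, float]:
    text = str(cell).replace("−", "-").replace("±", "±")
    m = _CELL_RE.match(text)
    if not m:
        raise ValueError(f"{path}:{line_no}: malformed energy cell {cell!r}")
    return float(m.group("value")), float(m.group("sd") or 0.0)


def read_energy_table(path, system: str | None = None) -> list[EnergyTable]:
    """Parse a TSV in the five-column decomposition layout.

    Expected columns: ``system``, ``residue`` (e.g. ``"117 (K115)"`` or a
    bare number with a ``native`` column), then the four components and
    ``E_TOT``, each accepting ``value ± sd`` cells.  Unicode minus signs
    are normalized.  Returns one :class:`EnergyTable` per system (filtered
    to ``system`` when given).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty:
        warnings.warn(f"{path}: empty energy table")
        return []
    required = {"system", "residue", *COMPONENTS, "E_TOT"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    tables: dict[str, list[EnergyRecord]] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        m = re.match(r"^\s*(\d+)\s*(?:\(\s*([A-Z]\d+)\s*\))?\s*$",
                     str(row["residue"]))
        if not m:
            raise ValueError(
                f"{path}:{line_no}: malformed residue cell {row['residue']!r}"
            )
        residue = int(m.group(1))
        native = m.group(2) or str(row.get("native", "")) or f"X{residue}"
        vals, sds = {}, {}
        for col in (*COMPONENTS, "E_TOT"):
            vals[col], sds[col] = _parse_cell(row[col], path, line_no)
        rec = EnergyRecord(
            residue=residue, native=native,
            e_vdw=vals["E_VDW"], e_ele=vals["E_ELE"], e_gb=vals["E_GB"],
            e_gbsur=vals["E_GBSUR"], e_tot=vals["E_TOT"], sd=sds,
        )
        tables.setdefault(str(row["system"]), []).append(rec)
    out = [EnergyTable(system=s, records=recs) for s, recs in tables.items()]
    if system is not None:
        out = [t for t in out if t.system == system]
    return out


def compute_etot(record: EnergyRecord) -> float:
    """Component sum E_VDW + E_ELE + E_GB + E_GBSUR, rounded to 2 decimals
    for comparison against printed totals."""
    return round(record.e_vdw + record.e_ele + record.e_gb + record.e_gbsur, 2)


def key_residues(table: EnergyTable, threshold: float = -1.00) -> list[EnergyRecord]:
    """Records with E_TOT strictly below ``threshold``, most favorable first."""
    hits = [r for r in table.records if r.e_tot < threshold]
    return sorted(hits, key=lambda r: r.e_tot)


def load_reference_energy_table() -> list[EnergyTable]:
    """The packaged key-residue decomposition table for the GlnBP/HisJ/LAOBP
    complexes (transcribed from the published per-residue MM-GBSA
    decomposition)."""
    with resources.as_file(
        resources.files("aabp_allostery.data") / "aabp_key_residues.tsv"
    ) as p:
        return read_energy_table(p)
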