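"""Cα-level structure reading, sequence extraction and domain assignment.

All coordinates are in Ångström.  Cross-protein residue statements use a
consensus numbering 1–238 defined by the three-way alignment of the
amino-acid-binding-protein (AABP) sequences; the default
:class:`DomainPartition` encodes the eight-segment partition of that
consensus frame (T-α, T-αβα, IT1, I-β, I-Loop, I-βα, I-2βα, IT2) plus the
coarse Thumb / Index-Finger / Linker regions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

# 3-letter -> 1-letter, standard residues plus common modified forms.
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine / selenocysteine and frequent variants
    "MSE": "M", "SEC": "U", "PYL": "O", "HSD": "H", "HSE": "H", "HSP": "H",
}


@dataclass
class CaStructure:
    """One node per residue with a Cα record, in file order.

    Attributes
    ----------
    residue_ids : author residue numbers (int, ordered as in the file)
    residue_names : 3-letter residue codes
    coords : (N, 3) Cα positions in Å
    chain_id : single-character chain identifier
    label : free-text system name, e.g. ``"GlnBP-open"``
    icodes : PDB insertion codes ('' when absent); insertion-coded residues
        are kept as distinct nodes in file order
    """

    residue_ids: np.ndarray
    residue_names: list[str]
    coords: np.ndarray
    chain_id: str = "A"
    label: str = ""
    icodes: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.residue_ids)
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{n} residues"
            )
        if len(self.residue_names) != n:
            raise ValueError("residue_names length mismatch")
        if not self.icodes:
            self.icodes = [""] * n
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        keys = list(zip(self.residue_ids.tolist(), self.icodes))
        if len(set(keys)) != n:
            raise ValueError("duplicate (residue id, insertion code) pairs")

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def sequence(self) -> str:
        return extract_sequence(self)


def read_pdb_ca(path, chain: str | None = None, label: str = "") -> CaStructure:
    """Read one chain of a PDB file as a Cα-only structure.

    Residues without a Cα atom are skipped with a warning; alternate
    locations are resolved to the highest-occupancy conformer (first wins a
    tie, which is Biopython's selection rule).  Missing interior residues
    (crystal gaps) stay missing and are reported in the log.

    Parameters
    ----------
    path : PDB-format text file
    chain : chain identifier; default = first chain in the first model
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"no coordinate records in {path}") from None
    chains = {c.id: c for c in model.get_chains()}
    if chain is None:
        chain = next(iter(chains))
    if chain not in chains:
        raise ValueError(f"chain {chain!r} not in {sorted(chains)}")

    ids, names, icodes, xyz = [], [], [], []
    skipped = []
    for res in chains[chain].get_residues():
        hetflag, resseq, icode = res.get_id()
        if hetflag == "W":
            continue
        if "CA" not in res:
            # het ligands have no CA; only warn for peptidic residues
            if res.get_resname() in _THREE_TO_ONE:
                skipped.append((resseq, res.get_resname()))
            continue
        atom = res["CA"]
        ids.append(resseq)
        names.append(res.get_resname())
        icodes.append(icode.strip())
        xyz.append(atom.get_coord())
    if skipped:
        warnings.warn(
            f"{len(skipped)} residue(s) without a Cα atom skipped: "
            f"{skipped[:5]}{'...' if len(skipped) > 5 else ''}"
        )
    if not ids:
        raise ValueError(f"no Cα atoms found in chain {chain!r} of {path}")
    gaps = [
        (a, b) for a, b in zip(ids, ids[1:]) if b - a > 1
    ]
    if gaps:
        logger.warning("chain %s has %d numbering gap(s): %s", chain,
                       len(gaps), gaps)
    return CaStructure(
        residue_ids=np.array(ids),
        residue_names=names,
        coords=np.array(xyz, dtype=float),
        chain_id=chain,
        label=label or str(path),
        icodes=icodes,
    )


def write_pdb_ca(s: CaStructure, path) -> None:
    """Write a Cα trace as PDB-format ATOM records (3-decimal coordinates)."""
    with open(path, "w") as fh:
        for k in range(s.n_residues):
            x, y, z = s.coords[k]
            fh.write(
                "ATOM  {serial:>5} {name:^4}{alt}{res:>3} {chain}{rid:>4}"
                "{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
                "          {el:>2}\n".format(
                    serial=k + 1, name="CA", alt=" ",
                    res=s.residue_names[k], chain=s.chain_id,
                    rid=s.residue_ids[k], icode=s.icodes[k] or " ",
                    x=x, y=y, z=z, occ=1.0, b=0.0, el="C",
                )
            )
        fh.write("END\n")


def extract_sequence(s: CaStructure) -> str:
    """One-letter sequence of the structure; unknown codes become ``X``."""
    out = []
    unknown = set()
    for name in s.residue_names:
        code = _THREE_TO_ONE.get(name.upper())
        if code is None:
            unknown.add(name)
            code = "X"
        out.append(code)
    if unknown:
        warnings.warn(f"unknown residue codes mapped to 'X': {sorted(unknown)}")
    return "".join(out)


# ---------------------------------------------------------------------------
# Domain partition

#: Eight-segment partition of the consensus frame (consensus residues 1-238).
DEFAULT_FINE_DOMAINS: tuple[tuple[str, int, int], ...] = (
    ("T-alpha", 1, 17),
    ("T-alphabetaalpha", 18, 60),
    ("IT1", 61, 91),
    ("I-beta", 92, 97),
    ("I-Loop", 98, 112),
    ("I-betaalpha", 113, 156),
    ("I-2betaalpha", 157, 185),
    ("IT2", 186, 238),
)

#: Coarse Thumb / Index Finger / Linker regions in the same frame.  The two
#: lobes are joined by two hinge segments; these ranges come from the
#: superposition of the three open-state structures.
DEFAULT_COARSE_REGIONS: tuple[tuple[str, int, int], ...] = (
    ("Thumb", 1, 85),
    ("Linker", 86, 90),
    ("Index", 91, 192),
    ("Linker", 193, 196),
    ("Thumb", 197, 238),
)


@dataclass
class DomainPartition:
    """Named, ordered residue ranges in consensus numbering.

    ``fine`` segments must be contiguous, non-overlapping and cover the whole
    consensus frame.  ``coarse`` ranges assign each consensus position one of
    the Thumb / Index / Linker labels; they are an independent track (the
    fine segment IT1, for instance, straddles the Thumb–Linker–Index
    boundary region).
    """

    fine: tuple[tuple[str, int, int], ...] = DEFAULT_FINE_DOMAINS
    coarse: tuple[tuple[str, int, int], ...] = DEFAULT_COARSE_REGIONS

    def __post_init__(self):
        prev_end = 0
        for name, start, end in self.fine:
            if start != prev_end + 1:
                raise ValueError(
                    f"fine domains not contiguous at {name} ({start})"
                )
            if end < start:
                raise ValueError(f"empty range for {name}")
            prev_end = end
        self.n_consensus = prev_end
        cov = np.zeros(self.n_consensus, dtype=int)
        for _, start, end in self.coarse:
            cov[start - 1:end] += 1
        if not np.all(cov == 1):
            raise ValueError("coarse regions must cover each position once")

    def fine_label(self, pos: int) -> str:
        for name, start, end in self.fine:
            if start <= pos <= end:
                return name
        raise ValueError(f"consensus position {pos} outside 1-{self.n_consensus}")

    def coarse_label(self, pos: int) -> str:
        for name, start, end in self.coarse:
            if start <= pos <= end:
                return name
        raise ValueError(f"consensus position {pos} outside 1-{self.n_consensus}")

    def fine_index(self, pos: int) -> int:
        """1-based index of the fine segment containing ``pos`` (1..8)."""
        for k, (_, start, end) in enumerate(self.fine, start=1):
            if start <= pos <= end:
                return k
        raise ValueError(f"consensus position {pos} outside 1-{self.n_consensus}")


def assign_domains(n_residues: int, position_map, part: DomainPartition | None = None):
    """Per-residue fine and coarse domain labels for one protein.

    Parameters
    ----------
    n_residues : number of residues in the protein
    position_map : mapping from residue index (1-based, sequential) to
        consensus column, e.g. one protein's entry of a
        :class:`~aabp_allostery.sequence_align.PositionMap`; residues that
        map to an alignment gap inherit the consensus position of the
        nearest mapped residue.  Pass ``None`` for the identity map.
    part : domain partition (default: the built-in eight-segment partition)

    Returns
    -------
    (fine_labels, coarse_labels) : two lists of length ``n_residues``
    """
    part = part or DomainPartition()
    if position_map is None:
        consensus = {i: i for i in range(1, n_residues + 1)}
    else:
        consensus = dict(position_map)
    if not consensus:
        raise ValueError("empty position map")
    if max(consensus) > n_residues or min(consensus) < 1:
        raise ValueError("position map indices outside 1..n_residues")

    mapped = sorted(consensus)
    fine, coarse = [], []
    for i in range(1, n_residues + 1):
        if i in consensus:
            pos = consensus[i]
        else:  # gap residue: borrow nearest mapped neighbour's column
            nearest = min(mapped, key=lambda j: (abs(j - i), j))
            pos = consensus[nearest]
        pos = min(max(pos, 1), part.n_consensus)
        fine.append(part.fine_label(pos))
        coarse.append(part.coarse_label(pos))
    return fine, coarse
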