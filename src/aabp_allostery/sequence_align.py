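"""Pairwise and three-way protein sequence alignment.

Global affine-gap alignment (BLOSUM62, gap open 11, gap extend 1 — the
classic protein-BLAST parameterization) drives the identity / coverage /
conservation statistics and the consensus-position map that every
cross-protein analysis in this package relies on.  Identity is reported on
the trimmed alignment core (terminal gap runs excluded), matching how
pairwise identity is conventionally reported by alignment servers.

The three-way alignment is progressive: the closest pair is aligned first
and the third sequence is then aligned against the pair's column profile.
Alignment columns define the consensus numbering (1-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = set(str(_BLOSUM62.alphabet))

#: BLAST-style affine penalty: a gap of length L costs open + L*extend.
GAP_OPEN = 11.0
GAP_EXTEND = 1.0


def _check_sequence(seq: str, name: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"{name}: invalid characters {sorted(bad)}")
    return seq


@dataclass
class PairwiseAlignment:
    """Global alignment of two sequences with affine gap penalties."""

    aligned_a: str
    aligned_b: str
    score: float
    identity: float = field(init=False)
    coverage: float = field(init=False)

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")
        self.identity = percent_identity(self)
        self.coverage = _coverage(self)

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


def align_global(a: str, b: str, *, matrix=None,
                 gap_open: float = GAP_OPEN,
                 gap_extend: float = GAP_EXTEND) -> PairwiseAlignment:
    """Optimal global alignment of two amino-acid sequences.

    The gap convention is BLAST's: a run of L gaps costs
    ``gap_open + L * gap_extend``.  Traceback is deterministic (the
    aligner's canonical first optimal path).
    """
    a = _check_sequence(a, "a")
    b = _check_sequence(b, "b")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix if matrix is not None else _BLOSUM62
    # Biopython charges open_gap_score for the first gap position and
    # extend_gap_score for each further one: open+extend reproduces the
    # "open + L*extend" convention.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(a, b)[0]
    return PairwiseAlignment(aligned_a=str(aln[0]), aligned_b=str(aln[1]),
                             score=float(aln.score))


def _core_slice(aln: PairwiseAlignment) -> slice:
    """Columns remaining after trimming terminal gap runs of either row."""
    sa, sb = aln.aligned_a, aln.aligned_b
    n = len(sa)
    start = 0
    while start < n and (sa[start] == "-" or sb[start] == "-"):
        start += 1
    end = n
    while end > start and (sa[end - 1] == "-" or sb[end - 1] == "-"):
        end -= 1
    return slice(start, end)


def percent_identity(aln: PairwiseAlignment) -> float:
    """Identities / trimmed alignment columns, as a percentage (2 decimals).

    Terminal gap runs (in either row) are excluded from the denominator;
    internal gap columns count as mismatches.
    """
    core = _core_slice(aln)
    sa, sb = aln.aligned_a[core], aln.aligned_b[core]
    if not sa:
        return 0.0
    ident = sum(x == y and x != "-" for x, y in zip(sa, sb))
    return round(100.0 * ident / len(sa), 2)


def _coverage(aln: PairwiseAlignment) -> float:
    """Aligned-region length over query (first sequence) length, percent."""
    core = _core_slice(aln)
    span = sum(c != "-" for c in aln.aligned_a[core])
    qlen = sum(c != "-" for c in aln.aligned_a)
    return round(100.0 * span / qlen, 2) if qlen else 0.0


# ---------------------------------------------------------------------------
# Three-way progressive alignment


@dataclass
class MultipleAlignment:
    """Three aligned rows; columns define consensus numbering (1-based)."""

    rows: tuple[str, str, str]
    order: tuple[int, int, int] = (0, 1, 2)  # input index of each row

    def __post_init__(self):
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def conserved_flags(self) -> np.ndarray:
        """True where all three rows carry the same residue (no gap)."""
        flags = np.zeros(self.n_columns, dtype=bool)
        for c in range(self.n_columns):
            chars = {row[c] for row in self.rows}
            flags[c] = len(chars) == 1 and "-" not in chars
        return flags


def _profile_align(rows: list[str], seq: str, gap_open: float,
                   gap_extend: float):
    """Affine-gap global alignment of ``seq`` against profile columns.

    Column score = mean BLOSUM62 score of the residue against the non-gap
    members of the column.  Deterministic tie-break: substitution preferred
    over a gap in the new sequence, preferred over a gap column in the
    profile.
    """
    ncol, m = len(rows[0]), len(seq)
    open_cost = gap_open + gap_extend

    def col_score(c: int, ch: str) -> float:
        vals = [_BLOSUM62[r[c], ch] for r in rows if r[c] != "-"]
        return float(np.mean(vals)) if vals else -gap_extend

    NEG = -1e18
    # M: seq[j] in column c; X: gap in seq (consume column); Y: gap column
    M = np.full((ncol + 1, m + 1), NEG)
    X = np.full((ncol + 1, m + 1), NEG)
    Y = np.full((ncol + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for c in range(1, ncol + 1):
        X[c, 0] = -(open_cost + (c - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0, j] = -(open_cost + (j - 1) * gap_extend)
    ptrM = np.zeros((ncol + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((ncol + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((ncol + 1, m + 1), dtype=np.int8)
    for c in range(1, ncol + 1):
        for j in range(1, m + 1):
            s = col_score(c - 1, seq[j - 1])
            prev = (M[c - 1, j - 1], X[c - 1, j - 1], Y[c - 1, j - 1])
            k = int(np.argmax(prev))
            M[c, j] = prev[k] + s
            ptrM[c, j] = k
            ox = (M[c - 1, j] - open_cost, X[c - 1, j] - gap_extend)
            k = int(np.argmax(ox))
            X[c, j] = ox[k]
            ptrX[c, j] = 0 if k == 0 else 1
            oy = (M[c, j - 1] - open_cost, Y[c, j - 1] - gap_extend)
            k = int(np.argmax(oy))
            Y[c, j] = oy[k]
            ptrY[c, j] = 0 if k == 0 else 2
        # borders for j == 0 handled above
        X[c, 0] = X[c, 0]
    for j in range(1, m + 1):
        Y[0, j] = Y[0, j]

    ends = (M[ncol, m], X[ncol, m], Y[ncol, m])
    state = int(np.argmax(ends))
    score = ends[state]
    out_rows = [[] for _ in rows]
    out_seq = []
    c, j = ncol, m
    while c > 0 or j > 0:
        if state == 0:  # M
            for r, row in enumerate(rows):
                out_rows[r].append(row[c - 1])
            out_seq.append(seq[j - 1])
            state = int(ptrM[c, j])
            c, j = c - 1, j - 1
        elif state == 1:  # X: column consumed, gap in seq
            for r, row in enumerate(rows):
                out_rows[r].append(row[c - 1])
            out_seq.append("-")
            nxt = ptrX[c, j] if j > 0 else (0 if c == 1 else 1)
            state = int(nxt)
            c -= 1
        else:  # Y: gap column inserted into profile
            for r in range(len(rows)):
                out_rows[r].append("-")
            out_seq.append(seq[j - 1])
            nxt = ptrY[c, j] if c > 0 else (0 if j == 1 else 2)
            state = int(nxt)
            j -= 1
    aligned_rows = ["".join(reversed(r)) for r in out_rows]
    return aligned_rows, "".join(reversed(out_seq)), float(score)


def align_three(a: str, b: str, c: str) -> MultipleAlignment:
    """Progressive three-way alignment.

    The pair with the highest pairwise identity (ties broken by input
    order) is aligned first; the remaining sequence is aligned against the
    pair's column profile.  Rows are returned in input order.
    """
    seqs = [_check_sequence(s, n) for s, n in ((a, "a"), (b, "b"), (c, "c"))]
    pairs = [(0, 1), (0, 2), (1, 2)]
    idents = [align_global(seqs[i], seqs[j]).identity for i, j in pairs]
    i, j = pairs[int(np.argmax(idents))]
    k = ({0, 1, 2} - {i, j}).pop()
    pair_aln = align_global(seqs[i], seqs[j])
    rows2 = [pair_aln.aligned_a, pair_aln.aligned_b]
    aligned_pair, aligned_third, _ = _profile_align(
        rows2, seqs[k], GAP_OPEN, GAP_EXTEND
    )
    by_input = {i: aligned_pair[0], j: aligned_pair[1], k: aligned_third}
    return MultipleAlignment(rows=(by_input[0], by_input[1], by_input[2]))


def conserved_positions(msa: MultipleAlignment) -> list[int]:
    """1-based consensus columns where all rows agree with no gap."""
    return [c + 1 for c, f in enumerate(msa.conserved_flags()) if f]


@dataclass
class PositionMap:
    """Residue index ↔ consensus column maps for each aligned protein.

    ``forward[p]`` maps protein ``p``'s residue index (1-based, sequential
    over its residues) to the consensus column; gap cells have no entry.
    """

    forward: list[dict[int, int]]

    def __post_init__(self):
        for p, fwd in enumerate(self.forward):
            cols = [fwd[i] for i in sorted(fwd)]
            if any(b <= a for a, b in zip(cols, cols[1:])):
                raise ValueError(f"protein {p}: map not strictly increasing")

    def inverse(self, p: int) -> dict[int, int]:
        """Consensus column → residue index for protein ``p``."""
        return {c: i for i, c in self.forward[p].items()}

    def to_consensus(self, p: int, residue_index: int) -> int | None:
        return self.forward[p].get(residue_index)


def build_position_map(msa: MultipleAlignment) -> PositionMap:
    """Map each protein's sequential residue index to its MSA column."""
    forward = []
    for row in msa.rows:
        fwd, res = {}, 0
        for col, ch in enumerate(row, start=1):
            if ch != "-":
                res += 1
                fwd[res] = col
        forward.append(fwd)
    return PositionMap(forward=forward)
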