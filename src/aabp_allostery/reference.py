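"""Analyses on the reference amino-acid-binding-protein structures.

The three *E. coli* AABPs studied here — the glutamine-binding protein
(GlnBP), histidine-binding protein (HisJ) and lysine/arginine/ornithine-
binding protein (LAOBP) — each have open (substrate-free) and closed
(substrate-bound) crystal/NMR structures in the RCSB PDB.  This module
loads those six entries (from a local directory of PDB files, or by
download when a network is available), and reproduces the cross-protein
sequence statistics and Gaussian-network fluctuation comparisons on them.

The rest of the package never requires these structures: every algorithm is
exercised on synthetic two-domain systems.
"""

from __future__ import annotations

import itertools
import urllib.request
from pathlib import Path

import numpy as np

from aabp_allostery import gnm
from aabp_allostery.sequence_align import (
    align_global,
    align_three,
    build_position_map,
    conserved_positions,
)
from aabp_allostery.structure_io import CaStructure, read_pdb_ca

#: system name → (RCSB accession, chain)
ACCESSIONS = {
    "GlnBP-open": ("1GGG", "A"),
    "GlnBP-closed": ("1WDN", "A"),
    "HisJ-open": ("2M8C", "A"),
    "HisJ-closed": ("1HPB", "A"),
    "LAOBP-open": ("2LAO", "A"),
    "LAOBP-closed": ("1LST", "A"),
}

OPEN_SYSTEMS = ("GlnBP-open", "HisJ-open", "LAOBP-open")
CLOSED_SYSTEMS = ("GlnBP-closed", "HisJ-closed", "LAOBP-closed")
PROTEINS = ("GlnBP", "HisJ", "LAOBP")

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


class ReferenceDataUnavailable(RuntimeError):
    """Raised when the reference PDB entries can be neither found locally
    nor downloaded."""


def fetch_rcsb(pdb_id: str, dest_dir, timeout: float = 30.0) -> Path:
    """Download one PDB entry into ``dest_dir`` (requires network)."""
    dest_dir = Path(dest_dir)
    dest_dir.mkdir(parents=True, exist_ok=True)
    dest = dest_dir / f"{pdb_id}.pdb"
    if dest.exists():
        return dest
    with urllib.request.urlopen(RCSB_URL.format(pdb_id=pdb_id),
                                timeout=timeout) as resp:
        dest.write_bytes(resp.read())
    return dest


def load_reference_structures(directory=None,
                              allow_download: bool = True
                              ) -> dict[str, CaStructure]:
    """Load the six reference structures as Cα traces.

    Looks for ``<accession>.pdb`` files in ``directory`` first; missing
    entries are downloaded from the RCSB when ``allow_download`` is set.
    Raises :class:`ReferenceDataUnavailable` if any entry cannot be
    obtained (e.g. offline with no local copies).
    """
    directory = Path(directory) if directory else None
    out: dict[str, CaStructure] = {}
    missing = []
    for name, (pdb_id, chain) in ACCESSIONS.items():
        path = directory / f"{pdb_id}.pdb" if directory else None
        if path is None or not path.exists():
            if allow_download:
                try:
                    path = fetch_rcsb(pdb_id, directory or Path.cwd() / "pdb")
                except Exception as exc:   # noqa: BLE001 — report, don't mask
                    missing.append(f"{name} ({pdb_id}): {exc}")
                    continue
            else:
                missing.append(f"{name} ({pdb_id}): no local file")
                continue
        out[name] = read_pdb_ca(path, chain=chain, label=name)
    if missing:
        raise ReferenceDataUnavailable(
            "reference PDB entries unavailable (provide a directory of "
            "downloaded .pdb files or run with network access):\n  "
            + "\n  ".join(missing)
        )
    return out


def sequence_report(structures: dict[str, CaStructure]) -> dict:
    """Pairwise identity/coverage and three-way conservation statistics.

    Sequences are taken from the closed-state structures (the complete
    chains); identities are reported for the three protein pairs, plus the
    number of fully conserved columns of the progressive three-way
    alignment.
    """
    seqs = {p: structures[f"{p}-closed"].sequence() for p in PROTEINS}
    pair_stats = {}
    for a, b in itertools.combinations(PROTEINS, 2):
        aln = align_global(seqs[a], seqs[b])
        pair_stats[f"{a}-{b}"] = {
            "identity": aln.identity,
            "coverage": aln.coverage,
            "score": aln.score,
        }
    msa = align_three(seqs["GlnBP"], seqs["HisJ"], seqs["LAOBP"])
    cons = conserved_positions(msa)
    return {
        "pairwise": pair_stats,
        "n_conserved": len(cons),
        "conserved_columns": cons,
        "msa": msa,
        "position_map": build_position_map(msa),
    }


def _consensus_maps(structures: dict[str, CaStructure]):
    """Residue→consensus maps per protein from the three-way alignment of
    the closed-state sequences (238-residue consensus frame)."""
    seqs = [structures[f"{p}-closed"].sequence() for p in PROTEINS]
    msa = align_three(*seqs)
    pm = build_position_map(msa)
    return {p: pm.forward[i] for i, p in enumerate(PROTEINS)}


def gnm_report(structures: dict[str, CaStructure],
               params: gnm.GNMParams | None = None,
               slow_k: int = 2, fast_k: int = 10) -> dict:
    """Fast/slow fluctuation comparison across the six systems.

    Computes per-system fast- and slow-mode mean-square-fluctuation
    profiles, the pairwise Pearson correlations of the fast profiles within
    the open and closed triads (on shared consensus columns), the
    fast-profile hot spots and slow-profile hinge minima of the closed
    states in consensus numbering.
    """
    params = params or gnm.GNMParams()
    maps = _consensus_maps(structures)
    profiles_fast, profiles_slow, system_maps = {}, {}, {}
    for name, s in structures.items():
        protein = name.split("-")[0]
        res = gnm.gnm_decompose(gnm.build_kirchhoff(s.coords, params), params)
        profiles_fast[name] = gnm.mode_fluctuations(res, "fast", fast_k)
        profiles_slow[name] = gnm.mode_fluctuations(res, "slow", slow_k)
        system_maps[name] = maps[protein]

    def triad_correlations(names, profs):
        out = {}
        for a, b in itertools.combinations(names, 2):
            out[f"{a}/{b}"] = gnm.profile_correlation(
                profs[a], profs[b], system_maps[a], system_maps[b]
            )
        return out

    fast_open = triad_correlations(OPEN_SYSTEMS, profiles_fast)
    fast_closed = triad_correlations(CLOSED_SYSTEMS, profiles_fast)

    hotspots, hinges = {}, {}
    for name in CLOSED_SYSTEMS:
        fwd = system_maps[name]
        hs = gnm.detect_extrema(profiles_fast[name], "hotspot", quantile=0.25)
        hotspots[name] = sorted(
            fwd[i + 1] for i in hs if (i + 1) in fwd
        )
        hg = gnm.detect_extrema(profiles_slow[name], "hinge", quantile=0.25)
        hinges[name] = sorted(
            fwd[i + 1] for i in hg if (i + 1) in fwd
        )
    return {
        "fast_profiles": profiles_fast,
        "slow_profiles": profiles_slow,
        "fast_corr_open": fast_open,
        "fast_corr_closed": fast_closed,
        "hotspots_closed": hotspots,
        "hinges_closed": hinges,
        "consensus_maps": system_maps,
    }
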