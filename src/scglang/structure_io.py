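"""Readers for classic DSSP output and PDB chain sequences.

Per-residue records carry the 8-state secondary-structure class and the six
numeric DSSP fields (ACC, TCO, KAPPA, ALPHA, PHI, PSI) that the fragment
featurizer consumes. Only the classic fixed-width DSSP dialect is supported;
the mmCIF dialect is not. Chain-break rows ('!') carry no residue but are
recorded as break positions so that no fragment ever spans a break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .constants import AA_ALPHABET, SS_ALPHABET


class DsspFormatError(ValueError):
    """Raised when a classic DSSP file cannot be parsed."""


@dataclass(frozen=True)
class ResidueRecord:
    """One residue: identity, SS class, and six DSSP numeric fields."""

    aa: str                  # one-letter code, 'X' for nonstandard
    ss: str                  # one of H,B,E,G,I,T,S,C
    acc: float               # solvent-accessible surface area, A^2
    tco: float               # cosine of C=O(i-1)..C=O(i) angle, dimensionless
    kappa: float             # virtual bond angle, degrees (360 = undefined)
    alpha: float             # virtual torsion, degrees (360 = undefined)
    phi: float               # backbone torsion, degrees (360 = undefined)
    psi: float               # backbone torsion, degrees (360 = undefined)
    seq_index: int           # 0-based position within the chain


@dataclass
class Chain:
    """An ordered run of residues from one chain, plus break positions."""

    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)
    source: str = "synthetic"
    #: seq_index values at which a new segment must start (chain breaks);
    #: a break before residue i means i is in `breaks`.
    breaks: frozenset[int] = frozenset()

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def ss_string(self) -> str:
        return "".join(r.ss for r in self.residues)


# classic DSSP fixed-width column offsets (0-based python slices)
_COL_CHAIN = 11
_COL_AA = 13
_COL_SS = 16
_SL_ACC = slice(34, 38)
_SL_TCO = slice(85, 91)
_SL_KAPPA = slice(91, 97)
_SL_ALPHA = slice(97, 103)
_SL_PHI = slice(103, 109)
_SL_PSI = slice(109, 115)

_HEADER_MARK = "#  RESIDUE AA STRUCTURE"


def _map_ss(letter: str) -> str:
    if letter == " " or letter == "":
        return "C"
    if letter in SS_ALPHABET:
        return letter
    raise DsspFormatError(f"unknown secondary-structure letter {letter!r}")


def _map_aa(letter: str) -> str:
    if letter in AA_ALPHABET:
        return letter
    if letter.islower():
        # DSSP labels half-cystines with lower-case letters a-z
        return "C"
    return "X"


def read_dssp(path: str | Path) -> list[Chain]:
    """Parse a classic DSSP file into per-chain residue tables.

    The block following the ``#  RESIDUE AA STRUCTURE ...`` header line is
    read with fixed-width slicing. Blank SS codes map to coil ('C');
    chain-break rows ('!') emit no residue but mark a break so downstream
    segmentation never crosses them.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise DsspFormatError(f"{path}: empty file")
    start = None
    for i, line in enumerate(lines):
        if _HEADER_MARK in line:
            start = i + 1
            break
    if start is None:
        raise DsspFormatError(f"{path}: no residue-table header line found")

    chains: dict[str, Chain] = {}
    pending_break: set[str] = set()
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        if len(line) <= _COL_SS:
            raise DsspFormatError(f"{path}:{lineno}: truncated data row")
        aa_raw = line[_COL_AA]
        if aa_raw == "!":
            # break row: every open chain gets a break before its next residue
            pending_break.update(chains.keys())
            continue
        chain_id = line[_COL_CHAIN].strip() or "A"
        try:
            rec = ResidueRecord(
                aa=_map_aa(aa_raw),
                ss=_map_ss(line[_COL_SS]),
                acc=float(line[_SL_ACC]),
                tco=float(line[_SL_TCO]),
                kappa=float(line[_SL_KAPPA]),
                alpha=float(line[_SL_ALPHA]),
                phi=float(line[_SL_PHI]),
                psi=float(line[_SL_PSI]),
                seq_index=len(chains[chain_id].residues) if chain_id in chains else 0,
            )
        except (ValueError, IndexError) as exc:
            raise DsspFormatError(f"{path}:{lineno}: unparseable row: {exc}") from exc
        if chain_id not in chains:
            chains[chain_id] = Chain(chain_id=chain_id, residues=[], source=str(path))
        ch = chains[chain_id]
        if chain_id in pending_break and ch.residues:
            ch.breaks = ch.breaks | {len(ch.residues)}
        pending_break.discard(chain_id)
        ch.residues.append(rec)
    if not chains:
        raise DsspFormatError(f"{path}: no residue rows found")
    return list(chains.values())


def dssp_total_residues(path: str | Path) -> int:
    """Integer from the ``TOTAL NUMBER OF RESIDUES`` header line."""
    for line in Path(path).read_text().splitlines():
        if "TOTAL NUMBER OF RESIDUES" in line:
            return int(line.split()[0])
    raise DsspFormatError(f"{path}: no TOTAL NUMBER OF RESIDUES line")


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def read_pdb_chain(path: str | Path, chain_id: str) -> str:
    """One-letter sequence of CA-bearing residues of one chain in a PDB file.

    Nonstandard residues (e.g. MSE) become 'X'. Used only to cross-check
    DSSP/sequence agreement; DSSP stays authoritative on mismatch.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    if chain_id not in [c.id for c in model.get_chains()]:
        raise KeyError(f"chain {chain_id!r} not found in {path}")
    seq = []
    for res in model[chain_id].get_residues():
        if "CA" not in res:
            continue
        seq.append(_THREE_TO_ONE.get(res.get_resname().strip().upper(), "X"))
    if not seq:
        raise ValueError(f"chain {chain_id!r} in {path} has no CA atoms")
    return "".join(seq)


def validate_against_pdb(chain: Chain, pdb_path: str | Path) -> bool:
    """Warn (and return False) if the PDB sequence disagrees with DSSP."""
    pdb_seq = read_pdb_chain(pdb_path, chain.chain_id)
    if pdb_seq != chain.sequence:
        warnings.warn(
            f"chain {chain.chain_id}: PDB sequence differs from DSSP; "
            "keeping DSSP as authoritative",
            stacklevel=2,
        )
        return False
    return True


def split_chains(chains: list[Chain]) -> list[Chain]:
    """Return single-chain units; identity on already-split input."""
    return list(chains)


def write_residue_table(chains: list[Chain], path: str | Path) -> None:
    """Dump chains as a TSV of per-residue records."""
    cols = "chain_id\tseq_index\taa\tss\tacc\ttco\tkappa\talpha\tphi\tpsi"
    rows = [cols]
    for ch in chains:
        for r in ch.residues:
            rows.append(
                f"{ch.chain_id}\t{r.seq_index}\t{r.aa}\t{r.ss}\t{r.acc:.1f}\t"
                f"{r.tco:.3f}\t{r.kappa:.1f}\t{r.alpha:.1f}\t{r.phi:.1f}\t{r.psi:.1f}"
            )
    Path(path).write_text("\n".join(rows) + "\n")
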