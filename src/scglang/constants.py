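"""Shared alphabets and normalization tables.

The eight-state secondary-structure alphabet follows DSSP: H (alpha-helix),
B (isolated beta-bridge), E (extended strand), G (3-10 helix), I (pi-helix),
T (hydrogen-bonded turn), S (bend) and C (coil; DSSP prints a blank for it).
The fixed order below is used everywhere a one-hot or index is needed.
"""

from __future__ import annotations

import numpy as np

#: Eight-state secondary-structure alphabet, fixed order.
SS_ALPHABET: str = "HBEGITSC"
SS_INDEX: dict[str, int] = {c: i for i, c in enumerate(SS_ALPHABET)}

#: Twenty standard amino acids, alphabetical one-letter order.
AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {c: i for i, c in enumerate(AA_ALPHABET)}

#: PSI-BLAST PSSM column order (the order printed in ascii PSSM headers).
PSSM_AA_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

#: HH-suite match-emission column order.
HHM_AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"

#: Theoretical maximum solvent-accessible surface area per residue (A^2),
#: Tien et al. 2013 values; used to turn DSSP ACC into relative accessibility.
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Fallback max-ASA for 'X' (mean of the twenty standard values).
MAX_ASA_UNKNOWN: float = float(np.mean(list(MAX_ASA.values())))

#: DSSP sentinel for undefined angles (chain termini, breaks).
ANGLE_SENTINEL: float = 360.0

#: Feature-vector block layout: [composition | evolutionary | geometry].
N_COMPOSITION: int = 20
N_EVOLUTIONARY: int = 40
N_GEOMETRY: int = 14
N_FEATURES: int = N_COMPOSITION + N_EVOLUTIONARY + N_GEOMETRY  # 74

COMPOSITION_SLICE = slice(0, N_COMPOSITION)
EVOLUTIONARY_SLICE = slice(N_COMPOSITION, N_COMPOSITION + N_EVOLUTIONARY)
GEOMETRY_SLICE = slice(N_COMPOSITION + N_EVOLUTIONARY, N_FEATURES)
ONEHOT_SLICE = slice(N_COMPOSITION + N_EVOLUTIONARY,
                     N_COMPOSITION + N_EVOLUTIONARY + len(SS_ALPHABET))

#: Default commitment weight and vocabulary size.
DEFAULT_BETA: float = 0.25
DEFAULT_VOCAB_SIZE: int = 1024

#: Random-segmentation fragment-length range (inclusive).
RANDOM_FRAGMENT_MIN: int = 3
RANDOM_FRAGMENT_MAX: int = 60

#: Default sentence truncation length at corpus write time.
DEFAULT_TRUNCATION: int = 512
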