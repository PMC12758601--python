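"""Fragment featurization: the 74-dimensional fragment descriptor.

Each fragment is described by three concatenated blocks:

* composition, 20-d — fraction of each standard amino acid in the fragment;
* evolutionary conservation, 40-d — column means over the fragment's rows of
  a sigmoid-normalized PSSM (20) and of an HH-suite match-emission profile
  (20), PSSM block first;
* spatial geometry, 14-d — an 8-d one-hot over the secondary-structure
  alphabet plus the fragment means of six normalized DSSP fields
  (relative accessibility, TCO, and the four angles divided by 180 deg).

Profiles are optional: without them the evolutionary block is zero-imputed
and flagged, so a vocabulary can be trained structure-only.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import (
    AA_ALPHABET,
    AA_INDEX,
    ANGLE_SENTINEL,
    COMPOSITION_SLICE,
    EVOLUTIONARY_SLICE,
    GEOMETRY_SLICE,
    HHM_AA_ORDER,
    MAX_ASA,
    MAX_ASA_UNKNOWN,
    N_FEATURES,
    PSSM_AA_ORDER,
    SS_ALPHABET,
    SS_INDEX,
)
from .segmentation import Fragment


class ProfileFormatError(ValueError):
    """Raised when a PSSM or HHM file cannot be parsed."""


@dataclass(frozen=True)
class ProfilePair:
    """Per-residue evolutionary profiles for one chain.

    ``pssm``: n x 20 sigmoid-normalized PSI-BLAST scores, in (0, 1).
    ``hmm``: n x 20 HH-suite match-emission values, in [0, 1].
    Both use the package's canonical amino-acid column order.
    """

    pssm: np.ndarray
    hmm: np.ndarray

    def __post_init__(self):
        if self.pssm.shape != self.hmm.shape or self.pssm.shape[1] != 20:
            raise ValueError("profile matrices must both be n x 20")


@dataclass(frozen=True)
class FragmentFeature:
    """The 74-d fragment vector with its block layout and provenance."""

    x: np.ndarray
    fragment_ref: tuple[str, int, int]
    profiles_imputed: bool = False

    layout = {
        "composition": (COMPOSITION_SLICE.start, COMPOSITION_SLICE.stop),
        "evolutionary": (EVOLUTIONARY_SLICE.start, EVOLUTIONARY_SLICE.stop),
        "geometry": (GEOMETRY_SLICE.start, GEOMETRY_SLICE.stop),
    }


def composition_feature(fragment: Fragment) -> np.ndarray:
    """Fraction of each standard amino acid among the fragment's residues.

    'X' residues are excluded from both numerator and denominator; a fragment
    of only 'X' residues yields the zero vector.
    """
    if not fragment.residues:
        raise ValueError("empty fragment")
    counts = Counter(r.aa for r in fragment.residues if r.aa in AA_INDEX)
    total = sum(counts.values())
    v = np.zeros(20)
    if total == 0:
        return v
    for aa, c in counts.items():
        v[AA_INDEX[aa]] = c / total
    return v


# -- profile readers ------------------------------------------------------

# reorder columns from each file dialect into the canonical AA_ALPHABET order
_PSSM_PERM = [PSSM_AA_ORDER.index(a) for a in AA_ALPHABET]
_HHM_PERM = [HHM_AA_ORDER.index(a) for a in AA_ALPHABET]


def read_pssm(path: str | Path) -> np.ndarray:
    """Raw log-odds block of a PSI-BLAST ascii PSSM (-out_ascii_pssm).

    Returns the n x 20 integer matrix (first of the two 20-column blocks),
    columns reordered to the package's canonical amino-acid order.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        toks = line.split()
        # data rows: index, residue letter, 20 log-odds, [20 pct, 2 floats]
        if len(toks) >= 22 and toks[0].isdigit() and len(toks[1]) == 1:
            try:
                rows.append([int(t) for t in toks[2:22]])
            except ValueError as exc:
                raise ProfileFormatError(
                    f"{path}:{lineno}: bad PSSM row: {exc}") from exc
    if not rows:
        raise ProfileFormatError(f"{path}: no PSSM data rows found")
    mat = np.asarray(rows, dtype=float)
    return mat[:, _PSSM_PERM]


def normalize_pssm(raw: np.ndarray) -> np.ndarray:
    """Elementwise logistic sigmoid 1/(1+exp(-s)) of the raw scores."""
    return 1.0 / (1.0 + np.exp(-np.asarray(raw, dtype=float)))


def read_hhm(path: str | Path) -> np.ndarray:
    """Match-emission probabilities from an HH-suite .hhm file.

    Integer scores s become 2**(-s/1000); '*' (zero probability) becomes 0.
    Returns an n x 20 matrix in the canonical amino-acid column order.
    """
    lines = Path(path).read_text().splitlines()
    # find the per-state block: starts after the line beginning with "HMM"
    # followed by the two transition header lines
    start = None
    for i, line in enumerate(lines):
        if line.startswith("HMM"):
            start = i + 3
            break
    if start is None:
        raise ProfileFormatError(f"{path}: no HMM block header found")
    rows = []
    i = start
    while i < len(lines):
        line = lines[i]
        if line.startswith("//"):
            break
        toks = line.split()
        if len(toks) >= 22 and len(toks[0]) == 1 and toks[0].isalpha():
            scores = toks[2:22]
            try:
                row = [0.0 if s == "*" else 2.0 ** (-int(s) / 1000.0)
                       for s in scores]
            except ValueError as exc:
                raise ProfileFormatError(
                    f"{path}:{i + 1}: bad emission score: {exc}") from exc
            rows.append(row)
            i += 3  # skip the transition line and the blank separator
        else:
            i += 1
    if not rows:
        raise ProfileFormatError(f"{path}: truncated emission block")
    mat = np.asarray(rows, dtype=float)
    return mat[:, _HHM_PERM]


def load_profiles(pssm_path: str | Path, hhm_path: str | Path) -> ProfilePair:
    """Read, normalize and pair the two profile files for one chain."""
    pssm = normalize_pssm(read_pssm(pssm_path))
    hmm = read_hhm(hhm_path)
    if pssm.shape[0] != hmm.shape[0]:
        raise ProfileFormatError(
            f"profile length mismatch: PSSM {pssm.shape[0]} vs HHM {hmm.shape[0]}")
    return ProfilePair(pssm=pssm, hmm=hmm)


def evolutionary_feature(fragment: Fragment, profiles: ProfilePair) -> np.ndarray:
    """Column means of the fragment's profile rows, PSSM block then HMM."""
    idx = np.arange(fragment.start, fragment.end)
    if fragment.end > profiles.pssm.shape[0]:
        raise IndexError(
            f"fragment [{fragment.start},{fragment.end}) outside profile of "
            f"length {profiles.pssm.shape[0]}")
    return np.concatenate([profiles.pssm[idx].mean(axis=0),
                           profiles.hmm[idx].mean(axis=0)])


def _majority_ss(fragment: Fragment) -> str:
    counts = Counter(r.ss for r in fragment.residues)
    best = max(counts.values())
    # tie-break by the fixed alphabet order
    for c in SS_ALPHABET:
        if counts.get(c, 0) == best:
            return c
    raise AssertionError("unreachable")


def _norm_angle(value: float) -> float:
    if value == ANGLE_SENTINEL:
        return 0.0
    return value / 180.0


def geometry_feature(fragment: Fragment) -> np.ndarray:
    """8-d SS one-hot plus means of the six normalized DSSP fields.

    ACC is divided by the residue's theoretical maximum accessibility and
    clipped to [0, 1]; TCO passes through; KAPPA/ALPHA/PHI/PSI are divided
    by 180 deg, with the 360-deg missing sentinel mapped to 0 first.
    """
    if not fragment.residues:
        raise ValueError("empty fragment")
    if fragment.ss in SS_INDEX:
        classes = {r.ss for r in fragment.residues}
        if classes != {fragment.ss}:
            raise ValueError(
                f"fragment labelled {fragment.ss!r} contains classes {classes}")
        ss_class = fragment.ss
    else:
        ss_class = _majority_ss(fragment)
    onehot = np.zeros(8)
    onehot[SS_INDEX[ss_class]] = 1.0
    per_res = np.array([
        [
            min(max(r.acc / MAX_ASA.get(r.aa, MAX_ASA_UNKNOWN), 0.0), 1.0),
            r.tco,
            _norm_angle(r.kappa),
            _norm_angle(r.alpha),
            _norm_angle(r.phi),
            _norm_angle(r.psi),
        ]
        for r in fragment.residues
    ])
    return np.concatenate([onehot, per_res.mean(axis=0)])


def featurize(fragment: Fragment,
              profiles: ProfilePair | None = None) -> FragmentFeature:
    """Concatenate [composition | evolutionary | geometry] into 74 elements."""
    comp = composition_feature(fragment)
    if profiles is None:
        evo = np.zeros(40)
        imputed = True
    else:
        evo = evolutionary_feature(fragment, profiles)
        imputed = False
    geo = geometry_feature(fragment)
    x = np.concatenate([comp, evo, geo])
    assert x.shape == (N_FEATURES,)
    return FragmentFeature(
        x=x,
        fragment_ref=(fragment.chain_id, fragment.start, fragment.end),
        profiles_imputed=imputed,
    )


def feature_matrix(fragments: list[Fragment],
                   profiles: ProfilePair | None = None) -> np.ndarray:
    """Stack fragment feature vectors into an m x 74 matrix."""
    return np.vstack([featurize(f, profiles).x for f in fragments])


@dataclass(frozen=True)
class Standardization:
    """Per-dimension z-scoring parameters fitted on a training corpus."""

    mean: np.ndarray
    scale: np.ndarray   # stds, with zero-variance dims held at 1

    @classmethod
    def fit(cls, features: np.ndarray) -> "Standardization":
        mean = features.mean(axis=0)
        scale = features.std(axis=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
        return cls(mean=mean, scale=scale)

    def apply(self, features: np.ndarray) -> np.ndarray:
        return (np.asarray(features) - self.mean) / self.scale

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardization":
        return cls(mean=np.asarray(d["mean"], dtype=float),
                   scale=np.asarray(d["scale"], dtype=float))


def save_features(features: np.ndarray, path: str | Path,
                  imputed_flags: list[bool] | None = None,
                  standardization: Standardization | None = None) -> None:
    """Write the feature matrix (.npy) with a JSON sidecar of metadata."""
    path = Path(path)
    np.save(path, features)
    sidecar = {
        "n_fragments": int(features.shape[0]),
        "layout": {k: list(v) for k, v in FragmentFeature.layout.items()},
        "imputed": imputed_flags,
        "standardization": standardization.to_dict() if standardization else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
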