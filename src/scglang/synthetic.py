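"""Synthetic fixtures: toy chains, DSSP/PSSM/HHM files, and feature mixtures.

The chain generator emulates the statistical shape of real single-chain
protein data: secondary-structure classes succeed each other under a
no-immediate-repeat Markov law with PDB-like class weights, run lengths are
geometric with class-specific means (helices long, bridges mostly single),
and the per-residue DSSP fields are drawn from class-conditional Gaussians
centred on textbook values (helix phi/psi near -60/-45, strand near
-120/+135). Profile files are written in the exact on-disk dialects the
package's readers expect, so reader tests are self-contained. A separate
generator produces cluster-structured 74-d feature matrices (a Gaussian
mixture projected onto the feature invariants) for vocabulary-recovery
tests.

What this does not emulate: real tertiary packing, hydrogen-bond patterns,
database redundancy, or correlations between profiles and structure beyond
residue identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

from .constants import (
    AA_ALPHABET,
    ANGLE_SENTINEL,
    HHM_AA_ORDER,
    MAX_ASA,
    N_COMPOSITION,
    N_FEATURES,
    PSSM_AA_ORDER,
    SS_ALPHABET,
    SS_INDEX,
)
from .features import ProfilePair, normalize_pssm
from .structure_io import Chain, ResidueRecord

# -- class-conditional laws ------------------------------------------------

#: PDB-like relative frequency of each SS class (order: H B E G I T S C).
DEFAULT_SS_WEIGHTS = {
    "H": 0.32, "B": 0.01, "E": 0.21, "G": 0.04,
    "I": 0.005, "T": 0.11, "S": 0.085, "C": 0.22,
}

#: Mean geometric run length per class, residues.
DEFAULT_RUN_MEANS = {
    "H": 10.0, "B": 1.0, "E": 5.0, "G": 3.3,
    "I": 5.0, "T": 3.3, "S": 1.8, "C": 4.0,
}

#: (phi, psi, tco, kappa, alpha) means and sds per class; angles in degrees.
DEFAULT_DSSP_LAWS = {
    #        phi          psi          tco          kappa        alpha
    "H": ((-63, 8),   (-42, 8),   (0.90, 0.06), (49, 10),   (50, 8)),
    "G": ((-71, 10),  (-18, 12),  (0.75, 0.10), (65, 15),   (70, 15)),
    "I": ((-57, 10),  (-70, 10),  (0.85, 0.08), (40, 10),   (45, 10)),
    "E": ((-118, 18), (134, 18),  (-0.85, 0.10), (25, 12),  (-170, 15)),
    "B": ((-110, 25), (130, 25),  (-0.70, 0.20), (40, 20),  (-160, 25)),
    "T": ((-75, 35),  (-10, 45),  (0.20, 0.40), (80, 25),   (30, 60)),
    "S": ((-90, 50),  (60, 70),   (0.00, 0.40), (95, 25),   (-10, 90)),
    "C": ((-95, 55),  (110, 70),  (-0.10, 0.45), (70, 35),  (20, 100)),
}


@dataclass
class GeneratorSpec:
    """Study conditions for the synthetic corpus; all laws are seeded."""

    n_chains: int = 30
    length_range: tuple[int, int] = (50, 300)
    ss_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SS_WEIGHTS))
    run_length_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RUN_MEANS))
    dssp_laws: dict = field(default_factory=lambda: dict(DEFAULT_DSSP_LAWS))
    profile_noise_sd: float = 1.0
    break_prob: float = 0.15       # chance a chain contains one chain break
    seed: int = 0


def _clip_angle(v: float) -> float:
    return float(np.clip(v, -180.0, 180.0))


def _q1(v: float) -> float:
    return float(f"{v:.1f}")


def sample_ss_string(spec: GeneratorSpec, rng: np.random.Generator,
                     length: int) -> str:
    """Concatenated class runs: no-repeat Markov classes, geometric lengths."""
    classes = list(spec.ss_weights)
    weights = np.array([spec.ss_weights[c] for c in classes], dtype=float)
    weights /= weights.sum()
    out: list[str] = []
    prev = None
    while len(out) < length:
        w = weights.copy()
        if prev is not None:
            w[classes.index(prev)] = 0.0
            w /= w.sum()
        cls = classes[rng.choice(len(classes), p=w)]
        run = int(rng.geometric(1.0 / spec.run_length_means[cls]))
        out.extend(cls * min(run, length - len(out)))
        prev = cls
    return "".join(out)


def gen_chain(spec: GeneratorSpec, seed: int, chain_id: str = "A",
              out_dir: str | Path | None = None,
              ) -> tuple[Chain, ProfilePair, dict[str, Path]]:
    """One synthetic chain with matching profile matrices and, optionally,
    .dssp/.pssm/.hhm files on disk.

    All numeric fields are quantized to the on-disk print precision before
    being stored, so a written file re-read through the package's parsers
    reproduces the in-memory objects exactly.
    """
    rng = np.random.default_rng([spec.seed, seed])
    length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    ss = sample_ss_string(spec, rng, length)
    seq = "".join(AA_ALPHABET[i]
                  for i in rng.integers(0, len(AA_ALPHABET), size=length))
    break_at = None
    if length > 20 and rng.random() < spec.break_prob:
        break_at = int(rng.integers(5, length - 5))

    residues = []
    for i in range(length):
        (phi_m, phi_s), (psi_m, psi_s), (tco_m, tco_s), (kap_m, kap_s), \
            (alp_m, alp_s) = spec.dssp_laws[ss[i]]
        phi = _clip_angle(rng.normal(phi_m, phi_s))
        psi = _clip_angle(rng.normal(psi_m, psi_s))
        kappa = _clip_angle(rng.normal(kap_m, kap_s))
        alpha = _clip_angle(rng.normal(alp_m, alp_s))
        if i == 0:
            phi = kappa = alpha = ANGLE_SENTINEL
        if i == length - 1:
            psi = kappa = alpha = ANGLE_SENTINEL
        residues.append(ResidueRecord(
            aa=seq[i], ss=ss[i],
            acc=float(int(rng.uniform(0.0, 0.7 * MAX_ASA[seq[i]]))),
            tco=float(f"{np.clip(rng.normal(tco_m, tco_s), -1, 1):.3f}"),
            kappa=_q1(kappa), alpha=_q1(alpha), phi=_q1(phi), psi=_q1(psi),
            seq_index=i,
        ))
    chain = Chain(chain_id=chain_id, residues=residues, source="synthetic",
                  breaks=frozenset({break_at} if break_at else set()))

    pssm_raw, hhm_scores = _gen_profile_scores(spec, rng, seq)
    profiles = ProfilePair(
        pssm=normalize_pssm(pssm_raw),
        hmm=np.where(hhm_scores < 0, 0.0, 2.0 ** (-hhm_scores / 1000.0)),
    )

    files: dict[str, Path] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = f"chain_{chain_id}_{seed}"
        files["dssp"] = out_dir / f"{stem}.dssp"
        files["dssp"].write_text(render_dssp(chain))
        files["pssm"] = out_dir / f"{stem}.pssm"
        files["pssm"].write_text(render_pssm(seq, pssm_raw))
        files["hhm"] = out_dir / f"{stem}.hhm"
        files["hhm"].write_text(render_hhm(seq, hhm_scores))
    return chain, profiles, files


def _gen_profile_scores(spec: GeneratorSpec, rng: np.random.Generator,
                        seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Integer PSSM log-odds and HHM emission scores (canonical AA order).

    PSSM favours the observed residue (+5 on the diagonal, ~N(-1, noise)
    elsewhere); HHM emissions put ~70% mass on the observed residue. HHM
    scores use -1 as the '*' (zero-probability) marker.
    """
    n = len(seq)
    pssm = np.rint(rng.normal(-1.0, spec.profile_noise_sd, (n, 20))).astype(int)
    hhm = np.full((n, 20), -1, dtype=int)
    for i, aa in enumerate(seq):
        j = AA_ALPHABET.index(aa)
        pssm[i, j] = int(round(5 + rng.normal(0, spec.profile_noise_sd)))
        p_own = float(np.clip(rng.normal(0.70, 0.05), 0.4, 0.95))
        others = rng.integers(0, 20, size=3)
        rest = [k for k in set(others.tolist()) if k != j]
        probs = np.zeros(20)
        probs[j] = p_own
        if rest:
            probs[rest] = (1.0 - p_own) / len(rest)
        for k in range(20):
            if probs[k] > 0:
                hhm[i, k] = int(round(-1000.0 * np.log2(probs[k])))
    return pssm, hhm


# -- on-disk renderers -----------------------------------------------------

def render_dssp(chain: Chain) -> str:
    """Classic fixed-width DSSP text for one chain, breaks as '!' rows."""
    lines = [
        "==== Secondary Structure Definition by the program DSSP, "
        "NKI version 4 ==== DATE=2024-03-01        .",
        "REFERENCE W. KABSCH AND C.SANDER, BIOPOLYMERS 22 (1983) "
        "2577-2637                                                              .",
        "SYNTHETIC CHAIN GENERATED FOR PIPELINE "
        "TESTS                                                                  .",
        f"{len(chain):5d}  1  0  0  0 TOTAL NUMBER OF RESIDUES, NUMBER OF "
        "CHAINS, NUMBER OF SS-BRIDGES(TOTAL,INTRACHAIN,INTERCHAIN)        .",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
        "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
    ]
    serial = 1
    for r in chain.residues:
        if r.seq_index in chain.breaks:
            lines.append(f"{serial:5d}        !              0   0    0")
            serial += 1
        ss = " " if r.ss == "C" else r.ss
        row = (
            f"{serial:5d}{r.seq_index + 1:5d} {chain.chain_id} {r.aa}  {ss}"
            + " " * 17
            + f"{int(r.acc):4d}"
            + "      0, 0.0" + "     0, 0.0" * 3 + "  "
            + f"{r.tco:6.3f}{r.kappa:6.1f}{r.alpha:6.1f}{r.phi:6.1f}{r.psi:6.1f}"
            + f"{0.0:7.1f}{0.0:7.1f}{0.0:7.1f}"
        )
        lines.append(row)
        serial += 1
    return "\n".join(lines) + "\n"


def render_pssm(seq: str, pssm_canonical: np.ndarray) -> str:
    """PSI-BLAST ascii PSSM text (log-odds block in PSI-BLAST column order)."""
    perm = [AA_ALPHABET.index(a) for a in PSSM_AA_ORDER]
    header = "            " + "   ".join(PSSM_AA_ORDER) + "    " + \
        "   ".join(PSSM_AA_ORDER)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        header,
    ]
    for i, aa in enumerate(seq):
        scores = pssm_canonical[i][perm]
        pct = np.zeros(20, dtype=int)
        pct[PSSM_AA_ORDER.index(aa)] = 100
        lines.append(
            f"{i + 1:5d} {aa}  "
            + " ".join(f"{int(s):3d}" for s in scores) + "  "
            + " ".join(f"{p:3d}" for p in pct) + "  0.50 1.00"
        )
    lines += ["", "                      K         Lambda", ""]
    return "\n".join(lines) + "\n"


def render_hhm(seq: str, hhm_scores: np.ndarray) -> str:
    """HH-suite .hhm text; score -1 marks the '*' zero-probability entry."""
    perm = [AA_ALPHABET.index(a) for a in HHM_AA_ORDER]
    lines = [
        "HHsearch 1.5",
        "NAME  synthetic chain",
        f"LENG  {len(seq)} match states",
        "#",
        "NULL   3706 5728 4211 4064 4839 3729 4763 4308 4069 3323 5509 "
        "4640 4464 4937 4285 4423 3815 3783 6325 4665",
        "HMM    " + "\t".join(HHM_AA_ORDER),
        "       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\tNeff_I\tNeff_D",
        "       0\t*\t*\t0\t*\t0\t*\t*\t*\t*",
    ]
    for i, aa in enumerate(seq):
        scores = hhm_scores[i][perm]
        txt = "\t".join("*" if s < 0 else str(int(s)) for s in scores)
        lines.append(f"{aa} {i + 1}\t{txt}\t{i + 1}")
        lines.append("       0\t*\t*\t*\t*\t*\t*\t1000\t0\t0")
        lines.append("")
    lines.append("//")
    return "\n".join(lines) + "\n"


_CHAIN_IDS = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
              "abcdefghijklmnopqrstuvwxyz0123456789")


def gen_corpus(spec: GeneratorSpec, out_dir: str | Path | None = None,
               ) -> list[tuple[Chain, ProfilePair, dict[str, Path]]]:
    """``spec.n_chains`` chains, single-character PDB-style chain ids.

    Ids cycle through A-Z, a-z, 0-9 (the classic DSSP chain column holds one
    character); the per-chain file stem also carries the chain's seed, so
    file names stay unique for corpora larger than 62 chains.
    """
    out = []
    for i in range(spec.n_chains):
        cid = _CHAIN_IDS[i % len(_CHAIN_IDS)]
        out.append(gen_chain(spec, seed=i, chain_id=cid, out_dir=out_dir))
    return out


# -- feature-space mixture fixture ----------------------------------------

def gen_fragment_mixture(n_components: int, n_samples: int,
                         separation: float = 10.0,
                         within_sd: float | None = None,
                         seed: int = 0,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Cluster-structured 74-d feature rows with known component labels.

    Component centres are valid feature vectors (Dirichlet composition,
    uniform conservation block, a one-hot SS class, uniform geometry means);
    isotropic Gaussian noise of per-coordinate sd ``within_sd`` is added and
    the rows are projected back onto the feature invariants (simplex
    composition, snapped one-hot, clipped conservation). When ``within_sd``
    is not given it is set to (minimum centre distance) / ``separation``,
    so centres sit ``separation`` within-sds apart.
    """
    if n_components < 2:
        raise ValueError("need at least two mixture components")
    rng = np.random.default_rng(seed)
    centers = np.zeros((n_components, N_FEATURES))
    for k in range(n_components):
        comp = rng.dirichlet(np.full(20, 0.5))
        evo = rng.uniform(0.0, 1.0, 40)
        onehot = np.zeros(8)
        onehot[k % len(SS_ALPHABET)] = 1.0
        geom_num = rng.uniform(-1.0, 1.0, 6)
        centers[k] = np.concatenate([comp, evo, onehot, geom_num])
    dmin = float(pdist(centers).min())
    if within_sd is None:
        within_sd = dmin / separation
    labels = rng.integers(0, n_components, size=n_samples)
    x = centers[labels] + rng.normal(0.0, within_sd, (n_samples, N_FEATURES))
    # project back onto the fragment-feature invariants
    comp = np.clip(x[:, :N_COMPOSITION], 0.0, None)
    comp_sum = comp.sum(axis=1, keepdims=True)
    comp_sum[comp_sum == 0] = 1.0
    x[:, :N_COMPOSITION] = comp / comp_sum
    x[:, 20:60] = np.clip(x[:, 20:60], 0.0, 1.0)
    onehot_cls = [SS_INDEX[SS_ALPHABET[k % 8]] for k in labels]
    oh = np.zeros((n_samples, 8))
    oh[np.arange(n_samples), onehot_cls] = 1.0
    x[:, 60:68] = oh
    x[:, 68:] = np.clip(x[:, 68:], -1.0, 1.0)
    return x, labels
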