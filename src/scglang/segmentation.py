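"""Chain segmentation into fragments.

The primary segmenter groups maximal runs of consecutive residues sharing one
secondary-structure class into a fragment — the "word"-level unit of the
coarse-grained protein language. Three alternative segmenters (uniform-random
length, dynamic-random length, and SS-length shuffling) are provided for
ablation studies. All segmenters tile the chain with 0-based half-open
intervals and never cross a chain break.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .constants import RANDOM_FRAGMENT_MAX, RANDOM_FRAGMENT_MIN
from .structure_io import Chain, ResidueRecord


@dataclass(frozen=True)
class Fragment:
    """A half-open residue interval of one chain.

    ``ss`` is the shared class for SS-based segmentation and 'N' for the
    ablation segmenters, whose fragments are not SS-homogeneous.
    """

    chain_id: str
    start: int
    end: int
    ss: str
    residues: tuple[ResidueRecord, ...]

    def __len__(self) -> int:
        return self.end - self.start


def _chain_rng(seed: int, chain_id: str) -> np.random.Generator:
    # per-chain generator derived from (seed, chain_id): corpus order-independent
    return np.random.default_rng([seed, zlib.crc32(chain_id.encode())])


def _check_nonempty(chain: Chain) -> None:
    if not chain.residues:
        raise ValueError(f"chain {chain.chain_id!r} is empty")


def _blocks(chain: Chain) -> list[tuple[int, int]]:
    """Break-delimited half-open blocks covering the chain."""
    cuts = sorted(b for b in chain.breaks if 0 < b < len(chain))
    edges = [0, *cuts, len(chain)]
    return list(zip(edges[:-1], edges[1:]))


def _make(chain: Chain, start: int, end: int, ss: str) -> Fragment:
    return Fragment(chain.chain_id, start, end, ss,
                    tuple(chain.residues[start:end]))


def segment_by_ss(chain: Chain) -> list[Fragment]:
    """Maximal same-SS runs, in chain order; breaks always start a new run."""
    _check_nonempty(chain)
    frags: list[Fragment] = []
    for lo, hi in _blocks(chain):
        run_start = lo
        for i in range(lo + 1, hi):
            if chain.residues[i].ss != chain.residues[run_start].ss:
                frags.append(_make(chain, run_start, i,
                                   chain.residues[run_start].ss))
                run_start = i
        frags.append(_make(chain, run_start, hi, chain.residues[run_start].ss))
    return frags


def _tile_with_lengths(chain: Chain, lengths: list[int]) -> list[Fragment]:
    frags = []
    pos = 0
    for L in lengths:
        frags.append(_make(chain, pos, pos + L, "N"))
        pos += L
    assert pos == len(chain)
    return frags


def segment_uniform_random(chain: Chain, seed: int) -> list[Fragment]:
    """One length L ~ U{3..60} per chain; even division, shorter tail allowed.

    Within each break-delimited block, fragments have length L except for the
    block's final remainder fragment.
    """
    _check_nonempty(chain)
    rng = _chain_rng(seed, chain.chain_id)
    L = int(rng.integers(RANDOM_FRAGMENT_MIN, RANDOM_FRAGMENT_MAX + 1))
    lengths: list[int] = []
    for lo, hi in _blocks(chain):
        n = hi - lo
        lengths.extend([L] * (n // L))
        if n % L:
            lengths.append(n % L)
    return _tile_with_lengths(chain, lengths)


def segment_dynamic_random(chain: Chain, seed: int) -> list[Fragment]:
    """Lengths drawn i.i.d. from U{3..60} until the chain is exhausted."""
    _check_nonempty(chain)
    rng = _chain_rng(seed, chain.chain_id)
    lengths: list[int] = []
    for lo, hi in _blocks(chain):
        remaining = hi - lo
        while remaining > 0:
            L = min(int(rng.integers(RANDOM_FRAGMENT_MIN,
                                     RANDOM_FRAGMENT_MAX + 1)), remaining)
            lengths.append(L)
            remaining -= L
    return _tile_with_lengths(chain, lengths)


def segment_length_shuffle(chain: Chain, seed: int) -> list[Fragment]:
    """SS-run lengths, permuted uniformly at random, retile the chain.

    The multiset of fragment lengths equals that of :func:`segment_by_ss`;
    the permutation is applied within each break-delimited block so breaks
    remain fragment boundaries.
    """
    _check_nonempty(chain)
    rng = _chain_rng(seed, chain.chain_id)
    ss_frags = segment_by_ss(chain)
    lengths: list[int] = []
    for lo, hi in _blocks(chain):
        block = [len(f) for f in ss_frags if lo <= f.start and f.end <= hi]
        lengths.extend(rng.permutation(block).astype(int).tolist())
    return _tile_with_lengths(chain, lengths)


SEGMENTERS = {
    "ss": lambda chain, seed=0: segment_by_ss(chain),
    "uniform": segment_uniform_random,
    "dynamic": segment_dynamic_random,
    "shuffle": segment_length_shuffle,
}


def segment(chain: Chain, segmenter: str, seed: int = 0) -> list[Fragment]:
    """Dispatch by segmenter name: one of ss, uniform, dynamic, shuffle."""
    try:
        fn = SEGMENTERS[segmenter]
    except KeyError:
        raise ValueError(f"unknown segmenter {segmenter!r}; "
                         f"choose from {sorted(SEGMENTERS)}") from None
    return fn(chain, seed)


@dataclass(frozen=True)
class CompressionStats:
    """Corpus-level sentence-length statistics for one segmenter."""

    per_chain_residues: tuple[int, ...]
    per_chain_fragments: tuple[int, ...]
    mean_length_ratio: float      # total residues / total fragments
    n_over_truncation: int
    truncation: int


def compression_stats(chains: list[Chain], segmenter: str = "ss",
                      seed: int = 0, truncation: int = 512) -> CompressionStats:
    """How much shorter are fragment sentences than residue sequences?

    The mean length ratio is total residues over total fragments across the
    corpus; sentences longer than ``truncation`` fragments are counted.
    """
    if not chains:
        raise ValueError("empty corpus")
    n_res, n_frag = [], []
    for ch in chains:
        frags = segment(ch, segmenter, seed)
        n_res.append(len(ch))
        n_frag.append(len(frags))
    return CompressionStats(
        per_chain_residues=tuple(n_res),
        per_chain_fragments=tuple(n_frag),
        mean_length_ratio=sum(n_res) / sum(n_frag),
        n_over_truncation=sum(1 for n in n_frag if n > truncation),
        truncation=truncation,
    )


def write_fragments_bed(frags: list[Fragment], path) -> None:
    """BED-like TSV dump: chain_id, start, end, ss, length."""
    from pathlib import Path

    rows = ["chain_id\tstart\tend\tss\tlength"]
    rows += [f"{f.chain_id}\t{f.start}\t{f.end}\t{f.ss}\t{len(f)}" for f in frags]
    Path(path).write_text("\n".join(rows) + "\n")
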