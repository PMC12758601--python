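"""Serialize protein chains into coarse-grained token sentences.

Each chain is segmented into fragments, every fragment featurized and mapped
to its nearest vocabulary entry, and the token ids assembled in fragment
order along the sequence. Corpora are plain text: a header line recording
the vocabulary hash, then one ``chain_id<TAB>t1 t2 ... tn`` line per chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .constants import DEFAULT_TRUNCATION
from .features import ProfilePair, feature_matrix
from .segmentation import segment
from .structure_io import Chain
from .vocabulary import Vocabulary


class CorpusError(ValueError):
    """Raised on corpus/vocabulary mismatch or malformed corpus files."""


@dataclass(frozen=True)
class ProteinSentence:
    """Ordered token ids for one chain, with fragment provenance."""

    chain_id: str
    tokens: tuple[int, ...]
    fragments: tuple[tuple[int, int, str], ...]   # (start, end, ss)
    vocab_id: str

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize_chain(chain: Chain, vocab: Vocabulary,
                   profiles: ProfilePair | None = None,
                   segmenter: str = "ss", seed: int = 0) -> ProteinSentence:
    """segment -> featurize -> standardize -> encode -> quantize, in order."""
    frags = segment(chain, segmenter, seed)
    feats = feature_matrix(frags, profiles)
    tokens = vocab.tokenize_features(feats)
    return ProteinSentence(
        chain_id=chain.chain_id,
        tokens=tuple(int(t) for t in tokens),
        fragments=tuple((f.start, f.end, f.ss) for f in frags),
        vocab_id=vocab.manifest_hash,
    )


def write_corpus(sentences: list[ProteinSentence], path: str | Path,
                 truncation: int | None = DEFAULT_TRUNCATION) -> int:
    """Write one sentence per line; returns the number truncated.

    Sentences longer than ``truncation`` tokens are cut at write time (the
    in-memory sentences are untouched); pass ``None`` to disable.
    """
    vocab_id = sentences[0].vocab_id if sentences else "none"
    lines = [f"#scg-corpus\tvocab={vocab_id}"]
    n_trunc = 0
    for s in sentences:
        toks = s.tokens
        if truncation is not None and len(toks) > truncation:
            toks = toks[:truncation]
            n_trunc += 1
        lines.append(f"{s.chain_id}\t{' '.join(map(str, toks))}")
    Path(path).write_text("\n".join(lines) + "\n")
    return n_trunc


def read_corpus(path: str | Path, K: int | None = None) -> list[ProteinSentence]:
    """Read a token corpus; validates token range when K is given."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#scg-corpus"):
        raise CorpusError(f"{path}: missing corpus header line")
    vocab_id = "none"
    for fieldtok in lines[0].split("\t")[1:]:
        if fieldtok.startswith("vocab="):
            vocab_id = fieldtok[len("vocab="):]
    sentences = []
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        chain_id, _, rest = line.partition("\t")
        tokens = tuple(int(t) for t in rest.split()) if rest.strip() else ()
        if K is not None and any(t >= K or t < 0 for t in tokens):
            raise CorpusError(
                f"{path}:{lineno}: token id outside [0, {K}) — "
                "corpus/vocabulary mismatch")
        sentences.append(ProteinSentence(
            chain_id=chain_id, tokens=tokens,
            fragments=(), vocab_id=vocab_id))
    return sentences
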