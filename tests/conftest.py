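import numpy as np
import pytest

from scglang import GeneratorSpec, gen_chain, gen_corpus, gen_fragment_mixture
from scglang.structure_io import Chain, ResidueRecord


def make_chain(ss: str, seq: str | None = None, chain_id: str = "A",
               breaks=(), acc: float = 50.0, tco: float = 0.5,
               kappa: float = 60.0, alpha: float = 50.0,
               phi: float = -60.0, psi: float = -45.0) -> Chain:
    """Hand-built chain with uniform DSSP fields, for targeted examples."""
    seq = seq or "A" * len(ss)
    residues = [
        ResidueRecord(aa=seq[i], ss=ss[i], acc=acc, tco=tco, kappa=kappa,
                      alpha=alpha, phi=phi, psi=psi, seq_index=i)
        for i in range(len(ss))
    ]
    return Chain(chain_id=chain_id, residues=residues,
                 breaks=frozenset(breaks))


@pytest.fixture(scope="session")
def generator_spec() -> GeneratorSpec:
    return GeneratorSpec(n_chains=8, length_range=(40, 160), seed=123)


@pytest.fixture(scope="session")
def synthetic_corpus(generator_spec, tmp_path_factory):
    """Eight generated chains with their .dssp/.pssm/.hhm files on disk."""
    out = tmp_path_factory.mktemp("corpus")
    return gen_corpus(generator_spec, out_dir=out)


@pytest.fixture(scope="session")
def synthetic_chain(generator_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("chain")
    return gen_chain(generator_spec, seed=5, chain_id="A", out_dir=out)


@pytest.fixture(scope="session")
def mixture16():
    """Well-separated 16-component mixture with generator labels."""
    X, labels = gen_fragment_mixture(16, 4000, separation=10.0, seed=3)
    return X, labels
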