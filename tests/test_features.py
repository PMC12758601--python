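"""Fragment featurization: block contents, normalizations, profile readers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scglang import (
    composition_feature,
    evolutionary_feature,
    feature_matrix,
    featurize,
    geometry_feature,
    load_profiles,
    normalize_pssm,
    read_hhm,
    read_pssm,
)
from scglang.constants import (
    AA_ALPHABET,
    AA_INDEX,
    N_FEATURES,
    SS_ALPHABET,
    SS_INDEX,
)
from scglang.features import ProfileFormatError, ProfilePair, Standardization
from scglang.segmentation import Fragment, segment_by_ss
from scglang.synthetic import render_hhm, render_pssm

from conftest import make_chain


def frag_of(chain, lo=None, hi=None, ss=None):
    lo = 0 if lo is None else lo
    hi = len(chain) if hi is None else hi
    return Fragment(chain.chain_id, lo, hi,
                    ss or chain.residues[lo].ss,
                    tuple(chain.residues[lo:hi]))


class TestComposition:
    @pytest.mark.parametrize("seq,expect", [
        ("AAAA", {"A": 1.0}),
        ("ACDE", {"A": .25, "C": .25, "D": .25, "E": .25}),
        ("AXA", {"A": 1.0}),
    ])
    def test_examples(self, seq, expect, ):
        chain = make_chain("H" * len(seq), seq=seq)
        v = composition_feature(frag_of(chain))
        for aa, val in expect.items():
            assert v[AA_INDEX[aa]] == pytest.approx(val)
        assert v.sum() == pytest.approx(1.0)

    def test_all_x_fragment_is_zero(self):
        chain = make_chain("HH", seq="XX")
        assert composition_feature(frag_of(chain)).sum() == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(seq=st.text(alphabet=AA_ALPHABET + "X", min_size=1, max_size=40))
    def test_simplex_and_permutation_invariance(self, seq):
        chain = make_chain("H" * len(seq), seq=seq)
        v = composition_feature(frag_of(chain))
        assert (v >= 0).all()
        if set(seq) != {"X"}:
            assert v.sum() == pytest.approx(1.0, abs=1e-9)
        shuffled = "".join(sorted(seq))
        chain2 = make_chain("H" * len(seq), seq=shuffled)
        assert np.allclose(v, composition_feature(frag_of(chain2)))


class TestProfiles:
    def test_pssm_roundtrip_via_renderer(self):
        rng = np.random.default_rng(0)
        seq = "ACDEFGHIK"
        raw = rng.integers(-10, 11, (9, 20))
        text = render_pssm(seq, raw)
        got = read_pssm_text(text)
        assert np.array_equal(got, raw)

    def test_sigmoid_values(self):
        assert normalize_pssm(np.array([0.0]))[0] == pytest.approx(0.5)
        assert normalize_pssm(np.array([2.0]))[0] == pytest.approx(
            0.8807970779778823)
        big = normalize_pssm(np.array([-50.0, 50.0]))
        assert big[0] < 1e-20 and big[1] >= 1 - 1e-15

    def test_sigmoid_preserves_ordering(self):
        rng = np.random.default_rng(1)
        raw = rng.integers(-12, 13, (5, 20))
        norm = normalize_pssm(raw)
        assert np.array_equal(np.argsort(raw, axis=1),
                              np.argsort(norm, axis=1))

    def test_hhm_score_conversion(self, tmp_path):
        # scores 0 -> 1.0, 1000 -> 0.5, '*' -> 0.0
        scores = np.full((2, 20), -1)
        scores[0, AA_INDEX["A"]] = 0
        scores[1, AA_INDEX["D"]] = 1000
        p = tmp_path / "t.hhm"
        p.write_text(render_hhm("AD", scores))
        mat = read_hhm(p)
        assert mat[0, AA_INDEX["A"]] == pytest.approx(1.0)
        assert mat[1, AA_INDEX["D"]] == pytest.approx(0.5)
        assert mat[0, 1:].sum() == 0.0

    def test_truncated_hhm_raises(self, tmp_path):
        p = tmp_path / "t.hhm"
        p.write_text("HHsearch 1.5\nNAME x\n")
        with pytest.raises(ProfileFormatError):
            read_hhm(p)

    def test_length_mismatch_raises(self, tmp_path, synthetic_chain):
        _, _, files = synthetic_chain
        short = tmp_path / "short.hhm"
        short.write_text(render_hhm("AC", np.zeros((2, 20), dtype=int)))
        with pytest.raises(ProfileFormatError, match="mismatch"):
            load_profiles(files["pssm"], short)


def read_pssm_text(text):
    import tempfile, pathlib
    with tempfile.TemporaryDirectory() as d:
        p = pathlib.Path(d) / "t.pssm"
        p.write_text(text)
        return read_pssm(p)


class TestEvolutionary:
    def _profiles(self, n):
        rng = np.random.default_rng(2)
        return ProfilePair(pssm=rng.uniform(0, 1, (n, 20)),
                           hmm=rng.uniform(0, 1, (n, 20)))

    def test_single_residue_fragment_is_row_concat(self):
        chain = make_chain("HHH")
        pp = self._profiles(3)
        v = evolutionary_feature(frag_of(chain, 1, 2), pp)
        assert np.allclose(v, np.concatenate([pp.pssm[1], pp.hmm[1]]))

    def test_two_residue_mean(self):
        chain = make_chain("HH")
        pp = self._profiles(2)
        v = evolutionary_feature(frag_of(chain), pp)
        assert np.allclose(v[:20], pp.pssm.mean(axis=0))
        assert np.allclose(v[20:], pp.hmm.mean(axis=0))

    def test_out_of_range_raises(self):
        chain = make_chain("HHHH")
        with pytest.raises(IndexError):
            evolutionary_feature(frag_of(chain), self._profiles(2))


class TestGeometry:
    def test_documented_normalizations(self):
        chain = make_chain("HHH", phi=-60.0, psi=-45.0, acc=0.0)
        v = geometry_feature(frag_of(chain))
        assert v[SS_INDEX["H"]] == 1.0 and v[:8].sum() == 1.0
        assert v[8] == 0.0                                  # acc
        assert v[12] == pytest.approx(-60 / 180)            # phi
        assert v[13] == pytest.approx(-0.25)                # psi

    def test_sentinel_angles_impute_to_zero(self):
        chain = make_chain("EE", phi=360.0, psi=360.0, kappa=360.0,
                           alpha=360.0)
        v = geometry_feature(frag_of(chain))
        assert np.allclose(v[10:14], 0.0)

    def test_acc_clipped_to_relative_unit_range(self):
        chain = make_chain("G", seq="G", acc=500.0)   # above max ASA
        v = geometry_feature(frag_of(chain))
        assert v[8] == 1.0

    def test_mixed_ss_under_ss_label_raises(self):
        chain = make_chain("HE")
        bad = Fragment("A", 0, 2, "H", tuple(chain.residues))
        with pytest.raises(ValueError, match="contains classes"):
            geometry_feature(bad)

    def test_ablation_fragment_uses_majority_class(self):
        chain = make_chain("HHE")
        frag = Fragment("A", 0, 3, "N", tuple(chain.residues))
        v = geometry_feature(frag)
        assert v[SS_INDEX["H"]] == 1.0

    def test_majority_tie_breaks_by_alphabet_order(self):
        chain = make_chain("EH")   # tie; alphabet order is H,B,E,...
        frag = Fragment("A", 0, 2, "N", tuple(chain.residues))
        v = geometry_feature(frag)
        assert v[SS_INDEX["H"]] == 1.0


class TestFeaturize:
    def test_dimension_law_and_block_slices(self, synthetic_chain):
        chain, profiles, _ = synthetic_chain
        for frag in segment_by_ss(chain)[:10]:
            ff = featurize(frag, profiles)
            assert ff.x.shape == (N_FEATURES,)
            assert np.allclose(ff.x[:20], composition_feature(frag))
            assert np.allclose(ff.x[20:60],
                               evolutionary_feature(frag, profiles))
            assert np.allclose(ff.x[60:], geometry_feature(frag))
            assert np.isfinite(ff.x).all()

    def test_missing_profiles_zero_imputed_and_flagged(self, synthetic_chain):
        chain, _, _ = synthetic_chain
        frag = segment_by_ss(chain)[0]
        ff = featurize(frag, None)
        assert ff.profiles_imputed
        assert np.all(ff.x[20:60] == 0.0)

    def test_deterministic(self, synthetic_chain):
        chain, profiles, _ = synthetic_chain
        frags = segment_by_ss(chain)
        a = feature_matrix(frags, profiles)
        b = feature_matrix(frags, profiles)
        assert np.array_equal(a, b)


class TestStandardization:
    def test_roundtrip_and_zero_variance_guard(self):
        rng = np.random.default_rng(3)
        X = rng.normal(2.0, 3.0, (50, N_FEATURES))
        X[:, 7] = 1.25   # constant dimension
        std = Standardization.fit(X)
        Z = std.apply(X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        assert np.all(Z[:, 7] == 0.0)
        back = Standardization.from_dict(std.to_dict())
        assert np.allclose(back.apply(X), Z)
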