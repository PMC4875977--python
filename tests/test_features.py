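"""Feature encoders against independent loop oracles and analytic limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import remhom as rh
from remhom.features import (
    DegenerateIndexError,
    SequenceTooShortError,
    kmer_labels,
)
from remhom.seqio import ALPHABET

from conftest import acc_oracle, kmer_oracle, pseaac_oracle, random_sequence, tau_oracle

CANONICAL = st.text(alphabet=ALPHABET, min_size=1, max_size=60)
IDX = rh.PhysChemIndexSet.default()


def seq(residues: str) -> rh.ProteinSequence:
    return rh.ProteinSequence(id="t", residues=residues)


class TestNormalizeIndex:
    @pytest.mark.parametrize("name", IDX.names)
    def test_zero_mean_unit_population_variance(self, name):
        i = IDX.names.index(name)
        norm = rh.normalize_index(IDX.raw[i])
        assert abs(norm.mean()) < 1e-12
        assert abs(np.mean(norm**2) - 1.0) < 1e-12

    def test_constant_index_rejected(self):
        with pytest.raises(DegenerateIndexError):
            rh.normalize_index(np.full(20, 3.3))

    def test_index_set_invariants(self):
        assert IDX.normalized.shape == (3, 20)
        np.testing.assert_allclose(IDX.normalized.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose((IDX.normalized**2).mean(axis=1), 1.0, atol=1e-12)

    def test_override_table_round_trips(self, tmp_path):
        path = tmp_path / "idx.tsv"
        lines = ["residue\th1\th2\tmass"]
        for j, aa in enumerate(ALPHABET):
            lines.append(f"{aa}\t{IDX.raw[0, j]}\t{IDX.raw[1, j]}\t{IDX.raw[2, j]}")
        path.write_text("\n".join(lines) + "\n")
        loaded = rh.PhysChemIndexSet.from_tsv(path)
        np.testing.assert_allclose(loaded.normalized, IDX.normalized)


class TestKmer:
    @pytest.mark.parametrize(
        "residues, k, expected",
        [
            ("MM", 2, {"MM": 1.0}),
            ("ACA", 2, {"AC": 0.5, "CA": 0.5}),
            ("AAC", 1, {"A": 2 / 3, "C": 1 / 3}),
        ],
    )
    def test_frozen_examples(self, residues, k, expected):
        vec = rh.kmer_encode(seq(residues), rh.KmerConfig(k=k)).values
        labels = kmer_labels(k)
        nonzero = {labels[i]: v for i, v in enumerate(vec) if v > 0}
        assert set(nonzero) == set(expected)
        for mer, v in expected.items():
            assert nonzero[mer] == pytest.approx(v, abs=1e-12)

    def test_too_short_errors(self):
        with pytest.raises(SequenceTooShortError):
            rh.kmer_encode(seq("A"), rh.KmerConfig(k=2))

    def test_sentinel_windows_skipped(self):
        vec = rh.kmer_encode(seq("ACXAC"), rh.KmerConfig(k=2)).values
        labels = kmer_labels(2)
        nonzero = {labels[i]: v for i, v in enumerate(vec) if v > 0}
        assert nonzero == {"AC": pytest.approx(1.0)}  # 2 counted of 4 windows

    @settings(deadline=None, derandomize=True)
    @given(CANONICAL, st.integers(min_value=1, max_value=3))
    def test_matches_oracle_and_sums_to_one(self, residues, k):
        if len(residues) < k:
            return
        vec = rh.kmer_encode(seq(residues), rh.KmerConfig(k=k)).values
        assert vec.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(vec, kmer_oracle(residues, k), atol=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_dimension(self, k):
        assert rh.KmerConfig(k=k).dimension == 20**k


class TestAcc:
    def test_default_dimension_is_126(self):
        cfg = rh.AccConfig()
        assert cfg.lag == 14 and cfg.dimension == 126
        rng = np.random.default_rng(0)
        vec = rh.acc_encode(random_sequence(rng, 40), cfg).values
        assert vec.shape == (126,)

    def test_homopolymer_vanishes(self):
        for aa in "AKW":
            vec = rh.acc_encode(seq(aa * 30), rh.AccConfig(lag=5)).values
            np.testing.assert_allclose(vec, 0.0, atol=1e-12)

    def test_cc_equals_ac_on_diagonal(self):
        # the (u, u) components are exactly the autocovariance terms
        rng = np.random.default_rng(3)
        s = random_sequence(rng, 50)
        vec = rh.acc_encode(s, rh.AccConfig(lag=4)).values.reshape(4, 3, 3)
        oracle = acc_oracle(s.residues, 4).reshape(4, 3, 3)
        np.testing.assert_allclose(np.diagonal(vec, axis1=1, axis2=2),
                                   np.diagonal(oracle, axis1=1, axis2=2), atol=1e-12)

    def test_toy_sequence_matches_loop_oracle(self):
        vec = rh.acc_encode(seq("ACDEF"), rh.AccConfig(lag=1)).values
        np.testing.assert_allclose(vec, acc_oracle("ACDEF", 1), atol=1e-12)

    def test_too_short_names_lag(self):
        with pytest.raises(SequenceTooShortError, match="14"):
            rh.acc_encode(seq("ACDEF"), rh.AccConfig(lag=14))

    def test_renaming_invariance(self):
        # swapping two residues with identical index values leaves ACC fixed;
        # no canonical pair is identical, so build a two-index custom set
        raw = IDX.raw.copy()
        raw[:, ALPHABET.index("C")] = raw[:, ALPHABET.index("A")]
        idx = rh.PhysChemIndexSet(names=IDX.names, raw=raw)
        cfg = rh.AccConfig(lag=3, index_set=idx)
        a = rh.acc_encode(seq("ACDAC"), cfg).values
        b = rh.acc_encode(seq("CADCA"), cfg).values
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestTauAndPseaac:
    def test_homopolymer_tau_is_squared_values(self):
        taus = rh.tau_factors(seq("AAAA"), 1)
        expected = IDX.normalized[:, ALPHABET.index("A")] ** 2
        np.testing.assert_allclose(taus, expected, atol=1e-12)

    def test_lambda_bound_enforced(self):
        with pytest.raises(SequenceTooShortError):
            rh.tau_factors(seq("ACDE"), 3)  # needs lambda < L - 1 = 3
        rh.tau_factors(seq("ACDE"), 2)  # boundary-legal

    def test_tau_matches_loop_oracle(self):
        np.testing.assert_allclose(
            rh.tau_factors(seq("ACDEFG"), 2), tau_oracle("ACDEFG", 2), atol=1e-12
        )

    def test_default_dimension_is_35(self):
        assert rh.PseaacConfig().dimension == 35
        rng = np.random.default_rng(1)
        vec = rh.sc_pseaac_encode(random_sequence(rng, 30)).values
        assert vec.shape == (35,)

    def test_w_zero_reduces_to_composition(self):
        vec = rh.sc_pseaac_encode(seq("ACDEFGHIK"), rh.PseaacConfig(lam=2, w=0.0)).values
        np.testing.assert_allclose(vec[20:], 0.0, atol=1e-15)
        assert vec[:20].sum() == pytest.approx(1.0, abs=1e-12)

    def test_example_matches_scalar_oracle(self):
        vec = rh.sc_pseaac_encode(seq("ACDEFGHIK"), rh.PseaacConfig(lam=2, w=0.2)).values
        np.testing.assert_allclose(vec, pseaac_oracle("ACDEFGHIK", 2, 0.2), atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.text(alphabet=ALPHABET, min_size=8, max_size=60),
           st.integers(min_value=1, max_value=5),
           st.floats(min_value=0.0, max_value=1.0))
    def test_first_block_proportional_to_composition(self, residues, lam, w):
        if lam >= len(residues) - 1:
            return
        try:
            vec = rh.sc_pseaac_encode(seq(residues), rh.PseaacConfig(lam=lam, w=w)).values
        except rh.features.DegenerateEncodingError:
            return  # 1 + w*sum(tau) <= 0: encoding is undefined by contract
        comp = rh.kmer_encode(seq(residues), rh.KmerConfig(k=1)).values
        block = vec[:20]
        np.testing.assert_allclose(block / block.sum(), comp, atol=1e-10)


class TestDispatch:
    def test_encode_all_schemes(self):
        rng = np.random.default_rng(5)
        s = random_sequence(rng, 60)
        dims = {"kmer": 400, "acc": 126, "sc-pseaac": 35}
        for scheme, dim in dims.items():
            assert rh.encode(s, scheme).values.shape == (dim,)
        with pytest.raises(ValueError):
            rh.encode(s, "embedding")

    def test_feature_tsv_output(self, tmp_path):
        rng = np.random.default_rng(6)
        seqs = [random_sequence(rng, 30, sid=f"s{i}") for i in range(3)]
        vectors = rh.encode_all(seqs, "sc-pseaac")
        path = tmp_path / "f.tsv"
        from remhom.features import write_feature_tsv

        write_feature_tsv(vectors, "sc-pseaac", rh.PseaacConfig(), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 4 and lines[0].count("\t") == 35
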