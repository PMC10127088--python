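"""Physicochemical encoders against independent brute-force oracles.

Each oracle below is a direct, literal transcription of the encoder's
defining formula, written without reference to the implementation: plain
dictionary counting for Kmer/ENAC/CKSNAP and a term-by-term evaluation
of the pseudo-dinucleotide composition equations.
"""

from itertools import product

import numpy as np
import pytest

from m5u.encoders import (
    DINUCLEOTIDES,
    FeatureVector,
    PropertyTable,
    PropertyTableError,
    PseDncConfig,
    encode_cksnap,
    encode_enac,
    encode_kmer,
    encode_matrix,
    encode_physchem,
    encode_psednc,
)
from m5u.windows import generate_synthetic

from conftest import random_window_seq

# ---------------------------------------------------------------- oracles


def oracle_kmer(seq, k):
    mers = ["".join(p) for p in product("ACGU", repeat=k)]
    counts = {m: 0 for m in mers}
    for i in range(len(seq) - k + 1):
        counts[seq[i : i + k]] += 1
    return np.array([counts[m] / (len(seq) - k + 1) for m in mers])


def oracle_enac(seq, w):
    out = []
    for start in range(len(seq) - w + 1):
        win = seq[start : start + w]
        out.extend(win.count(nt) / w for nt in "ACGU")
    return np.array(out)


def oracle_cksnap(seq, k_max):
    out = []
    for k in range(k_max + 1):
        pairs = [seq[i] + seq[i + k + 1] for i in range(len(seq) - k - 1)]
        for d in DINUCLEOTIDES:
            out.append(pairs.count(d) / (len(seq) - (k + 1)))
    return np.array(out)


def oracle_psednc(seq, lam, w, table):
    """Term-by-term evaluation of the PseDNC definition."""
    L = len(seq)
    col = {d: i for i, d in enumerate(DINUCLEOTIDES)}

    def theta_fn(a, b):
        ca = table.matrix[:, col[a]]
        cb = table.matrix[:, col[b]]
        return sum((ca[u] - cb[u]) ** 2 for u in range(table.n_indices)) / table.n_indices

    counts = [0] * 16
    for i in range(L - 1):
        counts[col[seq[i : i + 2]]] += 1
    f = [c / (L - 1) for c in counts]

    thetas = []
    for j in range(1, lam + 1):
        vals = [
            theta_fn(seq[i : i + 2], seq[i + j : i + j + 2])
            for i in range(L - 1 - j)
        ]
        thetas.append(sum(vals) / (L - 1 - j))

    denom = sum(f) + w * sum(thetas)
    return np.array([x / denom for x in f] + [w * t / denom for t in thetas])


# ------------------------------------------------------------------ tests


class TestKmer:
    def test_homopolymer(self):
        fv = encode_kmer("AAAA", k=2)
        assert fv.as_series()["kmer2_AA"] == 1.0  # 3 of 3 positions
        assert fv.values.sum() == 1.0

    def test_uniform_composition(self):
        np.testing.assert_allclose(encode_kmer("ACGU", k=1).values, [0.25] * 4)

    def test_length_denominator_flag(self):
        fv = encode_kmer("AAAA", k=2, denominator="length")
        assert fv.as_series()["kmer2_AA"] == 3 / 4

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_counting_oracle(self, rng, k):
        for _ in range(20):
            seq = random_window_seq(rng)
            np.testing.assert_allclose(
                encode_kmer(seq, k).values, oracle_kmer(seq, k), atol=1e-12
            )

    def test_k1_permutation_invariant(self, rng):
        seq = random_window_seq(rng)
        perm = "".join(rng.permutation(list(seq)))
        np.testing.assert_allclose(
            encode_kmer(seq, 1).values, encode_kmer(perm, 1).values
        )

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            encode_kmer("ACGU", k=5)


class TestEnac:
    def test_homopolymer_blocks(self):
        fv = encode_enac("AAAAAAA", window_len=5)
        assert np.array_equal(fv.values.reshape(-1, 4), [[1, 0, 0, 0]] * 3)

    def test_dimension_41nt(self):
        seq = "A" * 20 + "U" + "A" * 20
        assert len(encode_enac(seq, window_len=5)) == 4 * (41 - 5 + 1) == 148

    def test_matches_window_counting_oracle(self, rng):
        for _ in range(20):
            seq = random_window_seq(rng)
            np.testing.assert_allclose(
                encode_enac(seq, 5).values, oracle_enac(seq, 5), atol=1e-12
            )

    def test_each_window_block_sums_to_one(self, rng):
        fv = encode_enac(random_window_seq(rng), 5)
        np.testing.assert_allclose(fv.values.reshape(-1, 4).sum(axis=1), 1.0, atol=1e-9)

    def test_order_sensitive(self):
        a = encode_enac("AACCUCCAA", 3).values
        b = encode_enac("CCAAUAACC", 3).values
        assert not np.allclose(a, b)


class TestCksnap:
    def test_gap0_enumerates_16_ordered_pairs(self):
        fv = encode_cksnap("ACGUU", k_max=0)
        expected = [f"cksnap_g0_{p}" for p in DINUCLEOTIDES]
        assert fv.names == expected
        assert DINUCLEOTIDES == (
            "AA", "AC", "AG", "AU", "CA", "CC", "CG", "CU",
            "GA", "GC", "GG", "GU", "UA", "UC", "UG", "UU",
        )

    def test_homopolymer_gap0(self):
        s = encode_cksnap("AAAA", k_max=0).as_series()
        assert s["cksnap_g0_AA"] == 1.0

    def test_gap1_enumeration(self):
        s = encode_cksnap("ACAC", k_max=1).as_series()
        assert s["cksnap_g1_AA"] == 0.5 and s["cksnap_g1_CC"] == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(20):
            seq = random_window_seq(rng)
            np.testing.assert_allclose(
                encode_cksnap(seq, 5).values, oracle_cksnap(seq, 5), atol=1e-12
            )

    def test_gap_blocks_sum_to_one(self, rng):
        fv = encode_cksnap(random_window_seq(rng), 5)
        np.testing.assert_allclose(fv.values.reshape(6, 16).sum(axis=1), 1.0, atol=1e-9)


class TestPropertyTable:
    def test_bundled_table_shape_and_standardization(self):
        t = PropertyTable.default()
        assert t.index_names == ("rise", "roll", "shift", "slide", "tilt", "twist")
        assert t.matrix.shape == (6, 16)
        np.testing.assert_allclose(t.matrix.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(t.matrix.std(axis=1), 1, atol=1e-9)

    def test_tsv_roundtrip(self, tmp_path):
        t = PropertyTable.default()
        t.to_tsv(tmp_path / "t.tsv")
        t2 = PropertyTable.from_tsv(tmp_path / "t.tsv", standardize=False)
        np.testing.assert_allclose(t2.matrix, t.matrix, atol=1e-12)

    def test_unstandardized_flag_rejected(self):
        with pytest.raises(PropertyTableError):
            PropertyTable(("a",), np.arange(16)[None, :] * 1.0, standardized=True)


class TestPseDnc:
    def test_w_zero_reduces_to_dinucleotide_frequencies(self, rng):
        seq = random_window_seq(rng)
        fv = encode_psednc(seq, PseDncConfig(lam=3, w=0.0))
        freqs = oracle_kmer(seq, 2)
        np.testing.assert_allclose(fv.values[:16], freqs, atol=1e-12)
        np.testing.assert_allclose(fv.values[16:], 0, atol=1e-12)

    def test_constant_table_kills_correlations(self, rng):
        const = PropertyTable(("i1", "i2"), np.zeros((2, 16)), standardized=False)
        # bypass standardization on purpose: all theta terms vanish
        const.standardized = True
        seq = random_window_seq(rng)
        fv = encode_psednc(seq, PseDncConfig(lam=3, w=0.5), const)
        np.testing.assert_allclose(fv.values[16:], 0, atol=1e-12)
        np.testing.assert_allclose(fv.values[:16], oracle_kmer(seq, 2), atol=1e-12)

    def test_matches_literal_equation_oracle(self, rng):
        table = PropertyTable.default()
        for _ in range(20):
            seq = random_window_seq(rng)
            np.testing.assert_allclose(
                encode_psednc(seq, PseDncConfig(lam=3, w=0.5), table).values,
                oracle_psednc(seq, 3, 0.5, table),
                atol=1e-9,
            )

    def test_vector_sums_to_one(self, rng):
        fv = encode_psednc(random_window_seq(rng), PseDncConfig(lam=5, w=0.8))
        assert abs(fv.values.sum() - 1.0) < 1e-9

    def test_theta_symmetry(self):
        """The correlation function is a squared difference, hence symmetric."""
        table = PropertyTable.default()
        col = {d: i for i, d in enumerate(DINUCLEOTIDES)}

        def theta(a, b):
            d = table.matrix[:, col[a]] - table.matrix[:, col[b]]
            return float(np.mean(d**2))

        for a in DINUCLEOTIDES:
            for b in DINUCLEOTIDES:
                assert theta(a, b) == pytest.approx(theta(b, a))
                assert theta(a, b) >= 0

    def test_lambda_too_large(self):
        with pytest.raises(ValueError, match="lambda"):
            encode_psednc("ACGUA", PseDncConfig(lam=10, w=0.5))

    def test_unstandardized_table_rejected(self, rng):
        t = PropertyTable(("rise",), np.arange(16)[None, :] * 1.0, standardized=False)
        with pytest.raises(PropertyTableError, match="standardized"):
            encode_psednc(random_window_seq(rng), PseDncConfig(), t)


class TestFusedView:
    def test_concatenation_order_and_prefixes(self, rng):
        fv = encode_physchem(random_window_seq(rng))
        prefixes = [n.split("_")[0] for n in fv.names]
        # CKSNAP, ENAC, Kmer, PseDNC blocks in that order
        seen = []
        for p in prefixes:
            tag = "kmer" if p.startswith("kmer") else p
            if not seen or seen[-1] != tag:
                seen.append(tag)
        assert seen == ["cksnap", "enac", "kmer", "psednc"]
        assert len(fv) == 96 + 148 + (4 + 16 + 64) + 19

    def test_unique_names_enforced(self):
        with pytest.raises(ValueError, match="unique"):
            FeatureVector(["a", "a"], np.zeros(2), "kmer")

    def test_matrix_rows_match_single_encoding(self):
        ws = generate_synthetic(3, 3, seed=5)
        X = encode_matrix(ws)
        fv = encode_physchem(ws[0])
        np.testing.assert_allclose(X.iloc[0].to_numpy(), fv.values)
        assert list(X.columns) == fv.names
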