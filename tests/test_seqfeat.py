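"""Feature encoders: k-mers, autocorrelation, profile aggregation,
physicochemical summaries and secondary-structure composition."""

import numpy as np
import pytest

from melmp.errors import DegenerateInputError, FormatError, InvalidSymbolError
from melmp.seqfeat import (
    AA_ALPHABET,
    RAWKMERS_LENGTH,
    SS_ALPHABET,
    SS_LENGTH,
    AcfParams,
    ProfileMatrix,
    PropertyTable,
    ProteinRecord,
    aa_features,
    acf_transform,
    build_rawkmers,
    count_kmers,
    pssm_aggregate,
    read_ascii_pssm,
    read_property_table,
    seq_features,
    ss_features,
)


def kmer_oracle(seq, k, alphabet):
    """Brute-force sliding-window count over the lexicographic index."""
    from itertools import product

    kmers = ["".join(p) for p in product(alphabet, repeat=k)]
    index = {km: i for i, km in enumerate(kmers)}
    counts = np.zeros(len(kmers), dtype=int)
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if window in index:
            counts[index[window]] += 1
    return counts


class TestCountKmers:
    @pytest.mark.parametrize(
        "seq,k,expected_nonzero",
        [
            ("AAA", 1, {"A": 3}),
            ("ACD", 2, {"AC": 1, "CD": 1}),
            ("ACACA", 2, {"AC": 2, "CA": 2}),
        ],
    )
    def test_hand_counts(self, seq, k, expected_nonzero):
        from itertools import product

        counts = count_kmers(seq, k, AA_ALPHABET)
        kmers = ["".join(p) for p in product(AA_ALPHABET, repeat=k)]
        observed = {km: int(c) for km, c in zip(kmers, counts) if c}
        assert observed == expected_nonzero

    def test_three_mer_vector_has_20_cubed_cells(self):
        assert count_kmers("ACD", 3, AA_ALPHABET).shape == (8000,)

    def test_windows_with_nonstandard_residues_are_skipped(self):
        counts = count_kmers("AXA", 2, AA_ALPHABET)
        assert counts.sum() == 0
        counts = count_kmers("AXAC", 2, AA_ALPHABET)
        assert counts.sum() == 1  # only the AC window is clean

    def test_sequence_shorter_than_k_gives_zero_vector(self):
        assert count_kmers("AC", 3, AA_ALPHABET).sum() == 0

    @pytest.mark.parametrize("bad_call", [
        lambda: count_kmers("ACD", 0, AA_ALPHABET),
        lambda: count_kmers("ACD", 2, ()),
        lambda: count_kmers("", 1, AA_ALPHABET),
    ])
    def test_invalid_arguments_raise(self, bad_call):
        with pytest.raises(ValueError):
            bad_call()

    def test_agrees_with_sliding_window_oracle(self, rng):
        symbols = list(AA_ALPHABET) + ["X"]
        for _ in range(100):
            L = int(rng.integers(1, 51))
            k = int(rng.integers(1, 4))
            seq = "".join(rng.choice(symbols, size=L))
            got = count_kmers(seq, k, AA_ALPHABET)
            np.testing.assert_array_equal(got, kmer_oracle(seq, k, AA_ALPHABET))


class TestRawKmers:
    def test_length_and_block_order(self):
        v = build_rawkmers(ProteinRecord("p", "ACDEF"))
        assert v.shape == (RAWKMERS_LENGTH,)
        # window counts L-k+1 per block for a clean 5-mer
        assert v[:8000].sum() == 3
        assert v[8000:8400].sum() == 4
        assert v[8400:].sum() == 5

    def test_single_residue_sequence(self):
        v = build_rawkmers(ProteinRecord("p", "A"))
        assert v[:8400].sum() == 0
        assert v[8400:].sum() == 1
        assert (v[8400:] > 0).sum() == 1


class TestAcf:
    def acf_oracle(self, x, m):
        """Direct double-loop evaluation of the centered formula."""
        x = np.asarray(x, float)
        n = len(x)
        xb = x.mean()
        denom = np.sum((x - xb) ** 2)
        return np.array(
            [
                sum((x[i] - xb) * (x[i + j] - xb) for i in range(n - j)) / denom
                for j in range(1, m + 1)
            ]
        )

    def test_hand_example(self):
        r = acf_transform(np.array([1.0, 2, 3, 4]), AcfParams(m=2))
        np.testing.assert_allclose(r.values, [0.25, -0.30], atol=1e-12)

    def test_constant_series_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning, match="constant"):
            r = acf_transform(np.full(10, 3.0), AcfParams(m=4))
        assert not r.values.any()

    def test_lag_count_must_be_below_length(self):
        with pytest.raises(ValueError, match="m=5"):
            acf_transform(np.arange(5.0), AcfParams(m=5))

    def test_matches_direct_formula_on_random_series(self, rng):
        for _ in range(20):
            n = int(rng.integers(25, 200))
            m = int(rng.integers(1, 21))
            x = rng.normal(size=n)
            got = acf_transform(x, AcfParams(m=m)).values
            np.testing.assert_allclose(got, self.acf_oracle(x, m), atol=1e-10)

    def test_default_compression_of_rawkmers_is_400(self):
        fv = seq_features(ProteinRecord("p", "ACDEFGHIKLMNPQRSTVWY" * 3))
        assert fv.view == "Seq"
        assert fv.values.shape == (400,)


class TestProfileReader:
    def _roundtrip(self, tmp_path, scores, sequence):
        from melmp.synthgen import write_ascii_pssm

        path = tmp_path / "x.pssm"
        write_ascii_pssm(ProfileMatrix(scores, sequence), path)
        return read_ascii_pssm(path)

    def test_roundtrip_shape_and_values(self, tmp_path, rng):
        seq = "".join(rng.choice(list(AA_ALPHABET), size=30))
        scores = rng.integers(-8, 9, size=(30, 20)).astype(float)
        pm = self._roundtrip(tmp_path, scores, seq)
        assert pm.scores.shape == (30, 20)
        assert pm.sequence == seq
        np.testing.assert_array_equal(pm.scores, scores)

    def test_all_zero_block(self, tmp_path):
        pm = self._roundtrip(tmp_path, np.zeros((5, 20)), "ACDEF")
        assert not pm.scores.any()

    def test_truncated_row_raises_format_error(self, tmp_path):
        from melmp.synthgen import write_ascii_pssm

        path = tmp_path / "x.pssm"
        write_ascii_pssm(ProfileMatrix(np.zeros((5, 20)), "ACDEF"), path)
        lines = path.read_text().splitlines()
        # drop one numeric cell from a data row
        broken = lines[:]
        broken[4] = " ".join(broken[4].split()[:21])
        path.write_text("\n".join(broken))
        with pytest.raises(FormatError, match=":5"):
            read_ascii_pssm(path)

    def test_non_numeric_cell_raises(self, tmp_path):
        from melmp.synthgen import write_ascii_pssm

        path = tmp_path / "x.pssm"
        write_ascii_pssm(ProfileMatrix(np.zeros((3, 20)), "ACD"), path)
        path.write_text(path.read_text().replace("  0 ", "  ? ", 1))
        with pytest.raises(FormatError):
            read_ascii_pssm(path)


class TestProfileAggregation:
    def test_output_length_400(self, rng):
        pm = ProfileMatrix(rng.normal(size=(12, 20)), "ACDEFGHIKLMN")
        assert pssm_aggregate(pm).values.shape == (400,)

    def test_single_position_trace(self, rng):
        v = rng.normal(size=20)
        M = pssm_aggregate(ProfileMatrix(v[None, :], "A")).values.reshape(20, 20)
        a = AA_ALPHABET.index("A")
        np.testing.assert_allclose(M[:, a], v)
        M[:, a] = 0
        assert not M.any()

    def test_all_ones_aac(self):
        M = pssm_aggregate(ProfileMatrix(np.ones((3, 20)), "AAC")).values.reshape(20, 20)
        np.testing.assert_allclose(M[:, AA_ALPHABET.index("A")], 2 / 3)
        np.testing.assert_allclose(M[:, AA_ALPHABET.index("C")], 1 / 3)
        M[:, [AA_ALPHABET.index("A"), AA_ALPHABET.index("C")]] = 0
        assert not M.any()

    def test_conservation_of_unnormalized_total(self, rng):
        """The 400-cell unnormalized sum equals the profile total over
        standard-residue positions."""
        symbols = list(AA_ALPHABET) + ["X", "U"]
        for _ in range(100):
            L = int(rng.integers(1, 40))
            seq = "".join(rng.choice(symbols, size=L))
            scores = rng.normal(size=(L, 20))
            total = pssm_aggregate(
                ProfileMatrix(scores, seq), normalize=False
            ).values.sum()
            standard = [j for j, c in enumerate(seq) if c in AA_ALPHABET]
            np.testing.assert_allclose(total, scores[standard, :].sum(), atol=1e-9)

    def test_row_permutation_invariance_for_constant_sequence(self, rng):
        scores = rng.normal(size=(8, 20))
        seq = "A" * 8
        base = pssm_aggregate(ProfileMatrix(scores, seq)).values
        perm = rng.permutation(8)
        shuffled = pssm_aggregate(ProfileMatrix(scores[perm], seq)).values
        np.testing.assert_allclose(base, shuffled)

    def test_nonstandard_positions_count_in_length_only(self):
        pm = ProfileMatrix(np.ones((4, 20)), "AAXA")
        M = pssm_aggregate(pm).values.reshape(20, 20)
        np.testing.assert_allclose(M[:, AA_ALPHABET.index("A")], 3 / 4)


class TestPropertyTable:
    def test_na_filter(self, tmp_path):
        from melmp.synthgen import SynthConfig, gen_property_table

        path = tmp_path / "aa.txt"
        path.write_text(gen_property_table(P=5, n_missing=1, cfg=SynthConfig()))
        table = read_property_table(path)
        assert table.n_retained == 4
        assert len(table.missing_ids) == 1

    def test_no_missing_values(self, tmp_path):
        from melmp.synthgen import SynthConfig, gen_property_table

        path = tmp_path / "aa.txt"
        path.write_text(gen_property_table(P=3, n_missing=0, cfg=SynthConfig()))
        assert read_property_table(path).n_retained == 3

    def test_malformed_row_names_property(self, tmp_path):
        path = tmp_path / "aa.txt"
        path.write_text(
            "H BADPROP\nD x\nI    A/L R/K N/M D/F C/P Q/S E/T G/W H/Y I/V\n"
            "   1.0 2.0 3.0\n//\n"
        )
        with pytest.raises(FormatError, match="BADPROP"):
            read_property_table(path)


class TestAaFeatures:
    def _single_property_table(self):
        vals = np.zeros(20)
        vals[AA_ALPHABET.index("A")] = 1.0
        vals[AA_ALPHABET.index("C")] = 3.0
        return PropertyTable(properties={"P1": vals})

    def test_mean_and_population_variance(self):
        fv = aa_features(ProteinRecord("p", "AC"), self._single_property_table())
        np.testing.assert_allclose(fv.values, [2.0, 1.0])

    def test_single_residue_has_zero_variance(self):
        fv = aa_features(ProteinRecord("p", "C"), self._single_property_table())
        np.testing.assert_allclose(fv.values, [3.0, 0.0])

    def test_output_length_is_twice_property_count(self, rng):
        table = PropertyTable(
            properties={f"P{i}": rng.normal(size=20) for i in range(7)}
        )
        fv = aa_features(ProteinRecord("p", "ACDEF"), table)
        assert fv.values.shape == (14,)

    def test_nonstandard_residues_dropped(self):
        table = self._single_property_table()
        with_x = aa_features(ProteinRecord("p", "AXC"), table)
        without = aa_features(ProteinRecord("p", "AC"), table)
        np.testing.assert_allclose(with_x.values, without.values)

    def test_all_nonstandard_sequence_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            aa_features(ProteinRecord("p", "XXX"), self._single_property_table())

    def test_variance_zero_iff_series_constant(self, rng):
        table = PropertyTable(properties={"P1": rng.normal(size=20)})
        constant = aa_features(ProteinRecord("p", "AAAA"), table)
        assert constant.values[1] == 0.0
        varying = aa_features(ProteinRecord("p", "ACAC"), table)
        assert varying.values[1] > 0.0


class TestSsFeatures:
    def test_length_584(self):
        assert ss_features("HCET").values.shape == (SS_LENGTH,)

    def test_hhh_hand_count(self):
        from itertools import product

        v = ss_features("HHH").values
        three = ["".join(p) for p in product(SS_ALPHABET, repeat=3)]
        two = ["".join(p) for p in product(SS_ALPHABET, repeat=2)]
        assert v[three.index("HHH")] == 1
        assert v[512 + two.index("HH")] == 2
        assert v[512 + 64 + SS_ALPHABET.index("H")] == 3
        assert v.sum() == 6

    def test_invalid_symbol_raises(self):
        with pytest.raises(InvalidSymbolError, match="Q"):
            ss_features("HHQ")
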