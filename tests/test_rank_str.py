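import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bitrank import (
    Alphabet,
    AlphabetError,
    ConfigError,
    FormatError,
    RangeError,
    RankConfig,
    StringRank,
    encode_text,
    read_fasta,
    read_raw_bytes,
    reconstruct_word,
    storage_bits_string,
)
from bitrank.oracle_fixtures import oracle_rank_text_all, random_text

from conftest import BLOCK_WIDTHS, DEFAULT_SB, SMALL_SB, two_layer_config

DNA = Alphabet.dna()
EXAMPLE = "CAAGTACG"
A, C, G, T = 0, 1, 2, 3


def build_all_kinds(text, alphabet, block, sb=DEFAULT_SB, strategy="mask"):
    out = {}
    for kind in ("mbv", "fbv", "pfbv"):
        cfg = two_layer_config(block, kind == "pfbv", sb, strategy)
        out[kind] = StringRank.build(text, alphabet, kind=kind, config=cfg)
    return out


def set_positions(word, n):
    return [j for j in range(n) if (word >> j) & 1]


class TestAlphabet:
    def test_dna_codes(self):
        assert np.array_equal(DNA.encode("ACGT"), [0, 1, 2, 3])

    def test_code_bits(self):
        assert Alphabet.integer(2).code_bits == 1
        assert Alphabet.integer(4).code_bits == 2
        assert Alphabet.integer(5).code_bits == 3
        assert Alphabet.integer(21).code_bits == 5
        assert Alphabet.integer(255).code_bits == 8
        assert Alphabet.integer(256).code_bits == 8

    def test_invalid(self):
        with pytest.raises(AlphabetError):
            Alphabet.integer(1)
        with pytest.raises(AlphabetError):
            Alphabet.integer(257)
        with pytest.raises(AlphabetError):
            DNA.encode("ACGN")
        with pytest.raises(AlphabetError):
            Alphabet.integer(4).encode(np.array([4], dtype=np.uint8))


class TestEncodeText:
    def test_worked_example_planes(self):
        # b0 marks C and T positions, b1 marks G and T positions
        ft = encode_text(DNA.encode(EXAMPLE), DNA, two_layer_config(64, False))
        assert set_positions(int(ft.planes[0].words[0]), 8) == [0, 4, 6]
        assert set_positions(int(ft.planes[1].words[0]), 8) == [3, 4, 7]

    def test_empty_text(self):
        ft = encode_text(np.zeros(0, dtype=np.uint8), DNA, two_layer_config(64, False))
        assert ft.length == 0
        assert len(ft.planes) == 2
        assert all(len(p) == 0 for p in ft.planes)

    def test_binary_plane_is_identity(self):
        codes = np.array([0, 1, 1, 0, 1], dtype=np.uint8)
        ft = encode_text(codes, Alphabet.integer(2), two_layer_config(64, False))
        assert len(ft.planes) == 1
        assert np.array_equal(ft.planes[0].to_bits()[:5], codes)

    def test_code_out_of_range(self):
        with pytest.raises(AlphabetError):
            encode_text(np.array([4], dtype=np.uint8), DNA, two_layer_config(64, False))

    def test_padded_to_span(self):
        for paired in (False, True):
            cfg = two_layer_config(64, paired)
            ft = encode_text(DNA.encode(EXAMPLE), DNA, cfg)
            assert ft.padded_bits == cfg.span_bits


class TestReconstruct:
    @pytest.fixture
    def example_text(self):
        return encode_text(DNA.encode(EXAMPLE), DNA, two_layer_config(64, False))

    def test_c_positions(self, example_text):
        assert set_positions(reconstruct_word(example_text, C, 0), 64) == [0, 6]

    def test_a_positions(self, example_text):
        assert set_positions(reconstruct_word(example_text, A, 0), 64) == [1, 2, 5]

    def test_padding_never_counts(self, example_text):
        # A has code 00: both planes complemented; padding must stay zero
        assert reconstruct_word(example_text, A, 0) >> 8 == 0
        assert reconstruct_word(example_text, A, 1) == 0

    def test_codes_partition_full_words(self, rng):
        codes = rng.integers(0, 4, size=256).astype(np.uint8)
        ft = encode_text(codes, DNA, two_layer_config(64, False))
        for widx in range(4):
            total = sum(int(reconstruct_word(ft, c, widx)).bit_count() for c in range(4))
            assert total == 64

    def test_bad_code(self, example_text):
        with pytest.raises(AlphabetError):
            reconstruct_word(example_text, 4, 0)


class TestRankString:
    def test_worked_example_all_kinds(self):
        for block in BLOCK_WIDTHS:
            for kind, s in build_all_kinds(EXAMPLE, DNA, block).items():
                assert s.rank(8, C) == 2, kind
                assert s.rank(0, G) == 0
                assert s.rank(1, C) == 1
                assert s.rank(8, G) == 2

    def test_access_round_trip(self):
        codes = DNA.encode(EXAMPLE)
        for kind, s in build_all_kinds(EXAMPLE, DNA, 64).items():
            assert [s.access(i) for i in range(8)] == list(codes), kind
        assert build_all_kinds(EXAMPLE, DNA, 64)["fbv"].access(0) == C
        assert build_all_kinds(EXAMPLE, DNA, 64)["fbv"].access(3) == G

    @pytest.mark.parametrize("sigma", [4, 5, 16, 21, 255])
    def test_random_texts_match_oracle(self, sigma):
        n = 4000
        text = random_text(sigma, n, sigma)
        alpha = Alphabet.integer(sigma)
        i = np.arange(n + 1)
        for block in BLOCK_WIDTHS:
            structures = build_all_kinds(text, alpha, block, SMALL_SB[block])
            for c in range(sigma):
                expected = oracle_rank_text_all(text, c)
                for kind, s in structures.items():
                    assert np.array_equal(s.rank(i, c), expected), (kind, c)

    def test_conservation(self):
        n = 3000
        for sigma in (5, 21):
            text = random_text(sigma + 1, n, sigma)
            for kind, s in build_all_kinds(text, Alphabet.integer(sigma), 64, SMALL_SB[64]).items():
                i = np.arange(n + 1)
                total = sum(s.rank(i, c) for c in range(sigma))
                assert np.array_equal(total, i), kind

    def test_unit_step(self):
        text = random_text(42, 2000, 16)
        s = StringRank.build(text, Alphabet.integer(16), kind="pfbv",
                             config=two_layer_config(64, True, SMALL_SB[64]))
        for c in (0, 7, 15):
            r = s.rank(np.arange(2001), c)
            assert np.array_equal(np.diff(r), (text == c).astype(np.int64))

    def test_strategies_agree(self):
        text = random_text(5, 3000, 5)
        alpha = Alphabet.integer(5)
        for kind in ("fbv", "pfbv", "mbv"):
            cfg_m = two_layer_config(512, kind == "pfbv", SMALL_SB[512], "mask")
            s = StringRank.build(text, alpha, kind=kind, config=cfg_m)
            s_shift = s.with_strategy("shift")
            i = np.arange(3001)
            for c in range(5):
                assert np.array_equal(s.rank(i, c), s_shift.rank(i, c))

    def test_errors(self):
        s = build_all_kinds(EXAMPLE, DNA, 64)["fbv"]
        with pytest.raises(RangeError):
            s.rank(9, C)
        with pytest.raises(AlphabetError):
            s.rank(4, 4)
        with pytest.raises(RangeError):
            s.access(8)

    def test_kind_config_consistency(self):
        with pytest.raises(ConfigError):
            StringRank.build(EXAMPLE, DNA, kind="fbv", config=two_layer_config(64, True))
        with pytest.raises(ConfigError):
            StringRank.build(EXAMPLE, DNA, kind="pfbv", config=two_layer_config(64, False))
        with pytest.raises(ConfigError):
            StringRank.build(EXAMPLE, DNA, kind="mbv",
                             config=RankConfig(block_bits=64, layers=1))

    def test_empty_text(self):
        s = StringRank.build(np.zeros(0, dtype=np.uint8), Alphabet.integer(4), kind="fbv")
        assert s.rank(0, 0) == 0


class TestStorage:
    @pytest.mark.parametrize("kind", ["mbv", "fbv", "pfbv"])
    @pytest.mark.parametrize("n", [10**4, 70001])
    def test_measured_equals_closed_form(self, kind, n):
        sigma = 5
        text = random_text(n, n, sigma)
        cfg = two_layer_config(64, kind == "pfbv")
        s = StringRank.build(text, Alphabet.integer(sigma), kind=kind, config=cfg)
        measured = s.storage_bits()
        analytic = storage_bits_string(kind, cfg, n, sigma)
        assert measured.payload_bits == analytic.payload_bits
        assert measured.l1_bits == analytic.l1_bits
        assert measured.l0_bits == analytic.l0_bits
        assert measured.bits_per_char == analytic.bits_per_char


class TestSerialization:
    @pytest.mark.parametrize("kind", ["mbv", "fbv", "pfbv"])
    def test_roundtrip_bit_exact(self, kind):
        text = random_text(3, 2000, 5)
        cfg = two_layer_config(64, kind == "pfbv", SMALL_SB[64])
        s = StringRank.build(text, Alphabet.integer(5), kind=kind, config=cfg)
        blob = s.to_bytes()
        s2 = StringRank.from_bytes(blob)
        assert s2.to_bytes() == blob
        i = np.arange(2001)
        for c in range(5):
            assert np.array_equal(s2.rank(i, c), s.rank(i, c))

    def test_save_load_with_symbol_alphabet(self, tmp_path):
        s = StringRank.build(EXAMPLE, DNA, kind="fbv")
        p = tmp_path / "s.idx"
        s.save(p)
        s2 = StringRank.load(p)
        assert s2.alphabet.symbols == ("A", "C", "G", "T")
        assert s2.rank(8, C) == 2

    def test_bad_magic(self):
        with pytest.raises(FormatError):
            StringRank.from_bytes(b"NOTANIDX" + b"\x00" * 64)


class TestReaders:
    def test_fasta_dna(self, tmp_path):
        p = tmp_path / "toy.fa"
        p.write_text(">r1\nCAAG\ntacg\n")
        codes, alpha = read_fasta(p)
        assert alpha.symbols == ("A", "C", "G", "T")
        assert np.array_equal(codes, DNA.encode(EXAMPLE))

    def test_fasta_unknown_error_names_char(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">r1\nCANG\n")
        with pytest.raises(AlphabetError, match="'N'"):
            read_fasta(p)

    def test_fasta_unknown_extra(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">r1\nCANG\n")
        codes, alpha = read_fasta(p, unknown="extra")
        assert alpha.sigma == 5
        assert list(codes) == [1, 0, 4, 2]

    def test_fasta_empty(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(FormatError, match="empty input"):
            read_fasta(p)

    def test_raw_bytes_inferred(self, tmp_path):
        p = tmp_path / "raw.bin"
        p.write_bytes(b"\x05\x09\x05\x07")
        codes, alpha = read_raw_bytes(p)
        assert alpha.sigma == 3
        assert list(codes) == [0, 2, 0, 1]

    def test_raw_bytes_sigma_given(self, tmp_path):
        p = tmp_path / "raw.bin"
        p.write_bytes(bytes([0, 3, 1]))
        codes, alpha = read_raw_bytes(p, sigma=4)
        assert list(codes) == [0, 3, 1]
        with pytest.raises(AlphabetError):
            read_raw_bytes(p, sigma=3)


@settings(max_examples=25, deadline=None)
@given(
    n=st.integers(0, 300),
    sigma=st.sampled_from([2, 3, 4, 6]),
    seed=st.integers(0, 2**31),
    kind=st.sampled_from(["mbv", "fbv", "pfbv"]),
)
def test_property_conservation_and_oracle(n, sigma, seed, kind):
    text = random_text(seed, n, sigma)
    cfg = two_layer_config(64, kind == "pfbv", SMALL_SB[64])
    s = StringRank.build(text, Alphabet.integer(sigma), kind=kind, config=cfg)
    i = np.arange(n + 1)
    total = np.zeros(n + 1, dtype=np.int64)
    for c in range(sigma):
        got = s.rank(i, c)
        assert np.array_equal(got, oracle_rank_text_all(text, c))
        total += got
    assert np.array_equal(total, i)
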