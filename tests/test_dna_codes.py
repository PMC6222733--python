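"""Constraint evaluators, codeword-set validation and the stochastic designer."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnacipher import (
    CodeSet,
    Codebook,
    DesignError,
    build_codebook,
    design_code_set,
    gc_content,
    hamming_distance,
    read_codebook_tsv,
    reverse_complement,
    sc_distance,
    ss_distance,
    validate_code_set,
    write_codebook_tsv,
)
from dnacipher.io_synth import load_table2_fixture

words3 = st.text(alphabet="ACGT", min_size=3, max_size=3)
words8 = st.text(alphabet="ACGT", min_size=8, max_size=8)


@pytest.mark.parametrize(
    "u, v, expected",
    [
        ("ACTG", "ACTG", 0),
        ("ATCATGCC", "CTCGATCA", 5),  # first two published codewords
        ("GCCTATCT", "GCGTATCT", 1),  # the worked single-base corruption
        ("AAAA", "TTTT", 4),
    ],
)
def test_hamming_distance_examples(u, v, expected):
    assert hamming_distance(u, v) == expected
    assert hamming_distance(v, u) == expected


def test_hamming_distance_rejects_length_mismatch():
    with pytest.raises(ValueError, match="incomparable"):
        hamming_distance("ACT", "ACTG")


def test_hamming_is_a_metric_on_length3_words():
    """Identity, symmetry and triangle inequality, exhaustively for n=3."""
    words = ["".join(w) for w in itertools.product("ACGT", repeat=3)]
    mat = np.array([[ord(c) for c in w] for w in words])
    d = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
    assert np.array_equal(d, d.T)
    assert np.all(np.diag(d) == 0)
    assert np.all((d == 0) == np.eye(len(words), dtype=bool))
    # d[i,j] <= d[i,k] + d[k,j] for every k
    assert np.all(d[:, None, :] <= d[:, :, None] + d[None, :, :])


@pytest.mark.parametrize(
    "word, expected",
    [("ACTG", "CAGT"), ("AAAA", "TTTT"), ("GCCTATCT", "AGATAGGC")],
)
def test_reverse_complement_examples(word, expected):
    assert reverse_complement(word) == expected


@settings(derandomize=True, max_examples=50)
@given(words8)
def test_reverse_complement_involution_and_gc_preserving(word):
    assert reverse_complement(reverse_complement(word)) == word
    assert gc_content(reverse_complement(word)) == gc_content(word)


@pytest.mark.parametrize(
    "word, expected",
    [("ATCATGCC", 50.0), ("AAAATTTT", 0.0), ("GGGGCCCC", 100.0)],
)
def test_gc_content_examples(word, expected):
    assert gc_content(word) == expected


def test_gc_content_rejects_empty_and_invalid():
    with pytest.raises(ValueError):
        gc_content("")
    with pytest.raises(ValueError):
        gc_content("ACGU")


def test_ss_distance_examples():
    assert ss_distance(0, ["ACTG", "ACTT", "GGGG"]) == 1
    assert ss_distance(0, ["AAAA", "TTTT"]) == 4
    with pytest.raises(ValueError):
        ss_distance(0, ["ACTG"])


def test_sc_distance_examples():
    # reverse_complement("CAGT") == "ACTG", so the SC distance collapses to 0
    assert sc_distance(0, ["ACTG", "CAGT"]) == 0
    assert sc_distance(0, ["AAAA", "CCCC"]) == 4
    with pytest.raises(ValueError):
        sc_distance(0, ["ACTG"])


def test_published_table_passes_combined_constraints():
    """All 50 published octamers: SS >= 3, SC >= 3, GC = 50% each."""
    words = load_table2_fixture()
    report = validate_code_set(words, d=3, gc_target=50.0)
    assert report.passed
    assert all(e.ss >= 3 and e.sc >= 3 and e.gc == 50.0 for e in report.entries)


def test_validate_flags_close_pairs():
    report = validate_code_set(["AAAA", "AAAT"], d=3, gc_target=0.0)
    assert not report.passed
    assert report.entries[0].ss == 1


def test_validate_rejects_singleton_and_mixed_lengths():
    with pytest.raises(ValueError):
        validate_code_set(["ATCG"], d=3)
    with pytest.raises(ValueError):
        validate_code_set(["ATCG", "ATC"], d=1)


def test_design_rejects_infeasible_distance():
    with pytest.raises(ValueError, match="infeasible"):
        design_code_set(n=4, d=5, gc_target=50.0, size_target=4, seed=0)


def test_design_length2_capacity_is_four():
    """The 8 GC-balanced 2-mers split into 4 reverse-complement pairs
    (AC-GT, AG-CT, CA-TG, GA-TC), so SC >= 1 admits at most one word per
    pair: 4 words are reachable, 8 are not."""
    got = design_code_set(n=2, d=1, gc_target=50.0, size_target=4, seed=0)
    assert len(got) == 4
    assert validate_code_set(got, d=1, gc_target=50.0).passed
    with pytest.raises(DesignError) as err:
        design_code_set(n=2, d=1, gc_target=50.0, size_target=8, seed=0)
    assert err.value.best_size == 4


@pytest.mark.parametrize("seed", [0, 7])
def test_designed_sets_certify_and_are_seed_deterministic(seed):
    a = design_code_set(n=8, d=3, gc_target=50.0, size_target=64, seed=seed)
    b = design_code_set(n=8, d=3, gc_target=50.0, size_target=64, seed=seed)
    assert a.words == b.words
    assert len(a) == 64
    assert validate_code_set(a, d=3, gc_target=50.0).passed


def test_design_reaches_full_codebook_size(gen_book):
    assert len(gen_book.words) == 256
    assert gen_book.validate().passed


def test_build_codebook_from_published_table(table2_book):
    """Pixels 0..49 keep the printed assignments; the worked-example word
    sits at pixel 50; the whole book re-certifies at d=3, GC=50%."""
    fixture = load_table2_fixture()
    assert table2_book.words[:50] == fixture
    assert table2_book.word(0) == "ATCATGCC"
    assert table2_book.word(16) == "TACTACCG"
    assert table2_book.word(49) == "CTTGGTTG"
    assert table2_book.word(50) == "GCCTATCT"
    assert table2_book.validate().passed


def test_build_codebook_requires_256_words():
    small = design_code_set(n=8, d=3, gc_target=50.0, size_target=16, seed=0)
    with pytest.raises(ValueError, match="256"):
        build_codebook(small)


def test_build_codebook_random_selection_is_injective_and_seeded():
    big = design_code_set(n=8, d=3, gc_target=50.0, size_target=280, seed=1)
    a = build_codebook(big, selection_seed=11)
    b = build_codebook(big, selection_seed=11)
    assert a.words == b.words
    assert len(set(a.words)) == 256
    assert set(a.words) <= set(big.words)


def test_codebook_tsv_round_trip(tmp_path, table2_book):
    path = tmp_path / "book.tsv"
    write_codebook_tsv(table2_book, path)
    back = read_codebook_tsv(path)
    assert back.words == table2_book.words
    assert back.pixel(table2_book.word(42)) == 42


def test_codebook_reader_rejects_non_bijective_table(tmp_path):
    path = tmp_path / "bad.tsv"
    words = list(load_table2_fixture())
    with open(path, "w") as fh:
        for p in range(256):
            fh.write(f"{p}\t{words[p % 50]}\n")
    with pytest.raises(ValueError):
        read_codebook_tsv(path)


def test_single_mutant_neighbourhoods_are_unambiguous(table2_book):
    """d_min = 3 radius: every single-base mutant of a codeword has that
    codeword as its unique neighbour within Hamming distance 1 (brute force
    over the published 50 words: 50 x 24 mutants x 50 codewords)."""
    words = table2_book.words[:50]
    for w in words:
        for pos in range(8):
            for b in "ACGT":
                if b == w[pos]:
                    continue
                mutant = w[:pos] + b + w[pos + 1 :]
                near = [v for v in words if hamming_distance(mutant, v) <= 1]
                assert near == [w]
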