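"""Cre/loxPsym rearrangement mechanics checked against naive string surgery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scramblekit import (
    LOXPSYM,
    RearrangedGenome,
    ScrambleEvent,
    SyntheticChromosome,
    apply_event,
    build_toy_genome,
    derive_segment_map,
    random_scramble,
)
from scramblekit.sequtils import is_palindromic, revcomp


def surgery_oracle(seq: str, etype: str, a: int, b: int, site_len: int) -> str:
    """Independent string-level statement of the Cre model."""
    if etype == "deletion":
        return seq[:a] + seq[b:]
    if etype == "inversion":
        return seq[: a + site_len] + revcomp(seq[a + site_len : b]) + seq[b:]
    return seq[:b] + seq[a:b] + seq[b:]  # tandem_duplication


def test_default_loxpsym_is_a_34bp_palindrome():
    assert len(LOXPSYM) == 34
    assert is_palindromic(LOXPSYM)


def test_single_segment_has_no_sites():
    chrom = build_toy_genome([500], seed=0)
    assert len(chrom.sequence) == 500
    assert chrom.loxpsym_starts == []
    segmap = derive_segment_map(chrom)
    assert [(s.start, s.end) for s in segmap] == [(0, 500)]


def test_three_segment_layout_and_determinism(small_chrom):
    assert len(small_chrom.sequence) == 668  # 600 + 2 x 34
    assert small_chrom.loxpsym_starts == [100, 334]
    again = build_toy_genome([100, 200, 300], seed=1)
    assert again.sequence == small_chrom.sequence
    assert build_toy_genome([100, 200, 300], seed=2).sequence != small_chrom.sequence


def test_segment_map_tiles_chromosome(small_chrom):
    segmap = derive_segment_map(small_chrom)
    assert [(s.start, s.end) for s in segmap] == [(0, 100), (134, 334), (368, 668)]


def test_segment_lengths_sum_to_chromosome_length():
    lengths = list(np.random.default_rng(3).integers(50, 400, size=10))
    chrom = build_toy_genome(lengths, seed=3)
    segmap = derive_segment_map(chrom)
    assert sum(len(s) for s in segmap) + 9 * 34 == len(chrom.sequence)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        build_toy_genome([])
    with pytest.raises(ValueError):
        build_toy_genome([100, 0, 100])
    with pytest.raises(ValueError):
        build_toy_genome([100, 100], loxpsym="ACGU")


def test_non_palindromic_site_warns():
    with pytest.warns(UserWarning):
        build_toy_genome([60, 60], loxpsym="ATAACTTCGTATAATGTACATTATACGAAGTTAA")


@pytest.mark.parametrize(
    "etype,expected_len",
    [("deletion", 434), ("inversion", 668), ("tandem_duplication", 902)],
)
def test_event_lengths_on_toy(small_chrom, etype, expected_len):
    g = apply_event(small_chrom, ScrambleEvent(etype, small_chrom.id, 100, 334))
    assert len(g.sequence) == expected_len
    assert g.sequence == surgery_oracle(small_chrom.sequence, etype, 100, 334, 34)


def test_deletion_retains_single_loxpsym(small_chrom):
    g = apply_event(small_chrom, ScrambleEvent("deletion", small_chrom.id, 100, 334))
    assert g.loxpsym_starts == [100]
    assert g.sequence[100:134] == LOXPSYM


def test_inversion_provenance_orientation(small_chrom):
    g = apply_event(small_chrom, ScrambleEvent("inversion", small_chrom.id, 100, 334))
    assert [(b.segment, b.orientation) for b in g.blocks] == [
        (0, "+"),
        (1, "-"),
        (2, "+"),
    ]


def test_duplication_provenance_copies(small_chrom):
    g = apply_event(
        small_chrom, ScrambleEvent("tandem_duplication", small_chrom.id, 100, 334)
    )
    segs = [b.segment for b in g.blocks]
    assert segs == [0, 1, 1, 2]
    assert [b.copy for b in g.blocks] == [0, 0, 1, 0]


def test_event_site_validation(small_chrom):
    with pytest.raises(ValueError):
        apply_event(small_chrom, ScrambleEvent("deletion", small_chrom.id, 99, 334))
    with pytest.raises(ValueError):
        ScrambleEvent("deletion", "x", 334, 100)
    with pytest.raises(ValueError):
        ScrambleEvent("translocation", "x", 1, 2)


@given(st.integers(0, 2**31 - 1), st.integers(0, 2), st.data())
def test_random_event_matches_surgery_oracle(seed, type_idx, data):
    etype = ("deletion", "inversion", "tandem_duplication")[type_idx]
    chrom = build_toy_genome([137, 260, 81, 190, 145], seed=seed % 1000)
    starts = chrom.loxpsym_starts
    ia = data.draw(st.integers(0, len(starts) - 2))
    ib = data.draw(st.integers(ia + 1, len(starts) - 1))
    a, b = starts[ia], starts[ib]
    g = apply_event(chrom, ScrambleEvent(etype, chrom.id, a, b))
    assert g.sequence == surgery_oracle(chrom.sequence, etype, a, b, 34)
    # loxPsym bookkeeping: every occurrence is the palindromic site, and the
    # count moves exactly as the Cre model dictates.
    n_before = chrom.sequence.count(LOXPSYM)
    n_inside = chrom.sequence[a:b].count(LOXPSYM)  # includes the site at a
    n_after = g.sequence.count(LOXPSYM)
    if etype == "deletion":
        assert n_after == n_before - n_inside
    elif etype == "inversion":
        assert n_after == n_before
    else:
        assert n_after == n_before + n_inside
    assert len(g.loxpsym_starts) == n_after


def test_scramble_zero_events_is_identity(toy_chrom):
    g = random_scramble(toy_chrom, 0, seed=5)
    assert g.sequence == toy_chrom.sequence
    assert g.truth_events == []


def test_scramble_determinism(toy_chrom):
    g1 = random_scramble(toy_chrom, 5, seed=42)
    g2 = random_scramble(toy_chrom, 5, seed=42)
    assert g1.truth_events == g2.truth_events
    assert g1.sequence == g2.sequence


def test_scramble_needs_two_sites():
    chrom = build_toy_genome([500], seed=0)
    with pytest.raises(ValueError):
        random_scramble(chrom, 1, seed=0)


def test_scramble_type_frequencies_within_three_se(toy_chrom):
    probs = (0.5, 0.3, 0.2)
    counts = {"deletion": 0, "inversion": 0, "tandem_duplication": 0}
    n = 1000
    for i in range(n):
        g = random_scramble(toy_chrom, 1, type_probabilities=probs, seed=i)
        counts[g.truth_events[0].type] += 1
    for p, etype in zip(probs, counts):
        se = np.sqrt(p * (1 - p) / n)
        assert abs(counts[etype] / n - p) <= 3 * se


def test_provenance_reconstruction_after_event_chain(toy_chrom):
    g = random_scramble(toy_chrom, 6, seed=9)
    rebuilt = RearrangedGenome(parent=toy_chrom, blocks=list(g.blocks))
    assert rebuilt.sequence == g.sequence
    for s in g.loxpsym_starts:
        assert g.sequence[s : s + 34] == LOXPSYM
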