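"""Split-read junction detection, clustering, and event typing."""

import random

import pytest

from scramblekit import (
    LOXPSYM,
    PipelineConfig,
    ReferenceIndex,
    ScrambleEvent,
    apply_event,
    call_events_from_pairs,
    classify_events,
    cluster_junctions,
    derive_segment_map,
    locate_junction,
    simulate_read_pairs,
    split_mate,
    split_read_at_loxpsym,
)
from scramblekit.align import DepthProfile
from scramblekit.junctions import Junction, Locus, SplitFragment, SupportedJunction
from scramblekit.reads import ReadPair
from scramblekit.sequtils import random_dna, revcomp

import numpy as np


# ---------------------------------------------------------------- splitting

def test_split_yields_both_flanks():
    rng = np.random.default_rng(0)
    read = random_dna(40, rng) + LOXPSYM + random_dna(26, rng)
    frags = split_read_at_loxpsym(read)
    assert [f.side for f in frags] == ["left", "right"]
    assert [f.flank_length for f in frags] == [40, 26]
    # split correctness: left + site + right reconstructs the window
    assert frags[0].sequence + LOXPSYM + frags[1].sequence == read


def test_split_rejects_short_flank():
    rng = np.random.default_rng(1)
    read = random_dna(80, rng) + LOXPSYM + random_dna(14, rng)
    assert split_read_at_loxpsym(read) == []
    read = random_dna(15, rng) + LOXPSYM + random_dna(15, rng)
    assert len(split_read_at_loxpsym(read)) == 2


def test_split_no_site_no_fragments():
    rng = np.random.default_rng(2)
    assert split_read_at_loxpsym(random_dna(100, rng)) == []


def test_split_tolerates_site_mismatches():
    rng = np.random.default_rng(3)
    site = "GG" + LOXPSYM[2:]
    read = random_dna(20, rng) + site + random_dna(20, rng)
    assert len(split_read_at_loxpsym(read)) == 2
    site3 = "GGG" + LOXPSYM[3:]
    read = random_dna(20, rng) + site3 + random_dna(20, rng)
    assert split_read_at_loxpsym(read) == []


def test_split_site_longer_than_read_rejected():
    with pytest.raises(ValueError):
        split_read_at_loxpsym("ACGT")


# ----------------------------------------------------------------- locating

@pytest.fixture(scope="module")
def toy_setup():
    from scramblekit import build_toy_genome

    chrom = build_toy_genome([1800] * 11, seed=11)
    return chrom, ReferenceIndex({chrom.id: chrom.sequence}), derive_segment_map(chrom)


def junction_read(molecule: str, site_start: int, left=30, right=30) -> tuple[str, str]:
    frag_l = molecule[site_start - left : site_start]
    frag_r = molecule[site_start + 34 : site_start + 34 + right]
    return frag_l, frag_r


def test_deletion_junction_located(toy_setup):
    chrom, index, segmap = toy_setup
    starts = chrom.loxpsym_starts
    g = apply_event(chrom, ScrambleEvent("deletion", chrom.id, starts[2], starts[5]))
    frag_l, frag_r = junction_read(g.sequence, g.loxpsym_starts[2])
    j = locate_junction(
        SplitFragment("r", "left", frag_l), SplitFragment("r", "right", frag_r),
        index, segmap,
    )
    assert j == Junction.make(
        Locus(chrom.id, 2, "tail"), Locus(chrom.id, 6, "head")
    )


def test_wildtype_adjacency_returns_none(toy_setup):
    chrom, index, segmap = toy_setup
    frag_l, frag_r = junction_read(chrom.sequence, chrom.loxpsym_starts[4])
    j = locate_junction(
        SplitFragment("r", "left", frag_l), SplitFragment("r", "right", frag_r),
        index, segmap,
    )
    assert j is None


def test_inversion_junction_has_flipped_orientation(toy_setup):
    chrom, index, segmap = toy_setup
    starts = chrom.loxpsym_starts
    g = apply_event(chrom, ScrambleEvent("inversion", chrom.id, starts[3], starts[6]))
    j = locate_junction(
        *[
            SplitFragment("r", side, frag)
            for side, frag in zip(
                ("left", "right"), junction_read(g.sequence, g.loxpsym_starts[3])
            )
        ],
        index, segmap,
    )
    # seg3.tail joined to seg6.tail: the right flank maps reverse-complemented
    assert j == Junction.make(Locus(chrom.id, 3, "tail"), Locus(chrom.id, 6, "tail"))


def test_unmappable_fragment_yields_no_junction(toy_setup):
    chrom, index, segmap = toy_setup
    rng = np.random.default_rng(5)
    j = locate_junction(
        SplitFragment("r", "left", random_dna(30, rng)),
        SplitFragment("r", "right", chrom.sequence[100:130]),
        index, segmap,
    )
    assert j is None


# ---------------------------------------------------------------- clustering

def test_cluster_support_threshold_boundary():
    j = Junction.make(Locus("c", 2, "tail"), Locus("c", 5, "head"))
    obs5 = [(f"r{i}", j) for i in range(5)]
    out = cluster_junctions(obs5, min_support=5)
    assert len(out) == 1 and out[0].support == 5
    assert cluster_junctions(obs5[:4], min_support=5) == []


def test_cluster_counts_distinct_reads_and_matches_tally():
    rng = random.Random(7)
    j1 = Junction.make(Locus("c", 1, "tail"), Locus("c", 4, "head"))
    j2 = Junction.make(Locus("c", 2, "tail"), Locus("c", 6, "tail"))
    obs = [(f"r{rng.randrange(30)}", rng.choice([j1, j2])) for _ in range(200)]
    out = cluster_junctions(obs, min_support=1)
    tally = {}
    for rid, j in obs:
        tally.setdefault(j, set()).add(rid)
    assert {s.junction: s.support for s in out} == {
        j: len(ids) for j, ids in tally.items()
    }
    # duplicate read ids count once
    dup = [("same", j1)] * 10
    assert cluster_junctions(dup, min_support=5) == []


# -------------------------------------------------------------- classifying

def fake_depth(chrom_id, ratios):
    return DepthProfile(
        segment_mean={(chrom_id, i): r for i, r in enumerate(ratios)},
        chrom_median={chrom_id: 1.0},
    )


def test_classify_deletion_archetype(toy_setup):
    chrom, _, segmap = toy_setup
    # single junction skipping one segment at ~zero depth: minimal deletion
    sj = SupportedJunction(
        Junction.make(Locus(chrom.id, 2, "tail"), Locus(chrom.id, 4, "head")), 8
    )
    ratios = [1.0] * 11
    ratios[3] = 0.02
    calls = classify_events([sj], fake_depth(chrom.id, ratios), segmap)
    assert [(c.type, c.seg_start, c.seg_end) for c in calls] == [("deletion", 3, 3)]


def test_classify_duplication_archetype(toy_setup):
    chrom, _, segmap = toy_setup
    # junction looping seg_k tail back to its own head at doubled depth
    sj = SupportedJunction(
        Junction.make(Locus(chrom.id, 7, "tail"), Locus(chrom.id, 7, "head")), 6
    )
    ratios = [1.0] * 11
    ratios[7] = 2.05
    calls = classify_events([sj], fake_depth(chrom.id, ratios), segmap)
    assert [(c.type, c.seg_start, c.seg_end) for c in calls] == [
        ("tandem_duplication", 7, 7)
    ]


def test_classify_inversion_needs_reciprocal_pair(toy_setup):
    chrom, _, segmap = toy_setup
    tt = SupportedJunction(
        Junction.make(Locus(chrom.id, 2, "tail"), Locus(chrom.id, 5, "tail")), 7
    )
    hh = SupportedJunction(
        Junction.make(Locus(chrom.id, 3, "head"), Locus(chrom.id, 6, "head")), 9
    )
    depth = fake_depth(chrom.id, [1.0] * 11)
    calls = classify_events([tt, hh], depth, segmap)
    assert [(c.type, c.seg_start, c.seg_end, c.support) for c in calls] == [
        ("inversion", 3, 5, 7)
    ]
    # an unpaired flipped junction stays complex
    calls = classify_events([tt], depth, segmap)
    assert [c.type for c in calls] == ["complex"]


def test_classify_depth_contradiction_degrades_to_complex(toy_setup):
    chrom, _, segmap = toy_setup
    sj = SupportedJunction(
        Junction.make(Locus(chrom.id, 2, "tail"), Locus(chrom.id, 4, "head")), 8
    )
    calls = classify_events([sj], fake_depth(chrom.id, [1.0] * 11), segmap)
    assert calls[0].type == "complex"
    assert "depth" in calls[0].notes


def test_classify_missing_depth_noted(toy_setup):
    chrom, _, segmap = toy_setup
    sj = SupportedJunction(
        Junction.make(Locus(chrom.id, 2, "tail"), Locus(chrom.id, 4, "head")), 8
    )
    depth = DepthProfile(segment_mean={}, chrom_median={chrom.id: 1.0})
    calls = classify_events([sj], depth, segmap)
    assert calls[0].type == "complex" and "missing depth" in calls[0].notes


# -------------------------------------------------------------- end to end

def test_pipeline_symmetry_under_mate_swap_and_order(toy_setup, config):
    chrom, _, _ = toy_setup
    starts = chrom.loxpsym_starts
    g = apply_event(chrom, ScrambleEvent("deletion", chrom.id, starts[4], starts[6]))
    pairs = simulate_read_pairs(g.sequence, coverage=30, error_rate=0.001, seed=21)
    calls_a, _ = call_events_from_pairs(chrom, pairs, config)

    swapped = [
        ReadPair(p.id, p.mate2_seq, p.mate1_seq, p.mate2_qual, p.mate1_qual)
        for p in pairs
    ]
    random.Random(1).shuffle(swapped)
    calls_b, _ = call_events_from_pairs(chrom, swapped, config)

    key = lambda c: (c.type, c.seg_start, c.seg_end)
    assert sorted(map(key, calls_a)) == sorted(map(key, calls_b))
    assert [c.support for c in calls_a] == [c.support for c in calls_b]


def test_split_mate_attaches_read_id():
    rng = np.random.default_rng(9)
    read = random_dna(30, rng) + LOXPSYM + random_dna(30, rng)
    frags = split_mate("abc/1", read)
    assert all(f.read_id == "abc/1" for f in frags)
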