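"""Synthetic chromosomes partitioned by loxPsym sites and Cre-mediated rearrangements.

The model mirrors SCRaMbLE in Sc2.0 yeast: a linear chromosome is a series of
segments separated by 34-bp palindromic loxPsym sites.  Cre recombination
between two sites on the same molecule produces one of three primitive events:

* ``deletion``           — the material between the sites is excised; exactly one
                           loxPsym is retained at the junction.
* ``inversion``          — the material between the sites is reverse-complemented
                           in place; both sites are retained (the palindromic
                           site is its own reverse complement).
* ``tandem_duplication`` — a second copy of the inter-site material is inserted
                           at the downstream site, gaining one loxPsym copy.

Events are bookkept at segment resolution (the ``provenance`` block list), so
the emitted sequence can always be reconstructed exactly and ground truth is
available for benchmarking the split-read caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .sequtils import is_dna, is_palindromic, random_dna, revcomp

#: Canonical Sc2.0 loxPsym site: the 13-bp loxP inverted repeats around a
#: symmetric 8-bp spacer, making the whole 34-mer a perfect palindrome so Cre
#: can recombine sites in either orientation.
LOXPSYM = "ATAACTTCGTATAATGTACATTATACGAAGTTAT"

EVENT_TYPES = ("deletion", "inversion", "tandem_duplication")


@dataclass(frozen=True)
class Gene:
    name: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class SyntheticChromosome:
    """A linear chromosome whose loxPsym sites are annotated by start coordinate."""

    id: str
    sequence: str
    loxpsym_starts: list[int]
    genes: list[Gene] = field(default_factory=list)
    loxpsym: str = LOXPSYM

    def __post_init__(self) -> None:
        site_len = len(self.loxpsym)
        if not is_dna(self.loxpsym):
            raise ValueError("loxPsym sequence must be non-empty A/C/G/T")
        if not is_palindromic(self.loxpsym):
            warnings.warn(
                "configured loxPsym site is not a reverse-complement palindrome; "
                "orientation-independent recombination no longer holds",
                stacklevel=2,
            )
        starts = list(self.loxpsym_starts)
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("loxpsym_starts must be strictly increasing")
        if any(b - a < site_len for a, b in zip(starts, starts[1:])):
            raise ValueError("loxPsym sites overlap")
        for s in starts:
            if self.sequence[s : s + site_len] != self.loxpsym:
                raise ValueError(f"sequence at {s} does not match the loxPsym site")
        for g in self.genes:
            if not (0 <= g.start < g.end <= len(self.sequence)):
                raise ValueError(f"gene {g.name} outside chromosome bounds")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_sites(self) -> int:
        return len(self.loxpsym_starts)


@dataclass(frozen=True)
class Segment:
    index: int
    start: int
    end: int  # half-open

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SegmentMap:
    """Ordered inter-loxPsym segments — the coordinate system for all events."""

    chrom_id: str
    segments: list[Segment]

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def __getitem__(self, i: int) -> Segment:
        return self.segments[i]


@dataclass(frozen=True)
class ScrambleEvent:
    """One Cre recombination between the loxPsym sites starting at site_a < site_b.

    Coordinates refer to the molecule the event was applied to (for chains of
    events, the intermediate molecule).  ``segments`` records the parental
    segment indices of the blocks lying between the two sites at application
    time, which is the ground truth the junction caller is benchmarked against.
    """

    type: str
    chrom: str
    site_a: int
    site_b: int
    segments: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if self.site_a >= self.site_b:
            raise ValueError("site_a must be < site_b")


@dataclass(frozen=True)
class Block:
    """Provenance unit: one (possibly reoriented, possibly copied) parental segment."""

    segment: int
    orientation: str  # '+' or '-'
    copy: int = 0


@dataclass
class RearrangedGenome:
    """A rearranged molecule plus the provenance needed to rebuild it exactly."""

    parent: SyntheticChromosome
    blocks: list[Block]
    truth_events: list[ScrambleEvent] = field(default_factory=list)

    @classmethod
    def identity(cls, chrom: SyntheticChromosome) -> "RearrangedGenome":
        n = chrom.n_sites + 1
        return cls(parent=chrom, blocks=[Block(i, "+", 0) for i in range(n)])

    def _segment_seqs(self) -> list[str]:
        segmap = derive_segment_map(self.parent)
        return [self.parent.sequence[s.start : s.end] for s in segmap]

    @property
    def sequence(self) -> str:
        """Concatenate provenance blocks with loxPsym separators (the Cre model)."""
        seqs = self._segment_seqs()
        parts = []
        for b in self.blocks:
            s = seqs[b.segment]
            parts.append(s if b.orientation == "+" else revcomp(s))
        return self.parent.loxpsym.join(parts)

    @property
    def loxpsym_starts(self) -> list[int]:
        """Site start coordinates on the current molecule, from block lengths."""
        seqs = self._segment_seqs()
        site_len = len(self.parent.loxpsym)
        starts, pos = [], 0
        for b in self.blocks[:-1]:
            pos += len(seqs[b.segment])
            starts.append(pos)
            pos += site_len
        return starts

    def __len__(self) -> int:
        seqs = self._segment_seqs()
        site_len = len(self.parent.loxpsym)
        return sum(len(seqs[b.segment]) for b in self.blocks) + site_len * (
            len(self.blocks) - 1
        )


def build_toy_genome(
    segment_lengths: Sequence[int],
    genes: Iterable[tuple[str, int, int, str]] = (),
    loxpsym: str = LOXPSYM,
    seed: int = 0,
    chrom_id: str = "toy_chr",
    gc: float = 0.40,
) -> SyntheticChromosome:
    """Build a random chromosome of L segments separated by L-1 internal loxPsym sites.

    Gene placements are absolute (name, start, end, strand) coordinates on the
    finished chromosome; content is reproducible under ``seed``.
    """
    lengths = list(segment_lengths)
    if not lengths or any(x <= 0 for x in lengths):
        raise ValueError("need at least one segment, all lengths > 0")
    if not is_dna(loxpsym):
        raise ValueError("loxPsym sequence must be non-empty A/C/G/T")
    rng = np.random.default_rng(seed)
    parts, starts, pos = [], [], 0
    for i, n in enumerate(lengths):
        parts.append(random_dna(n, rng, gc=gc))
        pos += n
        if i < len(lengths) - 1:
            starts.append(pos)
            parts.append(loxpsym)
            pos += len(loxpsym)
    gene_objs = [Gene(*g) for g in genes]
    return SyntheticChromosome(
        id=chrom_id,
        sequence="".join(parts),
        loxpsym_starts=starts,
        genes=gene_objs,
        loxpsym=loxpsym,
    )


def derive_segment_map(chrom: SyntheticChromosome) -> SegmentMap:
    """Maximal non-site intervals, in order, tiling the chromosome exactly."""
    site_len = len(chrom.loxpsym)
    bounds = [0]
    for s in chrom.loxpsym_starts:
        bounds.extend([s, s + site_len])
    bounds.append(len(chrom.sequence))
    segs = [
        Segment(i, bounds[2 * i], bounds[2 * i + 1]) for i in range(len(bounds) // 2)
    ]
    return SegmentMap(chrom_id=chrom.id, segments=segs)


def _as_rearranged(genome: SyntheticChromosome | RearrangedGenome) -> RearrangedGenome:
    if isinstance(genome, SyntheticChromosome):
        return RearrangedGenome.identity(genome)
    return genome


def apply_event(
    genome: SyntheticChromosome | RearrangedGenome, event: ScrambleEvent
) -> RearrangedGenome:
    """Apply one Cre recombination between two loxPsym sites of the current molecule.

    Returns a new RearrangedGenome; the input is not modified.  Site
    coordinates must be loxPsym start positions on the *current* molecule.
    """
    g = _as_rearranged(genome)
    starts = g.loxpsym_starts
    try:
        ia = starts.index(event.site_a)
        ib = starts.index(event.site_b)
    except ValueError as exc:
        raise ValueError(
            f"event site is not a loxPsym start on this molecule: {exc}"
        ) from None
    # site i sits between block i and block i+1: the affected blocks are
    # ia+1 .. ib inclusive.
    inner = g.blocks[ia + 1 : ib + 1]
    before = g.blocks[: ia + 1]
    after = g.blocks[ib + 1 :]
    if event.type == "deletion":
        blocks = before + after
    elif event.type == "inversion":
        flipped = [
            Block(b.segment, "-" if b.orientation == "+" else "+", b.copy)
            for b in reversed(inner)
        ]
        blocks = before + flipped + after
    else:  # tandem_duplication
        max_copy: dict[int, int] = {}
        for b in g.blocks:
            max_copy[b.segment] = max(max_copy.get(b.segment, -1), b.copy)
        dup = [Block(b.segment, b.orientation, max_copy[b.segment] + 1) for b in inner]
        blocks = before + inner + dup + after
    truth = replace(event, segments=tuple(b.segment for b in inner))
    return RearrangedGenome(
        parent=g.parent, blocks=blocks, truth_events=g.truth_events + [truth]
    )


def random_scramble(
    genome: SyntheticChromosome | RearrangedGenome,
    n_events: int,
    type_probabilities: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
) -> RearrangedGenome:
    """Apply ``n_events`` sequential events on uniformly chosen valid site pairs.

    ``type_probabilities`` follows the order (deletion, inversion,
    tandem_duplication) and must sum to 1.  Fully reproducible under ``seed``.
    """
    probs = np.asarray(type_probabilities, dtype=float)
    if probs.shape != (3,) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("type_probabilities must be three values summing to 1")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    g = _as_rearranged(genome)
    if n_events > 0 and len(g.loxpsym_starts) < 2:
        raise ValueError("need at least 2 loxPsym sites to recombine")
    rng = np.random.default_rng(seed)
    for _ in range(n_events):
        starts = g.loxpsym_starts
        if len(starts) < 2:
            raise ValueError("molecule ran out of loxPsym sites mid-scramble")
        etype = EVENT_TYPES[rng.choice(3, p=probs)]
        ia, ib = sorted(rng.choice(len(starts), size=2, replace=False))
        g = apply_event(
            g,
            ScrambleEvent(
                type=etype, chrom=g.parent.id, site_a=starts[ia], site_b=starts[ib]
            ),
        )
    return g


def scramble_collection(
    chroms: Sequence[SyntheticChromosome],
    n_events: int,
    type_probabilities: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
) -> list[RearrangedGenome]:
    """Scramble a multi-chromosome genome, confining each event to one chromosome.

    Chromosomes are chosen with probability proportional to their number of
    recombinable site pairs; no interchromosomal events are produced.
    """
    rng = np.random.default_rng(seed)
    genomes = [RearrangedGenome.identity(c) for c in chroms]
    weights = np.array(
        [c.n_sites * (c.n_sites - 1) / 2 for c in chroms], dtype=float
    )
    if n_events > 0 and weights.sum() == 0:
        raise ValueError("no chromosome has 2+ loxPsym sites")
    for _ in range(n_events):
        idx = int(rng.choice(len(chroms), p=weights / weights.sum()))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        genomes[idx] = random_scramble(genomes[idx], 1, type_probabilities, sub_seed)
    return genomes
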