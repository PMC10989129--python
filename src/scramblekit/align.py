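"""Desk-scale ungapped seed-and-extend read mapper plus per-segment depth profiling.

Reads are placed by best Hamming distance over both strands of the reference.
Seeding uses an exact k-mer index; by the pigeonhole principle a placement with
m mismatches is guaranteed to share an exact k-mer with the read only when
ceil((L - m) / (m + 1)) >= k.  Whenever the seeded search cannot certify the
result to the configured mismatch ceiling, the mapper falls back to a full
vectorized scan of every position on both strands, so its output is exactly
the best-Hamming placement set by construction — ties yield status ``multi``
so that repeats (notably the loxPsym site itself) never fake unique evidence.

Depth is a per-base pileup of uniquely mapped reads, averaged per inter-loxPsym
segment and normalized by the chromosome's median segment depth: the copy-ratio
signal that, together with junction orientations, types SCRaMbLE events.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import SegmentMap
from .sequtils import encode, revcomp


@dataclass(frozen=True)
class Placement:
    chrom: str
    start: int
    strand: str  # '+': read matches forward reference; '-': matches reverse complement


@dataclass
class Alignment:
    read_id: str
    chrom: str | None
    start: int | None
    strand: str | None
    mismatches: int | None
    status: str  # unique | multi | unmapped
    length: int
    placements: tuple[Placement, ...] = ()


def _pigeonhole_limit(read_len: int, k: int) -> int:
    """Largest mismatch count m whose placements are guaranteed to be seeded."""
    m = -1
    while (read_len - (m + 1)) // (m + 2) + (1 if (read_len - (m + 1)) % (m + 2) else 0) >= k:
        m += 1
    return m


class ReferenceIndex:
    """Exact k-mer index over one or more reference chromosomes."""

    def __init__(self, sequences: Mapping[str, str], k: int = 21):
        self.k = k
        self.seqs = {c: s.upper() for c, s in sequences.items()}
        self.codes = {c: encode(s) for c, s in self.seqs.items()}
        self.kmers: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in self.seqs.items():
            for i in range(len(seq) - k + 1):
                self.kmers[seq[i : i + k]].append((chrom, i))
        self.kmers = dict(self.kmers)

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}


def scan_all(
    index: ReferenceIndex, seq: str, max_mismatch: int
) -> list[tuple[Placement, int]]:
    """Exhaustive best-Hamming scan: every position x both strands.

    Returns all placements with mismatches <= max_mismatch.
    """
    out: list[tuple[Placement, int]] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        codes = encode(s)
        L = codes.size
        for chrom, ref in index.codes.items():
            if ref.size < L:
                continue
            wins = np.lib.stride_tricks.sliding_window_view(ref, L)
            nm = (wins != codes).sum(axis=1)
            for pos in np.nonzero(nm <= max_mismatch)[0]:
                out.append((Placement(chrom, int(pos), strand), int(nm[pos])))
    return out


def _seed_candidates(index: ReferenceIndex, seq: str) -> set[Placement]:
    k = index.k
    cands: set[Placement] = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for off in range(len(s) - k + 1):
            for chrom, pos in index.kmers.get(s[off : off + k], ()):
                start = pos - off
                if 0 <= start <= len(index.seqs[chrom]) - len(s):
                    cands.add(Placement(chrom, start, strand))
    return cands


def map_sequence(
    index: ReferenceIndex, read_id: str, seq: str, max_mismatch: int = 4
) -> Alignment:
    """Best ungapped placement of one sequence over both strands.

    Deterministic, and provably identical to the exhaustive scan: the seeded
    result is only trusted when the pigeonhole bound certifies completeness.
    """
    L = len(seq)
    if L < index.k:
        hits = scan_all(index, seq, max_mismatch)
    else:
        limit = _pigeonhole_limit(L, index.k)
        enc = {"+": encode(seq), "-": encode(revcomp(seq))}
        hits = []
        best = None
        for p in _seed_candidates(index, seq):
            nm = int(
                np.count_nonzero(
                    index.codes[p.chrom][p.start : p.start + L] != enc[p.strand]
                )
            )
            if nm <= max_mismatch:
                hits.append((p, nm))
                best = nm if best is None else min(best, nm)
        # Completeness: every placement with nm <= limit is seeded.  If the
        # best seeded hit is above the limit (or absent) a better or tying
        # unseeded placement could exist, so re-scan exhaustively.
        if (best is None and limit < max_mismatch) or (best is not None and best > limit):
            hits = scan_all(index, seq, max_mismatch)

    if not hits:
        return Alignment(read_id, None, None, None, None, "unmapped", L)
    best_nm = min(nm for _, nm in hits)
    best_places = sorted(
        {p for p, nm in hits if nm == best_nm},
        key=lambda p: (p.chrom, p.start, p.strand),
    )
    if len(best_places) == 1:
        p = best_places[0]
        return Alignment(
            read_id, p.chrom, p.start, p.strand, best_nm, "unique", L,
            tuple(best_places),
        )
    return Alignment(
        read_id, None, None, None, best_nm, "multi", L, tuple(best_places)
    )


def map_mates(
    index: ReferenceIndex,
    mates: Iterable[tuple[str, str, str]] | Iterable[tuple[str, str]],
    max_mismatch: int = 4,
) -> list[Alignment]:
    """Map (id, sequence[, quality]) records independently."""
    return [map_sequence(index, rec[0], rec[1], max_mismatch) for rec in mates]


def map_reads(index, pairs, max_mismatch: int = 4) -> list[Alignment]:
    """Map every mate of a ReadPair collection (k must not exceed read length)."""
    from .reads import iter_mates

    mates = list(iter_mates(pairs))
    if any(len(seq) < index.k for _, seq, _ in mates):
        raise ValueError("k larger than read length")
    return map_mates(index, mates, max_mismatch)


@dataclass
class DepthProfile:
    """Per-segment mean depth and copy ratio versus the chromosome median."""

    segment_mean: dict[tuple[str, int], float]
    chrom_median: dict[str, float]

    def copy_ratio(self, chrom: str, segment: int) -> float | None:
        mean = self.segment_mean.get((chrom, segment))
        med = self.chrom_median.get(chrom)
        if mean is None or not med:
            return None
        return mean / med

    @property
    def copy_ratios(self) -> dict[tuple[str, int], float]:
        return {
            (c, i): m / self.chrom_median[c]
            for (c, i), m in self.segment_mean.items()
            if self.chrom_median.get(c)
        }


def pileup(
    alignments: Sequence[Alignment], chrom_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Per-base coverage from uniquely mapped reads."""
    cov = {c: np.zeros(n + 1, dtype=np.int64) for c, n in chrom_lengths.items()}
    for a in alignments:
        if a.status != "unique":
            continue
        d = cov[a.chrom]
        d[a.start] += 1
        d[a.start + a.length] -= 1
    return {c: np.cumsum(d[:-1]) for c, d in cov.items()}


def compute_depth(
    alignments: Sequence[Alignment],
    segment_maps: Mapping[str, SegmentMap] | SegmentMap,
    chrom_lengths: Mapping[str, int],
) -> DepthProfile:
    """Segment-mean depth from the unique-read pileup; median taken over segments."""
    if isinstance(segment_maps, SegmentMap):
        segment_maps = {segment_maps.chrom_id: segment_maps}
    if not any(a.status == "unique" for a in alignments):
        raise ValueError("no uniquely mapped reads")
    cov = pileup(alignments, chrom_lengths)
    seg_mean: dict[tuple[str, int], float] = {}
    med: dict[str, float] = {}
    for chrom, segmap in segment_maps.items():
        depths = cov.get(chrom)
        if depths is None:
            continue
        means = []
        for seg in segmap:
            m = float(depths[seg.start : seg.end].mean()) if len(seg) else 0.0
            seg_mean[(chrom, seg.index)] = m
            means.append(m)
        med[chrom] = float(np.median(means)) if means else 0.0
    return DepthProfile(segment_mean=seg_mean, chrom_median=med)


def write_alignment_table(alignments: Sequence[Alignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("read\tchrom\tpos\tstrand\tNM\tstatus\n")
        for a in alignments:
            fh.write(
                f"{a.read_id}\t{a.chrom or '.'}\t"
                f"{a.start if a.start is not None else -1}\t{a.strand or '.'}\t"
                f"{a.mismatches if a.mismatches is not None else -1}\t{a.status}\n"
            )


def write_sam(
    alignments: Sequence[Alignment], chrom_lengths: Mapping[str, int], path
) -> None:
    """Minimal SAM export: ungapped M-only CIGAR, FLAG 0/16 for strand, 4 unmapped."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for c, n in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{c}\tLN:{n}\n")
        for a in alignments:
            if a.status == "unique":
                flag = 0 if a.strand == "+" else 16
                fh.write(
                    f"{a.read_id}\t{flag}\t{a.chrom}\t{a.start + 1}\t60\t"
                    f"{a.length}M\t*\t0\t0\t*\t*\tNM:i:{a.mismatches}\n"
                )
            else:
                fh.write(f"{a.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")
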