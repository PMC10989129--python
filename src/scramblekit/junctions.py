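"""loxPsym split-read junction detection and SCRaMbLE event classification.

Reads that fail contiguous mapping but contain a loxPsym site with at least
``min_flank`` bases on each side are split at the site; the two flanks are
located independently on the reference (both strands).  Each flank end that
abuts the loxPsym is snapped to the nearest inter-loxPsym segment boundary,
giving a junction: the unordered pair of segment ends newly joined across a
site.  Junctions seen in at least ``min_support`` distinct reads are kept and
typed from their end-orientation pattern plus segment copy ratios:

* ``tail(i) ~ head(j), j > i+1`` with the skipped segments depleted   -> deletion
* ``head(i) ~ tail(j), i <= j`` with the spanned segments amplified   -> tandem_duplication
* reciprocal ``tail(a) ~ tail(b)`` + ``head(a+1) ~ head(b+1)`` at
  neutral copy ratio                                                   -> inversion
* any other pattern or failed depth corroboration                      -> complex

``tail`` is the segment end adjacent to the downstream site, ``head`` the end
adjacent to the upstream site; the wild-type adjacency tail(i) ~ head(i+1) is
discarded at locate time.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import DepthProfile, ReferenceIndex, scan_all
from .genome import LOXPSYM, SegmentMap
from .sequtils import encode, is_palindromic, revcomp


@dataclass(frozen=True)
class SplitFragment:
    read_id: str
    side: str  # left | right
    sequence: str

    @property
    def flank_length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Locus:
    """One side of a junction: the segment end abutting the loxPsym site."""

    chrom: str
    segment: int
    end: str  # head (segment start) | tail (segment end)


@dataclass(frozen=True)
class Junction:
    """Canonical (sorted) unordered pair of segment ends joined across a site."""

    locus_a: Locus
    locus_b: Locus

    @classmethod
    def make(cls, x: Locus, y: Locus) -> "Junction":
        a, b = sorted((x, y))
        return cls(a, b)


@dataclass
class SupportedJunction:
    junction: Junction
    support: int
    read_ids: tuple[str, ...] = ()


@dataclass
class Thresholds:
    """Copy-ratio corroboration thresholds for event typing."""

    deletion_max_ratio: float = 0.25
    duplication_min_ratio: float = 1.6
    inversion_ratio_range: tuple[float, float] = (0.75, 1.25)


@dataclass
class EventCall:
    type: str  # deletion | tandem_duplication | inversion | complex
    chrom: str
    seg_start: int | None
    seg_end: int | None
    junctions: list[Junction]
    support: int
    copy_ratios: list[float | None] = field(default_factory=list)
    notes: str = ""


def split_read_at_loxpsym(
    read: str,
    loxpsym: str = LOXPSYM,
    min_flank: int = 15,
    max_site_mismatch: int = 2,
) -> list[SplitFragment]:
    """Split an unmapped read at its best loxPsym occurrence.

    The site is matched with up to ``max_site_mismatch`` substitutions in
    either orientation (for the canonical palindromic site both are the same
    pattern).  Fragments are emitted only when both flanks reach ``min_flank``.
    """
    site_len = len(loxpsym)
    if site_len > len(read):
        raise ValueError("loxPsym sequence longer than read")
    codes = encode(read)
    wins = np.lib.stride_tricks.sliding_window_view(codes, site_len)
    nm = (wins != encode(loxpsym)).sum(axis=1)
    if not is_palindromic(loxpsym):
        nm = np.minimum(nm, (wins != encode(revcomp(loxpsym))).sum(axis=1))
    best = int(nm.min())
    if best > max_site_mismatch:
        return []
    off = int(np.flatnonzero(nm == best)[0])
    left, right = read[:off], read[off + site_len :]
    if len(left) < min_flank or len(right) < min_flank:
        return []
    rid = ""  # caller attaches ids via split_mate
    return [
        SplitFragment(rid, "left", left),
        SplitFragment(rid, "right", right),
    ]


def split_mate(
    read_id: str,
    seq: str,
    loxpsym: str = LOXPSYM,
    min_flank: int = 15,
    max_site_mismatch: int = 2,
) -> list[SplitFragment]:
    frags = split_read_at_loxpsym(seq, loxpsym, min_flank, max_site_mismatch)
    return [SplitFragment(read_id, f.side, f.sequence) for f in frags]


def _snap(coord: int, boundaries: Sequence[tuple[int, int]], tol: int) -> int | None:
    """Return the segment index whose boundary is within tol of coord, else None."""
    best_idx, best_d = None, tol + 1
    for b, idx in boundaries:
        d = abs(coord - b)
        if d < best_d:
            best_idx, best_d = idx, d
    return best_idx


def _unique_placement(index: ReferenceIndex, seq: str, max_mismatch: int):
    hits = scan_all(index, seq, max_mismatch)
    if not hits:
        return None
    best = min(nm for _, nm in hits)
    places = {p for p, nm in hits if nm == best}
    if len(places) != 1:
        return None
    return places.pop()


def locate_junction(
    left: SplitFragment,
    right: SplitFragment,
    index: ReferenceIndex,
    segment_maps: Mapping[str, SegmentMap] | SegmentMap,
    snap_tol: int = 2,
    max_frag_mismatch: int = 1,
) -> Junction | None:
    """Map both flanks, snap to segment boundaries, and form the novel junction.

    Returns None when either flank is unmappable or multi-mapped, when a flank
    end does not abut a segment boundary, or when the two boundaries form the
    reference (wild-type) adjacency.
    """
    if isinstance(segment_maps, SegmentMap):
        segment_maps = {segment_maps.chrom_id: segment_maps}
    heads = {
        c: [(seg.start, seg.index) for seg in sm] for c, sm in segment_maps.items()
    }
    tails = {c: [(seg.end, seg.index) for seg in sm] for c, sm in segment_maps.items()}

    loci: list[Locus] = []
    for frag in (left, right):
        p = _unique_placement(index, frag.sequence, max_frag_mismatch)
        if p is None:
            return None
        n = len(frag.sequence)
        # Which fragment end abuts the loxPsym depends on side and strand:
        # the left fragment's 3' end and the right fragment's 5' end touch the
        # site in read orientation.
        if (frag.side == "left") == (p.strand == "+"):
            idx = _snap(p.start + n, tails[p.chrom], snap_tol)
            end = "tail"
        else:
            idx = _snap(p.start, heads[p.chrom], snap_tol)
            end = "head"
        if idx is None:
            return None
        loci.append(Locus(p.chrom, idx, end))

    a, b = loci
    if a.chrom == b.chrom and {a.end, b.end} == {"head", "tail"}:
        t = a if a.end == "tail" else b
        h = a if a.end == "head" else b
        if h.segment == t.segment + 1:
            return None  # wild-type adjacency
    return Junction.make(a, b)


def cluster_junctions(
    observations: Iterable[tuple[str, Junction]], min_support: int = 5
) -> list[SupportedJunction]:
    """Group identical junctions; support counts distinct read ids."""
    groups: dict[Junction, set[str]] = defaultdict(set)
    for read_id, j in observations:
        groups[j].add(read_id)
    out = [
        SupportedJunction(j, len(ids), tuple(sorted(ids)))
        for j, ids in groups.items()
        if len(ids) >= min_support
    ]
    out.sort(key=lambda s: (s.junction.locus_a, s.junction.locus_b))
    return out


def _ratios(
    depth: DepthProfile, chrom: str, lo: int, hi: int
) -> list[float | None]:
    return [depth.copy_ratio(chrom, i) for i in range(lo, hi + 1)]


def classify_events(
    supported: Sequence[SupportedJunction],
    depth: DepthProfile,
    segment_maps: Mapping[str, SegmentMap] | SegmentMap,
    thresholds: Thresholds | None = None,
) -> list[EventCall]:
    """Type each supported junction (or reciprocal junction pair) from
    orientation pattern plus copy-ratio corroboration."""
    th = thresholds or Thresholds()
    if isinstance(segment_maps, SegmentMap):
        segment_maps = {segment_maps.chrom_id: segment_maps}

    calls: list[EventCall] = []
    tail_tail: list[SupportedJunction] = []
    head_head: list[SupportedJunction] = []

    def corroborated(ratios: list[float | None], ok) -> tuple[bool, str]:
        if any(r is None for r in ratios):
            return False, "missing depth for implicated segments"
        if all(ok(r) for r in ratios):
            return True, ""
        return False, "depth inconsistent with junction orientation"

    for sj in supported:
        a, b = sj.junction.locus_a, sj.junction.locus_b
        if a.chrom != b.chrom:
            calls.append(
                EventCall("complex", a.chrom, None, None, [sj.junction], sj.support,
                          notes="interchromosomal junction")
            )
            continue
        ends = (a.end, b.end)
        if ends == ("tail", "tail"):
            tail_tail.append(sj)
            continue
        if ends == ("head", "head"):
            head_head.append(sj)
            continue
        t = a if a.end == "tail" else b
        h = a if a.end == "head" else b
        if h.segment > t.segment + 1:
            lo, hi = t.segment + 1, h.segment - 1
            ratios = _ratios(depth, a.chrom, lo, hi)
            ok, note = corroborated(ratios, lambda r: r < th.deletion_max_ratio)
            calls.append(
                EventCall(
                    "deletion" if ok else "complex", a.chrom, lo, hi,
                    [sj.junction], sj.support, ratios, note,
                )
            )
        elif h.segment <= t.segment:
            lo, hi = h.segment, t.segment
            ratios = _ratios(depth, a.chrom, lo, hi)
            ok, note = corroborated(ratios, lambda r: r >= th.duplication_min_ratio)
            calls.append(
                EventCall(
                    "tandem_duplication" if ok else "complex", a.chrom, lo, hi,
                    [sj.junction], sj.support, ratios, note,
                )
            )
        else:
            calls.append(
                EventCall("complex", a.chrom, None, None, [sj.junction], sj.support,
                          notes="wild-type-like adjacency")
            )

    rlo, rhi = th.inversion_ratio_range
    used_hh: set[int] = set()
    for sj in tail_tail:
        a, b = sj.junction.locus_a, sj.junction.locus_b
        mate_idx = None
        for i, hh in enumerate(head_head):
            if i in used_hh:
                continue
            ha, hb = hh.junction.locus_a, hh.junction.locus_b
            if ha.chrom == a.chrom and {ha.segment, hb.segment} == {
                a.segment + 1,
                b.segment + 1,
            }:
                mate_idx = i
                break
        if mate_idx is None:
            calls.append(
                EventCall("complex", a.chrom, None, None, [sj.junction], sj.support,
                          notes="unpaired inverted junction")
            )
            continue
        used_hh.add(mate_idx)
        hh = head_head[mate_idx]
        lo, hi = a.segment + 1, b.segment
        ratios = _ratios(depth, a.chrom, lo, hi)
        ok, note = corroborated(ratios, lambda r: rlo <= r <= rhi)
        calls.append(
            EventCall(
                "inversion" if ok else "complex", a.chrom, lo, hi,
                [sj.junction, hh.junction], min(sj.support, hh.support), ratios, note,
            )
        )
    for i, hh in enumerate(head_head):
        if i not in used_hh:
            calls.append(
                EventCall("complex", hh.junction.locus_a.chrom, None, None,
                          [hh.junction], hh.support,
                          notes="unpaired inverted junction")
            )
    calls.sort(key=lambda c: (c.chrom, c.seg_start if c.seg_start is not None else -1))
    return calls
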