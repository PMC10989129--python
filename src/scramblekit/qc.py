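"""Read-pair quality filtering before mapping.

A pair is dropped when either mate fails the quality rule (default: mean Phred
below 10) or, optionally, contains any unknown base.  Removal is pair-level so
downstream files stay properly paired.  The quality rule is configurable
because "Phred-score < 10" filters in the wild differ on whether the score is
the per-read mean, the minimum, or a fraction of low-quality bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .reads import ReadPair


@dataclass
class FilterStats:
    pairs_in: int = 0
    pairs_removed_quality: int = 0
    pairs_removed_n: int = 0

    @property
    def pairs_removed(self) -> int:
        return self.pairs_removed_quality + self.pairs_removed_n

    @property
    def fraction_removed(self) -> float:
        return self.pairs_removed / self.pairs_in if self.pairs_in else 0.0


def _phreds(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(float) - 33.0


def _fails_quality(qual: str, threshold: float, mode: str, low_fraction: float) -> bool:
    q = _phreds(qual)
    if q.size == 0:
        return True
    if mode == "mean":
        return bool(q.mean() < threshold)
    if mode == "min":
        return bool(q.min() < threshold)
    if mode == "fraction_below":
        return bool((q < threshold).mean() > low_fraction)
    raise ValueError(f"unknown quality mode {mode!r}")


def filter_reads(
    pairs: Sequence[ReadPair],
    min_mean_phred: float = 10.0,
    drop_if_any_n: bool = True,
    mode: str = "mean",
    low_fraction: float = 0.5,
) -> tuple[list[ReadPair], FilterStats]:
    """Return surviving pairs (unmodified) plus removal statistics.

    Quality failure is checked first, so a pair failing both rules counts once
    under ``pairs_removed_quality``.
    """
    stats = FilterStats(pairs_in=len(pairs))
    kept: list[ReadPair] = []
    for p in pairs:
        if len(p.mate1_seq) != len(p.mate1_qual) or len(p.mate2_seq) != len(
            p.mate2_qual
        ):
            raise ValueError(f"malformed quality string for pair {p.id}")
        if _fails_quality(p.mate1_qual, min_mean_phred, mode, low_fraction) or (
            _fails_quality(p.mate2_qual, min_mean_phred, mode, low_fraction)
        ):
            stats.pairs_removed_quality += 1
            continue
        if drop_if_any_n and ("N" in p.mate1_seq or "N" in p.mate2_seq):
            stats.pairs_removed_n += 1
            continue
        kept.append(p)
    return kept, stats
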