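"""Paired-end short-read simulation with a Phred-scored substitution error model.

Emulates a PE100 whole-genome sequencing run: fragments are drawn uniformly
from the molecule with truncated-normal insert sizes, mate 1 reads the forward
strand of the fragment's 5' end and mate 2 the reverse complement of its 3'
end.  Base qualities are constant per run and the per-base substitution
probability equals the error rate implied by the emitted Phred value, so the
quality strings are honest.  A ``contaminate_fraction`` knob produces the
low-quality / N-containing reads the QC stage is meant to remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.stats import truncnorm

from .sequtils import encode

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_a] = _b


@dataclass
class ReadPair:
    id: str
    mate1_seq: str
    mate2_seq: str
    mate1_qual: str
    mate2_qual: str
    #: per-mate truth origin: (0-based start on the source molecule, strand)
    truth_origin: tuple[tuple[int, str], tuple[int, str]] | None = None

    def __post_init__(self) -> None:
        if len(self.mate1_seq) != len(self.mate1_qual) or len(self.mate2_seq) != len(
            self.mate2_qual
        ):
            raise ValueError("sequence and quality lengths differ")

    @property
    def mates(self) -> list[tuple[str, str, str]]:
        return [
            (self.id + "/1", self.mate1_seq, self.mate1_qual),
            (self.id + "/2", self.mate2_seq, self.mate2_qual),
        ]


def phred_char(q: int) -> str:
    return chr(q + 33)


def mean_phred(qual: str) -> float:
    if not qual:
        return 0.0
    return float(np.frombuffer(qual.encode("ascii"), dtype=np.uint8).mean()) - 33.0


def simulate_read_pairs(
    genome: str,
    coverage: float = 85.0,
    read_length: int = 100,
    insert_mean: float = 350.0,
    insert_sd: float = 35.0,
    error_rate: float = 0.001,
    seed: int = 0,
    contaminate_fraction: float = 0.0,
    id_prefix: str = "sim",
) -> list[ReadPair]:
    """Simulate ``ceil(coverage * L / (2 * read_length))`` read pairs.

    Insert sizes follow a Normal(insert_mean, insert_sd) truncated to
    [2*read_length, insert_mean + 4*insert_sd]; fragment starts are uniform.
    With ``error_rate`` > 0 every base carries Phred q = round(-10 log10 rate)
    and is substituted with probability 10^(-q/10); ``error_rate`` = 0 emits
    error-free reads at Phred 40.  ``contaminate_fraction`` of pairs have mate 1
    degraded (alternately Phred 8 throughout, or three injected N bases).
    """
    L = len(genome)
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if read_length > insert_mean:
        raise ValueError("read_length must be <= insert_mean")
    hi = insert_mean + 4 * insert_sd
    if L < hi:
        raise ValueError("genome shorter than insert_mean + 4 sd")
    rng = np.random.default_rng(seed)
    n_pairs = math.ceil(coverage * L / (2 * read_length))

    lo = 2 * read_length
    a, b = (lo - insert_mean) / insert_sd, (hi - insert_mean) / insert_sd
    inserts = np.rint(
        truncnorm.rvs(a, b, loc=insert_mean, scale=insert_sd, size=n_pairs,
                      random_state=rng)
    ).astype(np.int64)
    starts = rng.integers(0, L - inserts + 1)

    gcodes = encode(genome)
    offs = np.arange(read_length)
    m1 = gcodes[starts[:, None] + offs]
    ends = starts + inserts
    m2 = _COMPLEMENT[gcodes[ends[:, None] - 1 - offs]]

    if error_rate > 0:
        q = max(2, round(-10 * math.log10(error_rate)))
        p = 10 ** (-q / 10)
        for m in (m1, m2):
            mask = rng.random(m.shape) < p
            shift = rng.integers(1, 4, size=int(mask.sum()))
            idx = (np.searchsorted(_BASES, m[mask]) + shift) % 4
            m[mask] = _BASES[idx]
    else:
        q = 40
    qual = phred_char(q) * read_length

    n_bad = round(contaminate_fraction * n_pairs)
    bad = rng.choice(n_pairs, size=n_bad, replace=False) if n_bad else np.array([], int)

    pairs: list[ReadPair] = []
    low_qual = phred_char(8) * read_length
    bad_set = set(int(i) for i in bad)
    for i in range(n_pairs):
        s1 = m1[i].tobytes().decode("ascii")
        s2 = m2[i].tobytes().decode("ascii")
        q1 = q2 = qual
        if i in bad_set:
            if i % 2 == 0:
                q1 = low_qual
            else:
                pos = rng.choice(read_length, size=3, replace=False)
                chars = np.frombuffer(s1.encode("ascii"), dtype=np.uint8).copy()
                chars[pos] = ord("N")
                s1 = chars.tobytes().decode("ascii")
        pairs.append(
            ReadPair(
                id=f"{id_prefix}_{i}",
                mate1_seq=s1,
                mate2_seq=s2,
                mate1_qual=q1,
                mate2_qual=q2,
                truth_origin=(
                    (int(starts[i]), "+"),
                    (int(ends[i]) - read_length, "-"),
                ),
            )
        )
    return pairs


def iter_mates(pairs: Sequence[ReadPair]) -> Iterator[tuple[str, str, str]]:
    """Flatten pairs into (mate_id, sequence, quality) records."""
    for p in pairs:
        yield from p.mates
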