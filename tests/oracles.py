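"""Independent brute-force oracles used by multiple test modules."""

import numpy as np

from scramblekit.mining import _STOPS
from scramblekit.sequtils import revcomp


def oracle_scan(ref: dict, seq: str, max_mm: int):
    """Exhaustive best-Hamming scan: all positions x both strands."""
    hits = []
    for strand, q in (("+", seq), ("-", revcomp(seq))):
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        for chrom, s in ref.items():
            sa = np.frombuffer(s.encode(), dtype=np.uint8)
            if sa.size < qa.size:
                continue
            wins = np.lib.stride_tricks.sliding_window_view(sa, qa.size)
            nm = (wins != qa).sum(axis=1)
            for pos in np.flatnonzero(nm <= max_mm):
                hits.append(((chrom, int(pos), strand), int(nm[pos])))
    if not hits:
        return "unmapped", None, frozenset()
    best = min(nm for _, nm in hits)
    places = frozenset(p for p, nm in hits if nm == best)
    status = "unique" if len(places) == 1 else "multi"
    return status, best, places


def orf_oracle(seq: str, both: bool = True):
    """Exhaustive enumeration of every ATG..stop span in all frames.

    Returns (strand, forward_start, forward_end) of the longest complete ORF
    with the forward-strand-first / smallest-start tie-break, or None.
    """
    n = len(seq)
    best = None
    for rank, strand in enumerate(("+", "-") if both else ("+",)):
        s = seq if strand == "+" else revcomp(seq)
        for i in range(n - 2):
            if s[i : i + 3] != "ATG":
                continue
            j = i + 3
            while j + 3 <= n:
                if s[j : j + 3] in _STOPS:
                    end = j + 3
                    fstart = i if strand == "+" else n - end
                    fend = end if strand == "+" else n - i
                    cand = (-(end - i), rank, fstart, (strand, fstart, fend))
                    if best is None or cand[:3] < best[:3]:
                        best = cand
                    break
                j += 3
    return None if best is None else best[3]
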