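"""Pairwise p-distances from a protein alignment and neighbor-joining trees.

The distance step consumes an existing multiple alignment (equal-length
sequences); alignment itself is out of scope.  Distances are p-distances with
pairwise deletion — the proportion of differing residues over columns ungapped
in both sequences — optionally Poisson-corrected (d = -ln(1 - p)).

The tree step is the classical Saitou-Nei neighbor-joining algorithm:
iteratively join the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j, assign
branch lengths by the two-point formulas, reduce the matrix, and close with
the 3-taxon (or 2-taxon) star.  Ties break lexicographically on taxon labels
(internal nodes inherit the smallest leaf label of their clade) so the output
is deterministic.  Negative branch lengths, a known NJ artifact, are reported
as computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

GAP_CHARS = set("-.")


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal
    comparable: np.ndarray | None = None  # per-pair comparable column counts

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        if (m < 0).any():
            raise ValueError("distances must be >= 0")
        self.matrix = m


@dataclass
class PhyloTree:
    """Unrooted tree as a Newick string with branch lengths."""

    newick: str
    labels: list[str]


def read_alignment(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def p_distance_matrix(
    alignment: Sequence[tuple[str, str]] | Mapping[str, str],
    model: str = "p",
) -> DistanceMatrix:
    """Pairwise-deletion p-distances (or Poisson-corrected) from an alignment."""
    if isinstance(alignment, Mapping):
        records = list(alignment.items())
    else:
        records = list(alignment)
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    labels = [r[0] for r in records]
    seqs = [r[1].upper() for r in records]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    arr = np.array([list(s) for s in seqs])
    gap = np.isin(arr, list(GAP_CHARS))
    n = len(seqs)
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            c = int(ok.sum())
            if c == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]} and {labels[j]}"
                )
            p = float((arr[i][ok] != arr[j][ok]).sum()) / c
            if model == "p":
                dist = p
            elif model == "poisson":
                if p >= 1:
                    raise ValueError("Poisson correction undefined at p >= 1")
                dist = -math.log(1 - p)
            else:
                raise ValueError(f"unknown distance model {model!r}")
            d[i, j] = d[j, i] = dist
            comp[i, j] = comp[j, i] = c
    return DistanceMatrix(labels=labels, matrix=d, comparable=comp)


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Classical Saitou-Nei neighbor joining with deterministic tie-breaking."""
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        half = dm.matrix[0, 1] / 2
        a, b = dm.labels
        return PhyloTree(f"({a}:{_fmt(half)},{b}:{_fmt(half)});", list(dm.labels))

    # active nodes: (tie-break key, newick fragment)
    keys = list(dm.labels)
    nwk = list(dm.labels)
    D = dm.matrix.astype(float).copy()

    while len(keys) > 3:
        m = len(keys)
        r = D.sum(axis=1)
        best = None  # (Q, sorted key pair, i, j)
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, f, g = best
        lf = 0.5 * D[f, g] + (r[f] - r[g]) / (2 * (m - 2))
        lg = D[f, g] - lf
        new_nwk = f"({nwk[f]}:{_fmt(lf)},{nwk[g]}:{_fmt(lg)})"
        new_key = min(keys[f], keys[g])
        du = 0.5 * (D[f, :] + D[g, :] - D[f, g])
        keep = [x for x in range(m) if x not in (f, g)]
        newD = np.zeros((len(keep) + 1, len(keep) + 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = du[keep]
        D = newD
        keys = [keys[x] for x in keep] + [new_key]
        nwk = [nwk[x] for x in keep] + [new_nwk]

    if len(keys) == 3:
        la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
        lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
        lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
        newick = (
            f"({nwk[0]}:{_fmt(la)},{nwk[1]}:{_fmt(lb)},{nwk[2]}:{_fmt(lc)});"
        )
    else:  # exactly 2 active nodes remain (n was even... defensive)
        newick = f"({nwk[0]}:{_fmt(D[0, 1] / 2)},{nwk[1]}:{_fmt(D[0, 1] / 2)});"
    return PhyloTree(newick, list(dm.labels))


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(dm.labels) + "\n")
        for i, lab in enumerate(dm.labels):
            fh.write(lab + "\t" + "\t".join(f"{x:.6g}" for x in dm.matrix[i]) + "\n")
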