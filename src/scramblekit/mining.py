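"""Homolog-mining filter chain and protein-engineering sequence operations.

The mining workflow consumes a BLAST-style tabular hit file (outfmt-6 columns
plus a subject nucleotide sequence and a source-family column), applies the
strict screening thresholds (bit score > 1000, percent identity > 75,
alignment length > 1000) together with a taxon-family whitelist of
MIA-producing plants, and extracts the longest open reading frame from each
surviving subject sequence.  Two small protein-engineering helpers implement
the N-terminal chimera swap between cytochrome P450 homologs and the
truncation of plastid-targeting sequences at the conserved RR motif used for
geraniol synthases.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .sequtils import revcomp

#: Plant families rich in monoterpenoid indole alkaloids; the default
#: taxonomic whitelist for G8H candidate hits.
MIA_FAMILIES = ("Apocynaceae", "Rubiaceae", "Gentianaceae", "Loganiaceae")

#: BLAST outfmt-6 dialect with two extra columns.
HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "sseq", "family",
]

_STOPS = {"TAA", "TAG", "TGA"}


def read_hits_table(path) -> pd.DataFrame:
    """Read a tab-separated hits file (header optional, outfmt-6 + sseq + family)."""
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    has_header = str(first.iloc[0, 0]) == "qseqid"
    if has_header:
        return pd.read_csv(path, sep="\t")
    return pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)


def filter_hits(
    hits: pd.DataFrame,
    min_bit_score: float = 1000.0,
    min_identity: float = 75.0,
    min_alignment_length: int = 1000,
    family_whitelist: tuple[str, ...] | None = MIA_FAMILIES,
) -> pd.DataFrame:
    """Strictly-greater-than screening of homolog hits (order-preserving).

    A row passes iff bitscore > min_bit_score AND pident > min_identity AND
    length > min_alignment_length AND, when a whitelist is given, its family
    matches case-insensitively.
    """
    required = {"bitscore", "pident", "length"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    mask = (
        (hits["bitscore"] > min_bit_score)
        & (hits["pident"] > min_identity)
        & (hits["length"] > min_alignment_length)
    )
    if family_whitelist:
        if "family" not in hits.columns:
            raise ValueError("hit table missing columns: ['family']")
        allowed = {f.lower() for f in family_whitelist}
        mask &= hits["family"].str.lower().isin(allowed)
    return hits[mask]


@dataclass(frozen=True)
class OrfRecord:
    strand: str  # '+' or '-'
    frame: int  # 0, 1, 2 offset within the scanned strand
    start: int  # 0-based on the input (forward) sequence, half-open
    end: int
    protein: str

    def __len__(self) -> int:
        return self.end - self.start


def _scan_strand(seq: str) -> list[tuple[int, int, int]]:
    """All maximal ATG..stop spans on one strand: (start, end, frame).

    Within a frame, only the longest ORF per stop codon is kept (the earliest
    open ATG), which is sufficient to find the global maximum.
    """
    n = len(seq)
    spans = []
    for frame in range(3):
        open_start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in _STOPS:
                if open_start is not None:
                    spans.append((open_start, i + 3, frame))
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = i
    return spans


def longest_orf(sequence: str, search_both_strands: bool = True) -> OrfRecord | None:
    """Longest complete ATG..stop open reading frame over all frames.

    Codons containing N translate to X and can be neither start nor stop.
    Ties break to the forward strand first, then to the smallest start on the
    input sequence.  Returns None when no complete ORF exists.
    """
    seq = sequence.upper()
    n = len(seq)
    candidates: list[tuple[int, int, int, OrfRecord]] = []
    for strand in ("+", "-") if search_both_strands else ("+",):
        s = seq if strand == "+" else revcomp(seq)
        for start, end, frame in _scan_strand(s):
            if strand == "+":
                fstart, fend = start, end
            else:
                fstart, fend = n - end, n - start
            protein = str(Seq(s[start : end - 3]).translate())
            rec = OrfRecord(strand, frame, fstart, fend, protein)
            candidates.append((-(end - start), 0 if strand == "+" else 1, fstart, rec))
    if not candidates:
        return None
    candidates.sort(key=lambda t: t[:3])
    return candidates[0][3]


def make_chimera(
    donor_protein: str, acceptor_protein: str, n_terminal_length: int = 29
) -> str:
    """Graft the donor's first n residues onto the acceptor's remainder.

    Residue numbering is 1-based inclusive: result = donor[1..n] +
    acceptor[n+1..end], so the product has the acceptor's length.
    """
    n = n_terminal_length
    if n < 0:
        raise ValueError("n_terminal_length must be >= 0")
    if n >= len(donor_protein) or n >= len(acceptor_protein):
        raise ValueError("n_terminal_length must be shorter than both proteins")
    return donor_protein[:n] + acceptor_protein[n:]


def truncate_at_rr(protein: str) -> str:
    """Remove the plastid-targeting stretch before the first RR dipeptide.

    Keeps the initial methionine: residues 2..(p-1) are removed where p is the
    1-based position of the first R of the first RR motif.
    """
    if not protein.startswith("M"):
        raise ValueError("protein must start with M")
    pos = protein.find("RR")
    if pos < 0:
        raise ValueError("no RR motif found")
    return "M" + protein[pos:]
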