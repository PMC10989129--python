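"""File formats: FASTA/FASTQ via Biopython, BED and TSV sidecars."""

from __future__ import annotations

from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Gene, ScrambleEvent, SyntheticChromosome
from .reads import ReadPair


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_sites_bed(chrom: SyntheticChromosome, path) -> None:
    """loxPsym sites as 0-based half-open BED intervals."""
    L = len(chrom.loxpsym)
    with open(path, "w") as fh:
        for i, s in enumerate(chrom.loxpsym_starts):
            fh.write(f"{chrom.id}\t{s}\t{s + L}\tloxPsym_{i}\n")


def read_sites_bed(path) -> dict[str, list[int]]:
    sites: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, *_ = line.split("\t")
            sites.setdefault(chrom, []).append(int(start))
    for v in sites.values():
        v.sort()
    return sites


def write_genes_bed(chrom: SyntheticChromosome, path) -> None:
    with open(path, "w") as fh:
        for g in chrom.genes:
            fh.write(f"{chrom.id}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")


def read_genes_bed(path) -> list[tuple[str, Gene]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], Gene(f[3], int(f[1]), int(f[2]), f[5] if len(f) > 5 else "+")))
    return out


def write_events_tsv(events: Sequence[ScrambleEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\ttype\tsite_a\tsite_b\tsegments\n")
        for e in events:
            segs = ",".join(map(str, e.segments))
            fh.write(f"{e.chrom}\t{e.type}\t{e.site_a}\t{e.site_b}\t{segs}\n")


def write_fastq_pairs(pairs: Sequence[ReadPair], path1, path2) -> None:
    def rec(rid, seq, qual):
        r = SeqRecord(Seq(seq), id=rid, description="")
        r.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        return r

    SeqIO.write(
        (rec(p.id + "/1", p.mate1_seq, p.mate1_qual) for p in pairs), str(path1), "fastq"
    )
    SeqIO.write(
        (rec(p.id + "/2", p.mate2_seq, p.mate2_qual) for p in pairs), str(path2), "fastq"
    )


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    def strip_mate(rid: str) -> str:
        return rid[:-2] if rid.endswith(("/1", "/2")) else rid

    recs1 = list(SeqIO.parse(str(path1), "fastq"))
    recs2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(recs1) != len(recs2):
        raise ValueError("FASTQ mate files have different read counts")
    pairs = []
    for r1, r2 in zip(recs1, recs2):
        if strip_mate(r1.id) != strip_mate(r2.id):
            raise ValueError(f"mate id mismatch: {r1.id} vs {r2.id}")
        pairs.append(
            ReadPair(
                id=strip_mate(r1.id),
                mate1_seq=str(r1.seq).upper(),
                mate2_seq=str(r2.seq).upper(),
                mate1_qual="".join(
                    chr(q + 33) for q in r1.letter_annotations["phred_quality"]
                ),
                mate2_qual="".join(
                    chr(q + 33) for q in r2.letter_annotations["phred_quality"]
                ),
            )
        )
    return pairs


def write_truth_origins_tsv(pairs: Sequence[ReadPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("read\tmate1_start\tmate1_strand\tmate2_start\tmate2_strand\n")
        for p in pairs:
            if p.truth_origin is None:
                continue
            (s1, st1), (s2, st2) = p.truth_origin
            fh.write(f"{p.id}\t{s1}\t{st1}\t{s2}\t{st2}\n")
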