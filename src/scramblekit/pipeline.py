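"""End-to-end orchestration: simulate -> sequence -> QC -> map -> call.

One configuration object carries every stage parameter with defaults matching
the published thresholds (min flank 15 bp, min support 5 reads, Phred 10 QC,
mining triple 1000/75/1000, screening fold 1.5).  A single master seed derives
independent per-stage seeds so an entire run is reproducible from one integer.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import io as skio
from .align import ReferenceIndex, compute_depth, map_reads
from .genome import (
    LOXPSYM,
    RearrangedGenome,
    ScrambleEvent,
    SyntheticChromosome,
    apply_event,
    build_toy_genome,
    derive_segment_map,
    random_scramble,
)
from .junctions import (
    EventCall,
    Thresholds,
    classify_events,
    cluster_junctions,
    locate_junction,
    split_mate,
)
from .qc import filter_reads
from .reads import simulate_read_pairs

log = logging.getLogger("scramblekit")


@dataclass
class PipelineConfig:
    # genome simulation
    segment_lengths: list[int] = field(default_factory=lambda: [1800] * 11)
    loxpsym: str = LOXPSYM
    n_events: int = 1
    type_probabilities: list[float] = field(default_factory=lambda: [1 / 3, 1 / 3, 1 / 3])
    # sequencing
    coverage: float = 30.0
    read_length: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 35.0
    error_rate: float = 0.001
    contaminate_fraction: float = 0.0
    # QC
    min_mean_phred: float = 10.0
    drop_if_any_n: bool = True
    quality_mode: str = "mean"
    # mapping
    k: int = 21
    max_mismatch: int = 4
    # junction calling
    min_flank: int = 15
    max_site_mismatch: int = 2
    min_support: int = 5
    snap_tol: int = 2
    max_frag_mismatch: int = 1
    deletion_max_ratio: float = 0.25
    duplication_min_ratio: float = 1.6
    inversion_ratio_low: float = 0.75
    inversion_ratio_high: float = 1.25
    # screening / mining defaults (used by their subcommands)
    fold_threshold: float = 1.5
    min_bit_score: float = 1000.0
    min_identity: float = 75.0
    min_alignment_length: int = 1000
    # reproducibility
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def thresholds(self) -> Thresholds:
        return Thresholds(
            deletion_max_ratio=self.deletion_max_ratio,
            duplication_min_ratio=self.duplication_min_ratio,
            inversion_ratio_range=(self.inversion_ratio_low, self.inversion_ratio_high),
        )


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    h = np.random.SeedSequence([master, sum(ord(c) for c in stage) + len(stage) * 131])
    return int(h.generate_state(1)[0] % 2**31)


def call_events_from_pairs(
    chrom: SyntheticChromosome, pairs, config: PipelineConfig
) -> tuple[list[EventCall], dict]:
    """QC, map, depth-profile, split unmapped mates, cluster and classify."""
    kept, stats = filter_reads(
        pairs,
        min_mean_phred=config.min_mean_phred,
        drop_if_any_n=config.drop_if_any_n,
        mode=config.quality_mode,
    )
    index = ReferenceIndex({chrom.id: chrom.sequence}, k=config.k)
    alignments = map_reads(index, kept, max_mismatch=config.max_mismatch)
    segmap = derive_segment_map(chrom)
    depth = compute_depth(alignments, segmap, index.chrom_lengths())

    kept_seqs = {}
    for p in kept:
        kept_seqs[p.id + "/1"] = p.mate1_seq
        kept_seqs[p.id + "/2"] = p.mate2_seq
    observations = []
    n_split = n_located = 0
    for a in alignments:
        if a.status != "unmapped":
            continue
        frags = split_mate(
            a.read_id,
            kept_seqs[a.read_id],
            loxpsym=chrom.loxpsym,
            min_flank=config.min_flank,
            max_site_mismatch=config.max_site_mismatch,
        )
        if not frags:
            continue
        n_split += 1
        j = locate_junction(
            frags[0],
            frags[1],
            index,
            segmap,
            snap_tol=config.snap_tol,
            max_frag_mismatch=config.max_frag_mismatch,
        )
        if j is not None:
            n_located += 1
            observations.append((a.read_id, j))
    supported = cluster_junctions(observations, min_support=config.min_support)
    calls = classify_events(supported, depth, segmap, config.thresholds())
    diagnostics = {
        "pairs_in": stats.pairs_in,
        "pairs_removed": stats.pairs_removed,
        "fraction_removed": stats.fraction_removed,
        "unmapped_mates": sum(a.status == "unmapped" for a in alignments),
        "split_reads": n_split,
        "junction_observations": n_located,
        "supported_junctions": len(supported),
        "depth": depth,
    }
    return calls, diagnostics


def truth_spans(genome: RearrangedGenome) -> list[tuple[str, tuple[int, ...]]]:
    """(event type, parental segment indices) for each ground-truth event."""
    return [(e.type, e.segments) for e in genome.truth_events]


def match_calls(
    truth: list[tuple[str, tuple[int, ...]]], calls: list[EventCall]
) -> dict:
    """Exact (type, segment span) matching; precision/recall over events."""
    called = [
        (c.type, tuple(range(c.seg_start, c.seg_end + 1)))
        for c in calls
        if c.seg_start is not None
    ]
    truth_left = list(truth)
    tp = 0
    for c in called:
        if c in truth_left:
            truth_left.remove(c)
            tp += 1
    precision = tp / len(called) if called else (1.0 if not truth else 0.0)
    recall = tp / len(truth) if truth else 1.0
    return {
        "n_truth": len(truth),
        "n_called": len(calls),
        "n_typed_called": len(called),
        "true_positives": tp,
        "precision": precision,
        "recall": recall,
    }


def write_calls_tsv(calls: list[EventCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\ttype\tseg_start\tseg_end\tjunctionA\tjunctionB\t"
            "orientations\tsupport\tmean_copy_ratio\tnotes\n"
        )
        for c in calls:
            ja = c.junctions[0] if c.junctions else None
            jb = c.junctions[1] if len(c.junctions) > 1 else None

            def jstr(j):
                if j is None:
                    return "."
                return (
                    f"{j.locus_a.chrom}:seg{j.locus_a.segment}.{j.locus_a.end}"
                    f"-{j.locus_b.chrom}:seg{j.locus_b.segment}.{j.locus_b.end}"
                )

            ori = ";".join(
                f"{j.locus_a.end}/{j.locus_b.end}" for j in c.junctions
            )
            ratios = [r for r in c.copy_ratios if r is not None]
            mean_ratio = f"{np.mean(ratios):.3f}" if ratios else "."
            fh.write(
                f"{c.chrom}\t{c.type}\t"
                f"{c.seg_start if c.seg_start is not None else '.'}\t"
                f"{c.seg_end if c.seg_end is not None else '.'}\t"
                f"{jstr(ja)}\t{jstr(jb)}\t{ori}\t{c.support}\t{mean_ratio}\t"
                f"{c.notes or '.'}\n"
            )


def run_end_to_end(config: PipelineConfig, outdir) -> dict:
    """Full demo workflow on a seeded toy genome; writes standard-format files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, force=False)
    config.to_yaml(out / "config.yaml")

    stage = "simulate-genome"
    try:
        chrom = build_toy_genome(
            config.segment_lengths,
            loxpsym=config.loxpsym,
            seed=derive_seed(config.seed, stage),
        )
        skio.write_fasta({chrom.id: chrom.sequence}, out / "reference.fa")
        skio.write_sites_bed(chrom, out / "sites.bed")

        stage = "scramble"
        scrambled = random_scramble(
            chrom,
            config.n_events,
            config.type_probabilities,
            seed=derive_seed(config.seed, stage),
        )
        skio.write_fasta({chrom.id + "_scrambled": scrambled.sequence}, out / "scrambled.fa")
        skio.write_events_tsv(scrambled.truth_events, out / "truth_events.tsv")

        stage = "simulate-reads"
        pairs = simulate_read_pairs(
            scrambled.sequence,
            coverage=config.coverage,
            read_length=config.read_length,
            insert_mean=config.insert_mean,
            insert_sd=config.insert_sd,
            error_rate=config.error_rate,
            seed=derive_seed(config.seed, stage),
            contaminate_fraction=config.contaminate_fraction,
        )
        skio.write_fastq_pairs(pairs, out / "reads_1.fq", out / "reads_2.fq")

        stage = "call-events"
        calls, diagnostics = call_events_from_pairs(chrom, pairs, config)
        write_calls_tsv(calls, out / "events.tsv")

        stage = "report"
        truth = truth_spans(scrambled)
        summary = match_calls(truth, calls)
        summary.update(
            {k: v for k, v in diagnostics.items() if k != "depth"}
        )
        report = out / "report.txt"
        with open(report, "w") as fh:
            fh.write("SCRaMbLE demo pipeline report\n")
            fh.write(f"genome: {len(chrom.sequence)} bp, {chrom.n_sites} loxPsym sites\n")
            fh.write(f"truth events: {truth}\n")
            fh.write(
                "calls: "
                + str([(c.type, c.seg_start, c.seg_end, c.support) for c in calls])
                + "\n"
            )
            for k, v in summary.items():
                fh.write(f"{k}: {v}\n")
        log.info("pipeline finished: %s", summary)
        return summary
    except Exception:
        log.error("pipeline failed at stage %r (outputs under %s)", stage, out)
        raise
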