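# Methods

## The rearrangement model

A synthetic chromosome is modeled as L segments separated by L−1 internal
copies of the 34-bp loxPsym site (default
`ATAACTTCGTATAATGTACATTATACGAAGTTAT`: the 13-bp loxP inverted repeats around
the symmetric 8-bp spacer `ATGTACAT`, a perfect reverse-complement palindrome;
the site is configurable and the model warns if a configured site is not
palindromic, since orientation-independent recombination then no longer
holds). Cre recombination between the sites starting at `a < b` on one linear
molecule is implemented at segment (block) resolution:

* **deletion** removes `[a, b)`, retaining exactly one loxPsym at the
  junction — length change −(b−a);
* **inversion** reverse-complements the material between the two sites, both
  sites retained — length unchanged (the palindromic site makes the junction
  sequence well defined without moving either site);
* **tandem duplication** inserts a second copy of `[a, b)` at `b` — length
  change +(b−a), gaining one loxPsym copy per site in the copied interval.

Because events are bookkept as an ordered list of (segment, orientation,
copy) blocks joined by single loxPsym separators, the emitted sequence is
reconstructable byte-for-byte and every simulation carries exact ground truth
(`ScrambleEvent.segments` records the parental segment indices affected).
Only intramolecular events on single linear chromosomes are simulated;
multi-chromosome genomes are lists of chromosomes and `scramble_collection`
confines each event to one chromosome (no translocations). Composite
outcomes ("duplication & deletion") arise as sequences of primitive events,
not as a fourth primitive. Circular excision intermediates that could
re-integrate elsewhere are not modeled; none of the event patterns this
package targets require them.

## Read simulation and what it does and does not emulate

`simulate_read_pairs` draws `ceil(coverage × L / (2 × read_length))` fragments
with truncated-normal insert sizes (Normal(350, 35) clipped to
[2·read_length, mean+4σ]; real library preparation reports nothing that
constrains this, so a conventional short-insert library is assumed) and
uniform start positions. Mate 1 reads the fragment 5′ end forward; mate 2 is
the reverse complement of the 3′ end. Defaults are PE100 at 85× — the
sequencing design of the study this package emulates — though the bundled
analyses run at 30× to stay desk-scale. Base errors are substitutions at a
constant Phred quality q = round(−10·log10(error_rate)), applied at exactly
the probability the emitted quality string implies, so quality-aware
consumers see an honest error model. A `contaminate_fraction` knob degrades a
chosen fraction of pairs (mate 1 at Phred 8, or with three injected N bases)
to exercise QC.

Not emulated: indel errors, GC-dependent coverage bias, optical/PCR
duplicates, adapter read-through, or a machine-specific error profile.
Passing tests therefore demonstrate the logic of the pipeline under a clean
substitution-error regime, not robustness to every artifact of real
sequencers.

## QC

A pair is dropped when either mate fails the quality rule or (by default)
contains any N. "Phred < 10" is interpreted as the per-mate **mean** Phred;
because filtering tools differ on mean versus minimum versus
fraction-of-low-bases, the rule is a config choice (`mean` | `min` |
`fraction_below`). Removal is pair-level to keep mate files synchronized.

## Mapping and depth

The mapper is deliberately ungapped: every SCRaMbLE junction co-occurs with a
full loxPsym copy, so junction evidence is carried by split reads, not gapped
alignments. Reads are placed by best Hamming distance over both strands,
seeded by an exact k-mer index (k = 21, ≤ 4 mismatches per 100 bp by
default). By the pigeonhole principle a placement with m mismatches must
share an exact k-mer with the read only when ceil((L−m)/(m+1)) ≥ k — for
L = 100, k = 21 that guarantees m ≤ 3. Whenever the seeded best exceeds that
bound (or nothing is seeded), the mapper re-scans every position of both
strands vectorized, making its output provably identical to an exhaustive
scan; the tests verify this equivalence read-by-read against an independently
written oracle. Ties in best Hamming distance yield status `multi` rather
than an arbitrary placement, so the highly repeated loxPsym site can never
fake unique evidence.

Depth is a per-base pileup of **unique** alignments only (multi-reads are
discarded from depth), averaged per segment; the copy ratio divides each
segment mean by the chromosome's median segment mean. At 30× over ~1.8-kb
segments the sampling SD of a neutral ratio is ≈ 0.05, far inside every
decision band below.

## Junction calling

Unmapped reads are scanned for the loxPsym site allowing ≤ 2 substitutions
(sequencing error inside the site); both flanks must reach 15 bp — the
published rule says "at least 15 bp flanked" without specifying one or both
sides, and requiring both avoids single-anchor false junctions. Flanks are
mapped exhaustively with ≤ 1 mismatch and must place uniquely; a fragment end
must fall within 2 bp (`snap_tol`, sequencing-error slack) of a segment
boundary. Junctions are keyed on the exact snapped boundary pair, so
clustering is exact grouping, and support counts distinct read ids; the
support threshold is ≥ 5 (the source phrasing "more than five breakpoint
sequences" is ambiguous between > 5 and ≥ 5; this package reads it
inclusively and exposes `min_support`). Wild-type adjacencies are discarded
at locate time.

Typing rules and their copy-ratio corroboration bands (< 0.25 for deleted
segments, ≥ 1.6 for duplicated, [0.75, 1.25] for inverted) are package
choices — the published pipeline states only "breakpoint direction and
sequence coverage depth" — and all are exposed in `Thresholds` /
`PipelineConfig`. A junction whose orientation pattern and depth disagree, an
unpaired inverted junction, or one spanning segments with missing depth
degrades to `complex` with a note and its per-segment copy ratios attached,
so composite events remain interpretable.

**Known statistical limitation.** At 30× PE100, the expected number of
usable split reads per junction is ≈ 0.3 reads/bp × 37 valid site offsets
≈ 11, so P(support < 5) ≈ 1–2% per junction. Single-event recovery is
therefore not mathematically guaranteed at 30×: rare simulations leave one
junction (most visibly one of an inversion's reciprocal pair) under-supported
and the call degrades to `complex`. This is a property of the support
threshold at that coverage, not of the caller; at the study's 85× design the
margin is ~3× larger.

## Homolog mining and sequence engineering

`filter_hits` is a pure row predicate with **strict** inequalities
(> 1000 / > 75 / > 1000, matching the published wording at its boundaries) and
a case-insensitive family whitelist defaulting to the four MIA-rich plant
families named across the source material. Alignment-length units follow the
input table. `longest_orf` requires an explicit stop codon (an open-ended
reading frame is not "protein-encoding"), scans all six frames, translates
stops-excluded, treats N-containing codons as neither start nor stop
(translated X), and breaks exact-length ties forward-strand-first, then
smallest start. `make_chimera` uses 1-based inclusive residue arithmetic
(`donor[1..n] + acceptor[n+1..end]`, default n = 29); `truncate_at_rr`
removes residues 2..(p−1) where p is the first R of the first RR dipeptide,
keeping the initial methionine.

## Neighbor joining

p-distances use pairwise deletion (columns gapped in either sequence are
excluded per pair); a Poisson-corrected option (−ln(1−p)) is available since
the original tree's distance settings are unstated. NJ is the classical
Saitou–Nei reduction; branch lengths come from the standard two-point
formulas, negative lengths are reported as computed, and ties in the
Q-criterion break lexicographically (internal nodes inherit the smallest leaf
label of their clade), so output is deterministic and permutation-invariant
up to isomorphism. No bootstrap. On additive matrices the algorithm provably
returns the generating tree; the tests check path-length recovery to 1e-9
and topology equality, plus agreement with an independent NJ implementation.

## Plate-screen statistics

ΔOD340 defaults to the endpoint difference over the kinetic window (the
assay reads "within 30 min"); a max-slope option over a sliding window serves
early-saturating wells. Calibration needs ≥ 3 distinct standard
concentrations, is blank-corrected when blank wells exist, and refuses to
invert signals outside the calibrated range (0–8 mg/l in the bundled
examples). Hit calling is scale-invariant by construction (relative ΔOD
against the mean reference well) with an **inclusive** 1.5-fold threshold
("1.5-fold increase" is ambiguous; inclusive is the documented choice).
Specific activity assumes 1:1 NADH:geraniol stoichiometry and the standard
NADH extinction coefficient 6220 M⁻¹cm⁻¹ (configurable; the constant is not
printed in the source). Reporting broth concentrations applies the 1:1
broth:buffer dilution factor of 2.

## Reproducibility and problem sizes

A single master seed derives per-stage seeds (`derive_seed`), and every
simulation, plate, and matrix in the tests and in `scripts/acceptance.py` is
seeded. The bundled analyses use a ~20-kb toy chromosome with 10 loxPsym
sites at 30× coverage, 50 small random genomes × 1000 reads for mapper
equivalence, 200 random 2-kb sequences for ORF checking, and 100 random 5–8
taxon additive matrices for NJ — sizes chosen so the whole suite runs in a
few minutes on one CPU while still exercising every code path at the
published thresholds. The configuration defaults (`PipelineConfig`) are the
published operating points: min_flank 15, min_support 5, QC Phred 10, mining
triple 1000/75/1000, screen fold 1.5.
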