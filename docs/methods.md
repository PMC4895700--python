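# Methods

This note records the models, defaults and design choices behind the
package, and what the synthetic benchmarks do and do not demonstrate.

## Read filtration

A raw library read is modelled as `insert + 3'-adapter prefix`. The
cascade applies checks in a fixed order so each read has exactly one
primary drop reason: ambiguous base (any `N`) → 5'-adapter content → 3'-
adapter match → poly-A → insert length. Defaults, all configurable:

| parameter | default | rationale |
| --- | --- | --- |
| 3' adapter | `TGGAATTCTCGGGTGCCAAGG` | standard Illumina small-RNA chemistry; no particular library kit is assumed |
| 5' adapter | `GTTCAGAGTTCTACAGTCCGACGATC` | same |
| matched 3'-adapter length | 6–18 nt required | reads must end in a recognisable adapter stretch; more than 18 nt of adapter in a 36-nt-insert window indicates a short or empty insert |
| poly-A rule | ≥6 trailing A, or ≥80 % A overall (on the trimmed insert) | catches oligo-dA artifacts without discarding A-rich miRNAs |
| 5'-adapter rule | any exact 10-mer of the 5' adapter present | adapter-dimer hallmark |
| insert length | 16–27 nt | the mature range 18–24 nt plus a margin for border species |

The matched-length rule is interpreted as "matched length ∈ [6, 18]":
a read ending in 19+ nt of adapter is dropped, as is an adapterless read.
Adapter matching is exact; the simulator is error-free by default, and a
configurable error rate exists for users who want to stress this
assumption (the exact-match mapper will then undercount).

Collapsing maps identical inserts to unique tags (count-descending,
ties lexicographic); the collapsed-FASTA dialect `tag{serial}_x{count}`
is written for interoperability with common small-RNA tools.

## Placement and annotation

Tags are placed by exact match on both genome strands (12-mer seed index,
verified extension; a naive scan serves as the test oracle). Annotation
precedence: (1) tags that are substrings of any mRNA reference sequence
are labelled `mRNA` and excluded from miRNA quantification — a sequence
screen, mirroring the use of a transcript database to remove degraded
mRNA fragments; (2) tags with a placement covering ≥90 % of the tag
inside an annotated mature interval on the same strand are `known_miRNA`;
(3) mapped but unannotated tags feed novel discovery; (4) the rest are
unmapped. The 90 % overlap rule is this package's own concretisation —
no published overlap criterion exists for this pipeline. Coordinates are
1-based closed (GFF3); BED output converts to 0-based half-open.

The E-box scanner reports all (overlapping) occurrences of `CANNTG`,
forward strand only — the motif's fixed positions are their own reverse
complement, so a reverse scan finds the same sites.

## Quantification

`RPM = C/(M·N)·10⁹` exactly as defined, including the 10⁹ scale (no
silent "per-million" correction). `N` counts every genome-mapped read,
including mRNA-screened tags that map — whether the original pipeline did
so is unknowable, and the choice is flagged here. `M` ("multiple mapping
numbers across all miRNA regions") is ambiguous when several tags serve
one miRNA; three semantics are implemented (`m_mode`):

- `max` (default): the largest placement count among the miRNA's tags;
- `mean`: count-weighted mean multiplicity;
- `per-read`: each read contributes 1/m to each of its m regions, M ≡ 1.

For unique mappers all three coincide; the per-read mode doubles as the
brute-force oracle in tests. miRNAs with zero reads are absent from the
profile rather than zero rows, so the fold floor handles them uniformly.

Fold change is `max(rpm_a, floor)/max(rpm_b, floor)` with the floor
defaulting to the RPM of one read in the larger library (the published
tables contain no zero RPMs, so their zero handling is unobservable).
The differential threshold is ≥1.5 inclusive for up, ≤1/1.5 for down.

The published top-50 tables ship as package data. The extracted text of
those tables concatenates the four numeric columns; the transcription was
resolved by requiring each row to satisfy the internal identity
`rpm_a/rpm_b = fold_a/fold_b` and each table its fold sort order, which
yields a unique split per row. Under that transcription all 100 rows are
internally consistent to ~10⁻⁹; `verify_tables` recomputes this and also
derives the unprinted baseline RPM (`rpm_b/fold_b`) per row.

## Novel discovery

Stacks: single-linkage clustering of unannotated placements per
chromosome and strand, joining intervals separated by ≤10 nt, keeping
stacks with ≥5 reads. The modal (highest-count) tag defines the putative
mature species, ties broken 5'-most — the dominant-read convention.

Precursor proposal is anchored: within a ±70 nt window the mature's
reverse complement is slid along the flanks scoring antiparallel
pairability (Watson-Crick + G-U); the three best non-overlapping peaks
propose candidate precursor spans (mature through putative star). Each
span is folded in isolation and classified. An earlier design folded
fixed excision windows directly, but random flank tails routinely fold
into incidental secondary hairpins under pair maximisation, masking
genuine precursors (and occasionally promoting decoys); anchoring on the
star arm removed both failure modes.

Folding is a Nussinov-style dynamic programme maximising pair count over
nested structures, minimum hairpin loop 3, with a deterministic traceback
(closing pair preferred on ties, then end-trimming, then the leftmost
bifurcation). Pair-count maximisation stands in for thermodynamic
folding because acceptance is topological, not energetic; sequences are
DNA-alphabet with T read as U.

A folded precursor passes a preset when it has (a) exactly one terminal
loop, of at least the preset's minimum size, (b) the mature entirely on
one arm, (c) enough mature bases paired across the duplex, (d) a
well-paired stem overall, and (e) a compact, near-canonical duplex:

| preset | mature paired | stem fraction | partner-span excess | G-U in duplex | min loop |
| --- | --- | --- | --- | --- | --- |
| relaxed | ≥14 | ≥0.50 | ≤6 | ≤4 | ≥4 |
| standard | ≥15 | ≥0.55 | ≤4 | ≤3 | ≥5 |
| strict | ≥16 | ≥0.60 | ≤2 | ≤2 | ≥6 |

Criteria (a)–(d) encode the textbook pre-miRNA shape. The duplex
criteria in (e) carry the discrimination against chance structures:
a real mature:star duplex is a near-reverse-complement — partners nearly
contiguous, pairs overwhelmingly canonical — whereas stems assembled by
pair maximisation from random sequence are bulge-riddled and wobble-heavy,
and chance duplexes close on implausibly small terminal loops. On 200
planted and 200 decoy loci (decoys = expressed unique mature sequences
whose precursor context is randomised, so stacks form but no hairpin
exists) the default presets gave full recall and zero false consensus
candidates.

Consensus emulates intersecting independent discovery tools with one
detector at three stringencies: a candidate is consensus when a quorum
(default 3/3) of presets accepts the same precursor span. Consensus is
monotone in the quorum. Ago-RIP verification requires ≥5 reads covering
≥50 % of their length inside the mature interval, same strand, in ≥1
dataset (both configurable); the simulator's supported candidates receive
≥10 reads in each of nine datasets, unsupported ones none, so exact
recovery of the supported set is the expected outcome and is asserted.

## Signature analysis

Overlap is exact set intersection, reported as a percentage of the first
set (display rounded to one decimal; raw value retained). Enrichment is
the classic unweighted KS running sum: +1/N_hit on hits, −1/N_miss on
misses, ES the signed maximum deviation; the null permutes the gene set
(uniform same-size draws), and p = (1 + #{|ES*| ≥ |ES|})/(n_perm + 1)
with n_perm = 1000 by default. Gene-set permutation is the only option —
the design has no replicate phenotypes — and the ranking metric defaults
to fold change (descending). The add-one estimator is mildly
conservative in the presence of ES ties, which shows up as decile
deviations of up to ~0.1 in 200-trial null calibrations.

## Synthetic data

The generator defines the study conditions: three libraries (empty
vector baseline, Kaposin B, Kaposin B + c-Myc) of 10⁵ reads each over a
100 kb, 42 % GC genome carrying 20 known and 10 novel planted hairpins;
contaminant fractions poly-A 5 %, ambiguous 2 %, adapter dimer 3 %, mRNA
fragments 10 %; nine Ago-RIP datasets at depth 10 covering a supported
subset (70 %) of the novel loci. Planted precursors are mature (22 nt) +
loop (12 nt, A/C alphabet so it cannot self-pair) + star
(reverse complement with 1 internal non-pairing mismatch), re-drawn until
the construct passes every preset and the mature occurs exactly once in
the genome. Reads are mature + a uniform 6–18 nt adapter prefix with
constant quality "I"; contaminant reads are constructed (and re-drawn if
necessary) to classify as exactly their intended drop reason, so QC
counters are exact ground truth.

True abundances are per-condition multinomial weights; a miRNA's fold is
the ratio of its normalised weights. Requested folds are realised
*exactly* by solving for baseline weights with `Σw = 1` and `Σw·f_c = 1`
per condition (minimum-norm correction of the uniform weights, falling
back to a maximin linear programme), feasible whenever folds straddle 1;
otherwise uniform weights are kept and the realised folds (requested ×
common scale) are stored in the truth table. The default fold design
permutes a balanced multiset over {4, 2, 1, 0.5} (mean 1 per 20 loci) and
lets further conditions keep 70 % of the first condition's assignments —
the overlap structure the signature analysis is meant to detect.

What the synthetic data does not emulate: sequencing errors and quality
variation (reads are error-free; the mapper is exact-match), isomiRs and
heterogeneous 5'/3' ends (each locus yields one exact mature sequence, so
read stacks are single-tag), RNA editing, expression from repetitive
regions beyond the deliberately planted duplicates, and realistic genome
composition (i.i.d. bases). Passing benchmarks therefore demonstrate
correctness of the pipeline's logic and arithmetic under its own model,
not robustness to real-library noise.

## Problem sizes and numerics

Benchmarks run at 10⁵ reads per condition for recovery analyses, 10⁴
reads for the per-read RPM oracle, 500 sequences ≤12 nt for the folding
oracle (exhaustive enumeration), 200 trials × 199 permutations for null
calibration, and a 5 000-read three-condition double run for byte-level
determinism — sizes at which every check completes in seconds on one
CPU while keeping binomial sampling error well inside the asserted
tolerances (e.g. ≥800 reads per miRNA at the recovery depth gives ~3.5 %
fold error against a 10 % bound). Determinism rests on a single global
seed fanned out to fixed per-stage seeds via `numpy.random.SeedSequence`;
all outputs are plain text with stable formatting, and run manifests
record SHA-256 hashes per output.

## Known limitations

- Exact-match placement cannot tolerate sequencing errors or SNPs; with a
  nonzero simulated error rate, mapping rates drop accordingly.
- Nussinov pair maximisation ignores stacking energetics; a thermodynamic
  folder would be the natural upgrade path for real data (the classifier
  only needs a pairing list, so swapping the folder is mechanical).
- The multiplicity semantics `max` can differ from per-read assignment
  when a miRNA is served by a mixture of unique and multi-mapped tags;
  both are exposed precisely because the printed definition is ambiguous.
- GSEA with gene-set permutation tests a different null than phenotype
  permutation; with no replicates this is the only computable variant.
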