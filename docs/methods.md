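# Methods

## Amplicon model

An amplicon target is a pair of restriction-site occurrences of two
*different* enzymes on the same chromosome, in either forward-strand order
("A-first": PstI site left of the MspI site; "B-first": the converse),
whose insert — the open interval between the two site intervals, sites
excluded — satisfies three criteria: (1) length within a configured window
(default 60–250 bp; 77–202 bp for the stricter primer-design pass),
(2) no further occurrence of either recognition motif intersecting the
open insert, and (3) validity in both orientations. Coordinates are
0-based, half-open throughout; exports that use 1-based conventions
(HapMap `pos`) say so at the column.

Interpretation choices worth stating explicitly:

- *Intervening site* means any motif occurrence whose interval intersects
  the **open** insert. The two flanking sites themselves never count, and
  an occurrence that merely touches an insert boundary does not count.
  This keeps flanks legal while enforcing criterion (2).
- Site occurrences are matched on the forward strand against the motif
  and its reverse complement, deduplicated, so palindromes (both default
  enzymes) count once. Motif windows containing `N` never match —
  conservative behaviour on gapped references.
- Same-enzyme pairs (PstI…PstI) are never targets: the two-enzyme design
  is what the fusion-primer chemistry amplifies.
- Overlapping occurrences of the two motifs at one locus (impossible for
  PstI/MspI, possible for other enzyme pairs) are skipped and tallied in
  diagnostics rather than reported.
- Inter-amplicon distances in `gap_stats` are insert-start to
  insert-start of consecutive targets per chromosome (sample sd, ddof 1).
  Start-to-start differs from end-to-start by roughly one insert length
  and is unambiguous for mixed orientations.
- The length spectrum fits ordinary least squares of count against
  integer insert length. A perfectly flat spectrum reports slope 0 and
  r² 0 (the trend explains none of the — zero — variance); r² is reported
  as undefined only when the fit itself is degenerate.

The miner is checked two ways: set-equality against a brute-force oracle
that tests every ordered site pair directly (on random genomes whose
backgrounds are free to contain motifs), and exact recovery of planted
targets in synthetic genomes (below).

## Melting temperatures

`thermo.nn_tm` implements the unified nearest-neighbour model with the
SantaLucia & Hicks (2004) ΔH°/ΔS° parameter set: duplex initiation
(+0.2 kcal/mol, −5.7 cal/mol·K), a per-terminal A·T penalty
(+2.2, +6.9), a −1.4 cal/mol·K symmetry term for self-complementary
primers (detected automatically), and T_m = 1000·ΔH°/(ΔS° + R ln C_T)
with C_T the primer concentration (primer assumed in excess over
template). Salt effects follow the Owczarzy decision tree: free Mg²⁺
after dNTP chelation (K_a = 3·10⁴ M⁻¹); if √[Mg²⁺]/[Mon⁺] < 0.22 the
monovalent-only quadratic in ln[Mon⁺] applies, otherwise the Mg²⁺
correction with mixed-ion coefficients for ratios up to 6; the correction
is applied to 1/T_m.

Defaults — 50 mM monovalent, 1.5 mM Mg²⁺, 0.2 mM dNTP, 200 nM primer —
are generic PCR conditions, exposed in `ThermoParams` (config keys
`tm.monovalent_mM`, `tm.divalent_mM`, `tm.dntp_mM`, `tm.primer_nM`).
Downstream only the screen thresholds matter (≥ 38 °C at k = 12,
≥ 50 °C at k = 16, linear interpolation between, flat above 16; all
configurable), so moderate changes in ionic assumptions shift absolute
Tms but rarely the pass/fail pattern; pair counts on a real genome are
nevertheless somewhat sensitive to the chosen conditions, which is why
they are configuration, not constants.

Internally the sequence is canonicalized to the lexicographically smaller
of (primer, reverse complement) before summation, making
Tm(s) == Tm(revcomp(s)) bitwise exact rather than merely equal to within
float summation order. Agreement with an independently coded
nearest-neighbour implementation (Biopython's, same published parameter
set) is ~3·10⁻¹³ °C over thousands of random 12–18-mers.

## Primer extraction, counting, degeneracy

Each target offers one primer per side: the k forward-strand bases ending
at the A-site's 3′ boundary (A side), and the reverse complement of the k
bases starting at the B-site's 5′ boundary (B side), so both primers end
3′ in their recognition site and point into the insert; B-first targets
mirror through the reverse complement. Extraction returns "absent" when a
flank runs off the contig or contains `N` (unsynthesizable), and those
cases are tallied, not errored.

Pair counting aggregates qualifying targets (length window, both primers
extractable, both Tms above the length-dependent threshold) by the exact
(A-sequence, B-sequence) pair, so Σ counts == number of qualifying
targets by construction. Both orientations feed the same pair key — with
palindromic sites the chemistry cannot distinguish them. Ranking is by
count descending with a lexicographic tie-break for reproducible tables.
Distinct (A, B) pairs are counted as distinct even when they share one
primer; pool naming follows the `KK–NN` convention (A-primer length,
dash, total primer count = 2 × pairs; hyphen or en-dash parse).

IUPAC degeneracy is the product of per-position code cardinalities;
pair degeneracy multiplies both sides. The enumeration identity
(number of distinct expansions == degeneracy) is verified exhaustively
for small patterns. `consensus_degenerate` builds the minimal
positionwise union covering a set of specific primers — by construction
every input matches the consensus, and the positionwise union
deliberately over-covers combinations absent from the input (degeneracy
≥ number of distinct inputs); that over-coverage is the standard
trade-off of consensus degenerate design.

## In-silico PCR and library simulation

Prediction is anchored matching only: the k genomic bases ending at each
site are compared to the primer set — exact equality for specific pools,
IUPAC containment for degenerate pairs. No internal mismatches, no
off-site binding, no amplification-efficiency model: flank identity is
the selectivity mechanism of the assay, and mismatch tolerance is not
modeled. Consequences: predictions are always a subset of the mined set,
and a fully degenerate (all-N) pair with the Tm screen off predicts
exactly the mined, extractable targets — both properties are tested.

Simulated reads follow the two-step-PCR construct:
`barcode + M13 tail (GATGTAAAACGACGGCCAGTG) + A-spacer + CTGCAG + insert
+ CCGG + revcomp(B-spacer) + revcomp(trP1B)`, where the spacers are the
actual genomic flanks of the matched locus and B-first inserts enter
reverse-complemented (sequencing always proceeds from the forward-primer
side). Per amplicon and sample the read count is negative-binomial
(mean, dispersion) to mimic the uneven coverage of real reduced-
representation libraries, or constant when the dispersion is `None`
(exact round-trip tests). Read lengths are normal, truncated below at
25 nt and above at the construct length — emulating variable-length
semiconductor sequencing reads. Errors are substitutions only (no
homopolymer indels), flagged by a low quality character against an
otherwise constant high quality; downstream GBS callers ignore quality
by default, so quality realism is not a goal. The construct writer
assumes palindromic recognition sites when emitting the site bases in
read orientation — true for the default enzymes; non-palindromic pairs
would need strand-aware site emission there.

## Read preprocessing

GBS-style callers key reads on barcode + remnant restriction site. For
each read, the longest matching barcode is found; the following
tail + spacer + full recognition site is excised and replaced by the
remnant (`TGCAG` by default — the recognition site minus its first base,
the keyfile convention; the full-site alternative is a config switch).
The quality string is cut at identical offsets, the remnant bases keeping
the qualities of the site bases they derive from, so the length invariant
holds through every edit. A read already beginning barcode + remnant
passes through untouched, which makes the operation idempotent. Unmatched
reads are dropped (default) or passed, and the report conserves counts
exactly. Poly-A padding appends 80 A's (Phred 0 quality `!`) so callers
that discard short reads will still consider them; both the count and the
quality character are parameters.

Barcode matching is exact and longest-first — deterministic stream
editing, not error-tolerant demultiplexing; a sequencing error inside a
barcode loses that read, as in the real pipeline.

## Genotype statistics

Calls are biallelic (hom-A / het / hom-B / missing). MCR is the fraction
of samples with a non-missing call — note this is *call rate*, the
convention of GBS pipelines, not "fraction of samples carrying the minor
allele". MAF counts two alleles per homozygote and one of each per
heterozygote, over non-missing calls; het rate is het / non-missing.
Filtering keeps markers passing all three thresholds and attributes each
removal to its first failing criterion in the order MCR → MAF → het.
Multi-allelic rows are dropped with a tally on import (the pipeline is
biallelic). The RIL simulator draws per-marker allele frequencies
(default 0.5, the biparental expectation), applies a residual
heterozygosity rate (default 0.06, roughly an F6 level — configured, not
derived), then masks calls missing at the configured rate; it exists to
exercise the statistics and filters, not to model linkage (markers are
unlinked, samples independent).

## Synthetic genomes and what passing tests show

`generate_genome` builds backgrounds by GC-biased sampling and then
*scrubs* every motif occurrence outside the planted constructs by
re-drawing single bases until the only occurrences of either motif (on
either strand) are the planted sites. Planted constructs (site + insert +
site) are placed with ≥ 300 bp spacing by default — above the upper
insert bound, so facing sites of adjacent constructs can never pair into
an unplanned target — and ≥ 300 bp from chromosome ends, which also
guarantees primer extractability at every k ≤ 18. This makes the truth
set exact and recovery testable at precision = recall = 1. The variant
injector (`mutate_genome`) substitutes bases at a configured rate; with
site protection on, it neither edits existing recognition sites nor
accepts a substitution that would create a new motif occurrence, so the
amplicon landscape is invariant — the intended use is deriving biparental
parents/RILs that differ inside inserts only.

What the synthetic setting deliberately does *not* emulate: repeat
structure and paralogy (every flank is random, so primer pairs rarely
recur — real genomes concentrate counts onto few pairs), reference gaps
beyond literal `N` handling, PCR efficiency differences between loci,
and indel sequencing errors. Passing tests therefore demonstrate
correctness of the algorithms and bookkeeping, not performance claims on
any real genome.

## Problem sizes

Default verification sizes were chosen as the smallest that exercise
every code path with comfortable statistical margin: 100 random 50-kb
genomes for oracle equivalence, 50 planted genomes (10–50 targets each)
for recovery, 1000 random primers for the Tm cross-check, ~10⁵ simulated
reads for the end-to-end round trip, and one random 2-Mb chromosome for
the mining summary. All are parameters of the respective functions and
scale up directly.
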