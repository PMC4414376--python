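# Methods

## Coordinates and sequence conventions

All coordinates are 0-based, half-open; 1-based inclusive appears only at
the GFF3 boundary. Sequences are normalized to uppercase {A,C,G,T,N};
IUPAC ambiguity codes other than N are mapped to N, since an ambiguous
base can anchor neither a perfect-repeat call nor a flank match. Contigs
are obtained by cutting scaffolds at every run of at least `min_gap`
consecutive N (default 10, an NCBI-style spanned-gap heuristic; the value
is configurable because published contig counts depend on the submitter's
gap convention). Runs shorter than `min_gap` stay inside a contig, so a
contig's N-free length is what enters contig N50.

## Assembly statistics

`nstat(lengths, f)` returns the smallest length L whose descending
cumulative sum first reaches f × total; N50 is `f = 0.5`. Scaffold
statistics use gapped spans (a scaffold "spans" its estimated gaps);
contig statistics use N-free lengths. The minimum scaffold length filter
is strict (`> min_scaffold_len`), matching the usual "longer than 1,000
bp" convention, and is applied before any statistic — including contig
derivation — is computed. Mb/Kb values for table display are rounded half
away from zero to one decimal.

## SSR detection

Only perfect tandem repeats are used: matching is anchored on the flanks,
so repeat purity contributes nothing and imperfect-repeat scoring is out
of scope. Minimum unit counts are the community-standard defaults
(mononucleotide 12; di 6; tri/tetra/penta/hexa 5). Detection is a
period-k self-comparison: positions j with `seq[j] == seq[j+k]` (neither
N) form maximal equality runs; a run of length r spans a tandem array of
total length r + k, of which only whole units anchored at the run start
are reported. A run whose leading motif is itself a repetition of a
shorter motif (e.g. "ACAC" at k = 4, or a homopolymer seen at k = 2) is
left to its minimal period. Motifs are named by their canonical form, the
lexicographic minimum over all rotations of the motif and of its reverse
complement, so the same repeat found on either strand or in any phase
compares equal.

Flanks of up to 200 bp per side are extracted, truncated at scaffold
edges and at the nearest N; loci with under 60 bp of combined flank are
unusable (too little information for specific matching). 200/60 balance
specificity at the ~2% pairwise flank divergence the defaults emulate
against staying within short scaffolds.

## Marker matching

Left and right flank pairs are aligned separately (the aligner can
therefore never bridge across the repeat — equivalent to concatenation
with an unalignable separator) with semi-global dynamic programming (free
end gaps; match +1, mismatch −1, gap open −2, extend −1), in both the
given and the reverse-complement orientation (a strand flip swaps and
reverse-complements the flank pair). Identity is pooled matches over
pooled aligned columns; the aligned fraction is pooled aligned columns
over the shorter combined flank. Acceptance requires identity ≥ 0.90,
aligned fraction ≥ 0.80, same canonical motif (configurable off), and a
reciprocal best hit on both sides whose runner-up is at least 0.02
identity lower; loci with tied top candidates are dropped entirely. The
reciprocal-best-hit-with-margin rule enforces the one-to-one marker map
the ordering step assumes. A bounded edit-distance screen (edlib)
discards hopeless candidates before the affine alignment is computed;
accepted identities always come from the affine aligner, so the screen is
a pure speedup.

## Synteny blocks and rearrangements

One assembly is the reference; markers on each reference scaffold are
sorted by position and chained greedily: a block extends while the next
marker keeps the partner scaffold, the orientation, and a monotone
partner coordinate (increasing for "+", decreasing for "−"). A
discordant run of length ≤ 1 (`max_singleton_ignore`) is skipped and the
chain continues; a run of ≥ 2 (`min_break_support`) ends the block.
Blocks need ≥ 2 markers; sub-threshold chains join the ignored markers.

Along each reference scaffold, rearrangements are read off the block
sequence as maximal discordant *runs*, not boundaries: a run of blocks on
a non-modal partner chromosome is one inter-chromosomal event (a
translocated segment creates two switch boundaries but is one event); a
run of minority-orientation blocks within the modal partner chromosome,
or a same-scaffold partner-order discontinuity, is one intra-chromosomal
event. Modal context is marker-weighted. Block boundaries at reference
scaffold ends are never events — a draft-assembly break cannot be
distinguished from biology — which mirrors the linked-scaffold treatment:
two reference scaffolds are linked when one partner scaffold carries
consecutive blocks at a terminal end of each, each scaffold end joining
at most one link (better-supported candidate wins; losers are reported).
Unplaced reference scaffolds are putatively placed when a block of ≥ 3
consecutive markers (`min_placement_support`, the smallest count
exceeding the ignored singleton plus one) ties them to a partner context
whose chromosome is unambiguous; placements are annotations and never
modify the input chromosome map.

Event breakpoints are reported as the inter-marker interval between the
bounding blocks; on simulations they are validated to lie within one
inter-marker interval of the true breakpoint. Reference asymmetry is
deliberate (the reference defines marker order); swapping roles is a
consistency check, not required to be identical.

## Protein-domain statistics

Inputs are per-species hit tables (gene, domain, protein and model
coordinates), one record per gene (longest transcript upstream). Two
same-domain hits merge when the second resumes on the model within ±10
positions of where the first ended *and* lies within 30 residues on the
protein — split coverage of one model — while two full-model copies
remain a genuine tandem repeat; both tolerances are configurable.
Occurrence counts are once per gene. Expansion/contraction uses a
two-sided Fisher's exact test on [[count, total−count] per species] where
the margins are total once-per-gene domain instances (occurrence
proportions; per-gene margins are a configuration away), with raw P
values by design — a Benjamini-Hochberg-style correction can be applied
downstream but is off by default so single-domain signals at P < 0.05 are
visible. Repeat-number comparison clusters proteins by arrangement (the
set of distinct domains in a protein, ignoring copy number and order),
keeps arrangements present in both species and occurring ≥ 2 times in at
least one, and flags domains whose per-species (min, max) repeat-count
ranges do not overlap.

## CpG methylation prediction

CpG[O/E] = (#CpG × L)/(#C × #G) with overlapping "CG" counting, N
excluded from all counts and from L; the value is undefined (never 0)
when C or G is absent, and undefined genes are tallied separately and
never predicted methylated. The default region is the gene body (all
exons concatenated; junction-spanning CG between exons is not a genomic
dinucleotide and the concatenation bias is bounded by junctions/L);
exon-only and intron-only regions support the exon-vs-intron comparison.
CpG is its own reverse complement, so the statistic is strand-invariant
and gene strand is ignored.

## Synthetic data

The genome generator defines the study conditions: 10 Mb in 5
chromosomes of i.i.d. background at GC 0.38 (AT-rich, bumblebee-like),
40 implanted SSR loci per Mb (motif mix: half di-, 0.3 tri-, 0.2
tetranucleotide) at uniform positions with ≥ 500 bp spacing and a 400 bp
edge margin; per-lineage substitution rate 0.005 and small-indel rate
2×10⁻⁴ (lengths 1–3), both kept out of the repeat tracts so that
detection thresholds rather than repeat decay are tested; 6 inversions
and 4 translocations of runs of 5–8 consecutive markers applied to one
lineage, with breakpoints at inter-marker midpoints. Background sequence
occasionally contains chance tandem repeats meeting the detection
minimums; these are real homologous loci of the two descendants, so the
generator records them in the truth table too (using the package scanner
— acceptable here because truth completeness, not detector correctness,
is at stake; detector correctness is checked against an independent
brute-force oracle). Where the background happens to extend an implanted
tract, the truth interval is the maximal one. Fragmentation (off by
default, since the recovery conditions above are defined on whole
chromosomes) cuts chromosomes at random points outside loci and inserts
fixed-length 100-N gap runs, lifting all truth coordinates; a
configurable fraction of scaffolds can be withheld from the chromosome
map to exercise placement.

The domain generator draws per-domain mean gene counts log-uniformly in
[5, 100] (totals ≈ 1.6×10⁴ across 500 domains) and Poisson counts per
species; implanted effects multiply one species' mean. In the repeat
tables the null repeat count is a conserved property of the domain family
(identical in both species), so the null comparison flags nothing —
matching the biological claim the statistic tests — while implanted
shifts draw per-protein counts from species-specific ranges. The
methylome generator draws per-gene O/E targets around the class centres
(0.65 depleted / 1.05 background, dispersion 0.02) and realizes each
exactly (up to integer rounding) by a composition-constrained
construction: base composition is multinomial at GC 0.42, the CpG count
is pinned to round(t·nC·nG/L), and single G tokens are placed only where
they cannot create an accidental CpG. What this does *not* emulate:
selection on flank sequence, heterogeneous mutation rates, repeat decay
(available as an option), transposable elements, or the long-tailed O/E
dispersion of real methylomes — so passing tests demonstrate correctness
of the computations under the stated model, not performance on real
genomes, where thresholds may need retuning.

All generators are deterministic given a seed (numpy `default_rng`).

## Numerical choices and degenerate inputs

Fisher's P values come from `scipy.stats.fisher_exact` and are verified
against full hypergeometric enumeration with exact integer binomials to
1e-9 (two-sided tie tolerance 1+1e-7, the standard convention). Alignment
identity ties between orientations break toward "+". `nstat` of an empty
list, an assembly emptied by the length filter, an empty domain table,
and zero Fisher margins are errors; an empty pair list yields empty
tracks/blocks and a zero-coverage summary. Mean/median block lengths are
reported separately per assembly side since block spans differ between
the two coordinate systems.

## Problem sizes used in the shipped checks

The recovery experiment runs the full 10-Mb conditions over 20 seeds; the
oracle comparisons use 1,000 random 1-kb sequences and 10,000 random 2×2
tables with margins ≤ 200; null calibration uses one 500-domain table per
seed; the methylome check uses 2,000 genes of 2 kb. These sizes make the
whole suite comfortably reproducible on a laptop while keeping every
binomial check well-powered.

## Known limitations

Event counting assumes rearranged segments are small relative to their
chromosome (modal-context logic); reciprocal translocations exchanging
whole arms would be read as two events. Overlapping or nested
rearrangements are not modelled by the generator and not guaranteed to be
counted correctly. Marker order jitter from near-identical coordinates is
handled only via the singleton-ignore rule. Real-data runs depend on
threshold choices (SSR minimums, flank identity) that the original
two-bumblebee analysis delegated to its own tooling; block counts and
coverage on real assemblies are therefore comparable in order of
magnitude, not digit for digit.
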