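# Methods

`droughtmir` reimplements, as a tested pipeline, the computational analysis
used to identify and comparatively classify dehydration-responsive miRNAs
in two wheat genotypes (a drought-tolerant and a drought-susceptible
cultivar) from four unreplicated small-RNA libraries: control and stress
for each genotype (C1/T1, C2/T2). A synthetic-data generator stands in for
the original raw sequencing data, so every stage can be validated against
known ground truth.

## Preprocessing

Reads are 3'-adapter trimmed (leftmost full adapter match, else the
longest adapter prefix of at least 6 nt at the read 3' end; untrimmed
reads already within the insert range are kept, since inserts shorter than
the read length need not show read-through). "Low quality" is
operationalised in the FASTX tradition: drop inserts containing N or with
more than 20% of bases below Q20. Inserts of 16-30 nt are retained and
collapsed into unique tags with per-library counts; conservation
(raw = retained + dropped-by-cause) is asserted per library. No additional
abundance ("noise") filter is applied by default — the cascade annotation
downstream absorbs that role — but a `min_count` cutoff is exposed.

## Cascade annotation

Tags are assigned first-match-wins against ordered reference sets:
rRNA > tRNA > snoRNA > snRNA > (optional repeat set) > mature miRNA
catalog > other. The default match policy is exact substring containment
of the tag (either strand) in a reference record; a <=1-mismatch policy
(edit distance via edlib) is available. Exact matching is reproducible and
adequate for synthetic fixtures; it understates the sensitivity a tuned
BLAST search would reach on real data.

## Novel miRNA calling

Unannotated tags are mapped to the genome requiring perfect matches on
either strand (up to 20 loci per tag). Around each locus two candidate
windows are excised — 20 nt 5' + mature + 200 nt 3', and the mirror — and
folded. The folder is an internal weighted maximum-pairing (Nussinov)
dynamic program: nested structures, minimum loop 3, pair weights GC=3,
AU=2, GU=1, deterministic traceback (prefer a pair at the smallest 5'
index, then the largest partner). It is a combinatorial stand-in for a
thermodynamic model: deterministic, dependency-free, and exhaustively
verifiable (tests compare it against full structure enumeration up to
18 nt). It does not produce free energies, so no MFE-based filtering is
attempted.

A candidate passes when (a) the mature lies entirely in one stem arm,
(b) at most 4 mature bases are unpaired in the miRNA/miRNA* duplex,
(c) no asymmetric bulge in the duplex exceeds 2 nt, (d) at least 60% of
stem bases are paired, and (e) the mature is 20-24 nt. The star sequence
is derived with the canonical 2-nt 3' overhang. These thresholds
operationalise the community criteria for plant miRNA annotation. The best
passing window per tag (highest paired fraction) yields one call per
distinct mature sequence.

## Expression and differential screening

Expression is tags per million: mapped reads for a miRNA divided by the
library's clean-read total, x 10^6. A TPM of 0.01 is substituted whenever
the underlying count is zero, so log2 stress/control ratios are always
defined; substitutions are flagged. Counts per conserved miRNA are the
summed counts of tags matching that catalog entry; novel miRNAs use their
calling tag's counts.

Significance between two unreplicated libraries uses the exact
Poisson test: conditional on a count x in a library of total N1, the
probability of y' in a library of total N2 (f = N2/N1) is

    p(y' | x) = f^y' (x + y')! / (x! y'! (1 + f)^(x + y' + 1)),

summed in log-space via log-gamma; the two-sided p doubles the smaller
tail, capped at 1. The upper tail is summed explicitly well past the
conditional mode rather than via 1 − CDF, preserving relative accuracy of
tiny tails. A Pearson chi-square on the 2x2 table (1 df, no continuity
correction; degenerate tables flagged with p = 1) is available as the
alternative test. FDR control is Benjamini–Hochberg. The screen keeps
miRNAs with p < 0.01, q < 0.01 and fold change >= 2; all comparisons use
unrounded values, with 2-decimal formatting applied only in emitted
tables.

Both tests assume (multinomial/Poisson) counting noise only. Under
biological overdispersion the exact test is anticonservative — a property
the generator's `dispersion` parameter exists to demonstrate.

## Cross-genotype pattern classification

Each miRNA carries log2 ratios L1 (genotype 1) and L2 (genotype 2),
computed after pseudocount substitution. With threshold t = 1: up in both
(L1 > t and L2 > t), down in both (both < −t), opposite (both exceed t in
magnitude, opposite signs), single-genotype (exactly one exceeds t),
otherwise unclassified. "Expressed predominantly in one genotype" is
operationalised as exactly one |L| > t with no additional expression
floor; in the pipeline the classification is applied to miRNAs passing
the significance screen in at least one genotype. The package ships the
curated 46-row table of conserved dehydration-responsive wheat miRNAs
(TPM quadruples and published log2 pairs); applying the rule to the
published pairs reproduces the published grouping (14 up / 6 down /
13 opposite / 13 single-genotype). A few published log2 entries do not
round-trip from their 2-decimal TPMs (they were evidently computed from
unrounded values; one row shows transposed columns) and are excluded from
exact recomputation tests — see `datasets.LOG2_ROUNDTRIP_EXCLUSIONS`.

## Target prediction

Sites are scored with a miRU-style penalty scheme over the first 20 miRNA
positions after optimal gapped alignment (antiparallel): Watson–Crick 0,
G:U wobble 0.5, mismatch 1.0, bulge 2.0, all doubled at miRNA positions
2–13 (the seed). At most one bulge is allowed, which keeps the dynamic
program to a three-diagonal band and matches typical plant duplex
topology. Sites with E <= 3.0 are reported, non-overlapping per
transcript, ordered by score; a central mismatch (positions 9–11) is
flagged as putative translational repression. Target-site accessibility
(the energy term some tools add) is out of scope; the parameter is parsed
and ignored with a warning.

qPCR validation arithmetic is the 2^-ΔΔCT method against an 18S rRNA
reference, averaging the three technical replicates' CTs before
differencing; miRNA–target concordance is the Pearson correlation of log2
relative levels (cleavage predicts a negative sign).

## Synthetic data generator

The generator emulates the study design: four libraries of
insert + 3' adapter reads (default 200,000 reads/library, a desk-scale
depth two orders below the original libraries), insert lengths 16–30 nt
with the mode at 24 nt as in plant small-RNA data, contaminant fragments
drawn from generated rRNA/tRNA/snoRNA/snRNA references (30/30/8/4% of
reads), conserved mature miRNAs (8%), unassignable background (20%), a
2% low-quality read fraction (two-level Q40/Q2 quality scheme), and a
0.5% per-base substitution error rate. Novel-miRNA hairpins are planted
in a 100 kb toy genome: 30–45 nt arms reverse-complementary up to 2
substitutions, 4–8 nt loops, the 20–24 nt mature in the 5' arm at least
2 nt from the loop — passing the calling criteria by construction.

Counts are negative binomial with planned means (dispersion 0 gives
Poisson). The default dispersion is 0.005: effectively Poisson, matching
the sampling model the exact test assumes, while leaving overdispersion
available as an explicit robustness dial. The default fold-change plan
assigns four miRNAs to each of the five non-null pattern categories at
fold 4 (opposite-pattern miRNAs go down in genotype 1 and up in
genotype 2, the direction reported for tolerant vs susceptible
cultivars; single-genotype miRNAs alternate direction), with the
remaining 16 of 36 planted miRNAs null. All randomness flows from one
root seed through named substreams, so identical configurations are
bitwise reproducible.

What the generator does not emulate: realistic sequencer error profiles
or quality distributions, 5' adapters, repeat-derived reads, genuine
Rfam/miRBase sequence families (references are random sequences, so
annotation sensitivity under family divergence is untested), and genome-
scale multi-mapping. Passing recovery tests therefore demonstrates the
correctness of the pipeline's logic and statistics under the stated
sampling model, not performance on real wheat libraries.

## Numerical and design notes

- T and U are equivalent; all sequences are stored in the DNA alphabet.
- Library totals N in the tests are the clean-read totals — the same
  denominator as the TPM equation.
- q-values are computed within each genotype contrast, mirroring
  per-genotype DE lists.
- Percentages are rounded to 2 decimals for display; identities
  (columns summing to 100%) hold to rounding slack 0.05.
- The folder's tie-break and the aligner's (fewer gaps, then leftmost)
  make all outputs deterministic; end-to-end runs with the same seed
  produce identical file checksums.
- Published totals that depend on the original libraries and genome
  snapshot (counts of DE/novel miRNAs and predicted targets) are not
  reproducible at desk scale and are validated instead through planted-
  truth recovery: at the default study conditions, all planted non-null
  miRNAs are recovered into their true category and no null miRNA passes
  the screen (the acceptance tests require >= 80% and <= 5%).
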