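# Methods notes

This note records the models, parameter choices and numerical conventions
behind `crypticsplice`, and what the synthetic benchmark does and does not
demonstrate.

## Coordinates and formats

Every coordinate inside the package is 0-based half-open on the forward
genomic strand.  Conversions happen only at the I/O boundary: GTF (1-based
closed) through `pyranges.read_gtf`, STAR `SJ.out.tab` (1-based inclusive
intron coordinates, so `donor_end = start − 1`, `acceptor_start = end`),
BED and bedGraph natively half-open, RepeatMasker tables with strand `C`
mapped to `−`.  Junction "donor/acceptor" field names refer to genomic
left/right; transcript 5′/3′ semantics are resolved against the gene strand
where they matter (extension naming, site extraction, sequence fetch).

Annotation flattening follows the disjoint-bin convention used by
exon-level differential-usage frameworks: the exons of all transcripts of
a gene are partitioned at every distinct exon boundary; genes whose exon
spans overlap on the same strand are merged into `+`-joined aggregate ids;
introns are the within-aggregate complement.  Flattening is idempotent and
per-base equivalent to a brute-force partition (tested).

## Discovery model

*Tag construction.* Only primary alignments are used; duplicate-marked
reads are retained for junction/tag discovery but excluded from counting,
so duplicates can reveal a junction without inflating its evidence.  A
spliced read enters discovery when it overlaps at least one annotated exon
bin and at least one of its blocks extends into an intron; reads bridging
two annotated exons carry no cryptic signal and are discarded.  Intronic
fragments pooled over **all** samples (both conditions) are single-linkage
merged at a gap of ≤ 500 bp (inclusive) and clipped to the intron list.

*Usage test.* For tag *t* in sample *j*, let *k* = tag count and *n* = tag
plus gene-remainder count (all annotated bins of the aggregate).  *k* ~
BetaBinomial(*n*, *p*, ρ) in the mean/overdispersion parameterization; the
likelihood-ratio statistic compares a shared *p* against per-condition
*p*(depletion), *p*(control), referred to χ²₁.  ρ is estimated per tag by
moments (Pearson dispersion of the pooled-proportion fit), then shrunk
toward a rolling-mean trend over tags ordered by depth with weight
**0.25 raw / 0.75 trend** and floored at 1e-6.  The strong shrinkage is
deliberate: the raw moment estimate is unbiased but noisy, and its noise is
positively correlated with the between-condition contrast, which deflates
the LRT; with 0.25 raw weight the empirical type-I error at α = 0.05 over
2000 simulated null tags is ≈ 0.035–0.05 (it is ≈ 0.05 exactly when the
true ρ is supplied).  Fold changes use pooled per-condition proportions
with a 0.5 pseudocount on every count, so zero-count tags get finite
log₂FC.  Candidate thresholds default to adjusted *p* < 0.05 (BH) and
|log₂FC| > 0.6.  Designs with fewer than two replicates per condition are
rejected; an externally computed per-tag results table can be imported
instead (`discovery.import_usage_results`).

## Classification and filters

The canonical junction must span the tag; an exact match to the flattened
intron boundaries wins, otherwise the spanning junction with the highest
control-sample count.  Cryptic junctions are rediscovered from the
**depletion** samples' junction tables (the event is defined by what
emerges under depletion) and then quantified in every sample.  Extension
contiguity is exact (0 bp gap between tag and annotated exon boundary);
anything else with a single spliced side is dropped as unclassifiable.

Filter semantics: (i) every depletion sample needs ≥ 1 cryptic junction
read on at least one side; (ii) canonical junction reads are summed over
**all** samples and must reach 10 — the permissive reading, since
per-sample thresholds are not stated anywhere; (iii) each side the event
actually uses needs ΔPSI ≥ 0.05.  ΔPSI is the difference of per-condition
means of per-sample PSI (not pooled-count PSI); the headline ΔPSI of a
cassette is the mean of its two sides, and both sides are always reported.

## Length-matched nulls and enrichment

Null intervals preserve the flanked exon's length exactly.  Same-intron
draws are uniform over all admissible start positions of the host intron
that avoid the flanked exon (a union of at most two ranges, sampled by a
single uniform offset — uniformity is chi-square-tested in the suite);
adjacent-intron draws pick a fitting adjacent intron uniformly per draw.
Exons that cannot fit yield fewer draws with a logged deficit; missing
adjacent introns skip that mode.

"Proportion test" means the two-proportion chi-square with Yates
continuity correction (matching `prop.test`), with a Fisher-exact fallback
when any observed cell is below 5; the chi-square p is always reported
alongside and the method used is flagged.  The multi-RBP screen keeps, per
RBP, the **maximum** p over replicates × null modes and Bonferroni-corrects
across RBPs — an intentionally strict rule; a single weak replicate
disqualifies the protein.  RBP clustering uses Jaccard distance with
complete linkage on the binary exon×RBP overlap matrix (the metric/linkage
choice is recorded in the outputs; the suite checks the merge tree against
a brute-force agglomeration).  Repeat families are kept disjoint — Alu
elements are counted under Alu only, never under SINE — and are crossed
with sense/antisense orientation relative to the gene strand ("unoriented"
for unstranded genes).  Dinucleotide counting uses overlapping windows and
an RNA alphabet; the background is the concatenated adjacent-intron
sequence of the same genes.  Peak overlap uses the full peak interval by
default; the narrowPeak point (first nucleotide / summit) is stored and a
point-overlap mode is available.

## Conservation

Per-interval means are computed over covered bases only; fully unscored
intervals are reported as missing, never as zero, and means are invariant
to how a track's runs are split into rows (overlapping rows are rejected
as malformed).  Group comparisons (cryptic vs same-intron random, cryptic
vs adjacent annotated exons) use Mann-Whitney rank tests with Bonferroni
over the two tests — the original figure does not name a test, so the
choice is recorded here and in the output metadata.

## Coding impact

Only cassette exons with both junction sides are analysed.  The host
intron is matched to a coding transcript whose consecutive exons flank it
and whose CDS span covers it; among several matches the longest CDS wins
(recorded in output).  The inclusion variant inserts the cryptic sequence
between those exons; translation runs from the CDS start through the
transcript end, so frameshifted stops in the 3′ UTR are found.  The
annotated stop position is taken from the exclusion variant's own
translation, which makes the logic independent of whether the GTF's CDS
includes the stop codon.  A PTC is any in-frame stop strictly upstream of
the annotated stop; it escapes NMD when its first base lies within 50 nt
of the final exon–exon junction (inclusive) or downstream of it.

The seven outcome categories partition (frameshift × PTC × escape), with
one disambiguation: a frameshifted event whose first PTC lies **within the
cryptic exon itself** is "frameshift and PTC included", while one whose
first PTC arises downstream (created by the shift) is plain "frameshift".
The partition is exhaustive and mutually exclusive (property-tested), and
the classifier is checked input-by-input against an independent plain
codon-scan translator.  The random-sequence null regenerates every cryptic
exon as uniform random nucleotides of identical length, so the null's
frameshift fraction is fixed by the observed length distribution.

## Splice-site scoring

Donor sites are 9-mers (last 3 exonic + first 6 intronic nt, GT invariant
at intronic positions 1–2); acceptors are 23-mers (last 20 intronic nt
ending AG + first 3 exonic).  The scorer is a per-position log₂-odds
matrix with pseudocount 1 against a uniform 0.25 background, trained on
the annotated internal-exon sites of the input annotation (≥ 50
consensus-valid sites required).  These scores share the *direction* of
maximum-entropy scorers (higher = more splice-site-like) but are **not on
the MaxEnt scale**; externally computed scores can be imported for parity.
Random baselines fix the invariant GT/AG and draw everything else
uniformly.  Paired cryptic-vs-canonical comparisons use paired t-tests per
class and side; zero-variance differences are reported as degenerate
rather than raising.

## Expression

Gene counting is union-mode over flattened bins (ambiguous multi-aggregate
reads dropped, duplicates ignored).  The built-in DE test is a minimal
negative-binomial Wald test — median-of-ratios size factors, per-gene
moment dispersion with a 1e-8 floor, delta-method standard error on the
log ratio of condition means, BH adjustment — and is deliberately not a
moderated framework (no shrinkage, no trend); external DE tables import
verbatim.  The bespoke statistic is the expression-matched enrichment: the
background is every tested gene with mean normalized expression at or
above the least-expressed cryptic-exon gene, and the overlap between the
cryptic set and each direction's DE genes gets an upper-tail
hypergeometric p, Bonferroni-corrected over the directions tested in one
invocation.  Proportions carry Clopper–Pearson 95% intervals.

## Synthetic data generator

The generator is the package's study-condition definition, not a tuning
surface.  Defaults: 4 exons per gene (120–180 nt), introns 1.5–2.5 kb,
single transcript per gene with a stop-free CDS assembled from non-stop
codons (60 nt 5′ UTR, ~90 nt 3′ UTR; CDS includes the terminal stop),
annotated donors `GT`+consensus-like head (15% per-position noise) and
acceptors with an 85% polypyrimidine tract ending `AG`; cryptic sites
carry only the invariant dinucleotides, so annotated sites are stronger by
construction.  30% of genes are minus-strand (built in transcript space
and mirrored, so all downstream strand handling is exercised).  Controls
include every event at a baseline PSI of 0.02, and unspiked genes carry an
equal-inclusion (ΔPSI = 0) event at PSI 0.02 in both conditions — false
positives are therefore a real possibility that the usage test and ΔPSI
filters must reject, not an artifact of absent signal.  Reads are
junction-level: canonical and cryptic junction reads drawn binomially at
the condition's PSI with uniformly placed anchors, plus plain exonic
coverage (depth 20), duplicate-flagged and secondary reads injected to
exercise the filters.  SAM sequences are copied from the simulated genome,
so alignments validate against their FASTA.

The benchmark ("standard configuration", seed-parameterized) plants 20
cassette exons at ΔPSI ∈ {0.4, 0.6, 0.8} and 10 extensions (30–60 nt)
across 60 genes with 3v3 replicates at junction depth 100.  Problem sizes
were chosen so the full benchmark plus downstream analyses completes in
well under a minute.

*What passing does not show.*  The generator produces clean junctions with
exact splice sites, no alignment errors, no multi-mapping ambiguity, no
expression-level or fragment-length realism, single-isoform genes and one
contig.  Recovery and calibration on it demonstrate the correctness of the
pipeline's logic and statistics under its stated model, not performance on
real libraries, where alignment artifacts, annotation incompleteness and
overdispersed coverage will dominate error rates.

## Degenerate inputs and numerical conventions

PSI with zero cryptic and canonical reads is 0 with a flag; samples with
zero canonical reads are skipped in the inclusion-ratio screen; a
condition with zero total gene counts marks the tag untested rather than
erroring; empty peak sets yield proportions of 0 with the test skipped;
Bonferroni never lowers a p-value, and significance tiers (\*, \*\*,
\*\*\*) at 0.05, 1e-3, 1e-16 are derived from adjusted values only.  All
randomness flows through `numpy.random.default_rng` seeded explicitly;
every CLI command stamps a manifest (parameters, seed, input checksums,
version) into its output directory.

## Known limitations

Intron retention, alternative first/last exons and mutually exclusive
exons are out of scope by design.  Single-replicate designs are only
supported through the import paths.  The splice-site scorer's absolute
values are not comparable across training sets.  The beta-binomial LRT is
mildly conservative at small replicate numbers (see above); with ≥ 5
replicates per condition the effect is negligible.
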