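# Methods

This note documents the models, parameter choices and numerical
conventions behind `kinspector`, and what the synthetic-data tests do
and do not demonstrate about real data.

## The assay model

The package analyses a circularized-library digest. Genomic DNA is
fragmented to a mean of 300 bp, circularized, digested in vitro with a
Cas9 ribonucleoprotein and sequenced as 150-bp paired-end reads. Two
physical facts drive all downstream logic:

1. SpCas9 cuts bluntly 3 bp 5′ of the PAM, between protospacer
   positions 17 and 18. We adopt this convention throughout: a "cut
   coordinate" is the first base 3′ of the break on the forward
   strand. (The convention is standard SpCas9 enzymology; nothing in
   the pipeline depends on it being exact to the base, since calling
   windows tolerate ±`window_size`.)
2. Sequencing a linearized circle places the two mate 5′ ends
   immediately on either side of the break: forward-strand 5′ ends at
   the cut coordinate *c*, reverse-strand 5′ ends at *c − 1*.

## Simulator

`simulate` builds random genomes (default 2 × 50 kb, GC 0.42) with
recorded repeat tracts (CA microsatellites, LTR-like and SINE-like
consensus repeats) and exon/intron gene models, plants guide-matching
23-mers at exact mismatch counts, applies donor-insertion events, and
emits read pairs.

**Defaults and why.** Fragment mean 300 bp and read length 150 bp are
the assay's stated library geometry; the library-molecule model
(300 bp insert + 30 bp hairpin adaptor + 120 bp sequencing adaptor =
450 bp) lives in `protocol`. Cleavage probability per mismatch count
defaults to a linear decay 1.0 (0 mm) → 0.1 (6 mm), zero beyond: in
vitro per-site efficiencies are known to be site-specific and span a
wide range, so only the ordering is meaningful and nothing downstream
depends on the exact values. Base qualities are constant Q37.
Two sampling modes compose: uniformly drawn circles cleaved by the
Bernoulli model, and coverage targeting (`min_pairs_per_site`) that
draws circles over each cut until a requested number of cleaved pairs
is reached — the mode used in recovery experiments where read support
is a controlled variable, not an outcome.

**Insertion archetypes.** The seven `InsertionEvent` kinds reproduce
the junction configurations observed at sequenced integration loci:
precise on-target knock-in; on-target insertion with a ~4 kb deletion;
clean random insertion; random insertion with a ~1.7 kb tandem
duplication of adjacent genome; insertion into a microsatellite with a
62 bp junction gap; co-insertion of 623 bp of LTR-like sequence; and an
inverted-orientation insertion. Event records validate that exactly
the fields relevant to the kind are set, and genome length accounting
round-trips per kind.

**What the simulator does not model:** sequencing errors, PCR
duplicates, adaptor chemistry, chimeric artefacts of enzymatic
fragmentation, or reads crossing the circle's ligation junction
(fragments are sampled so both mates fit inside the fragment around
the cut). Passing recovery tests therefore demonstrates the logic of
the pipeline — thresholds, clustering, coordinate conventions — not
robustness to noisy base calls or mapping ambiguity on a real genome.

## Cleavage-site calling

Per (chromosome, strand), read 5′-end positions with MAPQ ≥ 50 are
tallied; reverse-strand 5′ ends at *p* are evidence for a cut at
*p + 1*. Evidence positions chain into candidates within
`window_size` (3 bp); a candidate is retained only with both strands
represented; candidates merge across gaps ≤ `gap_threshold` (3 bp);
a site requires ≥ 4 supporting reads and ≥ 1 distinct start position.
The merged window is anchored at the evidence span; read counts sum
both strands. Control subtraction (off by default — wildtype libraries
are analysed as separate samples) removes cut positions present in the
control before thresholding. `merged_analysis` records the upstream
convention of treating overlapping mate alignments as one molecule; in
this implementation mates never overlap (they flank the cut), so the
flag is carried in the parameter block for provenance.

The exact upstream semantics of `start_threshold` and `gap_threshold`
are not publicly specified; the interpretations above (distinct
evidence positions; merge distance) are configurable rather than
asserted as faithful.

Site sequences are extracted ±20 bp around the window midpoint (an
extraction width wide enough for any single-bulge placement of a
23-mer) and annotated with the best guide placement on either strand:
fewest mismatches, bulge-free preferred on ties; the PAM trinucleotide
is reported and flagged canonical/non-canonical rather than filtered.
Consensus PWMs are built over guide-oriented 23-mers; ties in the
per-column argmax break in fixed A<C<G<T order.

## Reference-free junction clustering

A read pair's junction signature is the concatenation of the two mate
5′ prefixes (k = 25 by default), canonicalized by taking the
lexicographic minimum over mate order and strand, so one junction
sequenced in any orientation maps to one key. Clustering is exact
signature equality; support is conserved (cluster supports sum to the
number of intact pairs, orphans logged). Exact matching is adequate
for error-free simulated reads; on real data a near-duplicate
collapse would be required first (known limitation).

## Protospacer search

Alignment topologies: bulge-free; a DNA bulge (one extra genomic base)
at each of the 19 interior gap positions; an RNA bulge (one unpaired
guide base) at each of positions 1–18. Ambiguous bases count as
mismatches; PAM patterns are NGG plus NGA/NAG when non-canonical PAMs
are enabled, with N matching any unambiguous base. A locus is keyed by
(chromosome, strand, PAM position) and reported once with its best
alignment — (mismatches, bulge) lexicographic rank, bulge-free
preferred on ties. Consequently a locus can report a bulged 0-mm
alignment in preference to a bulge-free 1-mm one, and planted sites
are commonly flanked by 1-bp-shifted "ghost" loci where a bulge plus a
shifted non-canonical PAM also satisfies the ceiling: both behaviors
follow from the locus definition and are covered by the exhaustive
oracle contract. The implementation is a numpy sliding comparison per
topology; the tests hold it equal to a per-position brute-force oracle
across mismatch ceilings and bulge settings.

The published post-filter sentence for in-silico candidates admits two
readings; both are provided as named predicates
(`keep_mm6_or_pam_mm_le2`, `drop_mm6_or_pam_mm_le2`) with pass-through
as the default, and neither is asserted as the original intent.

## Insertion-candidate pipeline

Reads from junction clusters are locally aligned to the donor cassette
(word size 11, match +2 / mismatch −3, ungapped X-drop extension);
significance uses Karlin–Altschul statistics, E = K·m·n·e^(−λS) with
the standard ungapped nucleotide parameters λ = 1.28, K = 0.46, and
the 1e-10 ceiling. Reads **with** a cassette hit carry the insertion
evidence; their longest non-cassette segment (≥ 20 bp) is aligned to
the genome under the same significance rule. Segments with multiple
equal-score loci are excluded as multi-mapping (repeat-borne
insertions therefore localize only from the side with unique flank —
the LTR co-insertion archetype demonstrates this, localizing from its
right-arm guide only). Genomic hits within 500 bp cluster; clusters
below 5 reads are eliminated; survivors are numbered by descending
support. The 500 bp gap is a read-length-scale choice (breakpoint
evidence from 150-bp reads spans ≲ 300 bp); the 2 kb on-target margin
covers homology-arm reach. Both are configurable.

Duplication and large-deletion events genuinely produce a second
junction whose genomic side lies 1–4 kb from the insertion point; the
pipeline reports these as separate candidates, mirroring how a
duplicated locus appears twice in a real candidate table before manual
merging. Cross-guide merging joins left/right-guide candidates within
the cluster gap, sums support, records provenance ids, and is
idempotent.

## Annotation

Region classes follow containment logic: fully intronic, exonic,
spanning an exon/intron boundary, or intergenic (the exonic-only label
is included for completeness). With several overlapping genes the one
covering most of the interval wins. Flanks are
[start − 500, start) ∪ [end, end + 500) — the candidate interval
itself is excluded — clipped at chromosome ends, with the clipped
width as the denominator of the repeat fraction, so the value is exact
under merged-interval arithmetic and stays in [0, 1]. DHS overlap is
plain interval intersection per embryonic stage. The flank-vs-cassette
homology scan reuses the local aligner with a 9-nt dotplot word and a
bit-score floor (default 28 bits).

## Validation statistics

Amplicon reads below mean Phred 30 are discarded; usable reads are
globally aligned (match 5 / mismatch −4 / gap −10/−1, free end gaps)
and count as mutated iff an insertion or deletion intersects the cut
± 10 bp; substitutions never count by default since they are
indistinguishable from PCR/sequencing noise at the relevant
frequencies. Fewer than 100 usable reads flags the sample; fewer than
2,000 total founder reads makes a site unevaluable.

**Verdict rule.** A mutation present by the four-cell stage is
expected in ~12.5 % of a founder's reads, versus a ~0.1 % background
observed equally in wildtype amplicons. A hard cutoff exactly at the
expectation would miss half of truly mosaic founders through binomial
sampling alone, so the positive call requires the founder frequency to
be consistent with the expectation — at least 12.5 % minus 3 binomial
standard errors at the site's read depth (≈ 10.3 % at 2,000 reads) —
and to exceed the wildtype maximum by more than the 0.1 % detection
limit (applied per site). Under this rule, simulated
wildtype-vs-wildtype comparisons at ≤ 0.2 % background produce no
positive calls across 50 sites, and a true 12.5 % mosaic at 2,000
reads is detected with empirical power > 0.99 over 1,000 binomial
replicates.

**Copy number.** Per (sample, primer set), Cq is regressed on
log2(input mass) over a seven-point dilution series (20 → 0.3125 ng);
the per-primer amplification factor is estimated from the pooled slope
(f = 2^(−1/slope), 2 at perfect efficiency) rather than assumed.
Quantities at the geometric-mean reference mass are normalized
target/normalizer and scaled to a calibrator of known copy number
(default 2, a homozygous reference animal). The estimator is invariant
to rescaling all input masses and recovers a true copy number of 3
within ±10 % at Cq noise σ = 0.05.

## Problem sizes

Recovery experiments run on 2 × 50 kb genomes with 12 planted sites
(0–6 mismatches, 5 pairs each) and one event of each insertion
archetype; the search-oracle sweep uses ten random 20-kb genomes
across mismatch ceilings {0, 3, 6} and both bulge settings; verdict
simulations use 50 sites / 1,000 replicates at 2,000 reads. These
sizes exercise every code path and keep the whole suite and the
acceptance script at desk scale.

## Known limitations

- Exact-signature junction clustering and the toy exact-match mapper
  assume error-free reads; real libraries need an external aligner
  (any SAM/BAM producer) and duplicate collapse.
- The local aligner extends seeds without gaps; donor/genome junctions
  with small indels near the breakpoint would shorten, not lose, their
  hits.
- Whole-genome (Gb-scale) enumeration is functional but not
  performance-engineered; no CFD/MIT-style cleavage scoring is
  provided.
- Repeat-mediated insertions localize only from flanks with unique
  sequence, as in the real assay.
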