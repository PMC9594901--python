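# kinspector

Screening CRISPR knock-in founder animals for the two lesions that
standard junction-PCR genotyping cannot see: **off-target Cas9
cleavage** and **random insertion of the donor DNA**. Both are read out
from one sequencing assay: genomic DNA is enzymatically fragmented
(~300 bp), self-ligated into circles, digested in vitro with a
Cas9–gRNA ribonucleoprotein, and sequenced as 150-bp read pairs. A
circle containing a protospacer match is linearized by the blunt
double-strand break, so the mate 5′ ends map immediately on either side
of the cut. Aiming the assay guides at the donor's homology arms turns
the same chemistry into a donor-integration detector: junction reads
carry cassette sequence on one side and the integration locus on the
other.

`kinspector` implements the complete computational side of this design,
plus a deterministic simulator so every stage can be exercised on toy
genomes with planted ground truth.

## What is in the box

| module | role |
|---|---|
| `kinspector.simulate` | toy genomes (repeats, gene models), planted protospacer matches at 0–7 mismatches, seven donor-insertion archetypes, circularized-library read pairs with truth records |
| `kinspector.sitecall` | cleavage-site calling from aligned reads (read_threshold 4, window_size 3, MAPQ ≥ 50, gap_threshold 3), reference-free junction clustering, guide-match annotation, consensus PWM, ranked report |
| `kinspector.offtarget` | genome-wide protospacer search: ≤ 6 mismatches, single-base DNA/RNA bulges, NGG plus NGA/NAG PAMs; postfilters; Venn comparison with called sites |
| `kinspector.insertion` | insertion-candidate pipeline: cassette classification by local alignment (E ≤ 1e-10), genomic localization of the non-cassette read segment, clustering (500 bp), ≥ 5-read filter, on-target flag, cross-guide merging |
| `kinspector.annotate` | region class (intronic / exonic / both / intergenic), flank repeat fraction (±500 bp), DHS overlap, flank-vs-cassette homology scan |
| `kinspector.validate` | amplicon indel frequency (mean Q ≥ 30, substitutions ignored, ±10 bp window), founder-vs-wildtype verdict against the 12.5 % mosaic expectation, qPCR donor copy number from dilution series |
| `kinspector.cli` | `kinspector sim / callsites / reffree / offtarget / ics / annotate / validate-amplicons / copy-number / run` |

### The statistics at the core

*Cleavage calling.* Read 5′-end pileups per strand; a cut at coordinate
*c* places forward 5′ ends at *c* and reverse 5′ ends at *c − 1*. A site
needs co-located starts on both strands within `window_size`, merged
over `gap_threshold`, with total supporting reads ≥ `read_threshold`.

*Protospacer search.* A locus (strand + PAM position) is reported with
its best alignment to the 20-nt guide: fewest mismatches, bulge-free on
ties. The scan is vectorised over every alignment topology (no bulge;
one extra genomic base at each interior gap position; one unpaired
guide base) and is contracted in the tests to equal an exhaustive
per-position oracle.

*Alignment significance.* Cassette and genome hits use word-seeded
ungapped local alignment (match +2 / mismatch −3) with Karlin–Altschul
E-values, `E = K·m·n·e^{−λS}` (λ = 1.28, K = 0.46), thresholded at
1e-10.

*Validation.* A founder is OT-positive only when its indel frequency is
consistent with the four-cell-stage mosaic expectation (12.5 %, minus a
3σ binomial allowance) **and** exceeds the wildtype maximum by more than
the 0.1 % detection limit. Donor copies come from efficiency-calibrated
ΔΔCq against a two-copy calibrator.

## Worked example

```python
from kinspector import simulate as sim, sitecall as sc

cfg = sim.SimConfig(seed=1)                      # 2 x 50 kb toy genome
toy = sim.build_toy_genome(cfg)
cassette, guide_l, guide_r = sim.make_cassette(seed=1)

sites = [sim.PlantedSite("chr1", 3000 + 2500 * i, "+", i % 7) for i in range(6)]
genome, truth = sim.plant_guide_sites(toy.genome, guide_l, sites, seed=1)
lib = sim.simulate_circle_library(genome, [guide_l], cfg,
                                  min_pairs_per_site=5,
                                  cuts=sim.cuts_from_planted(sites))
called = sc.call_cleavage_sites(sc.exact_map(lib.pairs, genome),
                                genome=genome, guide=guide_l)
print(sc.rank_report(called).head(6).to_string(index=False))
```

```
 rank chrom   pos  window_start  window_end  read_count  mismatches pam  on_target
    1  chr1  3001          3000        3001          10           0 AGG      False
    2  chr1  5501          5500        5501          10           1 AGG      False
    3  chr1  8001          8000        8001          10           2 AGG      False
    4  chr1 10501         10500       10501          10           3 AGG      False
    5  chr1 13001         13000       13001          10           4 AGG      False
    6  chr1 15501         15500       15501          10           5 AGG      False
```

Each planted cut is recovered at its exact coordinate (`pos` is
1-based), with 10 supporting reads (5 pairs, both mates counted) and
the correct mismatch annotation against the guide.

The same library drives the insertion workflow: plant an
`InsertionEvent` (e.g. `ri_flank_duplication`, duplication_len 1700),
simulate with both arm guides, and `kinspector.insertion.ics_pipeline`
returns one candidate at the breakpoint — plus, for duplication and
deletion archetypes, the genuine distal-junction cluster the real assay
also reports.

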