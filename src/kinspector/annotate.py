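"""Characterization of insertion-candidate loci.

Covers the descriptive layer of the analysis: which genomic
compartment a candidate falls in (intron / exon / both / intergenic),
how much of its flanking sequence (500 bp each side by default) is
repeat-masked, whether it touches DNase I hypersensitive sites from
early embryonic stages, and whether its flanks carry local homology to
the donor cassette.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import alignment


@dataclass(frozen=True)
class AnnotateParams:
    flank: int = 500
    min_homology_bits: float = 28.0
    dotplot_word: int = 9

    def __post_init__(self):
        if self.flank <= 0:
            raise ValueError("flank must be positive")


@dataclass(frozen=True)
class RegionCall:
    label: str  # on_target | intronic | exonic | exonic/intronic | intergenic
    gene_name: str | None = None

    def __post_init__(self):
        if (self.label == "intergenic") == (self.gene_name is not None):
            raise ValueError("gene_name present iff the region is genic")


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def classify_genomic_region(
    interval: tuple[str, int, int], gene_models
) -> RegionCall:
    """Classify an interval against exon/intron gene structure.

    Fully inside an intron -> intronic; touching both exon and intron
    of a gene -> exonic/intronic; inside exon only -> exonic; no gene
    overlap -> intergenic.  With several overlapping genes the one
    covering most of the interval wins.
    """
    chrom, start, end = interval
    if start >= end:
        raise ValueError("malformed interval")
    best = None
    for g in gene_models:
        if g.chrom != chrom:
            continue
        if not (g.start < end and start < g.end):
            continue
        ov = _overlap(start, end, g.start, g.end)
        if best is None or ov > best[0]:
            best = (ov, g)
    if best is None:
        return RegionCall("intergenic")
    g = best[1]
    if not g.exons:
        raise ValueError(f"gene model {g.name} has no exons")
    exon_ov = sum(_overlap(start, end, es, ee) for es, ee in g.exons)
    genic_ov = _overlap(start, end, g.start, g.end)
    intron_ov = genic_ov - exon_ov
    if exon_ov and intron_ov:
        return RegionCall("exonic/intronic", g.name)
    if exon_ov:
        return RegionCall("exonic", g.name)
    return RegionCall("intronic", g.name)


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def flank_repeat_fraction(
    interval: tuple[str, int, int],
    repeats,
    params: AnnotateParams = AnnotateParams(),
    chrom_length: int | None = None,
) -> float:
    """Fraction of the two flanks covered by (merged) repeat intervals.

    Flanks are [start-flank, start) and [end, end+flank), excluding the
    interval itself, clipped at the chromosome ends; the denominator is
    the clipped flank width so the value stays in [0, 1].
    """
    chrom, start, end = interval
    f = params.flank
    flanks = [(max(0, start - f), start), (end, end + f)]
    if chrom_length is not None:
        flanks = [(s, min(e, chrom_length)) for s, e in flanks]
    flanks = [(s, e) for s, e in flanks if e > s]
    total = sum(e - s for s, e in flanks)
    if total == 0:
        return 0.0
    reps = _merge_intervals(
        [
            (r.start, r.end)
            for r in repeats
            if r.chrom == chrom
        ]
    )
    covered = 0
    for fs, fe in flanks:
        for rs, re in reps:
            covered += _overlap(fs, fe, rs, re)
    return covered / total


def dhs_overlap(
    ics_list, dhs_by_stage: dict[str, list]
) -> pd.DataFrame:
    """Per-candidate, per-stage boolean open-chromatin overlap table."""
    stages = list(dhs_by_stage)
    rows = []
    for rec in ics_list:
        chrom, start, end = rec.interval() if hasattr(rec, "interval") else rec
        row = {"ics_id": getattr(rec, "id", None)}
        for stage in stages:
            hit = any(
                d.chrom == chrom and d.start < end and start < d.end
                for d in dhs_by_stage[stage]
            )
            row[stage] = hit
        rows.append(row)
    return pd.DataFrame(rows, columns=["ics_id"] + stages)


def flank_cassette_homology(
    flank_seq: str,
    cassette: str,
    params: AnnotateParams = AnnotateParams(),
) -> list[alignment.LocalHit]:
    """Dotplot-style local similarity segments flank vs cassette.

    All word-seeded maximal local alignments (both orientations) whose
    bit score reaches ``min_homology_bits`` are returned with
    coordinates on both sequences.
    """
    if not flank_seq or not cassette:
        raise ValueError("sequences must be non-empty")
    hits = alignment.local_align_hits(
        flank_seq, cassette, word_size=params.dotplot_word
    )
    return [h for h in hits if h.bitscore >= params.min_homology_bits]
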