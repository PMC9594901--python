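"""Donor-insertion candidate (ICS) pipeline.

Junction reads from the reference-free clustering stage are classified
by local alignment against the donor cassette; reads carrying cassette
sequence are the carriers of insertion evidence, and their non-cassette
segments are aligned to the genome to localize the integration locus.
Genomic hits cluster within ``cluster_gap``; clusters below
``min_reads`` supporting reads are eliminated; clusters at the intended
knock-in locus (within ``on_target_margin``) are flagged on-target; and
loci detected independently by the left- and right-arm assay guides are
merged into single insertion loci.

Significance for both alignment steps uses the extreme-value model over
the read x subject search space with a 1e-10 E-value ceiling by
default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import alignment
from .alignment import LocalHit, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ICSParams:
    evalue_max: float = 1e-10
    min_reads: int = 5
    cluster_gap: int = 500
    on_target_margin: int = 2000
    min_genomic_segment: int = 20
    word_size: int = 11

    def __post_init__(self):
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")


@dataclass(frozen=True)
class CassetteHit:
    read_id: str
    score: int
    evalue: float
    read_span: tuple[int, int]  # 0-based half-open on the read
    cassette_span: tuple[int, int]
    orientation: str  # '+' read matches cassette as given, '-' reverse


@dataclass
class GenomicCluster:
    chrom: str
    start: int
    end: int
    read_ids: list[str] = field(default_factory=list)
    guide_used: str = ""
    orientation: str = "+"

    @property
    def read_count(self) -> int:
        return len(set(self.read_ids))


@dataclass
class ICSRecord:
    id: int
    guide_used: str
    read_count: int
    chrom: str
    start: int
    end: int
    on_target: bool = False
    region_class: str = ""
    # provenance labels like "left:3" once records merge across guides
    merged_from: list[str] = field(default_factory=list)

    def interval(self) -> tuple[str, int, int]:
        return self.chrom, self.start, self.end


def cassette_classify(
    reads: dict[str, str],
    cassette: str,
    params: ICSParams = ICSParams(),
) -> tuple[list[CassetteHit], list[str]]:
    """Partition reads into cassette-positive hits and negative ids.

    Each read is locally aligned to the cassette in both orientations;
    the best hit is retained when its E-value is within
    ``params.evalue_max``.  The partition is exhaustive and disjoint.
    """
    if len(cassette) < params.word_size:
        raise ValueError("cassette shorter than the seeding word size")
    positive: list[CassetteHit] = []
    negative: list[str] = []
    for rid, seq in reads.items():
        hit = alignment.best_local_hit(
            seq, cassette, word_size=params.word_size, evalue_max=params.evalue_max
        )
        if hit is None:
            negative.append(rid)
        else:
            positive.append(
                CassetteHit(
                    read_id=rid,
                    score=hit.score,
                    evalue=hit.evalue,
                    read_span=(hit.query_start, hit.query_end),
                    cassette_span=(hit.subject_start, hit.subject_end),
                    orientation=hit.strand,
                )
            )
    return positive, negative


def _non_cassette_segment(seq: str, span: tuple[int, int]) -> tuple[str, int] | None:
    """Longest read segment outside the cassette hit, with its offset."""
    left = seq[: span[0]]
    right = seq[span[1] :]
    if len(left) >= len(right):
        return (left, 0) if left else None
    return (right, span[1]) if right else None


def localize_ics(
    hits: list[CassetteHit],
    reads: dict[str, str],
    genome,
    params: ICSParams = ICSParams(),
    guide_used: str = "",
) -> list[GenomicCluster]:
    """Map the genomic side of cassette-positive reads and cluster it.

    Reads whose non-cassette segment is shorter than
    ``min_genomic_segment`` or maps equally well to several loci are
    logged and excluded from localization.  Hits on one chromosome
    within ``cluster_gap`` of each other form one cluster; the cluster
    read count is the number of distinct supporting reads.
    """
    chroms = genome.chroms if hasattr(genome, "chroms") else dict(genome)
    indices = {
        name: alignment.WordIndex(seq, params.word_size)
        for name, seq in chroms.items()
    }
    placements: list[tuple[str, int, int, str, str]] = []
    short, multi, unmapped = 0, 0, 0
    for hit in hits:
        seq = reads[hit.read_id]
        seg = _non_cassette_segment(seq, hit.read_span)
        if seg is None or len(seg[0]) < params.min_genomic_segment:
            short += 1
            continue
        segment = seg[0]
        ghits = alignment.search_genome(
            segment, indices, evalue_max=params.evalue_max, word_size=params.word_size
        )
        if not ghits:
            unmapped += 1
            continue
        best = ghits[0][1].score
        top = [g for g in ghits if g[1].score == best]
        # distinct equal-score loci -> ambiguous, excluded
        loci = {(c, h.subject_start // max(1, params.cluster_gap)) for c, h in top}
        if len(loci) > 1:
            multi += 1
            continue
        chrom, h = top[0]
        placements.append((chrom, h.subject_start, h.subject_end, hit.read_id, h.strand))
    if short or multi or unmapped:
        logger.info(
            "localization skipped reads: %d short segment, %d multi-mapping, %d unmapped",
            short,
            multi,
            unmapped,
        )
    placements.sort(key=lambda t: (t[0], t[1]))
    clusters: list[GenomicCluster] = []
    for chrom, s, e, rid, strand in placements:
        last = clusters[-1] if clusters else None
        if last is not None and last.chrom == chrom and s - last.end <= params.cluster_gap:
            last.end = max(last.end, e)
            last.read_ids.append(rid)
        else:
            clusters.append(
                GenomicCluster(chrom, s, e, [rid], guide_used, strand)
            )
    return clusters


def filter_ics(
    clusters: list[GenomicCluster], params: ICSParams = ICSParams()
) -> list[ICSRecord]:
    """Eliminate clusters below the read-support floor; number survivors.

    Survivors are numbered 1..n by descending read count (ties broken
    by genomic position) — the ordering used in candidate tables.
    """
    keep = [c for c in clusters if c.read_count >= params.min_reads]
    keep.sort(key=lambda c: (-c.read_count, c.chrom, c.start))
    return [
        ICSRecord(
            id=i + 1,
            guide_used=c.guide_used,
            read_count=c.read_count,
            chrom=c.chrom,
            start=c.start,
            end=c.end,
            merged_from=[f"{c.guide_used}:{i + 1}" if c.guide_used else str(i + 1)],
        )
        for i, c in enumerate(keep)
    ]


def flag_on_target(
    ics: list[ICSRecord],
    target_locus: tuple[str, int, int],
    params: ICSParams = ICSParams(),
) -> list[ICSRecord]:
    """Mark candidates intersecting the knock-in locus +/- margin."""
    tc, ts, te = target_locus
    m = params.on_target_margin
    for rec in ics:
        rec.on_target = (
            rec.chrom == tc and rec.start < te + m and ts - m < rec.end
        )
    return ics


def merge_equivalent_ics(
    left_ics: list[ICSRecord],
    right_ics: list[ICSRecord],
    params: ICSParams = ICSParams(),
) -> list[ICSRecord]:
    """Merge candidates from the two assay guides at one locus.

    Records on the same chromosome within ``cluster_gap`` merge into a
    single locus carrying both source ids, with summed read support.
    Merging is idempotent.
    """
    pool = [
        ICSRecord(
            id=r.id,
            guide_used=r.guide_used,
            read_count=r.read_count,
            chrom=r.chrom,
            start=r.start,
            end=r.end,
            on_target=r.on_target,
            region_class=r.region_class,
            merged_from=list(r.merged_from)
            or [f"{r.guide_used}:{r.id}" if r.guide_used else str(r.id)],
        )
        for r in list(left_ics) + list(right_ics)
    ]
    pool.sort(key=lambda r: (r.chrom, r.start))
    merged: list[ICSRecord] = []
    for rec in pool:
        last = merged[-1] if merged else None
        if (
            last is not None
            and last.chrom == rec.chrom
            and rec.start - last.end <= params.cluster_gap
        ):
            last.end = max(last.end, rec.end)
            last.read_count += rec.read_count
            last.merged_from = sorted(set(last.merged_from + rec.merged_from))
            last.on_target = last.on_target or rec.on_target
            if rec.guide_used and rec.guide_used not in last.guide_used:
                last.guide_used = (
                    f"{last.guide_used}+{rec.guide_used}"
                    if last.guide_used
                    else rec.guide_used
                )
        else:
            merged.append(rec)
    merged.sort(key=lambda r: (-r.read_count, r.chrom, r.start))
    for i, rec in enumerate(merged):
        rec.id = i + 1
    return merged


def ics_vs_ocs_overlap(ics: list[ICSRecord], ocs, slop: int = 0) -> pd.DataFrame:
    """Per-candidate nearest cleavage site distance and overlap flag.

    ``ocs`` items need chrom plus window_start/window_end (called
    sites) or start/end attributes.  One row per insertion candidate.
    """
    rows = []
    for rec in ics:
        nearest = None
        overlap = False
        for s in ocs:
            if s.chrom != rec.chrom:
                continue
            ss = getattr(s, "window_start", getattr(s, "start", None))
            se = getattr(s, "window_end", getattr(s, "end", None))
            if rec.start < se + slop and ss - slop < rec.end:
                overlap = True
                dist = 0
            else:
                dist = max(ss - rec.end + 1, rec.start - se + 1)
            nearest = dist if nearest is None else min(nearest, dist)
        rows.append(
            {
                "ics_id": rec.id,
                "chrom": rec.chrom,
                "start": rec.start,
                "end": rec.end,
                "nearest_ocs_distance": nearest,
                "overlaps_ocs": overlap,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ics_id",
            "chrom",
            "start",
            "end",
            "nearest_ocs_distance",
            "overlaps_ocs",
        ],
    )


def ics_table(ics: list[ICSRecord]) -> pd.DataFrame:
    """Candidate table in the standard column layout."""
    return pd.DataFrame(
        [
            {
                "ics_id": r.id,
                "guide_used": r.guide_used,
                "n_reads": r.read_count,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "on_target": r.on_target,
                "region": r.region_class,
                "merged_from": ",".join(map(str, r.merged_from)),
            }
            for r in ics
        ],
        columns=[
            "ics_id",
            "guide_used",
            "n_reads",
            "chrom",
            "start",
            "end",
            "on_target",
            "region",
            "merged_from",
        ],
    )


def ics_pipeline(
    pairs_by_guide: dict[str, list],
    cassette: str,
    genome,
    params: ICSParams = ICSParams(),
    target_locus: tuple[str, int, int] | None = None,
) -> list[ICSRecord]:
    """Reference-free clusters -> cassette classify -> localize ->
    filter -> on-target flag -> cross-guide merge, per assay guide."""
    from .sitecall import reference_free_identify

    per_guide: dict[str, list[ICSRecord]] = {}
    for label, pairs in pairs_by_guide.items():
        reads = {}
        for p in pairs:
            reads[f"{p.name}/1"] = p.seq1
            reads[f"{p.name}/2"] = p.seq2
        reference_free_identify(pairs)  # junction QC/grouping stage
        hits, _neg = cassette_classify(reads, cassette, params)
        clusters = localize_ics(hits, reads, genome, params, guide_used=label)
        records = filter_ics(clusters, params)
        if target_locus is not None:
            records = flag_on_target(records, target_locus, params)
        per_guide[label] = records
    labels = list(per_guide)
    if len(labels) == 1:
        merged = merge_equivalent_ics(per_guide[labels[0]], [], params)
    else:
        merged = merge_equivalent_ics(
            per_guide.get("left", per_guide[labels[0]]),
            per_guide.get("right", per_guide[labels[1]]),
            params,
        )
    if target_locus is not None:
        merged = flag_on_target(merged, target_locus, params)
    return merged
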