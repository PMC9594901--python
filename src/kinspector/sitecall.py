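"""Cleavage-site calling from digest read alignments.

Reference-based mode tallies read 5'-end positions per strand: a blunt
double-strand break in a circularized fragment produces forward-strand
5' ends at the cut coordinate and reverse-strand 5' ends immediately
upstream, so a genuine cleavage shows co-located start pileups on both
strands.  Candidate positions require both strands within
``window_size``; nearby candidates merge within ``gap_threshold``; a
site is emitted when its supporting read count reaches
``read_threshold`` (default 4) with at least ``start_threshold``
distinct start positions, after discarding alignments below
``mapq_threshold`` (default 50).

Reference-free mode clusters read pairs by a strand-canonical junction
signature built from the mate 5' prefixes, so cleavage loci can be
grouped without a genome — the entry point of the insertion-candidate
workflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import revcomp
from .offtarget import GuideMatch, GuideSpec, align_guide_to_window

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SiteCallParams:
    read_threshold: int = 4
    window_size: int = 3
    mapq_threshold: int = 50
    start_threshold: int = 1
    gap_threshold: int = 3
    mismatch_threshold: int = 6
    merged_analysis: bool = True
    site_seq_flank: int = 20  # extraction half-width around the window midpoint

    def __post_init__(self):
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        for f in (
            "read_threshold",
            "mapq_threshold",
            "start_threshold",
            "gap_threshold",
            "mismatch_threshold",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


@dataclass(frozen=True)
class AlignedRead:
    read_id: str
    chrom: str
    start: int  # 0-based leftmost aligned position
    end: int  # half-open rightmost
    strand: str
    mapq: int
    sample_tag: str = ""
    mate_id: str | None = None

    @property
    def five_prime(self) -> int:
        """5'-end coordinate: leftmost for '+', rightmost base for '-'."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class CleavageSite:
    chrom: str
    window_start: int
    window_end: int
    read_count: int
    fwd_starts: int
    rev_starts: int
    site_seq: str = ""
    guide_match: GuideMatch | None = None

    @property
    def midpoint(self) -> int:
        return (self.window_start + self.window_end) // 2


def reads_from_sam(path, sample_tag: str = "") -> list[AlignedRead]:
    """Load mapped primary alignments from a SAM/BAM file."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path)) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            out.append(
                AlignedRead(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    mapq=rec.mapping_quality,
                    sample_tag=sample_tag,
                )
            )
    return out


def exact_map(pairs, genome) -> list[AlignedRead]:
    """Toy exact-match mapper for simulated error-free reads.

    Each mate is located by exact substring search on both strands;
    unique hits get MAPQ 60, multi-mapping reads MAPQ 0, unmapped
    reads are dropped.  Only suitable for toy genomes.
    """
    out: list[AlignedRead] = []
    chrom_items = list(genome.chroms.items()) if hasattr(genome, "chroms") else list(
        genome.items()
    )
    for pair in pairs:
        for mate, seq in (("1", pair.seq1), ("2", pair.seq2)):
            hits = []
            rc = revcomp(seq)
            for chrom, cseq in chrom_items:
                for strand, probe in (("+", seq), ("-", rc)):
                    p = cseq.find(probe)
                    while p != -1:
                        hits.append((chrom, p, strand))
                        p = cseq.find(probe, p + 1)
                        if len(hits) > 2:
                            break
            if not hits:
                continue
            mapq = 60 if len(hits) == 1 else 0
            chrom, p, strand = hits[0]
            out.append(
                AlignedRead(
                    read_id=f"{pair.name}/{mate}",
                    chrom=chrom,
                    start=p,
                    end=p + len(seq),
                    strand=strand,
                    mapq=mapq,
                    mate_id=f"{pair.name}/{'2' if mate == '1' else '1'}",
                )
            )
    return out


def _cut_evidence(reads: list[AlignedRead], mapq_threshold: int):
    """Per-(chrom, inferred cut) forward/reverse 5'-end counts.

    A forward 5' end at p is evidence for a cut at p; a reverse 5'
    end at p is evidence for a cut at p+1 (the blunt break sits
    between the two mate 5' ends).
    """
    fwd: dict[tuple[str, int], int] = {}
    rev: dict[tuple[str, int], int] = {}
    for r in reads:
        if r.mapq < mapq_threshold:
            continue
        if r.strand == "+":
            key = (r.chrom, r.five_prime)
            fwd[key] = fwd.get(key, 0) + 1
        else:
            key = (r.chrom, r.five_prime + 1)
            rev[key] = rev.get(key, 0) + 1
    return fwd, rev


def call_cleavage_sites(
    reads: list[AlignedRead],
    params: SiteCallParams = SiteCallParams(),
    control: list[AlignedRead] | None = None,
    genome=None,
    guide: GuideSpec | None = None,
) -> list[CleavageSite]:
    """Call cleavage sites from aligned digest reads.

    When ``genome`` (and optionally ``guide``) are supplied, a
    sequence window around each site is extracted and annotated with
    the best guide alignment.  Output is sorted by read count,
    descending, with a stable (chrom, position) tie-break.
    """
    if not reads:
        return []
    fwd, rev = _cut_evidence(reads, params.mapq_threshold)
    if control:
        cf, cr = _cut_evidence(control, params.mapq_threshold)
        for key in list(fwd):
            if key in cf:
                del fwd[key]
        for key in list(rev):
            if key in cr:
                del rev[key]
    positions: dict[str, list[int]] = {}
    for chrom, pos in set(fwd) | set(rev):
        positions.setdefault(chrom, []).append(pos)
    sites: list[CleavageSite] = []
    for chrom, plist in positions.items():
        plist.sort()
        # chain evidence positions into candidate clusters within
        # window_size, then merge candidates separated by <= gap_threshold
        clusters: list[list[int]] = []
        for p in plist:
            if clusters and p - clusters[-1][-1] <= params.window_size:
                clusters[-1].append(p)
            else:
                clusters.append([p])
        # keep candidates with both strands represented
        candidates = []
        for cl in clusters:
            has_f = any((chrom, p) in fwd for p in cl)
            has_r = any((chrom, p) in rev for p in cl)
            if has_f and has_r:
                candidates.append(cl)
        # merge candidates separated by <= gap_threshold
        merged: list[list[int]] = []
        for cl in candidates:
            if merged and cl[0] - merged[-1][-1] <= params.gap_threshold:
                merged[-1].extend(cl)
            else:
                merged.append(list(cl))
        for cl in merged:
            f_reads = sum(fwd.get((chrom, p), 0) for p in cl)
            r_reads = sum(rev.get((chrom, p), 0) for p in cl)
            n_reads = f_reads + r_reads
            f_starts = sum(1 for p in cl if (chrom, p) in fwd)
            r_starts = sum(1 for p in cl if (chrom, p) in rev)
            if n_reads < params.read_threshold:
                continue
            if f_starts + r_starts < params.start_threshold:
                continue
            sites.append(
                CleavageSite(
                    chrom=chrom,
                    window_start=cl[0],
                    window_end=cl[-1] + 1,
                    read_count=n_reads,
                    fwd_starts=f_starts,
                    rev_starts=r_starts,
                )
            )
    if genome is not None:
        for s in sites:
            s.site_seq = extract_site_window(genome, s, params.site_seq_flank)
            if guide is not None and s.site_seq:
                m = align_guide_to_window(
                    s.site_seq, guide, max_mismatches=params.mismatch_threshold
                )
                s.guide_match = m
                if m is not None:
                    s.site_seq = m.site_seq  # 23-mer in guide orientation
    sites.sort(key=lambda s: (-s.read_count, s.chrom, s.window_start))
    return sites


def extract_site_window(genome, site: CleavageSite, flank: int = 20) -> str:
    """Sequence +/- ``flank`` bp around the site-window midpoint."""
    if site.chrom not in genome:
        raise KeyError(f"chromosome {site.chrom!r} absent from genome")
    seq = genome[site.chrom]
    mid = site.midpoint
    return seq[max(0, mid - flank) : min(len(seq), mid + flank + 1)]


def annotate_site_vs_guide(
    site_seq: str, guide: GuideSpec, params: SiteCallParams = SiteCallParams()
) -> GuideMatch | None:
    """Best guide alignment inside an extracted site window.

    Returns None when the best alignment exceeds the mismatch
    threshold.  Ambiguous bases count as mismatches; non-canonical
    PAMs are reported with ``canonical=False`` rather than rejected.
    """
    return align_guide_to_window(
        site_seq, guide, max_mismatches=params.mismatch_threshold
    )


# ---------------------------------------------------------------------------
# reference-free junction clustering

@dataclass
class JunctionCluster:
    signature: str
    support: int
    members: list[str] = field(default_factory=list)  # read-pair names


def junction_signature(seq1: str, seq2: str, k: int) -> str:
    """Strand-canonical junction signature of a read pair.

    The concatenated mate prefixes read the genomic sequence flanking
    the cut; the signature is the lexicographic minimum over mate
    order and strand so that the same junction sequenced in either
    orientation, with either end labelled read 1, collapses to one key.
    """
    a, b = seq1[:k].upper(), seq2[:k].upper()
    ra, rb = revcomp(a), revcomp(b)
    return min(a + b, b + a, rb + ra, ra + rb)


def reference_free_identify(pairs, k: int = 25) -> list[JunctionCluster]:
    """Cluster read pairs by junction signature, no genome required.

    Pairs are conserved: the supports of all clusters sum to the
    number of intact input pairs; mates that cannot be paired are
    counted, logged and excluded.
    """
    clusters: dict[str, JunctionCluster] = {}
    orphans = 0
    for pair in pairs:
        if not pair.seq1 or not pair.seq2:
            orphans += 1
            continue
        sig = junction_signature(pair.seq1, pair.seq2, k)
        cl = clusters.get(sig)
        if cl is None:
            cl = clusters[sig] = JunctionCluster(sig, 0)
        cl.support += 1
        cl.members.append(pair.name)
    if orphans:
        logger.info("%d orphan mates excluded from junction clustering", orphans)
    out = list(clusters.values())
    out.sort(key=lambda c: (-c.support, c.signature))
    return out


# ---------------------------------------------------------------------------
# consensus PWM and ranking report

PWM_BASES = "ACGT"


@dataclass
class PWM:
    matrix: np.ndarray  # 4 x L column-stochastic
    consensus: str

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


def consensus_pwm(sites: list[CleavageSite], weight_by_reads: bool = False) -> PWM:
    """Position weight matrix over guide-oriented site sequences.

    Columns are base frequencies (optionally read-count weighted);
    the consensus takes the argmax base per column with ties broken
    in fixed A<C<G<T order.
    """
    seqs = [(s.site_seq, s.read_count) for s in sites if s.site_seq]
    if not seqs:
        raise ValueError("no site sequences to build a PWM from")
    L = len(seqs[0][0])
    if any(len(q) != L for q, _ in seqs):
        raise ValueError("site sequences must share one length")
    counts = np.zeros((4, L))
    for seq, rc in seqs:
        w = rc if weight_by_reads else 1
        for j, b in enumerate(seq):
            i = PWM_BASES.find(b)
            if i >= 0:
                counts[i, j] += w
    colsum = counts.sum(axis=0)
    colsum[colsum == 0] = 1
    matrix = counts / colsum
    consensus = "".join(PWM_BASES[int(np.argmax(matrix[:, j]))] for j in range(L))
    return PWM(matrix, consensus)


def rank_report(
    sites: list[CleavageSite], target_locus: tuple[str, int, int] | None = None
) -> pd.DataFrame:
    """Ranked site table (Manhattan-plot input).

    Columns: rank, chrom, pos (1-based midpoint), window_start,
    window_end, read_count, mismatches, pam, on_target.  Sorted by
    read count descending with a stable (chrom, pos) tie-break.
    """
    rows = []
    for s in sorted(sites, key=lambda x: (-x.read_count, x.chrom, x.window_start)):
        on_target = False
        if target_locus is not None:
            tc, ts, te = target_locus
            on_target = s.chrom == tc and s.window_start < te and ts < s.window_end
        rows.append(
            {
                "chrom": s.chrom,
                "pos": s.midpoint + 1,
                "window_start": s.window_start,
                "window_end": s.window_end,
                "read_count": s.read_count,
                "mismatches": s.guide_match.mismatches if s.guide_match else None,
                "pam": s.guide_match.pam if s.guide_match else None,
                "on_target": on_target,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "window_start",
            "window_end",
            "read_count",
            "mismatches",
            "pam",
            "on_target",
        ],
    )
    df.insert(0, "rank", range(1, len(df) + 1))
    return df
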