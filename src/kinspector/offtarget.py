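"""Genome-wide in-silico enumeration of candidate protospacer matches.

For an SpCas9-style guide the search reports every locus whose best
alignment to the 20-nt protospacer has at most ``max_mismatches``
mismatches, allowing single-base bulges on either strand of the
RNA:DNA duplex (a DNA bulge is an extra genomic base, an RNA bulge an
unpaired guide base), with the adjacent PAM trinucleotide drawn from
the canonical NGG or, optionally, the common non-canonical NGA/NAG
set.  Both genomic strands are scanned.  Each locus (keyed by strand
and PAM position) is reported once with its best alignment: fewest
mismatches first, bulge-free alignments preferred on ties.

The scan itself is a vectorised sliding comparison over every
alignment topology; correctness is contracted against an exhaustive
per-position oracle in the test-suite rather than against any
particular search heuristic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import revcomp

logger = logging.getLogger(__name__)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class GuideSpec:
    """A guide RNA: 20-nt protospacer plus PAM model for SpCas9."""

    name: str
    protospacer: str
    pam_canonical: str = "NGG"
    pam_noncanonical: tuple[str, ...] = ("NGA", "NAG")
    cut_offset: int = -3  # blunt cut 3 bp 5' of the PAM

    def __post_init__(self):
        ps = self.protospacer.upper()
        if len(ps) != 20 or set(ps) - set("ACGT"):
            raise ValueError("protospacer must be a 20-nt ACGT string")
        object.__setattr__(self, "protospacer", ps)

    @property
    def length(self) -> int:
        return len(self.protospacer)


@dataclass(frozen=True)
class SearchParams:
    max_mismatches: int = 6
    max_dna_bulge: int = 1
    max_rna_bulge: int = 1
    pam_mode: str = "include_noncanonical"  # or "canonical_only"
    postfilter: str = "identity"

    def __post_init__(self):
        if self.max_dna_bulge > 1 or self.max_rna_bulge > 1:
            raise ValueError("bulge sizes above 1 are not supported")
        if self.pam_mode not in ("canonical_only", "include_noncanonical"):
            raise ValueError(f"unknown pam_mode {self.pam_mode!r}")


@dataclass(frozen=True)
class CandidateSite:
    """An enumerated protospacer match (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    matched_seq: str
    mismatches: int
    bulge_kind: str  # "none" | "dna" | "rna"
    bulge_size: int
    pam: str
    canonical: bool


def _pam_matches(pam: str, pattern: str) -> bool:
    return all(p == "N" or p == b for p, b in zip(pattern, pam))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.upper().translate(str.maketrans("ACGTN", "\x00\x01\x02\x03\x04")).encode(
            "latin1"
        ),
        dtype=np.uint8,
    )


def _alignment_topologies(params: SearchParams, glen: int):
    """Yield (bulge_kind, bulge_pos, guide_offsets, target_offsets, span).

    ``span`` is the length of the genomic protospacer region (PAM
    immediately follows it).  Offsets pair guide base k with a target
    offset; RNA bulges drop one guide base from the pairing.
    """
    yield "none", 0, list(range(glen)), list(range(glen)), glen
    if params.max_dna_bulge >= 1:
        for j in range(1, glen):  # extra target base between guide j-1 and j
            t = [k if k < j else k + 1 for k in range(glen)]
            yield "dna", j, list(range(glen)), t, glen + 1
    if params.max_rna_bulge >= 1:
        for j in range(1, glen - 1):  # guide base j unpaired
            g = [k for k in range(glen) if k != j]
            t = [k if k < j else k - 1 for k in g]
            yield "rna", j, g, t, glen - 1


def _pam_patterns(guide: GuideSpec, params: SearchParams) -> list[tuple[str, bool]]:
    pats = [(guide.pam_canonical, True)]
    if params.pam_mode == "include_noncanonical":
        pats += [(p, False) for p in guide.pam_noncanonical]
    return pats


def enumerate_offtargets(
    genome: dict[str, str],
    guide: GuideSpec,
    params: SearchParams = SearchParams(),
) -> list[CandidateSite]:
    """Enumerate all candidate protospacer matches in a genome.

    Returns candidates sorted by (chrom, start, strand); each locus
    appears exactly once with its best-scoring alignment.
    """
    glen = guide.length
    gcode = _encode(guide.protospacer)
    pam_patterns = _pam_patterns(guide, params)
    topologies = list(_alignment_topologies(params, glen))
    # best alignment per locus key (chrom, strand, pam genomic start)
    best: dict[tuple[str, str, int], tuple] = {}

    for chrom, seq in genome.items():
        seq = seq.upper()
        n_count = seq.count("N")
        if n_count:
            logger.info("%s: %d ambiguous bases treated as mismatches", chrom, n_count)
        L = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            code = _encode(s)
            is_n = code == 4
            for kind, bpos, goffs, toffs, span in topologies:
                win = L - span - 3 + 1
                if win <= 0:
                    continue
                mm = np.zeros(win, dtype=np.int16)
                for gk, tk in zip(goffs, toffs):
                    seg = code[tk : tk + win]
                    mm += (seg != gcode[gk]) | is_n[tk : tk + win]
                ok = mm <= params.max_mismatches
                if not ok.any():
                    continue
                # PAM check for each pattern
                pam_ok = np.zeros(win, dtype=bool)
                for pat, _canon in pam_patterns:
                    this = np.ones(win, dtype=bool)
                    for pi, pb in enumerate(pat):
                        if pb == "N":
                            this &= ~is_n[span + pi : span + pi + win]
                        else:
                            this &= code[span + pi : span + pi + win] == _BASE_CODE[pb]
                    pam_ok |= this
                idx = np.nonzero(ok & pam_ok)[0]
                bsize = 0 if kind == "none" else 1
                for i in idx:
                    i = int(i)
                    pam = s[i + span : i + span + 3]
                    # genomic coordinates of the full protospacer+PAM window
                    if strand == "+":
                        gstart, gend = i, i + span + 3
                        pam_start = i + span
                    else:
                        gstart, gend = L - (i + span + 3), L - i
                        pam_start = gstart  # PAM is at the low-coordinate end
                    key = (chrom, strand, pam_start)
                    rank = (int(mm[i]), bsize, 0 if kind == "none" else 1)
                    prev = best.get(key)
                    if prev is None or rank < prev[0]:
                        matched = s[i : i + span + 3]
                        best[key] = (
                            rank,
                            CandidateSite(
                                chrom=chrom,
                                start=gstart,
                                end=gend,
                                strand=strand,
                                matched_seq=matched,
                                mismatches=int(mm[i]),
                                bulge_kind=kind,
                                bulge_size=bsize,
                                pam=pam,
                                canonical=_pam_matches(pam, guide.pam_canonical),
                            ),
                        )
    out = [v[1] for v in best.values()]
    out.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return out


# ---------------------------------------------------------------------------
# post-filters

def _pam_mismatches_vs_ngg(pam: str) -> int:
    return sum(1 for a, b in zip("NGG", pam) if a != "N" and a != b)


POSTFILTERS = {
    # report everything (default: the published filter sentence admits
    # two readings, both provided below without asserting either)
    "identity": lambda c: True,
    # keep sites that either carry exactly six spacer mismatches or a
    # PAM within two mismatches of canonical NGG
    "keep_mm6_or_pam_mm_le2": lambda c: c.mismatches == 6
    or _pam_mismatches_vs_ngg(c.pam) <= 2,
    # drop that same class
    "drop_mm6_or_pam_mm_le2": lambda c: not (
        c.mismatches == 6 or _pam_mismatches_vs_ngg(c.pam) <= 2
    ),
    "mm_le_5": lambda c: c.mismatches <= 5,
}


def apply_postfilter(
    candidates: list[CandidateSite], rule: str = "identity"
) -> list[CandidateSite]:
    """Apply a registered pure predicate; output is a subset of input."""
    try:
        pred = POSTFILTERS[rule]
    except KeyError:
        raise ValueError(
            f"unknown postfilter {rule!r}; known: {sorted(POSTFILTERS)}"
        ) from None
    return [c for c in candidates if pred(c)]


# ---------------------------------------------------------------------------
# set comparison against empirically called sites

@dataclass
class OverlapSummary:
    a_only: int
    b_only: int
    both: int
    matched_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def total_a(self) -> int:
        return self.a_only + self.both

    @property
    def total_b(self) -> int:
        return self.b_only + self.both


def intersect_site_sets(empirical, insilico, slop: int = 0) -> OverlapSummary:
    """Venn-style comparison of two interval site sets.

    ``empirical`` items need chrom/window_start/window_end attributes
    (called cleavage sites); ``insilico`` items are CandidateSites.
    Intervals overlap when they intersect after padding each empirical
    window by ``slop`` on both sides.  Each site counts once.
    """
    a_chroms = {getattr(s, "chrom") for s in empirical}
    b_chroms = {c.chrom for c in insilico}
    if empirical and insilico and not (a_chroms & b_chroms):
        logger.warning("site sets share no chromosome names; build mismatch?")
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for ia, s in enumerate(empirical):
        s_start = getattr(s, "window_start", getattr(s, "start", None))
        s_end = getattr(s, "window_end", getattr(s, "end", None))
        hit = None
        for ib, c in enumerate(insilico):
            if ib in used_b or c.chrom != s.chrom:
                continue
            if s_start - slop < c.end and c.start < s_end + slop:
                hit = ib
                break
        if hit is not None:
            used_b.add(hit)
            pairs.append((ia, hit))
    both = len(pairs)
    return OverlapSummary(
        a_only=len(list(empirical)) - both,
        b_only=len(list(insilico)) - both,
        both=both,
        matched_pairs=pairs,
    )


# ---------------------------------------------------------------------------
# small-window guide alignment (shared with site annotation)

@dataclass(frozen=True)
class GuideMatch:
    mismatches: int
    bulge_kind: str
    bulge_size: int
    pam: str
    canonical: bool
    strand: str
    site_seq: str  # protospacer+PAM in guide orientation


def align_guide_to_window(
    window: str,
    guide: GuideSpec,
    max_mismatches: int = 6,
    max_dna_bulge: int = 1,
    max_rna_bulge: int = 1,
) -> GuideMatch | None:
    """Best placement of the guide inside a short sequence window.

    Both orientations of the window are tried; the PAM trinucleotide
    is reported but not constrained (non-canonical PAMs are flagged,
    not rejected).  Returns None when no placement is within the
    mismatch ceiling.
    """
    params = SearchParams(
        max_mismatches=max_mismatches,
        max_dna_bulge=max_dna_bulge,
        max_rna_bulge=max_rna_bulge,
    )
    glen = guide.length
    gp = guide.protospacer
    best: tuple | None = None
    for strand in "+-":
        s = window.upper() if strand == "+" else revcomp(window.upper())
        for kind, _bpos, goffs, toffs, span in _alignment_topologies(params, glen):
            for i in range(len(s) - span - 3 + 1):
                mm = 0
                for gk, tk in zip(goffs, toffs):
                    b = s[i + tk]
                    if b != gp[gk] or b == "N":
                        mm += 1
                        if mm > max_mismatches:
                            break
                else:
                    pam = s[i + span : i + span + 3]
                    bsize = 0 if kind == "none" else 1
                    rank = (mm, bsize, 0 if kind == "none" else 1)
                    if best is None or rank < best[0]:
                        best = (
                            rank,
                            GuideMatch(
                                mismatches=mm,
                                bulge_kind=kind,
                                bulge_size=bsize,
                                pam=pam,
                                canonical=_pam_matches(pam, guide.pam_canonical),
                                strand=strand,
                                site_seq=s[i : i + span + 3],
                            ),
                        )
    return best[1] if best else None
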