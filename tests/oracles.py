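"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written as direct, per-position loops
(or delegated to Biopython's dynamic-programming aligner) so that it
shares no code path with the package's own vectorised or seeded
algorithms.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def pam_ok(pam: str, patterns) -> bool:
    for pat in patterns:
        if len(pam) == len(pat) and all(
            (p == "N" and b in "ACGT") or p == b for p, b in zip(pat, pam)
        ):
            return True
    return False


def brute_force_offtargets(
    genome: dict[str, str],
    protospacer: str,
    max_mm: int,
    pam_patterns=("NGG", "NGA", "NAG"),
    allow_dna_bulge: bool = True,
    allow_rna_bulge: bool = True,
):
    """Every locus matching the guide, by per-position direct comparison.

    Returns {(chrom, strand, pam_genomic_start): (mm, bulge_size, kind_rank)}
    keeping the best (fewest mismatches, bulge-free preferred) per locus.
    """
    g = protospacer
    n = len(g)
    best: dict[tuple, tuple] = {}

    def consider(chrom, strand, pam_start, mm, bulge):
        key = (chrom, strand, pam_start)
        rank = (mm, bulge, bulge)
        if key not in best or rank < best[key]:
            best[key] = rank

    for chrom, fwd in genome.items():
        L = len(fwd)
        for strand in "+-":
            s = fwd if strand == "+" else rc(fwd)
            for i in range(L):
                # bulge-free: target[i:i+n] vs guide, PAM at i+n
                if i + n + 3 <= L:
                    mm = 0
                    for k in range(n):
                        if s[i + k] != g[k] or s[i + k] == "N":
                            mm += 1
                            if mm > max_mm:
                                break
                    if mm <= max_mm and pam_ok(s[i + n : i + n + 3], pam_patterns):
                        pam_start = i + n if strand == "+" else L - (i + n) - 3
                        consider(chrom, strand, pam_start, mm, 0)
                # DNA bulge: one extra target base at gap position j
                if allow_dna_bulge and i + n + 4 <= L:
                    for j in range(1, n):
                        mm = 0
                        for k in range(n):
                            t = s[i + k] if k < j else s[i + k + 1]
                            if t != g[k] or t == "N":
                                mm += 1
                                if mm > max_mm:
                                    break
                        if mm <= max_mm and pam_ok(
                            s[i + n + 1 : i + n + 4], pam_patterns
                        ):
                            pam_start = (
                                i + n + 1 if strand == "+" else L - (i + n + 1) - 3
                            )
                            consider(chrom, strand, pam_start, mm, 1)
                # RNA bulge: guide base j unpaired (target one shorter)
                if allow_rna_bulge and i + n + 2 <= L:
                    for j in range(1, n - 1):
                        mm = 0
                        for k in range(n):
                            if k == j:
                                continue
                            t = s[i + k] if k < j else s[i + k - 1]
                            if t != g[k] or t == "N":
                                mm += 1
                                if mm > max_mm:
                                    break
                        if mm <= max_mm and pam_ok(
                            s[i + n - 1 : i + n + 2], pam_patterns
                        ):
                            pam_start = (
                                i + n - 1 if strand == "+" else L - (i + n - 1) - 3
                            )
                            consider(chrom, strand, pam_start, mm, 1)
    return {k: (v[0], v[1]) for k, v in best.items()}


def best_local_score(query: str, subject: str) -> int:
    """Best Smith-Waterman local score (both strands) via Biopython."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    fwd = aligner.score(subject, query)
    rev = aligner.score(subject, rc(query))
    return int(max(fwd, rev))
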