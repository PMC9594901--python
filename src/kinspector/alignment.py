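"""Word-seeded local sequence alignment with extreme-value significance.

Small BLASTN-flavoured aligner used to classify junction reads against a
donor cassette and to localize their genomic segments on toy genomes.
Seeds are exact words shared between query and subject; each seed is
extended without gaps in both directions under an X-drop rule.  Hit
significance follows the Karlin-Altschul theory for local alignment
scores: E = K * m * n * exp(-lambda * S), with the standard nucleotide
parameters for the +2/-3 match/mismatch scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Karlin-Altschul parameters for match +2 / mismatch -3 (ungapped).
KA_LAMBDA = 1.28
KA_K = 0.46

DEFAULT_MATCH = 2
DEFAULT_MISMATCH = -3
DEFAULT_WORD_SIZE = 11
DEFAULT_XDROP = 20


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LocalHit:
    """A local alignment segment between a query and a subject sequence.

    Coordinates are 0-based half-open on the forward strand of each
    sequence.  ``strand`` is '+' when the query aligns to the subject
    as given and '-' when it aligns to the reverse complement; in the
    latter case ``query_start/query_end`` still refer to the forward
    orientation of the query.
    """

    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    score: int
    evalue: float

    @property
    def length(self) -> int:
        return self.query_end - self.query_start

    @property
    def bitscore(self) -> float:
        return (KA_LAMBDA * self.score - math.log(KA_K)) / math.log(2)


def evalue(score: int, query_len: int, subject_len: int) -> float:
    """Karlin-Altschul expected number of chance hits at this score."""
    return KA_K * query_len * subject_len * math.exp(-KA_LAMBDA * score)


class WordIndex:
    """Reusable exact-word index of a subject sequence.

    Build once per subject when aligning many queries (e.g. localizing
    every junction read against a genome).
    """

    def __init__(self, subject: str, word_size: int = DEFAULT_WORD_SIZE):
        self.subject = subject.upper()
        self.word_size = word_size
        self.words = _index_words(self.subject, word_size)


def _index_words(seq: str, w: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - w + 1):
        word = seq[i : i + w]
        if "N" in word:
            continue
        idx.setdefault(word, []).append(i)
    return idx


def _extend_seed(
    query: str,
    subject: str,
    qpos: int,
    spos: int,
    w: int,
    match: int,
    mismatch: int,
    xdrop: int,
) -> tuple[int, int, int]:
    """Ungapped X-drop extension of an exact word seed.

    Returns (query_start, query_end, score) of the maximal-scoring
    segment containing the seed on the seed's diagonal.
    """
    score = w * match
    # extend right
    best = score
    best_right = 0
    i, j, cur = qpos + w, spos + w, score
    k = 0
    while i < len(query) and j < len(subject):
        cur += match if query[i] == subject[j] else mismatch
        k += 1
        if cur > best:
            best, best_right = cur, k
        if best - cur > xdrop:
            break
        i += 1
        j += 1
    # extend left
    score = best
    best_left = 0
    i, j, cur = qpos - 1, spos - 1, best
    k = 0
    while i >= 0 and j >= 0:
        cur += match if query[i] == subject[j] else mismatch
        k += 1
        if cur > score:
            score, best_left = cur, k
        if score - cur > xdrop:
            break
        i -= 1
        j -= 1
    qs = qpos - best_left
    qe = qpos + w + best_right
    return qs, qe, score


def local_align_hits(
    query: str,
    subject: str | WordIndex,
    *,
    word_size: int = DEFAULT_WORD_SIZE,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    xdrop: int = DEFAULT_XDROP,
    evalue_max: float | None = None,
    both_strands: bool = True,
) -> list[LocalHit]:
    """All maximal word-seeded ungapped local hits of query vs subject.

    ``subject`` may be a raw string or a prebuilt :class:`WordIndex`.
    Hits on the same diagonal are deduplicated (the best-scoring
    extension is kept).  Results are sorted by score, descending, with
    a deterministic positional tie-break.
    """
    if isinstance(subject, WordIndex):
        sidx = subject.words
        word_size = subject.word_size
        subject = subject.subject
    else:
        subject = subject.upper()
        sidx = _index_words(subject, word_size)
    if len(subject) < word_size:
        raise ValueError(
            f"subject length {len(subject)} is shorter than word size {word_size}"
        )
    query = query.upper()
    m, n = len(query), len(subject)
    hits: list[LocalHit] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        q = query if strand == "+" else revcomp(query)
        seen: dict[tuple[int, int], tuple[int, int, int]] = {}  # diag -> best
        for qpos in range(len(q) - word_size + 1):
            word = q[qpos : qpos + word_size]
            for spos in sidx.get(word, ()):
                diag = spos - qpos
                prev = seen.get((diag, 0))
                if prev is not None and prev[0] <= qpos < prev[1]:
                    continue  # seed inside an already-extended segment
                qs, qe, score = _extend_seed(
                    q, subject, qpos, spos, word_size, match, mismatch, xdrop
                )
                if prev is None or score > prev[2]:
                    seen[(diag, 0)] = (qs, qe, score)
                else:
                    seen[(diag, 0)] = (min(prev[0], qs), max(prev[1], qe), prev[2])
        for (diag, _), (qs, qe, score) in seen.items():
            e = evalue(score, m, n)
            if evalue_max is not None and e > evalue_max:
                continue
            ss, se = qs + diag, qe + diag
            if strand == "-":
                # map query coordinates back to forward orientation
                fqs, fqe = len(q) - qe, len(q) - qs
            else:
                fqs, fqe = qs, qe
            hits.append(LocalHit(fqs, fqe, ss, se, strand, score, e))
    hits.sort(key=lambda h: (-h.score, h.subject_start, h.query_start, h.strand))
    return hits


def best_local_hit(query: str, subject: str, **kwargs) -> LocalHit | None:
    """Highest-scoring local hit, or None when nothing seeds."""
    hits = local_align_hits(query, subject, **kwargs)
    return hits[0] if hits else None


def search_genome(
    query: str,
    chromosomes: dict[str, str] | Iterable[tuple[str, str]],
    *,
    evalue_max: float | None = None,
    **kwargs,
) -> list[tuple[str, LocalHit]]:
    """Align a query against every chromosome; hits sorted by score."""
    if isinstance(chromosomes, dict):
        items = chromosomes.items()
    else:
        items = chromosomes
    out: list[tuple[str, LocalHit]] = []
    for name, seq in items:
        for h in local_align_hits(query, seq, evalue_max=evalue_max, **kwargs):
            out.append((name, h))
    out.sort(key=lambda t: (-t[1].score, t[0], t[1].subject_start))
    return out
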