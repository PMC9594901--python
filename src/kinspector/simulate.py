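"""Synthetic genomes, planted cleavage/insertion truth, and digest reads.

Everything downstream (site calling, off-target enumeration, the
insertion-candidate pipeline, annotation) is exercised on genomes built
here, so the generator records complete ground truth: where guide-like
sequences were planted and at how many mismatches, where donor-cassette
insertion events were applied and of which archetype, and which read
pairs arose from which cleavage.

The read model mirrors a circularized-library digest: genomic fragments
(mean 300 bp) are self-ligated into circles; a circle containing a
protospacer match is linearized by Cas9 with a probability that decays
with the mismatch count; sequencing the linearized molecule yields a
150-bp read pair whose mate 5' ends abut the blunt cut on opposite
strands.  Circles that escape cleavage contribute read pairs only at a
configurable background rate.  Base qualities are constant (Q37);
sequencing errors, PCR duplicates and adaptor chemistry are not
modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import revcomp
from .offtarget import GuideSpec

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

# Cut 3 bp 5' of the PAM: between protospacer positions 17 and 18.
CUT_OFFSET_IN_PROTOSPACER = 17


class ConfigError(ValueError):
    pass


def _default_cleavage_probs() -> dict[int, float]:
    # 1.0 at 0 mismatches, linear decay to 0.1 at 6, 0 beyond
    return {m: round(1.0 - 0.15 * m, 3) for m in range(7)}


@dataclass
class SimConfig:
    seed: int = 42
    n_chroms: int = 2
    chrom_length: int = 50_000
    gc_fraction: float = 0.42
    # (kind, tract length bp, count); kinds: CA_microsatellite, LTR_like, SINE_like
    repeat_tracts: list[tuple[str, int, int]] = field(
        default_factory=lambda: [
            ("CA_microsatellite", 38, 2),
            ("CA_microsatellite", 142, 1),
            ("LTR_like", 623, 1),
            ("SINE_like", 150, 3),
        ]
    )
    # per-chromosome gene layouts: list of exon lengths alternating with
    # intron lengths is derived from these (n_exons, exon_len, intron_len)
    gene_models: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(3, 200, 1500), (4, 150, 2000)]
    )
    read_length: int = 150
    fragment_mean: int = 300
    fragment_sd: int = 30
    background_pair_rate: float = 0.0
    cleavage_prob_by_mismatch: dict[int, float] = field(
        default_factory=_default_cleavage_probs
    )

    def validate(self) -> None:
        if self.chrom_length <= 2 * self.fragment_mean:
            raise ConfigError("chrom_length must exceed 2x fragment_mean")
        if self.read_length > self.fragment_mean:
            raise ConfigError("read_length must not exceed fragment_mean")
        probs = list(self.cleavage_prob_by_mismatch.values()) + [
            self.background_pair_rate,
            self.gc_fraction,
        ]
        if any(p < 0 or p > 1 for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedSite:
    chrom: str
    pos: int  # 0-based cut coordinate (first base 3' of the blunt cut)
    strand: str
    mismatches: int
    pam: str = "AGG"
    bulge: tuple[str, int] | None = None  # ("dna"|"rna", size) or None

    def beyond_search_ceiling(self, ceiling: int = 6) -> bool:
        return self.mismatches > ceiling


INSERTION_KINDS = (
    "precise_on_target",
    "on_target_deletion",
    "ri_clean",
    "ri_flank_duplication",
    "ri_repeat_gap",
    "ri_ltr_coinsert",
    "ri_inverted",
)

_KIND_FIELDS = {
    "precise_on_target": set(),
    "on_target_deletion": {"deletion_len"},
    "ri_clean": set(),
    "ri_flank_duplication": {"duplication_len"},
    "ri_repeat_gap": {"gap_len"},
    "ri_ltr_coinsert": {"coinsert_len"},
    "ri_inverted": set(),
}


@dataclass(frozen=True)
class InsertionEvent:
    """A planted donor-integration event of one archetype.

    Archetypes cover the configurations seen at sequenced insertion
    loci: a precise on-target knock-in, an on-target insertion with a
    multi-kb deletion, a clean random insertion, one accompanied by a
    tandem duplication of flanking genome, one with a small gap at the
    junction, one co-inserting a stretch of LTR-like sequence, and an
    inverted-orientation insertion.
    """

    kind: str
    chrom: str
    pos: int
    deletion_len: int | None = None
    duplication_len: int | None = None
    gap_len: int | None = None
    coinsert_len: int | None = None
    orientation: str = "forward"

    def __post_init__(self):
        if self.kind not in INSERTION_KINDS:
            raise ConfigError(f"unknown insertion kind {self.kind!r}")
        want = _KIND_FIELDS[self.kind]
        for f in ("deletion_len", "duplication_len", "gap_len", "coinsert_len"):
            val = getattr(self, f)
            if f in want and not val:
                raise ConfigError(f"{self.kind} requires {f}")
            if f not in want and val:
                raise ConfigError(f"{self.kind} does not take {f}")
        if self.kind == "ri_inverted" and self.orientation != "reverse":
            object.__setattr__(self, "orientation", "reverse")

    def length_delta(self, cassette_len: int) -> int:
        """Expected genome length change once applied."""
        d = cassette_len
        if self.deletion_len:
            d -= self.deletion_len
        if self.duplication_len:
            d += self.duplication_len
        if self.gap_len:
            d -= self.gap_len
        if self.coinsert_len:
            d += self.coinsert_len
        return d


@dataclass(frozen=True)
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: int | str = 0
    strand: str = "."

    def to_line(self) -> str:
        return (
            f"{self.chrom}\t{self.start}\t{self.end}\t{self.name}"
            f"\t{self.score}\t{self.strand}"
        )


@dataclass
class GeneModel:
    name: str
    chrom: str
    start: int
    end: int
    exons: list[tuple[int, int]]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]


class Genome:
    """A small in-memory genome with FASTA serialization."""

    def __init__(self, chroms: dict[str, str]):
        self.chroms = dict(chroms)

    def __getitem__(self, name: str) -> str:
        return self.chroms[name]

    def __contains__(self, name: str) -> bool:
        return name in self.chroms

    def names(self) -> list[str]:
        return list(self.chroms)

    def total_length(self) -> int:
        return sum(len(s) for s in self.chroms.values())

    def copy(self) -> "Genome":
        return Genome(self.chroms)

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chroms.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from Bio import SeqIO

        return cls(
            {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        )


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def _repeat_unit(kind: str, length: int, rng: np.random.Generator) -> str:
    if kind == "CA_microsatellite":
        return ("CA" * (length // 2 + 1))[:length]
    if kind in ("LTR_like", "SINE_like"):
        # a fixed consensus per kind, drawn from a kind-specific stream so
        # every tract of the same kind shares recognisable sequence
        sub = np.random.default_rng(abs(hash(kind)) % (2**31))
        consensus = _random_seq(sub, 400, 0.45)
        reps = consensus * (length // len(consensus) + 1)
        return reps[:length]
    raise ConfigError(f"unknown repeat kind {kind!r}")


@dataclass
class ToyGenome:
    genome: Genome
    repeats: list[BedInterval]
    genes: list[GeneModel]
    config: SimConfig


def build_toy_genome(cfg: SimConfig) -> ToyGenome:
    """Deterministically build a random genome with repeats and genes.

    Repeat tracts and gene models are placed left-to-right with random
    spacing; their intervals are recorded as annotation truth.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chroms: dict[str, str] = {}
    repeats: list[BedInterval] = []
    genes: list[GeneModel] = []
    tract_list = [
        (kind, length)
        for kind, length, count in cfg.repeat_tracts
        for _ in range(count)
    ]
    if sum(t[1] for t in tract_list) > cfg.chrom_length // 2:
        raise ConfigError("repeat tracts exceed half the chromosome length")
    for ci in range(cfg.n_chroms):
        name = f"chr{ci + 1}"
        seq = list(_random_seq(rng, cfg.chrom_length, cfg.gc_fraction))
        # place repeat tracts at spaced random positions
        cursor = 1000
        for kind, length in tract_list:
            gap = int(rng.integers(500, 2500))
            start = cursor + gap
            if start + length > cfg.chrom_length - 1000:
                raise ConfigError("repeat tracts exceed chromosome length")
            seq[start : start + length] = _repeat_unit(kind, length, rng)
            repeats.append(BedInterval(name, start, start + length, kind))
            cursor = start + length
        # gene models in the downstream half of the chromosome
        gstart = cfg.chrom_length // 2
        for gi, (n_exons, exon_len, intron_len) in enumerate(cfg.gene_models):
            span = n_exons * exon_len + (n_exons - 1) * intron_len
            if gstart + span > cfg.chrom_length - 500:
                break
            exons = []
            p = gstart
            for _ in range(n_exons):
                exons.append((p, p + exon_len))
                p += exon_len + intron_len
            genes.append(
                GeneModel(f"gene{ci + 1}_{gi + 1}", name, gstart, gstart + span, exons)
            )
            gstart += span + int(rng.integers(1000, 3000))
        chroms[name] = "".join(seq)
    return ToyGenome(Genome(chroms), repeats, genes, cfg)


# ---------------------------------------------------------------------------
# planting guide-matching sites

def _mutate_protospacer(
    protospacer: str, n_mismatches: int, rng: np.random.Generator
) -> str:
    """A copy of the protospacer differing at exactly n positions."""
    seq = list(protospacer)
    # avoid the seed-proximal PAM edge being the only difference driver:
    # positions are drawn uniformly over all 20
    pos = rng.choice(len(seq), size=n_mismatches, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != seq[p]]
        seq[p] = choices[int(rng.integers(3))]
    return "".join(seq)


def _site_window(site: PlantedSite) -> tuple[int, int]:
    """Genomic span of the 23-mer (protospacer+PAM) for a planted site."""
    if site.strand == "+":
        start = site.pos - CUT_OFFSET_IN_PROTOSPACER
        return start, start + 23
    else:
        start = site.pos - 6
        return start, start + 23


def plant_guide_sites(
    genome: Genome,
    guide: GuideSpec,
    sites: list[PlantedSite],
    seed: int = 0,
) -> tuple[Genome, list[PlantedSite]]:
    """Write guide-like 23-mers into a genome at the requested cuts.

    For a '+' strand site the protospacer occupies
    [pos-17, pos+3) and the PAM [pos+3, pos+6); the blunt cut falls
    immediately 5' of ``pos``, 3 bp from the PAM.  Minus-strand sites
    are the reverse-complement arrangement.  Each planted 20-mer
    differs from the guide protospacer at exactly ``mismatches``
    positions.  Returns the modified genome and the truth list.
    """
    rng = np.random.default_rng(seed + 7)
    spans: list[tuple[str, int, int]] = []
    new = genome.copy()
    for site in sites:
        ps, pe = _site_window(site)
        if ps < 0 or pe > len(new[site.chrom]):
            raise ConfigError(f"site at {site.chrom}:{site.pos} outside chromosome")
        for c, s, e in spans:
            if c == site.chrom and ps < e and s < pe:
                raise ConfigError(
                    f"planted site at {site.chrom}:{site.pos} overlaps another"
                )
        spans.append((site.chrom, ps, pe))
        proto = _mutate_protospacer(guide.protospacer, site.mismatches, rng)
        if site.bulge is not None:
            kind, size = site.bulge
            if size != 1:
                raise ConfigError("only single-base bulges are supported")
            j = int(rng.integers(1, len(proto) - 1))
            if kind == "dna":  # extra genomic base
                extra = "ACGT"[int(rng.integers(4))]
                proto = proto[:j] + extra + proto[j:]
            elif kind == "rna":  # genomic base missing vs guide
                proto = proto[:j] + proto[j + 1 :]
            else:
                raise ConfigError(f"unknown bulge kind {kind!r}")
        payload = proto + site.pam
        if site.strand == "-":
            payload = revcomp(payload)
        # splice payload in place of the window (window resized for bulges)
        chrom_seq = new.chroms[site.chrom]
        end = ps + len(payload)
        new.chroms[site.chrom] = chrom_seq[:ps] + payload + chrom_seq[end:]
    return new, list(sites)


def cuts_from_planted(sites: list[PlantedSite]) -> list[tuple[str, int, str, int]]:
    """Planted sites as (chrom, cut, strand, mismatches) cleavage tuples."""
    return [(s.chrom, s.pos, s.strand, s.mismatches) for s in sites]


def planted_truth_bed(sites: list[PlantedSite]) -> list[BedInterval]:
    return [
        BedInterval(
            s.chrom,
            s.pos,
            s.pos + 1,
            f"mm{s.mismatches}" + ("_bulge" if s.bulge else ""),
            s.mismatches,
            s.strand,
        )
        for s in sites
    ]


# ---------------------------------------------------------------------------
# donor cassette and insertion events

def make_cassette(
    seed: int = 42, length: int = 1200
) -> tuple[str, GuideSpec, GuideSpec]:
    """A synthetic donor cassette with embedded left/right assay guides.

    The left guide sits near the cassette's 5' end and the right guide
    near its 3' end, so that a cleavage inside an integrated cassette
    yields one read crossing the cassette/genome junction — the
    configuration the insertion-candidate pipeline relies on.
    """
    rng = np.random.default_rng(seed + 13)
    seq = list(_random_seq(rng, length, 0.5))
    # left guide: protospacer at [43, 63), PAM AGG at [63, 66) -> cut at 60
    seq[63:66] = "AGG"
    guide_l = GuideSpec("gRNA-L", "".join(seq[43:63]))
    # right guide: protospacer ending 46 bp before cassette end; cut at len-49
    rs = length - 66
    seq[rs + 20 : rs + 23] = "AGG"
    guide_r = GuideSpec("gRNA-R", "".join(seq[rs : rs + 20]))
    return "".join(seq), guide_l, guide_r


def plant_insertion_event(
    genome: Genome,
    cassette: str,
    ev: InsertionEvent,
    ltr_seq: str | None = None,
) -> tuple[Genome, InsertionEvent]:
    """Apply one insertion event; the truth record round-trips lengths."""
    if not cassette:
        raise ConfigError("cassette must be non-empty")
    seq = genome[ev.chrom]
    L = len(seq)
    if ev.pos < 0 or ev.pos > L:
        raise ConfigError("event position outside chromosome")
    ins = revcomp(cassette) if ev.kind == "ri_inverted" else cassette
    if ev.kind in ("precise_on_target", "ri_clean", "ri_inverted"):
        new = seq[: ev.pos] + ins + seq[ev.pos :]
    elif ev.kind == "on_target_deletion":
        if ev.pos + ev.deletion_len > L:
            raise ConfigError("deletion crosses chromosome end")
        new = seq[: ev.pos] + ins + seq[ev.pos + ev.deletion_len :]
    elif ev.kind == "ri_flank_duplication":
        if ev.pos - ev.duplication_len < 0:
            raise ConfigError("duplication crosses chromosome start")
        dup = seq[ev.pos - ev.duplication_len : ev.pos]
        new = seq[: ev.pos] + ins + dup + seq[ev.pos :]
    elif ev.kind == "ri_repeat_gap":
        if ev.pos + ev.gap_len > L:
            raise ConfigError("gap crosses chromosome end")
        new = seq[: ev.pos] + ins + seq[ev.pos + ev.gap_len :]
    elif ev.kind == "ri_ltr_coinsert":
        if ltr_seq is None:
            ltr_seq = _repeat_unit("LTR_like", ev.coinsert_len, None)
        if len(ltr_seq) != ev.coinsert_len:
            ltr_seq = (ltr_seq * (ev.coinsert_len // len(ltr_seq) + 1))[
                : ev.coinsert_len
            ]
        new = seq[: ev.pos] + ltr_seq + ins + seq[ev.pos :]
    else:  # pragma: no cover
        raise ConfigError(ev.kind)
    out = genome.copy()
    out.chroms[ev.chrom] = new
    assert len(new) == L + ev.length_delta(len(cassette))
    return out, ev


def apply_insertion_events(
    genome: Genome, cassette: str, events: list[InsertionEvent]
) -> Genome:
    """Apply several events; per-chromosome, highest coordinate first so
    that every event position stays valid in original coordinates."""
    out = genome.copy()
    for ev in sorted(events, key=lambda e: (e.chrom, -e.pos)):
        out, _ = plant_insertion_event(out, cassette, ev)
    return out


# ---------------------------------------------------------------------------
# circularized-library read simulation

@dataclass(frozen=True)
class ReadPair:
    name: str
    seq1: str
    seq2: str
    qual: str = ""

    def fastq_records(self) -> tuple[str, str]:
        q1 = self.qual or "F" * len(self.seq1)
        q2 = self.qual or "F" * len(self.seq2)
        return (
            f"@{self.name}/1\n{self.seq1}\n+\n{q1}\n",
            f"@{self.name}/2\n{self.seq2}\n+\n{q2}\n",
        )


@dataclass
class LibrarySim:
    pairs: list[ReadPair]
    truth: list[BedInterval]  # one record per cleaved circle (cut position)

    def write_fastq(self, prefix) -> tuple[str, str]:
        p1, p2 = f"{prefix}_R1.fastq", f"{prefix}_R2.fastq"
        with open(p1, "w") as f1, open(p2, "w") as f2:
            for pair in self.pairs:
                r1, r2 = pair.fastq_records()
                f1.write(r1)
                f2.write(r2)
        return p1, p2


def _find_guide_cuts(genome: Genome, guide: GuideSpec, max_mm: int = 6):
    """All cut positions for a guide in a genome (exposed for truth).

    Returns (chrom, cut_pos, strand, mismatches) tuples via the
    off-target scanner with canonical and non-canonical PAMs.
    """
    from .offtarget import SearchParams, enumerate_offtargets

    cuts = []
    cands = enumerate_offtargets(
        genome.chroms, guide, SearchParams(max_mismatches=max_mm)
    )
    for c in cands:
        if c.strand == "+":
            cut = c.end - 6  # 3 bp 5' of PAM; PAM at [end-3, end)
        else:
            cut = c.start + 6  # PAM at [start, start+3)
        cuts.append((c.chrom, cut, c.strand, c.mismatches))
    return cuts


def _emit_pair(
    seq: str, chrom: str, cut: int, read_length: int, name: str
) -> ReadPair | None:
    if cut - read_length < 0 or cut + read_length > len(seq):
        return None
    r1 = seq[cut : cut + read_length]
    r2 = revcomp(seq[cut - read_length : cut])
    return ReadPair(name, r1, r2)


def simulate_circle_library(
    genome: Genome,
    guides: list[GuideSpec],
    cfg: SimConfig,
    n_fragments: int = 0,
    min_pairs_per_site: int = 0,
    max_mismatches: int = 6,
    cuts: list[tuple[str, int, str, int]] | None = None,
) -> LibrarySim:
    """Simulate digest read pairs from a circularized fragment library.

    Two sampling modes compose: ``n_fragments`` circles drawn uniformly
    from the genome (each cleaved per the mismatch-dependent Bernoulli
    model when it contains a cut site), and coverage targeting via
    ``min_pairs_per_site`` which keeps drawing circles over each known
    cut until that many cleaved pairs have been emitted (capped at
    100x attempts), so planted loci reach a requested support.

    Mate 5' ends sit immediately on either side of the blunt cut:
    read 1 runs 3'-ward from the cut on the forward strand, read 2
    3'-ward from the cut on the reverse strand.  Read names encode the
    originating cut for test introspection
    (``cut:<chrom>:<pos>:<strand>:mm<k>:<serial>`` or ``bg:<serial>``).

    By default cleavable positions are found by scanning the genome for
    guide matches up to ``max_mismatches`` (every chance match is then a
    legitimate substrate, as for an RNP on real DNA).  Pass ``cuts`` —
    (chrom, cut_pos, strand, mismatches) tuples — to restrict cleavage
    to a known truth set, e.g. the planted sites of a recovery
    experiment.
    """
    if not guides:
        raise ConfigError("at least one guide required")
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 101)
    rl = cfg.read_length
    pairs: list[ReadPair] = []
    truth: list[BedInterval] = []
    if cuts is None:
        cuts = []
        for g in guides:
            cuts.extend(_find_guide_cuts(genome, g, max_mismatches))
    cuts = sorted(set(cuts))
    if not cuts:
        logger.warning("no guide match in genome; no cleavage possible")
    serial = 0

    def cleave_prob(mm: int) -> float:
        return cfg.cleavage_prob_by_mismatch.get(mm, 0.0)

    def record(chrom: str, cut: int, strand: str, mm: int) -> None:
        nonlocal serial
        name = f"cut:{chrom}:{cut}:{strand}:mm{mm}:{serial}"
        pair = _emit_pair(genome[chrom], chrom, cut, rl, name)
        if pair is None:
            return
        serial += 1
        pairs.append(pair)
        truth.append(BedInterval(chrom, cut, cut + 1, f"mm{mm}", mm, strand))

    # genome-wide uniform circles
    names = genome.names()
    lengths = np.array([len(genome[c]) for c in names], dtype=float)
    for _ in range(n_fragments):
        ci = int(rng.choice(len(names), p=lengths / lengths.sum()))
        chrom = names[ci]
        flen = max(2 * rl, int(rng.normal(cfg.fragment_mean, cfg.fragment_sd)))
        start = int(rng.integers(0, max(1, len(genome[chrom]) - flen)))
        inside = [
            (c, p, s, m)
            for (c, p, s, m) in cuts
            if c == chrom and start + rl <= p <= start + flen - rl
        ]
        cleaved = False
        for c, p, s, m in inside:
            if rng.random() < cleave_prob(m):
                record(c, p, s, m)
                cleaved = True
                break
        if not cleaved and rng.random() < cfg.background_pair_rate:
            pair = _emit_pair(
                genome[chrom], chrom, start + flen // 2, rl, f"bg:{serial}"
            )
            if pair is not None:
                serial += 1
                pairs.append(pair)

    # coverage targeting over known cuts
    if min_pairs_per_site:
        for c, p, s, m in cuts:
            prob = cleave_prob(m)
            if prob <= 0:
                continue
            emitted, attempts = 0, 0
            while emitted < min_pairs_per_site and attempts < 100 * min_pairs_per_site:
                attempts += 1
                if rng.random() < prob:
                    record(c, p, s, m)
                    emitted += 1
    return LibrarySim(pairs, truth)
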