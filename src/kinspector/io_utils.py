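"""Plain-text format helpers: BED, TSV, FASTQ pairs, gene models."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotate import AnnotateParams  # noqa: F401  (re-export convenience)
from .simulate import BedInterval, GeneModel, ReadPair


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(iv.to_line() + "\n")


def read_bed(path) -> list[BedInterval]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.append(
            BedInterval(
                f[0],
                int(f[1]),
                int(f[2]),
                f[3] if len(f) > 3 else ".",
                f[4] if len(f) > 4 else 0,
                f[5] if len(f) > 5 else ".",
            )
        )
    return out


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    """Zip two FASTQ mate files back into read pairs by record order."""
    from Bio import SeqIO

    r1 = list(SeqIO.parse(str(path1), "fastq"))
    r2 = list(SeqIO.parse(str(path2), "fastq"))
    pairs = []
    for a, b in zip(r1, r2):
        name = a.id.rsplit("/", 1)[0]
        pairs.append(ReadPair(name, str(a.seq), str(b.seq)))
    return pairs


def read_gene_models_bed12(path) -> list[GeneModel]:
    """Gene models from BED12 (blocks are exons)."""
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        chrom, start, name = f[0], int(f[1]), f[3]
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        genes.append(GeneModel(name, chrom, start, int(f[2]), exons))
    return genes


def read_gene_models_gff3(path) -> list[GeneModel]:
    """Gene models from GFF3 gene/exon features (Parent-linked)."""
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        attrs = dict(
            kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
        )
        if f[2] == "gene":
            gid = attrs.get("ID", attrs.get("Name", f"{f[0]}:{f[3]}"))
            genes[gid] = GeneModel(
                attrs.get("Name", gid), f[0], int(f[3]) - 1, int(f[4]), []
            )
        elif f[2] == "exon":
            parent = attrs.get("Parent", "")
            exons.setdefault(parent, []).append((int(f[3]) - 1, int(f[4])))
    for gid, g in genes.items():
        g.exons = sorted(exons.get(gid, [(g.start, g.end)]))
    return list(genes.values())


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
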