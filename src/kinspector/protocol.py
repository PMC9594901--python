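"""Library-construction arithmetic and the packaged candidate table.

Two small worked quantities of the assay protocol live here — the
expected sequencing-library molecule length (sheared insert plus the
two adaptor contributions) and the genomic-DNA input advantage of
enzymatic fragmentation over sonication — together with a loader for
the packaged insertion-candidate reference table used by the
annotation and reporting examples.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# protocol constants: enzymatically sheared insert, hairpin adaptor,
# sequencing adaptor (bp); and gDNA input (ug) for the sonication-based
# versus enzymatic protocol
FRAGMENT_MEAN_BP = 300
HAIRPIN_ADAPTOR_BP = 30
SEQUENCING_ADAPTOR_BP = 120
GDNA_SONICATION_UG = 25.0
GDNA_ENZYMATIC_UG = 3.4


def library_molecule_length(
    fragment_bp: int = FRAGMENT_MEAN_BP,
    hairpin_bp: int = HAIRPIN_ADAPTOR_BP,
    adaptor_bp: int = SEQUENCING_ADAPTOR_BP,
) -> int:
    """Average final library molecule length in bp."""
    return fragment_bp + hairpin_bp + adaptor_bp


def gdna_fold_reduction(
    sonication_ug: float = GDNA_SONICATION_UG,
    enzymatic_ug: float = GDNA_ENZYMATIC_UG,
) -> float:
    """How many times more input gDNA the sonication protocol needs."""
    if enzymatic_ug <= 0:
        raise ValueError("enzymatic input must be positive")
    return sonication_ug / enzymatic_ug


def load_ics_reference_table() -> pd.DataFrame:
    """The packaged insertion-candidate summary table (26 records).

    Columns: ics_id, guide_used, n_reads, founder, chrom, start, end,
    region (on_target / intronic / exonic/intronic / intergenic), gene.
    Coordinates are mm10, 1-based as printed in the source table.
    """
    with resources.files("kinspector.data").joinpath("ics_candidates.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


ON_TARGET_LOCUS = ("chr2", 164954709, 164955063)  # knock-in region span


def summarize_ics_table(df: pd.DataFrame | None = None) -> dict[str, int]:
    """Headline counts from the candidate table.

    Applies the on-target interval flag and the region tally:
    candidates away from the knock-in locus, and how many of those
    fall inside annotated genes.
    """
    from .insertion import ICSParams, ICSRecord, flag_on_target

    if df is None:
        df = load_ics_reference_table()
    records = [
        ICSRecord(
            id=int(r.ics_id),
            guide_used=r.guide_used,
            read_count=int(r.n_reads),
            chrom=r.chrom,
            start=int(r.start),
            end=int(r.end),
            region_class=r.region,
        )
        for r in df.itertuples()
    ]
    flag_on_target(records, ON_TARGET_LOCUS, ICSParams())
    off = [r for r in records if not r.on_target]
    genic = [
        r for r in off if r.region_class in ("intronic", "exonic", "exonic/intronic")
    ]
    return {
        "total": len(records),
        "on_target": sum(r.on_target for r in records),
        "non_on_target": len(off),
        "gene_associated": len(genic),
    }
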