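"""Chromosome painting by homeolog origin.

Given a table of gene loci with an origin tag (a donor section, an
ancestor combination such as ``Noctiflorae-Petunioides``, or
``unresolved``), summarize the per-chromosome composition as percentages
of the *resolved* loci, and flag the combination of origins that exceed an
enrichment threshold on each chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import PolyOriginError

logger = logging.getLogger(__name__)

UNRESOLVED_LABEL = "unresolved"

LOCUS_COLUMNS = ["chrom", "start", "end", "gene_id", "origin"]


def read_locus_table(path) -> pd.DataFrame:
    """BED-like TSV: chrom, start, end (0-based half-open), gene_id, origin."""
    df = pd.read_csv(path, sep="\t", header=None, names=LOCUS_COLUMNS, comment="#")
    validate_locus_table(df)
    return df


def write_locus_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False, columns=LOCUS_COLUMNS)


def validate_locus_table(df: pd.DataFrame) -> None:
    missing = set(LOCUS_COLUMNS) - set(df.columns)
    if missing:
        raise PolyOriginError(f"locus table missing columns: {sorted(missing)}")
    if len(df) and not (df["start"] < df["end"]).all():
        raise PolyOriginError("locus table: start must be < end")


@dataclass
class ChromosomePainting:
    """Per-chromosome and genome-wide origin percentages over resolved loci."""

    percentages: pd.DataFrame  # index: chromosome, columns: origin, values: %
    genome_wide: pd.Series  # origin -> % over all resolved loci
    n_resolved: pd.Series  # chromosome -> resolved locus count
    skipped_chromosomes: list = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.percentages.round(6).to_csv(path, sep="\t", index_label="chromosome")


def paint_chromosomes(
    loci: pd.DataFrame, unresolved_label: str = UNRESOLVED_LABEL
) -> ChromosomePainting:
    """Percentage of each origin per chromosome, over resolved loci only.

    Unresolved loci are excluded from the denominator (percentages are of
    assigned homeologs).  Chromosomes with zero resolved loci are excluded
    with a warning; at least one resolved locus overall is required.
    """
    validate_locus_table(loci)
    resolved = loci[loci["origin"] != unresolved_label]
    if resolved.empty:
        raise PolyOriginError("no loci with resolved origin")
    skipped = sorted(set(loci["chrom"]) - set(resolved["chrom"]))
    for chrom in skipped:
        logger.warning("chromosome %s has no resolved loci; excluded", chrom)
    counts = (
        resolved.groupby(["chrom", "origin"]).size().unstack(fill_value=0).sort_index()
    )
    n_resolved = counts.sum(axis=1)
    percentages = counts.div(n_resolved, axis=0) * 100.0
    genome_counts = resolved.groupby("origin").size()
    genome_wide = genome_counts / genome_counts.sum() * 100.0
    return ChromosomePainting(
        percentages=percentages,
        genome_wide=genome_wide,
        n_resolved=n_resolved,
        skipped_chromosomes=skipped,
    )


def flag_enriched_combinations(
    percentages: pd.DataFrame, threshold: float = 20.0
) -> dict:
    """Per-chromosome combination label of origins strictly above threshold.

    With >= 2 origins above threshold the label is their sorted join
    (e.g. ``Alatae-Sylvestres``); otherwise the chromosome is labeled by
    its single dominant origin.
    """
    labels = {}
    for chrom, row in percentages.iterrows():
        above = sorted(origin for origin, pct in row.items() if pct > threshold)
        if len(above) >= 2:
            labels[chrom] = "-".join(above)
        else:
            labels[chrom] = str(row.idxmax())
    return labels


def combinations_to_tsv(labels: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tcombination\n")
        for chrom in sorted(labels):
            fh.write(f"{chrom}\t{labels[chrom]}\n")
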