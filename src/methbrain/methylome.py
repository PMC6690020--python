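"""Per-sample methylation quantification.

Depth filtering, promoter derivation (2 kb upstream of the TSS), genomic
feature classification with the priority promoter > gene body > intergenic,
the CpG vs non-CpG context split, and methylation-level quartile binning.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genomic_io import beta
from .intervals import GeneModel, GenomicInterval, IntervalIndex

LEVEL_BINS = ("b0_25", "b25_50", "b50_75", "b75_100")
FEATURES = ("promoter", "gene_body", "intergenic")

DEFAULT_MIN_DEPTH = 10  # sites with fewer reads are discarded
DEFAULT_PROMOTER_LENGTH = 2000  # bp upstream of the TSS


def filter_by_depth(sites: pd.DataFrame, min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """Discard sites with read depth below ``min_depth``; order is preserved."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    depth = sites["n_meth"] + sites["n_unmeth"]
    return sites[depth >= min_depth].reset_index(drop=True)


def promoter_of(
    gene: GeneModel,
    length: int = DEFAULT_PROMOTER_LENGTH,
    chrom_length: int | None = None,
) -> GenomicInterval | None:
    """The promoter: ``length`` bp immediately upstream of the TSS.

    On ``+`` this is ``[tx_start - length, tx_start)`` clipped at 0; on ``-``
    it is ``[tx_end, tx_end + length)`` clipped at the chromosome length when
    known. Returns ``None`` when clipping leaves an empty interval (a gene
    whose TSS sits at the chromosome edge).
    """
    if length <= 0:
        raise ValueError("promoter length must be > 0")
    if gene.strand == "+":
        start, end = max(0, gene.tx_start - length), gene.tx_start
    else:
        start, end = gene.tx_end, gene.tx_end + length
        if chrom_length is not None:
            end = min(end, chrom_length)
    if start >= end:
        return None
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def promoters_of(
    genes: Iterable[GeneModel],
    length: int = DEFAULT_PROMOTER_LENGTH,
    chrom_lengths: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    out = []
    for g in genes:
        clen = chrom_lengths.get(g.chrom) if chrom_lengths else None
        p = promoter_of(g, length=length, chrom_length=clen)
        if p is not None:
            out.append(p)
    return out


def level_bin(b: float) -> str:
    """Quartile bin of a methylation level: half-open except the last bin.

    ``[0, .25) -> b0_25``, ``[.25, .5) -> b25_50``, ``[.5, .75) -> b50_75``,
    ``[.75, 1] -> b75_100``.
    """
    if not (0.0 <= b <= 1.0):
        raise ValueError(f"methylation level {b} outside [0, 1]")
    return LEVEL_BINS[min(int(b // 0.25), 3)]


def classify_sites(
    sites: pd.DataFrame,
    genes: Sequence[GeneModel],
    promoters: Sequence[GenomicInterval] | None = None,
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
) -> pd.DataFrame:
    """Attach feature, context-group, level and level-bin columns to sites.

    Each site receives exactly one ``feature`` label with the priority
    promoter > gene_body > intergenic, and one ``context_group`` (``CpG`` or
    ``non-CpG`` = CHG plus CHH). Sites on chromosomes absent from the
    annotation are labelled intergenic, with a single aggregate warning.
    """
    if promoters is None:
        promoters = promoters_of(genes, length=promoter_length)
    prom_idx = IntervalIndex(promoters)
    body_idx = IntervalIndex(g.body for g in genes)

    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    in_prom = prom_idx.covers_points(chroms, pos)
    in_body = body_idx.covers_points(chroms, pos)

    annotated = prom_idx.chromosomes | body_idx.chromosomes
    orphan = sorted(set(chroms) - annotated)
    if orphan:
        warnings.warn(
            f"{len(orphan)} chromosome(s) in sites absent from annotation "
            f"(labelled intergenic): {orphan[:5]}"
        )

    out = sites.copy()
    out["feature"] = np.where(in_prom, "promoter", np.where(in_body, "gene_body", "intergenic"))
    out["context_group"] = np.where(out["context"] == "CpG", "CpG", "non-CpG")
    b = beta(out)
    out["beta"] = b
    bins = np.full(len(out), "", dtype=object)
    ok = b.notna().to_numpy()
    bins[ok] = np.asarray(LEVEL_BINS, dtype=object)[
        np.minimum((b.to_numpy()[ok] // 0.25).astype(int), 3)
    ]
    out["level_bin"] = bins
    return out


def level_bin_proportions(
    classified: pd.DataFrame,
    group_by: Sequence[str] = ("feature", "context_group"),
) -> pd.DataFrame:
    """Proportion of sites in each methylation-level bin, per group.

    Requires every site to have positive depth (a defined level). Within each
    observed group the four bin proportions sum to 1; empty groups are simply
    absent from the output rather than reported as zeros.
    """
    if (classified["n_meth"] + classified["n_unmeth"] == 0).any():
        raise ValueError("level_bin_proportions requires all sites to have depth > 0")
    group_by = list(group_by)
    counts = (
        classified.groupby(group_by + ["level_bin"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby(group_by, observed=True)["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts


def write_classification_summary(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", index=False)
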