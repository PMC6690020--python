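"""Correlation screen linking promoter-CGI methylation to expression.

CpG islands overlapping a gene's promoter (2 kb upstream of the TSS) are
paired with that gene; each region contributes the median methylation level
over the CpG sites falling inside the island, and the per-region methylation
vector is correlated (Pearson) with the gene's per-region expression vector.
Pairs with p at or below the threshold are kept and split into positively and
negatively correlated genes, then flagged against the brain-region-specific
gene (BRSG) sets from clustering and the DMG calls from the differential
stage.

No multiple-testing correction is applied by default — the screen is a raw
p <= 0.05 filter over all candidate pairs — but BH q-values can be requested.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import DMGRecord, bh_adjust
from .genomic_io import beta
from .intervals import GeneModel, GenomicInterval, IntervalIndex
from .methylome import promoters_of


def cgi_promoter_pairs(
    cgis: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_length: int = 2000,
) -> list[tuple[GenomicInterval, GeneModel]]:
    """All (CGI, gene) pairs whose CGI overlaps the gene's promoter by >= 1 bp.

    A CGI spanning two promoters yields two pairs; a gene with two promoter
    CGIs likewise.
    """
    by_gene = {}
    for g in genes:
        by_gene[g.gene_id] = g
    promoters = []
    owners = []
    for g in genes:
        p = promoters_of([g], length=promoter_length)
        if p:
            promoters.append(p[0])
            owners.append(g)
    pairs: list[tuple[GenomicInterval, GeneModel]] = []
    cgi_index = IntervalIndex(cgis)
    for prom, gene in zip(promoters, owners):
        for cgi in sorted(cgi_index.overlapping(prom.chrom, prom.start, prom.end)):
            pairs.append((cgi, gene))
    return pairs


def cgi_median_methylation(
    cgi: GenomicInterval,
    region_sites: Mapping[str, pd.DataFrame],
) -> pd.Series:
    """Median methylation level inside the CGI, one value per region.

    Regions with no covered site inside the island get NaN. The even-count
    median is the midpoint of the two central order statistics.
    """
    out = {}
    for region, sites in region_sites.items():
        inside = sites[
            (sites["chrom"] == cgi.chrom)
            & (sites["pos"] >= cgi.start)
            & (sites["pos"] < cgi.end)
        ]
        b = beta(inside).dropna()
        out[region] = float(np.median(b)) if len(b) else np.nan
    return pd.Series(out)


def _region_medians_bulk(
    cgis: Sequence[GenomicInterval],
    region_sites: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Median beta per (CGI, region); rows indexed by CGI position in input."""
    records = np.full((len(cgis), len(region_sites)), np.nan)
    for r_idx, (region, sites) in enumerate(region_sites.items()):
        b_all = beta(sites)
        for c_idx, cgi in enumerate(cgis):
            mask = (
                (sites["chrom"] == cgi.chrom)
                & (sites["pos"] >= cgi.start)
                & (sites["pos"] < cgi.end)
            )
            b = b_all[mask].dropna()
            if len(b):
                records[c_idx, r_idx] = np.median(b)
    return pd.DataFrame(records, columns=list(region_sites))


def pearson_screen(
    pairs: Sequence[tuple[GenomicInterval, GeneModel]],
    region_sites: Mapping[str, pd.DataFrame],
    expr_matrix: pd.DataFrame,
    p_threshold: float = 0.05,
    add_bh: bool = False,
    dedup_genes: bool = True,
) -> pd.DataFrame:
    """Pearson screen of CGI methylation against expression across regions.

    For each candidate pair the per-region median CGI methylation is
    correlated with the gene's expression over the same regions (the region
    set is the expression matrix's column order). Pairs with a region lacking
    coverage, a gene absent from the matrix, or a zero-variance vector are
    dropped and counted in a warning. Records with p <= ``p_threshold`` are
    returned with their correlation sign; when a gene has several qualifying
    CGIs only the smallest-p pair is kept (``dedup_genes``).
    """
    regions = list(expr_matrix.columns)
    missing_region = {r for r in regions if r not in region_sites}
    if missing_region:
        raise ValueError(f"regions without methylation data: {sorted(missing_region)}")
    ordered_sites = {r: region_sites[r] for r in regions}

    unique_cgis = sorted({cgi for cgi, _ in pairs})
    cgi_pos = {cgi: i for i, cgi in enumerate(unique_cgis)}
    medians = _region_medians_bulk(unique_cgis, ordered_sites)

    rows = []
    n_dropped = 0
    for cgi, gene in pairs:
        if gene.gene_id not in expr_matrix.index:
            n_dropped += 1
            continue
        meth = medians.iloc[cgi_pos[cgi]].to_numpy()
        if np.isnan(meth).any():
            n_dropped += 1
            continue
        expr = expr_matrix.loc[gene.gene_id].to_numpy(dtype=float)
        if len(regions) < 3 or np.std(meth) == 0 or np.std(expr) == 0:
            n_dropped += 1
            continue
        r, p = stats.pearsonr(meth, expr)
        rows.append(
            (
                gene.gene_id, cgi.chrom, cgi.start, cgi.end,
                len(regions), float(r), float(p),
                "positive" if r > 0 else "negative",
            )
        )
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} pair(s) with incomplete or degenerate vectors")

    cols = ["gene_id", "cgi_chrom", "cgi_start", "cgi_end", "n_regions", "r", "p_value", "sign"]
    table = pd.DataFrame(rows, columns=cols)
    if add_bh and len(table):
        table["q_value"] = bh_adjust(table["p_value"])
    table = table[table["p_value"] <= p_threshold].reset_index(drop=True)
    if dedup_genes and len(table):
        table = (
            table.sort_values(["p_value", "gene_id"], kind="stable")
            .drop_duplicates("gene_id", keep="first")
            .sort_index()
            .reset_index(drop=True)
        )
    return table


def categorize(
    records: pd.DataFrame,
    brsg_sets: Mapping[str, set[str]],
    dmg_records: Sequence[DMGRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag correlated genes as BRSG and/or DMG and summarise the categories.

    Returns the flagged record table and a summary of counts by
    sign x is_brsg x is_dmg.
    """
    brsg_genes = set().union(*brsg_sets.values()) if brsg_sets else set()
    dmg_genes = {rec.gene_id for rec in dmg_records}
    flagged = records.copy()
    flagged["is_brsg"] = flagged["gene_id"].isin(brsg_genes)
    flagged["is_dmg"] = flagged["gene_id"].isin(dmg_genes)
    summary = (
        flagged.groupby(["sign", "is_brsg", "is_dmg"], observed=True)
        .size()
        .rename("n_genes")
        .reset_index()
    )
    return flagged, summary
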