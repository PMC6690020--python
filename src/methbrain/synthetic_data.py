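"""Seeded generator of toy genomes, multi-region methylomes and expression.

The generator emulates the data structure of a multi-region WGBS +
transcriptome study: a small genome with genes, promoter CpG islands and
intergenic repeat elements; per-region cytosine reports whose CpG dyads share
a latent methylation level drawn from compartment-specific Beta distributions
(hypomethylated promoter CGIs, hypermethylated gene bodies and repeats,
elevated repeat flanks for LINE-like classes); and a gene-by-region
expression matrix carrying planted region-specific clusters and
methylation-coupled genes. Planted signals — differential sites, cluster
memberships, correlated genes — are returned as machine-readable truth
tables so every downstream stage can be scored against ground truth.

All outputs are pure functions of (config, seed): the same configuration
always produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genomic_io import (
    write_bed,
    write_cytosine_report,
    write_expression,
    write_gene_models,
    write_rmsk,
)
from .intervals import GeneModel, GenomicInterval, RepeatElement

#: the seven sampled brain regions (used when n_regions == 7)
BRAIN_REGIONS = (
    "angular_gyrus",
    "anterior_caudate",
    "cingulate_gyrus",
    "hippocampus_middle",
    "inferior_temporal",
    "dorsolateral_pfc",
    "ventrolateral_pfc",
)

_SUBTYPES = {
    "LINE": ("L1MA1", "L1MB2", "L2a"),
    "SINE": ("AluJo", "AluSx", "MIRc"),
    "LTR": ("MLT1A", "ERVL1"),
    "Simple_repeat": ("(TA)n", "(CA)n"),
}

_REPEAT_LENGTHS = {
    "LINE": (800, 3000),
    "SINE": (150, 350),
    "LTR": (400, 900),
    "Simple_repeat": (100, 220),
}

#: per-class body shape: how the element interior is methylated relative to
#: its edges (LINE-like bodies dip in the middle; SINE-like peak there)
_REPEAT_SHAPES = {"LINE": "edge_high", "SINE": "center_high"}


class CapacityError(ValueError):
    """Requested features do not fit on the configured chromosomes."""


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with desk-scale defaults.

    The defaults emulate the study design end to end: 7 regions, a
    negative-binomial depth model with mean 15 (so the depth-10 discard rule
    is exercised nontrivially), hypomethylated promoter CGIs (Beta(1, 9)),
    hypermethylated gene bodies/intergenic/repeats (Beta(8, 2)), elevated
    repeat flanks (Beta(9, 1.5)), and rare low-level non-CpG methylation
    (Beta(0.5, 20)).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 300
    n_cgis: int = 200
    n_repeats: dict = field(
        default_factory=lambda: {"LINE": 120, "SINE": 150, "LTR": 60, "Simple_repeat": 40}
    )
    n_repeat_cgis: int = 8
    n_regions: int = 7
    depth_mean: float = 15.0
    depth_size: float = 5.0
    beta_params: dict = field(
        default_factory=lambda: {
            "cgi_promoter": (1.0, 9.0),
            "gene_body": (8.0, 2.0),
            "intergenic": (8.0, 2.0),
            "repeat_inner": (8.0, 2.0),
            "repeat_flank": (9.0, 1.5),
            "repeat_mid_low": (6.0, 4.0),   # dips/rises inside shaped bodies
            "repeat_edge_high": (18.0, 2.0),
            "non_cpg": (0.5, 20.0),
        }
    )
    cpg_spacing: int = 150        # mean bp between CpG dyads genome-wide
    cgi_cpg_spacing: int = 40     # denser dyads inside CpG islands
    n_noncpg_sites: int = 8000    # per chromosome
    n_planted_dms: int = 300
    planted_dms_delta: float = 0.5
    n_cluster_genes_per_region: int = 30
    cluster_effect_size: float = 3.0   # log2 units added in the high region
    n_planted_corr_pos: int = 5
    n_planted_corr_neg: int = 3
    corr_strength: float = 0.95
    corr_meth_sd: float = 0.15    # per-region latent shift of coupled CGIs
    expr_baseline_mean: float = 4.0    # log2 FPKM
    expr_baseline_sd: float = 1.5
    expr_noise_sd: float = 0.15
    flank_bp: int = 100

    def validate(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.n_cgis > self.n_genes:
            raise ValueError("n_cgis cannot exceed n_genes (CGIs sit in promoters)")
        for name, (a, b) in self.beta_params.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"beta_params[{name!r}] must be positive")
        if not 0 < self.corr_strength < 1:
            raise ValueError("corr_strength must be in (0, 1)")
        if self.planted_dms_delta <= 0:
            raise ValueError("planted_dms_delta must be positive")

    def region_names(self) -> list[str]:
        if self.n_regions == len(BRAIN_REGIONS):
            return list(BRAIN_REGIONS)
        return [f"region{i + 1}" for i in range(self.n_regions)]


@dataclass
class Annotation:
    """In-memory annotation bundle emitted by :func:`make_annotation`."""

    genes: list[GeneModel]
    cgis: list[GenomicInterval]
    repeats: list[RepeatElement]
    chrom_lengths: dict[str, int]
    promoter_cgi: dict[str, GenomicInterval]  # gene_id -> its promoter CGI


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def make_annotation(config: SimulationConfig) -> Annotation:
    """Lay out genes, promoter CGIs and intergenic repeats on toy chromosomes.

    Genes are non-overlapping, each with >= 2 exons so the first exon is a
    proper sub-interval; each of ``n_cgis`` randomly chosen genes receives a
    CGI spanning its TSS (overlapping both the promoter and the first exon).
    Repeats are placed in the intergenic gaps with at least ``2 * flank_bp``
    between copies so flank windows never overlap a neighbouring element.
    """
    config.validate()
    rng = _rng(config, 0)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_lengths = {c: config.chrom_length for c in chroms}

    genes: list[GeneModel] = []
    gaps: list[tuple[str, int, int]] = []  # intergenic spans usable for repeats
    per_chrom = np.array_split(np.arange(config.n_genes), config.n_chroms)
    for chrom, gene_idx in zip(chroms, per_chrom):
        cursor = 3000
        for gi in gene_idx:
            gap = int(rng.integers(2500, 5000))
            gene_len = int(rng.integers(3000, 8000))
            start_block = cursor + gap
            end_block = start_block + 2000 + gene_len
            if end_block > config.chrom_length - 3000:
                need = end_block + 3000
                raise CapacityError(
                    f"cannot place gene {gi} on {chrom}: requires chrom_length >= {need}"
                )
            gaps.append((chrom, cursor + config.flank_bp, start_block - config.flank_bp))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                tx_start, tx_end = start_block + 2000, end_block
            else:
                tx_start, tx_end = start_block, start_block + gene_len
            exons = _make_exons(chrom, strand, tx_start, tx_end, rng)
            genes.append(
                GeneModel(
                    gene_id=f"gene{gi + 1:04d}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    exons=exons,
                )
            )
            cursor = end_block
        gaps.append((chrom, cursor + config.flank_bp, config.chrom_length - 1000))

    # promoter CGIs spanning the TSS of a random gene subset
    cgi_gene_pos = rng.choice(len(genes), size=config.n_cgis, replace=False)
    cgis: list[GenomicInterval] = []
    promoter_cgi: dict[str, GenomicInterval] = {}
    for pos in sorted(cgi_gene_pos):
        g = genes[pos]
        up = int(rng.integers(250, 450))     # extends into the promoter
        down = int(rng.integers(150, 250))   # extends into the first exon
        if g.strand == "+":
            cgi = GenomicInterval(g.chrom, g.tx_start - up, g.tx_start + down)
        else:
            cgi = GenomicInterval(g.chrom, g.tx_end - down, g.tx_end + up)
        cgis.append(cgi)
        promoter_cgi[g.gene_id] = cgi

    repeats = _place_repeats(config, rng, gaps)

    # a few CGIs inside repeat copies, to exercise the CGI-content split
    big = [r for r in repeats if len(r.interval) >= 400]
    n_rep_cgi = min(config.n_repeat_cgis, len(big))
    for ridx in rng.choice(len(big), size=n_rep_cgi, replace=False):
        iv = big[int(ridx)].interval
        mid = (iv.start + iv.end) // 2
        cgis.append(GenomicInterval(iv.chrom, mid - 100, mid + 100))

    cgis = sorted(set(cgis))
    return Annotation(genes, cgis, repeats, chrom_lengths, promoter_cgi)


def _make_exons(chrom, strand, tx_start, tx_end, rng) -> tuple[GenomicInterval, ...]:
    n_exons = int(rng.integers(2, 5))
    e_first = int(rng.integers(250, 500))
    e_last = int(rng.integers(250, 500))
    exons = [GenomicInterval(chrom, tx_start, tx_start + e_first, strand)]
    inner_span = (tx_end - e_last) - (tx_start + e_first)
    n_mid = max(0, n_exons - 2)
    if n_mid and inner_span > 1200 * n_mid:
        step = inner_span // (n_mid + 1)
        for m in range(n_mid):
            s = tx_start + e_first + (m + 1) * step
            exons.append(GenomicInterval(chrom, s, s + int(rng.integers(150, 400)), strand))
    exons.append(GenomicInterval(chrom, tx_end - e_last, tx_end, strand))
    return tuple(exons)


def _place_repeats(config, rng, gaps) -> list[RepeatElement]:
    spacing = 2 * config.flank_bp
    wanted = [
        (cls, count) for cls, count in sorted(config.n_repeats.items()) if count > 0
    ]
    total = sum(c for _, c in wanted)
    repeats: list[RepeatElement] = []
    gap_list = [list(g) for g in gaps]
    gi = 0
    for cls, count in wanted:
        lo, hi = _REPEAT_LENGTHS.get(cls, (150, 500))
        names = _SUBTYPES.get(cls, (f"{cls}_syn",))
        for _ in range(count):
            length = int(rng.integers(lo, hi))
            placed = False
            tries = 0
            while not placed and tries <= len(gap_list):
                chrom, s, e = gap_list[gi % len(gap_list)]
                if e - s >= length + 2 * spacing:
                    start = s + spacing
                    repeats.append(
                        RepeatElement(
                            GenomicInterval(
                                chrom, start, start + length,
                                "+" if rng.random() < 0.5 else "-",
                            ),
                            rep_name=str(names[int(rng.integers(len(names)))]),
                            rep_class=cls,
                        )
                    )
                    gap_list[gi % len(gap_list)][1] = start + length
                    placed = True
                gi += 1
                tries += 1
            if not placed:
                raise CapacityError(
                    f"cannot place all {total} repeats: increase chrom_length or "
                    "reduce n_repeats"
                )
    return sorted(repeats, key=lambda r: (r.interval.chrom, r.interval.start))


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------

@dataclass
class MethylomeTruth:
    """Planted differential-methylation ground truth."""

    dms: pd.DataFrame          # chrom, pos, strand, region, direction, base/shifted beta
    dmg_gene_ids: list[str]    # genes whose promoter CGI holds >= 1 planted DMS
    corr_genes: list[str] = field(default_factory=list)  # CGIs with regional variation


def simulate_methylomes(
    annotation: Annotation, config: SimulationConfig
) -> tuple[dict[str, pd.DataFrame], MethylomeTruth]:
    """Simulate one cytosine report per region, with planted DMS truth.

    CpG dyads are placed genome-wide (denser inside CGIs); each dyad's two
    strand sites share a latent level drawn from the Beta distribution of the
    compartment the dyad falls in. The latent level is shared across regions
    except at planted sites, where it is shifted by ``planted_dms_delta`` in
    exactly one region (clipped into [0.02, 0.98] with a warning if needed).
    Read depth is negative-binomial per site and region; methylated counts
    are binomial in the latent level.

    Genes destined for methylation-expression coupling additionally receive
    latent per-region shifts of their whole promoter CGI (Normal with sd
    ``corr_meth_sd``), so their CGI medians genuinely vary across regions —
    the variation the expression simulator couples to. Those genes are listed
    in the returned truth (``corr_genes``) and their dyads are excluded from
    DMS planting.
    """
    rng = _rng(config, 1)
    regions = config.region_names()

    dyad_chrom, dyad_pos, compartment = _place_dyads(annotation, config, rng)
    n_dyads = len(dyad_pos)
    base_beta = _draw_compartment_beta(compartment, config, rng)

    # ---- latent regional variation for the methylation-coupled genes -------
    corr_genes, corr_dyads, corr_offsets = _plant_regional_cgi_variation(
        annotation, config, rng, dyad_chrom, dyad_pos
    )
    corr_dyad_set = (
        np.zeros(n_dyads, dtype=bool)
        if not corr_dyads
        else np.isin(np.arange(n_dyads), np.concatenate(list(corr_dyads.values())))
    )

    # ---- plant DMS dyads: prefer promoter-CGI dyads so DMGs exist ----------
    delta = config.planted_dms_delta
    shiftable_up = base_beta + delta <= 0.98
    shiftable_dn = base_beta - delta >= 0.02
    in_cgi = (compartment == "cgi_promoter") & ~corr_dyad_set
    cgi_pool = np.flatnonzero(in_cgi & (shiftable_up | shiftable_dn))
    other_pool = np.flatnonzero(
        (compartment != "cgi_promoter") & ~corr_dyad_set & (shiftable_up | shiftable_dn)
    )
    n_from_cgi = min(len(cgi_pool), config.n_planted_dms // 3)
    n_other = min(len(other_pool), config.n_planted_dms - n_from_cgi)
    chosen = np.concatenate(
        [
            rng.choice(cgi_pool, size=n_from_cgi, replace=False) if n_from_cgi else [],
            rng.choice(other_pool, size=n_other, replace=False) if n_other else [],
        ]
    ).astype(int)
    if len(chosen) < config.n_planted_dms:
        warnings.warn(
            f"only {len(chosen)} of {config.n_planted_dms} requested DMSs could be planted"
        )

    affected_region = rng.integers(0, config.n_regions, size=len(chosen))
    up = np.where(
        shiftable_up[chosen] & shiftable_dn[chosen],
        rng.random(len(chosen)) < 0.5,
        shiftable_up[chosen],
    )
    shifted_beta = base_beta[chosen] + np.where(up, delta, -delta)
    n_clip = int(((shifted_beta < 0.02) | (shifted_beta > 0.98)).sum())
    if n_clip:
        warnings.warn(f"clipped {n_clip} shifted level(s) into [0.02, 0.98]")
    shifted_beta = np.clip(shifted_beta, 0.02, 0.98)

    # ---- expand dyads to both strands --------------------------------------
    site_chrom = np.repeat(dyad_chrom, 2)
    site_pos = np.empty(2 * n_dyads, dtype=np.int64)
    site_pos[0::2] = dyad_pos
    site_pos[1::2] = dyad_pos + 1
    site_strand = np.tile(np.array(["+", "-"]), n_dyads)
    site_beta = np.repeat(base_beta, 2)

    # non-CpG sites: sparse, low-level, uncoupled across compartments
    nc_chrom, nc_pos, nc_strand, nc_context, nc_beta = _place_noncpg(annotation, config, rng)

    region_tables: dict[str, pd.DataFrame] = {}
    nbp = config.depth_size / (config.depth_size + config.depth_mean)
    for r_idx, region in enumerate(regions):
        beta_r = site_beta.copy()
        mask = affected_region == r_idx
        if mask.any():
            dyads = chosen[mask]
            for d, bshift in zip(dyads, shifted_beta[mask]):
                beta_r[2 * d] = bshift
                beta_r[2 * d + 1] = bshift
        for gid in corr_genes:
            dyads = corr_dyads[gid]
            levels, scatter = corr_offsets[gid]
            shifted = np.clip(levels[r_idx] + scatter, 0.02, 0.98)
            beta_r[2 * dyads] = shifted
            beta_r[2 * dyads + 1] = shifted
        all_chrom = np.concatenate([site_chrom, nc_chrom])
        all_pos = np.concatenate([site_pos, nc_pos])
        all_strand = np.concatenate([site_strand, nc_strand])
        all_context = np.concatenate(
            [np.repeat("CpG", len(site_pos)), nc_context]
        )
        all_beta = np.concatenate([beta_r, nc_beta])
        depth = rng.negative_binomial(config.depth_size, nbp, size=len(all_pos))
        n_meth = rng.binomial(depth, all_beta)
        df = pd.DataFrame(
            {
                "chrom": all_chrom,
                "pos": all_pos,
                "strand": all_strand,
                "context": all_context,
                "n_meth": n_meth,
                "n_unmeth": depth - n_meth,
            }
        )
        region_tables[region] = (
            df.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)
        )

    truth_rows = []
    for d, r_idx, is_up, b0, b1 in zip(
        chosen, affected_region, up, base_beta[chosen], shifted_beta
    ):
        for strand, offset in (("+", 0), ("-", 1)):
            truth_rows.append(
                (
                    dyad_chrom[d], int(dyad_pos[d]) + offset, strand,
                    regions[int(r_idx)],
                    "hyper" if is_up else "hypo",
                    float(b0), float(b1),
                )
            )
    dms_truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "strand", "region", "direction", "base_beta", "shifted_beta"],
    )

    planted_pos = {(c, p) for c, p, _s, *_ in truth_rows}
    dmg_ids = sorted(
        gene_id
        for gene_id, cgi in annotation.promoter_cgi.items()
        if any(
            (cgi.chrom, p) in planted_pos for p in range(cgi.start, cgi.end)
        )
    )
    return region_tables, MethylomeTruth(
        dms=dms_truth, dmg_gene_ids=dmg_ids, corr_genes=corr_genes
    )


def _plant_regional_cgi_variation(annotation, config, rng, dyad_chrom, dyad_pos):
    """Choose the coupled genes and give their CGIs per-region latent shifts."""
    n_corr = config.n_planted_corr_pos + config.n_planted_corr_neg
    order = pd.DataFrame({"chrom": dyad_chrom, "pos": dyad_pos, "i": np.arange(len(dyad_pos))})
    by_chrom = {c: g for c, g in order.groupby("chrom")}

    def dyads_in(cgi):
        g = by_chrom.get(cgi.chrom)
        if g is None:
            return np.array([], dtype=int)
        pos = g["pos"].to_numpy()
        lo = np.searchsorted(pos, cgi.start, side="left")
        hi = np.searchsorted(pos, cgi.end, side="left")
        return g["i"].to_numpy()[lo:hi]

    candidates = [
        gid for gid, cgi in sorted(annotation.promoter_cgi.items())
        if len(dyads_in(cgi)) >= 3
    ]
    if n_corr == 0:
        return [], {}, {}
    if len(candidates) < n_corr:
        raise CapacityError(
            f"only {len(candidates)} promoter CGIs hold >= 3 CpG dyads; "
            f"cannot plant {n_corr} methylation-coupled genes"
        )
    picked = sorted(rng.choice(len(candidates), size=n_corr, replace=False))
    corr_genes = [candidates[int(i)] for i in picked]
    corr_dyads = {gid: dyads_in(annotation.promoter_cgi[gid]) for gid in corr_genes}
    # per-region latent mean level of the whole island, mid-range so clipping
    # never distorts the regional pattern, plus a small fixed per-dyad scatter
    corr_offsets = {
        gid: (
            np.clip(rng.normal(0.4, config.corr_meth_sd, size=config.n_regions), 0.05, 0.9),
            rng.normal(0.0, 0.05, size=len(corr_dyads[gid])),
        )
        for gid in corr_genes
    }
    return corr_genes, corr_dyads, corr_offsets


def _place_dyads(annotation, config, rng):
    chroms, positions = [], []
    for chrom, clen in annotation.chrom_lengths.items():
        steps = rng.integers(
            max(2, config.cpg_spacing // 3), 2 * config.cpg_spacing,
            size=clen // config.cpg_spacing + 10,
        )
        pos = 50 + np.cumsum(steps)
        pos = pos[pos < clen - 2]
        chroms.append(np.repeat(chrom, len(pos)))
        positions.append(pos)
    # extra density inside CGIs
    for cgi in annotation.cgis:
        steps = rng.integers(
            max(2, config.cgi_cpg_spacing // 2), 2 * config.cgi_cpg_spacing,
            size=len(cgi) // config.cgi_cpg_spacing + 4,
        )
        pos = cgi.start + np.cumsum(steps)
        pos = pos[pos < cgi.end]
        chroms.append(np.repeat(cgi.chrom, len(pos)))
        positions.append(pos)
    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions).astype(np.int64)
    # dedupe (CGI densification may collide with the genome-wide lattice)
    key = pd.DataFrame({"chrom": chrom_arr, "pos": pos_arr})
    key = key.drop_duplicates().sort_values(["chrom", "pos"], kind="stable")
    # dyads occupy pos and pos+1; drop dyads that would overlap the next one
    keep = np.ones(len(key), dtype=bool)
    same = key["chrom"].to_numpy()[1:] == key["chrom"].to_numpy()[:-1]
    adjacent = key["pos"].to_numpy()[1:] - key["pos"].to_numpy()[:-1] < 2
    keep[1:] = ~(same & adjacent)
    key = key[keep]
    chrom_arr = key["chrom"].to_numpy()
    pos_arr = key["pos"].to_numpy()
    compartment = _compartment_of(annotation, config, chrom_arr, pos_arr, rng)
    return chrom_arr, pos_arr, compartment


def _compartment_of(annotation, config, chrom_arr, pos_arr, rng):
    """Compartment label per dyad, priority CGI > repeat > flank > body > intergenic."""
    comp = np.full(len(pos_arr), "intergenic", dtype=object)
    order = pd.DataFrame({"chrom": chrom_arr, "pos": pos_arr, "i": np.arange(len(pos_arr))})
    by_chrom = {c: g for c, g in order.groupby("chrom")}

    def assign(intervals, labels):
        for iv, lab in zip(intervals, labels):
            g = by_chrom.get(iv.chrom)
            if g is None:
                continue
            pos = g["pos"].to_numpy()
            lo = np.searchsorted(pos, iv.start, side="left")
            hi = np.searchsorted(pos, iv.end, side="left")
            comp[g["i"].to_numpy()[lo:hi]] = lab

    assign((g.body for g in annotation.genes), ("gene_body" for _ in annotation.genes))
    # repeat flanks first so element bodies override them where they touch
    flank_ivs, flank_labels = [], []
    body_ivs, body_labels = [], []
    for rep in annotation.repeats:
        iv = rep.interval
        flank_ivs.append(GenomicInterval(iv.chrom, max(0, iv.start - config.flank_bp), iv.start))
        flank_ivs.append(GenomicInterval(iv.chrom, iv.end, iv.end + config.flank_bp))
        flank_labels += ["repeat_flank", "repeat_flank"]
        shape = _REPEAT_SHAPES.get(rep.rep_class)
        length = len(iv)
        third = length // 3
        if shape == "edge_high":
            body_ivs += [
                GenomicInterval(iv.chrom, iv.start, iv.start + third),
                GenomicInterval(iv.chrom, iv.start + third, iv.end - third),
                GenomicInterval(iv.chrom, iv.end - third, iv.end),
            ]
            body_labels += ["repeat_edge_high", "repeat_mid_low", "repeat_edge_high"]
        elif shape == "center_high":
            body_ivs += [
                GenomicInterval(iv.chrom, iv.start, iv.start + third),
                GenomicInterval(iv.chrom, iv.start + third, iv.end - third),
                GenomicInterval(iv.chrom, iv.end - third, iv.end),
            ]
            body_labels += ["repeat_mid_low", "repeat_edge_high", "repeat_mid_low"]
        else:
            body_ivs.append(iv)
            body_labels.append("repeat_inner")
    assign(flank_ivs, flank_labels)
    assign(body_ivs, body_labels)
    assign(annotation.cgis, ("cgi_promoter" for _ in annotation.cgis))
    return comp


def _draw_compartment_beta(compartment, config, rng):
    beta = np.empty(len(compartment))
    for label in np.unique(compartment):
        a, b = config.beta_params.get(label, config.beta_params["intergenic"])
        mask = compartment == label
        beta[mask] = rng.beta(a, b, size=mask.sum())
    return np.clip(beta, 0.001, 0.999)


def _place_noncpg(annotation, config, rng):
    chroms, positions = [], []
    for chrom, clen in annotation.chrom_lengths.items():
        pos = np.sort(rng.choice(clen - 2, size=config.n_noncpg_sites, replace=False))
        chroms.append(np.repeat(chrom, len(pos)))
        positions.append(pos.astype(np.int64))
    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions)
    strand = np.where(rng.random(len(pos_arr)) < 0.5, "+", "-")
    context = np.where(rng.random(len(pos_arr)) < 0.5, "CHG", "CHH")
    a, b = config.beta_params["non_cpg"]
    beta = np.clip(rng.beta(a, b, size=len(pos_arr)), 0.0, 0.999)
    return chrom_arr, pos_arr, strand, context, beta


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTruth:
    """Planted expression-structure ground truth."""

    clusters: pd.DataFrame     # gene_id, cluster, high_region
    correlated: pd.DataFrame   # gene_id, sign, target_r


def simulate_expression(
    annotation: Annotation,
    config: SimulationConfig,
    region_sites: dict[str, pd.DataFrame],
    corr_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, ExpressionTruth]:
    """Simulate the gene-by-region expression matrix with planted structure.

    Cluster genes get ``cluster_effect_size`` extra log2 units in exactly one
    region (one planted cluster per region); methylation-coupled genes get a
    log2 expression that is a linear function of their promoter-CGI median
    methylation across regions, with noise calibrated so the expected
    absolute Pearson correlation is ``corr_strength``. Values are returned on
    an FPKM-like nonnegative scale (2 to the simulated log2 value).

    ``corr_genes`` (from :class:`MethylomeTruth`) names the genes whose CGIs
    carry planted regional methylation variation; when omitted, any genes
    with fully covered, variable promoter-CGI medians are used instead.
    """
    from .integration import _region_medians_bulk  # local import avoids a cycle
    from .methylome import filter_by_depth

    rng = _rng(config, 2)
    regions = config.region_names()
    # couple to the medians the analysis itself will measure: depth-filtered CpGs
    region_sites = {
        r: filter_by_depth(s[s["context"] == "CpG"].reset_index(drop=True))
        for r, s in region_sites.items()
    }
    gene_ids = [g.gene_id for g in annotation.genes]
    n_genes = len(gene_ids)
    n_regions = len(regions)

    baseline = rng.normal(config.expr_baseline_mean, config.expr_baseline_sd, size=n_genes)
    log_expr = baseline[:, None] + rng.normal(0, config.expr_noise_sd, size=(n_genes, n_regions))

    # ---- methylation-coupled genes -----------------------------------------
    n_corr = config.n_planted_corr_pos + config.n_planted_corr_neg
    if corr_genes is not None:
        chosen_genes = list(corr_genes)
    else:
        chosen_genes = []
    cgi_genes = [gid for gid in gene_ids if gid in annotation.promoter_cgi]
    cgi_list = [annotation.promoter_cgi[gid] for gid in cgi_genes]
    medians = _region_medians_bulk(cgi_list, {r: region_sites[r] for r in regions})
    row_of = {gid: i for i, gid in enumerate(cgi_genes)}
    usable = [
        gid for gid in cgi_genes
        if not np.isnan(medians.iloc[row_of[gid]].to_numpy()).any()
        and np.std(medians.iloc[row_of[gid]].to_numpy()) > 1e-6
    ]
    dropped = [g for g in chosen_genes if g not in usable]
    if dropped:
        warnings.warn(
            f"{len(dropped)} planted gene(s) had unusable CGI medians; replaced"
        )
        chosen_genes = [g for g in chosen_genes if g in usable]
    pool = [g for g in usable if g not in chosen_genes]
    if len(chosen_genes) < n_corr:
        extra = n_corr - len(chosen_genes)
        if len(pool) < extra:
            raise CapacityError(
                f"only {len(usable)} genes have usable promoter-CGI medians; "
                f"cannot plant {n_corr} correlated genes"
            )
        chosen_genes += [pool[int(i)] for i in rng.choice(len(pool), size=extra, replace=False)]
    chosen_genes = chosen_genes[:n_corr]
    signs = np.array([1] * config.n_planted_corr_pos + [-1] * config.n_planted_corr_neg)
    # a 2-fold expression swing per SD of methylation keeps the exponentiated
    # (FPKM-scale) correlation close to the log-scale target
    amp = 1.0
    noise_sd = amp * np.sqrt(1.0 / config.corr_strength**2 - 1.0)
    corr_rows = []
    corr_gene_pos = set()
    for gid, sign in zip(chosen_genes, signs):
        gpos = gene_ids.index(gid)
        corr_gene_pos.add(gpos)
        m = medians.iloc[row_of[gid]].to_numpy()
        ms = (m - m.mean()) / m.std()
        log_expr[gpos] = (
            config.expr_baseline_mean
            + sign * amp * ms
            + rng.normal(0, noise_sd, size=n_regions)
        )
        corr_rows.append((gid, "positive" if sign > 0 else "negative", config.corr_strength))
    corr_truth = pd.DataFrame(corr_rows, columns=["gene_id", "sign", "target_r"])

    # ---- region-specific clusters ------------------------------------------
    eligible = [i for i in range(n_genes) if i not in corr_gene_pos]
    need = config.n_cluster_genes_per_region * n_regions
    if len(eligible) < need:
        raise CapacityError(
            f"n_genes={n_genes} too small for {need} cluster genes plus "
            f"{n_corr} correlated genes"
        )
    cluster_pick = rng.choice(eligible, size=need, replace=False)
    cluster_rows = []
    for c in range(n_regions):
        members = cluster_pick[
            c * config.n_cluster_genes_per_region : (c + 1) * config.n_cluster_genes_per_region
        ]
        log_expr[members, c] += config.cluster_effect_size
        for m in members:
            cluster_rows.append((gene_ids[int(m)], c + 1, regions[c]))
    cluster_truth = pd.DataFrame(cluster_rows, columns=["gene_id", "cluster", "high_region"])

    matrix = pd.DataFrame(2.0 ** log_expr, index=pd.Index(gene_ids, name="gene_id"), columns=regions)
    return matrix, ExpressionTruth(clusters=cluster_truth, correlated=corr_truth)


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------

def write_dataset(config: SimulationConfig, outdir) -> dict:
    """Generate the full synthetic dataset and write every file under outdir.

    Emits per-region cytosine reports, ``genes.tsv``, ``cgis.bed``,
    ``rmsk.tsv``, ``expr.tsv``, ``truth/*.tsv`` and the resolved config
    (``sim_config.yaml``). Returns the in-memory bundle.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    annotation = make_annotation(config)
    region_sites, meth_truth = simulate_methylomes(annotation, config)
    expr, expr_truth = simulate_expression(
        annotation, config, region_sites, corr_genes=meth_truth.corr_genes
    )

    params = {"seed": config.seed}
    write_gene_models(annotation.genes, outdir / "genes.tsv", params)
    write_bed(annotation.cgis, outdir / "cgis.bed", params)
    write_rmsk(annotation.repeats, outdir / "rmsk.tsv", params)
    write_expression(expr.round(6), outdir / "expr.tsv", params)
    for region, sites in region_sites.items():
        write_cytosine_report(sites, outdir / f"{region}.cov.tsv", params)

    meth_truth.dms.to_csv(outdir / "truth" / "dms.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": meth_truth.dmg_gene_ids}).to_csv(
        outdir / "truth" / "dmg.tsv", sep="\t", index=False
    )
    expr_truth.clusters.to_csv(outdir / "truth" / "clusters.tsv", sep="\t", index=False)
    expr_truth.correlated.to_csv(outdir / "truth" / "correlated.tsv", sep="\t", index=False)

    resolved = dataclasses.asdict(config)
    with open(outdir / "sim_config.yaml", "wt") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)

    return {
        "annotation": annotation,
        "region_sites": region_sites,
        "expression": expr,
        "methylome_truth": meth_truth,
        "expression_truth": expr_truth,
    }
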