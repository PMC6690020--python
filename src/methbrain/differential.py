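"""Pairwise differential methylation at single-site resolution.

Each CpG shared by two depth-filtered samples is tested with a two-sided
Fisher's exact test on its 2x2 methylated/unmethylated count table; p-values
are Benjamini-Hochberg adjusted over all sites tested for that sample pair,
and significant sites (q below threshold) are classified hyper- or
hypo-methylated by the sign of the level difference. Differentially methylated
genes (DMGs) are genes whose first exon overlaps a CpG island containing at
least one significant site.

The Fisher test is computed by the probability-mass rule — summing the
hypergeometric probabilities of every table with the observed margins whose
probability does not exceed the observed table's — vectorised over all sites
of a genome scan via log-gamma arithmetic, so a 21-pair regional comparison
finishes in seconds.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .intervals import GeneModel, GenomicInterval, IntervalIndex

DMS_COLUMNS = [
    "chrom", "pos", "strand", "context",
    "level_a", "level_b", "diff", "p_value", "q_value", "direction",
]

# relative slack when comparing hypergeometric masses for the two-sided rule;
# absorbs floating-point noise on mathematically tied tables
_TIE_RTOL = 1e-7


def _log_choose(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def fisher_exact_many(
    n_meth_a: np.ndarray,
    n_unmeth_a: np.ndarray,
    n_meth_b: np.ndarray,
    n_unmeth_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher's exact test for many 2x2 tables at once.

    Returns ``(p_values, degenerate)`` where ``degenerate`` marks tables with
    a zero margin (p is reported as 1 there). p-values lie in ``(0, 1]``.
    """
    a = np.asarray(n_meth_a, dtype=np.int64)
    b = np.asarray(n_unmeth_a, dtype=np.int64)
    c = np.asarray(n_meth_b, dtype=np.int64)
    d = np.asarray(n_unmeth_b, dtype=np.int64)
    if (np.minimum.reduce([a, b, c, d]) < 0).any():
        raise ValueError("counts must be nonnegative")

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    degenerate = (r1 == 0) | (r2 == 0) | (c1 == 0) | (c1 == n)
    p = np.ones(len(a), dtype=float)

    live = ~degenerate
    if not live.any():
        return p, degenerate
    a_l, r1_l, r2_l, c1_l, n_l = a[live], r1[live], r2[live], c1[live], n[live]

    kmin = np.maximum(0, c1_l - r2_l)
    kmax = np.minimum(r1_l, c1_l)
    lengths = kmax - kmin + 1
    total = int(lengths.sum())
    table_idx = np.repeat(np.arange(len(a_l)), lengths)
    offsets = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    k = kmin[table_idx] + (np.arange(total) - offsets[table_idx])

    log_denom = _log_choose(n_l, c1_l)
    logpmf = (
        _log_choose(r1_l[table_idx], k)
        + _log_choose(r2_l[table_idx], c1_l[table_idx] - k)
        - log_denom[table_idx]
    )
    logpmf_obs = (
        _log_choose(r1_l, a_l) + _log_choose(r2_l, c1_l - a_l) - log_denom
    )
    include = logpmf <= logpmf_obs[table_idx] + np.log1p(_TIE_RTOL)
    p_live = np.bincount(
        table_idx[include], weights=np.exp(logpmf[include]), minlength=len(a_l)
    )
    p[live] = np.clip(p_live, np.exp(logpmf_obs), 1.0)
    return p, degenerate


def fisher_exact_2x2(
    n_meth_a: int, n_unmeth_a: int, n_meth_b: int, n_unmeth_b: int
) -> float:
    """Two-sided Fisher's exact p for a single 2x2 count table.

    A zero margin (an empty row or column) makes the test degenerate; p = 1
    is returned in that case.
    """
    p, _ = fisher_exact_many(
        np.array([n_meth_a]), np.array([n_unmeth_a]),
        np.array([n_meth_b]), np.array([n_unmeth_b]),
    )
    return float(p[0])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dms(
    sample_a: pd.DataFrame,
    sample_b: pd.DataFrame,
    q_threshold: float = 0.05,
    min_abs_diff: float = 0.0,
) -> pd.DataFrame:
    """Call differentially methylated sites between two depth-filtered samples.

    Only sites present in both samples (matched on chromosome, position and
    strand) are tested; the BH family is exactly that intersection. A site is
    called hyper (``diff > 0``, i.e. higher in sample B) or hypo when its
    q-value is at most ``q_threshold`` and ``|diff| >= min_abs_diff``;
    otherwise its direction is ``ns``.
    """
    shared = sample_a.merge(
        sample_b, on=["chrom", "pos", "strand"], suffixes=("_a", "_b")
    )
    if shared.empty:
        warnings.warn("no shared sites between the two samples; empty DMS result")
        return pd.DataFrame(columns=DMS_COLUMNS)

    depth_a = shared["n_meth_a"] + shared["n_unmeth_a"]
    depth_b = shared["n_meth_b"] + shared["n_unmeth_b"]
    level_a = shared["n_meth_a"] / depth_a
    level_b = shared["n_meth_b"] / depth_b
    diff = level_b - level_a

    p, _ = fisher_exact_many(
        shared["n_meth_a"].to_numpy(), shared["n_unmeth_a"].to_numpy(),
        shared["n_meth_b"].to_numpy(), shared["n_unmeth_b"].to_numpy(),
    )
    q = bh_adjust(p)
    sig = (q <= q_threshold) & (np.abs(diff) >= min_abs_diff) & (diff != 0)
    direction = np.where(sig & (diff > 0), "hyper", np.where(sig & (diff < 0), "hypo", "ns"))

    return pd.DataFrame(
        {
            "chrom": shared["chrom"],
            "pos": shared["pos"],
            "strand": shared["strand"],
            "context": shared["context_a"],
            "level_a": level_a,
            "level_b": level_b,
            "diff": diff,
            "p_value": p,
            "q_value": q,
            "direction": direction,
        }
    )


def dms_count_matrix(
    samples: Mapping[str, pd.DataFrame],
    q_threshold: float = 0.05,
    min_abs_diff: float = 0.0,
) -> pd.DataFrame:
    """Symmetric sample-by-sample matrix of significant DMS counts."""
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least 2 samples")
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, j in itertools.combinations(range(len(names)), 2):
        dms = call_dms(samples[names[i]], samples[names[j]], q_threshold, min_abs_diff)
        count = 0 if dms.empty else int((dms["direction"] != "ns").sum())
        mat.iloc[i, j] = count
        mat.iloc[j, i] = count
    return mat


@dataclass(frozen=True)
class DMGRecord:
    """A differentially methylated gene and its supporting CpG island."""

    gene_id: str
    cgi: GenomicInterval
    supporting_dms_count: int
    region_pairs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.supporting_dms_count < 1:
            raise ValueError("a DMG needs at least one supporting DMS")


def call_dmgs(
    dms: pd.DataFrame,
    cgis: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    q_threshold: float = 0.05,
) -> list[DMGRecord]:
    """Genes whose first exon overlaps a CGI containing >= 1 significant DMS.

    ``dms`` may carry an optional ``pair`` column naming the sample pair each
    record came from; contributing pairs are then reported per gene. Genes
    without exons are skipped with a warning.
    """
    if dms.empty:
        sig = dms
    else:
        sig = dms[(dms["direction"] != "ns") & (dms["q_value"] <= q_threshold)]
    cgi_index = IntervalIndex(cgis)

    out: list[DMGRecord] = []
    skipped = 0
    for gene in genes:
        fe = gene.first_exon
        if fe is None:
            skipped += 1
            continue
        for cgi in sorted(cgi_index.overlapping(fe.chrom, fe.start, fe.end)):
            if sig.empty:
                continue
            inside = sig[
                (sig["chrom"] == cgi.chrom)
                & (sig["pos"] >= cgi.start)
                & (sig["pos"] < cgi.end)
            ]
            if len(inside) == 0:
                continue
            pairs = (
                tuple(sorted(inside["pair"].unique())) if "pair" in inside.columns else ()
            )
            out.append(
                DMGRecord(
                    gene_id=gene.gene_id,
                    cgi=cgi,
                    supporting_dms_count=len(inside),
                    region_pairs=pairs,
                )
            )
    if skipped:
        warnings.warn(f"skipped {skipped} gene(s) without exon structure")
    return out


def write_dms(dms: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "wt") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        dms.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_dmgs(dmgs: Sequence[DMGRecord], path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "wt") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("gene_id\tcgi_chrom\tcgi_start\tcgi_end\tsupporting_dms\tregion_pairs\n")
        for rec in dmgs:
            pairs = ",".join(rec.region_pairs)
            fh.write(
                f"{rec.gene_id}\t{rec.cgi.chrom}\t{rec.cgi.start}\t{rec.cgi.end}"
                f"\t{rec.supporting_dms_count}\t{pairs}\n"
            )
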