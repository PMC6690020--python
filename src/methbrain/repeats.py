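"""Repeat-element methylation: stratification, metaprofiles, flank statistics.

Repeats are grouped by class (LINE, SINE, LTR, ...) or subtype (AluJo, L1
copies, ...) and by whether they contain a CpG island. Metaprofiles scale
every element body to a common number of bins, add fixed-width flanks, and
average methylation per bin over all elements, optionally LOESS-smoothed;
inner-vs-outer statistics compare the site-level mean methylation inside
elements against the 100-bp flanks just outside them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genomic_io import beta
from .intervals import GenomicInterval, IntervalIndex, RepeatElement


def split_by_cgi(
    repeats: Sequence[RepeatElement],
    cgis: Sequence[GenomicInterval],
) -> tuple[list[RepeatElement], list[RepeatElement]]:
    """Partition repeats into (overlapping a CGI, CGI-free)."""
    cgi_index = IntervalIndex(cgis)
    with_cgi, without = [], []
    for rep in repeats:
        iv = rep.interval
        (with_cgi if cgi_index.any_overlap(iv.chrom, iv.start, iv.end) else without).append(rep)
    return with_cgi, without


def element_methylation(
    repeats: Sequence[RepeatElement],
    sites: pd.DataFrame,
    stat: str = "mean",
    context: str | None = "CpG",
) -> pd.DataFrame:
    """Per-element summary (mean or median) of methylation levels.

    Elements with no covered site get NaN. Columns: rep_name, rep_class,
    chrom, start, end, length, n_sites, beta.
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    if context is not None:
        sites = sites[sites["context"] == context]
    b = beta(sites)
    rows = []
    by_chrom = {c: g for c, g in sites.groupby("chrom")}
    for rep in repeats:
        iv = rep.interval
        chrom_sites = by_chrom.get(iv.chrom)
        if chrom_sites is None:
            vals = pd.Series(dtype=float)
        else:
            mask = (chrom_sites["pos"] >= iv.start) & (chrom_sites["pos"] < iv.end)
            vals = b.loc[chrom_sites.index[mask]].dropna()
        summary = (
            float(vals.mean() if stat == "mean" else vals.median()) if len(vals) else np.nan
        )
        rows.append(
            (rep.rep_name, rep.rep_class, iv.chrom, iv.start, iv.end, len(iv), len(vals), summary)
        )
    return pd.DataFrame(
        rows,
        columns=["rep_name", "rep_class", "chrom", "start", "end", "length", "n_sites", "beta"],
    )


@dataclass
class MetaProfile:
    """Mean methylation across scaled repeat bodies plus fixed-width flanks.

    Bins with no covered site are NaN (missing), never zero. ``body`` bins
    live in scaled element coordinates; flank bins are fixed base-pair widths
    in element orientation (upstream = 5' of the element).
    """

    label: str
    n_elements: int
    upstream_mean: np.ndarray
    body_mean: np.ndarray
    downstream_mean: np.ndarray
    upstream_n: np.ndarray
    body_n: np.ndarray
    downstream_n: np.ndarray
    loess_span: float = 0.3
    smoothed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.upstream_mean, self.body_mean, self.downstream_mean])

    def to_frame(self) -> pd.DataFrame:
        kinds = (
            ["up"] * len(self.upstream_mean)
            + ["body"] * len(self.body_mean)
            + ["down"] * len(self.downstream_mean)
        )
        idx = np.concatenate(
            [
                np.arange(len(self.upstream_mean)),
                np.arange(len(self.body_mean)),
                np.arange(len(self.downstream_mean)),
            ]
        )
        return pd.DataFrame(
            {
                "label": self.label,
                "bin_kind": kinds,
                "bin_index": idx,
                "n_sites": np.concatenate([self.upstream_n, self.body_n, self.downstream_n]),
                "mean_beta": self.concatenated(),
                "loess_beta": self.smoothed,
            }
        )


def metaprofile(
    repeats: Sequence[RepeatElement],
    sites: pd.DataFrame,
    body_bins: int = 100,
    flank_bp: int = 100,
    flank_bins: int = 20,
    loess_span: float = 0.3,
    min_length: int | None = None,
    label: str = "",
    context: str | None = "CpG",
) -> MetaProfile:
    """Average methylation metaprofile over scaled element bodies and flanks.

    Each element's body is divided into ``body_bins`` equal fractions; a site
    at offset ``o`` in an element of length ``L`` falls in bin
    ``floor(body_bins * o / L)``. Flanks of ``flank_bp`` bp on each side are
    divided into ``flank_bins`` fixed-width bins. Minus-strand elements are
    flipped so every profile runs 5' to 3' in element orientation. Elements
    shorter than ``min_length`` (default: ``body_bins``, so each bin can hold
    at least one base) are dropped. The raw per-bin means are LOESS-smoothed
    (tricube weights, local degree 1) with the given span.
    """
    if min_length is None:
        min_length = body_bins
    kept = [r for r in repeats if len(r.interval) >= min_length]
    if not kept:
        warnings.warn(f"metaprofile {label!r}: no elements of length >= {min_length}")
        nanarr = lambda k: np.full(k, np.nan)
        return MetaProfile(
            label, 0, nanarr(flank_bins), nanarr(body_bins), nanarr(flank_bins),
            np.zeros(flank_bins, int), np.zeros(body_bins, int), np.zeros(flank_bins, int),
            loess_span, nanarr(flank_bins * 2 + body_bins),
        )

    if context is not None:
        sites = sites[sites["context"] == context]
    b_all = beta(sites)
    by_chrom = {c: g for c, g in sites.groupby("chrom")}

    up_sum = np.zeros(flank_bins); up_n = np.zeros(flank_bins, int)
    body_sum = np.zeros(body_bins); body_n = np.zeros(body_bins, int)
    down_sum = np.zeros(flank_bins); down_n = np.zeros(flank_bins, int)

    for rep in kept:
        iv = rep.interval
        chrom_sites = by_chrom.get(iv.chrom)
        if chrom_sites is None:
            continue
        pos = chrom_sites["pos"].to_numpy()
        window = (pos >= iv.start - flank_bp) & (pos < iv.end + flank_bp)
        if not window.any():
            continue
        p = pos[window]
        bv = b_all.loc[chrom_sites.index[window]].to_numpy()
        ok = ~np.isnan(bv)
        p, bv = p[ok], bv[ok]
        length = len(iv)
        minus = iv.strand == "-"

        in_body = (p >= iv.start) & (p < iv.end)
        off = p[in_body] - iv.start
        if minus:
            off = length - 1 - off
        bins = np.minimum(body_bins * off // length, body_bins - 1).astype(int)
        np.add.at(body_sum, bins, bv[in_body])
        np.add.at(body_n, bins, 1)

        left = p < iv.start
        loff = p[left] - (iv.start - flank_bp)          # 0 .. flank_bp-1
        lbins = np.minimum(flank_bins * loff // flank_bp, flank_bins - 1).astype(int)
        right = p >= iv.end
        roff = p[right] - iv.end
        rbins = np.minimum(flank_bins * roff // flank_bp, flank_bins - 1).astype(int)
        if minus:
            # genomic right flank is the element's upstream; flip bin order
            np.add.at(up_sum, flank_bins - 1 - rbins, bv[right])
            np.add.at(up_n, flank_bins - 1 - rbins, 1)
            np.add.at(down_sum, flank_bins - 1 - lbins, bv[left])
            np.add.at(down_n, flank_bins - 1 - lbins, 1)
        else:
            np.add.at(up_sum, lbins, bv[left])
            np.add.at(up_n, lbins, 1)
            np.add.at(down_sum, rbins, bv[right])
            np.add.at(down_n, rbins, 1)

    with np.errstate(invalid="ignore"):
        up_mean = np.where(up_n > 0, up_sum / np.maximum(up_n, 1), np.nan)
        body_mean = np.where(body_n > 0, body_sum / np.maximum(body_n, 1), np.nan)
        down_mean = np.where(down_n > 0, down_sum / np.maximum(down_n, 1), np.nan)

    profile = MetaProfile(
        label=label or (kept[0].rep_class if kept else ""),
        n_elements=len(kept),
        upstream_mean=up_mean, body_mean=body_mean, downstream_mean=down_mean,
        upstream_n=up_n, body_n=body_n, downstream_n=down_n,
        loess_span=loess_span,
    )
    profile.smoothed = _loess_series(profile.concatenated(), loess_span)
    return profile


def _loess_series(series: np.ndarray, span: float) -> np.ndarray:
    out = np.full(len(series), np.nan)
    ok = ~np.isnan(series)
    if ok.sum() < 3:
        out[ok] = series[ok]
        return out
    x = np.arange(len(series), dtype=float)[ok]
    smoothed = lowess(series[ok], x, frac=span, it=0, return_sorted=False)
    out[ok] = smoothed
    return out


@dataclass(frozen=True)
class InnerOuterStat:
    """Site-level methylation inside elements vs the outer flanks."""

    label: str
    inner_mean: float
    inner_sd: float
    outer_mean: float
    outer_sd: float
    n_inner: int
    n_outer: int
    flank_bp: int = 100

    @property
    def difference(self) -> float:
        return self.outer_mean - self.inner_mean

    @property
    def defined(self) -> bool:
        return self.n_inner > 0 and self.n_outer > 0


def inner_outer_stats(
    repeats: Sequence[RepeatElement],
    sites: pd.DataFrame,
    flank_bp: int = 100,
    exclude_repeats: Sequence[RepeatElement] | None = None,
    label: str = "",
    context: str | None = "CpG",
) -> InnerOuterStat:
    """Mean/SD of methylation inside elements vs the ``flank_bp`` outer flanks.

    The inner pool aggregates every covered site inside any element of the
    set; the outer pool takes sites within ``flank_bp`` of an element
    boundary, excluding sites that fall inside any element of
    ``exclude_repeats`` (default: the input set itself, so a flank overlapping
    a neighbouring copy is not double-counted as "outside").
    """
    if exclude_repeats is None:
        exclude_repeats = repeats
    if context is not None:
        sites = sites[sites["context"] == context]
    b_all = beta(sites)
    excl = IntervalIndex(r.interval for r in exclude_repeats)

    inner_vals: list[np.ndarray] = []
    outer_vals: list[np.ndarray] = []
    by_chrom = {c: g for c, g in sites.groupby("chrom")}
    for rep in repeats:
        iv = rep.interval
        chrom_sites = by_chrom.get(iv.chrom)
        if chrom_sites is None:
            continue
        pos = chrom_sites["pos"].to_numpy()
        bvals = b_all.loc[chrom_sites.index].to_numpy()
        inside = (pos >= iv.start) & (pos < iv.end)
        inner_vals.append(bvals[inside & ~np.isnan(bvals)])
        flank = (
            ((pos >= max(0, iv.start - flank_bp)) & (pos < iv.start))
            | ((pos >= iv.end) & (pos < iv.end + flank_bp))
        )
        fp = pos[flank]
        fb = bvals[flank]
        keep = ~np.isnan(fb)
        keep &= ~excl.covers_points(
            np.repeat(iv.chrom, len(fp)), fp
        )
        outer_vals.append(fb[keep])

    inner = np.concatenate(inner_vals) if inner_vals else np.array([])
    outer = np.concatenate(outer_vals) if outer_vals else np.array([])
    if len(inner) == 0 or len(outer) == 0:
        warnings.warn(f"inner_outer_stats {label!r}: empty inner or outer pool")
        return InnerOuterStat(label, np.nan, np.nan, np.nan, np.nan, len(inner), len(outer), flank_bp)
    return InnerOuterStat(
        label=label,
        inner_mean=float(inner.mean()),
        inner_sd=float(inner.std(ddof=1)) if len(inner) > 1 else 0.0,
        outer_mean=float(outer.mean()),
        outer_sd=float(outer.std(ddof=1)) if len(outer) > 1 else 0.0,
        n_inner=len(inner),
        n_outer=len(outer),
        flank_bp=flank_bp,
    )


def subtype_summary(
    repeats: Sequence[RepeatElement],
    sites: pd.DataFrame,
    hypo_cut: float = 0.25,
    hyper_cut: float = 0.75,
) -> pd.DataFrame:
    """Per-subtype methylation summary with a hypo/intermediate/hyper call.

    Each element is summarised by its median site methylation; the subtype's
    level is the median over its elements. Subtypes below ``hypo_cut`` are
    hypo-methylated, at or above ``hyper_cut`` hyper-methylated.
    """
    per_element = element_methylation(repeats, sites, stat="median")
    rows = []
    for name, grp in per_element.groupby("rep_name"):
        med = grp["beta"].median()
        if np.isnan(med):
            call = "uncovered"
        elif med < hypo_cut:
            call = "hypo"
        elif med >= hyper_cut:
            call = "hyper"
        else:
            call = "intermediate"
        rows.append((name, grp["rep_class"].iloc[0], len(grp),
                     float(grp["length"].median()), float(med) if not np.isnan(med) else np.nan,
                     call))
    return pd.DataFrame(
        rows, columns=["rep_name", "rep_class", "n", "length_median", "beta_median", "call"]
    ).sort_values("rep_name").reset_index(drop=True)
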