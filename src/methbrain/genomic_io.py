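"""Readers and writers for the external formats the pipeline touches.

Supported formats
-----------------
* Bismark-style cytosine reports (7-column TSV, 1-based positions),
* BED3/BED6 interval files,
* UCSC rmsk tables and RepeatMasker ``.out`` files,
* a minimal gene-model TSV (BED-style 0-based, comma-separated exon bounds),
* gene x sample expression TSV (FPKM-like nonnegative values).

Every reader normalises to 0-based half-open coordinates; every writer emits
commented ``#`` header lines recording the tool version so outputs are
self-describing. Malformed lines raise (with the offending line number) unless
``tolerant=True``, which skips them with a warning.

Methylation-site collections are plain :class:`pandas.DataFrame` objects with
columns ``chrom, pos, strand, context, n_meth, n_unmeth`` (``pos`` 0-based);
:func:`beta` derives per-site methylation levels from the counts.
"""

from __future__ import annotations

import io
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .intervals import GeneModel, GenomicInterval, RepeatElement, normalize_strand

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]
CONTEXTS = ("CpG", "CHG", "CHH")

_CONTEXT_ALIASES = {
    "CPG": "CpG",
    "CG": "CpG",
    "CHG": "CHG",
    "CHH": "CHH",
}


class FormatError(ValueError):
    """A file does not conform to its declared format (e.g. missing columns)."""


class ValidationError(ValueError):
    """A file parses but violates a content invariant (counts, coordinates)."""


def _header_lines(params: dict | None = None) -> list[str]:
    lines = [f"# methbrain {__version__}"]
    if params:
        kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
        lines.append(f"# params: {kv}")
    return lines


def _open_lines(path) -> Iterable[tuple[int, str]]:
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def normalize_context(raw: str) -> str:
    ctx = _CONTEXT_ALIASES.get(raw.strip().upper())
    if ctx is None:
        raise ValueError(f"unknown cytosine context {raw!r}")
    return ctx


def beta(sites: pd.DataFrame) -> pd.Series:
    """Per-site methylation level ``n_meth / depth``; NaN where depth is 0."""
    depth = sites["n_meth"] + sites["n_unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        b = sites["n_meth"] / depth
    return b.where(depth > 0)


def empty_sites() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "context": pd.Series(dtype=str),
            "n_meth": pd.Series(dtype=np.int64),
            "n_unmeth": pd.Series(dtype=np.int64),
        }
    )


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

def read_cytosine_report(
    path,
    context: str | Sequence[str] | None = None,
    tolerant: bool = False,
) -> pd.DataFrame:
    """Read a Bismark-style cytosine report into a site table.

    The report is a TSV with columns chromosome, position (1-based), strand,
    methylated count, unmethylated count, context, trinucleotide. Positions
    are shifted to 0-based; contexts normalised to ``CpG``/``CHG``/``CHH``.

    Parameters
    ----------
    path : path-like
    context : str or sequence of str, optional
        Keep only sites in the given context(s), e.g. ``"CpG"``.
    tolerant : bool
        Skip malformed lines with a warning instead of raising.

    Returns
    -------
    pandas.DataFrame
        Columns ``chrom, pos, strand, context, n_meth, n_unmeth``.
    """
    wanted = None
    if context is not None:
        if isinstance(context, str):
            context = [context]
        wanted = {normalize_context(c) for c in context}

    rows: list[tuple] = []
    n_bad = 0
    for lineno, line in _open_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            if tolerant:
                n_bad += 1
                continue
            raise FormatError(
                f"{path}:{lineno}: expected >= 6 tab-separated columns "
                "(chrom, pos, strand, count_meth, count_unmeth, context), "
                f"got {len(fields)}"
            )
        chrom, pos_s, strand_s, meth_s, unmeth_s, ctx_s = fields[:6]
        try:
            pos = int(pos_s)
            n_meth = int(meth_s)
            n_unmeth = int(unmeth_s)
            strand = normalize_strand(strand_s)
            ctx = normalize_context(ctx_s)
            if pos < 1:
                raise ValueError("position must be >= 1 (1-based)")
            if n_meth < 0 or n_unmeth < 0:
                raise ValueError("negative read count")
            if strand not in ("+", "-"):
                raise ValueError("cytosine strand must be + or -")
        except ValueError as exc:
            if tolerant:
                n_bad += 1
                continue
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        if wanted is not None and ctx not in wanted:
            continue
        rows.append((chrom, pos - 1, strand, ctx, n_meth, n_unmeth))

    if n_bad:
        warnings.warn(f"{path}: skipped {n_bad} malformed line(s)")
    if not rows:
        return empty_sites()
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    df["pos"] = df["pos"].astype(np.int64)
    return df


# trinucleotide placeholders used when writing reports (the true sequence
# context is not retained in memory)
_TRINUC = {"CpG": "CGN", "CHG": "CAG", "CHH": "CAA"}


def write_cytosine_report(sites: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a site table back to the 7-column 1-based report format."""
    with open(path, "wt") as fh:
        for line in _header_lines(params):
            fh.write(line + "\n")
        for row in sites.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.strand}\t{row.n_meth}"
                f"\t{row.n_unmeth}\t{row.context}\t{_TRINUC[row.context]}\n"
            )


def merge_dyads(sites: pd.DataFrame) -> pd.DataFrame:
    """Sum the counts of the two strands of each CpG dyad.

    A minus-strand CpG at position ``p`` is the complement of the plus-strand
    CpG at ``p - 1``; merged sites keep the plus-strand coordinate. Non-CpG
    sites and unpaired CpGs pass through unchanged.
    """
    cpg = sites[sites["context"] == "CpG"]
    other = sites[sites["context"] != "CpG"]
    plus = cpg[cpg["strand"] == "+"].copy()
    minus = cpg[cpg["strand"] == "-"].copy()
    minus["pos"] = minus["pos"] - 1
    merged = plus.merge(
        minus[["chrom", "pos", "n_meth", "n_unmeth"]],
        on=["chrom", "pos"],
        how="outer",
        suffixes=("", "_minus"),
    )
    merged["n_meth"] = merged["n_meth"].fillna(0) + merged["n_meth_minus"].fillna(0)
    merged["n_unmeth"] = merged["n_unmeth"].fillna(0) + merged["n_unmeth_minus"].fillna(0)
    merged["strand"] = "+"
    merged["context"] = "CpG"
    merged = merged[SITE_COLUMNS].astype({"n_meth": np.int64, "n_unmeth": np.int64, "pos": np.int64})
    out = pd.concat([merged, other], ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path, tolerant: bool = False) -> list[GenomicInterval]:
    """Read BED3/BED6 into :class:`GenomicInterval` records (already 0-based)."""
    out: list[GenomicInterval] = []
    n_bad = 0
    for lineno, line in _open_lines(path):
        if line.startswith(("track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            if tolerant:
                n_bad += 1
                continue
            raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
        try:
            strand = normalize_strand(fields[5]) if len(fields) >= 6 else "."
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
        except ValueError as exc:
            if tolerant:
                n_bad += 1
                continue
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    if n_bad:
        warnings.warn(f"{path}: skipped {n_bad} malformed line(s)")
    return out


def write_bed(intervals: Iterable[GenomicInterval], path, params: dict | None = None) -> None:
    with open(path, "wt") as fh:
        for line in _header_lines(params):
            fh.write(line + "\n")
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# repeats
# ---------------------------------------------------------------------------

RMSK_DIALECTS = ("ucsc_table", "repeatmasker_out")


def read_rmsk(path, dialect: str = "ucsc_table", tolerant: bool = False) -> list[RepeatElement]:
    """Read repeat annotation in either the UCSC table or ``.out`` dialect.

    ``ucsc_table`` is a TSV with a header naming at least ``genoName,
    genoStart, genoEnd, strand, repName, repClass`` (0-based half-open, as the
    table browser exports). ``repeatmasker_out`` is the whitespace-delimited
    RepeatMasker output (1-based inclusive; strand ``C`` means complement).
    Both normalise to 0-based half-open intervals.
    """
    if dialect not in RMSK_DIALECTS:
        raise ValueError(f"unknown rmsk dialect {dialect!r}; choose from {RMSK_DIALECTS}")
    if dialect == "ucsc_table":
        return _read_rmsk_ucsc(path, tolerant)
    return _read_rmsk_out(path, tolerant)


def _read_rmsk_ucsc(path, tolerant: bool) -> list[RepeatElement]:
    lines = list(_open_lines(path))
    if not lines:
        return []
    header = lines[0][1].split("\t")
    needed = ["genoName", "genoStart", "genoEnd", "strand", "repName", "repClass"]
    idx = {}
    for col in needed:
        if col not in header:
            raise FormatError(f"{path}: missing required rmsk column {col!r}")
        idx[col] = header.index(col)
    fam_idx = header.index("repFamily") if "repFamily" in header else None

    out: list[RepeatElement] = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        try:
            iv = GenomicInterval(
                fields[idx["genoName"]],
                int(fields[idx["genoStart"]]),
                int(fields[idx["genoEnd"]]),
                normalize_strand(fields[idx["strand"]]),
            )
            out.append(
                RepeatElement(
                    iv,
                    rep_name=fields[idx["repName"]],
                    rep_class=fields[idx["repClass"]],
                    rep_family=fields[fam_idx] if fam_idx is not None else "",
                )
            )
        except (ValueError, IndexError) as exc:
            if tolerant:
                continue
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def _read_rmsk_out(path, tolerant: bool) -> list[RepeatElement]:
    out: list[RepeatElement] = []
    for lineno, line in _open_lines(path):
        fields = line.split()
        # the two banner lines of .out start with "SW"/"score" labels
        if not fields or not fields[0].lstrip("-").isdigit():
            continue
        try:
            chrom = fields[4]
            start = int(fields[5]) - 1  # 1-based inclusive -> 0-based half-open
            end = int(fields[6])
            strand = normalize_strand(fields[8])
            rep_name = fields[9]
            cls_fam = fields[10]
            cls, _, fam = cls_fam.partition("/")
            out.append(
                RepeatElement(
                    GenomicInterval(chrom, start, end, strand),
                    rep_name=rep_name,
                    rep_class=cls,
                    rep_family=fam,
                )
            )
        except (ValueError, IndexError) as exc:
            if tolerant:
                continue
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_rmsk(repeats: Iterable[RepeatElement], path, params: dict | None = None) -> None:
    """Write repeats in the ucsc_table dialect."""
    with open(path, "wt") as fh:
        for line in _header_lines(params):
            fh.write(line + "\n")
        fh.write("genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\trepFamily\n")
        for rep in repeats:
            iv = rep.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}"
                f"\t{rep.rep_name}\t{rep.rep_class}\t{rep.rep_family}\n"
            )


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gene_models(path, tolerant: bool = False) -> list[GeneModel]:
    """Read the minimal gene-model TSV.

    Columns: ``gene_id, chrom, strand, tx_start, tx_end, exon_starts,
    exon_ends`` with the exon bounds as comma-separated 0-based half-open
    lists (BED-style; a trailing comma is tolerated).
    """
    lines = list(_open_lines(path))
    if not lines:
        return []
    header = lines[0][1].split("\t")
    needed = ["gene_id", "chrom", "strand", "tx_start", "tx_end", "exon_starts", "exon_ends"]
    for col in needed:
        if col not in header:
            raise FormatError(f"{path}: missing gene-model column {col!r}")
    idx = {col: header.index(col) for col in needed}

    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        try:
            gene_id = fields[idx["gene_id"]]
            if gene_id in seen:
                raise ValueError(f"duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            chrom = fields[idx["chrom"]]
            strand = fields[idx["strand"]]
            starts = [int(x) for x in fields[idx["exon_starts"]].rstrip(",").split(",") if x]
            ends = [int(x) for x in fields[idx["exon_ends"]].rstrip(",").split(",") if x]
            if len(starts) != len(ends):
                raise ValueError("exon_starts and exon_ends differ in length")
            exons = tuple(
                GenomicInterval(chrom, s, e, strand) for s, e in zip(starts, ends)
            )
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    tx_start=int(fields[idx["tx_start"]]),
                    tx_end=int(fields[idx["tx_end"]]),
                    exons=exons,
                )
            )
        except (ValueError, IndexError) as exc:
            if tolerant:
                continue
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_models(genes: Iterable[GeneModel], path, params: dict | None = None) -> None:
    with open(path, "wt") as fh:
        for line in _header_lines(params):
            fh.write(line + "\n")
        fh.write("gene_id\tchrom\tstrand\ttx_start\ttx_end\texon_starts\texon_ends\n")
        for g in genes:
            starts = ",".join(str(e.start) for e in g.exons)
            ends = ",".join(str(e.end) for e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}"
                f"\t{starts}\t{ends}\n"
            )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Read a gene x sample expression TSV into a validated DataFrame.

    First column is the gene id; remaining columns are one sample each. The
    returned frame is indexed by gene id with float values.

    Raises
    ------
    ValidationError
        On duplicate gene ids, duplicate sample names, missing cells,
        non-numeric cells, or negative values (with coordinates).
    """
    with open(path, "rt") as fh:
        text = "".join(line for line in fh if not line.startswith("#"))
    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene id(s): {dups[:5]}")
    if df.columns.has_duplicates:
        raise ValidationError(f"{path}: duplicate sample name(s)")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric or missing value at gene {bad[0]!r}, sample {col!r}"
            )
        df[col] = numeric
    if (df.values < 0).any():
        g, s = np.argwhere(df.values < 0)[0]
        raise ValidationError(
            f"{path}: negative expression at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    df.index.name = "gene_id"
    return df.astype(float)


def write_expression(matrix: pd.DataFrame, path, params: dict | None = None) -> None:
    with open(path, "wt") as fh:
        for line in _header_lines(params):
            fh.write(line + "\n")
        matrix.to_csv(fh, sep="\t", index_label="gene_id", lineterminator="\n")
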