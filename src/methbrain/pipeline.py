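"""Config-driven orchestration of the full analysis with provenance.

A :class:`PipelineConfig` names the input files (per-region cytosine reports,
gene models, CGI BED, repeat annotation, expression matrix) and all analysis
thresholds. :func:`run_all` executes methylome classification, pairwise
differential methylation, expression clustering, the methylation-expression
correlation screen, and repeat profiling in order, writing every output with
a commented provenance header (package version, config hash, seed) and a
manifest of content digests, so identical config + inputs yield identical
digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import differential, expression, genomic_io, integration, methylome, repeats

logger = logging.getLogger("methbrain")


class ConfigError(ValueError):
    """Bad pipeline configuration (unknown key, threshold out of domain)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs, thresholds and flags for a full run.

    Thresholds default to the study's printed rules: depth >= 10, DMS at
    q <= 0.05, DMGs at q <= 0.01, correlation screen at p <= 0.05, fold
    change 4, k = 7 clusters, 100-bp repeat flanks.
    """

    calls: dict = field(default_factory=dict)   # region name -> cytosine report path
    genes: str = ""
    cgis: str = ""
    rmsk: str = ""
    expr: str = ""
    out_dir: str = "results"
    seed: int = 0
    min_depth: int = 10
    dms_q: float = 0.05
    dmg_q: float = 0.01
    corr_p: float = 0.05
    fc: float = 4.0
    k: int = 7
    flank_bp: int = 100
    min_abs_diff: float = 0.0
    promoter_length: int = 2000
    merge_dyads: bool = False
    bh_on_screen: bool = False
    tolerant_io: bool = False
    config_version: int = 1

    def validate(self) -> None:
        if self.min_depth < 1:
            raise ConfigError("min_depth must be >= 1")
        for name in ("dms_q", "dmg_q", "corr_p"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must lie in (0, 1]")
        if self.fc <= 1:
            raise ConfigError("fc must be > 1")
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.flank_bp < 1:
            raise ConfigError("flank_bp must be >= 1")
        if len(self.calls) < 2:
            raise ConfigError("need cytosine reports for at least 2 regions")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "wt") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def semantic_hash(self) -> str:
        """Hash of every field that changes the analysis (not out_dir)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        text = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class ValidationReport:
    row_counts: dict
    chrom_namespaces: dict
    issues: list

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Pre-flight report: row counts, chromosome namespaces, mismatches."""
    row_counts: dict = {}
    namespaces: dict = {}
    issues: list[str] = []

    def count_rows(path):
        n = 0
        with open(path) as fh:
            for line in fh:
                if line.strip() and not line.startswith("#"):
                    n += 1
        return n

    for name, path in [("genes", config.genes), ("cgis", config.cgis),
                       ("rmsk", config.rmsk), ("expr", config.expr)]:
        if not path:
            continue
        if not Path(path).exists():
            issues.append(f"missing input file: {name} ({path})")
            continue
        row_counts[name] = count_rows(path)
        if row_counts[name] == 0:
            issues.append(f"{name}: zero data rows")
    for region, path in config.calls.items():
        key = f"calls:{region}"
        if not Path(path).exists():
            issues.append(f"missing input file: {key} ({path})")
            continue
        row_counts[key] = count_rows(path)
        if row_counts[key] == 0:
            issues.append(f"{key}: zero data rows")

    try:
        if config.genes and Path(config.genes).exists():
            namespaces["genes"] = sorted({g.chrom for g in genomic_io.read_gene_models(config.genes)})
        if config.cgis and Path(config.cgis).exists():
            namespaces["cgis"] = sorted({iv.chrom for iv in genomic_io.read_bed(config.cgis)})
        for region, path in config.calls.items():
            if Path(path).exists():
                sites = genomic_io.read_cytosine_report(path)
                namespaces[f"calls:{region}"] = sorted(sites["chrom"].unique())
    except Exception as exc:  # surfaced as an issue, not a crash: this is a report
        issues.append(f"parse failure during validation: {exc}")

    if namespaces:
        universes = {k: set(v) for k, v in namespaces.items()}
        union = set().union(*universes.values())
        for k, v in universes.items():
            if v and not (v & (union - v)) and len(universes) > 1 and union - v:
                issues.append(
                    f"{k}: chromosome namespace {sorted(v)[:3]} shares nothing "
                    "with the other inputs"
                )
    return ValidationReport(row_counts, namespaces, issues)


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, index=False) -> None:
    with open(path, "wt") as fh:
        fh.write(f"# methbrain {__version__} config={config.semantic_hash()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the result bundle and writes outputs.

    Outputs land under ``config.out_dir`` together with the resolved config
    and ``manifest.tsv`` (sha256 per file). A stage failure raises
    :class:`StageError` naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    results: dict = {}

    def stage(name):
        logger.info("stage %s", name)

    try:
        stage("load")
        genes = genomic_io.read_gene_models(config.genes, tolerant=config.tolerant_io)
        cgis = genomic_io.read_bed(config.cgis, tolerant=config.tolerant_io)
        reps = genomic_io.read_rmsk(config.rmsk, tolerant=config.tolerant_io) if config.rmsk else []
        expr = genomic_io.read_expression(config.expr)
        raw_sites = {
            r: genomic_io.read_cytosine_report(p, tolerant=config.tolerant_io)
            for r, p in config.calls.items()
        }
        if config.merge_dyads:
            raw_sites = {r: genomic_io.merge_dyads(s) for r, s in raw_sites.items()}
        sites = {r: methylome.filter_by_depth(s, config.min_depth) for r, s in raw_sites.items()}
        for r in sites:
            logger.info("region %s: %d sites (%d pre-filter)", r, len(sites[r]), len(raw_sites[r]))
    except Exception as exc:
        raise StageError("load", str(exc)) from exc

    try:
        stage("methylome")
        summaries = []
        for region, s in sites.items():
            classified = methylome.classify_sites(s, genes, promoter_length=config.promoter_length)
            prop = methylome.level_bin_proportions(classified)
            prop.insert(0, "sample", region)
            summaries.append(prop)
        results["classification"] = pd.concat(summaries, ignore_index=True)
        _write_tsv(results["classification"], out / "classification.tsv", config)
    except Exception as exc:
        raise StageError("methylome", str(exc)) from exc

    try:
        stage("differential")
        cpg = {r: s[s["context"] == "CpG"].reset_index(drop=True) for r, s in sites.items()}
        regions = list(cpg)
        dms_frames = []
        counts = pd.DataFrame(0, index=regions, columns=regions, dtype=int)
        for a, b in itertools.combinations(regions, 2):
            dms = differential.call_dms(cpg[a], cpg[b], config.dms_q, config.min_abs_diff)
            n_sig = 0 if dms.empty else int((dms["direction"] != "ns").sum())
            counts.loc[a, b] = counts.loc[b, a] = n_sig
            if not dms.empty:
                sig = dms[dms["direction"] != "ns"].copy()
                sig.insert(0, "pair", f"{a}|{b}")
                dms_frames.append(sig)
        all_dms = (
            pd.concat(dms_frames, ignore_index=True)
            if dms_frames
            else pd.DataFrame(columns=["pair"] + differential.DMS_COLUMNS)
        )
        dmgs = differential.call_dmgs(all_dms, cgis, genes, q_threshold=config.dmg_q)
        results["dms"] = all_dms
        results["dms_matrix"] = counts
        results["dmgs"] = dmgs
        _write_tsv(all_dms, out / "dms.tsv", config)
        _write_tsv(counts, out / "dms_matrix.tsv", config, index=True)
        differential.write_dmgs(
            dmgs, out / "dmgs.tsv",
            [f"methbrain {__version__} config={config.semantic_hash()} seed={config.seed}"],
        )
    except Exception as exc:
        raise StageError("differential", str(exc)) from exc

    try:
        stage("expression")
        factors = expression.tmm_factors(expr)
        normed = expression.apply_tmm(expr, factors)
        filtered = expression.fold_change_filter(normed, fc=config.fc)
        logger.info("fold-change filter kept %d of %d genes", len(filtered), len(normed))
        zmat = expression.log_z_capped(filtered)
        assignment = expression.pam_cluster(zmat.z, k=config.k)
        region_map, brsg = expression.assign_region_clusters(assignment, zmat.z)
        results["tmm_factors"] = factors
        results["clusters"] = assignment
        results["region_map"] = region_map
        results["brsg"] = brsg
        cluster_table = assignment.labels.rename("cluster").reset_index()
        cluster_table["is_medoid"] = cluster_table["gene_id"].isin(assignment.medoids.values())
        _write_tsv(cluster_table, out / "clusters.tsv", config)
        _write_tsv(
            pd.DataFrame(sorted(region_map.items()), columns=["region", "cluster"]),
            out / "region_clusters.tsv", config,
        )
    except Exception as exc:
        raise StageError("expression", str(exc)) from exc

    try:
        stage("integration")
        cpg_by_region = {r: cpg[r] for r in expr.columns if r in cpg}
        pairs = integration.cgi_promoter_pairs(cgis, genes, config.promoter_length)
        records = integration.pearson_screen(
            pairs, cpg_by_region, normed,
            p_threshold=config.corr_p, add_bh=config.bh_on_screen,
        )
        flagged, summary = integration.categorize(records, brsg, dmgs)
        results["correlations"] = flagged
        results["correlation_summary"] = summary
        _write_tsv(flagged, out / "correlations.tsv", config)
        _write_tsv(summary, out / "correlation_summary.tsv", config)
    except Exception as exc:
        raise StageError("integration", str(exc)) from exc

    try:
        stage("repeats")
        pooled = pd.concat(list(cpg.values()), ignore_index=True)
        profile_frames, stat_rows = [], []
        for cls in sorted({r.rep_class for r in reps}):
            members = [r for r in reps if r.rep_class == cls]
            prof = repeats.metaprofile(
                members, pooled, flank_bp=config.flank_bp, label=cls
            )
            profile_frames.append(prof.to_frame())
            st = repeats.inner_outer_stats(
                members, pooled, flank_bp=config.flank_bp,
                exclude_repeats=reps, label=cls,
            )
            stat_rows.append(
                (cls, st.inner_mean, st.inner_sd, st.outer_mean, st.outer_sd,
                 st.difference, st.n_inner, st.n_outer)
            )
        results["repeat_profiles"] = (
            pd.concat(profile_frames, ignore_index=True) if profile_frames else pd.DataFrame()
        )
        results["repeat_stats"] = pd.DataFrame(
            stat_rows,
            columns=["rep_class", "inner_mean", "inner_sd", "outer_mean",
                     "outer_sd", "difference", "n_inner", "n_outer"],
        )
        results["subtypes"] = repeats.subtype_summary(reps, pooled) if reps else pd.DataFrame()
        _write_tsv(results["repeat_profiles"], out / "repeat_profiles.tsv", config)
        _write_tsv(results["repeat_stats"], out / "repeat_stats.tsv", config)
        _write_tsv(results["subtypes"], out / "repeat_subtypes.tsv", config)
    except Exception as exc:
        raise StageError("repeats", str(exc)) from exc

    manifest = write_manifest(out)
    results["manifest"] = manifest
    return results


def write_manifest(out_dir: Path) -> pd.DataFrame:
    """Record a sha256 digest for every output file under out_dir."""
    rows = []
    for path in sorted(Path(out_dir).glob("*.tsv")):
        if path.name == "manifest.tsv":
            continue
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        rows.append((path.name, digest))
    manifest = pd.DataFrame(rows, columns=["file", "sha256"])
    manifest.to_csv(Path(out_dir) / "manifest.tsv", sep="\t", index=False)
    return manifest
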