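"""Expression normalisation, filtering and region-specific clustering.

The workflow mirrors a regional transcriptome characterisation: TMM scaling
factors bring the per-region FPKM columns onto a common scale, genes are
filtered to those with at least a 4-fold difference between some pair of
regions, log2(FPKM + 1) values are converted to per-gene z-scores capped at
+/-2, and the capped matrix is partitioned with the deterministic PAM
(k-medoids) algorithm, k equal to the number of regions. Each region is then
assigned the cluster with the highest mean z in that region; that cluster's
genes form the region's brain-region-specific gene (BRSG) set.

TMM here operates on FPKM-scale values, not raw counts: M and A statistics
are computed from the values directly (no library-size term, which FPKM has
already absorbed) and gene weights use the asymptotic 1/x variance
approximation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def tmm_factors(
    matrix: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, one per sample column.

    The reference sample is the one whose upper-quartile expression is closest
    to the mean upper quartile (or ``ref_sample`` when given, mirroring
    edgeR's ``refColumn``). For every other sample, genes positive in both
    it and the reference contribute M = log2(x/x_ref) and A = log2(x*x_ref)/2;
    the top and bottom ``trim_m`` of M and ``trim_a`` of A are discarded and
    the factor is 2 to the precision-weighted mean of the remaining M values.
    Factors are rescaled to geometric mean 1.
    """
    if matrix.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    if ref_sample is not None:
        ref_idx = matrix.columns.get_loc(ref_sample)
    else:
        uq = np.nanpercentile(np.where(values > 0, values, np.nan), 75, axis=0)
        uq = np.where(np.isnan(uq), 0.0, uq)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = values[:, ref_idx]

    log_factors = np.zeros(matrix.shape[1])
    for j in range(matrix.shape[1]):
        if j == ref_idx:
            continue
        x = values[:, j]
        both = (x > 0) & (ref > 0)
        if both.sum() < 2:
            warnings.warn(
                f"sample {matrix.columns[j]!r}: fewer than 2 genes shared with "
                "the reference; factor set to 1"
            )
            continue
        m = np.log2(x[both] / ref[both])
        a = 0.5 * np.log2(x[both] * ref[both])
        keep = _doubly_trimmed(m, a, trim_m, trim_a)
        if not keep.any():
            warnings.warn(
                f"sample {matrix.columns[j]!r}: trimming removed every gene; "
                "using the untrimmed weighted mean"
            )
            keep = np.ones(len(m), dtype=bool)
        w = 1.0 / (1.0 / x[both][keep] + 1.0 / ref[both][keep])
        log_factors[j] = np.average(m[keep], weights=w)

    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(2.0 ** log_factors, index=matrix.columns, name="tmm_factor")


def _doubly_trimmed(m: np.ndarray, a: np.ndarray, trim_m: float, trim_a: float) -> np.ndarray:
    n = len(m)
    lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    return keep if n else np.zeros(0, dtype=bool)


def apply_tmm(matrix: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Divide each sample column by its TMM factor."""
    if factors is None:
        factors = tmm_factors(matrix)
    return matrix / factors


# ---------------------------------------------------------------------------
# z-score transform
# ---------------------------------------------------------------------------

@dataclass
class ZMatrix:
    """Per-gene z-scores of log2(FPKM + 1), capped at +/-2."""

    z: pd.DataFrame
    excluded: list[str]  # zero-variance genes dropped before scaling


def log_z_capped(matrix: pd.DataFrame, cap: float = 2.0) -> ZMatrix:
    """log2(x + 1), per-gene standardisation, then clipping to [-cap, cap].

    Genes whose log-values are constant across samples carry no pattern and
    would divide by zero; they are excluded and listed in the result.
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression values must be nonnegative")
    logged = np.log2(matrix + 1.0)
    sd = logged.std(axis=1, ddof=1)
    excluded = logged.index[sd == 0].tolist()
    if excluded:
        warnings.warn(f"excluded {len(excluded)} zero-variance gene(s) from z-scoring")
    kept = logged.loc[sd > 0]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    return ZMatrix(z=z.clip(-cap, cap), excluded=excluded)


# ---------------------------------------------------------------------------
# fold-change filter
# ---------------------------------------------------------------------------

def fold_change_filter(
    matrix: pd.DataFrame, fc: float = 4.0, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Keep genes with a >= fc ratio between some pair of samples.

    The ratio is computed on pseudocounted values, so zeros are handled the
    same way as in the log2(FPKM + 1) transform. Because the extreme ratio is
    (max + pc)/(min + pc), the result does not depend on sample order.
    """
    if fc <= 1:
        raise ValueError("fold-change threshold must be > 1")
    vals = matrix.to_numpy(dtype=float) + pseudocount
    ratio = vals.max(axis=1) / vals.min(axis=1)
    return matrix.loc[ratio >= fc]


# ---------------------------------------------------------------------------
# PAM (k-medoids)
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Result of PAM clustering: labels in 1..k, one medoid gene per cluster."""

    labels: pd.Series          # gene_id -> cluster label
    medoids: dict[int, str]    # cluster label -> medoid gene_id
    cost: float                # total distance of genes to their medoids

    @property
    def k(self) -> int:
        return len(self.medoids)


#: exact enumeration is used whenever the medoid-set space is this small;
#: best-improvement local search can miss the optimum on tiny instances
_PAM_EXACT_LIMIT = 5000


def pam_cluster(zmatrix: pd.DataFrame, k: int = 7) -> ClusterAssignment:
    """Partitioning Around Medoids, deterministic and exact on small inputs.

    When the number of candidate medoid sets C(n, k) is small (at most
    5000) every set is enumerated and the global optimum returned. Larger
    instances use the classical deterministic BUILD phase (greedy medoid
    selection minimising total distance) followed by a SWAP phase that
    repeatedly applies the best strictly improving medoid/non-medoid
    exchange until none exists. With no random restarts the result is a
    pure function of the input. Ties are broken toward the lower gene
    index, and cluster labels 1..k are assigned in sorted order of the
    medoid gene ids so labels are stable across runs.
    """
    n = len(zmatrix)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of genes ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    x = zmatrix.to_numpy(dtype=float)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))

    if math.comb(n, k) <= _PAM_EXACT_LIMIT:
        medoids, cost = _pam_exact(d, k)
    else:
        medoids = _pam_build(d, k)
        medoids, cost = _pam_swap(d, medoids)

    medoid_ids = [zmatrix.index[m] for m in medoids]
    order = np.argsort(medoid_ids, kind="stable")
    ordered = [medoids[i] for i in order]
    # nearest medoid; argmin returns the first minimum, i.e. the
    # lowest-labelled medoid on ties
    nearest = np.argmin(d[:, ordered], axis=1)
    labels = pd.Series(nearest + 1, index=zmatrix.index, name="cluster")
    medoid_map = {lab + 1: zmatrix.index[m] for lab, m in enumerate(ordered)}
    return ClusterAssignment(labels=labels, medoids=medoid_map, cost=float(cost))


def _pam_exact(d: np.ndarray, k: int) -> tuple[list[int], float]:
    """Global optimum by enumerating every medoid set (small instances only).

    Lexicographic enumeration with strict improvement keeps ties on the
    lowest-index medoid set.
    """
    best_cost = np.inf
    best: tuple[int, ...] = ()
    for medoids in itertools.combinations(range(d.shape[0]), k):
        cost = d[:, medoids].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost = cost
            best = medoids
    return list(best), float(best_cost)


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = d.shape[0]
    first = int(np.argmin(d.sum(axis=1)))
    medoids = [first]
    dist_near = d[:, first].copy()
    while len(medoids) < k:
        # gain of adding candidate c = sum of reductions in nearest-distance
        gain = np.maximum(dist_near[:, None] - d, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        best = int(np.argmax(gain))  # first max -> lowest index on ties
        medoids.append(best)
        dist_near = np.minimum(dist_near, d[:, best])
    return medoids


def _pam_swap(d: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    medoids = list(medoids)
    n = d.shape[0]
    while True:
        dm = d[:, medoids]                      # n x k
        order = np.argsort(dm, axis=1, kind="stable")
        d1 = dm[np.arange(n), order[:, 0]]
        if len(medoids) > 1:
            d2 = dm[np.arange(n), order[:, 1]]
        else:
            d2 = np.full(n, np.inf)
        nearest = np.asarray(medoids)[order[:, 0]]

        best_delta = -1e-12
        best_swap = None
        for mi, m in enumerate(medoids):
            owns = nearest == m
            # cost after replacing medoid m with candidate h, for all h at once
            with_m = np.minimum(d, d2[:, None])       # points that lose m
            without = np.minimum(d, d1[:, None])      # points keeping their medoid
            contrib = np.where(owns[:, None], with_m, without)
            delta = contrib.sum(axis=0) - d1.sum()
            delta[medoids] = np.inf
            h = int(np.argmin(delta))
            if delta[h] < best_delta:
                best_delta = float(delta[h])
                best_swap = (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    dm = d[:, medoids]
    return medoids, float(dm.min(axis=1).sum())


def pam_total_cost(d: np.ndarray, medoids: list[int]) -> float:
    """Total distance of every point to its nearest medoid."""
    return float(d[:, medoids].min(axis=1).sum())


# ---------------------------------------------------------------------------
# region <-> cluster assignment
# ---------------------------------------------------------------------------

def assign_region_clusters(
    assignment: ClusterAssignment, zmatrix: pd.DataFrame
) -> tuple[dict[str, int], dict[str, set[str]]]:
    """Map each region to its highest-expressing cluster and derive BRSG sets.

    A region's cluster is the one maximising the cluster's mean z in that
    region (ties toward the lower label). The map need not be a bijection;
    a warning is raised when two regions select the same cluster, or when k
    differs from the number of regions.
    """
    regions = list(zmatrix.columns)
    if assignment.k != len(regions):
        warnings.warn(
            f"k={assignment.k} differs from the number of regions ({len(regions)})"
        )
    cluster_means = zmatrix.groupby(assignment.labels).mean()  # cluster x region
    region_map = {r: int(cluster_means[r].idxmax()) for r in regions}
    if len(set(region_map.values())) < len(regions):
        warnings.warn("two or more regions selected the same cluster")
    brsg = {
        r: set(assignment.labels.index[assignment.labels == c])
        for r, c in region_map.items()
    }
    return region_map, brsg
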