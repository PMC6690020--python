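import numpy as np
import pandas as pd
import pytest

from methbrain import repeats as rep_mod
from methbrain.intervals import GenomicInterval, RepeatElement

from .oracles import positional_mean_profile


def element(chrom, start, end, strand="+", name="L1MA1", cls="LINE"):
    return RepeatElement(GenomicInterval(chrom, start, end, strand), name, cls)


def sites_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]
    )


def beta_sites(chrom, positions, betas, depth=1000):
    return sites_frame(
        [
            (chrom, int(p), "+", "CpG", int(round(b * depth)), depth - int(round(b * depth)))
            for p, b in zip(positions, betas)
        ]
    )


# ---------------------------------------------------------------------------
# CGI split
# ---------------------------------------------------------------------------

def test_split_by_cgi_partitions_input():
    reps = [element("chr1", 1000, 1400), element("chr1", 2000, 2300),
            element("chr1", 3000, 3500)]
    cgis = [GenomicInterval("chr1", 1200, 1250),   # inside the first repeat
            GenomicInterval("chr1", 2300, 2400)]   # 0-bp gap to the second: no overlap
    with_cgi, without = rep_mod.split_by_cgi(reps, cgis)
    assert [r.interval.start for r in with_cgi] == [1000]
    assert len(with_cgi) + len(without) == len(reps)
    assert set(id(r) for r in with_cgi).isdisjoint(id(r) for r in without)


# ---------------------------------------------------------------------------
# per-element summaries
# ---------------------------------------------------------------------------

def test_element_methylation_mean_median_and_missing():
    reps = [element("chr1", 100, 200), element("chr1", 500, 600)]
    sites = beta_sites("chr1", [110, 150, 190], [0.1, 0.9, 0.8])
    mean_out = rep_mod.element_methylation(reps, sites, stat="mean")
    med_out = rep_mod.element_methylation(reps, sites, stat="median")
    assert mean_out["beta"].iloc[0] == pytest.approx(0.6)
    assert med_out["beta"].iloc[0] == pytest.approx(0.8)
    assert np.isnan(mean_out["beta"].iloc[1])  # no covered site


def test_element_methylation_ignores_non_cpg_by_default():
    reps = [element("chr1", 100, 200)]
    sites = sites_frame(
        [("chr1", 150, "+", "CpG", 9, 1), ("chr1", 160, "+", "CHH", 0, 10)]
    )
    out = rep_mod.element_methylation(reps, sites)
    assert out["n_sites"].iloc[0] == 1


# ---------------------------------------------------------------------------
# metaprofiles
# ---------------------------------------------------------------------------

def test_constant_methylation_gives_flat_profile_and_flat_loess():
    reps = [element("chr1", 1000, 1500), element("chr1", 3000, 3600)]
    positions = list(range(900, 1620, 7)) + list(range(2900, 3720, 7))
    sites = beta_sites("chr1", positions, [0.8] * len(positions))
    prof = rep_mod.metaprofile(reps, sites, body_bins=20, flank_bins=5)
    defined = ~np.isnan(prof.concatenated())
    assert np.allclose(prof.concatenated()[defined], 0.8, atol=1e-9)
    assert np.allclose(prof.smoothed[defined], 0.8, atol=1e-6)


def test_uncovered_bins_are_missing_not_zero():
    reps = [element("chr1", 1000, 1200)]
    sites = beta_sites("chr1", [1005], [0.5])  # only the first body bin covered
    prof = rep_mod.metaprofile(reps, sites, body_bins=4, flank_bins=2)
    assert prof.body_mean[0] == pytest.approx(0.5)
    assert np.isnan(prof.body_mean[1:]).all()
    assert np.isnan(prof.upstream_mean).all()


def test_strand_flip_reverses_bin_series():
    rng = np.random.default_rng(0)
    positions = np.arange(1000, 1500, 3)
    betas = rng.uniform(0, 1, size=len(positions))
    sites = beta_sites("chr1", positions, betas)
    fwd = rep_mod.metaprofile([element("chr1", 1000, 1500, "+")], sites,
                              body_bins=25, flank_bins=4)
    rev = rep_mod.metaprofile([element("chr1", 1000, 1500, "-")], sites,
                              body_bins=25, flank_bins=4)
    np.testing.assert_allclose(fwd.body_mean, rev.body_mean[::-1], atol=1e-9)


def test_equal_length_profile_matches_positional_oracle():
    rng = np.random.default_rng(1)
    length, n_elements = 200, 12
    elements, site_rows, lookup = [], [], {}
    for i in range(n_elements):
        start = 10_000 * (i + 1)
        strand = "+" if i % 2 == 0 else "-"
        elements.append(element("chr1", start, start + length, strand))
        for pos in range(start, start + length, 5):
            b = round(float(rng.uniform(0, 1)), 3)  # representable at depth 1000
            site_rows.append(("chr1", pos, b))
            lookup[("chr1", pos)] = b
    sites = beta_sites("chr1", [p for _, p, _ in site_rows], [b for _, _, b in site_rows])
    prof = rep_mod.metaprofile(elements, sites, body_bins=40, flank_bins=2)
    oracle_mean, oracle_n = positional_mean_profile(
        [(e.interval.chrom, e.interval.start, e.interval.strand) for e in elements],
        lookup, length, 40,
    )
    np.testing.assert_allclose(prof.body_mean, oracle_mean, atol=1e-6)
    np.testing.assert_array_equal(prof.body_n, oracle_n)


def test_planted_edge_and_center_shapes():
    rng = np.random.default_rng(2)
    edge_reps, center_reps, rows = [], [], []
    for i in range(30):
        start = 20_000 * (i + 1)
        length = 900
        edge_reps.append(element("chr1", start, start + length))
        center_reps.append(element("chr2", start, start + length, cls="SINE", name="AluJo"))
        for pos in range(start, start + length, 6):
            off = pos - start
            inner = length // 3 <= off < 2 * length // 3
            b_edge = 0.6 if inner else 0.9
            b_center = 0.9 if inner else 0.6
            rows.append(("chr1", pos, np.clip(b_edge + rng.normal(0, 0.03), 0, 1)))
            rows.append(("chr2", pos, np.clip(b_center + rng.normal(0, 0.03), 0, 1)))
    sites = pd.concat(
        [
            beta_sites("chr1", [p for c, p, _ in rows if c == "chr1"],
                       [b for c, _, b in rows if c == "chr1"]),
            beta_sites("chr2", [p for c, p, _ in rows if c == "chr2"],
                       [b for c, _, b in rows if c == "chr2"]),
        ],
        ignore_index=True,
    )
    edge_prof = rep_mod.metaprofile(edge_reps, sites, body_bins=30)
    center_prof = rep_mod.metaprofile(center_reps, sites, body_bins=30)
    for prof, direction in ((edge_prof, -1), (center_prof, +1)):
        mid = np.nanmean(prof.body_mean[10:20])
        edges = np.nanmean(np.r_[prof.body_mean[:10], prof.body_mean[20:]])
        assert direction * (mid - edges) > 0.15  # half the planted 0.3 contrast


def test_empty_class_warns():
    with pytest.warns(UserWarning, match="no elements"):
        prof = rep_mod.metaprofile([], sites_frame([]), label="LTR")
    assert prof.n_elements == 0


# ---------------------------------------------------------------------------
# inner / outer statistics
# ---------------------------------------------------------------------------

def test_identical_levels_give_zero_difference():
    reps = [element("chr1", 1000, 1400)]
    positions = list(range(950, 1460, 10))
    sites = beta_sites("chr1", positions, [0.7] * len(positions))
    st = rep_mod.inner_outer_stats(reps, sites)
    assert st.difference == pytest.approx(0.0, abs=1e-12)
    assert st.inner_mean == pytest.approx(0.7)


def test_flank_sites_inside_other_repeats_are_excluded():
    target = element("chr1", 1000, 1400)
    neighbour = element("chr1", 1450, 1800)
    sites = beta_sites("chr1", [1100, 1420, 1460], [0.5, 0.9, 0.1])
    st_with = rep_mod.inner_outer_stats([target], sites, exclude_repeats=[target, neighbour])
    # the 1460 site falls in the neighbour and must not count as "outside"
    assert st_with.n_outer == 1 and st_with.outer_mean == pytest.approx(0.9)


def test_flanks_truncate_at_chromosome_start():
    reps = [element("chr1", 30, 200)]  # left flank clipped to [0, 30)
    sites = beta_sites("chr1", [10, 100], [0.4, 0.8])
    st = rep_mod.inner_outer_stats(reps, sites)
    assert st.n_outer == 1 and st.outer_mean == pytest.approx(0.4)


def test_planted_inner_outer_gap_recovered_within_monte_carlo_error():
    rng = np.random.default_rng(3)
    reps, rows = [], []
    for i in range(150):
        start = 5_000 * (i + 1)
        reps.append(element("chr1", start, start + 300))
        for pos in range(start, start + 300, 20):          # inner, mean 0.80
            rows.append((pos, rng.beta(32, 8)))
        for pos in list(range(start - 90, start, 30)) + list(range(start + 310, start + 400, 30)):
            rows.append((pos, rng.beta(25.5, 4.5)))        # outer, mean 0.85
    sites = beta_sites("chr1", [p for p, _ in rows], [b for _, b in rows])
    st = rep_mod.inner_outer_stats(reps, sites)
    se = np.sqrt(st.inner_sd**2 / st.n_inner + st.outer_sd**2 / st.n_outer)
    assert abs(st.difference - 0.05) <= 3 * se


def test_empty_pool_marks_stat_undefined():
    reps = [element("chr1", 1000, 1400)]
    sites = beta_sites("chr1", [5000], [0.5])
    with pytest.warns(UserWarning, match="empty"):
        st = rep_mod.inner_outer_stats(reps, sites)
    assert not st.defined


# ---------------------------------------------------------------------------
# subtype summaries
# ---------------------------------------------------------------------------

def test_subtype_hypo_hyper_classification():
    reps = [
        element("chr1", 1000, 1200, name="HyperSub"),
        element("chr1", 3000, 3200, name="HypoSub"),
        element("chr1", 5000, 5200, name="MidSub"),
    ]
    sites = pd.concat(
        [
            beta_sites("chr1", [1050, 1100, 1150], [0.9, 0.92, 0.88]),
            beta_sites("chr1", [3050, 3100, 3150], [0.1, 0.12, 0.08]),
            beta_sites("chr1", [5050, 5100, 5150], [0.5, 0.52, 0.48]),
        ],
        ignore_index=True,
    )
    table = rep_mod.subtype_summary(reps, sites).set_index("rep_name")
    assert table.loc["HyperSub", "call"] == "hyper"
    assert table.loc["HypoSub", "call"] == "hypo"
    assert table.loc["MidSub", "call"] == "intermediate"
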