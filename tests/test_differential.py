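import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methbrain import differential
from methbrain.intervals import GeneModel, GenomicInterval

from .oracles import bh_step_up, fisher_p_enumeration


def sites_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]
    )


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def test_fisher_identical_rows_give_p_one():
    assert differential.fisher_exact_2x2(5, 5, 5, 5) == 1.0


def test_fisher_extreme_table_matches_enumeration():
    p = differential.fisher_exact_2x2(10, 0, 0, 10)
    assert abs(p - fisher_p_enumeration(10, 0, 0, 10)) < 1e-9


def test_fisher_moderate_table_matches_enumeration():
    p = differential.fisher_exact_2x2(3, 7, 7, 3)
    assert abs(p - fisher_p_enumeration(3, 7, 7, 3)) < 1e-9


def test_fisher_zero_margin_is_degenerate():
    p, deg = differential.fisher_exact_many(
        np.array([0, 0]), np.array([0, 3]), np.array([5, 0]), np.array([5, 4])
    )
    assert deg[0] and p[0] == 1.0          # empty first row
    assert deg[1] and p[1] == 1.0          # empty methylated column


def test_fisher_rejects_negative_counts():
    with pytest.raises(ValueError):
        differential.fisher_exact_2x2(-1, 2, 3, 4)


@settings(max_examples=150, deadline=None)
@given(
    a=st.integers(0, 15), b=st.integers(0, 15),
    c=st.integers(0, 15), d=st.integers(0, 15),
)
def test_fisher_matches_enumeration_oracle_property(a, b, c, d):
    p = differential.fisher_exact_2x2(a, b, c, d)
    assert abs(p - fisher_p_enumeration(a, b, c, d)) < 1e-9
    assert 0 < p <= 1


@settings(max_examples=60, deadline=None)
@given(
    a=st.integers(0, 20), b=st.integers(0, 20),
    c=st.integers(0, 20), d=st.integers(0, 20),
)
def test_fisher_cross_checks_against_scipy(a, b, c, d):
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        return  # scipy's convention for degenerate margins differs
    ours = differential.fisher_exact_2x2(a, b, c, d)
    theirs = stats.fisher_exact([[a, b], [c, d]])[1]
    assert abs(ours - theirs) < 1e-9


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def test_bh_single_p_unchanged():
    assert differential.bh_adjust([0.05]) == pytest.approx([0.05])


def test_bh_hand_worked_step_up():
    q = differential.bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_ties_pass_through():
    q = differential.bh_adjust([0.5] * 10)
    assert np.allclose(q, 0.5)


@settings(max_examples=100, deadline=None)
@given(
    st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=60)
)
def test_bh_matches_brute_force_and_is_permutation_invariant(p_values):
    p = np.array(p_values)
    q = differential.bh_adjust(p)
    assert np.allclose(q, bh_step_up(p), atol=1e-12)
    perm = np.random.default_rng(0).permutation(len(p))
    assert np.allclose(differential.bh_adjust(p[perm]), q[perm], atol=1e-12)
    # monotone nondecreasing when sorted by p
    order = np.argsort(p, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# DMS calling
# ---------------------------------------------------------------------------

def test_null_self_comparison_yields_no_calls():
    rows = [("chr1", i, "+", "CpG", 5 + i % 5, 10) for i in range(50)]
    a = sites_frame(rows)
    dms = differential.call_dms(a, a.copy())
    assert (dms["direction"] == "ns").all()
    assert np.allclose(dms["p_value"], 1.0)


def test_single_planted_site_survives_bh():
    null_rows = [("chr1", i, "+", "CpG", 5, 5) for i in range(10)]
    a = sites_frame(null_rows + [("chr1", 99, "+", "CpG", 30, 0)])
    b = sites_frame(null_rows + [("chr1", 99, "+", "CpG", 0, 30)])
    dms = differential.call_dms(a, b)
    hit = dms[dms.pos == 99].iloc[0]
    # hand-applied BH: m = 11, the planted p is the smallest
    p_exp = fisher_p_enumeration(30, 0, 0, 30)
    assert hit.p_value == pytest.approx(p_exp, abs=1e-12)
    assert hit.q_value == pytest.approx(min(1.0, p_exp * 11), rel=1e-9)
    assert hit.direction == "hypo" and hit["diff"] == -1.0
    assert (dms[dms.pos != 99]["direction"] == "ns").all()


def test_sites_absent_from_one_sample_are_not_tested():
    a = sites_frame([("chr1", 1, "+", "CpG", 5, 5), ("chr1", 2, "+", "CpG", 5, 5)])
    b = sites_frame([("chr1", 2, "+", "CpG", 5, 5)])
    dms = differential.call_dms(a, b)
    assert dms["pos"].tolist() == [2]


def test_no_shared_sites_warns_and_returns_empty():
    a = sites_frame([("chr1", 1, "+", "CpG", 5, 5)])
    b = sites_frame([("chr2", 9, "+", "CpG", 5, 5)])
    with pytest.warns(UserWarning, match="shared"):
        dms = differential.call_dms(a, b)
    assert dms.empty


def test_call_dms_is_mirror_symmetric():
    rng = np.random.default_rng(1)
    rows_a, rows_b = [], []
    for i in range(40):
        rows_a.append(("chr1", i, "+", "CpG", int(rng.integers(0, 20)), int(rng.integers(1, 20))))
        rows_b.append(("chr1", i, "+", "CpG", int(rng.integers(0, 20)), int(rng.integers(1, 20))))
    ab = differential.call_dms(sites_frame(rows_a), sites_frame(rows_b))
    ba = differential.call_dms(sites_frame(rows_b), sites_frame(rows_a))
    assert np.allclose(ab["p_value"], ba["p_value"])
    assert np.allclose(ab["q_value"], ba["q_value"])
    assert np.allclose(ab["diff"], -ba["diff"])
    flip = {"hyper": "hypo", "hypo": "hyper", "ns": "ns"}
    assert [flip[d] for d in ab["direction"]] == ba["direction"].tolist()


def test_min_abs_diff_suppresses_small_effects():
    null_rows = [("chr1", i, "+", "CpG", 5, 5) for i in range(5)]
    a = sites_frame(null_rows + [("chr1", 99, "+", "CpG", 60, 40)])
    b = sites_frame(null_rows + [("chr1", 99, "+", "CpG", 30, 70)])
    loose = differential.call_dms(a, b, min_abs_diff=0.0)
    strict = differential.call_dms(a, b, min_abs_diff=0.5)
    assert (loose[loose.pos == 99]["direction"] == "hypo").all()
    assert (strict[strict.pos == 99]["direction"] == "ns").all()


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def test_count_matrix_identical_samples_all_zero():
    a = sites_frame([("chr1", i, "+", "CpG", 8, 8) for i in range(20)])
    mat = differential.dms_count_matrix({"x": a, "y": a.copy()})
    assert (mat.values == 0).all()


def test_count_matrix_is_symmetric_with_zero_diagonal():
    rng = np.random.default_rng(2)
    samples = {}
    for name in ("r1", "r2", "r3"):
        samples[name] = sites_frame(
            [("chr1", i, "+", "CpG", int(rng.integers(0, 30)), int(rng.integers(1, 30)))
             for i in range(60)]
        )
    mat = differential.dms_count_matrix(samples)
    assert mat.shape == (3, 3)
    assert (mat.values == mat.values.T).all()
    assert (np.diag(mat.values) == 0).all()


def test_count_matrix_needs_two_samples():
    a = sites_frame([("chr1", 1, "+", "CpG", 5, 5)])
    with pytest.raises(ValueError):
        differential.dms_count_matrix({"only": a})


# ---------------------------------------------------------------------------
# DMG calling
# ---------------------------------------------------------------------------

def make_gene(gid, strand, tx_start, tx_end, chrom="chr1"):
    exons = (
        GenomicInterval(chrom, tx_start, tx_start + 200, strand),
        GenomicInterval(chrom, tx_end - 200, tx_end, strand),
    )
    return GeneModel(gid, chrom, strand, tx_start, tx_end, exons)


def dms_record(chrom, pos, q=0.01, direction="hyper"):
    return dict(
        chrom=chrom, pos=pos, strand="+", context="CpG", level_a=0.1, level_b=0.9,
        diff=0.8, p_value=q / 2, q_value=q, direction=direction,
    )


def test_dmg_rule_first_exon_cgi_dms():
    g = make_gene("G", "+", 10_000, 20_000)
    cgi = GenomicInterval("chr1", 9_900, 10_150)  # overlaps first exon [10000,10200)
    dms = pd.DataFrame([dms_record("chr1", 10_050)])
    out = differential.call_dmgs(dms, [cgi], [g])
    assert [r.gene_id for r in out] == ["G"]
    assert out[0].supporting_dms_count == 1


def test_cgi_on_second_exon_does_not_qualify():
    g = make_gene("G", "+", 10_000, 20_000)
    cgi = GenomicInterval("chr1", 19_850, 19_950)  # overlaps the last exon only
    dms = pd.DataFrame([dms_record("chr1", 19_900)])
    assert differential.call_dmgs(dms, [cgi], [g]) == []


def test_two_dms_in_one_cgi_are_counted():
    g = make_gene("G", "+", 10_000, 20_000)
    cgi = GenomicInterval("chr1", 9_900, 10_150)
    dms = pd.DataFrame([dms_record("chr1", 10_050), dms_record("chr1", 10_100)])
    out = differential.call_dmgs(dms, [cgi], [g])
    assert out[0].supporting_dms_count == 2


def test_dmg_q_threshold_applies():
    g = make_gene("G", "+", 10_000, 20_000)
    cgi = GenomicInterval("chr1", 9_900, 10_150)
    dms = pd.DataFrame([dms_record("chr1", 10_050, q=0.04)])
    assert differential.call_dmgs(dms, [cgi], [g], q_threshold=0.05) != []
    assert differential.call_dmgs(dms, [cgi], [g], q_threshold=0.01) == []


def test_dmg_ten_gene_fixture_exactly_three_qualify():
    """Of 10 genes, exactly the 3 with a first-exon/CGI/DMS configuration."""
    genes, cgis, dms_rows = [], [], []
    for i in range(10):
        base = 100_000 * (i + 1)
        strand = "+" if i % 2 == 0 else "-"
        genes.append(make_gene(f"g{i}", strand, base, base + 10_000))
    # g0: CGI on first exon with a DMS inside -> DMG
    cgis.append(GenomicInterval("chr1", 100_050, 100_250))
    dms_rows.append(dms_record("chr1", 100_100))
    # g1 (minus strand; first exon is the rightmost [209800, 210000)) -> DMG
    cgis.append(GenomicInterval("chr1", 209_850, 210_050))
    dms_rows.append(dms_record("chr1", 209_900))
    # g2: CGI on first exon but the only DMS lies outside the CGI -> no
    cgis.append(GenomicInterval("chr1", 300_050, 300_150))
    dms_rows.append(dms_record("chr1", 305_000))
    # g3: DMS-bearing CGI in the gene body, not the first exon -> no
    cgis.append(GenomicInterval("chr1", 405_000, 405_200))
    dms_rows.append(dms_record("chr1", 405_100))
    # g4: CGI on first exon, two DMSs inside -> DMG
    cgis.append(GenomicInterval("chr1", 500_020, 500_220))
    dms_rows.append(dms_record("chr1", 500_100))
    dms_rows.append(dms_record("chr1", 500_150))
    # g5: first-exon CGI, DMS present but not significant -> no
    cgis.append(GenomicInterval("chr1", 600_050, 600_250))
    dms_rows.append(dms_record("chr1", 600_100, q=0.5, direction="ns"))
    # g6-g9: no CGI at all
    out = differential.call_dmgs(pd.DataFrame(dms_rows), cgis, genes)
    assert sorted(r.gene_id for r in out) == ["g0", "g1", "g4"]
    counts = {r.gene_id: r.supporting_dms_count for r in out}
    assert counts["g4"] == 2


def test_gene_without_exons_is_skipped_with_warning():
    g = GeneModel("bare", "chr1", "+", 1000, 2000, ())
    dms = pd.DataFrame([dms_record("chr1", 1500)])
    with pytest.warns(UserWarning, match="without exon"):
        assert differential.call_dmgs(dms, [GenomicInterval("chr1", 900, 1100)], [g]) == []
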