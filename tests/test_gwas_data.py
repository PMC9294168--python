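"""Reading, selection, pruning, harmonization, instrument strength."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cytomr as c
from cytomr.gwas_data import DropVerdict, SummaryStatError


def snp(rsid, pval=1e-9, beta=0.1, se=0.02, ea="A", oa="G", eaf=0.3, **kw):
    return c.SnpAssociation(rsid=rsid, chrom="1", pos=1000, effect_allele=ea,
                            other_allele=oa, beta=beta, se=se, pval=pval,
                            eaf=eaf, **kw)


# ---------------------------------------------------------------------------
# SnpAssociation invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kwargs", [
    {"se": 0.0},
    {"se": -1.0},
    {"pval": 0.0},
    {"pval": 1.5},
    {"eaf": 1.2},
    {"ea": "A", "oa": "A"},
])
def test_association_invariants_rejected(kwargs):
    with pytest.raises(ValueError):
        snp("rs1", **kwargs)


def test_alleles_uppercased():
    a = snp("rs1", ea="a", oa="g")
    assert (a.effect_allele, a.other_allele) == ("A", "G")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def test_read_summary_stats_roundtrip(tmp_path):
    path = tmp_path / "stats.tsv"
    path.write_text(
        "rsid\tchr\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"
        "rs1\t1\t100\ta\tg\t0.2\t0.15\t0.02\t1e-9\t8293\n"
        "rs2\t2\t200\tC\tT\t0.4\t-0.08\t0.01\t2e-10\t8293\n"
    )
    recs = c.read_summary_stats(path)
    assert [r.rsid for r in recs] == ["rs1", "rs2"]
    assert recs[0].beta == 0.15 and recs[1].beta == -0.08
    assert recs[0].effect_allele == "A"  # upper-cased


def test_read_rejects_invalid_row_keeps_valid(tmp_path, caplog):
    path = tmp_path / "stats.csv"
    path.write_text(
        "rsid,chr,pos,effect_allele,other_allele,beta,se,pval\n"
        "rs1,1,100,A,G,0.1,0.0,1e-9\n"   # se = 0 -> rejected
        "rs2,1,200,A,G,0.1,0.02,1e-9\n"
    )
    with caplog.at_level("WARNING", logger="cytomr"):
        recs = c.read_summary_stats(path)
    assert [r.rsid for r in recs] == ["rs2"]
    assert any("rejected" in m for m in caplog.messages)


def test_read_missing_column_and_parse_errors(tmp_path):
    bad_cols = tmp_path / "nocol.tsv"
    bad_cols.write_text("rsid\tchr\tpos\tbeta\tse\tpval\nrs1\t1\t1\t0.1\t0.2\t0.5\n")
    with pytest.raises(SummaryStatError, match="missing mandatory"):
        c.read_summary_stats(bad_cols)
    bad_num = tmp_path / "badnum.tsv"
    bad_num.write_text(
        "rsid\tchr\tpos\teffect_allele\tother_allele\tbeta\tse\tpval\n"
        "rs1\t1\t1\tA\tG\tnot_a_number\t0.2\t0.5\n")
    with pytest.raises(SummaryStatError, match="line 2"):
        c.read_summary_stats(bad_num)


def test_read_custom_dialect(tmp_path):
    path = tmp_path / "alt.tsv"
    path.write_text("SNP\tCHR\tBP\tA1\tA2\tb\tstderr\tp\n"
                    "rs9\t3\t42\tA\tG\t0.2\t0.03\t1e-12\n")
    recs = c.read_summary_stats(path, dialect={
        "rsid": "SNP", "chrom": "CHR", "pos": "BP", "effect_allele": "A1",
        "other_allele": "A2", "beta": "b", "se": "stderr", "pval": "p"})
    assert recs[0].rsid == "rs9" and recs[0].pos == 42


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def test_select_instruments_strict_threshold():
    assocs = [snp("rs1", 1e-9), snp("rs2", 1e-7), snp("rs3", 4.9e-8)]
    kept = c.select_instruments(assocs, 5e-8)
    assert [a.rsid for a in kept] == ["rs1", "rs3"]
    assert c.select_instruments(assocs, 1.0) == assocs
    assert c.select_instruments([snp("rs1", 0.5)], 5e-8) == []


@given(st.lists(st.floats(1e-300, 1.0), min_size=0, max_size=30),
       st.floats(1e-10, 0.99))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_select_instruments_idempotent(pvals, threshold):
    assocs = [snp(f"rs{i}", p) for i, p in enumerate(pvals)]
    once = c.select_instruments(assocs, threshold)
    assert c.select_instruments(once, threshold) == once


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def test_ld_prune_independent_and_forced_discard():
    free = [snp(f"rs{i}", 10 ** -(9 + i)) for i in range(3)]
    assert c.ld_prune(free, c.LdTable(), 0.1) == free
    a, b = snp("rsA", 1e-10), snp("rsB", 1e-9)
    ld = c.LdTable({("rsA", "rsB"): 0.5})
    assert [x.rsid for x in c.ld_prune([a, b], ld, 0.1)] == ["rsA"]


def test_ld_prune_chain():
    # chain A-B r2=0.2, B-C r2=0.2, A-C free, D free; p ascending A<B<C<D
    assocs = [snp("rsA", 1e-12), snp("rsB", 1e-11), snp("rsC", 1e-10), snp("rsD", 1e-9)]
    ld = c.LdTable({("rsA", "rsB"): 0.2, ("rsB", "rsC"): 0.2})
    kept = {a.rsid for a in c.ld_prune(assocs, ld, 0.1)}
    assert kept == {"rsA", "rsC", "rsD"}


def test_ld_prune_order_invariant_and_pairwise_clean():
    assocs = [snp(f"rs{i}", p) for i, p in enumerate([1e-9, 1e-11, 1e-10, 1e-8, 1e-12])]
    ld = c.LdTable({("rs0", "rs1"): 0.3, ("rs2", "rs4"): 0.15, ("rs3", "rs4"): 0.05})
    kept = c.ld_prune(assocs, ld, 0.1)
    for perm in (assocs[::-1], assocs[2:] + assocs[:2]):
        assert {a.rsid for a in c.ld_prune(perm, ld, 0.1)} == {a.rsid for a in kept}
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            assert ld.r2(a.rsid, b.rsid) < 0.1
    # globally lowest-p SNP always retained
    assert "rs4" in {a.rsid for a in kept}


def test_ld_prune_unknown_rsid_warns(caplog):
    ld = c.LdTable({("rsX", "rsY"): 0.9})
    with caplog.at_level("WARNING", logger="cytomr"):
        kept = c.ld_prune([snp("rs1")], ld, 0.1)
    assert [a.rsid for a in kept] == ["rs1"]
    assert any("absent" in m for m in caplog.messages)


# ---------------------------------------------------------------------------
# Shared-SNP exclusion
# ---------------------------------------------------------------------------

def test_exclude_shared_snps():
    shared = snp("rsX")
    lists = {
        "IL-18": [shared, snp("rs1")],
        "IL-17": [shared, snp("rs2")],
        "IL-6": [snp("rs3"), snp("rs4"), snp("rs5")],
    }
    filtered, removed = c.exclude_shared_snps(lists)
    assert set(removed) == {"rsX"}
    assert sorted(removed["rsX"]) == ["IL-17", "IL-18"]
    all_kept = [a.rsid for lst in filtered.values() for a in lst]
    assert sorted(all_kept) == ["rs1", "rs2", "rs3", "rs4", "rs5"]

    disjoint = {"a": [snp("rs1")], "b": [snp("rs2")]}
    same, none_removed = c.exclude_shared_snps(disjoint)
    assert same == disjoint and none_removed == {}


def test_exclude_shared_three_exposures_one_shared():
    shared = snp("rsS")
    lists = {f"E{i}": [shared, snp(f"rs{i}a"), snp(f"rs{i}b")] for i in range(3)}
    lists["E0"] = [shared, snp("rs0a"), snp("rs0b"), snp("rs0c")]
    # 1 shared + (4 + 3 + 3) - 2 duplicates of shared = 8 unique non-shared... count directly
    filtered, removed = c.exclude_shared_snps(lists)
    assert len(removed) == 1
    remaining = sum(len(v) for v in filtered.values())
    assert remaining == sum(len(v) for v in lists.values()) - 3  # shared removed from all 3


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def test_harmonize_identity_swap_and_strand():
    exp = snp("rs1", beta=0.1, ea="A", oa="G")
    same = c.harmonize(exp, snp("rs1", beta=0.3, ea="A", oa="G"))
    assert same.Gamma == 0.3 and same.aligned_allele == "A"
    swapped = c.harmonize(exp, snp("rs1", beta=0.3, ea="G", oa="A"))
    assert swapped.Gamma == -0.3
    strand = c.harmonize(exp, snp("rs1", beta=0.3, ea="T", oa="C"))
    assert strand.Gamma == 0.3
    strand_swap = c.harmonize(exp, snp("rs1", beta=0.3, ea="C", oa="T"))
    assert strand_swap.Gamma == -0.3
    bad = c.harmonize(exp, snp("rs1", beta=0.3, ea="C", oa="A"))
    assert isinstance(bad, DropVerdict) and bad.reason == "irreconcilable_alleles"


def test_harmonize_palindromic_by_frequency():
    exp = snp("rs1", beta=0.1, ea="A", oa="T", eaf=0.10)
    out = snp("rs1", beta=0.2, ea="T", oa="A", eaf=0.88)
    inst = c.harmonize(exp, out, palindrome_policy="freq")
    assert inst.Gamma == pytest.approx(-0.2)
    # same minor-allele side: keep sign
    out2 = snp("rs1", beta=0.2, ea="T", oa="A", eaf=0.12)
    assert c.harmonize(exp, out2).Gamma == pytest.approx(0.2)


def test_harmonize_palindromic_drop_policies():
    exp = snp("rs1", beta=0.1, ea="C", oa="G", eaf=0.10)
    out = snp("rs1", beta=0.2, ea="C", oa="G", eaf=0.12)
    assert isinstance(c.harmonize(exp, out, "drop"), DropVerdict)
    ambiguous = c.harmonize(
        snp("rs1", ea="C", oa="G", eaf=0.45),
        snp("rs1", beta=0.2, ea="C", oa="G", eaf=0.44), "freq")
    assert isinstance(ambiguous, DropVerdict)
    assert ambiguous.reason == "palindromic_ambiguous"


def test_harmonize_idempotent_and_swap_involution():
    exp = snp("rs1", beta=0.1, ea="A", oa="G", eaf=0.2)
    out = snp("rs1", beta=-0.4, ea="A", oa="G", eaf=0.2)
    inst = c.harmonize(exp, out)
    # re-harmonizing the aligned pair changes nothing
    realigned = c.harmonize(exp, snp("rs1", beta=inst.Gamma, ea="A", oa="G", eaf=0.2))
    assert realigned.Gamma == inst.Gamma
    # swapping alleles twice restores the original sign
    swapped_once = c.harmonize(exp, snp("rs1", beta=0.4, ea="G", oa="A", eaf=0.8))
    swapped_back = c.harmonize(
        exp, snp("rs1", beta=swapped_once.Gamma, ea="G", oa="A", eaf=0.8))
    assert swapped_back.Gamma == pytest.approx(0.4)


# ---------------------------------------------------------------------------
# Instrument strength
# ---------------------------------------------------------------------------

def test_instrument_strength_unadjusted_vs_classical():
    # 16 SNPs at eaf 0.5 with 2f(1-f)gamma^2 = 0.1/16 each -> total R^2 = 0.1
    gamma = math.sqrt((0.1 / 16) / 0.5)
    gammas, sigmas, eafs = [gamma] * 16, [0.01] * 16, [0.5] * 16
    r2, f_unadj = c.instrument_strength(gammas, sigmas, eafs, 8293, "unadjusted")
    assert r2 == pytest.approx(0.1)
    assert f_unadj == pytest.approx(0.1 * (8293 - 1 - 16) / 0.9, rel=1e-12)
    assert f_unadj == pytest.approx(919.56, abs=0.01)
    _, f_classical = c.instrument_strength(gammas, sigmas, eafs, 8293, "classical")
    assert f_classical == pytest.approx(f_unadj / 16)
    assert f_classical == pytest.approx(57.47, abs=0.01)


def test_instrument_strength_zero_fallback_and_errors():
    r2, f = c.instrument_strength([0.0], [0.01], [0.3], 1000)
    assert r2 == 0 and f == 0
    # missing eaf falls back to beta/SE/N form
    r2f, _ = c.instrument_strength([0.1], [0.02], [None], 1000)
    assert r2f == pytest.approx(0.1**2 / (0.1**2 + 0.02**2 * 1000))
    with pytest.raises(ValueError, match="R"):
        c.instrument_strength([2.0], [0.01], [0.5], 1000)
    with pytest.raises(ValueError, match="sample size"):
        c.instrument_strength([0.1] * 10, [0.01] * 10, None, 10)


@given(st.floats(0.01, 0.5), st.floats(0.51, 0.95))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_instrument_strength_increasing_in_r2(g_small, g_big):
    # single SNP at eaf 0.5: R2 = g^2/2, strictly increasing in |g|
    _, f_small = c.instrument_strength([g_small], [0.01], [0.5], 5000)
    _, f_big = c.instrument_strength([g_big], [0.01], [0.5], 5000)
    assert f_big > f_small


def test_per_snp_f_stats():
    fs = c.per_snp_f_stats([0.2, 0.1], [0.02, 0.02], [0.3, 0.3], 8293)
    assert fs.shape == (2,) and fs[0] > fs[1] > 0
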