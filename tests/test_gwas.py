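"""Tests for GWAS summary-statistics tools: meta-analysis, TDT odds ratios,
genomic control, LD clumping, signal grouping and enrichment tests.

The clumping test includes an independent brute-force reference
implementation, written directly from the clumping rules, and checks
equivalence on randomized fixtures.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from priorityrank import (
    LDTable,
    Signal,
    assign_groups,
    enrichment_test,
    flag_new_signals,
    lambda_gc,
    ld_clump,
    meta_analyse,
    tdt_oddsratio,
)


# ---------------------------------------------------------------------------
# meta-analysis


def test_meta_analyse_oracle():
    # weights 100 and 25: beta = (100*0.1 + 25*0.2)/125, se = sqrt(1/125)
    beta, se, p = meta_analyse([0.1, 0.2], [0.1, 0.2])
    assert beta == pytest.approx(0.12)
    assert se == pytest.approx(math.sqrt(1 / 125))
    assert p == pytest.approx(stats.chi2.sf((beta / se) ** 2, df=1))


def test_meta_analyse_missing_cohort():
    # infinite se = variant absent from that cohort: zero weight
    beta, se, _ = meta_analyse([0.1, 0.0], [0.1, np.inf])
    only, se_only, _ = meta_analyse([0.1], [0.1])
    assert (beta, se) == (only, se_only)
    with pytest.raises(ValueError):
        meta_analyse([0.1], [np.inf])


def test_meta_analyse_single_cohort_identity():
    beta, se, _ = meta_analyse([0.25], [0.04])
    assert (beta, se) == (pytest.approx(0.25), pytest.approx(0.04))


# ---------------------------------------------------------------------------
# TDT / lambda


def test_tdt_oddsratio_continuity_correction():
    # min(T, U) <= 5: 0.5 added to both counts
    or_, se = tdt_oddsratio(10, 5)
    assert or_ == pytest.approx(10.5 / 5.5)
    assert se == pytest.approx(math.sqrt(1 / 10.5 + 1 / 5.5))
    # no correction when both counts exceed 5
    assert tdt_oddsratio(100, 50)[0] == pytest.approx(2.0)
    assert tdt_oddsratio(0, 0)[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        tdt_oddsratio(-1, 3)


def test_lambda_gc():
    assert lambda_gc([0.456]) == pytest.approx(1.0)
    # null chi-square draws: lambda near 1
    chisq = stats.chi2.rvs(1, size=200_000, random_state=0)
    assert lambda_gc(chisq) == pytest.approx(1.0, abs=0.02)
    # uniform inflation scales lambda linearly
    assert lambda_gc(2.0 * chisq) == pytest.approx(2.0, abs=0.04)


# ---------------------------------------------------------------------------
# enrichment


def test_enrichment_cmle_worked_examples():
    # conditional-MLE odds ratios of the printed 2x2 tables
    assert enrichment_test(6, 11, 10, 112)[0] == pytest.approx(5.983, abs=0.01)
    assert enrichment_test(6, 27, 10, 112)[0] == pytest.approx(2.471, abs=0.01)
    assert enrichment_test(12, 38, 10, 112)[0] == pytest.approx(3.506, abs=0.01)


def test_enrichment_p_matches_fisher():
    _, p = enrichment_test(6, 11, 10, 112)
    assert p == pytest.approx(stats.fisher_exact([[6, 11], [10, 112]])[1])


def test_enrichment_degenerate_table():
    or_, p = enrichment_test(0, 0, 10, 112)
    assert math.isnan(or_)
    assert p == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# LD table


def test_ld_table_symmetric_lookup():
    df = pd.DataFrame({"id_a": ["a"], "id_b": ["b"], "r2": [0.4]})
    ld = LDTable(df)
    assert ld.r2("a", "b") == ld.r2("b", "a") == 0.4
    assert ld.r2("a", "zzz") == 0.0


def test_ld_table_window_filter():
    df = pd.DataFrame({"id_a": ["a", "a"], "id_b": ["b", "c"], "r2": [0.4, 0.4]})
    pos = {"a": ("1", 0), "b": ("1", 500_000), "c": ("1", 2_000_000)}
    ld = LDTable(df, positions=pos)
    assert ld.r2("a", "b") == 0.4
    assert ld.r2("a", "c") == 0.0        # beyond the 1 Mb window: dropped


def test_ld_table_rejects_bad_r2():
    with pytest.raises(ValueError):
        LDTable(pd.DataFrame({"id_a": ["a"], "id_b": ["b"], "r2": [1.5]}))


# ---------------------------------------------------------------------------
# clumping


def make_stats(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "beta", "se",
                                       "p", "fdr_tail"])


def test_ld_clump_toy():
    # cluster of three in LD plus an isolated significant variant with a
    # qualifying partner, plus an insignificant background variant
    rows = [
        ("1", 100, "a", 0.4, 0.05, 1e-12, 1e-4),
        ("1", 200, "b", 0.3, 0.05, 1e-9, 1e-4),
        ("1", 300, "c", 0.2, 0.05, 1e-7, 1e-3),
        ("1", 9000, "d", -0.3, 0.05, 1e-10, 1e-4),
        ("1", 9100, "e", -0.1, 0.05, 1e-5, 0.5),
        ("1", 20000, "f", 0.1, 0.05, 0.5, 0.9),
    ]
    ld = LDTable(pd.DataFrame({
        "id_a": ["a", "a", "b", "d"],
        "id_b": ["b", "c", "c", "e"],
        "r2":   [0.8, 0.3, 0.5, 0.9],
    }))
    stats_df = make_stats(rows)
    signals = ld_clump(stats_df, ld, stats_df["fdr_tail"])
    assert [s.lead_id for s in signals] == ["a", "d"]
    assert signals[0].member_ids == ["a", "b", "c"]
    # d's only partner e is not itself significant, but qualifies as partner
    assert signals[1].member_ids == ["d"]
    assert signals[0].or_risk == pytest.approx(math.exp(0.4))
    assert signals[1].or_risk == pytest.approx(math.exp(0.3))   # risk OR >= 1


def test_ld_clump_singleton_rule():
    # lead at p=1e-30 requires a partner with log10 p < -11
    base = [("1", 100, "lead", 0.5, 0.05, 1e-30, 1e-8)]
    ld = LDTable(pd.DataFrame({"id_a": ["lead"], "id_b": ["pp"], "r2": [0.5]}))
    # partner p = 1e-12 (< -11): lead kept
    ok = make_stats(base + [("1", 200, "pp", 0.3, 0.05, 1e-12, 1e-4)])
    sig_ok = ld_clump(ok, ld, ok["fdr_tail"])
    assert [s.lead_id for s in sig_ok] == ["lead"]
    assert sig_ok[0].member_ids == ["lead", "pp"]   # pp absorbed (r2 > 0.01)
    # partner p = 1e-9 (> -11): lead excluded entirely, partner survives
    weak = make_stats(base + [("1", 200, "pp", 0.3, 0.05, 1e-9, 1e-4)])
    leads = [s.lead_id for s in ld_clump(weak, ld, weak["fdr_tail"])]
    assert "lead" not in leads
    assert "pp" in leads          # pp's own partner (lead) easily qualifies


def brute_force_clump(stats_df, ld, fdr_threshold=0.01, r2_clump=0.01,
                      r2_partner=0.1):
    """Independent reference clumping, straight from the rules."""
    df = stats_df.copy()
    out = []
    for chrom in sorted(df["chrom"].unique()):
        rem = df[(df["chrom"] == chrom)
                 & (df["fdr_tail"] <= fdr_threshold)].copy()
        rem = rem.sort_values(["p", "chrom", "pos", "id"], kind="mergesort")
        alive = list(rem["id"])
        pmap = dict(zip(df["id"], df["p"]))
        while alive:
            lead = alive[0]
            cut = math.log10(pmap[lead]) / 3 - 1
            has_partner = any(
                r2 > r2_partner and o in pmap and math.log10(pmap[o]) < cut
                for o, r2 in ld.neighbours(lead).items())
            if not has_partner:
                alive = alive[1:]
                continue
            members = [lead] + [v for v in alive[1:]
                                if ld.r2(lead, v) > r2_clump]
            out.append((lead, tuple(sorted(members))))
            alive = [v for v in alive if v not in members]
    return out


@pytest.mark.parametrize("master_seed", [101, 202])
def test_ld_clump_matches_brute_force(master_seed):
    rng = np.random.default_rng(master_seed)
    for _ in range(50):
        n = 50
        pos = np.sort(rng.integers(0, 500_000, size=n))
        p = 10.0 ** (-rng.uniform(0, 14, size=n))
        df = make_stats([
            ("1", int(pos[i]), f"v{i}", float(rng.normal(0, 0.2)), 0.05,
             float(p[i]), float(p[i] * rng.uniform(1, 50)))
            for i in range(n)
        ])
        n_pairs = int(rng.integers(20, 80))
        ia = rng.integers(0, n, size=n_pairs)
        ib = rng.integers(0, n, size=n_pairs)
        keep = ia != ib
        ld = LDTable(pd.DataFrame({
            "id_a": [f"v{i}" for i in ia[keep]],
            "id_b": [f"v{i}" for i in ib[keep]],
            "r2": rng.uniform(0, 1, size=int(keep.sum())),
        }))
        got = [(s.lead_id, tuple(sorted(s.member_ids)))
               for s in ld_clump(df, ld, df["fdr_tail"])]
        assert got == brute_force_clump(df, ld)


# ---------------------------------------------------------------------------
# new-signal flags and grouping


def test_flag_new_signals():
    leads = pd.DataFrame({"id": ["x", "y", "z"], "chrom": ["1", "1", "2"],
                          "pos": [1_000_000, 5_000_000, 1_000_000]})
    est = pd.DataFrame({"id": ["k"], "chrom": ["1"], "pos": [1_100_000]})
    ld = LDTable(pd.DataFrame({"id_a": ["y"], "id_b": ["k"], "r2": [0.2]}))
    flags = flag_new_signals(leads, est, ld)
    # x: within 250 kb of k -> not new; y: r2 0.2 >= 0.05 -> not new;
    # z: other chromosome, no LD -> new
    np.testing.assert_array_equal(flags, [False, False, True])


def sig(i, or_risk, pfdr):
    return Signal(lead_id=f"s{i}", member_ids=[], chrom="1", pos=i,
                  p=1e-8, or_risk=or_risk, fdr_tail=1e-4, pfdr_tail=pfdr)


def test_assign_groups():
    signals = [sig(0, 1.8, 1e-4),    # red
               sig(1, 2.0, 0.5),     # blue: OR above red floor
               sig(2, 1.9, 0.9),     # blue
               sig(3, 1.2, 0.9)]     # grey
    assert assign_groups(signals) == ["red", "blue", "blue", "grey"]
    assert signals[1].label == "blue"


def test_assign_groups_empty_red_all_grey():
    signals = [sig(0, 2.0, 0.5), sig(1, 1.5, 0.9)]
    assert assign_groups(signals) == ["grey", "grey"]
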