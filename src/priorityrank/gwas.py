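"""GWAS summary-statistics post-processing.

Inverse-variance fixed-effects meta-analysis, TDT odds ratios with continuity
correction, the genomic-control inflation factor, greedy LD clumping with a
singleton-exclusion rule guarding against genotyping/imputation artifacts,
flagging of signals not previously reported, red/blue/grey prioritisation of
signals on the priorityFDR-vs-effect-size plane, and 2x2 exact enrichment
tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

__all__ = [
    "Signal",
    "CHI2_NULL_MEDIAN",
    "meta_analyse",
    "tdt_oddsratio",
    "lambda_gc",
    "LDTable",
    "ld_clump",
    "flag_new_signals",
    "assign_groups",
    "enrichment_test",
]

logger = logging.getLogger(__name__)

#: median of the chi-square(1 df) distribution, to the precision
#: conventionally used for the genomic-control inflation factor
CHI2_NULL_MEDIAN = 0.456


def meta_analyse(betas, ses):
    """Inverse-variance-weighted fixed-effects meta-analysis of one variant.

    beta_meta = sum(beta_i / se_i^2) / sum(1 / se_i^2) and
    se_meta^2 = 1 / sum(1 / se_i^2); cohorts where the variant is missing
    enter with beta 0 and infinite SE (zero weight).  The p value comes from
    the 1-df chi-square statistic (beta_meta / se_meta)^2.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    ok = np.isfinite(ses) & (ses > 0) & np.isfinite(betas)
    if not ok.any():
        raise ValueError("no cohort with a finite standard error")
    w = 1.0 / ses[ok] ** 2
    beta_meta = float(np.sum(w * betas[ok]) / np.sum(w))
    se_meta = float(np.sqrt(1.0 / np.sum(w)))
    chi2 = (beta_meta / se_meta) ** 2
    p = float(stats.chi2.sf(chi2, df=1))
    return beta_meta, se_meta, p


def tdt_oddsratio(T: int, U: int):
    """Transmission disequilibrium test odds ratio with continuity correction.

    OR = T/U on transmitted/untransmitted counts; 0.5 is added to both counts
    whenever either is 5 or lower, keeping the OR finite and nonzero.  The SE
    of the log OR is sqrt(1/T' + 1/U') on the corrected counts.
    """
    if T < 0 or U < 0:
        raise ValueError("counts must be nonnegative")
    t, u = float(T), float(U)
    if min(t, u) <= 5:
        t += 0.5
        u += 0.5
    return t / u, math.sqrt(1.0 / t + 1.0 / u)


def lambda_gc(chisq) -> float:
    """Genomic-control inflation: median observed chi-square over 0.456."""
    chisq = np.asarray(chisq, dtype=float)
    if chisq.size == 0:
        raise ValueError("lambda_gc of empty input")
    return float(np.median(chisq) / CHI2_NULL_MEDIAN)


# ---------------------------------------------------------------------------
# LD clumping


@dataclass
class Signal:
    """An LD-clumped independent association signal."""

    lead_id: str
    member_ids: list
    chrom: str
    pos: int
    p: float
    or_risk: float = np.nan
    fdr_tail: float = np.nan
    pfdr_tail: float = np.nan
    is_new: bool | None = None
    label: str | None = None


class LDTable:
    """Symmetric variant-pair r-squared lookup, restricted to 1 Mb windows."""

    def __init__(self, pairs_df: pd.DataFrame, positions: dict | None = None,
                 max_dist: int = 1_000_000):
        self._nbr: dict[str, dict[str, float]] = {}
        a = pairs_df["id_a"].to_numpy()
        b = pairs_df["id_b"].to_numpy()
        r2 = pairs_df["r2"].to_numpy(float)
        if np.any((r2 < 0) | (r2 > 1)):
            raise ValueError("r2 values must lie in [0, 1]")
        for x, y, v in zip(a, b, r2):
            if x == y:
                continue
            if positions is not None and x in positions and y in positions:
                (ca, pa), (cb, pb) = positions[x], positions[y]
                if ca != cb or abs(pa - pb) > max_dist:
                    logger.warning("ignoring LD pair (%s, %s): beyond %d bp window",
                                   x, y, max_dist)
                    continue
            self._nbr.setdefault(x, {})[y] = max(v, self._nbr.get(x, {}).get(y, -1.0))
            self._nbr.setdefault(y, {})[x] = max(v, self._nbr.get(y, {}).get(x, -1.0))

    def neighbours(self, vid: str) -> dict:
        return self._nbr.get(vid, {})

    def r2(self, a: str, b: str) -> float:
        return self._nbr.get(a, {}).get(b, 0.0)


def _p_order_key(row):
    # deterministic tie-break: p, then genomic coordinate, then id
    return (row.p, row.chrom, row.pos, row.id)


def ld_clump(stats_df: pd.DataFrame, ld: LDTable, fdr,
             fdr_threshold: float = 0.01, r2_clump: float = 0.01,
             r2_partner: float = 0.1) -> list[Signal]:
    """Greedy LD clumping of significant variants into independent signals.

    Working per chromosome from the most significant remaining variant with
    tail FDR <= fdr_threshold: the candidate lead is discarded outright
    (singleton rule) unless it has at least one LD partner (r2 > r2_partner,
    searched among all variants in the LD table) with log10 p value below
    log10(P_lead)/3 - 1; otherwise a signal is emitted containing every
    remaining significant variant with r2 > r2_clump to the lead, and those
    variants are removed.  Ties in p break by (chrom, pos, id).
    """
    df = stats_df.reset_index(drop=True).copy()
    df["fdr_tail"] = np.asarray(fdr, dtype=float)
    known = set(df["id"])
    pvals = dict(zip(df["id"], df["p"].astype(float)))

    for vid in list(ld._nbr):
        if vid not in known:
            logger.warning("LD table variant %s absent from summary stats; ignored", vid)

    signals: list[Signal] = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sig = sub[sub["fdr_tail"] <= fdr_threshold].copy()
        sig = sig.sort_values(["p", "chrom", "pos", "id"], kind="mergesort")
        remaining = list(sig.itertuples(index=False))
        while remaining:
            lead = remaining[0]
            log10p = math.log10(lead.p)
            cutoff = log10p / 3.0 - 1.0
            partners = [
                other for other, r2 in ld.neighbours(lead.id).items()
                if r2 > r2_partner and other in pvals
                and math.log10(pvals[other]) < cutoff
            ]
            if not partners:
                # likely a genotyping/imputation artifact: exclude entirely
                remaining = remaining[1:]
                continue
            nbr = ld.neighbours(lead.id)
            members = [lead] + [v for v in remaining[1:] if nbr.get(v.id, 0.0) > r2_clump]
            member_ids = [v.id for v in members]
            or_risk = np.nan
            if hasattr(lead, "beta"):
                or_risk = max(math.exp(lead.beta), math.exp(-lead.beta))
            signals.append(Signal(
                lead_id=lead.id,
                member_ids=member_ids,
                chrom=chrom,
                pos=int(lead.pos),
                p=float(lead.p),
                or_risk=or_risk,
                fdr_tail=float(lead.fdr_tail),
                pfdr_tail=float(getattr(lead, "pfdr_tail", np.nan)),
            ))
            taken = set(member_ids)
            remaining = [v for v in remaining if v.id not in taken]
    return signals


def flag_new_signals(leads: pd.DataFrame, established: pd.DataFrame,
                     ld: LDTable, r2_new: float = 0.05,
                     dist: int = 250_000) -> np.ndarray:
    """Boolean per lead: new iff r2 < r2_new with every established lead and
    at least ``dist`` bp from each (leads on other chromosomes count as
    infinitely distant)."""
    flags = []
    est = list(established.itertuples(index=False))
    for lead in leads.itertuples(index=False):
        new = True
        for e in est:
            if ld.r2(lead.id, e.id) >= r2_new:
                new = False
                break
            if lead.chrom == e.chrom and abs(int(lead.pos) - int(e.pos)) < dist:
                new = False
                break
        flags.append(new)
    return np.asarray(flags, dtype=bool)


def assign_groups(signals: list[Signal], pfdr_threshold: float = 0.001) -> list[str]:
    """Red/blue/grey prioritisation labels.

    Red: tail priorityFDR at or below the threshold (an inflection point in
    the priorityFDR-vs-effect-size plane, supplied by the user).  Blue: not
    red, but risk OR at least the smallest risk OR in the red group — effect
    estimates comparable to the red group with more statistical uncertainty.
    Grey: the rest.  With an empty red group everything is grey.
    """
    red = [s.pfdr_tail <= pfdr_threshold for s in signals]
    if not any(red):
        logger.warning("no signal passes the priorityFDR threshold; all grey")
        labels = ["grey"] * len(signals)
    else:
        or_floor = min(s.or_risk for s, r in zip(signals, red) if r)
        labels = []
        for s, r in zip(signals, red):
            if r:
                labels.append("red")
            elif s.or_risk >= or_floor:
                labels.append("blue")
            else:
                labels.append("grey")
    for s, lab in zip(signals, labels):
        s.label = lab
    return labels


def enrichment_test(a: int, b: int, c: int, d: int):
    """Exact test of a 2x2 table [[a, b], [c, d]].

    Returns the conditional maximum-likelihood odds ratio (as in R's
    fisher.test) and the two-sided Fisher exact p value.  Tables with a zero
    row or column have no defined odds ratio (NaN).
    """
    table = np.array([[a, b], [c, d]], dtype=int)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), float(stats.fisher_exact(table)[1])
    res = _odds_ratio(table, kind="conditional")
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return float(res.statistic), p
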