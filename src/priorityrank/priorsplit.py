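"""Prior splitting: sign-constrained decomposition of the non-null
distribution, pairwise effect-difference models, and the priorityFDR.

The non-null distribution of Z-scores is split into two components
constrained to contain only negative and only positive true effects.  The
constraint is realized as monotone likelihood ratio against the N(0,1) null:
any location mixture of N(theta, 1) with theta > 0 has g(z)/f0(z)
nondecreasing in z, and symmetrically for theta < 0.  Writing
r(z) = g(z)/f0(z), the fitted ratio is decomposed on the evaluation grid as

    r = u + v,   u nondecreasing (positive component * weight / f0),
                 v nonincreasing (negative component * weight / f0),

with u' = max(r', 0), v' = min(r', 0) and boundary mass placed so both parts
are nonnegative.  The posterior sign probability is then u / (u + v).

The same machinery applied to standardized pairwise differences
d = (bhat_j - bhat_i)/sqrt(se_i^2 + se_j^2) and sums
s = (bhat_j + bhat_i)/sqrt(se_i^2 + se_j^2) gives posterior sign
probabilities for D = beta_j - beta_i and S = beta_j + beta_i.  Since
|beta_j| > |beta_i|  <=>  D * S > 0, factorizing the joint sign posterior
as P(D-sign) * P(S-sign) yields the order probability, with posterior tie
mass (either pair landing in its point-null) split equally to preserve
order_prob(i, j) + order_prob(j, i) = 1.

Averaging order probabilities over partners drawn from the non-null-weighted
resample estimates the effect priority

    effect_priority_i = P(|beta_j| > |beta_i| | j random non-null,
                          i non-null),

and the two headline quantities are

    priorityFDR_i       = FDR_i + effect_priority_i * (1 - FDR_i)
    priorityFDR_i^(inc) = FDR_i * (1 - pi + pi/2)
                          + effect_priority_i * (1 - pi) * (1 - FDR_i).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .density import (
    EffectsTable,
    GridDensity,
    TwoGroupsModel,
    fit_marginal_density,
    fit_two_groups,
    local_fdr,
    norm_logpdf,
    tail_average,
)

__all__ = [
    "SignSplitModel",
    "PairModel",
    "PriorityResult",
    "resample_nonnull",
    "fit_sign_split",
    "sign_prob",
    "build_pair_models",
    "order_prob",
    "effect_priority",
    "priority_fdr",
    "priority_fdr_inc",
    "estimate",
]


# ---------------------------------------------------------------------------
# sign splitting


@dataclass
class SignSplitModel:
    """Sign-constrained split of a (non-null) density g.

    g = w_minus * g_minus + w_plus * g_plus with g_plus/f0 nondecreasing and
    g_minus/f0 nonincreasing on the grid.  ``sign_p`` holds the posterior
    probability of a positive true effect at each grid point.
    """

    grid: np.ndarray
    log_g: np.ndarray      # fitted non-null density on the grid
    sign_p: np.ndarray     # u/(u+v) on the grid
    w_plus: float
    w_minus: float

    def g(self, z):
        return np.exp(GridDensity(self.grid, self.log_g).logpdf(z))

    def g_plus(self, z):
        z = np.asarray(z, float)
        return self._signed(z, positive=True)

    def g_minus(self, z):
        z = np.asarray(z, float)
        return self._signed(z, positive=False)

    def _signed(self, z, positive):
        s = self.sign_probability(z)
        w = self.w_plus if positive else self.w_minus
        part = s if positive else 1.0 - s
        if w <= 0:
            return np.zeros_like(np.asarray(z, float))
        return part * self.g(z) / w

    def sign_probability(self, z):
        z = np.asarray(z, dtype=float)
        out = np.interp(z, self.grid, self.sign_p,
                        left=self.sign_p[0], right=self.sign_p[-1])
        return out


def _monotone_split(grid, log_r):
    """Decompose exp(log_r) into nondecreasing u and nonincreasing v.

    Works in log space: log v(z_k) = logsumexp over decreases of r to the
    right of k, which is stable even when r spans hundreds of orders of
    magnitude in the tails.  Returns (sign_p, log_u, log_v) on the grid with
    sign_p = u / (u + v).
    """
    log_r = np.asarray(log_r, dtype=float)
    n = log_r.size
    # log of positive decreases r_k - r_{k+1}
    a, b = log_r[:-1], log_r[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        log_dec = np.where(a > b, a + np.log1p(-np.exp(np.minimum(b - a, -1e-300))), -np.inf)
    # log v_k = logsumexp(log_dec[k:])
    log_v = np.full(n, -np.inf)
    running = -np.inf
    for k in range(n - 2, -1, -1):
        running = np.logaddexp(running, log_dec[k])
        log_v[k] = running
    # u = r - v >= 0 (clip at 0 in linear space)
    with np.errstate(invalid="ignore"):
        diff = log_v - log_r
    frac_v = np.exp(np.minimum(diff, 0.0))      # v/r in [0, 1] up to fp noise
    frac_v = np.clip(frac_v, 0.0, 1.0)
    sign_p = 1.0 - frac_v
    with np.errstate(divide="ignore"):
        log_u = log_r + np.log(sign_p)
    return sign_p, log_u, log_v


def resample_nonnull(effects: EffectsTable, local_fdr_values, m: int, rng) -> np.ndarray:
    """Indices of m rows drawn with replacement, weighted by 1 - local fdr."""
    if m < 1:
        raise ValueError("m must be >= 1")
    w = 1.0 - np.asarray(local_fdr_values, dtype=float)
    w = np.clip(w, 0.0, 1.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("no non-null mass: all local fdr values are 1")
    rng = np.random.default_rng(rng)
    return rng.choice(len(effects), size=m, replace=True, p=w / total)


def fit_sign_split(z_sample, n_bins: int = 120, degree: int = 8,
                   symmetric: bool = False, support=None) -> SignSplitModel:
    """Fit the sign-constrained pair of components to a non-null pseudo-sample."""
    g = fit_marginal_density(np.asarray(z_sample, float), n_bins=n_bins,
                             degree=degree, symmetric=symmetric, support=support)
    log_r = g.logf - norm_logpdf(g.grid)
    sign_p, _, _ = _monotone_split(g.grid, log_r)
    if symmetric:
        # make p(+|z) = 1 - p(+|-z) hold exactly, not just to fp accuracy
        sign_p = 0.5 * (sign_p + (1.0 - sign_p[::-1]))
    # mixture weights: integrals of the signed parts of g
    gz = np.exp(g.logf)
    w_plus = float(np.trapezoid(sign_p * gz, g.grid))
    w_minus = float(np.trapezoid((1.0 - sign_p) * gz, g.grid))
    tot = w_plus + w_minus
    return SignSplitModel(grid=g.grid, log_g=g.logf, sign_p=sign_p,
                          w_plus=w_plus / tot, w_minus=w_minus / tot)


def sign_prob(model: SignSplitModel, z):
    """P(true effect > 0 | z, non-null) = w+ g+(z) / (w- g-(z) + w+ g+(z))."""
    return model.sign_probability(z)


# ---------------------------------------------------------------------------
# pairwise difference / sum models


@dataclass
class _ScaleModel:
    """Two-group + sign-split model on one pair scale (differences or sums)."""

    two_groups: TwoGroupsModel
    split: SignSplitModel

    @property
    def pi0(self):
        return self.two_groups.pi0

    def posteriors(self, x):
        """(p_plus, p_minus, p_null) for the sign of the true pair quantity."""
        x = np.asarray(x, dtype=float)
        p0 = self.two_groups.local_fdr(x)
        sp = self.split.sign_probability(x)
        nn = 1.0 - p0
        return nn * sp, nn * (1.0 - sp), p0


@dataclass
class PairModel:
    """Models of standardized pairwise effect differences and sums."""

    diff: _ScaleModel
    sum: _ScaleModel

    @property
    def pi0_diff(self):
        return self.diff.pi0

    @property
    def pi0_sum(self):
        return self.sum.pi0


def _pair_quantities(beta, se, i_idx, j_idx):
    denom = np.sqrt(se[i_idx] ** 2 + se[j_idx] ** 2)
    d = (beta[j_idx] - beta[i_idx]) / denom
    s = (beta[j_idx] + beta[i_idx]) / denom
    return d, s


def build_pair_models(effects: EffectsTable, local_fdr_values, n_pairs: int,
                      rng, n_bins: int = 120, degree: int = 8) -> PairModel:
    """Fit point-null + sign-split models to random non-null pair differences
    and sums.

    Ordered pairs are drawn (both members) from the (1 - local fdr)-weighted
    resample; the difference model is fitted on a sample augmented with its
    negation and symmetrized exactly, so that posterior sign probabilities
    satisfy p_plus(-d) = p_minus(d) and order probabilities are symmetric.
    """
    if len(effects) < 2:
        raise ValueError("need at least 2 distinct variables for pair models")
    rng = np.random.default_rng(rng)
    i_idx = resample_nonnull(effects, local_fdr_values, n_pairs, rng)
    j_idx = resample_nonnull(effects, local_fdr_values, n_pairs, rng)
    clash = i_idx == j_idx
    while clash.any():
        j_idx[clash] = resample_nonnull(effects, local_fdr_values, int(clash.sum()), rng)
        clash = i_idx == j_idx
    d, s = _pair_quantities(effects.beta_hat, effects.se, i_idx, j_idx)

    def scale_model(sample, symmetric):
        tg = fit_two_groups(sample, n_bins=n_bins, degree=degree, symmetric=symmetric)
        lf = tg.local_fdr(sample)
        w = 1.0 - lf
        if w.sum() <= 0:
            # fully null pair scale: split is irrelevant, use a flat 0.5
            grid = tg.f.grid
            sp = np.full(grid.size, 0.5)
            split = SignSplitModel(grid=grid, log_g=tg.f.logf, sign_p=sp,
                                   w_plus=0.5, w_minus=0.5)
            return _ScaleModel(tg, split)
        sub = rng.choice(sample.size, size=sample.size, replace=True, p=w / w.sum())
        resampled = sample[sub]
        if symmetric:
            resampled = np.concatenate([resampled, -resampled])
        split = fit_sign_split(resampled, n_bins=n_bins, degree=degree,
                               symmetric=symmetric,
                               support=(sample.min() - 0.5, sample.max() + 0.5))
        return _ScaleModel(tg, split)

    diff_model = scale_model(np.concatenate([d, -d]), symmetric=True)
    sum_model = scale_model(s, symmetric=False)
    return PairModel(diff=diff_model, sum=sum_model)


def order_prob(pair: PairModel, d, s):
    """P(|beta_j| > |beta_i|) for pairs at observed standardized difference d
    and sum s, with posterior tie mass contributing 1/2."""
    dp, dm, d0 = pair.diff.posteriors(d)
    sp_, sm, s0 = pair.sum.posteriors(s)
    p_larger = dp * sp_ + dm * sm
    p_smaller = dp * sm + dm * sp_
    tie = 1.0 - p_larger - p_smaller
    return p_larger + 0.5 * tie


def order_prob_pairs(pair: PairModel, effects: EffectsTable, i, j):
    """order_prob evaluated at the observed (d, s) of variable pairs (i, j)."""
    d, s = _pair_quantities(effects.beta_hat, effects.se, np.asarray(i), np.asarray(j))
    return order_prob(pair, d, s)


def effect_priority(effects: EffectsTable, local_fdr_values, pair: PairModel,
                    k_pairs: int, rng) -> np.ndarray:
    """Per-variable probability of being out-ranked by a random non-null effect.

    For each variable i, k_pairs partners j are drawn from the non-null
    resample (excluding i) and order_prob(i, j) is averaged.
    """
    n = len(effects)
    if n < 2:
        raise ValueError("effect_priority requires at least 2 variables")
    if k_pairs < 1:
        raise ValueError("k_pairs must be >= 1")
    rng = np.random.default_rng(rng)
    partners = resample_nonnull(effects, local_fdr_values, n * k_pairs, rng)
    partners = partners.reshape(n, k_pairs)
    own = np.arange(n)[:, None]
    clash = partners == own
    while clash.any():
        partners[clash] = resample_nonnull(effects, local_fdr_values, int(clash.sum()), rng)
        clash = partners == own
    i_idx = np.broadcast_to(own, partners.shape).ravel()
    op = order_prob_pairs(pair, effects, i_idx, partners.ravel())
    return op.reshape(n, k_pairs).mean(axis=1)


# ---------------------------------------------------------------------------
# the priorityFDR


def priority_fdr(fdr_local, ep):
    """priorityFDR = FDR + effect_priority * (1 - FDR)."""
    fdr_local = np.asarray(fdr_local, dtype=float)
    ep = np.asarray(ep, dtype=float)
    return fdr_local + ep * (1.0 - fdr_local)


def priority_fdr_inc(fdr_local, ep, pi0):
    """Inclusive priorityFDR, ranking against all variables, nulls included.

    FDR * (1 - pi + pi/2) + effect_priority * (1 - pi) * (1 - FDR): a null
    variable is out-ranked by every non-null variable and, splitting ties in
    the all-null block, half of the other nulls.
    """
    fdr_local = np.asarray(fdr_local, dtype=float)
    ep = np.asarray(ep, dtype=float)
    return fdr_local * (1.0 - pi0 + 0.5 * pi0) + ep * (1.0 - pi0) * (1.0 - fdr_local)


@dataclass
class PriorityResult:
    """Per-variable output of the full estimation pipeline."""

    table: pd.DataFrame          # id, beta, se, z, fdr/ep/pfdr columns
    pi0: float
    model: TwoGroupsModel
    pair_model: PairModel

    def __getitem__(self, col):
        return self.table[col].to_numpy()


_RESULT_COLUMNS = [
    "z", "fdr_local", "fdr_tail", "effect_priority", "ep_tail",
    "pfdr_local", "pfdr_tail", "pfdr_inc", "pfdr_inc_tail",
]


def estimate(effects: EffectsTable, seed=None, n_bins: int = 120, degree: int = 8,
             m: int = 100_000, n_pairs: int = 200_000, k_pairs: int = 500) -> PriorityResult:
    """Run the full priorityFDR pipeline on an effects table.

    Fits the two-group model to the Z-scores, builds the pairwise
    difference/sum models from the non-null-weighted resample, estimates the
    effect priority by Monte Carlo over partner pairs, and assembles local
    and tail-area FDR, priorityFDR and inclusive priorityFDR estimates.
    """
    ss = np.random.SeedSequence(seed)
    rng_pairs, rng_ep = [np.random.default_rng(s) for s in ss.spawn(2)]

    model = fit_two_groups(effects.z, n_bins=n_bins, degree=degree)
    lf = model.local_fdr(effects.z)
    if (1.0 - lf).sum() <= 0:
        raise ValueError("no non-null mass: all local fdr values are 1")
    pair = build_pair_models(effects, lf, n_pairs=n_pairs, rng=rng_pairs,
                             n_bins=n_bins, degree=degree)
    ep = effect_priority(effects, lf, pair, k_pairs=k_pairs, rng=rng_ep)

    pfdr_local = priority_fdr(lf, ep)
    pfdr_inc = priority_fdr_inc(lf, ep, model.pi0)
    df = pd.DataFrame({
        "id": effects.variable_id,
        "beta": effects.beta_hat,
        "se": effects.se,
        "z": effects.z,
        "fdr_local": lf,
        "fdr_tail": tail_average(lf),
        "effect_priority": ep,
        "ep_tail": tail_average(ep),
        "pfdr_local": pfdr_local,
        "pfdr_tail": tail_average(pfdr_local),
        "pfdr_inc": pfdr_inc,
        "pfdr_inc_tail": tail_average(pfdr_inc),
    })
    return PriorityResult(table=df, pi0=model.pi0, model=model, pair_model=pair)
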