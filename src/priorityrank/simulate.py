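"""Synthetic effect architectures and benchmark datasets.

An *architecture* is a 20-component scale-mixture prior for true effects on
the Z-score scale: 19 zero-mean normal (or Laplace) components with SDs drawn
from an exponential distribution, plus a point-null component.  Mixing
proportions come from a Dirichlet whose concentration favours the
narrow-component end, emulating polygenic risk architectures in which large
effects are rare.  Datasets drawn from an architecture emulate GWAS summary
statistics: Beta-distributed allele frequencies, the binomial log-OR standard
error formula, a per-architecture coupling gamma between effect size and
standard error, and observed estimates with additive normal noise.  Optional
block-correlated shifts emulate linkage disequilibrium between test
statistics.

Ground-truth error functionals (err_FDR, err_effect_priority,
err_priorityFDR), threshold calibration curves and rank-recovery metrics are
computed here for scoring estimates against the known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .density import tail_average

__all__ = [
    "ALPHA_GRID",
    "Architecture",
    "SimulatedDataset",
    "EvaluationResult",
    "draw_architecture",
    "draw_dataset",
    "boost_power",
    "add_ld_blocks",
    "true_errors",
    "true_overall_quantile",
    "evaluate_error_control",
    "rank_metrics",
    "quantile_to_tail",
]

#: thresholds at which empirical error control is evaluated
ALPHA_GRID = (0.001, 0.01, 0.025, 0.05, 0.1, 0.2, 0.3,
              0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass
class Architecture:
    """Mixture prior for true effects on the Z-score scale."""

    rate: float                 # exponential rate for component SDs
    sds: np.ndarray             # 19 component SDs
    mix: np.ndarray             # 20 proportions; mix[-1] is the null mass
    gamma: float                # effect-SE coupling in [0, 1]
    family: str = "normal"      # "normal" or "laplace"

    def __post_init__(self):
        self.sds = np.asarray(self.sds, dtype=float)
        self.mix = np.asarray(self.mix, dtype=float)
        if abs(self.mix.sum() - 1.0) > 1e-12:
            raise ValueError("mixture proportions must sum to 1")
        if self.family not in ("normal", "laplace"):
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def null_prop(self) -> float:
        return float(self.mix[-1])


def draw_architecture(seed, null_prop: float = 0.5, family: str = "normal") -> Architecture:
    """Draw one random effect architecture.

    rate ~ U(0.1, 1); component SDs s_k ~ Exp(rate); Dirichlet concentration
    (e^{-s_k} / sum e^{-s_k}) / median(.), favouring narrow components; the 19
    non-null proportions are rescaled to sum to 1 - null_prop; the effect-SE
    coupling gamma ~ U(0, 1).
    """
    rng = np.random.default_rng(seed)
    rate = rng.uniform(0.1, 1.0)
    sds = rng.exponential(scale=1.0 / rate, size=19)
    w = np.exp(-sds)
    conc = (w / w.sum()) / np.median(w / w.sum())
    p = rng.dirichlet(conc)
    mix = np.append(p * (1.0 - null_prop), null_prop)
    gamma = rng.uniform(0.0, 1.0)
    return Architecture(rate=rate, sds=sds, mix=mix, gamma=gamma, family=family)


def boost_power(arch: Architecture) -> Architecture:
    """Higher-powered variant: component SDs x4, null proportion 0.1."""
    nonnull = arch.mix[:-1]
    nonnull = nonnull / nonnull.sum() * 0.9
    return replace(arch, sds=arch.sds * 4.0, mix=np.append(nonnull, 0.1))


def se_log_or(maf, N: float, c: float):
    """Approximate SE of a log odds-ratio estimate for a binomial variant
    with allele frequency ``maf``, sample size N and case proportion c."""
    maf = np.asarray(maf, dtype=float)
    terms = (1.0 / (maf * c) + 1.0 / ((1.0 - maf) * c)
             + 1.0 / (maf * (1.0 - c)) + 1.0 / ((1.0 - maf) * (1.0 - c)))
    return np.sqrt(terms / N)


@dataclass
class SimulatedDataset:
    """Ground truth plus observed summary statistics for one dataset."""

    component: np.ndarray       # 0..19; 19 is the null component
    theta: np.ndarray           # true effect on the Z-score scale
    maf: np.ndarray
    se: np.ndarray
    sigma_bar: float
    beta_true: np.ndarray
    beta_hat: np.ndarray
    arch: Architecture
    block_id: np.ndarray | None = None
    block_loading: np.ndarray | None = None

    def __len__(self):
        return self.theta.size

    @property
    def is_null(self):
        return self.beta_true == 0.0

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame({
            "id": [f"v{i}" for i in range(n)],
            "component": self.component,
            "theta": self.theta,
            "maf": self.maf,
            "se": self.se,
            "beta_true": self.beta_true,
            "beta": self.beta_hat,
        })


def draw_dataset(arch: Architecture, n: int = 10_000, N: float = 15_000,
                 c: float = 0.5, seed=None,
                 laplace_scale_literal: bool = False) -> SimulatedDataset:
    """Draw one dataset of n variables from an architecture.

    True effects theta come from the architecture's mixture (zero for the
    null component); allele frequencies from Beta(0.8, 0.8) rescaled to
    [0.005, 0.995]; standard errors from the binomial log-OR formula; true
    log-ORs beta = theta * (gamma*se + (1-gamma)*sigma_bar); observed
    beta_hat = beta + N(0, se).

    For the Laplace family the component scale is s_k/sqrt(2) so each
    component keeps SD s_k; ``laplace_scale_literal`` uses s_k/2 instead.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    comp = rng.choice(20, size=n, p=arch.mix)
    theta = np.zeros(n)
    nonnull = comp < 19
    sds = arch.sds[comp[nonnull]]
    if arch.family == "normal":
        theta[nonnull] = rng.normal(0.0, sds)
    else:
        scale = sds / (2.0 if laplace_scale_literal else np.sqrt(2.0))
        theta[nonnull] = rng.laplace(0.0, scale)
    maf = 0.005 + 0.99 * rng.beta(0.8, 0.8, size=n)
    se = se_log_or(maf, N, c)
    sigma_bar = float(se.mean())
    beta_true = theta * (arch.gamma * se + (1.0 - arch.gamma) * sigma_bar)
    beta_hat = beta_true + rng.normal(0.0, se)
    return SimulatedDataset(component=comp, theta=theta, maf=maf, se=se,
                            sigma_bar=sigma_bar, beta_true=beta_true,
                            beta_hat=beta_hat, arch=arch)


def add_ld_blocks(data: SimulatedDataset, n_blocks: int = 100,
                  block_size: int = 100, shift_sd: float = 0.1,
                  seed=None) -> SimulatedDataset:
    """Add block-correlated shifts to both observed and true effects.

    Variables are assigned to blocks with replacement (a variable may sit in
    several blocks).  Each block receives a shared shift |N(0, shift_sd)|
    centred by subtracting the half-normal mean shift_sd*sqrt(2/pi) (about
    0.0798 at the default), and each membership a uniform loading.  Absolute
    Z-scores are moved by loading * shift with the original sign restored,
    for the observed statistics and (with the true sign) the true effects, so
    null effects stay exactly null.
    """
    rng = np.random.default_rng(seed)
    n = len(data)
    members = rng.choice(n, size=(n_blocks, block_size), replace=True)
    shifts = np.abs(rng.normal(0.0, shift_sd, size=n_blocks)) - shift_sd * np.sqrt(2.0 / np.pi)
    loadings = rng.uniform(0.0, 1.0, size=(n_blocks, block_size))
    delta = np.zeros(n)
    np.add.at(delta, members.ravel(), (loadings * shifts[:, None]).ravel())

    z_obs = data.beta_hat / data.se
    z_true = data.beta_true / data.se
    z_obs = np.sign(z_obs) * (np.abs(z_obs) + delta)
    z_true = np.sign(z_true) * (np.abs(z_true) + delta)

    block_id = np.full(n, -1)
    loading_of = np.zeros(n)
    block_id[members.ravel()] = np.repeat(np.arange(n_blocks), block_size)
    loading_of[members.ravel()] = loadings.ravel()
    return replace(data,
                   beta_hat=z_obs * data.se,
                   beta_true=z_true * data.se,
                   block_id=block_id,
                   block_loading=loading_of)


# ---------------------------------------------------------------------------
# ground-truth errors and evaluation


def true_errors(data: SimulatedDataset, i: int | None = None):
    """Ground-truth error functionals (err_fdr, err_ep, err_pfdr).

    err_fdr_i = I(beta_i = 0); err_ep_i is the proportion of non-null
    variables whose true |beta| exceeds |beta_i| (hence 1 for null i);
    err_pfdr_i = err_fdr_i + (1 - err_fdr_i) * err_ep_i.  Pure functions of
    the dataset; with ``i`` given, returns the scalars for that variable.
    """
    beta = data.beta_true
    err_fdr = (beta == 0.0).astype(float)
    nn_abs = np.sort(np.abs(beta[beta != 0.0]))
    n_nn = nn_abs.size
    if n_nn == 0:
        err_ep = np.ones_like(err_fdr)
    else:
        greater = n_nn - np.searchsorted(nn_abs, np.abs(beta), side="right")
        err_ep = greater / n_nn
        err_ep[err_fdr == 1.0] = 1.0
    err_pfdr = err_fdr + (1.0 - err_fdr) * err_ep
    if i is not None:
        return float(err_fdr[i]), float(err_ep[i]), float(err_pfdr[i])
    return err_fdr, err_ep, err_pfdr


def true_overall_quantile(data: SimulatedDataset) -> np.ndarray:
    """True rank quantile of |beta| among all variables (1 = smallest effect);
    the tied null block shares its mid-rank quantile."""
    r = rankdata(-np.abs(data.beta_true), method="average")
    return r / len(data)


@dataclass
class EvaluationResult:
    """Mean empirical errors among variables passing each alpha threshold."""

    alphas: tuple
    mean_err_fdr: np.ndarray     # NaN where no variable passes
    mean_err_ep: np.ndarray
    mean_err_pfdr: np.ndarray
    n_selected: np.ndarray = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "alpha": self.alphas,
            "mean_err_fdr": self.mean_err_fdr,
            "mean_err_ep": self.mean_err_ep,
            "mean_err_pfdr": self.mean_err_pfdr,
        })


def evaluate_error_control(estimates, data: SimulatedDataset,
                           alphas=ALPHA_GRID) -> EvaluationResult:
    """Mean true errors among variables whose tail estimates pass each alpha.

    ``estimates`` is the result table of the estimation pipeline (or any
    mapping with fdr_tail / ep_tail / pfdr_tail vectors); each error type is
    thresholded on its own tail estimate.  Thresholds selecting no variable
    are recorded as NaN (missing), not zero.
    """
    err_fdr, err_ep, err_pfdr = true_errors(data)
    pairs = [("fdr_tail", err_fdr), ("ep_tail", err_ep), ("pfdr_tail", err_pfdr)]
    out = {name: [] for name, _ in pairs}
    n_sel = []
    for a in alphas:
        for name, err in pairs:
            est = np.asarray(estimates[name], dtype=float)
            sel = est <= a
            out[name].append(err[sel].mean() if sel.any() else np.nan)
        n_sel.append(int((np.asarray(estimates["pfdr_tail"], float) <= a).sum()))
    return EvaluationResult(
        alphas=tuple(alphas),
        mean_err_fdr=np.array(out["fdr_tail"]),
        mean_err_ep=np.array(out["ep_tail"]),
        mean_err_pfdr=np.array(out["pfdr_tail"]),
        n_selected=np.array(n_sel),
    )


def quantile_to_tail(quantiles) -> np.ndarray:
    """Convert per-variable rank-quantile estimates (e.g. from an external
    ranking method) into tail-area estimates by sorting and taking running
    means, the same conversion applied to local priorityFDR values."""
    return tail_average(quantiles)


def rank_metrics(estimates_tail, true_quantile, x_list=(0.05, 0.01, 0.005)):
    """Rank-recovery metrics against the true overall quantile.

    metricA(x): proportion of variables truly in the top x% that are assigned
    a tail rank estimate <= x (power-like; larger is better).
    metricB(x): mean true quantile over the set claimed to rank within x%,
    i.e. variables with tail estimate <= x (type-I-like; values at or below x
    indicate success).  Empty selections are recorded as NaN.
    """
    est = np.asarray(estimates_tail, dtype=float)
    q = np.asarray(true_quantile, dtype=float)
    metric_a, metric_b = {}, {}
    for x in x_list:
        top = q <= x
        metric_a[x] = float((est[top] <= x).mean()) if top.any() else np.nan
        sel = est <= x
        metric_b[x] = float(q[sel].mean()) if sel.any() else np.nan
    return metric_a, metric_b
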