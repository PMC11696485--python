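"""Two-group empirical-Bayes model on the Z-score scale.

The marginal distribution of Z-scores is modelled as a mixture of a fixed
standard-normal point-null and a flexible non-null component,

    f(z) = pi0 * f0(z) + (1 - pi0) * g(z),      f0 = N(0, 1),

where f is estimated by Poisson (Lindsey-style) count regression of histogram
bin counts on a polynomial basis, and pi0 is the null proportion.  The local
false discovery rate is the posterior null probability pi0*f0(z)/f(z); the
tail-area FDR is the running mean of local values over the more-significant
tail.

Histogram binning and the polynomial basis are laid out on an asinh-warped
axis by default, so that architectures mixing unit-scale null statistics with
very large non-null Z-scores keep full resolution near zero without needing
thousands of bins; ``transform="identity"`` gives plain equal-width bins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from numpy.polynomial import legendre

__all__ = [
    "EffectsTable",
    "GridDensity",
    "TwoGroupsModel",
    "ConvergenceError",
    "standardize",
    "fit_marginal_density",
    "estimate_pi0",
    "local_fdr",
    "tail_average",
    "fit_two_groups",
]

logger = logging.getLogger(__name__)

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """Raised when the histogram count regression fails to converge."""


def norm_logpdf(z):
    """log density of the standard-normal null."""
    z = np.asarray(z, dtype=float)
    return -0.5 * z * z - _LOG_SQRT_2PI


def norm_pdf(z):
    return np.exp(norm_logpdf(z))


# ---------------------------------------------------------------------------
# effects table


@dataclass
class EffectsTable:
    """Per-variable effect estimates on the log odds-ratio scale.

    Attributes
    ----------
    variable_id : ndarray of str
        Unique identifiers.
    beta_hat : ndarray
        Effect estimates (log-OR scale).
    se : ndarray
        Standard errors, strictly positive.
    z : ndarray
        Standardized effects beta_hat / se.
    """

    variable_id: np.ndarray
    beta_hat: np.ndarray
    se: np.ndarray
    z: np.ndarray = field(init=False)

    def __post_init__(self):
        self.variable_id = np.asarray(self.variable_id, dtype=object)
        self.beta_hat = np.asarray(self.beta_hat, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if len(set(self.variable_id)) != len(self.variable_id):
            raise ValueError("variable_id values must be unique")
        bad = ~(self.se > 0) | ~np.isfinite(self.se) | ~np.isfinite(self.beta_hat)
        if bad.any():
            for vid in self.variable_id[bad]:
                logger.warning("dropping variable %s: nonpositive or missing se/beta", vid)
            self.variable_id = self.variable_id[~bad]
            self.beta_hat = self.beta_hat[~bad]
            self.se = self.se[~bad]
        self.z = self.beta_hat / self.se

    def __len__(self):
        return self.beta_hat.size

    @classmethod
    def from_frame(cls, df):
        return cls(df["id"].to_numpy(), df["beta"].to_numpy(float), df["se"].to_numpy(float))


def standardize(effects: EffectsTable) -> np.ndarray:
    """Z-scores beta_hat / se, in input order (rows with invalid se are
    already rejected, with a diagnostic, by the EffectsTable constructor)."""
    return effects.z


# ---------------------------------------------------------------------------
# density evaluator


@dataclass
class GridDensity:
    """Density defined by log-values on a strictly increasing grid.

    Evaluation interpolates the log-density linearly; outside the grid the
    edge segments are extended linearly, so tails decay (log-linearly) rather
    than being clamped.
    """

    grid: np.ndarray
    logf: np.ndarray

    def logpdf(self, z):
        z = np.asarray(z, dtype=float)
        scalar = z.ndim == 0
        zf = np.atleast_1d(z)
        out = np.interp(zf, self.grid, self.logf)
        g, lf = self.grid, self.logf
        left = zf < g[0]
        if left.any():
            s = (lf[1] - lf[0]) / (g[1] - g[0])
            out[left] = lf[0] + s * (zf[left] - g[0])
        right = zf > g[-1]
        if right.any():
            s = (lf[-1] - lf[-2]) / (g[-1] - g[-2])
            out[right] = lf[-1] + s * (zf[right] - g[-1])
        return out[0] if scalar else out

    def __call__(self, z):
        return np.exp(self.logpdf(z))

    def integral(self) -> float:
        return float(np.trapezoid(np.exp(self.logf), self.grid))

    def normalized(self) -> "GridDensity":
        return GridDensity(self.grid, self.logf - np.log(self.integral()))


@dataclass
class FitInfo:
    """Diagnostics of the histogram count regression.

    ``se_logf`` holds the pointwise standard error of the fitted log-density
    on the evaluation grid (from the GLM coefficient covariance), used to
    correct the null-proportion estimator for selection noise.
    """

    bin_edges: np.ndarray
    bin_counts: np.ndarray
    basis_degree: int
    coefficients: np.ndarray
    deviance: float
    converged: bool
    se_logf: np.ndarray | None = None


def _basis(t, t_lo, t_hi, degree):
    # Legendre basis on the bin axis rescaled to [-1, 1]
    x = (2.0 * t - (t_lo + t_hi)) / (t_hi - t_lo)
    return legendre.legvander(x, degree)


def fit_marginal_density(
    z,
    n_bins: int = 120,
    degree: int = 8,
    transform: str = "asinh",
    pad: float = 0.5,
    support=None,
    symmetric: bool = False,
    grid_mult: int = 4,
    return_info: bool = False,
):
    """Fit a smooth density to the histogram of ``z`` by Poisson regression.

    Bin counts over ``n_bins`` bins (equal width on the transformed axis) are
    regressed, with a log link, on a Legendre polynomial basis of the bin
    centres; the exponentiated fit is normalized to integrate to one over the
    support ``[min(z) - pad, max(z) + pad]``.

    Parameters
    ----------
    transform : {"asinh", "identity"}
        Axis warp for binning and basis.  The asinh warp keeps bin resolution
        near zero for samples with very large outlying Z-scores.
    support : (lo, hi), optional
        Override the fitted support.
    symmetric : bool
        Force a support symmetric about zero and symmetrize the fitted
        log-density exactly (used for models of pairwise effect differences).

    Returns
    -------
    GridDensity, or (GridDensity, FitInfo) when ``return_info``.
    """
    z = np.asarray(z, dtype=float)
    if z.size <= degree + 1:
        raise ValueError(
            f"sample of {z.size} is too small for a degree-{degree} fit")
    if z.size < 2:
        raise ValueError("need at least 2 observations to fit a density")
    if np.ptp(z) == 0:
        raise ValueError("degenerate input: all z values identical")
    if n_bins < 20:
        raise ValueError("n_bins must be at least 20")

    if support is None:
        lo, hi = z.min() - pad, z.max() + pad
    else:
        lo, hi = support
    if symmetric:
        hi = max(abs(lo), abs(hi))
        lo = -hi

    if transform == "asinh":
        fwd, inv = np.arcsinh, np.sinh
    elif transform == "identity":
        fwd, inv = (lambda x: np.asarray(x, float)), (lambda x: np.asarray(x, float))
    else:
        raise ValueError(f"unknown transform {transform!r}")

    t_lo, t_hi = float(fwd(lo)), float(fwd(hi))
    t_edges = np.linspace(t_lo, t_hi, n_bins + 1)
    edges = inv(t_edges)
    counts, _ = np.histogram(np.clip(z, lo, hi), bins=edges)
    t_centres = 0.5 * (t_edges[:-1] + t_edges[1:])

    X = _basis(t_centres, t_lo, t_hi, degree)
    glm = sm.GLM(counts, X, family=sm.families.Poisson())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = glm.fit(maxiter=200)
        except (ValueError, np.linalg.LinAlgError):
            res = None
        if res is None or not res.converged:
            # IRLS can overflow for wide untransformed supports; quasi-Newton
            # on the Poisson log-likelihood is slower but robust
            res = glm.fit(method="lbfgs", start_params=np.zeros(degree + 1),
                          maxiter=500, disp=False)
    if not np.all(np.isfinite(res.params)):
        raise ConvergenceError(
            f"histogram count regression did not converge "
            f"(n_bins={n_bins}, degree={degree})"
        )

    # evaluate on a finer grid of the transformed axis
    t_grid = np.linspace(t_lo, t_hi, n_bins * grid_mult + 1)
    B = _basis(t_grid, t_lo, t_hi, degree)
    eta = B @ res.params
    try:
        cov = np.asarray(res.cov_params())
        se_eta = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, cov, B), 0.0))
    except (ValueError, np.linalg.LinAlgError):
        se_eta = np.zeros_like(eta)
    z_grid = inv(t_grid)
    if transform == "asinh":
        # density of T = asinh(Z) back to the z axis: dT/dz = 1/sqrt(1+z^2)
        log_jac = -0.5 * np.log1p(z_grid * z_grid)
    else:
        log_jac = 0.0
    logf = eta + log_jac
    if symmetric:
        logf = 0.5 * (logf + logf[::-1])
        se_eta = 0.5 * (se_eta + se_eta[::-1])
        z_grid = 0.5 * (z_grid - z_grid[::-1])  # exact antisymmetric grid
    dens = GridDensity(z_grid, logf).normalized()
    if return_info:
        info = FitInfo(edges, counts, degree, np.asarray(res.params),
                       float(res.deviance), True, se_logf=se_eta)
        return dens, info
    return dens


def estimate_pi0(f: GridDensity, window: float = 2.0, n_eval: int = 201,
                 se_logf=None, z_mult: float = 2.0) -> float:
    """Null proportion as the minimum of f/f0 over the central window.

    The ratio f(z)/phi(z) lower-bounds any valid pi0 at every z; its minimum
    over |z| <= window is the canonical conservative (upper-bound) estimator
    for a point-null + flexible non-null mixture.  Minimizing a noisy fitted
    ratio selects downward noise, so when pointwise standard errors of the
    fitted log-density are available (``se_logf`` aligned with ``f.grid``)
    the minimum is taken over the ``z_mult``-SE upper band of the ratio
    instead, cancelling the selection bias.
    """
    inside = np.abs(f.grid) <= window
    if inside.any():
        zz = f.grid[inside]
        log_ratio = f.logf[inside] - norm_logpdf(zz)
        if se_logf is not None:
            log_ratio = log_ratio + z_mult * np.asarray(se_logf, float)[inside]
    else:
        # support away from zero: extrapolate (no SE band available there)
        zz = np.linspace(-window, window, n_eval)
        log_ratio = f.logpdf(zz) - norm_logpdf(zz)
    return float(np.clip(np.exp(log_ratio.min()), 0.0, 1.0))


def local_fdr(f: GridDensity, pi0: float, z) -> np.ndarray:
    """Posterior null probability min(1, pi0 * f0(z) / f(z))."""
    z = np.asarray(z, dtype=float)
    if pi0 <= 0:
        return np.zeros_like(z, dtype=float)
    logf = np.asarray(f.logpdf(z), dtype=float)
    if np.any(np.isneginf(logf)):
        warnings.warn("f(z) = 0 at some evaluation points; local fdr set to 1")
    with np.errstate(over="ignore"):
        ratio = np.exp(np.log(pi0) + norm_logpdf(z) - logf)
    return np.clip(ratio, 0.0, 1.0)


def tail_average(local_values) -> np.ndarray:
    """Tail-area estimates: mean of local values at least as small.

    For each element, the mean of all local values <= it; tied locals share
    one tail value (the mean up to and including the tied block).  The output,
    sorted by local value, is nondecreasing.
    """
    x = np.asarray(local_values, dtype=float)
    if x.size == 0:
        raise ValueError("tail_average of empty input")
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    cummean = np.cumsum(xs) / np.arange(1, xs.size + 1)
    # each value takes the cumulative mean at the end of its tied block
    last = np.searchsorted(xs, xs, side="right") - 1
    tails_sorted = cummean[last]
    out = np.empty_like(x)
    out[order] = tails_sorted
    return out


# ---------------------------------------------------------------------------
# fitted two-group model


@dataclass
class TwoGroupsModel:
    """Point-null + flexible non-null mixture fitted to Z-scores."""

    f: GridDensity
    pi0: float
    info: FitInfo

    @property
    def bin_edges(self):
        return self.info.bin_edges

    @property
    def bin_counts(self):
        return self.info.bin_counts

    def f0(self, z):
        return norm_pdf(z)

    def local_fdr(self, z):
        return local_fdr(self.f, self.pi0, z)


def fit_two_groups(
    z,
    n_bins: int = 120,
    degree: int = 8,
    transform: str = "asinh",
    symmetric: bool = False,
    support=None,
) -> TwoGroupsModel:
    """Fit the marginal density, estimate pi0 and enforce pi0*f0 <= f.

    The constraint is enforced by lifting the fitted log-density to
    log(pi0*f0) wherever it dips below, renormalizing, and repeating; the
    adjustment is ordinarily far below the normalization tolerance.
    """
    f, info = fit_marginal_density(
        z, n_bins=n_bins, degree=degree, transform=transform,
        symmetric=symmetric, support=support, return_info=True,
    )
    pi0 = estimate_pi0(f, se_logf=info.se_logf)
    if pi0 > 0:
        floor = np.log(pi0) + norm_logpdf(f.grid)
        logf = f.logf
        for _ in range(3):
            logf = np.maximum(logf, floor)
            d = GridDensity(f.grid, logf)
            logf = d.normalized().logf
        logf = np.maximum(logf, floor)
        f = GridDensity(f.grid, logf)
    return TwoGroupsModel(f=f, pi0=pi0, info=info)
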