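"""Power-law summary of a correlation estimate, with Monte-Carlo bands.

The chromosomal clustering metric is the model 1 + xi(r) = A * r^beta fitted
over the intermediate separations that show a clustering signal: starting
from the smallest valid bin, bins are used up to (excluding) the first one
whose 1+xi is consistent with random, i.e. within ``n_sigma`` bootstrap
errors of 1. The fit is a chi^2 minimization in log10-log10 space — a
weighted linear least squares solved in closed form — with the measurement
errors propagated onto the log scale, sigma_log = sigma / ((1+xi) ln 10).

Confidence bands come from a parametric Monte Carlo: each realization
perturbs the per-bin estimate with a Gaussian of the stated error (Poisson
by default, bootstrap behind a flag), is refitted, and the 99% band at each
separation is read off as ranks ceil(0.005 n) and floor(0.995 n) of the
sorted fitted values (realizations 50 and 9,950 of 10,000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .tpcf import CorrelationEstimate

__all__ = [
    "PowerLawFit",
    "ConfidenceBand",
    "select_fit_bins",
    "fit_powerlaw",
    "goodness_of_fit",
    "mc_confidence_band",
]

LN10 = np.log(10.0)


@dataclass(frozen=True)
class PowerLawFit:
    """1 + xi = A * r^beta with covariance of (log10 A, beta)."""

    amplitude: float
    index: float
    covariance: np.ndarray
    fit_bins: np.ndarray
    chi2: float
    chi2_nu: float
    p_value: float

    @property
    def amplitude_err(self) -> float:
        """Error on A propagated from the log10 A diagonal term."""
        return float(self.amplitude * LN10 * np.sqrt(self.covariance[0, 0]))

    @property
    def index_err(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))

    def model(self, r) -> np.ndarray:
        return self.amplitude * np.asarray(r, dtype=float) ** self.index


@dataclass(frozen=True)
class ConfidenceBand:
    """Pointwise Monte-Carlo band of the fitted curve on the 1+xi scale."""

    r: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_realizations: int
    amp_draws: np.ndarray    # fitted A per realization
    beta_draws: np.ndarray   # fitted beta per realization

    def contains_params(self, amplitude: float, index: float,
                        level: float = 0.99) -> bool:
        """Is (A, beta) inside the central ``level`` interval of the draws,
        marginally for each parameter?"""
        a = (1.0 - level) / 2.0
        lo_a, hi_a = np.quantile(self.amp_draws, [a, 1 - a])
        lo_b, hi_b = np.quantile(self.beta_draws, [a, 1 - a])
        return bool(lo_a <= amplitude <= hi_a and lo_b <= index <= hi_b)


def select_fit_bins(est: CorrelationEstimate, n_sigma: float = 1.0) -> np.ndarray:
    """Bins to fit: valid bins from the smallest separation up to (excluding)
    the first bin whose 1+xi lies within ``n_sigma`` bootstrap errors of 1.

    Raises when the very first valid bin is already consistent with random
    (no clustering signal) or when fewer than 3 bins survive.
    """
    valid = np.flatnonzero(est.valid)
    if valid.size < 3:
        raise ValueError("need at least 3 valid bins")
    consistent = np.abs(est.one_plus_xi[valid] - 1.0) <= n_sigma * est.sigma_boot[valid]
    if consistent[0]:
        raise ValueError("no clustering signal: smallest-separation bin is "
                         "already consistent with random")
    first = np.flatnonzero(consistent)
    selected = valid[: first[0]] if first.size else valid
    if selected.size < 3:
        raise ValueError("fewer than 3 bins above the random level; cannot fit")
    return selected


def _wls_logspace(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Closed-form weighted linear least squares y = a + b x.

    Returns (a, b, cov, chi2). ``w`` are inverse-variance weights.
    """
    s = w.sum(axis=-1)
    sx = (w * x).sum(axis=-1)
    sy = (w * y).sum(axis=-1)
    sxx = (w * x * x).sum(axis=-1)
    sxy = (w * x * y).sum(axis=-1)
    delta = s * sxx - sx * sx
    if np.any(delta <= 0):
        raise ValueError("singular design: separations are not distinct")
    a = (sxx * sy - sx * sxy) / delta
    b = (s * sxy - sx * sy) / delta
    if np.ndim(x) == 1:
        cov = np.array([[sxx, -sx], [-sx, s]]) / delta
    else:
        cov = None
    resid = y - (np.expand_dims(a, -1) if np.ndim(x) > 1 else a) \
        - (np.expand_dims(b, -1) if np.ndim(x) > 1 else b) * x
    chi2 = (w * resid**2).sum(axis=-1)
    return a, b, cov, chi2


def fit_powerlaw(est: CorrelationEstimate, fit_bins: np.ndarray,
                 sigma: str = "boot", quantity: str = "one_plus_xi") -> PowerLawFit:
    """Weighted least-squares power-law fit over the selected bins.

    ``sigma`` chooses the per-bin error used for the weights ("boot" or
    "poisson"); ``quantity`` fits 1+xi (default) or xi. Requires >= 3 bins
    with positive fitted quantity and finite positive errors.
    """
    fit_bins = np.asarray(fit_bins, dtype=int)
    if fit_bins.size < 3:
        raise ValueError("need at least 3 fit bins (dof >= 1)")
    vals = est.one_plus_xi[fit_bins]
    if quantity == "xi":
        vals = vals - 1.0
    elif quantity != "one_plus_xi":
        raise ValueError(f"unknown quantity {quantity!r}")
    sig = {"boot": est.sigma_boot, "poisson": est.sigma_poisson}[sigma][fit_bins]
    if np.any(vals <= 0):
        raise ValueError("non-positive values in fit range; cannot log-transform")
    if not np.all(np.isfinite(sig)) or np.any(sig < 0):
        raise ValueError("fit range has non-finite errors")
    r = est.bins.centers[fit_bins]
    if np.unique(r).size < 2:
        raise ValueError("singular design: separations are not distinct")
    x = np.log10(r)
    y = np.log10(vals)
    sig_log = sig / (vals * LN10)
    if np.any(sig_log == 0):
        # noiseless input: unweighted fit (exact when the model is exact)
        sig_log = np.ones_like(sig_log)
    a, b, cov, chi2 = _wls_logspace(x, y, 1.0 / sig_log**2)
    dof = fit_bins.size - 2
    return PowerLawFit(
        amplitude=float(10.0**a),
        index=float(b),
        covariance=cov,
        fit_bins=fit_bins,
        chi2=float(chi2),
        chi2_nu=float(chi2 / dof),
        p_value=float(sps.chi2.sf(chi2, dof)),
    )


def goodness_of_fit(est: CorrelationEstimate, fit: PowerLawFit) -> tuple[float, float, float]:
    """(traditional chi2, its upper-tail p, error-weighted reduced chi2).

    The traditional statistic is Pearson's sum (O - E)^2 / E on the 1+xi
    scale with E the fitted model at the bin centers; p uses n_fit - 2
    degrees of freedom. The reduced statistic is the error-weighted chi^2 of
    the fit divided by its degrees of freedom.
    """
    obs = est.one_plus_xi[fit.fit_bins]
    exp = fit.model(est.bins.centers[fit.fit_bins])
    if np.any(exp <= 0):
        raise ValueError("fitted model non-positive at a fit bin")
    chi2_trad = float(((obs - exp) ** 2 / exp).sum())
    dof = fit.fit_bins.size - 2
    p = float(sps.chi2.sf(chi2_trad, dof))
    return chi2_trad, p, fit.chi2_nu


def mc_confidence_band(est: CorrelationEstimate, fit_bins: np.ndarray,
                       n_real: int = 10_000,
                       rng: np.random.Generator | None = None,
                       sigma: str = "poisson", level: float = 0.99) -> ConfidenceBand:
    """Monte-Carlo confidence band for the fitted power law.

    Each realization draws per-bin values from Gaussians centered on the
    estimate with sd ``sigma`` ("poisson" default, "boot" optional), refits
    the power law, and the band at each bin center is read from the sorted
    fitted values at 1-based ranks ceil((1-level)/2 * n) and
    floor((1+level)/2 * n) — realizations 50 and 9,950 for the default
    99% band of 10,000. Non-positive draws are redrawn (values must admit a
    log transform).
    """
    if n_real < 100:
        raise ValueError("need at least 100 realizations")
    if rng is None:
        rng = np.random.default_rng()
    fit_bins = np.asarray(fit_bins, dtype=int)
    center = est.one_plus_xi[fit_bins]
    sig = {"boot": est.sigma_boot, "poisson": est.sigma_poisson}[sigma][fit_bins]
    if not np.all(np.isfinite(sig)):
        raise ValueError("fit bins have non-finite errors")
    draws = rng.normal(center, sig, size=(n_real, fit_bins.size))
    for _ in range(1000):
        bad = draws <= 0
        if not bad.any():
            break
        draws[bad] = rng.normal(np.broadcast_to(center, draws.shape)[bad],
                                np.broadcast_to(sig, draws.shape)[bad])
    else:
        raise RuntimeError("could not draw positive realizations; errors too large")
    x = np.log10(est.bins.centers[fit_bins])
    y = np.log10(draws)
    sig_log = sig / (draws * LN10)
    if np.any(sig_log == 0):
        sig_log = np.ones_like(sig_log)  # degenerate zero-error case
    a, b, _, _ = _wls_logspace(np.broadcast_to(x, draws.shape), y, 1.0 / sig_log**2)
    curves = 10.0 ** (a[:, None] + b[:, None] * x[None, :])
    curves_sorted = np.sort(curves, axis=0)
    alpha = (1.0 - level) / 2.0
    # epsilon guards against float representation of alpha (0.005 is inexact)
    lo_rank = int(np.ceil(alpha * n_real - 1e-9))   # 1-based
    hi_rank = int(np.floor((1.0 - alpha) * n_real + 1e-9))
    return ConfidenceBand(
        r=est.bins.centers[fit_bins],
        lower=curves_sorted[lo_rank - 1],
        upper=curves_sorted[hi_rank - 1],
        n_realizations=n_real,
        amp_draws=10.0**a,
        beta_draws=b,
    )
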