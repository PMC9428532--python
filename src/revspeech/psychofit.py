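"""Psychometric-function fitting and derived intelligibility statistics.

The sigmoid is a logistic parametrized by its inflexion point ``m`` and
width ``w`` (the SNR range spanning 5 %-95 % of the curve), scaled
between a guess rate ``gamma`` (0.1 for the 10-alternative closed set)
and ``1 - lambda``:

    psi(x) = gamma + (1 - gamma - lambda) / (1 + exp(-2 ln(19) (x - m)/w))

Parameters are estimated by maximum likelihood on binomial word counts,
with the lapse rate box-constrained to [0, 0.05].  Proportions are
converted to rationalized arcsine units (RAU) for the statistical
analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "LN19",
    "PsychometricFit",
    "psychometric",
    "fit_psychometric",
    "rau",
    "rau_counts",
    "inverse_rau",
    "mean_group_curve",
    "optimal_snr",
    "dip_benefit",
    "srt",
]

#: ln(1/0.05 - 1): scales the logistic so that ``w`` spans 5 %-95 %.
LN19: float = math.log(19.0)

DEFAULT_GAMMA: float = 0.1
LAMBDA_MAX: float = 0.05


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted (or latent) psychometric parameters for one condition."""

    m: float
    w: float
    gamma: float = DEFAULT_GAMMA
    lam: float = 0.0
    loglik: float = math.nan
    converged: bool = True

    def __post_init__(self):
        if self.w <= 0:
            raise ValueError(f"width must be > 0, got {self.w}")
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError(f"gamma out of range: {self.gamma}")
        if not (0.0 <= self.lam <= 1.0 - self.gamma):
            raise ValueError(f"lambda out of range: {self.lam}")

    def __call__(self, snr):
        return psychometric(snr, self.m, self.w, self.gamma, self.lam)


def psychometric(snr, m: float, w: float,
                 gamma: float = DEFAULT_GAMMA, lam: float = 0.0):
    """Proportion correct at ``snr`` for the scaled logistic sigmoid."""
    if w <= 0:
        raise ValueError("width must be > 0")
    x = np.asarray(snr, dtype=float)
    core = 1.0 / (1.0 + np.exp(-2.0 * LN19 * (x - m) / w))
    out = gamma + (1.0 - gamma - lam) * core
    return float(out) if np.isscalar(snr) else out


def _negloglik(params, snrs, n_words, n_correct, gamma):
    m, w, lam = params
    p = psychometric(snrs, m, w, gamma, lam)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(np.sum(n_correct * np.log(p)
                         + (n_words - n_correct) * np.log(1.0 - p)))


def fit_psychometric(
    snrs,
    n_words,
    n_correct,
    gamma_fixed: float = DEFAULT_GAMMA,
    lambda_max: float = LAMBDA_MAX,
) -> PsychometricFit:
    """Maximum-likelihood fit of (m, w, lambda) to per-SNR word counts.

    Parameters
    ----------
    snrs, n_words, n_correct : array-like
        Matched vectors: tested SNRs, words presented and words correct.
    gamma_fixed : float
        Guess rate, fixed (0.1 for the 10-alternative closed set).
    lambda_max : float
        Upper box constraint on the lapse rate.

    Notes
    -----
    A multistart over a coarse ``m`` grid guards against local optima.
    The ``converged`` flag is set to False for all-floor / all-ceiling
    data (where the threshold is unidentified) and when the optimizer
    fails or the threshold runs into its search bound.
    """
    snrs = np.asarray(snrs, dtype=float)
    n_words = np.asarray(n_words, dtype=float)
    n_correct = np.asarray(n_correct, dtype=float)
    if len(np.unique(snrs)) < 3:
        raise ValueError("need data at >= 3 distinct SNRs")
    if np.any(n_correct > n_words) or np.any(n_correct < 0):
        raise ValueError("0 <= n_correct <= n_words violated")

    lo, hi = snrs.min() - 5.0, snrs.max() + 5.0
    bounds = [(lo, hi), (1.0, 30.0), (0.0, lambda_max)]
    best = None
    for m0 in np.linspace(lo + 1.0, hi - 1.0, 5):
        for w0 in (5.0, 15.0):
            res = minimize(
                _negloglik, x0=[m0, w0, 0.01],
                args=(snrs, n_words, n_correct, gamma_fixed),
                method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-10, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res

    m_hat, w_hat, lam_hat = best.x
    props = n_correct / np.maximum(n_words, 1)
    all_floor = np.all(props <= gamma_fixed + 0.05)
    all_ceiling = np.all(props >= 0.92)
    at_bound = m_hat <= lo + 1e-6 or m_hat >= hi - 1e-6
    converged = bool(best.success and not (all_floor or all_ceiling
                                           or at_bound))
    return PsychometricFit(
        m=float(m_hat), w=float(w_hat), gamma=gamma_fixed,
        lam=float(lam_hat), loglik=-float(best.fun), converged=converged,
    )


def fit_gaussian_psychometric(snrs, n_words, n_correct,
                              gamma_fixed: float = DEFAULT_GAMMA,
                              lambda_max: float = LAMBDA_MAX
                              ) -> PsychometricFit:
    """Variant fit with a cumulative-Gaussian core instead of the logistic.

    ``w`` keeps its 5 %-95 % span meaning (so the Gaussian sd is
    ``w / (2 z_0.95)``).  Provided for sensitivity analyses only.
    """
    z95 = norm.ppf(0.95)

    def nll(params):
        m, w, lam = params
        p = gamma_fixed + (1 - gamma_fixed - lam) * norm.cdf(
            np.asarray(snrs, float), loc=m, scale=w / (2 * z95))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -float(np.sum(np.asarray(n_correct) * np.log(p)
                             + (np.asarray(n_words)
                                - np.asarray(n_correct)) * np.log(1 - p)))

    snrs_arr = np.asarray(snrs, dtype=float)
    lo, hi = snrs_arr.min() - 5.0, snrs_arr.max() + 5.0
    best = None
    for m0 in np.linspace(lo + 1, hi - 1, 5):
        res = minimize(nll, x0=[m0, 8.0, 0.01], method="L-BFGS-B",
                       bounds=[(lo, hi), (1.0, 30.0), (0.0, lambda_max)])
        if best is None or res.fun < best.fun:
            best = res
    m, w, lam = best.x
    return PsychometricFit(m=float(m), w=float(w), gamma=gamma_fixed,
                           lam=float(lam), loglik=-float(best.fun),
                           converged=bool(best.success))


def rau(p):
    """Rationalized arcsine transform of a continuous proportion.

    Maps [0, 1] onto [-23, 123] with R = (146/pi) * 2 arcsin(sqrt(p)) - 23.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    out = (146.0 / math.pi) * 2.0 * np.arcsin(np.sqrt(arr)) - 23.0
    return float(out) if np.isscalar(p) else out


def rau_counts(x, n):
    """Studebaker's integer-count RAU for ``x`` correct out of ``n``."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("need 0 <= x <= n")
    t = np.arcsin(np.sqrt(x / (n + 1.0))) + np.arcsin(
        np.sqrt((x + 1.0) / (n + 1.0)))
    out = (146.0 / math.pi) * t - 23.0
    return float(out) if out.ndim == 0 else out


def inverse_rau(r):
    """Inverse of :func:`rau` (continuous form)."""
    arr = np.asarray(r, dtype=float)
    theta = (arr + 23.0) * math.pi / 146.0 / 2.0
    out = np.sin(theta) ** 2
    return float(out) if np.isscalar(r) else out


def mean_group_curve(fits: list[PsychometricFit]) -> PsychometricFit:
    """Parameter-wise arithmetic mean across listeners' fits.

    The group curve is built by averaging (m, w, gamma, lambda) -- RAU
    conversion is applied afterwards to the resulting curve, never to
    already-averaged RAU values.
    """
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValueError("no converged fits to average")
    return PsychometricFit(
        m=float(np.mean([f.m for f in fits])),
        w=float(np.mean([f.w for f in fits])),
        gamma=float(np.mean([f.gamma for f in fits])),
        lam=float(np.mean([f.lam for f in fits])),
        converged=True,
    )


def optimal_snr(fits: list[PsychometricFit], snr_grid,
                bounds: tuple[float, float] = (0.15, 0.95)) -> float:
    """Grid SNR maximizing the count of predicted scores strictly inside
    ``bounds`` (floor/ceiling avoidance); ties break toward the lower SNR.
    """
    grid = np.sort(np.asarray(snr_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty SNR grid")
    lo, hi = bounds
    counts = [
        sum(1 for f in fits if lo < f(s) < hi)
        for s in grid
    ]
    return float(grid[int(np.argmax(counts))])


def dip_benefit(fit_modulated: PsychometricFit,
                fit_stationary: PsychometricFit, snr: float) -> float:
    """RAU score difference (modulated minus stationary) at ``snr``."""
    return rau(fit_modulated(snr)) - rau(fit_stationary(snr))


def srt(fit: PsychometricFit, criterion: float = 0.5) -> float:
    """SNR at which the fitted curve reaches ``criterion`` (default 50 %).

    Closed-form inversion of the logistic sigmoid.
    """
    span = 1.0 - fit.gamma - fit.lam
    if not (fit.gamma < criterion < 1.0 - fit.lam):
        raise ValueError(
            f"criterion {criterion} outside attainable range "
            f"({fit.gamma}, {1.0 - fit.lam})")
    ratio = span / (criterion - fit.gamma) - 1.0
    return fit.m - fit.w / (2.0 * LN19) * math.log(ratio)
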