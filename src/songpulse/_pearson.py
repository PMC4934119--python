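"""Four-moment sampling from the Pearson distribution system.

Given a target mean, standard deviation, skewness and (conventional)
kurtosis, the Pearson system singles out one distribution family whose
density p solves  p'/p = -(c1 + x) / (c0 + c1*x + c2*x**2)  in standardized
coordinates, with the polynomial coefficients fixed by the moments. The
discriminant of the quadratic selects the family:

* no real roots   -> Type IV (or VII when symmetric): sampled by inverse
  CDF after the compactifying substitution x = lam + a*tan(theta), under
  which the density becomes cos(theta)^(2m-2) * exp(-nu*theta) on
  (-pi/2, pi/2);
* real roots of opposite sign -> Type I/II, a four-parameter beta;
* real roots of the same sign -> Type VI, a shifted/scaled beta-prime;
* c2 == 0 -> Type III, a shifted/scaled gamma;
* skew == 0 and kurtosis == 3 -> Type 0, the normal.

Feasibility requires kurtosis > skewness**2 + 1; specs at or below the
bound are clamped to just above it with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps

__all__ = ["pearson_rvs", "pearson_standardized_rvs"]

_EPS_FEASIBLE = 1e-3
_THETA_GRID = 16385  # inverse-CDF grid for Type IV


def pearson_standardized_rvs(
    skew: float, kurt: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``size`` values with mean 0, variance 1 and the given shape moments."""
    if size < 0:
        raise ValueError("size must be non-negative")
    beta1 = skew**2
    if kurt <= beta1 + 1 + _EPS_FEASIBLE:
        clamped = beta1 + 1 + _EPS_FEASIBLE
        warnings.warn(
            f"kurtosis {kurt} at or below the feasibility bound "
            f"skew^2+1={beta1 + 1:.4g}; clamped to {clamped:.4g}",
            stacklevel=2,
        )
        kurt = clamped
    if skew < 0:
        return -pearson_standardized_rvs(-skew, kurt, size, rng)
    if skew == 0 and abs(kurt - 3) < 1e-12:
        return rng.standard_normal(size)

    beta2 = kurt
    denom = 10 * beta2 - 12 * beta1 - 18
    if abs(denom) < 1e-10:
        # measure-zero line where the coefficients are singular; nudge
        beta2 = beta2 + 1e-6
        denom = 10 * beta2 - 12 * beta1 - 18
    c0 = (4 * beta2 - 3 * beta1) / denom
    c1 = skew * (beta2 + 3) / denom
    c2 = (2 * beta2 - 3 * beta1 - 6) / denom

    if abs(c2) < 1e-12:
        # Type III: gamma on its skew line (kurt = 3 + 1.5*skew^2)
        k = 4.0 / beta1
        g = rng.standard_gamma(k, size)
        return (g - k) / np.sqrt(k)

    disc = c1**2 - 4 * c2 * c0
    if abs(disc) < 1e-14:
        return pearson_standardized_rvs(skew, kurt + 1e-6, size, rng)
    if disc < 0:
        return _type_iv_rvs(c0, c1, c2, size, rng)

    sq = np.sqrt(disc)
    a1 = (-c1 - sq) / (2 * c2)
    a2 = (-c1 + sq) / (2 * c2)
    a1, a2 = min(a1, a2), max(a1, a2)
    # exponents from partial fractions of -(x + c1) / (c2 (x - a1)(x - a2))
    expo1 = (a1 + c1) / (c2 * (a2 - a1))
    expo2 = -(a2 + c1) / (c2 * (a2 - a1))
    if a1 < 0 < a2:
        # Type I/II: beta on (a1, a2)
        alpha, beta = expo1 + 1, expo2 + 1
        if alpha <= 0 or beta <= 0:
            raise ValueError(
                f"infeasible Pearson Type I shape ({alpha}, {beta}) for "
                f"skew={skew}, kurt={kurt}"
            )
        y = rng.beta(alpha, beta, size)
        return a1 + (a2 - a1) * y
    # Type VI: beta-prime beyond the larger root (positive skew after mirror)
    a = expo2 + 1
    b = -expo1 - expo2 - 1
    if a <= 0 or b <= 0:
        raise ValueError(
            f"infeasible Pearson Type VI shape ({a}, {b}) for skew={skew}, kurt={kurt}"
        )
    y = sps.betaprime.rvs(a, b, size=size, random_state=rng)
    return a2 + (a2 - a1) * y


def _type_iv_rvs(
    c0: float, c1: float, c2: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF sampling of Pearson Type IV via the arctan substitution."""
    lam = -c1 / (2 * c2)
    alpha2 = c0 / c2 - lam**2
    if alpha2 <= 0:
        raise ValueError("Type IV requires a positive quadratic discriminant")
    alpha = np.sqrt(alpha2)
    m = 1.0 / (2 * c2)
    nu = (lam + c1) / (c2 * alpha)
    theta = np.linspace(-np.pi / 2, np.pi / 2, _THETA_GRID)
    with np.errstate(divide="ignore"):
        log_pdf = (2 * m - 2) * np.log(np.cos(theta)) - nu * theta
    log_pdf[[0, -1]] = -np.inf
    pdf = np.exp(log_pdf - np.max(log_pdf))
    cdf = np.concatenate(([0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2)))
    cdf /= cdf[-1]
    u = rng.uniform(0, 1, size)
    th = np.interp(u, cdf, theta)
    return lam + alpha * np.tan(th)


def pearson_rvs(
    mean: float,
    std: float,
    skew: float,
    kurt: float,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw from the Pearson-family member matching the four moments."""
    if std < 0:
        raise ValueError("std must be non-negative")
    if std == 0:
        return np.full(size, float(mean))
    return mean + std * pearson_standardized_rvs(skew, kurt, size, rng)
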