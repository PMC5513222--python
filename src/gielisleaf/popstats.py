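"""Population-level statistics for leaf-length and leaf-shape surveys.

Covers the statistical workflow around the shape model: test each
species' leaf-length sample for normality (Shapiro--Wilk) and for
agreement with a two-parameter Weibull distribution (maximum likelihood
fit plus a Kolmogorov--Smirnov test); select the leaves nearest the
median length for digitization; compare fitted shape parameters across
species with Tukey's honestly-significant-difference procedure; and
summarize how closely model-predicted blade areas track observed polygon
areas (ideally the identity line y = x).

Weibull convention used throughout: CDF ``1 - exp(-(x/lam)^k)`` with
shape ``k`` and scale ``lam`` (cm).

The plain KS p-value treats the fitted Weibull as fully specified; with
parameters estimated from the same sample it is anticonservative.  A
parametric-bootstrap p-value (refit on each resample) is available where
calibration matters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "LengthSample",
    "WeibullFit",
    "HsdPair",
    "HsdTable",
    "AreaAgreement",
    "shapiro_wilk",
    "fit_weibull",
    "ks_weibull",
    "select_representative",
    "tukey_hsd",
    "area_agreement",
]


@dataclass(frozen=True)
class LengthSample:
    """Per-species leaf-length vector (cm)."""

    species_id: str
    lengths: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.lengths, dtype=float)
        if arr.ndim != 1 or arr.size < 3:
            raise ValueError("lengths must be a 1D vector of size >= 3")
        if not np.all(arr > 0):
            raise ValueError("all lengths must be positive")
        object.__setattr__(self, "lengths", arr)

    @property
    def size(self) -> int:
        return self.lengths.size


@dataclass(frozen=True)
class WeibullFit:
    """Maximum-likelihood Weibull(shape k, scale lam) fit with its KS test."""

    k: float
    lam: float
    loglik: float
    ks_statistic: float
    ks_p: float
    ks_p_bootstrap: float | None = None


@dataclass(frozen=True)
class HsdPair:
    species_a: str
    species_b: str
    mean_diff: float
    adjusted_p: float
    significant: bool


@dataclass(frozen=True)
class HsdTable:
    pairs: tuple[HsdPair, ...]
    alpha: float


@dataclass(frozen=True)
class AreaAgreement:
    """OLS of predicted on observed areas, with identity-line diagnostics."""

    slope: float
    intercept: float
    r_squared: float
    max_identity_deviation: float


def shapiro_wilk(lengths) -> tuple[float, float]:
    """Shapiro--Wilk normality test: returns (W, p)."""
    x = np.asarray(lengths, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= size <= 5000")
    if np.ptp(x) == 0:
        raise ZeroDivisionError("constant sample: W undefined")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _profile_terms(logx: np.ndarray, k: float) -> tuple[float, float]:
    # stable Sum x^k ln x / Sum x^k via shift by max(k*logx)
    z = k * logx
    z -= z.max()
    w = np.exp(z)
    return float(np.sum(w * logx) / np.sum(w)), float(np.mean(logx))


def _profile_equation(k: float, logx: np.ndarray) -> float:
    ratio, mean_log = _profile_terms(logx, k)
    return ratio - 1.0 / k - mean_log


def fit_weibull(lengths) -> WeibullFit:
    """Maximum-likelihood Weibull fit by the profiled shape equation.

    Profiling the scale out of the likelihood leaves a single monotone
    equation in the shape, ``sum(x^k ln x)/sum(x^k) - 1/k = mean(ln x)``,
    solved by Brent's method; the scale then follows in closed form as
    ``lam = (mean(x^k))^(1/k)``.  The plain KS test against the fitted
    distribution is attached.
    """
    x = np.asarray(lengths, dtype=float)
    if x.size < 10:
        raise ValueError("need >= 10 observations for a Weibull fit")
    if np.any(x <= 0):
        raise ValueError("Weibull requires strictly positive data")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: shape is unidentifiable")
    logx = np.log(x)
    lo, hi = 1e-3, 1.0
    while _profile_equation(hi, logx) < 0 and hi < 1e4:
        hi *= 2.0
    if _profile_equation(lo, logx) > 0 or _profile_equation(hi, logx) < 0:
        raise RuntimeError("Weibull profile equation could not be bracketed")
    k = brentq(_profile_equation, lo, hi, args=(logx,), xtol=1e-12, rtol=1e-14)
    # lam = (mean(x^k))^(1/k), computed through the same stable shift
    z = k * logx
    m = z.max()
    lam = float(np.exp((m + np.log(np.mean(np.exp(z - m)))) / k))
    n = x.size
    loglik = float(
        n * (np.log(k) - k * np.log(lam))
        + (k - 1) * np.sum(logx)
        - np.sum((x / lam) ** k)
    )
    D, p = _ks_against(x, k, lam)
    return WeibullFit(k=float(k), lam=lam, loglik=loglik, ks_statistic=D, ks_p=p)


def _ks_against(x: np.ndarray, k: float, lam: float) -> tuple[float, float]:
    res = stats.kstest(x, stats.weibull_min(k, scale=lam).cdf)
    return float(res.statistic), float(res.pvalue)


def ks_weibull(
    lengths, fit: WeibullFit, bootstrap: int | None = None, seed=None
) -> tuple[float, float]:
    """One-sample KS test of the data against a fitted Weibull.

    Returns ``(D, p)`` with p from the asymptotic KS distribution.  With
    ``bootstrap=B``, p is instead calibrated by a parametric bootstrap:
    draw B samples from the fitted distribution, refit each, and count
    how often the resampled D reaches the observed one
    (``p = (1 + #{D_b >= D}) / (B + 1)``).
    """
    x = np.asarray(lengths, dtype=float)
    D, p = _ks_against(x, fit.k, fit.lam)
    if bootstrap is None:
        return D, p
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(int(bootstrap)):
        sample = fit.lam * rng.weibull(fit.k, size=x.size)
        refit = fit_weibull(sample)
        if refit.ks_statistic >= D:
            exceed += 1
    return D, (1 + exceed) / (bootstrap + 1)


def select_representative(lengths, k: int, tol: float = 0.05) -> np.ndarray:
    """Indices of the ``k`` lengths nearest the sample median.

    Ties in distance are broken by lower index.  For even-sized samples
    the median is the mean of the two central order statistics.  A
    warning is issued if any selected length deviates from the median by
    more than ``tol`` relative.
    """
    x = np.asarray(lengths, dtype=float)
    if k > x.size:
        raise ValueError(f"cannot select {k} of {x.size} leaves")
    med = float(np.median(x))
    dist = np.abs(x - med)
    order = np.lexsort((np.arange(x.size), dist))
    chosen = np.sort(order[:k])
    if med > 0 and np.any(dist[chosen] / med > tol):
        warnings.warn(
            f"selected lengths deviate from the median by more than "
            f"{tol:.0%}; the sample may be too small or too dispersed",
            stacklevel=2,
        )
    return chosen


def tukey_hsd(groups: dict, alpha: float = 0.05) -> HsdTable:
    """All-pairs comparison of group means by Tukey's HSD.

    ``groups`` maps species_id to a vector of per-leaf shape estimates.
    Adjusted p-values come from the studentized-range distribution in a
    one-way layout (Tukey--Kramer for unequal group sizes).
    """
    if len(groups) < 2:
        raise ValueError("Tukey HSD needs at least two groups")
    ids = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in ids]
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs at least two values")
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        raise ZeroDivisionError("all groups constant and identical: undefined")
    res = stats.tukey_hsd(*samples)
    pairs = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            p = float(res.pvalue[i, j])
            pairs.append(
                HsdPair(
                    species_a=ids[i],
                    species_b=ids[j],
                    mean_diff=float(samples[i].mean() - samples[j].mean()),
                    adjusted_p=p,
                    significant=bool(p < alpha),
                )
            )
    return HsdTable(pairs=tuple(pairs), alpha=alpha)


def area_agreement(observed, predicted) -> AreaAgreement:
    """OLS regression of predicted on observed blade areas.

    A model that predicts areas perfectly puts every point on y = x:
    slope 1, intercept 0, R^2 = 1.  ``max_identity_deviation`` is the
    largest absolute difference between a predicted and its observed
    area, regardless of the regression.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("need matched area vectors of length >= 3")
    if np.ptp(obs) == 0:
        raise ZeroDivisionError("zero variance in observed areas")
    fit = stats.linregress(obs, pred)
    return AreaAgreement(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        max_identity_deviation=float(np.max(np.abs(pred - obs))),
    )
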