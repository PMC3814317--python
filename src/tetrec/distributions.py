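"""Log-normal tract-length distributions: fitting, summaries, comparison, extrapolation.

Gene-conversion tract lengths are well described by a log-normal law (the
outcome of multiplicative/processive tract growth).  A distribution is carried
around as a :class:`LogNormalFit` — the pair ``(mu, sigma)`` on the log-bp
scale — together with the uncertainty on ``mu`` and the sample size behind it.

Fitting is maximum likelihood on log-transformed lengths (``sigma`` uses the
MLE, i.e. population, convention); ``sd_mean = sigma / sqrt(n)``.  Summaries
report ``exp(mu)`` — the distribution median, equal to the geometric mean of
the 95% quantile bounds — because that is the natural "average length" for a
log-normal and is exactly invertible from a printed (lower, upper) interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LogNormalFit",
    "FitSummary",
    "ExtrapolationModel",
    "ExtrapolatedProfile",
    "CoFractionModel",
    "fit_lognormal",
    "lognormal_from_interval",
    "compare_fits",
    "fit_co_fraction_regression",
    "extrapolate_profile",
]

#: z quantile defining the reported 95% interval.
_Z95 = 1.96


@dataclass(frozen=True)
class LogNormalFit:
    """A fitted log-normal tract-length distribution.

    mu, sigma are on the log-bp scale.  ``sd_mean`` is the standard error of
    ``mu``; ``n`` the number of tract lengths behind the fit.  Fits
    reconstructed from a printed interval carry ``sd_mean=None, n=None``.
    """

    mu: float
    sigma: float
    sd_mean: float | None = None
    n: int | None = None
    ks_stat: float | None = None
    ks_pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.n is not None and self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")

    def summary(self) -> "FitSummary":
        lo = math.exp(self.mu - _Z95 * self.sigma)
        hi = math.exp(self.mu + _Z95 * self.sigma)
        return FitSummary(central_length=math.exp(self.mu), interval_95=(lo, hi))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` tract lengths (bp, continuous) from the distribution."""
        return rng.lognormal(self.mu, self.sigma, size=n)

    def cdf(self, x) -> np.ndarray:
        """Log-normal CDF at length ``x`` (bp)."""
        return stats.lognorm.cdf(x, s=max(self.sigma, 1e-300), scale=math.exp(self.mu))


@dataclass(frozen=True)
class FitSummary:
    """Central length exp(mu) with the 95% interval exp(mu +/- 1.96 sigma)."""

    central_length: float
    interval_95: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.interval_95
        if not (lo <= self.central_length <= hi):
            raise ValueError("interval must bracket the central length")


def fit_lognormal(lengths) -> LogNormalFit:
    """Maximum-likelihood log-normal fit to tract lengths (bp).

    Requires n >= 2 strictly positive lengths.  A Kolmogorov–Smirnov
    goodness-of-fit test against the fitted distribution is attached to the
    result (``ks_stat``, ``ks_pvalue``).
    """
    x = np.asarray(lengths, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 lengths to fit, got {x.size}")
    if np.any(x < 1):
        raise ValueError("tract lengths must be >= 1 bp")
    logs = np.log(x)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))  # MLE convention
    sd_mean = sigma / math.sqrt(x.size)
    if sigma > 0:
        ks = stats.kstest(x, stats.lognorm(s=sigma, scale=math.exp(mu)).cdf)
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat, ks_p = 0.0, 1.0
    return LogNormalFit(mu=mu, sigma=sigma, sd_mean=sd_mean, n=int(x.size),
                        ks_stat=ks_stat, ks_pvalue=ks_p)


def lognormal_from_interval(lower: float, upper: float) -> LogNormalFit:
    """Reconstruct (mu, sigma) from printed 95% interval bounds.

    (lower, upper) are treated as the 2.5% / 97.5% quantiles, so
    ``mu = (ln lower + ln upper)/2`` and ``sigma = ln(upper/lower)/(2*1.96)``.
    The summary's central length is then the geometric mean of the bounds.
    """
    if lower <= 0:
        raise ValueError(f"lower bound must be > 0, got {lower}")
    if lower >= upper:
        raise ValueError(f"need lower < upper, got ({lower}, {upper})")
    mu = 0.5 * (math.log(lower) + math.log(upper))
    sigma = (math.log(upper) - math.log(lower)) / (2.0 * _Z95)
    return LogNormalFit(mu=mu, sigma=sigma)


def compare_fits(fit_a: LogNormalFit, fit_b: LogNormalFit,
                 n_resamples: int = 10_000, seed: int | None = None) -> float:
    """Two-sided resampling p-value for mu_A != mu_B.

    Each mu is resampled from a normal with its own sd_mean (which is already
    corrected for sample size, being sigma/sqrt(n)); the p-value is twice the
    smaller tail fraction of the resampled difference.
    """
    for f in (fit_a, fit_b):
        if f.sd_mean is None:
            raise ValueError("both fits must carry sd_mean (fit from data)")
    if n_resamples < 1000:
        warnings.warn("fewer than 1000 resamples gives a coarse p-value",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    d = (rng.normal(fit_a.mu, fit_a.sd_mean, size=n_resamples)
         - rng.normal(fit_b.mu, fit_b.sd_mean, size=n_resamples))
    p = 2.0 * min(float(np.mean(d > 0)), float(np.mean(d < 0)))
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# CO-fraction regression (CO homeostasis trend) and tract-length extrapolation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoFractionModel:
    """OLS of per-tetrad CO fraction co/(co+nco) on per-tetrad CO count."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def predict_fraction(self, co_count: float) -> float:
        return self.intercept + self.slope * co_count

    def predict_nco(self, co_count: float) -> float:
        """Expected total NCOs for a (hypothetical) mutant with ``co_count`` COs."""
        f = self.predict_fraction(co_count)
        if not 0 < f <= 1:
            raise ValueError(f"predicted CO fraction {f:.3f} outside (0, 1] "
                             f"at {co_count} COs; extrapolation out of range")
        return co_count * (1.0 - f) / f


def fit_co_fraction_regression(tallies) -> CoFractionModel:
    """Fit the CO-homeostasis trend: CO fraction regressed on CO count.

    ``tallies`` is a sequence of ``(co_total, nco_total)`` pairs or of objects
    with ``co_total``/``nco_total`` attributes (e.g. :class:`~tetrec.events.EventTally`).
    """
    pairs = []
    for t in tallies:
        if hasattr(t, "co_total"):
            pairs.append((float(t.co_total), float(t.nco_total)))
        else:
            co, nco = t
            pairs.append((float(co), float(nco)))
    if len(pairs) < 2:
        raise ValueError("need at least 2 tetrads")
    co = np.array([p[0] for p in pairs])
    frac = co / (co + np.array([p[1] for p in pairs]))
    if np.ptp(co) == 0:
        raise ValueError("degenerate regressor: all CO counts identical")
    res = stats.linregress(co, frac)
    return CoFractionModel(slope=float(res.slope), intercept=float(res.intercept),
                           r_squared=float(res.rvalue**2), n=len(pairs))


_FAMILIES = {
    "linear": lambda x: x,
    "sqrt": np.sqrt,
    "log": np.log,
    "inverse": lambda x: 1.0 / x,
}


@dataclass(frozen=True)
class ExtrapolationModel:
    """Regression of mean tract length on a transform of the CO count.

    ``mean_length = a + b * f(co_count)`` with ``f`` given by ``family``
    (linear, sqrt, log or inverse); sigma is always regressed linearly on the
    CO count.  "Mean" here is the distribution median exp(mu).
    """

    family: str
    mean_coef: tuple[float, float]   # (a, b)
    sd_coef: tuple[float, float]     # sigma = a + b * co_count

    def predict_fit(self, co_count: float) -> LogNormalFit:
        if co_count <= 0 and self.family in ("log", "inverse"):
            raise ValueError(f"family={self.family} undefined at co_count={co_count}")
        f = _FAMILIES[self.family]
        mean = self.mean_coef[0] + self.mean_coef[1] * float(f(co_count))
        sigma = self.sd_coef[0] + self.sd_coef[1] * co_count
        if mean <= 0:
            raise ValueError(f"extrapolated mean length {mean:.1f} <= 0 at "
                             f"{co_count} COs ({self.family} family)")
        return LogNormalFit(mu=math.log(mean), sigma=max(sigma, 0.0))


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor in extrapolation fit")
    res = stats.linregress(x, y)
    return float(res.intercept), float(res.slope)


def fit_extrapolation(anchors, family: str = "inverse") -> ExtrapolationModel:
    """Fit an :class:`ExtrapolationModel` from ``(co_count, LogNormalFit)`` anchors."""
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(_FAMILIES)}")
    anchors = list(anchors)
    if len(anchors) < 3:
        raise ValueError("need at least 3 anchor activities")
    co = np.array([a[0] for a in anchors], dtype=float)
    mean = np.array([math.exp(a[1].mu) for a in anchors])
    sigma = np.array([a[1].sigma for a in anchors])
    mean_coef = _ols(np.asarray(_FAMILIES[family](co), dtype=float), mean)
    sd_coef = _ols(co, sigma)
    return ExtrapolationModel(family=family, mean_coef=mean_coef, sd_coef=sd_coef)


@dataclass(frozen=True)
class ExtrapolatedProfile:
    """Tract distributions and event mix predicted for a hypothetical mutant."""

    co_count: float
    co_fit: LogNormalFit
    nco_fit: LogNormalFit
    expected_nco: float | None = None
    co_fraction: float | None = None


def extrapolate_profile(co_anchors, nco_anchors, target_co: float,
                        family: str = "inverse",
                        co_fraction_model: CoFractionModel | None = None,
                        ) -> ExtrapolatedProfile:
    """Predict CO/NCO tract distributions (and event mix) at ``target_co`` COs.

    CO mean tract length follows the chosen regression family; the NCO mean is
    always extrapolated linearly (NCO tracts shrink roughly linearly with
    activity); both sigmas are linear in the CO count.  If a
    :class:`CoFractionModel` is supplied the expected NCO count and CO
    fraction are filled in as well.
    """
    if target_co <= 0:
        raise ValueError(f"target_co must be > 0, got {target_co}")
    co_model = fit_extrapolation(co_anchors, family=family)
    nco_model = fit_extrapolation(nco_anchors, family="linear")
    expected_nco = co_fraction = None
    if co_fraction_model is not None:
        expected_nco = co_fraction_model.predict_nco(target_co)
        co_fraction = co_fraction_model.predict_fraction(target_co)
    return ExtrapolatedProfile(co_count=float(target_co),
                               co_fit=co_model.predict_fit(target_co),
                               nco_fit=nco_model.predict_fit(target_co),
                               expected_nco=expected_nco,
                               co_fraction=co_fraction)
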