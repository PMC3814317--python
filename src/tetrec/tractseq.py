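"""Monte Carlo gene-conversion tract-length estimation from marker intervals.

Genotyping brackets a conversion tract between a *core* interval (first to
last converted marker — certainly converted) and a *maximal* interval
(bounded by the innermost flanking 2:2 markers — certainly not converted).
The true endpoints lie somewhere in the flanking gaps, and the gaps are often
wildly asymmetric, so midpoints bias length estimates.

The estimator models tract growth as a processive enzyme: starting from each
core edge, the machinery extends one more base with probability ``p``
(default 0.999) and falls off with probability ``1 - p``, so the outward
offset on each side is geometric, ``P(offset = k) = (1 - p) p^k`` for
``k >= 0``.  Offsets that would reach the flanking 2:2 marker are rejected
(the tract must not include it), which truncates the geometric law at
``gap - 1`` where ``gap`` is the core-edge-to-flank distance.  Per iteration
the two sides are drawn independently; the iteration length is
``left offset + core length + right offset`` and the reported estimate is the
median over iterations (even counts: mean of the two central order
statistics, rounded to the nearest bp).

Truncation is applied by direct inverse-CDF sampling of the truncated
geometric — exactly equivalent to rejection-with-resampling per side — and
the would-be acceptance rate ``(1 - p^gap_left)(1 - p^gap_right)`` is
reported for diagnostics.

Tracts defined by a single marker have a degenerate 1-bp core inside an
often-huge maximal interval; estimating them the same way would just echo
the flank geometry.  They are instead predicted from the linear relationship
between maximal length and estimated length learned on multi-marker tracts
(:func:`calibrate_single_snp`), clamped to ``[1, maximal length]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .events import ConversionTract

__all__ = [
    "TractSeqConfig",
    "TractEstimate",
    "SingleSnpCalibration",
    "estimate_tract",
    "estimate_from_intervals",
    "calibrate_single_snp",
    "estimate_single_snp_tract",
]


@dataclass(frozen=True)
class TractSeqConfig:
    """Estimator settings: processivity, iteration budget, seed, direction."""

    p: float = 0.999
    n_iterations: int = 10_000
    seed: int | None = None
    #: draw a single offset on one side per iteration (side chosen uniformly)
    #: instead of one per side; models strictly unidirectional tract growth.
    unidirectional: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError(f"p must be in (0, 1), got {self.p}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass(frozen=True)
class TractEstimate:
    """Median estimated length with iteration quantiles and diagnostics."""

    estimated_length: int
    quantiles: dict[str, float]
    acceptance_rate: float
    n_iterations: int

    def __post_init__(self) -> None:
        if not 0 < self.acceptance_rate <= 1:
            raise ValueError("acceptance_rate must be in (0, 1]")


@dataclass(frozen=True)
class SingleSnpCalibration:
    """Linear model estimated_length ~ maximal_length from multi-marker tracts."""

    slope: float
    intercept: float
    n_training_tracts: int

    def __post_init__(self) -> None:
        if self.n_training_tracts < 2:
            raise ValueError("calibration needs at least 2 training tracts")

    def predict(self, max_length: float) -> int:
        raw = self.slope * max_length + self.intercept
        return int(round(min(max(raw, 1.0), max_length)))


def _truncated_geometric(u: np.ndarray, p: float, gap: int) -> np.ndarray:
    """Inverse-CDF draws of P(k) ∝ (1-p) p^k on k = 0..gap-1.

    Monotone in u, in gap and in p — so common random numbers give exactly
    monotone estimates under parameter changes.
    """
    if gap <= 0:
        raise ValueError("flanking gap must be >= 1 bp")
    if gap == 1:
        return np.zeros(u.shape, dtype=np.int64)
    trunc = 1.0 - p**gap
    k = np.floor(np.log1p(-u * trunc) / math.log(p)).astype(np.int64)
    return np.minimum(k, gap - 1)  # guard the u -> 1 numeric edge


def estimate_from_intervals(core_length: int, gap_left: int, gap_right: int,
                            config: TractSeqConfig) -> TractEstimate:
    """Estimate a tract length from its core length and flanking gaps (bp).

    ``gap_left``/``gap_right`` are the distances from the core edges to the
    flanking 2:2 markers; both must be >= 1 (the maximal interval strictly
    contains the core).
    """
    if core_length < 1:
        raise ValueError("core_length must be >= 1")
    if gap_left < 1 or gap_right < 1:
        raise ValueError(
            "maximal interval must strictly contain the core: both flanking "
            f"gaps must be >= 1 bp, got ({gap_left}, {gap_right})")
    rng = np.random.default_rng(config.seed)
    n = config.n_iterations
    if config.unidirectional:
        side_right = rng.random(n) < 0.5
        u = rng.random(n)
        off = np.where(side_right,
                       _truncated_geometric(u, config.p, gap_right),
                       _truncated_geometric(u, config.p, gap_left))
        lengths = core_length + off
        acceptance = 0.5 * ((1.0 - config.p**gap_left)
                            + (1.0 - config.p**gap_right))
    else:
        left = _truncated_geometric(rng.random(n), config.p, gap_left)
        right = _truncated_geometric(rng.random(n), config.p, gap_right)
        lengths = core_length + left + right
        acceptance = (1.0 - config.p**gap_left) * (1.0 - config.p**gap_right)
    qs = np.percentile(lengths, [2.5, 25, 50, 75, 97.5])
    quantiles = dict(zip(("q2.5", "q25", "q50", "q75", "q97.5"),
                         (float(q) for q in qs)))
    return TractEstimate(estimated_length=int(round(float(np.median(lengths)))),
                         quantiles=quantiles,
                         acceptance_rate=float(acceptance),
                         n_iterations=n)


def estimate_tract(tract: ConversionTract, config: TractSeqConfig) -> TractEstimate:
    """Estimate one multi-marker tract; see :func:`estimate_from_intervals`."""
    gap_left = tract.core_start - tract.max_start
    gap_right = tract.max_end - tract.core_end
    return estimate_from_intervals(tract.core_length, gap_left, gap_right, config)


def calibrate_single_snp(tracts) -> SingleSnpCalibration:
    """OLS of estimated length on maximal length over multi-marker tracts.

    ``tracts`` must carry ``n_markers >= 2`` and a filled ``estimated_length``.
    """
    pairs = [(t.max_length, t.estimated_length) for t in tracts
             if t.n_markers >= 2 and t.estimated_length is not None]
    if len(pairs) < 2:
        raise ValueError("need at least 2 multi-marker tracts with estimates")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: all maximal lengths identical")
    res = stats.linregress(x, y)
    return SingleSnpCalibration(slope=float(res.slope),
                                intercept=float(res.intercept),
                                n_training_tracts=len(pairs))


def estimate_single_snp_tract(tract: ConversionTract,
                              calibration: SingleSnpCalibration) -> TractEstimate:
    """Predict a single-marker tract's length from its maximal interval."""
    est = calibration.predict(tract.max_length)
    return TractEstimate(estimated_length=est,
                         quantiles={"q50": float(est)},
                         acceptance_rate=1.0,
                         n_iterations=0)
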