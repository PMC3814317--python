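"""Virtual heteroallele-prototrophy simulation at an ARG4-like hotspot cluster.

A diploid carrying two different point alleles of one gene (heteroalleles)
yields a prototrophic spore when a gene-conversion tract converts one allele
but not the other.  Given the initiation sites (DSB hotspots) near the locus,
their relative usage, and — for each site — the window of tract lengths whose
endpoint falls between the two heteroalleles, prototroph formation reduces to
drawing tract lengths from per-class log-normal distributions and checking
windows.

The default hotspot model is the ARG4 region: three sites used at 6% / 53% /
41%, with prototroph-forming length windows (1544, 2818), (204, 1478) and
(2354, 3628) bp.  The whole tract is laid from the initiation site toward the
heteroalleles, exactly as those printed windows presuppose; "half-tract" mode
instead centres the initiation site within the tract and tests length/2.

Events are composed from an :class:`EventMixture`: a CO event contributes a
tract with probability ``co_with_tract`` plus an independent third-chromatid
tract with probability ``co_third_strand``; a two-chromatid NCO draws two
tracts and forms a prototroph if either does.  Switching homeostasis off
replays the wild-type CO fraction regardless of activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .distributions import LogNormalFit
from .genome import SnpMap

__all__ = [
    "EventMixture",
    "HotspotSite",
    "HotspotModel",
    "ARG4_HOTSPOTS",
    "PrototrophResult",
    "simulate_prototrophy",
    "equal_usage_mode",
    "estimate_nco_detection_loss",
]


@dataclass(frozen=True)
class EventMixture:
    """Event-class proportions used when composing simulated recombination.

    Defaults are the pooled estimates across activity groups: 71% of COs
    carry a detectable conversion tract, 14% of NCO events place tracts on
    two chromatids, and 7% of COs carry a tract on a third chromatid.
    """

    co_fraction: float
    co_with_tract: float = 0.71
    nco_two_chromatid: float = 0.14
    co_third_strand: float = 0.07

    def __post_init__(self) -> None:
        for name in ("co_fraction", "co_with_tract", "nco_two_chromatid",
                     "co_third_strand"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class HotspotSite:
    site_id: str
    usage: float                       # percent of initiations
    window: tuple[float, float]        # prototroph-forming tract lengths (bp)

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo < hi:
            raise ValueError(f"window min must be < max, got {self.window}")
        if self.usage < 0:
            raise ValueError("usage must be non-negative")


@dataclass(frozen=True)
class HotspotModel:
    sites: tuple[HotspotSite, ...]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("need at least one hotspot site")
        total = sum(s.usage for s in self.sites)
        if not math.isclose(total, 100.0, abs_tol=1e-6):
            raise ValueError(f"usages must sum to 100, got {total}")

    @property
    def usages(self) -> np.ndarray:
        return np.array([s.usage for s in self.sites]) / 100.0

    @property
    def windows(self) -> np.ndarray:
        return np.array([s.window for s in self.sites])


#: The ARG4-region model: three DSB hotspots, relative usage 6/53/41.
ARG4_HOTSPOTS = HotspotModel(sites=(
    HotspotSite("site1", 6.0, (1544.0, 2818.0)),
    HotspotSite("site2", 53.0, (204.0, 1478.0)),
    HotspotSite("site3", 41.0, (2354.0, 3628.0)),
))


def equal_usage_mode(hotspots: HotspotModel) -> HotspotModel:
    """Same sites and windows, but uniform initiation usage."""
    u = 100.0 / len(hotspots.sites)
    return HotspotModel(sites=tuple(replace(s, usage=u) for s in hotspots.sites))


@dataclass(frozen=True)
class PrototrophResult:
    prototroph_fraction: float         # per simulated event
    co_associated_fraction: float      # of prototrophs, from a CO event
    prototroph_sd: float               # Monte Carlo sd over iterations
    co_associated_sd: float
    n_iterations: int
    n_events_per_iteration: int

    def __post_init__(self) -> None:
        if not 0 <= self.prototroph_fraction <= 1:
            raise ValueError("prototroph_fraction must be in [0, 1]")
        if self.prototroph_sd < 0 or self.co_associated_sd < 0:
            raise ValueError("Monte Carlo sd must be >= 0")


def _tract_prototroph(rng: np.random.Generator, fit: LogNormalFit,
                      hotspots: HotspotModel, n: int,
                      half_tract: bool) -> np.ndarray:
    """Simulate n tracts of one class; True where prototroph-forming."""
    if n == 0:
        return np.zeros(0, dtype=bool)
    site = rng.choice(len(hotspots.sites), size=n, p=hotspots.usages)
    length = fit.sample(n, rng)
    if half_tract:
        length = length / 2.0
    win = hotspots.windows[site]
    return (length >= win[:, 0]) & (length <= win[:, 1])


def simulate_prototrophy(hotspots: HotspotModel,
                         co_fit: LogNormalFit,
                         nco_fit: LogNormalFit,
                         mix: EventMixture,
                         nco_2chtd_fit: LogNormalFit | None = None,
                         nco_with_co_fit: LogNormalFit | None = None,
                         n_events_per_iteration: int = 100_000,
                         n_iterations: int = 200,
                         seed: int | None = None,
                         half_tract: bool = False,
                         homeostasis: bool = True,
                         wt_co_fraction: float | None = None,
                         count_mode: str = "event") -> PrototrophResult:
    """Monte Carlo prototroph formation for one activity profile.

    With ``homeostasis=False`` the event kind is drawn with
    ``wt_co_fraction`` (required) instead of ``mix.co_fraction``, keeping the
    NCO share of events at its wild-type value while tract lengths still
    reflect the mutant.  ``count_mode="event"`` scores an event as
    prototroph-forming if any of its tracts is; ``"tract"`` reports the
    expected number of prototroph-forming tracts per event (the additive
    convention, useful against closed-form checks).
    """
    if count_mode not in ("event", "tract"):
        raise ValueError("count_mode must be 'event' or 'tract'")
    if mix.nco_two_chromatid > 0 and nco_2chtd_fit is None:
        raise ValueError("mix has two-chromatid NCOs but no nco_2chtd_fit")
    if mix.co_third_strand > 0 and nco_with_co_fit is None:
        raise ValueError("mix has third-strand CO tracts but no nco_with_co_fit")
    co_fraction = mix.co_fraction
    if not homeostasis:
        if wt_co_fraction is None:
            raise ValueError("homeostasis=False requires wt_co_fraction")
        co_fraction = wt_co_fraction

    rng = np.random.default_rng(seed)
    frac = np.empty(n_iterations)
    co_assoc = np.full(n_iterations, np.nan)
    for it in range(n_iterations):
        n = n_events_per_iteration
        is_co = rng.random(n) < co_fraction
        n_co = int(is_co.sum())
        n_nco = n - n_co

        # CO events: main tract (co_with_tract) + third-strand tract (independent)
        has_main = rng.random(n_co) < mix.co_with_tract
        main_ok = np.zeros(n_co, dtype=bool)
        main_ok[has_main] = _tract_prototroph(
            rng, co_fit, hotspots, int(has_main.sum()), half_tract)
        has_third = rng.random(n_co) < mix.co_third_strand
        third_ok = np.zeros(n_co, dtype=bool)
        if mix.co_third_strand > 0:
            third_ok[has_third] = _tract_prototroph(
                rng, nco_with_co_fit, hotspots, int(has_third.sum()), half_tract)

        # NCO events: single tract, or two tracts for the two-chromatid class
        is_2ch = rng.random(n_nco) < mix.nco_two_chromatid
        n_2ch = int(is_2ch.sum())
        single_ok = np.zeros(n_nco, dtype=bool)
        single_ok[~is_2ch] = _tract_prototroph(
            rng, nco_fit, hotspots, n_nco - n_2ch, half_tract)
        t1 = t2 = np.zeros(n_2ch, dtype=bool)
        if n_2ch:
            t1 = _tract_prototroph(rng, nco_2chtd_fit, hotspots, n_2ch, half_tract)
            t2 = _tract_prototroph(rng, nco_2chtd_fit, hotspots, n_2ch, half_tract)

        if count_mode == "event":
            co_score = (main_ok | third_ok).astype(float)
            nco_score = single_ok.astype(float)
            nco_score[is_2ch] = (t1 | t2).astype(float)
        else:
            co_score = main_ok.astype(float) + third_ok.astype(float)
            nco_score = single_ok.astype(float)
            nco_score[is_2ch] = t1.astype(float) + t2.astype(float)

        total = co_score.sum() + nco_score.sum()
        frac[it] = total / n
        if total > 0:
            co_assoc[it] = co_score.sum() / total

    valid = ~np.isnan(co_assoc)
    return PrototrophResult(
        prototroph_fraction=float(frac.mean()),
        co_associated_fraction=float(co_assoc[valid].mean()) if valid.any() else 0.0,
        prototroph_sd=float(frac.std(ddof=1)) if n_iterations > 1 else 0.0,
        co_associated_sd=(float(co_assoc[valid].std(ddof=1))
                          if valid.sum() > 1 else 0.0),
        n_iterations=n_iterations,
        n_events_per_iteration=n_events_per_iteration)


def estimate_nco_detection_loss(snp_map: SnpMap, nco_fit: LogNormalFit,
                                n_tracts: int = 100_000,
                                seed: int | None = None) -> float:
    """Percent of NCO tracts that would span zero markers on this SNP map.

    Tract start positions are uniform over the genome (chromosomes weighted
    by length); lengths are drawn from ``nco_fit``.  Shorter tracts are more
    likely to fall between adjacent markers and so escape detection by
    genotyping — the quantity returned is that missed percentage.
    """
    rng = np.random.default_rng(seed)
    lengths = np.array([l for _, l in snp_map.chromosomes], dtype=float)
    weights = lengths / lengths.sum()
    chrom_idx = rng.choice(len(lengths), size=n_tracts, p=weights)
    tract_len = np.maximum(1, np.round(nco_fit.sample(n_tracts, rng))).astype(np.int64)
    missed = 0
    for ci, (name, chrom_len) in enumerate(snp_map.chromosomes):
        sel = chrom_idx == ci
        if not sel.any():
            continue
        n = int(sel.sum())
        start = rng.integers(1, chrom_len + 1, size=n)
        end = np.minimum(start + tract_len[sel] - 1, chrom_len)
        pos = snp_map.positions[name]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        missed += int((hi == lo).sum())
    return 100.0 * missed / n_tracts
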