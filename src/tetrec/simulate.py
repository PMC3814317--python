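"""Synthetic tetrads with known ground truth.

One simulated meiosis produces four chromatids (columns 0,1 = parent P1
copies; 2,3 = parent P2 copies) genotyped at every SNP of a
:class:`~tetrec.genome.SnpMap`.  The generative model assembles, per genome:

* crossovers from a stationary gamma renewal process (shape = interference
  strength; 1 = none, ~2 = the interference measured in hypomorph tetrads)
  with mean spacing set so the genome-wide expected CO count is met; each CO
  exchanges flanking arms between one chromatid of each homolog;
* non-crossovers at a Poisson count chosen so the expected CO fraction of
  events matches the configured homeostasis level;
* log-normal gene-conversion tracts per event class (CO-associated, simple
  NCO, two-chromatid NCO, NCO-with-CO), with the complex classes appearing at
  configurable mixture proportions;
* optional genotyping noise (missing and erroneous calls) via ``add_noise``.

Calls are stored as int8: 0 = P1, 1 = P2, -1 = missing.  Coordinates are
1-based inclusive; tract length = end - start + 1.

Randomness uses one master seed; per-chromosome generators are spawned
deterministically from it (``numpy.random.SeedSequence.spawn``), with one
extra stream for genome-level NCO placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .arg4 import EventMixture
from .distributions import LogNormalFit
from .genome import MISSING, P1, P2, SnpMap, TetradGenotypes
from . import tables

__all__ = [
    "P1", "P2", "MISSING",
    "SimulationProfile",
    "TetradGenotypes",
    "TrueTract",
    "GroundTruthEvent",
    "GroundTruth",
    "simulate_tetrad",
    "add_noise",
]

@dataclass(frozen=True)
class SimulationProfile:
    """All knobs of the tetrad generator.

    Defaults reproduce a wild-type-like hybrid meiosis: 92 expected COs,
    interference shape 2.0, CO fraction of events 0.657 (the per-tetrad mean
    of the wild-type tallies), tract distributions reconstructed from the
    printed wild-type 95% intervals, and the pooled complex-event mixture
    (71% of COs with a tract, 14% two-chromatid NCOs, 7% third-strand CO
    tracts).
    """

    expected_co_count: float = 92.0
    interference_shape: float = 2.0
    co_fraction_of_events: float = tables.GROUP_MEAN_CO_FRACTION["WT"]
    tract_fit_co: LogNormalFit = field(
        default_factory=lambda: tables.tract_fit("WT", "CO"))
    tract_fit_nco: LogNormalFit = field(
        default_factory=lambda: tables.tract_fit("WT", "NCO"))
    tract_fit_nco_2chtd: LogNormalFit = field(
        default_factory=lambda: tables.tract_fit("POOLED", "NCO_2CHTD"))
    tract_fit_nco_with_co: LogNormalFit = field(
        default_factory=lambda: tables.tract_fit("POOLED", "NCO_W_CO"))
    event_mix: EventMixture | None = None
    #: probability that an NCO event is a 4:0 conversion (off by default;
    #: such events are rare in real tetrads).
    four_to_zero_rate: float = 0.0
    missing_rate: float = 0.01
    error_rate: float = 0.0
    #: minimum bp between the footprints of distinct events (NCO placement is
    #: rejection-sampled); keeps independent events from superimposing into
    #: composite signals, so ground truth and genotype signal correspond 1:1.
    event_separation: float = 3500.0
    #: a CO's conversion tract is bounded this many bp short of an adjacent
    #: exchange point (repair tracts are local to their own DSB).
    co_tract_guard: float = 1500.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.expected_co_count < 0:
            raise ValueError("expected_co_count must be >= 0")
        if self.interference_shape < 1:
            raise ValueError("interference_shape must be >= 1")
        if not 0 < self.co_fraction_of_events <= 1:
            raise ValueError("co_fraction_of_events must be in (0, 1]")
        for name in ("missing_rate", "error_rate", "four_to_zero_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.event_mix is None:
            object.__setattr__(self, "event_mix",
                               EventMixture(co_fraction=self.co_fraction_of_events))


@dataclass(frozen=True)
class TrueTract:
    chromatid: int
    start: int
    end: int
    clipped: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GroundTruthEvent:
    chromosome: str
    kind: str                      # "CO" | "NCO"
    subtypes: frozenset[str]       # e.g. {"with_tract"}, {"two_chromatid"}
    chromatids: frozenset[int]     # CO: the two exchanged chromatids
    position: float                # breakpoint (CO) or initiation site (NCO)
    tracts: tuple[TrueTract, ...]

    def __post_init__(self) -> None:
        if self.kind == "CO" and len(self.chromatids) != 2:
            raise ValueError("a CO names exactly two chromatids")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator did, recorded before any noise."""

    events: tuple[GroundTruthEvent, ...]

    def co_events(self) -> list[GroundTruthEvent]:
        return [e for e in self.events if e.kind == "CO"]

    def nco_events(self) -> list[GroundTruthEvent]:
        return [e for e in self.events if e.kind == "NCO"]

    @property
    def co_count(self) -> int:
        return len(self.co_events())

    def co_positions(self) -> dict[str, np.ndarray]:
        """Sorted crossover breakpoints per chromosome."""
        out: dict[str, list[float]] = {}
        for e in self.co_events():
            out.setdefault(e.chromosome, []).append(e.position)
        return {c: np.sort(np.array(p)) for c, p in out.items()}


def _draw_length(rng: np.random.Generator, fit: LogNormalFit) -> int:
    return max(1, int(round(rng.lognormal(fit.mu, fit.sigma))))


def _clip_tract(chromatid: int, start: int, end: int, chrom_len: int) -> TrueTract:
    clipped = start < 1 or end > chrom_len
    return TrueTract(chromatid=chromatid, start=max(start, 1),
                     end=min(end, chrom_len), clipped=clipped)


def _renewal_points(rng: np.random.Generator, chrom_len: int,
                    shape: float, mean_spacing: float) -> list[float]:
    """Stationary gamma renewal process on [0, chrom_len].

    The first point is U * Y with Y a length-biased spacing (gamma with shape
    k+1): the interval covering a stationary origin is length-biased and the
    origin sits uniformly within it, so the process carries no edge artifact
    even on chromosomes shorter than the mean spacing.
    """
    theta = mean_spacing / shape
    x = rng.uniform() * rng.gamma(shape + 1.0, theta)
    points = []
    while x <= chrom_len:
        points.append(float(x))
        x += rng.gamma(shape, theta)
    return points


_CHROMATID_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def simulate_tetrad(snp_map: SnpMap, profile: SimulationProfile,
                    seed: int | None = None,
                    ) -> tuple[TetradGenotypes, GroundTruth]:
    """Simulate one meiosis: genotypes for four spores plus full ground truth.

    ``seed`` overrides ``profile.seed`` when given.  Output genotypes are
    noise-free; apply :func:`add_noise` separately.
    """
    if seed is None:
        seed = profile.seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(snp_map.chromosomes) + 1)
    mix = profile.event_mix
    total_len = snp_map.total_length
    events: list[GroundTruthEvent] = []

    # footprints of placed events, per chromosome, for separation checks
    footprints: dict[str, list[tuple[float, float]]] = {n: []
                                                        for n in snp_map.names}

    # --- crossovers, chromosome by chromosome -----------------------------
    guard = profile.co_tract_guard
    for i, (name, length) in enumerate(snp_map.chromosomes):
        rng = np.random.default_rng(children[i])
        if profile.expected_co_count <= 0:
            continue
        mean_spacing = total_len / profile.expected_co_count
        xs = _renewal_points(rng, length, profile.interference_shape,
                             mean_spacing)
        # A CO exchanges arms between one molecule locally carrying P1 and one
        # locally carrying P2, so track who carries P1 while sweeping left to
        # right: after each exchange the two partners trade membership.
        p1_carriers = [0, 1]
        for k, x in enumerate(xs):
            p2_carriers = [c for c in range(4) if c not in p1_carriers]
            a = p1_carriers[int(rng.integers(0, 2))]
            b = p2_carriers[int(rng.integers(0, 2))]
            p1_carriers = sorted(set(p1_carriers) - {a} | {b})
            # tracts stay on this CO's side of the midpoint to the adjacent
            # exchange points, leaving a clear zone >= guard bp between the
            # tract sets of neighbouring COs
            left_limit = (x + xs[k - 1]) / 2 + guard / 2 if k > 0 else 1.0
            right_limit = ((x + xs[k + 1]) / 2 - guard / 2
                           if k + 1 < len(xs) else float(length))
            left_span = max(0, int(math.floor(x)) - int(math.ceil(left_limit)) + 1)
            right_span = max(0, int(math.floor(right_limit)) - int(math.floor(x)))
            tracts: list[TrueTract] = []
            subtypes: set[str] = set()
            if rng.random() < mix.co_with_tract:
                tl = _draw_length(rng, profile.tract_fit_co)
                chtd = a if rng.random() < 0.5 else b
                sides = [s for s, span in (("L", left_span), ("R", right_span))
                         if span >= tl]
                if sides:
                    side = sides[int(rng.integers(0, len(sides)))]
                    truncated = False
                elif right_span >= left_span:
                    side, tl, truncated = "R", max(1, right_span), True
                else:
                    side, tl, truncated = "L", max(1, left_span), True
                if side == "R":
                    start = int(math.floor(x)) + 1
                    end = start + tl - 1
                else:
                    end = int(math.floor(x))
                    start = end - tl + 1
                t = _clip_tract(chtd, start, end, length)
                if truncated:
                    t = TrueTract(t.chromatid, t.start, t.end, clipped=True)
                tracts.append(t)
                subtypes.add("with_tract")
            if rng.random() < mix.co_third_strand:
                # a separate tract on an uninvolved chromatid, close enough to
                # the exchange to merge with it but not overlapping the main
                # tract (overlap would superimpose two conversions)
                tl = _draw_length(rng, profile.tract_fit_nco_with_co)
                third = [c for c in range(4) if c not in (a, b)]
                chtd = third[int(rng.integers(0, 2))]
                gap = int(rng.integers(50, 501))
                if "with_tract" in subtypes:
                    go_right = side == "L"
                else:
                    go_right = rng.random() < 0.5
                if go_right:
                    start = int(math.floor(x)) + 1 + gap
                    end = min(start + tl - 1, int(math.floor(right_limit)))
                else:
                    end = int(math.floor(x)) - gap
                    start = max(end - tl + 1, int(math.ceil(left_limit)))
                if end >= start:
                    t = _clip_tract(chtd, start, end, length)
                    if t.length < tl:
                        t = TrueTract(t.chromatid, t.start, t.end, clipped=True)
                    tracts.append(t)
                    subtypes.add("third_strand")
            events.append(GroundTruthEvent(
                chromosome=name, kind="CO", subtypes=frozenset(subtypes),
                chromatids=frozenset((a, b)), position=x, tracts=tuple(tracts)))
            span_lo = min([x] + [float(t.start) for t in tracts])
            span_hi = max([x] + [float(t.end) for t in tracts])
            footprints[name].append((span_lo, span_hi))

    # --- non-crossovers, genome-wide --------------------------------------
    rng_g = np.random.default_rng(children[-1])
    f = profile.co_fraction_of_events
    if profile.expected_co_count > 0 and f < 1:
        n_nco = int(rng_g.poisson(profile.expected_co_count * (1 - f) / f))
    else:
        n_nco = 0
    lengths = np.array([length for _, length in snp_map.chromosomes], dtype=float)
    weights = lengths / lengths.sum()
    sep = profile.event_separation

    def _clear(name: str, lo: float, hi: float) -> bool:
        return all(hi < a - sep or lo > b + sep for a, b in footprints[name])

    for _ in range(n_nco):
        u = rng_g.random()
        if u < profile.four_to_zero_rate:
            subtypes, n_tracts = frozenset({"four_to_zero"}), 2
            homolog = int(rng_g.integers(0, 2))
            chtds = (0, 1) if homolog == 0 else (2, 3)
            fit = profile.tract_fit_nco
        elif u < profile.four_to_zero_rate + mix.nco_two_chromatid:
            subtypes, n_tracts = frozenset({"two_chromatid"}), 2
            chtds = _CHROMATID_PAIRS[int(rng_g.integers(0, 6))]
            fit = profile.tract_fit_nco_2chtd
        else:
            subtypes, n_tracts = frozenset({"simple"}), 1
            chtds = (int(rng_g.integers(0, 4)),)
            fit = profile.tract_fit_nco
        # rejection placement: keep the footprint clear of existing events
        for _attempt in range(200):
            ci = int(rng_g.choice(len(lengths), p=weights))
            name, length = snp_map.chromosomes[ci]
            site = int(rng_g.integers(1, length + 1))
            if "four_to_zero" in subtypes:
                tl = _draw_length(rng_g, fit)
                start = site - tl // 2
                tracts = tuple(_clip_tract(c, start, start + tl - 1, length)
                               for c in chtds)
            elif "two_chromatid" in subtypes:
                # two disjoint tracts flanking the initiation site
                l1 = _draw_length(rng_g, fit)
                l2 = _draw_length(rng_g, fit)
                g1, g2 = (int(g) for g in rng_g.integers(50, 501, size=2))
                tracts = (_clip_tract(chtds[0], site - g1 - l1 + 1, site - g1,
                                      length),
                          _clip_tract(chtds[1], site + g2, site + g2 + l2 - 1,
                                      length))
            else:
                tl = _draw_length(rng_g, fit)
                start = site - tl // 2
                tracts = (_clip_tract(chtds[0], start, start + tl - 1, length),)
            lo = min(float(t.start) for t in tracts)
            hi = max(float(t.end) for t in tracts)
            if _clear(name, lo, hi):
                break
        events.append(GroundTruthEvent(
            chromosome=name, kind="NCO", subtypes=subtypes,
            chromatids=frozenset(chtds), position=float(site), tracts=tracts))
        footprints[name].append((lo, hi))

    # --- genotype matrices -------------------------------------------------
    calls: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[GroundTruthEvent]] = {n: [] for n in snp_map.names}
    for e in events:
        by_chrom[e.chromosome].append(e)
    for name, length in snp_map.chromosomes:
        pos = snp_map.positions[name]
        H = np.zeros((len(pos), 4), dtype=np.int8)
        H[:, 2:] = P2
        cos = sorted((e for e in by_chrom[name] if e.kind == "CO"),
                     key=lambda e: e.position)
        for e in cos:
            a, b = sorted(e.chromatids)
            ci = int(np.searchsorted(pos, e.position, side="right"))
            tmp = H[ci:, a].copy()
            H[ci:, a] = H[ci:, b]
            H[ci:, b] = tmp
        for e in by_chrom[name]:
            for t in e.tracts:
                lo = int(np.searchsorted(pos, t.start, side="left"))
                hi = int(np.searchsorted(pos, t.end, side="right"))
                H[lo:hi, t.chromatid] ^= 1
        calls[name] = H

    return (TetradGenotypes(snp_map=snp_map, calls=calls),
            GroundTruth(events=tuple(events)))


def add_noise(tetrad: TetradGenotypes, missing_rate: float, error_rate: float,
              seed: int | None = None) -> TetradGenotypes:
    """Independently drop calls to MISSING and flip surviving calls.

    Each call becomes MISSING with ``missing_rate``; otherwise it is flipped
    to the other parent with ``error_rate``.  Rates must lie in [0, 1).
    """
    for name, v in (("missing_rate", missing_rate), ("error_rate", error_rate)):
        if not 0 <= v < 1:
            raise ValueError(f"{name} must be in [0, 1), got {v}")
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for name, arr in tetrad.calls.items():
        noisy = arr.copy()
        if missing_rate > 0:
            drop = rng.random(arr.shape) < missing_rate
            noisy[drop] = MISSING
        if error_rate > 0:
            flip = (rng.random(arr.shape) < error_rate) & (noisy != MISSING)
            noisy[flip] ^= 1
        out[name] = noisy
    return replace(tetrad, calls=out)
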