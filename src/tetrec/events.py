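"""Recombination event calling from four-spore genotype matrices.

A marker where all four chromatids are called is classified by its P1:P2
segregation ratio; 2:2 is the Mendelian expectation, 3:1/1:3 marks a gene
conversion and 4:0/0:4 a conversion of both chromatids of one homolog.
Markers with any missing call are INCOMPLETE: they are skipped for
segregation but retained as coordinates.

Calling proceeds per chromosome:

1. crossover breakpoints: between consecutive informative 2:2 markers whose
   "pairing pattern" (which two chromatids carry P1) differs.  A pattern
   change flipping two chromatids — necessarily one per homolog — is one CO;
   flipping all four is a four-chromatid double CO.  The breakpoint
   coordinate is the midpoint of the two flanking informative markers.
2. conversion tracts: maximal runs of consecutive informative non-2:2
   markers.  Within a run, each marker's converted chromatids are read
   against the flanking 2:2 background (the side giving the smaller
   deviation set; ties go left — the two readings of a CO-abutting tract
   name different single chromatids but yield the same event).  Consecutive
   converted markers on one chromatid form a tract: core = first..last
   converted marker, maximal interval = the innermost flanking 2:2 markers
   (or the chromosome edge when a run touches an end).
3. merging: tracts and breakpoints within ``merge_distance`` of one another
   (end-to-end, nearest core boundaries; breakpoint position for tract-less
   COs) are merged transitively into single events, and subtype flags are
   assigned: an event is a CO if it contains any breakpoint; an NCO tract
   merged onto a CO on an uninvolved chromatid is flagged
   ``nco_on_third_strand`` and the event counts as a CO.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome import MISSING, TetradGenotypes

__all__ = [
    "SEG_2_2", "SEG_3_1", "SEG_1_3", "SEG_4_0", "SEG_0_4", "SEG_INCOMPLETE",
    "ConversionTract",
    "CrossoverBreakpoint",
    "RecombinationEvent",
    "EventTally",
    "InterferenceFit",
    "classify_segregation",
    "segregation_classes",
    "call_events",
    "tally_events",
    "mean_co_count",
    "mean_co_fraction",
    "intercrossover_distances",
    "fit_interference",
]

SEG_2_2 = "2:2"
SEG_3_1 = "3:1"
SEG_1_3 = "1:3"
SEG_4_0 = "4:0"
SEG_0_4 = "0:4"
SEG_INCOMPLETE = "INCOMPLETE"

# number of set bits for each 4-bit chromatid mask
_POPCOUNT = np.array([bin(i).count("1") for i in range(16)], dtype=np.int8)
_BIT_WEIGHTS = np.array([1, 2, 4, 8], dtype=np.int8)


@dataclass
class ConversionTract:
    """A gene-conversion tract on one chromatid (1-based inclusive bp).

    ``core_*`` span the first..last converted marker; ``max_*`` are the
    innermost flanking 2:2 markers (0 / chromosome length + 1 at chromosome
    edges), strictly outside the core.  ``estimated_length`` is filled by the
    tract-length estimator.
    """

    chromosome: str
    chromatid: int
    core_start: int
    core_end: int
    max_start: int
    max_end: int
    n_markers: int
    has_4_0: bool = False
    estimated_length: int | None = None

    def __post_init__(self) -> None:
        if not (self.max_start < self.core_start <= self.core_end < self.max_end):
            raise ValueError(
                f"need max_start < core_start <= core_end < max_end, got "
                f"({self.max_start}, {self.core_start}, {self.core_end}, {self.max_end})")
        if self.n_markers < 1:
            raise ValueError("a tract spans at least one marker")

    @property
    def core_length(self) -> int:
        return self.core_end - self.core_start + 1

    @property
    def max_length(self) -> int:
        return self.max_end - self.max_start + 1


@dataclass(frozen=True)
class CrossoverBreakpoint:
    """A reciprocal exchange between two chromatids, one per homolog."""

    chromosome: str
    position: float               # midpoint of flanking informative markers
    chromatids: frozenset[int]


@dataclass
class RecombinationEvent:
    chromosome: str
    kind: str                     # "CO" | "NCO"
    chromatids: frozenset[int]
    tracts: list[ConversionTract] = field(default_factory=list)
    breakpoints: list[CrossoverBreakpoint] = field(default_factory=list)
    co_no_tract: bool = False
    two_strand_nco: bool = False
    four_to_zero: bool = False
    discontinuous: bool = False
    four_strand_double_co: bool = False
    nco_on_third_strand: bool = False
    single_snp: bool = False

    @property
    def start(self) -> float:
        coords = [t.core_start for t in self.tracts]
        coords += [b.position for b in self.breakpoints]
        return min(coords)

    @property
    def end(self) -> float:
        coords = [t.core_end for t in self.tracts]
        coords += [b.position for b in self.breakpoints]
        return max(coords)


@dataclass(frozen=True)
class EventTally:
    """Event-type counts per tetrad (the standard taxonomy columns)."""

    nco_total: int
    four_to_zero: int
    two_strand_nco: int
    nco_disc: int
    nco_gc1snp: int
    co_total: int
    co_no_tract: int
    nco_on_third_strand: int
    four_strand_double_co: int
    co_disc: int
    co_gc1snp: int
    gc_total: int
    total_events: int

    def __post_init__(self) -> None:
        if self.total_events != self.nco_total + self.co_total:
            raise ValueError("total_events must equal nco_total + co_total")

    @property
    def co_fraction(self) -> float:
        return self.co_total / self.total_events


@dataclass(frozen=True)
class InterferenceFit:
    """Gamma fit to pooled inter-crossover distances (shape 1 = no interference)."""

    shape: float
    scale: float
    n_distances: int

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")


# ---------------------------------------------------------------------------
# segregation
# ---------------------------------------------------------------------------

def classify_segregation(tetrad: TetradGenotypes, chromosome: str,
                         marker_index: int) -> str:
    """Segregation class of one marker: counts P1 vs P2 among non-missing calls."""
    row = tetrad.calls[chromosome][marker_index]
    if np.any(row == MISSING):
        return SEG_INCOMPLETE
    n_p2 = int(row.sum())
    return {0: SEG_4_0, 1: SEG_3_1, 2: SEG_2_2, 3: SEG_1_3, 4: SEG_0_4}[n_p2]


def segregation_classes(calls: np.ndarray) -> np.ndarray:
    """Vectorized segregation classes for a (markers x 4) call matrix."""
    out = np.full(calls.shape[0], SEG_INCOMPLETE, dtype=object)
    complete = (calls != MISSING).all(axis=1)
    n_p2 = calls[complete].sum(axis=1)
    labels = np.array([SEG_4_0, SEG_3_1, SEG_2_2, SEG_1_3, SEG_0_4], dtype=object)
    out[complete] = labels[n_p2]
    return out


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def _bits(mask: int) -> tuple[int, ...]:
    return tuple(c for c in range(4) if mask >> c & 1)


@dataclass
class _Item:
    start: float
    end: float
    breakpoint: CrossoverBreakpoint | None = None
    tract: ConversionTract | None = None
    run_id: int = -1              # run index, to detect discontinuity


def _call_chromosome(chrom: str, pos: np.ndarray, calls: np.ndarray,
                     chrom_len: int, merge_distance: float,
                     ) -> list[RecombinationEvent]:
    complete = (calls != MISSING).all(axis=1)
    if not complete.any():
        warnings.warn(f"chromosome {chrom!r}: all markers incomplete; "
                      "no events called", stacklevel=3)
        return []
    idx = np.nonzero(complete)[0]          # informative marker indices
    mask = (calls[idx].astype(np.int16) * _BIT_WEIGHTS).sum(axis=1)
    pop = _POPCOUNT[mask]
    is22 = pop == 2

    items: list[_Item] = []

    # crossover breakpoints from pattern changes between 2:2 markers
    j22 = np.nonzero(is22)[0]
    m22 = mask[j22]
    if j22.size >= 2:
        for c in np.nonzero(m22[:-1] != m22[1:])[0]:
            xor = int(m22[c] ^ m22[c + 1])
            mid = 0.5 * (pos[idx[j22[c]]] + pos[idx[j22[c + 1]]])
            chtds = _bits(xor)
            if len(chtds) == 2:
                bps = [frozenset(chtds)]
            else:
                # all four chromatids switch: two COs; pairing across homologs
                # is not identifiable, pair P1-copies with P2-copies arbitrarily
                p1 = [c_ for c_ in chtds if c_ < 2]
                p2 = [c_ for c_ in chtds if c_ >= 2]
                bps = [frozenset((p1[0], p2[0])), frozenset((p1[1], p2[1]))]
            for pair in bps:
                items.append(_Item(start=mid, end=mid, breakpoint=
                                   CrossoverBreakpoint(chrom, mid, pair)))

    # conversion tracts from runs of non-2:2 informative markers
    non22 = np.nonzero(~is22)[0]
    if non22.size:
        splits = np.nonzero(np.diff(non22) > 1)[0]
        run_bounds = zip(np.insert(non22[splits + 1], 0, non22[0]),
                         np.append(non22[splits], non22[-1]))
        for run_id, (s, e) in enumerate(run_bounds):
            left22 = j22[j22 < s]
            right22 = j22[j22 > e]
            bg_left = int(mask[left22[-1]]) if left22.size else None
            bg_right = int(mask[right22[0]]) if right22.size else None
            if bg_left is None and bg_right is None:
                warnings.warn(f"chromosome {chrom!r}: no 2:2 marker flanks a "
                              "conversion run; run skipped", stacklevel=3)
                continue
            flank_lo = int(pos[idx[left22[-1]]]) if left22.size else 0
            flank_hi = int(pos[idx[right22[0]]]) if right22.size else chrom_len + 1
            run = np.arange(s, e + 1)
            conv = np.zeros((run.size, 4), dtype=bool)
            has40 = pop[run] % 4 == 0          # 4:0 or 0:4 markers
            for k, j in enumerate(run):
                dev_l = mask[j] ^ bg_left if bg_left is not None else None
                dev_r = mask[j] ^ bg_right if bg_right is not None else None
                if dev_l is None:
                    dev = dev_r
                elif dev_r is None or _POPCOUNT[dev_l] <= _POPCOUNT[dev_r]:
                    dev = dev_l
                else:
                    dev = dev_r
                for c in _bits(int(dev)):
                    conv[k, c] = True
            for c in range(4):
                where = np.nonzero(conv[:, c])[0]
                if not where.size:
                    continue
                breaks = np.nonzero(np.diff(where) > 1)[0]
                starts = np.insert(where[breaks + 1], 0, where[0])
                ends = np.append(where[breaks], where[-1])
                for a, b in zip(starts, ends):
                    core_lo = int(pos[idx[run[a]]])
                    core_hi = int(pos[idx[run[b]]])
                    tract = ConversionTract(
                        chromosome=chrom, chromatid=c,
                        core_start=core_lo, core_end=core_hi,
                        max_start=flank_lo, max_end=flank_hi,
                        n_markers=int(b - a + 1),
                        has_4_0=bool(has40[a:b + 1].any()))
                    items.append(_Item(start=core_lo, end=core_hi,
                                       tract=tract, run_id=run_id))

    if not items:
        return []

    # transitive (single-linkage) merge along the chromosome
    items.sort(key=lambda it: (it.start, it.end))
    clusters: list[list[_Item]] = [[items[0]]]
    reach = items[0].end
    for it in items[1:]:
        if it.start - reach <= merge_distance:
            clusters[-1].append(it)
        else:
            clusters.append([it])
            reach = it.end
        reach = max(reach, it.end)

    events = []
    for cluster in clusters:
        bps = [it.breakpoint for it in cluster if it.breakpoint is not None]
        tracts = [it.tract for it in cluster if it.tract is not None]
        kind = "CO" if bps else "NCO"
        co_chtds: set[int] = set()
        for b in bps:
            co_chtds |= b.chromatids
        chromatids = co_chtds | {t.chromatid for t in tracts}
        tract_chtds = {t.chromatid for t in tracts}
        by_chtd: dict[int, list[int]] = {}
        for it in cluster:
            if it.tract is not None:
                by_chtd.setdefault(it.tract.chromatid, []).append(it.run_id)
        disc = any(len(set(runs)) > 1 for runs in by_chtd.values())
        events.append(RecombinationEvent(
            chromosome=chrom, kind=kind, chromatids=frozenset(chromatids),
            tracts=tracts, breakpoints=bps,
            co_no_tract=kind == "CO" and not tracts,
            two_strand_nco=kind == "NCO" and len(tract_chtds) == 2,
            four_to_zero=any(t.has_4_0 for t in tracts),
            discontinuous=disc,
            four_strand_double_co=len(bps) >= 2 and len(co_chtds) == 4,
            nco_on_third_strand=kind == "CO" and bool(tract_chtds - co_chtds),
            single_snp=any(t.n_markers == 1 for t in tracts)))
    return events


def call_events(tetrad: TetradGenotypes,
                merge_distance: float = 3000.0) -> list[RecombinationEvent]:
    """Detect and classify all recombination events in one tetrad."""
    events: list[RecombinationEvent] = []
    lengths = tetrad.snp_map.lengths
    for chrom in tetrad.snp_map.names:
        events.extend(_call_chromosome(
            chrom, tetrad.snp_map.positions[chrom], tetrad.calls[chrom],
            lengths[chrom], merge_distance))
    return events


# ---------------------------------------------------------------------------
# tallies and interference
# ---------------------------------------------------------------------------

def tally_events(events) -> EventTally:
    """Count events per the standard taxonomy columns."""
    cos = [e for e in events if e.kind == "CO"]
    ncos = [e for e in events if e.kind == "NCO"]
    return EventTally(
        nco_total=len(ncos),
        four_to_zero=sum(e.four_to_zero for e in ncos),
        two_strand_nco=sum(e.two_strand_nco for e in ncos),
        nco_disc=sum(e.discontinuous for e in ncos),
        nco_gc1snp=sum(e.single_snp for e in ncos),
        co_total=len(cos),
        co_no_tract=sum(e.co_no_tract for e in cos),
        nco_on_third_strand=sum(e.nco_on_third_strand for e in cos),
        four_strand_double_co=sum(e.four_strand_double_co for e in cos),
        co_disc=sum(e.discontinuous for e in cos),
        co_gc1snp=sum(e.single_snp for e in cos),
        gc_total=sum(bool(e.tracts) for e in cos),
        total_events=len(events))


def mean_co_count(tallies) -> float:
    """Mean CO count over a group of tetrad tallies."""
    return float(np.mean([t.co_total for t in tallies]))


def mean_co_fraction(tallies) -> float:
    """Mean per-tetrad CO fraction of total events over a group of tallies."""
    return float(np.mean([t.co_fraction for t in tallies]))


def intercrossover_distances(co_positions_per_tetrad) -> np.ndarray:
    """Pool adjacent-CO distances (bp) within chromosomes across tetrads.

    Input: an iterable of dicts mapping chromosome -> sorted CO positions
    (one dict per tetrad), e.g. ``GroundTruth.co_positions()`` or positions
    collected from called breakpoints.
    """
    out: list[np.ndarray] = []
    for per_chrom in co_positions_per_tetrad:
        for positions in per_chrom.values():
            p = np.sort(np.asarray(positions, dtype=float))
            if p.size >= 2:
                out.append(np.diff(p))
    return np.concatenate(out) if out else np.array([])


def fit_interference(distances) -> InterferenceFit:
    """Maximum-likelihood gamma fit to pooled inter-crossover distances.

    Shape 1 means no interference; larger shapes mean more even spacing.
    Requires at least 20 pooled distances — with few COs per tetrad, pool
    distances across tetrads before fitting.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 20:
        raise ValueError(
            f"only {d.size} inter-crossover distances; need >= 20 — pool "
            "distances across tetrads to fit interference")
    shape, _, scale = stats.gamma.fit(d, floc=0)
    return InterferenceFit(shape=float(shape), scale=float(scale),
                           n_distances=int(d.size))
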