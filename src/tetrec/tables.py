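"""Transcribed study inputs: per-tetrad event tallies and tract summaries.

These printed values are inputs to the analysis (anchors for regressions,
defaults for the simulator) — nothing here is computed by this package.

``EVENT_TALLIES`` holds the eight sequenced tetrads (three wild type, two
high-functioning and three low-functioning hypomorphs) in the standard
taxonomy columns.  ``TRACT_SUMMARIES`` holds the fitted tract-length
distributions as (average, 95% interval) in bp, per activity group and event
class; the average equals exp(mu), the geometric mean of the interval bounds,
so each row inverts exactly to a (mu, sigma) pair via
:func:`~tetrec.distributions.lognormal_from_interval`.
"""

from __future__ import annotations

import numpy as np

from .distributions import LogNormalFit, lognormal_from_interval
from .events import EventTally

__all__ = [
    "EVENT_TALLIES",
    "TETRAD_GROUPS",
    "TRACT_SUMMARIES",
    "GROUP_MEAN_CO_COUNT",
    "GROUP_MEAN_CO_FRACTION",
    "tract_fit",
    "anchor_points",
]


def _tally(nco, n40, n2s, ndisc, n1snp, co, cont, n3rd, c4s, cdisc, c1snp,
           gc, total) -> EventTally:
    return EventTally(nco_total=nco, four_to_zero=n40, two_strand_nco=n2s,
                      nco_disc=ndisc, nco_gc1snp=n1snp, co_total=co,
                      co_no_tract=cont, nco_on_third_strand=n3rd,
                      four_strand_double_co=c4s, co_disc=cdisc,
                      co_gc1snp=c1snp, gc_total=gc, total_events=total)


#: Eight sequenced tetrads: event counts per taxonomy column.
EVENT_TALLIES: dict[str, EventTally] = {
    "WT29":       _tally(59, 1, 5, 4, 9, 92, 23, 10, 1, 9, 8, 69, 151),
    "WT30":       _tally(40, 0, 4, 0, 7, 94, 29, 6, 1, 8, 12, 65, 134),
    "WT46":       _tally(46, 1, 4, 1, 12, 90, 22, 4, 0, 14, 11, 68, 136),
    "HI-217-31":  _tally(35, 0, 3, 2, 1, 83, 26, 2, 0, 6, 6, 57, 118),
    "HI-217-24":  _tally(24, 0, 5, 0, 2, 78, 22, 4, 1, 8, 9, 55, 102),
    "LO-32-31a":  _tally(13, 0, 2, 1, 0, 58, 16, 2, 0, 8, 5, 42, 71),
    "LO-32-31b":  _tally(18, 0, 2, 0, 3, 54, 13, 3, 0, 2, 4, 41, 72),
    "LO-217-24":  _tally(17, 0, 2, 0, 3, 50, 15, 6, 0, 8, 4, 35, 67),
}

#: Activity-group membership of the eight tetrads.
TETRAD_GROUPS: dict[str, tuple[str, ...]] = {
    "WT": ("WT29", "WT30", "WT46"),
    "HI": ("HI-217-31", "HI-217-24"),
    "LO": ("LO-32-31a", "LO-32-31b", "LO-217-24"),
}

#: Fitted tract-length summaries: (average bp, (95% lower, 95% upper)).
#: Keys: activity group ("WT"/"HI"/"LO", extrapolated "30CO"/"10CO"/"3CO",
#: or "POOLED" for the complex classes) then event class.
TRACT_SUMMARIES: dict[str, dict[str, tuple[float, tuple[float, float]]]] = {
    "WT":   {"NCO": (1649, (382, 7124)),   "CO": (1906, (435, 8350))},
    "HI":   {"NCO": (1515, (228, 10068)),  "CO": (1962, (427, 9010))},
    "LO":   {"NCO": (1357, (87, 21191)),   "CO": (2222, (334, 14775))},
    "30CO": {"NCO": (1180, (35, 39656)),   "CO": (2427, (287, 20523))},
    "10CO": {"NCO": (1037, (16, 66055)),   "CO": (5497, (525, 57591))},
    "3CO":  {"NCO": (987, (12, 78627)),    "CO": (14879, (1318, 168011))},
    "POOLED": {"NCO_2CHTD": (2436, (428, 13869)),
               "NCO_W_CO":  (2575, (244, 27149))},
}

#: Mean CO count per activity group (per-tetrad means of the raw tallies).
GROUP_MEAN_CO_COUNT: dict[str, float] = {
    g: float(np.mean([EVENT_TALLIES[t].co_total for t in members]))
    for g, members in TETRAD_GROUPS.items()
}

#: Mean per-tetrad CO fraction of total events per activity group.
GROUP_MEAN_CO_FRACTION: dict[str, float] = {
    g: float(np.mean([EVENT_TALLIES[t].co_fraction for t in members]))
    for g, members in TETRAD_GROUPS.items()
}


def tract_fit(group: str, event_class: str) -> LogNormalFit:
    """(mu, sigma) reconstructed from the printed 95% interval of one class."""
    _, (lo, hi) = TRACT_SUMMARIES[group][event_class]
    return lognormal_from_interval(lo, hi)


def anchor_points(event_class: str) -> list[tuple[float, LogNormalFit]]:
    """(CO count, fit) anchors over WT/HI/LO for extrapolation regressions."""
    return [(GROUP_MEAN_CO_COUNT[g], tract_fit(g, event_class))
            for g in ("WT", "HI", "LO")]
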