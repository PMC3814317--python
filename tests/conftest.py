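"""Shared fixtures: the default study-scale genome and a batch of simulated
tetrads with ground truth, plus a truth-side oracle for the number of
genotype-visible crossovers (used to validate the caller)."""

from __future__ import annotations

import numpy as np
import pytest

from tetrec import (SimulationProfile, call_events, generate_snp_map,
                    simulate_tetrad)

N_BATCH = 500


@pytest.fixture(scope="session")
def snp_map():
    """Study-scale hybrid map: 16 chromosomes, ~55k markers over ~12 Mb."""
    return generate_snp_map(seed=11)


@pytest.fixture(scope="session")
def wt_profile():
    return SimulationProfile()


@pytest.fixture(scope="session")
def tetrad_batch(snp_map, wt_profile):
    """500 wild-type-like tetrads (noise-free genotypes + ground truth)."""
    return [simulate_tetrad(snp_map, wt_profile, seed=20_000 + i)
            for i in range(N_BATCH)]


@pytest.fixture(scope="session")
def called_batch(tetrad_batch):
    """Events called on every tetrad of the batch (noise-free)."""
    return [call_events(genotypes) for genotypes, _ in tetrad_batch]


def visible_co_count(snp_map, truth) -> int:
    """Crossover breakpoints recoverable from genotypes, from truth alone.

    A CO is visible iff at least one marker lies on each side of the
    breakpoint outside the event's own conversion tracts (such markers
    segregate 2:2).  Adjacent COs with no marker between their breakpoints
    compose: each shared chromatid hides one exchange (two-strand double COs
    restore the parental configuration entirely).
    """
    n = 0
    by_chrom: dict[str, list] = {}
    for e in truth.co_events():
        by_chrom.setdefault(e.chromosome, []).append(e)
    for chrom, cos in by_chrom.items():
        pos = snp_map.positions[chrom]
        cos.sort(key=lambda e: e.position)
        total = 0
        for e in cos:
            visible = True
            for side in "LR":
                cand = pos[pos < e.position] if side == "L" else pos[pos > e.position]
                for t in e.tracts:
                    cand = cand[(cand < t.start) | (cand > t.end)]
                visible &= cand.size > 0
            total += visible
        for e1, e2 in zip(cos[:-1], cos[1:]):
            if not np.any((pos > e1.position) & (pos < e2.position)):
                total -= len(e1.chromatids & e2.chromatids)
        n += max(total, 0)
    return n
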