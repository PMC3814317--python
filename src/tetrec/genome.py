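"""SNP maps for a hybrid diploid: marker positions distinguishing two parents.

The default genome mirrors an S96 x YJM789-like *S. cerevisiae* hybrid:
16 chromosomes totalling ~12.07 Mb carrying ~55,000 biallelic markers, i.e.
one informative SNP every ~220 bp.  All coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SnpMap",
    "TetradGenotypes",
    "generate_snp_map",
    "YEAST_CHROMOSOME_LENGTHS",
    "DEFAULT_MARKER_COUNT",
    "P1", "P2", "MISSING",
]

#: Genotype call codes: parental origin P1/P2, or missing.
P1: int = 0
P2: int = 1
MISSING: int = -1

#: Approximate S. cerevisiae (S288C) chromosome lengths in bp, chrI..chrXVI.
YEAST_CHROMOSOME_LENGTHS: tuple[int, ...] = (
    230_218, 813_184, 316_620, 1_531_933, 576_874, 270_161, 1_090_940,
    562_643, 439_888, 745_751, 666_816, 1_078_177, 924_431, 784_333,
    1_091_291, 948_066,
)

#: Genome-wide marker count of the hybrid the simulator emulates.
DEFAULT_MARKER_COUNT = 55_000


@dataclass(frozen=True)
class SnpMap:
    """Per-chromosome sorted marker positions of a two-parent hybrid.

    ``chromosomes`` is an ordered tuple of (name, length-in-bp);
    ``positions[name]`` is a strictly increasing int array of 1-based marker
    positions.  Every marker is biallelic with alleles labelled P1/P2.
    """

    chromosomes: tuple[tuple[str, int], ...]
    positions: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if set(lengths) != set(self.positions):
            raise ValueError("chromosome names and position keys disagree")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            pos = np.asarray(self.positions[name])
            if pos.size and (np.any(np.diff(pos) <= 0)):
                raise ValueError(f"positions not strictly increasing on {name!r}")
            if pos.size and (pos[0] < 1 or pos[-1] > length):
                raise ValueError(f"marker positions out of bounds on {name!r}")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    @property
    def total_markers(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def n_markers(self, chrom: str) -> int:
        return len(self.positions[chrom])


def generate_snp_map(n_chromosomes: int = 16,
                     chromosome_lengths=None,
                     marker_density: float | None = None,
                     seed: int | None = None) -> SnpMap:
    """Draw a random hybrid SNP map.

    Marker counts per chromosome are Poisson with mean ``length * density``;
    positions are uniform, deduplicated and sorted.  The default density
    reproduces ~55,000 markers over the default 16-chromosome yeast genome.

    Raises ``ValueError`` (naming the chromosome) if a chromosome ends up with
    zero markers — downstream analysis needs at least flanking markers.
    """
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    if chromosome_lengths is None:
        if n_chromosomes > len(YEAST_CHROMOSOME_LENGTHS):
            raise ValueError("no default lengths for more than 16 chromosomes")
        chromosome_lengths = YEAST_CHROMOSOME_LENGTHS[:n_chromosomes]
    chromosome_lengths = [int(x) for x in chromosome_lengths]
    if len(chromosome_lengths) != n_chromosomes:
        raise ValueError("chromosome_lengths must match n_chromosomes")
    if any(x <= 0 for x in chromosome_lengths):
        raise ValueError("chromosome lengths must be positive")
    if marker_density is None:
        marker_density = DEFAULT_MARKER_COUNT / sum(chromosome_lengths)
    if marker_density <= 0:
        raise ValueError("marker_density must be positive")

    rng = np.random.default_rng(seed)
    chromosomes = []
    positions: dict[str, np.ndarray] = {}
    for i, length in enumerate(chromosome_lengths):
        name = f"chr{i + 1:02d}"
        n = rng.poisson(length * marker_density)
        pos = np.unique(rng.integers(1, length + 1, size=n))
        if pos.size == 0:
            raise ValueError(f"chromosome {name!r} received zero markers; "
                             "increase marker_density or chromosome length")
        chromosomes.append((name, length))
        positions[name] = pos.astype(np.int64)
    return SnpMap(chromosomes=tuple(chromosomes), positions=positions)


@dataclass(frozen=True)
class TetradGenotypes:
    """Per-chromosome (markers x 4 chromatids) parental-origin call matrices.

    Calls are int8 with values P1 (0), P2 (1) or MISSING (-1); with zero
    noise and zero recombination events every marker segregates 2:2.
    """

    snp_map: SnpMap
    calls: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        for name in self.snp_map.names:
            arr = self.calls[name]
            if arr.ndim != 2 or arr.shape[1] != 4:
                raise ValueError(f"calls for {name!r} must be (markers, 4)")
            if arr.shape[0] != self.snp_map.n_markers(name):
                raise ValueError(f"marker count mismatch on {name!r}")
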