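"""Tab-separated file formats for maps, genotypes, events, truth and fits.

All coordinates in files are 1-based inclusive, except the BED export which
follows BED's 0-based half-open convention.  Files whose name ends in ``.gz``
are read and written gzip-compressed transparently.  Every writer emits
``#``-prefixed header comments carrying the package version and the
parameters (seed included) needed to reproduce the file; readers skip them.

Formats
-------
SNP map         chrom, pos
genotypes       chrom, pos, s1..s4 with values P1 | P2 | NA
events          one row per tract (or per tract-less CO), keyed by event_id
ground truth    one row per true tract (or tract-less event)
fits            class, mu, sigma, sd_mean, n
"""

from __future__ import annotations

import gzip

from importlib import metadata
from pathlib import Path

import numpy as np

from .distributions import LogNormalFit
from .events import ConversionTract, CrossoverBreakpoint, RecombinationEvent
from .genome import MISSING, P1, P2, SnpMap, TetradGenotypes
from .simulate import GroundTruth

__all__ = [
    "read_snp_map", "write_snp_map",
    "read_genotypes", "write_genotypes",
    "read_events", "write_events", "events_to_bed",
    "write_ground_truth",
    "read_fits", "write_fits",
]

try:
    _VERSION = metadata.version("tetrec")
except metadata.PackageNotFoundError:  # pragma: no cover
    _VERSION = "unknown"

_CALL_TO_TEXT = {P1: "P1", P2: "P2", MISSING: "NA"}
_TEXT_TO_CALL = {"P1": P1, "P2": P2, "NA": MISSING}

_FLAG_NAMES = ("co_no_tract", "two_strand_nco", "four_to_zero", "discontinuous",
               "four_strand_double_co", "nco_on_third_strand", "single_snp")


def _open_read(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _open_write(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "wt")


def _header_lines(kind: str, **params) -> list[str]:
    items = " ".join(f"{k}={v}" for k, v in params.items())
    line = f"# tetrec v{_VERSION} {kind}"
    return [line + (f" {items}" if items else "") + "\n"]


class ParseError(ValueError):
    """A malformed row; the message names the file and 1-based line number."""


def _rows(path, expected_fields: int):
    """Yield (line_number, fields) for data rows, validating the field count."""
    with _open_read(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != expected_fields:
                raise ParseError(f"{path}, line {lineno}: expected "
                                 f"{expected_fields} fields, got {len(fields)}")
            yield lineno, fields


# ---------------------------------------------------------------------------
# SNP map
# ---------------------------------------------------------------------------

def write_snp_map(snp_map: SnpMap, path, seed=None) -> None:
    with _open_write(path) as fh:
        lengths = ",".join(f"{name}:{length}" for name, length in snp_map.chromosomes)
        fh.writelines(_header_lines("snp_map", seed=seed, chrom_lengths=lengths))
        fh.write("chrom\tpos\n")
        for name in snp_map.names:
            for p in snp_map.positions[name]:
                fh.write(f"{name}\t{p}\n")


def _parse_chrom_lengths(path) -> dict[str, int] | None:
    with _open_read(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return None
            if "chrom_lengths=" in line:
                spec = line.split("chrom_lengths=", 1)[1].strip()
                out = {}
                for item in spec.split(","):
                    name, length = item.split(":")
                    out[name] = int(length)
                return out
    return None


def read_snp_map(path, chromosome_lengths: dict[str, int] | None = None) -> SnpMap:
    """Read a SNP map; lengths come from the header, the argument, or max(pos)."""
    if chromosome_lengths is None:
        chromosome_lengths = _parse_chrom_lengths(path)
    positions: dict[str, list[int]] = {}
    order: list[str] = []
    for lineno, fields in _rows(path, 2):
        chrom, pos = fields
        if chrom == "chrom":
            continue
        try:
            p = int(pos)
        except ValueError:
            raise ParseError(f"{path}, line {lineno}: bad position {pos!r}") from None
        if chrom not in positions:
            positions[chrom] = []
            order.append(chrom)
        positions[chrom].append(p)
    chroms = []
    arrays = {}
    for name in order:
        arr = np.asarray(positions[name], dtype=np.int64)
        if np.any(np.diff(arr) <= 0):
            raise ParseError(f"{path}: positions on {name!r} not strictly increasing")
        length = (chromosome_lengths or {}).get(name, int(arr[-1]))
        chroms.append((name, length))
        arrays[name] = arr
    return SnpMap(chromosomes=tuple(chroms), positions=arrays)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_genotypes(tetrad: TetradGenotypes, path, seed=None) -> None:
    with _open_write(path) as fh:
        lengths = ",".join(f"{n}:{l}" for n, l in tetrad.snp_map.chromosomes)
        fh.writelines(_header_lines("genotypes", seed=seed, chrom_lengths=lengths))
        fh.write("chrom\tpos\ts1\ts2\ts3\ts4\n")
        for name in tetrad.snp_map.names:
            pos = tetrad.snp_map.positions[name]
            calls = tetrad.calls[name]
            for i, p in enumerate(pos):
                vals = "\t".join(_CALL_TO_TEXT[int(c)] for c in calls[i])
                fh.write(f"{name}\t{p}\t{vals}\n")


def read_genotypes(path, chromosome_lengths: dict[str, int] | None = None,
                   ) -> TetradGenotypes:
    """Read a genotypes TSV back into a :class:`TetradGenotypes` (with map).

    Rows must be ``chrom, pos, s1..s4`` with calls in {P1, P2, NA}; positions
    must be strictly increasing within each chromosome (duplicates rejected).
    Malformed rows raise :class:`ParseError` naming the line.
    """
    if chromosome_lengths is None:
        chromosome_lengths = _parse_chrom_lengths(path)
    positions: dict[str, list[int]] = {}
    calls: dict[str, list[list[int]]] = {}
    order: list[str] = []
    for lineno, fields in _rows(path, 6):
        chrom, pos, *spores = fields
        if chrom == "chrom":
            continue
        try:
            p = int(pos)
        except ValueError:
            raise ParseError(f"{path}, line {lineno}: bad position {pos!r}") from None
        row = []
        for s in spores:
            if s not in _TEXT_TO_CALL:
                raise ParseError(f"{path}, line {lineno}: bad call {s!r} "
                                 "(expected P1, P2 or NA)")
            row.append(_TEXT_TO_CALL[s])
        if chrom not in positions:
            positions[chrom] = []
            calls[chrom] = []
            order.append(chrom)
        if positions[chrom] and p <= positions[chrom][-1]:
            raise ParseError(f"{path}, line {lineno}: position {p} not "
                             f"strictly increasing on {chrom!r}")
        positions[chrom].append(p)
        calls[chrom].append(row)
    chroms = []
    arrays = {}
    call_arrays = {}
    for name in order:
        arr = np.asarray(positions[name], dtype=np.int64)
        length = (chromosome_lengths or {}).get(name, int(arr[-1]))
        chroms.append((name, length))
        arrays[name] = arr
        call_arrays[name] = np.asarray(calls[name], dtype=np.int8)
    snp_map = SnpMap(chromosomes=tuple(chroms), positions=arrays)
    return TetradGenotypes(snp_map=snp_map, calls=call_arrays)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ("event_id", "chrom", "kind", "flags", "chromatids",
                  "breakpoints", "tract_chromatid", "core_start", "core_end",
                  "max_start", "max_end", "n_markers", "estimated_length")


def write_events(events, path, seed=None, **params) -> None:
    """One row per tract; tract-less events get one row with NA tract fields."""
    with _open_write(path) as fh:
        fh.writelines(_header_lines("events", seed=seed, **params))
        fh.write("\t".join(_EVENT_COLUMNS) + "\n")
        for eid, e in enumerate(events):
            flags = ",".join(n for n in _FLAG_NAMES if getattr(e, n)) or "-"
            chtds = ",".join(str(c) for c in sorted(e.chromatids))
            bps = ",".join(f"{b.position:.1f}:{min(b.chromatids)}-{max(b.chromatids)}"
                           for b in e.breakpoints) or "-"
            base = [str(eid), e.chromosome, e.kind, flags, chtds, bps]
            if e.tracts:
                for t in e.tracts:
                    est = "NA" if t.estimated_length is None else str(t.estimated_length)
                    fh.write("\t".join(base + [str(t.chromatid), str(t.core_start),
                                               str(t.core_end), str(t.max_start),
                                               str(t.max_end), str(t.n_markers),
                                               est]) + "\n")
            else:
                fh.write("\t".join(base + ["NA"] * 7) + "\n")


def read_events(path) -> list[RecombinationEvent]:
    by_id: dict[str, RecombinationEvent] = {}
    order: list[str] = []
    for lineno, fields in _rows(path, len(_EVENT_COLUMNS)):
        if fields[0] == "event_id":
            continue
        (eid, chrom, kind, flags, chtds, bps, t_chtd, c_lo, c_hi,
         m_lo, m_hi, n_mark, est) = fields
        if eid not in by_id:
            breakpoints = []
            if bps != "-":
                for item in bps.split(","):
                    pos_s, pair = item.split(":")
                    a, b = pair.split("-")
                    breakpoints.append(CrossoverBreakpoint(
                        chrom, float(pos_s), frozenset((int(a), int(b)))))
            flag_set = set() if flags == "-" else set(flags.split(","))
            bad = flag_set - set(_FLAG_NAMES)
            if bad:
                raise ParseError(f"{path}, line {lineno}: unknown flags {bad}")
            ev = RecombinationEvent(
                chromosome=chrom, kind=kind,
                chromatids=frozenset(int(c) for c in chtds.split(",")),
                tracts=[], breakpoints=breakpoints,
                **{n: n in flag_set for n in _FLAG_NAMES})
            by_id[eid] = ev
            order.append(eid)
        if t_chtd != "NA":
            by_id[eid].tracts.append(ConversionTract(
                chromosome=chrom, chromatid=int(t_chtd),
                core_start=int(c_lo), core_end=int(c_hi),
                max_start=int(m_lo), max_end=int(m_hi),
                n_markers=int(n_mark),
                estimated_length=None if est == "NA" else int(est)))
    return [by_id[eid] for eid in order]


def events_to_bed(events, path) -> None:
    """Export tract core intervals (and breakpoints) as 0-based half-open BED."""
    with _open_write(path) as fh:
        for eid, e in enumerate(events):
            for t in e.tracts:
                fh.write(f"{e.chromosome}\t{t.core_start - 1}\t{t.core_end}"
                         f"\tevent{eid}_{e.kind}_tract_chtd{t.chromatid}\n")
            for b in e.breakpoints:
                lo = int(b.position)
                fh.write(f"{e.chromosome}\t{lo}\t{lo + 1}\tevent{eid}_CO_breakpoint\n")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path, seed=None) -> None:
    """Columns: event_id, chrom, kind, subtypes, chromatids, position,
    tract_chromatid, tract_start, tract_end, clipped (one row per tract)."""
    with _open_write(path) as fh:
        fh.writelines(_header_lines("ground_truth", seed=seed))
        fh.write("event_id\tchrom\tkind\tsubtypes\tchromatids\tposition"
                 "\ttract_chromatid\ttract_start\ttract_end\tclipped\n")
        for eid, e in enumerate(truth.events):
            subtypes = ",".join(sorted(e.subtypes)) or "-"
            chtds = ",".join(str(c) for c in sorted(e.chromatids))
            base = f"{eid}\t{e.chromosome}\t{e.kind}\t{subtypes}\t{chtds}\t{e.position:.1f}"
            if e.tracts:
                for t in e.tracts:
                    fh.write(f"{base}\t{t.chromatid}\t{t.start}\t{t.end}"
                             f"\t{int(t.clipped)}\n")
            else:
                fh.write(f"{base}\tNA\tNA\tNA\tNA\n")


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def write_fits(fits: dict[str, LogNormalFit], path, seed=None, **params) -> None:
    with _open_write(path) as fh:
        fh.writelines(_header_lines("fits", seed=seed, **params))
        fh.write("class\tmu\tsigma\tsd_mean\tn\n")
        for name, f in fits.items():
            sd = "NA" if f.sd_mean is None else f"{f.sd_mean:.6g}"
            n = "NA" if f.n is None else str(f.n)
            fh.write(f"{name}\t{f.mu:.6g}\t{f.sigma:.6g}\t{sd}\t{n}\n")


def read_fits(path) -> dict[str, LogNormalFit]:
    out: dict[str, LogNormalFit] = {}
    for lineno, fields in _rows(path, 5):
        name, mu, sigma, sd, n = fields
        if name == "class":
            continue
        try:
            out[name] = LogNormalFit(
                mu=float(mu), sigma=float(sigma),
                sd_mean=None if sd == "NA" else float(sd),
                n=None if n == "NA" else int(n))
        except ValueError as exc:
            raise ParseError(f"{path}, line {lineno}: {exc}") from None
    return out
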