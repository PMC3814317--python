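"""End-to-end pipeline: simulate -> call -> estimate -> fit -> prototrophy.

The pipeline is driven by a :class:`PipelineConfig` (constructible from a
YAML file) and writes, under ``out_dir``: per-tetrad genotype/truth/event
TSVs, a fits file, and ``report.txt`` containing a per-tetrad event tally
table, a tract-distribution summary table, and the hotspot-prototrophy
numbers.  All randomness derives from the single master seed, so a repeated
run is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io, tables
from .arg4 import ARG4_HOTSPOTS, EventMixture, simulate_prototrophy
from .distributions import LogNormalFit, fit_lognormal
from .events import EventTally, call_events, tally_events
from .genome import SnpMap, generate_snp_map
from .simulate import SimulationProfile, add_noise, simulate_tetrad
from .tractseq import (TractSeqConfig, calibrate_single_snp, estimate_tract,
                       estimate_single_snp_tract)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("tetrec")


@dataclass
class PipelineConfig:
    out_dir: str = "tetrec_out"
    n_tetrads: int = 3
    seed: int = 0
    # genome
    n_chromosomes: int = 16
    chromosome_lengths: list[int] | None = None
    marker_density: float | None = None
    # simulation profile overrides (None -> profile default)
    expected_co_count: float | None = None
    interference_shape: float | None = None
    co_fraction_of_events: float | None = None
    missing_rate: float | None = None
    error_rate: float | None = None
    # calling
    merge_distance: float = 3000.0
    # tract-length estimation
    tractseq_p: float = 0.999
    tractseq_iterations: int = 10_000
    # prototrophy simulation
    arg4_events_per_iteration: int = 20_000
    arg4_iterations: int = 50
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def profile(self) -> SimulationProfile:
        overrides = {k: getattr(self, k) for k in
                     ("expected_co_count", "interference_shape",
                      "co_fraction_of_events", "missing_rate", "error_rate")
                     if getattr(self, k) is not None}
        return SimulationProfile(**overrides)


@dataclass
class PipelineResult:
    out_dir: Path
    tallies: list[EventTally]
    fits: dict[str, LogNormalFit]
    report: str


def _tally_table(tallies: list[EventTally]) -> str:
    cols = ("tetrad", "nco_total", "4:0", "2strand_nco", "nco_disc",
            "nco_gc1snp", "co_total", "co_no_tract", "nco_3rd_strand",
            "4strand_dco", "co_disc", "co_gc1snp", "gc_total", "total")
    lines = ["\t".join(cols)]
    for i, t in enumerate(tallies):
        lines.append("\t".join(str(v) for v in (
            f"tetrad{i}", t.nco_total, t.four_to_zero, t.two_strand_nco,
            t.nco_disc, t.nco_gc1snp, t.co_total, t.co_no_tract,
            t.nco_on_third_strand, t.four_strand_double_co, t.co_disc,
            t.co_gc1snp, t.gc_total, t.total_events)))
    return "\n".join(lines)


def _fit_table(fits: dict[str, LogNormalFit]) -> str:
    lines = ["class\tavg_bp\tci95_lo\tci95_hi\tmu\tsigma\tn"]
    for name, f in fits.items():
        s = f.summary()
        lines.append(f"{name}\t{s.central_length:.0f}\t{s.interval_95[0]:.0f}"
                     f"\t{s.interval_95[1]:.0f}\t{f.mu:.4f}\t{f.sigma:.4f}"
                     f"\t{f.n if f.n is not None else 'NA'}")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage; returns the result and writes all files under out_dir."""
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    # sub-seeds kept below 2**31 for portability of downstream consumers
    sub = [int(s) & 0x7FFF_FFFF for s in ss.generate_state(2 * config.n_tetrads + 2)]

    log.info("stage: simulate (%d tetrads)", config.n_tetrads)
    snp_map = generate_snp_map(n_chromosomes=config.n_chromosomes,
                               chromosome_lengths=config.chromosome_lengths,
                               marker_density=config.marker_density,
                               seed=sub[0])
    io.write_snp_map(snp_map, out / "snp_map.tsv", seed=config.seed)
    profile = config.profile()

    tallies: list[EventTally] = []
    all_events = []
    for t in range(config.n_tetrads):
        genotypes, truth = simulate_tetrad(snp_map, profile, seed=sub[1 + 2 * t])
        noisy = add_noise(genotypes, profile.missing_rate, profile.error_rate,
                          seed=sub[2 + 2 * t])
        io.write_genotypes(noisy, out / f"tetrad{t}.genotypes.tsv", seed=config.seed)
        io.write_ground_truth(truth, out / f"tetrad{t}.truth.tsv", seed=config.seed)
        events = call_events(noisy, merge_distance=config.merge_distance)
        tallies.append(tally_events(events))
        all_events.append(events)

    log.info("stage: tract-length estimation")
    ts_config = TractSeqConfig(p=config.tractseq_p,
                               n_iterations=config.tractseq_iterations,
                               seed=sub[-2])
    multi = []
    singles = []
    for events in all_events:
        for e in events:
            for tract in e.tracts:
                if tract.n_markers >= 2:
                    tract.estimated_length = estimate_tract(tract, ts_config
                                                            ).estimated_length
                    multi.append(tract)
                else:
                    singles.append(tract)
    if len(multi) >= 2:
        calibration = calibrate_single_snp(multi)
        for tract in singles:
            tract.estimated_length = estimate_single_snp_tract(
                tract, calibration).estimated_length
    elif singles:
        log.warning("too few multi-marker tracts to calibrate single-SNP "
                    "tracts; leaving %d unestimated", len(singles))
    for t, events in enumerate(all_events):
        io.write_events(events, out / f"tetrad{t}.events.tsv", seed=config.seed)

    log.info("stage: distribution fitting")
    co_lengths = [tr.estimated_length for evs in all_events for e in evs
                  if e.kind == "CO" for tr in e.tracts
                  if tr.estimated_length is not None]
    nco_lengths = [tr.estimated_length for evs in all_events for e in evs
                   if e.kind == "NCO" for tr in e.tracts
                   if tr.estimated_length is not None]
    fits: dict[str, LogNormalFit] = {}
    for name, lengths in (("CO", co_lengths), ("NCO", nco_lengths)):
        if len(lengths) >= 3:
            fits[name] = fit_lognormal(lengths)
        else:
            log.warning("only %d %s tract estimates; falling back to the "
                        "wild-type reference distribution", len(lengths), name)
            fits[name] = tables.tract_fit("WT", name)
    io.write_fits(fits, out / "fits.tsv", seed=config.seed)

    log.info("stage: prototrophy simulation")
    co_fraction = (np.sum([t.co_total for t in tallies])
                   / np.sum([t.total_events for t in tallies]))
    proto = simulate_prototrophy(
        ARG4_HOTSPOTS, fits["CO"], fits["NCO"],
        mix=EventMixture(co_fraction=float(co_fraction)),
        nco_2chtd_fit=tables.tract_fit("POOLED", "NCO_2CHTD"),
        nco_with_co_fit=tables.tract_fit("POOLED", "NCO_W_CO"),
        n_events_per_iteration=config.arg4_events_per_iteration,
        n_iterations=config.arg4_iterations, seed=sub[-1])

    report = "\n".join([
        f"# tetrec pipeline report (seed={config.seed}, "
        f"n_tetrads={config.n_tetrads})",
        "",
        "## Event tallies",
        _tally_table(tallies),
        "",
        "## Tract-length distributions (from estimated lengths)",
        _fit_table(fits),
        "",
        "## Hotspot prototrophy",
        f"prototroph_fraction\t{proto.prototroph_fraction:.5f}"
        f"\t(MC sd {proto.prototroph_sd:.5f})",
        f"co_associated_fraction\t{proto.co_associated_fraction:.4f}"
        f"\t(MC sd {proto.co_associated_sd:.4f})",
        "",
    ])
    (out / "report.txt").write_text(report)
    log.info("pipeline complete: %s", out)
    return PipelineResult(out_dir=out, tallies=tallies, fits=fits, report=report)
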