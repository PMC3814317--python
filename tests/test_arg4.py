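"""Hotspot prototrophy simulator tests: closed-form log-normal CDF oracles,
usage modes, homeostasis ablation, half-tract mode and NCO detection loss."""

import math

import numpy as np
import pytest
from scipy import stats

from tetrec import (ARG4_HOTSPOTS, EventMixture, HotspotModel, HotspotSite,
                    SnpMap, equal_usage_mode, estimate_nco_detection_loss,
                    simulate_prototrophy)
from tetrec import tables
from tetrec.distributions import LogNormalFit


def lognorm_window_prob(fit, lo, hi):
    """Closed-form P(lo <= L <= hi) for a log-normal tract length."""
    d = stats.lognorm(s=fit.sigma, scale=math.exp(fit.mu))
    return float(d.cdf(hi) - d.cdf(lo))


def mixture_oracle(hotspots, fit, half=False):
    """Per-tract prototroph probability: usage-weighted window mass."""
    total = 0.0
    for site in hotspots.sites:
        lo, hi = site.window
        if half:
            lo, hi = 2 * lo, 2 * hi
        total += site.usage / 100.0 * lognorm_window_prob(fit, lo, hi)
    return total


WT_CO = tables.tract_fit("WT", "CO")
WT_NCO = tables.tract_fit("WT", "NCO")
NCO_2CH = tables.tract_fit("POOLED", "NCO_2CHTD")
NCO_WCO = tables.tract_fit("POOLED", "NCO_W_CO")


class TestSimulatePrototrophy:
    def test_window_covering_support_gives_certain_prototrophy(self):
        hs = HotspotModel(sites=(HotspotSite("s", 100.0, (1.0, 1e9)),))
        r = simulate_prototrophy(
            hs, WT_CO, WT_NCO,
            mix=EventMixture(co_fraction=1.0, co_with_tract=1.0,
                             nco_two_chromatid=0.0, co_third_strand=0.0),
            n_events_per_iteration=2000, n_iterations=20, seed=1)
        assert r.prototroph_fraction == pytest.approx(1.0)
        assert r.co_associated_fraction == 1.0

    def test_single_site_matches_lognormal_cdf(self):
        # CO-only events through one window: the per-tract closed form
        hs = HotspotModel(sites=(HotspotSite("s2", 100.0, (204.0, 1478.0)),))
        r = simulate_prototrophy(
            hs, WT_CO, WT_NCO,
            mix=EventMixture(co_fraction=1.0, co_with_tract=1.0,
                             nco_two_chromatid=0.0, co_third_strand=0.0),
            n_events_per_iteration=20_000, n_iterations=50, seed=2)
        expected = lognorm_window_prob(WT_CO, 204, 1478)  # ~0.366
        se = r.prototroph_sd / math.sqrt(r.n_iterations)
        assert abs(r.prototroph_fraction - expected) <= 3 * se

    def test_simple_mixture_matches_cdf_oracle(self):
        # one tract per event: event-level and per-tract conventions coincide
        f = 0.66
        mix = EventMixture(co_fraction=f, co_with_tract=1.0,
                           nco_two_chromatid=0.0, co_third_strand=0.0)
        r = simulate_prototrophy(ARG4_HOTSPOTS, WT_CO, WT_NCO, mix=mix,
                                 n_events_per_iteration=20_000,
                                 n_iterations=50, seed=3)
        expected = (f * mixture_oracle(ARG4_HOTSPOTS, WT_CO)
                    + (1 - f) * mixture_oracle(ARG4_HOTSPOTS, WT_NCO))
        se = r.prototroph_sd / math.sqrt(r.n_iterations)
        assert abs(r.prototroph_fraction - expected) <= 3 * se

    def test_full_mixture_matches_oracle_in_tract_mode(self):
        # per-tract counting: expected prototroph tracts per event is additive
        f = 0.66
        mix = EventMixture(co_fraction=f)      # 0.71 / 0.14 / 0.07 defaults
        r = simulate_prototrophy(ARG4_HOTSPOTS, WT_CO, WT_NCO, mix=mix,
                                 nco_2chtd_fit=NCO_2CH, nco_with_co_fit=NCO_WCO,
                                 n_events_per_iteration=20_000,
                                 n_iterations=50, seed=4, count_mode="tract")
        q_co = mixture_oracle(ARG4_HOTSPOTS, WT_CO)
        q_nco = mixture_oracle(ARG4_HOTSPOTS, WT_NCO)
        q_2ch = mixture_oracle(ARG4_HOTSPOTS, NCO_2CH)
        q_wco = mixture_oracle(ARG4_HOTSPOTS, NCO_WCO)
        expected = (f * (0.71 * q_co + 0.07 * q_wco)
                    + (1 - f) * (0.14 * 2 * q_2ch + 0.86 * q_nco))
        se = r.prototroph_sd / math.sqrt(r.n_iterations)
        assert abs(r.prototroph_fraction - expected) <= 3 * se

    def test_half_tract_mode_tests_half_length(self):
        hs = HotspotModel(sites=(HotspotSite("s", 100.0, (204.0, 1478.0)),))
        mix = EventMixture(co_fraction=1.0, co_with_tract=1.0,
                           nco_two_chromatid=0.0, co_third_strand=0.0)
        r = simulate_prototrophy(hs, WT_CO, WT_NCO, mix=mix, half_tract=True,
                                 n_events_per_iteration=20_000,
                                 n_iterations=50, seed=5)
        expected = lognorm_window_prob(WT_CO, 2 * 204, 2 * 1478)
        se = r.prototroph_sd / math.sqrt(r.n_iterations)
        assert abs(r.prototroph_fraction - expected) <= 3 * se

    def test_homeostasis_off_uses_wild_type_fraction(self):
        mix = EventMixture(co_fraction=0.9, co_with_tract=1.0,
                           nco_two_chromatid=0.0, co_third_strand=0.0)
        kwargs = dict(n_events_per_iteration=20_000, n_iterations=40, seed=6)
        with_h = simulate_prototrophy(ARG4_HOTSPOTS, WT_CO, WT_NCO, mix=mix,
                                      **kwargs)
        without = simulate_prototrophy(ARG4_HOTSPOTS, WT_CO, WT_NCO, mix=mix,
                                       homeostasis=False, wt_co_fraction=0.5,
                                       **kwargs)
        # CO tracts dominate prototrophy here, so halving the CO share drops it
        assert without.co_associated_fraction < with_h.co_associated_fraction
        with pytest.raises(ValueError, match="wt_co_fraction"):
            simulate_prototrophy(ARG4_HOTSPOTS, WT_CO, WT_NCO, mix=mix,
                                 homeostasis=False, **kwargs)

    def test_missing_complex_fit_rejected(self):
        with pytest.raises(ValueError, match="nco_2chtd"):
            simulate_prototrophy(ARG4_HOTSPOTS, WT_CO, WT_NCO,
                                 mix=EventMixture(co_fraction=0.5))

    def test_co_association_invariant_to_event_count(self):
        mix = EventMixture(co_fraction=0.66)
        a = simulate_prototrophy(ARG4_HOTSPOTS, WT_CO, WT_NCO, mix=mix,
                                 nco_2chtd_fit=NCO_2CH, nco_with_co_fit=NCO_WCO,
                                 n_events_per_iteration=10_000,
                                 n_iterations=40, seed=7)
        b = simulate_prototrophy(ARG4_HOTSPOTS, WT_CO, WT_NCO, mix=mix,
                                 nco_2chtd_fit=NCO_2CH, nco_with_co_fit=NCO_WCO,
                                 n_events_per_iteration=40_000,
                                 n_iterations=40, seed=8)
        tol = 3 * math.hypot(a.co_associated_sd / math.sqrt(40),
                             b.co_associated_sd / math.sqrt(40))
        assert abs(a.co_associated_fraction - b.co_associated_fraction) <= tol


class TestEqualUsage:
    def test_three_sites_become_uniform(self):
        eq = equal_usage_mode(ARG4_HOTSPOTS)
        assert [s.usage for s in eq.sites] == pytest.approx([100 / 3] * 3)
        assert [s.window for s in eq.sites] == [s.window
                                                for s in ARG4_HOTSPOTS.sites]

    def test_single_site_identity(self):
        hs = HotspotModel(sites=(HotspotSite("s", 100.0, (10.0, 20.0)),))
        assert equal_usage_mode(hs).sites[0].usage == 100.0

    def test_four_sites_quarter_each(self):
        hs = HotspotModel(sites=tuple(
            HotspotSite(f"s{i}", 25.0, (10.0, 20.0)) for i in range(4)))
        skewed = HotspotModel(sites=tuple(
            HotspotSite(f"s{i}", u, (10.0, 20.0))
            for i, u in enumerate((70.0, 20.0, 5.0, 5.0))))
        assert equal_usage_mode(skewed) == hs

    def test_usages_must_sum_to_hundred(self):
        with pytest.raises(ValueError, match="100"):
            HotspotModel(sites=(HotspotSite("a", 60.0, (1.0, 2.0)),
                                HotspotSite("b", 60.0, (1.0, 2.0))))


class TestDetectionLoss:
    def _uniform_map(self, spacing, length=2_000_000):
        pos = np.arange(spacing, length + 1, spacing, dtype=np.int64)
        return SnpMap(chromosomes=(("chr01", length),),
                      positions={"chr01": pos})

    def test_marker_at_every_position_misses_nothing(self):
        m = self._uniform_map(1, length=5000)
        fit = LogNormalFit(mu=math.log(100), sigma=0.5)
        assert estimate_nco_detection_loss(m, fit, 5000, seed=1) == 0.0

    def test_tract_longer_than_spacing_always_spans_a_marker(self):
        m = self._uniform_map(1000)
        fit = LogNormalFit(mu=math.log(2000), sigma=0.0)  # fixed 2 kb tracts
        assert estimate_nco_detection_loss(m, fit, 20_000, seed=2) == 0.0

    def test_short_tracts_miss_at_geometric_rate(self):
        # fixed 100 bp tract on 1 kb spacing: missed with probability 0.9
        m = self._uniform_map(1000)
        fit = LogNormalFit(mu=math.log(100), sigma=0.0)
        n = 100_000
        missed = estimate_nco_detection_loss(m, fit, n, seed=3)
        se = 100 * math.sqrt(0.9 * 0.1 / n)
        assert abs(missed - 90.0) <= 3 * se

    def test_loss_grows_as_tracts_shrink(self, snp_map):
        losses = [estimate_nco_detection_loss(
            snp_map, tables.tract_fit(g, "NCO"), 30_000, seed=4)
            for g in ("WT", "HI", "LO")]
        # NCO tracts shorten from WT to LO, so more are missed
        assert losses[0] < losses[1] < losses[2]
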