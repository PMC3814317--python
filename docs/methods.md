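# Methods

This note documents the models behind `tetrec`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic-data tests do
and do not demonstrate about real tetrad data.

## The biological setting

In budding-yeast meiosis, Spo11 makes programmed DSBs whose repair from the
homolog produces either a crossover (CO, reciprocal exchange of flanking
arms) or a non-crossover (NCO, gene conversion without exchange).  Both leave
a *gene-conversion tract*: a run of markers converted to the other parent's
allele, visible in a four-spore tetrad as 3:1 (or 1:3) segregation flanked by
2:2.  When DSB activity drops, the CO:NCO ratio shifts toward COs (CO
homeostasis), CO-associated tracts lengthen, and NCO tracts shorten — with
consequences for any assay (such as heteroallele prototrophy) whose readout
depends on tract geometry.  `tetrec` implements the quantitative machinery
needed to study these effects: event calling, tract-length estimation,
distribution fitting/extrapolation and hotspot-level prototrophy simulation,
driven by a simulator with known ground truth.

## The tetrad simulator

One simulated meiosis produces four chromatids genotyped at every marker of a
hybrid SNP map (default: 16 chromosomes of *S. cerevisiae* lengths, ~12.07
Mb, ~55,000 markers placed uniformly — one per ~220 bp).

**Crossovers.**  CO positions per chromosome follow a stationary gamma
renewal process: inter-CO spacings are Gamma(γ, θ) with γ the interference
shape (γ = 1 is a Poisson process, i.e. no interference) and θ chosen so the
genome-wide expected CO count is met (default 92, the wild-type mean; default
γ = 2.0, the value measured for pooled hypomorph tetrads, with 1.8 the
wild-type reference).  The process is made stationary by drawing the first
interval length-biased (the spacing covering a fixed point is size-biased and
the point is uniform within it), which avoids edge artifacts on short
chromosomes.  Each CO exchanges downstream arms between one molecule locally
carrying P1 and one locally carrying P2 — the bookkeeping that reproduces the
classical two-, three- and four-strand double-CO marker patterns.

**Non-crossovers.**  The genome-wide NCO count is Poisson with mean
`E[CO]·(1−f)/f`, where `f` is the CO fraction of events (default 0.657, the
per-tetrad mean of the wild-type tallies), placed uniformly with chromosomes
weighted by length.

**Conversion tracts.**  Tract lengths are log-normal per event class, with
defaults reconstructed from the printed wild-type 95% intervals (CO: centre
1906 bp; NCO: 1649 bp) and, for the complex classes pooled across genotypes,
two-chromatid NCO (2436 bp) and NCO-with-CO (2575 bp).  Event-class
proportions default to the pooled estimates: 71% of COs carry a tract
(abutting the exchange point, side and chromatid uniform), 7% of COs carry an
additional tract on a third chromatid placed beside the exchange, and 14% of
NCO events are two-chromatid — realised as two disjoint tracts flanking the
initiation site (gaps uniform on 50–500 bp) on two distinct chromatids.
Conversion is applied by flipping the parental calls of the covered markers
on the recipient chromatid.  4:0 events (both chromatids of one homolog
converted) are off by default and available via `four_to_zero_rate`.

**Event separation.**  Independent events are kept apart: NCO placement is
rejection-sampled so event footprints stay ≥3.5 kb from one another, a CO's
tracts are confined to its own side of the midpoint toward neighbouring
exchange points (≥1.5 kb clear zone), and the third-strand tract sits beside
rather than across the exchange.  Without this, at study densities a few
percent of tetrads contain superimposed events (e.g. overlapping tracts on
opposite homologs, which genuinely read as a double CO) whose composite
signals no genotype-based caller can decompose; real pipelines report them as
merged or complex events.  The separation makes ground truth and genotype
signal correspond one-to-one — which is precisely what the caller-vs-truth
tests exploit — at the cost of not emulating the rare coincident-event
configurations of real genomes.

**Noise.**  `add_noise` independently sets calls to missing (default rate
0.01, emulating depth dropouts) and flips survivors (default 0.0: the study's
marker QC removed error-prone markers before event calling, so the emulated
post-QC input is effectively error-free; any nonzero error rate fabricates
single-marker conversions at rate ≈ 4·55,000·error per tetrad and is left as
an explicit robustness knob).

**Randomness.**  One master seed; per-chromosome generators plus one
genome-level stream are spawned deterministically via
`numpy.random.SeedSequence.spawn`, so results are independent of evaluation
order.

## Event calling

Markers with all four calls present are classified by P1:P2 count; markers
with any missing call are skipped for segregation but retained as
coordinates.  Crossover breakpoints are detected between consecutive
informative 2:2 markers whose pairing pattern differs, at the midpoint of the
two markers (the convention consumed by interference distances); a change
flipping all four chromatids is two COs (pairing across homologs is not
identifiable and is assigned arbitrarily; such events are flagged
four-chromatid double COs and merged into one event).  Maximal runs of
non-2:2 markers become conversion tracts: each marker's converted chromatids
are read against the flanking 2:2 background — the side giving the smaller
deviation set, ties to the left.  A CO-abutting tract is intrinsically
ambiguous (tract on chromatid *a* with the exchange on the far side is
genotypically identical to tract on *b* with the exchange on the near side);
both readings give the same event-level chromatid set, which is what the
tests assert.  The tract core spans the first to last converted marker; the
maximal interval is bounded by the innermost flanking 2:2 markers (chromosome
edge coordinates 0 and L+1 when a run touches an end).

Breakpoints and tracts within 3 kb of one another — end-to-end, nearest core
boundaries, breakpoint position for tract-less COs — are merged transitively
(single linkage) into events, and taxonomy flags are assigned.  An NCO tract
merged onto a CO on an uninvolved chromatid makes the event a CO flagged
`nco_on_third_strand`, matching how the source taxonomy columns are
organised.  Whether the 3 kb rule applies to core or maximal boundaries is
not specified by the source; core boundaries are used (configurable via
`merge_distance` only in aggregate).

Interference is quantified by maximum-likelihood gamma fitting
(`scipy.stats.gamma.fit`, location fixed at 0) of adjacent-CO distances
pooled within chromosomes across tetrads; at least 20 distances are required,
reflecting that sparse mutant tetrads must be pooled.

## Tract-length estimation

A tract is observed only as a core (certainly converted) inside a maximal
interval (certainly not converted beyond).  The estimator draws, per
iteration, an independent outward offset per side from the geometric law
`P(k) = (1−p)·p^k` (processivity p = 0.999 by default, the literature
meta-analysis value), rejecting offsets that reach the flanking 2:2 marker.
Truncation is implemented by inverse-CDF sampling of the truncated geometric
— distributionally identical to per-side rejection-with-resampling, without
the unbounded loop when a flank gap is 1 bp; the would-be acceptance rate
`(1−p^gapL)(1−p^gapR)` is reported as a diagnostic.  The estimate is the
median over `n_iterations ≥ 10,000` (even counts: mean of central order
statistics, rounded to the nearest bp).  Offsets of 0 are accepted: the tract
may end exactly at the core edge but may not be shorter than the core.
Because the inverse CDF is monotone in the uniform draw, the flank size and
p, estimates under a common seed are exactly monotone in those parameters —
a property the tests exercise directly.  A unidirectional mode (one offset on
one side, side uniform per iteration) is provided for contrast.

Single-marker tracts (a 1 bp core in an often huge maximal interval) would
only echo the flank geometry, and at ~15% of events would bias the fits; they
are instead predicted from an OLS calibration of estimated length on maximal
length learned from multi-marker tracts, clamped to `[1, maximal length]`.

## Distribution fitting, comparison and extrapolation

Tract lengths are fitted by maximum likelihood on logs: `μ = mean(ln L)`,
`σ = population sd(ln L)` (MLE convention, documented because a two-point fit
makes the choice visible), `sd_mean = σ/√n`, with a Kolmogorov–Smirnov
goodness-of-fit statistic attached.  This replaces the original MCMC
machinery; the two are asymptotically equivalent for this model and the MLE
is dependency-light.  A fitted distribution is summarised as
`exp(μ)` — the median and geometric mean, conserved as the geometric mean of
the 95% bounds `exp(μ ± 1.96σ)` — which makes printed summaries exactly
invertible (`lognormal_from_interval`).  Distribution means are compared by
resampling each μ from a normal with its `sd_mean` (already size-corrected,
being σ/√n) and doubling the smaller tail fraction of the difference.

CO homeostasis is summarised by OLS of per-tetrad CO fraction `co/(co+nco)`
on CO count over the eight transcribed tetrads; a hypothetical mutant with
`x` COs is then predicted to have `x·(1−f(x))/f(x)` NCOs.  Mean CO tract
length is regressed on `f(#CO)` for `f ∈ {x, √x, ln x, 1/x}` (the inverse
family fits the genetic data best and is the default); the NCO mean is always
linear in the CO count, and both σ's are linear.  Anchor CO counts default to
the per-group tetrad means of the raw tallies (WT 92, HI 80.5, LO 54) since
the exact anchors behind the printed extrapolations are not fully specified;
with these anchors the inverse-family 10-CO central length lands within ~2%
of the printed 5497 bp.

## Hotspot prototrophy simulation

The ARG4-like model has three DSB sites used at 6/53/41%, each with a window
of tract lengths whose endpoint falls between the two heteroalleles
((1544, 2818), (204, 1478), (2354, 3628) bp); the whole tract is laid from
the initiation site toward the heteroalleles, as the windows presuppose.
Per simulated event: kind is CO with probability `co_fraction` (or the
wild-type fraction when homeostasis is switched off); a CO contributes a
tract with probability 0.71 plus an independent third-strand tract with
probability 0.07 (drawn from the NCO-with-CO distribution); a two-chromatid
NCO (14% of NCOs) draws two tracts and succeeds if either does; each tract
picks a site by usage and succeeds if its length lies in the site's window
(half-tract mode: length/2, for the scenario where the DSB sits mid-tract).
Third-strand prototrophs count as CO-associated — the event is a CO; a
per-tract counting mode (`count_mode="tract"`, additive expected prototroph
tracts per event) is provided because the original adjustment convention is
under-specified, and it is the mode the closed-form oracle
`Σ_c w_c Σ_i u_i [F_c(hi_i) − F_c(lo_i)]` checks exactly.

Default budget is 10^5 events × 200 iterations (desk scale, preserving the
original's ratio of ~10^6 × 1000 which remains available by raising the
parameters); reported values carry the Monte Carlo sd over iterations.
With the transcribed group fits and fractions the acceptance tests verify
the rising CO-association series from wild type through the high- and
low-activity groups (≈56% → 64% → 69% in the suite's seed-fixed runs), its
collapse for a 3-CO mutant, and prototroph output falling several-fold
faster than CO count — the trends are the supported surface; exact printed
point values depend on the under-specified adjustment and are not asserted.

NCO detection loss — the fraction of NCO tracts spanning zero markers, hence
invisible to genotyping — is estimated by dropping tracts uniformly on the
SNP map (chromosomes weighted by length, lengths from the fitted NCO
distribution).  On a uniform map this reduces to the closed form
`P(miss) = 1 − L/s` for tract length L below marker spacing s, which the
tests check; values on a synthetic uniform-random map differ from those on
the real (clustered) marker map, so the published loss figure is not a target.

## Problem sizes in the test suite

The suite simulates 500 study-scale tetrads (~55k markers each) once and
shares them across tests; caller-vs-truth equivalence is asserted on all 500,
interference recovery uses 500 sparse-map tetrads per shape and n = 2000
sampled spacings, estimator oracles use 2·10^4–5·10^4 iterations, and
prototrophy oracles 2–4·10^4 events × 30–50 iterations.  These sizes hold
every Monte Carlo comparison at ≥3 standard errors while keeping the suite
in the minutes range.

## What passing tests do and do not show

The simulator realises the same generative assumptions the analysis methods
invert (log-normal tracts, gamma-renewal COs, binomial noise), so parameter
recovery demonstrates internal consistency, not correctness on real data.
Real tetrads additionally contain: clustered markers (the synthetic map is
uniform), indels and mis-annotated markers (excluded here; the study removed
them by parental resequencing QC), centromere-proximal CO suppression and
hotspot-structured event placement (not modelled), occasional coincident
events closer than the separation floor (deliberately not generated, see
above), and aneuploid or gene-converted-marker edge cases.  The caller's
exact-match guarantees are therefore statements about well-separated events
on QC'd SNP markers; on real data the composite-signal classes (discontinuous,
multi-strand) absorb the remainder.

## Known limitations

* The caller does not attempt to decompose composite signals from
  superimposed independent events; they surface as merged/complex events.
* Chromatid assignment of a CO-abutting tract is reported by the left-background
  convention; only the event-level chromatid set is identifiable.
* The MCMC posterior machinery of the original distribution fitting is not
  reproduced; `sd_mean` is the asymptotic σ/√n.
* Extrapolation families are fitted on three anchor activities; with three
  points the family choice is a modelling assumption, not a model selection.
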