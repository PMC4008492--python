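# Methods

## Coordinates and spacers

All intervals are BED-convention: 0-based, half-open `[start, end)`.
Overlapping or book-ended elements on a chromosome are unioned before
any spacer computation, so every spacer
`S_i = start(i+1) − end(i)` is strictly positive. Distances from the
chromosome boundaries to the first/last element are not spacers and are
excluded. The spacer metric is the end-to-start gap, not a
midpoint-to-midpoint distance: it is the only definition under which
merged tracks give positive spacers, and at the chromosomal scales
analysed the difference is negligible because element lengths (tens to
hundreds of bp) are small against spacers (kb–Mb).

## The cumulative distribution and the linear-region detector

The statistic of record is the complementary cumulative distribution
`N(S)` — the number of spacers of length at least S. It is independent
of any binning choice and has a smoother tail than the histogram. For a
power-law spacer density `p(S) ∝ S^(−α)` the CCDF is again a power law
with exponent `α − 1`, so the fitted slope magnitude µ estimates
`α − 1` and the density exponent is reported as `µ + 1`.

The detector probes `log10 N` at log-spaced values of S (default 20 per
decade) between the smallest and largest spacer. Probing on a log grid
rather than at the raw spacer values keeps the dense small-spacer end of
the sample from dominating the regression. Every pair of probe cutoffs
is scanned with O(1) prefix-sum least squares; a window qualifies when

* it contains at least `min_points` probes (default 10, i.e. half a
  decade at the default grid),
* the regression reaches `r² ≥ r2_min` (default 0.97; 0.98 for
  simulator snapshots, matching the stricter display threshold used for
  model output),
* the slope is negative with magnitude at least `min_slope`
  (default 0.1).

Among qualifying windows the one with the largest extent
`E = log10(S_upper/S_lower)` wins; ties go to the larger r². With this
selection rule the reported r² sits close to the chosen threshold by
construction — the window is grown until linearity is about to fail.

The `min_slope` floor is a necessary guard, not a cosmetic one: just
above its minimum spacer every CCDF declines smoothly and very slowly,
and such a quasi-flat stretch can satisfy any r² threshold over many
decades while representing no power law at all (fitted slopes ≈ 0.04 in
practice). Windows shallower than 0.1 are therefore never candidates.
The genuinely flat stretch below the minimum spacer has zero variance
in y and is already unfittable.

Fits with µ ≥ 2 are reported but logged with a warning, since genomic
spacer tracks characteristically stay below 2 (diverging variance
regime); simulator snapshots occasionally exceed it when the detector
locks onto the steep tail shoulder.

`avg E` averages the extent over chromosomes with accepted fits only;
`avg E-5` averages the five largest accepted extents (all of them when
fewer than five exist).

## Surrogate nulls

Each genomic curve is accompanied by 10 replicates in which the same
number of point markers is placed uniformly at random over the
chromosome, excluding any masked space. Markers are sampled as distinct
integer positions; spacers are consecutive-position differences.
Marker length is taken as zero because element lengths are negligible
against the chromosome. Uniform placement yields near-exponential
spacers (each gap is approximately Exp(L/(n+1))), which in log-log
scale produce only a short steep linear stretch — the contrast that
makes an extended genomic E meaningful.

## Gene masking

Genes are extended strand-awarely: `flank5` bp upstream of the 5′ end
and `flank3` bp downstream of the 3′ end (5000/2000 by default; 10 kb
and 100 kb variants are symmetric). Unstranded records get the larger
flank on both sides — the conservative choice. Extended intervals are
merged; any element overlapping the mask by one bp or more is removed.
Surviving elements keep their original coordinates: removing the masked
*space* (rather than just the elements) would itself reshape the
spacer distribution, which is exactly what the protocol must not do.

## The duplication–loss simulator

State: a sequence of integer length L carrying sorted distinct point
markers. Defaults mirror the showcase conditions: 1000 markers placed
uniformly on 2 Mbp, 150 segmental duplications, SD length drawn
uniformly from 1 to 5% of the *current* L, `fr = 0.9`, snapshots every
50 SDs.

Per SD event:

1. **Segmental duplication** — the copy is inserted in tandem,
   immediately downstream of the source region; markers inside the
   source are duplicated at preserved offsets, downstream markers shift
   right. Tandem placement is the plain reading of segmental
   duplication; marker collisions are impossible under it.
2. **Elimination** — `round(fr × d)` markers are removed, where d is
   the number just duplicated and rounding is half-away-from-zero. The
   elimination pool is the duplicated markers themselves: the 2d
   originals-plus-copies of the event, so either copy of a redundant
   pair may be the one lost. This is the model reading under which the
   simulated extents behave like the genomic ones (see below); drawing
   the eliminations from *all* markers (available as
   `elim_pool="all"`) erases the dependence of E on SD count and on fr
   and caps mean extents near 0.7 decades, and eliminating only the
   fresh copies collapses the `fr = 1` limit (no marker turnover at
   all).
3. **Extra eliminations** — `extra_elims` further markers drawn from
   the whole population (clamped to it), modelling loss of
   non-duplicated elements.
4. Optional **insertions** (Poisson count per SD, exponential lengths)
   shift markers without creating any, and **deletions** remove
   marker-free windows only, resampling up to 100 times before skipping
   the event; markers are under purifying selection and protected.

Runs terminate early (logged, partial snapshots kept) if fewer than 3
markers remain. All bookkeeping identities (L versus summed event
lengths, marker count versus the event log) are exact and tested; with
`fr = 1` and no extras the marker count equals its initial value after
every event.

Under the defaults the mean detected extent grows from ≈1.2 decades at
50 SDs to ≈1.7 at 200, and increases with fr (≈1.6 / 1.7 / 1.9 at
0.8 / 0.9 / 1.0 over 50 replicates) — duplication-plus-loss alone
produces the pattern. The dependence on *extra* eliminations is flat at
these conditions: replicate means over 0/1/2 extras differ by less than
their between-batch scatter, with no stable ordering. Two effects
cancel: each extra elimination fattens the tail by merging neighbouring
spacers, but it also erodes the dense short-spacer backbone (raising
the lower cutoff) and lowers the final marker count, which caps the
attainable extent. The package reports what it measures.

## Synthetic tracks

The generators emit the study conditions, not a dial to turn: uniform
placement (the null), i.i.d. Pareto spacers with density exponent α and
minimum spacer 100 bp (the standard heavy-tail stand-in; the analysis
must recover `µ = α − 1` within ±0.1 on 10-seed means at n = 50,000),
i.i.d. exponential spacers, and simulator output wrapped as a track.
Element lengths default to zero (rendered as 1 bp intervals in BED)
since only the gaps matter. A toy stranded, non-overlapping gene
annotation supports masking tests.

What the synthetic tracks deliberately lack: sequence content,
conservation scores, the clustering of real CNEs around trans-dev
genes, and any correlation between element length and local spacer
scale. Passing tests therefore validate the statistical machinery and
the model dynamics, not claims about any particular genome; analysing
real tracks requires only a BED file and a chrom.sizes file.

## Numerical choices and problem sizes

* Probe grids, not raw values, feed the regression (see above);
  20 points/decade balances resolution against O(P²) window scans.
* Slope-recovery checks use n = 50,000 spacers and 10 seeds; single
  seeds scatter by up to ±0.15 from extreme-tail step noise, the
  10-seed mean is stable to ±0.03.
* Trend experiments use 20 replicates (SD-count emergence, tested by
  per-replicate Spearman rank correlation with a one-sided Wilcoxon
  test) or 50 replicates (fr and extra-elimination sweeps, compared as
  means); each run takes ~30 ms, keeping the whole suite desk-scale.
* The exponential-tail null check uses a Dvoretzky–Kiefer–Wolfowitz
  band at confidence 99.9% around the fitted-mean exponential CCDF at
  n = 10,000 — a deliberately loose envelope since the theoretical
  comparison estimates its mean from the sample.
* Every stochastic operation takes an explicit seed or Generator;
  seeds derived inside pipelines come from `numpy.random.SeedSequence`
  spawning and stay below 2³¹.

## Known limitations

* The linear-region selection (maximise E subject to an r² threshold)
  is one of several defensible readings of "extent of linearity"; its
  reported r² hugs the threshold, so cross-study comparison should fix
  the threshold first.
* The simulator is a coordinate model only: no sequence, no fitness,
  no interaction between gene positions and element positions.
* Whole-genome duplication is reachable only as the `sd_max_frac → 1`
  limit; it has no dedicated event type.
* Real-genome summaries (Table-1-style per-dataset avg E / avg E-5)
  require external element tracks and gene annotations; the test suite
  exercises that pipeline on synthetic genomes only.
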