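# cnespacers

Statistics of the distances between consecutive conserved noncoding
elements (CNEs) on a chromosome, and a genome-dynamics simulator that
explains where their heavy-tailed, power-law-like pattern comes from.

## The problem

CNEs — ultraconserved elements, UCNEs, HCNEs and kin — are scattered
non-randomly along chromosomes. A robust way to quantify their
arrangement is the distribution of *spacers*: the gaps
`S_i = start(i+1) − end(i)` between consecutive elements. For many
element classes the complementary cumulative distribution

    N(S) = number of spacers of length ≥ S

is approximately a straight line in double-logarithmic scale over
several orders of magnitude: `log10 N(S) ≈ c − µ·log10 S`. Two numbers
summarise each chromosome:

* **E** — the *extent* of the linear region in decades,
  `E = log10(S_upper / S_lower)`, how far the self-similar arrangement
  spans;
* **µ** — the magnitude of the log-log slope (the spacer *density*
  exponent is `µ + 1`; genomic tracks typically have `µ < 2`, the
  regime of diverging spacer variance).

A fit is accepted when ordinary least squares on log-spaced probes of
the CCDF reaches `r² ≥ 0.97` over at least 10 probe points. Genome
summaries report `avg E` (mean over chromosomes with accepted fits) and
`avg E-5` (mean over the five best chromosomes). Every genomic curve is
compared against a bundle of 10 *surrogates* — the same number of
markers dropped uniformly at random on the (optionally gene-masked)
chromosome — whose near-exponential spacers produce only short linear
regions.

Because CNEs cluster near developmental genes, the package implements a
strand-aware gene-masking protocol: genes are extended by 5 kb upstream
of the 5′ end and 2 kb downstream of the 3′ end (10 kb / 100 kb
symmetric variants available), and every element overlapping the
extended regions is removed *without collapsing the coordinate space*.

The **duplication–loss simulator** models why the pattern emerges: a
sequence of length L carries point markers; segmental duplications
(length uniform up to 5% of the current L, tandem copy) duplicate the
markers they contain; a fraction `fr` of each event's duplicated
markers is then eliminated; optional extra eliminations, neutral
insertions and marker-free deletions complete the event repertoire.
Duplication plus loss alone turn an initially random arrangement into
one with an extended log-log linear spacer region.

## Worked example

```python
from cnespacers import (GeneratorSpec, gen_spacer_track, merge_overlapping,
                        compute_spacers, ccdf, fit_linear_region)

track = gen_spacer_track(GeneratorSpec(kind="pareto_spacers", n=50_001,
                                       alpha=2.0, s_min=100, seed=1))
spacers = compute_spacers(merge_overlapping(track), "chr1")
fit = fit_linear_region(ccdf(spacers))
print(f"E = {fit.E:.2f} decades, mu = {fit.mu:.3f}, r2 = {fit.r2:.4f}")
```

prints

```
E = 4.95 decades, mu = 0.900, r2 = 0.9925
```

A track whose 50,000 spacers follow a Pareto density `p(S) ~ S^-2`
yields a cumulative slope close to `2 − 1 = 1` (single-seed fits
scatter by ~0.1 from tail noise; the 10-seed mean lands on 1.00) over
roughly five decades. The same pipeline from the command line:

```
cnespacers synth --kind pareto_spacers -n 50001 --alpha 2.0 -o cnes.bed
cnespacers analyze --elements cnes.bed -o out/
cnespacers simulate --n-sd 150 --fr 0.9 -o sim/
```

`analyze` writes `per_chromosome.tsv` (chrom, n, cutoffs, µ, E, r²),
`surrogates.tsv`, `summary.tsv` (avg E, avg E-5) and a run manifest;
`simulate` writes per-snapshot CCDF tables, a fits table and an event
log.

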