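"""Synthetic element tracks with known spacer statistics.

These generators stand in for real CNE coordinate tracks: they emit
per-chromosome BED-writable tracks whose spacers follow a chosen law —
uniform random placement (exponential-like spacers, the null),
i.i.d. Pareto spacers with a chosen density exponent alpha (so the
spacer CCDF is a power law of exponent alpha - 1), i.i.d. exponential
spacers, or the output of the duplication-loss simulator.  A toy
stranded gene annotation supports masking tests.

All tracks are synthetic: they carry no sequence content, conservation
scores, or the gene-proximal clustering of real conserved elements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import ElementTrack

__all__ = [
    "GeneratorSpec", "gen_uniform_track", "gen_spacer_track",
    "gen_toy_annotation", "pareto_spacers", "track_from_simulation",
]


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic chromosome track.

    Parameters
    ----------
    kind
        One of ``uniform``, ``pareto_spacers``, ``exponential_spacers``,
        ``simulator``.
    n
        Element count (>= 2).
    chrom_length
        Chromosome length in bp (for ``uniform``); spacer-driven kinds
        derive the length from the laid-out span.
    alpha
        Pareto density exponent (spacer density ~ S^-alpha); the CCDF
        exponent is alpha - 1.
    s_min
        Minimum Pareto spacer in bp.
    mean_spacer
        Mean for exponential spacers, bp.
    element_length
        Constant element length in bp; 0 gives point elements (spacer
        analysis only concerns the gaps, so lengths default to 0).
    """

    kind: str = "uniform"
    n: int = 1000
    chrom_length: int = 1_000_000
    alpha: float = 2.0
    s_min: int = 100
    mean_spacer: float = 1000.0
    element_length: int = 0
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.alpha <= 1:
            raise ValueError("alpha must exceed 1 for a normalisable tail")
        if self.s_min <= 0 or self.mean_spacer <= 0 or self.chrom_length <= 0:
            raise ValueError("parameters must be positive")
        if self.element_length < 0:
            raise ValueError("element_length must be >= 0")


def _track_from_starts(
    starts: np.ndarray, width: int, chrom: str, chrom_length: int
) -> ElementTrack:
    width_eff = max(width, 1)  # BED needs end > start; points become 1 bp
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts.astype(np.int64),
            "end": starts.astype(np.int64) + width_eff,
            "name": [f"el{i}" for i in range(len(starts))],
            "strand": ".",
        }
    )
    size = max(chrom_length, int(df["end"].max()))
    return ElementTrack(df, chrom_sizes={chrom: size})


def gen_uniform_track(spec: GeneratorSpec) -> ElementTrack:
    """``n`` non-overlapping elements placed uniformly at random.

    Placement is uniform over all feasible non-overlapping arrangements:
    element starts are distinct uniform draws over the free space,
    spread back out by the element width.
    """
    w = max(spec.element_length, 1)
    free = spec.chrom_length - spec.n * w
    if free < 0:
        raise ValueError("elements do not fit in the chromosome")
    rng = np.random.default_rng(spec.seed)
    from .powerlaw import _distinct_uniform

    slots = np.sort(_distinct_uniform(spec.n, free + spec.n, rng))
    starts = slots + np.arange(spec.n) * (w - 1)
    return _track_from_starts(starts, spec.element_length, spec.chrom, spec.chrom_length)


def pareto_spacers(
    n: int, alpha: float, s_min: int, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. Pareto spacers: density ~ S^-alpha for S >= s_min (integer bp)."""
    u = rng.random(n)
    s = s_min * u ** (-1.0 / (alpha - 1.0))
    return np.maximum(np.rint(s).astype(np.int64), s_min)


def gen_spacer_track(spec: GeneratorSpec) -> ElementTrack:
    """Lay elements left to right with i.i.d. spacers of the named law.

    For ``pareto_spacers`` the n-1 gaps follow a Pareto law with density
    exponent ``alpha`` and minimum ``s_min``; for ``exponential_spacers``
    they are exponential with mean ``mean_spacer`` (floored at 1 bp).
    The chromosome size is set to cover the span.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "pareto_spacers":
        gaps = pareto_spacers(spec.n - 1, spec.alpha, spec.s_min, rng)
    elif spec.kind == "exponential_spacers":
        gaps = np.maximum(
            np.rint(rng.exponential(spec.mean_spacer, spec.n - 1)).astype(np.int64),
            1,
        )
    else:
        raise ValueError(f"unknown spacer kind {spec.kind!r}")
    w = max(spec.element_length, 1)
    starts = np.concatenate([[0], np.cumsum(gaps + w)])
    return _track_from_starts(starts, spec.element_length, spec.chrom, 0)


def gen_toy_annotation(
    n_genes: int,
    chrom_length: int,
    strand_mix: float = 0.5,
    seed: int = 0,
    chrom: str = "chr1",
    gene_length: int = 5000,
) -> ElementTrack:
    """Non-overlapping stranded toy genes for masking tests.

    ``strand_mix`` is the fraction of genes on the + strand.
    """
    if n_genes == 0:
        return ElementTrack(chrom_sizes={chrom: chrom_length})
    if n_genes * gene_length > chrom_length:
        raise ValueError("genes do not fit in the chromosome")
    rng = np.random.default_rng(seed)
    from .powerlaw import _distinct_uniform

    free = chrom_length - n_genes * gene_length
    slots = np.sort(_distinct_uniform(n_genes, free + n_genes, rng))
    starts = slots + np.arange(n_genes) * (gene_length - 1)
    strands = np.where(rng.random(n_genes) < strand_mix, "+", "-")
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts.astype(np.int64),
            "end": starts.astype(np.int64) + gene_length,
            "name": [f"gene{i}" for i in range(n_genes)],
            "strand": strands,
        }
    )
    return ElementTrack(df, chrom_sizes={chrom: chrom_length})


def track_from_simulation(markers: np.ndarray, L: int, chrom: str = "chr1") -> ElementTrack:
    """Wrap simulator marker positions as a 1 bp element track."""
    markers = np.asarray(markers, dtype=np.int64)
    return _track_from_starts(markers, 0, chrom, L)
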