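"""Genomic element tracks: BED I/O, interval arithmetic and gene masking.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  An :class:`ElementTrack` is a thin wrapper around a
sorted :class:`pandas.DataFrame` of intervals plus optional chromosome
sizes; a :class:`MaskTrack` is a merged, disjoint set of intervals used
to exclude elements that fall inside genes and their flanks.

The masking protocol removes every element overlapping a gene or its
flanks by at least one base pair while keeping the coordinates of the
survivors untouched — the coordinate space is deliberately *not*
collapsed, so that inter-element distances are measured on the original
chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

__all__ = [
    "GenomicElement", "ElementTrack", "MaskTrack", "SpacerSet",
    "read_elements", "write_elements", "merge_overlapping",
    "compute_spacers", "build_gene_mask", "apply_mask", "downsample",
    "merge_tracks", "read_chrom_sizes",
]


@dataclass(frozen=True)
class GenomicElement:
    """One genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "name": pd.Series(dtype=str),
            "strand": pd.Series(dtype=str),
        }
    )


def _normalise_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "name" not in df:
        df["name"] = "."
    if "strand" not in df:
        df["strand"] = "."
    df = df[["chrom", "start", "end", "name", "strand"]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    return df.reset_index(drop=True)


@dataclass
class ElementTrack:
    """Per-chromosome sorted genomic intervals (CNEs, genes, ...).

    Parameters
    ----------
    df
        Interval table with columns ``chrom, start, end, name, strand``.
        Sorted by (chrom, start) on construction.
    chrom_sizes
        Optional mapping of chromosome name to length in bp.  When
        present, every interval must end at or before its chromosome
        size.
    """

    df: pd.DataFrame = field(default_factory=_empty_frame)
    chrom_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.df = _normalise_frame(self.df)
        if len(self.df):
            bad = self.df["start"] >= self.df["end"]
            if bad.any():
                row = self.df[bad].iloc[0]
                raise ValueError(
                    f"interval with end <= start: "
                    f"{row.chrom}:{row.start}-{row.end}"
                )
            if (self.df["start"] < 0).any():
                raise ValueError("negative start coordinate")
        if self.chrom_sizes is not None:
            for chrom, sub in self.df.groupby("chrom", sort=False):
                size = self.chrom_sizes.get(str(chrom))
                if size is None:
                    raise ValueError(f"no size for chromosome {chrom}")
                if int(sub["end"].max()) > size:
                    raise ValueError(
                        f"element beyond declared size of {chrom} ({size} bp)"
                    )

    # -- convenience accessors -------------------------------------------
    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def __len__(self) -> int:
        return len(self.df)

    def counts(self) -> dict[str, int]:
        """Element count per chromosome."""
        return {str(c): int(n) for c, n in self.df["chrom"].value_counts().items()}

    def intervals(self, chrom: str) -> np.ndarray:
        """(n, 2) array of [start, end) pairs on one chromosome."""
        sub = self.df[self.df["chrom"] == chrom]
        return sub[["start", "end"]].to_numpy(dtype=np.int64)

    def chrom_length(self, chrom: str) -> int:
        """Declared size, or the end of the last element as a fallback."""
        if self.chrom_sizes and chrom in self.chrom_sizes:
            return int(self.chrom_sizes[chrom])
        iv = self.intervals(chrom)
        if not len(iv):
            raise KeyError(f"chromosome {chrom} not in track")
        return int(iv[:, 1].max())


@dataclass
class MaskTrack:
    """Merged, disjoint intervals marking excluded (genic + flank) space."""

    intervals: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for chrom, iv in self.intervals.items():
            iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
            iv = _merge_interval_array(iv)
            clean[chrom] = iv
        self.intervals = clean

    @property
    def masked_length(self) -> dict[str, int]:
        return {
            c: int((iv[:, 1] - iv[:, 0]).sum()) for c, iv in self.intervals.items()
        }

    def free_intervals(self, chrom: str, length: int) -> np.ndarray:
        """Complement of the mask within [0, length) on one chromosome."""
        iv = self.intervals.get(chrom)
        if iv is None or not len(iv):
            return np.array([[0, length]], dtype=np.int64)
        iv = iv[(iv[:, 0] < length)]
        edges = [0]
        for s, e in iv:
            edges.extend([int(s), int(min(e, length))])
        edges.append(length)
        pairs = np.array(edges, dtype=np.int64).reshape(-1, 2)
        return pairs[pairs[:, 1] > pairs[:, 0]]


@dataclass
class SpacerSet:
    """Gap lengths between consecutive elements on one chromosome."""

    chrom: str
    spacers: np.ndarray
    n_elements: int

    def __post_init__(self) -> None:
        self.spacers = np.asarray(self.spacers, dtype=np.int64)
        if len(self.spacers) and self.spacers.min() <= 0:
            raise ValueError("spacers must be strictly positive")
        if self.n_elements >= 1 and len(self.spacers) != self.n_elements - 1:
            raise ValueError("expected n_elements - 1 spacers")

    def __len__(self) -> int:
        return len(self.spacers)


# ---------------------------------------------------------------------------
# I/O


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``name<TAB>length`` chromosome-sizes file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            sizes[parts[0]] = int(parts[1])
    return sizes


def read_elements(path, chrom_sizes=None) -> ElementTrack:
    """Read a 3+ column BED file into an :class:`ElementTrack`.

    The strand column (column 6) is used when present, otherwise strand
    is recorded as unknown (``.``).  Lines with ``end <= start`` or
    elements beyond a declared chromosome size raise :class:`ValueError`
    naming the offending line.
    """
    if chrom_sizes is None or isinstance(chrom_sizes, dict):
        sizes = chrom_sizes
    else:
        sizes = read_chrom_sizes(chrom_sizes)
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if end <= start or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            if sizes is not None:
                size = sizes.get(chrom)
                if size is not None and end > size:
                    raise ValueError(
                        f"{path}:{lineno}: interval ends beyond {chrom} "
                        f"size {size}"
                    )
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            rows.append((chrom, start, end, name, strand))
    df = (
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
        if rows
        else _empty_frame()
    )
    return ElementTrack(df, chrom_sizes=sizes)


def write_elements(track: ElementTrack, path) -> None:
    """Write a track as 6-column BED (score fixed at 0)."""
    with open(path, "w") as fh:
        for row in track.df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t0\t"
                f"{row.strand if row.strand in '+-' else '.'}\n"
            )


# ---------------------------------------------------------------------------
# Interval arithmetic


def _merge_interval_array(iv: np.ndarray) -> np.ndarray:
    """Union of intervals; book-ended (end == next start) runs are joined."""
    if len(iv) <= 1:
        return np.array(iv, dtype=np.int64).reshape(-1, 2)
    order = np.lexsort((iv[:, 1], iv[:, 0]))
    iv = iv[order]
    cummax_end = np.maximum.accumulate(iv[:, 1])
    # a new block starts where the interval begins strictly after all
    # previous coverage (book-ended intervals are unioned)
    new_block = np.empty(len(iv), dtype=bool)
    new_block[0] = True
    new_block[1:] = iv[1:, 0] > cummax_end[:-1]
    block_id = np.cumsum(new_block) - 1
    starts = iv[new_block, 0]
    ends = np.maximum.reduceat(iv[:, 1], np.flatnonzero(new_block))
    out = np.column_stack([starts, ends])
    del block_id
    return out.astype(np.int64)


def merge_overlapping(track: ElementTrack) -> ElementTrack:
    """Union overlapping or book-ended elements per chromosome.

    Required before spacer computation so every spacer is strictly
    positive.  Idempotent; names and strands of merged blocks are
    dropped (set to ``.``).
    """
    frames = []
    for chrom in track.chromosomes:
        merged = _merge_interval_array(track.intervals(chrom))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": merged[:, 0],
                    "end": merged[:, 1],
                    "name": ".",
                    "strand": ".",
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else _empty_frame()
    return ElementTrack(df, chrom_sizes=track.chrom_sizes)


def compute_spacers(track: ElementTrack, chrom: str) -> SpacerSet:
    """Gaps between consecutive elements: ``S_i = start(i+1) - end(i)``.

    Distances from the chromosome boundaries to the first/last element
    are not included.  The track must already be overlap-merged.  A
    chromosome absent from the track yields an empty SpacerSet.
    """
    iv = track.intervals(chrom)
    if len(iv) == 0:
        return SpacerSet(chrom, np.array([], dtype=np.int64), 0)
    gaps = iv[1:, 0] - iv[:-1, 1]
    if len(gaps) and gaps.min() <= 0:
        raise ValueError(
            f"non-positive spacer on {chrom}: merge the track first"
        )
    return SpacerSet(chrom, gaps, int(len(iv)))


def build_gene_mask(
    genes: ElementTrack, flank5: int = 5000, flank3: int = 2000
) -> MaskTrack:
    """Extend every gene by its flanks, strand-aware, and merge.

    ``flank5`` bp are added upstream of the 5' end and ``flank3`` bp
    downstream of the 3' end; on the minus strand the sides swap.
    Records without strand get the larger flank on both sides
    (conservative masking).  Extensions are clipped to
    ``[0, chrom_size]`` when sizes are known.
    """
    if flank5 < 0 or flank3 < 0:
        raise ValueError("flanks must be non-negative")
    big = max(flank5, flank3)
    intervals: dict[str, np.ndarray] = {}
    for chrom in genes.chromosomes:
        sub = genes.df[genes.df["chrom"] == chrom]
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        strand = sub["strand"].to_numpy()
        left = np.where(
            strand == "+", flank5, np.where(strand == "-", flank3, big)
        )
        right = np.where(
            strand == "+", flank3, np.where(strand == "-", flank5, big)
        )
        lo = np.maximum(starts - left, 0)
        hi = ends + right
        if genes.chrom_sizes and chrom in genes.chrom_sizes:
            hi = np.minimum(hi, genes.chrom_sizes[chrom])
        intervals[chrom] = np.column_stack([lo, hi])
    return MaskTrack(intervals)


def apply_mask(track: ElementTrack, mask: MaskTrack) -> ElementTrack:
    """Drop every element overlapping the mask by >= 1 bp.

    Survivors keep their original coordinates: the masked space is
    excluded from the element set but the coordinate axis is not
    collapsed, so spacers remain distances on the physical chromosome.
    """
    keep_parts = []
    for chrom in track.chromosomes:
        sub = track.df[track.df["chrom"] == chrom]
        miv = mask.intervals.get(chrom)
        if miv is None or not len(miv):
            keep_parts.append(sub)
            continue
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        # element [s, e) overlaps some mask [ms, me) iff s < me and ms < e;
        # with disjoint sorted mask intervals a searchsorted test suffices
        idx = np.searchsorted(miv[:, 1], starts, side="right")
        overlaps = (idx < len(miv)) & (miv[np.minimum(idx, len(miv) - 1), 0] < ends)
        keep_parts.append(sub[~overlaps])
    df = pd.concat(keep_parts, ignore_index=True) if keep_parts else _empty_frame()
    return ElementTrack(df, chrom_sizes=track.chrom_sizes)


def downsample(track: ElementTrack, n: int, seed: int) -> ElementTrack:
    """Uniform random subset of ``n`` elements, without replacement."""
    total = len(track)
    if n > total:
        raise ValueError(f"cannot downsample {total} elements to {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(total, size=n, replace=False)
    df = track.df.iloc[np.sort(idx)].reset_index(drop=True)
    return ElementTrack(df, chrom_sizes=track.chrom_sizes)


def merge_tracks(a: ElementTrack, b: ElementTrack) -> ElementTrack:
    """Union of two tracks: concatenate, re-sort, overlap-merge."""
    if a.chrom_sizes and b.chrom_sizes:
        for chrom in set(a.chrom_sizes) & set(b.chrom_sizes):
            if a.chrom_sizes[chrom] != b.chrom_sizes[chrom]:
                raise ValueError(f"conflicting sizes for {chrom}")
    sizes = None
    if a.chrom_sizes or b.chrom_sizes:
        sizes = {**(a.chrom_sizes or {}), **(b.chrom_sizes or {})}
    df = pd.concat([a.df, b.df], ignore_index=True)
    return merge_overlapping(ElementTrack(df, chrom_sizes=sizes))
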