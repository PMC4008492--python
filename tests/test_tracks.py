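"""Interval arithmetic, BED I/O, spacers and the gene-masking protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnespacers.tracks import (
    ElementTrack,
    GenomicElement,
    apply_mask,
    build_gene_mask,
    compute_spacers,
    downsample,
    merge_overlapping,
    merge_tracks,
    read_elements,
    write_elements,
)

from conftest import make_track, random_intervals


def occupancy_union(intervals, span):
    """Brute-force per-base boolean occupancy, as disjoint intervals."""
    occ = np.zeros(span, dtype=bool)
    for s, e in intervals:
        occ[s:e] = True
    edges = np.flatnonzero(np.diff(np.concatenate([[0], occ.view(np.int8), [0]])))
    return edges.reshape(-1, 2)


class TestGenomicElement:
    def test_rejects_inverted_interval(self):
        with pytest.raises(ValueError):
            GenomicElement("chr1", 30, 20)

    def test_rejects_empty_chrom(self):
        with pytest.raises(ValueError):
            GenomicElement("", 0, 10)


class TestReadElements:
    def test_basic_parse(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t0\t10\nchr1\t20\t30\nchr2\t5\t8\n")
        track = read_elements(bed)
        assert track.counts() == {"chr1": 2, "chr2": 1}
        assert track.chromosomes == ["chr1", "chr2"]

    def test_empty_file(self, tmp_path):
        bed = tmp_path / "empty.bed"
        bed.write_text("")
        assert len(read_elements(bed)) == 0

    def test_inverted_interval_names_line(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t0\t10\nchr1\t30\t20\n")
        with pytest.raises(ValueError, match=":2"):
            read_elements(bed)

    def test_beyond_chrom_size(self, tmp_path):
        bed = tmp_path / "b.bed"
        bed.write_text("chr1\t0\t10\nchr1\t90\t200\n")
        sizes = tmp_path / "c.sizes"
        sizes.write_text("chr1\t100\n")
        with pytest.raises(ValueError, match=":2"):
            read_elements(bed, chrom_sizes=sizes)

    def test_strand_column_used_when_present(self, tmp_path):
        bed = tmp_path / "s.bed"
        bed.write_text("chr1\t0\t10\tg1\t0\t-\nchr1\t20\t30\n")
        track = read_elements(bed)
        assert list(track.df["strand"]) == ["-", "."]

    def test_roundtrip(self, tmp_path, rng):
        iv = random_intervals(rng, 50, 10_000)
        track = merge_overlapping(make_track(iv))
        out = tmp_path / "out.bed"
        write_elements(track, out)
        back = read_elements(out)
        assert (back.df[["start", "end"]].values == track.df[["start", "end"]].values).all()


class TestMergeOverlapping:
    def test_union_definition(self):
        track = make_track([(0, 10), (5, 15), (20, 30)])
        merged = merge_overlapping(track)
        assert merged.intervals("chr1").tolist() == [[0, 15], [20, 30]]

    def test_book_ended_joined(self):
        merged = merge_overlapping(make_track([(0, 10), (10, 20)]))
        assert merged.intervals("chr1").tolist() == [[0, 20]]

    def test_idempotent_on_disjoint(self):
        track = make_track([(0, 10), (20, 30)])
        merged = merge_overlapping(track)
        assert (merged.df[["start", "end"]].values == track.df[["start", "end"]].values).all()

    def test_random_against_occupancy_oracle(self, rng):
        iv = random_intervals(rng, 200, 5000)
        merged = merge_overlapping(make_track(iv)).intervals("chr1")
        expected = occupancy_union(iv, 6000)
        assert (merged == expected).all()

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 60)), min_size=1, max_size=40))
    def test_idempotence_property(self, raw):
        iv = [(s, s + l) for s, l in raw]
        once = merge_overlapping(make_track(iv))
        twice = merge_overlapping(once)
        assert once.intervals("chr1").tolist() == twice.intervals("chr1").tolist()
        # disjoint with strictly positive gaps
        arr = once.intervals("chr1")
        assert (arr[1:, 0] > arr[:-1, 1]).all()


class TestComputeSpacers:
    def test_definition(self):
        track = make_track([(0, 10), (20, 30), (50, 60)])
        assert sorted(compute_spacers(track, "chr1").spacers.tolist()) == [10, 20]

    def test_single_element(self):
        s = compute_spacers(make_track([(5, 9)]), "chr1")
        assert len(s) == 0 and s.n_elements == 1

    def test_absent_chromosome_is_empty_not_error(self):
        s = compute_spacers(make_track([(5, 9)]), "chrX")
        assert len(s) == 0 and s.n_elements == 0

    def test_random_against_pairwise_oracle(self, rng):
        iv = random_intervals(rng, 500, 200_000)
        merged = merge_overlapping(make_track(iv))
        arr = merged.intervals("chr1")
        expected = [int(arr[i + 1, 0] - arr[i, 1]) for i in range(len(arr) - 1)]
        got = compute_spacers(merged, "chr1")
        assert got.spacers.tolist() == expected
        assert len(got) == got.n_elements - 1
        assert (got.spacers > 0).all()


class TestGeneMask:
    def test_plus_strand_flanks(self):
        genes = make_track([(10_000, 20_000)], strands=["+"])
        mask = build_gene_mask(genes, 5000, 2000)
        assert mask.intervals["chr1"].tolist() == [[5000, 22_000]]

    def test_minus_strand_swaps_sides(self):
        genes = make_track([(10_000, 20_000)], strands=["-"])
        mask = build_gene_mask(genes, 5000, 2000)
        assert mask.intervals["chr1"].tolist() == [[8000, 25_000]]

    def test_clip_at_chromosome_start(self):
        genes = make_track([(1000, 2000)], strands=["+"])
        mask = build_gene_mask(genes, 5000, 2000)
        assert mask.intervals["chr1"].tolist() == [[0, 4000]]

    def test_unstranded_gets_larger_flank_both_sides(self):
        genes = make_track([(10_000, 20_000)])
        mask = build_gene_mask(genes, 5000, 2000)
        assert mask.intervals["chr1"].tolist() == [[5000, 25_000]]

    def test_zero_flanks_equal_merged_genes(self, rng):
        iv = random_intervals(rng, 60, 100_000, max_len=500)
        genes = make_track(iv, strands=list(np.where(rng.random(60) < 0.5, "+", "-")))
        mask = build_gene_mask(genes, 0, 0)
        merged = merge_overlapping(genes).intervals("chr1")
        assert mask.intervals["chr1"].tolist() == merged.tolist()

    def test_masked_length_equals_interval_sum(self):
        genes = make_track([(10_000, 20_000), (100_000, 110_000)], strands=["+", "-"])
        mask = build_gene_mask(genes, 5000, 2000)
        iv = mask.intervals["chr1"]
        assert mask.masked_length["chr1"] == int((iv[:, 1] - iv[:, 0]).sum())


class TestApplyMask:
    def test_any_overlap_removes(self):
        track = make_track([(100, 200)])
        mask = build_gene_mask(make_track([(150, 300)]), 0, 0)
        assert len(apply_mask(track, mask)) == 0

    def test_half_open_boundary_retained(self):
        track = make_track([(100, 200)])
        mask = build_gene_mask(make_track([(200, 300)]), 0, 0)
        assert len(apply_mask(track, mask)) == 1

    def test_survivor_coordinates_unchanged(self, rng):
        iv = random_intervals(rng, 300, 50_000)
        track = make_track(iv)
        mask = build_gene_mask(make_track(random_intervals(rng, 20, 50_000, 800)), 0, 0)
        survivors = apply_mask(track, mask)
        orig = {tuple(r) for r in track.df[["start", "end"]].values}
        assert all(tuple(r) in orig for r in survivors.df[["start", "end"]].values)

    def test_random_against_overlap_oracle(self, rng):
        iv = random_intervals(rng, 300, 50_000)
        track = make_track(iv)
        genes = make_track(random_intervals(rng, 20, 50_000, 800))
        mask = build_gene_mask(genes, 1000, 500)
        survivors = apply_mask(track, mask)
        miv = mask.intervals["chr1"]
        expected = sum(
            1
            for s, e in track.df[["start", "end"]].values
            if not any(s < me and ms < e for ms, me in miv)
        )
        assert len(survivors) == expected


class TestDownsample:
    def test_identity_at_full_count(self, rng):
        track = make_track(random_intervals(rng, 40, 10_000))
        same = downsample(track, len(track), seed=1)
        assert (same.df[["start", "end"]].values == track.df[["start", "end"]].values).all()

    def test_subset_and_determinism(self, rng):
        track = make_track(random_intervals(rng, 500, 1_000_000))
        a = downsample(track, 50, seed=7)
        b = downsample(track, 50, seed=7)
        c = downsample(track, 50, seed=8)
        assert (a.df.values == b.df.values).all()
        assert not (a.df[["start", "end"]].values == c.df[["start", "end"]].values).all()
        orig = {tuple(r) for r in track.df[["start", "end"]].values}
        assert all(tuple(r) in orig for r in a.df[["start", "end"]].values)

    def test_oversample_errors(self):
        with pytest.raises(ValueError):
            downsample(make_track([(0, 5)]), 2, seed=0)


class TestMergeTracks:
    def test_disjoint_union(self):
        a = make_track([(0, 10), (20, 30)])
        b = make_track([(40, 50), (60, 70), (80, 90)])
        assert len(merge_tracks(a, b)) == 5

    def test_identity_with_empty(self):
        a = make_track([(0, 10), (20, 30)])
        out = merge_tracks(a, ElementTrack())
        assert out.intervals("chr1").tolist() == [[0, 10], [20, 30]]

    def test_overlap_count_against_occupancy(self, rng):
        iva = random_intervals(rng, 100, 5000)
        ivb = random_intervals(rng, 100, 5000)
        merged = merge_tracks(make_track(iva), make_track(ivb))
        expected = occupancy_union(np.vstack([iva, ivb]), 6000)
        assert merged.intervals("chr1").tolist() == expected.tolist()

    def test_conflicting_sizes_error(self):
        a = make_track([(0, 10)], sizes={"chr1": 1000})
        b = make_track([(0, 10)], sizes={"chr1": 2000})
        with pytest.raises(ValueError, match="conflicting"):
            merge_tracks(a, b)

    def test_commutes_with_merge_overlapping(self, rng):
        iva = random_intervals(rng, 80, 4000)
        ivb = random_intervals(rng, 80, 4000)
        a, b = make_track(iva), make_track(ivb)
        left = merge_tracks(merge_overlapping(a), merge_overlapping(b))
        right = merge_tracks(a, b)
        assert left.intervals("chr1").tolist() == right.intervals("chr1").tolist()


def test_merge_matches_pyranges():
    """Independent cross-check of interval union against pyranges."""
    pr = pytest.importorskip("pyranges")
    rng = np.random.default_rng(3)
    iv = random_intervals(rng, 150, 8000)
    ours = merge_overlapping(make_track(iv)).intervals("chr1")
    gr = pr.PyRanges(
        pd.DataFrame({"Chromosome": "chr1", "Start": iv[:, 0], "End": iv[:, 1]})
    ).merge(slack=0)
    theirs = gr.df[["Start", "End"]].sort_values("Start").values
    assert ours.tolist() == theirs.tolist()
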