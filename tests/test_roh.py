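"""Window ROH caller vs an exhaustive brute-force oracle, plus FROH/dating."""

import numpy as np
import pytest

from erosim.engine import GenotypeMatrix
from erosim.roh import (
    DatingParams,
    ROHParams,
    ROHSegment,
    call_roh_hetrate,
    call_roh_window,
    date_roh,
    froh,
    merge_segments,
)


def brute_force_roh(positions, geno_row, p: ROHParams):
    """Direct re-statement of the window rules with plain loops."""
    n = len(positions)
    w = p.window_snp
    windows = []
    for a in range(0, n - w + 1):
        block = geno_row[a: a + w]
        windows.append(
            (block == 1).sum() <= p.window_het and (block == -1).sum() <= p.window_missing
        )
    eligible = []
    for j in range(n):
        cover = [windows[a] for a in range(max(0, j - w + 1), min(j + 1, len(windows)))]
        eligible.append(
            len(cover) > 0 and sum(cover) / len(cover) >= 1 - p.window_threshold
        )
    segments = []
    run = []
    for j in range(n):
        if eligible[j]:
            if run and (positions[j] - positions[run[-1]]) > p.max_gap_kb * 1000:
                segments.append(run)
                run = []
            run.append(j)
        else:
            if run:
                segments.append(run)
            run = []
    if run:
        segments.append(run)
    out = []
    for run in segments:
        start, end = positions[run[0]], positions[run[-1]] + 1
        length_kb = (end - start) / 1000
        if (
            length_kb >= p.min_length_kb
            and len(run) >= p.min_snps
            and length_kb / len(run) <= p.min_density_kb_per_snp
        ):
            out.append((int(start), int(end), len(run)))
    return out


def as_tuples(segments):
    return [(s.start, s.end, s.n_snps) for s in segments]


def matrix(positions, rows):
    return GenotypeMatrix(np.asarray(rows, np.int8), np.asarray(positions, np.int64))


class TestWindowCallerOracle:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(40, 200))
        positions = np.sort(rng.choice(2_000_000, n, replace=False))
        # blocky genotypes so candidate runs actually form
        geno = np.zeros(n, np.int8)
        i = 0
        while i < n:
            span = int(rng.integers(5, 70))
            kind = rng.choice([0, 1, 2, -1], p=[0.45, 0.3, 0.2, 0.05])
            geno[i: i + span] = kind
            i += span
        params = ROHParams(min_snps=int(rng.integers(5, 50)),
                           min_length_kb=float(rng.integers(1, 20)))
        got = as_tuples(call_roh_window(matrix(positions, [geno]), params))
        assert got == brute_force_roh(positions, geno, params)

    def test_planted_tract_recovered_once(self):
        """A long homozygous tract in het-dense flanks yields exactly one
        segment, inside the tract, matching the oracle."""
        rng = np.random.default_rng(42)
        # 60 flank SNPs, 140 tract SNPs over ~100 kb, 60 flank SNPs
        pos = np.sort(rng.choice(200_000, 120, replace=False))
        tract_pos = np.sort(rng.choice(100_000, 140, replace=False)) + 250_000
        pos2 = np.sort(rng.choice(200_000, 120, replace=False)) + 400_000
        positions = np.concatenate([pos[:60], tract_pos, pos2[:60]])
        geno = np.concatenate(
            [rng.choice([1, 2], 60, p=[0.8, 0.2]),
             np.zeros(140, np.int8),
             rng.choice([1, 2], 60, p=[0.8, 0.2])]
        ).astype(np.int8)
        params = ROHParams()
        segs = call_roh_window(matrix(positions, [geno]), params)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.start >= tract_pos[0] and seg.end <= tract_pos[-1] + 1
        assert seg.length_kb > 40  # covers the tract core
        assert as_tuples(segs) == brute_force_roh(positions, geno, params)

    def test_all_heterozygous_yields_nothing(self):
        positions = np.arange(100) * 1000
        geno = np.ones(100, np.int8)
        assert call_roh_window(matrix(positions, [geno])) == []

    def test_short_tract_fails_length_filter(self):
        # fully homozygous but spanning only 5 kb < 10 kb minimum
        positions = np.sort(np.random.default_rng(0).choice(5000, 60, replace=False))
        geno = np.zeros(60, np.int8)
        assert call_roh_window(matrix(positions, [geno])) == []

    def test_sparse_tract_fails_density_filter(self):
        # 60 hom SNPs spread over 4 Mb: 66 kb/SNP > 50 kb/SNP limit
        positions = np.arange(60) * 67_000
        geno = np.zeros(60, np.int8)
        assert call_roh_window(matrix(positions, [geno])) == []

    def test_too_few_snps_fails_count_filter(self):
        positions = np.arange(40) * 1000
        geno = np.zeros(40, np.int8)
        assert call_roh_window(matrix(positions, [geno])) == []

    def test_large_gap_splits_run(self):
        # two dense hom clusters separated by 150 kb > 100 kb gap
        cluster = np.arange(100) * 3000
        positions = np.concatenate([cluster, cluster + cluster[-1] + 150_001])
        geno = np.zeros(200, np.int8)
        segs = call_roh_window(matrix(positions, [geno]))
        assert len(segs) == 2

    def test_unsorted_sites_rejected(self):
        gm = GenotypeMatrix(np.zeros((1, 3), np.int8), np.array([1, 5, 9]))
        gm.positions = np.array([5, 1, 9])  # corrupt after validation
        with pytest.raises(ValueError):
            call_roh_window(gm)


class TestHetRateCaller:
    def test_rate_thresholds(self):
        # 500 kb windows, rohmu 2e-5 -> <= 10 hets is ROH (boundary inclusive)
        segs = call_roh_hetrate([0, 5, 10, 11, 50, 0], 500_000, 2e-5)
        assert [(s.start, s.end) for s in segs] == [
            (0, 1_500_000),
            (2_500_000, 3_000_000),
        ]

    def test_all_roh_merges_to_one(self):
        segs = call_roh_hetrate([0, 0, 0], 500_000, 2e-5)
        assert [(s.start, s.end) for s in segs] == [(0, 1_500_000)]

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            call_roh_hetrate([0], 0, 2e-5)


class TestFroh:
    def test_simple_fraction(self):
        segs = [ROHSegment(0, 0, 12_000_000)]
        assert froh(segs, 120_000_000) == pytest.approx(0.1)

    def test_no_segments(self):
        assert froh([], 1000) == 0.0

    def test_overlap_merged_and_order_invariant(self):
        a = ROHSegment(0, 0, 10_000)
        b = ROHSegment(0, 5_000, 15_000)
        assert froh([a, b], 100_000) == pytest.approx(0.15)
        assert froh([b, a], 100_000) == pytest.approx(0.15)
        # splitting a segment changes nothing
        c1, c2 = ROHSegment(0, 0, 7_000), ROHSegment(0, 7_000, 10_000)
        assert froh([c1, c2, b], 100_000) == pytest.approx(0.15)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            froh([ROHSegment(0, 0, 2000)], 1000)


class TestDating:
    @pytest.mark.parametrize(
        "length_mb,cm,gens,years",
        [
            (1.0, 2.0, 25.0, 85.0),
            # mean observed tract length 22.6 kb on a 1.86 cM/Mb map
            (0.0226, 1.86, 1189.5, 4044.1),
            (50.0, 1.0, 1.0, 3.4),
        ],
    )
    def test_examples(self, length_mb, cm, gens, years):
        g, y = date_roh(length_mb, DatingParams(cM_per_Mb=cm))
        assert g == pytest.approx(gens, abs=0.05)
        assert y == pytest.approx(years, abs=0.2)

    def test_strictly_decreasing_in_length_and_map(self):
        lengths = np.linspace(0.01, 10, 40)
        gens = [date_roh(l, DatingParams(cM_per_Mb=1.8))[0] for l in lengths]
        assert all(a > b for a, b in zip(gens, gens[1:]))
        cms = np.linspace(1.0, 3.0, 20)
        gens = [date_roh(1.0, DatingParams(cM_per_Mb=c))[0] for c in cms]
        assert all(a > b for a, b in zip(gens, gens[1:]))

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            date_roh(0.0)


def test_merge_segments_union():
    segs = [ROHSegment(0, 10, 20), ROHSegment(0, 15, 30), ROHSegment(0, 50, 60)]
    assert merge_segments(segs) == [(10, 30), (50, 60)]
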