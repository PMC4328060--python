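"""Run-of-homozygosity detection, parental exclusion, shared consensus."""

import numpy as np
import pandas as pd
import pytest

from recmap.roh import (
    MISSING,
    GenotypeMatrix,
    ROHParams,
    ROHSegment,
    detect_roh,
    exclude_parental,
    genome_fraction_homozygous,
    intersect_candidates,
    shared_homozygosity,
)


# ---------------------------------------------------------------------------
# Independent brute-force oracle: same documented selection rule, but every
# window's constraints are recomputed from scratch, quadratically.
# ---------------------------------------------------------------------------

def _window_ok(pos, call, s, j, p):
    window = call[s:j + 1]
    if (window == 1).sum() > p.max_het_per_run:
        return False
    if (window == MISSING).sum() > p.max_missing_per_run:
        return False
    gaps = np.diff(pos[s:j + 1])
    return len(gaps) == 0 or gaps.max() <= p.max_gap_bp


def brute_force_roh(pos, call, p):
    n = len(pos)
    segs = []
    s = 0
    while s < n:
        j = s
        while j + 1 < n and _window_ok(pos, call, s, j + 1, p):
            j += 1
        ts, tj = s, j
        while ts <= tj and call[ts] in (1, MISSING):
            ts += 1
        while tj >= ts and call[tj] in (1, MISSING):
            tj -= 1
        if (
            tj >= ts
            and tj - ts + 1 >= p.min_markers
            and pos[tj] - pos[ts] + 1 >= p.min_length_bp
        ):
            segs.append((int(pos[ts]), int(pos[tj]), tj - ts + 1))
            s = j + 1
        else:
            s += 1
    return segs


def _matrix(pos, call, chrom="1", ind="X"):
    mm = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"})
    return GenotypeMatrix(mm, np.array(call, dtype=np.int8)[:, None], [ind])


class TestDetectROH:
    def test_all_het_individual_empty(self):
        pos = np.arange(1, 101) * 10_000
        gm = _matrix(pos, [1] * 100)
        assert detect_roh(gm, "X") == []

    def test_planted_tract_with_one_het(self):
        # 60-marker 1.5 Mb homozygous tract with a single het call inside,
        # flanked by heterozygous background
        pos = np.concatenate([
            np.arange(10) * 30_000 + 1,
            np.arange(60) * 25_000 + 1_000_000,     # tract: 1.475 Mb span
            np.arange(10) * 30_000 + 3_000_000,
        ])
        call = [1] * 10 + [2] * 30 + [1] + [2] * 29 + [1] * 10
        gm = _matrix(pos, call)
        params = ROHParams(min_markers=50, min_length_bp=1_000_000,
                          max_het_per_run=1, max_missing_per_run=2,
                          max_gap_bp=1_000_000)
        segs = detect_roh(gm, "X", params)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.start <= 1_000_000 and seg.end >= 1_000_000 + 59 * 25_000
        assert seg.n_het <= 1 and seg.n_markers >= 50

    def test_short_tract_below_min_markers_dropped(self):
        pos = np.concatenate([
            np.arange(10) * 30_000 + 1,
            np.arange(40) * 30_000 + 1_000_000,     # only 40 markers
            np.arange(10) * 30_000 + 3_000_000,
        ])
        call = [1] * 10 + [0] * 40 + [1] * 10
        gm = _matrix(pos, call)
        assert detect_roh(gm, "X", ROHParams(min_markers=50)) == []

    def test_unknown_individual_raises(self):
        gm = _matrix(np.arange(1, 11) * 1000, [0] * 10)
        with pytest.raises(KeyError):
            detect_roh(gm, "ghost")

    def test_unsorted_map_rejected_at_construction(self):
        mm = pd.DataFrame({"chrom": "1", "pos": [5, 3, 9],
                           "ref": "A", "alt": "G"})
        with pytest.raises(ValueError, match="increasing"):
            GenotypeMatrix(mm, np.zeros((3, 1), dtype=np.int8), ["X"])

    @pytest.mark.parametrize("trial", range(30))
    def test_equals_brute_force_on_random_matrices(self, trial):
        rng = np.random.default_rng(7000 + trial)
        n = int(rng.integers(20, 500))
        pos = np.cumsum(rng.integers(1_000, 60_000, size=n))
        call = rng.choice(
            [0, 1, 2, MISSING], size=n, p=[0.42, 0.12, 0.42, 0.04]
        ).astype(np.int8)
        params = ROHParams(
            min_markers=int(rng.integers(3, 12)),
            min_length_bp=int(rng.integers(10_000, 300_000)),
            max_het_per_run=int(rng.integers(0, 3)),
            max_missing_per_run=int(rng.integers(0, 3)),
            max_gap_bp=int(rng.integers(30_000, 200_000)),
        )
        gm = _matrix(pos, call)
        got = [(s.start, s.end, s.n_markers) for s in detect_roh(gm, "X", params)]
        assert got == brute_force_roh(pos, call, params)

    def test_segments_satisfy_all_thresholds(self, small_cohort, small_config):
        gm = GenotypeMatrix(small_cohort.marker_map, small_cohort.calls,
                            small_cohort.individuals)
        p = ROHParams()
        for seg in detect_roh(gm, "case1", p):
            assert seg.n_markers >= p.min_markers
            assert seg.length >= p.min_length_bp
            assert seg.n_het <= p.max_het_per_run
            assert seg.n_missing <= p.max_missing_per_run

    def test_segments_non_overlapping_per_chromosome(self, small_cohort):
        gm = GenotypeMatrix(small_cohort.marker_map, small_cohort.calls,
                            small_cohort.individuals)
        segs = detect_roh(gm, "case1")
        by_chrom = {}
        for s in segs:
            by_chrom.setdefault(s.chrom, []).append(s.interval())
        for ivals in by_chrom.values():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                assert s2 > e1


def _seg(ind, chrom, start, end):
    return ROHSegment(individual=ind, chrom=chrom, start=start, end=end,
                      n_markers=100)


class TestExcludeParental:
    def test_case_segment_inside_parental_removed(self):
        case = [_seg("c", "1", 2_000_000, 4_000_000)]
        parents = {"p": [_seg("p", "1", 1_000_000, 5_000_000)]}
        assert exclude_parental(case, parents, 1_000_000) == []

    def test_no_overlap_unchanged(self):
        case = [_seg("c", "1", 2_000_000, 4_000_000)]
        parents = {"p": [_seg("p", "2", 2_000_000, 4_000_000)]}
        assert exclude_parental(case, parents, 1_000_000) == case

    def test_left_end_subtraction_leaves_two_mb(self):
        case = [_seg("c", "1", 1_000_000, 4_000_000)]      # 3 Mb + 1 bp
        parents = {"p": [_seg("p", "1", 500_000, 2_000_000)]}
        out = exclude_parental(case, parents, 1_000_000)
        assert [(s.start, s.end) for s in out] == [(2_000_001, 4_000_000)]

    def test_piece_below_min_novel_dropped(self):
        case = [_seg("c", "1", 1_000_000, 4_000_000)]
        parents = {"p": [_seg("p", "1", 1_500_000, 4_000_000)]}
        assert exclude_parental(case, parents, 1_000_000) == []

    def test_reject_mode_drops_whole_segment(self):
        case = [_seg("c", "1", 1_000_000, 4_000_000)]
        parents = {"p": [_seg("p", "1", 3_999_999, 5_000_000)]}
        assert exclude_parental(case, parents, 1, mode="reject") == []
        kept = exclude_parental(case, parents, 1, mode="subtract")
        assert [(s.start, s.end) for s in kept] == [(1_000_000, 3_999_998)]

    def test_output_never_overlaps_parents(self):
        rng = np.random.default_rng(3)
        case, parents = [], {"p1": [], "p2": []}
        for _ in range(30):
            s = int(rng.integers(1, 50_000_000))
            case.append(_seg("c", "1", s, s + int(rng.integers(1, 5_000_000))))
        for p in parents:
            for _ in range(30):
                s = int(rng.integers(1, 50_000_000))
                parents[p].append(
                    _seg(p, "1", s, s + int(rng.integers(1, 5_000_000))))
        out = exclude_parental(case, parents, 100_000)
        for seg in out:
            for psegs in parents.values():
                for p in psegs:
                    assert seg.end < p.start or seg.start > p.end


class TestSharedHomozygosity:
    def _two_case_matrix(self, calls_a, calls_b, pos=None):
        n = len(calls_a)
        pos = pos if pos is not None else np.arange(1, n + 1) * 10_000
        mm = pd.DataFrame({"chrom": "1", "pos": pos, "ref": "A", "alt": "G"})
        calls = np.stack([calls_a, calls_b], axis=1).astype(np.int8)
        return GenotypeMatrix(mm, calls, ["c1", "c2"])

    def test_single_case_identity(self, small_cohort):
        gm = GenotypeMatrix(small_cohort.marker_map, small_cohort.calls,
                            small_cohort.individuals)
        segs = detect_roh(gm, "case1")
        assert shared_homozygosity({"case1": segs}, gm) == segs

    def test_opposite_alleles_excluded(self):
        gm = self._two_case_matrix([2] * 50, [0] * 50)
        segs = {
            "c1": [_seg("c1", "1", 10_000, 500_000)],
            "c2": [_seg("c2", "1", 10_000, 500_000)],
        }
        assert shared_homozygosity(segs, gm) == []

    def test_same_allele_intersection_kept(self):
        gm = self._two_case_matrix([2] * 50, [2] * 50)
        segs = {
            "c1": [_seg("c1", "1", 10_000, 400_000)],
            "c2": [_seg("c2", "1", 200_000, 500_000)],
        }
        out = shared_homozygosity(segs, gm)
        assert [(s.start, s.end) for s in out] == [(200_000, 400_000)]

    def test_shared_tract_vs_private_tracts(self, small_config):
        # on the simulated family, tracts shared by all three cases must
        # contain the planted deletion locus (it is IBD in all cases)
        from recmap.cohort import simulate_cohort

        c = simulate_cohort(small_config)
        gm = GenotypeMatrix(c.marker_map, c.calls, c.individuals)
        segs = {case: detect_roh(gm, case) for case in
                ("case1", "case2", "case3")}
        shared = shared_homozygosity(segs, gm)
        d = c.truth["deletion"]
        hit = [s for s in shared if s.chrom == d["chrom"]
               and s.start <= d["start"] and s.end >= d["end"]]
        assert len(hit) == 1


class TestSummaries:
    def test_no_segments_zero(self):
        assert genome_fraction_homozygous([], 1_000_000) == 0.0

    def test_single_segment_quarter(self):
        seg = _seg("x", "1", 1, 25_000_000)
        assert genome_fraction_homozygous([seg], 100_000_000) == 0.25

    def test_overlapping_segments_rejected(self):
        segs = [_seg("x", "1", 1, 100), _seg("x", "1", 50, 200)]
        with pytest.raises(ValueError, match="overlap"):
            genome_fraction_homozygous(segs, 1_000)

    def test_invalid_genome_length(self):
        with pytest.raises(ValueError):
            genome_fraction_homozygous([], 0)


class TestIntersectCandidates:
    BED = pd.DataFrame({
        "chrom": ["1", "1", "2"],
        "start": [999, 5_000, 100],      # 0-based BED starts
        "end": [2_000, 6_000, 200],
        "name": ["G1", "G2", "G3"],
    })

    def test_empty_regions(self):
        assert intersect_candidates([], self.BED) == []

    def test_one_bp_overlap_counts(self):
        region = _seg("c", "1", 2_000, 3_000)     # touches G1's last base
        out = intersect_candidates([region], self.BED)
        assert [g for g, _ in out] == ["G1"]

    def test_abutting_gene_excluded(self):
        region = _seg("c", "1", 2_001, 3_000)     # starts just past G1
        assert intersect_candidates([region], self.BED) == []

    def test_eight_of_eighteen_recovered(self):
        # 18 genes, 8 placed inside mapped regions
        rng = np.random.default_rng(2)
        rows, regions = [], []
        for i in range(18):
            if i < 8:
                start = 10_000_000 * (i + 1)
                regions.append(_seg("c", "1", start - 50_000, start + 50_000))
            else:
                start = 10_000_000 * (i + 1) + 2_000_000   # off-region
            rows.append({"chrom": "1", "start": start - 1,
                         "end": start + 5_000, "name": f"G{i}"})
        bed = pd.DataFrame(rows)
        hit = sorted({g for g, _ in intersect_candidates(regions, bed)})
        assert hit == [f"G{i}" for i in range(8)]
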