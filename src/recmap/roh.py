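"""Runs-of-homozygosity detection and autozygosity mapping.

The mapping stage of the pipeline: per-individual ROH detection on a dense
SNP genotype matrix, subtraction of regions already homozygous in the
parents, shared-allele consensus across multiple cases, genome-fraction
summaries, and intersection with candidate-gene intervals.

Run detection is exact and run-based rather than a sliding-window
proportion heuristic: a reported segment is a maximal stretch of
consecutive markers satisfying hard het/missing/gap allowances, found by a
deterministic leftmost-maximal greedy scan with homozygous-end trimming.
This diverges from PLINK's windowed scoring by design — it is oracle-
checkable against brute-force window enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROHParams",
    "ROHSegment",
    "GenotypeMatrix",
    "detect_roh",
    "exclude_parental",
    "shared_homozygosity",
    "genome_fraction_homozygous",
    "intersect_candidates",
]

MISSING = -1  # call coding: 0 hom-ref, 1 het, 2 hom-alt, -1 missing


@dataclass(frozen=True)
class ROHParams:
    """Hard thresholds for a reportable run.

    Defaults are PLINK-homozyg-like: at least 50 markers and 1 Mb, at most
    1 heterozygous and 2 missing calls per run, and no inter-marker gap
    above 1 Mb.
    """

    min_markers: int = 50
    min_length_bp: int = 1_000_000
    max_het_per_run: int = 1
    max_missing_per_run: int = 2
    max_gap_bp: int = 1_000_000


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run; coordinates 1-based inclusive marker positions."""

    individual: str
    chrom: str
    start: int
    end: int
    n_markers: int = 0
    n_het: int = 0
    n_missing: int = 0
    signature: tuple = ()   # homozygous calls (0/2) over the run, missing/het as -9

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def interval(self) -> tuple[int, int]:
        return self.start, self.end


class GenotypeMatrix:
    """Individuals x ordered biallelic markers with bp positions.

    ``calls`` is (n_markers, n_individuals) int8 in {0, 1, 2, -1}; marker
    positions must strictly increase within each chromosome.
    """

    def __init__(self, marker_map: pd.DataFrame, calls: np.ndarray,
                 individuals: Sequence[str]):
        if len(marker_map) != calls.shape[0]:
            raise ValueError("marker map and call matrix disagree on marker count")
        if len(individuals) != calls.shape[1]:
            raise ValueError("individual list and call matrix disagree")
        for chrom, grp in marker_map.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos"].values) > 0):
                raise ValueError(f"marker positions not strictly increasing on {chrom}")
        self.marker_map = marker_map.reset_index(drop=True)
        self.calls = np.asarray(calls, dtype=np.int8)
        self.individuals = list(individuals)
        self._col = {iid: i for i, iid in enumerate(self.individuals)}

    @classmethod
    def from_tsv(cls, path: str) -> "GenotypeMatrix":
        """Read the transposed text dialect: columns chrom, pos, ref, alt,
        then one call column per individual ('.' = missing)."""
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        fixed = ["chrom", "pos", "ref", "alt"]
        inds = [c for c in df.columns if c not in fixed]
        calls = (
            df[inds].replace(".", str(MISSING)).astype(np.int8).values
        )
        return cls(df[fixed], calls, inds)

    @classmethod
    def from_vcf(cls, path: str) -> "GenotypeMatrix":
        """Read a multi-sample VCF of biallelic sites (via cyvcf2)."""
        from cyvcf2 import VCF

        vcf = VCF(path, gts012=True)
        rows, calls = [], []
        for var in vcf:
            if len(var.ALT) != 1:
                continue
            rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
            g = var.gt_types.astype(np.int8)  # 0,1,2; 3 = unknown
            g[g == 3] = MISSING
            calls.append(g)
        mm = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
        return cls(mm, np.array(calls, dtype=np.int8), list(vcf.samples))

    def column(self, individual: str) -> np.ndarray:
        if individual not in self._col:
            raise KeyError(f"unknown individual {individual!r}")
        return self.calls[:, self._col[individual]]

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.marker_map["chrom"]))


# ---------------------------------------------------------------------------
# Run detection
# ---------------------------------------------------------------------------

def detect_roh(
    genotypes: GenotypeMatrix, individual: str, params: ROHParams = ROHParams()
) -> list[ROHSegment]:
    """Maximal homozygous runs for one individual.

    Scans each chromosome left to right; from the current anchor marker the
    run is extended as far as the het/missing allowances and the gap limit
    permit (extension is monotone, so a two-pointer scan is exact), then
    trimmed so it starts and ends on a homozygous call. A trimmed run is
    reported when it meets both ``min_markers`` and ``min_length_bp``; the
    scan resumes after the reported run, so segments never overlap.
    """
    g = genotypes.column(individual)
    out: list[ROHSegment] = []
    mm = genotypes.marker_map
    for chrom in genotypes.chromosomes():
        idx = np.where(mm["chrom"].values == chrom)[0]
        pos = mm["pos"].values[idx].astype(np.int64)
        call = g[idx]
        out.extend(
            _scan_chromosome(individual, str(chrom), pos, call, params)
        )
    return out


def _scan_chromosome(ind, chrom, pos, call, p: ROHParams) -> list[ROHSegment]:
    n = len(pos)
    segs = []
    s = 0
    j = -1
    n_het = n_miss = 0
    while s < n:
        if j < s:
            j = s
            n_het = int(call[s] == 1)
            n_miss = int(call[s] == MISSING)
        # extend
        while j + 1 < n:
            if pos[j + 1] - pos[j] > p.max_gap_bp:
                break
            h = n_het + int(call[j + 1] == 1)
            m = n_miss + int(call[j + 1] == MISSING)
            if h > p.max_het_per_run or m > p.max_missing_per_run:
                break
            n_het, n_miss = h, m
            j += 1
        seg = _trim_and_build(ind, chrom, pos, call, s, j, p)
        if seg is not None:
            segs.append(seg)
            s = j + 1
            j = -1
        else:
            # slide the anchor one marker right
            n_het -= int(call[s] == 1)
            n_miss -= int(call[s] == MISSING)
            s += 1
            if j < s:
                j = -1
    return segs


def _trim_and_build(ind, chrom, pos, call, s, j, p: ROHParams):
    while s <= j and call[s] in (1, MISSING):
        s += 1
    while j >= s and call[j] in (1, MISSING):
        j -= 1
    if j < s:
        return None
    window = call[s:j + 1]
    n_markers = j - s + 1
    length = int(pos[j] - pos[s] + 1)
    if n_markers < p.min_markers or length < p.min_length_bp:
        return None
    sig = tuple(int(c) if c in (0, 2) else -9 for c in window)
    return ROHSegment(
        individual=ind, chrom=chrom, start=int(pos[s]), end=int(pos[j]),
        n_markers=n_markers,
        n_het=int((window == 1).sum()),
        n_missing=int((window == MISSING).sum()),
        signature=sig,
    )


# ---------------------------------------------------------------------------
# Parental exclusion
# ---------------------------------------------------------------------------

def exclude_parental(
    case_segments: Sequence[ROHSegment],
    parent_segments_by_parent: Mapping[str, Sequence[ROHSegment]],
    min_novel_length_bp: int,
    mode: str = "subtract",
) -> list[ROHSegment]:
    """Remove case homozygosity already present in either parent.

    ``mode='subtract'`` (default) performs interval subtraction and keeps
    the novel pieces at least ``min_novel_length_bp`` long; the alternative
    ``mode='reject'`` drops any case segment with >= 1 bp parental overlap
    wholesale. Marker counts are not recomputed on subtracted pieces.
    """
    if mode not in ("subtract", "reject"):
        raise ValueError("mode must be 'subtract' or 'reject'")
    parental: dict[str, list[tuple[int, int]]] = {}
    for segs in parent_segments_by_parent.values():
        for seg in segs:
            parental.setdefault(seg.chrom, []).append(seg.interval())
    for chrom in parental:
        parental[chrom] = _merge_intervals(parental[chrom])

    out = []
    for seg in case_segments:
        blockers = parental.get(seg.chrom, [])
        overlaps = [
            (max(s, seg.start), min(e, seg.end))
            for s, e in blockers
            if s <= seg.end and e >= seg.start
        ]
        if not overlaps:
            out.append(seg)
            continue
        if mode == "reject":
            continue
        for s, e in _subtract_interval(seg.interval(), overlaps):
            if e - s + 1 >= min_novel_length_bp:
                out.append(replace(seg, start=s, end=e,
                                   n_markers=0, n_het=0, n_missing=0,
                                   signature=()))
    return out


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivals = sorted(ivals)
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def _subtract_interval(ival, blockers):
    """1-based inclusive interval minus a sorted list of merged blockers."""
    s, e = ival
    pieces = []
    cur = s
    for bs, be in sorted(blockers):
        if be < cur or bs > e:
            continue
        if bs > cur:
            pieces.append((cur, bs - 1))
        cur = max(cur, be + 1)
    if cur <= e:
        pieces.append((cur, e))
    return pieces


# ---------------------------------------------------------------------------
# Shared-allele consensus across cases
# ---------------------------------------------------------------------------

def shared_homozygosity(
    segments_by_case: Mapping[str, Sequence[ROHSegment]],
    genotypes: GenotypeMatrix,
) -> list[ROHSegment]:
    """Intersect ROH segments across all cases and keep only intersections
    where every case is homozygous for the same allele at every genotyped
    marker inside; returns consensus regions labelled 'shared'.

    With a single case this is the identity.
    """
    if not segments_by_case:
        raise ValueError("need at least one case")
    cases = list(segments_by_case)
    if len(cases) == 1:
        return list(segments_by_case[cases[0]])

    out = []
    chroms = sorted({seg.chrom for segs in segments_by_case.values() for seg in segs})
    mm = genotypes.marker_map
    for chrom in chroms:
        ival_sets = []
        for case in cases:
            ivals = sorted(
                seg.interval() for seg in segments_by_case[case]
                if seg.chrom == chrom
            )
            ival_sets.append(ivals)
        common = ival_sets[0]
        for nxt in ival_sets[1:]:
            common = _intersect_sets(common, nxt)
        if not common:
            continue
        cidx = np.where(mm["chrom"].values == chrom)[0]
        pos = mm["pos"].values[cidx].astype(np.int64)
        cols = np.stack([genotypes.column(c)[cidx] for c in cases], axis=1)
        for s, e in common:
            inside = (pos >= s) & (pos <= e)
            win = cols[inside]
            genotyped = win != MISSING
            # at every marker, all genotyped calls homozygous and equal
            ok = True
            for row, grow in zip(win, genotyped):
                vals = row[grow]
                if len(vals) == 0:
                    continue
                if np.any((vals != 0) & (vals != 2)) or len(set(vals.tolist())) > 1:
                    ok = False
                    break
            if ok:
                out.append(
                    ROHSegment(individual="shared", chrom=chrom, start=int(s),
                               end=int(e), n_markers=int(inside.sum()))
                )
    return out


def _intersect_sets(a, b):
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if s <= e:
                out.append((s, e))
    return sorted(out)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def genome_fraction_homozygous(
    segments: Sequence[ROHSegment], genome_length_bp: int
) -> float:
    """Total non-overlapping segment length over genome length.

    Overlapping segments for one individual violate the detect_roh contract
    and raise.
    """
    if genome_length_bp <= 0:
        raise ValueError("genome length must be positive")
    per: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for seg in segments:
        per.setdefault((seg.individual, seg.chrom), []).append(seg.interval())
    total = 0
    for key, ivals in per.items():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping segments for {key[0]} on {key[1]}")
        total += sum(e - s + 1 for s, e in ivals)
    return total / genome_length_bp


def intersect_candidates(
    regions: Sequence[ROHSegment], candidate_genes: pd.DataFrame
) -> list[tuple[str, ROHSegment]]:
    """Candidate genes overlapping any mapped region by >= 1 bp.

    ``candidate_genes`` is BED-like (chrom, start [0-based], end, name);
    coordinates are normalised to 1-based inclusive before comparison.
    Returns (gene name, region) pairs, one per overlapping pair.
    """
    out = []
    for row in candidate_genes.itertuples(index=False):
        g_start, g_end = int(row.start) + 1, int(row.end)  # BED -> 1-based incl.
        for seg in regions:
            if seg.chrom == str(row.chrom) and not (
                g_end < seg.start or g_start > seg.end
            ):
                out.append((row.name, seg))
    return out
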