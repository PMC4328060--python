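"""Discordant read-pair deletion calling.

A simplified paired-end deletion caller in the Delly tradition: fit a
robust insert-size model from concordant forward-reverse pairs, flag pairs
whose apparent reference span exceeds the model by k robust standard
deviations, single-linkage-cluster their implied deleted intervals, report
per-cluster breakpoint intervals and a span-based size estimate, then
genotype each call from the discordant/concordant ratio at the breakpoints
corroborated by the read-depth ratio inside versus flanking the call.

Only deletions are called. Breakpoints are reported as confidence
intervals (the intersection of the implied inner gaps), not refined to
base pair resolution by split reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InsertSizeModel",
    "DeletionCall",
    "SVParams",
    "load_read_pairs",
    "read_pairs_from_sam",
    "apparent_span",
    "fit_insert_model",
    "find_discordant",
    "cluster_discordant",
    "genotype_deletion",
    "private_deletions",
    "supporting_pairs",
    "write_deletion_vcf",
]

READPAIR_COLUMNS = [
    "fragment_id", "chrom", "mate1_start", "mate1_end",
    "mate2_start", "mate2_end", "orientation", "mapq",
]


@dataclass(frozen=True)
class SVParams:
    """Caller heuristics (the field's conventional paired-end defaults)."""

    k: float = 3.0              # discordance at k robust SDs
    min_support: int = 3
    mapq_min: int = 20
    min_reciprocal_overlap: float = 0.5   # for cross-genome privacy matching
    # genotyping thresholds on r = discordant fraction, d = depth ratio
    hom_r: float = 0.8
    hom_d: float = 0.2
    het_r_lo: float = 0.3
    het_d_lo: float = 0.3
    het_d_hi: float = 0.7


@dataclass(frozen=True)
class InsertSizeModel:
    location: float    # median apparent span of concordant FR pairs (bp)
    scale: float       # 1.4826 x MAD (bp)
    k: float = 3.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("degenerate insert-size scale (<= 0)")
        if self.k <= 0:
            raise ValueError("k must be positive")

    @property
    def cutoff(self) -> float:
        return self.location + self.k * self.scale


@dataclass(frozen=True)
class DeletionCall:
    chrom: str
    start: int                  # breakpoint interval, 1-based inclusive
    end: int
    support: int
    estimated_size: float
    genotype: str = "unknown"   # hom_del | het_del | ref | ambiguous
    depth_ratio: float = float("nan")
    discordant_fraction: float = float("nan")
    genotype_reasons: tuple = ()
    fragment_ids: tuple = ()

    @property
    def size(self) -> int:
        return self.end - self.start + 1


def load_read_pairs(path: str) -> pd.DataFrame:
    """Read the flat read-pair table (TSV, SAM-subset semantics)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(READPAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"read-pair table missing columns: {sorted(missing)}")
    return df


def read_pairs_from_sam(path: str) -> pd.DataFrame:
    """Extract FR/RF/FF/RR pair records from a coordinate-sorted SAM/BAM.

    Uses only positions, flags and MAPQ of primary proper read-1 records
    paired with their mates on the same reference.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(path) as sam:
        for aln in sam:
            if (
                not aln.is_paired or aln.is_secondary or aln.is_supplementary
                or aln.is_unmapped or aln.mate_is_unmapped
                or not aln.is_read1
                or aln.reference_id != aln.next_reference_id
            ):
                continue
            a = (aln.reference_start + 1, aln.reference_end, aln.is_reverse)
            b_start = aln.next_reference_start + 1
            b_len = aln.query_length or (aln.reference_end - aln.reference_start)
            b = (b_start, b_start + b_len - 1, aln.mate_is_reverse)
            left, right = (a, b) if a[0] <= b[0] else (b, a)
            orient = ("R" if left[2] else "F") + ("R" if right[2] else "F")
            rows.append(
                (aln.query_name, aln.reference_name,
                 left[0], left[1], right[0], right[1], orient,
                 int(aln.mapping_quality))
            )
    return pd.DataFrame(rows, columns=READPAIR_COLUMNS)


def apparent_span(pairs: pd.DataFrame) -> np.ndarray:
    """Outer reference distance of each pair (1-based inclusive)."""
    return (pairs["mate2_end"] - pairs["mate1_start"] + 1).to_numpy()


# ---------------------------------------------------------------------------
# Insert-size model
# ---------------------------------------------------------------------------

def fit_insert_model(pairs: pd.DataFrame, k: float = 3.0) -> InsertSizeModel:
    """Robust location/scale of the FR apparent-span distribution.

    Median and 1.4826 x median absolute deviation tolerate a contaminating
    discordant fraction well above the ~10% a heterozygous deletion locus
    produces. Requires >= 50 FR pairs and a non-degenerate spread.
    """
    fr = pairs[pairs["orientation"] == "FR"]
    if len(fr) < 50:
        raise ValueError(f"need >= 50 FR pairs to fit insert model, got {len(fr)}")
    spans = apparent_span(fr).astype(float)
    loc = float(np.median(spans))
    scale = float(1.4826 * np.median(np.abs(spans - loc)))
    return InsertSizeModel(location=loc, scale=scale, k=k)


def find_discordant(
    pairs: pd.DataFrame, model: InsertSizeModel, mapq_min: int = 20
) -> pd.DataFrame:
    """FR pairs with apparent span strictly above location + k x scale and
    adequate mapping quality; other orientations carry no deletion signal."""
    fr = pairs[
        (pairs["orientation"] == "FR") & (pairs["mapq"] >= mapq_min)
    ]
    spans = apparent_span(fr)
    return fr[spans > model.cutoff]


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_discordant(
    discordant: pd.DataFrame,
    model: InsertSizeModel,
    min_support: int = 3,
) -> list[DeletionCall]:
    """Single-linkage clustering of discordant pairs into deletion calls.

    Each pair implies a candidate deleted interval — the inner gap between
    its mates. Pairs whose implied intervals overlap are chained into one
    cluster. Per cluster the breakpoint interval is the intersection of the
    implied intervals; when pairs accumulated by chaining have an empty
    common intersection the cluster is split (documented rule): the pairs
    whose implied intervals cover the point of maximum coverage form one
    sub-cluster (in one dimension they are guaranteed a non-empty common
    intersection), and the remainder is re-split the same way, so a lone
    long-insert outlier chained onto a real deletion cannot poison its
    breakpoints. The size estimate is mean(apparent span) - model location.
    """
    if len(discordant) == 0:
        return []
    if discordant["chrom"].nunique() > 1:
        raise ValueError("cluster_discordant expects pairs from one chromosome")
    df = discordant.copy()
    df["gap_start"] = df["mate1_end"] + 1
    df["gap_end"] = df["mate2_start"] - 1
    df = df[df["gap_start"] <= df["gap_end"]].sort_values(
        ["gap_start", "gap_end"]).reset_index(drop=True)
    calls = []
    cluster: list[int] = []
    reach = -1
    for i in range(len(df)):
        s, e = int(df.at[i, "gap_start"]), int(df.at[i, "gap_end"])
        if cluster and s > reach:
            calls.extend(_emit_cluster(df.iloc[cluster], model, min_support))
            cluster = []
        cluster.append(i)
        reach = max(reach, e)
    if cluster:
        calls.extend(_emit_cluster(df.iloc[cluster], model, min_support))
    return calls


def _emit_cluster(rows: pd.DataFrame, model, min_support) -> list[DeletionCall]:
    out = []
    members = list(rows.itertuples(index=False))
    # size-consistency trim: members whose implied size strays more than
    # 4 robust SDs from the cluster median are re-clustered separately, so
    # a chained long-insert outlier (or a short tail pair nested inside a
    # real deletion's implied intervals) cannot poison the breakpoints
    sizes = np.array([r.mate2_end - r.mate1_start + 1 - model.location
                      for r in members])
    med = float(np.median(sizes))
    tol = 4.0 * model.scale
    core = [r for r, s in zip(members, sizes) if abs(s - med) <= tol]
    rest = [r for r, s in zip(members, sizes) if abs(s - med) > tol]
    out.extend(_split_by_coverage(core, model, min_support))
    if rest:
        out.extend(_emit_cluster(pd.DataFrame(rest), model, min_support))
    return out


def _split_by_coverage(members, model, min_support) -> list[DeletionCall]:
    # split at the point of maximum implied-interval coverage; intervals
    # containing a common point always have a non-empty intersection
    out = []
    remaining = list(members)
    while remaining:
        events = []
        for row in remaining:
            events.append((int(row.gap_start), 1))
            events.append((int(row.gap_end) + 1, -1))
        events.sort()
        best_pt, best_cov, cov = None, 0, 0
        for pos, delta in events:
            cov += delta
            if cov > best_cov:
                best_cov, best_pt = cov, pos
        group = [
            r for r in remaining
            if int(r.gap_start) <= best_pt <= int(r.gap_end)
        ]
        remaining = [r for r in remaining if r not in group]
        lo = max(int(r.gap_start) for r in group)
        hi = min(int(r.gap_end) for r in group)
        out.append(_build_call(group, lo, hi, model, min_support))
    return [c for c in out if c is not None]


def _build_call(group, lo, hi, model, min_support):
    if len(group) < min_support:
        return None
    spans = np.array([r.mate2_end - r.mate1_start + 1 for r in group], dtype=float)
    return DeletionCall(
        chrom=str(group[0].chrom),
        start=int(lo), end=int(hi),
        support=len(group),
        estimated_size=float(spans.mean() - model.location),
        fragment_ids=tuple(r.fragment_id for r in group),
    )


# ---------------------------------------------------------------------------
# Genotyping
# ---------------------------------------------------------------------------

def genotype_deletion(
    call: DeletionCall,
    all_pairs: pd.DataFrame,
    model: InsertSizeModel,
    params: SVParams = SVParams(),
) -> DeletionCall:
    """Assign a diploid genotype from two independent signals.

    r = spanning discordant pairs over (discordant + concordant pairs at
    the breakpoints), where the concordant count is the mean of the counts
    crossing each breakpoint — a deleted haplotype contributes one
    spanning pair where a reference haplotype contributes one concordant
    pair per breakpoint, so averaging keeps r near the allele fraction.
    d = read-base depth inside the call interval over the mean depth in
    equal-width flanks. hom_del needs r >= 0.8 and d <= 0.2; het_del needs
    0.3 <= r < 0.8 and 0.3 <= d <= 0.7; anything else is ref/ambiguous
    with the failing signals recorded.
    """
    pairs = all_pairs[all_pairs["chrom"] == call.chrom]
    frag_lo = pairs["mate1_start"].to_numpy()
    frag_hi = pairs["mate2_end"].to_numpy()
    spans = apparent_span(pairs)
    disc = spans > model.cutoff

    crosses = np.zeros(len(pairs), dtype=bool)
    conc_per_bp = []
    for bp in (call.start, call.end):
        at_bp = (frag_lo <= bp) & (frag_hi >= bp)
        crosses |= at_bp
        conc_per_bp.append(int((at_bp & ~disc).sum()))
    if int(crosses.sum()) == 0:
        return replace(call, genotype="ambiguous",
                       genotype_reasons=("no pairs cross the breakpoints",))
    n_disc = int((crosses & disc).sum())
    n_conc = sum(conc_per_bp) / 2
    r = n_disc / (n_disc + n_conc)

    d = _depth_ratio(call, pairs)

    reasons = [f"r={r:.3f}", f"d={d:.3f}"]
    if r >= params.hom_r and d <= params.hom_d:
        gt = "hom_del"
    elif params.het_r_lo <= r < params.hom_r and params.het_d_lo <= d <= params.het_d_hi:
        gt = "het_del"
    else:
        gt = "ref" if r < params.het_r_lo else "ambiguous"
        reasons.append("signals inconsistent with hom_del or het_del")
    return replace(call, genotype=gt, depth_ratio=float(d),
                   discordant_fraction=float(r), genotype_reasons=tuple(reasons))


def _depth_ratio(call: DeletionCall, pairs: pd.DataFrame) -> float:
    """Read-base coverage of the call interval versus equal-width flanks."""
    width = call.size
    inside = (call.start, call.end)
    left = (call.start - width, call.start - 1)
    right = (call.end + 1, call.end + width)

    def read_bases(window):
        lo, hi = window
        total = 0
        for s_col, e_col in (("mate1_start", "mate1_end"),
                             ("mate2_start", "mate2_end")):
            s = pairs[s_col].to_numpy()
            e = pairs[e_col].to_numpy()
            ov = np.minimum(e, hi) - np.maximum(s, lo) + 1
            total += int(np.clip(ov, 0, None).sum())
        return total / (hi - lo + 1)

    flank = (read_bases(left) + read_bases(right)) / 2
    if flank == 0:
        return float("nan")
    return read_bases(inside) / flank


# ---------------------------------------------------------------------------
# Cross-genome privacy
# ---------------------------------------------------------------------------

def private_deletions(
    case_calls: Sequence[DeletionCall],
    control_call_sets: Sequence[Sequence[DeletionCall]],
    min_reciprocal_overlap: float = 0.5,
) -> list[DeletionCall]:
    """Case calls with no reciprocal-overlap match in any control genome.

    Two calls match when they share the same chromosome and their overlap
    covers at least ``min_reciprocal_overlap`` of both intervals.
    """
    out = []
    for call in case_calls:
        matched = any(
            _reciprocal(call, other) >= min_reciprocal_overlap
            for calls in control_call_sets
            for other in calls
            if other.chrom == call.chrom
        )
        if not matched:
            out.append(call)
    return out


def _reciprocal(a: DeletionCall, b: DeletionCall) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / a.size, ov / b.size)


# ---------------------------------------------------------------------------
# Audit and output
# ---------------------------------------------------------------------------

def supporting_pairs(call: DeletionCall, pairs: pd.DataFrame) -> pd.DataFrame:
    """The discordant pairs behind a call, for manual inspection."""
    return pairs[pairs["fragment_id"].isin(call.fragment_ids)]


def write_deletion_vcf(
    calls: Sequence[DeletionCall], path: str, contigs: Sequence[tuple]
) -> None:
    """Write calls as VCF symbolic-allele records (SVTYPE=DEL, END, CIPOS).

    POS anchors one base before the breakpoint interval start; END is the
    breakpoint interval end; CIPOS/CIEND carry the interval widths.
    """
    import pysam

    header = pysam.VariantHeader()
    for name, length in contigs:
        header.contigs.add(str(name), length=length)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "Deleted bases, POS-anchored")
    header.info.add("SVSIZE", 1, "Float", "Span-based deletion size estimate")
    header.info.add("CIPOS", 2, "Integer", "Confidence interval around POS")
    header.info.add("CIEND", 2, "Integer", "Confidence interval around END")
    header.info.add("PE", 1, "Integer", "Supporting discordant pairs")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample("CASE")
    gt_codes = {"hom_del": (1, 1), "het_del": (0, 1), "ref": (0, 0)}
    with pysam.VariantFile(path, "w", header=header) as out:
        for call in calls:
            rec = out.new_record(
                contig=call.chrom, start=max(call.start - 2, 0),
                stop=call.end, alleles=("N", "<DEL>"),
            )
            rec.info["SVTYPE"] = "DEL"
            rec.info["SVLEN"] = -(call.end - call.start + 1)
            rec.info["SVSIZE"] = float(call.estimated_size)
            rec.info["CIPOS"] = (0, call.size)
            rec.info["CIEND"] = (-call.size, 0)
            rec.info["PE"] = call.support
            rec.samples["CASE"]["GT"] = gt_codes.get(call.genotype, (None, None))
            rec.stop = call.end   # re-assert: sample/INFO edits can reset rlen
            out.write(rec)


def call_deletions(
    pairs: pd.DataFrame, params: SVParams = SVParams()
) -> tuple[list[DeletionCall], InsertSizeModel]:
    """Convenience end-to-end: fit, flag, cluster and genotype per chromosome."""
    model = fit_insert_model(pairs, k=params.k)
    disc = find_discordant(pairs, model, mapq_min=params.mapq_min)
    calls = []
    for chrom, grp in disc.groupby("chrom", sort=True):
        for call in cluster_discordant(grp, model, min_support=params.min_support):
            calls.append(
                genotype_deletion(
                    call, pairs[pairs["chrom"] == chrom], model, params
                )
            )
    return calls, model
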