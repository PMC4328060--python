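"""Seeded synthetic cohort generator.

Emulates the data a recessive-disease mapping study of an inbred cattle
family works from, with every planted feature recorded in a truth record:

* dense biallelic SNP-array genotypes on a four-generation inbred pedigree
  (son x mother and mother x son matings), produced by gene-dropping founder
  haplotypes with recombination;
* a recessive ~2.4 kb deletion segregating from one founder, placed over the
  first exon of one candidate gene so that it removes the start codon and
  the first 79 coding bases;
* small-variant VCFs for the sequenced case and an unrelated 40-genome
  control cohort, with a configurable number of case-private variants
  planted outside candidate-gene bodies;
* a paired-end fragment library (300 bp insert, 2 x 100 bp reads) over the
  deletion locus for the case, its genotyped relatives and the controls.

All randomness flows from ``SimConfig.seed`` through one
``numpy.random.Generator``; re-simulation with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .pedigree import (
    Pedigree,
    IndividualRecord,
    drop_haplotypes,
    founder_haplotype_labels,
    write_pedigree,
    _label_at,
    _ibd_length,
)

__all__ = [
    "SimConfig",
    "CohortData",
    "study_pedigree",
    "simulate_cohort",
    "simulate_read_pairs",
    "write_cohort",
]


# ---------------------------------------------------------------------------
# The study family
# ---------------------------------------------------------------------------

def study_pedigree() -> Pedigree:
    """The four-generation inbred Hereford family with three affected calves.

    Founders IV/A (cow) and IV/B (sire) produced a son III/A, who was bred
    back to his own mother IV/A (case 1), to his full sister III/B (case 2),
    and to a cow of unknown descent III/C (son II/C). II/C was then mated to
    his mother III/B, producing case 3. II/2 is a recorded but unconnected
    relative of unknown descent. III/B and III/C are obligate carriers.
    """
    rows = [
        IndividualRecord("IV/A", None, None, "female", "unaffected", True),
        IndividualRecord("IV/B", None, None, "male", "unaffected", False),
        IndividualRecord("III/C", None, None, "female", "unaffected", False),
        IndividualRecord("II/2", None, None, "unknown", "unknown", False),
        IndividualRecord("III/A", "IV/B", "IV/A", "male", "unaffected", True),
        IndividualRecord("III/B", "IV/B", "IV/A", "female", "unaffected", False),
        IndividualRecord("II/C", "III/A", "III/C", "male", "unaffected", True),
        IndividualRecord("case1", "III/A", "IV/A", "female", "affected", True),
        IndividualRecord("case2", "III/A", "III/B", "unknown", "affected", False),
        IndividualRecord("case3", "II/C", "III/B", "male", "affected", False),
    ]
    return Pedigree(rows)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Simulation parameters; defaults are the study conditions.

    The genome is scaled to desk size: 29 autosomes (the bovine autosome
    count) of 40 Mb with 2,000 evenly spaced (jittered) markers each, i.e.
    one marker per ~20 kb, so a 1 Mb homozygous run spans ~50 markers.
    """

    seed: int = 0
    n_chrom: int = 29
    chrom_length: int = 40_000_000
    n_markers_per_chrom: int = 2_000
    allele_freq_beta: tuple[float, float] = (0.5, 0.5)  # founder freq distribution
    recomb_rate: float = 1e-8  # per bp per meiosis (1 cM/Mb, Haldane)

    # the planted recessive deletion (2,433 bp, like the LAMC2 exon-1 loss)
    deletion_chrom: int = 16          # 1-based chromosome index
    deletion_length: int = 2_433
    deletion_carrier: str = "IV/A"    # founder whose haplotype A carries it
    sequenced_case: str = "case1"

    n_candidate_genes: int = 18
    n_controls: int = 40
    n_snv_sites: int = 2_000
    n_private_snvs: int = 12          # planted case-private small variants
    low_qual_fraction: float = 0.01   # sites emitted with a non-PASS filter

    # fragment library over the deletion locus
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    read_length: int = 100
    depth: float = 20.0
    locus_flank: int = 20_000         # simulated window around the deletion
    min_anchor: int = 20              # bp a clipped read needs to stay mapped

    max_rejection_tries: int = 500_000

    def __post_init__(self):
        if self.insert_sd <= 0:
            raise ValueError("insert_sd must be > 0")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.deletion_length < 1:
            raise ValueError("deletion length must be >= 1 bp")
        if not 1 <= self.deletion_chrom <= self.n_chrom:
            raise ValueError("deletion_chrom outside the simulated genome")


@dataclass
class GeneModelSpec:
    """Gene-model record matching the gene-model JSON schema."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list            # [(start, end)] 1-based inclusive, ordered
    cds_start: int         # genomic, 1-based inclusive
    cds_end: int

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CohortData:
    """In-memory bundle of everything :func:`simulate_cohort` produces."""

    config: SimConfig
    pedigree: Pedigree
    marker_map: pd.DataFrame          # chrom, pos, ref, alt
    calls: np.ndarray                 # markers x individuals; 0/1/2, -1 missing
    individuals: list
    deletion_genotypes: dict          # id -> wt/wt | wt/del | del/del
    gene_models: list                 # of GeneModelSpec
    candidate_bed: pd.DataFrame       # chrom, start0, end, name (BED half-open)
    transcript_cds: str               # wildtype CDS of the hit gene, 5'->3'
    case_variants: pd.DataFrame       # chrom,pos,ref,alt,filter,case_gt
    control_variants: pd.DataFrame    # chrom,pos,ref,alt + one gt column/control
    read_pairs: dict                  # sample -> DataFrame (read-pair table)
    truth: dict


# ---------------------------------------------------------------------------
# Descent simulation with the deletion conditioned into the family
# ---------------------------------------------------------------------------

def _drop_conditioned(ped: Pedigree, cfg: SimConfig, rng: np.random.Generator):
    """Gene-drop every chromosome; on the deletion chromosome, redraw until
    all affected individuals are autozygous for the carrier founder's
    haplotype A at the deletion midpoint (rejection sampling — the study
    family is ascertained on three affected calves)."""
    founder_labels = founder_haplotype_labels(ped)
    if cfg.deletion_carrier not in founder_labels:
        raise ValueError(
            f"deletion carrier {cfg.deletion_carrier!r} is not a pedigree founder"
        )
    carrier_hap = founder_labels[cfg.deletion_carrier][0]
    del_mid = float(_deletion_interval(cfg)[0] + cfg.deletion_length // 2)
    affected = sorted(ped.affected())

    L = float(cfg.chrom_length)
    per_chrom_haps = []
    for ci in range(cfg.n_chrom):
        if ci + 1 != cfg.deletion_chrom:
            per_chrom_haps.append(drop_haplotypes(ped, [L], cfg.recomb_rate, rng))
            continue
        for attempt in range(cfg.max_rejection_tries):
            haps = drop_haplotypes(ped, [L], cfg.recomb_rate, rng)
            ok = all(
                _label_at(haps[a][0][0], del_mid) == carrier_hap
                and _label_at(haps[a][0][1], del_mid) == carrier_hap
                for a in affected
            )
            if ok:
                per_chrom_haps.append(haps)
                break
        else:
            raise RuntimeError(
                "rejection sampling failed to place the deletion; "
                "check the pedigree allows the affected to be autozygous "
                "for the carrier founder"
            )
    return per_chrom_haps, carrier_hap


def _deletion_interval(cfg: SimConfig) -> tuple[int, int]:
    """Planted deletion interval (1-based inclusive) on its chromosome.

    Fixed at mid-chromosome so the locus is independent of the seed; the
    surrounding gene model is anchored to it.
    """
    start = cfg.chrom_length // 2
    return start, start + cfg.deletion_length - 1


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

_NONSTART_CODONS = [
    "GCT", "GCC", "GAA", "GAT", "GGA", "CTG", "CCT", "CAG", "TCT", "ACC",
    "TAC", "TGG", "AAG", "AGA", "GTG", "ATC", "TTC", "CGT",
]


def _build_hit_gene(cfg: SimConfig, rng: np.random.Generator):
    """The candidate gene the deletion disrupts, mirrored on the real lesion:
    the deletion spans >900 bp upstream through exon 1 (which carries the
    start codon and the first 79 coding bases) and ~1.1 kb of intron 1.

    Returns (GeneModelSpec, wildtype CDS sequence). The CDS is 3,600 nt with
    its first downstream in-frame ATG at offset 900, so a start-loss rescue
    scan reports a 25% truncation.
    """
    del_start, del_end = _deletion_interval(cfg)
    upstream, exon1_len = 933, 400
    downstream = cfg.deletion_length - upstream - exon1_len
    assert downstream > 0, "deletion too short for the mirrored gene layout"
    exon1_start = del_start + upstream
    exon1_end = exon1_start + exon1_len - 1
    cds1 = 79                           # coding bases in exon 1 (incl. ATG)
    cds_start = exon1_end - cds1 + 1    # 321 nt 5'UTR before it

    cds_total = 3_600
    intron1 = downstream + 1_500        # exon 2 starts well beyond the deletion
    exon2_start = exon1_end + intron1 + 1
    exon2_len = 1_600
    exon3_start = exon2_start + exon2_len + 800
    exon3_len = cds_total - cds1 - exon2_len + 250   # 250 nt 3'UTR
    exons = [
        (exon1_start, exon1_end),
        (exon2_start, exon2_start + exon2_len - 1),
        (exon3_start, exon3_start + exon3_len - 1),
    ]
    cds_end = exon3_start + (cds_total - cds1 - exon2_len) - 1
    model = GeneModelSpec(
        gene_id="LAMC2L", transcript_id="TX_LAMC2L",
        chrom=str(cfg.deletion_chrom), strand="+",
        exons=exons, cds_start=cds_start, cds_end=cds_end,
    )

    codons = rng.choice(_NONSTART_CODONS, size=cds_total // 3)
    codons[0] = "ATG"
    codons[900 // 3] = "ATG"            # second in-frame start, 900 nt downstream
    cds_seq = "".join(codons)
    return model, cds_seq


def _build_background_genes(cfg: SimConfig, rng: np.random.Generator):
    """The remaining candidate genes: simple two-exon models scattered over
    the genome away from the deletion chromosome's planted locus."""
    genes = []
    for i in range(cfg.n_candidate_genes - 1):
        chrom = int(rng.integers(1, cfg.n_chrom + 1))
        start = int(rng.integers(2_000_000, cfg.chrom_length - 2_000_000))
        if chrom == cfg.deletion_chrom:
            # keep clear of the planted locus and its simulated read window
            lo, hi = _deletion_interval(cfg)
            if abs(start - lo) < 2 * cfg.locus_flank + 100_000:
                start = (lo - 3 * cfg.locus_flank - 500_000) if start < lo else (
                    hi + 3 * cfg.locus_flank + 500_000)
        e1 = (start, start + 300)
        e2 = (start + 2_000, start + 3_500)
        genes.append(
            GeneModelSpec(
                gene_id=f"CAND{i + 2:02d}", transcript_id=f"TX_CAND{i + 2:02d}",
                chrom=str(chrom), strand="+" if rng.random() < 0.5 else "-",
                exons=[e1, e2], cds_start=start + 100, cds_end=start + 3_200,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Read-pair simulation
# ---------------------------------------------------------------------------

def simulate_read_pairs(
    genotype: str,
    reference_span: tuple[int, int],
    deletion: tuple[int, int],
    config: SimConfig,
    rng: np.random.Generator,
    sample: str = "S",
) -> pd.DataFrame:
    """Simulate a paired-end fragment library over one locus.

    Fragments are drawn with length ~ Normal(insert_mean, insert_sd) and
    placed uniformly on each haplotype; a deleted haplotype lacks the
    deleted bases, so a fragment spanning the deletion point maps back to
    the reference with an apparent span inflated by the deletion length.
    A read that straddles the breakpoint junction is soft-clipped the way
    an aligner would map it: it stays mapped on whichever side holds it,
    provided at least ``min_anchor`` bases anchor there; otherwise the
    fragment is lost. Orientation is forward-reverse throughout.

    ``genotype`` is the diploid state at the locus: wt/wt, wt/del or
    del/del. Coordinates are 1-based inclusive on the reference.
    """
    if genotype not in ("wt/wt", "wt/del", "del/del"):
        raise ValueError(f"bad genotype {genotype!r}")
    if config.depth < 0:
        raise ValueError("depth must be >= 0")
    del_start, del_end = deletion
    if del_end < del_start:
        raise ValueError("deletion interval is empty (end < start)")
    ref_start, ref_end = reference_span
    del_len = del_end - del_start + 1
    rl = config.read_length

    rows = []
    frag_no = 0
    for hap_idx, deleted in enumerate(_hap_flags(genotype)):
        ref_len = ref_end - ref_start + 1
        hap_len = ref_len - (del_len if deleted else 0)
        n_frags = int(round(config.depth / 2 * hap_len / (2 * rl)))
        if n_frags == 0:
            continue
        frag_len = np.maximum(
            rng.normal(config.insert_mean, config.insert_sd, size=n_frags),
            2 * rl,
        ).round().astype(int)
        max_start = hap_len - frag_len
        keep = max_start >= 0
        frag_len = frag_len[keep]
        starts = (rng.random(frag_len.size) * (max_start[keep] + 1)).astype(int)
        # haplotype coordinate -> reference coordinate
        h1 = starts + ref_start              # fragment first base (1-based)
        h2 = h1 + frag_len - 1               # fragment last base, hap coords
        if deleted:
            dl = del_len
            # read 1 occupies hap [h1, h1+rl-1]
            s1h, e1h = h1, h1 + rl - 1
            # read 2 occupies hap [h2-rl+1, h2]
            s2h, e2h = h2 - rl + 1, h2
            straddle1 = (s1h < del_start) & (e1h >= del_start)
            straddle2 = (s2h < del_start) & (e2h >= del_start)
            anchor1 = del_start - s1h        # left anchor of a clipped read 1
            anchor2 = e2h - del_start + 1    # right anchor of a clipped read 2
            ok = (~straddle1 | (anchor1 >= config.min_anchor)) & (
                ~straddle2 | (anchor2 >= config.min_anchor)
            )
            m1s = np.where(s1h >= del_start, s1h + dl, s1h)
            m1e = np.where(
                straddle1, del_start - 1,
                np.where(e1h >= del_start, e1h + dl, e1h),
            )
            m2s = np.where(
                straddle2, del_start + dl,
                np.where(s2h >= del_start, s2h + dl, s2h),
            )
            m2e = np.where(e2h >= del_start, e2h + dl, e2h)
            m1s, m1e = m1s[ok], m1e[ok]
            m2s, m2e = m2s[ok], m2e[ok]
        else:
            m1s, m1e = h1, h1 + rl - 1
            m2s, m2e = h2 - rl + 1, h2
        for a, b, c, d in zip(m1s.tolist(), m1e.tolist(),
                              m2s.tolist(), m2e.tolist()):
            rows.append(
                (f"{sample}_frag{frag_no}", str(config.deletion_chrom),
                 a, b, c, d, "FR", 60)
            )
            frag_no += 1
    return pd.DataFrame(
        rows,
        columns=["fragment_id", "chrom", "mate1_start", "mate1_end",
                 "mate2_start", "mate2_end", "orientation", "mapq"],
    )


def _hap_flags(genotype: str) -> tuple[bool, bool]:
    return {
        "wt/wt": (False, False),
        "wt/del": (False, True),
        "del/del": (True, True),
    }[genotype]


# ---------------------------------------------------------------------------
# The full cohort
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: SimConfig, ped: Pedigree | None = None, out_dir: str | None = None
) -> CohortData:
    """Generate the full synthetic cohort; optionally write it to ``out_dir``.

    Returns a :class:`CohortData`. The truth record is an audit of the
    generated data (realised deletion genotypes, realised case-private
    variant count, realised autozygous fraction), not of the intent.
    """
    ped = ped if ped is not None else study_pedigree()
    if not ped.affected():
        raise ValueError("pedigree has no affected individual")
    rng = np.random.default_rng(config.seed)

    # 1. marker map: even spacing with jitter, strictly increasing
    maps = []
    spacing = config.chrom_length / (config.n_markers_per_chrom + 1)
    for ci in range(config.n_chrom):
        base = (np.arange(1, config.n_markers_per_chrom + 1)) * spacing
        jitter = rng.uniform(-0.3, 0.3, size=config.n_markers_per_chrom) * spacing
        pos = np.sort(np.round(base + jitter).astype(np.int64))
        pos = np.maximum.accumulate(pos + np.arange(len(pos)) * 0)  # sorted
        pos = _make_strict(pos)
        maps.append(pd.DataFrame({"chrom": str(ci + 1), "pos": pos}))
    marker_map = pd.concat(maps, ignore_index=True)
    marker_map["ref"] = "A"
    marker_map["alt"] = "G"

    # 2. founder allele frequencies and haplotype alleles
    a, b = config.allele_freq_beta
    freqs = np.clip(rng.beta(a, b, size=len(marker_map)), 0.05, 0.95)
    n_labels = 2 * len(ped.founders()) + 2 * len(ped)  # headroom for unknowns
    hap_alleles = (rng.random((n_labels, len(marker_map))) < freqs).astype(np.int8)

    # 3. descent with the deletion conditioned into the affected
    per_chrom_haps, carrier_hap = _drop_conditioned(ped, config, rng)
    del_start, del_end = _deletion_interval(config)
    del_mid = float(del_start + config.deletion_length // 2)

    individuals = ped.topological_order()
    calls = np.empty((len(marker_map), len(individuals)), dtype=np.int8)
    offsets = np.concatenate(
        ([0], np.cumsum([config.n_markers_per_chrom] * config.n_chrom))
    )
    deletion_gts = {}
    ibd_len_case = 0.0
    case = config.sequenced_case
    for col, iid in enumerate(individuals):
        for ci in range(config.n_chrom):
            h1, h2 = per_chrom_haps[ci][iid][0]
            lo, hi = offsets[ci], offsets[ci + 1]
            pos = marker_map["pos"].values[lo:hi].astype(float)
            lab1 = _labels_at(h1, pos)
            lab2 = _labels_at(h2, pos)
            g = hap_alleles[lab1, np.arange(lo, hi)] + hap_alleles[
                lab2, np.arange(lo, hi)
            ]
            calls[lo:hi, col] = g
            if iid == case:
                ibd_len_case += _ibd_length(h1, h2, float(config.chrom_length))
        # deletion genotype + array behaviour over deleted DNA
        ci = config.deletion_chrom - 1
        h1, h2 = per_chrom_haps[ci][iid][0]
        n_del = int(_label_at(h1, del_mid) == carrier_hap) + int(
            _label_at(h2, del_mid) == carrier_hap
        )
        deletion_gts[iid] = ("wt/wt", "wt/del", "del/del")[n_del]
        lo, hi = offsets[ci], offsets[ci + 1]
        pos = marker_map["pos"].values[lo:hi]
        inside = (pos >= del_start) & (pos <= del_end)
        if inside.any() and n_del > 0:
            idx = np.where(inside)[0] + lo
            if n_del == 2:
                calls[idx, col] = -1            # no DNA: missing call
            else:
                wt_hap = h2 if _label_at(h1, del_mid) == carrier_hap else h1
                lab = _labels_at(wt_hap, pos[inside].astype(float))
                calls[idx, col] = 2 * hap_alleles[lab, idx]  # hemizygous-as-hom

    autozygous_fraction_case = ibd_len_case / (config.n_chrom * config.chrom_length)

    # 4. candidate genes (the hit gene first) and BED
    hit_gene, cds_seq = _build_hit_gene(config, rng)
    gene_models = [hit_gene] + _build_background_genes(config, rng)
    candidate_bed = pd.DataFrame(
        [
            {"chrom": g.chrom, "start": g.span[0] - 1, "end": g.span[1],
             "name": g.gene_id}
            for g in gene_models
        ]
    )

    # 5. small variants: shared polymorphisms + planted case-private variants
    case_variants, control_variants, n_private_audit = _simulate_small_variants(
        config, gene_models, rng
    )

    # 6. fragment libraries over the deletion locus
    locus = (max(1, del_start - config.locus_flank), del_end + config.locus_flank)
    read_pairs = {}
    sequenced = [case] + sorted(
        iid for iid in individuals
        if iid != case and ped.record(iid).genotyped
    )
    for iid in sequenced:
        read_pairs[iid] = simulate_read_pairs(
            deletion_gts[iid], locus, (del_start, del_end), config, rng, sample=iid
        )
    for k in range(config.n_controls):
        name = f"CTRL{k + 1:02d}"
        read_pairs[name] = simulate_read_pairs(
            "wt/wt", locus, (del_start, del_end), config, rng, sample=name
        )

    truth = {
        "seed": config.seed,
        "deletion": {
            "chrom": str(config.deletion_chrom),
            "start": del_start,
            "end": del_end,
            "length": config.deletion_length,
            "carrier_founder": config.deletion_carrier,
            "hit_gene": hit_gene.gene_id,
        },
        "deletion_genotypes": deletion_gts,
        "sequenced_case": case,
        "autozygous_fraction_case": autozygous_fraction_case,
        "n_private_variants": n_private_audit,
        "locus_window": list(locus),
        "control_samples": [f"CTRL{k + 1:02d}" for k in range(config.n_controls)],
        "candidate_genes": [g.gene_id for g in gene_models],
    }

    cohort = CohortData(
        config=config,
        pedigree=ped,
        marker_map=marker_map,
        calls=calls,
        individuals=individuals,
        deletion_genotypes=deletion_gts,
        gene_models=gene_models,
        candidate_bed=candidate_bed,
        transcript_cds=cds_seq,
        case_variants=case_variants,
        control_variants=control_variants,
        read_pairs=read_pairs,
        truth=truth,
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def _make_strict(pos: np.ndarray) -> np.ndarray:
    """Force strictly increasing integer positions."""
    out = pos.copy()
    for i in range(1, len(out)):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + 1
    return out


def _labels_at(hap, pos: np.ndarray) -> np.ndarray:
    starts = np.array([s for s, _ in hap])
    labs = np.array([l for _, l in hap])
    idx = np.searchsorted(starts, pos, side="right") - 1
    return labs[np.maximum(idx, 0)]


def _simulate_small_variants(cfg: SimConfig, gene_models, rng):
    """Shared polymorphisms plus planted case-private hom-alt variants.

    Private variants are placed outside every candidate-gene span, mirroring
    the study's negative small-variant result (the causal lesion being
    structural). The returned audit count is measured from the emitted
    genotypes: PASS sites where the case is hom-alt and no control carries
    the alternate allele.
    """
    gene_spans = {}
    for g in gene_models:
        gene_spans.setdefault(g.chrom, []).append(g.span)

    n_shared = cfg.n_snv_sites - cfg.n_private_snvs
    chroms = rng.integers(1, cfg.n_chrom + 1, size=cfg.n_snv_sites)
    positions = rng.integers(1, cfg.chrom_length + 1, size=cfg.n_snv_sites)
    is_private = np.zeros(cfg.n_snv_sites, dtype=bool)
    is_private[n_shared:] = True
    # move private sites off candidate-gene bodies
    for i in np.where(is_private)[0]:
        while _in_any_span(str(chroms[i]), positions[i], gene_spans):
            chroms[i] = rng.integers(1, cfg.n_chrom + 1)
            positions[i] = rng.integers(1, cfg.chrom_length + 1)

    q = rng.beta(1.5, 3.0, size=cfg.n_snv_sites)
    case_gt = (rng.random(cfg.n_snv_sites) < q).astype(int) + (
        rng.random(cfg.n_snv_sites) < q
    ).astype(int)
    ctrl_gt = (
        (rng.random((cfg.n_snv_sites, cfg.n_controls)) < q[:, None]).astype(int)
        + (rng.random((cfg.n_snv_sites, cfg.n_controls)) < q[:, None]).astype(int)
    )
    case_gt[is_private] = 2
    ctrl_gt[is_private, :] = 0

    filt = np.where(rng.random(cfg.n_snv_sites) < cfg.low_qual_fraction,
                    "LowQual", "PASS")

    df = pd.DataFrame({
        "chrom": chroms.astype(str),
        "pos": positions,
        "ref": "C",
        "alt": "T",
        "filter": filt,
        "case_gt": case_gt,
    })
    order = np.lexsort((positions, chroms))
    df = df.iloc[order].reset_index(drop=True)
    ctrl_gt = ctrl_gt[order]
    # collapse accidental duplicate sites
    dup = df.duplicated(subset=["chrom", "pos"], keep="first").values
    df = df.loc[~dup].reset_index(drop=True)
    ctrl_gt = ctrl_gt[~dup]

    controls = df[["chrom", "pos", "ref", "alt"]].copy()
    for k in range(cfg.n_controls):
        controls[f"CTRL{k + 1:02d}"] = ctrl_gt[:, k]

    n_private_audit = int(
        ((df["case_gt"] == 2) & (df["filter"] == "PASS")
         & (ctrl_gt.sum(axis=1) == 0)).sum()
    )
    return df, controls, n_private_audit


def _in_any_span(chrom: str, pos: int, spans: dict) -> bool:
    return any(s <= pos <= e for s, e in spans.get(chrom, []))


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortData, out_dir: str) -> dict:
    """Write every cohort artefact as plain-text files; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    cfg = cohort.config
    paths = {
        "ped": os.path.join(out_dir, "family.ped"),
        "genotypes": os.path.join(out_dir, "genotypes.tsv"),
        "case_vcf": os.path.join(out_dir, "case.vcf"),
        "controls_vcf": os.path.join(out_dir, "controls.vcf"),
        "candidates_bed": os.path.join(out_dir, "candidate_genes.bed"),
        "gene_models": os.path.join(out_dir, "gene_models.json"),
        "transcript_fasta": os.path.join(out_dir, "hit_transcript_cds.fa"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_pedigree(cohort.pedigree, paths["ped"])

    gm = cohort.marker_map.copy()
    for i, iid in enumerate(cohort.individuals):
        gm[iid] = [str(c) if c >= 0 else "." for c in cohort.calls[:, i]]
    gm.to_csv(paths["genotypes"], sep="\t", index=False)

    contigs = [(str(c + 1), cfg.chrom_length) for c in range(cfg.n_chrom)]
    _write_vcf(
        paths["case_vcf"], contigs, [cfg.sequenced_case],
        cohort.case_variants[["chrom", "pos", "ref", "alt", "filter"]],
        cohort.case_variants[["case_gt"]].values,
    )
    ctrl_cols = [c for c in cohort.control_variants.columns if c.startswith("CTRL")]
    _write_vcf(
        paths["controls_vcf"], contigs, ctrl_cols,
        cohort.control_variants.assign(filter="PASS")[
            ["chrom", "pos", "ref", "alt", "filter"]],
        cohort.control_variants[ctrl_cols].values,
    )

    cohort.candidate_bed.to_csv(
        paths["candidates_bed"], sep="\t", header=False, index=False
    )
    with open(paths["gene_models"], "w") as fh:
        json.dump([g.to_dict() for g in cohort.gene_models], fh, indent=2)
    with open(paths["transcript_fasta"], "w") as fh:
        fh.write(f">{cohort.gene_models[0].transcript_id}_CDS\n")
        for i in range(0, len(cohort.transcript_cds), 60):
            fh.write(cohort.transcript_cds[i:i + 60] + "\n")
    for sample, df in cohort.read_pairs.items():
        p = os.path.join(out_dir, f"reads_{sample.replace('/', '_')}.tsv")
        df.to_csv(p, sep="\t", index=False)
        paths[f"reads_{sample}"] = p
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
    return paths


def _write_vcf(path, contigs, samples, sites: pd.DataFrame, gts: np.ndarray):
    """Write diploid genotypes (0/1/2 dosage coding) as an uncompressed VCF."""
    header = pysam.VariantHeader()
    for name, length in contigs:
        header.contigs.add(name, length=length)
    header.filters.add("LowQual", None, None, "Low quality site")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(path, "w", header=header) as out:
        for i, row in enumerate(sites.itertuples(index=False)):
            rec = out.new_record(
                contig=row.chrom, start=row.pos - 1, stop=row.pos,
                alleles=(row.ref, row.alt),
            )
            if row.filter == "PASS":
                rec.filter.add("PASS")
            else:
                rec.filter.add(row.filter)
            for j, s in enumerate(samples):
                rec.samples[s]["GT"] = gt_map[int(gts[i, j])]
                rec.samples[s].phased = False
            out.write(rec)
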