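"""Private coding-variant prioritisation.

Filters the case's small variants down to the recessive-IBD candidates:
homozygous-alternate PASS calls, absent from every control genome at any
zygosity ("private"), inside the mapped homozygous regions, annotated with
the candidate gene and coding status of each survivor. The three filters
are pure set filters and commute; every surviving variant carries its full
list of rank reasons.

Multi-allelic records are decomposed into biallelic records at load time so
that privacy is well-defined per alternate allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .roh import ROHSegment

__all__ = [
    "VariantRecord",
    "PrioritizedVariant",
    "ControlCohort",
    "load_vcf_records",
    "filter_case_homozygous_alt",
    "filter_private",
    "restrict_to_regions",
    "report_table",
]


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic small-variant site with per-sample dosage genotypes."""

    chrom: str
    pos: int                      # 1-based
    ref: str
    alt: str
    genotypes: tuple              # (sample, dosage) pairs; dosage 0/1/2, -1 missing
    filter: str = "PASS"

    def dosage(self, sample: str) -> int:
        for s, d in self.genotypes:
            if s == sample:
                return d
        raise KeyError(f"sample {sample!r} absent from record {self.chrom}:{self.pos}")

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PrioritizedVariant:
    record: VariantRecord
    gene: str | None
    region_id: str
    coding: bool
    rank_reasons: tuple


def load_vcf_records(path: str, decompose: bool = True) -> list[VariantRecord]:
    """Load a VCF into biallelic :class:`VariantRecord` rows (cyvcf2).

    Multi-allelic sites are split into one record per alternate allele;
    the per-sample dosage then counts copies of that allele only.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    out = []
    for var in vcf:
        filt = var.FILTER or "PASS"   # cyvcf2 reports PASS as None
        alleles_per_sample = [
            tuple(a for a in gt[:2]) for gt in var.genotypes
        ]
        for ai, alt in enumerate(var.ALT, start=1):
            gts = []
            for s, alleles in zip(samples, alleles_per_sample):
                if any(a is None or a < 0 for a in alleles):
                    gts.append((s, -1))
                else:
                    gts.append((s, sum(1 for a in alleles if a == ai)))
            out.append(
                VariantRecord(
                    chrom=var.CHROM, pos=var.POS, ref=var.REF, alt=alt,
                    genotypes=tuple(gts), filter=filt,
                )
            )
        if not decompose and len(var.ALT) > 1:
            raise ValueError("multi-allelic record with decompose=False")
    return out


class ControlCohort:
    """Alternate-allele observations across the control genomes.

    Indexed by (chrom, pos, ref, alt); a site missing from a control's VCF,
    or a missing genotype, does not count as an observation.
    """

    def __init__(self, records: Iterable[VariantRecord]):
        self._seen: dict = {}
        self.n_controls = 0
        for rec in records:
            carriers = sum(1 for _, d in rec.genotypes if d > 0)
            self.n_controls = max(self.n_controls, len(rec.genotypes))
            if carriers:
                self._seen[rec.key] = self._seen.get(rec.key, 0) + carriers

    @classmethod
    def from_vcf(cls, *paths: str) -> "ControlCohort":
        recs: list[VariantRecord] = []
        for p in paths:
            recs.extend(load_vcf_records(p))
        return cls(recs)

    def observed(self, rec: VariantRecord) -> bool:
        return self._seen.get(rec.key, 0) > 0


# ---------------------------------------------------------------------------
# Filters (set semantics: order-independent)
# ---------------------------------------------------------------------------

def filter_case_homozygous_alt(
    records: Sequence[VariantRecord], case_id: str
) -> list[VariantRecord]:
    """Keep PASS records where the case is homozygous for the alternate
    allele (the IBD expectation for a recessive causal variant)."""
    out = []
    for rec in records:
        d = rec.dosage(case_id)   # raises KeyError if the sample is absent
        if d == 2 and rec.filter == "PASS":
            out.append(rec)
    return out


def filter_private(
    records: Sequence[VariantRecord], control_cohort: ControlCohort
) -> list[VariantRecord]:
    """Drop any record whose alternate allele is observed, het or hom, in
    any control genome."""
    return [rec for rec in records if not control_cohort.observed(rec)]


def restrict_to_regions(
    records: Sequence[VariantRecord],
    regions: Sequence[ROHSegment],
    gene_models: Sequence = (),
) -> list[PrioritizedVariant]:
    """Keep records inside any mapped region; annotate the overlapped
    candidate gene (None when intergenic) and whether the position falls in
    coding sequence (inside an exon and within the CDS bounds)."""
    out = []
    for rec in records:
        region = next(
            (
                seg for seg in regions
                if seg.chrom == rec.chrom and seg.start <= rec.pos <= seg.end
            ),
            None,
        )
        if region is None:
            continue
        gene, coding = None, False
        for gm in gene_models:
            if gm.chrom != rec.chrom:
                continue
            lo, hi = gm.span
            if lo <= rec.pos <= hi:
                gene = gm.gene_id
                in_exon = any(s <= rec.pos <= e for s, e in gm.exons)
                coding = in_exon and gm.cds_start <= rec.pos <= gm.cds_end
                break
        reasons = ["case_hom_alt", "private_vs_controls",
                   f"in_region_{region.chrom}:{region.start}-{region.end}"]
        if gene:
            reasons.append(f"gene_{gene}" + ("_coding" if coding else "_noncoding"))
        out.append(
            PrioritizedVariant(
                record=rec, gene=gene,
                region_id=f"{region.chrom}:{region.start}-{region.end}",
                coding=coding, rank_reasons=tuple(reasons),
            )
        )
    return out


def report_table(variants: Sequence[PrioritizedVariant]) -> pd.DataFrame:
    """TSV-ready table of prioritised variants."""
    rows = [
        {
            "chrom": v.record.chrom, "pos": v.record.pos,
            "ref": v.record.ref, "alt": v.record.alt,
            "gene": v.gene or ".", "region": v.region_id,
            "coding": v.coding, "reasons": ";".join(v.rank_reasons),
        }
        for v in variants
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "gene", "region",
                       "coding", "reasons"]
    )
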