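"""End-to-end orchestration of the mapping pipeline on a synthetic cohort.

Order of operations, mirroring the study design:

1. simulate (or load) the cohort;
2. pedigree analysis: inbreeding coefficients, obligate carriers;
3. trio homozygosity mapping: ROH in the sequenced case, subtraction of
   regions homozygous in its genotyped parents, optional shared-allele
   consensus across all cases, >= 1 Mb threshold, candidate-gene overlap;
4. small-variant prioritisation: case hom-alt, private versus the control
   cohort, restricted to mapped regions with coding annotation;
5. deletion calling from the paired-end library, genotyping, privacy
   filtering against control libraries;
6. consequence classification of private deletions and the final
   nomination report with cascade counts.

Every stage logs its count into the cascade audit trail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import cohort as cohort_mod
from . import consequence as cons_mod
from . import roh as roh_mod
from . import svcall as sv_mod
from . import variants as var_mod
from .pedigree import inbreeding_coefficient, obligate_carriers

log = logging.getLogger("recmap")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    cohort: cohort_mod.CohortData
    case_segments: list
    novel_segments: list
    mapped_regions: list
    candidate_hits: list
    prioritized_variants: list
    private_variant_count: int
    deletion_calls: list
    private_deletion_calls: list
    consequences: list
    report: dict
    shared_across_cases: bool
    insert_model: object = None


def run_pipeline(
    config: cohort_mod.SimConfig,
    roh_params: roh_mod.ROHParams = roh_mod.ROHParams(),
    sv_params: sv_mod.SVParams = sv_mod.SVParams(),
    shared_across_cases: bool = False,
    exclude_mode: str = "subtract",
) -> PipelineResult:
    """Run the whole cascade on a freshly simulated cohort.

    ``shared_across_cases`` selects whether mapped regions are additionally
    intersected across all affected individuals with the shared-allele rule
    (the default maps on the sequenced trio alone; the report records which
    ordering was used).
    """
    cohort = cohort_mod.simulate_cohort(config)
    ped = cohort.pedigree
    case = config.sequenced_case
    cascade: dict[str, int] = {}

    gm = roh_mod.GenotypeMatrix(
        cohort.marker_map, cohort.calls, cohort.individuals
    )

    # --- homozygosity mapping on the sequenced trio
    case_segments = roh_mod.detect_roh(gm, case, roh_params)
    cascade["case_roh_segments"] = len(case_segments)
    sire, dam = ped.parents(case)
    parent_segments = {
        p: roh_mod.detect_roh(gm, p, roh_params) for p in (sire, dam) if p
    }
    novel = roh_mod.exclude_parental(
        case_segments, parent_segments, roh_params.min_length_bp,
        mode=exclude_mode,
    )
    cascade["novel_roh_regions_1mb"] = len(novel)

    if shared_across_cases:
        segs_by_case = {case: novel}
        for other in sorted(ped.affected() - {case}):
            segs_by_case[other] = roh_mod.detect_roh(gm, other, roh_params)
        regions = roh_mod.shared_homozygosity(segs_by_case, gm)
    else:
        regions = novel
    cascade["mapped_regions"] = len(regions)

    hits = roh_mod.intersect_candidates(regions, cohort.candidate_bed)
    genes_hit = sorted({g for g, _ in hits})
    cascade["candidate_genes_in_regions"] = len(genes_hit)
    log.info("mapped %d regions; %d/%d candidate genes overlap",
             len(regions), len(genes_hit), len(cohort.gene_models))

    # --- small variants
    import tempfile

    gene_models = [
        cons_mod.GeneModel(
            gene_id=g.gene_id, transcript_id=g.transcript_id, chrom=g.chrom,
            strand=g.strand, exons=tuple(tuple(e) for e in g.exons),
            cds_start=g.cds_start, cds_end=g.cds_end,
        )
        for g in cohort.gene_models
    ]
    with tempfile.TemporaryDirectory() as td:
        paths = cohort_mod.write_cohort(cohort, td)
        case_records = var_mod.load_vcf_records(paths["case_vcf"])
        controls = var_mod.ControlCohort.from_vcf(paths["controls_vcf"])
    cascade["case_variants"] = len(case_records)
    hom_alt = var_mod.filter_case_homozygous_alt(case_records, case)
    cascade["case_hom_alt_pass"] = len(hom_alt)
    private = var_mod.filter_private(hom_alt, controls)
    cascade["private_vs_controls"] = len(private)
    prioritized = var_mod.restrict_to_regions(private, regions, gene_models)
    cascade["private_in_regions"] = len(prioritized)
    coding = [v for v in prioritized if v.coding]
    cascade["private_coding_in_candidates"] = len(coding)

    # --- structural variants
    case_pairs = cohort.read_pairs[case]
    calls, model = sv_mod.call_deletions(case_pairs, sv_params)
    cascade["case_deletion_clusters"] = len(calls)
    # only calls genotyped as carrying a deleted allele are disease candidates
    calls = [c for c in calls if c.genotype in ("hom_del", "het_del")]
    cascade["case_deletion_calls"] = len(calls)
    control_sets = []
    for name in cohort.truth["control_samples"]:
        pairs = cohort.read_pairs.get(name)
        if pairs is None or len(pairs) == 0:
            control_sets.append([])
            continue
        try:
            ccalls, _ = sv_mod.call_deletions(pairs, sv_params)
        except ValueError:
            ccalls = []
        control_sets.append(ccalls)
    private_dels = sv_mod.private_deletions(
        calls, control_sets, sv_params.min_reciprocal_overlap
    )
    cascade["private_deletions"] = len(private_dels)

    # --- consequences on private deletions overlapping candidate genes
    consequences = []
    for call in private_dels:
        best = None
        for gmodel in gene_models:
            c = cons_mod.classify_consequence(
                (call.chrom, call.start, call.end), gmodel
            )
            if c.consequence != "intergenic":
                best = (gmodel, c)
                break
        if best is None:
            continue
        gmodel, c = best
        if c.consequence == "start_lost" and gmodel.gene_id == gene_models[0].gene_id:
            off, frac = cons_mod.downstream_start_rescue(
                gmodel, cohort.transcript_cds, (call.chrom, call.start, call.end), c
            )
            c = cons_mod.ConsequenceCall(
                deletion=c.deletion, gene=c.gene, consequence=c.consequence,
                deleted_coding_bases=c.deleted_coding_bases,
                whole_exons_deleted=c.whole_exons_deleted,
                alt_start_offset=off, fraction_cds_removed=frac, notes=c.notes,
            )
        consequences.append((call, c))
    cascade["private_deletions_in_genes"] = len(consequences)

    report = cons_mod.final_report(
        prioritized, consequences,
        [g.gene_id for g in cohort.gene_models], cascade,
    )
    report["shared_across_cases"] = shared_across_cases
    report["pedigree"] = {
        "inbreeding": {
            a: inbreeding_coefficient(ped, a) for a in sorted(ped.affected())
        },
        "obligate_carriers": sorted(obligate_carriers(ped, ped.affected())),
    }

    return PipelineResult(
        cohort=cohort,
        case_segments=case_segments,
        novel_segments=novel,
        mapped_regions=regions,
        candidate_hits=hits,
        prioritized_variants=prioritized,
        private_variant_count=len(private),
        deletion_calls=calls,
        private_deletion_calls=private_dels,
        consequences=consequences,
        report=report,
        shared_across_cases=shared_across_cases,
        insert_model=model,
    )
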