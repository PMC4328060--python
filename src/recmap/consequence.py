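"""Loss-of-function consequence classification and the final report.

Classifies a genomic deletion against a transcript model (strand-aware
start-codon loss, whole-exon loss, CDS truncation, intronic/upstream/
intergenic), scans the wildtype coding sequence for a downstream in-frame
rescue start, predicts the band patterns of a three-primer PCR genotyping
assay, and assembles the end-of-pipeline nomination report with the full
filter-cascade audit trail.

Genomic deletion coordinates follow HGVS g. convention: 1-based, inclusive
at both ends, so the length of g.start_enddel is end - start + 1. VCF
symbolic DEL records anchor POS one base before the first deleted base
with END at the last deleted base; the conversion lives here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GeneModel",
    "ConsequenceCall",
    "GenotypingAssay",
    "deletion_length",
    "classify_consequence",
    "downstream_start_rescue",
    "predict_genotyping_bands",
    "final_report",
    "load_gene_models",
    "read_fasta_sequence",
    "hgvs_to_vcf_anchor",
    "vcf_anchor_to_hgvs",
]


@dataclass(frozen=True)
class GeneModel:
    """A transcript: ordered exons and genomic CDS bounds, 1-based inclusive.

    ``cds_start``/``cds_end`` are genomic low/high coordinates; the
    translation start is ``cds_start`` on the plus strand and ``cds_end``
    on the minus strand.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple                  # ((start, end), ...) ordered, non-overlapping
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError("exons must be ordered and non-overlapping")
        if not any(s <= self.translation_start() <= e for s, e in self.exons):
            raise ValueError("CDS start must lie within an exon")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def translation_start(self) -> int:
        return self.cds_start if self.strand == "+" else self.cds_end

    def start_codon_interval(self) -> tuple[int, int]:
        """Genomic interval of the 3 start-codon bases (assumed intra-exon)."""
        if self.strand == "+":
            return self.cds_start, self.cds_start + 2
        return self.cds_end - 2, self.cds_end

    def cds_exon_pieces(self) -> list[tuple[int, int]]:
        """Genomic intervals of coding sequence (exon intersect CDS bounds)."""
        pieces = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                pieces.append((lo, hi))
        return pieces

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_exon_pieces())


@dataclass(frozen=True)
class ConsequenceCall:
    deletion: tuple               # (chrom, start, end) HGVS-style
    gene: str
    consequence: str              # start_lost | exon_loss | cds_truncation |
                                  # intronic | upstream | intergenic
    deleted_coding_bases: int = 0
    whole_exons_deleted: int = 0
    alt_start_offset: int | None = None   # from downstream_start_rescue
    fraction_cds_removed: float | None = None
    notes: tuple = ()


@dataclass(frozen=True)
class GenotypingAssay:
    """Three-primer deletion assay: a common forward primer, a reverse
    primer inside the deleted region (Rev1) and a reverse primer
    immediately downstream of it (Rev2)."""

    forward_pos: int
    rev1_pos: int
    rev2_pos: int
    deletion: tuple               # (start, end) 1-based inclusive

    def __post_init__(self):
        s, e = self.deletion
        if not self.forward_pos < s:
            raise ValueError("forward primer must lie upstream of the deletion")
        if not s <= self.rev1_pos <= e:
            raise ValueError("Rev1 must lie inside the deletion")
        if not self.rev2_pos > e:
            raise ValueError("Rev2 must lie downstream of the deletion")


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------

def deletion_length(start: int, end: int) -> int:
    """Length in bp of g.start_enddel (1-based inclusive): end - start + 1."""
    if end < start:
        raise ValueError(f"end ({end}) < start ({start})")
    return end - start + 1


def hgvs_to_vcf_anchor(start: int, end: int) -> tuple[int, int]:
    """HGVS g.start_end -> (POS, END) for a symbolic DEL record."""
    deletion_length(start, end)  # validates
    return start - 1, end


def vcf_anchor_to_hgvs(pos: int, end: int) -> tuple[int, int]:
    """(POS, END) of a symbolic DEL record -> HGVS g.start_end."""
    if end <= pos:
        raise ValueError("END must exceed the anchor POS")
    return pos + 1, end


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    ov = min(a[1], b[1]) - max(a[0], b[0]) + 1
    return max(ov, 0)


def classify_consequence(
    deletion: tuple,
    gene_model: GeneModel,
    upstream_window: int = 2_000,
) -> ConsequenceCall:
    """Classify a deletion against one transcript model.

    Classes, in precedence order: ``start_lost`` when any of the 3
    start-codon bases is deleted (any disruption of the codon is
    disruptive); ``exon_loss`` when at least one whole exon is contained in
    the deletion; ``cds_truncation`` for partial coding overlap;
    ``intronic`` within the transcript span without exon overlap;
    ``upstream`` within ``upstream_window`` bp 5' of the transcript
    (strand-aware); ``intergenic`` otherwise. Deleted coding bases are
    counted over the exon-CDS intersections whatever the class.
    """
    chrom, dstart, dend = deletion
    if dend < dstart:
        raise ValueError("deletion end < start")
    notes = []
    if str(chrom) != str(gene_model.chrom):
        return ConsequenceCall(
            deletion=tuple(deletion), gene=gene_model.gene_id,
            consequence="intergenic",
            notes=("chromosome mismatch with the gene model",),
        )
    ival = (dstart, dend)
    coding = sum(_overlap(ival, piece) for piece in gene_model.cds_exon_pieces())
    whole = sum(
        1 for s, e in gene_model.exons if dstart <= s and e <= dend
    )
    start_hit = _overlap(ival, gene_model.start_codon_interval()) > 0
    span = gene_model.span
    exon_overlap = any(_overlap(ival, ex) > 0 for ex in gene_model.exons)

    if start_hit:
        cls = "start_lost"
    elif whole > 0:
        cls = "exon_loss"
    elif coding > 0:
        cls = "cds_truncation"
    elif _overlap(ival, span) > 0:
        cls = "intronic" if not exon_overlap else "exon_loss"
        if exon_overlap:
            notes.append("partial non-coding exon overlap")
    else:
        # strand-aware upstream window
        if gene_model.strand == "+":
            up = (span[0] - upstream_window, span[0] - 1)
        else:
            up = (span[1] + 1, span[1] + upstream_window)
        cls = "upstream" if _overlap(ival, up) > 0 else "intergenic"
    return ConsequenceCall(
        deletion=tuple(deletion), gene=gene_model.gene_id, consequence=cls,
        deleted_coding_bases=int(coding), whole_exons_deleted=int(whole),
        notes=tuple(notes),
    )


def downstream_start_rescue(
    gene_model: GeneModel,
    transcript_cds: str,
    deletion: tuple,
    call: ConsequenceCall | None = None,
) -> tuple[int | None, float]:
    """First downstream in-frame ATG after a start-loss deletion.

    ``transcript_cds`` is the wildtype coding sequence 5'->3'. Scans
    in-frame codon positions whose bases survive the deletion and returns
    (offset of the first intact ATG from the lost start, fraction of the
    wildtype CDS removed up to that start). Returns (None, 1.0) when no
    in-frame ATG survives (total loss).
    """
    call = call or classify_consequence(deletion, gene_model)
    if call.consequence != "start_lost":
        raise ValueError("rescue scan applies to start_lost deletions only")
    seq = transcript_cds.upper()
    deleted = _deleted_cds_positions(gene_model, deletion)
    for p in range(0, len(seq) - 2, 3):
        codon_positions = {p, p + 1, p + 2}
        if codon_positions & deleted:
            continue
        if seq[p:p + 3] == "ATG":
            return p, p / len(seq)
    return None, 1.0


def _deleted_cds_positions(gene_model: GeneModel, deletion: tuple) -> set:
    """0-based CDS coordinates (translation order) removed by the deletion."""
    chrom, dstart, dend = deletion
    pieces = gene_model.cds_exon_pieces()
    if gene_model.strand == "-":
        pieces = pieces[::-1]
    deleted = set()
    offset = 0
    for s, e in pieces:
        plen = e - s + 1
        lo, hi = max(s, dstart), min(e, dend)
        if lo <= hi:
            if gene_model.strand == "+":
                deleted.update(range(offset + (lo - s), offset + (hi - s) + 1))
            else:
                deleted.update(range(offset + (e - hi), offset + (e - lo) + 1))
        offset += plen
    return deleted


# ---------------------------------------------------------------------------
# PCR genotyping bands
# ---------------------------------------------------------------------------

def predict_genotyping_bands(assay: GenotypingAssay, genotype: str) -> set:
    """Band pattern of the three-primer assay for a diploid genotype.

    A wild-type allele amplifies F+Rev1 (the F+Rev2 product is too long to
    amplify by design); a deleted allele loses the Rev1 site and brings
    Rev2 into range, amplifying F+Rev2. A diploid genotype shows the union
    over its two alleles.
    """
    per_allele = {"wt": "F+Rev1", "del": "F+Rev2"}
    try:
        a1, a2 = genotype.split("/")
        return {per_allele[a1], per_allele[a2]}
    except (ValueError, KeyError):
        raise ValueError(f"bad genotype {genotype!r}") from None


# ---------------------------------------------------------------------------
# Final report
# ---------------------------------------------------------------------------

def final_report(
    prioritized_variants: Sequence,
    private_deletion_consequences: Sequence[tuple],
    candidate_genes: Sequence[str],
    cascade_counts: Mapping[str, int],
) -> dict:
    """Rank surviving events and nominate the causal candidate.

    ``private_deletion_consequences`` is (DeletionCall, ConsequenceCall)
    pairs for the case's private deletions. An event is disruptive when it
    hits a candidate gene's transcript with a coding consequence
    (start_lost, exon_loss or cds_truncation) — for deletions — or is a
    private homozygous coding variant in a candidate gene — for small
    variants. Exactly one disruptive event is flagged as the causal
    nomination; zero or several are reported as such.
    """
    candidate = set(candidate_genes)
    nominations = []
    for call, cons in private_deletion_consequences:
        if cons.gene in candidate and cons.consequence in (
            "start_lost", "exon_loss", "cds_truncation"
        ):
            nominations.append({
                "type": "deletion",
                "chrom": call.chrom,
                "breakpoint_interval": [call.start, call.end],
                "estimated_size": call.estimated_size,
                "genotype": call.genotype,
                "gene": cons.gene,
                "consequence": cons.consequence,
                "deleted_coding_bases": cons.deleted_coding_bases,
                "alt_start_offset": cons.alt_start_offset,
                "fraction_cds_removed": cons.fraction_cds_removed,
            })
    for v in prioritized_variants:
        if v.gene in candidate and v.coding:
            nominations.append({
                "type": "small_variant",
                "chrom": v.record.chrom, "pos": v.record.pos,
                "ref": v.record.ref, "alt": v.record.alt,
                "gene": v.gene, "consequence": "coding_variant",
            })
    return {
        "cascade": dict(cascade_counts),
        "n_candidate_events": len(nominations),
        "unique_nomination": len(nominations) == 1,
        "nominations": nominations,
    }


def render_report_text(report: Mapping) -> str:
    """Human-readable rendering of the final report."""
    lines = ["== Recessive-mapping final report ==", "", "Filter cascade:"]
    for k, v in report["cascade"].items():
        lines.append(f"  {k}: {v}")
    lines.append("")
    if report["unique_nomination"]:
        n = report["nominations"][0]
        lines.append("Causal nomination (unique):")
    elif report["n_candidate_events"] == 0:
        lines.append("No disruptive candidate-gene event survived the cascade.")
    else:
        lines.append(
            f"NON-UNIQUE: {report['n_candidate_events']} candidate events survive:"
        )
    for n in report["nominations"]:
        if n["type"] == "deletion":
            lines.append(
                f"  {n['gene']}: {n['consequence']} deletion on chr{n['chrom']}"
                f" [{n['breakpoint_interval'][0]:,}-{n['breakpoint_interval'][1]:,}],"
                f" ~{n['estimated_size']:.0f} bp, genotype {n['genotype']},"
                f" {n['deleted_coding_bases']} coding bases removed"
            )
        else:
            lines.append(
                f"  {n['gene']}: private coding variant"
                f" {n['chrom']}:{n['pos']} {n['ref']}>{n['alt']}"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_gene_models(path: str) -> list[GeneModel]:
    """Read the gene-model JSON (list of transcript dicts)."""
    with open(path) as fh:
        data = json.load(fh)
    return [
        GeneModel(
            gene_id=d["gene_id"], transcript_id=d["transcript_id"],
            chrom=str(d["chrom"]), strand=d["strand"],
            exons=tuple(tuple(e) for e in d["exons"]),
            cds_start=d["cds_start"], cds_end=d["cds_end"],
        )
        for d in data
    ]


def read_fasta_sequence(path: str, name: str | None = None) -> str:
    """First (or named) sequence from a FASTA file."""
    seqs: dict[str, list[str]] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                current = line[1:].split()[0]
                seqs[current] = []
            elif current is not None:
                seqs[current].append(line)
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    key = name if name is not None else next(iter(seqs))
    return "".join(seqs[key])
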