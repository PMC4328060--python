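"""Pedigree representation, kinship/inbreeding, carrier inference, gene dropping.

A pedigree is a directed acyclic sire/dam graph with affection status. It is
the substrate for three computations used in recessive-disease mapping of
consanguineous families:

* recursive kinship and inbreeding coefficients (the probability that two
  homologous alleles are identical by descent, IBD),
* obligate-carrier inference under an autosomal recessive model,
* gene-dropping Monte Carlo, which transmits uniquely labelled founder
  haplotypes down the pedigree with Haldane (no-interference) recombination
  and measures the autozygous genome fraction per individual.

Unknown parents are modelled as unique, unrelated founders, which makes every
reported inbreeding coefficient a conservative lower bound when pedigree
records are incomplete.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "IndividualRecord",
    "Pedigree",
    "PedigreeError",
    "parse_pedigree",
    "write_pedigree",
    "kinship_coefficient",
    "inbreeding_coefficient",
    "obligate_carriers",
    "gene_drop",
    "mendelian_check",
    "MendelianViolation",
    "kinship_table_json",
]

SEX_CODES = {"1": "male", "2": "female"}
STATUS_CODES = {"1": "unaffected", "2": "affected"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees or unknown individual ids."""


@dataclass(frozen=True)
class IndividualRecord:
    """One pedigree member.

    ``sire_id``/``dam_id`` are ``None`` when the parent is unknown (PED "0").
    """

    id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = "unknown"          # {male, female, unknown}
    status: str = "unknown"       # {affected, unaffected, unknown}
    genotyped: bool = False
    family: str = "FAM1"

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None and self.dam_id is None


class Pedigree:
    """Directed acyclic sire/dam graph keyed by individual id."""

    def __init__(self, individuals: Iterable[IndividualRecord]):
        self.individuals: dict[str, IndividualRecord] = {}
        for rec in individuals:
            if rec.id in self.individuals:
                raise PedigreeError(f"duplicate individual id: {rec.id!r}")
            self.individuals[rec.id] = rec
        # Parents referenced but not given their own row become implicit
        # founders (unknown-descent individuals such as a bought-in cow).
        for rec in list(self.individuals.values()):
            for pid in (rec.sire_id, rec.dam_id):
                if pid is not None and pid not in self.individuals:
                    self.individuals[pid] = IndividualRecord(id=pid, family=rec.family)
        self._generation = self._toposort()
        self._kinship_cache: dict[tuple[str, str], float] = {}

    def _toposort(self) -> dict[str, int]:
        """Generation index per individual (founders 0); raises on cycles."""
        gen: dict[str, int] = {}

        def depth(iid: str, stack: tuple[str, ...]) -> int:
            if iid in stack:
                raise PedigreeError(
                    f"pedigree cycle: {iid!r} is its own ancestor"
                )
            if iid in gen:
                return gen[iid]
            rec = self.individuals[iid]
            parents = [p for p in (rec.sire_id, rec.dam_id) if p is not None]
            g = 0 if not parents else 1 + max(
                depth(p, stack + (iid,)) for p in parents
            )
            gen[iid] = g
            return g

        for iid in self.individuals:
            depth(iid, ())
        return gen

    # -- basic queries -----------------------------------------------------

    def __contains__(self, iid: str) -> bool:
        return iid in self.individuals

    def __len__(self) -> int:
        return len(self.individuals)

    def record(self, iid: str) -> IndividualRecord:
        try:
            return self.individuals[iid]
        except KeyError:
            raise PedigreeError(f"unknown individual id: {iid!r}") from None

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        rec = self.record(iid)
        return rec.sire_id, rec.dam_id

    def founders(self) -> list[str]:
        return [i for i, r in self.individuals.items() if r.is_founder]

    def affected(self) -> set[str]:
        return {i for i, r in self.individuals.items() if r.status == "affected"}

    def topological_order(self) -> list[str]:
        """Ids ordered so every parent precedes its offspring."""
        return sorted(self.individuals, key=lambda i: (self._generation[i], i))

    # -- kinship -----------------------------------------------------------

    def kinship(self, a: str, b: str) -> float:
        """Recursive (tabular-method) kinship coefficient f(a, b).

        f(x, x) = 1/2 (1 + f(sire_x, dam_x)); for distinct x, y the
        recursion descends on whichever individual is in the later
        generation (hence never an ancestor of the other):
        f(x, y) = 1/2 (f(sire_x, y) + f(dam_x, y)). Unknown parents
        contribute 0 (unique unrelated founders).
        """
        self.record(a), self.record(b)
        return self._kinship(a, b)

    def _kinship(self, a: str | None, b: str | None) -> float:
        if a is None or b is None:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        if key in self._kinship_cache:
            return self._kinship_cache[key]
        if a == b:
            s, d = self.parents(a)
            val = 0.5 * (1.0 + self._kinship(s, d))
        else:
            # recurse on the later-generation individual
            if self._generation[a] < self._generation[b]:
                a, b = b, a
            s, d = self.parents(a)
            val = 0.5 * (self._kinship(s, b) + self._kinship(d, b))
        self._kinship_cache[key] = val
        return val

    def inbreeding(self, iid: str) -> float:
        """F(ind) = kinship of the parents; 0 if either parent is unknown."""
        s, d = self.parents(iid)
        if s is None or d is None:
            return 0.0
        return self._kinship(s, d)


# ---------------------------------------------------------------------------
# PED I/O
# ---------------------------------------------------------------------------

def parse_pedigree(rows: Iterable[str] | str) -> Pedigree:
    """Parse PED-format rows into a :class:`Pedigree`.

    Accepts an iterable of lines or a path to a PED file. Columns
    (whitespace delimited): family, id, sire, dam, sex, phenotype; "0"
    denotes an unknown parent; sex 1=male 2=female; phenotype 1=unaffected
    2=affected 0/-9=unknown. Extra columns are ignored.
    """
    if isinstance(rows, str):
        with open(rows) as fh:
            lines = fh.readlines()
    else:
        lines = list(rows)
    records = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise PedigreeError(f"PED row has {len(cols)} columns, need >= 6: {line!r}")
        fam, iid, sire, dam, sex, pheno = cols[:6]
        if sire == iid or dam == iid:
            raise PedigreeError(f"pedigree cycle: {iid!r} is its own ancestor")
        records.append(
            IndividualRecord(
                id=iid,
                sire_id=None if sire == "0" else sire,
                dam_id=None if dam == "0" else dam,
                sex=SEX_CODES.get(sex, "unknown"),
                status=STATUS_CODES.get(pheno, "unknown"),
                family=fam,
            )
        )
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path: str) -> None:
    """Write a pedigree as 6-column PED."""
    sex_out = {"male": "1", "female": "2", "unknown": "0"}
    status_out = {"unaffected": "1", "affected": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for iid in ped.topological_order():
            r = ped.record(iid)
            fh.write(
                f"{r.family}\t{r.id}\t{r.sire_id or '0'}\t{r.dam_id or '0'}\t"
                f"{sex_out[r.sex]}\t{status_out[r.status]}\n"
            )


def kinship_table_json(ped: Pedigree, path: str | None = None) -> str:
    """JSON export of the pairwise kinship matrix and per-individual F."""
    ids = ped.topological_order()
    table = {
        "individuals": ids,
        "kinship": {a: {b: ped.kinship(a, b) for b in ids} for a in ids},
        "inbreeding": {a: ped.inbreeding(a) for a in ids},
    }
    text = json.dumps(table, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Module-level functional API
# ---------------------------------------------------------------------------

def kinship_coefficient(ped: Pedigree, a: str, b: str) -> float:
    """Kinship coefficient f(a, b); see :meth:`Pedigree.kinship`."""
    return ped.kinship(a, b)


def inbreeding_coefficient(ped: Pedigree, ind: str) -> float:
    """Inbreeding coefficient F(ind) = kinship(sire, dam)."""
    ped.record(ind)
    return ped.inbreeding(ind)


def obligate_carriers(ped: Pedigree, affected: set[str]) -> set[str]:
    """Unaffected parents of affected individuals (autosomal recessive model).

    Every parent of an affected individual must carry at least one copy of
    the causal allele; those not themselves affected are obligate carriers.
    """
    if not affected:
        raise PedigreeError("affected set is empty")
    carriers: set[str] = set()
    for iid in affected:
        rec = ped.record(iid)
        for pid in (rec.sire_id, rec.dam_id):
            if pid is not None and ped.record(pid).status != "affected":
                carriers.add(pid)
    return carriers


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------
#
# Haplotypes are piecewise-constant label maps over [0, L): a list of
# (start_bp, founder_haplotype_label) segments, sorted by start. Meiosis
# places crossovers by a Poisson process (Haldane, no interference) and
# alternates between the two parental haplotypes.


def _meiosis(
    hap_a: list[tuple[float, int]],
    hap_b: list[tuple[float, int]],
    length: float,
    rate: float,
    rng: np.random.Generator,
) -> list[tuple[float, int]]:
    """One gamete from a parent's two haplotypes."""
    n_xo = rng.poisson(rate * length)
    cuts = np.sort(rng.uniform(0.0, length, size=n_xo)) if n_xo else np.empty(0)
    cur = int(rng.integers(2))  # random starting phase
    source = (hap_a, hap_b)
    gamete: list[tuple[float, int]] = []
    bounds = np.concatenate(([0.0], cuts, [length]))
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        if hi <= lo:
            cur ^= 1
            continue
        for start, lab in _slice(source[cur], lo, hi):
            if gamete and gamete[-1][1] == lab:
                pass  # merge identical adjacent labels
            else:
                gamete.append((start, lab))
        cur ^= 1
    return gamete


def _slice(hap: list[tuple[float, int]], lo: float, hi: float):
    """Segments of ``hap`` restricted to [lo, hi)."""
    out = []
    for i, (start, lab) in enumerate(hap):
        end = hap[i + 1][0] if i + 1 < len(hap) else np.inf
        s, e = max(start, lo), min(end, hi)
        if s < e:
            out.append((s, lab))
    return out


def _ibd_length(
    hap1: list[tuple[float, int]],
    hap2: list[tuple[float, int]],
    length: float,
) -> float:
    """Total length where both haplotypes carry the same founder label."""
    starts = sorted({s for s, _ in hap1} | {s for s, _ in hap2})
    total = 0.0
    for i, s in enumerate(starts):
        e = starts[i + 1] if i + 1 < len(starts) else length
        if _label_at(hap1, s) == _label_at(hap2, s):
            total += e - s
    return total


def _label_at(hap: list[tuple[float, int]], pos: float) -> int:
    lab = hap[0][1]
    for s, l in hap:
        if s <= pos:
            lab = l
        else:
            break
    return lab


def drop_haplotypes(
    ped: Pedigree,
    chrom_lengths: Sequence[float],
    recomb_rate: float,
    rng: np.random.Generator,
) -> dict[str, list[tuple[list, list]]]:
    """One gene-dropping replicate: per individual, per chromosome, the two
    transmitted haplotypes as (start, founder-label) segment lists.

    Founder haplotype labels are globally unique integers, so two segments
    with equal labels are identical by descent.
    """
    order = ped.topological_order()
    founders = set(ped.founders())
    label = 0
    haps: dict[str, list[tuple[list, list]]] = {}
    for iid in order:
        if iid in founders:
            per_chrom = []
            for L in chrom_lengths:
                per_chrom.append(([(0.0, label)], [(0.0, label + 1)]))
                # same founder haplotype label across chromosomes is fine:
                # autozygosity compares labels within a chromosome only
            label += 2
            haps[iid] = per_chrom
        else:
            s, d = ped.parents(iid)
            per_chrom = []
            for ci, L in enumerate(chrom_lengths):
                pat = _meiosis(*haps[s][ci], L, recomb_rate, rng) if s else [(0.0, label)]
                if s is None:
                    label += 1
                mat = _meiosis(*haps[d][ci], L, recomb_rate, rng) if d else [(0.0, label)]
                if d is None:
                    label += 1
                per_chrom.append((pat, mat))
            haps[iid] = per_chrom
    return haps


def founder_haplotype_labels(ped: Pedigree) -> dict[str, tuple[int, int]]:
    """Founder-haplotype label pairs as assigned by :func:`drop_haplotypes`.

    Labels are allocated in topological-order iteration, two per founder,
    so callers can identify e.g. "haplotype A of founder IV/A" across
    replicates.
    """
    founders = set(ped.founders())
    labels: dict[str, tuple[int, int]] = {}
    label = 0
    for iid in ped.topological_order():
        if iid in founders:
            labels[iid] = (label, label + 1)
            label += 2
    return labels


def gene_drop(
    ped: Pedigree,
    chrom_lengths: Sequence[float],
    recomb_rate: float,
    n_rep: int,
    seed: int,
) -> dict[str, np.ndarray]:
    """Monte-Carlo distribution of the autozygous genome fraction.

    Returns, per individual, an array of ``n_rep`` genome fractions that are
    IBD (both haplotype labels descend from the same founder haplotype). The
    mean converges to the pedigree inbreeding coefficient.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if recomb_rate <= 0 or any(L <= 0 for L in chrom_lengths):
        raise ValueError("chromosome lengths and recombination rate must be positive")
    rng = np.random.default_rng(seed)
    genome = float(sum(chrom_lengths))
    out = {iid: np.empty(n_rep) for iid in ped.individuals}
    for rep in range(n_rep):
        haps = drop_haplotypes(ped, chrom_lengths, recomb_rate, rng)
        for iid, per_chrom in haps.items():
            ibd = sum(
                _ibd_length(h1, h2, L)
                for (h1, h2), L in zip(per_chrom, chrom_lengths)
            )
            out[iid][rep] = ibd / genome
    return out


# ---------------------------------------------------------------------------
# Mendelian consistency of deletion genotypes
# ---------------------------------------------------------------------------

_GT_ALLELES = {
    "wt/wt": ("wt", "wt"),
    "wt/del": ("wt", "del"),
    "del/wt": ("wt", "del"),
    "del/del": ("del", "del"),
}


@dataclass(frozen=True)
class MendelianViolation:
    offspring: str
    offspring_gt: str
    parent_gts: tuple
    reason: str


def mendelian_check(
    ped: Pedigree, genotypes: Mapping[str, str]
) -> list[MendelianViolation]:
    """Flag offspring genotypes incompatible with biallelic transmission.

    The genotype map may be partial; trios with missing members are checked
    against whichever parents are genotyped. For a single genotyped parent
    the offspring must carry at least one allele that parent can transmit;
    with both parents genotyped the offspring's allele pair must be
    assignable one-from-each.
    """
    violations = []
    for iid, gt in genotypes.items():
        if gt not in _GT_ALLELES or iid not in ped:
            continue
        child = _GT_ALLELES[gt]
        s, d = ped.parents(iid)
        sgt = genotypes.get(s) if s else None
        dgt = genotypes.get(d) if d else None
        sa = set(_GT_ALLELES[sgt]) if sgt in _GT_ALLELES else None
        da = set(_GT_ALLELES[dgt]) if dgt in _GT_ALLELES else None
        ok = True
        if sa is not None and da is not None:
            ok = (child[0] in sa and child[1] in da) or (
                child[1] in sa and child[0] in da
            )
        elif sa is not None:
            ok = child[0] in sa or child[1] in sa
        elif da is not None:
            ok = child[0] in da or child[1] in da
        if not ok:
            violations.append(
                MendelianViolation(
                    offspring=iid,
                    offspring_gt=gt,
                    parent_gts=(sgt, dgt),
                    reason=f"{iid} is {gt} but parents are {sgt}/{dgt}",
                )
            )
    return violations
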