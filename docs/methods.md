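# Methods

This note documents the models, parameter choices and numerical rules
behind `recmap`, and what the synthetic cohort does and does not emulate.

## Pedigree model

The pedigree is a directed acyclic sire/dam graph. Kinship is computed by
the standard tabular recursion — φ(x,x) = ½(1 + φ(sire_x, dam_x)); for
distinct individuals the recursion descends on the later-generation member,
φ(x,y) = ½(φ(sire_x, y) + φ(dam_x, y)) — with memoisation, and is verified
in the test suite against an independent Wright path-counting oracle
(Σ (½)^(n₁+n₂+1)(1 + F_A) over ancestor-path pairs meeting only in the
common ancestor). Unknown parents are modelled as unique unrelated
founders, making every F a conservative lower bound under incomplete
records. Parents referenced in a PED file without a row of their own are
materialised as implicit founders rather than rejected.

For the study family this gives F(case 1) = F(case 2) = 0.25 and
F(case 3) = 0.125.

**Obligate carriers** are the unaffected parents of affected individuals:
{IV/A, III/A, III/B, II/C}. The original pedigree figure additionally
marks the unknown-descent cow III/C as an obligate carrier; that status is
not derivable under the autosomal recessive model (II/C's carrier allele
could equally descend from III/A) and appears to rest on the authors'
conjecture that III/C and IV/A share an ancestor. The package deliberately
reports only what the model forces.

**Gene dropping** assigns each founder two uniquely labelled haplotypes and
transmits them with crossovers placed by a Poisson process (Haldane, no
interference) at 10⁻⁸ per bp per meiosis (1 cM/Mb), random starting phase
per meiosis. The autozygous fraction is the genome proportion where an
individual's two haplotype labels coincide. Sex chromosomes are not
modelled; the mapped locus is autosomal. The Monte-Carlo mean converges to
the analytical F (checked at 3 MC standard errors with 1,000 replicates
over 29 × 90 Mb).

## Synthetic cohort

The generator's defaults are the study conditions at desk scale:

| parameter | default | rationale |
|---|---|---|
| autosomes | 29 × 40 Mb | bovine autosome count; length scaled for runtime |
| markers | 2,000/chromosome (~20 kb spacing, jittered) | ≥ 50 markers per Mb so the 1 Mb / 50-marker ROH thresholds are commensurate with the real array's density-to-threshold ratio |
| founder allele frequencies | Beta(0.5, 0.5), clipped to [0.05, 0.95] | U-shaped spectrum gives realistic background homozygosity-by-state |
| deletion | 2,433 bp on chromosome 16, founder carrier IV/A | the reported lesion; only an IV/A haplotype can be autozygous in case 1 (its dam), so the carrier defaults to IV/A rather than IV/B |
| controls | 40 unrelated genomes | the control cohort size |
| fragment library | insert Normal(300, 30), 2 × 100 bp, 20× | the sequencing design |
| small variants | 2,000 sites, 12 planted case-private | desk-scale stand-in for the exome-wide variant load |

Descent is simulated by gene-dropping; on the deletion chromosome the drop
is rejection-sampled until all three affected animals are autozygous for
the carrier founder's deletion haplotype (the family is ascertained on
three affected calves, so conditioning is the correct emulation). Genotyped
relatives then come out wt/del automatically. Array behaviour over deleted
DNA is emulated: del/del individuals get missing calls at markers inside
the deletion, carriers get hemizygous-genotypes-as-homozygous.

The truth record audits the *generated* data rather than the intent: the
private-variant count is measured from the emitted genotype tables (PASS,
case hom-alt, alternate allele absent from all 40 controls), so pipeline
counts can be compared exactly even when a randomly drawn shared site
happens to be private.

What the generator does **not** emulate: linkage disequilibrium beyond
pedigree descent, genotyping error, sequence content (no base qualities or
alignment), population demography in the controls. Consequences: the gap
between homozygosity-by-state and autozygosity is only a few tenths of a
percent here, whereas the real array's LD produced ~37% observed
homozygosity against the expected 25% — the pipeline checks the
qualitative inequality (ROH fraction ≥ realised IBD fraction), not the
magnitude. Passing tests therefore demonstrate correct mapping logic, not
robustness to array noise.

**Read simulation.** Fragment lengths are Normal(300, 30) (floored at two
read lengths), placed uniformly per haplotype at depth/2 each. On a
deleted haplotype, coordinates at/after the breakpoint map back to the
reference shifted by the deletion length, so a spanning fragment's
apparent span is inflated by exactly that length. A read straddling the
breakpoint junction is modelled the way an aligner treats it: soft-clipped
and kept on whichever side anchors it with ≥ 20 bp (`min_anchor`),
otherwise the fragment is lost. Dropping straddlers entirely would deplete
the spanning-pair count by ~2/3 and push the heterozygous discordant
fraction below any usable genotyping threshold; clipping is both more
realistic and what the genotyping thresholds presuppose.

## ROH detection

Detection is exact and run-based, not a PLINK-style sliding-window
proportion heuristic (a deliberate, documented divergence chosen for
determinism and oracle-checkability). Parameters: min 50 markers, min
1 Mb, ≤ 1 heterozygous and ≤ 2 missing calls per run, inter-marker gap
≤ 1 Mb.

The selection rule is a leftmost-maximal greedy scan: from the current
anchor marker the run is extended as far as the allowances permit
(extension is monotone, so a two-pointer scan is exact), trimmed so it
starts and ends on a homozygous call, reported if it meets both minimums,
and the scan resumes after the reported run — segments therefore never
overlap. The same rule implemented with naive quadratic window checks
serves as the brute-force oracle in the tests.

Parental exclusion is interval subtraction (novel sub-regions survive if
≥ 1 Mb); whole-segment rejection on any overlap is available as
`mode="reject"`. The shared-allele consensus intersects case segments and
keeps an intersection only if every case is homozygous for the same allele
at every genotyped marker inside (missing calls are skipped). The pipeline
defaults to the trio ordering — exclusion on the sequenced case's parents,
no cross-case consensus — because only the sequenced trio was array-typed
in the study design; `shared_across_cases=True` switches the ordering, and
the report records which was used.

Coordinates are 1-based inclusive internally; BED input/output is
converted at the boundary.

## Variant prioritisation

"Private" means the alternate allele is observed in no control at any
zygosity; a missing control genotype is not an observation. Multi-allelic
records are decomposed per alternate allele at load time. Site quality is
consumed through the FILTER column only (PASS required); variant-calling
internals are out of scope. The three filters are set filters and commute;
each survivor carries its complete list of rank reasons. Region
restriction is an explicit, logged cascade stage (the study's own
exome-vs-genome accounting is ambiguous, so the package makes the
restriction visible rather than implicit).

## Deletion calling

Insert-size model: location = median apparent span of concordant FR pairs,
scale = 1.4826 × MAD — robust to the ≤ 10% discordant contamination a
het locus produces. Discordant pairs are FR with span strictly greater
than location + 3·scale and MAPQ ≥ 20; non-FR orientations carry no
deletion signal. Clustering is single linkage on the pairs' implied
deleted intervals (the inner gap between mates); the breakpoint interval
is the cluster's intersection. Two guards keep chained outliers from
poisoning a call: members whose implied size (span − location) strays
more than 4 robust SDs from the cluster median are re-clustered
separately, and clusters without a common intersection are split at the
point of maximum implied-interval coverage (in one dimension, intervals
sharing a point always intersect). Minimum support is 3.

The size estimate, mean span − location, carries a small positive bias
(≈ scale²/insert ≈ 3 bp at the defaults) because spanning fragments are
length-biased; this is well inside the ±2·scale/√support band the tests
assert and is left uncorrected, as in the callers this module simplifies.

Genotyping uses two signals: the discordant fraction r and the depth ratio
d (read bases inside the call interval over the mean of equal-width
flanks). The concordant count in r's denominator is averaged over the two
breakpoints: a deleted haplotype contributes one spanning pair where a
reference haplotype contributes one concordant pair *per breakpoint*, so
summing over both breakpoints (the naive definition) halves r for
deletions longer than the insert and makes a het locus sit at r ≈ 1/3 —
below its own threshold. With the averaged denominator r centres on the
variant allele fraction. Thresholds (config-exposed): hom_del requires
r ≥ 0.8 and d ≤ 0.2; het_del requires 0.3 ≤ r < 0.8 and 0.3 ≤ d ≤ 0.7;
anything else is ref/ambiguous with the failing signals recorded. At 20×
a het locus has only ~13 expected spanning pairs and r is noisy; the tests
exercise het genotyping at 40×, and genotypes should be treated as
provisional below ~30×.

Privacy across genomes uses 50% reciprocal overlap (the comparison rule is
not published; this is the package's documented choice). Breakpoints are
reported as confidence intervals; split-read refinement is out of scope —
confirmation in the original study was by PCR and Sanger sequencing,
modelled here as the three-primer band predictor. Calls can be dumped with
their supporting pairs for manual inspection, and are exportable as VCF
symbolic DEL records (POS anchored one base before the first deleted base;
SVLEN coordinate-consistent; the span-based estimate in SVSIZE).

## Consequence classification

Classes in precedence order: `start_lost` (any of the three start-codon
bases deleted — any disruption of the codon is disruptive, full
containment is not required), `exon_loss` (a whole exon contained in the
deletion), `cds_truncation` (partial coding overlap), `intronic`,
`upstream` (within a 2 kb strand-aware window), `intergenic`. A deletion
overlapping only the non-coding part of an exon is labelled `exon_loss`
with an explanatory note. Deleted coding bases are counted over
exon-CDS intersections and include the start codon (the "first 79 coding
bases" convention counts the ATG within the 79). Classification is
strand-symmetric: reflecting all coordinates and flipping the strand
preserves the class, which the tests check by mirror-image oracle.

The rescue scan walks in-frame codon positions of the wildtype CDS whose
bases all survive the deletion and reports the first intact ATG's offset
and the fraction of CDS removed up to it; no surviving in-frame ATG is
reported as total loss.

HGVS g. deletion coordinates are 1-based inclusive (length = end − start
+ 1); VCF symbolic records anchor POS = start − 1 with END = end, and the
conversion is centralised and round-trip tested.

## Problem sizes and determinism

Default problem sizes — 58,000 markers, 2,000 variant sites, ~4,000 case
read pairs plus 43 additional libraries, 1,000 gene-drop replicates, 100
SV-recovery replicates — were chosen so the full suite and the acceptance
script each run in well under a minute of CPU apiece while keeping every
statistical check adequately powered. All randomness flows from a single
integer seed through `numpy.random.Generator`; identical seeds reproduce
identical files byte for byte (hash-checked in the tests).

## Known limitations

* No LD in the synthetic markers, hence the HBS-vs-IBD gap is qualitative
  only (see above).
* The ROH scanner is not a bit-for-bit PLINK emulation.
* Only deletions are called; duplications, inversions and translocations
  are out of scope, as are CNV segmentation from depth alone and
  likelihood-based segregation analysis.
* Deletion genotypes below ~30× coverage are noisy in r; the pipeline
  treats ref/ambiguous calls as non-candidates rather than re-testing.
* The cohort's "genome" is 1.16 Gb (29 × 40 Mb); counts that scale with
  genome size (ROH regions, private deletions) mirror the study
  qualitatively, not numerically.
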