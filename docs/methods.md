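# Methods

## Model and assumptions

famseg implements a dominant-model co-segregation screen for small family
studies. The underlying genetic model is that each family segregates a
rare, heterozygous, protein-altering variant of large effect, transmitted
from an affected parent to an affected child. Consequently:

- The carrier test is **strictly heterozygous** in both members of a pair.
  Homozygous-alt carriers do not qualify (a `allow_hom` switch relaxes this
  to "carries ≥ 1 alt allele" for sensitivity analysis).
- Unaffected carriers elsewhere in the family do **not** disqualify a
  variant: the screen models incomplete penetrance rather than strict
  Mendelian segregation of the phenotype.
- In families with two affected parents, a variant qualifies if *any*
  affected parent–child pair shares it; maternal and paternal variants can
  each segregate independently in the same family.
- Phase is ignored throughout (`0/1` ≡ `0|1`); compound-heterozygote
  flagging therefore cannot distinguish cis from trans configurations.

Rarity is operationalized as exact-key absence from a user-supplied
known-variant set, standing in for dbSNP/1000 Genomes membership. No
population allele-frequency model is used.

## Quality exclusions

A variant is excluded when (a) it lies in any 10-bp genomic window
containing ≥ 3 variant positions, (b) its site-level mapping quality is
below 30, or (c) any judged genotype has depth < 5 or genotype quality
< 30. All thresholds are strict "less than" exclusions, so values exactly
at a threshold are retained. Missing MQ/DP/GQ fields count as failures
(conservative), while missing genotypes are skipped — they carry no call to
judge. DP and GQ are per-genotype FORMAT fields, MQ a per-site INFO field,
matching common caller output. When a merged file carries several families,
the genotype criteria are evaluated over the family being analysed only, so
a site can fail for one family and pass for another. The cluster filter is
site-level (per file): the window interpretation is "any fixed 10-bp window",
so membership in one qualifying window suffices and the result is
order-independent; windows anchored at variant positions are sufficient
because any qualifying window can be shifted until its leftmost variant
sits at the window start.

## Consequence annotation

Gene models are minimal single-transcript records: exons, CDS bounds, and
the spliced coding-strand CDS sequence. Carrying the sequence in the model
is what allows reference-codon checks (a VCF REF base that contradicts the
model raises an error rather than silently skipping — this surfaces fixture
bugs) and full codon translation with the standard nuclear genetic code via
Biopython's codon table. Coordinates are 1-based fully closed. Intronic
positions anchor to the nearest exon boundary with a signed HGVS-style
offset (`+k` after a donor, `−k` before an acceptor, ties to the donor);
offsets ±1/±2 are classified as canonical splice-site disruption, deeper
positions as plain intronic. External splice-strength predictors are
consumed as annotations, never re-implemented. Indels are classified purely
by `(len(alt) − len(ref)) mod 3`. Protein changes are rendered with
one-letter amino-acid codes (`p.E201D`).

The predictor consensus counts deleterious-class calls (`damaging`,
`conserved`, `disease_causing`) across SIFT, PolyPhen2, PhyloP and
MutationTaster; ≥ 2 votes (default) qualifies. In the final report the
consensus gates **missense substitutions only**: splice-donor/acceptor,
frameshift and stop-gain variants qualify by category, since
missense-trained predictors are undefined for them and loss-of-function
classes carry intrinsic functional support.

## Differential expression and enrichment

The expression stage is a deliberately standard, dependency-light
microarray analysis: per-gene two-sided Welch *t* on log2 intensities,
Benjamini–Hochberg step-up across all genes, and a DE call at q ≤ 0.05 with
|log2FC| ≥ 1 (both configurable). Genes with zero variance in both groups
and equal means receive p = 1. No probe collapsing, normalization or
moderated-variance shrinkage is performed; the matrix is assumed gene-level
and normalized upstream.

Over-representation uses the one-tailed hypergeometric upper tail
P(X ≥ k) for a query of n genes against a background of N genes with K set
members, with BH adjustment across sets. EASE mode (default on) replaces k
by k−1 (p = 1 whenever k ≤ 1), reproducing DAVID's conservative statistic.
The background universe defaults to the genes of the gene-model file and
can be overridden with an explicit universe file; the packaged scenario
uses its 20,000 expression genes as the universe, mirroring a genome-wide
background. Enrichment p-values are sensitive to this choice, which is why
absolute enrichment p-values are not comparable across backgrounds and are
not treated as reproducible quantities.

The final report is the conjunction: co-segregating candidate ∧ gene in DE
set ∧ gene in ≥ 1 enriched set (q ≤ 0.05) ∧ functional support. Each
conjunct is independently switchable for ablation. Cross-family sharing
(genes hit in ≥ 2 families) is computed and reported but is *not* a
conjunct of the final report — it is a parallel line of evidence, and in
the packaged scenario its three genes are deliberately excluded from the DE
list to exercise that distinction. Compound-heterozygote carriers (≥ 2
distinct final-report variants, any gene pair) are flagged as "candidate
severe"; no quantitative severity model is implemented.

## Serology

ImmunoCAP classes follow the printed class bounds; because the printed
intervals leave small gaps (0.70→0.71, 3.5→3.51, 7.5→7.6, 17.5→17.6), bins
are half-open at the printed lower bounds with class 5 closed at 50 kU/l,
giving exhaustive, gap-free coverage consistent with every printed
boundary. Dust-mite eligibility requires *both* Der f and Der p at class
≥ 2 (a disjunctive switch exists) and no exclusion comorbidity. Total IgE
> 100 kU/l is reported as an annotation flag only, not an eligibility
criterion.

## Synthetic-data generator

The generator emits a complete input bundle plus a ground-truth ledger of
everything planted, using one named RNG stream per file (derived from a
single seed via spawn keys) so adding a stream never perturbs the others;
identical configurations are byte-identical.

The packaged scenario emulates a four-family dust-mite study:

- **Pedigrees**: three nuclear trios (affected mother + affected child,
  unaffected father) and one 12-member extended family with 6 affected
  members across three generations.
- **Causal variants**: a missense at CDS 603 (reference codon GAA → GAT,
  residue 201) in FLT1, a missense at CDS 322 (AGC → CGC, residue 108) in
  VEGFB, and a canonical splice-donor G>A at c.502+1 in ITGA2, planted
  heterozygously in their carriers. The ITGA2 allele enters the extended
  family through an unaffected founder carrier so every genotype
  configuration is transmission-consistent.
- **Decoys**: three cross-family genes (five missense variants segregating
  in two families each), plus variants designed to be removed by one
  specific stage — a 3-variant cluster inside 10 bp, low-DP/GQ/MQ variants,
  known-set members, variants carried only outside affected pairs, and a
  hom-alt parent violating the strict heterozygous rule.
- **Background variation**: 200 variants per family, either intergenic or
  synonymous third-base edits, genotypes Mendelian-transmitted from random
  founder carriers, with 95% of keys placed in the known-variant set.
  Background is deliberately neutral so every NS/SS/I tally is attributable
  to planted variants and the ground truth is exact.
- **Expression**: 20,000 genes, 7 cases vs 5 controls, within-group SD 0.1,
  1117 planted DE genes with a ±10 mean shift (100 × SD, random sign);
  22 of them coincide with candidate genes, fixing the candidate/DE
  intersection at 22 by construction. With these settings the DE stage
  recovers the planted set exactly: the BH threshold sits near
  p ≈ 2.8 × 10⁻³ while a null gene would need a ≥ 10-SD mean difference to
  pass the fold-change filter.
- **Gene sets**: a focal-adhesion-like set containing the three causal
  genes plus 22 padding genes (EASE p ≈ 3.4 × 10⁻⁴ at this geometry), and
  two decoy sets with zero query overlap.

What the generator does **not** emulate: linkage disequilibrium, realistic
allele-frequency spectra, sequencing error profiles, probe-level microarray
noise, batch effects, or multi-transcript genes. Passing the end-to-end
recovery tests therefore demonstrates the correctness of the cascade's
logic under its own model, not robustness to real-data artefacts.

## Numerical choices

- Hypergeometric tails via `scipy.stats.hypergeom.sf`; BH via a direct
  numpy step-up (min-over-suffix with monotonicity enforcement), verified
  in tests against an independent reference implementation and exhaustive
  pmf summation up to N = 60.
- Welch p-values from `scipy.stats.ttest_ind(equal_var=False)`; degenerate
  (zero-variance) genes are post-processed to p = 1 (equal means) or p = 0.
- Stable mergesort ordering in BH keeps ties deterministic; report entries
  are ordered by (family, chrom, pos); all writers emit fixed-format floats
  so reruns are byte-identical.
- Problem sizes in tests (2,000-gene null panels, 200-replicate FDR
  simulations, 60-gene enrichment grids, ≤ 50-variant cluster instances)
  were chosen so each suite completes in seconds while keeping Monte-Carlo
  standard errors small enough for 3-SE bounds to be meaningful.

## Known limitations

- One transcript per gene; no UTR/promoter consequences; no multi-gene
  overlap resolution (first containing model wins).
- Known-variant lookup is exact-key; left-normalization of indels is the
  caller's responsibility.
- The cluster filter is per-file (per-cohort), as the per-sample/per-cohort
  choice is underdetermined; this is the conservative site-level reading.
- X-linked inheritance, de-novo detection and linkage/LOD scoring are out
  of scope.
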