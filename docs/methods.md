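# Methods

## The problem

DNA methylation differs strongly between brain cell types, and those
differences themselves evolve. With methylomes from two sorted nuclei
populations (NeuN+ neurons, OLIG2+ oligodendrocytes) in three species —
human, chimpanzee, and rhesus macaque as outgroup — one can ask, for every
differentially methylated region (DMR), *when* the difference arose: before
the ape–monkey split (conserved), on the human lineage, or on the chimpanzee
lineage. The package implements that polarization pipeline for both cytosine
contexts: CG (high methylation, both cell types, rapid evolutionary loss of
the dinucleotide itself) and CH (low, neuron-biased, postnatally acquired,
sequence-stable).

## Site-level model

For cytosine *s* and individual *i* with methylated count *m* out of *t*
reads, the response is the arcsine-transformed proportion

    y = arcsin( 2 (m + δ) / (t + 2δ) − 1 ),    δ = 0.5.

For a binomial proportion this transform makes Var(y) ≈ 1/t independently of
the methylation level, which justifies weighted least squares with weights
*t* and a single per-site residual variance. The stabiliser δ = 0.5 (a
standard continuity correction) keeps 0/t and t/t off the ±π/2 saturation
points; it is exposed as a parameter (δ = 0 gives the exactly
count-scale-invariant statistic).

The design is `cell_type + species + species:cell_type + sex + age_class +
conversion_rate` with treatment coding (OLIG2, first species alphabetically,
female, youngest age class as references; conversion rate centred). CG
testing is a human–chimpanzee fit — macaque CG data enter only at the
region-polarization step, because CpG decay leaves too few three-way
conserved CG sites for a joint model — so each term is one column and its
Wald statistic t = β̂/SE is scalar, with p-values from the t distribution at
(observations − parameters) degrees of freedom. The per-site residual
variance absorbs biological overdispersion across individuals. Sites where a
design cell is entirely uncovered are flagged untested rather than imputed.

BH correction is applied per (context, term) family. Empirically (20
simulated null cohorts, ~83,000 tested sites), the fraction of null sites at
q < 0.05 is ~1e-5: the per-dataset "any rejection" indicator is a degenerate
0/1 statistic under a global null, so calibration is summarised as this
pooled site-level false-positive rate.

Filters follow the study design: CG sites need ≥5× coverage in ≥80% of
individuals within every species group and every cell-type group; CH sites
are dropped when any (species, cell-type) group has a strict majority of
individuals under 5 reads; CH analyses use only samples with bisulfite
conversion >99.5% and down-sample every group to N = 11 (uniformly without
replacement, seed-deterministic) so no species contributes more power than
another.

## DMR construction

Significant sites (q < 0.05) are merged into maximal same-sign runs with
inter-site gaps ≤ `max_gap` = 100 bp (the merging distance is not dictated by
the statistics; 100 bp reflects common WGBS practice and is configurable). A
run must span ≥50 bp and contain ≥4 significant positions. Member sites are
*all* tested cytosines inside the span; `areaStat` is the sum of their Wald
statistics, and regions with |areaStat|/n below t* — the smallest |Wald|
statistic among FDR-significant sites in the same family — are discarded as
weak. Species DMRs must show >10 points of human−chimpanzee difference in
coverage-weighted regional means, cell-type DMRs >15 points between NeuN and
OLIG2 (all strict inequalities). Cell-type and species DMRs overlapping an
interaction (cell-type-restricted species change) DMR are removed as
redundant. CH DMRs add a strict >10-cytosine floor and >10 points of
regional difference. "Average methylation difference" is implemented as the
difference of coverage-weighted regional means (robust at low coverage), not
the mean of per-site differences; this dialect choice is exposed in the code.

Note one non-property of this procedure: loosening the q threshold does not
always increase the DMR count, because a newly significant bridge site can
merge two runs and added weak members can dilute |areaStat|/n below t*.

## Outgroup polarization

A DMR maps to macaque through the orthology map (alignable-block
arithmetic); coverage <50% or <4 macaque CG sites ⇒ unclassified. For mapped
DMRs, each individual's regional mean (Σm/Σt over member sites) is the
response of a beta regression with logit mean link (statsmodels `BetaModel`)
on species plus the covariates; responses at 0/1 are squeezed by
(y(n−1)+0.5)/n. Wald contrasts give human–chimp, human–macaque and
chimp–macaque p-values, BH-corrected per contrast across DMRs;
non-convergent fits fall to unclassified.

Classification is a partition — every DMR gets exactly one label:

- **Conserved cell-type DMR**: macaque shows a same-direction NeuN−OLIG2
  difference >15 points.
- **Human-specific hypo** (mirrored for hyper and for chimpanzee): human
  significantly below both other species (FDR < 0.05 in both contrasts),
  |human−macaque| > |chimp−macaque|, |human−macaque| > 5 points, and both
  cell types satisfying all of it. The "5 points" clause is read as an
  absolute fractional-methylation difference (paralleling the CH rule); a
  ratio reading is available behind `criterion3_as_ratio`.
- **Cell-type-restricted species change**: the same species criteria applied
  within the single affected cell type (the one with the larger
  human−chimp difference) for interaction-term DMRs.
- **CH sites** use strict parsimony: a site is species-specific iff the two
  comparisons involving that species are significant, the third is not, and
  its fractional methylation differs from both other species by >10 points
  in the same direction (raw group-mean differences for the magnitude
  clause). **CH DMRs**: |focal−macaque| > 5 points and greater than the
  other lineage's difference; regions derived on both ape lineages come from
  overlapping the human–macaque and chimp–macaque DMR sets.

## Gene assignment and enrichment

A DMR supports every gene whose body extended by 3 kb on both sides it
overlaps by ≥1 bp (strand-agnostic — the window is symmetric). Gene-body
methylation is Σm/Σt over the gene's cytosines of the requested context. CH
DMR-gene categories require a member DMR of the class, the gene-body
ordering (focal species above/below both others), and dominance of the
focal−outgroup difference; genes qualifying for several categories resolve
to the one with the larger focal−outgroup margin.

Enrichment controls match each query region's length exactly, G+C fraction
within ±0.02 and CpG count within ±10% (tolerances are config; the matching
requirement itself is qualitative), sampled rejection-wise from a fixed-step
composition track, never overlapping the query set. Fold enrichment is
observed/mean(control) region-overlap counts; the empirical p-value uses the
+1 correction so it is never 0. The specificity classifier calls a feature
A-specific iff its enrichment frequency across 100 runs is >0.95 in A and
<0.05 in B (strict, antisymmetric — the mirrored rule for B). The
down-sampler matches a reference set's size and length distribution by
decile binning.

## Synthetic cohort

The generator is the package's study-condition twin, not a fixture: two
50 kb chromosomes carrying ~5,000 CG and ~15,000 CH sites; group sizes
25/20 (human), 11/11 (chimpanzee), 15/13 (macaque) NeuN/OLIG2; coverage per
site negative-binomial with mean 20.6 and dispersion 10, times a lognormal
per-individual depth factor (σ = 0.15); individual methylation propensities
Beta-distributed around the group mean (concentration κ = 120, so the
count model is beta-binomial and the tests face real overdispersion);
observed methylated counts binomial at probability 1 − c(1 − p), where c is
the individual's conversion rate (uniform in 0.9955–0.9995) — a conversion
failure reads an unmethylated cytosine as methylated, which is what the
spike-in conversion estimate measures.

Baselines: CH is strongly neuron-biased (NeuN 0.06 vs OLIG2 0.01). CG
baselines default to equal (0.77) across cell types so that a roster-free
run is an *exact* null for every model term — the genome-wide
neuron>oligodendrocyte CG offset of real brains can be reinstated via the
per-cell-type baselines but would, by design, make every site weakly
cell-type differential. A site-level jitter (σ = 0.04), shared across
groups, adds between-site heterogeneity without breaking the null.

Orthology: each non-focal lineage loses whole alignment blocks (exponential
segments, mean 2 kb; retention 0.98 chimp / 0.95 macaque — alignability
between these genomes is high, and block loss is not the driver of CG
attrition) plus individual sites at context-specific rates (CG 0.15/0.50,
CH 0.05/0.10 for chimp/macaque), reproducing the defining asymmetry that
three-way-conserved CG sites (~0.37 of focal CGs) are far scarcer than
conserved CH sites (~0.77). Planted DMRs cover every evolutionary class at
25–30-point effects, placed disjointly with ≥600 bp separation so
independent plants can never merge during calling.

What the generator does *not* emulate: sequence context (no real CpG
islands, no GC–methylation coupling), spatial correlation of methylation
beyond the planted regions, hydroxymethylation, SNP-induced artefacts, and
read-level error. Passing tests therefore demonstrate the statistical
machinery under the stated noise model, not robustness to alignment or
sequence artefacts of real WGBS.

## Problem sizes and determinism

The default scenario keeps every stage in seconds on one core: ~83,000
null-site tests across 20 cohorts, ~45 beta regressions per run, 100 control
sets per enrichment. All stochastic steps draw from
`numpy.random.default_rng` seeded from the configuration; reruns are
byte-identical (the output manifest records SHA-256 hashes to prove it).

## Known limitations

- The site test is the documented essence of arcsine-link count regression —
  no empirical-Bayes dispersion shrinkage or spatial smoothing, so it is the
  package's reference statistic rather than a re-implementation of any
  specific external tool.
- At coverage ~20× and N = 11 per group, single-site power at p < 1e-4 for a
  30-point effect is ~0.90 (noncentral-t ceiling), which is why region-level
  aggregation, not site-level significance, carries the recovery guarantees.
- Genes that carry qualifying DMRs of both lineages are resolved by the
  gene-body margin and flagged; there is no principled precedence order.
- The orthology map is a reduced alignable-block format; chain-file liftover
  and paralog filtering of real alignments are out of scope.
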