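# Methods

This note documents the models behind `svqtl`, the defaults that matter,
the numerical choices, and what the synthetic data do and do not emulate.

## Population model

A nested association mapping (NAM) design: `n_founders` fully inbred lines
(default 7), one flagged as the common parent, each other founder crossed
to it and the F1 advanced to a subfamily of doubled-haploid (DH) lines.
Default subfamily sizes are 60 with one subfamily of 54 (354 lines in
total), matching the design the package models; sizes are configurable.

**Meiosis.** One recombinant gamete per DH line, doubled. Crossover counts
per chromosome are Poisson with mean equal to the map length in Morgans and
positions are uniform on the cM scale — the Haldane model, no interference.
Interference changes crossover spacing but not the expectations any stage
here relies on (1:1 segregation, map-proportional recombination), so the
simpler model is used. An optional per-locus viability weight (`viability`
in `make_dh_population`, default off) prunes gametes carrying a chosen
allele with probability 1 − w, injecting segregation distortion so the χ²
stage can be exercised on both outcomes.

**Founder haplotypes.** I.i.d. Bernoulli(0.5) per marker by default. With
`block_cm` set, markers are partitioned into consecutive blocks of that
genetic length and each founder carries one of `n_ancestral` (default 2)
shared ancestral haplotypes per block. This plants linkage disequilibrium
with sharp, known boundaries — the ground truth for the block-finding
tests. With two ancestral haplotypes, an expected half of markers are
monomorphic inside any one block; these are removed by the MAF filter and
shrink the *apparent* physical block size, which is why recovered block
sizes cluster at or below the planted length.

**SV loci.** Each simulated SV locus segregates like a marker (its cM
position interpolated from the physical map, sampled on the same gamete as
the markers of its chromosome, so linkage is respected). Carrier founders
can be fixed or drawn (1..n−1 of them, guaranteeing polymorphism).

## Phenotype model

days = grand mean + environment effect + Σ (QTL effect × dose)
      + polygenic value + G×E + residual,

all noise Gaussian. Doses are 0/1 (DH lines are homozygous), so a QTL
effect *is* the difference between genotype-class means, in days to
flowering (BBCH 61 treated as continuous). `var_polygenic` adds an i.i.d.
N(0, σ²) genetic value per line — the way to set genotypic variance
directly when individual QTL are not the object of study. Defaults:
grand mean 245 days (winter crop, autumn sowing), environment effects
N(0, 4) unless supplied, 5 environments × 2 replicates.

**Heritability.** For a balanced genotype × environment design with R
replicates, entry-mean broad-sense heritability is
H² = σ²G / (σ²G + σ²GE/E + σ²e/(E·R)). The estimator uses the classical
expected-mean-squares identities (σ²e = MS_error,
σ²GE = (MS_GE − MS_error)/R, σ²G = (MS_G − MS_GE)/(E·R)), computed directly
from group means; negative component estimates are clipped at zero. The
reference variance setting σ²G = 1.953, σ²GE = 1.0, σ²e = 2.0 gives
H² = 0.830 exactly; the simulation studies recover it to within ±0.02 when
averaged over 20 seeds.

## Marker QC and SNaP calling

"Missing" and "failed" are distinct states: QC missingness counts both,
SNaP candidacy counts only systematic failures. Thresholds: markers
excluded at missingness > 0.10 or MAF < 0.05, individuals at
missingness > 0.10; individuals are filtered before marker statistics. The
passes iterate to a fixed point, which makes the filter idempotent —
a single pass is not, because removing markers changes individual
missingness.

A SNaP candidate is a marker whose failed-call fraction is ≥ 0.10. In each
subfamily where both called and failed states occur, presence:absence is
tested against 1:1 with a one-df χ² without continuity correction — the
only variant consistent with the printed probabilities this stage is
validated against (29:31 → p = 0.796; with a continuity correction it
would be 0.897). Acceptance requires every polymorphic subfamily to fit
(`mode="all"`, default); `mode="any"` is available because real data show
loci that fit in some crosses and are distorted in others, and distortion
in one cross need not invalidate the marker elsewhere. Accepted markers are
recoded as dominant presence/absence calls.

## Association scan

An EMMA-style polygenic score test. Kinship is identity-by-state allele
sharing on the QC-passing matrix (unit diagonal, values in [0, 1]). Per
scan: eigendecompose K once, estimate the variance ratio δ = σ²e/σ²g by
REML (bounded scalar optimization of the profiled residual likelihood over
log δ), then for each marker compute the 1-df score statistic
χ = (gᵀV⁻¹r)² / (σ̂² · gᵀPg) with r the GLS residual and P the projected
inverse covariance. Covariates are an intercept plus `n_pcs` (default 2)
eigenvectors of K. With identity kinship and no PCs this reduces exactly
to the ordinary marker-regression score χ² (asserted against a hand-rolled
oracle). Missing genotypes are mean-imputed within a scan; the n in
R² = χ/(n − 2 + χ) counts only non-missing genotype–phenotype pairs.

Scans are per environment (entry means over replicates), aggregated only
at declaration: significant = BH-FDR q ≤ 0.1, suggestive = −log₁₀ p ≥ 3,
QTL = LD block containing a marker significant in ≥ 2 environments. A
qualifying marker that falls between blocks (block finding leaves gaps
where markers are uninformative) is reported as a point QTL rather than
silently dropped. SV presence/absence calls can be appended to the marker
matrix (`sv_marker_matrix`), mirroring how a locus-specific assay is added
to a scan.

Under a family-structured null (subfamily mean shifts, no causal marker)
the adjusted scan's type-I rate at p < 0.05 is ~0.05 and genomic inflation
λ ≈ 1, while the unadjusted scan on the same data is strongly inflated —
this is the calibration check in the acceptance suite.

## LD blocks

D = p(AB) − p(A)p(B); D′ = D/Dmax with the usual sign-dependent bound. The
confidence interval on |D′| is computed from the multinomial likelihood of
the haplotype counts over a |D′| grid (step 0.001), holding allele
frequencies and the sign of D at their observed values, taking the 5th and
95th percentiles of the normalized likelihood (two-sided 90%). Pair
classification and block rules use the Haploview defaults: strong LD when
CI ∈ [≥ 0.70, ≥ 0.98], strong recombination when the upper bound < 0.90,
otherwise uninformative; a span is a block when ≥ 95% of its informative
pairs are strong LD (and at least one is), resolved longest-first into
non-overlapping spans. Monomorphic loci classify as uninformative rather
than raising. DH lines are homozygous so haplotypes are read directly; a
two-locus EM over the double-heterozygote ambiguity is included for
unphased diploid input. Blocks are computed population-wide on the
combined panel (a per-subfamily mode was considered and not needed: the
QTL intervals the blocks serve are population-level objects).

## SV catalog

Internal coordinates are 0-based half-open everywhere; VCF and GFF3 are
converted at the I/O boundary. Monomorphic means all known founder alleles
equal — including all-alternate, which is a shared difference from the
reference assembly, not a segregating variant. Size classes are half-open,
lower-inclusive: [30, 100), [100, 1000), [1000, 10000), ≥ 10000. The
promoter window (default 10 kb) is anchored at the gene start on the coding
strand — an approximation of "upstream of the start codon" adequate for
annotations without CDS records. Insertions intersect as a 1 bp anchor.

## Locus validation

**PCR.** The reference amplicon runs from the start of the left primer
footprint to the end of the right one. A deletion strictly between the
footprints shortens the product by its size; an insertion anchored between
them lengthens it; any SV overlapping a footprint gives no product for that
allele; an SV elsewhere leaves both alleles at reference length (with a
warning when it is on another chromosome).

**Segregation.** χ² = Σ(obs − exp)²/exp against exp = n/2, one df, no
continuity correction; stars at 0.05/0.01/0.001.

**Allelic effects.** Per environment, individuals enter with entry means
over replicates; effect = mean(carrier) − mean(reference) (negative =
earlier flowering), two-sided pooled-variance Student's t. Environments
with an empty class are marked untestable, not dropped silently.

**NMC.** NMC = mean depth over the target interval divided by the per-copy
baseline mean (default baseline: the flanks of the track). Calls: deletion
below 0.5, reference above 1.5, ambiguous in between — boundary values
inclusive to ambiguous, since the rules are stated as strict inequalities.
Because NMC is linear in allele copies, one baseline convention cannot put
reference homozygotes at 2 and heterozygotes at 0.5 simultaneously. Two
conventions are therefore explicit:

* `baseline_copies=1` (default): baseline = true locus coverage; reference
  ≈ 1.0, heterozygote ≈ 0.5 — the raw dosage readout. A heterozygote sits
  exactly on the deletion boundary, so this convention is not suitable for
  three-way panel screening.
* `baseline_copies=2`: models the modified-reference screening protocol in
  which the gene body is present twice (once with, once without the
  deleted sequence), so flanking reads split across the copies while the
  deleted interval stays unique; reference ≈ 2.0, heterozygote ≈ 1.0,
  deletion ≈ 0. This is the convention under which the deletion /
  ambiguous / reference partition genotypes homozygotes with essentially
  perfect accuracy at 30× and leaves heterozygotes safely ambiguous.

The depth simulator draws per-base Poisson counts with in-interval mean
scaled by dosage (reference 1.0, het 0.5, homozygous deletion a residual
`dropout_rate`, default 0.05 — reads mis-mapping into the deleted span).

## Motif scanning

JASPAR matrices are parsed with Bio.motifs (after a light row-length
validation pass that reports the offending line). Log-odds use a total
pseudocount of 0.8 distributed by the background (default uniform), the
JASPAR convention. Both strands are scanned (minus strand via the
complement-reversed matrix); windows containing N are skipped; the
relative score (s − smin)/(smax − smin) is 1 exactly for the consensus.
The default reporting threshold of 0.8 relative score is a conservative,
documented choice — no p-value calibration is attempted. The demo motif is
an evening-element-like consensus of the class bound by CCA1/LHY-type MYB
clock factors; matrices and the scanned "deleted" sequence in examples and
tests are synthetic stand-ins generated in code.

## Simulation studies (`svqtl.studies`)

Problem sizes were chosen to keep each study in seconds while leaving
estimator noise well inside the checked tolerances: heritability averages
20 phenotype simulations of the 354-line design; effect recovery averages
50 replicates with fresh founder/carrier configurations; QTL power runs the
full chain (QC → SNaP → scan in 5 environments → blocks → declaration) on
a 7-chromosome, ~300-marker genome for 20 replicates; null calibration
scans 800 markers on 10 chromosomes once. All randomness flows from a
single seed through `SeedSequence` spawning.

## What the generator does not emulate

No read-level sequences (depth tracks only), no vernalization or
photoperiod physiology (environment effects are exchangeable draws, so
genuine QTL-by-environment structure — effects present only under some day
lengths — is not modelled), no genotyping-error model beyond call failure,
no homoeologous exchanges or assembly errors, and founder haplotypes carry
no mutation/drift history beyond the optional ancestral-block structure.
Passing tests therefore demonstrate the correctness and calibration of the
inference chain under its own assumptions, not performance on real
sequencing data.

## Known limitations

* The mixed model absorbs part of a founder-structured causal signal into
  the polygenic term (a known property of kinship adjustment); power
  figures from the studies are specific to the simulated design.
* The D′ CI grid (0.001) bounds CI resolution; counts far above ~10⁴ per
  pair would warrant a finer grid.
* `qc_filter`'s fixed-point iteration can, on adversarial inputs, remove
  more than a single-pass reading of the thresholds would suggest; the
  exclusion report records every removal with its reason.
* The amplicon predictor models size arithmetic only — no thermodynamics,
  no primer design.
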