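# svqtl

Structural-variant QTL discovery and validation in multiparental
doubled-haploid (DH) crop populations.

Small structural variants (SV; deletions and insertions of 30 bp to tens of
kb) are abundant in crop genomes and can fine-tune quantitative traits such
as flowering time, yet they are invisible to SNP arrays and hard to call
from short reads. `svqtl` implements, as a tested library, the full
inference chain used to find and validate trait-associated SV in an elite
nested association mapping (NAM) design — several inbred founders crossed
to one common parent, each cross advanced to a subfamily of fully
homozygous DH lines:

1. **Marker QC and SNaP calling** — markers with > 10% missing data or
   minor allele frequency < 5% are excluded (as are individuals with > 10%
   missing data); markers that fail *systematically* are rescued as
   dominant presence/absence ("single nucleotide absence polymorphism")
   markers when their failed-call pattern fits the 1:1 segregation expected
   in a DH subfamily (one-df χ², no continuity correction).
2. **Kinship-adjusted association mapping** — per-environment scans with a
   polygenic mixed model: trait = intercept + kinship principal components
   + polygenic value (covariance ∝ IBS kinship, variance ratio estimated by
   REML on the kinship eigendecomposition) + marker effect, tested with a
   1-df score test. Significance at Benjamini–Hochberg FDR ≤ 0.1, a
   suggestive threshold of −log₁₀ p ≥ 3, and the explained-variance
   statistic R² = χ/(n − 2 + χ).
3. **LD-block QTL delineation** — pairwise |D′| with likelihood-grid
   confidence intervals and the Gabriel/Haploview classification
   (90% CI; strong LD 0.70/0.98, recombination 0.90, ≥ 95% informative
   pairs); a QTL is a block holding markers significant in ≥ 2 of 5
   environments.
4. **SV catalog analysis** — polymorphic vs monomorphic classification
   across founders, size-class tables, intersection with gene bodies and
   10 kb promoter windows, a keyword filter for flowering-time annotation,
   and a per-QTL candidate report.
5. **Locus validation** — in-silico PCR product sizes per allele, χ²
   segregation-distortion tests, per-environment allelic effects (pooled-
   variance Student's *t*), and normalized mean coverage (NMC) deletion
   genotyping from read depth: NMC < 0.5 ⇒ deletion, > 1.5 ⇒ reference,
   between ⇒ ambiguous.
6. **Motif scanning** — JASPAR position-frequency matrices, log-odds
   scoring with a background-distributed pseudocount on both strands, and
   relative scores in [0, 1].

A first-class synthetic-data module (`svqtl.simulate`) generates the whole
study design — 7 founders, six subfamilies of 60 DH lines (one of 54; 354
total), Haldane meiosis, ancestral LD blocks, phenotypes with G×E and an
entry-mean broad-sense heritability near 0.83, array-call failure inside
deletions, and per-base depth dropout in deletion carriers — so every stage
runs and is tested without any external data.

The package is aimed at quantitative geneticists and breeders who want a
reproducible, scriptable desk model of this pipeline: to study its power
and calibration, to validate analysis code against known truth, or to run
the individual stages on their own tabular/VCF/GFF3/bedGraph inputs.

## Worked example

`examples/` holds one short narrative script per capability. For instance,
the validation walk-through:

```bash
$ python examples/06_sv_validation.py
PCR products per allele: {'ref': 797, 'alt': 509}

1:1 segregation tests:
  P2 cross: 43:17  chi2=11.27  p=0.001 ***
  P4 cross: 31:29  chi2=0.07  p=0.796
  P6 cross: 29:25  chi2=0.30  p=0.586
  ...
NMC vs PCR concordance (rows NMC, columns PCR):
           deletion  reference  heterozygous
deletion         10          0             0
reference         0         10             0
ambiguous         0          0             5
agreement excluding ambiguous NMC calls: 1.00
```

Reading: a 288 bp deletion inside a 797 bp amplicon yields a 509 bp
deletion-allele product; the 43:17 cross deviates from 1:1 at p = 0.001
(segregation distortion) while 31:29 and 29:25 fit; on a simulated 30×
panel every homozygote is genotyped correctly from coverage alone and all
heterozygotes land in the ambiguous NMC band, as the threshold rules imply.

The association example (`examples/03_association_scan.py`) plants a
deletion with a −0.88 day effect on flowering and prints, per environment,
the top marker with its χ², p, q and R², the genomic-inflation factor λ of
the scan (≈ 1 under proper adjustment), and the declared QTL containing the
planted locus.

Run the whole chain with the CLI:

```bash
svqtl run-all --seed 42 --out runs/demo     # per-stage TSVs + manifest.json
svqtl svgeno --counts 43 17                 # 43:17  chi2=11.267  p=0.001 ***
```

## Layout

- `src/svqtl/` — library modules (`simulate`, `markers`, `assoc`,
  `ldblocks`, `svcat`, `svgeno`, `tfbs`, `pipeline`, `studies`, `io`, `cli`)
- `examples/` — one runnable script per capability
- `docs/methods.md` — model assumptions, parameter defaults, numerical
  choices and limitations
- `tests/` — pytest suite including property-based tests
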