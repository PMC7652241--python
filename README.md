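# trisexscan

Family-based genomic analyses for a vertebrate sex-determination system with
**three co-segregating sex chromosomes** — W, Z and Y — as found in the
western clawed frog *Xenopus tropicalis*. Sex follows a dominance hierarchy:
any individual carrying a Y is male; otherwise a W makes it female; ZZ
individuals are male. Females are therefore WW or WZ, males ZZ, ZY or WY,
and the six possible parental combinations differ in offspring sex ratio and
in which parent's variation is completely sex-linked.

The package is a library (plus a thin `trisexscan` command-line wrapper) for
researchers analysing F1 family genotype data and gonadal RNAseq in such
systems. It provides:

- **Cross model** (`trisexscan.model`) — analytic offspring genotype
  distributions, sex ratios and sex-linkage expectations for all six
  crosses. A WZ mother × ZY father, for instance, yields
  WZ : WY : ZZ : ZY offspring in equal quarters — a 1:3 female:male ratio —
  and is the only cross with a skewed ratio. Under a null of no sex
  linkage, a marker heterozygous in all `n` males and homozygous in all `m`
  females has probability `(1/2)^(n+m)`.
- **Synthetic data** (`trisexscan.simulate`) — seeded generators for RAD-type
  family genotype matrices (negative-binomial depth, parents ~4× offspring
  coverage, het→hom genotyping error, missingness), unrelated wild cohorts,
  and tadpole gonad/mesonephros expression counts with gametolog divergence
  d_WZ ≈ d_WY > d_ZY. Every downstream stage is testable without external
  data.
- **Genotype QC** (`trisexscan.qc`) — depth/quality masking (DP ≥ 15,
  GQ ≥ 20), per-site offspring missingness (> 20%), exact Hardy–Weinberg,
  Mendelian-impossibility (> 10% of offspring), one SNP per RADtag, and
  per-individual missingness filters, with a per-filter report.
- **Sex-linkage scan** (`trisexscan.linkage_scan`) — parent-of-origin
  association between the inherited allele and offspring sex (two-sided
  Fisher exact test, BH-FDR), after masking genotype runs that would imply a
  double recombination within 10 Mb (a genotyping-error signature).
- **Between-sex FST** (`trisexscan.fst`) — per-SNP Weir–Cockerham θ between
  phenotypic females and males, 50-SNP moving averages, and a null band from
  resampling autosomal windows (bootstrap CI of the mean, or envelope).
- **Expression bias** (`trisexscan.expression`) — TPM normalization,
  log2 male/female ratios with a 0.125 prior count, significance at
  FDR < 0.05 and |logFC| > 2 (external DE table or internal Welch-t
  approximation), regional transcript densities per Mb and exact binomial
  enrichment tests.
- **Genotype inference from RNAseq** (`trisexscan.pi_genotypes`) —
  within-individual nucleotide diversity of expressed sex-linked transcripts
  (π = heterozygous / callable sites after DP ≥ 4, GQ ≥ 20, MQ ≥ 20 filters),
  two-level splits per sex, parental-cross resolution, and bootstrap
  inference of whether the Y derives from the Z or the W.
- **Recombination maps** (`trisexscan.maps`) — sex-specific Kosambi linkage
  maps from physically ordered markers, crossover localization, per-quartile
  crossover densities (tip bias), and the linear model
  `maplength ~ sex*family + sex:family:bpcovered`.

## Worked example

Infer each tadpole's sex-chromosome genotype from expressed-transcript
heterozygosity (`python examples/06_genotype_inference.py`):

```
individual  sex      pi_SL      pi_background  inferred
       d01  female  0.00876    0.00055        WZ (high)
       d02  female  0.00073    0.00046        WW (low)
       ...
       s03  male    0.00187    0.00056        ZY (low)
       s04  male    0.00997    0.00050        WY (high)

resolved parental cross: WZxWY
class mean pi: WZ=0.0095, WY=0.0103, ZY=0.0020
Y origin: from_Z (bootstrap support 1.00)
```

π in sex-linked transcripts is the per-site divergence between the two sex
chromosomes an individual carries. Two distinct levels within daughters
(WW ≈ 0.0005 vs WZ ≈ 0.01) and within sons (ZY ≈ 0.002 vs WY ≈ 0.01) pin
the parents to a WZ mother × WY father, and π(ZY) ≪ π(WZ) ≈ π(WY) shows the
Y chromosome is derived from the Z, not the W.

The other scripts in `examples/` each demonstrate one capability: the cross
model, family simulation + QC, the sex-linkage scan, the FST scan, expression
bias + enrichment, and the linkage maps. `trisexscan run --seed 1` executes
the full pipeline on a simulated dataset and writes TSV/JSON results.

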