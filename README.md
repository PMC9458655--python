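# clonalshift

Germline–somatic interaction analysis for *JAK2*-driven myeloproliferative
disease, built as a reusable, tested pipeline. It is aimed at statistical
geneticists and cancer-genomics analysts who want to study how an inherited
risk haplotype shapes the somatic landscape of a blood cancer: which
haplotype acquires the driver mutation, which haplotype a mosaic chromosomal
alteration (mCA) retains, in what order the two events occur, and how clonal
expansion relates to telomere biology.

The package covers five stages, each usable on its own:

1. **Synthetic cohorts** (`clonalshift.simulate`) — samples carrying two
   germline *JAK2* haplotypes (the 46/1 risk haplotype is the allele string
   G-G-C over rs3780367, rs10974944, rs12343867), somatic *JAK2* V617F
   mutations (chr9:5,073,770, GRCh38) enriched among carriers and acquired
   preferentially in *cis*, a 9p mCA that tends to retain the mutated
   haplotype, and relative telomere length declining with clonal fraction.
   Same seed ⇒ bitwise-identical cohort.
2. **mCA detection** (`clonalshift.mca`) — segmentation of phased array
   signal. For heterozygous sites the phase-oriented deviation
   s·(BAF − 0.5) is scanned exhaustively for mean shifts; an unphased
   |BAF − 0.5| pass rescues events when phase is uninformative. States
   follow the LRR sign (gain > 0, loss < 0, CNLOH ≈ 0) and cell fractions
   come from allele-copy accounting:

       CNLOH: f = 2·ΔBAF        loss: f = 4·ΔBAF / (1 + 2·ΔBAF)
       gain:  f = 4·ΔBAF / (1 − 2·ΔBAF)   (ΔBAF ≤ 1/6)

3. **Long-read haplotype calling** (`clonalshift.longread`) — 4-site
   haplotype tables from targeted reads, a strict <1% haplotype-frequency
   filter, QC (depth < 1000, >2 germline backgrounds, biallelic mutation),
   background allelic fraction, and cis/trans phase.
4. **Interaction statistics** (`clonalshift.stats`) — exact binomial
   allelic-shift tests (two-sided by tail doubling,
   p = min(1, 2·min(P[X≤k], P[X≥k]))), odds ratios from proportions,
   mutation–mCA co-occurrence (Fisher/chi-square), a sign test ordering the
   point mutation before the mCA (AF > CF), and locus enrichment against a
   population reference rate.
5. **Telomere genetics** (`clonalshift.telomere`, `clonalshift.mr`) — a
   standardized polygenic score for inherited telomere length, the MR
   estimator suite (IVW, MR-Egger, simple/weighted median, maximum
   likelihood) with leave-one-out pleiotropy screening at FDR 0.2,
   observed-to-liability heritability conversion, and qPCR T/S relative
   telomere length with CV and ICC quality metrics.

`clonalshift.pipeline.run_pipeline` chains everything into a deterministic
run with a `summary.json` and a digest manifest; the `clonalshift` CLI
(`simulate | mca-call | hap-call | stats | mr | run`) is a thin layer over
the library. Short narrative scripts live in `examples/`.

## Worked example

```bash
python examples/07_full_pipeline.py
```

prints (300 samples, seed 42):

```
cohort:
  v617f_mutated       179/299  = 59.87%
  carrier_46_1        203/299  = 67.89%
  any_mca             188/300  = 62.67%
  cis_among_mutated   113/179  = 63.13%
allelic shift (k risk-favoring / n informative, two-sided binomial):
  gain    13/17  p = 0.049
  loss    24/24  p = 1.19e-07
  CNLOH   43/54  p = 1.4e-05
cis (het-informative): 83/103  p = 2.66e-10
mCA x V617F co-occurrence: OR = 6.43, p = 1.66e-13
clonal order (AF > CF): 77/78  p = 5.23e-22
rTL vs clonal fraction: slope -1.10 (95% CI -1.23 to -0.97)
```

Reading the numbers: about 60% of simulated cases carry the driver
mutation and 68% the germline risk haplotype; among heterozygous carriers
the mutation sits on the risk haplotype far more often than chance
(83/103), and detected mCAs preferentially retain or duplicate it in every
copy-number state. Allelic fractions exceed mCA cell fractions in 77 of 78
informative samples — the mutation came first, the chromosomal alteration
expanded it — and samples with larger clones have measurably shorter
telomeres (about −1.1 relative T/S units per unit clonal fraction).

On published count tables the statistics are exact: 23/28 gains favoring
the risk haplotype gives p = 9.12×10⁻⁴, 14/16 losses 4.18×10⁻³, 51/59 CNLOH
9.05×10⁻⁹, and mCA frequencies of 78.35% vs 71.03% give OR 1.48
(see `examples/04_interaction_stats.py`).

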