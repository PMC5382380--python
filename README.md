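# methylgxe

An epigenome-wide **gene-environment interaction** analysis pipeline for
Illumina 450K-style DNA methylation data, built for the question: does a
prenatal environmental exposure leave a methylation signature specifically
in genetically susceptible children, and do specific methylation marks
mediate the exposure's cardio-metabolic effects?

The motivating design is a 48-child study crossed on prenatal pesticide
exposure and PON1 Q192R carrier status (QQ vs QR/RR). The pipeline covers,
end to end:

1. **Preprocessing** — probe filters (SNP-adjacent, iterative greedy
   detection-p pruning, missing values; then non-CpG and sex-chromosome
   probes), beta ↔ M transforms (M = log2(β/(1−β))), PCA batch diagnostics
   (Kruskal–Wallis / Wilcoxon per PC), and an evidence-gated location-only
   batch adjustment.
2. **Cell composition** — Houseman-style reference-based deconvolution of
   six leukocyte types by constrained projection (w ≥ 0, Σw = 1) on the
   top discriminating probes, plus ANOVA/regression association checks.
3. **sig-DMPs** — per-CpG dual-model analysis on M-values:
   interaction model (`M ~ exposure * carrier + sex`, interaction p ≤ 0.1
   and exposure-in-carriers contrast p ≤ 0.001) and no-interaction model
   (exposure p ≤ 0.001, genotype p ≤ 0.1), each with the extreme-group
   filter (exposed carriers strictly highest or lowest of the 4 cells).
4. **sig-DMRs** — kernel-smoothed t² region caller (Gaussian bandwidth
   λ/C, Satterthwaite-matched scaled-χ² p, BH-adjusted P_adj < 0.05,
   gap-grouping, direction filter) for exposed carriers vs each other group.
5. **Integration & enrichment** — DMP∩DMR overlap into a high-confidence
   gene list; Fisher-exact enrichment over gene elements, CpG context,
   chromatin states; TFBS enrichment with Bonferroni; gene-set and
   disease-association mapping (score > 0.1).
6. **Mediation** — Baron–Kenny four-model screen (exposure → mark →
   leptin/body-fat outcomes) on the DMP∩DMR subset within R-allele
   carriers, with bootstrap ACME confidence intervals.
7. **Targeted models** — PON1 promoter cluster vs −108 C/T genotype
   (ANOVA), `activity ~ M + genotype + sex`, and array-vs-pyrosequencing
   Pearson validation.

Because the original cohort's array data are not needed to test the
*machinery*, the package ships a first-class **synthetic data generator**
(`methylgxe.synthetic`) that emulates the study: 4-cell design
(n = 11/13/12/12), bimodal beta baselines with Beta(mφ,(1−m)φ) noise,
six-cell-type mixture convolution, planted interaction DMPs/DMRs, a
SNP-driven 9-probe promoter cluster, batch shifts, and outcomes partially
mediated by planted marks — all with exported ground truth.

## Worked example

The analysis is organized as numbered drivers under `analysis/`, writing
tables under `results/`:

```bash
python analysis/01_simulate.py --seed 1     # synthetic study + ground truth
python analysis/02_preprocess.py            # filters + batch diagnostics
python analysis/03_cell_composition.py      # deconvolution
python analysis/04_dmp_scan.py              # dual-model sig-DMPs
python analysis/05_dmr_scan.py              # kernel sig-DMRs
python analysis/06_integration_enrichment.py
python analysis/07_mediation.py
python analysis/08_targeted_models.py
```

Output of the run above (seed 1, 20,000 probes × 48 samples):

```
pre-normalization filter removed 390 probes: {'snp_within_3bp': 370, 'greedycut': 20}
post-normalization filter removed 391 probes: {'non_cpg': 198, 'sex_chromosome': 193}
19219 probes retained for analysis
...
116 sig-DMPs in the interaction model (53 hyper / 63 hypo in exposed carriers)
77 sig-DMPs in the no-interaction model (37 hyper / 40 hypo)
183 sig-DMR calls across the three contrasts (92 hyper / 91 hypo in exposed carriers)
98 of 116 sig-DMPs (84.5%) fall inside a sig-DMR -> high-confidence gene list of 47 genes
...
mediation restricted to the 98 sig-DMPs inside sig-DMRs
bmi_z: 0 candidate mediating marks (partial or full)
bodyfat: 3 candidate mediating marks (partial or full)
delta_bmi_z: 5 candidate mediating marks (partial or full)
leptin_ln: 5 candidate mediating marks (partial or full)
...
PON1 promoter cluster: 9/9 probes associated with the -108 genotype (ANOVA);
TT-vs-CC trend positive, heterozygotes intermediate
activity ~ M + genotype + sex: methylation slope -8.61 (p = 0.000592)
pyro validation: median Pearson r = 0.959 across 9 probes
```

Reading this: the 50 planted single-CpG effects plus the probes of the 8
planted regions dominate the 116 interaction-model hits; most single-CpG
hits sit inside a called region (the 84.5% overlap), which is the designed
high-confidence intersection; the three planted mediation paths surface in
the screen for exactly the three planted outcomes (and none for BMI Z,
which carries no planted path); the promoter cluster shows the additive
T-allele methylation gradient with heterozygotes intermediate, and higher
promoter methylation predicts lower enzyme activity.

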