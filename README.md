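# methylqc

Quality control, normalization, surrogate-variable adjustment and
cross-tissue concordance analysis for Illumina 450K-style DNA methylation
data, built around the two-tissue (blood + cerebrospinal fluid) study
design used in acute brain-injury cohorts: longitudinal CSF draws at target
days 1/4/7/10/13, one early blood draw per subject, samples arranged on
96-well plates (8 chips of 6 rows x 2 columns) with fixed-methylation
control samples and technical replicates on every plate.

The package is aimed at analysts who need a fully testable version of this
protocol: every stage can run on synthetic data with known ground truth, so
the sensitivity and calibration of each filter and adjustment can be
measured rather than assumed.

## What it computes

Methylation level at probe *p* in sample *s* is the beta-value
`beta = M_int / (M_int + U_int + 100)` from the methylated/unmethylated
intensities, and statistics run on the M-value `M = log2(beta / (1-beta))`.
The pipeline stages:

* **Sample QC** — detection p-values `p = 1 - Phi((M_int + U_int - mu_bg) / sd_bg)`
  with the background estimated from negative-control probes; a sample fails
  if its bisulfite-conversion control mean falls below `mean - 3 SD` of the
  cohort, if more than 1% of probes are poorly detected (detection p > 0.01
  or < 3 beads), or if it is a total-intensity or beta-distribution outlier.
  Failure rates of two tissues are compared with Fisher's exact test.
* **Normalization** — normal-exponential background deconvolution, linear
  dye-bias rescaling on the normalization controls, then functional
  normalization: within each probe stratum the per-sample quantile curves
  are adjusted by removing the component of their deviation from the mean
  curve explained by the first *k* principal components of the
  control-probe summaries.  Improvement is tested as a one-sided paired
  t-test on squared differences of technical-replicate median M-values.
* **Probe QC** — sequential filters (SNP overlap, cross-reactivity, sex
  chromosomes, multimodal beta distributions, low detection) with
  per-step bookkeeping; per-probe outcomes of two tissues are compared with
  McNemar's test.
* **Cell composition (blood)** — reference-based deconvolution: per sample,
  `min || y - X w ||^2` subject to `w >= 0, sum(w) = 1` over cell-type
  reference methylomes, solved exactly by active-set enumeration; samples
  with aberrant B-cell fractions (median + 4 MAD) are flagged.
* **SVA + null EWAS** — surrogate variables from an iteratively reweighted
  SVD conditional on the primary model; the number of SVs by permutation
  parallel analysis.  Calibration is probed by permuting an observed binary
  trait and computing the genomic inflation factor
  `lambda = median(chi2_obs) / 0.4549` with and without SV adjustment.
* **Blood-CSF concordance** — after removing CpGs that are uniformly
  extreme (> 90% or < 10% in both tissues) and adjusting M-values for age,
  sex and SVs, Pearson correlations are computed per CpG across paired
  subjects (within-CpG) and per subject across CpGs (within-individual),
  and within-CpG r is compared across CpG-island / shore / shelf / open-sea
  strata (Kruskal-Wallis + pairwise Mann-Whitney).

A synthetic-data generator (`methylqc.synthgen`) produces complete studies
with known cell fractions, batch effects, latent factors, planted failing
samples/probes and region-specific cross-tissue coupling, plus a
`TruthRecord` for recovery testing.

## Worked example

```python
from methylqc.pipeline import PipelineConfig, run_pipeline

report, bundle = run_pipeline(PipelineConfig(seed=1))

qc = report["sample_qc"]
print(f"CSF samples failing QC:   {qc['csf']['n_fail']} / {qc['csf']['n_total']}")
conc = report["normalization"]["csf"]
print(f"replicate median-M sq. diff: {conc['mean_d_before']:.3f} -> "
      f"{conc['mean_d_after']:.3f} (one-sided p = {conc['p_one_sided']:.3f})")
for name, entry in report["sva_ewas"].items():
    print(f"null EWAS {name}: lambda {entry['lambda_unadjusted']:.2f} -> "
          f"{entry['lambda_adjusted']:.2f} with {entry['n_sv']} SVs")
day1 = report["tissue_correlation"]["day1"]
print(f"day-1 blood-CSF: mean within-CpG r = {day1['mean_r']:.3f}, "
      f"mean within-individual r = {day1['mean_within_individual_r']:.3f}")
print({k: round(v, 3) for k, v in day1["region_mean_r"].items()})
```

prints (default synthetic scale, 2,000 probes x ~130 arrays):

```
CSF samples failing QC:   6 / 103
replicate median-M sq. diff: 0.333 -> 0.016 (one-sided p = 0.016)
null EWAS blood: lambda 0.77 -> 1.00 with 4 SVs
null EWAS csf_day1: lambda 1.19 -> 1.09 with 4 SVs
null EWAS csf_day4: lambda 1.67 -> 0.96 with 4 SVs
null EWAS csf_day7: lambda 0.90 -> 1.04 with 3 SVs
null EWAS csf_day13: lambda 1.00 -> 0.97 with 4 SVs
day-1 blood-CSF: mean within-CpG r = 0.201, mean within-individual r = 0.738
{'island': 0.343, 'open_sea': 0.047, 'shelf': 0.155, 'shore': 0.249}
```

The six planted failing CSF samples are exactly the six flagged;
normalization cuts replicate discordance twenty-fold; SV adjustment pulls
the null-EWAS inflation factor to ~1 in every sample set; and the planted
region ordering (island > shore > shelf > open sea) reappears in the
recovered correlations, with the characteristic dissociation between low
within-CpG and high within-individual correlation.

A command-line interface mirrors the stages:

```
methylqc simulate --seed 1 --out sim/
methylqc sample-qc --dataset sim/ --tissue csf --out qc.json
methylqc normalize --dataset sim/ --k 2 --out norm/
methylqc probe-qc --dataset norm/ --annotation sim/annotation.tsv --out probes.json
methylqc run --simulate --seed 1 --out results/
```

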