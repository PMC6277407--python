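# methylstage

Dual-platform differential DNA-methylation analysis across the stages of
intestinal-type gastric carcinogenesis: normal gastric mucosa (**GM**) →
intestinal metaplasia (**IM**) → gastric tumor (**GT**).

Two complementary assays see the same biology differently, and this
package implements both arms plus their integration:

* **MBD-seq arm** — methyl-CpG-binding-domain enrichment reads counted in
  200-bp bins and transformed into a *methylation enrichment score*,

  ```
  MES(bin_i) = log2( (n / bin_size) / (total_n / L) )
  ```

  the log ratio of a bin's per-bp read density to the genome-wide average
  (`n` reads in the bin, `total_n` reads in the library, `L` genome
  length).  Tumor counts are copy-number corrected (× 2/CN) first, so
  aneuploidy does not masquerade as methylation gain.  Differential
  regions (DMRs) come from a sliding 1-kb tile (five bins, 200-bp step):
  paired *t*-test on per-bin MES differences at *P* < 0.01 plus a 2-fold
  change threshold.  A promoter (2 kb centered on the TSS) overlapped by
  a DMR is a differentially methylated promoter (DMP).

* **RRBS arm** — per-CpG methylated (C) / unmethylated (T) read counts at
  sites with depth ≥ 10 in all three stages, tested with the
  Freeman–Halton exact test on the 2×3 table (meth/unmeth × GM/IM/GT),
  Bonferroni-corrected, then filtered to sites whose methylation level
  changes by more than 20 percentage points.  A promoter holding ≥ 3
  called sites is a DMP.

* **Integration** — DMPs are unioned by gene across platforms; each call
  is *hyper* or *hypo* and *early-onset* (already present in IM) or
  *GT-specific* (tumor only).  Genomic-feature tallies (promoter
  CGI/shore/shelf/non-CGI, intragenic, intergenic, repeat classes) and
  hypergeometric + Benjamini–Hochberg gene-set enrichment follow.

* **Survival** — a multigene risk score, `risk = Σ βᵢ·exprᵢ` with βᵢ the
  Cox proportional-hazards coefficient of gene *i* (Breslow ties, damped
  Newton, fitted in-package), median-split into high/low groups and
  compared by Kaplan–Meier curves and the log-rank test.

A synthetic-data generator produces a complete three-stage methylome with
known ground truth — annotation, MBD bin counts with CNV distortion, RRBS
counts with CpG-density-skewed coverage, a survival cohort — so the whole
pipeline runs and validates at desk scale in seconds.

## Worked example

```python
from methylstage.simulate import SimulationConfig, simulate_dataset
from methylstage.pipeline import run_full, recovery_metrics

ds = simulate_dataset(SimulationConfig(seed=1))   # 2 × 5 Mb, 300 genes,
res = run_full(ds)                                # 85 planted DMPs
print(res["overlap"])
print(res["tally"])
print(recovery_metrics(ds, res["union"]))
```

prints

```
{'n_mbd': 87, 'n_rrbs': 85, 'n_both': 84, 'n_union': 88}
       early-onset  GT-specific  total
hyper           12           49     61
hypo             2           25     27
total           14           74     88
{'n_planted': 85, ..., 'recovery_rate': 1.0, 'fdr': 0.034,
 'early_onset_fraction': 0.165, ...}
```

Reading: 87 MBD-seq DMPs and 85 RRBS DMPs share 84 promoters, for 88
combined DMPs (61 hyper, 27 hypo; 14 early-onset).  All 85 planted DMPs
are recovered, 3 of 88 calls are false (FDR 3.4%), and the early-onset
fraction 16.5% matches the configured 17%.

The survival arm on the simulated cohort (`simulate_survival`,
`risk_score_analysis`) fits the six-gene panel (NPY1R, PPYR1, PTGDR,
PTGER2, PTGER3, SSTR2), splits the cohort at the median risk score and
yields a log-rank χ² = 99.6 (p ≈ 2 × 10⁻²³) at n = 300 under the default
planted hazard coefficients.

The same stages are available from the shell:

```bash
methylstage simulate --seed 1 --outdir data/
methylstage mbd-call  --gm data/mbd_gm_bins.tsv --im data/mbd_im_bins.tsv \
    --gt data/mbd_gt_bins.tsv --cnv data/cnv.bed \
    --annotation data/annotation/annotation.yaml --outdir out/mbd
methylstage rrbs-call --counts data/rrbs_counts.tsv \
    --annotation data/annotation/annotation.yaml --outdir out/rrbs
methylstage integrate --mbd-dmps out/mbd/dmps_mbd.tsv \
    --rrbs-dmps out/rrbs/dmps_rrbs.tsv --out out/dmps.tsv
methylstage risk --survival data/survival.tsv --outdir out/risk
```

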