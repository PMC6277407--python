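# Methods

## The analytical model

The package compares three DNA methylomes from successive stages of
intestinal-type gastric carcinogenesis — gastric mucosa (GM), intestinal
metaplasia (IM), gastric tumor (GT) — on two platforms whose error models
differ, and integrates promoter-level calls.

### MBD-seq arm

Enrichment reads proxy methylation density.  Aligned read starts are
extended to the 200-bp fragment footprint (plus-strand rightward;
minus-strand reads extend leftward from their 3′-most aligned position —
the convention is ours, the direction of extension for minus reads being
otherwise underdetermined) and counted into fixed 200-bp bins, each read
incrementing every bin it overlaps by ≥ 1 bp.

Counts are converted to the methylation enrichment score
`MES = log2((n/bin_size)/(total_n/L))`.  The log base is chosen as 2 so
that the pipeline's 2-fold DMR threshold equals an MES difference of
exactly 1; MES is invariant under uniform library scaling and zero at
genome-average density.  Bins with zero reads carry an NaN "uncovered"
sentinel and are excluded from testing rather than pseudocounted (a
pseudocount mode is available as a flag; the sentinel is the default
because a pseudocount at 200-bp resolution manufactures strong negative
MES values in sparse libraries).

Tumor genomes are aneuploid, and enrichment counts scale with copy
number, so GT counts are corrected to a diploid reference
(`count × 2/CN`, CN=0 bins marked uncovered) *before* the MES transform;
GM and IM are assumed diploid.  Segment membership of a bin is decided by
its midpoint.

Differential testing slides a 1-kb tile (five bins) in 200-bp steps.
Within a tile the per-bin MES differences between two samples are treated
as matched pairs: a paired *t*-test with df = k−1 over the k bins covered
in both samples, requiring k ≥ 3.  The fold change is `2^mean(diff)` —
the ratio of geometric-mean densities, consistent with MES being the
analysis unit.  A tile is hyper when fold ≥ 2 and p < α (default 0.01),
hypo when fold ≤ ½ and p < α.  Zero-variance tiles with nonzero mean
difference are significant (the t statistic's limit); zero-variance
zero-mean tiles are not.  Overlapping or book-ended significant tiles of
one direction merge into a DMR spanning their union, carrying the best
tile p and its fold; opposite directions never merge.  The merge rule is
plumbing — published DMR counts depend on the (unstated) merge convention
and ours is one consistent reading.

A GT-vs-GM DMR is **early-onset** when a same-direction IM-vs-GM DMR
overlaps it by ≥ 1 bp, else **GT-specific**.  Promoters (2 kb centered on
the TSS, strand-independent) overlapped by ≥ 1 DMR become DMPs; when DMRs
of both directions touch one promoter the largest overlap wins, ties
breaking toward the smaller p.

### RRBS arm

Each CpG site carries methylated (C) and unmethylated (T) read counts per
stage; the methylation level is C/(C+T).  Sites with depth ≥ 10 in all
three stages are tested with the Freeman–Halton exact test on the 2×3
contingency table (rows meth/unmeth, columns GM/IM/GT): all tables with
the observed margins are enumerated and the p-value is the total
multivariate-hypergeometric probability of tables no more probable than
the observed one (relative tolerance 1e-12 on the probability ordering to
avoid floating-point tie misclassification; probabilities are normalized
by the enumerated total to absorb drift).  Degenerate margins need no
special case: a zero column reduces the enumeration to the classical 2×2
test, a zero row leaves a single admissible table and p = 1.  Tables
whose enumeration would exceed a cap fall back to seeded Monte-Carlo
sampling of margin-preserving tables; at RRBS depths the exact path is
always taken.

Bonferroni correction uses m = number of tested sites, significance
p·m < α (α = 0.05 by default; exposed as a flag).  The order of
operations is fixed: familywise significance first, then the >20
percentage-point level-difference filter per comparison (GM vs IM, GM vs
GT).  Each passing site is a width-1 DMR; the GT call is early-onset when
the same site carries a concordant IM call.  A promoter with ≥ 3 called
sites becomes a DMP; direction by site majority (ties to the direction
with larger mean |difference|), early-onset when ≥ 3 member sites are
early-onset.  The depth-10 floor extends the published scatter-analysis
threshold to testing; it is configurable.  A published manual curation
step by eye is not reproducible and is replaced by these deterministic
rules.

The bisulfite conversion-efficiency QC computes converted/total over
non-CpG cytosines and warns below a 0.98 floor.

### Genome model

Coordinates are 0-based half-open everywhere internally (BED native);
1-based only in human-readable output.  CGI *shores* are the 0–2 kb
flanks on **both** sides of a merged CpG island and *shelves* the 2–4 kb
flanks, shores excluding islands and shelves excluding both — the
symmetric reading is the standard shore/shelf convention; a literal
one-sided "upstream" reading would contradict it.  Region classification
uses ≥ 1 bp overlap with fixed precedence: promoter > intragenic >
intergenic; within promoters CGI > shore > shelf > non-CGI; within gene
bodies CGI > repeat > exon (first exon excluded — its territory falls in
the promoter class) > intron > 3′UTR; intergenic CGI > repeat.  The
CGI-vs-repeat order inside gene bodies is a documented choice; repeat >
intron is fixed.  Promoters overlapping other genes' bodies are not
excluded.

### Integration and enrichment

DMPs are merged by gene/promoter key (both arms emit per-promoter
records, so no fuzzy coordinate matching is needed).  Direction conflicts
resolve to the MBD-seq call purely for determinism and are flagged in the
output; timing resolves toward early-onset when either platform says so.
Tallies are direction × timing with marginals; the feature distribution
reports hyper/hypo counts and hyper fraction per feature class.

Gene-set enrichment is a one-sided hypergeometric tail with
Benjamini–Hochberg correction over the tested sets.  This deliberately
replaces the DAVID web tool's modified-Fisher EASE score, so published
Benjamini values are not reproduced exactly; the default background is
the genes assessable by at least one platform, and both background and
sets (GMT format) are configurable.

### Survival risk score

`risk = Σ βᵢ·exprᵢ`, median split (ties at the median to the low-risk
group, for determinism), Kaplan–Meier curves and the two-group log-rank
test.  The Cox partial likelihood is maximized in-package by damped
Newton iterations with Breslow tie handling (the simplest consistent
choice), converged at max|score| < 1e-8 within 100 iterations; zero
events or collinear covariates raise.  Both one multivariate fit and
assembled univariate fits are provided, since risk-score practice uses
either.  Published cohort p-values depend on patient data that are not
public; the module is validated by oracle tests (grid-search likelihood,
lifelines cross-check, permutation log-rank) and parameter recovery
instead.

## Synthetic data: what it emulates, what it does not

Defaults: 2 chromosomes × 5 Mb, 300 genes, 260 CGIs with 80% centered on
TSSs, 200-bp bins — large enough for Bonferroni behavior at ~1.4 × 10⁴
tested CpGs, small enough that the full pipeline runs in seconds.
Planted signal: 60 hypermethylated promoters (chosen among CGI promoters,
baseline 0.05 rising to 0.6–0.9 in GT), 25 hypomethylated promoters
(non-CGI promoters, 0.70 falling to 0.15–0.25), 20 hypomethylated
intergenic repeat blocks (0.85 → 0.30), with exactly round(0.17 · n)
planted events early-onset (also shifted in IM) — 17% mirroring the
published early-onset fraction.  Effect sizes are design choices (no
quantitative effect-size distribution is published) and are exposed in
the config.

Baseline methylation follows the stage-zero biology: CGI promoters
unmethylated, repeats and intergenic space heavily methylated, gene
bodies intermediate.  Per-region noise is a scaled symmetric Beta draw
per sample with peak-to-peak amplitude 0.05, so a null region's true
between-sample difference stays below 0.05 by construction.

MBD counts are Poisson with rate ∝ depth × (0.05 + methylation) ×
(CpG count per bin + 0.5), normalized to a genome-average 10 reads/bin;
CpG density is itself simulated (≈18 sites/bin in CGIs, 7 in promoters,
2 elsewhere) because MBD enrichment tracks CpG density.  The GT sample's
rates are scaled by CN/2 inside a simulated profile of 8 gains (CN 3–4)
and 6 losses (CN 1), 100 kb each — mirroring the published gain/loss
counts.

RRBS sites are covered with probability 0.25 inside CGIs/promoters and
0.039 elsewhere (the published per-class coverage fractions); the
coverage draw is shared across the three samples because MspI fragment
selection is a property of the genome — independent draws would cube the
jointly-deep fraction and starve the 2×3 test.  Depth is 1 + Poisson(29)
per sample; methylated counts are Binomial(depth, level) with an optional
flat conversion-error rate (default 0).

The survival cohort draws standard-normal expressions for the six-gene
GI-hormone-receptor panel, hazard `0.02·exp(Σ β·x)` per month with
default β = (0.8, −0.5, 0.6, 0.0, −0.3, 0.4), exponential event times
and uniform censoring on (1, 120) months.

All generators draw from named substreams of one seed (spawned
`SeedSequence` keys), so changing one component's parameters never
perturbs another's draws, and written outputs are byte-identical across
runs of the same (seed, config).

**Not emulated:** read-level sequence (no FASTQ), alignment artifacts,
duplicate reads, bisulfite conversion failure beyond a flat rate,
fragment-length biases, cell-type heterogeneity, and any correlation
between the methylome and the survival cohort.  Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under the stated generative model, not robustness to real-data artifacts
upstream of the count tables.

## Validation summary

The test suite checks, among others: exact agreement of the
Freeman–Halton implementation with an independent rational-arithmetic
enumeration oracle (exhaustively for all 2×3 tables of total ≤ 16, plus a
seeded sweep to total 30, plus reduction to the classical 2×2 test);
hand-computed paired-t and MES worked values; null calibration (≈ 0
Bonferroni hits at m ≈ 1.4 × 10⁴ sites, KS distance of tile p-values from
uniform below 0.05); ≥ 90% planted-DMP recovery at ≤ 10% FDR with the
early-onset fraction inside the binomial 95% band around 0.17;
copy-number correction eliminating spurious hyper calls inside CN=4
gains; and Cox coefficient recovery within ±0.1 at n = 2,000 with
log-rank p matching a permutation oracle.  `scripts/acceptance.py`
recomputes these quantities from scratch at the problem sizes stated
above.

## Known limitations

* The DMR merge rule and the MC fallback replicate count are conventions;
  absolute DMR counts are convention-dependent even when site/tile calls
  are identical.
* The paired t-test at k = 5 bins leans on approximate normality of MES
  differences; at very low coverage (λ ≲ 3 reads/bin) tile p-values grow
  conservative and the KS calibration bound loosens.
* Timing classification is overlap-based and inherits any IM-arm
  false negatives: an early-onset event missed in IM is labelled
  GT-specific.
* The enrichment module is not a DAVID replacement and its adjusted
  p-values are not comparable to published EASE/Benjamini numbers.
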