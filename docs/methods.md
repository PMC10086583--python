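# Methods

## Coordinate and genome model

All intervals are 1-based inclusive (SEG/ASCAT convention); lengths are
`end − start + 1`. Chromosome names are normalised to the `chr` prefix;
chrY and mitochondria are out of scoring scope (allele-specific copy
number is not defined there), chrX is kept when both alleles are
genotyped. A telomere is the first or last base of a chromosome — a
segment "reaches the telomere" iff `start == 1` or `end == length`,
which matches profiles emitted by segmentation tools that tile whole
chromosomes. The chromosome-arm boundary is the centromere midpoint.

Two builds ship with the package. The `toy` build (3 × 100 Mb
chromosomes, centromeres at [45, 55] Mb, four 25 Mb bands) keeps worked
examples arithmetic-friendly. The `hg38` build carries the GRCh38
chromosome lengths with approximate centromere intervals and
arm-resolution cytobands; any UCSC-format `cytoBand.txt` file can be
loaded instead when full banding resolution is wanted — every cytoband
feature is resolution-agnostic. The packaged 70-gene HRR catalog is a
curated stand-in (see its file header): the roster combines the named
pathway members with canonical HRR / Fanconi-anemia genes, and its
GRCh38 coordinates are Mb-scale approximations, which is adequate for
overlap tests against multi-megabase copy-number segments but not for
exon-level work.

## Scar scores

* **LOH**: maximal runs of abutting segments with `n_minor == 0` and
  `n_major ≥ 1`, counted when longer than `loh_min_len` (default 15 Mb)
  and not covering the whole chromosome (evaluated against the full
  chromosome, not the arm). Homozygous deletions (0, 0) break runs —
  deleted DNA carries no allele signal. A coverage gap also breaks a
  run.
* **Smoothing**: segments shorter than `lst_smooth_len` (default 3 Mb)
  are removed iteratively, shortest first (ties to the leftmost); the
  removed span is split at its midpoint between the two abutting
  neighbours, or absorbed whole by a single abutting neighbour at a
  block boundary. Smoothing operates within contiguous (abutting)
  blocks only and never fills coverage gaps, so the covered span is
  conserved exactly. A lone short segment with no abutting neighbour is
  left in place.
* **LST**: segments are split at the centromere midpoint, smoothed per
  arm, and a transition is counted for each adjacent pair that differs
  in allele state, with both segments at least `lst_min_segment`
  (default 10 Mb, boundary inclusive) and an inter-segment gap of at
  most `lst_smooth_len`.
* **TAI**: maximal runs of abutting allelic-imbalance segments
  (`n_major ≠ n_minor`, any copy-number states within a run) that reach
  a telomere, do not extend across the centromere (i.e. do not both
  start before it and end after it), do not span the whole chromosome,
  and exceed `tai_min_len` (default 0 — no size floor, but
  parameterised because the literature varies on this point).
* **HRD score** = LOH + LST + TAI. No ploidy or purity adjustment is
  applied.

Each scorer has an independent per-base brute-force re-implementation in
the test suite; the two agree exactly on 1,000+ random profiles.

## CIN features

Calls are strict-inequality threshold rules: ASCN mode calls gain iff
total copies > 2 and loss iff < 2; L2R mode calls gain above 0.1, loss
below −0.1, with amplification above 0.7 and deep deletion below −0.7.
Uncovered genome is treated as neutral. Per-chromosome gain/loss counts
default to merged runs (abutting same-call segments count once) to
remove segmentation-granularity sensitivity; raw segment-count semantics
is available (`merge_runs=False`). Fraction of genome altered divides
altered base pairs by the total length of in-scope chromosomes; a
chromosome is an aneuploidy event when its gained or lost fraction
exceeds 0.9. Cytoband counts use ≥ 1 bp interval overlap. HRR-CIN adds,
per catalog gene, one point for any overlapping gain and one for any
overlapping loss (0–2 per gene, so the 70-gene catalog bounds the score
at 140). Counting (gene, class) events — rather than segments or genes —
is a documented modelling choice.

## Cut-off inference

The two-component Gaussian mixture is fitted by EM with deterministic
initialisation (means at the 25th/75th percentiles, equal weights, both
SDs at half the sample SD), convergence at log-likelihood improvement
< 1e−8 or 500 iterations, components ordered by mean; a component SD
collapsing below 1e−6 flags the fit as degenerate. Gaussian components
are the default family; the mixture machinery is self-contained so the
family can be swapped. The cut-off is the root of
w₁·φ(x; μ₁, σ₁) = w₂·φ(x; μ₂, σ₂) between the means (equivalently the
posterior-0.5 point), found by bisection to 1e−6; if the weighted
densities do not cross in (μ₁, μ₂) — possible under extreme weight
imbalance — the midpoint is returned and flagged. The 95% CI is a
parametric bootstrap (default 1,000 replicates): simulate from the
fitted mixture, refit, take the 2.5/97.5 percentiles of the refitted
cut-offs; a degenerate-refit rate above 20% raises a warning.

ROC analysis evaluates candidate thresholds at the midpoints between
adjacent distinct scores plus ±∞ (calling positive at score ≥
threshold), maximises Youden's J with ties resolved to the higher
sensitivity and then the lower threshold, and computes AUC by the
trapezoid rule over the staircase corners. The optimal J equals
exhaustive threshold search on every tested instance, and the AUC
matches the Mann-Whitney statistic (cross-checked against scikit-learn).
Classification at any cut-off is boundary-inclusive: a value equal to
the cut-off is called high.

## Alteration matrices

Cells hold sets drawn from {missense, truncating, splice, other_variant,
amplification, deep_deletion, gain, loss}. MAF variant classes map as
Missense_Mutation → missense; Nonsense_Mutation and Frame_Shift_Ins/Del
→ truncating; Splice_Site → splice; everything else → other_variant
(configurable). Gene-level copy number accepts either log2 ratios (same
thresholds as segments) or GDC categorical codes {−2…2}. Per-sample
totals count (gene, category) events, not altered genes — a gene with a
missense variant and an amplification contributes 2.

## Expression signature

The SARC-HRD signature is the 10-gene up-regulated set BRCA1, BRCA2,
BLM, EME1, FANCB, FANCD2, FANCI, RAD51, RAD54L, XRCC2. The score is the
package's operationalisation (the source analyses show clustering
heatmaps rather than a numeric score): log2(x+1)-transform, z-score each
gene across the cohort, average over the signature genes. The cohort
mean of scores is 0 by construction, so the score is only meaningful
within a cohort; the +1 pseudocount makes per-gene rescaling invariance
exact only in the large-count regime. At least half the signature genes
must be present; zero-variance genes are dropped with a warning.
MDM2 and DMC1, which move in the opposite direction, are deliberately
not part of the signature definition. The DE filter keeps genes with at
least a two-fold change and p ≤ 0.05, both boundaries inclusive; it
consumes externally computed statistics — negative-binomial model
fitting is out of scope.

## Dose-response and synergy

Viability is normalised by the untreated-control mean. The 4PL model
v(x) = bottom + (top − bottom)/(1 + (x/IC50)^hill) is fitted by bounded
least squares from a fixed multi-start grid (hill ∈ {±0.5, ±1, ±2},
IC50 log-spaced over the dose range; bottom ∈ [−0.2, 1], top ∈
[0.5, 1.5]), making the fit deterministic. A curve with response range
< 0.05 (no dose effect) or no converging start is flagged and falls
back to a monotone PCHIP spline in log10(dose) for synergy use. AUC is
the trapezoid integral of viability over log10(dose) divided by the
log-dose span — a dimensionless mean viability (the plate-software
convention is unspecified upstream, so this explicit one is used).

Synergy works on inhibition y = clip(1 − viability, 0, 1). Expected
combination surfaces: Bliss y₁ + y₂ − y₁y₂; HSA max(y₁, y₂); Loewe
solves d₁/D₁(E) + d₂/D₂(E) = 1 with D(·) the inverse fitted monotherapy
curve (nested bisection to 1e−6; effects outside the invertible range
are clamped to it, and a non-invertible curve marks cells undefined);
ZIP fits the potency-shift curve to each observed row and column with
the baseline fixed at the other drug's monotherapy effect and averages
the two directions, falling back to the Bliss expectation where a
directional fit fails. The score is 100 × the mean over combination
cells of observed minus expected inhibition. Because the ZIP surface is
refitted to the observed matrix, a uniform inhibition boost is largely
absorbed by the refit: ZIP reacts to shape changes (potency shifts)
rather than level shifts, and scores near zero on smooth surfaces where
Bliss/Loewe/HSA report the level difference.

## Synthetic data

The profile generator starts from a diploid heterozygous genome and
implants events so that implanted counts are exact by construction:
every block is at least 3 Mb (the smoothing floor leaves it intact);
events are flanked by < 10 Mb balanced buffer blocks so no unintended
large-segment transition forms; LOH and imbalance blocks avoid
telomeres unless the event is telomeric; TAI blocks are telomere-
anchored (2, 1) runs capped by a balanced buffer; LST events are chains
of alternating balanced ≥ 10 Mb blocks; combined LOH+LST events (an LOH
block abutting a distinct ≥ 10 Mb block) allow dense packing on small
genomes; aneuploid chromosomes are > 90% balanced gains. Placement is
randomized greedy packing over chromosome arms with retries; an
infeasible request errors rather than silently under-implanting.

The cohort generator draws, per HRD-high sample, HRR-CIN ~ round
N(50, 8²) and heavy scar loads (LOH ~ N(12, 3²), LST ~ N(18, 4²),
TAI ~ N(8, 2²), clipped), and per HRD-low sample HRR-CIN ~ round
N(8, 3²) with light Poisson loads — a bimodal cohort whose high mode
HRD score sits near 40 and low mode near 4. Scar profiles are placed on
the hg38 build (the toy genome cannot host the high-mode event loads);
HRR-gene copy number is emitted as a separate gene-level L2R segment
table realising the drawn HRR-CIN exactly, mirroring real pipelines
where ASCAT segments and gene-level CN calls are distinct inputs.
Expression is log-normal (per-gene log2 means U(3, 10), within-gene SD
0.5) with a +1 log2 shift of the signature genes in HRD-high samples.
Dose matrices are sampled as expected-under-model plus Gaussian noise.

What the generator does not emulate: tumour purity and subclonality,
segmentation noise in BAF/LRR space, correlated gene-gene expression
structure, batch effects, and realistic scar-event co-location.
Passing closed-loop tests therefore demonstrates correctness of the
counting rules and inference machinery under clean conditions, not
robustness to segmentation artefacts.

## Problem sizes and experiment designs

Tests and the acceptance script use desk-scale designs chosen to make
the statistical claims stable: 100 profiles for the scar closed loop;
1,000 random profiles for oracle equivalence (on a base-pair-scale mini
genome where per-base brute force is exact and cheap); cohorts of
60 + 60 over 20 seeds for end-to-end classification; 50 replicates per
synergy null at noise SD 0.02; and, for noisy 4PL recovery, the
standard plate design of 8 log-spaced doses in triplicate at per-well
noise SD 0.05 — with single wells the IC50's sampling error exceeds
10% for any estimator, so replication is part of the stated assay
design, as it is on real plates.

## Known limitations

* Scar counts depend on the upstream segmentation dialect; the merged-
  run CIN default mitigates but does not remove this.
* No ploidy-relative LST or purity correction; near-tetraploid genomes
  will inflate scar counts.
* The mixture cut-off assumes two Gaussian modes; heavy-tailed or
  three-mode cohorts need a different family.
* The HRR catalog's coordinates are approximate (see above).
* Loewe/ZIP surfaces require fittable monotherapies; flat monotherapy
  responses degrade those models to fallbacks.
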