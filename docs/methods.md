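# Methods

`heteromir` implements the computational chain of a multi-region RT-qPCR
miRNA study: choosing reference genes by expression stability, converting
quantification cycles (Cq) to relative expression, and testing every pair
of tissue regions for differential expression. This note records the
models, the numerical choices, and what the synthetic cohorts do and do
not emulate.

## Study design assumed throughout

Each patient contributes five samples: adjacent normal mammary tissue (N),
tumor border (B), tumor center (C) and the two most spatially separated
tumor peripheries (P1, P2). The default design is 33 patients, one sample
per (patient, region), and a 22-species small-RNA panel: 16 target miRNAs,
three snRNAs (U6, U54, U58) historically used as qPCR normalizers, and the
reference candidates miRNA-100, miRNA-143 and miRNA-204. The region
vocabulary is closed; arbitrary region sets are deliberately unsupported so
that the ten pairwise contrasts are always well defined.

## Stability analysis (geNorm family)

Relative expression is taken as a = 2^(−Cq), i.e. 100% PCR efficiency for
every assay. No per-assay efficiency correction is applied: plate-level
efficiencies in this assay family span roughly 85–100% but are not
available per gene, and the downstream rank tests are invariant to any
common monotone rescaling anyway.

For genes j, k the per-sample log ratio is

    A_jk[s] = log2(a_sj / a_sk) = Cq_sk − Cq_sj,

the pairwise variation V_jk is the *sample* standard deviation (divisor
length−1) of A_jk, and the stability of gene j is

    M_j = mean over k ≠ j of V_jk.

Lower M means more stable expression. The sample (not population) standard
deviation is the convention of the original algorithm family; it is fixed,
not configurable, and the brute-force oracle in the test suite uses the
same divisor.

Two ranking modes ship because published tables of this kind are often
ambiguous about which was used:

* **iterative** (default): recompute M over the current candidate set,
  remove the gene with the highest M, repeat until two genes remain; those
  two are the jointly most stable pair and are recorded with their mutual
  V. Ties in M are broken lexicographically by gene name (the
  lexicographically last name is excluded first), which makes output
  deterministic; ties are logged.
* **single_pass**: one M computation over the full set, ranked ascending.

### Normalization factors

NFn is the per-sample geometric mean over the n most stable genes. The
default scale is the **Cq scale** — the geometric mean of the raw cycles
themselves, which is how the two-gene reference of this assay family is
written down — even though the classic algorithm uses relative quantities.
An expression-scale mode (geometric mean of 2^−Cq, equivalently
2^(−arithmetic mean Cq)) is available via `nf_scale="expression"` for
comparison. The successive pairwise variation

    V(n/n+1) = s.d. over samples of log2(NFn / NF(n+1))

is the usual criterion for how many reference genes suffice. Note the
Cq-scale NF is *not* invariant to adding a constant to a member gene's
cycles (the geometric mean of shifted cycles is not the shifted geometric
mean), unlike M, which is translation-invariant; the test suite asserts
both behaviors.

### NF stability (reconstructed)

Stability tables of this kind sometimes carry an "NFn stability" column
with no published definition. The package computes an M-like score that is
explicitly labelled **reconstructed** in all output: treat log2(NFn) as a
pseudo-gene expression profile and average, over every candidate outside
the top n, the sample standard deviation of log2(NFn_s) − log2(a_sg).
For n equal to the panel size no candidate remains and the value is
missing, not an error. This reconstruction should not be read as the
definition used by any particular published table.

## Relative quantification

ΔCt = Cq_target − Cq_reference per sample, expression = 2^−ΔCt, so one
cycle above the reference halves expression. The reference Cq is the
geometric mean of the reference genes' cycles in that sample. The default
reference is the two-miRNA set {miRNA-100, miRNA-143}; the four-gene
alternative additionally containing miRNA-126 and miRNA-125b is exposed as
`FOUR_GENE_REFERENCE`. In the pipeline's "auto" mode the reference is the
terminal pair of the stability ranking after removing genes on an
exclusion list, which defaults to {miRNA-126, miRNA-125b}: both are stable
candidates in this tissue but have documented functional roles in breast
cancer, which argues against normalizing to them. Reference genes never
appear as rows of the expression matrix.

Missing Cq values propagate: a sample missing any reference gene gets a
missing reference Cq and therefore a missing expression column (with a
warning); downstream tests drop missing values pairwise and record the
effective group sizes per cell.

## Region comparisons

Every gene is tested for each requested region pair with a two-sided
Mann-Whitney U test on the per-sample expression values, **unpaired**
(all patients pooled per region). The within-patient matching of regions
is deliberately ignored to match the two-independent-samples framing this
analysis family uses; a paired alternative is out of scope. No
multiple-testing correction is applied — significance is the raw
two-sided p < α with strict inequality, α = 0.05 by default — because the
downstream counts and marker sets are defined on raw p-values; the output
records this choice.

The U statistic uses the counting definition with ½ credit for ties. Two
p-value routes, recorded per cell:

* **exact**: the full null distribution of U over all C(n+m, n) rank
  assignments, computed with the classic count recursion
  N(u; n, m) = N(u−m; n−1, m) + N(u; n, m−1); selected automatically for
  tie-free samples with n+m ≤ 16 (a forced exact test runs at any size).
  The two-sided p sums both tails at the observed U's distance from the
  mean and is capped at 1.
* **asymptotic**: normal approximation with tie-corrected variance
  nm/12 · ((N+1) − Σ(t³−t)/(N(N−1))) and a 0.5 continuity correction.

If every pooled value is tied the test is degenerate and p = 1 by
convention (logged). Exact and asymptotic p agree to well within 0.01 at
group sizes (10, 10); at the study's 33 vs 33 the asymptotic route is
used. Because the test depends on ranks only, the comparison table is
identical whether computed on 2^−ΔCt or on −ΔCt; the suite asserts this.

## Published-table fixtures

The package ships verbatim transcriptions of the three published
region-pair p-value tables (normal-vs-regions, border-vs-regions,
center/periphery), including their significance stars. Applying the
p < 0.05 mask to the transcriptions reproduces every published
significance count (10/10/9/13, 11/8/13, 5/12/13) and the four-miRNA
consistently differentiating set {miRNA-21, miRNA-200b, miRNA-200a,
miRNA-191}. The underlying raw Cq data were never deposited, so the
numeric M and V values of the published stability table are *not*
reproducible; stability correctness is established against an independent
brute-force oracle instead (exact agreement to 1e-12 on random panels up
to 8 genes × 12 samples).

## Synthetic cohorts

The generator draws Cq additively on the cycle scale (equivalently
multiplicatively/lognormally on the expression scale), matching the
2^−ΔCt framework:

    Cq[g,(p,r)] = mu_g + shift_g[r] + u_{g,p} + ε,
    u ~ N(0, patient_sd_g²),  ε ~ N(0, noise_sd_g²),

with region N anchored at zero shift and all draws deterministic given the
seed. Patient intercepts are drawn per gene, keeping genes independent; a
shared-intercept mode (`shared_patient_sd`) mimics sample-quality
variation and is off by default. Dropouts are modelled only as
missing-at-random masking (`missing_rate`), not as a censoring mechanism.

Default condition choices, fixed once:

* baselines 20–32 cycles (typical for miRNA RT-qPCR on tissue imprints);
* target genes: residual noise 0.5 cycles, patient intercept 0.7 cycles,
  regional shifts 0–2 cycles with the largest effects in P2, mirroring the
  qualitative pattern of the published tables (the four consistent markers
  shift in every tumor region);
* reference candidates miRNA-100/-143 quiet (0.2-cycle noise, no shifts).

Presets:

* `paper_like` — the full heterogeneous panel above;
* `null` — zero shifts *and* zero patient intercepts, pure measurement
  noise. The patient intercept is zeroed here by design: the preset exists
  for type-I calibration against an independent-samples binomial band, and
  shared within-patient intercepts across regions would make the unpaired
  test conservative by construction rather than miscalibrated;
* `two_stable_refs` — two designated genes with 0.05-cycle noise and no
  effects against 20 noisy (≥0.5 cycles), shifted genes, for
  reference-recovery checks.

What the simulations do **not** emulate: PCR amplification kinetics and
efficiency variation, primer chemistry, informative dropout at high Cq,
inter-plate batch effects, and any correlation between miRNAs beyond an
optional shared patient intercept. Passing tests on these cohorts
establish that the algorithms are implemented correctly under the stated
generative model — not that the biological conclusions of any particular
tissue study are robust.

## Problem sizes used by the checks

The operating-characteristic checks run at the study's own design size
(33 patients × 5 regions): type-I calibration pools 10 null cohorts
(2000 gene-contrast tests, band [0.03, 0.07] ≈ the 99% binomial band
around 0.05); reference recovery and shift-detection power each use 100
replicate cohorts with thresholds of 95/100. Oracle equivalence for the
stability ranking uses random panels up to 8 genes × 12 samples;
Mann-Whitney enumeration checks use group sizes up to (6, 6).

## Known limitations

* Unpaired testing discards the within-patient design; with strong shared
  patient effects the region tests are conservative.
* The NF-stability column is a reconstruction (above), not a published
  definition.
* No effect sizes (fold changes, Hodges-Lehmann) and no FDR control; the
  outputs are raw p-value tables, counts, and marker sets.
* Instrument-native run files (RDML or vendor exports) are not parsed;
  inputs are plain delimited text.
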