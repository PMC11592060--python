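# Methods

## Problem

Relative RT-qPCR quantification divides a target gene's expression by that
of a reference ("housekeeping") gene, so any instability of the reference
propagates directly into the biological conclusion. `refstab` implements
the standard toolbox for choosing a reference from a candidate panel: four
stability algorithms with different operating principles, a consensus
ranking, amplification-efficiency QC, a co-regulation diagnostic, and a
ΔΔCt sensitivity analysis that quantifies how much the fold-change estimate
depends on the reference choice.

All computation happens on the Ct (cycle-threshold) scale. Ct is the cycle
at which fluorescence crosses a threshold, so it is a log2-scale abundance:
one cycle ≈ one doubling, and lower Ct = higher expression.

## Data model

A `CtTable` is a complete genes × samples matrix of finite, strictly
positive Ct values with exactly one group label per sample. Technical
replicates are kept distinct until `collapse_replicates` averages them
(arithmetic mean of Ct; cells whose replicate spread exceeds 0.5 cycles —
configurable — are flagged in a side report but never dropped). Missing
cells are an error, not imputed: every algorithm below assumes a complete
matrix, and silent imputation would silently change rankings. Applicability
QC flags any cell with Ct ≥ 40 (strict inequality on the usable side), the
conventional limit beyond which quantification is not trusted.

## Stability algorithms

**BestKeeper-style dispersion.** Per gene, over all samples pooled
(group-blind): geometric and arithmetic mean Ct, min, max, a dispersion
`SD`, and `CV% = SD / ArMean × 100`. The default dispersion is the mean
absolute deviation from the arithmetic mean, which is what the classic
spreadsheet tool reports as "SD [± CP]"; the n−1 sample SD is available via
`sd_mode="sample_sd"` since the two cannot be distinguished from published
tables alone. Genes are ranked 1..G by ascending SD, ties broken by
ascending CV%, then input order. A gene with SD > 1 cycle (strictly) is
flagged inconsistent.

**Comparative ΔCt.** For every gene pair, the per-sample Ct difference is
formed and its n−1 SD taken over all samples pooled; a gene's stability
value is the mean of these SDs over its partners. A gene whose ratio to
everything else is constant scores 0.

**geNorm.** Pairwise variation V_jk = SD of the log2-transformed expression
ratio of genes j and k — algebraically identical to SD(ΔCt_jk) when a
common base is used. M_j = mean of V_jk over partners. The gene with the
highest M is removed and M recomputed until two genes remain; that pair is
reported jointly at average rank 1.5 (removed genes take ranks 3..G in
reverse exclusion order, each with the M it had at removal). The mean M of
the remaining genes is non-increasing across steps. An exact mid-iteration
tie removes the later gene in input order, making runs deterministic.
First-pass geNorm M equals the comparative-ΔCt value exactly; the test
suite exploits this identity as a cross-check between two independently
written code paths.

**NormFinder-style model.** The only group-aware method. Within each
subgroup, samples are centered by their across-gene mean (removing
loading), giving a two-way decomposition into gene profile means and
residuals. Per gene and group it estimates

* the intergroup difference `d_ig` — the gene's group profile mean minus
  its across-group average (double-centered by construction);
* the intragroup variance `σ²_ig` — from the residuals, corrected for the
  bias introduced by centering over k genes:
  `σ²_ig = k/(k−2) · (s²_ig − Σ_l s²_lg / (k(k−1)))`, floored at 0.

The between-group variance of the true d's is estimated as
`γ² = Σ d² / ((k−1)(g−1)) − mean(σ²_ig/n_i)`, floored at 0 — the divisor is
the interaction degrees of freedom of the double-centered d matrix. Each
`d_ig` is shrunk toward 0 by the empirical-Bayes factor
`γ²/(γ² + σ²_ig/n_i)`, and the stability value is

    ρ_g = mean over groups of ( |d̃_ig| + sqrt(σ²_ig / n_i) )

combining the shrunken bias with the sampling SD of its estimate. With a
single group there is no intergroup bias to estimate and ρ reduces to the
residual SD `sqrt(σ²_g)` itself (not its standard error); the grouped
routine special-cases g = 1 so that both entry points agree exactly. This
discontinuity is intentional: the single-group value answers "how noisy is
this gene", the multi-group value "how biased and how noisy is its group
profile". Two grouping presets ship: `fine` (every experimental group its
own subgroup) and `coarse` (healthy vs tumor); subgroups need ≥ 2 samples.

**Consensus.** Each method contributes its rank vector as weights (tied
genes get the average of the tied positions, so a geNorm top pair
contributes 1.5 each); the comprehensive ranking orders genes by the
geometric mean of their weights. The geometric mean makes every method
count equally regardless of its raw stability scale, and is strictly
monotone: improving a gene's rank in one method can never worsen its
aggregate. The consensus re-ranks supplied rankings; it never re-runs the
algorithms internally.

### Known pitfalls (documented, and reproduced in the test suite)

* BestKeeper sees only marginal dispersion: a gene regulated consistently
  in a subset of groups can look acceptable if the shift is modest.
* The pairwise methods (ΔCt, geNorm) are blind to co-regulation: two
  strongly correlated genes hold each other's pairwise variation down and
  can survive to the geNorm final pair however unstable they jointly are.
  The Pearson correlation matrix on linearized quantities
  (`Q = base^(Ct_min − Ct)`, anchored per gene at its minimum-Ct sample) is
  the diagnostic; the simulator reproduces the effect via noise coupling.
* NormFinder's grouping is its power and its cost: with few samples per
  subgroup the intragroup variance estimates are themselves noisy.

## Efficiency QC

A dilution series (undiluted = log10 concentration 0; 10-fold = −1, …)
is fitted by OLS: `Ct = a + slope · log10(conc)`. Efficiency
`E% = (10^(−1/slope) − 1) × 100`; slope −3.3219 = perfect doubling = 100%.
Replicates enter as individual points. The practically acceptable window is
90–110%; outside it the result is flagged, as is a (physically invalid)
positive slope. Requires ≥3 distinct concentrations; a span under 2 log10
units warns. Adding a constant to all Ct changes only the intercept.

## ΔΔCt validation

`ΔCt = mean Ct_target − mean Ct_ref` per group; `ΔΔCt = ΔCt_case −
ΔCt_control`; `fold = base^(−ΔΔCt)` with base 2 unless per-gene
efficiencies are supplied. Both the group-mean estimate and per-sample fold
values (mean ± SD, control group anchored at 1) are reported, since
published figures use either convention. Multi-reference normalization
averages the references' Ct (= geometric mean of their quantities).
`compare_references` reports, across candidate references, the max/min fold
ratio, whether the qualitative call (fold ≷ 2 by default) flips, and which
candidate deviates most from the median log2 fold. A reference that drifts
by δ cycles between the groups multiplies the apparent fold by exactly
`2^δ` — the algebra behind "choosing the wrong reference halves your fold
change".

## Synthetic data

The generator draws `Ct_igj = B_g + L_ij + Δ_ig + ε_igj (+ c_g·ε_partner)`
with loading `L ~ N(0, σ_loading²)` shared by all genes of a sample, noise
Gaussian on the Ct scale, per-group regulation shifts Δ, and optional noise
coupling for co-regulated pairs. Ground-truth instability per gene is
`sqrt(σ_g² + (c_g σ_partner)² + Var(Δ over samples))`; loading is excluded
because it is common-mode and cancels in every method above.

`default_study_design()` emulates a murine splenic/bone-marrow neutrophil
panel: 7 groups (healthy bone marrow and spleen for two strains, three
tumor-bearing spleen groups) × 3 pooled samples × 10 genes, baselines set
to the panel's published mean Ct values (B2m most abundant at ~18 cycles,
Sdha least at ~28), σ_loading = 0.5 cycles. Hprt1 (σ = 0.15) and Tbp
(σ = 0.20) are the designed stable genes; Ywhaz shares Tbp's noise with
coupling 0.6 plus a common bone-marrow/spleen contrast of 0.2 cycles
(the co-regulation pitfall); B2m, Rpl13a and Rack1 carry tumor-group shifts
of −1.0, −1.5 and −1.2 cycles (up-regulation under tumor burden); Gapdh,
Sdha, Eef2 and Actb are unregulated but noisy (σ 0.5–0.9). The noise and
shift magnitudes were chosen once so that the designed ordering is
identifiable at this design size while keeping the top of the ranking
genuinely contested, mirroring how such panels behave in practice.

`parameter_recovery_design()` is the benchmark used by the acceptance
study: Tbp and Hprt1 at σ = 0.1 with no shifts versus eight genes with
σ ∈ [0.3, 1.0], three of them tumor-shifted up to 2 cycles (Rpl13a carries
the largest shift).

What the generator does *not* emulate: amplification-curve artifacts,
inhibition, primer-dimer effects, non-Gaussian outliers, and
between-batch structure. Passing recovery tests therefore show that the
algorithms identify the designed signal under the stated noise model, not
that they are robust to every failure mode of real qPCR data.

## Numerical choices

* All SDs are n−1 sample standard deviations except BestKeeper's default
  MAD-type dispersion (documented above).
* Log base 2 everywhere by default; per-gene bases (1 + efficiency)
  optional in linearization, geNorm and ΔΔCt.
* Ties: average ranks for ΔCt/NormFinder/consensus; BestKeeper and geNorm
  use their deterministic in-method tie-breaks (CV then input order;
  later-in-input-order removal). On a fully degenerate (noise-free) table
  all methods return all-zero stability values; ranks are then all tied for
  the average-rank methods and input-ordered for the others.
* Variance estimates (σ², γ²) are floored at zero; degenerate all-zero
  results warn rather than raise.
* Report files are written with fixed precision (4 d.p.; 2 d.p. for the
  classic BestKeeper table layout), making pipeline re-runs byte-identical.

## Problem sizes

Simulation-backed tests and the acceptance study use 50–200 seeds of the
21-sample design, 100 random tables for the ΔCt/geNorm identity, and a
4000-sample draw for the closed-form SD check — sizes at which the
Monte-Carlo error of the checked rates is comfortably below the asserted
margins.

## Limitations

* No printed reference values exist for NormFinder's ρ in the motivating
  use case, so its correctness is established by an independent
  brute-force oracle and invariance/recovery properties, not by a
  published-number comparison. Variant NormFinder implementations differ
  in the uncertainty term added to |d̃| (sampling SD vs posterior SD); this
  implementation uses the sampling SD, which preserves the single-group
  reduction to sqrt(σ²).
* geNorm's V_{n/n+1} criterion (how many references to use) is out of
  scope, as are the BestKeeper index regression statistics and RefFinder's
  internal re-implementations of the four algorithms.
* Efficiency estimation from individual amplification curves is out of
  scope; only dilution-series standard curves are supported.
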