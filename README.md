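# refstab

Reference-gene stability analysis for RT-qPCR Ct data.

Relative RT-qPCR quantification reports a target gene's expression as a
ratio to a reference ("housekeeping") gene assumed stable across all
conditions. When that assumption fails — common in activated immune cells
such as neutrophils, where classic references like *Gapdh*, *Actb* or
*B2m* can be regulated — the error propagates straight into the biology:
normalizing the same data to a drifting reference can halve or double an
apparent fold change. `refstab` is for experimentalists validating a
candidate reference panel before quantifying targets, and implements:

* **Four stability algorithms** over a genes × samples Ct matrix:
  * *BestKeeper-style dispersion* — per-gene SD/CV of raw Ct, pooled over
    all samples; SD > 1 cycle marks a gene inconsistent;
  * *comparative ΔCt* — mean over partner genes of SD(Ct_j − Ct_k);
  * *geNorm* — stability M = average pairwise variation (SD of the log2
    expression ratio), with iterative exclusion down to a final pair;
  * *NormFinder-style model* — combines intragroup variance σ²_ig with the
    (shrunken) intergroup bias d_ig into ρ_g = meanᵢ(|d̃_ig| + √(σ²_ig/nᵢ)),
    under user-definable sample groupings;
* **Consensus ranking** by geometric mean of per-method ranks;
* **Efficiency QC** from dilution-series standard curves,
  E% = (10^(−1/slope) − 1) × 100;
* **Pearson co-regulation diagnostic** on linearized quantities
  Q = base^(Ct_min − Ct) — the check for the pairwise methods' blind spot;
* **ΔΔCt validation**: fold = 2^(−ΔΔCt), compared across candidate
  references to show how the reference choice changes the conclusion;
* **A synthetic Ct generator** with per-sample loading shifts, per-gene
  noise, group-specific regulation and co-regulation coupling, plus a
  known ground-truth stability ordering for end-to-end testing.

See `docs/methods.md` for the model details and design decisions.

## Worked example

Simulate the default study design — 10 candidate genes over 7 experimental
groups × 3 pooled samples (healthy bone-marrow/spleen neutrophils from two
mouse strains plus three tumor-bearing spleen groups) — and rank:

```python
import refstab as rs

table, truth = rs.simulate_ct(rs.default_study_design(seed=1))
rankings, consensus = rs.rank_and_aggregate(table)
print(consensus.to_frame().round(3))
```

```
        BestKeeper  deltaCt  geNorm  NormFinder  geomean_weight  final_rank
gene
Tbp            2.0      1.0     1.5         1.0           1.316         1.0
Hprt1          1.0      2.0     1.5         2.0           1.565         2.0
Ywhaz          3.0      4.0     3.0         4.0           3.464         3.0
B2m            6.0      3.0     4.0         3.0           3.834         4.0
Gapdh          4.0      5.0     5.0         5.0           4.729         5.0
Actb           5.0      7.0     7.0         6.0           6.192         6.0
Rack1          9.0      6.0     6.0         7.0           6.901         7.0
Sdha           7.0      9.0     9.0         9.0           8.452         8.0
Eef2           8.0     10.0    10.0         8.0           8.944         9.5
Rpl13a        10.0      8.0     8.0        10.0           8.944         9.5
```

Each method column holds that algorithm's rank of the gene (the geNorm top
pair *Ywhaz*/*Tbp*-style ties carry average rank 1.5 each); the consensus
orders genes by the geometric mean of those ranks. Here the two genes
simulated as stable (*Tbp*, *Hprt1*) take the top two consensus positions,
while the coupled gene *Ywhaz* — noisy, but co-regulated with *Tbp* —
scores better in the pairwise methods than its true stability warrants:
exactly the pitfall the correlation diagnostic
(`rs.correlation_matrix(rs.linearize(table))`) is there to expose.

How much does the reference choice matter? Normalizing a target induced
5-fold in the tumor group to a stable reference recovers fold ≈ 5; using a
reference that is itself up-regulated by 1 cycle in tumors halves it:

```python
r = rs.ddct_fold_change(table_with_target, "Arg1", "Tbp", "healthy", "tumor")
r.fold_change   # ≈ 5.0
r = rs.ddct_fold_change(table_with_target, "Arg1", "Rpl13a", "healthy", "tumor")
r.fold_change   # ≈ 2.5
```

The same analyses are available from the shell:

```sh
refstab simulate --seed 1 --out ct.csv --truth-out truth.json
refstab rank ct.csv --outdir report/        # methods + consensus + QC
refstab efficiency dilutions.csv            # slope, E%, R² per gene
refstab validate-ddct ct.csv --target Arg1 --refs Tbp,Rpl13a \
    --control healthy --case tumor
```

`refstab rank` writes per-method stability TSVs, the consensus table, the
QC report, the correlation matrix and a `summary.json`; re-running with the
same inputs is byte-identical.

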