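# dnbtip

Dynamic-network-biomarker (DNB) tipping-point analysis for replicated
time-series transcriptomes, with a bistable toggle-switch model of the
downstream transition.

## The problem

Many chronic diseases progress through three phases: a robust normal
state, a short low-resilience *pre-disease* (critical) state, and a robust
disease state that is hard to reverse. In experimental liver fibrosis,
for example, the fibrotic transition is preceded by a tipping point at
which intervention is still effective. The DNB method detects that
tipping point from omics time series without any disease model: a small
*dominant group* of genes starts fluctuating collectively just before the
transition, so that at the critical timepoint

- the mean absolute Pearson correlation **within** the group (PCC_i)
  rises sharply,
- the mean absolute correlation between group members and all **other**
  genes (PCC_o) falls, and
- the mean replicate standard deviation of the group (SD_i) rises sharply.

These combine into the composite index

```
CI = PCC_i · SD_i / PCC_o
```

evaluated per timepoint for the best candidate group; a sharp CI peak
marks the pre-disease state and its genes are the DNB. `dnbtip`
implements the full analysis — control adjustment, module discovery,
CI, permutation-guarded tipping call, differential-expression
intersection, pathway/network ranking of DNB genes — together with a
synthetic-data generator that plants exactly this statistical structure
(no public dataset accompanies the motivating study), and the
dimensionless mutual-repression model

```
dx/dt = α₁ / (1 + y^β₁) − x
dy/dt = α₂ / (1 + x^β₂) − y
```

of two mutually repressing genes (Tgfb3 and Mmp13 in the fibrosis
system), whose bistability explains why crossing the tipping point is
irreversible. The package is aimed at computational biologists who want
a tested, reproducible DNB pipeline for small-replicate designs, or a
simulation bench for critical-transition detection methods.

## Worked example

```python
from dnbtip import (SimulationDesign, simulate_expression,
                    adjust_to_control, select_dnb, DnbParams)

design = SimulationDesign(seed=1)          # 500 genes, 20-gene module,
dataset, sheet, truth = simulate_expression(design)  # tipping at week 9
adj = adjust_to_control(dataset, sheet)    # centre on pooled control means
result = select_dnb(adj, sheet, DnbParams(seed=2))
print(result.ci_table().round(3).to_string(index=False))
print("tipping:", result.tipping_time, " p =", round(result.p_value, 4))
```

prints

```
 time  PCC_i  PCC_o  SD_i    CI  module_size
    3  0.833  0.432 0.778 1.500           15
    5  0.792  0.420 0.797 1.504           15
    9  0.904  0.429 0.968 2.040           25
   14  0.770  0.413 0.792 1.476           15
   17  0.735  0.404 0.773 1.404           15
tipping: 9  p = 0.005
```

The composite index sits at the noise floor of small-replicate
correlation estimates (~1.5) at every timepoint except week 9, where
the planted 20-gene module fluctuates collectively: PCC_i jumps to
0.90, SD_i is inflated, and CI peaks at 2.04. The permutation test
(200 block-constrained per-gene permutations) rejects the no-signal
null at p = 0.005, so week 9 is called as the tipping point; the 25
reported DNB genes overlap the planted module at Jaccard 0.80 for this
seed.
Downstream, `differential_around_tipping` contrasts post- vs
pre-tipping samples, `intersect_dnb_deg` intersects the DNB with the
significant genes, and `rank_dnbs` orders DNB genes by
fibrosis-pathway membership counts with network-neighbour tie-breaks.

The same run is available from the shell:

```bash
dnbtip run --seed 1 --out results/demo
dnbtip toggle --out results/toggle --scan   # fixed points + critical α
```

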