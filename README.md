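# bimodalgene

Genome-wide screening for **bimodally expressed genes** and evaluation of
their **prognostic relevance** in survival cohorts.

Many clinically interesting genes do not shift gradually between patients:
they split a cohort into a low- and a high-expression group (amplified
*erbB2*, estrogen-receptor status, germline polymorphisms affecting
expression). Such genes are attractive for prognostic signatures because the
two groups are cleanly separable. This package ranks every gene of an
expression matrix by seven scores for bimodality, splits patients into
low/high groups per gene, tests each split against right-censored survival
with a permutation logrank test, and asks globally whether prognostic genes
are overrepresented among the top-scoring bimodal genes.

## The seven scores

For a gene with expression values x₁,…,xₙ and a 2-cluster split with
within/between/total sums of squares (TSS = BSS + WSS):

| score | definition | bimodal genes score |
|---|---|---|
| VRS | WSS / TSS of the 2-means split (min/max-initialised) | low |
| WVRS | mean of the two within-cluster variances / sample variance | low |
| dip | supₓ&#124;F̂ₙ(x) − G(x)&#124; minimised over unimodal CDFs G | high |
| kurtosis | unbiased excess kurtosis K̂ (0 for gaussians) | both tails |
| log LR | log L₂/L₁, two- vs one-component normal ML fit | high |
| BI | √(π(1−π))·δ̂, δ̂ = &#124;μ̂₁−μ̂₂&#124;/σ̂ (equal-variance mixture) | high |
| outlier sum | Σ x′ᵢ over median/MAD-standardised values beyond the quartile fences (larger side in absolute value) | high |

Negative kurtosis flags balanced two-group genes, positive kurtosis flags
outlier-driven genes, so the kurtosis list is ranked in both directions
(eight ranked lists in total).

Per-gene survival splits use k-means for VRS/WVRS/dip, the posterior of a
two-component gaussian mixture for kurtosis/log LR/BI, and the
outliers-vs-main-group split for the outlier sum. Significance is always a
permutation p-value, p = (#{|Z_perm| ≥ |Z_obs|} + 1)/(B + 1) — the groups can
be tiny, so the normal approximation of the logrank Z is never used.
Genome-wide enrichment of the N₁ most prognostic genes in a bimodality-ranked
list is tested with a one-sided Kolmogorov–Smirnov statistic
D⁺ = maxⱼ (j/n − r₍ⱼ₎/m), hypergeometric top-k overlap tests, and a
running-sum trace.

The dip statistic and its Monte-Carlo null table (uniform samples; the dip is
asymptotically largest for the uniform among unimodal distributions) are
implemented in the package — e.g. the simulated 95th percentage point at
n = 200 is ≈ 0.037.

## Worked example

```python
import bimodalgene as bg

spec = bg.CohortSpec(n_genes=500, n_samples=200, n_prognostic=10, seed=1)
matrix, survival, truth = bg.simulate_cohort(spec)

table = bg.score_all(matrix)                      # seven scores + ranks
scan = bg.prognostic_scan(matrix, survival,       # permutation logrank
                          method="mixture", n_perm=2000, seed=1)
prognostic = bg.select_prognostic(scan["p_perm"], top_n=12)
ranks = table.loc[prognostic, "rank_bi"]
d_plus, p = bg.ks_enrichment(ranks.to_numpy(), matrix.shape[0])
```

Output for this seed:

```
top-3 genes by bimodality index:
        bimodality_index    dip   log_lr
g00165             3.506  0.017  251.456
g00275             3.441  0.109  117.501
g00208             3.251  0.113  106.638
planted prognostic among selected: 10 / 12
KS enrichment of BI list: D+ = 0.769, p = 2.93e-08
```

All 10 planted prognostic genes are recovered among the 12 smallest logrank
p-values, and their ranks on the bimodality-index list are so small that the
uniform-rank null is rejected at p ≈ 3·10⁻⁸: the bimodal genes carry the
survival signal, which is the pattern the screen is designed to detect.

The same pipeline runs from the shell:

```bash
bimodalgene all --genes 2000 --samples 200 --seed 1 --out-dir run/
# writes expression.tsv, survival.csv, scores.tsv, prognosis_<method>.tsv,
# enrichment_summary.tsv, running-sum traces and score dendrograms
```

`bimodalgene simulate-dip-null` regenerates the dip null table at any
replicate count (a compact 2,000-replicate table ships with the package).

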