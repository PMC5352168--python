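# thermode

Differential-expression analysis for **unreplicated, pooled-embryo RNA-seq
designs with a temperature contrast** — the setting of developmental
studies of temperature-dependent sex determination (TSD), where each
(species × embryonic stage × incubation temperature) cell is represented
by a single sequencing library made from a pool of embryos, and
conventional replicate-based count models (DESeq2, edgeR) cannot be fit.

The package is aimed at researchers analyzing such time-series designs:
two species (a TSD species and a genotypic-sex-determination (GSD)
negative control), five embryonic stages, and two incubation temperatures
(26 °C male-producing vs 31 °C female-producing in the TSD species), one
pooled library per cell.

## The method

**Normalization.** Four per-library scaling schemes are compared:

- `UQ100` — upper-quartile: scale each library by the 75th percentile of
  its nonzero gene counts;
- `UQ99` — upper-quartile after removing the top 1 % of genes by mean
  expression from factor estimation *and* downstream testing;
- `UQHK100` — the mixed upper-quartile + housekeeping scheme, anchored so
  constitutively expressed reference genes (*Tfr*, *Hprt1*) are exactly
  equalized across libraries;
- `UQHK99` — the mixed scheme with the top-1 % trim.

All factors are centered to geometric mean 1, so normalized values stay
on the raw count scale.

**Per-gene exact test.** For gene *X* at one stage, the two temperature
libraries form a 2×2 contingency table

|                 | 26 °C | 31 °C |
|-----------------|-------|-------|
| gene *X*        | n₁₁   | n₁₂   |
| remaining genes | n₂₁   | n₂₂   |

and Fisher's exact test evaluates H₀: θ = 1 with
θ = π₁₁π₂₂ / (π₁₂π₂₁) — i.e. that gene *X* takes the same share of the
transcriptome at both temperatures.  The two-sided p-value uses the
probability-mass convention (all tables with the same margins whose
probability does not exceed the observed table's).  Normalized values are
rounded half-up to integers before table construction.

**Tiered FDR.** P-values are Benjamini–Hochberg adjusted within each
species × stage family.  Because a single pooled library per condition
leaves biological variability between pools unmodeled, the exact test is
anti-conservative; calls are therefore tiered at a *stringent* FDR-adjusted
cutoff of 1e-10 and a *suggestive* 0.05.

**Pseudo-replication cross-check.** Each library is split into k ∈ {2, 3}
multinomial subsamples (the count-level equivalent of randomly assigning
reads).  Matched subsample pairs are tested per gene with an exact
conditional binomial test at 1 % FDR, and the consensus keeps genes
significant with a consistent direction in *all* pairs.

**Comparative layer.** Venn/Jaccard overlap of DE sets across schemes,
stages and species; per-gene direction profiles across development; a
reproducible direction-concordance score against external (e.g. qPCR)
profiles; and gene-category tagging from GMT gene sets.

**Synthetic data.** A generator reproduces the full design (gamma
per-embryo expression → pooled sums → multinomial sequencing at exact
depth) with known per-gene fold-changes, so power, realized FDR and
calibration are measurable.

## Worked example

```python
import thermode as tm

config = tm.SimulationConfig(n_genes=5000, depth=500_000, seed=7)
matrix, truth = tm.simulate_experiment(config)
normalized = tm.apply_scheme(matrix, tm.get_scheme("UQHK100"))
results = tm.call_de(normalized)

stringent = results[results["tier"] == "stringent"]
print(stringent.groupby(["species", "stage"]).size())
metrics = tm.evaluate_calls(results, truth, tier="stringent")
print(metrics[metrics["species"] == "TSD"][
    ["stage", "n_called", "tp", "fp", "fdr", "power"]].to_string(index=False))
```

prints

```
species  stage
GSD      12         4
         15         4
         19         3
         22         6
TSD      15       122
         19       109
         22       124

 stage  n_called  tp  fp  fdr  power
     9         0   0   0  NaN    NaN
    12         0   0   0  NaN    NaN
    15       122 122   0  0.0  0.488
    19       109 109   0  0.0  0.436
    22       124 124   0  0.0  0.496
```

The TSD species carries simulated 4-fold temperature effects at stages
15–22 and the stringent tier recovers them with zero realized false
discoveries at this depth.  The handful of stringent calls in the GSD
species — whose ground truth contains *no* temperature-responsive genes —
comes from between-pool biological dispersion (0.05 here), illustrating
exactly why an unreplicated design needs the stringent tier and the
subsampling cross-check rather than a nominal 0.05 threshold.

The same analysis is available from the shell:

```sh
thermode simulate --n-genes 5000 --depth 500000 --seed 7 -o sim/
thermode de --counts-dir sim/ --sheet sim/sample_sheet.tsv --scheme UQHK100 -o de.tsv
thermode run -o run/          # full pipeline with manifest + reports
```

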