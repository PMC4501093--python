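# riskcline

Do worldwide allele-frequency patterns of disease risk SNPs simply reflect
the serial founder effect of the out-of-Africa expansion, or do they track
climate?  `riskcline` is a tested, reusable pipeline for that question,
aimed at population geneticists working with per-population allele
frequencies of GWAS risk panels (e.g. HGDP + HapMap style data).

## The analysis

For a disease with $d$ risk SNPs, each population $j$ gets two panel
statistics from the risk-allele frequencies $p_{ij}$ ($q_{ij} = 1-p_{ij}$):

- average heterozygosity $\;\sum_{i=1}^{d} 2\,p_{ij} q_{ij} / d$
- average risk-allele frequency $\;\sum_{i=1}^{d} p_{ij} / d$

Under the serial founder model, expected heterozygosity shrinks by
$(1 - 1/2N)$ per founding bottleneck of diploid size $N$, producing a
near-linear decline with distance from Africa — distance computed as
great-circle legs from Addis Ababa through region-specific waypoints
(Cairo, Istanbul, Phnom Penh, Anadyr, Prince Rupert).  The pipeline:

1. regresses both statistics on distance and on nine climate variables,
   each predictor separately (OLS; optionally WLS with inverse
   population-variance weights);
2. subtracts the genome-wide per-population baseline from each statistic
   ("adjusted" statistics), removing the shared drift signature before
   climate regressions;
3. judges each observed $R^2$ against an empirical null: every risk SNP is
   replaced by a random SNP from the same 0.1-wide global-allele-frequency
   bin, the identical pipeline is run, and the process is repeated 10,000
   times; the empirical p is the fraction of resampled sets with a higher
   $R^2$.  Bonferroni (10 predictors × 2 statistics) and Benjamini–Hochberg
   (FDR 0.2) flags handle multiplicity;
4. post-processes per-SNP environmental-association scores (Bayes-factor
   tables in the Bayenv 2.0 output dialect, or a built-in surrogate
   statistic for synthetic data) into ranked empirical p-values, and tests
   whether a disease's risk SNPs are over-represented in the $p<0.05$ tail:
   $\text{enrichment} = (n_r/n_{nr}) / (N_r/N_{nr})$, with significance
   from 50,000 same-size random SNP sets (Bonferroni cutoff 0.00026);
5. annotates SNPs as genic when within 10 kb of a gene (refFlat or BED).

A first-class synthetic-data module generates serial-founder frequency
matrices, distance-loaded climate variables, and risk panels with optional
injected climate clines, so the whole pipeline is testable end to end
without external data.

## Worked example

```python
import riskcline as rc

cfg = rc.SimulationConfig(n_populations=61, n_snps=10_000, effective_size=500, seed=11)
matrix, panel = rc.simulate_serial_founder(cfg)
climate = rc.generate_climate(panel, seed=12)
predictors = climate.copy()
predictors.insert(0, "distance_km", panel.distances_km)

risk = rc.make_risk_sets(matrix, [15], seed=13)[0]          # a 15-SNP panel
profile = rc.adjusted_profile(rc.risk_profile(matrix, risk),
                              rc.genomewide_baseline(matrix))
fit = rc.ols(profile.table["avg_heterozygosity"], panel.distances_km)
print(f"heterozygosity on distance: slope={fit.slope:.3e}  r={fit.r:.2f}  R2={fit.r_squared:.2f}")

results = rc.evaluate_panel(risk, matrix, predictors, n_sets=10_000, seed=14)
for r in results:
    if r.statistic == "heterozygosity" and r.predictor in ("distance_km", "summer_humidity"):
        print(f"{r.predictor:>15}: observed R2={r.observed_r_squared:.3f}  "
              f"empirical p={r.empirical_p:.3f}  Bonferroni={r.bonferroni_significant}")
```

prints

```
heterozygosity on distance: slope=-2.077e-06  r=-0.84  R2=0.70
    distance_km: observed R2=0.453  empirical p=0.480  Bonferroni=False
summer_humidity: observed R2=0.029  empirical p=0.589  Bonferroni=False
```

Read: this neutral panel's heterozygosity declines steeply with distance
(r = −0.84), but after drift adjustment its R² (0.45) is unremarkable
against frequency-matched resampled panels (empirical p = 0.48) — exactly
what a panel shaped by migration alone should look like.  An injected
climate cline instead drives the empirical p toward 0 for its variable.

The same pipeline runs from the shell:

```
riskcline run --seed 11 --out results/        # synthetic demo, all stages
riskcline simulate / distances / stats / regress / null / test /
          scores-post / enrich / annotate     # stage-by-stage, see --help
```

Stage outputs are plain TSV with a seed-stamped header; `manifest.yaml`
echoes the configuration for reproducibility.

## Using real data

With a real frequency matrix, risk-SNP lists, population coordinates and a
climate table (TSV dialects documented in `riskcline.cli_io`), point
`riskcline run --config your.yaml` at the files instead of the `simulate`
block.  Expected qualitative behaviour on worldwide human data: negative
heterozygosity–distance slopes of order $10^{-6}$ per km, with type 2
diabetes panels among the steepest.  Bayenv 2.0 itself is not
re-implemented: run it externally (two MCMC runs per ascertainment panel,
averaged, panels combined, then ranked) and feed its score tables to
`scores-post`.
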