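# thermotol

Statistical pipeline for analyzing the costs and benefits of winter
acclimatization in *Drosophila melanogaster* — and, more generally, for
comparing thermal-tolerance assay groups and thermal performance curves
between field-acclimatized and laboratory-acclimated insects.

Overwintering flies acclimatize to cold microhabitats (e.g. fermenting
compost heaps that run ~8 °C above air temperature). That plasticity
brings a large benefit in cold tolerance (a much lower critical thermal
minimum, CTmin) but a cost in heat tolerance (lower CTmax, faster heat
knockdown) and a cross-generational cost: eggs laid by winter-acclimatized
females have reduced egg-to-adult viability at high developmental
temperatures. `thermotol` implements the statistics used to establish
those results, for anyone who needs them on their own assay data:

* **Randomization tests on median differences.** Tolerance scores are
  skewed and heteroscedastic, so groups are compared with the statistic
  `Md = median(A) − median(B)`, a two-tailed permutation null
  (100,000 re-partitions by default, exact enumeration for small samples),
  and percentile bootstrap CIs (n = 10,000) on every group median.
* **Quasi-binomial cubic thermal performance curves.** Vial-level
  egg-to-adult viability is fitted as a binomial logistic model in
  standardized temperature `z`, `logit p = β₀ + β₁z + β₂z² + β₃z³`, with a
  treatment indicator and treatment × polynomial interaction; vial
  overdispersion is absorbed by φ = Pearson χ²/df, and nested models are
  compared with F-tests on (Δdeviance/df)/φ.
* **Benign-temperature standardization** (each vial ÷ its treatment's mean
  viability at 20/25 °C) followed by per-temperature randomization tests,
  so curve *shape* is compared independently of overall level.
* **A calibrated synthetic-data generator** (skewed tolerance groups with
  exact target medians, beta-binomial viability vials, half-hourly
  microhabitat temperature logs) reproducing the published group medians
  and effect structure, so the full pipeline runs and is testable with no
  external data.

## Worked example

Run the full pipeline (simulate → analyze → report) at reduced resampling
budgets:

```python
import thermotol as tt

cfg = tt.AnalysisConfig(seed=1).fast()   # n_perm=5000, n_boot=1000
res = tt.run_all(cfg)

rep = res["tolerance_report"]
cold = rep[(rep.assay == "cold_ramp") & rep.comparison.str.startswith("lab25-field")]
print(cold[["comparison", "md_a", "md_b", "md_diff", "p_value"]].round(4))
```

```
        comparison   md_a   md_b  md_diff  p_value
lab25-field/female 5.7440 0.7382   5.0058   0.0002
  lab25-field/male 5.7838 1.1259   4.6580   0.0002
```

Each row is one randomization test: `md_a`/`md_b` are the group medians
(CTmin of laboratory-25 °C vs. field flies, °C), `md_diff` their
difference, and `p_value` the two-tailed permutation p — winter-
acclimatized flies enter chill coma ~5 °C colder, and the difference is
detected at the resolution floor of 5,000 permutations (p = 1/5001 ≈
0.0002). The same report carries bootstrap CIs for every median and the
knockdown/heat-ramp/recovery assays, including the 13 °C-reared
laboratory groups.

```python
v = res["viability"]
print(v["model_comparison"][["test", "f_stat", "df_num", "df_den"]].round(2))
print(v["per_temperature"][["temperature", "md_diff", "p_value"]].round(4))
```

```
        test  f_stat  df_num  df_den
full_vs_null  402.38       7     392
 interaction   50.48       3     392

 temperature  md_diff  p_value
        11.0   0.0064   0.7648
        14.0  -0.0432   0.7526
        17.0   0.0344   0.7590
        27.0   0.1989   0.0012
        29.0   0.5000   0.0002
        31.0   0.2421   0.0008
        32.0   0.0000   1.0000
        33.0   0.0000   1.0000
```

The interaction F-test (3 numerator df, 400 vials − 8 parameters = 392
denominator df) shows the two treatments' viability curves differ in
shape; the per-temperature block shows where: standardized viability of
field offspring is depressed at 27–31 °C only (`md_diff` is the
laboratory-minus-field difference in median relative viability), with no
difference at low temperatures and none at 32–33 °C where both curves have
collapsed.

The same pipeline is scriptable from the shell:

```bash
thermotol all --seed 1 --fast --out results/demo
thermotol simulate tolerance --seed 3 --out tolerance.csv
thermotol tolerance --input tolerance.csv --seed 3 --out report.tsv
thermotol verify
```

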