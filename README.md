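# ddpp — Digital Display Precision Predictor

A transcriptomic biomarker engine for small cohorts with paired tumor /
matched-normal expression profiles. Given per-patient tumor and normal
intensities, a drug-specific key-gene panel, and progression-free survival
(PFS) in months, `ddpp`:

1. computes per-gene features `F = log2(T/N) * log1.1(I)` where `I` is the
   intensity of one channel (tumor or normal); a tumor-only ablation mode
   (`log1.1(T)` alone) is also available;
2. ranks panel genes by the absolute Pearson correlation of their feature
   with PFS, choosing the channel that holds the single most-correlated gene;
3. scans every ranked prefix (K = 1..panel size) under five parameter-free
   summations — sum, mean, median, fold (product), fold_abs (absolute
   product) — and keeps the (K, method) cell whose per-patient scalar best
   correlates with PFS;
4. fits an ordinary least-squares line `PFS = slope * X + intercept` on the
   winning scalar;
5. validates by leave-one-out (the entire selection is refit per fold),
   reports concordance r/p, RMSE, and MAE, and probes specificity with
   cross-drug tests and 100k-iteration random-gene-set null scans.

Censored PFS values (written `60.0+`) are stored with a flag but enter all
computations de-censored.

## Package layout

| module              | contents                                                       |
|---------------------|----------------------------------------------------------------|
| `ddpp.datamodel`    | domain types and invariants (patients, cohorts, panels, models)|
| `ddpp.io`           | CSV/TSV and JSON readers/writers (long & wide expression dialects) |
| `ddpp.core`         | feature computation, Pearson ranking, summations, step-in selection |
| `ddpp.predict`      | OLS fit, prediction, leave-one-out validation                  |
| `ddpp.significance` | random-gene-set null scans, cross-drug tests, discovery scans  |
| `ddpp.panels`       | packaged drug panels, published equations, clinical fixture    |
| `ddpp.synthetic`    | cohort generator with a planted, exactly-linear signature      |
| `ddpp.cli`          | `ddpp` command-line front end                                  |

## CLI

```bash
ddpp simulate --out sim/ --seed 1 --n-genes 100        # synthetic cohort
ddpp rank  --drug everolimus --expr e.csv --clin c.csv
ddpp fit   --drug everolimus --expr e.csv --clin c.csv --out model.json
ddpp loo   --drug everolimus --expr e.csv --clin c.csv --out report.json
ddpp null  --drug everolimus --expr e.csv --clin c.csv \
           --panel-size 8 --iterations 100000 --seed 7 --out null.json
ddpp shuffle --model model.json --drug axitinib --expr e.csv --clin c.csv
ddpp scan  --drug everolimus --expr e.csv --clin c.csv --out scan.csv
```

`--panel` accepts a JSON file (`{"drug":…, "genes":[…], "aliases":{…}}`);
without it the packaged panel for `--drug` is used. `--config run.yaml`
supplies defaults for any flags (explicit flags win). Every command logs the
package version, a config hash, and the seed where randomness is involved.

Expression tables are accepted long
(`patient_id,gene,tumor_intensity,normal_intensity`) or wide (a `gene`
column plus `<patient>_tumor`/`<patient>_normal` pairs); the dialect is
auto-detected from the header. Clinical tables need
`patient_id,drug,pfs_months` (a `+` suffix on PFS marks censoring).

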