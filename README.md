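# tempovar

Temporal dataset-shift detection for record-level clinical data.

Statistical distributions in electronic health records and clinical
registries drift over time: coding practices change, certificates are
reformed, billing systems are replaced, diseases are seasonal. Any model or
study that pools such data across years silently inherits these shifts.
`tempovar` is for data scientists and epidemiologists who need to *see*
where a dataset's distributions change before they trust it.

## Method

Given one row per clinical record with a reference date and an analysis
variable (a diagnostic code, an age, a lab value), `tempovar`:

1. **Batches** records into calendar periods (week / month / year) and
   estimates, per batch *i*, the distribution *P<sub>i</sub>* of the
   variable over a shared support — the **data temporal map (DTM)**,
   visualised as a heat map of absolute or relative frequencies over time.
2. **Compares** batches with the Jensen–Shannon distance,

   JSD(P, Q) = √( ½ KL(P‖M) + ½ KL(Q‖M) ),  M = ½(P + Q),

   with base-2 logarithms, so JSD ∈ [0, 1] and is a true metric.
3. **Embeds** the batches by classical (Torgerson) multidimensional
   scaling of the pairwise JSD matrix into 2–3 coordinates ordered by
   variance explained — the **information-geometric temporal (IGT) plot**,
   a non-parametric temporal statistical manifold in which *trends* appear
   as flowing sequences of batches, *abrupt changes* as gaps, *temporal
   subgroups* as clusters and *seasonality* as yearly cycles (batches are
   labelled `yym` and colour-coded by month).

A synthetic-scenario generator produces record-level CSVs with injected
trends, abrupt changes, seasonal modulation and subgroup regimes — with
exact ground truth — so every property of the pipeline is testable without
access-restricted clinical data.

## Worked example

```python
import numpy as np
import tempovar as tv

scenario = tv.scenario_presets(seed=42)["abrupt"]     # 48 monthly batches,
truth = tv.realize_distributions(scenario)            # shift at batch 25
table = tv.sample_records(truth)

dtm = tv.estimate_data_temporal_map(table, "code", granularity="month")
print(f"{dtm.n_batches} monthly batches, support of {len(dtm.support)} codes")

series = tv.consecutive_dissimilarity_series(dtm)
date, peak = max(series, key=lambda item: item[1])
print(f"largest consecutive JSD = {peak:.3f}, entering batch {date}")

proj = tv.estimate_igt_projection(dtm, dims=3)
print("variance explained (D1-D3):", np.round(proj.variance_explained, 3))
print("label of the changed batch:", proj.labels[proj.batch_dates.index(date)])
```

prints

```
48 monthly batches, support of 10 codes
largest consecutive JSD = 0.439, entering batch 2010-02-01
variance explained (D1-D3): [0.95  0.012 0.009]
label of the changed batch: 10F
```

The injected abrupt change (batch 25 of a series starting 2008-01 is
2010-02, labelled `10F`) dominates the dissimilarity series — a JSD jump of
0.44 between adjacent months against a sampling-noise floor near 0.1 — and
the first IGT axis carries 95% of the distributional variance, separating
the pre- and post-change regimes.

The same pipeline runs from the shell:

```sh
tempovar simulate --preset abrupt --seed 42 --out-dir out/
tempovar estimate-dtm --input out/abrupt_records.csv --variable code --out-dir out/
tempovar estimate-igt --dtm out/dtm_code --dims 3 --trajectory --out out/igt_code
tempovar plot --dtm out/dtm_code --out out/heatmap.png
tempovar plot --igt out/igt_code --trajectory --out out/igt.html
```

`estimate-dtm` accepts `--treatment dx=categorical` for code columns whose
values look numeric (ICD-9-CM codes such as `780.9` would otherwise be
binned as numbers).

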