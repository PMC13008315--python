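# bbb-ivive

Analysis pipeline for bidirectional Transwell® blood–brain-barrier
permeability assays and in-vitro-to-in-vivo extrapolation (IVIVE) of brain
exposure:

1. **Simulate** (`bbb_ivive.synthetic`) — two-compartment Transwell transport
   with the standard sampling-with-replacement protocol (200 µL receiver
   samples at 30–180 min, refilled with blank buffer), multiplicative
   lognormal measurement noise, and synthetic toxicokinetic parameter tables.
2. **Estimate** (`bbb_ivive.papp`) — reconstruct cumulative transported mass
   (correcting for sampling dilution), fit flux by OLS, and compute the
   apparent permeability `Papp = (dM/dt) / (C0 · SA · 60)` in cm/s, with
   replicate aggregation and QC flags (sink violation, poor linearity,
   too-fast censoring reported as a typed "> 500×10⁻⁶ cm/s" bound).
3. **Metrics** (`bbb_ivive.metrics`) — efflux ratio `ER = Papp_BA / Papp_AB`
   with uncertainty propagation, permeability-rate classes
   (Slow/Moderate/Fast/Very fast) and directional-transport calls
   (Efflux ≥ 2.5, Influx < 0.4). Censored permeabilities propagate as
   one-sided bounds through every derived quantity.
4. **Predict** (`bbb_ivive.ivive`) — permeability–surface-area clearance
   `PS = Fub · A_BBB · Papp_AB` (A_BBB = 20 m²), first-order uptake rate
   constant `k = PS / V_ref` and half-life `ln(2)/k` for acute exposure, and
   steady-state brain concentration `Css,brain = Css,serum / ER` for chronic
   exposure. Note: the normalization volume `V_ref` (default 5 L) is a
   modeling choice required for dimensional consistency; it is configurable
   and recorded in the run manifest.
5. **Report / compare** (`bbb_ivive.io`) — tidy CSV writers/readers, a
   packaged 48-compound bidirectional reference panel, figure-ready report
   CSVs, and Pearson-r² comparison against an external permeability panel
   (e.g. Caco-2).

## CLI

```sh
# synthetic panel end to end
bbb-ivive simulate --truth truth.csv --seed 1 --out timecourse.csv
bbb-ivive estimate --timecourse timecourse.csv --out estimates.csv
bbb-ivive metrics  --estimates estimates.csv --out-dir reports/
bbb-ivive predict  --estimates estimates.csv --toxkinetics tk.csv \
                   --abbb-m2 20 --vref-l 5 --dose 1 --out-dir reports/
bbb-ivive compare  --measured measured.csv --external caco2.csv
```

`truth.csv` needs columns `compound_id,true_papp_AB,true_papp_BA[,noise_cv]`
(cm/s); `tk.csv` needs `compound_id,casrn,fub,css_serum_uM,
reference_dose_mg_kg_day`. An optional R exporter,
`scripts/export_httk.R`, writes `tk.csv` from the EPA `httk` package.

Thresholds (sink fraction, r² minimum, censor cutoff, rate-class boundaries,
ER call cutoffs) and physiology are all CLI flags, and every value actually
applied is logged to `run_manifest.json`.

## File formats

Tidy UTF-8 CSV throughout; `NA` for missing values; censored values appear
as `"> x"` / `"< x"` strings in report files and as typed
(value, bound_type) columns in machine files; infinite half-lives are
serialized as the token `inf`.
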