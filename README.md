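# shortcast

Forecasting drug-shortage impact for interchangeable drug groups from
pharmacy dispensing data and public shortage reports.

## The problem

When a drug product (DIN) goes into shortage, pharmacists substitute
within its interchangeable group (IG); when a whole IG runs dry they must
escalate to other therapeutic-class (TC) neighbours with physician
sign-off. Pharmacies see only their own dispensing and the public shortage
registry — no manufacturer supply data. `shortcast` asks how far that
limited view goes: it builds a monthly **shortage impact score** per IG,

    score(g, t) = Σ_{d ∈ g} w_d(t) · u_d(t)

where `w_d` is DIN *d*'s share of the IG's historical days of supply (DOS)
and `u_d` the fraction of its pack listings unavailable in month *t* —
0 means everything available, 1 means nothing is — and forecasts that
score one month ahead with one gradient-boosted tree model per IG, trained
on lagged demand, preference (Gini concentration of DIN shares,
month-to-month share changes) and TC-neighbour shortage features under
blocked expanding-window cross-validation.

Real dispensing data is proprietary, so the package ships a seeded
synthetic generator that emulates the catalog/dispensing/report tables —
including substitution away from shorted DINs, DOS rationing, free-text
pack sizes and date defects — plus a latent ground-truth ledger every
pipeline stage is tested against. See `docs/methods.md` for the full
model description and its limitations.

## Worked example

```python
import pandas as pd
from shortcast.impact import impact

catalog = pd.DataFrame([
    {"din": d, "ig_code": "IGW", "tc_code": "84:04.08.28",
     "strength": "40MG", "common_name": d} for d in ("x", "y", "z")])
packs = pd.DataFrame([
    {"din": "x", "listing_id": "x-100", "pack_size": 100},
    {"din": "x", "listing_id": "x-300", "pack_size": 300},
    {"din": "y", "listing_id": "y-1", "pack_size": 100},
    {"din": "z", "listing_id": "z-1", "pack_size": 100}])
dispense = pd.DataFrame([  # prior-month DOS: x holds 400 of 1000 = 40%
    {"din": "x", "ig_code": "IGW", "month": "2018-01", "tot_dos": 400,
     "tot_patients": 10, "tot_qty_disp": 400, "tot_rx": 10, "avgdos_pat": 40.0},
    {"din": "y", "ig_code": "IGW", "month": "2018-01", "tot_dos": 300,
     "tot_patients": 10, "tot_qty_disp": 300, "tot_rx": 10, "avgdos_pat": 30.0},
    {"din": "z", "ig_code": "IGW", "month": "2018-01", "tot_dos": 300,
     "tot_patients": 10, "tot_qty_disp": 300, "tot_rx": 10, "avgdos_pat": 30.0}])
intervals = pd.DataFrame([  # one of x's two packs short for all of February
    {"din": "x", "listing_ids": frozenset({"x-300"}),
     "start": pd.Timestamp("2018-02-01"), "end": pd.Timestamp("2018-02-28")}])

print(impact("IGW", "2018-02", dispense, intervals, packs, catalog))
```

prints `0.2`: DIN *x* carries weight 0.4 (40% of past DOS) and half its
packs are unavailable, so the IG's score is 0.5 × 0.4 = 0.2; the other
DINs contribute nothing.

## The analysis

The numbered scripts under `analysis/` run the full study on the synthetic
world (100 IGs, January 2017 – April 2021; 36 blocked resamples over
2017–2020; January–April 2021 held out):

```bash
cd analysis
python 01_simulate.py   # catalog, dispensing, raw shortage reports, latent truth
python 02_clean.py      # reports -> resolved shortage intervals + cleaning log
python 03_score.py      # monthly impact score per IG
python 04_features.py   # lagged per-IG feature table
python 05_train.py      # blocked CV, holdout forecasts, permutation importance
python 06_evaluate.py   # MAE, confusion matrix, kappa, detection table
```

Small summary tables land in `results/` (bulky intermediates go to
`scratch/`). On the default seed the run produces 100 IGs × 4 holdout
months = 400 forecasts and `05_train.py`/`06_evaluate.py` print

```
36 blocked resamples over 48 training months
cv_mae 0.0449   holdout_mae 0.0493   n_holdout_records 400
accuracy 0.412 (95% CI 0.364-0.462), kappa 0.076
impactful shortages detected: 1/6
```

— a cross-validated score error under 0.05 on the synthetic world, with
bin-level agreement (None/Low/Medium/High classes) and the count of
impactful shortages (actual score ≥ 0.5) whose forecasts also reached the
0.5 threshold. Absolute numbers are properties of the synthetic demand
process, not of real pharmacy data; what the suite certifies is the
pipeline's mechanics, leakage-freedom and oracle agreement, not field
accuracy.

The same stages are available as a CLI (`shortcast simulate|clean|score|
features|train|evaluate`) for running on arbitrary input tables.

## Layout

```
src/shortcast/      library: config, synthetic, ingest, impact, features,
                    model, evaluation, pipeline, cli
analysis/           numbered study drivers (thin wrappers over the library)
tests/              pytest suite incl. independent brute-force oracles
scripts/            acceptance.py
docs/methods.md     model, assumptions, parameter choices, limitations
```
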