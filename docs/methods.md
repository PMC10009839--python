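# Methods

## The problem

When a drug product (identified in Canada by its DIN) goes into shortage, a
pharmacist must substitute another product from the same interchangeable
group (IG); when the whole IG is short, substitution requires physician
authorization and moves to a broader therapeutic class (TC) of the AHFS
hierarchy. Pharmacies see only demand-side data — their own dispensing — and
the public shortage-report database; they have no visibility into
manufacturers' supply chains. The question this package addresses is whether
that limited information suffices to forecast, one month ahead, how much of
each IG will be unavailable.

## Outcome: the shortage impact score

Shortage reports are filed per DIN and pack size, over date intervals. For
IG *g* in month *t* the impact score is

```
score(g, t) = Σ_{d ∈ g} w_d(t) · u_d(t)
```

- `w_d(t)` — DIN *d*'s share of the IG's *historical* days of supply (DOS):
  cumulative DOS from the start of the series through month *t − 1*,
  normalised over the IG. A DIN holding 40% of past DOS gets weight 0.4.
  The window is cumulative-from-start because it is reproducible and cannot
  leak information from month *t*; a trailing-12-month alternative would
  react faster to preference drift but adds a tuning choice with no
  counterpart in the outcome's definition.
- `u_d(t)` — the fraction of *d*'s pack listings unavailable in month *t*.
  All pack sizes of a DIN are weighted equally (order-volume per pack is not
  observed). Each listing contributes the fraction of days of the month it
  spends inside a resolved shortage interval, with overlapping intervals
  counted once; `u` is therefore the average over listings of a day
  fraction. For month-aligned shortages this coincides with the binary
  convention (a listing is short the whole month or not at all), which is
  why the worked example (0.5 × 0.4 = 0.2) is insensitive to the choice.

The score is 0 when everything is available, 1 when nothing in the IG is,
and is clipped to [0, 1] (clipping can only trigger through floating-point
rounding). IGs with no dispensing history yet get uniform weights — a
degenerate case real data never reaches but synthetic edge cases do.

## Cleaning shortage reports

Raw reports need three repairs before they define intervals:

1. **Status filter** — only `actual` shortages form the outcome;
   `anticipated` and `avoided` reports are dropped. Reports starting before
   mandatory reporting (2017-03-01 by default) are excluded.
2. **Date imputation** — start: actual start, else anticipated start, else
   entry date; end: actual end, else last-updated date. Records whose end
   remains missing or whose start falls after the end are removed and
   counted in a cleaning log (removals are reported, never silent).
   Intervals still open at the data pull are clamped to the last data month.
3. **Pack-size resolution** — the free-text pack description is reduced to
   its digit runs and matched against the distributor catalog's numeric
   listings. A number matches *every* listing with that size (two
   manufacturers' 100-count bottles are equally affected). Multi-number
   texts ("10 x 50 Blister") additionally try the product of the numbers.
   If nothing matches — including unparseable text — the DIN is assumed
   short in all of its pack sizes; this fallback is the conservative reading
   of an ambiguous report and is counted in the log.

## Features

Per IG and month: per-DIN demand aggregates (average DOS per patient, total
DOS, quantity, prescriptions; one block per component DIN), IG aggregates
(dos, qty, rx, dos per patient), the maximum month-to-month change in
within-IG DIN shares by patients and by DOS (in percent; shares moving
(80, 10, 10) → (50, 30, 20) give 30), the Gini concentration of the shares
(preference strength), the IG's own impact score, and shortage pressure in
TC neighbours at four distances.

**Gini normalisation.** The raw Gini of *n* shares caps at (n − 1)/n, so the
value is rescaled by n/(n − 1): uniform shares give exactly 0 and total
single-DIN preference exactly 1 regardless of IG size. A single-DIN IG
returns 0 by convention (there is no preference to measure).

**Neighbour features.** The AHFS code `84:04.08.28` truncates to
`84:04.08`, `84:04`, `84` at levels 1–3. The level-ℓ feature is the mean
impact score of all *other* IGs sharing the target's level-ℓ prefix,
weighted by each neighbour's cumulative DOS through the prior month —
demand-weighting chosen for consistency with the outcome's own weighting;
an unweighted mean is a one-line change. No neighbours → 0.

**Lags.** Every feature is replicated at lags 1–4 and only lagged copies
enter the design matrix; the contemporaneous score exists solely as the
target. This enforces the 30-day forecast horizon structurally: no model
can peek, and a truncation test (recompute after dropping future months,
earlier rows must be identical) guards the property.

A month-over-month IG-DOS difference is available behind a flag
(`include_dos_change`, default off) as an explicit seasonality proxy; the
default roster leaves seasonality to the lagged DOS levels themselves.

## Models

One XGBoost regressor per IG (`n_estimators=300, max_depth=4,
learning_rate=0.1, subsample=0.9`, single-threaded, seeded). Per-IG rather
than pooled models because feature sets differ across IGs (different
component DINs) and shortage dynamics are IG-specific. Cross-validation is
blocked and expanding: a 12-month minimum window, 1-month test blocks, each
resample one month longer than the last — 36 resamples over a 48-month
span. Holdout forecasting refits on all pre-holdout months and predicts
each holdout month from *observed* lagged features (one-step-ahead):
shortage reports are public monthly facts, so at deployment the previous
month's score is always known. Predictions are clipped to [0, 1].

Feature importance is permutation-based: the mean MAE increase when a
column is independently shuffled (3–5 repeats, seeded), floored at zero,
normalised to percentage shares per IG, aggregated by feature family and by
family × lag, and averaged across IGs with equal weight. Floor-at-zero
discards noise-level negative "importances" rather than letting them
distort the shares. An IG whose model nothing degrades (typically a
shortage-free IG with a constant-zero target) reports uniform shares with
a warning; under equal-weight averaging such IGs pull the cross-IG table
toward column-count-proportional shares, which favours the per-DIN
families — worth remembering when reading the averaged table on worlds
where many IGs never see a shortage.

## Evaluation

MAE overall, per IG, and by the actual score's severity bin; bins are
None (= 0), Low (0, 0.33], Medium (0.33, 0.67], High (0.67, 1]. The 4-class
confusion matrix yields accuracy with an exact Clopper–Pearson 95% CI
(normal-approximation interval selectable), unweighted Cohen's kappa, and
one-vs-rest precision/recall/specificity. Undefined ratios surface as NaN
with an explicit flag. An IG-month with actual score ≥ 0.5 is an
*impactful* shortage — at least half the group unavailable — and counts as
detected when the forecast also reaches 0.5.

## The synthetic world

Real pharmacy dispensing data is proprietary, so a seeded generator emulates
the three input tables with the structure the method relies on:

- **Catalog** — 100 IGs (≈ 8 DINs each, ≈ 790 DINs total) on a 4-level
  AHFS-style hierarchy whose leaf pool is smaller than the IG count, so
  sibling IGs exist at every level (as dosage variants of one molecule do in
  reality). Pack sizes are drawn without replacement within a DIN so the
  latent schedule stays exactly recoverable from rendered reports.
- **Latent shortages** — each pack listing faces a monthly hazard of 0.007
  (anchored to the observed reporting rate: roughly 750 shortage entries
  over 4.5 years across ≈ 2000 listings); durations are 1 + Geometric(0.4)
  months (mean ≈ 2.5 — shortages typically persist several months); with
  probability 0.2 an event propagates to a sibling IG under the same TC
  parent. The schedule is emitted as a ground-truth ledger purely for
  testability.
- **Dispensing** — per-IG patient totals (scale ≈ 200/month, log-normal
  across IGs) with a 12-month seasonal cycle (amplitude 0.15) and Dirichlet
  DIN shares (concentration 0.5, skewed — pharmacists prefer one DIN)
  drifting as a slow random walk on the simplex. One month after a DIN's
  packs go short, its share is multiplied by (1 − 0.7 × unavailable
  fraction) and the IG renormalised (substitution), and DOS per patient
  falls by up to 30% (rationing). The one-month lag mirrors the lead–lag
  the dispensing data shows around shortages; it is a qualitative choice,
  not a calibration.
- **Reports** — every latent event is rendered as a status-`actual` report
  through a random free-text dialect ("100 Bottle", "100 BTL", …); date
  defects (blanked or inverted actual dates) are injected at configurable
  rates (0 by default), and spurious anticipated/avoided reports are added
  on top as filter fodder.

Demand-side magnitudes (patients per IG, DOS distributions) are not
published anywhere; the defaults above are order-of-magnitude choices, made
once and exposed in `SimConfig` rather than asserted as realistic.

**What passing tests do and do not show.** The generator reproduces the
mechanisms the features are designed to detect (persistence, substitution
shifts, preference collapse, TC propagation) but not real-world confounders:
reporting lags and mis-filed DINs, demand shocks uncorrelated with
shortages, pharmacy heterogeneity, or the actual magnitudes of any of these.
Green tests certify that the pipeline computes what it claims and that the
method recovers planted structure; they say nothing about predictive
accuracy on real dispensing data.

## Numerical choices and degenerate inputs

- Months are calendar months (`pandas.Period`, "YYYY-MM" at file
  boundaries); date arithmetic is whole days, intervals closed on both ends.
- Zero-history IGs: uniform DOS weights. Zero-patient months:
  `avgdos_pat = 0` (not NaN) to keep tree inputs dense.
- Impact equivalence with a brute-force daily oracle is held to 1e-12;
  Gini against the O(n²) pairwise oracle likewise.
- A constant training target is a supported case (the regressor returns the
  constant); zero total permutation importance yields uniform shares with a
  warning rather than a division by zero.
- Problem sizes in the test suite: the study-scale pipeline runs once at
  100 IGs × 52 months (the scale of the reference analysis); unit and
  property tests use 3–12 IGs over 18–36 months, which exercise every code
  path at a fraction of the cost.

## Known limitations

- The score treats reported shortages as total unavailability; residual
  pharmacy stock can partly fill demand during a shortage, so the score is
  an upper bound on felt impact.
- Holdout forecasting is one-step-ahead only; a recursive multi-step mode
  (feeding predicted scores back into lagged features) is not implemented.
- Permutation importance is shuffle-based; drop-and-refit importance would
  cost ~n_features refits per IG and is not provided.
- Pack-size text matching is digit-based; textual manufacturer hints are
  ignored, and a text whose numbers match nothing silently widens to all
  packs (by design, but it inflates impact for typo'd reports).
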