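# antelopy

Accelerometer-to-behaviour analysis for dryland antelope biologging.

Collar-borne tri-axial accelerometers on free-ranging antelope (springbok,
greater kudu, common eland in the Namibian arid savanna) record short
bursts — 3.3 s at 33 Hz, every 5 minutes — from which behaviour can be
classified and long-term activity patterns reconstructed. `antelopy`
implements that full analysis chain as a tested Python package, together
with a synthetic collar-data generator with known ground truth so every
stage is verifiable without any field data:

1. **Burst features** — centering raw 0–4095 counts to G (512 counts/G
   around 2048), per-individual axis harmonisation (x/y sign flips against
   a training reference), the rotation-invariant yz-plane magnitude, six
   time-domain and three frequency-domain features on x and yz, and ODBA
   (overall dynamic body acceleration, 22-sample running-mean window =
   0.67 s at 33 Hz) — 19 features per burst.
2. **Behaviour classification** — correlation-based feature selection
   (|Pearson r| < 0.9 greedy rule over features ranked by single-feature
   CV accuracy), a gradient-boosted tree classifier over 12 behaviour
   labels, stepwise per-feature accuracy contributions, and confusion
   matrices.
3. **Time budgets** — per-individual exclusion rules (first 10 days and
   the final incomplete day), the head-up/head-down feeding split at a
   neck pitch of −30° (pitch = asin of the mean static surge acceleration),
   daily and monthly budgets, season labels (Nov–Dec early-green, Jan–Apr
   green, May–Oct dry), and 96 × 365 diel actogram matrices.
4. **Moonlight analysis** — a from-first-principles low-precision
   ephemeris: lunar illuminated fraction k = (1 + cos i)/2 from truncated
   solar/lunar series (documented accuracy |Δk| ≤ 0.02) and NOAA sunrise/
   sunset (±2 min). Nights are moonlit if k > 0.9, dark if k < 0.1;
   midnight-hour (00:00–00:59 local) behaviour budgets are contrasted with
   a hand-implemented Wilcoxon rank-sum test (midranks, first-sample
   Mann–Whitney W, exact enumeration for small untied samples, tie-corrected
   normal approximation otherwise).
5. **GAM deviance partitioning** — per-behaviour quasibinomial GAMs,

   logit E[y] = β₀ + f₁(month) + f₂(NDVI) + f₃(T) + b_ind,

   with a cyclic cubic regression spline for month (k = 10), natural cubic
   splines for NDVI and temperature (k = 10), ridge-penalized individual
   intercepts, penalized IRLS with GCV smoothing selection, and
   hierarchical (Shapley) partitioning of explained deviance 1 − D/D₀ into
   per-predictor independent, unique and shared contributions via all
   2^G − 1 subset refits. Concurvity between smooths is reported.

The synthetic generator emulates the deployed study design: 288 bursts per
individual-day, 12 behaviours with 5 dominant ones, behaviour-specific
neck pitch and dynamic signal, diel structure, an additive lunar shift in
nocturnal feeding probability (default 0.10), NDVI-coupled seasonal
modulation, per-individual budget offsets, and collar-orientation nuisance
(axis flips, neck rotation).

## Worked example

```python
from datetime import date
from antelopy import synthetic, astro

cfg = synthetic.SimConfig(seed=3, n_individuals=5, lunar_effect=0.10,
                          start=date(2021, 1, 1), end=date(2021, 12, 31))
mb = synthetic.simulate_midnight_budgets(cfg)
feed = (mb[mb.label.isin(["feeding-head-up", "feeding-head-down"])]
        .groupby("night_date_local")
        .agg(prop=("proportion", "sum"), k=("fraction", "first")).reset_index())
moonlit = feed[feed.k > 0.9].prop
dark = feed[feed.k < 0.1].prop
print(len(moonlit), len(dark))
print(round(moonlit.mean() - dark.mean(), 4))
print(astro.wilcoxon_rank_sum(moonlit, dark))
```

prints

```
73 73
0.0868
RankSumResult(W=4033.0, p_two_sided=8.357909679977558e-08, n1=73, n2=73, method='normal')
```

i.e. one simulated year yields 73 moonlit and 73 dark nights; nocturnal
feeding is 8.7 percentage points higher on moonlit nights (the injected
effect is 0.10 scaled by the actual lunar fractions), and the rank-sum test
detects it decisively (W = 4033 of a possible 73 × 73 = 5329, p ≈ 1e−7).

A complete pipeline run on synthetic data (simulate → features → train →
classify → budgets → moonlight test → GAM partitioning):

```bash
antelopy run-all --seed 7 --out my_run
```

writes the ACC/env/labelled CSVs, the feature table, the trained model and
confusion matrix, daily/monthly budgets, actogram matrices and PNG, the
moonlight contrast JSON, the per-behaviour deviance-partition JSON, and a
run manifest with input checksums.

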