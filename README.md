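# guanokin

Quantitative toolkit for the excretory physiology of the predatory soil
mite *Pergamasus longicornis*: when, after a single meal, does guanine
(the mite's nitrogenous excretory crystal) appear in and disappear from
the Malpighian tubules — and what can a soil ecologist infer about
time-since-feeding from guanine seen in field-collected mites?

The underlying study design is a destructive time series: 34 mites fed
one fly larva and fixed at 28 log-spaced times from 0 min to 14 days,
with the Malpighian tubules associated with each of 15 gut regions
scored ordinally (0 = contracted/no guanine, 1 = some, 2 = expanded
with lots). This package implements the full analysis pipeline over
such score tables, plus a synthetic-data generator that stands in for
the histology.

## What it computes

**Bayesian occurrence estimation.** At each sampling time, the
probability π of tubule guanine (score ≥ 1, rectal vesicle excluded) is
estimated with a Jeffreys prior: π | data ~ Beta(x + ½, n − x + ½).
The anterior-vs-posterior contrast is the log odds ratio
ln[π₁/(1−π₁) · (1−π₂)/π₂], summarised by Monte-Carlo draws from the two
Beta posteriors alongside the Woolf asymptotic standard deviation
√(1/x₁ + 1/(n₁−x₁) + 1/x₂ + 1/(n₂−x₂)).

**Kinetic stripping.** The occurrence curve is modelled as

    M[t] = a_el·e^(b_el·t) − a_in·e^(b_in·t),    b_el, b_in < 0,

fitted by exponential stripping (log-linear fit of the late
elimination-dominated tail, then of the early positive residuals), with
half-lives t½ = ln 2/|b|, the knot constraint a_in = a_el (curves cross
at the peak), the dose relation
M(t_max) = (D/V)·b_in/(b_in−b_el)·(e^(b_el·t_max) − e^(b_in·t_max)),
linear superposition of repeated doses, and the power-law cascade

    M[t] = a_el·e^(b_el·t) − [a_in·e^(b_in·t)]^n,

which shortens the effective input half-life to t½/n (an empirical
deformation, not a mechanistic claim).

**Compartmental truth model.** A four-compartment first-order system —
gut G, haemocoel H, Malpighian tubules M, rectal vesicle R, with
assimilation A, catabolism C, voiding V, egestion E and anal loss L —
drives the synthetic score generator:

    dG/dt = I(t) − (A+E)·G,   dH/dt = A·G − C·H,
    dM/dt = C·H − V·M,        dR/dt = E·G + V·M − L·R.

Trajectories are computed exactly (matrix exponential), and an ordinal
emission layer with a Hill-type occurrence map converts the latent M(t)
into 0/1/2 scores.

**Field inference.** With a uniform prior over the 28 time groups, k
positives among N field mites update group membership through the
beta-binomial posterior predictive
P(g | k of N) ∝ BetaBin(k; N, α_g, β_g); nomogram tables and plots
stack these over k.

## Worked example

```sh
$ guanokin simulate --seed 1 --out scores.csv
wrote 34 mites x 15 regions to scores.csv
$ guanokin estimate --scores scores.csv --out estimates.csv
wrote 28 time-point estimates to estimates.csv
$ guanokin fit --estimates estimates.csv --n-grid off --out fit.json
t1/2 elimination 33.8 h, input 33.7 h, n=1 (effective input 33.7 h)
$ guanokin nomogram --estimates estimates.csv --k 5,6 --out nomogram.csv
wrote nomogram for k in [5, 6] (N=20) to nomogram.csv
```

The simulated study reproduces the structure of the real one: guanine
occurrence is confined to a late post-prandial window (roughly 2–8
days, peaking near day 4, well after the gut is void), and the
nomogram's most probable group for 5 or 6 positives out of 20 is the
6-day group (group 22 of 28; posterior-predictive mass 0.22 and 0.21
on the calibrated fixture). The stripping fit on one noisy 34-mite
replicate (here ≈ 34 h for both phases) illustrates how strongly
bi-exponential parameters scatter at these observation counts — at 14
scored regions per time point the two rates are barely separable,
which is quantified by the acceptance suite's replicate experiment.

In the library the same pipeline is three calls:

```python
import guanokin as gk

table = gk.generate_dataset(seed=1)                   # ScoreTable
est = gk.estimate_probabilities(gk.dichotomize(table))
dist = gk.predictive_count(gk.expected_occurrence_estimates(), k=5, N=20)
print(dist.mode_index, dist.mode_time_min / 1440)      # 22, 6.0 days
```

## Layout

- `src/guanokin/data.py` — domain types (gut regions, score tables,
  phase landmarks) and plain-text I/O with round-trip serialization
- `src/guanokin/simulate.py` — compartment ODE truth model and ordinal
  score emission
- `src/guanokin/occurrence.py` — Jeffreys-posterior occurrence
  estimates and the log odds-ratio contrast
- `src/guanokin/kinetics.py` — stripping, half-life arithmetic,
  dose/peak relations, power-law cascade
- `src/guanokin/inference.py` — posterior-predictive time-since-feeding
  distributions and nomograms
- `src/guanokin/report.py` — smoothers, phase classifier, hysteresis
  paths, figures
- `docs/methods.md` — model assumptions, calibration and limitations
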