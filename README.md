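# alsurv — multi-event survival analysis of functional decline in ALS

Amyotrophic lateral sclerosis progressively destroys distinct functional
systems — bulbar (speech, swallowing), fine and gross motor
(handwriting, walking), and respiratory (dyspnea) — at different rates
in different patients. `alsurv` predicts *when* a patient will lose each
of five such functions, defined as the first follow-up visit at which
the corresponding ALSFRS-R item (scored 4 = normal … 0 = complete loss)
drops to 2 or less. Each prediction is an individual survival
distribution (ISD): a per-patient curve s_k(t) = Pr(T_k > t) for each of
the K = 5 events over the 500 days following the baseline visit.

The package is an analysis pipeline for biostatisticians working with
right-censored longitudinal functional scores:

- a **synthetic cohort generator** with a known per-event Weibull
  accelerated-failure-time ground truth (real pooled-trial ALS data
  requires a data-use agreement; the generator emulates its structure
  and event frequencies, and makes every downstream stage testable);
- **event annotation** (first score ≤ 2 at a follow-up visit; baseline-
  impaired and history-less patients excluded; 500-day horizon);
- **stratified splitting** (70/10/20, consistent event times and
  censoring rates across splits and events) and train-only
  **preprocessing** (impute, one-hot, z-score);
- six models: Kaplan-Meier baseline, Cox proportional hazards (Efron
  ties), MTLR (discrete-time multi-task logistic regression), a deep Cox
  network, a random survival forest, and a jointly trained **multi-event
  mixture-of-Weibull network** with a shared covariate layer,
  S_k(t|x) = Σ_g w_{k,g}(x) exp(−(t/λ_{k,g}(x))^{a_{k,g}});
- censoring-aware **evaluation**: Harrell's and Uno's concordance,
  integrated Brier score, margin-MAE (censored patients replaced by a
  Kaplan-Meier best-guess time), and D-calibration (χ² uniformity of
  S_i(t_i) over deciles);
- **counterfactual prediction**: flip one covariate (Riluzole, onset
  site, FVC, baseline ALSFRS-R) and compare predicted ISDs, alongside
  group log-rank tests at the Bonferroni-adjusted level 0.05/5 = 0.01.

See `docs/methods.md` for the models, metrics, and generator design.

## Worked example

```bash
python analysis/01_simulate_cohort.py      # 2000-patient cohort -> results/cohort/
python analysis/02_annotate_events.py      # five right-censored outcomes per patient
python analysis/03_benchmark_models.py     # six models x five events x ten seeds
python analysis/04_counterfactuals.py      # individual what-if predictions
```

The first two steps print:

```
wrote 2000 patients, 19276 visit rows to results/cohort/
mean age 55.5 y, 31.5% female, 12.7% bulbar onset, mean baseline ALSFRS-R 39.3
annotated 2000 patients (0 excluded)
event           uncensored %
Speech                 38.0
Swallowing             30.3
Handwriting            50.0
Walking                58.8
Dyspnea                25.4
```

— the cohort reproduces the target demographics and per-event observed-
event fractions (Speech 37.8, Swallowing 31.9, Handwriting 50.3, Walking
60.6, Dyspnea 27.0 in the reference cohort; Walking and Dyspnea sit a
couple of points lower in this 2000-patient draw). The benchmark then
reports, per model × event, Harrell's/Uno's CI and IBS (×100), margin-
MAE in days, and D-calibration passes over the ten splits, ending with

```
  model       event  harrell_ci_mean  ibs_mean  mmae_mean  dcal_passes
     km      Speech            50.00     11.77      71.17           10
  coxph      Speech            87.40      6.82      51.06           10
  mensa      Speech            87.48      6.45      47.91           10
  ...
covariate models with mMAE >= KM: none — all beat the baseline
```

— the covariate-free baseline ranks patients at chance level (CI 50) and
every covariate-based model achieves lower margin-MAE than it on every
event: patient-specific information buys genuinely better time-to-event
estimates. (Concordance runs higher here than on real clinical data
because the synthetic cohort's decline timing is largely predictable
from its baseline profile by design.) The
counterfactual step prints, for one test patient, predicted median days
until each functional loss under each alternative; for example flipping
baseline ALSFRS-R from 45 to 33 moves the predicted Dyspnea median from
424 to 354 days, while flipping Riluzole moves no event's median
appreciably (the generator gives Riluzole zero effect, and the group
log-rank tests agree: p > 0.01 on every event).

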