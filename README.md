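# hrphase

Circadian timing is hard to measure at scale: questionnaires capture a
preference (chronotype), not physiology, and melatonin assays do not
scale to biobank cohorts. `hrphase` implements a wearable-derived
alternative — **heart-rate phase (HRP)** — and the downstream
epidemiological toolkit that connects it to genotypes, the clinical
phenome and type 2 diabetes, for biostatisticians working with
Fitbit-style heart-rate streams, OMOP-coded health records and
genotype tables.

## The model

Each participant's heart-rate samples are averaged into 5-minute bins
mapped to time-of-week (Sunday 00:00 origin), giving a weekly profile
of up to 2016 points. The profile is fit to a fixed-period sinusoid

$$\mathrm{HR}(t) = A\,\sin\!\left(\tfrac{\pi}{720}\,(t-\varphi)\right) + b,$$

with $t$ in minutes and a 24 h (1440 min) period. The phase
$\varphi$ (reported in hours, $[0,24)$) is the ascending mean-crossing
time; the heart-rate peak falls at $\varphi + 6$ h. The fit is linear
in $\{\sin\omega t, \cos\omega t, 1\}$ and therefore closed-form.
Participants are retained when they have heart-rate data on more than
30 days, a sine fit with $R^2$ above a cutoff selected by a Youden-type
index (retention rate $+$ threshold $-\,1$), and a phase within 3 SD of
the cohort mean.

On top of the phase sit four analysis stages:

- **genotype–phase association** — OLS of $\varphi$ on additive allele
  dosage plus age, Y-chromosome presence and five ancestry PCs, with
  sandwich (HC1) standard errors and Bonferroni adjustment over the
  variants passing a 1% alternate-allele-frequency screen;
- **PheWAS** — per-condition logistic regression of case status
  (defined by occurrences of a concept or its descendants within two
  degrees of an OMOP-style hierarchy, conditions with >100 cases) on
  $\varphi$ and covariates;
- **diabetes outcomes** — logistic models of T2DM (unlimited-depth
  concept closure) and of elevated HbA1c (maximum in-range value before
  the end of monitoring, >5.6%), and sex-stratified Cox regression of
  age at diagnosis;
- **Mendelian randomization** — one-sample two-stage residual
  inclusion (2SRI): stage 1 regresses $\varphi$ on the instrument
  dosage and exogenous covariates; stage 2 is a logistic outcome model
  including the stage-1 residual; confidence intervals come from a
  participant-level bootstrap re-fitting both stages.

Because the cohort data this design targets are controlled-access, the
package ships a first-class synthetic-cohort generator
(`hrphase.synthetic`) with a known genotype → phase → disease causal
structure (optionally confounded), so every estimator can be validated
for recovery of its generative truth.

## Worked example

```python
import hrphase as hp

cfg = hp.SimConfig(n_participants=300, n_days=60, seed=7)
rc = hp.RunConfig(seed=7, min_cases=20)
res = hp.run_synthetic_pipeline(cfg, rc, mr_resamples=200)

inc = res.cohort[res.cohort["included"]]
print(f"mean phi {inc['phi'].mean():.2f} sd {inc['phi'].std():.2f}")
print(res.snv_results[["snv_id", "beta_min", "se_min", "p", "p_adj"]]
      .round(4).to_string(index=False))
t = res.t2dm_logistic
print(f"T2DM OR/h {t.odds_ratio:.3f} CI [{t.or_ci[0]:.3f},{t.or_ci[1]:.3f}]")
print(res.mr.summary())
```

prints

```
mean phi 9.25 sd 1.52
   snv_id  beta_min  se_min      p  p_adj
rs1144566  -43.2670 18.2117 0.0175 0.0525
 rs684383    0.1312  8.1090 0.9871 1.0000
rs_null_1    6.6015  9.1658 0.4714 1.0000
T2DM OR/h 1.184 CI [0.883,1.589]
Two-stage residual inclusion (one-sample MR)
==============================================
n participants           278
Stage 1 instrument beta  -0.7223 (exposure/allele)
Stage 1 F-statistic      3.16  [WEAK INSTRUMENT]
...
```

Reading the output: 279 of 300 simulated participants survive the
inclusion filters and their phases centre near the generative mean of
9.48 h. The morningness variant `rs1144566` (simulated at −30
min/allele) comes out at −43 ± 18 min/allele — within sampling error of
truth at this small n — while the null variant is flat. The T2DM odds
ratio per hour of phase points the right way but is not significant at
n = 300, and the MR stage honestly flags that a 2.5%-frequency
instrument is weak in a cohort this small (stage-1 F = 3.2 < 10); at
n = 15,000 the same configuration yields F ≈ 300 and a stable 2SRI
estimate. Statistical power at biobank scale is exactly what the
larger experiments in `scripts/acceptance.py` probe.

The same stages are available as a CLI
(`hrphase simulate | phase | assoc | phewas | t2dm | mr | all`), e.g.

```bash
hrphase simulate --n 200 --seed 1 --out sim/
hrphase phase --hr sim/hr.csv --out cohort.csv
```

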