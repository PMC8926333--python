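# fairconn

Fairness auditing for connectome-based behavioral prediction.

Predictive models that map resting-state functional connectivity (RSFC) to
behavioral phenotypes are usually trained on samples dominated by one
subpopulation. `fairconn` implements the audit that asks whether such models
generalize equally across subpopulations: it builds demographically and
behaviorally **matched test pairs** between a minority and a majority group,
predicts behavior with **kernel ridge regression** under train-only confound
regression, quantifies group-wise accuracy with the **predictive coefficient
of determination** (COD) and its companion bias diagnostics, runs
**permutation inference** on the group accuracy difference, and checks
whether accuracy gaps track the validity of the **model-learned
brain–behavior association patterns**. Everything is exercised end-to-end on
a synthetic-data generator with known ground truth, so each stage is
testable without restricted neuroimaging data.

The package is aimed at researchers who build RSFC-based prediction models
and want to measure — not assume — their cross-population generalization.

## The model and metrics

Let `c_i` be the vectorized Fisher-z RSFC of subject *i* (strict lower
triangle, column-major) and `y_i` the behavioral score. Kernel ridge
regression with the correlation kernel predicts a test subject *s* as a
regularized weighted average of training scores:

    K(c_s, c_i) = Pearson(c_s, c_i)
    alpha = (K + lambda I)^{-1} y_train
    y_hat_s = sum_i K(c_s, c_i) alpha_i

with `lambda` selected by nested, family/site-grouped cross-validation.
Confounds (age, motion, gender, ...) are regressed from both `y` and every
FC edge, with coefficients estimated on training subjects only.

Group-wise accuracy for group *g* on matched test subjects:

    SSE_g = mean_{i in test g} (y_i - y_hat_i)^2
    SST   = mean_{j in matched train pool} (y_j - mean(y))^2   (shared across groups)
    predictive COD_g = 1 - SSE_g / SST

plus the Pearson correlation `r_g`, the **prediction shift**
`(mean(y_hat - y))^2` (a systematic group-level over/under-prediction that
COD penalizes but correlation cannot see), the group behavioral variance,
and Levene's test for variance differences. Significance of the group gap
comes from a **flip-label permutation** (group labels swapped within each
matched pair); predictability of a behavior from a **multilevel block
permutation** of predictions that moves whole families together. The
interpretable pattern behind a fitted model is recovered by the Haufe
inversion, `cov(FC_edge, y_hat_train)`, and compared to each group's true
pattern `cov(FC_edge, y_test_group)`.

## Worked example

The numbered scripts under `analysis/` run the audit on a synthetic
population of 500 subjects (400 majority / 100 minority, 40 ROIs = 780
edges) whose two group weight patterns correlate at r = 0.3:

```bash
python analysis/01_simulate.py    # writes results/dataset/
python analysis/02_match.py       # matched designs + validation
python analysis/03_predict.py     # the full audit bundle
python analysis/04_training_arms.py
python analysis/05_replicate_studies.py
```

`analysis/03_predict.py` prints, per behavior, the matched-group CODs and
the flip-label p value, e.g.:

```
behavior  cod_minority  cod_majority  flip_p  r_minority  r_majority
    beh0        -0.104         0.117   0.343       0.132       0.403
    beh4         0.038         0.144   0.465       0.290       0.399
mean predictive COD by group:
majority    0.084
minority   -0.049
similarity-accuracy correlation across behaviors: 0.198
```

Reading: models trained on the full (majority-dominated) sample predict the
majority group better on every behavior — the mean matched-group COD gap is
about 0.13 — even though the test pairs were matched on confounds and on the
behavior itself; the gap tracks how much better the learned association
pattern matches the majority's true pattern. `analysis/05_replicate_studies.py`
confirms the machinery: both permutation tests hold their 5% level under a
null generator (rates 0.060 and 0.020 at 100 replicates), the majority
advantage appears in 20/20 biased replicates, and training on the minority
alone lifts minority accuracy over majority-only training in 19/20.

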