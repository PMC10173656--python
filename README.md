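# labreduce

Selective ("select and predict") deep-learning recommendation of unnecessary
hemoglobin (Hgb) laboratory tests for hospitalized patients.

Repeated routine blood draws contribute to iatrogenic anemia and cost without
always adding information. `labreduce` trains a multi-task recurrent model
over an inpatient encounter's irregular hourly draws (12 labs, 5 vitals,
demographics, missingness indicators) that predicts, for each upcoming Hgb
test,

* **normality** `y_t` — will the result be at/above the lower bound of the
  age/sex-specific normal range (LBNR)?
* **stability** `z_t` — will it avoid a normal→abnormal drop?
* the **value** `v_t` itself (auxiliary regression), and
* a **selection probability** `p_t` — the model's own confidence that this
  prediction is reliable.

A test is recommended for omission only when all three hold:
`p_t > tau` (selected), predicted normal, predicted stable. The selection
head is trained jointly with the predictors under a coverage-constrained
objective

```
L = alpha * [ r(f_Y) + r(f_Z) + lambda * max(0, c - phi(P))^2 ] + (1 - alpha) * L_aux
phi(P) = mean(p_t),   r(f) = mean(L_bce * p_t) / phi(P)
```

so the model learns to abstain on its least predictable samples while
keeping its realized coverage `phi` pinned to a chosen target `c`. Training
additionally corrupts 10% of observed Hgb inputs at random to simulate the
downstream effect of tests that were skipped; evaluation includes a stepwise
*reduction* protocol that actually zeroes out every recommended-omitted Hgb
from later inputs. A synthetic inpatient-cohort generator (calibrated to
~19.5% normal draws and ~9.2% normal→abnormal transitions) stands in for
private clinical data, so the whole pipeline runs offline.

See `docs/methods.md` for the model, objective, protocols, and the
generator's assumptions and limits.

## Worked example

```python
from labreduce import HgbReductionModel

model = HgbReductionModel.from_synthetic(seed=1)   # calibrated 2000-encounter cohort
results = model.fit(coverage=[0.75, 0.85, 0.95])   # one model per target coverage
print(results.coverage_table())
print(results.summary())
```

Output from this exact run (seed 1; about 7 minutes on one CPU):

```
   target_coverage  model_coverage  abs_diff_pp
0             0.75        0.760188     1.018809
1             0.85        0.839734     1.026646
2             0.95        0.956897     0.689655

Selective Hgb test reduction — held-out evaluation
==================================================================
encounters: train=1600, test=400;  selection threshold tau=0.5
------------------------------------------------------------------
    c  cover%  reduc%  normAUC normAUPRC  stabAUC  stabAcc
 0.75   76.02    0.00    86.69      8.11    97.98    98.61
 0.85   84.44    2.13    96.94     83.77    97.03    97.08
 0.95   95.69    2.88    96.39     85.09    93.18    90.70
------------------------------------------------------------------
cover% = selected share of predictable Hgb draws; reduc% = omitted share of all observed Hgb draws
```

Read: each trained selector's realized coverage lands within ~1 percentage
point of its target. Tight selection (c = 0.75) keeps only the most
reliable candidates — almost all confidently-abnormal draws, so nothing
qualifies as normal-and-stable and no tests are recommended for omission;
loosening the constraint admits the predictable stable-normal runs, and at
c = 0.85 the model recommends omitting 2.1% of all observed Hgb tests under
the stepwise reduction simulation while normality/stability discrimination
on the selected candidates stays high (AUC ~97).

The same pipeline is scriptable from the shell:

```bash
labreduce simulate  --n 2000 --seed 1 --outdir out/data
labreduce preprocess --data out/data --seed 1 --outdir out/prep
labreduce train     --data out/prep --coverage-grid 0.75,0.85,0.95 --seed 1 --outdir out/ck
labreduce evaluate  --checkpoint out/ck --data out/prep --outdir out/eval
labreduce sweep     --checkpoint out/ck --data out/prep --coverage 0.85 --outdir out/sweep
labreduce report    --checkpoint out/ck --data out/prep --outdir out/report
```

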