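# mminet

Network analysis of multimorbidity and health outcomes in
spinal-cord-injury (SCI) survey data.

People living with SCI commonly experience many secondary health
conditions (SHCs) — pressure ulcers, urinary tract infections, autonomic
dysreflexia, depression, chronic pain — alongside pre-existing
comorbidities. A 30-item Multimorbidity Index (MMI-30, the plain sum of
binary SHC indicators) predicts healthcare utilization, health status and
quality of life in this population, but 30 items is long for routine
follow-up. `mminet` implements, as a tested reusable pipeline, the
network-analysis workflow that shortens such an index: it estimates
pairwise Markov-random-field networks over the SHC items and five health
outcomes, identifies items that are *isolated* in the fitted networks and
*null* in bivariate screening, removes them, and verifies with
side-by-side regressions that the reduced index predicts every outcome as
well as the full one.

The package is aimed at rehabilitation-outcomes and health-services
researchers who want to apply (or stress-test) this workflow on their own
survey data, and at methodologists studying when network-driven item
reduction is reliable.

## The models

An undirected network over variables `X_1 … X_p` is a pairwise Markov
random field: an edge `i – j` means `X_i` and `X_j` are dependent given
all other variables. Three estimators cover the data types:

* **GGM** (continuous): graphical lasso; edge weights are regularized
  partial correlations `w_ij = -K_ij / sqrt(K_ii K_jj)` of the selected
  precision matrix `K`, in [-1, 1].
* **Ising** (binary): nodewise L1 logistic regression (eLasso); each
  node's neighbour set is chosen by the extended BIC
  `EBIC = -2l + k ln n + 2 γ k ln p`, and an edge requires selection in
  both directions (AND rule), weighted by the mean coefficient.
* **MGM** (mixed): nodewise L1 regressions, linear or logistic per node
  kind, AND-symmetrized.

Node importance uses strength (Σ|w|), expected influence (Σw) and
weighted betweenness (edge length 1/|w|); their reliability is quantified
by bootstrapped edge intervals and the case-dropping CS-coefficient — the
largest fraction of participants that can be dropped while subsample and
full-sample centralities still correlate ≥ 0.7 with probability ≥ 0.95.

Because the original survey data is restricted, the package includes a
synthetic-cohort generator with planted network structure (a hub item,
five isolated + outcome-unlinked items, correlated outcome scores) so the
whole pipeline is testable against known ground truth; see
`docs/methods.md`.

## Worked example

```python
import mminet as mm
from mminet.mrf import PenaltyPath

result = mm.run_pipeline(mm.PipelineConfig(
    seed=0, path=PenaltyPath(n_points=10, min_ratio=0.05),
))
rep = result.report
print("removed:", sorted(rep.removal_set))
print("retained items:", len(rep.retained_index))
print(result.cohort_results[0].comparison.agreement[
    ["beta_full", "beta_reduced", "p_full", "p_reduced", "sig_match"]
].round(3))
```

prints

```
removed: ['Can', 'DVT', 'Dia', 'HBP', 'LD']
retained items: 25
         beta_full  beta_reduced  p_full  p_reduced  sig_match
outcome
Care         0.137         0.147     0.0        0.0       True
PCS         -0.555        -0.594     0.0        0.0       True
MCS         -0.766        -0.834     0.0        0.0       True
Satis       -0.196        -0.215     0.0        0.0       True
QoL         -0.192        -0.211     0.0        0.0       True
```

The pipeline simulated two survey-like cohorts of 4000 participants,
screened all 30 × 5 item–outcome pairs, fitted the GGM, Ising and MGM
networks, and removed exactly the five planted isolated,
outcome-unlinked items — the analogues of cancer, deep-vein thrombosis,
diabetes, high blood pressure and liver disease — leaving a 25-item
index. In the regression comparison each extra condition raises the odds
of unmet healthcare need by ~15% (`exp(0.137)`) under the full index and
~16% under the reduced one, and lowers the health-status and satisfaction
outcomes by near-identical amounts in both arms — the reduced index loses
no predictive information (its per-item coefficients are in fact slightly
larger, since the removed items contributed only noise to the sum).

A command-line interface wraps the same stages:

```sh
mminet simulate --n 4000 --seed 1 --out cohort
mminet fit --family ising --data cohort.csv --columns AD,Head,Spas,UTI,BI,Cons --out net
mminet shortform --seed 1 --outdir run1
```

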