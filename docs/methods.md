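# Methods

`mminet` implements a network-analysis workflow for multimorbidity survey
data: regularized pairwise Markov-random-field (MRF) estimation over binary
secondary-health-condition (SHC) items and health outcomes, centrality and
bootstrap-stability analysis of the fitted networks, and a network-driven
reduction of a 30-item multimorbidity index (MMI) whose validity is then
checked by side-by-side outcome regressions.

## Survey coding and scoring

SHC items are binary (condition present in the last 12 months). The coding
rule treats a "do not know" response as *not having* the condition; a
missing answer stays missing. The MMI is the unweighted sum of its items,
so a 30-item instrument scores 0–30 and any missing item makes the score
missing. The two ordinal quality-of-life outcomes are dichotomized before
analysis: the 1–6 life-satisfaction item at 5 (1–4 = not satisfied, 5–6 =
satisfied) and the 1–5 overall-QoL item at 4. The 1–5 cut-point is not
dictated by the instrument's documentation; we mirror the top-ratings
logic of the 1–6 item (and the item's observed mean near 3.8) and expose
the cut as a parameter. Missing data are handled complete-case per
analysis: each operation drops the rows missing among its own variables
only. Binary covariates are coded as 0/1 dummies (male = 1, incomplete
lesion = 1, living in own home = 1).

## Network estimators

All three estimators return a symmetric edge-weight matrix with zero
diagonal; an edge encodes conditional dependence between two nodes given
all others. Model selection everywhere uses the extended Bayesian
information criterion

    EBIC = -2 l + k ln n + 2 gamma k ln p,

with `k` the number of nonzero parameters and `p` the number of candidate
predictors (nodewise selection) or candidate edges' nodes (global
selection). The hyperparameter gamma trades sensitivity for false
positives; defaults are gamma = 0.5 for the Gaussian model and 0.25 for
the Ising and mixed models, the common defaults in the
psychometric-network literature. Penalty paths are glmnet-style: by
default 100 log-spaced values from the data-derived maximum penalty down
to 1% of it. The test and acceptance profiles use 10–12 points down to 5%
— EBIC selection on a log-spaced grid is insensitive to this resolution,
and the shorter path keeps resampling studies tractable; the fine-grained
default remains available everywhere. A penalty below 1e-8 is treated as
the unpenalized maximum-likelihood fit.

* **Gaussian graphical model (GGM).** Graphical lasso on the Pearson
  correlation matrix of the coded values (binary 0/1 columns included —
  the workflow this follows did the same and notes it as a limitation;
  a polychoric variant is out of scope). One global penalty is selected by
  EBIC with `k` = number of nonzero off-diagonal pairs; the selected
  precision matrix `K` becomes partial-correlation weights
  `w_ij = -K_ij / sqrt(K_ii K_jj)`, bounded in [-1, 1]. Because one
  global penalty serves all edges, the EBIC minimum sits where shrinkage
  on the strong true edges has resolved, letting a few near-zero spurious
  edges through; by default edges with `|w| < sqrt(ln(p(p-1)/2)/n)` are
  therefore zeroed after selection, the false-positive control
  recommended for this estimator (switchable off, e.g. when studying the
  unpenalized limit). The graphical lasso runs in LARS mode with a
  coordinate-descent fallback; LARS is substantially faster on these
  correlation matrices and returns the same selected support.
* **Ising model.** Nodewise L1-penalized logistic regression ("eLasso") on
  0/1 items, each node's neighbour set selected by EBIC with p-1 candidate
  predictors; continuous variables are excluded upstream. Edges are
  symmetrized with the AND rule (both directions must select the pair; OR
  available) and weighted by the mean of the two directional coefficients.
  The 0/1 domain (not ±1) with fields as intercepts makes the simulator
  and estimator conjugate, so recovery is exact in the large-n limit.
  Logistic fits use liblinear with `intercept_scaling = 50`, which keeps
  the intercept effectively unpenalized, and a fixed internal shuffle seed
  so repeated fits are bit-identical.
* **Mixed graphical model (MGM).** Nodewise L1 regressions — linear for
  continuous responses, logistic for binary — with continuous columns
  z-standardized first; AND-rule symmetrization as above. Only binary and
  continuous nodes are supported.

Node sets in the pipeline follow the study design: the GGM uses the 30
SHCs plus all five outcomes; the Ising network the SHCs plus the three
binary outcomes; the MGM additionally includes age.

## Centrality and stability

Strength is the absolute sum of a node's edge weights, expected influence
the signed sum (one-step version — the definition used is the single-step
one), and betweenness the fractionally credited count of weighted
geodesics through the node with edge lengths 1/|w| (Brandes convention
for ties). Both raw and z-standardized values are reported since plotted
conventions differ.

Stability follows the standard bootstrap workflow: (i) nonparametric row
bootstrap of the edge weights with percentile 95% intervals, where two
edges (or two nodes' centralities) differ significantly if the interval of
their bootstrapped difference excludes zero; (ii) case-dropping
subsampling over the grid {0.05, …, 0.75}, correlating subsample
centralities with the full-sample ones (Pearson; Spearman for the heavily
tied, zero-inflated betweenness). The CS-coefficient is the largest drop
proportion at which that correlation stays ≥ 0.7 with probability ≥ 0.95,
with a prefix rule (every smaller drop proportion must also qualify) so
non-monotone curve noise cannot inflate it. Defaults are B = 1000 edge
bootstraps and B = 250 subsamples per grid point; the test profile uses
50, the published scaled-down profile for this workflow. Resamples whose
refit fails are dropped and counted; a report with more than 10% failures
is flagged unstable.

## Short-form derivation

Candidate items for removal come from two evidence streams: (i) the
*bivariate null set* — items non-significant against **all five** outcomes
in the screen (chi-square for binary outcomes, Fisher's exact when any
expected cell count is below five; pooled t-test for continuous outcomes,
Mann–Whitney when Shapiro–Wilk at alpha = 0.05 rejects normality in either
group, group size capped at 5000 for the check; alpha = 0.05 two-sided
throughout, no multiplicity correction, matching the workflow being
implemented); and (ii) *network isolation* — zero degree in a fitted
model, by exact-zero criterion. The default combination rule removes
items that are bivariate-null **and** isolated in at least one fitted
model. The source workflow never states its Boolean explicitly; this
reading treats nullity as necessary and isolation as corroborating, which
is the only rule consistent with its retention of isolated but
outcome-associated items. The rule is configurable
(`null_only`, `isolated_in_all`) and recorded in the report. The pipeline
analyses each cohort separately and unions the per-cohort removal sets
into one generalized reduced index, then refits all five outcome models
with the full and reduced index on identical complete-case rows and
reports sign/significance agreement of the index term. Logistic models
report Wald odds-ratio intervals exp(beta ± 1.96 SE).

## Synthetic cohorts

The survey data this workflow was developed on is restricted, so the
package ships a generator whose planted truth makes every downstream
stage testable. The default cohort emulates the qualitative structure of
the real data:

* 30 binary SHC items Gibbs-sampled from a 0/1 Ising truth with
  exclusively positive couplings (multimorbidity items associate
  positively), a hub item `AD` with six couplings, one strong pair
  (`EP`–`SP`), a connected positive background in which every retained
  item has at least two couplings, and five isolated items
  (`Can`, `DVT`, `Dia`, `HBP`, `LD`) with no couplings;
* the five isolated items are also excluded from the outcome-linked
  condition count, making them isolated *and* outcome-unlinked — the
  planted ground truth for the short-form removal set;
* outcomes driven by `outcome_effect` × (centered linked-condition count)
  — default 0.2 per condition on each linear predictor, the scale of the
  index coefficients reported for such surveys — plus a shared standard
  normal "wellbeing" factor whose loadings reproduce the outcome
  intercorrelations published for community health surveys (satisfaction
  and QoL single items r ≈ 0.6–0.7 before dichotomization, mental-health
  score vs satisfaction ≈ 0.5, physical score and the unmet-care flag
  more weakly related). The two overall-satisfaction items threshold one
  shared latent score at their own fixed cut-points (both rate the same
  construct); the depression item additionally lowers the mental-health
  score directly (the planted depression–MCS association);
* covariates (age, sex, lesion completeness, days since injury, living
  setting) drawn independently with survey-like margins.

The Gibbs sampler runs one independent chain per row for `burn_in + thin`
full sweeps (default 200), so rows are independent draws; its pairwise
moments are validated against exhaustive state enumeration for small
systems. The Gaussian sampler draws from the covariance obtained by
inverting the unit-diagonal precision I − W, so the population partial
correlations equal the planted weights exactly. The mixed sampler draws
the binary block by Gibbs and the continuous block from the conditional
Gaussian; planted truths for it avoid binary nodes sharing continuous
neighbours so the conditional couplings equal the planted matrix.

What the generator deliberately does **not** emulate: the survey's exact
per-item prevalences (only their order of magnitude), item-level
measurement error, informative missingness, and sampling weights. Passing
recovery tests on these cohorts therefore demonstrates correctness of the
estimators and the derivation logic under a realistic correlation
structure, not reproduction of the original survey's fitted networks —
which are not reproducible without the restricted data.

## Problem sizes and numerical choices

Tests and the acceptance script use: edge-recovery studies at n = 5000,
p = 10 (100 seeds in the test suite, 30 in the acceptance script);
stability studies at B = 50 subsamples per grid point; the end-to-end
study at the default two cohorts of n = 4000 over 40 (tests) or 12
(acceptance script) seeds. Near-zero coefficients (|w| < 1e-8) are
truncated to exact zeros so the exact-zero isolation criterion is
well-defined; EBIC ties break toward the sparser model; weight matrices
are symmetrized by averaging and re-checked for symmetry on construction.

## Known limitations

* The exact-recovery rate of the five-item removal set is bounded by the
  screen's type-I error: an outcome-unlinked item must clear five
  5%-level tests in at least one cohort, so with moderately correlated
  outcomes the per-study exact-match probability has a structural ceiling
  around 0.8–0.9 under the default two-cohort union; this is a property
  of the screening rule (alpha = 0.05, no multiplicity correction,
  all-outcome nullity required), not of the estimators.
* GGM on binary items uses Pearson correlations, inheriting the
  well-known attenuation of phi coefficients; its isolation calls are
  correspondingly noisier than the Ising model's (the pipeline compensates
  by requiring isolation in only one of the three models).
* Ordinal variables with more than two levels are not supported as MGM
  nodes; they are dichotomized upstream.
* Betweenness on sparse survey networks is heavily zero-inflated; its
  drop-curve correlation uses Spearman, and its CS values should be read
  qualitatively.
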