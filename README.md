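# otsa — ensemble ligand-based off-target prediction

Most small molecules bind proteins beyond their intended pharmacological
target, and these off-target interactions are a leading cause of
safety-related attrition in drug discovery. `otsa` implements an
off-target safety assessment workflow for computational toxicologists and
cheminformaticians: six orthogonal ligand-centric target-prediction methods
are scored against a reference bioactivity database, aggregated into a
consensus pseudo-score, filtered by tissue expression, and summarized in a
reproducible off-target pharmacology report. A physicochemical promiscuity
profiler and a cohort-comparison statistics battery round out the analysis,
and a synthetic chemogenomics generator provides ground-truth benchmarks so
the whole stack is testable offline.

## The method

For a query molecule *q* and each target *t* with active ligand set *A(t)*,
six methods produce scores *m_i(q, t) ∈ [0, 1]*:

- **SIM** — nearest-ligand similarity:
  `max_{a∈A(t)} mean(Tc(q,a), PHRAG(q,a), exp(−‖SHED(q)−SHED(a)‖/σ))`,
  combining Morgan-fingerprint Tanimoto, pharmacophore-fragment multiset
  Tanimoto and Shannon-entropy descriptor distance.
- **SEA** — set-wise similarity: raw score
  `RS(q, A(t)) = Σ Tc·1[Tc ≥ τ_T]`, standardized by a random-set background
  with power-law mean and spread in `n₁n₂`, then
  `p = 1 − exp(−exp(−zπ/√6 − γ))` (extreme-value tail) and `E = p·N_targets`.
- **SAS** — similarity active subgraph: a minimal pharmacophore-labelled
  subgraph frequent (≥ 80 %) in a target's actives and rare (≤ 10 %) in a
  background sample; a match scores 0.6 plus a specificity bonus.
- **SAR** — per-target regularized logistic classifier on standardized
  FPD ⊕ SHED ⊕ global-property vectors, actives versus sampled decoys.
- **MLM** — per-target consensus of three classifiers on FPD vectors
  (random forest, calibrated kernel SVM, small feed-forward network); the
  mean probability counts only when ≥ 2 of 3 vote positive.
- **XPI** — cross-pharmacology index
  `X(t,u) = |A(t) ∩ A(u)| / min(|A(t)|, |A(u)|)`, propagating the query's
  nearest-neighbour similarity through shared-ligand links.

The pseudo-score is the weight-normalized mean of the present method scores;
a pair present in the training corpus scores exactly **1.00** (certainty).
An interaction is high-confidence when **≥ 3 of the 6 methods score ≥ 0.6**.
Passing interactions are classified as *training-set*, *confirmed* (present
in a supplied truth table) or *new*, and the report computes totals,
per-method coverage fractions, the all-six-methods fraction and mean
interactions per compound. All methods operate on the stereo-stripped 2-D
graph, so enantiomers are intentionally indistinguishable.

## Worked example

Generate a synthetic benchmark, predict, and evaluate recovery of the
withheld ground truth:

```sh
otsa simulate --out fixtures --seed 17
otsa predict --db fixtures/activity.tsv --query fixtures/queries.tsv \
             --seed 17 --out report
otsa evaluate --db fixtures/activity.tsv --queries fixtures/queries.tsv \
              --truth fixtures/truth.tsv --seed 17 --out metrics.json
```

`simulate` prints `wrote 220 compounds, 8 targets, 32 withheld queries`:
eight targets each own two chemotype series of twelve decorated scaffolds,
three series plant 30 % of their members onto an off-target, 60 decoys fill
the background, and 20 % of every series is withheld as queries. `predict`
reports 38 consensus-passing interactions for the 32 queries (mean 1.2 per
compound), and the head of `report/predictions.tsv` shows a withheld
chemotype member recovering its own target at rank 1:

```
mol_id   rank  target_id  pseudo_score  n_methods_above  consensus_pass  provenance
c0_0_2   1     t0         0.8961        5                True            new
c0_0_2   2     t4         0.8402        5                True            new
```

`t0` is the member's primary target and `t4` its planted off-target.
`evaluate` prints `"recall": 1.0, "precision": 0.89`: every expected
(query, target) pair — primary and planted — passes the consensus filter,
with four extra predictions arising from genuine scaffold cross-similarity.

The same molecules can be profiled (`otsa profile`) and two cohorts compared
descriptor-by-descriptor (`otsa compare`), yielding a table of group means,
medians, SDs, ANOVA/Welch/Wilcoxon/Tukey p-values and Benjamini–Hochberg
q-values at FDR 5 %.

## Layout

- `otsa.chemdata` — molecule / table I/O and the canonicalization contract
- `otsa.descriptors` — pharmacophore typing, PHRAG / FPD / SHED, fingerprints
- `otsa.predictors` — the six methods and their fitting
- `otsa.ensemble` — pseudo-score, consensus, classification, reporting
- `otsa.physchem` — properties, 3/75 and rule-of-five, promiscuity bins
- `otsa.stats` — the cohort-comparison battery
- `otsa.synthetic` — benchmark generator and recovery evaluation
- `docs/methods.md` — modelling assumptions, parameters and limitations
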