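# Methods

This note records the modelling choices behind the package: what each
component computes, the parameters that matter, what the synthetic benchmark
does and does not show, and the places where the design was genuinely open.

## Canonicalization contract

Every module operates on the stereo-stripped 2-D heavy-atom graph. Stereo
descriptors and isotope labels are removed before canonical SMILES
generation, so an enantiomer pair is one compound; this is a deliberate
property of 2-D ligand-based methods, not a loss of fidelity to be fixed.
Mixture and salt records are reduced to their largest fragment, and the
reduction is noted in the parse report — tautomer enumeration and further
standardization are out of scope. Compounds are deduplicated by canonical
SMILES on loading (first identifier wins, aliases recorded), and activity
labels are strictly binary; the optional potency column is carried but never
used by the predictors, which perform qualitative binding prediction.

## Pharmacophore typing

Six recognition elements are assigned per heavy atom: donor (N–H or O–H),
acceptor (neutral O; N with an available lone pair — amide, nitro-type and
pyrrole-type nitrogens excluded), hydrophobe, aromatic, positively ionizable
(aliphatic amines, amidines, quaternary N) and negatively ionizable (oxygens
of carboxylic / sulfonic / phosphonic acids). The hydrophobe rule admits any
carbon with fewer than two heteroatom neighbours: a carbinol carbon is still
a hydrophobe, while carboxyl, amide and nitro carbons are not. This keeps
hydrophobic path fragments contiguous across typical substituents while
excluding the centres of polar functional groups. A four-feature variant
(D/A/H/R only, 10 pairs) is available behind `four_feature_variant` for the
original entropy-descriptor convention.

## Descriptors

* **FPD** counts unordered feature pairs by topological distance, one bin per
  bond count up to the cap `L = 10` (longer distances pool into the last
  bin), normalized to frequencies. Featureless molecules yield a flagged
  all-zero vector.
* **SHED** is the Shannon entropy (nats, unnormalized) of each pair's
  distance distribution; an empty or point-mass distribution has entropy 0,
  and every entry lies in [0, ln L]. Vectors are compared by Euclidean
  distance.
* **PHRAG** reads feature-label sequences along all shortest paths of 2–7
  atoms; each fragment string uses the lexicographically smaller reading
  direction, making the multiset invariant under atom renumbering. Multisets
  are compared by Σmin/Σmax (multiset Tanimoto).
* The **fingerprint** is a hashed circular (Morgan) fingerprint, radius 2,
  2048 bits. Radius 2 was chosen as the default operating point for the
  small, decoration-scale differences the benchmark probes; radius 3 is one
  config field away. Two empty fingerprints define a similarity of 0.

## The six methods

**SIM** combines its three channels by mean-of-three then max-over-ligands.
Mean was chosen over max so that a single coincidentally matching channel
cannot dominate; the combination is config-exposed through `sigma_s` (the
SHED decay scale, default 1.0).

**SEA** sums pairwise Tanimoto values at or above `tau_T = 0.57` between the
query and a target's ligand set. The background samples 300 random set pairs
with sizes log-uniform in [2, min(200, n/2)], bins the raw scores by the
set-size product in 12 log-spaced bins, and fits power laws μ(x) = a·x^b and
σ(x) = c·x^e by least squares on logs. The standardized score feeds the
extreme-value tail p = 1 − exp(−exp(−zπ/√6 − γ)) and E = p·N_targets. The
score mapping s = min(1, −log10 E / 40) for E < 1 puts only very strong
E-values (≤ 1e−24) above the 0.6 consensus threshold; on the desk-scale
benchmark SEA therefore contributes sub-threshold supporting scores rather
than consensus votes, which the evaluation reports honestly as zero SEA
coverage. A degenerate background (all raw scores zero) aborts with advice
to lower `tau_T`.

**SAS** mines, per target, a minimal connected feature-labelled subgraph
that is frequent among actives (`f_a = 0.8`) and rare in a size-matched
random background sample (`f_b = 0.1`). Because a target's actives may span
several chemotype series — under which no single pattern can reach 80 %
support over the union — mining is seeded per similarity cluster
(deterministic leader clustering at Tanimoto 0.6): candidates are connected
subgraphs of the cluster's smallest member, grown from size 2 upward, and
the first size with a qualifying pattern wins (minimality). Up to three
patterns are stored per target, largest clusters first. A query matching a
pattern (labelled subgraph monomorphism) scores 0.6 + 0.4 × background
specificity; no match scores 0.

**SAR** fits a class-weighted L2 logistic regression per target on
standardized FPD ⊕ SHED ⊕ global-property vectors. **MLM** fits three
classifiers on FPD vectors alone — a 100-tree random forest, an RBF-kernel
SVM with calibrated probabilities, and a 16-unit single-layer perceptron —
and scores the mean probability when at least two vote positive at 0.5,
otherwise capping the score at 0.45 (below the consensus threshold by
construction). Both use 1:3 positive:decoy sampling from other targets'
actives, excluding (i) the target's own actives, (ii) actives of targets
with cross-pharmacology index above 0.8, and (iii) compounds with
fingerprint Tanimoto ≥ 0.6 to any active of the target. The third exclusion
extends the index-based rule to the compound level: planted cross-active
chemotype members would otherwise enter the negatives with descriptors
identical to positives and poison the decision boundary. Targets with fewer
than `min_actives = 5` ligands are skipped by SAS/SAR/MLM but remain
scoreable by SIM/SEA/XPI.

**XPI** links targets through shared actives and scores
`max_u simNN(q, A(u)) · X(u, t)`; since X(t, t) = 1, a target's own
nearest-neighbour similarity is always a lower bound.

## Consensus and reporting

Per-method scores below `report_floor = 0.2` are not emitted; absent scores
are excluded from the pseudo-score mean rather than counted as zeros (a
target unscoreable by one method is not thereby penalized; the alternative
is behind `absent_as_zero`). The threshold comparison is inclusive (≥ 0.6),
with the strict variant behind `tau_comparator`. Training-set membership
means an exact canonical-SMILES match with an active annotation —
near-duplicates are never training matches. Rankings sort by descending
pseudo-score, then methods-above-threshold, then target id, so reports are
byte-reproducible. Expression filtering keeps targets absent from the
matrix, flagged `expression_unknown`: the filter removes only where data
exists. Query-target pairs with no method signal at all are counted in a
`no_signal_pairs` tally rather than silently dropped.

## Physicochemical profiling

MW, Crippen clogP, Ertl TPSA and rotatable bonds come from standard
atom/fragment contribution schemes; donor/acceptor counts reuse the feature
table above. pKa is a representative-value lookup by ionizable-group pattern
(aliphatic amine 10.6, amidine 12.5, imidazole 7.0, pyridine 5.2, aniline
4.6; carboxylic acid 4.2, sulfonic −0.6, phosphonic 1.9, phenol 10.0,
tetrazole 4.9), reporting the most basic and most acidic site — bins are
what the downstream analysis needs, not full microstate prediction. logS is
an ESOL-type linear estimate
(0.16 − 0.63·clogP − 0.0062·MW + 0.066·rot − 0.74·aromatic fraction); it is
a stated in-package estimator, so absolute solubility values carry its
error. clogD and cell-permeability predictions are not computed. Rule
boundaries: 3/75 compliance is clogP ≤ 3 and TPSA ≥ 75 Å² (both inclusive);
rule-of-five violations count MW ≥ 500, clogP ≥ 5, HBD > 5, HBA > 10
(Lipinski's original "more than" convention for the count rules); the
basicity flag is pKa(basic) ∈ [7, 10]. Promiscuity cross-tabulates
consensus-passing non-training off-target counts against MW bins
(<200, 200–300, 300–500, 500–700, >700), TPSA bins of width 50 and clogP
bins of width 1 with a top bin ≥ 7, reported as percentages per axis.

## Statistics battery

Group summaries use the n−1 sample SD (defined as 0 for n = 1, flagged) and
midpoint medians. The battery per descriptor: one-way ANOVA, pairwise
Welch tests, pairwise Wilcoxon rank-sum tests and Tukey HSD. Wilcoxon
p-values are computed by exact enumeration of the rank-sum distribution
(midranks for ties) when both groups have n ≤ 10 — feasible at C(20,10)
assignments — and by the tie-corrected normal approximation otherwise. The
"pairwise Welch" phrase is implemented as Welch's two-sample test per group
pair feeding the multiplicity correction. Benjamini–Hochberg q-values are
step-up with monotonicity enforcement; significance is called on q ≤ 0.05,
and both raw and adjusted values are emitted. Identical constant groups
return p = 1 with a degenerate flag. Violin-style output is a
kernel-density summary table; rendering is left to the caller.

## Synthetic benchmark

The generator emulates a curated chemogenomics corpus at desk scale. Default
conditions: 8 targets across 5 families, 2 chemotype series per target, 12
members per series (a family-typical scaffold of 10–20 heavy atoms with one
small enumerated decoration), 60 decoy compounds, 20 % of each series
withheld as queries, and three planted cross-activities copying 30 % of a
series onto an off-target. These sizes make within-series similarity high
(easy for SIM/XPI), require generalization from SAR/MLM, and keep a full
fit-and-score cycle around ten seconds on one CPU; the withheld fraction and
planting fraction are spec fields. Generation is deterministic by seed with
sorted iteration everywhere.

What passing tests show: the pipeline recovers engineered ground truth —
near-duplicate actives, clean series separation, planted polypharmacology —
with high recall and precision. What they do not show: performance on real
chemical space, where series overlap, activity cliffs, assay noise and
database incompleteness dominate; the benchmark makes no attempt to mimic
real bioactivity-database distributions.

## Numerical and degenerate-input conventions

Distances on disconnected fragment pairs carry no descriptor signal; the
double exponential in the extreme-value tail is overflow-guarded; all
emitted scores are clipped to [0, 1]; featureless molecules and empty
fingerprints define similarity 0 with flags rather than errors; ties in
every ranking and mining step break lexicographically. Every stochastic step
(decoy sampling, background set sampling, classifier initialization) takes
an explicit seed, default 17.

## Known limitations

The methods are stereo-blind and isoform-coarse by construction; targets
with very few ligands are invisible to three of the six methods; the SAS
miner assumes the discriminating motif is a connected subgraph of a cluster
member; pKa and logS are pattern/linear estimates unsuited to absolute
comparisons against measured values; and the consensus threshold calibration
transfers to other databases only insofar as their score distributions
resemble the defaults documented here.
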