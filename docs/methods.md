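# Methods

This note documents the models and procedures implemented in `lfflnet`, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot tell you about real cohorts.

## Network model and motif enumeration

The regulatory network is a typed directed graph over three node classes
(TF, miRNA, lncRNA) and three edge classes (TF→miRNA, TF→lncRNA,
miRNA→lncRNA).  Node classes are inferred from the position an identifier
occupies in its edges; an identifier implied to be two classes raises a hard
error rather than a warning, because a silently misclassified node corrupts
every downstream motif.  Duplicate interaction rows are collapsed — multiple
binding-site hits for the same regulator/target pair count once.  Edge
direction is structural only; activation versus repression is not modelled,
which is consistent with the downstream scores using absolute correlation
differences.

An L-FFL motif is any triple (t, m, l) whose three typed edges all exist.
Enumeration walks each TF's miRNA and lncRNA target sets and intersects the
miRNA's lncRNA targets, which is exact (tested against an exhaustive triple
loop) and linear in the number of realised triangles.  Motif lists are
sorted lexicographically so ranks and output files are reproducible.

## Topology diagnostics

Degree, clustering coefficient, topological coefficient and the
degree-binned neighbourhood-connectivity distribution are computed on the
undirected projection, the convention under which these metrics are
classically defined (Cytoscape NetworkAnalyzer).  The topological
coefficient of node *n* with *k*ₙ neighbours averages
(shared neighbours + adjacency bonus)/*k*ₙ over all nodes sharing at least
one neighbour with *n*.  Nodes with *k* < 2 get a missing (not zero)
clustering/topological coefficient and are excluded from averages.  The
degree distribution is summarised by an OLS fit of log₁₀(count) on
log₁₀(degree) over nonzero bins; a clearly negative slope is reported as the
scale-free-like signature.  No formal power-law hypothesis test is
performed, and the package deliberately does not declare "small-worldness" —
it exposes the metrics and leaves the label to the analyst.

## Dysregulation scoring

All tests and correlations operate on log2(x + 1)-transformed values:
RPKM-like data are non-negative and heavy-tailed, and the log transform
keeps the t-statistics and Pearson correlations well behaved.

* `score_diff = p_t p_m p_l`, the product of the three transcripts'
  two-sided differential-expression P-values.  The unpaired test is Welch's
  t-test (no equal-variance assumption); the paired t-test is used when
  requested and at least 80% of tumour samples have a patient-matched
  normal.
* `score_cor = |(C_tm − N_tm)(C_tl − N_tl)(C_ml − N_ml)|`, the absolute
  product of tumour-minus-normal correlation differences over the motif's
  three edges.  It is zero whenever any single edge is unchanged — the score
  demands rewiring of the *whole* triangle.
* Rank aggregation: ascending ranks of `score_diff`, descending ranks of
  `score_cor`, average ties, final score = mean of the two ranks.  Mean
  versus sum is order-equivalent; the mean keeps the score on the
  interpretable [1, M] scale.

Degenerate inputs are defined away rather than fatal: a zero-variance
transcript gets P = 1 and correlation 0 (with warnings), so degenerate
motifs sink in the ranking.  P-values are floored at 1e-300 so score
products stay strictly positive in floating point.

### Permutation null

Tumour/normal labels are permuted jointly across the three matrices (the
samples are shared), B times, and the per-motif empirical P-value uses the
(1 + count)/(B + 1) estimator, so P ∈ [1/(B+1), 1] and is never zero.

The reference frame for the permuted final score is the one genuinely open
design choice.  Re-ranking *all* motifs against each other inside every
permutation makes any motif's permuted final score approximately uniform on
the ranks {1..M}, so perm_p ≈ observed rank/M and at most ≈ αM motifs can
ever be significant regardless of effect size — with several strong motifs
present, all but the top few are structurally undetectable.  The default
here is therefore an **insertion null**: motif *m*'s permuted
(score_diff, score_cor) pair is ranked against the *observed* scores of the
other motifs, measuring where a null realisation of *m* would land in the
observed field.  Under a global null this is calibrated (perm_p is uniform;
the acceptance suite verifies the 5% false-positive rate within [2%, 8%]),
and simultaneously all planted strong motifs reach the P floor.  The
re-ranked variant (`null_mode="reranked"`) and a pooled variant
(`null_mode="pooled"`) remain available.

Pairing and label permutation are mutually incompatible (permuting labels
breaks pairs), so a paired fit reports rank-based scores without
permutation P-values, with a warning.

An FDR column (Benjamini-Hochberg over perm_p) is emitted for information
only; the dysregulated flag uses the raw permutation P < α, default 0.05.

## Cross-cancer comparison

Common = dysregulated in ≥ 2 cancers, specific = exactly 1; motifs flagged
nowhere are excluded.  Matrix rows are ordered by descending cancer count,
then lexicographically.  The union sub-network is induced by the union of
flagged motifs; node attributes carry the degree and the number of cancers
the node participates in.  Cross-talk finders are pure structural joins:
L-M-FFL pairs share (TF, miRNA); ceRNA pairs share (miRNA, lncRNA).  ceRNA
triples are consumed as a provided table and never re-derived.  M-FFL
scoring, when wanted, reuses the dysregulation machinery verbatim with
mRNAs occupying the target slot.

## Survival model

Covariates are log2(x + 1)-transformed and z-scored over tumour samples
before the Cox fit, so the three coefficients — and hence the integrated
risk score — are on a comparable scale across transcripts.  Fitting uses
lifelines' `CoxPHFitter` with the Efron approximation for tied event times.
Preconditions: ≥ 10 events, no zero-variance covariate (error names the
transcript); non-convergence yields a flagged result that downstream steps
refuse.  The integrated risk score is the coefficient-weighted sum of
standardized expression; the median split sends ties to the low-risk group;
the two-group comparison is the standard log-rank test with Kaplan-Meier
curves (blue = low risk, red = high risk in the plots).  Per-component
log-rank P-values (median split on each standardized transcript alone) are
reported so the motif's added value over any single transcript is visible.
Patients with missing or non-positive follow-up are dropped with a logged
count.  No adjustment for clinical covariates (age, stage) is made.

## Synthetic-data generator

The generator's defaults are the package's study conditions:

* **Sizes** — 15 TFs, 40 miRNAs, 40 lncRNAs: regulatory networks of this
  kind have far fewer TFs than targets.  Layer densities 0.12/0.12/0.14
  yield on the order of 50–80 motifs; the null scenario uses
  0.15/0.15/0.20 (uniform attachment) for ≈ 100 motifs.  30 tumour and 30
  normal samples per cohort; the survival scenario uses 80 tumours
  (tumour ≫ normal, as in public cancer cohorts).
* **Expression** — background log2 expression N(5, 1), i.i.d. across
  transcripts (independence is conservative for false-positive
  calibration).  A planted motif draws its triple from per-condition
  trivariate normals: tumour mean shifted by δ·SD, equicorrelation
  ρ_tumor in tumours versus ρ_normal in normals.  A 3-variable
  equicorrelation matrix is positive definite only for ρ > −1/2, so the
  strongest feasible anti-correlated normal state is ρ_normal ≈ −0.45,
  which the strong scenarios use against ρ_tumor = +0.8 (per-edge
  correlation difference 1.25, score_cor ≈ 1.95); infeasible requests raise
  an error suggesting a feasible value.  Values are exported as
  2^log − 1 (floored at 0) so the pipeline's log2(x + 1) recovers the
  generative scale exactly; matching real RPKM marginals is a non-goal.
* **Survival** — exponential event times with hazard λ₀·exp(Σβᵢxᵢ),
  λ₀ = 10⁻³ per day (median ≈ 700 days at β = 0), true betas (1, −1, 0.5),
  uniform censoring tuned by bisection to a 30% censored fraction.
* **Scenarios** — `null`, `planted_weak` (δ = 0.5), `planted_strong`
  (δ = 2), `survival_linked`, `multi_cancer` (three cohorts sharing one
  network, with planted motifs overlapping so the common/specific
  classification is exercised; one motif is planted in all three cohorts,
  one in two, and the rest in single cohorts).

Everything derives from a single seed through named `SeedSequence` streams;
fixtures are byte-identical across reruns.

What passing tests on these data do **not** show: robustness to count-level
noise (negative binomial overdispersion), batch effects, copy-number
confounding, correlated background transcripts, or non-proportional
hazards.  Real-data behaviour on those axes is untested by construction.

Note that planting a mean shift on one transcript genuinely dysregulates
*every* motif containing it (its P-value enters their score_diff), so in
planted scenarios the set of truly non-null motifs is larger than the
planted list; recovery is therefore measured on the planted motifs and
false-positive calibration only on fully null scenarios.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use deliberately modest problem
sizes — 20 seeds × B = 200 permutations for calibration/power, 100 (tests)
or 50 (script) replicates at n = 400 for Cox recovery, 150–200 replicates
for log-rank properties — chosen so a full run completes in about a minute
while keeping Monte-Carlo error well inside the asserted margins.  Tie
handling is "average" everywhere ranks are computed; all sorts are stable
(mergesort) with lexicographic motif tie-breaks, which is what makes output
files byte-reproducible.

## Known limitations

* The insertion null treats the observed scores of *other* motifs as a
  fixed reference; with very few motifs (M ≲ 10) the rank lattice makes
  perm_p coarse.
* score_cor's all-edges product means a motif rewired on only two of three
  edges scores zero on that axis; this is faithful to the score's
  definition, not a bug.
* Raw permutation P < α across motifs is the flagging rule; no
  multiple-testing correction is applied to the flag (the BH column is
  informational).
* The CLI's `compare` path classifies motifs from pipeline output, whose
  ~5% per-cohort false-positive rate means occasional background motifs in
  the common/specific lists — exact agreement with a generative truth is
  only expected when classification is run on true dysregulated sets.
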