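# lfflnet

Analysis of **lncRNA-mediated feed-forward loops (L-FFLs)** in cancer
transcriptomes.  An L-FFL is a three-node regulatory motif in which a
transcription factor (TF) regulates a microRNA, and both the TF and the
miRNA regulate a common target long non-coding RNA:

```
        TF ──────► miRNA
         │           │
         ▼           ▼
        lncRNA ◄─────┘
```

`lfflnet` is for computational biologists who have (or can simulate) three
directed interaction tables (TF→miRNA, TF→lncRNA, miRNA→lncRNA) and matched
tumour/normal expression cohorts, and want to know **which motifs are
dysregulated in a cancer, which are shared across cancers, and which predict
patient survival**.

## The method

For every motif *(t, m, l)* and cohort, on log2(x+1) expression:

* **Expression-shift score** — Welch (or paired) t-tests give per-transcript
  differential-expression P-values and

  *score*<sub>diff</sub> = *p*<sub>t</sub> · *p*<sub>m</sub> · *p*<sub>l</sub>  (small ⇒ coordinated shift).

* **Co-expression-rewiring score** — Pearson correlations of the three motif
  edges, within tumours (*C*) and within normals (*N*):

  *score*<sub>cor</sub> = |(*C*<sub>tm</sub> − *N*<sub>tm</sub>)(*C*<sub>tl</sub> − *N*<sub>tl</sub>)(*C*<sub>ml</sub> − *N*<sub>ml</sub>)|  (large ⇒ rewired).

* **Rank aggregation** — motifs are ranked under each score (ties averaged)
  and the final score is the equally weighted mean of the two ranks.

* **Permutation significance** — tumour/normal labels are shuffled jointly
  across the three matrices; each motif's permuted final score is compared
  with its observed one and P = (1 + #better) / (B + 1).  Motifs with
  P < α (default α = 0.05, B = 1000) are *dysregulated*.

Across cohorts, a motif dysregulated in ≥ 2 cancers is **common**, in exactly
one **specific**.  Structural cross-talk with mRNA-mediated FFLs (shared TF +
miRNA) and ceRNA triples (shared miRNA + lncRNA) is enumerated from provided
tables.  Prognostic value is assessed per motif by a multivariate Cox fit on
the three (standardized) transcripts, the coefficient-weighted **integrated
risk score** β<sub>t</sub>x<sub>t</sub> + β<sub>m</sub>x<sub>m</sub> + β<sub>l</sub>x<sub>l</sub>, a median split into
high/low-risk groups, and a Kaplan-Meier log-rank test.

A fully seeded synthetic-data module generates three-layer networks with
heavy-tailed regulator degrees, expression cohorts with planted mean-shift
and correlation-rewiring effects, and survival times with motif-linked
hazards, so the whole pipeline is testable end to end.

## Worked example

```python
from lfflnet import make_fixture
from lfflnet.pipeline import PipelineConfig, run_cohort

make_fixture("planted_strong", seed=7, outdir="fixture")   # 5 planted motifs
config = PipelineConfig.from_fixture("fixture", "results",
                                     n_permutations=1000, seed=7)
res = run_cohort(config, "COHORT1")
print(res.summary(top=6))
```

```
Motif dysregulation results
============================================================
cohort:          COHORT1
motifs scored:   70 (0 dropped, no expression)
permutations:    1000 (null=insertion, seed=2083679832)
alpha:           0.05
dysregulated:    36
------------------------------------------------------------
   tf  mirna lncrna   score_diff  score_cor  final_score   perm_p
TF004 miR004 lnc004 1.788997e-30   1.730479          3.0 0.000999
TF000 miR000 lnc000 2.430297e-30   1.649848          4.5 0.000999
TF001 miR001 lnc001 4.082782e-28   2.135857          4.5 0.000999
TF002 miR002 lnc002 4.987984e-29   1.900509          4.5 0.000999
TF003 miR003 lnc003 2.917943e-29   1.672515          5.0 0.000999
TF000 miR001 lnc000 4.359022e-26   0.078825          9.0 0.000999
```

All five planted motifs (TF000…TF004 triangles) head the ranking with
minimal permutation P-values (0.000999 = 1/1001, the floor at B = 1000);
motifs that share a planted transcript are also flagged, since one shifted
component genuinely changes their expression-shift score.

Survival, on the fixture whose hazard follows motif 0 with true
coefficients (1, −1, 0.5):

```python
from lfflnet import LFFLMotif, ExpressionCohort
from lfflnet.survival import MotifPrognosis
res = MotifPrognosis(cohort, LFFLMotif("TF000", "miR000", "lnc000")).fit()
print(res.summary())
```

```
Cox betas:   beta_t=+0.8345  beta_m=-0.6314  beta_l=+0.3115
risk groups: high n=40, low n=40
log-rank P:  3.54e-05
single-component log-rank P: tf=0.02796  mirna=0.2079  lncrna=0.009071
```

The integrated three-transcript score separates the risk groups far more
sharply (P = 3.5 × 10⁻⁵) than any single component does.

The same pipeline is available from a shell:

```bash
lffl simulate --scenario planted_strong --seed 7 --out fixture
lffl build-network --tf-mirna fixture/edges_tf_mirna.tsv \
     --tf-lncrna fixture/edges_tf_lncrna.tsv \
     --mirna-lncrna fixture/edges_mirna_lncrna.tsv --out-motifs motifs.tsv
lffl run-all --config config.yaml
```

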