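"""Scoring motif dysregulation between tumour and normal cohorts.

For every (TF, miRNA, lncRNA) motif two complementary statistics are
computed on log2(x+1)-transformed expression:

* ``score_diff = p_t * p_m * p_l`` — the product of the three transcripts'
  two-sided differential-expression P-values (Welch t-test, or paired t-test
  on patient-matched samples); small values mean a coordinated tumour/normal
  expression shift.

* ``score_cor = |(C_tm - N_tm)(C_tl - N_tl)(C_ml - N_ml)|`` — the absolute
  product of the tumour-minus-normal Pearson-correlation differences over
  the motif's three edges; large values mean the co-expression structure of
  the whole triangle is rewired in tumours.

The two criteria are combined by equally weighted rank aggregation:
``rank_diff`` ranks ``score_diff`` ascending, ``rank_cor`` ranks
``score_cor`` descending (ties averaged), and the final score is the mean of
the two ranks — 1 is maximally dysregulated.

Significance comes from a label-permutation null: tumour/normal labels are
shuffled jointly across the three expression matrices (samples are shared)
and each motif's permuted final score is compared with its observed one.
In the default ``insertion`` null the permuted (score_diff, score_cor) pair
of motif *m* is ranked against the *observed* scores of the other motifs, so
the permuted final score measures where a null realisation of *m* would land
in the observed field.  This is calibrated under a global null (perm_p is
uniform) yet allows several strong motifs to be significant simultaneously.
Two alternatives are available: ``reranked`` (all motifs re-ranked against
each other within every permutation — note that this caps the number of
discoverable motifs near ``alpha * n_motifs``, because any permuted final
score is close to uniform on ranks) and ``pooled`` (permuted final scores
pooled over motifs).  The empirical P-value uses the positively biased
``(1 + count) / (B + 1)`` estimator, so P is never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .network import LFFLMotif, NodeClass

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionCohort",
    "MotifScore",
    "MotifCorrelations",
    "MotifDysregulation",
    "MotifDysregulationResults",
    "differential_expression",
    "motif_correlations",
    "compute_score_diff",
    "compute_score_cor",
    "aggregate_ranks",
    "permutation_pvalues",
    "identify_dysregulated",
]

TUMOR = "tumor"
NORMAL = "normal"

#: numerical floor for P-values (keeps score_diff strictly positive)
MIN_P = 1e-300

_CLASS_ATTR = {
    NodeClass.TF: "tf",
    NodeClass.MIRNA: "mirna",
    NodeClass.LNCRNA: "lncrna",
}


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------
@dataclass
class ExpressionCohort:
    """Aligned tumour/normal expression for the three transcript classes.

    Each matrix is transcripts x samples with non-negative RPKM-like values;
    the three matrices share one ordered sample set described by ``samples``
    (index sample_id; columns ``condition`` in {tumor, normal}, optional
    ``patient_id``, ``survival_time``, ``event``).
    """

    tf: pd.DataFrame
    mirna: pd.DataFrame
    lncrna: pd.DataFrame
    samples: pd.DataFrame
    cancer_label: str = "cohort"

    def __post_init__(self) -> None:
        cols = list(self.tf.columns)
        for name, mat in (("mirna", self.mirna), ("lncrna", self.lncrna)):
            if list(mat.columns) != cols:
                raise DataError(
                    f"{name} matrix sample columns differ from the TF matrix"
                )
        if list(self.samples.index) != cols:
            raise DataError("sample metadata index must equal the matrix columns, in order")
        cond = self.samples["condition"]
        bad = set(cond) - {TUMOR, NORMAL}
        if bad:
            raise DataError(f"unknown condition label(s): {sorted(bad)}")
        if (cond == TUMOR).sum() < 2 or (cond == NORMAL).sum() < 2:
            raise DataError("need at least 2 tumor and 2 normal samples")
        for name, mat in (("tf", self.tf), ("mirna", self.mirna), ("lncrna", self.lncrna)):
            if (mat.to_numpy() < 0).any():
                raise DataError(f"negative expression values in the {name} matrix")
            if mat.index.has_duplicates:
                raise DataError(f"duplicate transcript ids in the {name} matrix")

    # -- convenience ---------------------------------------------------------
    @property
    def tumor_mask(self) -> np.ndarray:
        return (self.samples["condition"] == TUMOR).to_numpy()

    @property
    def normal_mask(self) -> np.ndarray:
        return (self.samples["condition"] == NORMAL).to_numpy()

    def matrix(self, node_class: NodeClass | str) -> pd.DataFrame:
        return getattr(self, _CLASS_ATTR[NodeClass(node_class)])

    def has_transcripts(self, motif: LFFLMotif) -> bool:
        return (
            motif.tf_id in self.tf.index
            and motif.mirna_id in self.mirna.index
            and motif.lncrna_id in self.lncrna.index
        )

    @classmethod
    def from_tsv(
        cls,
        tf_path,
        mirna_path,
        lncrna_path,
        samples_path,
        cancer_label: str = "cohort",
    ) -> "ExpressionCohort":
        read = lambda p: pd.read_csv(p, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(read(tf_path), read(mirna_path), read(lncrna_path), samples, cancer_label)

    def to_tsv(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.tf.to_csv(outdir / "expression_tf.tsv", sep="\t")
        self.mirna.to_csv(outdir / "expression_mirna.tsv", sep="\t")
        self.lncrna.to_csv(outdir / "expression_lncrna.tsv", sep="\t")
        self.samples.to_csv(outdir / "samples.tsv", sep="\t")


class MotifCorrelations(NamedTuple):
    c_tm: float
    c_tl: float
    c_ml: float
    n_tm: float
    n_tl: float
    n_ml: float


@dataclass
class MotifScore:
    """All per-motif statistics of the dysregulation pipeline."""

    motif: LFFLMotif
    p_t: float
    p_m: float
    p_l: float
    c_tm: float
    c_tl: float
    c_ml: float
    n_tm: float
    n_tl: float
    n_ml: float
    score_diff: float
    score_cor: float
    rank_diff: float | None = None
    rank_cor: float | None = None
    final_score: float | None = None
    perm_p: float | None = None
    dysregulated: bool | None = None


# ---------------------------------------------------------------------------
# elementary statistics (vectorised kernels)
# ---------------------------------------------------------------------------
def _log2p1(x: np.ndarray) -> np.ndarray:
    return np.log2(np.asarray(x, dtype=float) + 1.0)


def _welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test P-values, row-wise; degenerate rows -> 1 or floor.

    Rows with zero variance in both groups get P=1 when the means agree
    (logged by callers) and the numerical floor otherwise.
    """
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise DataError("need at least 2 values per group for a t-test")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    p = np.where(degenerate, np.where(m1 == m2, 1.0, MIN_P), p)
    p = np.nan_to_num(p, nan=1.0)
    return np.clip(p, MIN_P, 1.0)


def _rowwise_pcc(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation between paired rows; zero-variance rows -> 0."""
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    r = np.where(den == 0, 0.0, r)
    return np.clip(r, -1.0, 1.0)


# ---------------------------------------------------------------------------
# operation-level surface
# ---------------------------------------------------------------------------
def differential_expression(
    cohort: ExpressionCohort,
    transcript_id: str,
    transcript_class: NodeClass | str,
    paired: bool = False,
) -> float:
    """Two-sided tumour-vs-normal P-value on log2(x+1) expression.

    Unpaired design uses Welch's t-test; ``paired=True`` uses a paired t-test
    on patient_id-matched tumour/normal pairs only.
    """
    mat = cohort.matrix(transcript_class)
    if transcript_id not in mat.index:
        raise DataError(f"transcript {transcript_id!r} not in the {transcript_class} matrix")
    x = _log2p1(mat.loc[transcript_id].to_numpy())
    if not paired:
        return float(_welch_p(x[cohort.tumor_mask][None, :], x[cohort.normal_mask][None, :])[0])

    if "patient_id" not in cohort.samples.columns:
        raise DataError("paired test requires a patient_id column")
    samples = cohort.samples
    tumor = samples[samples["condition"] == TUMOR]
    normal = samples[samples["condition"] == NORMAL]
    by_patient_n = {p: s for s, p in zip(normal.index, normal["patient_id"]) if pd.notna(p)}
    pairs = [
        (s, by_patient_n[p])
        for s, p in zip(tumor.index, tumor["patient_id"])
        if pd.notna(p) and p in by_patient_n
    ]
    if len(pairs) < 2:
        raise DataError("paired test needs at least 2 matched tumor/normal pairs")
    pos = {s: i for i, s in enumerate(samples.index)}
    diffs = np.array([x[pos[t]] - x[pos[n]] for t, n in pairs])
    if np.allclose(diffs.var(ddof=1), 0.0):
        if np.allclose(diffs.mean(), 0.0):
            log.warning("paired differences all zero for %s; P := 1", transcript_id)
            return 1.0
        return MIN_P
    res = stats.ttest_rel(diffs, np.zeros_like(diffs))
    return float(np.clip(res.pvalue, MIN_P, 1.0))


def motif_correlations(cohort: ExpressionCohort, motif: LFFLMotif) -> MotifCorrelations:
    """The six edge-wise Pearson correlations (tumour and normal separately)."""
    if not cohort.has_transcripts(motif):
        raise DataError(f"motif {motif.transcripts} not fully covered by expression data")
    if cohort.tumor_mask.sum() < 3 or cohort.normal_mask.sum() < 3:
        raise DataError("correlations need at least 3 samples per condition")
    t = _log2p1(cohort.tf.loc[motif.tf_id].to_numpy())
    m = _log2p1(cohort.mirna.loc[motif.mirna_id].to_numpy())
    l = _log2p1(cohort.lncrna.loc[motif.lncrna_id].to_numpy())
    tm, nm = cohort.tumor_mask, cohort.normal_mask

    def pcc(a, b, mask):
        r = float(_rowwise_pcc(a[mask][None, :], b[mask][None, :])[0])
        return r

    return MotifCorrelations(
        c_tm=pcc(t, m, tm), c_tl=pcc(t, l, tm), c_ml=pcc(m, l, tm),
        n_tm=pcc(t, m, nm), n_tl=pcc(t, l, nm), n_ml=pcc(m, l, nm),
    )


def compute_score_diff(p_t: float, p_m: float, p_l: float) -> float:
    """Product of the three differential-expression P-values (smaller = worse)."""
    for name, p in (("p_t", p_t), ("p_m", p_m), ("p_l", p_l)):
        if not (0.0 < p <= 1.0):
            raise ValueError(f"{name}={p} outside (0, 1]")
    return p_t * p_m * p_l


def compute_score_cor(
    c_tm: float, c_tl: float, c_ml: float, n_tm: float, n_tl: float, n_ml: float
) -> float:
    """|(C_tm-N_tm)(C_tl-N_tl)(C_ml-N_ml)| (larger = more rewired)."""
    for name, r in (
        ("c_tm", c_tm), ("c_tl", c_tl), ("c_ml", c_ml),
        ("n_tm", n_tm), ("n_tl", n_tl), ("n_ml", n_ml),
    ):
        if not (-1.0 <= r <= 1.0):
            raise ValueError(f"{name}={r} outside [-1, 1]")
    return abs((c_tm - n_tm) * (c_tl - n_tl) * (c_ml - n_ml))


def aggregate_ranks(scores: Sequence[MotifScore]) -> list[MotifScore]:
    """Fill rank_diff, rank_cor and final_score (equally weighted rank mean).

    rank_diff ranks score_diff ascending (smallest P-product first), rank_cor
    ranks score_cor descending (largest first); ties get average ranks; the
    final score is the mean of the two ranks.  The output is a new list in
    the input order; ranks are invariant to input order by construction.
    """
    if not scores:
        raise DataError("aggregate_ranks needs at least one motif score")
    sd = np.array([s.score_diff for s in scores], dtype=float)
    sc = np.array([s.score_cor for s in scores], dtype=float)
    if np.isnan(sd).any() or np.isnan(sc).any():
        raise DataError("aggregate_ranks: unset score_diff/score_cor")
    rank_diff = stats.rankdata(sd, method="average")
    rank_cor = stats.rankdata(-sc, method="average")
    final = (rank_diff + rank_cor) / 2.0
    return [
        replace(s, rank_diff=float(rd), rank_cor=float(rc), final_score=float(f))
        for s, rd, rc, f in zip(scores, rank_diff, rank_cor, final)
    ]


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------
class _ScoreArrays(NamedTuple):
    p_t: np.ndarray
    p_m: np.ndarray
    p_l: np.ndarray
    c_tm: np.ndarray
    c_tl: np.ndarray
    c_ml: np.ndarray
    n_tm: np.ndarray
    n_tl: np.ndarray
    n_ml: np.ndarray
    score_diff: np.ndarray
    score_cor: np.ndarray


def _insertion_rank(sorted_obs: np.ndarray, obs: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Rank of each motif's permuted key among {observed keys of the others, itself}.

    Ascending keys; ties get average ranks.  Result lies in [1, M].
    """
    less = np.searchsorted(sorted_obs, perm, side="left")
    leq = np.searchsorted(sorted_obs, perm, side="right")
    less_others = less - (obs < perm)
    eq_others = (leq - less) - (obs == perm)
    return less_others + 1.0 + eq_others / 2.0


class MotifDysregulation:
    """Dysregulation analysis of a motif set in one cancer cohort.

    statsmodels-style: build the model from data, then :meth:`fit` runs the
    scoring and the permutation test and returns a results object.

    Parameters
    ----------
    cohort
        Tumour/normal expression with sample metadata.
    motifs
        Candidate motifs; motifs with any transcript missing from the cohort
        are dropped with a logged count.
    paired
        Use paired t-tests for differential expression.  Honoured only when
        >=80% of tumour samples have a patient-matched normal; pairing is
        incompatible with the label-permutation null, so a paired fit reports
        rank-based scores without permutation P-values.
    null_mode
        ``"insertion"`` (default), ``"reranked"`` or ``"pooled"`` — see the
        module docstring.
    """

    def __init__(
        self,
        cohort: ExpressionCohort,
        motifs: Iterable[LFFLMotif],
        *,
        paired: bool = False,
        null_mode: str = "insertion",
    ) -> None:
        if null_mode not in {"insertion", "reranked", "pooled"}:
            raise ValueError(f"unknown null_mode {null_mode!r}")
        motifs = list(motifs)
        kept = [m for m in motifs if cohort.has_transcripts(m)]
        n_dropped = len(motifs) - len(kept)
        if n_dropped:
            log.info(
                "%s: dropped %d motif(s) with transcripts absent from expression",
                cohort.cancer_label, n_dropped,
            )
        if not kept:
            raise DataError("no motif is fully covered by the expression data")
        self.cohort = cohort
        self.motifs = kept
        self.n_dropped_motifs = n_dropped
        self.null_mode = null_mode
        self.paired = self._resolve_paired(paired)

        # unique used transcripts per class, log-transformed once
        tf_ids = sorted({m.tf_id for m in kept})
        mi_ids = sorted({m.mirna_id for m in kept})
        ln_ids = sorted({m.lncrna_id for m in kept})
        self._log_tf = _log2p1(cohort.tf.loc[tf_ids].to_numpy())
        self._log_mi = _log2p1(cohort.mirna.loc[mi_ids].to_numpy())
        self._log_ln = _log2p1(cohort.lncrna.loc[ln_ids].to_numpy())
        tf_pos = {t: i for i, t in enumerate(tf_ids)}
        mi_pos = {t: i for i, t in enumerate(mi_ids)}
        ln_pos = {t: i for i, t in enumerate(ln_ids)}
        self._ti = np.array([tf_pos[m.tf_id] for m in kept])
        self._mi = np.array([mi_pos[m.mirna_id] for m in kept])
        self._li = np.array([ln_pos[m.lncrna_id] for m in kept])

    def _resolve_paired(self, paired: bool) -> bool:
        if not paired:
            return False
        s = self.cohort.samples
        if "patient_id" not in s.columns:
            log.warning("paired requested but no patient_id column; using unpaired tests")
            return False
        tumor_patients = set(s.loc[s["condition"] == TUMOR, "patient_id"].dropna())
        normal_patients = set(s.loc[s["condition"] == NORMAL, "patient_id"].dropna())
        n_tumor = int((s["condition"] == TUMOR).sum())
        matched = len(tumor_patients & normal_patients)
        if n_tumor == 0 or matched / n_tumor < 0.8:
            log.warning(
                "paired requested but only %d/%d tumor samples matched; using unpaired tests",
                matched, n_tumor,
            )
            return False
        return True

    # -- score kernel --------------------------------------------------------
    def _scores(self, mask_t: np.ndarray, mask_n: np.ndarray) -> _ScoreArrays:
        p_tf = _welch_p(self._log_tf[:, mask_t], self._log_tf[:, mask_n])
        p_mi = _welch_p(self._log_mi[:, mask_t], self._log_mi[:, mask_n])
        p_ln = _welch_p(self._log_ln[:, mask_t], self._log_ln[:, mask_n])
        p_t, p_m, p_l = p_tf[self._ti], p_mi[self._mi], p_ln[self._li]

        a_t = self._log_tf[self._ti]
        a_m = self._log_mi[self._mi]
        a_l = self._log_ln[self._li]
        c_tm = _rowwise_pcc(a_t[:, mask_t], a_m[:, mask_t])
        c_tl = _rowwise_pcc(a_t[:, mask_t], a_l[:, mask_t])
        c_ml = _rowwise_pcc(a_m[:, mask_t], a_l[:, mask_t])
        n_tm = _rowwise_pcc(a_t[:, mask_n], a_m[:, mask_n])
        n_tl = _rowwise_pcc(a_t[:, mask_n], a_l[:, mask_n])
        n_ml = _rowwise_pcc(a_m[:, mask_n], a_l[:, mask_n])

        score_diff = np.clip(p_t * p_m * p_l, MIN_P, 1.0)
        score_cor = np.abs((c_tm - n_tm) * (c_tl - n_tl) * (c_ml - n_ml))
        return _ScoreArrays(
            p_t, p_m, p_l, c_tm, c_tl, c_ml, n_tm, n_tl, n_ml, score_diff, score_cor
        )

    def _paired_pvalues(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        p_t = np.array([
            differential_expression(self.cohort, m.tf_id, NodeClass.TF, paired=True)
            for m in self.motifs
        ])
        p_m = np.array([
            differential_expression(self.cohort, m.mirna_id, NodeClass.MIRNA, paired=True)
            for m in self.motifs
        ])
        p_l = np.array([
            differential_expression(self.cohort, m.lncrna_id, NodeClass.LNCRNA, paired=True)
            for m in self.motifs
        ])
        return p_t, p_m, p_l

    # -- permutation null ----------------------------------------------------
    def _permutation_p(
        self,
        obs: _ScoreArrays,
        final_obs: np.ndarray,
        n_permutations: int,
        seed: int,
    ) -> np.ndarray:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        labels = self.cohort.tumor_mask.copy()
        m_count = len(self.motifs)
        count = np.zeros(m_count)
        sd_sorted = np.sort(obs.score_diff)
        neg_sc = -obs.score_cor
        sc_sorted = np.sort(neg_sc)
        pooled: list[np.ndarray] = []
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            s = self._scores(perm, ~perm)
            if self.null_mode == "reranked":
                fb = (
                    stats.rankdata(s.score_diff, method="average")
                    + stats.rankdata(-s.score_cor, method="average")
                ) / 2.0
            else:
                r_sd = _insertion_rank(sd_sorted, obs.score_diff, s.score_diff)
                r_sc = _insertion_rank(sc_sorted, neg_sc, -s.score_cor)
                fb = (r_sd + r_sc) / 2.0
            if self.null_mode == "pooled":
                pooled.append(fb)
            else:
                count += fb <= final_obs
        if self.null_mode == "pooled":
            pool = np.concatenate(pooled)
            count = np.array([(pool <= f).sum() for f in final_obs], dtype=float)
            return (1.0 + count) / (pool.size + 1.0)
        return (1.0 + count) / (n_permutations + 1.0)

    # -- fitting -------------------------------------------------------------
    def fit(
        self,
        n_permutations: int = 1000,
        alpha: float = 0.05,
        seed: int = 2016,
    ) -> "MotifDysregulationResults":
        """Score all motifs, aggregate ranks and run the permutation test."""
        if not (0.0 < alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        obs = self._scores(self.cohort.tumor_mask, self.cohort.normal_mask)
        if self.paired:
            p_t, p_m, p_l = self._paired_pvalues()
            score_diff = np.clip(p_t * p_m * p_l, MIN_P, 1.0)
            obs = obs._replace(p_t=p_t, p_m=p_m, p_l=p_l, score_diff=score_diff)
        rank_diff = stats.rankdata(obs.score_diff, method="average")
        rank_cor = stats.rankdata(-obs.score_cor, method="average")
        final = (rank_diff + rank_cor) / 2.0

        if self.paired:
            log.warning(
                "paired design: sample-label permutation is incompatible with "
                "pairing; perm_p not computed"
            )
            perm_p = np.full(len(self.motifs), np.nan)
        else:
            perm_p = self._permutation_p(obs, final, n_permutations, seed)

        table = pd.DataFrame(
            {
                "tf": [m.tf_id for m in self.motifs],
                "mirna": [m.mirna_id for m in self.motifs],
                "lncrna": [m.lncrna_id for m in self.motifs],
                "p_t": obs.p_t,
                "p_m": obs.p_m,
                "p_l": obs.p_l,
                "C_tm": obs.c_tm,
                "C_tl": obs.c_tl,
                "C_ml": obs.c_ml,
                "N_tm": obs.n_tm,
                "N_tl": obs.n_tl,
                "N_ml": obs.n_ml,
                "score_diff": obs.score_diff,
                "score_cor": obs.score_cor,
                "rank_diff": rank_diff,
                "rank_cor": rank_cor,
                "final_score": final,
                "perm_p": perm_p,
            }
        )
        table["dysregulated"] = table["perm_p"] < alpha
        if np.isnan(perm_p).all():
            table["dysregulated"] = pd.NA
            table["fdr_bh"] = np.nan
        else:
            # informational extension; the dysregulated flag uses raw perm_p
            from statsmodels.stats.multitest import multipletests

            table["fdr_bh"] = multipletests(perm_p, method="fdr_bh")[1]
        table = table.sort_values(
            ["final_score", "tf", "mirna", "lncrna"], kind="mergesort"
        ).reset_index(drop=True)
        return MotifDysregulationResults(
            model=self,
            table=table,
            n_permutations=n_permutations,
            alpha=alpha,
            seed=seed,
        )


class MotifDysregulationResults:
    """Per-motif score table and the parameters that produced it."""

    def __init__(self, model, table, n_permutations, alpha, seed) -> None:
        self.model = model
        self.table = table
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.seed = seed

    @property
    def cancer_label(self) -> str:
        return self.model.cohort.cancer_label

    @property
    def dysregulated(self) -> pd.DataFrame:
        return self.table[self.table["dysregulated"] == True]  # noqa: E712

    def dysregulated_motifs(self) -> list[LFFLMotif]:
        return [
            LFFLMotif(r.tf, r.mirna, r.lncrna)
            for r in self.dysregulated.itertuples(index=False)
        ]

    def perm_p(self) -> np.ndarray:
        return self.table["perm_p"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self, top: int = 10) -> str:
        n = len(self.table)
        n_dys = int((self.table["dysregulated"] == True).sum())  # noqa: E712
        lines = [
            "Motif dysregulation results",
            "=" * 60,
            f"cohort:          {self.cancer_label}",
            f"motifs scored:   {n} ({self.model.n_dropped_motifs} dropped, no expression)",
            f"permutations:    {self.n_permutations} (null={self.model.null_mode}, seed={self.seed})",
            f"alpha:           {self.alpha}",
            f"dysregulated:    {n_dys}",
            "-" * 60,
        ]
        cols = ["tf", "mirna", "lncrna", "score_diff", "score_cor", "final_score", "perm_p"]
        lines.append(self.table[cols].head(top).to_string(index=False))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers (the operation-level surface)
# ---------------------------------------------------------------------------
def permutation_pvalues(
    cohort: ExpressionCohort,
    motifs: Iterable[LFFLMotif],
    n_permutations: int,
    seed: int,
    null_mode: str = "insertion",
) -> np.ndarray:
    """Permutation P-value per motif (order matches the input motif list)."""
    model = MotifDysregulation(cohort, motifs, null_mode=null_mode)
    res = model.fit(n_permutations=n_permutations, seed=seed)
    key = res.table.set_index(["tf", "mirna", "lncrna"])["perm_p"]
    return np.array([key.loc[m.as_tuple()] for m in model.motifs])


def identify_dysregulated(
    cohort: ExpressionCohort,
    motifs: Iterable[LFFLMotif],
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 2016,
    *,
    paired: bool = False,
    null_mode: str = "insertion",
) -> pd.DataFrame:
    """Full per-motif score table sorted by final score, with the dysregulated flag."""
    model = MotifDysregulation(cohort, motifs, paired=paired, null_mode=null_mode)
    return model.fit(n_permutations=n_permutations, alpha=alpha, seed=seed).table
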