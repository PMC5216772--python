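"""Motif-level survival analysis: Cox-weighted integrated risk score.

A motif is evaluated as a prognostic biomarker in four chained steps:

1. multivariate Cox proportional-hazards fit of survival on the motif's
   three transcripts (log2(x+1)-transformed, then z-scored across tumour
   samples so the coefficients are on a comparable scale);
2. integrated risk score per patient — the coefficient-weighted sum
   ``beta_t x_t + beta_m x_m + beta_l x_l`` of standardized expression;
3. median split of the risk scores into high-risk (score > median) and
   low-risk (score <= median; ties go low) groups;
4. Kaplan-Meier curves per group and a two-sample log-rank test.

Single-transcript log-rank P-values (median split on each standardized
component alone) are reported alongside, so the added value of the whole
triangle over any one transcript can be judged.

Cox fitting and the survival statistics are delegated to lifelines
(Efron approximation for tied event times, the lifelines default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .dysregulation import ExpressionCohort, _log2p1
from .errors import DataError
from .network import LFFLMotif

log = logging.getLogger(__name__)

__all__ = [
    "MotifPrognosis",
    "MotifPrognosisResults",
    "fit_motif_cox",
    "integrated_risk_scores",
    "stratify_risk_groups",
    "km_logrank",
    "evaluate_motif_prognosis",
    "standardized_motif_expression",
]

_COMPONENTS = ("tf", "mirna", "lncrna")


def standardized_motif_expression(
    cohort: ExpressionCohort, motif: LFFLMotif
) -> pd.DataFrame:
    """Tumour-sample expression of the three transcripts, log2(x+1) + z-score.

    Returns a samples x 3 frame with columns ``tf``, ``mirna``, ``lncrna``.

    Raises
    ------
    DataError
        If a transcript is missing or has zero variance (named in the message).
    """
    if not cohort.has_transcripts(motif):
        raise DataError(f"motif {motif.transcripts} not fully covered by expression data")
    mask = cohort.tumor_mask
    sample_ids = cohort.samples.index[mask]
    cols = {}
    for name, mat, tid in (
        ("tf", cohort.tf, motif.tf_id),
        ("mirna", cohort.mirna, motif.mirna_id),
        ("lncrna", cohort.lncrna, motif.lncrna_id),
    ):
        x = _log2p1(mat.loc[tid].to_numpy())[mask]
        sd = x.std(ddof=1)
        if sd == 0:
            raise DataError(f"zero-variance covariate: {name} transcript {tid!r}")
        cols[name] = (x - x.mean()) / sd
    return pd.DataFrame(cols, index=sample_ids)


def fit_motif_cox(
    expr: pd.DataFrame, surv: pd.DataFrame
) -> tuple[np.ndarray, bool]:
    """Cox partial-likelihood fit of survival on the three standardized covariates.

    ``expr`` is samples x 3 (columns tf/mirna/lncrna, already standardized),
    ``surv`` is indexed by the same samples with columns ``time`` and
    ``event``.  Returns ``(betas, converged)`` with betas ordered
    (beta_t, beta_m, beta_l); a non-converged fit carries NaN betas and must
    not be used downstream.
    """
    surv = surv.loc[expr.index]
    n_events = int(surv["event"].sum())
    if n_events < 10:
        raise DataError(f"Cox fit needs >=10 events, got {n_events}")
    for name in _COMPONENTS:
        if expr[name].std(ddof=1) == 0:
            raise DataError(f"zero-variance covariate: {name}")
    df = expr.copy()
    df["time"] = surv["time"].to_numpy(dtype=float)
    df["event"] = surv["event"].to_numpy(dtype=int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        log.warning("Cox fit did not converge: %s", exc)
        return np.full(3, np.nan), False
    betas = cph.params_.reindex(list(_COMPONENTS)).to_numpy(dtype=float)
    return betas, True


def integrated_risk_scores(expr: pd.DataFrame, betas: np.ndarray) -> pd.Series:
    """Per-patient coefficient-weighted risk score on standardized expression."""
    betas = np.asarray(betas, dtype=float)
    if np.isnan(betas).any():
        raise DataError("risk scores require betas from a converged fit")
    return pd.Series(expr[list(_COMPONENTS)].to_numpy() @ betas, index=expr.index,
                     name="risk_score")


def stratify_risk_groups(scores: pd.Series) -> pd.Series:
    """Median split: score > median -> ``high``, score <= median -> ``low``."""
    if len(scores) < 4:
        raise DataError("risk stratification needs at least 4 patients")
    if scores.nunique() == 1:
        raise DataError("all risk scores identical; cannot stratify")
    median = scores.median()
    n_ties = int((scores == median).sum())
    if n_ties:
        log.info("stratify_risk_groups: %d score(s) tied at the median go to low", n_ties)
    return pd.Series(
        np.where(scores > median, "high", "low"), index=scores.index, name="risk_group"
    )


def km_logrank(
    surv: pd.DataFrame,
) -> tuple[float, dict[str, pd.DataFrame]]:
    """Kaplan-Meier curves per risk group plus the two-sample log-rank P.

    ``surv`` needs columns ``time``, ``event``, ``risk_group``.  Returns
    ``(logrank_p, curves)`` where ``curves[group]`` is the product-limit
    survival function (index time, column survival).
    """
    groups = {g: d for g, d in surv.groupby("risk_group")}
    if len(groups) != 2 or any(len(d) == 0 for d in groups.values()):
        raise DataError("log-rank test needs exactly two non-empty risk groups")
    if int(surv["event"].sum()) < 1:
        raise DataError("log-rank test needs at least one event")
    (g1, d1), (g2, d2) = sorted(groups.items())
    res = logrank_test(
        d1["time"], d2["time"], event_observed_A=d1["event"], event_observed_B=d2["event"]
    )
    curves = {}
    for g, d in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(d["time"], event_observed=d["event"], label=g)
        sf = kmf.survival_function_
        sf.columns = ["survival"]
        curves[g] = sf
    p = float(res.p_value)
    # identical groups give chi2 = 0 -> p exactly 1
    return min(max(p, 0.0), 1.0) if p == p else 1.0, curves


class MotifPrognosis:
    """Prognostic evaluation of one motif in one cohort (model object).

    Construct from a cohort and a motif, then :meth:`fit` chains
    Cox fit -> integrated score -> median split -> KM/log-rank.

    Parameters
    ----------
    cohort
        Expression cohort; survival information is taken from its sample
        metadata (columns ``survival_time``, ``event`` on tumour samples)
        unless ``surv`` is given.
    motif
        The (TF, miRNA, lncRNA) triple to evaluate.
    surv
        Optional explicit survival frame indexed by tumour sample id with
        columns ``time`` and ``event``.  Patients with missing time/event or
        non-positive time are dropped with a logged count.
    """

    def __init__(
        self,
        cohort: ExpressionCohort,
        motif: LFFLMotif,
        surv: pd.DataFrame | None = None,
    ) -> None:
        self.cohort = cohort
        self.motif = motif
        expr = standardized_motif_expression(cohort, motif)
        if surv is None:
            meta = cohort.samples
            missing = [c for c in ("survival_time", "event") if c not in meta.columns]
            if missing:
                raise DataError(f"sample metadata lacks column(s): {missing}")
            tumor = meta[meta["condition"] == "tumor"]
            surv = pd.DataFrame(
                {"time": tumor["survival_time"], "event": tumor["event"]},
                index=tumor.index,
            )
        surv = surv.loc[surv.index.intersection(expr.index)]
        ok = surv["time"].notna() & surv["event"].notna() & (surv["time"] > 0)
        n_dropped = int((~ok).sum())
        if n_dropped:
            log.info("dropped %d patient(s) with missing/invalid follow-up", n_dropped)
        surv = surv[ok]
        self.expr = expr.loc[surv.index]
        self.surv = surv.astype({"time": float, "event": int})
        self.n_dropped_patients = n_dropped

    def fit(self) -> "MotifPrognosisResults":
        betas, converged = fit_motif_cox(self.expr, self.surv)
        if not converged:
            return MotifPrognosisResults(
                motif=self.motif,
                cancer_label=self.cohort.cancer_label,
                betas=betas,
                converged=False,
                logrank_p=float("nan"),
                group_sizes=(0, 0),
                single_component_p={},
                risk_table=pd.DataFrame(),
                km_curves={},
            )
        scores = integrated_risk_scores(self.expr, betas)
        groups = stratify_risk_groups(scores)
        table = self.surv.copy()
        table["risk_score"] = scores
        table["risk_group"] = groups
        logrank_p, curves = km_logrank(table)

        single = {}
        for name in _COMPONENTS:
            comp_groups = stratify_risk_groups(self.expr[name])
            comp = self.surv.copy()
            comp["risk_group"] = comp_groups
            p, _ = km_logrank(comp)
            single[name] = p

        n_high = int((groups == "high").sum())
        n_low = int((groups == "low").sum())
        return MotifPrognosisResults(
            motif=self.motif,
            cancer_label=self.cohort.cancer_label,
            betas=betas,
            converged=True,
            logrank_p=logrank_p,
            group_sizes=(n_high, n_low),
            single_component_p=single,
            risk_table=table,
            km_curves=curves,
        )


@dataclass
class MotifPrognosisResults:
    """Cox coefficients, risk groups and log-rank significance for one motif."""

    motif: LFFLMotif
    cancer_label: str
    betas: np.ndarray
    converged: bool
    logrank_p: float
    group_sizes: tuple[int, int]
    single_component_p: dict[str, float]
    risk_table: pd.DataFrame
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def beta_t(self) -> float:
        return float(self.betas[0])

    @property
    def beta_m(self) -> float:
        return float(self.betas[1])

    @property
    def beta_l(self) -> float:
        return float(self.betas[2])

    def to_row(self) -> dict:
        return {
            "cancer": self.cancer_label,
            "tf": self.motif.tf_id,
            "mirna": self.motif.mirna_id,
            "lncrna": self.motif.lncrna_id,
            "beta_t": self.beta_t,
            "beta_m": self.beta_m,
            "beta_l": self.beta_l,
            "converged": self.converged,
            "logrank_p": self.logrank_p,
            "n_high": self.group_sizes[0],
            "n_low": self.group_sizes[1],
            "logrank_p_tf": self.single_component_p.get("tf", float("nan")),
            "logrank_p_mirna": self.single_component_p.get("mirna", float("nan")),
            "logrank_p_lncrna": self.single_component_p.get("lncrna", float("nan")),
        }

    def summary(self) -> str:
        m = self.motif
        lines = [
            "Motif prognosis results",
            "=" * 60,
            f"cohort:      {self.cancer_label}",
            f"motif:       TF={m.tf_id}  miRNA={m.mirna_id}  lncRNA={m.lncrna_id}",
            f"converged:   {self.converged}",
        ]
        if self.converged:
            lines += [
                f"Cox betas:   beta_t={self.beta_t:+.4f}  beta_m={self.beta_m:+.4f}  "
                f"beta_l={self.beta_l:+.4f}",
                f"risk groups: high n={self.group_sizes[0]}, low n={self.group_sizes[1]}",
                f"log-rank P:  {self.logrank_p:.4g}",
                "single-component log-rank P: "
                + "  ".join(f"{k}={v:.4g}" for k, v in self.single_component_p.items()),
            ]
        return "\n".join(lines)

    def plot_km(self, path=None):
        """KM curves, blue = low risk, red = high risk; optionally saved as PNG."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        colors = {"low": "tab:blue", "high": "tab:red"}
        for group, sf in sorted(self.km_curves.items()):
            ax.step(sf.index, sf["survival"], where="post",
                    color=colors.get(group, "k"), label=f"{group} risk")
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend(frameon=False, fontsize=8,
                  title=f"log-rank P = {self.logrank_p:.3g}", title_fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
            return None
        return ax


def evaluate_motif_prognosis(
    cohort: ExpressionCohort,
    motif: LFFLMotif,
    surv: pd.DataFrame | None = None,
) -> MotifPrognosisResults:
    """Chain Cox fit -> risk score -> stratify -> KM/log-rank for one motif."""
    return MotifPrognosis(cohort, motif, surv=surv).fit()
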