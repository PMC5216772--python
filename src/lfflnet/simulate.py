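"""Synthetic interaction networks, expression cohorts and survival data.

Every pipeline stage is testable without downloads: the generator emulates
the statistical structure the analysis assumes rather than any particular
data release.

* **Topology** — three bipartite edge layers with heavy-tailed regulator
  out-degrees (preferential attachment within each layer, mimicking the
  scale-free-like topology of curated regulatory networks); requested
  planted motifs are guaranteed to exist as complete triangles.
* **Expression** — log2-scale values.  Background transcripts are i.i.d.
  normal (conservative for false-positive calibration).  Each planted motif
  draws its three transcripts from per-condition trivariate normals: tumour
  means shifted by ``mean_shift`` (in units of the baseline SD) and pairwise
  correlation ``rho_tumor`` on all three edges versus ``rho_normal`` in
  normals (the simplest positive-definite construction; a 3-variable
  equicorrelation requires rho > -1/2).  Values are exported as
  ``2**log - 1`` floored at 0, so the pipeline's log2(x+1) transform
  recovers the generative scale.
* **Survival** — event times are exponential with hazard
  ``lambda0 * exp(sum_i beta_i x_i)`` on standardized tumour expression of
  one motif; independent uniform censoring is tuned by bisection to the
  requested censoring fraction.

All outputs are deterministic functions of the seed (byte-identical files).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .dysregulation import ExpressionCohort
from .errors import ConfigError, DataError
from .network import EdgeClass, LFFLMotif, RegulatoryEdge
from .survival import standardized_motif_expression

log = logging.getLogger(__name__)

__all__ = [
    "PlantedMotif",
    "SurvivalSpec",
    "SimulationConfig",
    "simulate_interactions",
    "simulate_expression",
    "simulate_survival",
    "make_fixture",
    "SCENARIOS",
]


@dataclass(frozen=True)
class PlantedMotif:
    """Effect sizes planted on one motif.

    ``index`` selects the i-th reserved (TF_i, miR_i, lnc_i) triangle;
    ``mean_shift`` is the tumour log-scale mean shift in SD units;
    ``rho_tumor``/``rho_normal`` are the common pairwise correlations of the
    motif's three transcripts in tumours and normals.
    """

    index: int
    mean_shift: float = 0.0
    rho_tumor: float = 0.0
    rho_normal: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rho_tumor", "rho_normal"):
            r = getattr(self, name)
            if not (-1.0 < r < 1.0):
                raise ConfigError(f"{name}={r} outside (-1, 1)")


@dataclass(frozen=True)
class SurvivalSpec:
    """Ground-truth hazard model tied to one planted motif."""

    betas: tuple[float, float, float] = (1.0, -1.0, 0.5)
    baseline_hazard: float = 1e-3  # per day
    censoring: float = 0.3
    motif_index: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.censoring < 1.0):
            raise ConfigError("censoring fraction must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline hazard must be positive")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_tf: int = 15
    n_mirna: int = 40
    n_lncrna: int = 40
    density_tf_mirna: float = 0.12
    density_tf_lncrna: float = 0.12
    density_mirna_lncrna: float = 0.14
    attachment: str = "preferential"  # or "uniform"
    n_tumor: int = 30
    n_normal: int = 30
    planted: tuple[PlantedMotif, ...] = ()
    baseline_log_mean: float = 5.0
    noise_sd: float = 1.0
    survival: SurvivalSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tf", "n_mirna", "n_lncrna", "n_tumor", "n_normal"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.attachment not in {"preferential", "uniform"}:
            raise ConfigError(f"unknown attachment mode {self.attachment!r}")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        self.planted = tuple(self.planted)

    # reserved node ids for planted triangles
    def planted_motif(self, index: int) -> LFFLMotif:
        return LFFLMotif(_tf_id(index), _mirna_id(index), _lncrna_id(index))

    def planted_motifs(self) -> list[LFFLMotif]:
        return [self.planted_motif(p.index) for p in self.planted]


def _tf_id(i: int) -> str:
    return f"TF{i:03d}"


def _mirna_id(i: int) -> str:
    return f"miR{i:03d}"


def _lncrna_id(i: int) -> str:
    return f"lnc{i:03d}"


def _layer_edges(
    rng: np.random.Generator,
    regulators: Sequence[str],
    targets: Sequence[str],
    density: float,
    attachment: str,
    existing: set[tuple[str, str]],
) -> None:
    """Fill ``existing`` with random edges up to the requested density."""
    goal = int(round(density * len(regulators) * len(targets)))
    weights = np.ones(len(regulators))
    for r, t in existing:
        try:
            weights[regulators.index(r)] += 1
        except ValueError:
            pass
    attempts = 0
    max_attempts = 50 * max(goal, 1) + 1000
    while len(existing) < goal and attempts < max_attempts:
        attempts += 1
        if attachment == "preferential":
            ri = rng.choice(len(regulators), p=weights / weights.sum())
        else:
            ri = rng.integers(len(regulators))
        ti = rng.integers(len(targets))
        key = (regulators[ri], targets[ti])
        if key in existing:
            continue
        existing.add(key)
        weights[ri] += 1


def simulate_interactions(config: SimulationConfig) -> list[RegulatoryEdge]:
    """Generate the three edge layers; planted triangles are guaranteed."""
    n_planted = len(config.planted)
    if n_planted > min(config.n_tf, config.n_mirna, config.n_lncrna):
        raise ConfigError(
            f"{n_planted} planted motifs exceed the {min(config.n_tf, config.n_mirna, config.n_lncrna)} "
            "possible reserved triangles"
        )
    for p in config.planted:
        if p.index >= min(config.n_tf, config.n_mirna, config.n_lncrna):
            raise ConfigError(f"planted motif index {p.index} out of range")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    tfs = [_tf_id(i) for i in range(config.n_tf)]
    mirnas = [_mirna_id(i) for i in range(config.n_mirna)]
    lncrnas = [_lncrna_id(i) for i in range(config.n_lncrna)]

    tm: set[tuple[str, str]] = set()
    tl: set[tuple[str, str]] = set()
    ml: set[tuple[str, str]] = set()
    for p in config.planted:
        motif = config.planted_motif(p.index)
        tm.add((motif.tf_id, motif.mirna_id))
        tl.add((motif.tf_id, motif.lncrna_id))
        ml.add((motif.mirna_id, motif.lncrna_id))

    _layer_edges(rng, tfs, mirnas, config.density_tf_mirna, config.attachment, tm)
    _layer_edges(rng, tfs, lncrnas, config.density_tf_lncrna, config.attachment, tl)
    _layer_edges(rng, mirnas, lncrnas, config.density_mirna_lncrna, config.attachment, ml)

    edges = (
        [RegulatoryEdge(s, t, EdgeClass.TF_MIRNA) for s, t in sorted(tm)]
        + [RegulatoryEdge(s, t, EdgeClass.TF_LNCRNA) for s, t in sorted(tl)]
        + [RegulatoryEdge(s, t, EdgeClass.MIRNA_LNCRNA) for s, t in sorted(ml)]
    )
    return edges


def _equicorrelation(rho: float) -> np.ndarray:
    R = np.full((3, 3), rho)
    np.fill_diagonal(R, 1.0)
    eig = np.linalg.eigvalsh(R)
    if eig.min() <= 1e-10:
        raise ConfigError(
            f"correlation target rho={rho} is not positive definite for 3 "
            "variables; a 3-variable equicorrelation needs rho > -0.5 "
            "(e.g. use rho=-0.45)"
        )
    return R


def simulate_expression(
    config: SimulationConfig,
    motifs: Iterable[LFFLMotif],
    *,
    planted: Sequence[PlantedMotif] | None = None,
    cancer_label: str = "SIM",
    seed_stream: int = 2,
) -> ExpressionCohort:
    """Expression cohort with the configured effects planted.

    ``motifs`` is the enumerated motif list of the simulated network; every
    planted motif must be present in it.  ``planted`` overrides
    ``config.planted`` (used to plant different subsets in different cohorts
    of a multi-cancer fixture); ``seed_stream`` decorrelates cohorts drawn
    from the same config.
    """
    planted = tuple(config.planted if planted is None else planted)
    motif_set = set(motifs)
    for p in planted:
        if config.planted_motif(p.index) not in motif_set:
            raise DataError(f"planted motif index {p.index} missing from the motif list")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, seed_stream]))
    n_s = config.n_tumor + config.n_normal
    sd = config.noise_sd

    blocks = {}
    for prefix, count, idfun in (
        ("tf", config.n_tf, _tf_id),
        ("mirna", config.n_mirna, _mirna_id),
        ("lncrna", config.n_lncrna, _lncrna_id),
    ):
        ids = [idfun(i) for i in range(count)]
        vals = rng.normal(config.baseline_log_mean, sd, size=(count, n_s))
        blocks[prefix] = (ids, vals)

    tumor_slice = slice(0, config.n_tumor)
    normal_slice = slice(config.n_tumor, n_s)
    for p in planted:
        R_t = _equicorrelation(p.rho_tumor)
        R_n = _equicorrelation(p.rho_normal)
        cov_t = sd**2 * R_t
        cov_n = sd**2 * R_n
        mu = config.baseline_log_mean
        shift = p.mean_shift * sd
        draw_t = rng.multivariate_normal(
            [mu + shift] * 3, cov_t, size=config.n_tumor, method="cholesky"
        ).T
        draw_n = rng.multivariate_normal(
            [mu] * 3, cov_n, size=config.n_normal, method="cholesky"
        ).T
        for row, (prefix, count_idx) in zip(
            draw_t, (("tf", p.index), ("mirna", p.index), ("lncrna", p.index))
        ):
            blocks[prefix][1][count_idx, tumor_slice] = row
        for row, (prefix, count_idx) in zip(
            draw_n, (("tf", p.index), ("mirna", p.index), ("lncrna", p.index))
        ):
            blocks[prefix][1][count_idx, normal_slice] = row

    sample_ids = [f"{cancer_label}-T{i:03d}" for i in range(config.n_tumor)] + [
        f"{cancer_label}-N{i:03d}" for i in range(config.n_normal)
    ]
    conditions = ["tumor"] * config.n_tumor + ["normal"] * config.n_normal
    patients = [f"{cancer_label}-P{i:03d}" for i in range(config.n_tumor)] + [
        f"{cancer_label}-P{i:03d}" for i in range(config.n_normal)
    ]
    samples = pd.DataFrame(
        {
            "condition": conditions,
            "patient_id": patients,
            "survival_time": np.nan,
            "event": np.nan,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    def to_rpkm(vals: np.ndarray) -> np.ndarray:
        return np.maximum(np.exp2(vals) - 1.0, 0.0)

    frames = {
        prefix: pd.DataFrame(to_rpkm(vals), index=ids, columns=sample_ids)
        for prefix, (ids, vals) in blocks.items()
    }
    return ExpressionCohort(
        tf=frames["tf"],
        mirna=frames["mirna"],
        lncrna=frames["lncrna"],
        samples=samples,
        cancer_label=cancer_label,
    )


def simulate_survival(
    config: SimulationConfig,
    cohort: ExpressionCohort,
    motif: LFFLMotif,
    *,
    seed_stream: int = 3,
) -> pd.DataFrame:
    """Exponential event times with motif-expression-dependent hazard.

    Returns a frame indexed by tumour sample id with columns ``time`` and
    ``event``; the realised censoring fraction is tuned to the request by
    bisecting the uniform-censoring horizon.
    """
    sp = config.survival
    if sp is None:
        raise ConfigError("config.survival is not set")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, seed_stream]))
    X = standardized_motif_expression(cohort, motif)
    lam = sp.baseline_hazard * np.exp(X.to_numpy() @ np.asarray(sp.betas))
    times = rng.exponential(1.0 / lam)
    times = np.maximum(times, 1e-6)
    if sp.censoring == 0:
        events = np.ones_like(times, dtype=int)
        obs = times
    else:
        def frac(cmax: float) -> float:
            return float(np.mean(np.minimum(times / cmax, 1.0))) - sp.censoring

        hi = float(times.max()) * 1e4
        cmax = brentq(frac, 1e-9, hi)
        censor = rng.uniform(0.0, cmax, size=times.shape)
        events = (times <= censor).astype(int)
        obs = np.minimum(times, censor)
    return pd.DataFrame({"time": obs, "event": events}, index=X.index)


# ---------------------------------------------------------------------------
# on-disk fixtures
# ---------------------------------------------------------------------------
_STRONG = dict(mean_shift=2.0, rho_tumor=0.8, rho_normal=-0.45)
_WEAK = dict(mean_shift=0.5, rho_tumor=0.8, rho_normal=-0.45)

SCENARIOS = ("null", "planted_weak", "planted_strong", "survival_linked", "multi_cancer")


def _scenario_config(scenario: str, seed: int) -> tuple[SimulationConfig, dict]:
    """Config plus the scenario's per-cohort planting plan."""
    if scenario == "null":
        cfg = SimulationConfig(
            density_tf_mirna=0.15,
            density_tf_lncrna=0.15,
            density_mirna_lncrna=0.20,
            attachment="uniform",
            seed=seed,
        )
        return cfg, {"COHORT1": []}
    if scenario in {"planted_weak", "planted_strong"}:
        eff = _STRONG if scenario == "planted_strong" else _WEAK
        planted = tuple(PlantedMotif(i, **eff) for i in range(5))
        cfg = SimulationConfig(planted=planted, seed=seed)
        return cfg, {"COHORT1": list(planted)}
    if scenario == "survival_linked":
        planted = tuple(PlantedMotif(i, **_STRONG) for i in range(5))
        cfg = SimulationConfig(
            planted=planted,
            n_tumor=80,
            survival=SurvivalSpec(betas=(1.0, -1.0, 0.5), motif_index=0),
            seed=seed,
        )
        return cfg, {"COHORT1": list(planted)}
    if scenario == "multi_cancer":
        planted = tuple(PlantedMotif(i, **_STRONG) for i in range(5))
        cfg = SimulationConfig(planted=planted, seed=seed)
        plan = {
            "CANCER_A": [planted[0], planted[1], planted[2]],
            "CANCER_B": [planted[0], planted[1], planted[3]],
            "CANCER_C": [planted[0], planted[4]],
        }
        return cfg, plan
    raise ConfigError(f"unknown scenario {scenario!r}; valid: {', '.join(SCENARIOS)}")


def make_fixture(scenario: str, seed: int, outdir) -> dict:
    """Write a complete on-disk dataset plus a ground-truth manifest.

    Layout: three edge TSVs at the top level, one directory per cohort under
    ``cohorts/`` with the expression and sample TSVs, and ``manifest.yaml``
    recording every planted truth.  Returns the manifest as a dict.
    """
    cfg, plan = _scenario_config(scenario, seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    edges = simulate_interactions(cfg)
    by_class: dict[EdgeClass, list[RegulatoryEdge]] = {c: [] for c in EdgeClass}
    for e in edges:
        by_class[e.edge_class].append(e)
    edge_files = {}
    for cls, fname in (
        (EdgeClass.TF_MIRNA, "edges_tf_mirna.tsv"),
        (EdgeClass.TF_LNCRNA, "edges_tf_lncrna.tsv"),
        (EdgeClass.MIRNA_LNCRNA, "edges_mirna_lncrna.tsv"),
    ):
        with open(outdir / fname, "w", encoding="utf-8") as fh:
            for e in sorted(by_class[cls]):
                fh.write(f"{e.source_id}\t{e.target_id}\n")
        edge_files[cls.value] = fname

    from .network import build_network, enumerate_motifs

    motifs = enumerate_motifs(build_network(edges))

    manifest: dict = {
        "scenario": scenario,
        "seed": seed,
        "edge_files": edge_files,
        "n_motifs": len(motifs),
        "cohorts": {},
    }
    if scenario == "multi_cancer":
        counts: dict[tuple, int] = {}
        for label, ps in plan.items():
            for p in ps:
                key = cfg.planted_motif(p.index).as_tuple()
                counts[key] = counts.get(key, 0) + 1
        manifest["expected_labels"] = {
            "|".join(k): ("common" if c >= 2 else "specific") for k, c in sorted(counts.items())
        }

    for i, (label, planted) in enumerate(sorted(plan.items())):
        cohort = simulate_expression(
            cfg, motifs, planted=planted, cancer_label=label, seed_stream=10 + i
        )
        surv_truth = None
        if cfg.survival is not None:
            motif = cfg.planted_motif(cfg.survival.motif_index)
            surv = simulate_survival(cfg, cohort, motif, seed_stream=100 + i)
            cohort.samples.loc[surv.index, "survival_time"] = surv["time"]
            cohort.samples.loc[surv.index, "event"] = surv["event"]
            surv_truth = {
                "motif": "|".join(motif.as_tuple()),
                "betas": list(cfg.survival.betas),
                "baseline_hazard": cfg.survival.baseline_hazard,
                "censoring": cfg.survival.censoring,
            }
        cdir = outdir / "cohorts" / label
        cohort.to_tsv(cdir)
        manifest["cohorts"][label] = {
            "paths": {
                "expression_tf": f"cohorts/{label}/expression_tf.tsv",
                "expression_mirna": f"cohorts/{label}/expression_mirna.tsv",
                "expression_lncrna": f"cohorts/{label}/expression_lncrna.tsv",
                "samples": f"cohorts/{label}/samples.tsv",
            },
            "planted": [
                {
                    "tf": cfg.planted_motif(p.index).tf_id,
                    "mirna": cfg.planted_motif(p.index).mirna_id,
                    "lncrna": cfg.planted_motif(p.index).lncrna_id,
                    "mean_shift": p.mean_shift,
                    "rho_tumor": p.rho_tumor,
                    "rho_normal": p.rho_normal,
                }
                for p in planted
            ],
            "survival": surv_truth,
        }

    with open(outdir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
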