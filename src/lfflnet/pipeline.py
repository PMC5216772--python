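"""End-to-end orchestration: per-cohort runs and cross-cohort comparison.

``run_cohort`` executes build -> enumerate -> score -> permute -> flag ->
survival for one cancer cohort and writes all tables; ``run_cross_cohort``
combines several cohort runs into the motif x cancer matrix, common/specific
labels, the union sub-network and optional cross-talk tables.  Per-cohort
seeds are derived deterministically from the master seed and the cohort's
position, so a full run is reproducible from the config alone.
"""

from __future__ import annotations

import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import (
    MotifCancerMatrix,
    classify_common_specific,
    find_cerna_crosstalk,
    find_lmffl_crosstalk,
    read_cerna_table,
    read_mffl_table,
    union_subnetwork,
)
from .dysregulation import ExpressionCohort, MotifDysregulation
from .errors import ConfigError, DataError, LFFLError
from .network import (
    EdgeClass,
    LFFLMotif,
    build_network,
    enumerate_motifs,
    export_network,
    read_interaction_table,
    write_motif_table,
)
from .survival import MotifPrognosis

log = logging.getLogger(__name__)

__all__ = ["CohortPaths", "PipelineConfig", "run_cohort", "run_cross_cohort", "run_all"]


@dataclass
class CohortPaths:
    label: str
    expression_tf: Path
    expression_mirna: Path
    expression_lncrna: Path
    samples: Path

    def paths(self) -> list[Path]:
        return [self.expression_tf, self.expression_mirna, self.expression_lncrna, self.samples]


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from a single YAML file."""

    edges_tf_mirna: Path
    edges_tf_lncrna: Path
    edges_mirna_lncrna: Path
    cohorts: list[CohortPaths]
    output_dir: Path
    n_permutations: int = 1000
    alpha: float = 0.05
    paired: bool = False
    seed: int = 2016
    header: bool = False
    null_mode: str = "insertion"
    mffl_table: Path | None = None
    cerna_table: Path | None = None

    def __post_init__(self) -> None:
        for name in ("edges_tf_mirna", "edges_tf_lncrna", "edges_mirna_lncrna", "output_dir"):
            setattr(self, name, Path(getattr(self, name)))
        for c in self.cohorts:
            for name in ("expression_tf", "expression_mirna", "expression_lncrna", "samples"):
                setattr(c, name, Path(getattr(c, name)))
        if self.mffl_table is not None:
            self.mffl_table = Path(self.mffl_table)
        if self.cerna_table is not None:
            self.cerna_table = Path(self.cerna_table)

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must be in (0, 1)")
        if not self.cohorts:
            raise ConfigError("no cohorts configured")
        labels = [c.label for c in self.cohorts]
        if len(set(labels)) != len(labels):
            raise ConfigError("cohort labels must be unique")
        required = [self.edges_tf_mirna, self.edges_tf_lncrna, self.edges_mirna_lncrna]
        for c in self.cohorts:
            required.extend(c.paths())
        for p in (self.mffl_table, self.cerna_table):
            if p is not None:
                required.append(p)
        missing = [str(p) for p in required if not Path(p).exists()]
        if missing:
            raise ConfigError(f"missing input file(s): {', '.join(missing)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        base = Path(path).parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        try:
            cohorts = [
                CohortPaths(
                    label=c["label"],
                    expression_tf=resolve(c["expression_tf"]),
                    expression_mirna=resolve(c["expression_mirna"]),
                    expression_lncrna=resolve(c["expression_lncrna"]),
                    samples=resolve(c["samples"]),
                )
                for c in raw["cohorts"]
            ]
            return cls(
                edges_tf_mirna=resolve(raw["edges_tf_mirna"]),
                edges_tf_lncrna=resolve(raw["edges_tf_lncrna"]),
                edges_mirna_lncrna=resolve(raw["edges_mirna_lncrna"]),
                cohorts=cohorts,
                output_dir=resolve(raw["output_dir"]),
                n_permutations=int(raw.get("n_permutations", 1000)),
                alpha=float(raw.get("alpha", 0.05)),
                paired=bool(raw.get("paired", False)),
                seed=int(raw.get("seed", 2016)),
                header=bool(raw.get("header", False)),
                null_mode=str(raw.get("null_mode", "insertion")),
                mffl_table=resolve(raw["mffl_table"]) if raw.get("mffl_table") else None,
                cerna_table=resolve(raw["cerna_table"]) if raw.get("cerna_table") else None,
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: missing config key {exc}") from exc

    @classmethod
    def from_fixture(cls, fixture_dir, output_dir, **overrides) -> "PipelineConfig":
        """Build a config from a :func:`lfflnet.simulate.make_fixture` directory."""
        fixture_dir = Path(fixture_dir)
        with open(fixture_dir / "manifest.yaml", encoding="utf-8") as fh:
            manifest = yaml.safe_load(fh)
        cohorts = [
            CohortPaths(
                label=label,
                expression_tf=fixture_dir / info["paths"]["expression_tf"],
                expression_mirna=fixture_dir / info["paths"]["expression_mirna"],
                expression_lncrna=fixture_dir / info["paths"]["expression_lncrna"],
                samples=fixture_dir / info["paths"]["samples"],
            )
            for label, info in sorted(manifest["cohorts"].items())
        ]
        return cls(
            edges_tf_mirna=fixture_dir / manifest["edge_files"]["TF_MIRNA"],
            edges_tf_lncrna=fixture_dir / manifest["edge_files"]["TF_LNCRNA"],
            edges_mirna_lncrna=fixture_dir / manifest["edge_files"]["MIRNA_LNCRNA"],
            cohorts=cohorts,
            output_dir=Path(output_dir),
            **overrides,
        )


def _load_network(config: PipelineConfig):
    edges = (
        read_interaction_table(config.edges_tf_mirna, EdgeClass.TF_MIRNA, header=config.header)
        + read_interaction_table(config.edges_tf_lncrna, EdgeClass.TF_LNCRNA, header=config.header)
        + read_interaction_table(
            config.edges_mirna_lncrna, EdgeClass.MIRNA_LNCRNA, header=config.header
        )
    )
    net = build_network(edges)
    return net, enumerate_motifs(net)


def _cohort_seed(config: PipelineConfig, label: str) -> int:
    labels = sorted(c.label for c in config.cohorts)
    idx = labels.index(label)
    ss = np.random.SeedSequence([config.seed, idx])
    return int(ss.generate_state(1)[0] % (2**31))


def run_cohort(config: PipelineConfig, label: str):
    """Run the full per-cohort analysis; returns the dysregulation results.

    Writes ``scores.tsv``, ``dysregulated_motifs.tsv``, ``subnetwork.graphml``,
    ``survival.tsv`` (when follow-up data is present) and ``run.log`` under
    ``output_dir/<label>/``.  Partial outputs are removed on failure.
    """
    config.validate()
    by_label = {c.label: c for c in config.cohorts}
    if label not in by_label:
        raise ConfigError(f"unknown cohort label {label!r}")
    paths = by_label[label]
    outdir = config.output_dir / label
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: list[tuple[str, float]] = []

    def tick(stage: str) -> None:
        timings.append((stage, time.time() - t0))

    try:
        net, motifs = _load_network(config)
        tick("network")
        cohort = ExpressionCohort.from_tsv(
            paths.expression_tf,
            paths.expression_mirna,
            paths.expression_lncrna,
            paths.samples,
            cancer_label=label,
        )
        tick("expression")
        seed = _cohort_seed(config, label)
        model = MotifDysregulation(
            cohort, motifs, paired=config.paired, null_mode=config.null_mode
        )
        results = model.fit(
            n_permutations=config.n_permutations, alpha=config.alpha, seed=seed
        )
        results.to_tsv(outdir / "scores.tsv")
        dys = results.dysregulated_motifs()
        write_motif_table(dys, outdir / "dysregulated_motifs.tsv")
        tick("dysregulation")

        if dys:
            matrix = MotifCancerMatrix.from_dysregulated({label: dys})
            export_network(union_subnetwork(matrix), "graphml", outdir / "subnetwork.graphml")
        tick("subnetwork")

        surv_rows = []
        meta = cohort.samples
        has_followup = (
            "survival_time" in meta.columns
            and "event" in meta.columns
            and meta.loc[meta["condition"] == "tumor", "survival_time"].notna().sum() >= 4
        )
        if has_followup and dys:
            for motif in dys:
                try:
                    res = MotifPrognosis(cohort, motif).fit()
                    surv_rows.append(res.to_row())
                except DataError as exc:
                    log.warning("%s: survival skipped for %s: %s", label, motif, exc)
        elif dys:
            log.info("%s: no clinical follow-up; survival stage skipped", label)
        if surv_rows:
            pd.DataFrame(surv_rows).to_csv(outdir / "survival.tsv", sep="\t", index=False)
        tick("survival")

        with open(outdir / "run.log", "w", encoding="utf-8") as fh:
            fh.write(f"lfflnet version: {__version__}\n")
            fh.write(f"cohort: {label}\n")
            fh.write(f"master seed: {config.seed}  cohort seed: {seed}\n")
            fh.write(
                f"permutations: {config.n_permutations}  alpha: {config.alpha}  "
                f"null: {config.null_mode}  paired: {model.paired}\n"
            )
            fh.write(
                f"network: {net.n_nodes} nodes, {net.n_edges} edges, "
                f"{len(motifs)} motifs ({model.n_dropped_motifs} dropped)\n"
            )
            fh.write(f"dysregulated motifs: {len(dys)}\n")
            for stage, t in timings:
                fh.write(f"timing {stage}: {t:.2f}s\n")
        return results
    except Exception:
        shutil.rmtree(outdir, ignore_errors=True)
        raise


def run_cross_cohort(config: PipelineConfig, cohort_results: dict | None = None):
    """Motif x cancer matrix, labels, union network and cross-talk tables.

    ``cohort_results`` maps label -> MotifDysregulationResults; when omitted,
    every configured cohort is run first.  Requires >= 2 cohorts.
    """
    config.validate()
    if len(config.cohorts) < 2:
        raise ConfigError("cross-cohort comparison needs at least 2 cohorts")
    if cohort_results is None:
        cohort_results = {c.label: run_cohort(config, c.label) for c in config.cohorts}
    per_cancer = {label: res.dysregulated_motifs() for label, res in cohort_results.items()}
    outdir = config.output_dir / "cross_cohort"
    outdir.mkdir(parents=True, exist_ok=True)

    if all(len(ms) == 0 for ms in per_cancer.values()):
        raise DataError("no cohort produced any dysregulated motif")
    matrix = MotifCancerMatrix.from_dysregulated(per_cancer)
    matrix.to_tsv(outdir / "motif_cancer_matrix.tsv")
    labels = classify_common_specific(matrix)
    lab_df = labels.reset_index()
    lab_df.columns = ["tf", "mirna", "lncrna", "label"]
    lab_df.to_csv(outdir / "common_specific.tsv", sep="\t", index=False)
    export_network(union_subnetwork(matrix), "graphml", outdir / "union_subnetwork.graphml")

    all_dys = sorted({m for ms in per_cancer.values() for m in ms})
    if config.mffl_table is not None:
        pairs = find_lmffl_crosstalk(all_dys, read_mffl_table(config.mffl_table, config.header))
        pd.DataFrame(
            [
                {"tf": l.tf_id, "mirna": l.mirna_id, "lncrna": l.lncrna_id, "mrna": m.mrna_id}
                for l, m in pairs
            ],
            columns=["tf", "mirna", "lncrna", "mrna"],
        ).to_csv(outdir / "lmffl_crosstalk.tsv", sep="\t", index=False)
    if config.cerna_table is not None:
        pairs = find_cerna_crosstalk(all_dys, read_cerna_table(config.cerna_table, config.header))
        pd.DataFrame(
            [
                {"tf": l.tf_id, "mirna": l.mirna_id, "lncrna": l.lncrna_id, "mrna": c.mrna_id}
                for l, c in pairs
            ],
            columns=["tf", "mirna", "lncrna", "mrna"],
        ).to_csv(outdir / "cerna_crosstalk.tsv", sep="\t", index=False)
    return matrix, labels


def run_all(config: PipelineConfig):
    """Every cohort, then the cross-cohort comparison when >= 2 cohorts."""
    config.validate()
    results = {c.label: run_cohort(config, c.label) for c in config.cohorts}
    if len(config.cohorts) >= 2:
        run_cross_cohort(config, results)
    return results
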