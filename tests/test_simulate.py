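"""The synthetic-data generator: determinism, planted structure, survival tuning."""

import filecmp
from pathlib import Path

import numpy as np
import pytest

from lfflnet import (
    ConfigError,
    DataError,
    PlantedMotif,
    SimulationConfig,
    SurvivalSpec,
    enumerate_motifs,
    build_network,
    make_fixture,
    simulate_expression,
    simulate_interactions,
    simulate_survival,
)
from lfflnet.dysregulation import _log2p1


def _planted_cfg(seed=0, **kw):
    planted = tuple(
        PlantedMotif(i, mean_shift=2.0, rho_tumor=0.8, rho_normal=-0.45) for i in range(5)
    )
    return SimulationConfig(planted=planted, seed=seed, **kw)


class TestSimulateInteractions:
    def test_planted_triangles_guaranteed(self):
        cfg = _planted_cfg()
        motifs = set(enumerate_motifs(build_network(simulate_interactions(cfg))))
        for m in cfg.planted_motifs():
            assert m in motifs

    def test_same_seed_identical_edges(self):
        cfg = _planted_cfg(seed=4)
        assert simulate_interactions(cfg) == simulate_interactions(_planted_cfg(seed=4))

    def test_too_many_planted_rejected(self):
        planted = tuple(PlantedMotif(i) for i in range(10))
        with pytest.raises(ConfigError):
            simulate_interactions(SimulationConfig(n_tf=5, planted=planted))

    def test_preferential_attachment_more_skewed_than_uniform(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            ratios = {}
            for mode in ("preferential", "uniform"):
                cfg = SimulationConfig(attachment=mode, seed=seed)
                edges = simulate_interactions(cfg)
                outdeg = {}
                for e in edges:
                    if e.edge_class.value.startswith("TF"):
                        outdeg[e.source_id] = outdeg.get(e.source_id, 0) + 1
                degs = np.array(list(outdeg.values()), dtype=float)
                ratios[mode] = degs.max() / degs.mean()
            if ratios["preferential"] > ratios["uniform"]:
                hits += 1
        assert hits >= 0.7 * n_seeds


class TestSimulateExpression:
    def test_planted_effects_recoverable(self):
        cfg = _planted_cfg(seed=1)
        motifs = enumerate_motifs(build_network(simulate_interactions(cfg)))
        cohort = simulate_expression(cfg, motifs)
        m = cfg.planted_motif(0)
        t = _log2p1(cohort.tf.loc[m.tf_id].to_numpy())
        tm, nm = cohort.tumor_mask, cohort.normal_mask
        # planted mean shift delta=2 SD within 3 standard errors
        se = np.sqrt(1 / tm.sum() + 1 / nm.sum())
        assert abs((t[tm].mean() - t[nm].mean()) - 2.0) < 3 * se * 1.5
        # planted correlations near their targets
        l = _log2p1(cohort.lncrna.loc[m.lncrna_id].to_numpy())
        r_t = np.corrcoef(t[tm], l[tm])[0, 1]
        r_n = np.corrcoef(t[nm], l[nm])[0, 1]
        assert r_t > 0.5 and r_n < -0.1

    def test_infeasible_correlation_rejected(self):
        cfg = SimulationConfig(planted=(PlantedMotif(0, rho_normal=-0.8),))
        motifs = enumerate_motifs(build_network(simulate_interactions(cfg)))
        with pytest.raises(ConfigError, match="-0.5"):
            simulate_expression(cfg, motifs)

    def test_planted_motif_must_be_in_motif_list(self):
        cfg = _planted_cfg(seed=2)
        with pytest.raises(DataError):
            simulate_expression(cfg, motifs=[])

    def test_cohort_invariants_hold(self):
        cfg = _planted_cfg(seed=3)
        motifs = enumerate_motifs(build_network(simulate_interactions(cfg)))
        cohort = simulate_expression(cfg, motifs)
        # shared ordered sample set and non-negativity are enforced on build
        assert list(cohort.tf.columns) == list(cohort.samples.index)
        assert (cohort.lncrna.to_numpy() >= 0).all()


class TestSimulateSurvival:
    @staticmethod
    def _setup(lambda0=1e-3, n_tumor=2000, censoring=0.3, seed=5):
        cfg = SimulationConfig(
            planted=(PlantedMotif(0),),
            n_tumor=n_tumor,
            survival=SurvivalSpec(betas=(0.0, 0.0, 0.0), baseline_hazard=lambda0,
                                  censoring=censoring),
            seed=seed,
        )
        motifs = enumerate_motifs(build_network(simulate_interactions(cfg)))
        cohort = simulate_expression(cfg, motifs)
        return cfg, cohort, cfg.planted_motif(0)

    def test_null_betas_independent_of_expression(self):
        cfg, cohort, motif = self._setup(censoring=0.0)
        surv = simulate_survival(cfg, cohort, motif)
        from lfflnet.survival import standardized_motif_expression

        X = standardized_motif_expression(cohort, motif)
        r = np.corrcoef(X["tf"], np.log(surv["time"]))[0, 1]
        assert abs(r) < 0.1

    def test_doubling_hazard_halves_median_time(self):
        _, _, _ = self._setup()
        cfg1, cohort1, m1 = self._setup(lambda0=1e-3, censoring=0.0, seed=6)
        t1 = simulate_survival(cfg1, cohort1, m1)["time"].median()
        cfg2, cohort2, m2 = self._setup(lambda0=2e-3, censoring=0.0, seed=6)
        t2 = simulate_survival(cfg2, cohort2, m2)["time"].median()
        assert t1 / t2 == pytest.approx(2.0, rel=0.15)

    def test_censoring_fraction_tuned(self):
        cfg, cohort, motif = self._setup(censoring=0.3)
        surv = simulate_survival(cfg, cohort, motif)
        frac = 1 - surv["event"].mean()
        assert 0.25 <= frac <= 0.35


class TestMakeFixture:
    def test_unknown_scenario_lists_valid_names(self, tmp_path):
        with pytest.raises(ConfigError, match="planted_strong"):
            make_fixture("bogus", 0, tmp_path)

    def test_same_seed_byte_identical(self, tmp_path):
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        make_fixture("planted_strong", 9, d1)
        make_fixture("planted_strong", 9, d2)
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files
        for f in files:
            assert filecmp.cmp(d1 / f, d2 / f, shallow=False), f

    def test_multi_cancer_manifest_labels(self, tmp_path):
        manifest = make_fixture("multi_cancer", 1, tmp_path / "mc")
        assert len(manifest["cohorts"]) == 3
        labels = manifest["expected_labels"]
        assert set(labels.values()) <= {"common", "specific"}
        # the motif planted in all three cohorts must be common
        planted_all = [
            set("|".join((p["tf"], p["mirna"], p["lncrna"])) for p in info["planted"])
            for info in manifest["cohorts"].values()
        ]
        shared = set.intersection(*planted_all)
        assert shared and all(labels[k] == "common" for k in shared)

    def test_survival_linked_writes_followup(self, tmp_path):
        import pandas as pd

        make_fixture("survival_linked", 2, tmp_path / "sv")
        samples = pd.read_csv(
            tmp_path / "sv" / "cohorts" / "COHORT1" / "samples.tsv", sep="\t", index_col=0
        )
        tumor = samples[samples["condition"] == "tumor"]
        assert tumor["survival_time"].notna().all()
        assert tumor["event"].isin([0, 1]).all()
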