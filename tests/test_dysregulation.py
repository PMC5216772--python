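"""Dysregulation scores, rank aggregation and the permutation null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lfflnet import (
    DataError,
    ExpressionCohort,
    LFFLMotif,
    MotifDysregulation,
    NodeClass,
    PlantedMotif,
    SimulationConfig,
    aggregate_ranks,
    compute_score_cor,
    compute_score_diff,
    differential_expression,
    identify_dysregulated,
    motif_correlations,
    permutation_pvalues,
    simulate_expression,
    simulate_interactions,
)
from lfflnet.dysregulation import MotifScore, _rowwise_pcc, _welch_p
from lfflnet.network import build_network, enumerate_motifs

from conftest import make_cohort


def _strong_planted_setup(seed, delta=2.0, n_planted=5):
    cfg = SimulationConfig(
        planted=tuple(
            PlantedMotif(i, mean_shift=delta, rho_tumor=0.8, rho_normal=-0.45)
            for i in range(n_planted)
        ),
        seed=seed,
    )
    motifs = enumerate_motifs(build_network(simulate_interactions(cfg)))
    cohort = simulate_expression(cfg, motifs)
    return cfg, motifs, cohort


# ---------------------------------------------------------------------------
# score formulas
# ---------------------------------------------------------------------------
class TestScoreFormulas:
    def test_score_diff_is_plain_product(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=3)
            assert compute_score_diff(*p) == pytest.approx(p[0] * p[1] * p[2], abs=1e-15)

    def test_score_diff_identity_and_bounds(self):
        assert compute_score_diff(1.0, 1.0, 1.0) == 1.0
        assert compute_score_diff(0.1, 0.1, 0.1) == pytest.approx(1e-3)
        assert compute_score_diff(0.05, 1.0, 1.0) == pytest.approx(0.05)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                compute_score_diff(bad, 0.5, 0.5)

    def test_score_cor_is_abs_product_of_differences(self, rng):
        for _ in range(20):
            c = rng.uniform(-1, 1, size=6)
            expected = abs((c[0] - c[3]) * (c[1] - c[4]) * (c[2] - c[5]))
            assert compute_score_cor(*c) == pytest.approx(expected, abs=1e-15)

    def test_score_cor_boundary_cases(self):
        assert compute_score_cor(0.3, -0.2, 0.7, 0.3, -0.2, 0.7) == 0.0
        assert compute_score_cor(1, 1, 1, -1, -1, -1) == 8.0
        assert compute_score_cor(0.5, 0, 0, 0, 0, 0) == 0.0
        with pytest.raises(ValueError):
            compute_score_cor(1.2, 0, 0, 0, 0, 0)

    @settings(derandomize=True, max_examples=50)
    @given(
        c=st.lists(st.floats(-1, 1, allow_nan=False), min_size=6, max_size=6)
    )
    def test_score_cor_sign_flip_invariance(self, c):
        flipped = [-x for x in c]
        assert compute_score_cor(*c) == pytest.approx(compute_score_cor(*flipped))

    @settings(derandomize=True, max_examples=50)
    @given(
        p=st.lists(st.floats(1e-6, 1.0, allow_nan=False), min_size=3, max_size=3),
        bump=st.floats(1.0, 10.0),
    )
    def test_score_diff_monotone_in_each_pvalue(self, p, bump):
        base = compute_score_diff(*p)
        for i in range(3):
            q = list(p)
            q[i] = min(1.0, q[i] * bump)
            assert compute_score_diff(*q) >= base - 1e-18


# ---------------------------------------------------------------------------
# differential expression and correlations
# ---------------------------------------------------------------------------
class TestDifferentialExpression:
    def test_identical_groups_give_p_one(self, rng):
        cohort = make_cohort(rng)
        vals = cohort.tf.loc["T0"].to_numpy().copy()
        vals[cohort.tumor_mask] = vals[cohort.normal_mask]
        cohort.tf.loc["T0"] = vals
        assert differential_expression(cohort, "T0", NodeClass.TF) == 1.0

    def test_large_shift_is_significant(self, rng):
        cohort = make_cohort(rng, n_tumor=20, n_normal=20)
        x = np.exp2(rng.normal(5, 1, 40)) - 1
        x[:20] = np.exp2(np.log2(x[20:] + 1) + 10) - 1
        cohort.tf.loc["T0"] = x
        assert differential_expression(cohort, "T0", NodeClass.TF) < 1e-6

    def test_matches_scipy_welch(self, rng):
        cohort = make_cohort(rng)
        p = differential_expression(cohort, "M1", NodeClass.MIRNA)
        x = np.log2(cohort.mirna.loc["M1"].to_numpy() + 1)
        ref = stats.ttest_ind(
            x[cohort.tumor_mask], x[cohort.normal_mask], equal_var=False
        ).pvalue
        assert p == pytest.approx(ref, rel=1e-12)

    def test_paired_zero_offset_gives_p_one(self, rng):
        cohort = make_cohort(rng)
        # normal value of each patient replicated in the tumour sample
        vals = cohort.lncrna.loc["L0"].to_numpy().copy()
        vals[cohort.tumor_mask] = vals[cohort.normal_mask]
        cohort.lncrna.loc["L0"] = vals
        assert differential_expression(cohort, "L0", NodeClass.LNCRNA, paired=True) == 1.0

    def test_missing_transcript_rejected(self, rng):
        with pytest.raises(DataError):
            differential_expression(make_cohort(rng), "nope", NodeClass.TF)

    def test_welch_kernel_degenerate_rows(self):
        a = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        b = np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        p = _welch_p(a, b)
        assert p[0] == 1.0
        assert p[1] < 1e-200


class TestMotifCorrelations:
    def test_linear_relation_gives_unit_pcc(self, rng):
        cohort = make_cohort(rng)
        motif = LFFLMotif("T0", "M0", "L0")
        # L0 = exact linear function of T0 on the log scale, both conditions
        logt = np.log2(cohort.tf.loc["T0"].to_numpy() + 1)
        cohort.lncrna.loc["L0"] = np.exp2(2 * logt) - 1
        c = motif_correlations(cohort, motif)
        assert c.c_tl == pytest.approx(1.0)
        assert c.n_tl == pytest.approx(1.0)

    def test_sign_flip_between_conditions(self, rng):
        cohort = make_cohort(rng)
        logt = np.log2(cohort.tf.loc["T0"].to_numpy() + 1)
        y = logt.copy()
        center = logt.mean()
        y[cohort.tumor_mask] = 2 * center - logt[cohort.tumor_mask]  # reflected
        cohort.mirna.loc["M0"] = np.maximum(np.exp2(y) - 1, 0)
        c = motif_correlations(cohort, LFFLMotif("T0", "M0", "L0"))
        assert c.c_tm == pytest.approx(-1.0)
        assert c.n_tm == pytest.approx(1.0)

    def test_matches_scipy_pearsonr(self, rng):
        cohort = make_cohort(rng)
        c = motif_correlations(cohort, LFFLMotif("T1", "M1", "L1"))
        t = np.log2(cohort.tf.loc["T1"].to_numpy() + 1)
        m = np.log2(cohort.mirna.loc["M1"].to_numpy() + 1)
        ref = stats.pearsonr(t[cohort.tumor_mask], m[cohort.tumor_mask]).statistic
        assert c.c_tm == pytest.approx(ref, rel=1e-10)

    def test_zero_variance_maps_to_zero(self):
        x = np.array([[1.0, 1.0, 1.0]])
        y = np.array([[1.0, 2.0, 3.0]])
        assert _rowwise_pcc(x, y)[0] == 0.0

    def test_independent_draws_small_pcc(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 200))
        y = rng.normal(size=(1, 200))
        assert abs(_rowwise_pcc(x, y)[0]) < 0.2


# ---------------------------------------------------------------------------
# rank aggregation
# ---------------------------------------------------------------------------
def _score(i, sd, sc):
    return MotifScore(
        motif=LFFLMotif(f"T{i}", f"M{i}", f"L{i}"),
        p_t=1, p_m=1, p_l=1, c_tm=0, c_tl=0, c_ml=0, n_tm=0, n_tl=0, n_ml=0,
        score_diff=sd, score_cor=sc,
    )


class TestAggregateRanks:
    def test_single_motif(self):
        out = aggregate_ranks([_score(0, 0.5, 1.0)])
        assert out[0].rank_diff == 1 and out[0].rank_cor == 1
        assert out[0].final_score == 1

    def test_dominating_motif(self):
        out = aggregate_ranks([_score(0, 1e-6, 5.0), _score(1, 0.9, 0.1)])
        assert [s.final_score for s in out] == [1.0, 2.0]

    def test_matches_pairwise_comparison_oracle(self, rng):
        scores = [_score(i, rng.uniform(), rng.uniform(0, 8)) for i in range(20)]
        out = aggregate_ranks(scores)
        # oracle: rank = 1 + number of strictly better competitors (no ties here)
        for s in out:
            rd = 1 + sum(1 for t in scores if t.score_diff < s.score_diff)
            rc = 1 + sum(1 for t in scores if t.score_cor > s.score_cor)
            assert s.rank_diff == rd and s.rank_cor == rc
            assert s.final_score == (rd + rc) / 2

    def test_order_invariant_and_bounded(self, rng):
        scores = [_score(i, rng.uniform(), rng.uniform(0, 8)) for i in range(15)]
        out1 = {s.motif: s.final_score for s in aggregate_ranks(scores)}
        shuffled = list(scores)
        rng.shuffle(shuffled)
        out2 = {s.motif: s.final_score for s in aggregate_ranks(shuffled)}
        assert out1 == out2
        assert all(1 <= f <= 15 for f in out1.values())

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            aggregate_ranks([])


# ---------------------------------------------------------------------------
# permutation null and the full model
# ---------------------------------------------------------------------------
class TestPermutation:
    def test_reproducible_given_seed(self, rng):
        _, motifs, cohort = _strong_planted_setup(seed=5)
        p1 = permutation_pvalues(cohort, motifs, n_permutations=50, seed=11)
        p2 = permutation_pvalues(cohort, motifs, n_permutations=50, seed=11)
        assert np.array_equal(p1, p2)
        p3 = permutation_pvalues(cohort, motifs, n_permutations=50, seed=12)
        assert not np.array_equal(p1, p3)

    def test_bounds_and_floor(self):
        _, motifs, cohort = _strong_planted_setup(seed=6)
        B = 99
        p = permutation_pvalues(cohort, motifs, n_permutations=B, seed=0)
        assert np.all(p >= 1 / (B + 1)) and np.all(p <= 1.0)
        # the strongest planted motif beats every permutation: P hits the floor
        assert p.min() == pytest.approx(1 / (B + 1))

    def test_planted_motifs_flagged(self):
        cfg, motifs, cohort = _strong_planted_setup(seed=7)
        table = identify_dysregulated(cohort, motifs, n_permutations=100, seed=3)
        flagged = {
            (r.tf, r.mirna, r.lncrna)
            for r in table[table.dysregulated == True].itertuples()  # noqa: E712
        }
        planted = {m.as_tuple() for m in cfg.planted_motifs()}
        assert planted <= flagged

    def test_motif_missing_from_expression_dropped(self):
        _, motifs, cohort = _strong_planted_setup(seed=8)
        extra = LFFLMotif("TF999", "miR999", "lnc999")
        model = MotifDysregulation(cohort, motifs + [extra])
        assert model.n_dropped_motifs == 1
        assert len(model.motifs) == len(motifs)

    def test_no_covered_motif_is_error(self, rng):
        cohort = make_cohort(rng)
        with pytest.raises(DataError):
            MotifDysregulation(cohort, [LFFLMotif("X", "Y", "Z")])

    def test_reranked_null_flags_fewer_than_insertion(self):
        """Full re-ranking is rank-granular and flags far fewer motifs."""
        _, motifs, cohort = _strong_planted_setup(seed=9)
        counts = {}
        for mode in ("insertion", "reranked"):
            table = identify_dysregulated(
                cohort, motifs, n_permutations=100, seed=3, null_mode=mode
            )
            counts[mode] = int((table.perm_p < 0.05).sum())
        assert counts["reranked"] < counts["insertion"]

    def test_paired_fit_has_no_perm_p(self):
        _, motifs, cohort = _strong_planted_setup(seed=10)
        res = MotifDysregulation(cohort, motifs, paired=True).fit(n_permutations=10)
        assert res.table["perm_p"].isna().all()
        assert res.model.paired


class TestCohortValidation:
    def test_misaligned_columns_rejected(self, rng):
        cohort = make_cohort(rng)
        with pytest.raises(DataError):
            ExpressionCohort(
                tf=cohort.tf,
                mirna=cohort.mirna.iloc[:, ::-1],
                lncrna=cohort.lncrna,
                samples=cohort.samples,
            )

    def test_negative_values_rejected(self, rng):
        cohort = make_cohort(rng)
        tf = cohort.tf.copy()
        tf.iloc[0, 0] = -1.0
        with pytest.raises(DataError):
            ExpressionCohort(tf=tf, mirna=cohort.mirna, lncrna=cohort.lncrna,
                             samples=cohort.samples)

    def test_too_few_normals_rejected(self, rng):
        with pytest.raises(DataError):
            make_cohort(rng, n_normal=1)

    def test_tsv_round_trip(self, rng, tmp_path):
        cohort = make_cohort(rng)
        cohort.to_tsv(tmp_path)
        back = ExpressionCohort.from_tsv(
            tmp_path / "expression_tf.tsv",
            tmp_path / "expression_mirna.tsv",
            tmp_path / "expression_lncrna.tsv",
            tmp_path / "samples.tsv",
        )
        pd.testing.assert_frame_equal(cohort.tf, back.tf, check_names=False)
        assert list(back.samples["condition"]) == list(cohort.samples["condition"])
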