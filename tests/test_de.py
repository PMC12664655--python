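"""Engine contracts: BH oracle, rank-sum enumeration, symmetry, weights,
moderation machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from httrscreen.de import (
    DEDesign,
    ENGINES,
    _ls_fit,
    adjust_bh,
    de_ranksum,
    de_trend,
    de_voom,
    de_with_weights,
    squeeze_var,
    trigamma_inverse,
)
from scipy.special import polygamma

ALL_ENGINES = tuple(ENGINES)


def brute_force_bh(p):
    """O(m^2) transcription of the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos - 1, m)
        ]
        adj[idx] = min(1.0, min(candidates))
    return adj


class TestAdjustBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagation(self):
        out = adjust_bh([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        # m = 2 for the finite entries
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.04])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, pvals):
        np.testing.assert_allclose(adjust_bh(pvals), brute_force_bh(pvals))

    def test_monotone_in_sorted_order(self, rng):
        p = rng.random(100)
        adj = adjust_bh(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


def enumerate_ranksum_p(x, y):
    """Exact two-sided rank-sum p by full enumeration of group splits."""
    pooled = np.concatenate([x, y])
    n_x = len(x)
    obs_u = sum(1 for xi in x for yi in y if xi > yi) + 0.5 * sum(
        1 for xi in x for yi in y if xi == yi
    )
    mean_u = n_x * len(y) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_x):
        xs = pooled[list(combo)]
        ys = np.delete(pooled, list(combo))
        u = sum(1 for xi in xs for yi in ys if xi > yi) + 0.5 * sum(
            1 for xi in xs for yi in ys if xi == yi
        )
        total += 1
        if abs(u - mean_u) >= abs(obs_u - mean_u) - 1e-12:
            count += 1
    return count / total


def two_group_screen(treat, ctrl):
    """Build a 1..G gene screen from explicit per-well count columns."""
    from tests.test_qc import make_screen

    values = np.hstack([np.asarray(ctrl), np.asarray(treat)])
    n_c = np.asarray(ctrl).shape[1]
    n_t = np.asarray(treat).shape[1]
    screen = make_screen(
        values, treatments=["DMSO"] * n_c + ["drug"] * n_t
    )
    screen.metadata.table.loc[: n_c - 1, "sample_type"] = "vehicle"
    design = DEDesign(
        treatment_wells=np.arange(n_c, n_c + n_t),
        control_wells=np.arange(n_c),
    )
    return screen, design


class TestRanksum:
    def test_exact_small_case(self):
        # gene 0 CPM values {1,2}-like vs {3,4}-like: 2 of C(4,2)=6
        # orderings as extreme -> p = 1/3.  A filler gene keeps library
        # sizes equal so CPM preserves the raw ordering.
        screen, design = two_group_screen(
            treat=[[1000, 2000], [9000, 8000]], ctrl=[[3000, 4000], [7000, 6000]]
        )
        res = de_ranksum(screen, design)
        assert res.table["pvalue"][0] == pytest.approx(1 / 3)

    def test_identical_groups(self):
        screen, design = two_group_screen(
            treat=[[10, 10], [7, 7]], ctrl=[[10, 10], [7, 7]]
        )
        res = de_ranksum(screen, design)
        np.testing.assert_allclose(res.table["pvalue"], 1.0)
        np.testing.assert_allclose(res.table["log2fc"], 0.0)

    def test_asymptotic_close_to_enumeration_6v6(self, rng):
        treat = rng.poisson(40, size=(100, 6)) + 1
        ctrl = rng.poisson(40, size=(100, 6)) + 1
        screen, design = two_group_screen(treat, ctrl)
        res = de_ranksum(screen, design)
        from httrscreen.normalize import norm_cpm

        cpm, _ = norm_cpm(np.hstack([ctrl, treat]).astype(float))
        worst = 0.0
        for g in range(25):  # enumeration is C(12,6)=924 splits per gene
            p_exact = enumerate_ranksum_p(cpm[g, 6:], cpm[g, :6])
            worst = max(worst, abs(p_exact - res.table["pvalue"][g]))
        assert worst < 0.02


class TestEngineSymmetry:
    @pytest.mark.parametrize("engine", ALL_ENGINES)
    def test_label_swap_negates_lfc(self, engine, signal_screen):
        screen, _ = signal_screen
        treat = screen.wells_for("campto")
        ctrl = screen.vehicle_wells()
        fwd = ENGINES[engine](screen, DEDesign(treat, ctrl))
        rev = ENGINES[engine](screen, DEDesign(ctrl, treat))
        np.testing.assert_allclose(
            fwd.table["log2fc"], -rev.table["log2fc"], atol=1e-6
        )
        np.testing.assert_allclose(
            fwd.table["pvalue"], rev.table["pvalue"], atol=1e-6
        )

    @pytest.mark.parametrize("engine", ALL_ENGINES)
    def test_gene_permutation_equivariance(self, engine, signal_screen):
        screen, _ = signal_screen
        design = DEDesign(screen.wells_for("campto"), screen.vehicle_wells())
        base = ENGINES[engine](screen, design).table.set_index("gene_id")
        rng = np.random.default_rng(3)
        perm = rng.permutation(screen.n_genes)
        from httrscreen.plate_io import Screen

        shuffled = Screen(
            screen.counts.subset_genes(perm), screen.metadata, ["shuffled"]
        )
        out = ENGINES[engine](shuffled, design).table.set_index("gene_id")
        np.testing.assert_allclose(
            base.loc[out.index, "pvalue"], out["pvalue"], atol=1e-9
        )

    @pytest.mark.parametrize("engine", ALL_ENGINES)
    def test_pvalues_in_unit_interval(self, engine, null_screen):
        screen, _ = null_screen
        design = DEDesign(screen.wells_for("sham"), screen.vehicle_wells())
        p = ENGINES[engine](screen, design).table["pvalue"].dropna()
        assert ((p >= 0) & (p <= 1)).all()


class TestTrendVsVoom:
    def test_rank_correlation_without_mean_variance_trend(self, rng):
        # counts at a common abundance: no trend for voom's weights to chase
        treat = rng.poisson(200, size=(300, 4))
        ctrl = rng.poisson(200, size=(300, 4))
        screen, design = two_group_screen(treat, ctrl)
        pv = de_voom(screen, design).table["pvalue"]
        pt = de_trend(screen, design).table["pvalue"]
        rho = pd.Series(pv).corr(pd.Series(pt), method="spearman")
        assert rho > 0.95

    def test_constant_gene_has_zero_lfc(self):
        # equal library sizes (140 per well) so the constant gene stays
        # constant after normalisation
        with pytest.warns(UserWarning, match="fewer than 10"):
            screen, design = two_group_screen(
                treat=[[50, 50, 50], [10, 30, 50], [80, 60, 40]],
                ctrl=[[50, 50, 50], [20, 40, 20], [70, 50, 70]],
            )
            res = de_trend(screen, design)
        assert res.table["log2fc"][0] == pytest.approx(0.0, abs=1e-9)


class TestWeights:
    @pytest.mark.parametrize("engine", ["nbql", "voom"])
    def test_all_ones_weights_identical(self, engine, signal_screen):
        screen, _ = signal_screen
        design = DEDesign(screen.wells_for("campto"), screen.vehicle_wells())
        plain = ENGINES[engine](screen, design)
        ones = np.ones_like(screen.counts.values, dtype=float)
        weighted = de_with_weights(engine, screen, design, ones)
        pd.testing.assert_frame_equal(plain.table, weighted.table)

    def test_unsupported_engine_rejected(self, signal_screen):
        screen, _ = signal_screen
        design = DEDesign(screen.wells_for("campto"), screen.vehicle_wells())
        with pytest.raises(ValueError, match="nbql"):
            de_with_weights("ranksum", screen, design,
                            np.ones_like(screen.counts.values, dtype=float))

    def test_zero_weight_equals_removal_in_least_squares(self, rng):
        # the contract the engines rely on: weight 0 on an observation is
        # the same as leaving that observation out of the fit
        y = rng.normal(size=(20, 8))
        X = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
        w = np.ones_like(y)
        w[:, 2] = 0.0
        beta_w, _, _, _, _ = _ls_fit(y, X, w)
        beta_drop = np.linalg.lstsq(
            np.delete(X, 2, axis=0), np.delete(y, 2, axis=1).T, rcond=None
        )[0].T
        np.testing.assert_allclose(beta_w, beta_drop, atol=1e-8)

    def test_dropout_bias_reduced_by_weights(self):
        from httrscreen.zinb import estimate_zinb_weights
        from tests.test_qc import make_screen

        biases_w, biases_u = [], []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            g, n_t, n_c = 80, 3, 10
            mu = 200.0
            lfc = np.zeros(g)
            lfc[:20] = 2.0
            theta = 5.0
            ctrl = rng.negative_binomial(theta, theta / (theta + mu), (g, n_c))
            mu_t = mu * 2.0**lfc
            treat = rng.negative_binomial(
                theta, theta / (theta + mu_t[:, None]), (g, n_t)
            )
            counts = np.hstack([ctrl, treat])
            drop = rng.random(counts.shape) < 0.3
            counts = np.where(drop, 0, counts)
            screen, design = two_group_screen(counts[:, n_c:], counts[:, :n_c])
            grouping = np.array([0] * n_c + [1] * n_t)
            _, weights = estimate_zinb_weights(
                screen.counts.values, np.ones(n_c + n_t), grouping
            )
            res_w = de_with_weights("voom", screen, design, weights)
            res_u = de_voom(screen, design)
            est_w = res_w.table["log2fc"][:20].mean()
            est_u = res_u.table["log2fc"][:20].mean()
            biases_w.append(est_w - 2.0)
            biases_u.append(est_u - 2.0)
        assert abs(np.mean(biases_w)) < abs(np.mean(biases_u))

    def test_dimension_mismatch(self, signal_screen):
        screen, _ = signal_screen
        design = DEDesign(screen.wells_for("campto"), screen.vehicle_wells())
        with pytest.raises(ValueError, match="shape"):
            de_with_weights("voom", screen, design, np.ones((3, 3)))


class TestModeration:
    def test_trigamma_inverse_roundtrip(self):
        for x in (0.01, 0.1, 1.0, 5.0):
            assert polygamma(1, trigamma_inverse(x)) == pytest.approx(x, rel=1e-8)

    def test_posterior_variance_identity(self, rng):
        s_sq = rng.chisquare(6, 200) / 6 * 2.5
        eb = squeeze_var(s_sq, df=6)
        if np.isfinite(eb.d0):
            expected = (eb.d0 * eb.s0_sq + 6 * s_sq) / (eb.d0 + 6)
            np.testing.assert_allclose(eb.s_post_sq, expected)

    def test_constant_variances_give_complete_shrinkage(self):
        with pytest.warns(UserWarning, match="complete shrinkage"):
            eb = squeeze_var(np.full(50, 2.0), df=4)
        assert np.isinf(eb.d0)
        np.testing.assert_allclose(eb.s_post_sq, eb.s0_sq)

    def test_prior_df_recovery(self, rng):
        # s^2 ~ s0^2 * F(d, d0): moment matching should land near d0
        d, d0, s0 = 10, 20.0, 1.5
        s_sq = s0 * rng.f(d, d0, size=20000) * 1.0
        eb = squeeze_var(s_sq, df=d)
        assert 0.5 * d0 < eb.d0 < 2.0 * d0


class TestDesignValidation:
    def test_overlapping_wells_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            DEDesign(np.array([1, 2]), np.array([2, 3]))

    def test_single_well_warns(self):
        with pytest.warns(UserWarning, match="single well"):
            DEDesign(np.array([1]), np.array([2, 3]))

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError, match="at least one well"):
            DEDesign(np.array([], dtype=int), np.array([1, 2]))
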