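"""Update policies, PEV/CD criteria vs the MME-inverse oracle, exchange search."""

import itertools

import numpy as np
import pytest

from gssim import gp_engine as gp, tp_update as tu


def _toy_ctx(n=6, n_targets=2, seed=0, sigma2_e=1.5, sigma2_a=2.0,
             ridge=1e-6):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 12))
    A = X @ X.T / 12 + 0.5 * np.eye(n)  # well-conditioned PSD relationship
    C = tu.build_contrasts(np.arange(n_targets), n)
    return tu.OptimizationContext(A=A, sigma2_e=sigma2_e, sigma2_a=sigma2_a,
                                  C=C, ridge=ridge)


def _mme_oracle(ctx, phenotyped):
    """PEV and CD from the explicitly inverted mixed-model coefficient matrix."""
    n = ctx.A.shape[0]
    idx = np.asarray(phenotyped)
    nobs = len(idx)
    A_r = ctx.A + ctx.ridge * np.diag(ctx.A).mean() * np.eye(n)
    lam = ctx.sigma2_e / ctx.sigma2_a
    Zi = np.zeros((nobs, n))
    Zi[np.arange(nobs), idx] = 1.0
    X = np.ones((nobs, 1))
    top = np.block([[X.T @ X, X.T @ Zi],
                    [Zi.T @ X, Zi.T @ Zi + lam * np.linalg.inv(A_r)]])
    Cgg = np.linalg.inv(top)[1:, 1:]
    quad = np.einsum("it,ij,jt->t", ctx.C, Cgg, ctx.C)
    pev = ctx.sigma2_e * quad / (ctx.C * ctx.C).sum(axis=0)
    cac = np.einsum("it,ij,jt->t", ctx.C, A_r, ctx.C)
    cd = 1.0 - ctx.sigma2_e * quad / (ctx.sigma2_a * cac)
    return pev, cd


class TestContrasts:
    def test_single_target_column(self):
        C = tu.build_contrasts([0], 4)
        assert np.allclose(C[:, 0], [0.75, -0.25, -0.25, -0.25])

    def test_columns_sum_to_zero(self):
        C = tu.build_contrasts([1, 3, 4], 9)
        assert np.allclose(C.sum(axis=0), 0.0)

    def test_degenerate_pool_rejected(self):
        with pytest.raises(ValueError):
            tu.build_contrasts([0], 1)
        with pytest.raises(ValueError):
            tu.build_contrasts([], 5)


class TestPEVandCD:
    @pytest.mark.parametrize("phenotyped", [[0, 2, 4], [1, 3], [0, 1, 2, 3],
                                            [5]])
    def test_matches_mme_inverse_oracle(self, phenotyped):
        ctx = _toy_ctx()
        pev = tu.pev_of_contrasts(ctx, phenotyped)
        cd = tu.cd_of_contrasts(ctx, phenotyped)
        pev_o, cd_o = _mme_oracle(ctx, phenotyped)
        assert np.allclose(pev, pev_o, atol=1e-8)
        assert np.allclose(cd, cd_o, atol=1e-8)

    def test_pev_nonnegative_cd_in_unit_interval(self):
        ctx = _toy_ctx(seed=3)
        for subset in ([0], [0, 3], [1, 2, 4, 5]):
            pev = tu.pev_of_contrasts(ctx, subset)
            cd = tu.cd_of_contrasts(ctx, subset)
            assert np.all(pev >= 0)
            assert np.all((cd >= 0) & (cd <= 1 + 1e-12))

    def test_more_phenotypes_never_hurt(self):
        ctx = _toy_ctx(seed=5)
        base = [1, 4]
        pev0 = tu.pev_of_contrasts(ctx, base)
        for extra in set(range(6)) - set(base):
            pev1 = tu.pev_of_contrasts(ctx, base + [extra])
            assert np.all(pev1 <= pev0 + 1e-10)

    def test_no_phenotypes_gives_zero_cd(self):
        ctx = _toy_ctx()
        assert np.allclose(tu.cd_of_contrasts(ctx, []), 0.0)

    def test_phenotyping_the_target_beats_bystanders(self):
        ctx = _toy_ctx(seed=7, n_targets=1)
        cd_self = tu.cd_of_contrasts(ctx, [0, 5])[0]
        cd_other = tu.cd_of_contrasts(ctx, [4, 5])[0]
        assert cd_self > cd_other

    def test_single_observation_carries_no_information(self):
        # one phenotyped record is fully absorbed by the grand mean
        ctx = _toy_ctx(seed=7, n_targets=1)
        assert tu.cd_of_contrasts(ctx, [0])[0] == pytest.approx(0.0)


class TestExchange:
    def test_zero_iterations_returns_seeded_start(self):
        ctx = _toy_ctx()
        rng = np.random.default_rng(9)
        expected = np.sort(np.random.default_rng(9).choice(6, 2,
                                                           replace=False))
        got = tu.exchange_optimize("pevmean", ctx, 6, n_select=2,
                                   iterations=0, rng=rng)
        assert np.array_equal(got, expected)

    @pytest.mark.parametrize("criterion", ["pevmean", "cdmean"])
    def test_finds_exhaustive_optimum(self, criterion):
        ctx = _toy_ctx(seed=11)
        values = {}
        for subset in itertools.combinations(range(6), 2):
            values[subset] = tu._criterion_value(criterion, ctx,
                                                 np.array(subset))
        best = (min if criterion == "pevmean" else max)(values.values())
        got = tu.exchange_optimize(criterion, ctx, 6, n_select=2,
                                   iterations=200,
                                   rng=np.random.default_rng(2))
        assert tu._criterion_value(criterion, ctx, got) == pytest.approx(best)

    def test_trajectory_monotone(self):
        ctx = _toy_ctx(seed=13)
        _, traj = tu.exchange_optimize("pevmean", ctx, 6, n_select=3,
                                       iterations=50,
                                       rng=np.random.default_rng(3),
                                       return_trajectory=True)
        assert np.all(np.diff(traj) <= 1e-15)
        _, traj = tu.exchange_optimize("cdmean", ctx, 6, n_select=3,
                                       iterations=50,
                                       rng=np.random.default_rng(3),
                                       return_trajectory=True)
        assert np.all(np.diff(traj) >= -1e-15)


class TestSelectUpdateSet:
    def test_rank_methods_on_distinct_predictions(self, rng):
        g = rng.permutation(1000).astype(float)
        parents = gp.select_parents(g, 100, np.random.default_rng(0))
        top = tu.select_update_set("top", g, parents, rng=rng)
        bottom = tu.select_update_set("bottom", g, parents, rng=rng)
        tails = tu.select_update_set("tails", g, parents, rng=rng)
        assert len(top) == len(bottom) == len(tails) == 150
        # Top additions contain all 100 parents; Tails contain 75 of them
        assert len(np.intersect1d(top, parents)) == 100
        assert len(np.intersect1d(tails, parents)) == 75
        assert len(np.intersect1d(bottom, parents)) == 0
        assert g[top].min() > g[np.setdiff1d(np.arange(1000), top)].max()

    def test_forced_selection_small_pool(self, rng):
        g = rng.normal(size=150)
        parents = np.arange(100)
        for name in ("top", "bottom", "tails", "random"):
            got = tu.select_update_set(name, g, parents, rng=rng)
            assert sorted(got) == list(range(150))

    def test_nochange_returns_empty(self, rng):
        got = tu.select_update_set("nochange", np.zeros(10), [0], rng=rng)
        assert len(got) == 0

    def test_criterion_method_needs_context(self, rng):
        with pytest.raises(ValueError):
            tu.select_update_set("pevmean", np.zeros(200), [0, 1], rng=rng)

    def test_criterion_method_runs_on_small_pool(self, rng):
        n = 40
        X = rng.normal(size=(n, 30))
        A = X @ X.T / 30 + 0.3 * np.eye(n)
        eff = gp.MarkerEffects(0.0, np.zeros(25), 0.2, 1.0, np.arange(25))
        method = tu.UpdateMethod("cdmean", n_add=10, exchange_iterations=60)
        got = tu.select_update_set(method, rng.normal(size=n),
                                   np.arange(5), eff, A, rng)
        assert len(got) == 10
        assert np.all((got >= 0) & (got < n))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            tu.UpdateMethod("best")
        with pytest.raises(ValueError):
            tu.UpdateMethod("tails", n_add=151)


class TestApplyScenario:
    def _tp(self, n, cycle):
        Z = np.ones((n, 4), dtype=np.int8)
        return gp.TrainingSet([f"c{cycle}_{i}" for i in range(n)], Z,
                              np.zeros(n), np.full(n, cycle, int))

    def test_cumulative_growth_to_full_size(self):
        tp = self._tp(764, 0)
        for cycle in range(1, 15):
            tp = tu.apply_scenario(tp, self._tp(150, cycle), "cumulative")
        assert len(tp) == 2864

    def test_window_holds_size(self, rng):
        tp = self._tp(764, 0)
        for cycle in range(1, 8):
            tp = tu.apply_scenario(tp, self._tp(150, cycle), "window",
                                   window_size=764, rng=rng)
            assert len(tp) == 764

    def test_window_exhausts_base_then_oldest(self, rng):
        # 764 base lines, 150 discarded per update: 14 base lines remain
        # before update 6; update 6 removes them plus 136 cycle-1 lines
        tp = self._tp(764, 0)
        for cycle in range(1, 7):
            tp = tu.apply_scenario(tp, self._tp(150, cycle), "window",
                                   window_size=764, rng=rng)
        assert np.sum(tp.cycle_of_origin == 0) == 0
        assert np.sum(tp.cycle_of_origin == 1) == 150 - 136
        assert len(tp) == 764

    def test_no_additions_is_identity(self):
        tp = self._tp(20, 0)
        out = tu.apply_scenario(tp, None, "window", window_size=20)
        assert out is tp

    def test_oversized_window_errors(self, rng):
        tp = self._tp(10, 0)
        with pytest.raises(ValueError):
            tu.apply_scenario(tp, self._tp(5, 1), "window", window_size=20,
                              rng=rng)
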