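"""Structured variational inference: sum-product against exhaustive
enumeration, coordinate updates against direct evaluation, ELBO properties
and end-to-end fits on tiny genomes."""

from dataclasses import replace
from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

import clonebreak as cb
from clonebreak import inference as inf
from clonebreak.segments import Breakend, Breakpoint

from conftest import small_scenario, tiny_segments


def make_model(n_seg=6, breakpoints=(), max_total=4, b_max=2, lam=1.0,
               seed=0, **cfg_kwargs):
    """Small one-chromosome, one-tumour-clone chain with random counts."""
    rng = np.random.default_rng(seed)
    seg = tiny_segments(n_seg)
    seg["readcount"] = rng.poisson(10_000, size=n_seg)
    n_allele = rng.binomial(seg["readcount"], 0.25)
    xa = rng.binomial(n_allele, 0.55)
    seg["allele_a_readcount"] = xa
    seg["allele_b_readcount"] = n_allele - xa
    config = cb.FitConfig(n_tumour_clones=1, max_total_copies=max_total,
                          b_max=b_max, lam=lam, **cfg_kwargs)
    bps = []
    for i, (left, right, o1, o2) in enumerate(breakpoints):
        bps.append(Breakpoint(
            f"bp{i}",
            Breakend("1", left * 500_000, o1),
            Breakend("1", right * 500_000, o2)))
    return inf.ChainModel(seg, bps, config)


def random_state(model, seed=0):
    rng = np.random.default_rng(seed)
    h = np.array([0.005, 0.005])
    state = inf.VariationalState(model, h)
    if model.n_breakpoints:
        q = rng.random(state.q_bp.shape)
        state.q_bp = q / q.sum(axis=1, keepdims=True)
    inf.build_chain(model, state)
    return state


def enumerate_joint(model, state):
    """Explicit joint tensor over all state sequences of one chain, using
    the chain's built emission/transition terms.  Independent of the
    forward-backward implementation."""
    zeta = state.zeta_single
    n, S = zeta.shape
    joint = zeta[0]
    for i in range(n - 1):
        lt = inf._log_trans(model, state, i)
        joint = joint[..., None] + lt[(np.newaxis,) * (joint.ndim - 1)] \
            + zeta[i + 1]
    return joint  # shape (S,) * n


def enumerated_marginals(joint):
    n = joint.ndim
    logZ = logsumexp(joint)
    singles = []
    for i in range(n):
        axes = tuple(j for j in range(n) if j != i)
        singles.append(np.exp(logsumexp(joint, axis=axes) - logZ))
    pairs = {}
    for i in range(n - 1):
        axes = tuple(j for j in range(n) if j not in (i, i + 1))
        pairs[i] = np.exp(logsumexp(joint, axis=axes) - logZ)
    return logZ, np.array(singles), pairs


class TestSumProduct:
    def test_single_segment_chain(self):
        model = make_model(n_seg=1)
        state = random_state(model)
        inf.sum_product(model, state)
        z = state.zeta_single[0]
        np.testing.assert_allclose(state.gamma[0],
                                   np.exp(z - logsumexp(z)), atol=1e-12)
        assert state.logZ == pytest.approx(logsumexp(z))

    def test_uniform_terms_give_uniform_marginals(self):
        model = make_model(n_seg=4)
        state = random_state(model)
        state.zeta_single = np.zeros_like(state.zeta_single)
        model_uniform = model  # zero lambda: flat transitions
        model_uniform.log_trans_plain = np.zeros_like(model.log_trans_plain)
        model_uniform.exp_trans_plain = np.ones_like(model.exp_trans_plain)
        inf.sum_product(model_uniform, state)
        S = state.gamma.shape[1]
        np.testing.assert_allclose(state.gamma, 1.0 / S, atol=1e-12)

    @pytest.mark.parametrize("n_seg,bps", [
        (3, ()),
        (6, ()),
        (6, ((1, 4, 1, -1),)),
        (6, ((1, 3, 1, -1), (4, 5, -1, 1))),
    ])
    def test_matches_exhaustive_enumeration(self, n_seg, bps):
        model = make_model(n_seg=n_seg, breakpoints=bps, seed=3)
        state = random_state(model, seed=4)
        inf.sum_product(model, state)
        logZ, singles, pairs = enumerated_marginals(
            enumerate_joint(model, state))
        assert state.logZ == pytest.approx(logZ, abs=1e-10)
        np.testing.assert_allclose(state.gamma, singles, atol=1e-10)
        for i, gp in pairs.items():
            np.testing.assert_allclose(
                inf.pairwise_marginal(model, state, i), gp, atol=1e-10)

    def test_pairwise_marginalises_to_singles(self):
        model = make_model(n_seg=5, breakpoints=((2, 4, 1, -1),))
        state = random_state(model, seed=9)
        inf.sum_product(model, state)
        for i in range(4):
            gp = inf.pairwise_marginal(model, state, i)
            np.testing.assert_allclose(gp.sum(axis=1), state.gamma[i],
                                       atol=1e-8)
            np.testing.assert_allclose(gp.sum(axis=0), state.gamma[i + 1],
                                       atol=1e-8)

    def test_chromosome_ends_break_the_chain(self):
        seg = pd.concat([tiny_segments(3, chrom="1"),
                         tiny_segments(3, chrom="2")], ignore_index=True)
        seg["readcount"] = 10_000
        model = inf.ChainModel(seg, [], cb.FitConfig(n_tumour_clones=1))
        assert len(model.chains) == 2

    def test_infeasible_segment_raises(self):
        model = make_model(n_seg=3)
        state = random_state(model)
        state.zeta_single[1, :] = -np.inf
        with pytest.raises(ValueError, match="feasible"):
            inf.sum_product(model, state)


class TestBuildChain:
    def test_point_mass_q_recovers_exact_log_factor(self):
        model = make_model(n_seg=4, breakpoints=((1, 3, 1, -1),), lam=2.0)
        state = random_state(model)
        b_idx = 2
        state.q_bp[0] = 0.0
        state.q_bp[0, b_idx] = 1.0
        inf.build_chain(model, state)
        for i, o in model.bp_boundaries[0]:
            expected = -2.0 * model.bp_telomeres[o][b_idx]
            np.testing.assert_allclose(state.bp_trans[i], expected)

    def test_no_breakpoints_gives_plain_penalty(self):
        model = make_model(n_seg=4, lam=1.5)
        state = random_state(model)
        assert state.bp_trans == {}
        np.testing.assert_allclose(
            model.log_trans_plain,
            -1.5 * model.space.plain_telomere_matrix())

    def test_random_q_matches_direct_expectation(self):
        model = make_model(n_seg=5, breakpoints=((1, 3, 1, -1),), lam=1.0)
        state = random_state(model, seed=7)
        for i, o in model.bp_boundaries[0]:
            direct = sum(
                state.q_bp[0, b] * (-1.0 * model.bp_telomeres[o][b])
                for b in range(model.space.n_breakpoint_states))
            np.testing.assert_allclose(state.bp_trans[i], direct, atol=1e-12)


class TestBreakpointUpdate:
    def test_matches_direct_evaluation_from_enumerated_marginals(self):
        model = make_model(n_seg=6, breakpoints=((1, 4, 1, -1),), seed=5)
        state = random_state(model, seed=6)
        inf.sum_product(model, state)
        _, _, pairs = enumerated_marginals(enumerate_joint(model, state))
        scores = np.zeros(model.space.n_breakpoint_states)
        for i, o in model.bp_boundaries[0]:
            for b in range(len(scores)):
                scores[b] += np.sum(
                    pairs[i] * (-model.config.lam * model.bp_telomeres[o][b]))
        expected = np.exp(scores - logsumexp(scores))
        inf.update_q_breakpoints(model, state)
        np.testing.assert_allclose(state.q_bp[0], expected, atol=1e-9)

    def _forced_update(self, c_outer, c_inner):
        """Pin the chain to a deletion-like pattern: copies c_outer on the
        flanks and c_inner on the interval between the o=+1 and o=-1
        breakends of one breakpoint."""
        model = make_model(n_seg=4, breakpoints=((1, 3, 1, -1),), b_max=2)
        state = random_state(model)
        state.zeta_single[:] = -1e4
        for i, total in enumerate((c_outer, c_inner, c_inner, c_outer)):
            j = int(np.argmax(model.space.totals[:, 0] == total))
            state.zeta_single[i, j] = 0.0
        inf.sum_product(model, state)
        inf.update_q_breakpoints(model, state)
        return model.space.breakpoint_states[int(np.argmax(state.q_bp[0]))]

    def test_unit_copy_step_forces_b_one(self):
        assert self._forced_update(2, 1).tolist() == [1]

    def test_no_copy_step_forces_b_zero(self):
        assert self._forced_update(2, 2).tolist() == [0]


class TestDepthUpdate:
    def test_poisson_point_mass_closed_form(self):
        """With gamma a point mass at zero tumour copies and a Poisson
        likelihood only the normal clone contributes, so the optimal depth
        has the closed form sum(x) / sum(2 * l)."""
        rng = np.random.default_rng(0)
        n = 40
        model = make_model(n_seg=n, seed=1,
                           likelihood=cb.LikelihoodParams(
                               family="poisson", outlier_weight=0.0))
        h_true = 0.004
        model.x = rng.poisson(model.eff_len * 2 * h_true)
        model.x_major = np.zeros(n, dtype=int)
        model.x_minor = np.zeros(n, dtype=int)
        state = inf.VariationalState(model, np.array([0.003, 0.002]))
        zero_idx = int(np.argmax(model.space.totals[:, 0] == 0))
        state.gamma = np.zeros((n, model.space.n_states))
        state.gamma[:, zero_idx] = 1.0
        inf.update_h_theta(model, state)
        closed_form = model.x.sum() / (2.0 * model.eff_len.sum())
        assert state.h[0] == pytest.approx(closed_form, rel=1e-6)

    def test_poisson_joint_optimum_dominates_rate_closed_form(self):
        """For point-mass gamma at varying states the optimiser's joint
        (normal, tumour) depths must reach an objective at least as good as
        the single-rate closed form with the normal depth pinned to zero."""
        rng = np.random.default_rng(0)
        n = 40
        params = cb.LikelihoodParams(family="poisson", outlier_weight=0.0)
        model = make_model(n_seg=n, seed=1, likelihood=params)
        totals = rng.integers(1, 5, size=n)
        model.x = rng.poisson(model.eff_len * totals * 0.004)
        model.x_major = np.zeros(n, dtype=int)
        model.x_minor = np.zeros(n, dtype=int)
        state = inf.VariationalState(model, np.array([1e-12, 0.003]))
        idx = np.array([int(np.argmax((model.space.totals[:, 0] == t)
                                      & (model.space.minors[:, 0] == 0)))
                        for t in totals])
        state.gamma = np.zeros((n, model.space.n_states))
        state.gamma[np.arange(n), idx] = 1.0
        inf.update_h_theta(model, state)
        closed_form = model.x.sum() / (model.eff_len * totals).sum()

        def expected_ll(h):
            return inf._expected_emission(model, state, np.asarray(h), params)

        assert expected_ll(state.h) >= expected_ll([1e-12, closed_form]) - 1e-9
        # and the tumour depth sits within sampling error of the rate
        assert state.h[1] == pytest.approx(closed_form, rel=0.05)

    def test_all_zero_states_leave_tumour_depth_unchanged(self):
        model = make_model(n_seg=5, seed=2)
        model.x = np.zeros(5, dtype=int)
        model.x_major = np.zeros(5, dtype=int)
        model.x_minor = np.zeros(5, dtype=int)
        state = inf.VariationalState(model, np.array([0.004, 0.002]))
        zero_idx = int(np.argmax(model.space.totals[:, 0] == 0))
        state.gamma = np.zeros((5, model.space.n_states))
        state.gamma[:, zero_idx] = 1.0
        h_before = state.h.copy()
        inf.update_h_theta(model, state)
        assert state.h[1] == pytest.approx(h_before[1])

    def test_guard_never_decreases_expected_loglik(self):
        model = make_model(n_seg=10, seed=3)
        state = random_state(model, seed=3)
        inf.sum_product(model, state)
        before = inf._expected_emission(model, state, state.h, state.params)
        inf.update_h_theta(model, state)
        after = inf._expected_emission(model, state, state.h, state.params)
        assert after >= before - 1e-9


class TestElbo:
    def test_elbo_equals_enumerated_evidence_without_breakpoints(self):
        """For a pure chain, q(C) is the exact posterior, so the bound is
        tight: ELBO equals the enumerated log evidence."""
        model = make_model(n_seg=4)
        state = random_state(model)
        inf.sum_product(model, state)
        state.elbo = state.logZ + state.breakpoint_entropy()
        evidence = logsumexp(enumerate_joint(model, state))
        assert state.elbo == pytest.approx(evidence, abs=1e-8)
        assert inf.elbo(model, state) == pytest.approx(evidence, abs=1e-6)

    def test_elbo_lower_bounds_enumerated_evidence_with_breakpoints(self):
        model = make_model(n_seg=5, max_total=3, b_max=1,
                           breakpoints=((1, 3, 1, -1), (2, 4, -1, 1)))
        state = random_state(model, seed=11)
        tr = []
        for _ in range(4):
            inf._sweep(model, state, tr, update_h=False)
        # enumerate over joint breakpoint assignments and chain states
        S = model.space.n_states
        B = model.space.n_breakpoint_states
        terms = []
        for b1, b2 in product(range(B), repeat=2):
            st2 = inf.VariationalState(model, state.h)
            st2.q_bp = np.zeros((2, B))
            st2.q_bp[0, b1] = 1.0
            st2.q_bp[1, b2] = 1.0
            inf.build_chain(model, st2)
            terms.append(logsumexp(enumerate_joint(model, st2)))
        evidence = logsumexp(terms)
        assert state.elbo <= evidence + 1e-8
        assert inf.elbo(model, state) <= evidence + 1e-6

    def test_incremental_elbo_matches_recomputed(self):
        model = make_model(n_seg=6, breakpoints=((1, 4, 1, -1),), seed=8)
        state = random_state(model, seed=8)
        tr = []
        inf._sweep(model, state, tr)
        assert inf.elbo(model, state) == pytest.approx(state.elbo, abs=1e-6)

    def test_coordinate_updates_never_decrease_elbo(self):
        scen = small_scenario(seed=17)
        truth, seg, bp = cb.simulate(scen)
        res = cb.fit(seg, bp, cb.FitConfig(max_iter=12))
        for trace in res.elbo_traces:
            vals = np.array([v for _, v in trace])
            tol = 1e-6 * np.maximum(1.0, np.abs(vals[:-1]))
            assert (np.diff(vals) >= -tol).all()


class TestFit:
    def test_bmax_zero_equals_empty_breakpoint_list_on_clean_data(self):
        scen = small_scenario(seed=4, balanced_fraction=0.0)
        truth, seg, bp = cb.simulate(scen)
        cfg = replace(cb.FitConfig(), b_max=0, max_iter=15)
        r_with = cb.fit(seg, bp, cfg)
        r_without = cb.fit(seg, None, cfg)
        pd.testing.assert_frame_equal(r_with.segment_cn, r_without.segment_cn)
        np.testing.assert_array_equal(r_with.h, r_without.h)

    def test_clonal_only_simulation_collapses_clones(self):
        """With no divergent events the two tumour clones must either agree
        everywhere or the minor clone fraction must vanish."""
        scen = small_scenario(seed=6, target_divergent=0.0)
        truth = cb.sample_history(scen)
        truth.cn[:, 1, :] = truth.cn[:, 0, :]  # force zero divergence
        seg, bp = cb.simulate_counts(truth, seed=60)
        res = cb.fit(seg, bp, cb.FitConfig(max_iter=25))
        cn = res.cn_array()
        identical = np.all(cn[:, 0, :] == cn[:, 1, :])
        assert identical or min(res.rho[1:]) < 0.05

    def test_mixture_fractions_sum_to_one(self):
        scen = small_scenario(seed=9)
        truth, seg, bp = cb.simulate(scen)
        res = cb.fit(seg, bp, cb.FitConfig(max_iter=10))
        assert np.sum(res.rho) == pytest.approx(1.0)
        assert (res.rho >= 0).all()

    def test_unmappable_breakpoint_warned_and_zeroed(self):
        seg = tiny_segments(4)
        seg["readcount"] = 10_000
        bp = [Breakpoint("odd", Breakend("1", 123, 1),
                         Breakend("1", 1_000_000, -1))]
        model = inf.ChainModel(seg, bp, cb.FitConfig())
        assert model.n_breakpoints == 0
        assert any("not an interior segment boundary" in w
                   for w in model.warnings)
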