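import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cecganc.filters import (
    Algorithm,
    Branch,
    FilterConfig,
    SingularUpdateError,
    apa_step,
    apsa_step,
    dispatch_step,
    init_state,
    proposed_step,
    rvss_step,
)


def make_state(L=1, P=1, **kwargs):
    cfg = FilterConfig(L=L, P=P, **kwargs)
    return cfg, init_state(cfg)


class TestInitState:
    def test_weight_length(self):
        cfg, state = make_state(L=4)
        assert state.w.shape == (8,)
        assert np.all(state.w == 0)

    def test_delta0(self):
        cfg, state = make_state(delta0=0.01)
        assert state.delta == 0.01

    def test_repeatable(self):
        cfg = FilterConfig(L=3, P=2)
        s1, s2 = init_state(cfg), init_state(cfg)
        assert np.array_equal(s1.w, s2.w)
        assert s1.delta == s2.delta and s1.iteration == s2.iteration


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"L": 0},
            {"P": 0},
            {"mu": 0.0},
            {"mu": 1.5},
            {"gamma": 1.0},
            {"beta": 0.0},
            {"alpha": 1.5},
            {"delta0": 0.0},
            {"eps_reg": -1.0},
        ],
    )
    def test_rejects(self, kwargs):
        with pytest.raises(ValueError):
            FilterConfig(**kwargs)


class TestApaStep:
    def test_nlms_identity(self):
        cfg, state = make_state(L=1, P=1)
        U = np.array([[1.0], [0.0]])
        state, tr = apa_step(state, U, np.array([1.0]), mu=1.0, eps_reg=0.0)
        assert tr.error == 1.0
        assert np.allclose(state.w, [1.0, 0.0])

    def test_zero_error_leaves_weights(self):
        cfg, state = make_state(L=2, P=2)
        state.w = np.array([1.0, -1.0, 0.5, 2.0])
        rng = np.random.default_rng(0)
        U = rng.standard_normal((4, 2))
        d = U.T @ state.w  # zero a-priori error
        w_before = state.w.copy()
        state, tr = apa_step(state, U, d, mu=0.7, eps_reg=0.0)
        assert np.allclose(state.w, w_before, atol=1e-12)

    def test_matches_two_by_two_normal_equations(self, rng):
        for _ in range(50):
            cfg, state = make_state(L=2, P=2)
            state.w = rng.standard_normal(4)
            U = rng.standard_normal((4, 2))
            d = rng.standard_normal(2)
            mu = rng.uniform(0.1, 1.0)
            e = d - U.T @ state.w
            G = U.T @ U
            det = G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0]
            Ginv = np.array([[G[1, 1], -G[0, 1]], [-G[1, 0], G[0, 0]]]) / det
            expected = state.w + mu * U @ (Ginv @ e)
            state, _ = apa_step(state, U, d, mu=mu, eps_reg=0.0)
            assert np.allclose(state.w, expected, rtol=1e-9)

    def test_singular_without_regularizer(self):
        cfg, state = make_state(L=2, P=2)
        U = np.zeros((4, 2))
        with pytest.raises(SingularUpdateError):
            apa_step(state, U, np.ones(2), mu=0.5, eps_reg=0.0)

    def test_singular_ok_with_regularizer(self):
        cfg, state = make_state(L=2, P=2)
        U = np.zeros((4, 2))
        state, tr = apa_step(state, U, np.ones(2), mu=0.5, eps_reg=1e-6)
        assert np.allclose(state.w, 0.0)


class TestApsaStep:
    def test_fixed_norm_direction(self):
        cfg, state = make_state(L=1, P=1)
        U = np.array([[3.0], [4.0]])
        state, tr = apsa_step(state, U, np.array([2.0]), step=0.5)
        assert np.allclose(state.w, [0.3, 0.4])
        assert tr.branch is Branch.APSA
        assert np.isclose(np.linalg.norm(state.w), 0.5)

    def test_zero_error_skips(self):
        cfg, state = make_state(L=1, P=1)
        U = np.array([[3.0], [4.0]])
        state, tr = apsa_step(state, U, np.array([0.0]), step=0.5)
        assert tr.branch is Branch.SKIPPED
        assert np.all(state.w == 0)

    def test_degenerate_direction_skips(self):
        cfg, state = make_state(L=1, P=2)
        U = np.array([[1.0, -1.0], [2.0, -2.0]])
        state, tr = apsa_step(state, U, np.array([1.0, 1.0]), step=0.5)
        assert tr.branch is Branch.SKIPPED

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_step_norm_identity(self, seed):
        rng = np.random.default_rng(seed)
        L = rng.integers(1, 8)
        P = rng.integers(1, 6)
        cfg, state = make_state(L=int(L), P=int(P))
        state.w = rng.standard_normal(2 * L)
        w_before = state.w.copy()
        U = rng.standard_normal((2 * L, P))
        e = rng.standard_normal(P)
        step = float(rng.uniform(0.01, 2.0))
        state, tr = apsa_step(state, U, e, step=step)
        if tr.branch is Branch.APSA:
            assert np.isclose(np.linalg.norm(state.w - w_before), step, rtol=1e-10)


class TestRvssStep:
    def test_small_candidate_takes_apa(self):
        cfg, state = make_state(L=1, P=1, algorithm=Algorithm.RVSS, delta0=10.0, eps_reg=0.0)
        U = np.array([[1.0], [0.0]])
        state, tr = rvss_step(state, U, np.array([0.5]), cfg)
        assert tr.branch is Branch.APA
        assert np.allclose(state.w, [0.5, 0.0])  # unit-step update

    def test_large_candidate_takes_apsa_with_delta_norm(self):
        cfg, state = make_state(L=1, P=1, algorithm=Algorithm.RVSS, delta0=0.1, eps_reg=0.0)
        U = np.array([[1.0], [0.0]])
        state, tr = rvss_step(state, U, np.array([5.0]), cfg)
        assert tr.branch is Branch.APSA
        assert np.isclose(np.linalg.norm(state.w), 0.1)

    def test_alpha_one_freezes_delta(self):
        cfg, state = make_state(L=1, P=1, algorithm=Algorithm.RVSS, alpha=1.0, delta0=0.2, eps_reg=0.0)
        rng = np.random.default_rng(2)
        for _ in range(20):
            U = rng.standard_normal((2, 1))
            state, tr = rvss_step(state, U, rng.standard_normal(1), cfg)
            assert state.delta == 0.2


class TestProposedStep:
    def test_zero_error_apa_branch_delta_shrinks(self):
        cfg, state = make_state(
            L=1, P=1, algorithm=Algorithm.PROPOSED, alpha=0.9, delta0=0.1, eps_reg=0.0
        )
        U = np.array([[1.0], [0.0]])
        for k in range(1, 4):
            state, tr = proposed_step(state, U, np.array([0.0]), cfg)
            assert tr.branch is Branch.APA
            assert np.all(state.w == 0)
            assert np.isclose(state.delta, 0.1 * 0.9**k)

    def test_large_q_apsa_branch_gamma_delta_norm(self):
        cfg, state = make_state(
            L=1, P=1, algorithm=Algorithm.PROPOSED, delta0=0.1, gamma=0.01, eps_reg=0.0
        )
        U = np.array([[1.0], [0.0]])
        state, tr = proposed_step(state, U, np.array([100.0]), cfg)
        assert tr.branch is Branch.APSA
        assert np.isclose(np.linalg.norm(state.w), 0.01 * 0.1)
        assert state.delta == 0.1  # frozen on the sign branch

    def test_two_iteration_hand_recursion(self):
        # mu1=0.4, beta=3.5, gamma=0.01, alpha=0.9, delta0=0.1, eps=0
        cfg, state = make_state(
            L=1,
            P=1,
            algorithm=Algorithm.PROPOSED,
            mu1=0.4,
            beta=3.5,
            gamma=0.01,
            alpha=0.9,
            delta0=0.1,
            eps_reg=0.0,
        )
        # iteration 1: u=[1,0], d=0.01 -> e=0.01, q=0.004 < 0.35 -> APA
        U1 = np.array([[1.0], [0.0]])
        state, tr1 = proposed_step(state, U1, np.array([0.01]), cfg)
        assert tr1.branch is Branch.APA
        assert np.allclose(state.w, [0.004, 0.0])
        assert np.isclose(state.delta, 0.9 * 0.1 + 0.1 * 0.004)  # 0.0904
        # iteration 2: u=[0,1], d=10 -> e=10, q=4 >= 3.5*0.0904 -> APSA
        U2 = np.array([[0.0], [1.0]])
        state, tr2 = proposed_step(state, U2, np.array([10.0]), cfg)
        assert tr2.branch is Branch.APSA
        assert np.allclose(state.w, [0.004, 0.01 * 0.0904])
        assert np.isclose(state.delta, 0.0904)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_update_bound(self, seed):
        rng = np.random.default_rng(seed)
        cfg, state = make_state(L=3, P=2, algorithm=Algorithm.PROPOSED)
        for _ in range(30):
            U = rng.standard_normal((6, 2))
            d = rng.standard_normal(2) * rng.uniform(0.1, 20)
            delta_prev = state.delta
            w_before = state.w.copy()
            state, tr = proposed_step(state, U, d, cfg)
            bound = max(cfg.beta, cfg.gamma) * delta_prev
            assert np.linalg.norm(state.w - w_before) <= bound * (1 + 1e-9)


class TestNlmsEquivalence:
    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_p1_matches_scalar_nlms(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(1, 8))
        cfg, state = make_state(L=L, P=1)
        state.w = rng.standard_normal(2 * L)
        u = rng.standard_normal(2 * L)
        d = float(rng.standard_normal())
        mu = float(rng.uniform(0.05, 1.0))
        e = d - u @ state.w
        expected = state.w + mu * u * e / (u @ u)
        state, _ = apa_step(state, u[:, None], np.array([d]), mu=mu, eps_reg=0.0)
        assert np.allclose(state.w, expected, rtol=1e-9)


class TestDispatch:
    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(algorithm="kalman")

    @pytest.mark.parametrize("alg", list(Algorithm))
    def test_each_algorithm_steps(self, alg, rng):
        cfg = FilterConfig(L=2, P=2, algorithm=alg)
        state = init_state(cfg)
        U = rng.standard_normal((4, 2))
        d = rng.standard_normal(2)
        state, tr = dispatch_step(state, U, d, cfg)
        assert state.iteration == 1
        assert tr.apa_update_norm >= 0
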