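import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import matchedme as mm
from matchedme.model_core import LatentState, PriorSpec

from .oracles import conditional_logistic_set_probs, wishart_logpdf_textbook


def _two_set_study(x_sets):
    """Build a tiny P=1 study from a list of per-set exposure tuples."""
    sizes = np.array([len(s) for s in x_sets])
    W = np.concatenate([np.asarray(s, float) for s in x_sets])[:, None]
    return mm.MatchedStudy(
        set_ids=[f"s{i}" for i in range(len(x_sets))],
        sizes=sizes,
        W=W,
        Z=np.zeros((len(W), 0)),
    )


def _random_state(study, rng, P=None, K=None):
    P = study.P if P is None else P
    K = study.K if K is None else K
    A = rng.normal(size=(P, P))
    B = rng.normal(size=(P, P))
    return LatentState(
        beta=rng.normal(size=P),
        delta=rng.normal(size=K),
        X=rng.normal(size=(study.n_subjects, P)),
        M=rng.normal(size=(study.n_sets, P)),
        V_W=A @ A.T + 0.5 * np.eye(P),
        V_B=B @ B.T + 0.5 * np.eye(P),
    )


class TestLogDisease:
    def test_null_beta_gives_uniform_case_probabilities(self, default_synth):
        study = default_synth.study
        val = mm.log_disease(np.zeros(study.P), np.zeros(study.K), study.W, study.Z, study)
        assert val == pytest.approx(-np.sum(np.log(study.sizes)), abs=1e-10)

    def test_single_pair_closed_form(self):
        # two identical sets with x=(1,0), beta=2: each contributes
        # log(e^2/(e^2+1)) = -log(1+e^-2)
        study = _two_set_study([(1.0, 0.0), (1.0, 0.0)])
        val = mm.log_disease([2.0], None, study.W, None, study)
        assert val == pytest.approx(-2 * np.log(1 + np.exp(-2)), abs=1e-12)

    def test_stratum_intercepts_cancel(self, default_synth):
        study = default_synth.study
        rng = np.random.default_rng(3)
        beta = rng.normal(size=study.P)
        base = mm.log_disease(beta, None, study.W, None, study)
        X2 = study.W.copy()
        for sl in study.set_slices():
            X2[sl] += rng.normal(size=study.P)  # constant within the set
        shifted = mm.log_disease(beta, None, X2, None, study)
        assert shifted == pytest.approx(base, abs=1e-8)

    def test_case_probabilities_sum_to_one_exhaustively(self, default_synth):
        study = default_synth.study
        beta = np.array([0.4, -0.7, 0.2])
        for sl in list(study.set_slices())[:10]:
            probs = conditional_logistic_set_probs(study.W[sl], beta)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            # the model's per-set likelihood equals the enumerated probability
            sub = mm.MatchedStudy(
                ["a", "b"], [sl.stop - sl.start] * 2,
                np.vstack([study.W[sl]] * 2), np.zeros((2 * (sl.stop - sl.start), 0)),
            )
            val = mm.log_disease(beta, None, sub.W, None, sub)
            assert val == pytest.approx(2 * np.log(probs[0]), abs=1e-10)

    def test_dimension_mismatch_raises(self, default_synth):
        study = default_synth.study
        with pytest.raises(ValueError):
            mm.log_disease(np.zeros(study.P), None, study.W[:, :2], None, study)


class TestLogMeasurement:
    def test_exact_match_leaves_only_constants(self):
        spec = mm.MeasurementErrorSpec(sigma2=[0.1, 0.2])
        W = np.random.default_rng(0).normal(size=(7, 2))
        expected = -0.5 * 7 * np.sum(np.log(2 * np.pi * spec.sigma2))
        assert mm.log_measurement(W, W, spec) == pytest.approx(expected)

    def test_one_sigma_deviation(self):
        s2 = 0.3
        spec = mm.MeasurementErrorSpec(sigma2=[s2])
        val = mm.log_measurement([[np.sqrt(s2)]], [[0.0]], spec)
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi * s2) - 0.5)

    def test_equals_elementwise_normal_logpdf(self):
        rng = np.random.default_rng(4)
        W = rng.normal(size=(6, 3))
        X = rng.normal(size=(6, 3))
        sigma2 = np.array([0.1, 0.5, 1.3])
        spec = mm.MeasurementErrorSpec(sigma2=sigma2)
        oracle = norm.logpdf(W, loc=X, scale=np.sqrt(sigma2)).sum()
        assert mm.log_measurement(W, X, spec) == pytest.approx(oracle, rel=1e-12)

    def test_zero_variance_directs_to_naive(self):
        spec = mm.MeasurementErrorSpec(sigma2=[0.0])
        with pytest.raises(ValueError, match="naive"):
            mm.log_measurement([[1.0]], [[1.0]], spec)


class TestLogExposure:
    def test_degenerate_state_leaves_constants(self, default_synth):
        study = default_synth.study
        P = study.P
        V_W, V_B = 0.5 * np.eye(P), 0.3 * np.eye(P)
        mu = np.ones(P)
        prior = PriorSpec(mu=mu).resolved(P)
        X = np.tile(mu, (study.n_subjects, 1))
        M = np.tile(mu, (study.n_sets, 1))
        expected = -0.5 * study.n_sets * np.linalg.slogdet(2 * np.pi * V_B)[1]
        expected += -0.5 * study.n_subjects * np.linalg.slogdet(2 * np.pi * V_W)[1]
        val = mm.log_exposure(X, M, prior, V_W, V_B, study)
        assert val == pytest.approx(expected, rel=1e-12)

    def test_univariate_reduces_to_scalar_normals(self):
        study = _two_set_study([(0.3, -0.2, 0.5), (1.0, 0.2)])
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 1))
        M = rng.normal(size=(2, 1))
        v_w, v_b, mu = 0.7, 0.4, 0.1
        prior = PriorSpec(mu=[mu]).resolved(1)
        oracle = norm.logpdf(M[:, 0], mu, np.sqrt(v_b)).sum()
        oracle += norm.logpdf(X[:, 0], M[study.set_index, 0], np.sqrt(v_w)).sum()
        val = mm.log_exposure(X, M, prior, [[v_w]], [[v_b]], study)
        assert val == pytest.approx(oracle, rel=1e-12)

    def test_conditional_form_integrates_to_closed_form_marginal(self):
        """Integrating the set mean out numerically recovers N(mu 1, v_b J + v_w I)."""
        study = _two_set_study([(0.4, -0.1, 0.3), (0.8, 0.2, -0.5)])
        v_w, v_b, mu = 0.6, 0.35, 0.2
        prior = PriorSpec(mu=[mu]).resolved(1)
        X = study.W.copy()
        grid = np.linspace(-8, 8, 4001)
        dm = grid[1] - grid[0]
        log_marg_quad = 0.0
        for sl in study.set_slices():
            dens = norm.pdf(grid, mu, np.sqrt(v_b))
            for x in X[sl, 0]:
                dens = dens * norm.pdf(x, grid, np.sqrt(v_w))
            log_marg_quad += np.log(np.sum(dens) * dm)
        n = 3
        from scipy.stats import multivariate_normal

        log_marg_exact = sum(
            multivariate_normal.logpdf(
                X[sl, 0], np.full(n, mu), v_b * np.ones((n, n)) + v_w * np.eye(n)
            )
            for sl in study.set_slices()
        )
        assert log_marg_exact == pytest.approx(log_marg_quad, abs=1e-8)
        # and the implemented conditional form evaluated at M = posterior draw
        # integrates consistently: check via a coarse Monte-Carlo over M
        rng = np.random.default_rng(6)
        Ms = rng.normal(mu, np.sqrt(v_b), size=(40_000, 2))
        vals = np.zeros(len(Ms))
        for j, m in enumerate(Ms):
            w = 0.0
            for i, sl in enumerate(study.set_slices()):
                w += norm.logpdf(X[sl, 0], m[i], np.sqrt(v_w)).sum()
            vals[j] = w
        mc = np.log(np.exp(vals - vals.max()).mean()) + vals.max()
        assert mc == pytest.approx(log_marg_exact, abs=0.05)

    def test_non_pd_covariance_rejected(self, default_synth):
        study = default_synth.study
        prior = PriorSpec(mu=np.zeros(3)).resolved(3)
        with pytest.raises(ValueError, match="positive definite"):
            mm.log_exposure(
                study.W, np.zeros((study.n_sets, 3)), prior,
                -np.eye(3), np.eye(3), study,
            )


class TestLogPriors:
    def _state(self, P=2, K=2, beta=None, V=None):
        V = np.eye(P) if V is None else V
        return LatentState(
            beta=np.zeros(P) if beta is None else beta,
            delta=np.zeros(K),
            X=np.zeros((4, P)),
            M=np.zeros((2, P)),
            V_W=V,
            V_B=V,
        )

    def test_zero_coefficients_contribute_constants(self):
        prior = PriorSpec(mu=np.zeros(2)).resolved(2)
        st0 = self._state()
        expected_norm = -0.5 * 2 * np.log(2 * np.pi * prior.beta_var)
        expected_norm += -0.5 * 2 * np.log(2 * np.pi * prior.delta_var)
        wish = 2 * wishart_logpdf_textbook(
            np.eye(2), prior.wishart_df, np.linalg.inv(prior.wishart_R)
        )
        assert mm.log_priors(st0, prior) == pytest.approx(expected_norm + wish, rel=1e-10)

    def test_doubling_beta_var_costs_half_log_two_per_coordinate(self):
        p1 = PriorSpec(beta_var=100.0, mu=np.zeros(2)).resolved(2)
        p2 = PriorSpec(beta_var=200.0, mu=np.zeros(2)).resolved(2)
        st0 = self._state()
        diff = mm.log_priors(st0, p1) - mm.log_priors(st0, p2)
        assert diff == pytest.approx(2 * 0.5 * np.log(2), rel=1e-10)

    def test_wishart_term_matches_textbook_density(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(3, 3))
        V = A @ A.T + 0.5 * np.eye(3)
        prior = PriorSpec(wishart_df=5.0, mu=np.zeros(3)).resolved(3)
        base = self._state(P=3, K=2)
        alt = self._state(P=3, K=2)
        alt.V_W = V
        diff = mm.log_priors(alt, prior) - mm.log_priors(base, prior)
        scale = np.linalg.inv(prior.wishart_R)
        oracle = wishart_logpdf_textbook(
            np.linalg.inv(V), prior.wishart_df, scale
        ) - wishart_logpdf_textbook(np.eye(3), prior.wishart_df, scale)
        assert diff == pytest.approx(oracle, rel=1e-9)


class TestLogJoint:
    def test_additivity(self, default_synth, default_spec):
        study = default_synth.study
        rng = np.random.default_rng(9)
        prior = PriorSpec().resolved(study.P, study.W, study)
        for _ in range(3):
            state = _random_state(study, rng)
            total = mm.log_joint(state, study, default_spec, prior)
            parts = (
                mm.log_measurement(study.W, state.X, default_spec)
                + mm.log_disease(state.beta, state.delta, state.X, study.Z, study)
                + mm.log_exposure(state.X, state.M, prior, state.V_W, state.V_B, study)
                + mm.log_priors(state, prior)
            )
            assert total == pytest.approx(parts, rel=1e-12)

    def test_moving_x_away_from_w_and_m_decreases_joint(self, default_synth, default_spec):
        study = default_synth.study
        prior = PriorSpec().resolved(study.P, study.W, study)
        M = np.add.reduceat(study.W, study.offsets, axis=0) / study.sizes[:, None]
        state = LatentState(
            beta=np.zeros(study.P), delta=np.zeros(study.K),
            X=study.W.copy(), M=M, V_W=0.5 * np.eye(3), V_B=0.3 * np.eye(3),
        )
        vals = []
        start = max(study.W[0, 0], M[0, 0])  # beyond here both quadratics worsen
        for shift in (0.1, 0.5, 1.0, 2.0):
            s = LatentState(state.beta, state.delta, state.X.copy(), M,
                            state.V_W, state.V_B)
            s.X[0, 0] = start + shift
            vals.append(mm.log_joint(s, study, default_spec, prior))
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_huge_error_variance_decouples_measurement_from_x(
        self, default_synth
    ):
        """With sigma^2 -> infinity, joint differences in X are driven by the
        disease and exposure terms alone."""
        study = default_synth.study
        prior = PriorSpec().resolved(study.P, study.W, study)
        spec_big = mm.MeasurementErrorSpec(sigma2=np.full(3, 1e8))
        rng = np.random.default_rng(10)
        s1 = _random_state(study, rng)
        s2 = LatentState(s1.beta, s1.delta, s1.X + rng.normal(size=s1.X.shape),
                         s1.M, s1.V_W, s1.V_B)
        joint_diff = mm.log_joint(s2, study, spec_big, prior) - mm.log_joint(
            s1, study, spec_big, prior
        )
        expected = (
            mm.log_disease(s2.beta, s2.delta, s2.X, study.Z, study)
            - mm.log_disease(s1.beta, s1.delta, s1.X, study.Z, study)
            + mm.log_exposure(s2.X, s2.M, prior, s2.V_W, s2.V_B, study)
            - mm.log_exposure(s1.X, s1.M, prior, s1.V_W, s1.V_B, study)
        )
        assert joint_diff == pytest.approx(expected, abs=1e-4)


@given(seed=st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_log_densities_finite_on_valid_states(seed):
    """No NaN/Inf anywhere on random valid states (small random study)."""
    rng = np.random.default_rng(seed)
    sizes = rng.integers(2, 5, size=3)
    S = int(sizes.sum())
    study = mm.MatchedStudy(
        set_ids=list(range(3)), sizes=sizes,
        W=rng.normal(size=(S, 2)), Z=rng.normal(size=(S, 1)),
    )
    spec = mm.MeasurementErrorSpec(sigma2=rng.uniform(0.05, 2.0, size=2))
    prior = PriorSpec().resolved(2, study.W, study)
    state = _random_state(study, rng)
    val = mm.log_joint(state, study, spec, prior)
    assert np.isfinite(val)
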