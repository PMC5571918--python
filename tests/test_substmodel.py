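"""GTR+Gamma+I likelihood core: generator, transition probabilities, exact
pattern probabilities (vs the brute-force oracle), likelihood and fitting."""

import numpy as np
import pytest

from _oracles import continuous_gamma_midpoint_rates, site_pattern_probs
from conftest import tally_from_patterns
from phyquart.errors import InputError
from phyquart.patterns import tally_codes
from phyquart.simulate import STUDY_BASE_FREQS, STUDY_EXCHANGEABILITIES, study_model
from phyquart.substmodel import (
    FittedQuartet,
    QuartetTree,
    SubstitutionModel,
    discrete_gamma_rates,
    expected_counts,
    fit_quartet,
    log_likelihood,
    pattern_probs,
    rate_matrix,
    transition_probs,
)

JC = SubstitutionModel()


def random_model(rng, n_cat=None):
    return SubstitutionModel(
        tuple(rng.uniform(0.2, 2.0, 6)),
        tuple(rng.dirichlet([8, 8, 8, 8])),
        alpha=rng.uniform(0.3, 3.0),
        p_inv=rng.uniform(0.0, 0.6),
        n_cat=int(n_cat if n_cat is not None else rng.integers(1, 5)),
    )


class TestRateMatrix:
    def test_jukes_cantor_generator(self):
        Q = rate_matrix(JC)
        off = Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0 / 3.0)
        assert np.allclose(Q.sum(axis=1), 0.0)

    def test_study_model_normalization(self):
        m = study_model(1.0)
        Q = rate_matrix(m)
        pi = np.array(m.base_freqs)
        assert np.allclose(-(pi * np.diag(Q)).sum(), 1.0)
        assert np.allclose(Q.sum(axis=1), 0.0)

    def test_exchangeability_scale_invariance(self):
        m1 = study_model(1.0)
        scaled = SubstitutionModel(tuple(10 * np.array(STUDY_EXCHANGEABILITIES)),
                                   STUDY_BASE_FREQS, 1.0, 0.3, 4)
        assert np.allclose(rate_matrix(m1), rate_matrix(scaled))

    def test_rejects_bad_parameters(self):
        with pytest.raises(InputError):
            SubstitutionModel((0.0,) * 6)
        with pytest.raises(InputError):
            SubstitutionModel(base_freqs=(0.5, 0.5, 0.2, -0.2))


class TestTransitionProbs:
    def test_zero_time_is_identity(self):
        Q = rate_matrix(study_model(1.0))
        assert np.allclose(transition_probs(Q, 0.0), np.eye(4))

    def test_long_time_reaches_stationarity(self):
        m = study_model(1.0)
        P = transition_probs(rate_matrix(m), 500.0)
        assert np.allclose(P, np.tile(m.base_freqs, (4, 1)), atol=1e-10)

    def test_jc_closed_form(self):
        t = 0.1
        P = transition_probs(rate_matrix(JC), t)
        expected_off = 0.25 * (1 - np.exp(-4.0 * t / 3.0))
        off = P[~np.eye(4, dtype=bool)]
        assert np.allclose(off, expected_off)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_detailed_balance(self):
        m = study_model(0.7)
        pi = np.array(m.base_freqs)
        P = transition_probs(rate_matrix(m), 0.37)
        assert np.allclose(pi[:, None] * P, (pi[:, None] * P).T)


class TestDiscreteGamma:
    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0, 2.0, 10.0])
    @pytest.mark.parametrize("n_cat", [1, 4, 8])
    def test_rates_average_one(self, alpha, n_cat):
        r = discrete_gamma_rates(alpha, n_cat)
        assert len(r) == n_cat
        assert np.all(np.diff(r) >= 0)
        assert abs(r.mean() - 1.0) < 1e-12

    def test_small_alpha_is_more_dispersed(self):
        assert discrete_gamma_rates(0.2, 4).max() > discrete_gamma_rates(2.0, 4).max()


class TestPatternProbs:
    def test_matches_brute_force_oracle(self, rng):
        worst = 0.0
        for trial in range(8):
            m = random_model(rng)
            tree = QuartetTree(["q1", "q2", "q3"][trial % 3],
                               tuple(rng.uniform(0.005, 1.5, 5)))
            got = pattern_probs(tree, m)
            want = site_pattern_probs(tree.topology, tree.branch_lengths,
                                      m.exchangeabilities, m.base_freqs,
                                      discrete_gamma_rates(m.alpha, m.n_cat),
                                      m.p_inv)
            worst = max(worst, np.abs(got - want).max())
            assert abs(got.sum() - 1.0) < 1e-9
        assert worst < 1e-8

    def test_zero_branch_lengths_leave_only_constants(self):
        m = study_model(1.0, p_inv=0.0, n_cat=4)
        probs = pattern_probs(QuartetTree("q1", (0.0,) * 5), m)
        consts = [0, 85, 170, 255]
        assert np.allclose(probs[consts], m.base_freqs)
        mask = np.ones(256, bool)
        mask[consts] = False
        assert np.allclose(probs[mask], 0.0)

    def test_discretization_converges_to_continuous(self):
        """Mean-of-quantile discrete gamma converges to the midpoint-integrated
        continuous distribution as categories grow."""
        tree = QuartetTree("q2", (0.3, 0.1, 0.5, 0.2, 0.05))
        base = dict(exchangeabilities=STUDY_EXCHANGEABILITIES,
                    base_freqs=STUDY_BASE_FREQS, alpha=0.5, p_inv=0.3)
        cont = site_pattern_probs("q2", tree.branch_lengths,
                                  STUDY_EXCHANGEABILITIES, STUDY_BASE_FREQS,
                                  continuous_gamma_midpoint_rates(0.5, 4096), 0.3)
        errs = []
        for n_cat in (4, 16, 64):
            got = pattern_probs(tree, SubstitutionModel(**base, n_cat=n_cat))
            errs.append(np.abs(got - cont).max())
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-4

    def test_rejects_continuous_model(self):
        with pytest.raises(InputError):
            pattern_probs(QuartetTree("q1", (0.1,) * 5),
                          SubstitutionModel(n_cat=0))


class TestLogLikelihood:
    def test_constant_column_zero_tree(self):
        m = study_model(1.0, p_inv=0.0, n_cat=1)
        t = tally_from_patterns({"GGGG": 1})
        ll = log_likelihood(t, QuartetTree("q1", (0.0,) * 5), m)
        assert np.isclose(ll, np.log(m.base_freqs[2]))

    def test_linear_in_counts(self, rng):
        m = random_model(rng, n_cat=2)
        tree = QuartetTree("q3", tuple(rng.uniform(0.05, 0.5, 5)))
        codes = rng.integers(0, 4, size=(40, 4))
        t1 = tally_codes(codes)
        t2 = tally_codes(np.vstack([codes, codes]))
        assert np.isclose(2 * log_likelihood(t1, tree, m),
                          log_likelihood(t2, tree, m))

    def test_toy_tally_matches_per_site_product(self, rng):
        m = SubstitutionModel(n_cat=1)
        tree = QuartetTree("q1", (0.1, 0.2, 0.15, 0.05, 0.02))
        t = tally_from_patterns({"AACC": 1, "ACGT": 1, "TTTT": 1})
        oracle = site_pattern_probs("q1", tree.branch_lengths,
                                    m.exchangeabilities, m.base_freqs, [1.0], 0.0)
        from conftest import code_of
        want = sum(np.log(oracle[code_of(p)]) for p in ("AACC", "ACGT", "TTTT"))
        assert np.isclose(log_likelihood(t, tree, m), want)

    def test_structural_zero_gives_minus_inf(self):
        from phyquart.substmodel import _loglik_from_probs
        counts = np.zeros(256, dtype=np.int64)
        counts[5] = 1  # AACC observed
        probs = np.zeros(256)
        probs[[0, 85, 170, 255]] = 0.25  # only constants possible
        assert _loglik_from_probs(counts, probs) == -np.inf
        # tiny-but-positive probabilities are floored, not flagged impossible
        probs[5] = 1e-320
        assert np.isfinite(_loglik_from_probs(counts, probs))


class TestExpectedCounts:
    def test_class_totals_sum_to_L(self, rng):
        m = random_model(rng)
        f = FittedQuartet(QuartetTree("q1", (0.2,) * 5), m, 0.0,
                          pattern_probs(QuartetTree("q1", (0.2,) * 5), m))
        ec = expected_counts(f, 1000)
        assert ec.shape == (15,)
        assert np.isclose(ec.sum(), 1000.0)
        assert np.all(ec >= 0)
        assert np.allclose(expected_counts(f, 0), 0.0)

    def test_zero_length_tree_is_all_constant(self):
        m = study_model(1.0, p_inv=0.0, n_cat=1)
        tree = QuartetTree("q1", (0.0,) * 5)
        f = FittedQuartet(tree, m, 0.0, pattern_probs(tree, m))
        ec = expected_counts(f, 100)
        assert np.isclose(ec[0], 100.0)
        assert np.allclose(ec[1:], 0.0)


class TestFitQuartet:
    def test_all_constant_data_collapses_branches(self):
        t = tally_from_patterns({"AAAA": 50, "CCCC": 30, "GGGG": 10, "TTTT": 10})
        f = fit_quartet(t, "q1", "all_free")
        assert np.all(np.array(f.tree.branch_lengths) < 1e-6)

    def test_refit_from_optimum_is_stable(self, rng):
        from phyquart.simulate import SimulationConfig, simulate_alignment
        cfg = SimulationConfig("one_long", bl1=0.05, bl2=0.3, bl3=0.1,
                               L=5000, model=study_model(1.0, n_cat=4), seed=7)
        t = tally_codes(simulate_alignment(cfg).codes)
        f1 = fit_quartet(t, "q1", "fixed_alpha_inv", fixed_alpha=1.0, fixed_p_inv=0.3)
        f2 = fit_quartet(t, "q1", "fixed_alpha_inv", fixed_alpha=1.0, fixed_p_inv=0.3)
        assert abs(f1.logL - f2.logL) < 1e-6
        # the optimum cannot be beaten by the true generating parameters
        truth = QuartetTree("q1", (0.3, 0.1, 0.1, 0.1, 0.05))
        ll_truth = log_likelihood(t, truth, study_model(1.0, n_cat=4))
        assert f1.logL >= ll_truth - 1e-6

    def test_likelihood_invariant_under_topology_symmetry(self, rng):
        """Relabeling consistently with the split symmetry (A<->B, C<->D)
        leaves the fitted likelihood unchanged."""
        from phyquart.simulate import SimulationConfig, simulate_alignment
        cfg = SimulationConfig("one_long", bl1=0.05, bl2=0.4, bl3=0.2,
                               L=4000, model=study_model(1.0, n_cat=4), seed=11)
        codes = simulate_alignment(cfg).codes
        t = tally_codes(codes)
        t_swapped = tally_codes(codes[:, [1, 0, 3, 2]])
        f1 = fit_quartet(t, "q1", "fixed_alpha_inv", fixed_alpha=1.0, fixed_p_inv=0.3)
        f2 = fit_quartet(t_swapped, "q1", "fixed_alpha_inv", fixed_alpha=1.0,
                         fixed_p_inv=0.3)
        assert abs(f1.logL - f2.logL) < 1e-3

    def test_mode_validation(self):
        t = tally_from_patterns({"AACC": 5, "AAAA": 5})
        with pytest.raises(InputError):
            fit_quartet(t, "q1", "bogus")
        with pytest.raises(InputError):
            fit_quartet(t, "q1", "fixed_alpha_inv")
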