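"""QUEST+ engine: Bayesian updates, entropy-based selection, oracles."""

import numpy as np
import pytest

from vergesize.psychometric import PFParams, pf_prob
from vergesize.quest import QuestGrids, QuestPlus


def entropy_bits(p):
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def expected_entropies_bruteforce(engine):
    """Independent oracle: loop over stimuli and outcomes, renormalising
    the posterior explicitly for each branch."""
    out = np.empty(engine.stimulus_domain.size)
    for i, _x in enumerate(engine.stimulus_domain):
        eh = 0.0
        for r in (0, 1):
            lik = engine._L[i] if r == 1 else engine._M[i]
            w = engine.posterior * lik
            p_r = w.sum()
            eh += p_r * entropy_bits(w / p_r)
        out[i] = eh
    return out


class TestInit:
    def test_uniform_prior_entropy(self, tiny_engine):
        n = tiny_engine._cells.shape[0]
        assert tiny_engine.posterior_entropy() == pytest.approx(np.log2(n))

    def test_concentrated_prior_zero_entropy(self, tiny_engine):
        prior = np.zeros(tiny_engine._cells.shape[0])
        prior[5] = 1.0
        eng = tiny_engine.clone_reset(prior=prior)
        assert eng.posterior_entropy() == 0.0

    def test_unnormalised_prior_normalised(self, tiny_engine):
        prior = np.full(tiny_engine._cells.shape[0], 7.0)
        eng = tiny_engine.clone_reset(prior=prior)
        assert eng.posterior.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_domain_rejected(self):
        with pytest.raises(ValueError):
            QuestPlus(QuestGrids.reduced(), stimulus_domain=[])

    def test_zero_or_out_of_range_stimulus_rejected(self):
        with pytest.raises(ValueError):
            QuestPlus(QuestGrids.reduced(), stimulus_domain=[0.0, 1.0])
        with pytest.raises(ValueError):
            QuestPlus(QuestGrids.reduced(), stimulus_domain=[21.0])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            QuestPlus(QuestGrids(alpha=np.array([]), beta_log10=np.array([-0.5]),
                                 gamma=np.array([0.0]), lambda_=np.array([0.0])))


class TestUpdate:
    def test_two_hypothesis_hand_arithmetic(self):
        # P(bigger | x=5) is 0.9 under alpha=0 and 0.5 under alpha=5 when
        # beta = ln(9)/5; observing "bigger" gives 0.45/0.70
        beta = np.log(9.0) / 5.0
        grids = QuestGrids(
            alpha=np.array([0.0, 5.0]),
            beta_log10=np.array([np.log10(beta)]),
            gamma=np.array([0.0]), lambda_=np.array([0.0]),
        )
        eng = QuestPlus(grids, stimulus_domain=[5.0])
        eng.update(5.0, 1)
        assert eng.posterior[0] == pytest.approx(0.45 / 0.70, abs=1e-9)

    def test_impossible_outcome_annihilates_cell(self):
        # a lapse-free steep cell assigns ~0 to "bigger" far below its alpha
        grids = QuestGrids(
            alpha=np.array([-5.0, 10.0]), beta_log10=np.array([0.3]),
            gamma=np.array([0.0]), lambda_=np.array([0.0]),
        )
        eng = QuestPlus(grids, stimulus_domain=[-6.0])
        eng.update(-6.0, 1)  # "bigger" at -6: essentially excluded under alpha=10
        assert eng.posterior[1] < 1e-9

    def test_mass_sums_to_one_after_many_updates(self, tiny_engine):
        eng = tiny_engine.clone_reset()
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.choice(eng.stimulus_domain)
            eng.update(float(x), int(rng.integers(2)))
            assert abs(eng.posterior.sum() - 1.0) < 1e-10

    def test_unknown_stimulus_rejected(self, tiny_engine):
        eng = tiny_engine.clone_reset()
        with pytest.raises(ValueError):
            eng.update(3.14, 1)

    def test_sequential_equals_batch_likelihood_product(self, tiny_engine):
        eng = tiny_engine.clone_reset()
        obs = [(2.0, 1), (-6.0, 0), (2.0, 0), (12.0, 1)]
        for x, r in obs:
            eng.update(x, r)
        batch = np.ones(tiny_engine._cells.shape[0])
        for x, r in obs:
            i = int(np.flatnonzero(np.isclose(eng.stimulus_domain, x))[0])
            batch *= eng._L[i] if r else eng._M[i]
        batch /= batch.sum() * tiny_engine._cells.shape[0] ** 0  # normalised
        batch_post = batch / batch.sum()
        assert np.allclose(eng.posterior, batch_post, atol=1e-12)


class TestSelection:
    def test_matches_enumeration_oracle(self, tiny_engine):
        eng = tiny_engine.clone_reset()
        rng = np.random.default_rng(3)
        for _ in range(25):
            assert np.allclose(
                eng.expected_entropies(), expected_entropies_bruteforce(eng),
                atol=1e-12,
            )
            oracle_eh = expected_entropies_bruteforce(eng)
            best = oracle_eh.min()
            tied = np.flatnonzero(oracle_eh <= best + 1e-12)
            cand = eng.stimulus_domain[tied]
            order = np.lexsort((-np.sign(cand), np.abs(cand)))
            assert eng.next_stimulus() == cand[order[0]]
            x = eng.next_stimulus()
            eng.update(x, int(rng.integers(2)))

    def test_selection_never_expects_information_loss(self, tiny_engine):
        eng = tiny_engine.clone_reset()
        rng = np.random.default_rng(8)
        for _ in range(30):
            assert eng.expected_entropies().min() <= eng.posterior_entropy() + 1e-12
            eng.update(float(rng.choice(eng.stimulus_domain)), int(rng.integers(2)))

    def test_delta_posterior_triggers_tie_rule(self, tiny_engine):
        prior = np.zeros(tiny_engine._cells.shape[0])
        prior[0] = 1.0
        eng = tiny_engine.clone_reset(prior=prior)
        # every stimulus is equally uninformative: smallest |x|, positive first
        assert eng.next_stimulus() == 2.0

    def test_mirror_symmetry(self):
        grids = QuestGrids(
            alpha=np.array([-3.0, -1.0, 0.0, 1.0, 3.0]),
            beta_log10=np.array([-0.8, -0.4]),
            gamma=np.array([0.0, 0.03]), lambda_=np.array([0.0, 0.03]),
        )
        dom = [-9.0, -4.0, -1.5, 1.5, 4.0, 9.0]
        a = QuestPlus(grids, stimulus_domain=dom)
        b = QuestPlus(grids, stimulus_domain=dom)
        a.update(4.0, 1)
        b.update(-4.0, 0)
        # mirrored histories produce mirrored entropy landscapes
        assert np.allclose(
            a.expected_entropies(), b.expected_entropies()[::-1], atol=1e-12
        )
        assert abs(a.next_stimulus()) == abs(b.next_stimulus())


class TestEstimate:
    def test_delta_posterior_returns_exact_cell(self, tiny_engine):
        idx = 7
        prior = np.zeros(tiny_engine._cells.shape[0])
        prior[idx] = 1.0
        eng = tiny_engine.clone_reset(prior=prior)
        est = eng.estimate()
        cell = tiny_engine._cells[idx]
        assert est.alpha == pytest.approx(cell[0])
        assert np.log10(est.beta) == pytest.approx(cell[1])

    def test_estimate_within_grid_hull(self, tiny_engine):
        rng = np.random.default_rng(11)
        for _ in range(20):
            eng = tiny_engine.clone_reset(prior=rng.random(tiny_engine._cells.shape[0]))
            est = eng.estimate()
            g = tiny_engine.grids
            assert g.alpha.min() <= est.alpha <= g.alpha.max()
            assert g.beta_log10.min() <= np.log10(est.beta) <= g.beta_log10.max()
            assert g.gamma.min() <= est.gamma <= g.gamma.max()

    def test_mode_estimator(self, tiny_engine):
        prior = np.zeros(tiny_engine._cells.shape[0])
        prior[3] = 0.6
        prior[10] = 0.4
        eng = tiny_engine.clone_reset(prior=prior)
        est = eng.estimate(estimator="mode")
        assert est.alpha == pytest.approx(tiny_engine._cells[3, 0])


class TestBatchRunner:
    def test_matches_sequential_engine(self, tiny_engine):
        params = [PFParams(0.0, 0.4, 0.02, 0.02), PFParams(-2.0, 0.25, 0.0, 0.05)]
        stim, resp = tiny_engine.run_batch(params, 40, np.random.default_rng(5))
        for k in range(2):
            eng = tiny_engine.clone_reset()
            for t in range(40):
                assert eng.next_stimulus() == stim[k, t]
                eng.update(stim[k, t], int(resp[k, t]))

    def test_bias_recovery_over_seeds(self, design_observer, reduced_engine):
        # the engine's posterior-mean bias should land within +/-1.5% of the
        # true zero bias in at least 90% of adaptive sessions
        n_sessions = 60
        stim, resp, posts = reduced_engine.run_batch(
            [design_observer] * n_sessions, 200, np.random.default_rng(123),
            return_posteriors=True,
        )
        alphas = posts.T @ reduced_engine._cells[:, 0]
        assert np.mean(np.abs(alphas) <= 1.5) >= 0.9


class TestSerialisation:
    def test_roundtrip_preserves_state(self, tiny_engine):
        eng = tiny_engine.clone_reset()
        eng.update(2.0, 1)
        eng.update(-6.0, 0)
        back = QuestPlus.from_json(eng.to_json())
        assert np.allclose(back.posterior, eng.posterior, atol=1e-15)
        assert back.history == eng.history
        assert back.next_stimulus() == eng.next_stimulus()
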