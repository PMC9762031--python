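"""History aggregation, the sigmoid prediction head, BCE over visits, and the
FGM adversarial training step."""

import copy

import numpy as np
import pytest

from medrec.autodiff import Adam, Tensor
from medrec.prediction import (PredictionHead, adversarial_step,
                               aggregate_history, batch_prediction_loss,
                               build_history_batch, fgm_perturbation,
                               fine_tune, predict_medications, prediction_loss,
                               recommendation_set)
from medrec.records import Vocabulary


class TestAggregation:
    def test_t2_mean_is_the_first_visit(self, rng):
        embeds = {f: Tensor(rng.standard_normal((4, 8))) for f in "dms"}
        means = aggregate_history(embeds, t=2)
        for f in "dms":
            assert np.allclose(means[f].data, embeds[f].data[0])

    def test_identical_history_averages_to_itself(self):
        row = np.arange(8.0)
        embeds = {f: Tensor(np.tile(row, (5, 1))) for f in "dms"}
        means = aggregate_history(embeds, t=5)
        for f in "dms":
            assert np.allclose(means[f].data, row)

    @pytest.mark.parametrize("t", [2, 3, 5])
    def test_matches_loop_computed_means(self, rng, t):
        embeds = {f: Tensor(rng.standard_normal((6, 8))) for f in "dms"}
        means = aggregate_history(embeds, t=t)
        for f in "dms":
            loop = sum(embeds[f].data[i] for i in range(t - 1)) / (t - 1)
            assert np.max(np.abs(means[f].data - loop)) <= 1e-6

    def test_first_visit_has_no_history(self, rng):
        embeds = {f: Tensor(rng.standard_normal((3, 8))) for f in "dms"}
        with pytest.raises(ValueError):
            aggregate_history(embeds, t=1)


class TestHead:
    def test_zero_weights_give_half_probabilities(self, rng):
        head = PredictionHead(width=4, n_drugs=6, rng=rng)
        head.W.data[:] = 0.0
        means = {f: Tensor(np.zeros(4)) for f in "dms"}
        y = predict_medications(means, Tensor(np.ones(4)), Tensor(np.ones(4)), head)
        assert np.allclose(y.data, 0.5)
        assert y.data.shape == (6,)

    def test_hand_computed_two_drug_toy(self):
        # width 2 -> features are the 10-vector [m_d, m_s, m_m, cur_d, cur_s]
        head = PredictionHead(width=2, n_drugs=2, rng=np.random.default_rng(0))
        head.W.data[:] = 0.0
        head.W.data[0, 0] = 1.0   # drug 0 logit = mean_d[0]
        head.W.data[6, 1] = -2.0  # drug 1 logit = -2 * current_d[0]
        head.b.data[:] = np.array([0.5, 0.0])
        means = {"d": Tensor([2.0, 0.0]), "s": Tensor([0.0, 0.0]),
                 "m": Tensor([0.0, 0.0])}
        y = predict_medications(means, Tensor([1.5, 0.0]), Tensor([0.0, 0.0]), head)
        expect = 1 / (1 + np.exp(-np.array([2.0 + 0.5, -3.0])))
        assert np.allclose(y.data, expect, atol=1e-12)

    def test_feature_width_mismatch_rejected(self, rng):
        head = PredictionHead(width=4, n_drugs=3, rng=rng)
        with pytest.raises(ValueError):
            head.logits(Tensor(np.zeros((1, 12))))


class TestRecommendation:
    VOCAB = Vocabulary(["n1", "n2"])

    def test_thresholding_selects_high_probability_codes(self):
        assert recommendation_set(np.array([0.9, 0.1]), self.VOCAB, 0.5) == {"n1"}

    def test_lower_threshold_admits_more_drugs(self):
        y = np.array([0.35, 0.1])
        assert recommendation_set(y, self.VOCAB, 0.3) == {"n1"}
        assert recommendation_set(y, self.VOCAB, 0.5) == frozenset()

    def test_set_size_monotone_in_threshold(self, rng):
        y = rng.random(50)
        vocab = Vocabulary(f"c{i:02d}" for i in range(50))
        sizes = [len(recommendation_set(y, vocab, th))
                 for th in np.linspace(0.05, 0.95, 19)]
        assert sizes == sorted(sizes, reverse=True)


class TestPredictionLoss:
    def test_perfect_probabilities_give_zero(self):
        y = np.array([[1.0 - 1e-12, 1e-12], [1e-12, 1.0 - 1e-12]])
        t = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert prediction_loss(y, t) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_half_gives_ml_ln2_per_visit(self):
        y = np.full((3, 4), 0.5)
        t = np.zeros((3, 4))
        assert prediction_loss(y, t) == pytest.approx(4 * np.log(2), abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.uniform(0.01, 0.99, size=(5, 7))
        t = (rng.random((5, 7)) < 0.4).astype(float)
        loop = np.mean([
            sum(-(tt * np.log(pp) + (1 - tt) * np.log(1 - pp))
                for pp, tt in zip(row_y, row_t))
            for row_y, row_t in zip(y, t)])
        assert abs(prediction_loss(y, t) - loop) <= 1e-6

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            prediction_loss(np.zeros((2, 3)), np.zeros((2, 4)))


class TestFGM:
    def test_printed_example(self):
        r = fgm_perturbation(np.array([3.0, 4.0]), 1.0)
        assert np.allclose(r, [-0.6, -0.8])
        assert np.linalg.norm(r) == pytest.approx(1.0)

    def test_zero_epsilon_or_zero_gradient_gives_zero(self):
        assert np.array_equal(fgm_perturbation(np.array([1.0, 2.0]), 0.0),
                              np.zeros(2))
        assert np.array_equal(fgm_perturbation(np.zeros(3), 1.0), np.zeros(3))

    def test_norm_equals_epsilon_on_random_gradients(self, rng):
        for _ in range(1000):
            g = rng.standard_normal(rng.integers(1, 20))
            eps = float(rng.uniform(0.01, 5.0))
            assert abs(np.linalg.norm(fgm_perturbation(g, eps)) - eps) <= 1e-6

    def test_positive_sign_variant_flips_direction(self):
        g = np.array([3.0, 4.0])
        assert np.allclose(fgm_perturbation(g, 1.0, positive_sign=True),
                           [0.6, 0.8])


@pytest.fixture()
def history_batch(micro_dataset, micro_vocabs, micro_experiment):
    return build_history_batch(micro_dataset.multi_visit[:6], micro_vocabs,
                               micro_experiment.max_len)


class TestAdversarialStep:
    def test_zero_epsilon_step_equals_plain_step(self, micro_dataset,
                                                 micro_vocabs, micro_experiment,
                                                 history_batch):
        from medrec.orchestration import build_network

        def one_step(adversarial, epsilon):
            net = build_network(micro_vocabs, micro_dataset.diagnosis_ontology,
                                micro_dataset.drug_ontology, micro_experiment,
                                seed=9)
            opt = Adam(net.parameters, lr=5e-4)
            adversarial_step(net.encoder, net.prediction_head, history_batch,
                             opt, epsilon=epsilon, adversarial=adversarial)
            return [p.data.copy() for p in net.parameters]

        plain = one_step(adversarial=False, epsilon=0.0)
        adv0 = one_step(adversarial=True, epsilon=0.0)
        for a, b in zip(plain, adv0):
            assert np.max(np.abs(a - b)) <= 1e-7

    def test_no_perturbation_persists_after_the_step(self, micro_dataset,
                                                     micro_vocabs,
                                                     micro_experiment,
                                                     history_batch):
        """With a zero-learning-rate optimizer the whole step is a no-op on
        stored state, proving the perturbation is applied functionally and
        fully restored."""
        from medrec.orchestration import build_network

        net = build_network(micro_vocabs, micro_dataset.diagnosis_ontology,
                            micro_dataset.drug_ontology, micro_experiment, seed=9)
        before = [p.data.copy() for p in net.parameters]
        opt = Adam(net.parameters, lr=0.0)
        adversarial_step(net.encoder, net.prediction_head, history_batch, opt,
                         epsilon=1.0)
        for a, p in zip(before, net.parameters):
            assert np.array_equal(a, p.data)

    def test_accumulated_gradient_is_the_sum_of_both_passes(self, micro_dataset,
                                                            micro_vocabs,
                                                            micro_experiment,
                                                            history_batch):
        from medrec.orchestration import build_network
        from medrec.prediction import fgm_perturbation as fgm

        net = build_network(micro_vocabs, micro_dataset.diagnosis_ontology,
                            micro_dataset.drug_ontology, micro_experiment, seed=9)
        params = net.parameters
        eps = 0.5

        # pass 1 alone: gradient of half the clean loss
        for p in params:
            p.grad = None
        loss_clean, _ = batch_prediction_loss(net.encoder, net.prediction_head,
                                              history_batch)
        (loss_clean * 0.5).backward()
        g1 = [p.grad.copy() if p.grad is not None else 0.0 for p in params]
        perturbations = {
            f: fgm(net.encoder.embedders[f].last_code_table.grad, eps)
            for f in ("d", "m")}

        # pass 2 alone: gradient of half the perturbed loss
        for p in params:
            p.grad = None
        loss_adv, _ = batch_prediction_loss(net.encoder, net.prediction_head,
                                            history_batch, perturbations)
        (loss_adv * 0.5).backward()
        g2 = [p.grad.copy() if p.grad is not None else 0.0 for p in params]

        # the combined step accumulates exactly g1 + g2
        for p in params:
            p.grad = None
        loss_c, _ = batch_prediction_loss(net.encoder, net.prediction_head,
                                          history_batch)
        (loss_c * 0.5).backward()
        pert2 = {f: fgm(net.encoder.embedders[f].last_code_table.grad, eps)
                 for f in ("d", "m")}
        for f in ("d", "m"):
            assert np.array_equal(pert2[f], perturbations[f])
        loss_a, _ = batch_prediction_loss(net.encoder, net.prediction_head,
                                          history_batch, pert2)
        (loss_a * 0.5).backward()
        for p, a, b in zip(params, g1, g2):
            combined = p.grad if p.grad is not None else np.zeros_like(p.data)
            assert np.max(np.abs(combined - (a + b))) <= 1e-9


class TestFineTune:
    def test_loss_descends_and_runs_reproduce(self, micro_dataset, micro_vocabs,
                                              micro_experiment):
        from medrec.orchestration import build_network

        def run():
            net = build_network(micro_vocabs, micro_dataset.diagnosis_ontology,
                                micro_dataset.drug_ontology, micro_experiment,
                                seed=2)
            res = fine_tune(micro_dataset.multi_visit[:40],
                            micro_dataset.multi_visit[40:50], micro_vocabs,
                            net.encoder, net.prediction_head, net.parameters,
                            epochs=6, seed=4, batch_size=8, lr=2e-3,
                            max_len=micro_experiment.max_len)
            return [row["train"] for row in res.loss_log]

        first, second = run(), run()
        assert first == second
        assert first[-1] < first[0]

    def test_adversarial_regularization_lowers_validation_loss(
            self, micro_dataset, micro_vocabs, micro_experiment):
        """Median final-epoch validation loss over 3 seeds: the FGM-regularized
        run is no worse than the plain run on the same data and seeds."""
        from medrec.orchestration import build_network

        def final_val(adversarial, seed):
            net = build_network(micro_vocabs, micro_dataset.diagnosis_ontology,
                                micro_dataset.drug_ontology, micro_experiment,
                                seed=seed)
            res = fine_tune(micro_dataset.multi_visit[:40],
                            micro_dataset.multi_visit[40:50], micro_vocabs,
                            net.encoder, net.prediction_head, net.parameters,
                            epochs=15, seed=seed, batch_size=8, lr=2e-3,
                            adversarial=adversarial,
                            max_len=micro_experiment.max_len)
            return res.loss_log[-1]["val"]

        seeds = (0, 1, 2)
        adv = np.median([final_val(True, s) for s in seeds])
        plain = np.median([final_val(False, s) for s in seeds])
        assert adv <= plain

    def test_empty_training_set_rejected(self, micro_vocabs, micro_network):
        with pytest.raises(ValueError):
            fine_tune([], [], micro_vocabs, micro_network.encoder,
                      micro_network.prediction_head, micro_network.parameters,
                      epochs=1, seed=0)
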