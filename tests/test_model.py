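"""Latent tree inference, scores, and EM against independent oracles."""

import numpy as np
import pytest

from hlcm.cohort import MISSING, Cohort, SymptomCatalog
from hlcm.model import (FitConfig, LATENT, LatentTreeModel, OBSERVED,
                        bic_score, em_fit, flat_latent_class_model,
                        log_likelihood, model_dimension, node_marginals,
                        posterior_marginals, posterior_marginals_batch)
from hlcm.simulate import GeneratorSpec, LatentBlock, generate, spec_to_model

from conftest import (cohort_from_records, oracle_posteriors,
                      oracle_record_prob, random_record, random_small_model)


def one_latent_model(prior, leaf_probs):
    """1 binary latent over binary leaves; leaf_probs[i] = (p1, p0)."""
    leaves = [f"x{i}" for i in range(len(leaf_probs))]
    kind = {"Y": LATENT, **{l: OBSERVED for l in leaves}}
    card = {"Y": 2, **{l: 2 for l in leaves}}
    parent = {"Y": None, **{l: "Y" for l in leaves}}
    cpts = {"Y": np.array([1 - prior, prior])}
    for l, (p1, p0) in zip(leaves, leaf_probs):
        cpts[l] = np.array([[1 - p0, p0], [1 - p1, p1]])
    return LatentTreeModel(kind, card, parent, cpts)


def single_record_cohort(model, record):
    return cohort_from_records(model, [record])


class TestLogLikelihood:
    def test_symmetric_mixture_gives_log_half(self):
        model = one_latent_model(0.5, [(0.8, 0.2)])
        cohort = single_record_cohort(model, {"x0": 1})
        assert log_likelihood(model, cohort) == pytest.approx(np.log(0.5))

    def test_uninformative_latent_reduces_to_bernoulli_product(self):
        model = one_latent_model(0.3, [(0.7, 0.7), (0.2, 0.2)])
        cohort = single_record_cohort(model, {"x0": 1, "x1": 0})
        assert log_likelihood(model, cohort) == pytest.approx(
            np.log(0.7) + np.log(0.8), abs=1e-12)

    def test_missing_cells_are_marginalized(self):
        model = one_latent_model(0.4, [(0.9, 0.1), (0.8, 0.3)])
        full = single_record_cohort(model, {"x0": 1, "x1": MISSING})
        expected = oracle_record_prob(model, {"x0": 1})
        assert log_likelihood(model, full) == pytest.approx(np.log(expected),
                                                            abs=1e-12)

    def test_matches_enumeration_on_random_models(self, rng):
        for _ in range(25):
            model = random_small_model(rng)
            records = [random_record(rng, model) for _ in range(5)]
            cohort = cohort_from_records(model, records)
            _, per = log_likelihood(model, cohort, per_record=True)
            for r, rec in enumerate(records):
                assert per[r] == pytest.approx(
                    np.log(oracle_record_prob(model, rec)), abs=1e-10)

    def test_zero_probability_record_warns_and_is_minus_inf(self):
        model = one_latent_model(1.0, [(1.0, 1.0)])
        cohort = single_record_cohort(model, {"x0": 0})
        with pytest.warns(UserWarning, match="probability zero"):
            assert log_likelihood(model, cohort) == -np.inf


class TestPosteriors:
    def test_no_evidence_returns_prior(self):
        model = one_latent_model(0.3, [(0.9, 0.1)])
        post = posterior_marginals(model, {})
        assert post["Y"] == pytest.approx([0.7, 0.3], abs=1e-12)

    def test_uninformative_leaves_leave_prior_unchanged(self):
        model = one_latent_model(0.3, [(0.6, 0.6), (0.2, 0.2)])
        post = posterior_marginals(model, {"x0": 1, "x1": 0})
        assert post["Y"] == pytest.approx([0.7, 0.3], abs=1e-12)

    def test_matches_bayes_enumeration_on_random_models(self, rng):
        for _ in range(25):
            model = random_small_model(rng)
            rec = random_record(rng, model)
            if oracle_record_prob(model, rec) == 0:
                continue
            post = posterior_marginals(model, {k: v for k, v in rec.items()
                                               if v != MISSING})
            expected = oracle_posteriors(model, rec)
            for y in model.latents:
                assert post[y] == pytest.approx(expected[y], abs=1e-10)
                assert post[y].sum() == pytest.approx(1.0, abs=1e-9)


class TestScores:
    def test_dimension_of_single_latent_model(self):
        model = one_latent_model(0.4, [(0.9, 0.1)] * 5)
        assert model_dimension(model) == 1 + 2 * 5

    def test_dimension_of_four_latent_thirty_leaf_tree(self):
        from hlcm.simulate import default_study_spec
        model = spec_to_model(default_study_spec())
        assert model_dimension(model) == 67

    def test_adding_a_leaf_under_binary_parent_adds_two_parameters(self):
        model = one_latent_model(0.4, [(0.9, 0.1)] * 3)
        d = model_dimension(model)
        grown = model.copy()
        grown.kind["new_leaf"] = OBSERVED
        grown.card["new_leaf"] = 2
        grown.parent["new_leaf"] = grown.root
        grown.cpts["new_leaf"] = np.full((2, 2), 0.5)
        grown._rebuild()
        assert model_dimension(grown) == d + 2

    def test_bic_closed_form(self):
        model = one_latent_model(0.5, [(0.8, 0.2)])   # d = 3
        cohort = cohort_from_records(model, [{"x0": 1}] * 100)
        bic = bic_score(model, cohort, loglik=-50.0)
        assert bic == pytest.approx(-50.0 - 1.5 * np.log(100), abs=1e-12)

    def test_bic_penalty_difference_is_log_n(self):
        m1 = one_latent_model(0.5, [(0.8, 0.2)])          # d = 3
        m2 = one_latent_model(0.5, [(0.8, 0.2)] * 2)      # d = 5
        n = 64
        cohort1 = cohort_from_records(m1, [{"x0": 1}] * n)
        cohort2 = cohort_from_records(m2, [{"x0": 1, "x1": MISSING}] * n)
        b1 = bic_score(m1, cohort1, loglik=-10.0)
        b2 = bic_score(m2, cohort2, loglik=-10.0)
        assert b1 - b2 == pytest.approx(np.log(n), abs=1e-12)

    def test_model_implied_leaf_marginals_are_mixtures(self):
        model = one_latent_model(0.3, [(0.9, 0.1), (0.5, 0.2)])
        marg = node_marginals(model)
        assert marg["x0"][1] == pytest.approx(0.3 * 0.9 + 0.7 * 0.1, abs=1e-12)
        assert marg["x1"][1] == pytest.approx(0.3 * 0.5 + 0.7 * 0.2, abs=1e-12)


class TestStateRelabelling:
    def test_label_swap_leaves_likelihood_unchanged(self, rng):
        for _ in range(10):
            model = random_small_model(rng)
            records = [random_record(rng, model, p_missing=0.0)
                       for _ in range(8)]
            cohort = cohort_from_records(model, records)
            y = model.latents[int(rng.integers(len(model.latents)))]
            perm = list(rng.permutation(model.card[y]))
            swapped = model.permute_states(y, perm)
            assert log_likelihood(swapped, cohort) == pytest.approx(
                log_likelihood(model, cohort), abs=1e-10)


class TestEM:
    def test_all_ones_data_drives_leaf_cpts_to_one(self):
        structure = flat_latent_class_model(["a", "b"], 2)
        cohort = Cohort(SymptomCatalog.from_ids(["a", "b"]),
                        np.ones((200, 2), dtype=np.int8))
        fit = em_fit(structure, cohort, FitConfig(restarts=2, seed=0))
        marg = node_marginals(fit)
        for leaf in ("a", "b"):
            # the populated state is pinned near 1; the model-implied
            # marginal shows the vacated state only carries smoothing mass
            assert marg[leaf][1] > 0.995

    def test_loglik_nondecreasing_without_smoothing(self):
        spec = GeneratorSpec([LatentBlock("Y", 0.4, [("a", 0.9, 0.1),
                                                     ("b", 0.8, 0.2),
                                                     ("c", 0.7, 0.3)])],
                             n=2000, seed=3)
        cohort = generate(spec)
        fit = em_fit(flat_latent_class_model(["a", "b", "c"], 2), cohort,
                     FitConfig(restarts=3, seed=1, pseudocount=0.0))
        trace = np.array(fit.metadata["loglik_trace"])
        assert (np.diff(trace) > -1e-8).all()

    def test_recovers_generating_parameters(self):
        truth = [("a", 0.9, 0.1), ("b", 0.8, 0.2), ("c", 0.7, 0.3)]
        errs = []
        for seed in range(5):
            spec = GeneratorSpec([LatentBlock("Y", 0.4, truth)],
                                 n=10000, seed=seed)
            cohort = generate(spec)
            fit = em_fit(flat_latent_class_model(["a", "b", "c"], 2, "Y"),
                         cohort, FitConfig(restarts=4, seed=seed, tol=1e-8))
            # align labels: state with higher P(a=1|s) is the 0.9 class
            if fit.cpts["a"][1, 1] < fit.cpts["a"][0, 1]:
                fit = fit.permute_states("Y", [1, 0])
            errs.append([abs(fit.cpts[l][1, 1] - p1) for l, p1, _ in truth]
                        + [abs(fit.cpts[l][0, 1] - p0) for l, _, p0 in truth]
                        + [abs(fit.cpts["Y"][1] - 0.4)])
        assert np.mean(errs, axis=0).max() < 0.02

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(max_iters=0)
        with pytest.raises(ValueError):
            FitConfig(tol=0)
        with pytest.raises(ValueError):
            FitConfig(restarts=0)


class TestSerialization:
    def test_json_round_trip_preserves_distribution(self, rng, tmp_path):
        model = random_small_model(rng)
        model.metadata["note"] = "fixture"
        path = tmp_path / "m.json"
        model.save(path)
        back = LatentTreeModel.load(path)
        assert back.kind == model.kind and back.card == model.card
        assert back.parent == model.parent
        for i in model.cpts:
            np.testing.assert_allclose(back.cpts[i], model.cpts[i])
        assert back.metadata["note"] == "fixture"

    def test_bad_schema_rejected(self):
        with pytest.raises(ValueError, match="schema"):
            LatentTreeModel.from_json({"schema": "other/9"})

    def test_validate_flags_broken_structures(self):
        model = one_latent_model(0.4, [(0.9, 0.1)])   # root with 1 child
        assert any("at least two children" in p for p in model.validate())
        good = one_latent_model(0.4, [(0.9, 0.1), (0.8, 0.2)])
        assert good.validate() == []
        bad = good.copy()
        bad.cpts["x0"] = np.array([[0.5, 0.6], [0.5, 0.5]])
        assert any("sum to 1" in p for p in bad.validate())
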