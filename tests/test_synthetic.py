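import numpy as np
import pytest

from sentisess.agreement import icc_a1
from sentisess.pipeline import score_pipeline
from sentisess.preprocess import default_stopwords
from sentisess.scorer import score_corpus
from sentisess.synthetic import (
    CorpusSpec,
    RaterSpec,
    generate_corpus,
    simulate_raters,
)


class TestCorpusSpecValidation:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CorpusSpec(category_mix={"positive": 0.5, "negative": 0.2})

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            CorpusSpec(category_mix={"positive": 0.5, "sarcastic": 0.5})

    def test_probabilities_bounded(self):
        with pytest.raises(ValueError):
            CorpusSpec(p_negation=1.5)


class TestGenerateCorpus:
    def test_deterministic_per_seed(self, demo_lex):
        spec = CorpusSpec(n_patients=3, records_per_patient=10, seed=5)
        r1, t1 = generate_corpus(spec, demo_lex)
        r2, t2 = generate_corpus(spec, demo_lex)
        assert [x.text for x in r1] == [x.text for x in r2]
        assert t1.equals(t2)

    def test_different_seed_differs(self, demo_lex):
        a, _ = generate_corpus(CorpusSpec(n_patients=2, records_per_patient=10, seed=1), demo_lex)
        b, _ = generate_corpus(CorpusSpec(n_patients=2, records_per_patient=10, seed=2), demo_lex)
        assert [x.text for x in a] != [x.text for x in b]

    def test_all_irrelevant_mix_fails_relevance_filter(self, demo_lex):
        spec = CorpusSpec(
            n_patients=2,
            records_per_patient=15,
            category_mix={"irrelevant": 1.0},
            seed=3,
        )
        records, truth = generate_corpus(spec, demo_lex)
        results, summary = score_pipeline(records, demo_lex, default_stopwords(demo_lex.modifiers))
        assert summary["n_relevant_auto"] == 0
        assert (~truth.expected_relevant).all()

    def test_single_polarity_lexicon_infeasible_for_balanced_mix(self, demo_lex):
        from sentisess.lexicon import Lexicon

        pos_only = Lexicon(
            entries={w: p for w, p in demo_lex.entries.items() if p == 1},
            negators=demo_lex.negators,
            intensifiers=demo_lex.intensifiers,
        )
        with pytest.raises(ValueError):
            generate_corpus(CorpusSpec(seed=0), pos_only)

    def test_category_mix_matches_spec_within_sampling_error(self, demo_lex):
        spec = CorpusSpec(n_patients=8, records_per_patient=60, seed=11)
        _, truth = generate_corpus(spec, demo_lex)
        n = len(truth)
        for cat, p in spec.category_mix.items():
            observed = (truth.category == cat).mean()
            # binomial 4-sigma band
            assert abs(observed - p) < 4 * np.sqrt(p * (1 - p) / n) + 1e-9

    def test_ground_truth_matches_scorer_exactly(self, demo_lex):
        spec = CorpusSpec(n_patients=4, records_per_patient=30, seed=21)
        records, truth = generate_corpus(spec, demo_lex)
        results, _ = score_pipeline(records, demo_lex, default_stopwords(demo_lex.modifiers))
        by_id = {r.record_id: r for r in results}
        for row in truth.itertuples():
            res = by_id[row.record_id]
            assert res.relevant_auto == row.expected_relevant
            if row.expected_relevant:
                assert res.overall == pytest.approx(row.expected_overall, abs=1e-12)

    def test_balanced_categories_score_zero(self, demo_lex):
        spec = CorpusSpec(
            n_patients=2,
            records_per_patient=20,
            category_mix={"neutral": 0.5, "mixed": 0.5},
            seed=9,
        )
        records, truth = generate_corpus(spec, demo_lex)
        assert (truth.expected_overall == 0.0).all()


class TestSimulateRaters:
    def latent(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return {f"r{i}": v for i, v in enumerate(rng.normal(size=n))}

    def test_deterministic_per_seed(self):
        lat = self.latent(50)
        a = simulate_raters(lat, RaterSpec(true_icc=0.6, seed=4))
        b = simulate_raters(lat, RaterSpec(true_icc=0.6, seed=4))
        assert np.array_equal(a.continuous, b.continuous)
        assert a.ratings[0].scores == b.ratings[0].scores

    def test_near_one_icc_with_zero_bias_gives_identical_ratings(self):
        lat = self.latent(100)
        sim = simulate_raters(lat, RaterSpec(true_icc=1 - 1e-12, seed=1))
        assert np.allclose(sim.continuous[:, 0], sim.continuous[:, 1], atol=1e-4)
        assert sim.ratings[0].scores == sim.ratings[1].scores

    def test_bias_lowers_absolute_agreement(self):
        lat = self.latent(200)
        no_bias = simulate_raters(lat, RaterSpec(true_icc=0.9, seed=2))
        # same true_icc with bias: population ICC is held at true_icc by
        # shrinking the error variance, so the estimate stays close
        biased = simulate_raters(
            lat, RaterSpec(true_icc=0.9, rater_bias=(0.0, 0.2), seed=2)
        )
        e0 = icc_a1(no_bias.continuous).estimate
        e1 = icc_a1(biased.continuous).estimate
        assert abs(e0 - 0.9) < 0.1 and abs(e1 - 0.9) < 0.1

    def test_infeasible_bias_for_icc_rejected(self):
        with pytest.raises(ValueError, match="too large"):
            simulate_raters(
                self.latent(50), RaterSpec(true_icc=0.99, rater_bias=(0.0, 2.0), latent_var=1.0)
            )

    def test_irrelevant_disagreement_drops_records(self):
        lat = self.latent(300)
        sim = simulate_raters(
            lat, RaterSpec(true_icc=0.6, p_irrelevant_disagree=0.2, seed=8)
        )
        n0, n1 = len(sim.ratings[0].scores), len(sim.ratings[1].scores)
        assert 200 < n0 < 280 and 200 < n1 < 280

    def test_scale_cuts_produce_full_range_ints(self):
        lat = self.latent(500, seed=3)
        sim = simulate_raters(lat, RaterSpec(true_icc=0.8, seed=3))
        values = set(sim.ratings[0].scores.values())
        assert values <= set(range(1, 8))
        assert {3, 4, 5} <= values

    def test_estimator_recovers_true_icc_on_average(self):
        ests = []
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            lat = {f"r{i}": v for i, v in enumerate(rng.normal(size=250))}
            sim = simulate_raters(lat, RaterSpec(true_icc=0.9, latent_var=1.0, seed=2000 + s))
            ests.append(icc_a1(sim.continuous).estimate)
        assert abs(float(np.mean(ests)) - 0.9) < 0.03
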