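"""Section featurization and the per-subset linear discriminants (stage 3)."""

import numpy as np
import pytest

import tssmask as tm
from tssmask.kmer_stage import encode
from tssmask.ldf_stage import (
    N_SECTIONS,
    SECTION_LEN,
    LdfTrainingError,
    section_features_matrix,
)

from conftest import oracle_pwm_score, random_dna


def _random_pwms(rng, n=N_SECTIONS, length=SECTION_LEN):
    return [tm.Pwm(rng.normal(size=(4, length))) for _ in range(n)]


class TestSectionFeatures:
    def test_zero_weights_give_zero_vector(self, rng):
        pwms = [tm.Pwm(np.zeros((4, SECTION_LEN))) for _ in range(N_SECTIONS)]
        w = tm.TssWindow(random_dna(rng, 200))
        assert np.all(tm.section_features(w, pwms) == 0.0)

    def test_vector_length_is_40(self, rng, random_windows):
        pwms = _random_pwms(rng)
        for w in random_windows[:10]:
            assert tm.section_features(w, pwms).shape == (40,)

    def test_matches_slice_and_score_oracle(self, rng, random_windows):
        pwms = _random_pwms(rng)
        for w in random_windows[:100]:
            x = tm.section_features(w, pwms)
            for i in range(N_SECTIONS):
                sec = w.seq[SECTION_LEN * i : SECTION_LEN * (i + 1)]
                assert x[i] == pytest.approx(oracle_pwm_score(sec, pwms[i]), rel=1e-12)

    def test_batch_path_matches_scalar_path(self, rng, random_windows):
        pwms = _random_pwms(rng)
        codes = np.stack([encode(w.seq) for w in random_windows[:50]])
        batch = section_features_matrix(codes, pwms)
        for i, w in enumerate(random_windows[:50]):
            assert np.allclose(batch[i], tm.section_features(w, pwms), rtol=1e-12)

    def test_feature_determinism(self, rng, random_windows):
        pwms = _random_pwms(rng)
        w = random_windows[0]
        a = tm.section_features(w, pwms)
        b = tm.section_features(w, pwms)
        assert np.array_equal(a, b)


class TestFitLdf:
    def test_separates_gaussian_clouds(self, rng):
        """Two well-separated spherical clouds: the sign of the
        discriminant classifies >= 99% of a fresh sample."""
        d = 40
        mu = np.zeros(d)
        mu2 = np.full(d, 1.0)
        Xp = rng.normal(size=(1000, d)) + mu2
        Xn = rng.normal(size=(1000, d)) + mu
        c, c0 = tm.fit_ldf(Xp, Xn)
        fresh_p = rng.normal(size=(1000, d)) + mu2
        fresh_n = rng.normal(size=(1000, d)) + mu
        acc = ((fresh_p @ c + c0 > 0).mean() + (fresh_n @ c + c0 < 0).mean()) / 2
        assert acc >= 0.99

    def test_identical_classes_give_near_zero_direction(self, rng):
        X = rng.normal(size=(500, 10))
        c, _ = tm.fit_ldf(X, X.copy())
        assert np.linalg.norm(c) < 1e-8

    def test_recovers_analytic_fisher_direction(self, rng):
        """2-D problem embedded in 40-D (38 constant features): the
        recovered direction is parallel to Sw^-1 (mu1 - mu2)."""
        n = 2000
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        L = np.linalg.cholesky(cov)
        Xp2 = rng.normal(size=(n, 2)) @ L.T + [1.5, 0.5]
        Xn2 = rng.normal(size=(n, 2)) @ L.T
        pad = np.full((n, 38), 3.14)
        Xp = np.hstack([Xp2, pad])
        Xn = np.hstack([Xn2, pad])
        c, _ = tm.fit_ldf(Xp, Xn)
        mu_diff = Xp2.mean(0) - Xn2.mean(0)
        sw = ((n - 1) * np.cov(Xp2, rowvar=False) + (n - 1) * np.cov(Xn2, rowvar=False)) / (
            2 * n - 2
        )
        expected = np.linalg.solve(sw, mu_diff)
        got = c[:2]
        cos = got @ expected / (np.linalg.norm(got) * np.linalg.norm(expected))
        assert cos == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(c[2:], 0.0, atol=1e-6 * np.linalg.norm(got))

    def test_positive_class_scores_higher_on_average(self, rng):
        Xp = rng.normal(size=(200, 5)) + 2.0
        Xn = rng.normal(size=(200, 5))
        c, c0 = tm.fit_ldf(Xp, Xn)
        assert (Xp @ c + c0).mean() > (Xn @ c + c0).mean()

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(LdfTrainingError):
            tm.fit_ldf(rng.normal(size=(1, 4)), rng.normal(size=(10, 4)))


class TestLdfStage:
    def test_training_members_all_pass(self, small_corpus):
        models = tm.train_ldf_stage(small_corpus.positives, small_corpus.negatives)
        assert all(
            tm.classify_ldf_stage(w, models) for w in small_corpus.positives
        )

    def test_threshold_is_exhaustive_minimum(self, small_corpus):
        models = tm.train_ldf_stage(small_corpus.positives, small_corpus.negatives)
        by_subset = {}
        for w in small_corpus.positives:
            key = tm.central_dinucleotide(w)
            m = models[key]
            s = float(tm.section_features(w, m.section_pwms) @ m.coef + m.intercept)
            by_subset.setdefault(key, []).append(s)
        for key, scores in by_subset.items():
            assert models[key].ldf_min == pytest.approx(min(scores), rel=1e-9)

    def test_one_subset_per_observed_dinucleotide(self, small_corpus):
        models = tm.train_ldf_stage(small_corpus.positives, small_corpus.negatives)
        observed = {tm.central_dinucleotide(w) for w in small_corpus.positives}
        assert set(models) == observed
        assert observed <= set(tm.DINUCLEOTIDES)

    def test_all_16_subsets_present_with_spanning_positives(self):
        corpus = tm.generate_corpus(tm.SynthConfig(n_pos=3000, n_neg=1500, seed=33))
        observed = {tm.central_dinucleotide(w) for w in corpus.positives}
        assert observed == set(tm.DINUCLEOTIDES)
        models = tm.train_ldf_stage(corpus.positives, corpus.negatives)
        assert set(models) == set(tm.DINUCLEOTIDES)

    def test_absent_subset_rejects(self, rng, small_corpus):
        models = {
            k: v
            for k, v in tm.train_ldf_stage(
                small_corpus.positives, small_corpus.negatives
            ).items()
            if k != "GG"
        }
        s = random_dna(rng, 200)
        probe = tm.TssWindow(s[:99] + "GG" + s[101:])
        assert not tm.classify_ldf_stage(probe, models)

    def test_subset_without_negatives_raises_naming_subset(self, rng):
        wins = []
        for _ in range(10):
            s = random_dna(rng, 200)
            wins.append(tm.TssWindow(s[:99] + "CA" + s[101:]))
        negs = [
            tm.TssWindow(random_dna(rng, 99) + "GG" + random_dna(rng, 99))
            for _ in range(10)
        ]
        with pytest.raises(LdfTrainingError, match="CA"):
            tm.train_ldf_stage(wins, negs)

    def test_decisions_match_recompute_oracle(self, small_corpus, random_windows):
        models = tm.train_ldf_stage(small_corpus.positives, small_corpus.negatives)
        for w in random_windows[:500]:
            key = tm.central_dinucleotide(w)
            m = models.get(key)
            if m is None:
                expected = False
            else:
                x = np.array(
                    [
                        oracle_pwm_score(
                            w.seq[SECTION_LEN * i : SECTION_LEN * (i + 1)],
                            m.section_pwms[i],
                        )
                        for i in range(N_SECTIONS)
                    ]
                )
                expected = float(x @ m.coef + m.intercept) >= m.ldf_min - 1e-9
            assert tm.classify_ldf_stage(w, models) == expected

    def test_affine_feature_rescaling_preserves_decisions(self, rng):
        """Scaling all features by a positive constant and refitting leaves
        the sign of the discriminant (hence the stage decision relative to
        the rescaled threshold) unchanged."""
        Xp = rng.normal(size=(300, 40)) + 0.8
        Xn = rng.normal(size=(300, 40))
        c1, b1 = tm.fit_ldf(Xp, Xn)
        a = 4.2
        c2, b2 = tm.fit_ldf(a * Xp, a * Xn)
        probes = rng.normal(size=(200, 40))
        s1 = probes @ c1 + b1
        s2 = (a * probes) @ c2 + b2
        assert np.array_equal(np.sign(np.round(s1, 10)), np.sign(np.round(s2 * a, 10)))
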