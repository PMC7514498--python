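import numpy as np
import pandas as pd
import pytest

from speechlaws import (
    SynthSpec,
    UnitToken,
    analyze_brevity,
    analyze_herdan,
    analyze_lognormality,
    analyze_menzerath,
    analyze_size_rank,
    analyze_zipf,
    fit_lognormal,
    generate_corpus,
    predicted_theta,
    sample_phonemes,
    segment_breath_groups,
)
from speechlaws.laws import rank_frequency_table


class TestLognormality:
    def test_phoneme_location_recovered_from_generative_model(self):
        # stochastic-model conditions: X ~ N(-3, 2^2)
        y = sample_phonemes(SynthSpec(seed=21, mu=-3.0, sigma=2.0), 100_000)
        assert fit_lognormal(y).mu == pytest.approx(-3.0, abs=0.02)

    def test_all_levels_reported_on_synthetic_corpus(self, default_corpus):
        _, h = default_corpus
        res = analyze_lognormality(h)
        assert set(res.fits) == {"phoneme", "word", "breath_group"}
        for fit in res.fits.values():
            assert fit.sigma > 0 and 0 <= fit.ks_to_gaussian <= 1

    def test_coarsening_degrades_the_collapse(self, default_corpus):
        _, h = default_corpus
        res = analyze_lognormality(h, coarsening=(0.01, 0.03))
        assert (
            res.coarsened_fits["phoneme"].ks_to_gaussian
            > res.fits["phoneme"].ks_to_gaussian
        )
        assert (
            res.coarsened_fits["word"].ks_to_gaussian
            >= res.fits["word"].ks_to_gaussian
        )

    def test_word_only_corpus_reports_absent_level(self):
        words, t = [], 0.0
        for i in range(40):
            dur = 0.1 + 0.02 * (i % 5)
            words.append(
                UnitToken(label=f"w{i % 7}", level="word", start=t, end=t + dur, speaker="s1")
            )
            t += dur + (0.4 if i % 3 == 0 else 0.0)  # pauses -> many BGs
        h = segment_breath_groups(words, pause_threshold=0.2)
        res = analyze_lognormality(h)
        assert "word" in res.fits and "breath_group" in res.fits
        assert "phoneme" in res.errors


class TestZipf:
    def test_generating_exponent_recovered(self, coupled_corpus):
        spec, h = coupled_corpus
        res = analyze_zipf(h)
        assert res.word_fit.alpha == pytest.approx(spec.zipf_alpha, abs=0.05)
        assert res.phoneme_fit is not None  # Yule fit on phoneme ranks

    def test_rank_table_is_order_free(self, default_corpus):
        _, h = default_corpus
        tab1 = rank_frequency_table(h.words["label"])
        shuffled = h.words["label"].sample(frac=1.0, random_state=0).reset_index(drop=True)
        tab2 = rank_frequency_table(shuffled)
        assert tab1["freq"].tolist() == tab2["freq"].tolist()
        assert dict(zip(tab1["label"], tab1["freq"])) == dict(zip(tab2["label"], tab2["freq"]))

    def test_rank_frequency_invariants(self, default_corpus):
        _, h = default_corpus
        res = analyze_zipf(h)
        assert (np.diff(res.freqs) <= 0).all()
        assert res.freqs.sum() == h.n_tokens("word")

    def test_single_type_vocabulary_surfaces_fitter_error(self):
        h = generate_corpus(SynthSpec(seed=2, vocab_size=1), 200)
        res = analyze_zipf(h)
        assert res.word_fit is None
        assert "word" in res.errors and "1 word types" in res.errors["word"]


class TestHerdan:
    def test_all_new_types_gives_linear_growth(self):
        words = [
            UnitToken(label=f"w{i}", level="word", start=i * 0.2, end=i * 0.2 + 0.18,
                      speaker="s1")
            for i in range(200)
        ]
        h = segment_breath_groups(words)
        res = analyze_herdan(h, n_permutations=1, seed=0)
        curve = res.curves[0]
        assert (curve["V"] == curve["L"]).all()
        assert res.beta == pytest.approx(1.0, abs=1e-9)

    def test_sublinear_exponents_on_zipf_corpus(self, default_corpus):
        _, h = default_corpus
        res = analyze_herdan(h, n_permutations=6, seed=1)
        assert 0 < res.beta < 1
        assert 0 < res.gamma < 1
        assert res.beta == pytest.approx(res.gamma, abs=0.03)

    def test_growth_curves_monotone_and_bounded(self, default_corpus):
        _, h = default_corpus
        res = analyze_herdan(h, n_permutations=3, seed=2)
        for curve in res.curves:
            assert (np.diff(curve["V"]) >= 0).all()
            assert (curve["V"] <= curve["L"]).all()

    def test_fixed_seed_is_deterministic(self, default_corpus):
        _, h = default_corpus
        r1 = analyze_herdan(h, n_permutations=2, seed=7)
        r2 = analyze_herdan(h, n_permutations=2, seed=7)
        assert r1.beta == r2.beta and r1.gamma == r2.gamma


class TestBrevity:
    def test_generating_rate_recovered_in_physical_units(self, coupled_corpus):
        spec, h = coupled_corpus
        res = analyze_brevity(h, level="word")
        lam = res.fits["duration"].lambda_rate
        assert lam == pytest.approx(spec.brevity_lambda, rel=0.10)
        assert res.fits["duration"].spearman_rho < 0
        assert res.informative["duration"]

    def test_lambda_D_within_coding_bounds(self, coupled_corpus):
        _, h = coupled_corpus
        res = analyze_brevity(h, level="word")
        for unit, lam_D in res.lambda_D.items():
            assert 0 < lam_D <= 1, unit
            assert res.D[unit] > 1

    def test_uniform_frequencies_flagged_uninformative(self):
        # every type equally frequent: no size-frequency association
        words = []
        t = 0.0
        for rep in range(6):
            for i in range(12):
                dur = 0.1 + 0.02 * i
                words.append(
                    UnitToken(label=f"w{i}", level="word", start=t, end=t + dur, speaker="s1")
                )
                t += dur + 0.01
        h = segment_breath_groups(words, pause_threshold=0.5)
        res = analyze_brevity(h, level="word")
        assert not res.informative["duration"]

    def test_phoneme_level_physical_units(self, coupled_corpus):
        _, h = coupled_corpus
        res = analyze_brevity(h, level="phoneme")
        assert "duration" in res.fits
        assert "phonemes" not in res.fits


class TestSizeRank:
    def test_predicted_theta_is_alpha_over_lambda(self):
        assert predicted_theta(1.42, 23.8) == pytest.approx(0.060, abs=1e-3)
        assert predicted_theta(24.1, 24.1) == pytest.approx(1.0)

    def test_fitted_theta_matches_generator(self, coupled_corpus):
        spec, h = coupled_corpus
        zipf = analyze_zipf(h)
        brev = analyze_brevity(h, level="word")
        res = analyze_size_rank(zipf, brev, unit="duration")
        theta_true = spec.zipf_alpha / spec.brevity_lambda
        assert res.theta == pytest.approx(theta_true, rel=0.10)
        assert res.theta_predicted == pytest.approx(theta_true, rel=0.15)
        assert res.theta > 0

    def test_unknown_unit_rejected(self, coupled_corpus):
        _, h = coupled_corpus
        zipf = analyze_zipf(h)
        brev = analyze_brevity(h, level="word")
        with pytest.raises(Exception, match="duration|unit"):
            analyze_size_rank(zipf, brev, unit="syllables")


class TestMenzerath:
    def test_bg_words_fits_all_unit_systems(self, coupled_corpus):
        _, h = coupled_corpus
        res = analyze_menzerath(h, scale_pair="bg_words")
        assert {"duration", "phonemes", "characters"} <= set(res.fits) | set(res.errors)
        assert (res.table["n"] >= 1).all()
        assert (res.table["duration"] > 0).all()

    def test_word_phonemes_scale(self, coupled_corpus):
        _, h = coupled_corpus
        res = analyze_menzerath(h, scale_pair="word_phonemes")
        assert "duration" in res.fits
        # y is the mean phoneme duration within the word
        np.testing.assert_allclose(
            res.table["duration"] * res.table["n"], h.words["t"], rtol=1e-9
        )

    def test_unknown_scale_pair_rejected(self, coupled_corpus):
        _, h = coupled_corpus
        with pytest.raises(Exception, match="scale_pair"):
            analyze_menzerath(h, scale_pair="sentence_words")
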