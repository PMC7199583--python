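import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from megapath.effect_size import EffectEstimate
from megapath.mega_analysis import (
    FIXED,
    RANDOM,
    MegaAnalysis,
    fixed_effects,
    heterogeneity,
    meta_analyze,
    random_effects,
)


def E(lfc, se, study="s", gene="G"):
    return EffectEstimate(gene=gene, study_id=study, lfc=lfc, se=se,
                          n_case=10, n_control=10)


def effects(pairs):
    return [E(l, s, study=f"s{i}") for i, (l, s) in enumerate(pairs)]


class TestFixedEffects:
    def test_single_study_is_identity(self):
        r = fixed_effects([E(0.7, 0.2)])
        assert r.pooled_lfc == pytest.approx(0.7)
        assert r.pooled_se == pytest.approx(0.2)

    def test_two_study_closed_form(self):
        r = fixed_effects(effects([(1.0, 1.0), (3.0, 1.0)]))
        assert r.pooled_lfc == pytest.approx(2.0, abs=1e-12)
        assert r.pooled_se == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_shared_value_is_conserved(self):
        r = fixed_effects(effects([(0.3, 0.5), (0.3, 0.1), (0.3, 2.0)]))
        assert r.pooled_lfc == pytest.approx(0.3, abs=1e-12)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            MegaAnalysis([])

    @given(
        st.lists(
            st.tuples(st.floats(-3, 3), st.floats(0.05, 2.0)),
            min_size=1, max_size=4,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_closed_form_oracle_and_convexity(self, pairs):
        effs = effects(pairs)
        r = fixed_effects(effs)
        w = np.array([1 / s**2 for _, s in pairs])
        l = np.array([l for l, _ in pairs])
        assert r.pooled_lfc == pytest.approx((w * l).sum() / w.sum(), abs=1e-12)
        assert r.pooled_se == pytest.approx(1 / np.sqrt(w.sum()), abs=1e-12)
        assert min(l) - 1e-12 <= r.pooled_lfc <= max(l) + 1e-12


class TestHeterogeneity:
    def test_identical_effects_have_no_dispersion(self):
        het = heterogeneity(effects([(0.5, 1.0), (0.5, 1.0)]))
        assert het.Q == pytest.approx(0.0, abs=1e-12)
        assert het.ISq == 0.0
        assert het.Qp == pytest.approx(1.0)

    def test_hand_oracle_two_studies(self):
        het = heterogeneity(effects([(0.0, 1.0), (2.0, 1.0)]))
        assert het.Q == pytest.approx(2.0, abs=1e-10)
        assert het.df == 1
        assert het.ISq == pytest.approx(50.0, abs=1e-10)
        assert het.Qp == pytest.approx(stats.chi2.sf(2.0, 1), abs=1e-10)
        assert het.Qp == pytest.approx(0.1573, abs=5e-5)

    def test_single_study_is_precondition_error(self):
        with pytest.raises(ValueError, match="two studies"):
            heterogeneity([E(0.5, 1.0)])

    @given(
        st.lists(
            st.tuples(st.floats(-3, 3), st.floats(0.05, 2.0)),
            min_size=2, max_size=6,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_isq_bounds_and_clamp(self, pairs):
        het = heterogeneity(effects(pairs))
        assert 0.0 <= het.ISq <= 100.0
        if het.Q <= het.df:
            assert het.ISq == 0.0
        else:
            assert het.ISq == pytest.approx(100 * (het.Q - het.df) / het.Q)


class TestRandomEffects:
    def test_dl_hand_oracle(self):
        # w=1 each: C = 2 - 2/2 = 1, tau2 = (2-1)/1 = 1, w* = 1/2 each
        r = random_effects(effects([(0.0, 1.0), (2.0, 1.0)]))
        assert r.tau2 == pytest.approx(1.0, abs=1e-12)
        assert r.pooled_lfc == pytest.approx(1.0, abs=1e-12)
        assert r.pooled_se == pytest.approx(1.0, abs=1e-12)

    def test_homogeneous_data_reduces_to_fixed(self):
        effs = effects([(0.5, 1.0), (0.5, 0.8), (0.52, 1.2)])
        rnd, fix = random_effects(effs), fixed_effects(effs)
        assert heterogeneity(effs).Q <= heterogeneity(effs).df
        assert rnd.tau2 == 0.0
        assert rnd.pooled_lfc == fix.pooled_lfc
        assert rnd.pooled_se == fix.pooled_se
        assert rnd.p_value == fix.p_value

    def test_matches_statsmodels_combine_effects(self, rng):
        # independent oracle: statsmodels' inverse-variance pooling with DL
        from statsmodels.stats.meta_analysis import combine_effects

        # heterogeneous draws so the DL estimate is strictly positive
        # (statsmodels reports the unclamped moment estimate)
        lfc = rng.normal(0.4, 1.0, 8)
        se = rng.uniform(0.1, 0.3, 8)
        effs = [E(l, s, study=f"s{i}") for i, (l, s) in enumerate(zip(lfc, se))]
        ours_f, ours_r = fixed_effects(effs), random_effects(effs)
        ref = combine_effects(lfc, se**2, method_re="dl")
        assert ref.tau2 > 0
        frame = ref.summary_frame()
        assert ours_f.pooled_lfc == pytest.approx(
            frame.loc["fixed effect", "eff"], abs=1e-10
        )
        assert ours_r.pooled_lfc == pytest.approx(
            frame.loc["random effect", "eff"], abs=1e-10
        )
        assert ours_r.tau2 == pytest.approx(ref.tau2, abs=1e-10)

    def test_dl_recovers_planted_tau2_on_average(self, rng):
        true_tau2, k, reps = 0.3, 50, 200
        estimates = []
        for _ in range(reps):
            se = rng.uniform(0.1, 0.3, k)
            lfc = rng.normal(0.0, np.sqrt(true_tau2 + se**2))
            effs = [E(l, s, study=f"s{i}") for i, (l, s) in enumerate(zip(lfc, se))]
            estimates.append(random_effects(effs).tau2)
        assert abs(np.mean(estimates) - true_tau2) / true_tau2 < 0.5


class TestModelSelection:
    def test_low_dispersion_selects_fixed(self):
        r = meta_analyze(effects([(0.5, 1.0), (0.6, 1.0), (0.5, 1.0)]))
        assert r.model == FIXED and r.tau2 == 0.0

    def test_high_dispersion_selects_random(self):
        r = meta_analyze(effects([(0.0, 0.1), (2.0, 0.1)]))
        assert r.model == RANDOM and r.tau2 > 0.0

    def test_selection_matches_isq_clamp_exactly(self):
        for pairs in ([(0.0, 1.0), (1.3, 1.0)], [(0.0, 1.0), (1.5, 1.0)]):
            het = heterogeneity(effects(pairs))
            r = meta_analyze(effects(pairs))
            assert (r.model == FIXED) == (het.ISq == 0.0)

    def test_single_study_fixed_with_undefined_heterogeneity(self):
        r = meta_analyze([E(0.7, 0.2)])
        assert r.model == FIXED and r.k == 1 and r.het is None

    def test_qp_reported_but_never_gates(self):
        # Q > df yet Qp far from significant: random must still be chosen
        r = meta_analyze(effects([(0.0, 1.0), (1.5, 1.0)]))
        assert r.het.Q > r.het.df and r.het.Qp > 0.2
        assert r.model == RANDOM


class TestResultsObject:
    def test_summary_mentions_model_and_heterogeneity(self):
        res = MegaAnalysis(effects([(0.2, 0.5), (0.4, 0.5)])).fit()
        text = res.summary()
        for token in ("pooled LFC", "ISq", "Q-p", res.model):
            assert token in text

    def test_forcing_models_brackets_auto_choice(self):
        effs = effects([(0.0, 0.5), (1.0, 0.5), (2.0, 0.5)])
        model = MegaAnalysis(effs)
        auto = model.fit().result
        forced = model.fit(method=auto.model).result
        assert auto == forced
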