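"""Accumulator dynamics, input time courses, and variant resolution."""

import dataclasses

import numpy as np
import pytest
from scipy import integrate

import simonlca as sl
from simonlca.model import (Congruency, Response, TrialContext, Variant,
                            VariantSpec, irrelevant_timecourse,
                            noise_free_decision_time,
                            resolve_trial_parameters, simulate_condition,
                            simulate_trial, simulate_trials)


class TestIrrelevantTimecourse:
    def test_onset_value_and_zero_crossing(self):
        assert irrelevant_timecourse(0.0, 0.29, 100.0, +1) == pytest.approx(0.29)
        assert irrelevant_timecourse(0.0, 0.29, 100.0, -1) == pytest.approx(-0.29)
        # crosses zero exactly at tau (100 ms in the canonical example)
        assert irrelevant_timecourse(100.0, 0.29, 100.0) == pytest.approx(0.0, abs=1e-15)

    def test_sign_reversal_and_decay(self):
        t = np.linspace(0, 1000, 2001)
        h = irrelevant_timecourse(t, 1.0, 100.0)
        assert np.all(h[t < 100] > 0)
        assert np.all(h[(t > 100.5) & (t < 900)] < 0)
        assert abs(h[-1]) < 1e-3

    def test_zero_total_area(self):
        # quadrature oracle: the step response integrates to zero
        val, err = integrate.quad(
            lambda t: irrelevant_timecourse(t, 0.7, 80.0), 0, 50 * 80.0,
            limit=200)
        assert abs(val) < max(1e-8, 10 * err)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            irrelevant_timecourse(-1.0, 1.0, 100.0)
        with pytest.raises(ValueError):
            irrelevant_timecourse(1.0, 1.0, 0.0)


class TestParameterValidation:
    @pytest.mark.parametrize("kw", [
        {"rel_input": 0.0}, {"rel_input": 1.0}, {"irr_tau": 0.0},
        {"noise_sd": -0.1}, {"threshold": 0.0}, {"dt": 0.0},
        {"prep_bias": 50.0},  # >= threshold
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            sl.ModelParameters(**kw)

    def test_variant_requires_its_fields(self):
        with pytest.raises(ValueError):
            VariantSpec(variant=Variant.SHIELDING)
        with pytest.raises(ValueError):
            VariantSpec(pi_freq=1.5)


class TestResolveTrialParameters:
    def test_preparation_is_identity(self, default_params):
        ctx = TrialContext(Response.FREQUENT, Congruency.CONGRUENT,
                           Response.FREQUENT)
        out = resolve_trial_parameters(default_params, VariantSpec(), ctx)
        assert out == default_params

    def test_attention_selects_by_expected_side(self, default_params):
        v = VariantSpec(variant=Variant.ATTENTION, attention_rel_same=0.539,
                        attention_rel_opposite=0.502)
        # congruent + prepared: stimulus on the expected-response side
        ctx = TrialContext(Response.FREQUENT, Congruency.CONGRUENT,
                           Response.FREQUENT)
        assert resolve_trial_parameters(default_params, v, ctx).rel_input == 0.539
        ctx = TrialContext(Response.FREQUENT, Congruency.INCONGRUENT,
                           Response.FREQUENT)
        assert resolve_trial_parameters(default_params, v, ctx).rel_input == 0.502

    def test_contingency_selects_by_stimulus_location(self, default_params):
        v = VariantSpec(variant=Variant.CONTINGENCY,
                        contingency_rel_freqside=0.533,
                        contingency_rel_infrside=0.505,
                        contingency_irr_freqside=0.298,
                        contingency_irr_infrside=0.273)
        # frequent-congruent: stimulus on the frequent-response side
        ctx = TrialContext(Response.FREQUENT, Congruency.CONGRUENT,
                           Response.FREQUENT)
        out = resolve_trial_parameters(default_params, v, ctx)
        assert out.irr_amplitude == 0.298 and out.rel_input == 0.533
        # infrequent-congruent: stimulus on the infrequent side
        ctx = TrialContext(Response.INFREQUENT, Congruency.CONGRUENT,
                           Response.FREQUENT)
        out = resolve_trial_parameters(default_params, v, ctx)
        assert out.irr_amplitude == 0.273 and out.rel_input == 0.505

    def test_shielding_applies_only_when_prepared(self, default_params):
        v = VariantSpec(variant=Variant.SHIELDING, shield_irr_amplitude=0.18,
                        shield_irr_tau=180.0)
        prepared = TrialContext(Response.FREQUENT, Congruency.CONGRUENT,
                                Response.FREQUENT)
        unprepared = TrialContext(Response.FREQUENT, Congruency.CONGRUENT,
                                  Response.INFREQUENT)
        out = resolve_trial_parameters(default_params, v, prepared)
        assert (out.irr_amplitude, out.irr_tau) == (0.18, 180.0)
        out = resolve_trial_parameters(default_params, v, unprepared)
        assert out == default_params

    def test_vectorized_resolution_matches_scalar(self, default_params):
        from simonlca.model import _context_arrays
        rng = np.random.default_rng(5)
        v = VariantSpec(variant=Variant.CONTINGENCY,
                        contingency_rel_freqside=0.54, contingency_rel_infrside=0.51,
                        contingency_irr_freqside=0.3, contingency_irr_infrside=0.25)
        required = rng.random(64) < 0.75
        congruent = rng.random(64) < 0.5
        prepared = rng.random(64) < 0.9
        rel, amp, tau, sign = _context_arrays(default_params, v, required,
                                              congruent, prepared)
        for i in range(64):
            req = Response.FREQUENT if required[i] else Response.INFREQUENT
            congr = Congruency.CONGRUENT if congruent[i] else Congruency.INCONGRUENT
            exp = req if prepared[i] else req.other()
            ctx = TrialContext(req, congr, exp)
            p = resolve_trial_parameters(default_params, v, ctx)
            assert rel[i] == p.rel_input and amp[i] == p.irr_amplitude


class TestSimulation:
    def test_same_seed_bit_identical(self, default_params, preparation_variant):
        a = simulate_condition(default_params, preparation_variant,
                               (Response.FREQUENT, Congruency.INCONGRUENT),
                               500, np.random.default_rng(99))
        b = simulate_condition(default_params, preparation_variant,
                               (Response.FREQUENT, Congruency.INCONGRUENT),
                               500, np.random.default_rng(99))
        assert np.array_equal(a.correct_rts, b.correct_rts)
        assert a.n_errors == b.n_errors

    def test_single_trial_contract(self, default_params):
        ctx = TrialContext(Response.FREQUENT, Congruency.CONGRUENT,
                           Response.FREQUENT)
        trial = simulate_trial(default_params, ctx, np.random.default_rng(1))
        assert trial.rt is None or trial.rt > 0
        assert isinstance(trial.correct, bool)

    def test_degenerate_condition_size(self, default_params, preparation_variant):
        s = simulate_condition(default_params, preparation_variant,
                               (Response.FREQUENT, Congruency.CONGRUENT), 1,
                               np.random.default_rng(3))
        assert s.error_pct in (0.0, 100.0)

    def test_all_timeouts_raise(self, preparation_variant):
        p = sl.ModelParameters(threshold=39.0, prep_bias=0.0, max_time=5.0)
        with pytest.raises(RuntimeError):
            simulate_condition(p, preparation_variant,
                               (Response.FREQUENT, Congruency.CONGRUENT), 20,
                               np.random.default_rng(0))

    def test_response_label_symmetry(self, default_params):
        """Swapping frequency-class labels (and pi accordingly) is a no-op."""
        n = 400
        a = simulate_condition(default_params, VariantSpec(pi_freq=0.8),
                               (Response.FREQUENT, Congruency.CONGRUENT), n,
                               np.random.default_rng(77))
        b = simulate_condition(default_params, VariantSpec(pi_freq=0.2),
                               (Response.INFREQUENT, Congruency.CONGRUENT), n,
                               np.random.default_rng(77))
        assert np.array_equal(a.correct_rts, b.correct_rts)

    def test_preparation_speeds_responses(self, default_params):
        """A head start on the correct code stochastically lowers RTs."""
        n = 20_000
        fast = simulate_condition(default_params, VariantSpec(pi_freq=1.0),
                                  (Response.FREQUENT, Congruency.CONGRUENT), n,
                                  np.random.default_rng(8))
        slow = simulate_condition(default_params, VariantSpec(pi_freq=0.0),
                                  (Response.FREQUENT, Congruency.CONGRUENT), n,
                                  np.random.default_rng(8))
        assert np.all(fast.quantiles < slow.quantiles)

    def test_no_irrelevant_input_no_simon_effect_small(self, default_params):
        p = dataclasses.replace(default_params, irr_amplitude=1e-9)
        v = VariantSpec(pi_freq=0.5)
        n = 20_000
        c = simulate_condition(p, v, (Response.FREQUENT, Congruency.CONGRUENT),
                               n, np.random.default_rng(10))
        i = simulate_condition(p, v, (Response.FREQUENT, Congruency.INCONGRUENT),
                               n, np.random.default_rng(11))
        se = np.sqrt(c.correct_rts.var() / c.correct_rts.size
                     + i.correct_rts.var() / i.correct_rts.size)
        assert abs(i.mean_rt - c.mean_rt) < 3 * se


class TestNoiseFreeOracle:
    def test_crossing_matches_fine_reference_spotchecks(self, default_params):
        p = dataclasses.replace(default_params, noise_sd=0.0, lead_sd=0.0,
                                resid_sd=0.0, max_time=1500.0)
        for congr in (Congruency.CONGRUENT, Congruency.INCONGRUENT):
            ctx = TrialContext(Response.FREQUENT, congr, Response.FREQUENT)
            coarse = noise_free_decision_time(p, ctx)
            fine = noise_free_decision_time(p, ctx, dt=0.01)
            assert coarse == pytest.approx(fine, abs=1.0)
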