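"""Generator contracts: design structure, calibration, additivity."""
import numpy as np
import pytest

from costim.config import (
    BLOCK_TYPES,
    CONDITIONS,
    GeneratorConfig,
    SITE_BF,
    SITE_SPINAL,
    SITE_VL,
    SiteParams,
    StimTrain,
)
from costim.exceptions import ConfigurationError
from costim.extraction import demean_trace, steady_state_vector, steady_table
from costim.metrics import compute_error_table
from costim.synthetic import (
    generate_study,
    generate_trace,
    interaction_term,
    make_design,
    sample_subject_params,
)


def _steady(trace):
    return steady_state_vector(demean_trace(trace)).vector


class TestDesign:
    @pytest.mark.parametrize("n_subjects,n_blocks,expected_costim",
                             [(12, 8, 96), (1, 1, 1), (3, 5, 15)])
    def test_co_stimulation_trial_counts(self, n_subjects, n_blocks, expected_costim):
        design = make_design(GeneratorConfig(n_subjects=n_subjects, n_blocks=n_blocks))
        for bt in BLOCK_TYPES:
            assert design.co_stim_count(bt) == expected_costim
        assert len(design) == 2 * 3 * n_subjects * n_blocks

    def test_each_block_has_one_of_each_condition(self):
        design = make_design(GeneratorConfig(n_subjects=2, n_blocks=3, seed=1))
        for bt in BLOCK_TYPES:
            for subject in (1, 2):
                for block in (1, 2, 3):
                    conds = [s.condition for s in design.slots
                             if (s.subject_id, s.block_type, s.block_id)
                             == (subject, bt, block)]
                    assert sorted(conds) == sorted(CONDITIONS)
                    orders = [s.slot_order for s in design.slots
                              if (s.subject_id, s.block_type, s.block_id)
                              == (subject, bt, block)]
                    assert sorted(orders) == [0, 1, 2]

    def test_seeded_determinism_and_seed_sensitivity(self):
        cfg = GeneratorConfig(n_subjects=4, n_blocks=8, seed=3)
        a = make_design(cfg)
        b = make_design(cfg)
        assert a == b
        c = make_design(cfg.model_copy(update={"seed": 4}))
        assert a != c  # some block permutation differs with high probability

    def test_invalid_counts_rejected(self):
        with pytest.raises((ConfigurationError, ValueError)):
            GeneratorConfig(n_subjects=0)
        with pytest.raises((ConfigurationError, ValueError)):
            GeneratorConfig(n_blocks=0)


class TestStimTrain:
    def test_pulse_counts_match_train_arithmetic(self):
        assert StimTrain(period=0.015, pulse_width=0.0002,
                         train_duration=0.600).n_pulses == 40
        assert StimTrain(period=0.013, pulse_width=0.00012,
                         train_duration=0.520).n_pulses == 40

    def test_trace_metadata_records_pulse_count(self, tiny_study):
        spinal_only = next(t for t in tiny_study.traces
                           if t.meta["condition"] == "site_A_only"
                           and t.meta["site_a"] == SITE_SPINAL)
        assert spinal_only.meta["n_pulses_a"] == 40

    def test_pulse_width_must_be_less_than_period(self):
        with pytest.raises((ConfigurationError, ValueError)):
            StimTrain(period=0.001, pulse_width=0.002, train_duration=0.6)


class TestSubjectSampler:
    def test_zero_variance_reproduces_population_params(self):
        cfg = GeneratorConfig(between_subject_dir_sd=0.0, site_params={
            s: p.model_copy(update={"base_magnitude_sd": 0.0})
            for s, p in GeneratorConfig().site_params.items()})
        for sid in (1, 5):
            params = sample_subject_params(cfg, sid)
            for site, realized in params.items():
                expect = cfg.site_params[site]
                assert realized.magnitude == expect.base_magnitude_mean
                np.testing.assert_allclose(realized.direction,
                                           expect.direction_array(), atol=1e-12)

    def test_sampler_matches_stated_distribution(self):
        # Monte-Carlo check of the truncated-normal magnitude sampler
        cfg = GeneratorConfig(seed=21)
        mags = {SITE_SPINAL: [], SITE_VL: []}
        for sid in range(1, 10_001):
            p = sample_subject_params(cfg, sid)
            mags[SITE_SPINAL].append(p[SITE_SPINAL].magnitude)
            mags[SITE_VL].append(p[SITE_VL].magnitude)
        for site, anchor, sd in ((SITE_SPINAL, 0.55, 0.27), (SITE_VL, 0.70, 0.21)):
            arr = np.array(mags[site])
            assert np.all(arr > 0)
            # truncation at 0 shifts the mean up slightly; stay within 2 SE + shift
            se = sd / np.sqrt(arr.size)
            assert abs(arr.mean() - anchor) < 0.02 + 2 * se

    def test_magnitude_calibration_anchors(self):
        # 1000 subjects at defaults: means and medians near 0.55 / 0.70 N
        cfg = GeneratorConfig(seed=8)
        spinal, muscle = [], []
        for sid in range(1, 1001):
            p = sample_subject_params(cfg, sid)
            spinal.append(p[SITE_SPINAL].magnitude)
            muscle.append(p[SITE_VL].magnitude)
        assert abs(np.mean(spinal) - 0.55) < 0.05
        assert abs(np.mean(muscle) - 0.70) < 0.05
        assert abs(np.median(spinal) - 0.55) < 0.05
        assert abs(np.median(muscle) - 0.70) < 0.05


class TestTraceGeneration:
    def test_noiseless_muscle_plateau_reproduces_programmed_vector(self):
        direction = np.array([0.0, -0.5, -0.49]) / np.linalg.norm([0.0, -0.5, -0.49])
        site = SiteParams(base_direction=tuple(direction),
                          base_magnitude_mean=float(np.linalg.norm([0, -0.5, -0.49])),
                          base_magnitude_sd=0.0, transient_overshoot=0.0)
        cfg = GeneratorConfig(
            n_subjects=1, n_blocks=1, noise_sd=0.0, within_subject_dir_sd=0.0,
            between_subject_dir_sd=0.0,
            site_params={SITE_SPINAL: site, SITE_VL: site, SITE_BF: site})
        params = sample_subject_params(cfg, 1)
        slot = next(s for s in make_design(cfg).slots
                    if s.block_type == "muscle_muscle" and s.condition == "site_A_only")
        trace = generate_trace(slot, params, cfg)
        np.testing.assert_allclose(_steady(trace), [0.0, -0.5, -0.49], atol=1e-3)

    def test_additivity_by_construction(self, noiseless_study):
        steady = steady_table(noiseless_study.traces)
        errors = compute_error_table(steady)
        assert errors["force_prediction_error"].max() < 1e-3

    def test_gain_interaction_closed_form(self, noiseless_config):
        cfg = noiseless_config.model_copy(
            update={"interaction_gain": 0.2, "interaction_mode": "gain"})
        study = generate_study(cfg)
        by_key = {}
        for t in study.traces:
            key = (t.meta["subject_id"], t.meta["block_type"], t.meta["block_id"])
            by_key.setdefault(key, {})[t.meta["condition"]] = _steady(t)
        for key, conds in by_key.items():
            expected = 1.2 * (conds["site_A_only"] + conds["site_B_only"])
            np.testing.assert_allclose(conds["co_stim"], expected, atol=1e-3)

    def test_study_determinism(self, tiny_config):
        a = generate_study(tiny_config)
        b = generate_study(tiny_config)
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.force, tb.force)

    def test_default_design_size(self):
        assert len(make_design(GeneratorConfig())) == 576  # 12*8*2*3

    def test_noise_floor_scaling(self):
        # median prediction error grows with the sample-noise SD
        medians = []
        for noise in (0.0, 0.01, 0.05, 0.1):
            cfg = GeneratorConfig(n_subjects=5, n_blocks=5, noise_sd=noise,
                                  within_subject_dir_sd=0.0, seed=17)
            errors = compute_error_table(steady_table(generate_study(cfg).traces))
            medians.append(errors["force_prediction_error"].median())
        assert all(b > a for a, b in zip(medians, medians[1:]))


class TestInteractionTerm:
    def test_gain_mode_is_total(self):
        np.testing.assert_allclose(
            interaction_term([1, 0, 0], [0, 2, 0], "gain"), [1, 2, 0])

    def test_occlusion_removes_projection_of_smaller_onto_larger(self):
        out = interaction_term([0.5, 0, 0], [2.0, 0, 0], "occlusion")
        np.testing.assert_allclose(out, [-0.5, 0, 0], atol=1e-12)
        # orthogonal vectors: no projection, no occlusion
        np.testing.assert_allclose(
            interaction_term([0.5, 0, 0], [0, 2.0, 0], "occlusion"), [0, 0, 0],
            atol=1e-12)

    def test_facilitation_along_combined_direction(self):
        out = interaction_term([1.0, 0, 0], [1.0, 0, 0], "facilitation")
        np.testing.assert_allclose(out, [1.0, 0, 0], atol=1e-12)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            interaction_term([1, 0, 0], [0, 1, 0], "resonance")


def test_injected_nonlinearity_is_detected():
    """A 30% gain interaction on spinal/muscle blocks only should make the
    mixed-model type effect significant in nearly every replicate study."""
    detected = 0
    n_reps = 20
    for rep in range(n_reps):
        cfg = GeneratorConfig(n_subjects=6, n_blocks=4, seed=100 + rep,
                              interaction_gain=0.3, interaction_mode="gain",
                              interaction_on="spinal_muscle")
        errors = compute_error_table(steady_table(generate_study(cfg).traces))
        from costim.inference import fit_error_model
        res = fit_error_model(errors, response="force")
        p = res.fixed_effects["costim_type[spinal_muscle]"]["p"]
        if p < 0.05:
            detected += 1
    assert detected >= 0.9 * n_reps
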