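"""Synthetic generators: cohorts, patients, polygraphy, ground truth."""

import numpy as np
import pytest

from cstperf.atlas import (
    COMPARTMENT_KEYS,
    CompartmentKey,
    Hemisphere,
    Structure,
    Subdivision,
)
from cstperf.cbf import build_cbf_table
from cstperf.circuits import detect_circuits
from cstperf.errors import ConfigurationError
from cstperf.normative import classify_compartments, cohort_frame
from cstperf.synth import (
    CENTRAL_PARIETAL_CHANNELS,
    CohortSpec,
    EffectSpec,
    circuit_effect,
    es_cluster,
    generate_control_cohort,
    generate_patient,
    generate_polygraphy,
    lpd_focal,
    null_background,
    sspe_early,
    sspe_late,
    subcortical_ratio,
)

NOISELESS = dict(between_subject_cv=0.0, compartment_cv=0.0, voxel_noise_sd=0.0)


class TestAgeCurves:
    def test_first_year_ratio_is_one_point_five(self, small_atlas):
        spec = CohortSpec(n_controls=1, age_range_months=(6, 6), **NOISELESS)
        cohort = generate_control_cohort(spec, small_atlas)
        table = build_cbf_table(cohort.volumes[0], small_atlas)
        sub = table.frame[table.frame.structure != "cortex"]
        assert np.allclose(sub.r_cbf, 1.5, rtol=1e-10)

    def test_ratio_decays_to_one_by_adolescence(self, small_atlas):
        spec = CohortSpec(n_controls=1, age_range_months=(180, 180), **NOISELESS)
        assert abs(subcortical_ratio(180.0, spec) - 1.0) < 0.05
        cohort = generate_control_cohort(spec, small_atlas)
        table = build_cbf_table(cohort.volumes[0], small_atlas)
        sub = table.frame[table.frame.structure != "cortex"]
        assert np.all(np.abs(sub.r_cbf - 1.0) < 0.05)

    def test_ratio_monotone_nonincreasing(self):
        spec = CohortSpec()
        ages = np.linspace(0, 200, 60)
        ratios = [subcortical_ratio(a, spec) for a in ages]
        assert all(a >= b - 1e-12 for a, b in zip(ratios, ratios[1:]))
        assert ratios[0] == pytest.approx(1.5)


class TestControlCohort:
    def test_seed_determinism(self, small_atlas):
        spec = CohortSpec(n_controls=4, seed=9)
        a = generate_control_cohort(spec, small_atlas)
        b = generate_control_cohort(spec, small_atlas)
        for va, vb in zip(a.volumes, b.volumes):
            assert np.array_equal(va.data, vb.data)
        assert a.metadata.equals(b.metadata)

    def test_between_subject_cv_recovered(self, small_atlas):
        spec = CohortSpec(n_controls=232, age_range_months=(12, 12), seed=3)
        cohort = generate_control_cohort(spec, small_atlas)
        truth = cohort.ground_truth
        cortex = truth[truth.structure == "cortex"]
        per_subject = cortex.groupby("subject_id").true_mean.mean()
        cv = per_subject.std() / per_subject.mean()
        # subject factor CV plus a small compartment-jitter contribution
        assert abs(cv - spec.between_subject_cv) / spec.between_subject_cv < 0.2

    def test_metadata_and_ground_truth_shapes(self, small_atlas):
        spec = CohortSpec(n_controls=5, seed=1)
        cohort = generate_control_cohort(spec, small_atlas)
        assert len(cohort.volumes) == 5
        assert len(cohort.metadata) == 5
        assert len(cohort.ground_truth) == 5 * 36
        assert set(cohort.metadata.scanner) <= set(spec.scanners)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(between_subject_cv=-0.1)


class TestPatientGenerator:
    def test_null_effect_equals_control_draw(self, small_atlas):
        spec = CohortSpec()
        base = EffectSpec(age_months=10, effects={}, seed=4)
        unit = EffectSpec(
            age_months=10,
            effects={COMPARTMENT_KEYS[0]: 1.0},
            seed=4,
        )
        vol_a, _ = generate_patient(base, spec, small_atlas)
        vol_b, _ = generate_patient(unit, spec, small_atlas)
        assert np.array_equal(vol_a.data, vol_b.data)

    def test_uniform_cortical_effect_ratio_algebra(self, small_atlas):
        """Scaling all cortical compartments by k leaves cortical R-CBF at 1
        and divides subcortical R-CBF by k (zero-noise oracle)."""
        spec = CohortSpec(**NOISELESS)
        effects = {
            key: 1.2 for key in COMPARTMENT_KEYS if key.structure == Structure.CORTEX
        }
        vol, _ = generate_patient(
            EffectSpec(age_months=6, effects=effects, seed=0), spec, small_atlas
        )
        table = build_cbf_table(vol, small_atlas)
        plain, _ = generate_patient(
            EffectSpec(age_months=6, effects={}, seed=0), spec, small_atlas
        )
        base = build_cbf_table(plain, small_atlas)
        cortex = table.frame.structure == "cortex"
        assert np.allclose(table.frame.r_cbf[cortex], base.frame.r_cbf[cortex], rtol=1e-10)
        assert np.allclose(
            table.frame.r_cbf[~cortex], base.frame.r_cbf[~cortex] / 1.2, rtol=1e-10
        )

    def test_nonpositive_effect_rejected(self):
        key = CompartmentKey(Structure.CORTEX, Subdivision.PREFRONTAL, Hemisphere.LEFT)
        with pytest.raises(ConfigurationError):
            EffectSpec(age_months=6, effects={key: -1.0})

    def test_end_to_end_circuit_recovery_fixed_seed(self, small_atlas):
        """Injected left prefrontal C-S-T increase is recovered downstream."""
        spec = CohortSpec(
            n_controls=20, age_range_months=(12, 12),
            between_subject_cv=0.02, compartment_cv=0.01, voxel_noise_sd=1.0, seed=8,
        )
        cohort = generate_control_cohort(spec, small_atlas)
        long = cohort_frame(cohort.tables(small_atlas))
        eff = EffectSpec(
            age_months=12,
            effects=circuit_effect(Subdivision.PREFRONTAL, Hemisphere.LEFT, 1.5),
            seed=21,
        )
        vol, truth = generate_patient(eff, spec, small_atlas)
        assert len(truth["effects"]) == 3
        status = classify_compartments(build_cbf_table(vol, small_atlas), long)
        patterns = detect_circuits(status)
        hit = patterns[
            (patterns.label == "C-S-T")
            & (patterns.direction == "increase")
            & (patterns.subdivision == "prefrontal")
            & (patterns.hemisphere == "left")
            & (patterns.measure == "a_cbf")
        ]
        assert len(hit) == 1


class TestPolygraphy:
    def test_seed_determinism(self):
        a, ta = generate_polygraphy(sspe_late(), 60.0, seed=2)
        b, tb = generate_polygraphy(sspe_late(), 60.0, seed=2)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(ta["complex_peaks_s"], tb["complex_peaks_s"])

    def test_null_background_has_no_events(self):
        rec, truth = generate_polygraphy(null_background(), 60.0, seed=0)
        assert truth["complex_peaks_s"].size == 0
        emg = rec.channel("EMG_deltoid_right")
        assert np.std(emg) == pytest.approx(10.0, rel=0.15)  # noise only

    def test_sspe_early_event_count_and_intervals(self):
        rec, truth = generate_polygraphy(sspe_early(), 600.0, seed=5)
        n = truth["complex_peaks_s"].size
        assert abs(n - 100) <= 20  # ~600 s / 6 s mean interval
        assert np.all(truth["intervals_s"] >= 5.0)
        assert np.all(truth["intervals_s"] <= 7.0)
        assert truth["emg_onsets_s"].size == n

    def test_sspe_late_intervals_shorter(self):
        _, early = generate_polygraphy(sspe_early(), 300.0, seed=6)
        _, late = generate_polygraphy(sspe_late(), 300.0, seed=6)
        assert np.all((late["intervals_s"] >= 2.0) & (late["intervals_s"] <= 3.0))
        assert np.median(late["intervals_s"]) < np.median(early["intervals_s"])

    def test_latency_snapped_to_sample_grid(self):
        rec, truth = generate_polygraphy(sspe_early(latency_ms=40.0), 120.0, seed=1)
        assert truth["latency_samples"] == round(0.040 * rec.sfreq)
        np.testing.assert_allclose(
            truth["emg_onsets_s"] - truth["complex_peaks_s"],
            truth["latency_samples"] / rec.sfreq,
        )

    def test_sspe_latency_outside_range_rejected(self):
        with pytest.raises(ConfigurationError):
            sspe_early(latency_ms=80.0)

    def test_duration_precondition(self):
        with pytest.raises(ValueError):
            generate_polygraphy(sspe_early(), 30.0, seed=0)

    def test_sspe_topography_zero_sum(self):
        preset = sspe_early()
        assert abs(sum(preset.topography.values())) < 1e-12
        assert max(abs(w) for w in preset.topography.values()) == 1.0
        # negative (surface-negative sharp wave) on all central-parietal leads
        assert all(preset.topography[ch] < 0 for ch in CENTRAL_PARIETAL_CHANNELS)

    def test_lpd_focal_is_lateralized(self):
        rec, truth = generate_polygraphy(lpd_focal(), 120.0, seed=7)
        preset = lpd_focal()
        peaks = (truth["complex_peaks_s"] * rec.sfreq).astype(int)
        left_at_peaks = rec.channel("C3")[peaks]
        right_at_peaks = rec.channel("C4")[peaks]
        # complexes are surface-negative on the configured left leads only
        assert left_at_peaks.mean() < -0.5 * preset.amplitude_uv
        assert abs(right_at_peaks.mean()) < 3 * preset.eeg_noise_sd_uv / np.sqrt(len(peaks))
        # contralateral homologue stays within background-noise bounds
        assert np.std(rec.channel("C4")) == pytest.approx(preset.eeg_noise_sd_uv, rel=0.25)

    def test_es_cluster_bilateral_bursts(self):
        rec, truth = generate_polygraphy(es_cluster(), 150.0, seed=4)
        assert truth["complex_peaks_s"].size >= 10
        for name in ("EMG_deltoid_left", "EMG_deltoid_right"):
            burst_region = rec.channel(name)
            assert np.max(np.abs(burst_region)) > 50.0
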