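import numpy as np
import pandas as pd
import pytest

from pvpassport import (
    Event,
    ScenarioConfig,
    generate_cohort,
    inject_event,
    study_cohort_config,
    training_cohort_config,
)


def noise_free_config(**over):
    base = dict(
        n_subjects=6,
        n_visits=8,
        seed=3,
        pv_cv=0.0,
        hbmass_cv=0.0,
        analytic_cv={k: 0.0 for k in ("hb", "hct", "mcv", "rbc", "ret_pct")},
        pv_measurement_cv=0.0,
    )
    base.update(over)
    return ScenarioConfig(**base)


class TestConservation:
    def test_hb_equals_mass_over_volume(self, clean_cohort):
        _, truth = clean_cohort
        recomputed = 100.0 * truth.hbmass / (truth.pv + truth.rcv)
        assert np.max(np.abs(truth.hb_prenoise - recomputed)) < 1e-9

    def test_marker_consistency_within_noise(self, clean_cohort):
        samples, _ = clean_cohort
        hct_from_rbc = samples["rbc"] * samples["mcv"] / 10.0
        rel = (hct_from_rbc - samples["hct"]).abs() / samples["hct"]
        assert rel.max() < 0.05
        mchc_recomputed = samples["hb"] / samples["hct"] * 100.0
        np.testing.assert_allclose(samples["mchc"], mchc_recomputed, rtol=1e-9)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = study_cohort_config(seed=21, n_subjects=5)
        a, _ = generate_cohort(cfg)
        b, _ = generate_cohort(study_cohort_config(seed=21, n_subjects=5))
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_different_seed_differs(self):
        a, _ = generate_cohort(study_cohort_config(seed=1, n_subjects=5))
        b, _ = generate_cohort(study_cohort_config(seed=2, n_subjects=5))
        assert not a["hb"].equals(b["hb"])


class TestVarianceSources:
    def test_no_variance_means_constant_hb(self):
        samples, _ = generate_cohort(noise_free_config())
        for _, grp in samples.groupby("subject_id"):
            assert grp["hb"].nunique() == 1

    def test_dilution_closed_form(self):
        """+10% PV with Hbmass fixed drops [Hb] by 1 − BV₀/(BV₀+0.1·PV₀)."""
        cfg = noise_free_config(
            events=[Event("hyperhydration", 5, 0.10)]
        )
        samples, truth = generate_cohort(cfg)
        pv0 = truth.pv[:, 0]
        bv0 = pv0 + truth.rcv[:, 0]
        expected_ratio = bv0 / (bv0 + 0.1 * pv0)
        hb = samples.pivot(index="subject_id", columns="visit_index", values="hb")
        hb = hb.loc[truth.subject_ids]
        ratio = (hb[5] / hb[4]).to_numpy()
        np.testing.assert_allclose(ratio, expected_ratio, atol=1e-9)


class TestInjectEvent:
    def test_hyperhydration_scales_pv(self):
        _, truth = generate_cohort(noise_free_config())
        after = inject_event(truth, 3, "hyperhydration", 0.10)
        np.testing.assert_allclose(after.pv[:, 2], 1.1 * truth.pv[:, 2])
        np.testing.assert_allclose(after.pv[:, 3], truth.pv[:, 3])

    def test_transfusion_raises_hb_not_pv(self):
        _, truth = generate_cohort(noise_free_config())
        after = inject_event(truth, 3, "transfusion", 0.10)
        np.testing.assert_array_equal(after.pv, truth.pv)
        assert (after.hb_prenoise[:, 2] > truth.hb_prenoise[:, 2]).all()
        np.testing.assert_allclose(after.hbmass[:, 2], 1.1 * truth.hbmass[:, 2])
        # erythropoietic feedback suppresses reticulocytes
        assert (after.ret_mult[:, 2] < 1.0).all()

    def test_zero_magnitude_is_identity(self):
        _, truth = generate_cohort(noise_free_config())
        for kind in ("hyperhydration", "transfusion", "rhepo"):
            after = inject_event(truth, 3, kind, 0.0)
            np.testing.assert_array_equal(after.pv, truth.pv)
            np.testing.assert_array_equal(after.hbmass, truth.hbmass)

    def test_unknown_kind_rejected(self):
        _, truth = generate_cohort(noise_free_config())
        with pytest.raises(ValueError, match="unknown event kind"):
            inject_event(truth, 3, "bloodletting", 0.1)

    def test_event_visit_out_of_range(self):
        with pytest.raises(ValueError, match="visit"):
            ScenarioConfig(
                n_visits=12, events=[Event("hyperhydration", 13, 0.1)]
            ).validate()

    def test_pv_excursion_bound_enforced(self):
        with pytest.raises(ValueError, match="acute PV bound"):
            ScenarioConfig(
                events=[Event("hyperhydration", 3, 0.30)]
            ).validate()


class TestCohortShape:
    def test_default_mirrors_monitoring_design(self):
        cfg = study_cohort_config()
        samples, _ = generate_cohort(cfg)
        assert samples["subject_id"].nunique() == 40
        assert samples.groupby("subject_id")["visit_index"].max().eq(12).all()
        assert samples["sex"].value_counts()["female"] == 13 * 12

    def test_per_sex_hb_means_on_target(self):
        """Cohort [Hb] means land on the configured per-sex physiology."""
        samples, _ = generate_cohort(
            study_cohort_config(seed=17, n_subjects=1000, female_fraction=0.5)
        )
        targets = {"male": 15.2, "female": 13.4}
        subj = samples.groupby(["sex", "subject_id"], observed=True)["hb"].mean()
        for sex, target in targets.items():
            means = subj.loc[sex]
            se = means.std(ddof=1) / np.sqrt(len(means))
            assert abs(means.mean() - target) < 2 * se + 0.05

    def test_training_mix_includes_interventions(self):
        cfg = training_cohort_config(seed=2)
        kinds = {e.kind for e in cfg.events}
        assert {"transfusion", "rhepo", "hyperhydration"} <= kinds
        # per-subject events target single subjects
        assert all(len(e.subjects) == 1 for e in cfg.events)
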