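"""Generator behavior: determinism, event structure, degenerate limits, effects."""

import numpy as np
import pytest

from kinclust.config import CohortConfig
from kinclust.dfc import wilcoxon_ranksum
from kinclust.features import mean_angle
from kinclust.inventory import DOFS
from kinclust.preprocessing import last_segment_slice
from kinclust.synthetic import (
    EffectParams,
    GroupEffectSpec,
    ParticipantSpec,
    cohort_participants,
    draw_participant,
    generate_cohort,
    generate_trial,
    identity_effects,
    single_cell_effects,
)


def _participant(condition="Norm", pid="Norm01", seed=0, cfg=None):
    return draw_participant(pid, condition, seed, cfg)


class TestGenerateTrial:
    def test_same_seed_is_bit_identical(self):
        p = _participant()
        a = generate_trial(p, "JHFT2", identity_effects(), master_seed=3)
        b = generate_trial(p, "JHFT2", identity_effects(), master_seed=3)
        np.testing.assert_array_equal(a.angles, b.angles)
        assert a.events == b.events

    def test_page_turning_has_five_event_pairs(self):
        p = _participant()
        trial = generate_trial(p, "JHFT2", identity_effects(), master_seed=1)
        assert len(trial.events) == 5

    def test_block_transport_has_sixteen_event_pairs(self):
        p = _participant()
        trial = generate_trial(p, "TBBT_SIT", identity_effects(), master_seed=1)
        assert len(trial.events) == 16

    def test_zero_noise_zero_amplitude_trial_is_constant(self):
        cfg = CohortConfig(noise_sd_deg=0.0, segment_amplitude_frac_sd=0.0)
        p = ParticipantSpec(
            "Norm01", "Norm", baseline_deg=np.full(14, 30.0), amplitude_deg=np.zeros(14)
        )
        trial = generate_trial(p, "JHFT1", identity_effects(), 0, config=cfg)
        np.testing.assert_allclose(trial.angles, 30.0)

    def test_invalid_effect_specs_are_rejected(self):
        p = _participant()
        with pytest.raises(ValueError, match="amplitude_scale"):
            generate_trial(
                p,
                "JHFT1",
                single_cell_effects("BP", "JHFT1", "torso_rot", amplitude_scale=-1.0),
                0,
            )
        with pytest.raises(ValueError, match="oscillation_freq"):
            generate_trial(
                p,
                "JHFT1",
                single_cell_effects(
                    "BP", "JHFT1", "torso_rot", oscillation_amp=2.0,
                    oscillation_freq=60.0,
                ),
                0,
            )

    def test_event_windows_never_need_clamping(self):
        # +/-10 frame margins stay inside the trial for every generated trial
        p = _participant()
        for task in ("JHFT1", "JHFT2", "TBBT_STAND"):
            trial = generate_trial(p, task, identity_effects(), 5)
            assert trial.events[0].contact_frame >= 10
            assert trial.events[-1].release_frame + 10 <= trial.n_frames - 1
            for prev, nxt in zip(trial.events, trial.events[1:]):
                assert nxt.contact_frame - prev.release_frame > 20


class TestNormReference:
    def test_norm_effect_spec_must_be_identity(self):
        with pytest.raises(ValueError, match="Norm"):
            GroupEffectSpec(
                "Norm", {("JHFT1", "torso_rot"): EffectParams(offset_shift=5.0)}
            )


class TestGenerateCohort:
    def test_default_cohort_has_432_recordings(self):
        cohort = generate_cohort(CohortConfig(), master_seed=0)
        assert len(cohort) == 24 * 9 * 2 == 432
        assert len(cohort.participants()) == 24
        assert cohort.manifest["n_recordings"] == 432

    def test_counts_below_one_are_rejected(self):
        with pytest.raises(ValueError, match="count"):
            generate_cohort(CohortConfig(n_bp=0), master_seed=0)

    def test_norm_only_cohort_ignores_effect_specs(self, tiny_cohort_config):
        import dataclasses

        cfg = dataclasses.replace(tiny_cohort_config, n_bp=1, n_dk=1)
        effects = {
            "BP": single_cell_effects("BP", "JHFT1", "torso_rot", offset_shift=9.0)
        }
        cohort = generate_cohort(cfg, 0, effects)
        norm = cohort.select(condition="Norm")
        assert {r.condition for r in norm} == {"Norm"}

    def test_noise_level_changes_output_under_same_seed(self, tiny_cohort_config):
        import dataclasses

        a = generate_cohort(tiny_cohort_config, 4)
        noisier = dataclasses.replace(tiny_cohort_config, noise_sd_deg=2.0)
        b = generate_cohort(noisier, 4)
        assert not np.array_equal(a.recordings[0].angles, b.recordings[0].angles)

    def test_participant_ordering_is_canonical(self, tiny_cohort_config):
        pairs = cohort_participants(tiny_cohort_config)
        assert pairs[0] == ("Norm01", "Norm")
        assert pairs[-1] == ("DK02", "DK")


class TestStatisticalStructure:
    def test_offset_effect_shifts_mean_angle_feature(self, tiny_cohort_config):
        """A Delta-degree offset moves the last-segment mean angle by Delta.

        Checked two ways: paired under identical seeds (exact), and unpaired
        over 50 trials against 3 standard errors.
        """
        delta = 6.0
        task, dof = "JHFT1", "torso_rot"
        d = DOFS.index(dof)
        eff = single_cell_effects("BP", task, dof, offset_shift=delta)
        diffs = []
        for seed in range(50):
            p = draw_participant(f"BP{seed:02d}", "BP", seed, tiny_cohort_config)
            base = generate_trial(
                p, task, identity_effects("BP"), seed, config=tiny_cohort_config
            )
            shifted = generate_trial(p, task, eff, seed, config=tiny_cohort_config)
            w = last_segment_slice(base)
            diffs.append(
                mean_angle(shifted.angles[w, d]) - mean_angle(base.angles[w, d])
            )
        np.testing.assert_allclose(diffs, delta, atol=1e-9)  # paired: exact

        unpaired = []
        for seed in range(50):
            p = draw_participant(f"BP{seed:02d}", "BP", seed, tiny_cohort_config)
            t = generate_trial(p, task, eff, seed + 1000, config=tiny_cohort_config)
            unpaired.append(mean_angle(t.angles[last_segment_slice(t), d]))
        p0 = [
            mean_angle(t.angles[last_segment_slice(t), DOFS.index(dof)])
            for seed in range(50)
            for t in [
                generate_trial(
                    draw_participant(f"N{seed:02d}", "Norm", seed, tiny_cohort_config),
                    task,
                    identity_effects(),
                    seed + 1000,
                    config=tiny_cohort_config,
                )
            ]
        ]
        diff = np.mean(unpaired) - np.mean(p0)
        se = np.sqrt(np.var(unpaired, ddof=1) / 50 + np.var(p0, ddof=1) / 50)
        assert abs(diff - delta) <= 3 * se

    def test_conditions_exchangeable_without_effects(self):
        """With zero effects a rank test between groups rejects at ~alpha.

        200 seeded mini-cohorts; a two-sided rank-sum test on the mean-angle
        feature (6 BP vs 6 Norm participants) should reject in about 5% of
        runs. The binomial 3.5-sigma band for 200 draws at p=0.05 is [0, 21].
        """
        cfg = CohortConfig(
            n_norm=6,
            n_bp=6,
            n_dk=1,
            n_trials=1,
            tasks=("JHFT1",),
            segment_counts={"JHFT1": 1},
            segment_frames=60,
            gap_frames=30,
            lead_frames=20,
        )
        d = DOFS.index("r_shoulder_flex_ext")
        rejections = 0
        for seed in range(200):
            values = {"Norm": [], "BP": []}
            for pid, condition in cohort_participants(cfg):
                if condition == "DK":
                    continue
                p = draw_participant(pid, condition, seed, cfg)
                t = generate_trial(p, "JHFT1", identity_effects(condition), seed, 1, cfg)
                values[condition].append(
                    mean_angle(t.angles[last_segment_slice(t), d])
                )
            p_val = wilcoxon_ranksum(values["BP"], values["Norm"], side="two-sided")
            rejections += p_val < 0.05
        assert rejections <= 21
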