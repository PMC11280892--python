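"""Generator contracts: shapes, determinism, planted effects, spectral oracle."""

import numpy as np
import pytest
from scipy import stats

from pdeeg.montages import Montage, common_channels
from pdeeg.synthetic import (EffectProfile, Recording, band_power, band_power_1d,
                             generate_cohort, generate_recording)


class TestBandPowerOracle:
    def test_sine_concentrates_power(self, tiny_montage):
        t = np.arange(30000) / 500.0
        data = np.zeros((4, t.size))
        data[0] = np.sin(2 * np.pi * 10 * t)
        rec = Recording("s", "control", "open", 500.0, tiny_montage, data)
        in_band = band_power(rec, "Oz", 8, 13)
        out_band = band_power(rec, "Oz", 1, 4)
        assert in_band / max(out_band, 1e-30) > 100

    def test_zero_signal_zero_power(self, tiny_montage):
        rec = Recording("s", "control", "open", 500.0, tiny_montage, np.zeros((4, 4000)))
        assert band_power(rec, "Oz", 1, 30) == 0.0

    def test_white_noise_power_proportional_to_bandwidth(self, rng):
        x = rng.standard_normal(30000)
        narrow = band_power_1d(x, 500, 40, 50)
        wide = band_power_1d(x, 500, 60, 80)
        assert wide / narrow == pytest.approx(2.0, rel=0.2)

    def test_empty_band_rejected(self, rng):
        with pytest.raises(ValueError):
            band_power_1d(rng.standard_normal(4000), 500, 20, 20)


class TestGenerateRecording:
    def test_event_shape_64ch_60s(self, unm):
        rec = generate_recording("s", "control", "open", unm, duration_s=60.0, seed=1)
        assert rec.data.shape == (64, 30000)

    def test_deterministic_given_seed(self, tiny_montage):
        a = generate_recording("s", "pd", "open", tiny_montage, duration_s=8.0, seed=5)
        b = generate_recording("s", "pd", "open", tiny_montage, duration_s=8.0, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_unknown_target_channel_named_in_error(self, tiny_montage):
        effect = EffectProfile(target_channels=("Pz",), band="beta", power_ratio=2.0)
        with pytest.raises(ValueError, match="Pz"):
            generate_recording("s", "pd", "open", tiny_montage, effect, seed=0)

    def test_too_short_duration_rejected(self, tiny_montage):
        with pytest.raises(ValueError, match="segment"):
            generate_recording("s", "pd", "open", tiny_montage, duration_s=1.0, seed=0)

    def test_planted_beta_effect_detected_in_19_of_20_seeds(self, tiny_montage):
        """Group-mean beta power on the target channel exceeds control in ≥19/20 seeds."""
        effect = EffectProfile(target_channels=("Oz",), band="beta", power_ratio=4.0)
        wins = 0
        for seed in range(20):
            pd_p, ct_p = [], []
            for i in range(20):
                r = generate_recording(f"p{i}", "pd", "open", tiny_montage, effect,
                                       duration_s=4.0, seed=seed * 1000 + i)
                pd_p.append(band_power(r, "Oz", 13, 30))
                r = generate_recording(f"c{i}", "control", "open", tiny_montage, effect,
                                       duration_s=4.0, seed=seed * 1000 + 500 + i)
                ct_p.append(band_power(r, "Oz", 13, 30))
            wins += np.mean(pd_p) > np.mean(ct_p)
        assert wins >= 19

    def test_null_groups_indistinguishable(self, tiny_montage):
        """power_ratio 1 plants nothing: log band powers pass a two-sample t-test."""
        effect = EffectProfile(target_channels=("Oz",), band="beta", power_ratio=1.0)
        pd_p = [band_power(generate_recording(f"p{i}", "pd", "open", tiny_montage,
                                              effect, duration_s=4.0, seed=i), "Oz", 13, 30)
                for i in range(20)]
        ct_p = [band_power(generate_recording(f"c{i}", "control", "open", tiny_montage,
                                              effect, duration_s=4.0, seed=100 + i), "Oz", 13, 30)
                for i in range(20)]
        _, p = stats.ttest_ind(np.log(pd_p), np.log(ct_p))
        assert p > 0.01

    def test_effect_monotone_in_power_ratio(self, tiny_montage):
        """Observed PD/control band-power ratio grows with the planted ratio (1, 2, 4)."""
        observed = []
        for ratio in (1.0, 2.0, 4.0):
            effect = EffectProfile(target_channels=("Oz",), band="beta", power_ratio=ratio)
            pd_p = [band_power(generate_recording(f"p{i}", "pd", "open", tiny_montage,
                                                  effect, duration_s=4.0, seed=i),
                               "Oz", 13, 30) for i in range(20)]
            ct_p = [band_power(generate_recording(f"c{i}", "control", "open", tiny_montage,
                                                  effect, duration_s=4.0, seed=200 + i),
                               "Oz", 13, 30) for i in range(20)]
            observed.append(np.mean(pd_p) / np.mean(ct_p))
        assert observed[0] < observed[1] < observed[2]

    def test_eyes_closed_boosts_alpha(self, tiny_montage):
        open_p = [band_power(generate_recording(f"s{i}", "control", "open", tiny_montage,
                                                duration_s=4.0, seed=i), "Oz", 8, 13)
                  for i in range(10)]
        closed_p = [band_power(generate_recording(f"s{i}", "control", "closed", tiny_montage,
                                                  duration_s=4.0, seed=i), "Oz", 8, 13)
                    for i in range(10)]
        assert np.mean(closed_p) > np.mean(open_p)


class TestGenerateCohort:
    def test_cohort_sizes(self, unm, iowa):
        effect = EffectProfile()
        coh = generate_cohort(27, 26, unm, effect, eye_states=("open", "closed"),
                              duration_s=4.0, seed=0)
        assert len(coh) == 106  # 53 subjects × 2 eye states
        assert len({r.subject_id for r in coh}) == 53
        coh2 = generate_cohort(14, 14, iowa, effect, eye_states=("open",),
                               duration_s=4.0, seed=0)
        assert len(coh2) == 28

    def test_cohort_deterministic(self, tiny_montage):
        a = generate_cohort(1, 1, tiny_montage, eye_states=("open",), duration_s=4.0, seed=9)
        b = generate_cohort(1, 1, tiny_montage, eye_states=("open",), duration_s=4.0, seed=9)
        for ra, rb in zip(a, b):
            assert ra.subject_id == rb.subject_id
            assert np.array_equal(ra.data, rb.data)

    def test_needs_subjects_in_both_groups(self, tiny_montage):
        with pytest.raises(ValueError):
            generate_cohort(0, 5, tiny_montage, seed=0)


class TestMontages:
    def test_shipped_montages_share_59_channels(self, unm, iowa):
        assert unm.n_channels == iowa.n_channels == 64
        assert len(common_channels(unm, iowa)) == 59

    def test_reference_never_recorded(self):
        with pytest.raises(ValueError, match="reference"):
            Montage("bad", ("Cz", "Pz"), "Pz")
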