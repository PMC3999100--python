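"""Synthetic EEG generation, time-frequency power and ERSP feature extraction."""

import numpy as np
import pytest

from conftest import make_stop_go_records
from ctxstop.ersp import (
    BASELINE_S,
    DEFAULT_BANDS,
    DEFAULT_EOIS,
    EEGConfigError,
    EEGEpochs,
    Effect,
    EffectSpec,
    TFPower,
    baseline_normalize,
    baseline_power,
    compute_ersp,
    condition_ersp,
    default_freq_grid,
    extract_features,
    synthesize_epochs,
)


def tiny_tf(power, freqs, times, ch_names=("Cz",)):
    return TFPower(power=np.asarray(power, dtype=float), freqs=np.asarray(freqs, dtype=float),
                   times=np.asarray(times, dtype=float), ch_names=tuple(ch_names))


class TestBaselineNormalize:
    """The dB identities: 10*log10 of the power/baseline ratio."""

    def _tf(self, post_ratio):
        # 1 trial, 1 channel, 1 freq, 2 frames: baseline frame then post frame
        power = np.array([[[[1.0, post_ratio]]]])
        return tiny_tf(power, freqs=[10.0], times=[-0.4, 0.3])

    def test_ratio_one_is_zero_db(self):
        db = baseline_normalize(self._tf(1.0))
        assert db[0, 0, 0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_ratio_ten_is_ten_db(self):
        db = baseline_normalize(self._tf(10.0))
        assert db[0, 0, 0, 1] == pytest.approx(10.0, abs=1e-12)

    def test_ratio_half_is_minus_three_db(self):
        db = baseline_normalize(self._tf(0.5))
        assert db[0, 0, 0, 1] == pytest.approx(-3.0102999566398, abs=1e-10)

    def test_baseline_outside_epoch_rejected(self):
        tf = tiny_tf(np.ones((1, 1, 1, 2)), [10.0], [0.1, 0.3])
        with pytest.raises(EEGConfigError):
            baseline_power(tf, (-0.8, -0.1))

    def test_zero_baseline_power_rejected(self):
        tf = tiny_tf(np.zeros((1, 1, 1, 2)), [10.0], [-0.4, 0.3])
        with pytest.raises(EEGConfigError):
            baseline_power(tf)


class TestExtractFeatures:
    def test_constant_field_gives_constant_features(self):
        freqs = default_freq_grid()
        times = np.linspace(-0.5, 0.9, 71)
        ch = tuple(dict.fromkeys(c for e in DEFAULT_EOIS.values() for c in e))
        db = np.full((len(ch), freqs.size, times.size), 2.0)
        feats = extract_features(db, freqs, times, ch)
        assert np.allclose(feats["db"], 2.0)
        assert len(feats) == len(DEFAULT_BANDS) * len(DEFAULT_EOIS)

    def test_matches_bruteforce_mean_on_tiny_grid(self, rng):
        """Feature equals the exhaustive mean over enumerated (f, t, ch) bins."""
        from ctxstop.ersp import BandWindow

        freqs = np.array([1.0, 2.0, 3.0, 4.0])
        times = np.array([0.1, 0.2, 0.3])
        ch = ("Cz", "Pz")
        db = rng.standard_normal((2, 4, 3))
        bands = {"b": BandWindow("b", 1.5, 4.0, 150.0, 300.0)}
        eois = {"pair": ("Cz", "Pz")}
        feat = extract_features(db, freqs, times, ch, bands, eois)["db"].iloc[0]
        brute = np.mean([
            db[c, f, t]
            for c in (0, 1)
            for f in (1, 2, 3)      # 2.0, 3.0, 4.0 in (1.5, 4.0]
            for t in (1, 2)         # 200, 300 ms in [150, 300]
        ])
        assert feat == pytest.approx(brute, abs=1e-12)

    def test_single_electrode_eoi(self, rng):
        freqs = default_freq_grid()
        times = np.array([0.2, 0.35])  # one frame in the theta window, one in delta's
        db = rng.standard_normal((1, freqs.size, 2))
        feats = extract_features(db, freqs, times, ("FCz",), eois={"one": ("FCz",)})
        theta = feats[feats["band"] == "theta"]["db"].iloc[0]
        fmask = (freqs > 4.0) & (freqs <= 8.0)
        assert theta == pytest.approx(db[0, fmask, 0].mean(), abs=1e-12)

    def test_missing_electrode_named_in_error(self):
        db = np.zeros((1, 100, 5))
        with pytest.raises(EEGConfigError, match="Oz"):
            extract_features(db, default_freq_grid(), np.linspace(0.1, 0.5, 5), ("Cz",),
                             eois={"bad": ("Oz",)})

    def test_per_trial_variant_row_count(self, rng):
        freqs = default_freq_grid()
        times = np.linspace(0.1, 0.5, 10)
        db = rng.standard_normal((7, 1, freqs.size, times.size))
        feats = extract_features(db, freqs, times, ("Cz",), eois={"one": ("Cz",)})
        assert len(feats) == 7 * len(DEFAULT_BANDS)


class TestComputeErsp:
    def test_sinusoid_peaks_at_its_frequency(self):
        srate, n = 250.0, 504
        t = np.arange(n) / srate
        data = np.sin(2 * np.pi * 10.0 * t)[None, None, :] * np.ones((3, 1, 1))
        tfp = compute_ersp(EEGEpochs(data=data, ch_names=("Cz",)))
        mean_over_time = tfp.power[0, 0].mean(axis=1)
        assert abs(tfp.freqs[np.argmax(mean_over_time)] - 10.0) < 0.36

    def test_white_noise_spectrum_roughly_flat(self, rng):
        data = rng.standard_normal((60, 1, 504))
        tfp = compute_ersp(EEGEpochs(data=data, ch_names=("Cz",)))
        mean_p = tfp.power.mean(axis=(0, 1, 3))
        # expected power equal across bins; allow broad sampling slack
        assert mean_p.max() / mean_p.min() < 1.5

    def test_chirp_ridge_follows_instantaneous_frequency(self):
        """Ridge of the TF map tracks the analytic instantaneous frequency."""
        from scipy.signal import chirp

        srate, n = 250.0, 504
        t = np.arange(n) / srate
        f0, f1 = 6.0, 28.0
        data = chirp(t, f0=f0, t1=t[-1], f1=f1, method="linear")[None, None, :]
        epochs = EEGEpochs(data=data, ch_names=("Cz",))
        tfp = compute_ersp(epochs)
        inst_f = f0 + (f1 - f0) * (tfp.times - epochs.tmin) / t[-1]
        ridge = tfp.freqs[np.argmax(tfp.power[0, 0], axis=0)]
        assert np.max(np.abs(ridge - inst_f)) < 2.0

    def test_epoch_shorter_than_window_rejected(self, rng):
        data = rng.standard_normal((1, 1, 100))
        with pytest.raises(EEGConfigError):
            compute_ersp(EEGEpochs(data=data, ch_names=("Cz",)))

    def test_frequency_grid_is_100_steps_to_35(self):
        grid = default_freq_grid()
        assert grid.size == 100
        assert grid[-1] == 35.0
        assert np.allclose(np.diff(grid), grid[1] - grid[0])


class TestSynthesizeEpochs:
    def test_same_seed_identical_epochs(self):
        records = make_stop_go_records(5, 5)
        spec = EffectSpec(effects=[Effect.make({"stop_relevant": True}, "theta", "frontocentral", 3.0)])
        a = synthesize_epochs(records, spec, np.random.default_rng(5))
        b = synthesize_epochs(records, spec, np.random.default_rng(5))
        assert np.array_equal(a.data, b.data)

    def test_unknown_electrode_in_effect_rejected(self):
        spec = EffectSpec(
            effects=[Effect.make({"stop_relevant": True}, "theta", "occipital", 3.0)],
            eois={**DEFAULT_EOIS, "occipital": ("O1", "O2")},
        )
        with pytest.raises(EEGConfigError, match="O1"):
            synthesize_epochs(make_stop_go_records(2, 2), spec, np.random.default_rng(0))

    def test_unknown_band_rejected(self):
        spec = EffectSpec(effects=[Effect.make({}, "gamma", "frontocentral", 3.0)])
        with pytest.raises(EEGConfigError, match="gamma"):
            synthesize_epochs(make_stop_go_records(2, 2), spec, np.random.default_rng(0))

    def test_null_generator_features_near_zero(self):
        """No injected effects: condition-averaged features sit near 0 dB."""
        records = make_stop_go_records(0, 100)
        epochs = synthesize_epochs(records, EffectSpec(), np.random.default_rng(8))
        tfp = compute_ersp(epochs)
        db = condition_ersp(tfp)
        feats = extract_features(db, tfp.freqs, tfp.times, tfp.ch_names)
        assert feats["db"].abs().max() < 0.6

    def test_injected_theta_effect_recovered(self):
        """A +3 dB frontocentral theta increment on stop trials shows up in
        the stop-minus-go feature difference, and not in the beta bands."""
        records = make_stop_go_records(120, 120)
        spec = EffectSpec(effects=[Effect.make({"stop_relevant": True}, "theta", "frontocentral", 3.0)])
        epochs = synthesize_epochs(records, spec, np.random.default_rng(9))
        tfp = compute_ersp(epochs)
        base = baseline_power(tfp)
        stop_mask = epochs.metadata["stop_relevant"].to_numpy()
        f_stop = extract_features(condition_ersp(tfp, stop_mask, base=base),
                                  tfp.freqs, tfp.times, tfp.ch_names).set_index(["band", "eoi"])["db"]
        f_go = extract_features(condition_ersp(tfp, ~stop_mask, base=base),
                                tfp.freqs, tfp.times, tfp.ch_names).set_index(["band", "eoi"])["db"]
        diff = f_stop - f_go
        assert diff[("theta", "frontocentral")] == pytest.approx(3.0, abs=0.7)
        assert abs(diff[("low_beta", "frontocentral")]) < 0.4
        assert abs(diff[("high_beta", "frontocentral")]) < 0.4

    def test_ground_truth_metadata_recorded(self):
        records = make_stop_go_records(4, 4)
        spec = EffectSpec(
            effects=[Effect.make({"stop_relevant": True}, "delta", "centroparietal", 2.0)],
            trial_db_sd=1.0,
        )
        epochs = synthesize_epochs(records, spec, np.random.default_rng(10))
        assert len(epochs.truth) == 4  # one row per matching trial
        assert epochs.truth["db_injected"].std() > 0

    def test_save_load_round_trip(self, tmp_path):
        records = make_stop_go_records(2, 2)
        epochs = synthesize_epochs(records, EffectSpec(), np.random.default_rng(11))
        epochs.save(str(tmp_path / "ep"))
        loaded = EEGEpochs.load(str(tmp_path / "ep"))
        assert np.array_equal(loaded.data, epochs.data)
        assert loaded.ch_names == epochs.ch_names


class TestOrderingRecovery:
    def test_configured_condition_ordering_reproduced(self):
        """Stop > go in delta/theta and Stim1-context2 < Stim1-context1:
        the generator's configured ordering survives extraction."""
        records = []
        i = 0
        from ctxstop.race import BehavioralRecord, Outcome
        from ctxstop.task_design import Stimulus

        for ctx in (1, 2):
            for _ in range(90):
                records.append(BehavioralRecord(i, ctx, Stimulus.STIM1, True, 200.0,
                                                False, None, Outcome.STOP_SUCCESS))
                i += 1
        for _ in range(90):
            records.append(BehavioralRecord(i, 1, Stimulus.GO, False, None, True, 500.0,
                                            Outcome.GO_CORRECT))
            i += 1
        spec = EffectSpec(effects=[
            Effect.make({"stop_relevant": True}, "delta", "frontocentral", 2.5),
            Effect.make({"stop_relevant": True}, "theta", "frontocentral", 3.0),
            Effect.make({"stimulus": "stim1", "context": 2}, "delta", "frontocentral", -1.0),
            Effect.make({"stimulus": "stim1", "context": 2}, "theta", "frontocentral", -1.2),
        ])
        epochs = synthesize_epochs(records, spec, np.random.default_rng(13))
        tfp = compute_ersp(epochs)
        base = baseline_power(tfp)
        meta = epochs.metadata

        def feat(mask, band):
            db = condition_ersp(tfp, mask, base=base)
            f = extract_features(db, tfp.freqs, tfp.times, tfp.ch_names)
            return f[(f["band"] == band) & (f["eoi"] == "frontocentral")]["db"].iloc[0]

        s1c1 = (meta["stimulus"] == "stim1") & (meta["context"] == 1)
        s1c2 = (meta["stimulus"] == "stim1") & (meta["context"] == 2)
        go = (meta["stimulus"] == "go").to_numpy()
        for band in ("delta", "theta"):
            assert feat(s1c1.to_numpy(), band) > feat(go, band)
            assert feat(s1c2.to_numpy(), band) < feat(s1c1.to_numpy(), band)
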