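"""Feature formulas against an independent brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardioedge.delineation import BeatSeries
from cardioedge.features import (
    FEATURE_NAMES,
    InsufficientBeatsError,
    featurize,
    features_from_beats,
    hrv_features,
    median_beat_index,
    morphology_features,
)
from cardioedge.preprocessing import preprocess_record
from cardioedge.synthetic_ecg import RhythmSpec, generate_rhythm

# --------------------------------------------------------------------------
# independent oracle: literal, loop-based evaluation of each formula


def oracle_hrv(rr):
    n = len(rr)
    hr = [60000.0 / r for r in rr]
    d = [rr[i] - rr[i + 1] for i in range(n - 1)]
    mean_sq = sum(x * x for x in d) / len(d)
    mean_d = sum(d) / len(d)
    var_d = sum((x - mean_d) ** 2 for x in d) / len(d)
    mean_rr = sum(rr) / n
    var_rr = sum((x - mean_rr) ** 2 for x in rr) / n
    return {
        "min_hr": min(hr),
        "max_hr": max(hr),
        "mean_hr": sum(hr) / n,
        "rmssd": math.sqrt(mean_sq),
        "sdsd": math.sqrt(var_d),
        "sdrr": math.sqrt(var_rr),
        "prr50": sum(1 for x in d if abs(x) > 50.0) / (n - 1),
        "prr20": sum(1 for x in d if abs(x) > 20.0) / (n - 1),
    }


def oracle_morphology(waves, fs):
    r_amps = [b["R"][1] for b in waves]
    med = sorted(r_amps)[(len(r_amps) - 1) // 2]
    beat = waves[r_amps.index(med)]
    out = {}
    for w in ("P", "Q", "R", "S", "T"):
        out[f"{w.lower()}_amp"] = beat[w][1] if beat.get(w) is not None else 0.0
    for wx, wy in (("P", "Q"), ("Q", "R"), ("R", "S"), ("S", "T")):
        ex, ey = beat.get(wx), beat.get(wy)
        # the literal peak-difference-over-frequency formula
        out[f"{wx.lower()}{wy.lower()}_delay"] = (
            (ex[1] - ey[1]) / fs * 1000.0 if ex is not None and ey is not None else 0.0
        )
    return out


def random_beat_series(rng):
    n_beats = int(rng.integers(4, 40))
    r_idx = np.cumsum(rng.integers(30, 150, size=n_beats)) + 10
    waves = []
    for ri in r_idx:
        beat = {"R": (int(ri), float(rng.uniform(0.3, 1.0)))}
        offsets = {"P": -23, "Q": -5, "S": 5, "T": 30}
        for w, off in offsets.items():
            if rng.random() < 0.8:
                beat[w] = (int(ri + off), float(rng.normal(0, 0.2)))
            else:
                beat[w] = None
        waves.append(beat)
    return BeatSeries(r_peaks=np.asarray(r_idx), waves=waves, fs=128.0)


# --------------------------------------------------------------------------


class TestHrvFeatures:
    def test_constant_series(self):
        f = hrv_features([1000.0, 1000.0, 1000.0])
        assert f["min_hr"] == f["max_hr"] == f["mean_hr"] == 60.0
        assert f["rmssd"] == f["sdsd"] == f["sdrr"] == 0.0
        assert f["prr50"] == f["prr20"] == 0.0

    def test_worked_example(self):
        f = hrv_features([800.0, 850.0, 790.0])
        assert f["mean_hr"] == pytest.approx(73.85, abs=0.01)
        assert f["min_hr"] == pytest.approx(70.59, abs=0.01)
        assert f["max_hr"] == pytest.approx(75.95, abs=0.01)
        assert f["rmssd"] == pytest.approx(55.23, abs=0.01)
        assert f["prr50"] == 0.5
        assert f["prr20"] == 1.0
        assert f["sdsd"] == pytest.approx(55.0, abs=0.01)
        assert f["sdrr"] == pytest.approx(26.25, abs=0.01)

    def test_strict_inequality_at_threshold(self):
        # a successive difference of exactly 50 ms is excluded from PRR50
        f = hrv_features([800.0, 850.0, 800.0])
        assert f["prr50"] == 0.0
        assert f["prr20"] == 1.0

    def test_insufficient_intervals_rejected(self):
        with pytest.raises(InsufficientBeatsError):
            hrv_features([800.0, 850.0])

    @given(st.lists(st.floats(250.0, 2000.0), min_size=3, max_size=60))
    def test_prr20_at_least_prr50(self, rr):
        f = hrv_features(rr)
        assert f["prr20"] >= f["prr50"]


class TestMorphologyFeatures:
    def _series(self, r_amps):
        waves = [{"R": (100 * (i + 1), a), "P": None, "Q": None, "S": None, "T": None}
                 for i, a in enumerate(r_amps)]
        return BeatSeries(r_peaks=np.asarray([100 * (i + 1) for i in range(len(r_amps))]),
                          waves=waves, fs=128.0)

    def test_median_beat_selection(self):
        assert median_beat_index(self._series([0.5, 0.8, 1.0])) == 1

    def test_even_count_takes_lower_median(self):
        assert median_beat_index(self._series([0.5, 0.8, 1.0, 0.9])) == 1

    def test_ties_take_earliest_beat(self):
        assert median_beat_index(self._series([0.8, 0.8, 0.8])) == 0

    def test_missing_waves_encode_zero(self):
        f = morphology_features(self._series([0.5, 0.8, 1.0]))
        assert f["p_amp"] == 0.0 and f["pq_delay"] == 0.0 and f["st_delay"] == 0.0
        assert f["r_amp"] == 0.8

    def test_identical_beats_return_template_values(self):
        waves = []
        for i in range(4):
            r = 400 * (i + 1)
            waves.append({
                "P": (r - 23, 0.12), "Q": (r - 4, -0.12), "R": (r, 1.0),
                "S": (r + 4, -0.25), "T": (r + 32, 0.3),
            })
        beats = BeatSeries(np.asarray([400 * (i + 1) for i in range(4)]), waves, 128.0)
        f = morphology_features(beats)
        assert f["p_amp"] == 0.12 and f["r_amp"] == 1.0 and f["t_amp"] == 0.3
        assert f["qr_delay"] == pytest.approx((-0.12 - 1.0) / 128 * 1000)


class TestOracleEquivalence:
    def test_thousand_random_fixtures(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            beats = random_beat_series(rng)
            got = dict(zip(FEATURE_NAMES, features_from_beats(beats)))
            want = {**oracle_hrv(list(beats.rr_intervals_ms)),
                    **oracle_morphology(beats.waves, beats.fs)}
            for name in FEATURE_NAMES:
                assert got[name] == pytest.approx(want[name], rel=1e-9, abs=1e-12), name


class TestFeaturize:
    def test_mean_hr_recovered(self):
        rec = generate_rhythm(RhythmSpec(rhythm="NSR", mean_hr=80), 30.0, seed=2)
        data = preprocess_record(rec)[0].data
        f = dict(zip(FEATURE_NAMES, featurize(data)))
        assert f["mean_hr"] == pytest.approx(80.0, abs=5.0)

    def test_afib_signature(self):
        rec = generate_rhythm(
            RhythmSpec(rhythm="AFIB", mean_hr=110, rr_cv=0.25), 30.0, seed=2
        )
        data = preprocess_record(rec)[0].data
        f = dict(zip(FEATURE_NAMES, featurize(data)))
        assert f["p_amp"] <= 0.05
        assert f["prr20"] >= 0.5

    def test_vector_is_finite_and_canonical_length(self):
        rec = generate_rhythm(RhythmSpec(rhythm="NSR", mean_hr=70), 30.0, seed=3)
        v = featurize(preprocess_record(rec)[0].data)
        assert v.shape == (17,)
        assert np.all(np.isfinite(v))

    def test_two_beat_window_rejected(self):
        t = np.arange(3840) / 128.0
        x = np.exp(-0.5 * ((t - 10.0) / 0.01) ** 2) + np.exp(-0.5 * ((t - 20.0) / 0.01) ** 2)
        from cardioedge.delineation import UnfeaturizableError

        with pytest.raises(UnfeaturizableError):
            featurize(x / np.abs(x).max())

    def test_whole_sample_shift_preserves_hrv(self):
        rec = generate_rhythm(RhythmSpec(rhythm="NSR", mean_hr=70), 30.0, seed=4)
        data = preprocess_record(rec)[0].data
        shifted = np.roll(data, 64)  # 0.5 s; first beat wraps, so compare HRV core
        f0 = dict(zip(FEATURE_NAMES, featurize(data)))
        f1 = dict(zip(FEATURE_NAMES, featurize(shifted)))
        assert f1["mean_hr"] == pytest.approx(f0["mean_hr"], abs=2.0)
        assert f1["sdrr"] == pytest.approx(f0["sdrr"], abs=10.0)
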