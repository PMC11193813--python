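"""The 17 HRV and morphology features of one 30-s window.

Heart-rate-variability features are computed from the RR-interval series
(per-interval HR = 60,000 / RR_i ms): min/max/mean HR, rMSSD, SDSD, SDRR
(population SDs), and PRR50/PRR20 — the proportion of successive RR
differences strictly exceeding 50 / 20 ms, with n - 1 successive pairs for
n intervals in the denominator.

Morphology features come from the median beat — the beat whose R amplitude
is the (lower) median of all detected R amplitudes: the P/Q/R/S/T
amplitudes of that beat and, for each consecutive wave pair, the
amplitude-difference "delay" (amp_X - amp_Y) / fs x 1000 — the literal
peak-difference-over-signal-frequency formula, which makes the delay
features scaled contrasts of the wave amplitudes rather than independent
timing measurements. A missing wave contributes amplitude 0 and zeroes its
adjacent delays.
"""

from __future__ import annotations

import numpy as np

from cardioedge.delineation import BeatSeries, DelineationConfig, UnfeaturizableError, delineate
from cardioedge.preprocessing import TARGET_FS

FEATURE_NAMES = (
    "min_hr", "max_hr", "mean_hr",
    "rmssd", "sdsd", "sdrr",
    "prr50", "prr20",
    "p_amp", "q_amp", "r_amp", "s_amp", "t_amp",
    "pq_delay", "qr_delay", "rs_delay", "st_delay",
)

N_FEATURES = len(FEATURE_NAMES)

_WAVE_ORDER = ("P", "Q", "R", "S", "T")
_DELAY_PAIRS = (("P", "Q"), ("Q", "R"), ("R", "S"), ("S", "T"))


class InsufficientBeatsError(UnfeaturizableError):
    """Fewer beats/intervals than the feature formulas require."""


def hrv_features(rr_ms: np.ndarray) -> dict[str, float]:
    """Time-domain HRV statistics from an RR series in milliseconds."""
    rr = np.asarray(rr_ms, dtype=np.float64)
    n = len(rr)
    if n < 3:
        raise InsufficientBeatsError(f"need >= 3 RR intervals, got {n}")
    hr = 60000.0 / rr
    d = np.diff(rr)
    return {
        "min_hr": float(hr.min()),
        "max_hr": float(hr.max()),
        "mean_hr": float(hr.mean()),
        "rmssd": float(np.sqrt(np.mean(d**2))),
        "sdsd": float(np.std(d)),
        "sdrr": float(np.std(rr)),
        "prr50": float(np.count_nonzero(np.abs(d) > 50.0) / (n - 1)),
        "prr20": float(np.count_nonzero(np.abs(d) > 20.0) / (n - 1)),
    }


def median_beat_index(beats: BeatSeries) -> int:
    """Index of the beat whose R amplitude is the lower median.

    Even counts take the lower of the two central values; amplitude ties
    resolve to the earliest beat.
    """
    r_amps = np.array([b["R"][1] for b in beats.waves])
    if len(r_amps) == 0:
        raise InsufficientBeatsError("no beats with an R wave")
    order = np.argsort(r_amps, kind="stable")
    target = r_amps[order[(len(r_amps) - 1) // 2]]
    return int(np.flatnonzero(r_amps == target)[0])


def morphology_features(beats: BeatSeries) -> dict[str, float]:
    """Wave amplitudes and inter-wave delays of the median beat."""
    if len(beats.waves) < 3:
        raise InsufficientBeatsError("need >= 3 beats")
    beat = beats.waves[median_beat_index(beats)]
    out: dict[str, float] = {}
    for w in _WAVE_ORDER:
        entry = beat.get(w)
        out[f"{w.lower()}_amp"] = float(entry[1]) if entry is not None else 0.0
    for wx, wy in _DELAY_PAIRS:
        ex, ey = beat.get(wx), beat.get(wy)
        if ex is None or ey is None:
            delay = 0.0
        else:
            delay = (ex[1] - ey[1]) / beats.fs * 1000.0
        out[f"{wx.lower()}{wy.lower()}_delay"] = float(delay)
    return out


def features_from_beats(beats: BeatSeries) -> np.ndarray:
    """Assemble the canonical 17-vector from a delineated beat series."""
    vals = {**hrv_features(beats.rr_intervals_ms), **morphology_features(beats)}
    return np.array([vals[name] for name in FEATURE_NAMES])


def featurize(
    data: np.ndarray,
    fs: float = TARGET_FS,
    config: DelineationConfig | None = None,
) -> np.ndarray:
    """Delineate a (denoised, normalized) window and return its 17 features.

    Raises :class:`InsufficientBeatsError` /
    :class:`~cardioedge.delineation.UnfeaturizableError` on windows with too
    few beats; callers log and skip such windows.
    """
    beats = delineate(np.asarray(data, dtype=np.float64), fs, config)
    return features_from_beats(beats)
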