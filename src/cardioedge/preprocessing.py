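"""Harmonize raw records into normalized single-label 30-second samples.

Records are cut per lead into non-overlapping 30-s windows, band-limited
resampled to the 128-Hz standard rate, despiked against a 1-s rolling
average, mean-centered, scaled into [-1, 1] by the maximum absolute value
and zero-padded to the standard 3,840-sample length. Each window receives a
single rhythm label from the interval annotations; windows with conflicting
tachycardia labels or any non-studied rhythm are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from cardioedge.io_formats import AFIB, AFL, NSR, OTHER, EcgRecord, RhythmAnnotation

TARGET_FS = 128.0
WINDOW_S = 30.0
WINDOW_SAMPLES = int(WINDOW_S * TARGET_FS)  # 3,840
MIN_PARTIAL_S = 10.0  # shorter trailing fragments carry too few beats
ROLLING_WINDOW_S = 1.0
# despike gate in rolling SDs: ECG is intrinsically spiky (an R peak sits
# 5-6 rolling SDs above a quiet baseline), so the gate must be well above
# that while still catching rail/dropout artifacts an order of magnitude
# taller
OUTLIER_SD = 8.0

DISCARD = "DISCARD"
PENDING = "PENDING"


class UnsupportedRateError(ValueError):
    """Source sampling rate below the 128-Hz standard rate."""


@dataclass
class EcgSample:
    """One normalized 30-s single-lead window at 128 Hz.

    ``padded_from`` is the pre-padding length in samples (== 3,840 for a
    full window). ``degenerate`` flags all-constant inputs normalized to
    all-zeros.
    """

    data: np.ndarray
    fs: float = TARGET_FS
    label: str = PENDING
    database_id: str = ""
    patient_id: str = ""
    record_id: str = ""
    lead: str = ""
    window_index: int = 0
    padded_from: int = WINDOW_SAMPLES
    degenerate: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != (WINDOW_SAMPLES,):
            raise ValueError(
                f"sample length must be {WINDOW_SAMPLES}, got {self.data.shape}"
            )
        if self.window_index < 0:
            raise ValueError("window_index must be >= 0")


@dataclass
class RawWindow:
    """Unnormalized per-lead window still at the source rate."""

    data: np.ndarray
    src_fs: float
    lead: str
    window_index: int
    start_sample: int  # in source-rate samples
    end_sample: int


def segment_record(record: EcgRecord) -> list[RawWindow]:
    """Cut a record into per-lead non-overlapping 30-s windows.

    Trailing fragments of at least :data:`MIN_PARTIAL_S` seconds are kept
    (zero-padded later); shorter ones are dropped. A record shorter than
    the minimum yields an empty list.
    """
    win = int(round(WINDOW_S * record.fs))
    min_len = int(round(MIN_PARTIAL_S * record.fs))
    out: list[RawWindow] = []
    for li, lead in enumerate(record.lead_names):
        x = record.signals[li]
        idx = 0
        for start in range(0, len(x), win):
            chunk = x[start : start + win]
            if len(chunk) < min_len:
                break
            out.append(
                RawWindow(
                    data=chunk.copy(),
                    src_fs=record.fs,
                    lead=str(lead),
                    window_index=idx,
                    start_sample=start,
                    end_sample=start + len(chunk),
                )
            )
            idx += 1
    return out


def resample_window(data: np.ndarray, src_fs: float) -> np.ndarray:
    """Band-limited (polyphase anti-aliased) resampling to 128 Hz."""
    if src_fs < TARGET_FS:
        raise UnsupportedRateError(f"source rate {src_fs} Hz below {TARGET_FS} Hz")
    if src_fs == TARGET_FS:
        return np.asarray(data, dtype=np.float64)
    frac = Fraction(TARGET_FS / src_fs).limit_denominator(1000)
    return sps.resample_poly(np.asarray(data, dtype=np.float64), frac.numerator, frac.denominator)


def clean_normalize(
    data: np.ndarray,
    fs: float = TARGET_FS,
    n_target: int = WINDOW_SAMPLES,
    outlier_sd: float = OUTLIER_SD,
    rolling_window_s: float = ROLLING_WINDOW_S,
) -> tuple[np.ndarray, int, bool]:
    """Despike, center, scale into [-1, 1] and zero-pad to the standard length.

    Non-finite values and points deviating from a centered 1-s rolling mean
    by more than ``outlier_sd`` rolling standard deviations are replaced by
    linear interpolation. The window is then mean-centered, divided by its
    maximum absolute value, and finally zero-padded.

    Returns ``(sample, padded_from, degenerate)``.
    """
    x = np.asarray(data, dtype=np.float64).copy()
    n = len(x)
    if n > n_target:
        raise ValueError(f"window longer than {n_target} samples")

    bad = ~np.isfinite(x)
    x[bad] = 0.0
    w = max(3, int(round(rolling_window_s * fs)))
    rmean = ndimage.uniform_filter1d(x, size=w, mode="nearest")
    rsq = ndimage.uniform_filter1d(x**2, size=w, mode="nearest")
    rstd = np.sqrt(np.maximum(rsq - rmean**2, 0.0))
    bad |= np.abs(x - rmean) > outlier_sd * rstd
    if bad.any() and not bad.all():
        good = ~bad
        x[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good), x[good])

    x -= x.mean()
    peak = np.abs(x).max()
    degenerate = peak < 1e-12
    if degenerate:
        x[:] = 0.0
    else:
        x /= peak
    if n < n_target:
        x = np.concatenate([x, np.zeros(n_target - n)])
    return x, n, degenerate


def assign_label(
    window_interval: tuple[int, int],
    annotations: list[RhythmAnnotation],
    record_length: int | None = None,
) -> str:
    """Resolve the single rhythm label for a window from interval annotations.

    A label is in force over the half-open interval from its onset to the
    next onset (or the record end). Conflict rules: a tachycardia label
    (AFIB/AFL) overrides NSR; two distinct tachycardias, any non-studied
    (OTHER) rhythm, or no annotation coverage discard the window.
    """
    start, end = window_interval
    if not annotations:
        return DISCARD
    anns = sorted(annotations)
    in_force: set[str] = set()
    if start < anns[0].onset_sample:
        return DISCARD  # window begins before annotated coverage
    for i, ann in enumerate(anns):
        on = ann.onset_sample
        off = anns[i + 1].onset_sample if i + 1 < len(anns) else (
            record_length if record_length is not None else end
        )
        if on < end and off > start:
            in_force.add(ann.label)
    if not in_force or OTHER in in_force:
        return DISCARD
    tachy = in_force & {AFIB, AFL}
    if len(tachy) > 1:
        return DISCARD
    if len(tachy) == 1:
        return tachy.pop()
    return NSR if NSR in in_force else DISCARD


def preprocess_record(record: EcgRecord) -> list[EcgSample]:
    """Full per-record preprocessing: segment, resample, label, normalize.

    Windows labeled DISCARD (label conflicts, OTHER rhythms, uncovered
    spans) are dropped; window indices of kept samples are re-numbered to
    stay gap-free per lead.
    """
    samples: list[EcgSample] = []
    kept_idx: dict[str, int] = {}
    for rw in segment_record(record):
        label = assign_label(
            (rw.start_sample, rw.end_sample), record.annotations, record.n_samples
        )
        if label == DISCARD:
            continue
        data = resample_window(rw.data, rw.src_fs)
        data, padded_from, degenerate = clean_normalize(data)
        idx = kept_idx.get(rw.lead, 0)
        kept_idx[rw.lead] = idx + 1
        samples.append(
            EcgSample(
                data=data,
                label=label,
                database_id=record.database_id,
                patient_id=record.patient_id,
                record_id=record.record_id,
                lead=rw.lead,
                window_index=idx,
                padded_from=padded_from,
                degenerate=degenerate,
            )
        )
    return samples
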