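"""R-peak detection and P/Q/S/T wave delineation.

R peaks come from peak-picking the squared Gaussian-smoothed signal
(polarity-robust), thresholded against its own 95th percentile, with a
refractory minimum separation and refinement to the raw-signal extremum.
P and T waves are located on a low-frequency discrete-wavelet
reconstruction (approximation + coarsest detail of a 4-level sym4
decomposition); Q and S are raw-signal minima flanking R. A wave whose
prominence over the local baseline falls below a small gate is declared
missing.

All kernel widths, thresholds, windows and the wavelet family are
conventional delineation practice and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from cardioedge.preprocessing import TARGET_FS


class UnfeaturizableError(ValueError):
    """Too few beats to delineate or featurize a window."""


@dataclass
class DelineationConfig:
    smooth_sigma_ms: float = 12.0
    threshold_frac: float = 0.4  # of the reference percentile of smoothed-squared
    threshold_percentile: float = 99.0
    min_separation_ms: float = 250.0
    refine_ms: float = 40.0
    refractory_ms: float = 200.0
    wavelet: str = "sym4"
    dwt_level: int = 4
    #: coarsest detail levels joined to the approximation for the P/T search
    #: band; 2 -> A4+D4+D3 = 0-16 Hz at 128 Hz, wide enough to keep the
    #: P wave's energy while still rejecting QRS frequencies
    keep_details: int = 2
    prominence_gate: float = 0.02
    qrs_mask_ms: float = 60.0  # half-width of QRS blanking for the P/T search
    # per-wave search windows in ms relative to R
    q_window: tuple[float, float] = (-80.0, 0.0)
    s_window: tuple[float, float] = (0.0, 80.0)
    p_window: tuple[float, float] = (-240.0, -80.0)
    t_window: tuple[float, float] = (80.0, 400.0)


@dataclass
class BeatSeries:
    """Detected beats of one window: R-peak indices, per-beat wave locations
    and amplitudes (None when missing), and derived RR intervals."""

    r_peaks: np.ndarray
    waves: list[dict]  # per beat: {"P": (idx, amp) | None, ..., "T": ...}
    fs: float = TARGET_FS

    @property
    def rr_intervals_ms(self) -> np.ndarray:
        return np.diff(self.r_peaks) / self.fs * 1000.0

    @property
    def n(self) -> int:
        """Number of RR intervals."""
        return len(self.r_peaks) - 1


def detect_r_peaks(
    data: np.ndarray, fs: float = TARGET_FS, config: DelineationConfig | None = None
) -> np.ndarray:
    """Detect R peaks on the squared Gaussian-smoothed signal.

    Raises :class:`UnfeaturizableError` when fewer than 3 peaks are found.
    """
    cfg = config or DelineationConfig()
    x = np.asarray(data, dtype=np.float64)
    sigma = cfg.smooth_sigma_ms / 1000.0 * fs
    half = int(np.ceil(4 * sigma))
    k = np.exp(-0.5 * ((np.arange(-half, half + 1)) / sigma) ** 2)
    k /= k.sum()
    smoothed = np.convolve(x, k, mode="same")
    sq = smoothed**2
    if not sq.any():
        raise UnfeaturizableError("all-zero window")
    height = cfg.threshold_frac * np.percentile(sq, cfg.threshold_percentile)
    distance = max(1, int(round(cfg.min_separation_ms / 1000.0 * fs)))
    peaks, _ = sps.find_peaks(sq, height=height, distance=distance)

    # refine to the raw-signal extremum (largest |x|) within +-refine_ms
    r = int(round(cfg.refine_ms / 1000.0 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - r), min(len(x), p + r + 1)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    refined = np.unique(refined)

    # enforce the refractory period post-refinement: drop the smaller peak
    refractory = cfg.refractory_ms / 1000.0 * fs
    keep = list(refined)
    changed = True
    while changed and len(keep) > 1:
        changed = False
        for i in range(len(keep) - 1):
            if keep[i + 1] - keep[i] < refractory:
                drop = i if abs(x[keep[i]]) < abs(x[keep[i + 1]]) else i + 1
                del keep[drop]
                changed = True
                break
    peaks = np.asarray(keep, dtype=int)
    if len(peaks) < 3:
        raise UnfeaturizableError(f"only {len(peaks)} R peaks found")
    return peaks


def _lowfreq_reconstruction(
    x: np.ndarray, cfg: DelineationConfig, r_peaks: np.ndarray | None = None,
    fs: float = TARGET_FS,
) -> np.ndarray:
    """Approximation + coarsest-detail reconstruction of a 4-level DWT.

    When R peaks are given, the QRS segments (R +- qrs_mask_ms) are first
    replaced by linear interpolation so their low-frequency leakage does not
    swamp the P/T search windows.
    """
    x = np.asarray(x, dtype=np.float64)
    if r_peaks is not None and len(r_peaks):
        mask = np.zeros(len(x), dtype=bool)
        half = int(round(cfg.qrs_mask_ms / 1000.0 * fs))
        for rp in r_peaks:
            mask[max(0, rp - half) : rp + half + 1] = True
        if not mask.all():
            x = x.copy()
            good = ~mask
            x[mask] = np.interp(
                np.flatnonzero(mask), np.flatnonzero(good), x[good]
            )
    coeffs = pywt.wavedec(x, cfg.wavelet, level=cfg.dwt_level)
    n_keep = 1 + cfg.keep_details
    kept = [c if i < n_keep else np.zeros_like(c) for i, c in enumerate(coeffs)]
    return pywt.waverec(kept, cfg.wavelet)[: len(x)]


def delineate_pqrst(
    data: np.ndarray,
    r_peaks: np.ndarray,
    fs: float = TARGET_FS,
    config: DelineationConfig | None = None,
) -> BeatSeries:
    """Locate P/Q/S/T around each R peak.

    Q and S are raw-signal minima in their flanking windows; P and T are
    maxima of the low-frequency wavelet reconstruction. A wave is missing
    when its prominence over the window median is below the gate, or when
    its search window falls outside the sample.
    """
    cfg = config or DelineationConfig()
    x = np.asarray(data, dtype=np.float64)
    if len(r_peaks) < 3:
        raise UnfeaturizableError("need >= 3 R peaks to delineate")
    lf = _lowfreq_reconstruction(x, cfg, r_peaks=np.asarray(r_peaks, dtype=int), fs=fs)

    def ms2i(ms: float) -> int:
        return int(round(ms / 1000.0 * fs))

    waves: list[dict] = []
    for bi, rp in enumerate(r_peaks):
        beat: dict = {"R": (int(rp), float(x[rp]))}
        prev_r = r_peaks[bi - 1] if bi > 0 else None
        next_r = r_peaks[bi + 1] if bi + 1 < len(r_peaks) else None

        def search(window, source, mode, clip_lo=None, clip_hi=None):
            lo, hi = rp + ms2i(window[0]), rp + ms2i(window[1])
            if clip_lo is not None:
                lo = max(lo, clip_lo)
            if clip_hi is not None:
                hi = min(hi, clip_hi)
            if lo < 0 or hi > len(x) or hi - lo < 2:
                return None
            seg = source[lo:hi]
            base = float(np.median(seg))
            if mode == "max":
                idx = int(np.argmax(seg))
                prom = float(seg[idx]) - base
            else:
                idx = int(np.argmin(seg))
                prom = base - float(seg[idx])
            if prom < cfg.prominence_gate:
                return None
            # a maximum on the window boundary is a neighboring wave's
            # flank, not a wave apex
            if source is not x and idx in (0, hi - lo - 1):
                return None
            # amplitude is always read off the raw signal
            return (lo + idx, float(x[lo + idx]))

        beat["Q"] = search(cfg.q_window, x, "min")
        beat["S"] = search(cfg.s_window, x, "min")
        # clip P/T windows clear of the neighboring beats; the P search must
        # also stay clear of the previous beat's T wave and its tail — at
        # short RR the P window shrinks to nothing, as P does
        # physiologically. When the previous T was found, its measured
        # position bounds the clip; otherwise assume a late T.
        if prev_r is None:
            p_clip = None
        else:
            prev_t = waves[-1].get("T") if waves else None
            if prev_t is not None:
                p_clip = prev_t[0] + ms2i(150)
            else:
                p_clip = int(prev_r) + ms2i(420)
        t_clip = int(next_r) - ms2i(50) if next_r is not None else None
        beat["P"] = search(cfg.p_window, lf, "max", clip_lo=p_clip)
        beat["T"] = search(cfg.t_window, lf, "max", clip_hi=t_clip)

        # enforce wave ordering P < Q < R < S < T; drop violators
        if beat["Q"] is not None and beat["Q"][0] >= rp:
            beat["Q"] = None
        if beat["S"] is not None and beat["S"][0] <= rp:
            beat["S"] = None
        if beat["P"] is not None:
            q_idx = beat["Q"][0] if beat["Q"] is not None else rp
            if beat["P"][0] >= q_idx:
                beat["P"] = None
        if beat["T"] is not None:
            s_idx = beat["S"][0] if beat["S"] is not None else rp
            if beat["T"][0] <= s_idx:
                beat["T"] = None
        waves.append(beat)

    return BeatSeries(r_peaks=np.asarray(r_peaks, dtype=int), waves=waves, fs=fs)


def delineate(data: np.ndarray, fs: float = TARGET_FS,
              config: DelineationConfig | None = None) -> BeatSeries:
    """Convenience: R-peak detection followed by PQRST delineation."""
    cfg = config or DelineationConfig()
    peaks = detect_r_peaks(data, fs, cfg)
    return delineate_pqrst(data, peaks, fs, cfg)
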