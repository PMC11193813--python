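"""Reading standard ECG records and persisting windowed samples.

Implements a minimal WFDB-compatible codec (``.hea`` headers, format 16/212
signal files, MIT-format ``.atr`` rhythm annotations) and an HDF5-backed
hierarchical store for preprocessed 30-second samples keyed by
(database, patient, record, lead, window).

Rhythm labels live in a closed vocabulary {NSR, AFIB, AFL, OTHER}; source
aux strings (e.g. ``"(AFIB"``) are mapped through an explicit, extensible
table with OTHER as the conservative fallback.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# label vocabulary

NSR = "NSR"
AFIB = "AFIB"
AFL = "AFL"
OTHER = "OTHER"

RHYTHM_LABELS = (NSR, AFIB, AFL)

#: default mapping from WFDB aux rhythm strings to the closed vocabulary.
#: Anything not listed maps to OTHER (discarded downstream).
DEFAULT_AUX_MAP: Mapping[str, str] = {
    "(N": NSR,
    "(NSR": NSR,
    "(AFIB": AFIB,
    "(AFL": AFL,
}


class FormatError(ValueError):
    """Header or signal file could not be parsed."""


class UnitError(ValueError):
    """Signal units missing; required for amplitude normalization."""


class IntegrityError(ValueError):
    """Duplicate key or inconsistent metadata in a sample store."""


def map_aux_label(aux: str, table: Mapping[str, str] | None = None) -> str:
    """Map a source aux rhythm string into the closed vocabulary.

    The mapping is total: strings absent from the table return OTHER.
    """
    table = DEFAULT_AUX_MAP if table is None else table
    return table.get(aux.rstrip("\x00").strip(), OTHER)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True, order=True)
class RhythmAnnotation:
    """A rhythm label in force from ``onset_sample`` until the next onset."""

    onset_sample: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in (*RHYTHM_LABELS, OTHER):
            raise ValueError(f"label {self.label!r} outside closed vocabulary")
        if self.onset_sample < 0:
            raise ValueError("onset_sample must be >= 0")


@dataclass
class EcgRecord:
    """A raw multi-lead ECG record with rhythm-interval annotations.

    ``signals`` has shape (n_leads, n_samples) in the units given by
    ``units`` (one string per lead). Annotations are kept sorted by onset;
    each is in force over the half-open interval up to the next onset.
    """

    signals: np.ndarray
    fs: float
    lead_names: Sequence[str]
    units: Sequence[str]
    patient_id: str = ""
    record_id: str = ""
    database_id: str = ""
    annotations: list[RhythmAnnotation] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.lead_names) != self.signals.shape[0]:
            raise ValueError("one lead name per signal row required")
        if len(self.units) != self.signals.shape[0]:
            raise UnitError("one unit string per lead required")
        n = self.signals.shape[1]
        self.annotations = sorted(self.annotations)
        for ann in self.annotations:
            if ann.onset_sample > n:
                raise ValueError(
                    f"annotation onset {ann.onset_sample} beyond record length {n}"
                )

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# WFDB header + signal reading/writing (formats 16 and 212)


def _parse_gain_units(tok: str) -> tuple[float, int, str | None]:
    """Parse a WFDB gain token ``gain(baseline)/units`` -> (gain, baseline, units)."""
    units = None
    if "/" in tok:
        tok, units = tok.split("/", 1)
    baseline = 0
    if "(" in tok:
        tok, rest = tok.split("(", 1)
        baseline = int(rest.rstrip(")"))
    gain = float(tok) if tok else 200.0
    if gain == 0:
        gain = 200.0
    return gain, baseline, units


def read_record(path: str | Path, aux_map: Mapping[str, str] | None = None) -> EcgRecord:
    """Read a WFDB record (``.hea`` + signal file(s)), leads kept separate.

    Amplitudes are converted to physical units via per-lead gain/baseline.
    Rhythm annotations are loaded from ``<record>.atr`` when present.
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"missing header file {hea}")
    raw_lines = [ln.strip() for ln in hea.read_text().splitlines() if ln.strip()]
    lines = [ln for ln in raw_lines if not ln.startswith("#")]
    comments: dict[str, str] = {}
    for ln in raw_lines:
        if ln.startswith("#") and ":" in ln:
            key, _, val = ln.lstrip("# ").partition(":")
            comments[key.strip()] = val.strip()
    try:
        head = lines[0].split()
        record_name = head[0].split("/")[0]
        nsig = int(head[1])
        fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
        nsamp = int(head[3]) if len(head) > 3 else 0
    except (IndexError, ValueError) as exc:
        raise FormatError(f"garbled header line in {hea}: {lines[0]!r}") from exc

    sig_lines = lines[1 : 1 + nsig]
    if len(sig_lines) < nsig:
        raise FormatError(f"header declares {nsig} signals, found {len(sig_lines)}")

    files: list[str] = []
    fmts: list[int] = []
    gains: list[float] = []
    baselines: list[int] = []
    units: list[str] = []
    names: list[str] = []
    for i, ln in enumerate(sig_lines):
        toks = ln.split()
        if len(toks) < 2:
            raise FormatError(f"garbled signal line: {ln!r}")
        files.append(toks[0])
        fmts.append(int(toks[1].split("x")[0].split(":")[0].split("+")[0]))
        gain, baseline, unit = (200.0, 0, None)
        if len(toks) > 2:
            gain, baseline, unit = _parse_gain_units(toks[2])
        if unit is None:
            raise UnitError(
                f"units missing for signal {i} of {record_name}; "
                "required for normalization"
            )
        gains.append(gain)
        baselines.append(baseline)
        units.append(unit)
        names.append(toks[-1] if len(toks) > 3 else f"lead{i}")

    # all leads in one signal file (the common single-.dat layout)
    if len(set(files)) != 1:
        raise FormatError("multi-file signal layouts not supported")
    dat = path.parent / files[0]
    if not dat.exists():
        raise FormatError(f"missing signal file {dat}")
    raw = dat.read_bytes()
    fmt = fmts[0]
    if fmt == 16:
        adc = np.frombuffer(raw, dtype="<i2").astype(np.int64)
        adc = adc[: (len(adc) // nsig) * nsig].reshape(-1, nsig).T
    elif fmt == 212:
        adc = _decode_fmt212(raw)
        adc = adc[: (len(adc) // nsig) * nsig].reshape(-1, nsig).T
    else:
        raise FormatError(f"unsupported signal format {fmt}")
    if nsamp:
        adc = adc[:, :nsamp]

    signals = np.empty(adc.shape, dtype=np.float64)
    for i in range(nsig):
        signals[i] = (adc[i] - baselines[i]) / gains[i]

    annotations: list[RhythmAnnotation] = []
    atr = path.with_suffix(".atr")
    if atr.exists():
        annotations = read_rhythm_annotations(atr, n_samples=signals.shape[1], aux_map=aux_map)

    return EcgRecord(
        signals=signals,
        fs=fs,
        lead_names=names,
        units=units,
        record_id=record_name,
        patient_id=comments.get("patient_id", ""),
        database_id=comments.get("database_id", ""),
        annotations=annotations,
    )


def _decode_fmt212(raw: bytes) -> np.ndarray:
    b = np.frombuffer(raw[: (len(raw) // 3) * 3], dtype=np.uint8).reshape(-1, 3)
    s0 = (b[:, 0].astype(np.int64) | ((b[:, 1] & 0x0F).astype(np.int64) << 8))
    s1 = (b[:, 2].astype(np.int64) | ((b[:, 1] & 0xF0).astype(np.int64) << 4))
    s0[s0 > 2047] -= 4096
    s1[s1 > 2047] -= 4096
    out = np.empty(2 * len(b), dtype=np.int64)
    out[0::2] = s0
    out[1::2] = s1
    return out


def write_record(record: EcgRecord, path: str | Path, gain: float = 200.0) -> None:
    """Write a record as WFDB header + format-16 signal (+ ``.atr`` if annotated)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    name = path.stem
    nsig, nsamp = record.signals.shape
    adc = np.round(record.signals * gain).astype("<i2")
    (path.parent / f"{name}.dat").write_bytes(adc.T.tobytes())
    lines = [f"{name} {nsig} {record.fs:g} {nsamp}"]
    for i in range(nsig):
        lines.append(
            f"{name}.dat 16 {gain:g}(0)/{record.units[i]} 16 0 0 0 0 {record.lead_names[i]}"
        )
    # provenance carried as header comments
    if record.patient_id:
        lines.append(f"# patient_id: {record.patient_id}")
    if record.database_id:
        lines.append(f"# database_id: {record.database_id}")
    (path.parent / f"{name}.hea").write_text("\n".join(lines) + "\n")
    if record.annotations:
        write_rhythm_annotations(record.annotations, path.with_suffix(".atr"))


# ---------------------------------------------------------------------------
# MIT annotation codec (rhythm aux strings only)

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63
_RHYTHM = 28  # '+' rhythm-change annotation type

_INV_AUX_MAP = {NSR: "(N", AFIB: "(AFIB", AFL: "(AFL", OTHER: "(OTHER"}


def read_rhythm_annotations(
    path: str | Path,
    n_samples: int | None = None,
    aux_map: Mapping[str, str] | None = None,
) -> list[RhythmAnnotation]:
    """Read MIT-format annotations, keeping rhythm aux strings ``"(...)``.

    Returns annotations sorted by onset with labels mapped into the closed
    vocabulary. Raises if an onset lies beyond ``n_samples`` when given.
    """
    raw = Path(path).read_bytes()
    words = np.frombuffer(raw[: (len(raw) // 2) * 2], dtype="<u2")
    out: list[RhythmAnnotation] = []
    t = 0
    i = 0
    pending_time: int | None = None
    while i < len(words):
        w = int(words[i])
        code, data = w >> 10, w & 0x3FF
        if code == 0 and data == 0:
            break
        if code == _SKIP:
            interval = (int(words[i + 1]) << 16) | int(words[i + 2])
            if interval >= 1 << 31:
                interval -= 1 << 32
            t += interval
            i += 3
            continue
        if code in (_NUM, _SUB, _CHN):
            i += 1
            continue
        if code == _AUX:
            nbytes = data
            start = 2 * (i + 1)
            aux = raw[start : start + nbytes].decode("ascii", "replace")
            if aux.startswith("(") and pending_time is not None:
                out.append(
                    RhythmAnnotation(pending_time, map_aux_label(aux, aux_map))
                )
            i += 1 + (nbytes + 1) // 2
            continue
        # ordinary annotation: data is the interval from the previous one
        t += data
        pending_time = t
        i += 1
    out.sort()
    if n_samples is not None:
        for ann in out:
            if ann.onset_sample > n_samples:
                raise ValueError(
                    f"annotation onset {ann.onset_sample} beyond record length"
                )
    return out


def write_rhythm_annotations(
    annotations: Iterable[RhythmAnnotation], path: str | Path
) -> None:
    """Write rhythm annotations as MIT-format '+' annotations with aux strings."""
    buf = bytearray()
    t_prev = 0
    for ann in sorted(annotations):
        delta = ann.onset_sample - t_prev
        t_prev = ann.onset_sample
        if delta >= 1024 or delta < 0:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (_RHYTHM << 10) | delta)
        aux = _INV_AUX_MAP.get(ann.label, "(OTHER").encode("ascii")
        buf += struct.pack("<H", (_AUX << 10) | len(aux))
        buf += aux
        if len(aux) % 2:
            buf += b"\x00"
    buf += b"\x00\x00"
    Path(path).write_bytes(bytes(buf))


# ---------------------------------------------------------------------------
# sample store


class SampleStore:
    """In-memory hierarchical store of preprocessed samples, HDF5-persistable.

    Keys are (database_id, patient_id, record_id, lead, window_index);
    duplicates raise :class:`IntegrityError`. Queries by label (or any
    metadata field) return exactly the matching samples in insertion order.
    """

    def __init__(self) -> None:
        self._samples: dict[tuple, "EcgSample"] = {}

    def __len__(self) -> int:
        return len(self._samples)

    @staticmethod
    def _key(sample) -> tuple:
        return (
            sample.database_id,
            sample.patient_id,
            sample.record_id,
            sample.lead,
            sample.window_index,
        )

    def add(self, sample) -> None:
        key = self._key(sample)
        if key in self._samples:
            raise IntegrityError(f"duplicate sample key {key}")
        self._samples[key] = sample

    def samples(self, **filters):
        """Return samples whose metadata fields equal every given filter value."""
        out = []
        for s in self._samples.values():
            if all(getattr(s, k) == v for k, v in filters.items()):
                out.append(s)
        return out

    def save(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for i, s in enumerate(self._samples.values()):
                g = f.create_group(f"sample_{i:06d}")
                g.create_dataset("data", data=s.data)
                g.attrs["fs"] = s.fs
                g.attrs["label"] = s.label
                g.attrs["database_id"] = s.database_id
                g.attrs["patient_id"] = s.patient_id
                g.attrs["record_id"] = s.record_id
                g.attrs["lead"] = s.lead
                g.attrs["window_index"] = s.window_index
                g.attrs["padded_from"] = s.padded_from

    @classmethod
    def load(cls, path: str | Path) -> "SampleStore":
        import h5py

        from cardioedge.preprocessing import EcgSample

        store = cls()
        with h5py.File(path, "r") as f:
            for name in sorted(f):
                g = f[name]
                store.add(
                    EcgSample(
                        data=g["data"][()],
                        fs=float(g.attrs["fs"]),
                        label=str(g.attrs["label"]),
                        database_id=str(g.attrs["database_id"]),
                        patient_id=str(g.attrs["patient_id"]),
                        record_id=str(g.attrs["record_id"]),
                        lead=str(g.attrs["lead"]),
                        window_index=int(g.attrs["window_index"]),
                        padded_from=int(g.attrs["padded_from"]),
                    )
                )
        return store


def store_samples(samples: Iterable, path: str | Path | None = None) -> SampleStore:
    """Collect samples into a :class:`SampleStore`, optionally persisting to HDF5."""
    store = SampleStore()
    for s in samples:
        store.add(s)
    if path is not None:
        store.save(path)
    return store


def load_samples(store: SampleStore | str | Path, **filters):
    """Load samples from a store (or HDF5 path), filtered by metadata equality."""
    if not isinstance(store, SampleStore):
        store = SampleStore.load(store)
    return store.samples(**filters)
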