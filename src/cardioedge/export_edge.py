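"""Portable model export and end-to-end window inference.

The selected decision tree is serialized to a self-contained JSON graph
(split structure, thresholds, leaf class fractions, feature schema and
provenance) that any runtime with basic array support can evaluate — no
pickle, no framework dependency. Export verifies inference equivalence on
a 1,000-vector random probe before the file is considered valid: 100%
label agreement and probability agreement within 1e-6.

``infer_window`` runs the full operational pipeline on a raw signal
window: resample/normalize, gated VMD denoising, delineation,
featurization, prediction — returning an explicit "insufficient beats"
status instead of a label for windows with fewer than 3 detected beats.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from cardioedge.delineation import UnfeaturizableError
from cardioedge.denoising import VmdConfig, vmd_denoise
from cardioedge.features import FEATURE_NAMES, featurize
from cardioedge.preprocessing import clean_normalize, resample_window

FORMAT_NAME = "cardioedge-tree-v1"
PROBE_SIZE = 1000


class ExportError(RuntimeError):
    """Export failed or the portable file is unusable."""


@dataclass
class PortableModel:
    """A loaded portable decision tree, evaluated with numpy only."""

    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value_fractions: np.ndarray  # (n_nodes, n_classes) leaf class fractions
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.children_left)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        out = np.empty((len(X), len(self.classes)))
        for i, row in enumerate(X):
            node = 0
            while self.children_left[node] != -1:
                if row[self.feature[node]] <= self.threshold[node]:
                    node = self.children_left[node]
                else:
                    node = self.children_right[node]
            out[i] = self.value_fractions[node]
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.asarray(self.classes)[np.argmax(proba, axis=1)]


def export_portable(
    model,
    path: str | Path,
    feature_names=FEATURE_NAMES,
    provenance: dict | None = None,
    probe_seed: int = 0,
) -> PortableModel:
    """Serialize a fitted sklearn decision tree to the portable JSON format.

    The written file is reloaded and checked against the native model on a
    random probe (100% label agreement, probabilities within 1e-6); a
    mismatch raises :class:`ExportError` and removes the file.
    """
    try:
        tree = model.tree_
        classes = tuple(str(c) for c in model.classes_)
    except AttributeError as exc:
        raise ExportError(f"unsupported model attribute: {exc}") from exc

    values = tree.value[:, 0, :].astype(float)
    row_sums = values.sum(axis=1, keepdims=True)
    fractions = np.divide(
        values, row_sums, out=np.full_like(values, 1.0 / values.shape[1]),
        where=row_sums > 0,
    )
    doc = {
        "format": FORMAT_NAME,
        "feature_names": list(feature_names),
        "classes": list(classes),
        "children_left": tree.children_left.tolist(),
        "children_right": tree.children_right.tolist(),
        "feature": tree.feature.tolist(),
        "threshold": tree.threshold.tolist(),
        "value_fractions": fractions.tolist(),
        "provenance": provenance or {},
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc))

    portable = load_portable(path)
    rng = np.random.default_rng(probe_seed)
    probe = rng.normal(size=(PROBE_SIZE, len(feature_names)))
    native_labels = model.predict(probe)
    native_proba = model.predict_proba(probe)
    port_labels = portable.predict(probe)
    port_proba = portable.predict_proba(probe)
    if not np.array_equal(native_labels.astype(str), port_labels.astype(str)) or not np.allclose(
        native_proba, port_proba, atol=1e-6
    ):
        path.unlink(missing_ok=True)
        raise ExportError("portable model failed the inference-equivalence probe")
    return portable


def load_portable(path: str | Path) -> PortableModel:
    """Load a portable model file; corrupted files raise without a partial
    model object being produced."""
    try:
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != FORMAT_NAME:
            raise ExportError(f"unrecognized format {doc.get('format')!r}")
        return PortableModel(
            feature_names=tuple(doc["feature_names"]),
            classes=tuple(doc["classes"]),
            children_left=np.asarray(doc["children_left"], dtype=int),
            children_right=np.asarray(doc["children_right"], dtype=int),
            feature=np.asarray(doc["feature"], dtype=int),
            threshold=np.asarray(doc["threshold"], dtype=float),
            value_fractions=np.asarray(doc["value_fractions"], dtype=float),
            provenance=doc.get("provenance", {}),
        )
    except ExportError:
        raise
    except (OSError, ValueError, KeyError, json.JSONDecodeError) as exc:
        raise ExportError(f"cannot load portable model: {exc}") from exc


@dataclass
class InferenceResult:
    status: str  # "ok" or "insufficient beats"
    label: str | None = None
    probabilities: dict[str, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def infer_window(
    portable_model: PortableModel,
    raw_window: np.ndarray,
    fs: float,
    vmd_config: VmdConfig | None = None,
) -> InferenceResult:
    """Classify one raw single-lead window through the full pipeline.

    The window must cover at least 10 s. Provenance records whether the
    denoiser fired and the wall time of each stage (informational only).
    """
    x = np.asarray(raw_window, dtype=np.float64)
    if len(x) / fs < 10.0:
        raise ValueError("window must cover at least 10 s")
    prov: dict = {}

    t0 = time.perf_counter()
    data = resample_window(x[: int(30 * fs)], fs)
    data, padded_from, degenerate = clean_normalize(data)
    prov["preprocess_s"] = time.perf_counter() - t0
    prov["padded_from"] = padded_from

    t0 = time.perf_counter()
    data, info = vmd_denoise(data, vmd_config)
    prov["denoise_s"] = time.perf_counter() - t0
    prov["denoised"] = not info.bypassed
    prov["denoise_fallback"] = info.fallback_bandpass

    t0 = time.perf_counter()
    try:
        feats = featurize(data)
    except UnfeaturizableError:
        prov["featurize_s"] = time.perf_counter() - t0
        return InferenceResult(status="insufficient beats", provenance=prov)
    prov["featurize_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if tuple(portable_model.feature_names) != tuple(FEATURE_NAMES):
        feats = np.array(
            [feats[FEATURE_NAMES.index(f)] for f in portable_model.feature_names]
        )
    proba = portable_model.predict_proba(feats[np.newaxis, :])[0]
    label = portable_model.classes[int(np.argmax(proba))]
    prov["predict_s"] = time.perf_counter() - t0
    return InferenceResult(
        status="ok",
        label=str(label),
        probabilities={c: float(p) for c, p in zip(portable_model.classes, proba)},
        provenance=prov,
    )
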