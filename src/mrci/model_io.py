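"""Versioned text model bundles: trained codebook + protocluster labeling.

The bundle is a single JSON document so identical runs produce
byte-identical files; NPZ-style zip containers embed timestamps and were
deliberately avoided.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .clustering import ProtoclusterLabeling, SOMCodebook
from .io_preprocess import CHANNEL_ORDER

BUNDLE_FORMAT = "mrci-model"
BUNDLE_VERSION = 1


def save_model(
    path: str | Path,
    codebook: SOMCodebook,
    labeling: ProtoclusterLabeling,
    meta: dict | None = None,
) -> Path:
    """Serialize a trained model to a JSON bundle."""
    doc = {
        "format": BUNDLE_FORMAT,
        "version": BUNDLE_VERSION,
        "channel_order": list(CHANNEL_ORDER),
        "codebook": {
            "weights": codebook.weights.tolist(),
            "grid_rows": codebook.grid_rows,
            "grid_cols": codebook.grid_cols,
            "hit_counts": codebook.hit_counts.tolist(),
            "quantization_error_trace": list(codebook.quantization_error_trace),
            "squared_error_trace": list(codebook.squared_error_trace),
        },
        "labeling": {
            "K": labeling.K,
            "unit_class": labeling.unit_class.tolist(),
            "centers": labeling.centers.tolist(),
            "inertia": labeling.inertia,
            "seed": labeling.seed,
        },
        "meta": meta or {},
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return path


def load_model(path: str | Path) -> tuple[SOMCodebook, ProtoclusterLabeling, dict]:
    """Load a JSON model bundle back into codebook + labeling."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != BUNDLE_FORMAT:
        raise ValueError(f"{path} is not a {BUNDLE_FORMAT} bundle")
    cb = doc["codebook"]
    rows, cols = cb["grid_rows"], cb["grid_cols"]
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    codebook = SOMCodebook(
        weights=np.asarray(cb["weights"], dtype=float),
        grid_rows=rows,
        grid_cols=cols,
        unit_coords=np.stack([rr.ravel(), cc.ravel()], axis=1),
        hit_counts=np.asarray(cb["hit_counts"], dtype=np.int64),
        quantization_error_trace=list(cb["quantization_error_trace"]),
        squared_error_trace=list(cb.get("squared_error_trace", [])),
    )
    lb = doc["labeling"]
    labeling = ProtoclusterLabeling(
        K=int(lb["K"]),
        unit_class=np.asarray(lb["unit_class"], dtype=np.int64),
        centers=np.asarray(lb["centers"], dtype=float),
        inertia=float(lb["inertia"]),
        seed=int(lb["seed"]),
    )
    return codebook, labeling, doc.get("meta", {})
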