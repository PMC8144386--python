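"""File I/O: multi-page TIFF video, OCR trace CSV, result tables, run config.

Interchange formats are deliberately plain: CSV for traces and metrics,
TIFF for image-like artifacts, JSON for configuration and sidecar
metadata.  Every analysis output directory carries the exact RunConfig
used (plus its hash), so deterministic stages reproduce bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .bioenergetics import OCRTrace, TRACE_COLUMNS
from .cilia import CiliaryFieldMetrics, SpectralConfig, SpectralMap, VideoField

__all__ = [
    "RunConfig",
    "read_video_tiff",
    "write_video_tiff",
    "read_ocr_csv",
    "write_ocr_csv",
    "write_spectral_maps",
    "write_field_metrics",
]


@dataclass
class RunConfig:
    """Serializable record of every analysis knob.

    Embedded (with a SHA-256 hash) in each output directory so a run can be
    reproduced from its artifacts alone.
    """

    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    rate_rule: str = "mean"
    fence_multiplier: float = 1.5
    flag_outliers: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "spectral" in d and isinstance(d["spectral"], dict):
            d["spectral"] = SpectralConfig(**d["spectral"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def write(self, outdir: Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "run_config.json"
        payload = self.to_dict()
        payload["config_hash"] = self.config_hash
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


def read_video_tiff(
    path: str | Path,
    fps: float | None = None,
    field_id: str | None = None,
    well_id: str | None = None,
    donor_id: str | None = None,
    timepoint_label: str | None = None,
) -> VideoField:
    """Load a multi-page grayscale TIFF stack as a VideoField.

    The acquisition rate is not stored in plain TIFF; it must come either
    from the ``fps`` argument (the ``--fps`` flag on the CLI) or from a
    sidecar JSON next to the stack (``<name>.json`` with an ``fps`` key,
    optionally identifiers).  Integer stacks are promoted to float32.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        raise ValueError(f"{path}: single page; a video stack needs >= 4 pages")
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected a frames x height x width grayscale stack, "
            f"got shape {arr.shape} (ragged or multi-channel pages?)"
        )
    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if fps is None:
        fps = meta.get("fps")
    if fps is None:
        raise ValueError(
            f"{path}: acquisition rate unknown; pass --fps or provide a "
            f"sidecar {sidecar.name} with an 'fps' key"
        )
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    return VideoField(
        intensities=arr,
        fps=float(fps),
        field_id=field_id or meta.get("field_id", path.stem),
        well_id=well_id or meta.get("well_id", "well"),
        donor_id=donor_id or meta.get("donor_id", "donor"),
        timepoint_label=timepoint_label or meta.get("timepoint_label", ""),
    )


def write_video_tiff(video: VideoField, path: str | Path) -> Path:
    """Write a VideoField as a multi-page TIFF plus a JSON sidecar.

    Float stacks round-trip bit-exactly through ``read_video_tiff``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, video.intensities, photometric="minisblack")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "fps": video.fps,
                "field_id": video.field_id,
                "well_id": video.well_id,
                "donor_id": video.donor_id,
                "timepoint_label": video.timepoint_label,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return path


def read_ocr_csv(path: str | Path) -> OCRTrace:
    """Load and validate a long-format OCR trace CSV.

    Schema errors (missing columns, unknown segment labels, non-positive
    protein) are raised with row numbers by OCRTrace validation.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return OCRTrace(df[TRACE_COLUMNS].copy())


def write_ocr_csv(trace: OCRTrace, path: str | Path) -> Path:
    """Deterministic CSV dump of a trace (sorted, fixed column order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = trace.data.sort_values(
        ["plate_id", "well_id", "cycle_index"], kind="stable"
    )
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def write_spectral_maps(smap: SpectralMap, outdir: str | Path) -> dict[str, Path]:
    """Per-pixel frequency map, magnitude map and beating mask as TIFFs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = smap.field_id
    paths = {
        "frequency": outdir / f"{stem}_freq_hz.tif",
        "magnitude": outdir / f"{stem}_magnitude.tif",
        "mask": outdir / f"{stem}_beating_mask.tif",
    }
    tifffile.imwrite(paths["frequency"], smap.dominant_freq.astype(np.float32))
    tifffile.imwrite(paths["magnitude"], smap.dominant_mag.astype(np.float32))
    tifffile.imwrite(paths["mask"], smap.beating.astype(np.uint8))
    return paths


def write_field_metrics(
    metrics: list[CiliaryFieldMetrics], path: str | Path
) -> Path:
    """Sorted per-field metrics CSV (deterministic for identical inputs)."""
    from .cilia import metrics_frame

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = metrics_frame(metrics).sort_values(
        ["donor_id", "timepoint", "well_id", "field_id"], kind="stable"
    )
    df.to_csv(path, index=False, lineterminator="\n")
    return path
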