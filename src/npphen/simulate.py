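"""Synthetic high-speed video fields and OCR plates with known ground truth.

The cilia simulator lays spatially contiguous rectangular patches over a
static background; every pixel of a patch oscillates sinusoidally at the
patch frequency/amplitude/phase, with optional additive Gaussian noise.
Sinusoids are the natural fixture for a spectral pipeline: the per-pixel
truth (dominant frequency, amplitude, beating-mask membership) is known in
closed form.  Defaults mirror the acquisition conditions of the assay being
emulated: 1024 x 768 pixels, 360 frames/s, 720 frames.

The plate simulator draws per-well, per-cycle OCR values around true state
rates (baseline, oligomycin, FCCP, rotenone+antimycin A) with i.i.d.
Gaussian cycle noise, optional multiplicative per-well scatter, optional
gross-outlier wells, and per-well protein mass; the truth record carries
the corrected normalized state rates and RCR the pipeline should recover.

All randomness flows from the single spec seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .bioenergetics import OCRTrace, SEGMENTS, TRACE_COLUMNS
from .cilia import SpectralConfig, VideoField

__all__ = [
    "Patch",
    "CiliaSimSpec",
    "CiliaTruth",
    "simulate_cilia_video",
    "OCRPlateSimSpec",
    "simulate_ocr_plate",
    "simulate_ocr_study",
]


@dataclass(frozen=True)
class Patch:
    """A rectangular oscillating region: rows [row, row+height) x cols [col, col+width)."""

    row: int
    col: int
    height: int
    width: int
    frequency: float
    amplitude: float
    phase: float = 0.0


@dataclass
class CiliaSimSpec:
    """Design of one synthetic video field.

    Intensity model: ``background + sum over covering patches of
    A*sin(2*pi*f*t + phi) + N(0, noise_sd^2)``; overlapping patches sum.
    """

    height: int = 768
    width: int = 1024
    fps: float = 360.0
    frames: int = 720
    background: float = 100.0
    noise_sd: float = 0.0
    patches: Sequence[Patch] = ()
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        for p in self.patches:
            if not (
                0 <= p.row < p.row + p.height <= self.height
                and 0 <= p.col < p.col + p.width <= self.width
            ):
                raise ValueError(f"patch {p} outside {self.height}x{self.width} frame")
            if p.frequency >= self.fps / 2:
                raise ValueError(
                    f"patch frequency {p.frequency} Hz at or above Nyquist {self.fps / 2}"
                )

    @classmethod
    def from_json(cls, text: str) -> "CiliaSimSpec":
        d = json.loads(text)
        d["patches"] = [Patch(**p) for p in d.get("patches", [])]
        return cls(**d)

    def to_json(self) -> str:
        d = asdict(self)
        d["patches"] = [asdict(p) for p in self.patches]
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class CiliaTruth:
    """Ground truth for a simulated field.

    ``mask``: pixels covered by at least one detectable patch (amplitude
    above threshold, frequency inside the detection band).  ``freq_map``:
    frequency of the largest-amplitude covering patch, NaN elsewhere.
    ``overlap``: pixels covered by more than one patch (amplitudes sum
    there, so single-patch truth does not apply cleanly).
    """

    mask: np.ndarray
    freq_map: np.ndarray
    overlap: np.ndarray
    spec: CiliaSimSpec

    @property
    def cbs_percent(self) -> float:
        return 100.0 * float(self.mask.sum()) / self.mask.size


def simulate_cilia_video(
    spec: CiliaSimSpec,
    config: SpectralConfig = SpectralConfig(),
    field_id: str = "field",
    well_id: str = "well",
    donor_id: str = "donor",
    timepoint_label: str = "",
) -> tuple[VideoField, CiliaTruth]:
    """Render a video field and its ground truth from a design spec.

    ``config`` supplies the detection threshold and band used to decide
    which patches count toward the ground-truth beating mask.
    """
    dtype = np.dtype(spec.dtype)
    t = np.arange(spec.frames, dtype=np.float64) / spec.fps
    rng = np.random.default_rng(spec.seed)

    stack = np.full((spec.frames, spec.height, spec.width), spec.background, dtype)
    cover = np.zeros((spec.height, spec.width), dtype=np.int16)
    freq_map = np.full((spec.height, spec.width), np.nan)
    amp_map = np.full((spec.height, spec.width), -np.inf)
    mask = np.zeros((spec.height, spec.width), dtype=bool)

    for p in spec.patches:
        rs, cs = slice(p.row, p.row + p.height), slice(p.col, p.col + p.width)
        wave = p.amplitude * np.sin(2 * math.pi * p.frequency * t + p.phase)
        stack[:, rs, cs] += wave[:, None, None].astype(dtype)
        cover[rs, cs] += 1
        detectable = (
            p.amplitude > config.magnitude_threshold
            and config.band_low <= p.frequency <= config.band_high
        )
        if detectable:
            mask[rs, cs] = True
        region = np.zeros_like(mask)
        region[rs, cs] = True
        takeover = region & (p.amplitude > amp_map)
        amp_map[takeover] = p.amplitude
        freq_map[takeover] = p.frequency

    if spec.noise_sd > 0:
        stack += rng.normal(0.0, spec.noise_sd, stack.shape).astype(dtype)

    video = VideoField(
        intensities=stack,
        fps=spec.fps,
        field_id=field_id,
        well_id=well_id,
        donor_id=donor_id,
        timepoint_label=timepoint_label,
    )
    truth = CiliaTruth(mask=mask, freq_map=freq_map, overlap=cover > 1, spec=spec)
    return video, truth


@dataclass
class OCRPlateSimSpec:
    """Design of one synthetic extracellular-flux plate.

    True state rates default to a coupled, responsive profile on the scale
    of the assay (pmol O2/min before normalization): baseline 100,
    oligomycin 40, FCCP 150, rotenone+antimycin A 20, protein 10 ug/well —
    so the corrected normalized truth is (8.0, 2.0, 13.0) with RCR 6.5.
    Cycle noise defaults to 2 pmol O2/min (2% of baseline).
    """

    rate_baseline: float = 100.0
    rate_oligomycin: float = 40.0
    rate_fccp: float = 150.0
    rate_rot_antA: float = 20.0
    n_wells: int = 6
    cycles_per_segment: int = 3
    cycle_noise_sd: float = 2.0
    well_factor_sd: float = 0.0
    protein_ug_mean: float = 10.0
    protein_ug_sd: float = 0.0
    outlier_wells: int = 0
    outlier_multiplier: float = 10.0
    cycle_minutes: float = 6.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            self.rate_baseline > self.rate_oligomycin >= self.rate_rot_antA >= 0
            and self.rate_fccp > self.rate_baseline
        ):
            raise ValueError(
                "expected a responsive profile: baseline > oligomycin >= "
                "rot_antA >= 0 and fccp > baseline"
            )
        if self.outlier_wells > self.n_wells:
            raise ValueError("more outlier wells than wells")

    @classmethod
    def from_json(cls, text: str) -> "OCRPlateSimSpec":
        return cls(**json.loads(text))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @property
    def true_rates(self) -> dict[str, float]:
        return {
            "baseline": self.rate_baseline,
            "oligomycin": self.rate_oligomycin,
            "fccp": self.rate_fccp,
            "rot_antA": self.rate_rot_antA,
        }

    def truth_record(self) -> dict[str, float]:
        """Corrected normalized state rates and RCR the pipeline should recover."""
        r = self.rate_rot_antA
        p = self.protein_ug_mean
        corrected = {
            "baseline": (self.rate_baseline - r) / p,
            "oligomycin": (self.rate_oligomycin - r) / p,
            "fccp": (self.rate_fccp - r) / p,
        }
        corrected["rcr"] = corrected["fccp"] / corrected["oligomycin"]
        return corrected


def simulate_ocr_plate(
    spec: OCRPlateSimSpec,
    plate_id: str = "plate1",
    donor_id: str = "donor",
    group: str = "term",
    rng: np.random.Generator | None = None,
) -> tuple[OCRTrace, dict]:
    """One plate of per-well, per-cycle OCR values around the true rates.

    Each cycle value is ``truth[state] * well_factor + N(0, cycle_noise_sd^2)``;
    well factors are ``N(1, well_factor_sd^2)`` (exactly 1 when the sd is 0).
    The first ``outlier_wells`` wells are multiplied throughout by
    ``outlier_multiplier``, emulating gross replicate failures.

    Returns the trace and a truth dict with the corrected normalized rates,
    RCR, and the designed outlier well ids.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    rows = []
    outlier_ids = []
    for w in range(spec.n_wells):
        well_id = f"{plate_id}_W{w + 1:02d}"
        factor = 1.0 if spec.well_factor_sd == 0 else rng.normal(1.0, spec.well_factor_sd)
        protein = (
            spec.protein_ug_mean
            if spec.protein_ug_sd == 0
            else max(rng.normal(spec.protein_ug_mean, spec.protein_ug_sd), 1e-6)
        )
        is_outlier = w < spec.outlier_wells
        if is_outlier:
            outlier_ids.append(well_id)
        cycle = 0
        for seg in SEGMENTS:
            truth = spec.true_rates[seg]
            for _ in range(spec.cycles_per_segment):
                value = truth * factor
                if spec.cycle_noise_sd > 0:
                    value += rng.normal(0.0, spec.cycle_noise_sd)
                if is_outlier:
                    value *= spec.outlier_multiplier
                rows.append(
                    {
                        "plate_id": plate_id,
                        "well_id": well_id,
                        "donor_id": donor_id,
                        "group": group,
                        "cycle_index": cycle,
                        "time_min": round(cycle * spec.cycle_minutes, 3),
                        "segment": seg,
                        "ocr_pmol_min": value,
                        "protein_ug": protein,
                    }
                )
                cycle += 1
    trace = OCRTrace(pd.DataFrame(rows, columns=TRACE_COLUMNS))
    truth = {**spec.truth_record(), "outlier_wells": outlier_ids}
    return trace, truth


def simulate_ocr_study(
    spec: OCRPlateSimSpec,
    n_plates: int = 3,
    donor_id: str = "donor",
    group: str = "term",
) -> tuple[OCRTrace, dict]:
    """Several independent plates for one donor (one run per experiment day).

    Per-plate randomness is spawned from the spec seed so the whole study is
    reproducible from a single integer.
    """
    if n_plates < 1:
        raise ValueError("need at least one plate")
    child_seeds = np.random.SeedSequence(spec.seed).spawn(n_plates)
    frames = []
    outliers: list[str] = []
    for i, ss in enumerate(child_seeds):
        trace, plate_truth = simulate_ocr_plate(
            spec,
            plate_id=f"plate{i + 1}",
            donor_id=donor_id,
            group=group,
            rng=np.random.default_rng(ss),
        )
        frames.append(trace.data)
        outliers.extend(plate_truth["outlier_wells"])
    combined = OCRTrace(pd.concat(frames, ignore_index=True))
    truth = {**spec.truth_record(), "outlier_wells": outliers}
    return combined, truth
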