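"""Per-pixel spectral analysis of ciliary beating in high-speed video.

Each pixel of a high-speed video field is treated as an intensity time
series.  Its discrete Fourier spectrum is searched for the dominant
component inside the physiological frequency band (2-60 Hz by default);
pixels whose dominant in-band magnitude exceeds a detection threshold are
classified as *beating*.  Field-level metrics follow:

* CBF (ciliary beat frequency, Hz): unweighted mean of the dominant
  frequency over beating pixels.
* CBS (ciliary beating surface, %): 100 x beating pixels / total pixels.

Magnitudes are amplitude-normalized (``2|X_k|/N`` for a length-N series,
``|X_k|/N`` at the Nyquist bin), so an on-bin sinusoid of amplitude A
contributes magnitude A at its bin regardless of recording length, and the
detection threshold is expressed directly in intensity units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import get_window

__all__ = [
    "VideoField",
    "SpectralConfig",
    "SpectralMap",
    "CiliaryFieldMetrics",
    "pixel_spectrum",
    "dominant_component",
    "spectral_map",
    "field_metrics",
    "aggregate",
]

#: pixels per frame at the default acquisition geometry (1024 x 768)
DEFAULT_FRAME_PIXELS = 1024 * 768


@dataclass
class VideoField:
    """A frames x height x width intensity stack from one imaged field.

    Parameters
    ----------
    intensities
        Real-valued array indexed ``(frame, row, col)``; converted to float.
    fps
        Acquisition rate, frames per second.
    field_id, well_id, donor_id, timepoint_label
        Identifiers carried through to metrics tables (e.g. ``"ALI_d15"``).
    """

    intensities: np.ndarray
    fps: float = 360.0
    field_id: str = "field"
    well_id: str = "well"
    donor_id: str = "donor"
    timepoint_label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise ValueError(
                f"intensities must be (frames, height, width), got shape {arr.shape}"
            )
        if arr.shape[0] < 4:
            raise ValueError(f"need at least 4 frames, got {arr.shape[0]}")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        self.intensities = arr

    @property
    def frames(self) -> int:
        return self.intensities.shape[0]

    @property
    def height(self) -> int:
        return self.intensities.shape[1]

    @property
    def width(self) -> int:
        return self.intensities.shape[2]

    @property
    def n_pixels(self) -> int:
        """Pixels per frame (the CBS denominator)."""
        return self.height * self.width


@dataclass(frozen=True)
class SpectralConfig:
    """Detection band, magnitude threshold and window for beating-pixel calls.

    ``magnitude_threshold`` is in intensity units on the amplitude scale
    (an on-bin sinusoid of amplitude A has magnitude A).  The band is the
    closed interval ``[band_low, band_high]`` in Hz; beating requires
    dominant magnitude strictly greater than the threshold.
    """

    magnitude_threshold: float = 1.0
    band_low: float = 2.0
    band_high: float = 60.0
    window: str = "rectangular"

    def __post_init__(self) -> None:
        if self.magnitude_threshold < 0:
            raise ValueError("magnitude_threshold must be >= 0")
        if not 0 < self.band_low < self.band_high:
            raise ValueError(
                f"need 0 < band_low < band_high, got [{self.band_low}, {self.band_high}]"
            )

    def validate_for(self, fps: float) -> None:
        if self.band_high >= fps / 2:
            raise ValueError(
                f"band_high={self.band_high} Hz must lie below the Nyquist "
                f"frequency fps/2 = {fps / 2} Hz"
            )


@dataclass
class SpectralMap:
    """Per-pixel dominant in-band frequency/magnitude and the beating mask."""

    dominant_freq: np.ndarray
    dominant_mag: np.ndarray
    beating: np.ndarray
    config: SpectralConfig
    fps: float
    frames: int
    field_id: str = "field"
    well_id: str = "well"
    donor_id: str = "donor"
    timepoint_label: str = ""

    @property
    def n_beating(self) -> int:
        return int(self.beating.sum())

    @property
    def n_total(self) -> int:
        return int(self.beating.size)


@dataclass
class CiliaryFieldMetrics:
    """CBF (Hz) and CBS (% of frame) for one video field.

    ``cbf_mean`` is NaN when the field has no beating pixels.
    """

    cbf_mean: float
    cbs_percent: float
    n_beating: int
    n_total: int
    field_id: str = "field"
    well_id: str = "well"
    donor_id: str = "donor"
    timepoint_label: str = ""

    @property
    def cbf_defined(self) -> bool:
        return self.n_beating > 0


def _window_values(window: str, n: int) -> np.ndarray | None:
    """Taper values, or None for the rectangular (no-taper) default."""
    if window in ("rectangular", "boxcar", "rect", None):
        return None
    return get_window(window, n, fftbins=True)


def pixel_spectrum(
    series: Sequence[float] | np.ndarray,
    fps: float,
    window: str = "rectangular",
) -> tuple[np.ndarray, np.ndarray]:
    """Single-sided amplitude spectrum of one pixel's intensity time series.

    The series mean (DC component) is removed before the transform.  Returns
    frequencies ``k*fps/N`` for ``k = 1..N//2`` and magnitudes ``2|X_k|/N``
    (``|X_k|/N`` at the Nyquist bin when N is even), so an on-bin sinusoid
    of amplitude A yields magnitude A at its bin.  With a non-rectangular
    window the normalization divides by the window sum instead of N
    (coherent-gain correction).

    Raises
    ------
    ValueError
        If the series is shorter than 4 samples or contains non-finite
        values.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError(f"series must be 1-D, got shape {x.shape}")
    n = x.size
    if n < 4:
        raise ValueError(f"series must have at least 4 samples, got {n}")
    if not np.all(np.isfinite(x)):
        bad = int(np.flatnonzero(~np.isfinite(x))[0])
        raise ValueError(f"non-finite value at sample {bad}")
    if not fps > 0:
        raise ValueError(f"fps must be positive, got {fps}")

    x = x - x.mean()
    w = _window_values(window, n)
    norm = float(n)
    if w is not None:
        x = x * w
        norm = float(w.sum())
    spec = np.fft.rfft(x)
    # k*fps/n rather than rfftfreq's k/(n*d): exact for on-bin frequencies
    freqs = np.arange(1, n // 2 + 1, dtype=np.float64) * fps / n
    mags = 2.0 * np.abs(spec[1:]) / norm
    if n % 2 == 0:
        mags[-1] /= 2.0  # Nyquist bin appears once, not twice
    return freqs, mags


def dominant_component(
    frequencies: np.ndarray,
    magnitudes: np.ndarray,
    band: tuple[float, float],
) -> tuple[float, float]:
    """Largest-magnitude spectral bin inside the closed band [f_lo, f_hi].

    Ties are broken toward the lowest frequency.

    Raises
    ------
    ValueError
        If no spectral bin falls inside the band.
    """
    freqs = np.asarray(frequencies, dtype=np.float64)
    mags = np.asarray(magnitudes, dtype=np.float64)
    f_lo, f_hi = band
    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    if not in_band.any():
        res = float(np.min(np.diff(freqs))) if freqs.size > 1 else float("nan")
        raise ValueError(
            f"no spectral bins inside band [{f_lo}, {f_hi}] Hz "
            f"(frequency resolution {res} Hz)"
        )
    bf = freqs[in_band]
    bm = mags[in_band]
    # np.argmax returns the first maximum; frequencies ascend, so ties go low
    k = int(np.argmax(bm))
    return float(bf[k]), float(bm[k])


def spectral_map(
    video: VideoField,
    config: SpectralConfig = SpectralConfig(),
    row_chunk: int = 64,
) -> SpectralMap:
    """Per-pixel dominant in-band component and beating mask for a field.

    Pixels are processed in row blocks to bound memory on full-size
    (1024 x 768 x 720) stacks.  A pixel is beating iff its dominant in-band
    magnitude strictly exceeds ``config.magnitude_threshold``.
    """
    config.validate_for(video.fps)
    n = video.frames
    freqs = np.arange(1, n // 2 + 1, dtype=np.float64) * video.fps / n
    mags_scale = np.full(freqs.shape, 2.0 / n)
    w = _window_values(config.window, n)
    if w is not None:
        mags_scale[:] = 2.0 / w.sum()
    if n % 2 == 0:
        mags_scale[-1] /= 2.0

    in_band = (freqs >= config.band_low) & (freqs <= config.band_high)
    if n % 2 == 0:
        in_band[-1] = False  # Nyquist bin excluded from the search
    if not in_band.any():
        raise ValueError(
            f"no spectral bins inside band [{config.band_low}, {config.band_high}] Hz "
            f"(frequency resolution {video.fps / n} Hz)"
        )
    band_freqs = freqs[in_band]
    band_scale = mags_scale[in_band]

    h, wid = video.height, video.width
    dom_freq = np.empty((h, wid), dtype=np.float64)
    dom_mag = np.empty((h, wid), dtype=np.float64)

    for r0 in range(0, h, row_chunk):
        r1 = min(r0 + row_chunk, h)
        block = video.intensities[:, r0:r1, :].astype(np.float64, copy=True)
        if not np.all(np.isfinite(block)):
            t, rr, cc = np.unravel_index(
                int(np.flatnonzero(~np.isfinite(block))[0]), block.shape
            )
            raise ValueError(
                f"non-finite intensity at pixel (row={r0 + rr}, col={cc}), frame {t}"
            )
        block -= block.mean(axis=0)
        if w is not None:
            block *= w[:, None, None]
        spec = np.fft.rfft(block, axis=0)[1:]
        band_mags = np.abs(spec[in_band]) * band_scale[:, None, None]
        idx = np.argmax(band_mags, axis=0)  # first max -> lowest frequency
        dom_freq[r0:r1] = band_freqs[idx]
        dom_mag[r0:r1] = np.take_along_axis(band_mags, idx[None], axis=0)[0]

    beating = dom_mag > config.magnitude_threshold
    return SpectralMap(
        dominant_freq=dom_freq,
        dominant_mag=dom_mag,
        beating=beating,
        config=config,
        fps=video.fps,
        frames=n,
        field_id=video.field_id,
        well_id=video.well_id,
        donor_id=video.donor_id,
        timepoint_label=video.timepoint_label,
    )


def field_metrics(smap: SpectralMap) -> CiliaryFieldMetrics:
    """CBF and CBS for one field from its spectral map.

    CBS is the percentage of frame pixels that are beating; CBF is the
    unweighted mean dominant frequency over beating pixels (NaN when none).
    """
    n_beat = smap.n_beating
    n_tot = smap.n_total
    cbs = 100.0 * n_beat / n_tot
    cbf = float(smap.dominant_freq[smap.beating].mean()) if n_beat else math.nan
    return CiliaryFieldMetrics(
        cbf_mean=cbf,
        cbs_percent=cbs,
        n_beating=n_beat,
        n_total=n_tot,
        field_id=smap.field_id,
        well_id=smap.well_id,
        donor_id=smap.donor_id,
        timepoint_label=smap.timepoint_label,
    )


def metrics_frame(fields: Iterable[CiliaryFieldMetrics]) -> pd.DataFrame:
    """Tidy per-field table (one row per imaged field)."""
    rows = [
        {
            "donor_id": f.donor_id,
            "well_id": f.well_id,
            "field_id": f.field_id,
            "timepoint": f.timepoint_label,
            "cbf_mean": f.cbf_mean,
            "cbs_percent": f.cbs_percent,
            "n_beating": f.n_beating,
            "n_total": f.n_total,
        }
        for f in fields
    ]
    if not rows:
        raise ValueError("no fields to tabulate")
    return pd.DataFrame(rows)


def _sem(x: pd.Series) -> float:
    x = x.dropna()
    if len(x) == 0:
        return math.nan
    if len(x) == 1:
        return math.nan
    return float(x.std(ddof=1) / math.sqrt(len(x)))


def aggregate(
    fields: Iterable[CiliaryFieldMetrics],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Well-level and donor-level mean +/- SEM of CBF and CBS.

    Fields feed unweighted into well means; wells feed unweighted into donor
    means.  SEM is the sample SD over the sample size's square root at each
    level.  Fields with undefined CBF (no beating pixels) are excluded from
    CBF means; ``n_cbf`` counts the fields/wells that contributed.

    Returns ``(well_summary, donor_summary)`` DataFrames.
    """
    df = metrics_frame(fields)

    def _level(frame: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
        grouped = frame.groupby(keys, sort=True)
        out = grouped.agg(
            cbf_mean=("cbf_mean", "mean"),
            cbf_sem=("cbf_mean", _sem),
            n_cbf=("cbf_mean", lambda s: int(s.notna().sum())),
            cbs_mean=("cbs_percent", "mean"),
            cbs_sem=("cbs_percent", _sem),
            n=("cbs_percent", "size"),
        ).reset_index()
        return out

    well = _level(df, ["donor_id", "timepoint", "well_id"])
    well_as_obs = well[["donor_id", "timepoint", "well_id", "cbf_mean", "cbs_mean"]]
    well_as_obs = well_as_obs.rename(columns={"cbs_mean": "cbs_percent"})
    donor = _level(well_as_obs, ["donor_id", "timepoint"])
    return well, donor


def analyze_field(
    video: VideoField, config: SpectralConfig = SpectralConfig()
) -> CiliaryFieldMetrics:
    """Convenience: spectral map then field metrics in one call."""
    return field_metrics(spectral_map(video, config))
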