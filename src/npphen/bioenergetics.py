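"""Mitochondrial stress-test (extracellular-flux) rate analysis.

The four-injection protocol records oxygen consumption rate (OCR) per well
across ordered measurement cycles: baseline, then oligomycin (ATP-synthase
inhibited: resting respiration), then FCCP (uncoupled: maximal respiration),
then rotenone + antimycin A (complex I/III inhibited: non-mitochondrial
residual).  For each well this module

1. collapses each segment's cycles to a raw rate (mean by default),
2. subtracts the non-mitochondrial rate from baseline/oligomycin/FCCP and
   divides by the well's protein mass (pmol O2/min/ug protein),
3. derives the respiratory control ratio RCR = FCCP rate / oligomycin rate,

then flags replicate-well outliers on each plate (Tukey 1.5 x IQR fences,
per plate and state), averages kept wells into plate means, and averages
plate means (unweighted) into per-donor state rates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SEGMENTS",
    "OCRTrace",
    "MitoStateRates",
    "segment_rate",
    "correct_and_normalize",
    "flag_outlier_replicates",
    "well_rates",
    "plate_summary",
    "subject_summary",
    "analyze_trace",
]

#: protocol segments in injection order
SEGMENTS = ("baseline", "oligomycin", "fccp", "rot_antA")

#: states reported after non-mitochondrial correction
CORRECTED_STATES = ("baseline", "oligomycin", "fccp")

RateRule = Literal["mean", "last", "min", "max"]

TRACE_COLUMNS = [
    "plate_id",
    "well_id",
    "donor_id",
    "group",
    "cycle_index",
    "time_min",
    "segment",
    "ocr_pmol_min",
    "protein_ug",
]


@dataclass
class OCRTrace:
    """Long-format per-well, per-cycle OCR measurements with protein mass.

    ``data`` columns: plate_id, well_id, donor_id, group, cycle_index,
    time_min, segment, ocr_pmol_min, protein_ug.  Each (plate, well) must
    carry every protocol segment at least once, in injection order, and a
    single positive protein mass.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"OCR trace missing columns: {missing}")
        unknown = set(df["segment"]) - set(SEGMENTS)
        if unknown:
            rows = df.index[df["segment"].isin(unknown)].tolist()[:5]
            raise ValueError(
                f"unknown segment labels {sorted(unknown)} (rows {rows}); "
                f"expected one of {list(SEGMENTS)}"
            )
        bad_protein = df.index[~(df["protein_ug"] > 0)].tolist()
        if bad_protein:
            raise ValueError(
                f"non-positive protein_ug at rows {bad_protein[:5]}"
            )
        order = {s: i for i, s in enumerate(SEGMENTS)}
        for (plate, well), g in df.groupby(["plate_id", "well_id"], sort=False):
            have = set(g["segment"])
            lacking = [s for s in SEGMENTS if s not in have]
            if lacking:
                raise ValueError(
                    f"well {well!r} on plate {plate!r} missing segments {lacking}"
                )
            g = g.sort_values("cycle_index")
            seg_codes = g["segment"].map(order).to_numpy()
            if np.any(np.diff(seg_codes) < 0):
                raise ValueError(
                    f"well {well!r} on plate {plate!r}: segments out of "
                    f"protocol order {list(SEGMENTS)}"
                )
            if g["protein_ug"].nunique() > 1:
                raise ValueError(
                    f"well {well!r} on plate {plate!r}: inconsistent protein_ug"
                )
        self.data = df.reset_index(drop=True)

    @property
    def plates(self) -> list[str]:
        return sorted(self.data["plate_id"].unique())

    def wells(self, plate_id: str) -> list[str]:
        sub = self.data[self.data["plate_id"] == plate_id]
        return sorted(sub["well_id"].unique())


@dataclass
class MitoStateRates:
    """Corrected, protein-normalized state rates for one well.

    baseline/oligomycin/fccp are in pmol O2/min/ug protein after
    subtracting the non-mitochondrial (rotenone + antimycin A) rate;
    the corrected rot+antA state is identically zero by construction.
    ``rcr`` = fccp / oligomycin, NaN when the oligomycin rate is not
    positive.
    """

    baseline: float
    oligomycin: float
    fccp: float
    nonmito_raw: float
    protein_ug: float
    rcr: float = math.nan
    rcr_defined: bool = True
    negative_states: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "baseline": self.baseline,
            "oligomycin": self.oligomycin,
            "fccp": self.fccp,
            "nonmito_raw": self.nonmito_raw,
            "rcr": self.rcr,
        }


def segment_rate(
    well_cycles: pd.DataFrame, segment: str, rule: RateRule = "mean"
) -> float:
    """Collapse one well's cycles for a segment into a raw rate (pmol O2/min).

    Rules: ``mean`` of the segment's cycles (default), ``last`` cycle,
    ``min`` (conventional for oligomycin), ``max`` (conventional for FCCP).
    """
    if segment not in SEGMENTS:
        raise ValueError(f"unknown segment {segment!r}")
    g = well_cycles[well_cycles["segment"] == segment]
    if g.empty:
        well = well_cycles["well_id"].iloc[0] if len(well_cycles) else "?"
        raise ValueError(f"well {well!r} has no cycles for segment {segment!r}")
    vals = g.sort_values("cycle_index")["ocr_pmol_min"].to_numpy(dtype=float)
    if rule == "mean":
        return float(vals.mean())
    if rule == "last":
        return float(vals[-1])
    if rule == "min":
        return float(vals.min())
    if rule == "max":
        return float(vals.max())
    raise ValueError(f"unknown rate rule {rule!r}")


def correct_and_normalize(
    raw: Mapping[str, float], protein_ug: float
) -> MitoStateRates:
    """Non-mitochondrial subtraction and protein normalization for one well.

    corrected_state = (raw_state - raw_rot_antA) / protein_ug for baseline,
    oligomycin and FCCP.  Negative corrected rates are retained (clamping
    would bias the RCR) but reported in ``negative_states`` with a warning.
    RCR = corrected FCCP / corrected oligomycin; undefined (NaN, flagged)
    when corrected oligomycin is not positive.
    """
    if not protein_ug > 0:
        raise ValueError(f"protein_ug must be positive, got {protein_ug}")
    for s in SEGMENTS:
        if s not in raw:
            raise ValueError(f"raw rates missing segment {s!r}")
    nonmito = float(raw["rot_antA"])
    corrected = {
        s: (float(raw[s]) - nonmito) / protein_ug for s in CORRECTED_STATES
    }
    negative = tuple(s for s, v in corrected.items() if v < 0)
    if negative:
        warnings.warn(
            f"negative corrected rate(s) for {list(negative)}; retained",
            stacklevel=2,
        )
    if corrected["oligomycin"] > 0:
        rcr = corrected["fccp"] / corrected["oligomycin"]
        rcr_defined = True
    else:
        rcr = math.nan
        rcr_defined = False
        warnings.warn(
            "corrected oligomycin rate <= 0; RCR undefined", stacklevel=2
        )
    return MitoStateRates(
        baseline=corrected["baseline"],
        oligomycin=corrected["oligomycin"],
        fccp=corrected["fccp"],
        nonmito_raw=nonmito,
        protein_ug=float(protein_ug),
        rcr=rcr,
        rcr_defined=rcr_defined,
        negative_states=negative,
    )


def flag_outlier_replicates(
    plate_rates: pd.DataFrame,
    states: tuple[str, ...] = CORRECTED_STATES,
    fence_multiplier: float = 1.5,
) -> tuple[list[str], list[dict]]:
    """Tukey-fence replicate-well screen for one plate.

    ``plate_rates`` has one row per well (index or column ``well_id``) and
    one column per state.  A well is omitted when any of its state rates
    lies outside ``[Q1 - k*IQR, Q3 + k*IQR]`` of that state's distribution
    across the plate's wells (k = 1.5 by default).  With fewer than 4 wells
    the fences are not meaningful: nothing is flagged and a warning is
    emitted.

    Returns ``(kept_well_ids, omission_log)`` where each log entry names
    the well, state, value and fence violated.
    """
    df = plate_rates
    if "well_id" in df.columns:
        df = df.set_index("well_id")
    wells = list(df.index)
    if len(wells) < 4:
        warnings.warn(
            f"only {len(wells)} wells on plate; outlier fences not applied",
            stacklevel=2,
        )
        return wells, []
    log: list[dict] = []
    omitted: set[str] = set()
    for state in states:
        vals = df[state].to_numpy(dtype=float)
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - fence_multiplier * iqr, q3 + fence_multiplier * iqr
        for well, v in zip(wells, vals):
            if v < lo or v > hi:
                omitted.add(well)
                log.append(
                    {
                        "well_id": well,
                        "state": state,
                        "value": float(v),
                        "fence_low": float(lo),
                        "fence_high": float(hi),
                    }
                )
    kept = [w for w in wells if w not in omitted]
    return kept, log


def well_rates(
    trace: OCRTrace, rate_rule: RateRule = "mean"
) -> pd.DataFrame:
    """Corrected, normalized state rates for every well of a trace.

    One row per (plate_id, well_id) with donor/group identifiers, the three
    corrected states, the raw non-mitochondrial rate, protein mass and RCR.
    """
    rows = []
    for (plate, well), g in trace.data.groupby(
        ["plate_id", "well_id"], sort=True
    ):
        raw = {s: segment_rate(g, s, rate_rule) for s in SEGMENTS}
        rates = correct_and_normalize(raw, float(g["protein_ug"].iloc[0]))
        rows.append(
            {
                "plate_id": plate,
                "well_id": well,
                "donor_id": g["donor_id"].iloc[0],
                "group": g["group"].iloc[0],
                **rates.as_dict(),
                "protein_ug": rates.protein_ug,
            }
        )
    return pd.DataFrame(rows)


def plate_summary(
    wells_df: pd.DataFrame,
    flag_outliers: bool = True,
    fence_multiplier: float = 1.5,
) -> tuple[pd.DataFrame, list[dict]]:
    """Plate-level state means over outlier-screened replicate wells.

    Returns ``(plate_df, omission_log)``.  Plate RCR is the ratio of the
    plate FCCP mean to the plate oligomycin mean.
    """
    rows = []
    log: list[dict] = []
    for plate, g in wells_df.groupby("plate_id", sort=True):
        if flag_outliers:
            kept, plate_log = flag_outlier_replicates(
                g[["well_id", *CORRECTED_STATES]], fence_multiplier=fence_multiplier
            )
            for entry in plate_log:
                log.append({"plate_id": plate, **entry})
            g = g[g["well_id"].isin(kept)]
        if g.empty:
            warnings.warn(f"plate {plate!r}: no wells kept; skipped", stacklevel=2)
            continue
        means = {s: float(g[s].mean()) for s in CORRECTED_STATES}
        rcr = (
            means["fccp"] / means["oligomycin"]
            if means["oligomycin"] > 0
            else math.nan
        )
        rows.append(
            {
                "plate_id": plate,
                "donor_id": g["donor_id"].iloc[0],
                "group": g["group"].iloc[0],
                **means,
                "rcr": rcr,
                "n_wells_kept": int(len(g)),
            }
        )
    return pd.DataFrame(rows), log


def subject_summary(plate_df: pd.DataFrame) -> pd.DataFrame:
    """Per-donor state rates: unweighted mean of plate means.

    Plates contribute equally regardless of how many replicate wells each
    kept.  Donor RCR is the ratio of the donor FCCP mean to the donor
    oligomycin mean.
    """
    if plate_df.empty:
        raise ValueError("no plates to summarize")
    rows = []
    for donor, g in plate_df.groupby("donor_id", sort=True):
        means = {s: float(g[s].mean()) for s in CORRECTED_STATES}
        rcr = (
            means["fccp"] / means["oligomycin"]
            if means["oligomycin"] > 0
            else math.nan
        )
        rows.append(
            {
                "donor_id": donor,
                "group": g["group"].iloc[0],
                **means,
                "rcr": rcr,
                "n_plates": int(len(g)),
            }
        )
    return pd.DataFrame(rows)


def analyze_trace(
    trace: OCRTrace,
    rate_rule: RateRule = "mean",
    flag_outliers: bool = True,
    fence_multiplier: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[dict]]:
    """Full bioenergetics pipeline on one trace.

    Returns ``(well_df, plate_df, subject_df, omission_log)``.
    """
    wells_df = well_rates(trace, rate_rule)
    plate_df, log = plate_summary(
        wells_df, flag_outliers=flag_outliers, fence_multiplier=fence_multiplier
    )
    subject_df = subject_summary(plate_df)
    return wells_df, plate_df, subject_df, log
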