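"""Closed-form assay computations: mito-stress parameters and tumor volumes."""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["OcrTrace", "TumorMeasurement", "mito_stress_params",
           "tumor_volume", "growth_normalize"]


@dataclass(frozen=True)
class OcrTrace:
    """Normalized oxygen consumption rates (pmol O2/min) at the four
    mito-stress plateaus: baseline, post-oligomycin, post-FCCP and
    post-rotenone+antimycin A."""

    basal: float
    post_oligomycin: float
    post_fccp: float
    post_rot_antimycin: float

    def __post_init__(self):
        for name in ("basal", "post_oligomycin", "post_fccp",
                     "post_rot_antimycin"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class TumorMeasurement:
    """Caliper length/width in mm at a given day (length >= width by convention)."""

    length: float
    width: float
    day: int = 0

    def __post_init__(self):
        if not (self.length > 0 and self.width > 0):
            raise ValueError("dimensions must be positive")
        if self.day < 0:
            raise ValueError("day must be >= 0")


def mito_stress_params(t: OcrTrace) -> dict:
    """Decompose an OCR trace into the standard mito-stress parameters.

    BR (basal respiration) = basal - post_rot_antimycin;
    ATP (ATP-linked respiration) = basal - post_oligomycin;
    MRC (maximal respiratory capacity) = post_fccp - post_rot_antimycin;
    PL (proton leak) = post_oligomycin - post_rot_antimycin.
    The identity BR = ATP + PL holds exactly.
    """
    return {
        "BR": t.basal - t.post_rot_antimycin,
        "ATP": t.basal - t.post_oligomycin,
        "MRC": t.post_fccp - t.post_rot_antimycin,
        "PL": t.post_oligomycin - t.post_rot_antimycin,
    }


def tumor_volume(m: TumorMeasurement) -> float:
    """Ellipsoid-approximation tumor volume in cm^3: length*width^2/2/1000."""
    return m.length * m.width ** 2 / 2.0 / 1000.0


def growth_normalize(series) -> pd.DataFrame:
    """Tumor volumes relative to the day-0 volume.

    Returns a DataFrame (day, relative_volume) sorted by day; requires a
    day-0 measurement with positive volume.
    """
    vols = {m.day: tumor_volume(m) for m in series}
    if 0 not in vols:
        raise ValueError("series must include a day-0 measurement")
    v0 = vols[0]
    rows = [(day, vols[day] / v0) for day in sorted(vols)]
    return pd.DataFrame(rows, columns=["day", "relative_volume"])
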