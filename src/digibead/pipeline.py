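"""End-to-end orchestration: detect -> quantify -> calibrate.

Glues the per-frame primitives into experiment-level runs: a dilution
series of FrameSets becomes a per-condition quantification table (digital
and analog readouts side by side) and then a calibration report with the
4PL fit and LOD for each readout. The on/off threshold is computed once per
experiment from the pooled blank-condition bead intensities, exactly as a
zero-analyte control is used in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import FourPLFit, LODResult, calibrate_table
from .detection import DetectionParams, detect_frameset
from .errors import InvalidParameterError
from .quantify import BlankModel, analog_readout, classify_beads, compute_amb, fit_blank
from .synthetic import DilutionCondition

__all__ = [
    "QUANT_COLUMNS",
    "CalibrationReport",
    "quantify_conditions",
    "quantify_intensity_table",
    "calibrate_quantification",
    "blank_corrected_amb",
]

QUANT_COLUMNS = [
    "concentration",
    "replicate",
    "n_total",
    "n_on",
    "f_on",
    "amb",
    "saturated",
    "mean_intensity",
]


def quantify_conditions(
    conditions: list[DilutionCondition], params: DetectionParams
) -> tuple[pd.DataFrame, pd.DataFrame, BlankModel]:
    """Detect beads and quantify every (concentration, replicate) cell.

    Returns ``(per_bead, quant, blank_model)``: the per-bead detection table
    (with concentration/replicate columns), the per-condition quantification
    table, and the blank model fitted to the pooled blank-replicate bead
    intensities.
    """
    per_bead_parts = []
    for cond in conditions:
        df = _detections_table(cond, params)
        per_bead_parts.append(df)
    per_bead = pd.concat(per_bead_parts, ignore_index=True)

    analog = {
        (c.concentration, c.replicate): analog_readout(c.frameset.fluorescence_frames)
        for c in conditions
    }
    quant, blank_model = quantify_intensity_table(per_bead, analog_results=analog)
    return per_bead, quant, blank_model


def _detections_table(cond: DilutionCondition, params: DetectionParams) -> pd.DataFrame:
    dets = detect_frameset(cond.frameset, params)
    df = pd.DataFrame(
        [
            {
                "frame_index": d.frame_index,
                "row": d.center[0],
                "col": d.center[1],
                "radius": d.radius,
                "max_intensity": d.max_intensity,
            }
            for d in dets
        ],
        columns=["frame_index", "row", "col", "radius", "max_intensity"],
    )
    df.insert(0, "replicate", cond.replicate)
    df.insert(0, "concentration", cond.concentration)
    return df


def quantify_intensity_table(
    per_bead: pd.DataFrame,
    analog_results: dict | None = None,
    min_blank_beads: int = 30,
) -> tuple[pd.DataFrame, BlankModel]:
    """Build the per-condition quantification table from per-bead intensities.

    ``per_bead`` needs columns ``concentration, replicate, max_intensity``.
    Blank (concentration 0) intensities are pooled across replicates to fit
    the Gaussian blank model; each cell is then classified against the
    resulting mean + 2 SD threshold.
    """
    required = {"concentration", "replicate", "max_intensity"}
    if not required.issubset(per_bead.columns):
        raise InvalidParameterError(f"per-bead table must have columns {sorted(required)}")
    blank_vals = per_bead.loc[per_bead["concentration"] == 0, "max_intensity"]
    if blank_vals.empty:
        raise InvalidParameterError("no blank (concentration 0) beads; cannot set a threshold")
    blank_model = fit_blank(blank_vals.to_numpy(), min_beads=min_blank_beads)

    rows = []
    for (conc, rep), grp in per_bead.groupby(["concentration", "replicate"], sort=True):
        n_on, n_total = classify_beads(grp["max_intensity"].to_numpy(), blank_model)
        digital = compute_amb(n_on, n_total)
        mean_int = math.nan
        if analog_results is not None and (conc, rep) in analog_results:
            mean_int = analog_results[(conc, rep)].mean_intensity
        rows.append(
            {
                "concentration": conc,
                "replicate": rep,
                "n_total": n_total,
                "n_on": n_on,
                "f_on": digital.f_on,
                "amb": digital.amb,
                "saturated": digital.saturated,
                "mean_intensity": mean_int,
            }
        )
    return pd.DataFrame(rows, columns=QUANT_COLUMNS), blank_model


@dataclass(frozen=True)
class CalibrationReport:
    """4PL calibration of one readout: fit, LOD, per-concentration summary."""

    readout: str
    fit: FourPLFit
    lod: LODResult
    summary: pd.DataFrame

    def to_row(self) -> dict:
        return {
            "readout": self.readout,
            "a": self.fit.a,
            "b": self.fit.b,
            "c": self.fit.c,
            "d": self.fit.d,
            "rss": self.fit.rss,
            "n_points": self.fit.n_points,
            "y_lod": self.lod.y_lod,
            "lod_concentration_ng_ml": self.lod.lod_concentration,
            "lod_mass_pg": self.lod.lod_mass,
            "sample_volume_ul": self.lod.sample_volume,
        }


def calibrate_quantification(
    quant: pd.DataFrame,
    readout_mode: str = "both",
    sample_volume: float = 2.0,
    weighted: bool = False,
) -> list[CalibrationReport]:
    """Fit 4PL calibration curves and LODs for the requested readouts.

    ``digital`` calibrates the AMB column, ``analog`` the mean-intensity
    column, ``both`` does both on the same quantification table (and hence
    the same underlying frames). For the digital readout the blank SD is
    floored at the mean delta-method counting SE of the blank replicates,
    sqrt(f_on / ((1 - f_on) n)); replicate scatter cannot genuinely fall
    below the sampling noise of the bead counts.
    """
    if readout_mode not in ("digital", "analog", "both"):
        raise InvalidParameterError(f"readout_mode must be digital|analog|both, got {readout_mode!r}")
    wanted = {"digital": ["amb"], "analog": ["mean_intensity"], "both": ["amb", "mean_intensity"]}
    names = {"amb": "digital", "mean_intensity": "analog"}
    reports = []
    for col in wanted[readout_mode]:
        if quant[col].isna().any():
            raise InvalidParameterError(f"readout column {col!r} has missing values")
        floor = 0.0
        if col == "amb":
            blank = quant[quant["concentration"] == 0]
            if not blank.empty:
                ses = [
                    math.sqrt(f / ((1.0 - f) * n)) if 0 < f < 1 else math.sqrt(1.0 / n)
                    for f, n in zip(blank["f_on"], blank["n_total"])
                ]
                floor = float(np.mean(ses))
        fit, lod, summary = calibrate_table(
            quant,
            response_col=col,
            sample_volume=sample_volume,
            weighted=weighted,
            blank_sd_floor=floor,
        )
        reports.append(CalibrationReport(readout=names[col], fit=fit, lod=lod, summary=summary))
    return reports


def blank_corrected_amb(quant: pd.DataFrame) -> pd.DataFrame:
    """Blank-corrected molecule estimates per condition.

    With a blank mean + 2 SD threshold, a fixed fraction (~2.275%) of true
    blank beads falls above the threshold by construction. AMB is additive
    in that false-positive rate, so subtracting the mean blank AMB gives an
    unbiased estimate of the analyte-driven Poisson mean. Adds columns
    ``amb_net`` and its delta-method standard error ``amb_net_se``.
    """
    blank = quant[quant["concentration"] == 0]
    if blank.empty:
        raise InvalidParameterError("quantification table has no blank condition")
    amb_blank = float(blank["amb"].mean())

    def se(row):
        f, n = row["f_on"], row["n_total"]
        return math.sqrt(f / ((1.0 - f) * n)) if 0 < f < 1 else math.sqrt(1.0 / n)

    out = quant.copy()
    se_sample = out.apply(se, axis=1)
    se_blank2 = float(np.mean([se(r) for _, r in blank.iterrows()]) ** 2 / len(blank))
    out["amb_net"] = out["amb"] - amb_blank
    out["amb_net_se"] = np.sqrt(se_sample**2 + se_blank2)
    return out
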