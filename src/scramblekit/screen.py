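"""Plate-reader OD340 kinetics: geraniol calibration, hit calling, enzyme activity.

The screen couples geraniol oxidation by geraniol dehydrogenase (GeDH) to
NAD+ -> NADH reduction, read as absorbance gain at 340 nm.  For each well the
signal is dOD340, by default the endpoint difference over the kinetic window
(a max-slope option over a sliding window is available for early-saturating
wells).  Standards at known geraniol concentrations give an ordinary
least-squares calibration line; sample wells are scored relative to the mean
reference-well signal and called hits at a fold threshold (default 1.5,
boundary inclusive).  Specific activity converts a kinetic slope to
micromoles NADH per minute per milligram enzyme via Beer's law with the
standard NADH molar extinction coefficient (6220 1/M/cm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

NADH_EXTINCTION_M_CM = 6220.0

#: Dilution of fermentation broth 1:1 with enzyme reaction buffer; reporting
#: broth concentrations multiplies assay concentrations by this factor.
BROTH_DILUTION_FACTOR = 2.0


@dataclass
class PlateWell:
    strain: str
    role: str  # sample | reference | standard | blank
    times_min: np.ndarray
    od340: np.ndarray
    concentration: float | None = None  # mg/l, standards only
    well: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        y = np.asarray(self.od340, dtype=float)
        if t.size != y.size or t.size < 2:
            raise ValueError("need >= 2 (time, OD340) points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        self.times_min, self.od340 = t, y


def delta_od(well: PlateWell, method: str = "endpoint", window: int = 5) -> float:
    """Signal per well: endpoint difference, or max slope x window span."""
    if method == "endpoint":
        return float(well.od340[-1] - well.od340[0])
    if method == "max_slope":
        t, y = well.times_min, well.od340
        if t.size <= window:
            return float(y[-1] - y[0])
        slopes = [
            stats.linregress(t[i : i + window], y[i : i + window]).slope
            for i in range(t.size - window + 1)
        ]
        return float(max(slopes) * (t[-1] - t[0]))
    raise ValueError(f"unknown delta method {method!r}")


@dataclass
class CalibrationModel:
    slope: float  # dOD340 per mg/l
    intercept: float
    r_squared: float
    valid_range: tuple[float, float]  # mg/l

    def concentration(self, d_od: float, broth: bool = False) -> float:
        """Invert the line; refuses extrapolation outside the calibrated range."""
        c = (d_od - self.intercept) / self.slope
        lo, hi = self.valid_range
        if not (lo - 1e-9 <= c <= hi + 1e-9):
            raise ValueError(
                f"concentration {c:.3g} mg/l outside calibrated range [{lo}, {hi}]"
            )
        return c * (BROTH_DILUTION_FACTOR if broth else 1.0)


def delta_od_and_calibrate(
    standards: Sequence[PlateWell],
    blanks: Sequence[PlateWell] = (),
    method: str = "endpoint",
) -> CalibrationModel:
    """OLS line of dOD340 against standard concentration (blank-corrected)."""
    concs = [w.concentration for w in standards]
    if any(c is None for c in concs):
        raise ValueError("standard wells need a concentration")
    if len(set(concs)) < 3:
        raise ValueError("need >= 3 distinct standard concentrations")
    blank = float(np.mean([delta_od(w, method) for w in blanks])) if blanks else 0.0
    x = np.array(concs, dtype=float)
    y = np.array([delta_od(w, method) - blank for w in standards])
    if np.ptp(x) == 0:
        raise ValueError("zero concentration spread")
    fit = stats.linregress(x, y)
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        valid_range=(float(x.min()), float(x.max())),
    )


def call_hits(
    samples: Sequence[PlateWell],
    references: Sequence[PlateWell],
    fold_threshold: float = 1.5,
    calibration: CalibrationModel | None = None,
    method: str = "endpoint",
) -> pd.DataFrame:
    """Relative dOD340 against the mean reference well; hits at >= fold_threshold."""
    if not references:
        raise ValueError("need >= 1 reference well")
    ref = float(np.mean([delta_od(w, method) for w in references]))
    if ref <= 0:
        raise ValueError("non-positive reference signal")
    rows = []
    for w in samples:
        d = delta_od(w, method)
        rel = d / ref
        conc = None
        if calibration is not None:
            try:
                conc = calibration.concentration(d)
            except ValueError:
                conc = np.nan
        rows.append(
            {
                "well": w.well,
                "strain": w.strain,
                "delta_od": d,
                "relative_delta_od": rel,
                "is_hit": rel >= fold_threshold,
                "concentration_mg_per_l": conc,
            }
        )
    return pd.DataFrame(rows)


def specific_activity(
    slope_od_per_min: float,
    extinction_m_cm: float = NADH_EXTINCTION_M_CM,
    path_length_cm: float = 1.0,
    volume_l: float = 1e-4,
    enzyme_mg: float = 1.81e-4,
) -> float:
    """Specific activity in U/mg (umol NADH / min / mg enzyme, 1:1 with geraniol).

    activity = slope / (extinction x path) x volume x 1e6 / mass.
    """
    if min(extinction_m_cm, path_length_cm, volume_l, enzyme_mg) <= 0:
        raise ValueError("extinction, path length, volume and mass must be > 0")
    molar_per_min = slope_od_per_min / (extinction_m_cm * path_length_cm)
    umol_per_min = molar_per_min * volume_l * 1e6
    return umol_per_min / enzyme_mg


def load_plate_csv(path) -> list[PlateWell]:
    """Long-format CSV: well, strain, role, concentration (optional), time_min, od340."""
    df = pd.read_csv(path)
    required = {"well", "strain", "role", "time_min", "od340"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    wells = []
    for (well, strain, role), grp in df.groupby(["well", "strain", "role"], sort=False):
        grp = grp.sort_values("time_min")
        conc = None
        if "concentration" in grp.columns and grp["concentration"].notna().any():
            conc = float(grp["concentration"].iloc[0])
        wells.append(
            PlateWell(
                strain=str(strain),
                role=str(role),
                times_min=grp["time_min"].to_numpy(),
                od340=grp["od340"].to_numpy(),
                concentration=conc,
                well=str(well),
            )
        )
    return wells
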