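"""Closed-form assay arithmetic and the fluorescence-ratio estimator.

Three of these operations are exact bookkeeping on plate-reader /
respirometry readouts: complex-IV-dependent respiration (azide-sensitive
OCR), kinetic background subtraction, and COX-1 fold change normalised to
Janus-green cell counts. The fourth estimates the fraction of a cell's
mitochondrial content that is exogenous from two fluorescence channels —
a donor-specific marker (Dendra2, labelling only transferred mitochondria)
ratioed against a total-mitochondria stain (MitoTracker), calibrated on
fully-exogenous control cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, InvalidParameterError


@dataclass(frozen=True)
class OCRMeasurement:
    """Oxygen consumption rates (pmol O2/min) before and after azide."""

    ocr_tmpd_asc: float
    ocr_azide: float


@dataclass(frozen=True)
class KineticTrace:
    """A 590 nm kinetic absorbance trace and its matched no-substrate blank."""

    timepoints: tuple
    absorbance: tuple
    background: tuple

    def __post_init__(self) -> None:
        if not (len(self.timepoints) == len(self.absorbance) == len(self.background)):
            raise InvalidParameterError(
                "timepoints, absorbance and background must have equal length"
            )
        t = np.asarray(self.timepoints, dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise InvalidParameterError("timepoints must be strictly increasing")


@dataclass(frozen=True)
class Cox1Reading:
    """COX-1 immunoassay OD with its Janus-green cell-number normaliser."""

    cox1_signal: float
    janus_signal: float

    def __post_init__(self) -> None:
        if not self.janus_signal > 0:
            raise InvalidParameterError("janus_signal must be > 0")


def civ_respiration(m: OCRMeasurement) -> float:
    """Complex IV-dependent respiration: TMPD/ascorbate OCR minus the
    azide-insensitive residual.

    A negative result (azide rate above the substrate-driven rate) is
    returned as-is with a warning — it usually indicates instrument drift
    or a failed injection, and silent clamping would hide that.
    """
    rate = m.ocr_tmpd_asc - m.ocr_azide
    if rate < 0:
        warnings.warn(
            "complex IV respiration is negative (azide OCR exceeds TMPD/ASC "
            "OCR); check injections/drift",
            stacklevel=2,
        )
    return rate


def background_subtract(trace: KineticTrace) -> np.ndarray:
    """Pointwise no-substrate background subtraction of a kinetic trace.

    Negative corrected values are kept (and flagged with a warning) so that
    downstream slope fits see the raw instrument behaviour.
    """
    corrected = np.asarray(trace.absorbance, dtype=float) - np.asarray(
        trace.background, dtype=float
    )
    if np.any(corrected < 0):
        warnings.warn(
            "background exceeds signal at some timepoints", stacklevel=2
        )
    return corrected


def cox1_fold_change(treated: Cox1Reading, control: Cox1Reading) -> float:
    """Fold change of cell-number-normalised COX-1 signal.

    ``(treated.cox1 / treated.janus) / (control.cox1 / control.janus)``.
    """
    control_ratio = control.cox1_signal / control.janus_signal
    if control_ratio == 0:
        raise InvalidParameterError("control COX-1 signal is zero")
    return (treated.cox1_signal / treated.janus_signal) / control_ratio


_PANEL_COLUMNS = [
    "cell_id",
    "dendra2_intensity",
    "mitotracker_intensity",
    "dtomato_positive",
    "is_calibration",
]


@dataclass
class FluorescencePanel:
    """Per-cell two-channel intensities with fully-exogenous controls.

    ``cells`` holds one row per cell with columns ``cell_id``,
    ``dendra2_intensity`` (donor-mitochondria channel, a.u.),
    ``mitotracker_intensity`` (total-mitochondria channel, a.u.),
    ``dtomato_positive`` (lineage marker; recipient cells are negative) and
    ``is_calibration`` (cells whose mitochondrial content is entirely
    donor-derived, used to estimate the channel gain).
    """

    cells: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_PANEL_COLUMNS) - set(self.cells.columns)
        if missing:
            raise InvalidParameterError(f"panel missing columns: {sorted(missing)}")
        if len(self.cells) == 0:
            raise InvalidParameterError("fluorescence panel is empty")
        if (self.cells["dendra2_intensity"] < 0).any() or (
            self.cells["mitotracker_intensity"] < 0
        ).any():
            raise InvalidParameterError("intensities must be >= 0")

    @property
    def calibration(self) -> pd.DataFrame:
        return self.cells[self.cells["is_calibration"]]

    @property
    def recipients(self) -> pd.DataFrame:
        sel = ~self.cells["is_calibration"] & ~self.cells["dtomato_positive"]
        return self.cells[sel]

    def to_tsv(self, path: str | Path) -> None:
        self.cells.to_csv(path, sep="\t", index=False, columns=_PANEL_COLUMNS)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FluorescencePanel":
        df = pd.read_csv(path, sep="\t")
        for col in ("dtomato_positive", "is_calibration"):
            if col in df.columns:
                df[col] = df[col].astype(bool)
        return cls(cells=df)


@dataclass(frozen=True)
class ExoMitoEstimate:
    """Percent exogenous mitochondrial content with a bootstrap interval."""

    percent: float
    ci95: tuple[float, float]
    n_recipient_cells: int
    n_calibration_cells: int
    gain: float


def exo_mito_fraction(
    panel: FluorescencePanel,
    min_cells: int = 10,
    n_bootstrap: int = 500,
    seed: int = 0,
) -> ExoMitoEstimate:
    """Estimate percent exogenous mitochondrial content from a panel.

    The donor channel reads ``gain x (exogenous mito)`` while the total
    stain reads total mito, so on fully-exogenous calibration cells the
    per-cell ratio dendra2/mitotracker estimates the gain ``g``. For each
    recipient cell the exogenous fraction is then
    ``(dendra2 / g) / mitotracker``; the reported value is 100 x the median
    across recipient cells, with a percentile bootstrap 95% interval.
    Medians are used throughout because single-cell intensities are heavy-
    tailed (approximately lognormal).
    """
    cal = panel.calibration
    rec = panel.recipients
    if len(cal) < min_cells:
        raise CalibrationError(
            f"need >= {min_cells} calibration cells, found {len(cal)}"
        )
    if len(rec) < min_cells:
        raise InvalidParameterError(
            f"need >= {min_cells} recipient cells, found {len(rec)}"
        )
    cal_ok = cal["mitotracker_intensity"] > 0
    if not cal_ok.any():
        raise CalibrationError("all calibration cells have zero total signal")
    gain = float(
        np.median(
            cal.loc[cal_ok, "dendra2_intensity"]
            / cal.loc[cal_ok, "mitotracker_intensity"]
        )
    )
    if gain <= 0:
        raise CalibrationError("estimated channel gain is not positive")

    rec_ok = rec[rec["mitotracker_intensity"] > 0]
    fractions = (
        rec_ok["dendra2_intensity"].to_numpy()
        / gain
        / rec_ok["mitotracker_intensity"].to_numpy()
    )
    point = 100.0 * float(np.median(fractions))

    rng = np.random.default_rng(seed)
    n = len(fractions)
    boots = np.median(
        fractions[rng.integers(0, n, size=(n_bootstrap, n))], axis=1
    )
    lo, hi = 100.0 * np.quantile(boots, [0.025, 0.975])
    return ExoMitoEstimate(
        percent=point,
        ci95=(float(lo), float(hi)),
        n_recipient_cells=n,
        n_calibration_cells=int(cal_ok.sum()),
        gain=gain,
    )


def fit_slope(timepoints: Sequence[float], values: Sequence[float]) -> float:
    """Least-squares slope of a kinetic trace (signal units per minute)."""
    coeffs = np.polyfit(np.asarray(timepoints, float), np.asarray(values, float), 1)
    return float(coeffs[0])
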