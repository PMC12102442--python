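"""Conversion of raw tracer measurements into bacterial carbon fluxes.

Bacterial production (BP) is derived from ³H-leucine incorporation using a
leucine-to-carbon conversion factor of 0.37 kg C mol⁻¹ Leu, so that a rate in
nmol Leu L⁻¹ d⁻¹ maps directly to mg C m⁻³ d⁻¹.  Community respiration is
derived from the in vitro INT-formazan reduction rate of the whole community
(INT_T) through the empirical log-log calibration

    log10 CR_O2 = 0.72 · log10 INT_T + 0.44

and the bacterial share is taken as the 0.2–0.8 µm size fraction,
BR_O2 = CR_O2 · INT_0.2–0.8 / INT_T.  Oxygen consumption converts to carbon
at a respiratory quotient of 1 mol C per mol O₂ with an atomic mass of
12.011 µg C µmol⁻¹.  Cell-specific rates divide the volumetric rates by
bacterial abundance (cells mL⁻¹) and are reported in fg C cell⁻¹ d⁻¹.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConversionConstants",
    "RateInputError",
    "CalibrationError",
    "RateWarning",
    "blank_correct",
    "apply_standard_curve",
    "leucine_to_bp",
    "int_to_cr",
    "partition_br",
    "o2_to_carbon",
    "cell_specific",
    "compute_rate_panel",
    "PANEL_COLUMNS",
]

#: 1 mg C m⁻³ equals 10⁶ fg C mL⁻¹ (used for cell-specific rates).
_FG_PER_ML_PER_MG_PER_M3 = 1.0e6

PANEL_COLUMNS = ["sample_id", "bp", "cr_o2", "br", "cs_bp", "cs_br"]


class RateInputError(ValueError):
    """Raised for invalid raw measurement values."""


class CalibrationError(ValueError):
    """Raised for an unusable standard curve or calibration constant."""


class RateWarning(UserWarning):
    """Non-fatal data-quality flag (e.g. blank exceeding sample absorbance)."""


@dataclass(frozen=True)
class ConversionConstants:
    """Constants of the rate conversions; defaults are the published values.

    Attributes
    ----------
    leu_to_c:
        Leucine-to-carbon conversion factor, kg C mol⁻¹ Leu.
    cal_slope, cal_intercept:
        Slope and intercept of the log10–log10 INT_T → CR_O2 calibration.
    rq:
        Respiratory quotient, mol C produced per mol O₂ consumed.
    c_atomic_mass:
        Carbon atomic mass, µg C µmol⁻¹.
    """

    leu_to_c: float = 0.37
    cal_slope: float = 0.72
    cal_intercept: float = 0.44
    rq: float = 1.0
    c_atomic_mass: float = 12.011

    def __post_init__(self) -> None:
        for name in ("leu_to_c", "cal_slope", "cal_intercept", "rq", "c_atomic_mass"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise CalibrationError(f"{name} must be finite and > 0, got {value!r}")


DEFAULT_CONSTANTS = ConversionConstants()


def _check_finite_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise RateInputError(f"{name} must be finite and >= 0, got {value!r}")
    return value


def blank_correct(abs_sample: float, abs_blank: float) -> float:
    """Subtract the killed-control absorbance from the live-sample absorbance.

    A negative difference (blank exceeding sample, possible through instrument
    noise) is clamped to zero and flagged with a :class:`RateWarning`.
    """
    abs_sample = _check_finite_nonneg("abs_sample", abs_sample)
    abs_blank = _check_finite_nonneg("abs_blank", abs_blank)
    diff = abs_sample - abs_blank
    if diff < 0:
        warnings.warn(
            f"blank absorbance {abs_blank} exceeds sample absorbance "
            f"{abs_sample}; clamping corrected value to 0",
            RateWarning,
            stacklevel=2,
        )
        return 0.0
    return diff


def apply_standard_curve(absorbance: float, slope: float, intercept: float) -> float:
    """Invert a linear absorbance standard curve to an INT-formazan concentration.

    ``concentration = (absorbance - intercept) / slope``, clamped at zero.
    """
    if not (math.isfinite(slope) and slope > 0):
        raise CalibrationError(f"standard-curve slope must be > 0, got {slope!r}")
    absorbance = _check_finite_nonneg("absorbance", absorbance)
    return max((absorbance - intercept) / slope, 0.0)


def leucine_to_bp(leu: float, constants: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Convert leucine incorporation (nmol Leu L⁻¹ d⁻¹) to BP (mg C m⁻³ d⁻¹).

    1 nmol L⁻¹ d⁻¹ × 1 kg C mol⁻¹ = 1 µg C L⁻¹ d⁻¹ = 1 mg C m⁻³ d⁻¹, so the
    conversion is multiplication by ``leu_to_c``.
    """
    leu = _check_finite_nonneg("leu_incorporation", leu)
    return leu * constants.leu_to_c


def int_to_cr(int_total: float, constants: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Convert total INT reduction (µmol INT L⁻¹ d⁻¹) to community respiration.

    Applies ``CR_O2 = 10^(cal_slope·log10(INT_T) + cal_intercept)`` in
    µmol O₂ L⁻¹ d⁻¹.  The log form is undefined at zero: a measured zero must
    be mapped to CR_O2 = 0 explicitly by the caller rather than silently here.
    """
    int_total = float(int_total)
    if not math.isfinite(int_total) or int_total <= 0:
        raise RateInputError(
            f"int_total must be > 0 for the log-log calibration, got {int_total!r}"
        )
    return 10.0 ** (constants.cal_slope * math.log10(int_total) + constants.cal_intercept)


def partition_br(cr_o2: float, int_02_08: float, int_total: float) -> float:
    """Bacterial share of community respiration via the INT size fractions.

    ``BR_O2 = CR_O2 · INT_0.2–0.8 / INT_T`` (µmol O₂ L⁻¹ d⁻¹).
    """
    cr_o2 = _check_finite_nonneg("cr_o2", cr_o2)
    int_02_08 = _check_finite_nonneg("int_02_08", int_02_08)
    int_total = float(int_total)
    if not math.isfinite(int_total) or int_total <= 0:
        raise RateInputError(f"int_total must be > 0, got {int_total!r}")
    if int_02_08 > int_total:
        raise RateInputError(
            f"bacterial INT fraction {int_02_08} exceeds total {int_total}"
        )
    return cr_o2 * (int_02_08 / int_total)


def o2_to_carbon(rate_o2: float, constants: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Convert an O₂ consumption rate (µmol O₂ L⁻¹ d⁻¹) to carbon units.

    ``C = rate_o2 · RQ · 12.011`` µg C L⁻¹ d⁻¹ = mg C m⁻³ d⁻¹.
    """
    rate_o2 = _check_finite_nonneg("rate_o2", rate_o2)
    return rate_o2 * constants.rq * constants.c_atomic_mass


def cell_specific(rate: float, ba: float) -> float:
    """Divide a volumetric rate (mg C m⁻³ d⁻¹) by abundance (cells mL⁻¹).

    Returns fg C cell⁻¹ d⁻¹ (1 mg C m⁻³ = 10⁶ fg C mL⁻¹).
    """
    rate = _check_finite_nonneg("rate", rate)
    ba = float(ba)
    if not math.isfinite(ba) or ba <= 0:
        raise RateInputError(f"bacterial abundance must be > 0, got {ba!r}")
    return rate * _FG_PER_ML_PER_MG_PER_M3 / ba


def compute_rate_panel(
    inputs: pd.DataFrame,
    constants: ConversionConstants = DEFAULT_CONSTANTS,
) -> tuple[pd.DataFrame, dict]:
    """Compute a per-sample rate panel from raw tracer inputs.

    Parameters
    ----------
    inputs:
        One row per sample with columns ``sample_id``, ``leu_incorporation``
        (nmol Leu L⁻¹ d⁻¹), ``int_total`` and ``int_02_08`` (µmol INT L⁻¹ d⁻¹)
        and ``ba`` (cells mL⁻¹).  Missing values (NaN) propagate to the
        corresponding outputs; they are never coerced to zero.  An
        ``int_total`` measured as exactly 0 maps to CR_O2 = BR = 0.
    constants:
        Conversion constants; defaults are the published values.

    Returns
    -------
    (panel, report):
        ``panel`` has columns ``sample_id, bp, cr_o2, br, cs_bp, cs_br``
        (mg C m⁻³ d⁻¹, µmol O₂ L⁻¹ d⁻¹, fg C cell⁻¹ d⁻¹).  Samples with
        invalid measurements are dropped from the panel and recorded in
        ``report["errors"]`` as ``{"sample_id": ..., "error": ...}``.
    """
    required = {"sample_id", "leu_incorporation", "int_total", "int_02_08", "ba"}
    missing_cols = required - set(inputs.columns)
    if missing_cols:
        raise RateInputError(f"missing input columns: {sorted(missing_cols)}")
    if inputs["sample_id"].duplicated().any():
        dupes = inputs.loc[inputs["sample_id"].duplicated(), "sample_id"].tolist()
        raise RateInputError(f"duplicate sample_id values: {dupes}")

    rows = []
    errors: list[dict] = []
    flags: list[dict] = []
    for rec in inputs.itertuples(index=False):
        sid = rec.sample_id
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", RateWarning)
                row = _panel_row(rec, constants)
            for w in caught:
                flags.append({"sample_id": sid, "warning": str(w.message)})
        except (RateInputError, CalibrationError) as exc:
            errors.append({"sample_id": sid, "error": str(exc)})
            continue
        rows.append(row)

    panel = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    report = {
        "n_input": int(len(inputs)),
        "n_computed": int(len(panel)),
        "errors": errors,
        "warnings": flags,
    }
    return panel, report


def _panel_row(rec, constants: ConversionConstants) -> dict:
    ba = float(rec.ba)
    if not (math.isfinite(ba) and ba > 0):
        raise RateInputError(f"bacterial abundance must be > 0, got {ba!r}")

    leu = float(rec.leu_incorporation)
    if math.isnan(leu):
        bp = cs_bp = float("nan")
    else:
        bp = leucine_to_bp(leu, constants)
        cs_bp = cell_specific(bp, ba)

    int_total = float(rec.int_total)
    int_02_08 = float(rec.int_02_08)
    if math.isnan(int_total):
        cr = br = cs_br = float("nan")
    elif int_total == 0.0:
        # a true zero measurement sits outside the log-log calibration domain
        if not math.isnan(int_02_08) and int_02_08 > 0:
            raise RateInputError(
                f"bacterial INT fraction {int_02_08} exceeds total 0.0"
            )
        cr = br = cs_br = 0.0
    else:
        cr = int_to_cr(int_total, constants)
        if math.isnan(int_02_08):
            br = cs_br = float("nan")
        else:
            br_o2 = partition_br(cr, int_02_08, int_total)
            br = o2_to_carbon(br_o2, constants)
            cs_br = cell_specific(br, ba)

    return {
        "sample_id": rec.sample_id,
        "bp": bp,
        "cr_o2": cr,
        "br": br,
        "cs_bp": cs_bp,
        "cs_br": cs_br,
    }
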