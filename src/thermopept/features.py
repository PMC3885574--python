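"""Per-sample thermogram shape and feature metrics.

Eight quantitative descriptors of a final-stage thermogram: total peak
area, height, width at half height, the temperature of the peak maximum
(T_max), the first-moment temperature (T_FM, the area centroid of the
profile), the excess heat capacities of the primary (60-65 °C) and
secondary (68-72 °C) transitions, and their ratio.  T_FM is the geometric
centre of the thermogram and responds to redistribution of area even when
T_max does not move.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ThermogramRecord

#: temperature window of the primary (albumin-dominated) transition
PEAK1_WINDOW = (60.0, 65.0)
#: temperature window of the secondary (globulin-dominated) transition
PEAK2_WINDOW = (68.0, 72.0)

METRIC_NAMES = (
    "area",
    "width",
    "height",
    "t_max",
    "t_fm",
    "cp_peak1",
    "cp_peak2",
    "ratio",
)


@dataclass(frozen=True)
class MetricSet:
    """The eight shape/feature metrics of one thermogram."""

    area: float       # cal/g
    width: float      # °C, full width at half the global maximum
    height: float     # cal/°C·g, global maximum
    t_max: float      # °C
    t_fm: float       # °C, first-moment (centroid) temperature
    cp_peak1: float   # cal/°C·g, max in 60-65 °C
    cp_peak2: float   # cal/°C·g, max in 68-72 °C
    ratio: float      # cp_peak1 / cp_peak2

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def first_moment_temperature(thermogram: ThermogramRecord) -> float:
    """Area-weighted mean temperature, trapezoidal rule on the final grid.

    ``T_FM = ∫ T·Cp(T) dT / ∫ Cp(T) dT`` over the 45-90 °C window.
    """
    thermogram.require_stage("final")
    t, v = thermogram.temperatures, thermogram.values
    total = np.trapezoid(v, t)
    if total <= 0:
        raise ValueError("total thermogram area must be positive for T_FM")
    return float(np.trapezoid(t * v, t) / total)


def _crossing(t0, v0, t1, v1, level):
    # linear interpolation of the temperature at which v crosses level
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def width_at_half_height(thermogram: ThermogramRecord) -> float:
    """Full width of the envelope at half the global maximum.

    The first and last crossings of half-height are each located by linear
    interpolation between the bracketing grid points; for multimodal
    profiles the width spans the whole envelope.
    """
    thermogram.require_stage("final")
    t, v = thermogram.temperatures, thermogram.values
    peak = v.max()
    if peak <= 0:
        raise ValueError("thermogram maximum must be positive")
    half = peak / 2.0
    above = v >= half
    first = int(np.argmax(above))
    last = int(len(v) - 1 - np.argmax(above[::-1]))
    if first == 0 or last == len(v) - 1:
        raise ValueError(
            "curve does not fall below half height on both flanks; "
            "width is unbounded within the analysis window"
        )
    t_first = _crossing(t[first - 1], v[first - 1], t[first], v[first], half)
    t_last = _crossing(t[last], v[last], t[last + 1], v[last + 1], half)
    return float(t_last - t_first)


def peak_window_amplitudes(
    thermogram: ThermogramRecord,
) -> tuple[float, float, float]:
    """Amplitudes of the primary and secondary transitions and their ratio.

    Each amplitude is the maximum value inside the fixed window (robust to
    sub-degree drift of the transition midpoint).  A non-positive secondary
    amplitude leaves the ratio undefined (NaN, with a warning).
    """
    thermogram.require_stage("final")
    t, v = thermogram.temperatures, thermogram.values
    in1 = (t >= PEAK1_WINDOW[0]) & (t <= PEAK1_WINDOW[1])
    in2 = (t >= PEAK2_WINDOW[0]) & (t <= PEAK2_WINDOW[1])
    cp1 = float(v[in1].max())
    cp2 = float(v[in2].max())
    if cp2 <= 0:
        warnings.warn(
            "secondary transition amplitude is non-positive; ratio undefined",
            stacklevel=2,
        )
        return cp1, cp2, float("nan")
    return cp1, cp2, cp1 / cp2


def compute_metrics(thermogram: ThermogramRecord) -> MetricSet:
    """All eight metrics of one final-stage thermogram.

    ``t_max`` ties are broken to the lowest temperature; all integrals are
    trapezoidal on the common grid.
    """
    thermogram.require_stage("final")
    t, v = thermogram.temperatures, thermogram.values
    if v.max() <= 0:
        raise ValueError("thermogram has no positive signal; metrics undefined")
    area = float(np.trapezoid(v, t))
    height = float(v.max())
    t_max = float(t[np.argmax(v)])  # argmax returns the first (lowest-T) tie
    t_fm = first_moment_temperature(thermogram)
    width = width_at_half_height(thermogram)
    cp1, cp2, ratio = peak_window_amplitudes(thermogram)
    return MetricSet(
        area=area,
        width=width,
        height=height,
        t_max=t_max,
        t_fm=t_fm,
        cp_peak1=cp1,
        cp_peak2=cp2,
        ratio=ratio,
    )


def compute_metrics_table(
    thermograms: dict[str, ThermogramRecord]
) -> pd.DataFrame:
    """Metrics for a cohort: one row per sample, with sample_id and group."""
    rows = []
    for sample_id, rec in thermograms.items():
        row = {"sample_id": sample_id, "group": rec.group}
        row.update(compute_metrics(rec).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
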