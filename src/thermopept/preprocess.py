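"""DSC thermogram preprocessing.

Raw paired scans are turned into final analysis-ready thermograms by a
fixed-order pipeline: buffer-reference subtraction, normalisation by total
protein mass, linear baseline correction anchored in pre- and
post-transition windows, and truncation/resampling to the common 45-90 °C
grid on which all shape metrics are defined.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synthetic import DEFAULT_CELL_VOLUME_UL

#: processing stages, in the only order the pipeline accepts
STAGES = (
    "raw",
    "reference_subtracted",
    "normalized",
    "baseline_corrected",
    "final",
)

#: the analysis window spanning the complete denaturation profile
ANALYSIS_RANGE = (45.0, 90.0)
ANALYSIS_STEP = 0.1

# default anchor windows for the linear baseline fit, outside the
# denaturation envelope
DEFAULT_PRE_WINDOW = (45.0, 50.0)
DEFAULT_POST_WINDOW = (85.0, 90.0)


@dataclass(frozen=True)
class ThermogramRecord:
    """A thermogram at a given processing stage.

    Units of ``values`` depend on stage: raw scans are absolute heat
    capacities (cal/°C); from ``normalized`` on they are excess specific
    heat capacities (cal/°C·g).
    """

    sample_id: str
    group: str | None
    temperatures: np.ndarray
    values: np.ndarray
    stage: str
    protein_conc: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "values", v)
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing 1-D")
        if v.shape != t.shape:
            raise ValueError("values and temperatures shapes differ")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("thermogram contains non-finite values")

    def require_stage(self, stage: str) -> None:
        if self.stage != stage:
            raise ValueError(
                f"expected a {stage!r}-stage record, got {self.stage!r}"
            )


@dataclass(frozen=True)
class BaselineFit:
    """The linear instrumental baseline removed from a scan."""

    slope: float
    intercept: float
    residual_sd: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t, dtype=float)


def subtract_reference(
    sample: ThermogramRecord, buffer: ThermogramRecord
) -> ThermogramRecord:
    """Correct for the instrumental baseline with a buffer reference scan.

    The buffer is linearly interpolated onto the sample grid when the grids
    differ; the output is restricted to the overlapping temperature range,
    which must cover the 45-90 °C analysis window.
    """
    sample.require_stage("raw")
    buffer.require_stage("raw")
    lo = max(sample.temperatures[0], buffer.temperatures[0])
    hi = min(sample.temperatures[-1], buffer.temperatures[-1])
    if lo > ANALYSIS_RANGE[0] or hi < ANALYSIS_RANGE[1]:
        raise ValueError(
            f"scan overlap [{lo}, {hi}] does not cover the "
            f"{ANALYSIS_RANGE} °C analysis window"
        )
    keep = (sample.temperatures >= lo) & (sample.temperatures <= hi)
    t = sample.temperatures[keep]
    buffer_on_sample = np.interp(t, buffer.temperatures, buffer.values)
    return replace(
        sample,
        temperatures=t,
        values=sample.values[keep] - buffer_on_sample,
        stage="reference_subtracted",
    )


def normalize_concentration(
    scan: ThermogramRecord,
    protein_conc: float | None = None,
    cell_volume_ul: float = DEFAULT_CELL_VOLUME_UL,
) -> ThermogramRecord:
    """Normalise for total protein, yielding cal/(°C·g).

    The in-cell protein mass is ``protein_conc`` (g/L) times the thermal
    sensing volume (default 135 µL).
    """
    scan.require_stage("reference_subtracted")
    if protein_conc is None:
        protein_conc = scan.protein_conc
    if protein_conc is None or protein_conc <= 0:
        raise ValueError("protein_conc must be positive")
    mass_g = protein_conc * cell_volume_ul * 1e-6
    return replace(
        scan,
        values=scan.values / mass_g,
        stage="normalized",
        protein_conc=protein_conc,
    )


def correct_linear_baseline(
    scan: ThermogramRecord,
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
    post_window: tuple[float, float] = DEFAULT_POST_WINDOW,
) -> tuple[ThermogramRecord, BaselineFit]:
    """Remove a non-zero linear baseline fitted in two anchor windows.

    A least-squares line through the points of the pre- and post-transition
    windows is subtracted from the whole scan.  Windows must avoid the
    55-80 °C denaturation envelope.
    """
    scan.require_stage("normalized")
    for name, (a, b) in (("pre", pre_window), ("post", post_window)):
        if a >= b:
            raise ValueError(f"{name}_window must be an increasing pair")
        if a < scan.temperatures[0] - 1e-9 or b > scan.temperatures[-1] + 1e-9:
            raise ValueError(f"{name}_window lies outside the scan grid")
        if max(a, 55.0) < min(b, 80.0):
            raise ValueError(
                f"{name}_window overlaps the 55-80 °C denaturation envelope"
            )
    t = scan.temperatures
    mask = ((t >= pre_window[0]) & (t <= pre_window[1])) | (
        (t >= post_window[0]) & (t <= post_window[1])
    )
    pre_n = np.count_nonzero((t >= pre_window[0]) & (t <= pre_window[1]))
    post_n = np.count_nonzero((t >= post_window[0]) & (t <= post_window[1]))
    if pre_n < 2 or post_n < 2:
        raise ValueError("each anchor window needs at least 2 grid points")
    slope, intercept = np.polyfit(t[mask], scan.values[mask], 1)
    fitted = intercept + slope * t
    residual_sd = float(np.std(scan.values[mask] - fitted[mask], ddof=2))
    corrected = replace(
        scan, values=scan.values - fitted, stage="baseline_corrected"
    )
    return corrected, BaselineFit(float(slope), float(intercept), residual_sd)


def final_grid(
    t_range: tuple[float, float] = ANALYSIS_RANGE, step: float = ANALYSIS_STEP
) -> np.ndarray:
    n = int(round((t_range[1] - t_range[0]) / step)) + 1
    return np.linspace(t_range[0], t_range[1], n)


def truncate_and_resample(
    scan: ThermogramRecord,
    t_range: tuple[float, float] = ANALYSIS_RANGE,
    step: float = ANALYSIS_STEP,
) -> ThermogramRecord:
    """Truncate to the analysis range and resample on the uniform grid."""
    scan.require_stage("baseline_corrected")
    if scan.temperatures[0] > t_range[0] or scan.temperatures[-1] < t_range[1]:
        raise ValueError(
            f"scan [{scan.temperatures[0]}, {scan.temperatures[-1]}] does "
            f"not cover the analysis range {t_range}"
        )
    grid = final_grid(t_range, step)
    values = np.interp(grid, scan.temperatures, scan.values)
    return replace(scan, temperatures=grid, values=values, stage="final")


def average_duplicates(scans: list[ThermogramRecord]) -> ThermogramRecord:
    """Average duplicate final-stage scans of one sample pointwise."""
    if not scans:
        raise ValueError("no scans to average")
    for s in scans:
        s.require_stage("final")
        if not np.array_equal(s.temperatures, scans[0].temperatures):
            raise ValueError("duplicate scans must share the final grid")
    values = np.mean([s.values for s in scans], axis=0)
    return replace(scans[0], values=values)


def process_scan(
    sample: ThermogramRecord,
    buffer: ThermogramRecord,
    protein_conc: float | None = None,
    cell_volume_ul: float = DEFAULT_CELL_VOLUME_UL,
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
    post_window: tuple[float, float] = DEFAULT_POST_WINDOW,
) -> ThermogramRecord:
    """Run the full fixed-order preprocessing chain on one scan pair."""
    out = subtract_reference(sample, buffer)
    out = normalize_concentration(out, protein_conc, cell_volume_ul)
    out, _ = correct_linear_baseline(out, pre_window, post_window)
    return truncate_and_resample(out)


def process_cohort(records, **kwargs) -> dict[str, ThermogramRecord]:
    """Process a cohort of (sample, buffer) scan pairs to final thermograms.

    ``records`` maps sample_id to either one (sample, buffer) pair or a list
    of duplicate pairs, which are averaged after the final stage.
    """
    finals = {}
    for sample_id, pairs in records.items():
        if isinstance(pairs, tuple):
            pairs = [pairs]
        processed = [process_scan(s, b, **kwargs) for s, b in pairs]
        finals[sample_id] = average_duplicates(processed)
    return finals
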