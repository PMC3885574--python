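"""Synthetic cohorts: plasma DSC thermograms and MALDI-TOF peptide spectra.

Patient-level raw data for this kind of study are rarely deposited, so the
package ships a generator that emulates the statistical structure the
downstream analyses assume: multi-transition plasma denaturation profiles
whose control shape has a dominant transition near 62 °C and a secondary
transition near 70 °C, with disease modelled as a progressive thermal
stabilisation (shift) of the primary species plus a redistribution of its
area to the secondary species; and peptide mass spectra in 900-3000 m/z
carrying a panel of planted marker masses with group-dependent abundances
on top of shared nuisance peaks, a decaying chemical baseline and noise.

Everything is a pure function of its spec plus an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# gas constant in calorimetric units, cal/(mol*K)
R_CAL = 1.987

# van't Hoff enthalpy of the disease-stabilised complex species: broader
# than its parent transitions, reflecting the heterogeneity of ligated
# albumin, and what lets the disease envelope widen with burden
COMPLEX_DH_VH = 90_000.0

#: the five clinical groups of the thermogram study, in disease order
THERMO_GROUPS = ("control", "LSIL", "HSIL", "StageI", "StageII_IV")

#: the three groups of the peptidome study
MS_GROUPS = ("Control", "CIN 2", "Cerv Ca")

#: peptide fraction labels (plasma fractions plus urine)
FRACTIONS = ("FX1", "FX2", "FX3", "FX4", "urine")


# ---------------------------------------------------------------------------
# thermogram model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionSpec:
    """One two-state denaturation transition of a plasma component.

    Parameters
    ----------
    label : str
        Component name (informational).
    tm : float
        Midpoint temperature in °C.
    dh_vh : float
        Van't Hoff enthalpy in cal/mol; controls transition sharpness.
    dh_cal : float
        Calorimetric enthalpy per gram of this component (cal/g); controls
        the area the component contributes.
    mass_fraction : float
        Fraction of total protein mass carried by this component.
    is_primary, is_secondary : bool
        Flags the ~62 °C primary (albumin-like) and ~70 °C secondary
        (globulin-like) species targeted by the disease model.
    """

    label: str
    tm: float
    dh_vh: float
    dh_cal: float
    mass_fraction: float
    is_primary: bool = False
    is_secondary: bool = False

    def __post_init__(self) -> None:
        if not 20.0 < self.tm < 110.0:
            raise ValueError(f"tm must lie in (20, 110) °C, got {self.tm}")
        if self.dh_vh <= 0 or self.dh_cal <= 0:
            raise ValueError("enthalpies must be positive")
        if not 0.0 <= self.mass_fraction <= 1.0:
            raise ValueError("mass_fraction must lie in [0, 1]")


def two_state_excess_heat_capacity(t, spec: TransitionSpec) -> np.ndarray:
    """Excess specific heat capacity of a two-state transition, cal/(°C·g).

    For native <-> denatured with equilibrium constant
    ``K(T) = exp(-(dh_vh/R) * (1/T - 1/Tm))`` (T in kelvin), the excess heat
    capacity is ``dh_cal * dh_vh/(R T^2) * K/(1+K)^2``.  The curve peaks at
    ``Tm`` with height ``dh_cal*dh_vh/(4 R Tm^2)`` and integrates to
    ``dh_cal`` over temperature.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("temperature grid contains non-finite values")
    T = t + 273.15
    tm_k = spec.tm + 273.15
    x = (spec.dh_vh / R_CAL) * (1.0 / T - 1.0 / tm_k)
    # K/(1+K)^2 = 1/(4 cosh^2(x/2)); sech form avoids overflow in exp(x)
    with np.errstate(over="ignore"):
        shape = 0.25 / np.cosh(0.5 * x) ** 2
    return spec.dh_cal * (spec.dh_vh / (R_CAL * T**2)) * shape


@dataclass(frozen=True)
class MixtureSpec:
    """A plasma protein mixture plus instrument nuisance parameters.

    ``albumin_shift`` (°C) is added to the Tm of transitions flagged
    ``is_primary``; ``redistribution`` moves that fraction of the primary
    transition's mass into a thermally stabilised complex species whose
    midpoint sits ``albumin_shift`` above the ``is_secondary`` transition,
    so the positive lobe of disease-minus-control difference curves both
    grows and moves to higher temperature with disease burden.  With both
    knobs zero the disease generator reduces exactly to the control
    generator.
    ``baseline_offset``/``baseline_slope`` set the mean instrumental
    baseline (cal/°C·g and cal/°C²·g); ``noise_sd`` the additive Gaussian
    noise level (cal/°C·g).
    """

    transitions: tuple[TransitionSpec, ...]
    albumin_shift: float = 0.0
    redistribution: float = 0.0
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        object.__setattr__(self, "transitions", tuple(self.transitions))
        if not self.transitions:
            raise ValueError("mixture needs at least one transition")
        if not 0.0 <= self.redistribution < 1.0:
            raise ValueError("redistribution must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        total = sum(tr.mass_fraction for tr in self.transitions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions must sum to 1, got {total}")

    def effective_transitions(self) -> tuple[TransitionSpec, ...]:
        """Transitions after applying the disease shift and redistribution."""
        shifted: list[TransitionSpec] = []
        complexes: list[TransitionSpec] = []
        secondary = next(
            (tr for tr in self.transitions if tr.is_secondary), None
        )
        for tr in self.transitions:
            if tr.is_primary:
                if self.redistribution > 0.0:
                    if secondary is None:
                        raise ValueError(
                            "redistribution requires an is_secondary "
                            "transition as anchor"
                        )
                    # moved primary mass reappears as a stabilised complex
                    # above the secondary species
                    complexes.append(
                        replace(
                            tr,
                            label=f"{tr.label} complex",
                            tm=secondary.tm + self.albumin_shift,
                            dh_vh=COMPLEX_DH_VH,
                            mass_fraction=tr.mass_fraction
                            * self.redistribution,
                            is_primary=False,
                        )
                    )
                shifted.append(
                    replace(
                        tr,
                        tm=tr.tm + self.albumin_shift,
                        mass_fraction=tr.mass_fraction
                        * (1.0 - self.redistribution),
                    )
                )
            else:
                shifted.append(tr)
        return tuple(shifted + complexes)

    def specific_area(self) -> float:
        """Pre-noise, pre-baseline thermogram area, cal/g of total protein."""
        return sum(
            tr.mass_fraction * tr.dh_cal for tr in self.effective_transitions()
        )

    def excess_heat_capacity(self, t) -> np.ndarray:
        """Noise-free mixture curve in cal/(°C·g), no baseline."""
        t = np.asarray(t, dtype=float)
        total = np.zeros_like(t)
        for tr in self.effective_transitions():
            total += tr.mass_fraction * two_state_excess_heat_capacity(t, tr)
        return total


# Default control mixture: five two-state species emulating the abundant
# plasma proteins (fibrinogen-like shoulder ~51 °C, dominant albumin-like
# transition at 62.2 °C, globulin-like secondary at 70 °C and two high-
# temperature immunoglobulin-like shoulders).  Enthalpies and fractions were
# fixed once, numerically, so that the processed control profile reproduces
# the published healthy-plasma anchor values: area ~4.94 cal/g, first-moment
# temperature ~66.3 °C, peak maximum 62.2 °C and a primary/secondary
# amplitude ratio ~2.2.
_CONTROL_COMPONENTS = (
    # label, tm (°C), dh_vh (cal/mol), area contribution (cal/g), fraction
    ("fibrinogen", 55.0, 200_000.0, 0.26, 0.06),
    ("albumin", 62.2, 160_000.0, 2.45, 0.55, True, False),
    ("globulins", 70.0, 120_000.0, 1.50, 0.24, False, True),
    ("transferrin/IgA", 75.5, 140_000.0, 0.35, 0.08),
    ("IgG/IgM", 79.0, 250_000.0, 0.38, 0.07),
)


def default_control_mixture(
    noise_sd: float = 0.005,
    baseline_offset: float = 0.05,
    baseline_slope: float = 0.001,
) -> MixtureSpec:
    """The calibrated healthy-control plasma mixture."""
    transitions = []
    for comp in _CONTROL_COMPONENTS:
        label, tm, dh_vh, area, frac = comp[:5]
        flags = comp[5:] or (False, False)
        transitions.append(
            TransitionSpec(
                label=label,
                tm=tm,
                dh_vh=dh_vh,
                dh_cal=area / frac,
                mass_fraction=frac,
                is_primary=flags[0],
                is_secondary=flags[1],
            )
        )
    return MixtureSpec(
        transitions=tuple(transitions),
        baseline_offset=baseline_offset,
        baseline_slope=baseline_slope,
        noise_sd=noise_sd,
    )


@dataclass(frozen=True)
class CohortSpec:
    """One clinical group of a simulated thermogram cohort."""

    group_label: str
    n_samples: int
    mixture: MixtureSpec
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_label not in THERMO_GROUPS:
            raise ValueError(
                f"group_label must be one of {THERMO_GROUPS}, "
                f"got {self.group_label!r}"
            )
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


# Disease progression defaults: primary-transition stabilisation shift (°C)
# and area redistribution to the secondary species increase monotonically
# from control to advanced carcinoma, the qualitative mechanism behind the
# progressive thermogram changes the study reports.
DEFAULT_SHIFTS = {
    "control": 0.0,
    "LSIL": 1.5,
    "HSIL": 1.5,
    "StageI": 2.5,
    "StageII_IV": 3.5,
}
DEFAULT_REDISTRIBUTIONS = {
    "control": 0.0,
    "LSIL": 0.12,
    "HSIL": 0.22,
    "StageI": 0.38,
    "StageII_IV": 0.55,
}
# group sizes of the study cohort: 4 controls, 3 CIN1 (LSIL),
# 4+3+22 CIN2/CIN2-3/CIN3 (HSIL), 14 Stage I, 10+7+4 Stage II-IV
DEFAULT_GROUP_SIZES = {
    "control": 4,
    "LSIL": 3,
    "HSIL": 29,
    "StageI": 14,
    "StageII_IV": 21,
}


def default_cohort_specs(
    n_per_group: int | None = None,
    shifts: dict[str, float] | None = None,
    redistributions: dict[str, float] | None = None,
    noise_sd: float = 0.005,
) -> list[CohortSpec]:
    """Five-group cohort specs with the default disease progression."""
    shifts = dict(DEFAULT_SHIFTS if shifts is None else shifts)
    redis = dict(
        DEFAULT_REDISTRIBUTIONS if redistributions is None else redistributions
    )
    base = default_control_mixture(noise_sd=noise_sd)
    specs = []
    for group in THERMO_GROUPS:
        n = DEFAULT_GROUP_SIZES[group] if n_per_group is None else n_per_group
        mixture = replace(
            base,
            albumin_shift=shifts[group],
            redistribution=redis[group],
        )
        specs.append(CohortSpec(group_label=group, n_samples=n, mixture=mixture))
    return specs


def default_temperature_grid(
    start: float = 20.0, stop: float = 110.0, step: float = 0.1
) -> np.ndarray:
    """Uniform scan grid; default 20-110 °C at 0.1 °C."""
    n = int(round((stop - start) / step)) + 1
    return np.linspace(start, stop, n)


# per-scan jitter ranges for the instrumental baseline draw
_BASELINE_OFFSET_JITTER = 0.05   # cal/°C·g
_BASELINE_SLOPE_JITTER = 0.001   # cal/°C²·g

#: thermal sensing volume of the capillary cell, µL
DEFAULT_CELL_VOLUME_UL = 135.0
#: 25-fold diluted plasma total protein, g/L
DEFAULT_PROTEIN_CONC_G_PER_L = 2.8


def simulate_plasma_thermogram(
    mixture: MixtureSpec,
    grid: np.ndarray | None = None,
    rng_seed: int = 0,
    protein_conc: float = DEFAULT_PROTEIN_CONC_G_PER_L,
    cell_volume_ul: float = DEFAULT_CELL_VOLUME_UL,
    sample_id: str = "sample",
    group: str | None = None,
    baseline_jitter: tuple[float, float] = (
        _BASELINE_OFFSET_JITTER,
        _BASELINE_SLOPE_JITTER,
    ),
):
    """Simulate one raw DSC scan and its matched buffer reference scan.

    The per-gram signal is the mixture curve plus a per-scan linear
    instrumental baseline and i.i.d. Gaussian noise; the buffer scan carries
    an independently drawn baseline and noise but no protein signal.  Raw
    records are scaled to absolute heat capacity (cal/°C) by the in-cell
    protein mass so that concentration normalisation downstream recovers
    cal/(°C·g).

    Returns
    -------
    (sample, buffer) : tuple of ThermogramRecord
        Both at stage ``raw``, with ``protein_conc`` attached to the sample.
    """
    from .preprocess import ThermogramRecord  # local import: avoid cycle

    if grid is None:
        grid = default_temperature_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("temperature grid must be 1-D and strictly increasing")
    if grid[0] > 45.0 or grid[-1] < 90.0:
        raise ValueError("grid must cover at least 45-90 °C")

    rng = np.random.default_rng(rng_seed)
    mass_g = protein_conc * cell_volume_ul * 1e-6  # g in the cell

    signal = mixture.excess_heat_capacity(grid)

    def draw_baseline() -> np.ndarray:
        offset = mixture.baseline_offset + rng.uniform(
            -baseline_jitter[0], baseline_jitter[0]
        )
        slope = mixture.baseline_slope + rng.uniform(
            -baseline_jitter[1], baseline_jitter[1]
        )
        return offset + slope * (grid - grid[0])

    noise_s = rng.normal(0.0, mixture.noise_sd, size=grid.size)
    noise_b = rng.normal(0.0, mixture.noise_sd, size=grid.size)
    sample_vals = (signal + draw_baseline() + noise_s) * mass_g
    buffer_vals = (draw_baseline() + noise_b) * mass_g

    sample = ThermogramRecord(
        sample_id=sample_id,
        group=group,
        temperatures=grid,
        values=sample_vals,
        stage="raw",
        protein_conc=protein_conc,
    )
    buffer = ThermogramRecord(
        sample_id=f"{sample_id}_buffer",
        group=group,
        temperatures=grid,
        values=buffer_vals,
        stage="raw",
    )
    return sample, buffer


def simulate_cohort(
    specs: list[CohortSpec],
    seed: int = 0,
    grid: np.ndarray | None = None,
    protein_conc: float = DEFAULT_PROTEIN_CONC_G_PER_L,
    cell_volume_ul: float = DEFAULT_CELL_VOLUME_UL,
):
    """Simulate a full thermogram cohort.

    Deterministic given ``(specs, seed)``; each sample draws from a
    substream derived from the master seed and its (group, sample) index so
    that cohorts are reproducible under subsetting.

    Returns
    -------
    manifest : pandas.DataFrame
        Columns sample_id, group, protein_conc_g_per_L.
    records : dict[str, tuple[ThermogramRecord, ThermogramRecord]]
        sample_id -> (raw sample scan, matched buffer scan).
    """
    labels = [s.group_label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels in cohort specs")
    if grid is None:
        grid = default_temperature_grid()

    rows = []
    records = {}
    for g_idx, spec in enumerate(specs):
        for s_idx in range(spec.n_samples):
            sub = np.random.SeedSequence(
                entropy=seed, spawn_key=(g_idx, s_idx)
            )
            sample_seed = sub.generate_state(1)[0]
            sample_id = f"{spec.group_label}_{s_idx + 1:03d}"
            pair = simulate_plasma_thermogram(
                spec.mixture,
                grid=grid,
                rng_seed=sample_seed,
                protein_conc=protein_conc,
                cell_volume_ul=cell_volume_ul,
                sample_id=sample_id,
                group=spec.group_label,
            )
            records[sample_id] = pair
            rows.append(
                {
                    "sample_id": sample_id,
                    "group": spec.group_label,
                    "protein_conc_g_per_L": protein_conc,
                }
            )
    manifest = pd.DataFrame(rows)
    return manifest, records


# ---------------------------------------------------------------------------
# MALDI-TOF peptide spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeptidePanelEntry:
    """A planted marker peptide with its group abundance pattern."""

    mz: float
    group_means: dict[str, float] = field(compare=False)
    pattern: str = ""

    def __post_init__(self) -> None:
        if not 900.0 <= self.mz <= 3000.0:
            raise ValueError(f"panel m/z must lie in [900, 3000], got {self.mz}")
        if any(v < 0 for v in self.group_means.values()):
            raise ValueError("group mean intensities must be >= 0")


def default_peptide_panel() -> list[PeptidePanelEntry]:
    """The 15-peptide differential panel with its group abundance patterns.

    Mean intensities (arbitrary units) are chosen to realise each pattern:
    absent groups get mean 0, "=" pairs equal means, ">" at least two-fold.
    """
    C, N, V = MS_GROUPS  # Control, CIN 2, Cerv Ca
    rows = [
        (904.53, {C: 0, N: 100, V: 100}, f"Absent in {C}; {V} = {N}"),
        (1097.49, {C: 100, N: 100, V: 40}, f"{N} = {C}>{V}"),
        (1126.503, {C: 25, N: 145, V: 60}, f"{N}>{V}>{C}"),
        (1192.67, {C: 0, N: 80, V: 80}, f"Absent in {C}; {V} = {N}"),
        (1236.56, {C: 60, N: 150, V: 25}, f"{N}>{C}>{V}"),
        (1425.65, {C: 0, N: 100, V: 40}, f"Absent in {C}; {N}>{V}"),
        (1524.71, {C: 35, N: 105, V: 35}, f"{N}>{V} = {C}"),
        (1530.91, {C: 70, N: 0, V: 70}, f"Absent in {N}; {V} = {C}"),
        (1587.97, {C: 60, N: 150, V: 25}, f"{N}>{C}>{V}"),
        (1746.78, {C: 130, N: 45, V: 45}, f"{C}>{V} = {N}"),
        (1943.93, {C: 100, N: 0, V: 0}, f"Absent in {V}; Absent in {N}; {C}"),
        (2080.98, {C: 110, N: 0, V: 0}, f"Absent in {V}; Absent in {N}; {C}"),
        (2209.06, {C: 130, N: 45, V: 45}, f"{C}>{V} = {N}"),
        (2228.05, {C: 110, N: 0, V: 45}, f"Absent in {N}; {C}>{V}"),
        (2271.13, {C: 110, N: 40, V: 40}, f"{C}>{V} = {N}"),
    ]
    return [
        PeptidePanelEntry(mz=mz, group_means=means, pattern=pat)
        for mz, means, pat in rows
    ]


@dataclass(frozen=True)
class MaldiParams:
    """Nuisance structure of a simulated MALDI-TOF peptide spectrum."""

    mz_start: float = 900.0
    mz_stop: float = 3000.0
    mz_step: float = 0.5
    peak_sigma: float = 0.25          # Th, Gaussian peak width
    n_nuisance: int = 200             # shared non-differential peaks
    nuisance_mean: float = 60.0       # mean nuisance amplitude
    baseline_amplitude: float = 20.0  # chemical baseline at 900 m/z
    baseline_scale: float = 400.0     # exponential decay length, Th
    noise_sd: float = 2.0             # additive detector noise
    biological_cv: float = 0.25       # per-sample lognormal sigma
    spot_cv: float = 0.10             # per-replicate (spot) lognormal sigma


@dataclass(frozen=True)
class Spectrum:
    """One MALDI-TOF spectrum (profile-mode peak list)."""

    sample_id: str
    group: str
    fraction: str
    replicate: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)
        if mz.ndim != 1 or mz.size == 0 or np.any(np.diff(mz) <= 0):
            raise ValueError("mz must be 1-D and strictly increasing")
        if intensity.shape != mz.shape:
            raise ValueError("intensity and mz shapes differ")
        if np.any(intensity < 0):
            raise ValueError("intensities must be >= 0")
        if self.fraction not in FRACTIONS:
            raise ValueError(f"fraction must be one of {FRACTIONS}")


def simulate_maldi_cohort(
    panel: list[PeptidePanelEntry],
    groups: tuple[str, ...] = MS_GROUPS,
    n_per_group: int = 4,
    replicates: int = 3,
    params: MaldiParams | None = None,
    seed: int = 0,
    fraction: str = "FX2",
) -> list[Spectrum]:
    """Simulate spotted-in-triplicate MALDI spectra for a labelled cohort.

    Each spectrum is a sum of Gaussian peaks at the panel masses (group mean
    x per-sample biological factor x per-spot factor), nuisance peaks drawn
    once and shared by all groups, a smooth exponentially decaying chemical
    baseline, and additive Gaussian noise clipped at zero.
    """
    if not panel:
        raise ValueError("peptide panel must not be empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if params is None:
        params = MaldiParams()

    rng = np.random.default_rng(seed)
    n_grid = int(round((params.mz_stop - params.mz_start) / params.mz_step)) + 1
    mz = np.linspace(params.mz_start, params.mz_stop, n_grid)
    baseline = params.baseline_amplitude * np.exp(
        -(mz - params.mz_start) / params.baseline_scale
    )

    # nuisance peaks: positions and amplitudes shared across all groups;
    # kept at least 4 m/z off the planted masses so each marker's +/-1-bin
    # peak cluster stays free of confounding signal (markers a real study
    # could not resolve from background would never make a Table of calls)
    planted = np.array([p.mz for p in panel])
    nuisance_mz = []
    while len(nuisance_mz) < params.n_nuisance:
        cand = rng.uniform(params.mz_start + 5, params.mz_stop - 5)
        if np.min(np.abs(planted - cand)) > 4.0:
            nuisance_mz.append(cand)
    nuisance_mz = np.array(nuisance_mz)
    nuisance_amp = rng.lognormal(
        mean=math.log(params.nuisance_mean), sigma=0.5, size=params.n_nuisance
    )

    def add_peak(profile, center, amplitude):
        lo = np.searchsorted(mz, center - 5 * params.peak_sigma)
        hi = np.searchsorted(mz, center + 5 * params.peak_sigma)
        window = mz[lo:hi]
        profile[lo:hi] += amplitude * np.exp(
            -0.5 * ((window - center) / params.peak_sigma) ** 2
        )

    spectra = []
    for group in groups:
        for s_idx in range(n_per_group):
            sample_id = f"{group.replace(' ', '')}_{s_idx + 1:02d}"
            # per-sample biological variation of every peak
            bio_panel = rng.lognormal(0.0, params.biological_cv, size=len(panel))
            bio_nuis = rng.lognormal(
                0.0, params.biological_cv, size=params.n_nuisance
            )
            for rep in range(1, replicates + 1):
                spot = rng.lognormal(0.0, params.spot_cv)
                profile = baseline.copy()
                for p_idx, entry in enumerate(panel):
                    mean = entry.group_means.get(group, 0.0)
                    if mean > 0:
                        add_peak(profile, entry.mz, mean * bio_panel[p_idx] * spot)
                for n_idx in range(params.n_nuisance):
                    add_peak(
                        profile,
                        nuisance_mz[n_idx],
                        nuisance_amp[n_idx] * bio_nuis[n_idx] * spot,
                    )
                profile += rng.normal(0.0, params.noise_sd, size=mz.size)
                np.clip(profile, 0.0, None, out=profile)
                spectra.append(
                    Spectrum(
                        sample_id=sample_id,
                        group=group,
                        fraction=fraction,
                        replicate=rep,
                        mz=mz,
                        intensity=profile,
                    )
                )
    return spectra
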