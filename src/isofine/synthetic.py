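"""Forward model: synthetic profile spectra with exact fine structure.

Emulates the broad-isolation high-energy MS/MS acquisition used for
immonium-ion isotope-ratio measurements: a fixed number of ions per fill
(automatic gain control), several microscans co-added per reported
spectrum, Gaussian peaks whose width follows the Orbitrap resolution
model, a calibration offset with per-scan jitter, and additive baseline
noise. Ion counts are shot-noise limited: the total per spectrum is
exactly AGC x microscans, allocated multinomially over species (by molar
abundance) and over isotopologue lines (exact independent-site fine
structure up to M+2, with carbon-bonded and exchangeable hydrogens at
separately specified deuterium levels).

Every rendered line is recorded in a ground-truth ledger so recovery can
be tested against the planted values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import spectra_io
from .isotope_chem import (
    AbundanceSet,
    ImmoniumSpecies,
    isotopologue_distribution,
)
from .spectra_io import ProfileSpectrum

__all__ = [
    "SimInstrument",
    "SimSpeciesSpec",
    "SimRun",
    "effective_abundances",
    "simulate_spectrum",
    "iter_spectra",
    "simulate_run",
    "write_mzml",
    "infusion_mix",
    "titration_mix",
    "depletion_mix",
]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))
_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class SimInstrument:
    """Acquisition settings of the simulated analyzer.

    ``agc_target`` ions are accumulated per fill and ``microscans`` fills
    are averaged per reported spectrum. The profile grid is uniform per
    rendering window at FWHM/``grid_oversampling`` of the window start, so
    every peak is sampled by at least ~5 points.
    """

    resolution: float = 60000.0
    ref_mz: float = 200.0
    agc_target: int = 50_000
    microscans: int = 20
    mz_range: tuple[float, float] = (50.0, 200.0)
    cal_offset_ppm: float = 0.0
    jitter_ppm: float = 0.2
    baseline_sd: float = 0.1
    grid_oversampling: float = 8.0
    hcd_energy: float = 50.0
    isolation_center: float = 800.0
    isolation_width: float = 1000.0
    convention: str = "h_atom"

    def __post_init__(self) -> None:
        if min(
            self.resolution, self.agc_target, self.microscans,
            self.grid_oversampling,
        ) <= 0:
            raise ValueError("instrument parameters must be positive")

    def fwhm(self, mz: float) -> float:
        return mz / (self.resolution * math.sqrt(self.ref_mz / mz))


@dataclass(frozen=True)
class SimSpeciesSpec:
    """One species in a simulated mixture.

    ``abundances`` holds the planted heavy/light ratios; its ``"H"`` entry
    is the carbon-bonded 2H/1H while ``exchangeable_ppm`` pins the
    solvent-equilibrated sites (heteroatom hydrogens + ionizing proton).
    """

    species: ImmoniumSpecies
    abundance: float = 1.0
    abundances: AbundanceSet = field(default_factory=AbundanceSet.rounded_natural)
    exchangeable_ppm: float = 150.0

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("species molar abundance must be positive")

    def site_abundances(self) -> AbundanceSet:
        return self.abundances.with_ratio("Hx", self.exchangeable_ppm * 1e-6)


def effective_abundances(
    base: AbundanceSet,
    media_ppm: float,
    incorporation_frac: float,
    baseline_ppm: float = 150.0,
    control_ppm: float = 150.0,
) -> AbundanceSet:
    """C-bonded deuterium level under a labeled-media scenario.

    A fraction ``incorporation_frac`` of C-bonded hydrogens equilibrates
    with the growth media, so the C-bonded 2H/1H rises linearly with the
    media deuterium content above the control level.
    """
    if not (0.0 <= incorporation_frac <= 1.0):
        raise ValueError("incorporation_frac must lie in [0, 1]")
    if media_ppm < 0:
        raise ValueError("media_ppm must be >= 0")
    ppm = baseline_ppm + incorporation_frac * (media_ppm - control_ppm)
    if ppm <= 0:
        raise ValueError(f"resulting 2H/1H {ppm} ppm is not positive")
    return base.with_ratio("H", ppm * 1e-6)


@dataclass
class SimRun:
    """Rendered spectra plus the ground-truth ledger.

    ``truth`` has one row per (scan, species, line) with the exact ion
    count allocated to that line; ``planted`` maps species name to its
    :class:`SimSpeciesSpec`.
    """

    spectra: list[ProfileSpectrum]
    truth: pd.DataFrame
    planted: dict[str, SimSpeciesSpec]
    instrument: SimInstrument


def _species_lines(spec: SimSpeciesSpec, convention: str):
    comp = spec.species.site_composition()
    lines = isotopologue_distribution(comp, spec.site_abundances(), max_shell=2)
    base_mz = spec.species.mz(convention)
    probs = np.array([ln.probability for ln in lines])
    return lines, base_mz, probs / probs.sum()


def simulate_spectrum(
    mix: Sequence[SimSpeciesSpec],
    instrument: SimInstrument,
    rng: np.random.Generator | int,
    scan_index: int = 1,
    rt_s: float = 0.0,
) -> tuple[ProfileSpectrum, list[dict]]:
    """Render one profile scan and return it with its truth-ledger rows."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lo_range, hi_range = instrument.mz_range
    usable: list[tuple[SimSpeciesSpec, list, float, np.ndarray]] = []
    for spec in mix:
        lines, base_mz, probs = _species_lines(spec, instrument.convention)
        if not (lo_range <= base_mz <= hi_range):
            warnings.warn(
                f"{spec.species.name} at m/z {base_mz:.4f} outside the "
                f"detected range {instrument.mz_range}; skipped",
                stacklevel=2,
            )
            continue
        usable.append((spec, lines, base_mz, probs))
    if not usable:
        raise ValueError("no species inside the detected m/z range")

    weights = np.array([spec.abundance for spec, *_ in usable])
    weights = weights / weights.sum()
    p_all = np.concatenate([w * probs for w, (_, _, _, probs) in zip(weights, usable)])
    p_all = p_all / p_all.sum()
    total_ions = instrument.agc_target * instrument.microscans
    counts = rng.multinomial(total_ions, p_all)

    scale = 1.0 + (
        instrument.cal_offset_ppm + rng.normal(0.0, instrument.jitter_ppm)
    ) * 1e-6

    # rendering windows around each species, merged when overlapping
    windows = sorted(
        (base_mz - 1.0, base_mz + 2.6) for _, _, base_mz, _ in usable
    )
    merged: list[list[float]] = []
    for lo, hi in windows:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    grids = [
        np.arange(lo, hi, instrument.fwhm(lo) / instrument.grid_oversampling)
        for lo, hi in merged
    ]
    mz = np.concatenate(grids)
    intensity = np.zeros_like(mz)

    truth_rows: list[dict] = []
    offset = 0
    for spec, lines, base_mz, _ in usable:
        name = spec.species.name
        for ln in lines:
            count = int(counts[offset])
            offset += 1
            pos = (base_mz + ln.delta_m) * scale
            sigma = instrument.fwhm(pos) / _FWHM_TO_SIGMA
            if count > 0:
                lo_i = np.searchsorted(mz, pos - 6.0 * sigma)
                hi_i = np.searchsorted(mz, pos + 6.0 * sigma)
                x = mz[lo_i:hi_i]
                intensity[lo_i:hi_i] += (
                    count
                    / instrument.microscans
                    / (sigma * _SQRT_2PI)
                    * np.exp(-0.5 * ((x - pos) / sigma) ** 2)
                )
            truth_rows.append(
                {
                    "scan_index": scan_index,
                    "species": name,
                    "label": ln.label,
                    "count": count,
                    "mz": pos,
                    "planted_ratio": ln.ratio,
                }
            )
    if instrument.baseline_sd > 0:
        intensity = intensity + rng.normal(0.0, instrument.baseline_sd, mz.size)
    intensity = np.maximum(intensity, 0.0)
    spectrum = ProfileSpectrum(
        mz=mz,
        intensity=intensity,
        scan_index=scan_index,
        rt_s=rt_s,
        ms_level=2,
        hcd_energy=instrument.hcd_energy,
        isolation_center=instrument.isolation_center,
        isolation_width=instrument.isolation_width,
        microscans=instrument.microscans,
        tic=float(np.trapezoid(intensity, mz)),
        resolution_setting=instrument.resolution,
        is_profile=True,
    )
    return spectrum, truth_rows


def iter_spectra(
    mix: Sequence[SimSpeciesSpec],
    instrument: SimInstrument,
    n_spectra: int,
    seed: int | np.random.Generator,
    mode: str = "infusion",
    elution: dict[str, tuple[float, float]] | None = None,
    rt_step: float = 2.0,
) -> Iterator[tuple[ProfileSpectrum, list[dict]]]:
    """Yield scans one at a time (memory-friendly for long runs).

    ``mode="infusion"`` keeps the mixture constant; ``mode="lc"``
    modulates each species' molar abundance with a Gaussian elution
    profile ``elution[name] = (rt_center_s, rt_sigma_s)``.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if mode not in ("infusion", "lc"):
        raise ValueError(f"unknown mode {mode!r}")
    for i in range(n_spectra):
        rt = i * rt_step
        scan_mix = mix
        if mode == "lc":
            elution = elution or {}
            scan_mix = []
            for spec in mix:
                center, width = elution.get(spec.species.name, (0.0, math.inf))
                factor = math.exp(-0.5 * ((rt - center) / width) ** 2)
                if factor > 1e-12:
                    scan_mix.append(replace(spec, abundance=spec.abundance * factor))
            if not scan_mix:
                scan_mix = mix
        yield simulate_spectrum(scan_mix, instrument, rng, scan_index=i + 1, rt_s=rt)


def simulate_run(
    mix: Sequence[SimSpeciesSpec],
    instrument: SimInstrument,
    n_spectra: int,
    seed: int,
    mode: str = "infusion",
    elution: dict[str, tuple[float, float]] | None = None,
    rt_step: float = 2.0,
) -> SimRun:
    """Materialize a full run with its ground-truth ledger."""
    if n_spectra < 1:
        raise ValueError("n_spectra must be >= 1")
    spectra: list[ProfileSpectrum] = []
    rows: list[dict] = []
    for spectrum, truth in iter_spectra(
        mix, instrument, n_spectra, seed, mode, elution, rt_step
    ):
        spectra.append(spectrum)
        rows.extend(truth)
    return SimRun(
        spectra=spectra,
        truth=pd.DataFrame(rows),
        planted={spec.species.name: spec for spec in mix},
        instrument=instrument,
    )


def write_mzml(run: SimRun | Sequence[ProfileSpectrum], path: str | Path) -> None:
    """Write a simulated run (or bare spectrum list) as mzML 1.1."""
    spectra = run.spectra if isinstance(run, SimRun) else list(run)
    spectra_io.write_mzml(spectra, path)


# ---------------------------------------------------------------------------
# Scenario mixtures
# ---------------------------------------------------------------------------


def infusion_mix(
    registry: dict[str, ImmoniumSpecies],
    names: Sequence[str] = ("Pro", "Hyp", "Val"),
    abundances: AbundanceSet | None = None,
    solvent_ppm: float = 150.0,
    molar: Sequence[float] | None = None,
) -> list[SimSpeciesSpec]:
    """Free-amino-acid direct-infusion mixture at (by default) natural
    isotope abundances."""
    base = abundances or AbundanceSet.rounded_natural()
    molar = molar or [1.0] * len(names)
    return [
        SimSpeciesSpec(
            species=registry[n],
            abundance=m,
            abundances=base,
            exchangeable_ppm=solvent_ppm,
        )
        for n, m in zip(names, molar)
    ]


def titration_mix(
    registry: dict[str, ImmoniumSpecies],
    media_ppm: float,
    incorporation: dict[str, float] | None = None,
    control_ppm: float = 150.0,
    solvent_ppm: float = 150.0,
    base: AbundanceSet | None = None,
) -> list[SimSpeciesSpec]:
    """Deuterium-titration mixture (cell-lysate scenario).

    Default planted incorporation fractions: 4% for Leu/Ile and 15% for
    Pro — the levels at which the C-bonded 2H/1H rises with the media
    deuterium content.
    """
    incorporation = incorporation or {"Leu/Ile": 0.04, "Pro": 0.15}
    base = base or AbundanceSet.rounded_natural()
    mix = []
    for name, frac in incorporation.items():
        mix.append(
            SimSpeciesSpec(
                species=registry[name],
                abundance=1.0,
                abundances=effective_abundances(
                    base, media_ppm, frac, baseline_ppm=control_ppm,
                    control_ppm=control_ppm,
                ),
                exchangeable_ppm=solvent_ppm,
            )
        )
    return mix


def depletion_mix(
    registry: dict[str, ImmoniumSpecies],
    names: Sequence[str] = ("Pro", "Leu/Ile"),
    c_depletion: float = 20.0,
    n_depletion: float = 10.0,
    h_ppm: float = 80.0,
    solvent_ppm: float = 150.0,
) -> list[SimSpeciesSpec]:
    """Isotopically depleted growth scenario (depleted-media culture):
    13C and 15N at the stated depletion factors below natural, C-bonded
    2H at ``h_ppm``."""
    base = AbundanceSet.rounded_natural()
    depleted = AbundanceSet(
        {
            "C": base.ratio("C") / c_depletion,
            "N": base.ratio("N") / n_depletion,
            "H": h_ppm * 1e-6,
            "O": base.ratio("O"),
        },
        name="depleted",
    )
    return [
        SimSpeciesSpec(
            species=registry[n],
            abundances=depleted,
            exchangeable_ppm=solvent_ppm,
        )
        for n in names
    ]
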