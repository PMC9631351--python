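"""Fine-structure peak extraction from single profile spectra.

For each registered immonium ion the monoisotopic apex is located within a
ppm tolerance, the M+1 / M+2 fine-structure lines are placed relative to the
*observed* monoisotopic centroid (cancelling any calibration offset), and
component areas are estimated by non-negative linear least squares of
fixed-position, fixed-width Gaussians. Per-spectrum element ratios follow
from the area ratios divided by the number of substitutable atoms:

    r_X = A(M+1, X) / A(M) / n_X          (13C, 15N, 2H)
    r_O = A(M+2, 18O) / A(M) / n_O        (oxygen-bearing ions only)

The resolving power of an Orbitrap-type analyzer falls off as the inverse
square root of m/z; with the nominal setting R0 referenced at m/z 200,

    R(m/z) = R0 * sqrt(200 / m/z),    FWHM = m/z / R(m/z).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import nnls

from .isotope_chem import (
    AbundanceSet,
    ImmoniumSpecies,
    fine_structure_lines,
)
from .spectra_io import ProfileSpectrum

__all__ = [
    "InstrumentModel",
    "FinePeakMeasurement",
    "RatioRecord",
    "ExtractionResult",
    "resolution_fwhm",
    "is_resolved",
    "extract_fine_components",
    "spectrum_ratios",
    "extract_run",
    "run_mass_offset",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)
_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class InstrumentModel:
    """Resolution model and peak-lookup settings.

    ``resolution`` is the nominal setting at ``ref_mz``; ``tol_ppm`` is the
    monoisotopic lookup tolerance; ``kappa`` scales the FWHM in the
    resolvability test; ``neighbor_min_ratio`` is the minimum abundance of
    an unresolved neighbor (relative to the line itself, from the prior)
    for the overlap to be considered damaging.
    """

    resolution: float = 60000.0
    ref_mz: float = 200.0
    peak_shape: str = "gaussian"
    tol_ppm: float = 5.0
    kappa: float = 1.0
    # a merged neighbor below 1% of a line's own abundance biases its area
    # by well under the shot-noise floor and is ignored
    neighbor_min_ratio: float = 0.01

    def __post_init__(self) -> None:
        if self.resolution <= 0 or self.tol_ppm <= 0 or self.kappa <= 0:
            raise ValueError("resolution, tol_ppm and kappa must be positive")


def resolution_fwhm(
    mz: float, instrument: InstrumentModel
) -> tuple[float, float]:
    """(resolving power, FWHM in Da) at the given m/z."""
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    rp = instrument.resolution * math.sqrt(instrument.ref_mz / mz)
    return rp, mz / rp


def is_resolved(mz_a: float, mz_b: float, instrument: InstrumentModel) -> bool:
    """True iff the two line positions are separated by >= kappa * FWHM."""
    mid = 0.5 * (mz_a + mz_b)
    _, fwhm = resolution_fwhm(mid, instrument)
    return abs(mz_a - mz_b) >= instrument.kappa * fwhm


@dataclass(frozen=True)
class FinePeakMeasurement:
    species: str
    label: str
    expected_mz: float
    centroid_mz: float
    mass_error_ppm: float | None
    area: float
    area_sd: float
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return "unresolved" not in self.flags and "below_noise" not in self.flags


@dataclass(frozen=True)
class RatioRecord:
    """Per-spectrum, per-species measured isotope ratios (one datapoint)."""

    scan_index: int
    species: str
    rt_s: float | None = None
    tic: float | None = None
    area_m: float | None = None
    r_c: float | None = None
    r_h_raw: float | None = None
    r_n: float | None = None
    r_o: float | None = None
    mass_error_ppm: float | None = None
    flags: tuple[str, ...] = ()
    extras: dict = field(default_factory=dict)


@dataclass
class ExtractionResult:
    species: str
    found: bool
    reason: str | None
    anchor_mz: float | None
    noise_sd: float
    measurements: list[FinePeakMeasurement]


def _refine_centroid(
    mz: np.ndarray, intensity: np.ndarray, apex: int
) -> float:
    """Sub-grid apex position; log-parabola is exact for a Gaussian."""
    if apex <= 0 or apex >= mz.size - 1:
        return float(mz[apex])
    y = intensity[apex - 1 : apex + 2]
    if np.any(y <= 0):
        window = intensity[apex - 1 : apex + 2]
        return float(np.average(mz[apex - 1 : apex + 2], weights=window + 1e-30))
    x = mz[apex - 1 : apex + 2]
    a, b, _ = np.polyfit(x - x[1], np.log(y), 2)
    if a >= 0:
        return float(x[1])
    return float(x[1] - b / (2.0 * a))


def _noise_floor(
    spectrum: ProfileSpectrum, lo: float, hi: float
) -> float:
    """Robust noise SD in a signal-free strip of the profile.

    Uses the 84.1-50 inter-quantile distance, which estimates sigma both
    for plain Gaussian baseline noise and for noise clipped at zero (full
    profile mode stores no negative intensities).
    """
    sel = (spectrum.mz >= lo) & (spectrum.mz <= hi)
    if not np.any(sel):
        return 0.0
    y = spectrum.intensity[sel]
    q50, q84 = np.percentile(y, [50.0, 84.134])
    return float(q84 - q50)


def _fit_shell(
    spectrum: ProfileSpectrum,
    positions: Sequence[float],
    instrument: InstrumentModel,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NNLS fit of fixed Gaussians; returns (areas, area_sds, sigmas)."""
    sigmas = np.array(
        [resolution_fwhm(p, instrument)[1] / _FWHM_TO_SIGMA for p in positions]
    )
    lo = min(positions) - 4.0 * sigmas.max()
    hi = max(positions) + 4.0 * sigmas.max()
    sel = (spectrum.mz >= lo) & (spectrum.mz <= hi)
    x = spectrum.mz[sel]
    y = spectrum.intensity[sel]
    if x.size < len(positions) + 2:
        return (
            np.zeros(len(positions)),
            np.zeros(len(positions)),
            sigmas,
        )
    design = np.exp(
        -0.5 * ((x[:, None] - np.asarray(positions)[None, :]) / sigmas[None, :]) ** 2
    )
    amps, _ = nnls(design, y)
    areas = amps * sigmas * _SQRT_2PI
    # Amplitude covariance from the unconstrained normal equations; used
    # only as an indicative uncertainty.
    gram = design.T @ design
    try:
        diag = np.sqrt(np.clip(np.diag(np.linalg.inv(gram)), 0.0, None))
    except np.linalg.LinAlgError:
        diag = np.full(len(positions), np.nan)
    return areas, diag * sigmas * _SQRT_2PI, sigmas


def extract_fine_components(
    spectrum: ProfileSpectrum,
    species: ImmoniumSpecies,
    instrument: InstrumentModel,
    abundance_prior: AbundanceSet | None = None,
    convention: str = "h_atom",
    offset_ppm: float = 0.0,
) -> ExtractionResult:
    """Locate M and fit the M+1/M+2 fine-structure component areas.

    The shell lines are anchored at the observed monoisotopic centroid, so
    a run-level calibration offset (and per-scan jitter common to all
    peaks) cancels. Components are flagged ``unresolved`` when a neighbor
    of non-negligible prior abundance sits closer than kappa FWHM, and
    ``below_noise`` when the fitted amplitude is under 3x the local noise
    floor.
    """
    if not spectrum.is_profile:
        raise ValueError("profile-mode spectrum required for fine-structure fitting")
    prior = abundance_prior or AbundanceSet.natural()
    name = species.name
    target = species.mz(convention) * (1.0 + offset_ppm * 1e-6)
    rng = spectrum.mz_range
    if rng is None or rng[0] > target - 0.05 or rng[1] < target + 2.2:
        return ExtractionResult(name, False, "insufficient m/z coverage", None, 0.0, [])
    tol_da = instrument.tol_ppm * 1e-6 * target
    sel = np.flatnonzero(
        (spectrum.mz >= target - tol_da) & (spectrum.mz <= target + tol_da)
    )
    noise_sd = _noise_floor(spectrum, target + 0.30, target + 0.70)
    if sel.size == 0:
        return ExtractionResult(name, False, "not found", None, noise_sd, [])
    apex = int(sel[np.argmax(spectrum.intensity[sel])])
    # 5 sigma detection threshold for the monoisotopic apex: false peaks
    # from baseline noise are vanishingly rare at this level.
    if spectrum.intensity[apex] <= 5.0 * noise_sd or spectrum.intensity[apex] == 0.0:
        return ExtractionResult(name, False, "not found", None, noise_sd, [])
    anchor = _refine_centroid(spectrum.mz, spectrum.intensity, apex)
    mass_error = (anchor - target) / target * 1e6

    measurements: list[FinePeakMeasurement] = []
    m_area, m_sd, _ = _fit_shell(spectrum, [anchor], instrument)
    measurements.append(
        FinePeakMeasurement(
            species=name,
            label="M",
            expected_mz=target,
            centroid_mz=anchor,
            mass_error_ppm=mass_error,
            area=float(m_area[0]),
            area_sd=float(m_sd[0] * noise_sd),
            flags=() if m_area[0] > 0 else ("below_noise",),
        )
    )

    for shell in (1, 2):
        structure = fine_structure_lines(
            species, prior, shell, convention=convention
        )
        lines = structure.lines
        if not lines:
            continue
        positions = [anchor + ln.delta_m for ln in lines]
        areas, area_sds, sigmas = _fit_shell(spectrum, positions, instrument)
        for j, ln in enumerate(lines):
            flags: list[str] = []
            for k, other in enumerate(lines):
                if k == j:
                    continue
                significant = (
                    other.ratio >= instrument.neighbor_min_ratio * ln.ratio
                )
                if significant and not is_resolved(
                    positions[j], positions[k], instrument
                ):
                    flags.append("unresolved")
                    break
            amp = areas[j] / (sigmas[j] * _SQRT_2PI)
            if amp < 3.0 * noise_sd or areas[j] <= 0.0:
                flags.append("below_noise")
            measurements.append(
                FinePeakMeasurement(
                    species=name,
                    label=ln.label,
                    expected_mz=target + ln.delta_m,
                    centroid_mz=positions[j],
                    mass_error_ppm=None,
                    area=float(areas[j]),
                    area_sd=float(area_sds[j] * noise_sd),
                    flags=tuple(flags),
                )
            )
    return ExtractionResult(name, True, None, anchor, noise_sd, measurements)


def _area(
    result: ExtractionResult, label: str
) -> FinePeakMeasurement | None:
    for m in result.measurements:
        if m.label == label:
            return m
    return None


def spectrum_ratios(
    spectrum: ProfileSpectrum,
    species: ImmoniumSpecies,
    instrument: InstrumentModel,
    abundance_prior: AbundanceSet | None = None,
    convention: str = "h_atom",
    offset_ppm: float = 0.0,
) -> RatioRecord | None:
    """Per-spectrum isotope ratios for one species, or ``None`` if absent.

    Each ratio is the fine-structure component area normalized by the
    monoisotopic area and the number of substitutable atoms; components
    flagged unresolved or below the noise floor yield absent ratios.
    """
    res = extract_fine_components(
        spectrum, species, instrument, abundance_prior, convention, offset_ppm
    )
    if not res.found:
        return None
    mono = _area(res, "M")
    if mono is None or mono.area <= 0:
        return None

    def ratio(label: str, n_atoms: int) -> float | None:
        if n_atoms <= 0:
            return None
        m = _area(res, label)
        if m is None or not m.ok or m.area <= 0:
            return None
        return m.area / mono.area / n_atoms

    comp = species.composition
    flags = tuple(
        f"{m.label}:{f}" for m in res.measurements for f in m.flags
    )
    return RatioRecord(
        scan_index=spectrum.scan_index,
        species=species.name,
        rt_s=spectrum.rt_s,
        tic=spectrum.tic,
        area_m=mono.area,
        r_c=ratio("M1_13C", comp.get("C")),
        r_h_raw=ratio("M1_2H", comp.get("H")),
        r_n=ratio("M1_15N", comp.get("N")),
        r_o=ratio("M2_18O", comp.get("O")) if species.has_oxygen else None,
        mass_error_ppm=mono.mass_error_ppm,
        flags=flags,
    )


def run_mass_offset(
    spectra: Iterable[ProfileSpectrum],
    species_list: Sequence[ImmoniumSpecies],
    instrument: InstrumentModel,
    convention: str = "h_atom",
    max_scans: int = 50,
) -> float:
    """Median monoisotopic mass error (ppm) across a run.

    Used as a run-level recalibration pass: pass the returned value as
    ``offset_ppm`` to the extraction functions.
    """
    errors: list[float] = []
    for i, spec in enumerate(spectra):
        if i >= max_scans:
            break
        for sp in species_list:
            res = extract_fine_components(spec, sp, instrument, convention=convention)
            if res.found and res.measurements:
                err = res.measurements[0].mass_error_ppm
                if err is not None:
                    errors.append(err)
    return float(np.median(errors)) if errors else 0.0


def extract_run(
    spectra: Iterable[ProfileSpectrum],
    species_list: Sequence[ImmoniumSpecies],
    instrument: InstrumentModel,
    abundance_prior: AbundanceSet | None = None,
    convention: str = "h_atom",
    offset_ppm: float = 0.0,
) -> tuple[list[RatioRecord], dict[str, int]]:
    """Extract ratio records for every (scan, species) pair.

    Returns the records and a per-species count of skipped scans.
    """
    records: list[RatioRecord] = []
    skipped: dict[str, int] = {}
    for spec in spectra:
        for sp in species_list:
            if not sp.in_range:
                continue
            rec = spectrum_ratios(
                spec, sp, instrument, abundance_prior, convention, offset_ppm
            )
            if rec is None:
                skipped[sp.name] = skipped.get(sp.name, 0) + 1
            else:
                records.append(rec)
    return records, skipped
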