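"""Replicate statistics, delta values and diagnostic analyses.

Turns per-scan ratio records into solvent-corrected ratios, per-replicate
summaries, between-replicate coefficients of variation, delta values
against international reference standards, and the method's diagnostics:
ratio-vs-TIC trend, precision-vs-datapoint-count subsampling, deuterium
incorporation regression and the amino-acid contribution check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .isotope_chem import ImmoniumSpecies

__all__ = [
    "StandardSet",
    "ELEMENT_COLUMNS",
    "correct_exchangeable_h",
    "delta_value",
    "add_corrected_h",
    "trim_outliers",
    "aggregate_replicates",
    "summarize_elements",
    "cv_between_replicates",
    "tic_trend",
    "PrecisionCurve",
    "subsample_precision",
    "IncorporationFit",
    "incorporation_regression",
    "species_contributions",
]

# element -> column in the tidy records frame ("H" is the solvent-corrected,
# C-bonded ratio produced by add_corrected_h; "H_raw" the as-measured one)
ELEMENT_COLUMNS: dict[str, str] = {
    "C": "r_c",
    "N": "r_n",
    "H": "r_h",
    "H_raw": "r_h_raw",
    "O": "r_o",
}


@dataclass(frozen=True)
class StandardSet:
    """Reference isotope ratios for delta computation.

    Defaults are the standard literature values: VSMOW for 2H/1H and
    18O/16O, VPDB for 13C/12C, atmospheric N2 (AIR) for 15N/14N.
    """

    h: float = 1.5576e-4
    c: float = 1.11802e-2
    n: float = 3.6765e-3
    o: float = 2.0052e-3
    name: str = "VSMOW/VPDB/AIR"

    def __post_init__(self) -> None:
        if min(self.h, self.c, self.n, self.o) <= 0:
            raise ValueError("standard ratios must be positive")

    def ratio(self, element: str) -> float:
        return {"H": self.h, "C": self.c, "N": self.n, "O": self.o}[element]


def correct_exchangeable_h(
    r_raw: float, h_total: int, h_exch: int, r_solvent: float
) -> float:
    """C-bonded 2H/1H from the raw all-hydrogen ratio.

    The measured M+1 deuterium component averages over all hydrogens; the
    exchangeable sites (heteroatom-bonded plus the ionizing proton) carry
    the solvent deuterium level, so

        r_cb = (h_total * r_raw - h_exch * r_solvent) / (h_total - h_exch)
    """
    if not (0 <= h_exch < h_total):
        raise ValueError(f"need 0 <= h_exch < h_total, got {h_exch}/{h_total}")
    if r_raw <= 0 or r_solvent <= 0:
        raise ValueError("ratios must be positive")
    return (h_total * r_raw - h_exch * r_solvent) / (h_total - h_exch)


def delta_value(r_sample: float, r_standard: float) -> float:
    """Per-mil deviation from a standard: (r/R - 1) * 1000."""
    if r_standard <= 0:
        raise ValueError("standard ratio must be positive")
    return (r_sample / r_standard - 1.0) * 1000.0


def add_corrected_h(
    frame: pd.DataFrame,
    registry: Mapping[str, ImmoniumSpecies],
    solvent_ppm: float = 150.0,
) -> pd.DataFrame:
    """Add the solvent-corrected C-bonded 2H/1H column ``r_h``."""
    out = frame.copy()
    r_solvent = solvent_ppm * 1e-6
    corrected = np.full(len(out), np.nan)
    for name, sub in out.groupby("species"):
        sp = registry.get(str(name))
        if sp is None:
            continue
        raw = sub["r_h_raw"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            corrected[out.index.get_indexer(sub.index)] = (
                sp.h_total * raw - sp.h_exch * r_solvent
            ) / sp.h_cbonded
    out["r_h"] = corrected
    return out


def trim_outliers(
    values: np.ndarray, mad_k: float = 5.0
) -> np.ndarray:
    """Boolean mask keeping values inside median +/- mad_k * MAD."""
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() == 0:
        return ok
    med = np.median(values[ok])
    mad = 1.4826 * np.median(np.abs(values[ok] - med))
    if mad == 0:
        return ok
    return ok & (np.abs(values - med) <= mad_k * mad)


def aggregate_replicates(
    frame: pd.DataFrame,
    value_col: str,
    group_cols: Sequence[str] = ("sample", "replicate", "species"),
    mad_k: float | None = 5.0,
) -> pd.DataFrame:
    """n/mean/median/SD/SEM of one ratio column per replicate group.

    Records with an absent value are dropped; optional MAD-based trimming
    (median +/- mad_k MAD per group) is applied before the moments. Groups
    left empty after filtering are reported with n=0 and NaN moments plus
    a reason, rather than silently omitted.
    """
    rows = []
    for key, sub in frame.groupby(list(group_cols), sort=True, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        values = sub[value_col].to_numpy(dtype=float)
        keep = np.isfinite(values)
        if mad_k is not None:
            keep &= trim_outliers(values, mad_k)
        values = values[keep]
        row = dict(zip(group_cols, key))
        n = values.size
        if n == 0:
            row.update(
                n=0, mean=np.nan, median=np.nan, sd=np.nan, sem=np.nan,
                reason="no unflagged records",
            )
        else:
            sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
            row.update(
                n=n,
                mean=float(np.mean(values)),
                median=float(np.median(values)),
                sd=sd,
                sem=sd / np.sqrt(n),
                reason="",
            )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_elements(
    frame: pd.DataFrame,
    elements: Sequence[str] = ("C", "N", "H"),
    group_cols: Sequence[str] = ("sample", "replicate", "species"),
    mad_k: float | None = 5.0,
    standards: StandardSet | None = None,
) -> pd.DataFrame:
    """Long-form per-replicate summary over several elements.

    Adds a per-mil ``delta`` column when a :class:`StandardSet` is given.
    """
    pieces = []
    for element in elements:
        col = ELEMENT_COLUMNS[element]
        if col not in frame.columns:
            continue
        summary = aggregate_replicates(frame, col, group_cols, mad_k)
        summary.insert(len(group_cols), "element", element)
        if standards is not None:
            ref = standards.ratio(element.replace("_raw", ""))
            summary["delta"] = (summary["mean"] / ref - 1.0) * 1000.0
        pieces.append(summary)
    if not pieces:
        return pd.DataFrame()
    return pd.concat(pieces, ignore_index=True)


def cv_between_replicates(
    summary: pd.DataFrame,
    group_cols: Sequence[str] = ("sample", "species", "element"),
    value_col: str = "mean",
) -> pd.DataFrame:
    """CV% of per-replicate means, per group.

    CV = SD(replicate means) / mean(replicate means) * 100. Raises when a
    group has fewer than 2 replicates with a finite mean.
    """
    rows = []
    for key, sub in summary.groupby(list(group_cols), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        means = sub[value_col].to_numpy(dtype=float)
        means = means[np.isfinite(means)]
        if means.size < 2:
            raise ValueError(
                f"group {dict(zip(group_cols, key))} has < 2 replicates"
            )
        cv = float(np.std(means, ddof=1) / np.mean(means) * 100.0)
        row = dict(zip(group_cols, key))
        row.update(n_replicates=means.size, cv_pct=cv)
        rows.append(row)
    return pd.DataFrame(rows)


def tic_trend(
    frame: pd.DataFrame, species: str, element: str
) -> tuple[float, float, float]:
    """OLS of the ratio on log10(TIC): (slope, correlation r, p of slope).

    Requires >= 10 records spanning more than 0.5 decades of TIC; with
    automatic gain control there should be no discernible trend.
    """
    col = ELEMENT_COLUMNS[element]
    sub = frame[frame["species"] == species][["tic", col]].dropna()
    if len(sub) < 10:
        raise ValueError(f"need >= 10 records, got {len(sub)}")
    log_tic = np.log10(sub["tic"].to_numpy(dtype=float))
    if log_tic.max() - log_tic.min() <= 0.5:
        raise ValueError(
            f"TIC spans only {log_tic.max() - log_tic.min():.3f} decades (> 0.5 needed)"
        )
    fit = _scipy_stats.linregress(log_tic, sub[col].to_numpy(dtype=float))
    return float(fit.slope), float(fit.rvalue), float(fit.pvalue)


@dataclass(frozen=True)
class PrecisionCurve:
    """Average between-replicate CV vs datapoints per replicate."""

    ks: tuple[int, ...]
    mean_cv_pct: tuple[float, ...]
    median_cv_pct: tuple[float, ...]
    n_draws: int
    seed: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.ks,
                "mean_cv_pct": self.mean_cv_pct,
                "median_cv_pct": self.median_cv_pct,
            }
        )


def subsample_precision(
    frame: pd.DataFrame,
    ks: Sequence[int],
    n_draws: int = 20,
    seed: int = 0,
    elements: Sequence[str] = ("C", "N", "H"),
    replicate_col: str = "replicate",
) -> PrecisionCurve:
    """Precision-vs-datapoint-count curve by random subsampling.

    For each k and draw, k records are sampled without replacement per
    (replicate, species); replicate means and medians per element give a
    between-replicate CV, averaged over draws, species and elements. On
    shot-noise-limited data the curve falls as k**-0.5.
    """
    ks = sorted(int(k) for k in ks)
    cols = [ELEMENT_COLUMNS[e] for e in elements]
    groups: list[tuple[str, list[np.ndarray]]] = []
    for species, by_species in frame.groupby("species"):
        reps = [
            sub[cols].to_numpy(dtype=float)
            for _, sub in by_species.groupby(replicate_col)
        ]
        if len(reps) < 2:
            raise ValueError(f"species {species!r} has < 2 replicates")
        for rep_idx, arr in enumerate(reps):
            if arr.shape[0] < ks[-1]:
                raise ValueError(
                    f"replicate {rep_idx} of {species!r} has {arr.shape[0]} "
                    f"records, fewer than k={ks[-1]}"
                )
        groups.append((str(species), reps))
    rng = np.random.default_rng(seed)
    mean_curve, median_curve = [], []
    for k in ks:
        cv_means, cv_medians = [], []
        for _ in range(n_draws):
            for _, reps in groups:
                rep_means = np.array(
                    [
                        np.nanmean(arr[rng.choice(arr.shape[0], k, replace=False)], axis=0)
                        for arr in reps
                    ]
                )
                rep_medians = np.array(
                    [
                        np.nanmedian(
                            arr[rng.choice(arr.shape[0], k, replace=False)], axis=0
                        )
                        for arr in reps
                    ]
                )
                cv_means.append(
                    np.nanstd(rep_means, axis=0, ddof=1)
                    / np.nanmean(rep_means, axis=0)
                    * 100.0
                )
                cv_medians.append(
                    np.nanstd(rep_medians, axis=0, ddof=1)
                    / np.nanmean(rep_medians, axis=0)
                    * 100.0
                )
        mean_curve.append(float(np.nanmean(cv_means)))
        median_curve.append(float(np.nanmean(cv_medians)))
    return PrecisionCurve(
        ks=tuple(ks),
        mean_cv_pct=tuple(mean_curve),
        median_cv_pct=tuple(median_curve),
        n_draws=n_draws,
        seed=seed,
    )


@dataclass(frozen=True)
class IncorporationFit:
    """Linear fit of the measured 2H/1H ratio on media deuterium content."""

    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float

    @property
    def incorporation_pct(self) -> float:
        return self.slope * 100.0


def incorporation_regression(
    media_ppm: Sequence[float], r_h_ppm: Sequence[float]
) -> IncorporationFit:
    """Least squares of measured C-bonded 2H/1H (ppm) on media 2H (ppm).

    The slope is the fraction of C-bonded hydrogens equilibrated with the
    media; the incorporation degree is 100x the slope.
    """
    media = np.asarray(media_ppm, dtype=float)
    values = np.asarray(r_h_ppm, dtype=float)
    if np.unique(media).size < 3:
        raise ValueError("need >= 3 distinct media levels")
    fit = _scipy_stats.linregress(media, values)
    return IncorporationFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        slope_stderr=float(fit.stderr),
    )


def species_contributions(
    frame: pd.DataFrame,
    reference: Mapping[str, float] | None = None,
) -> tuple[pd.Series, float | None]:
    """Percent of summed monoisotopic area per species (+ optional R^2).

    The contribution of species i is the summed monoisotopic area of its
    records over the grand total, in percent. When a reference composition
    vector is supplied the squared Pearson correlation against it is
    returned as a sample-identity check.
    """
    if frame.empty:
        raise ValueError("no records")
    totals = frame.groupby("species")["area_m"].sum()
    contrib = totals / totals.sum() * 100.0
    r2 = None
    if reference is not None:
        common = [s for s in contrib.index if s in reference]
        if len(common) >= 2:
            obs = contrib[common].to_numpy(dtype=float)
            ref = np.array([reference[s] for s in common], dtype=float)
            r2 = float(np.corrcoef(obs, ref)[0, 1] ** 2)
    return contrib, r2
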