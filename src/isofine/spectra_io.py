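"""mzML and CSV input/output.

Reads profile-mode runs (mzML 1.1, plain or indexed; zlib-compressed or
raw 32/64-bit float arrays) with a compact lxml-based parser, writes runs
produced by the simulator with a minimal self-contained mzML writer,
selects broad-isolation high-energy MS/MS ("isoMS") scans by metadata, and
round-trips the per-scan ratio-record table and the experiment-design file
as CSV.
"""

from __future__ import annotations

import base64
import csv
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "ProfileSpectrum",
    "ScanSelectionCriteria",
    "SelectionResult",
    "read_run",
    "write_mzml",
    "select_isoms_scans",
    "write_records_csv",
    "read_records_csv",
    "records_to_frame",
    "read_design_csv",
    "DESIGN_COLUMNS",
]


@dataclass
class ProfileSpectrum:
    """One scan: m/z / intensity arrays plus acquisition metadata.

    Metadata fields are ``None`` when absent from the source file; they are
    never silently defaulted.
    """

    mz: np.ndarray
    intensity: np.ndarray
    scan_index: int = 0
    rt_s: float | None = None
    ms_level: int | None = None
    hcd_energy: float | None = None
    isolation_center: float | None = None
    isolation_width: float | None = None
    microscans: int | None = None
    tic: float | None = None
    resolution_setting: float | None = None
    is_profile: bool = True

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z array must be strictly increasing")
        if self.intensity.size and self.intensity.min() < 0:
            raise ValueError("negative intensities")

    @property
    def mz_range(self) -> tuple[float, float] | None:
        if self.mz.size == 0:
            return None
        return float(self.mz[0]), float(self.mz[-1])


# ---------------------------------------------------------------------------
# mzML writing (minimal mzML 1.1 document, 64-bit arrays, no compression)
# ---------------------------------------------------------------------------

_NS = "http://psi.hupo.org/ms/mzml"


def _cv(parent, accession, name, value=None, unit=None):
    el = etree.SubElement(parent, "cvParam")
    el.set("cvRef", accession.split(":")[0])
    el.set("accession", accession)
    el.set("name", name)
    el.set("value", "" if value is None else str(value))
    if unit is not None:
        el.set("unitCvRef", unit[0].split(":")[0])
        el.set("unitAccession", unit[0])
        el.set("unitName", unit[1])
    return el


def _user(parent, name, value, dtype="xsd:string"):
    el = etree.SubElement(parent, "userParam")
    el.set("name", name)
    el.set("value", str(value))
    el.set("type", dtype)
    return el


def _binary_array(parent, values, accession, name, unit=None):
    data = np.asarray(values, dtype="<f8").tobytes()
    encoded = base64.b64encode(zlib.compress(data)).decode("ascii")
    arr = etree.SubElement(parent, "binaryDataArray")
    arr.set("encodedLength", str(len(encoded)))
    _cv(arr, "MS:1000523", "64-bit float")
    _cv(arr, "MS:1000574", "zlib compression")
    _cv(arr, accession, name, unit=unit)
    etree.SubElement(arr, "binary").text = encoded


def write_mzml(spectra: Sequence[ProfileSpectrum], path: str | Path) -> None:
    """Write scans as a plain (non-indexed) mzML 1.1 document."""
    root = etree.Element("mzML", nsmap={None: _NS})
    root.set("version", "1.1.0")
    cvlist = etree.SubElement(root, "cvList", count="2")
    etree.SubElement(
        cvlist, "cv", id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    etree.SubElement(
        cvlist, "cv", id="UO", fullName="Unit Ontology",
        URI="http://ontologies.berkeleybop.org/uo.obo",
    )
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000580", "MSn spectrum")
    soft_list = etree.SubElement(root, "softwareList", count="1")
    soft = etree.SubElement(soft_list, "software", id="isofine", version="0.1.0")
    _cv(soft, "MS:1000799", "custom unreleased software tool", value="isofine")
    icl = etree.SubElement(root, "instrumentConfigurationList", count="1")
    ic = etree.SubElement(icl, "instrumentConfiguration", id="IC1")
    _cv(ic, "MS:1000031", "instrument model")
    dpl = etree.SubElement(root, "dataProcessingList", count="1")
    dp = etree.SubElement(dpl, "dataProcessing", id="DP1")
    pm = etree.SubElement(dp, "processingMethod", order="1", softwareRef="isofine")
    _cv(pm, "MS:1000544", "Conversion to mzML")
    run = etree.SubElement(root, "run", id="run", defaultInstrumentConfigurationRef="IC1")
    slist = etree.SubElement(
        run, "spectrumList", count=str(len(spectra)), defaultDataProcessingRef="DP1"
    )
    for i, spec in enumerate(spectra):
        el = etree.SubElement(
            slist,
            "spectrum",
            index=str(i),
            id=f"scan={spec.scan_index}",
            defaultArrayLength=str(spec.mz.size),
        )
        if spec.ms_level is not None:
            _cv(el, "MS:1000511", "ms level", value=spec.ms_level)
        _cv(el, "MS:1000580", "MSn spectrum")
        if spec.is_profile:
            _cv(el, "MS:1000128", "profile spectrum")
        else:
            _cv(el, "MS:1000127", "centroid spectrum")
        if spec.tic is not None:
            _cv(el, "MS:1000285", "total ion current", value=repr(float(spec.tic)))
        if spec.microscans is not None:
            _user(el, "microscans", spec.microscans, "xsd:integer")
        if spec.resolution_setting is not None:
            _user(el, "nominal resolution", spec.resolution_setting, "xsd:float")
        scan_list = etree.SubElement(el, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan = etree.SubElement(scan_list, "scan")
        if spec.rt_s is not None:
            _cv(
                scan, "MS:1000016", "scan start time", value=repr(float(spec.rt_s)),
                unit=("UO:0000010", "second"),
            )
        if spec.isolation_center is not None or spec.hcd_energy is not None:
            plist = etree.SubElement(el, "precursorList", count="1")
            prec = etree.SubElement(plist, "precursor")
            if spec.isolation_center is not None:
                iso = etree.SubElement(prec, "isolationWindow")
                _cv(iso, "MS:1000827", "isolation window target m/z",
                    value=repr(float(spec.isolation_center)),
                    unit=("MS:1000040", "m/z"))
                if spec.isolation_width is not None:
                    half = spec.isolation_width / 2.0
                    _cv(iso, "MS:1000828", "isolation window lower offset",
                        value=repr(half), unit=("MS:1000040", "m/z"))
                    _cv(iso, "MS:1000829", "isolation window upper offset",
                        value=repr(half), unit=("MS:1000040", "m/z"))
            sel_list = etree.SubElement(prec, "selectedIonList", count="1")
            sel = etree.SubElement(sel_list, "selectedIon")
            if spec.isolation_center is not None:
                _cv(sel, "MS:1000744", "selected ion m/z",
                    value=repr(float(spec.isolation_center)),
                    unit=("MS:1000040", "m/z"))
            act = etree.SubElement(prec, "activation")
            _cv(act, "MS:1000422", "beam-type collision-induced dissociation")
            if spec.hcd_energy is not None:
                _cv(act, "MS:1000045", "collision energy",
                    value=repr(float(spec.hcd_energy)))
        arrs = etree.SubElement(el, "binaryDataArrayList", count="2")
        _binary_array(arrs, spec.mz, "MS:1000514", "m/z array",
                      unit=("MS:1000040", "m/z"))
        _binary_array(arrs, spec.intensity, "MS:1000515", "intensity array",
                      unit=("MS:1000131", "number of detector counts"))
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


# ---------------------------------------------------------------------------
# mzML reading
# ---------------------------------------------------------------------------


def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _params(element) -> dict[str, str | None]:
    """cvParam/userParam name -> value for the element's direct children."""
    out: dict[str, str | None] = {}
    for child in element:
        if _local(child.tag) in ("cvParam", "userParam"):
            out[child.get("name", "")] = child.get("value")
    return out


def _decode_binary_array(array_el) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind, values)."""
    names = _params(array_el)
    kind = None
    if "m/z array" in names:
        kind = "mz"
    elif "intensity array" in names:
        kind = "intensity"
    dtype = "<f8" if "64-bit float" in names else "<f4"
    binary = None
    for child in array_el:
        if _local(child.tag) == "binary":
            binary = child.text or ""
    data = base64.b64decode(binary.encode("ascii")) if binary else b""
    if "zlib compression" in names and data:
        data = zlib.decompress(data)
    return kind, np.frombuffer(data, dtype=dtype).astype(np.float64)


def _parse_spectrum_element(el, fallback_index: int) -> ProfileSpectrum:
    params = _params(el)
    rt_s = None
    microscans = params.get("microscans")
    resolution = params.get("nominal resolution")
    hcd = None
    iso_center = iso_width = None
    mz = intensity = None
    for child in el:
        tag = _local(child.tag)
        if tag == "scanList":
            for scan in child:
                if _local(scan.tag) != "scan":
                    continue
                for p in scan:
                    if _local(p.tag) not in ("cvParam", "userParam"):
                        continue
                    name = p.get("name", "")
                    if name == "scan start time":
                        rt_s = float(p.get("value"))
                        if "minute" in (p.get("unitName") or ""):
                            rt_s *= 60.0
                    elif name == "microscans" and microscans is None:
                        microscans = p.get("value")
                    elif name == "nominal resolution" and resolution is None:
                        resolution = p.get("value")
        elif tag == "precursorList":
            for precursor in child:
                for part in precursor:
                    ptag = _local(part.tag)
                    if ptag == "isolationWindow":
                        iso = _params(part)
                        center = iso.get("isolation window target m/z")
                        lower = iso.get("isolation window lower offset")
                        upper = iso.get("isolation window upper offset")
                        iso_center = float(center) if center is not None else None
                        if lower is not None and upper is not None:
                            iso_width = float(lower) + float(upper)
                    elif ptag == "activation":
                        energy = _params(part).get("collision energy")
                        hcd = float(energy) if energy is not None else None
        elif tag == "binaryDataArrayList":
            for arr in child:
                if _local(arr.tag) != "binaryDataArray":
                    continue
                kind, values = _decode_binary_array(arr)
                if kind == "mz":
                    mz = values
                elif kind == "intensity":
                    intensity = values
    scan_id = el.get("id", "")
    scan_index = int(el.get("index", fallback_index))
    if "scan=" in scan_id:
        try:
            scan_index = int(scan_id.rsplit("scan=", 1)[1].split()[0])
        except ValueError:
            pass
    if mz is None or intensity is None:
        raise ValueError(f"spectrum {scan_id!r} lacks m/z or intensity array")
    tic = params.get("total ion current")
    level = params.get("ms level")
    return ProfileSpectrum(
        mz=mz,
        intensity=np.maximum(intensity, 0.0),
        scan_index=scan_index,
        rt_s=rt_s,
        ms_level=int(level) if level is not None else None,
        hcd_energy=hcd,
        isolation_center=iso_center,
        isolation_width=iso_width,
        microscans=int(microscans) if microscans is not None else None,
        tic=float(tic) if tic is not None else None,
        resolution_setting=float(resolution) if resolution is not None else None,
        is_profile="centroid spectrum" not in params,
    )


def read_run(path: str | Path) -> list[ProfileSpectrum]:
    """Read an mzML 1.1 run into a list of :class:`ProfileSpectrum`.

    Handles plain and indexed documents, zlib-compressed or raw 32/64-bit
    float arrays. Centroid scans are read but flagged
    ``is_profile=False`` (with a warning); downstream profile fitting
    refuses them. Malformed XML raises with the failing scan index.
    """
    spectra: list[ProfileSpectrum] = []
    n_centroid = 0
    index = -1
    try:
        for _, el in etree.iterparse(
            str(path), tag=f"{{{_NS}}}spectrum", events=("end",)
        ):
            index += 1
            spec = _parse_spectrum_element(el, index)
            if not spec.is_profile:
                n_centroid += 1
            spectra.append(spec)
            el.clear()
            while el.getprevious() is not None:
                del el.getparent()[0]
    except etree.XMLSyntaxError as exc:
        raise ValueError(
            f"malformed mzML in {path} near scan index {index + 1}: {exc}"
        ) from exc
    if n_centroid:
        warnings.warn(
            f"{path}: {n_centroid} centroid scan(s); profile fitting will refuse them",
            stacklevel=2,
        )
    return spectra


# ---------------------------------------------------------------------------
# isoMS scan selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanSelectionCriteria:
    """Metadata criteria identifying isoMS scans.

    Defaults match the broad-isolation acquisition: MS2, isolation window
    at least 100 Th wide, normalized HCD between 45 and 55 %, profile mode.
    ``required_mz_range`` (when set) demands the detected m/z axis cover
    that interval.
    """

    ms_level: int = 2
    min_isolation_width: float = 100.0
    hcd_range: tuple[float, float] = (45.0, 55.0)
    required_mz_range: tuple[float, float] | None = None
    profile_only: bool = True

    def __post_init__(self) -> None:
        if self.min_isolation_width < 0:
            raise ValueError("min_isolation_width must be >= 0")
        if self.hcd_range[0] > self.hcd_range[1]:
            raise ValueError("hcd_range reversed")


@dataclass
class SelectionResult:
    """Scans kept by :func:`select_isoms_scans` plus per-criterion drop counts."""

    kept: list[ProfileSpectrum]
    dropped: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.kept)

    def __len__(self):
        return len(self.kept)

    def __getitem__(self, item):
        return self.kept[item]


def select_isoms_scans(
    run: Iterable[ProfileSpectrum], criteria: ScanSelectionCriteria
) -> SelectionResult:
    """Filter a run down to isoMS scans, preserving order.

    A scan missing a piece of metadata fails the corresponding criterion
    only when that criterion is restrictive (e.g. an absent HCD energy
    passes a fully open energy range).
    """
    kept: list[ProfileSpectrum] = []
    dropped: dict[str, int] = {
        "ms_level": 0, "isolation_width": 0, "hcd": 0, "mz_range": 0, "profile": 0,
    }
    lo_e, hi_e = criteria.hcd_range
    for spec in run:
        if criteria.ms_level is not None and spec.ms_level != criteria.ms_level:
            dropped["ms_level"] += 1
            continue
        if criteria.min_isolation_width > 0:
            if spec.isolation_width is None or (
                spec.isolation_width < criteria.min_isolation_width
            ):
                dropped["isolation_width"] += 1
                continue
        if spec.hcd_energy is None:
            if (lo_e, hi_e) != (float("-inf"), float("inf")) and lo_e > 0:
                dropped["hcd"] += 1
                continue
        elif not (lo_e <= spec.hcd_energy <= hi_e):
            dropped["hcd"] += 1
            continue
        if criteria.required_mz_range is not None:
            rng = spec.mz_range
            lo, hi = criteria.required_mz_range
            if rng is None or rng[0] > lo or rng[1] < hi:
                dropped["mz_range"] += 1
                continue
        if criteria.profile_only and not spec.is_profile:
            dropped["profile"] += 1
            continue
        kept.append(spec)
    return SelectionResult(kept=kept, dropped=dropped)


# ---------------------------------------------------------------------------
# Ratio-record CSV
# ---------------------------------------------------------------------------

RECORD_COLUMNS = [
    "scan_index",
    "rt_s",
    "tic",
    "species",
    "area_m",
    "r_c",
    "r_h_raw",
    "r_n",
    "r_o",
    "mass_error_ppm",
    "flags",
]
_FLOAT_COLUMNS = {
    "rt_s", "tic", "area_m", "r_c", "r_h_raw", "r_n", "r_o", "mass_error_ppm",
}


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)  # shortest exact round-trip representation
    return str(value)


def write_records_csv(records: Iterable, path: str | Path) -> None:
    """One row per (scan, species); floats serialized losslessly."""
    records = list(records)
    extra_keys = sorted({k for r in records for k in r.extras})
    header = RECORD_COLUMNS + extra_keys
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in records:
            row = [
                _fmt(r.scan_index),
                _fmt(r.rt_s),
                _fmt(r.tic),
                r.species,
                _fmt(r.area_m),
                _fmt(r.r_c),
                _fmt(r.r_h_raw),
                _fmt(r.r_n),
                _fmt(r.r_o),
                _fmt(r.mass_error_ppm),
                ";".join(r.flags),
            ]
            row += [_fmt(r.extras.get(k)) for k in extra_keys]
            writer.writerow(row)


def read_records_csv(path: str | Path) -> list:
    """Read a records CSV; unknown extra columns are preserved opaquely."""
    from .fine_structure import RatioRecord  # deferred: avoids import cycle

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, no header") from None
        missing = [c for c in RECORD_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        idx = {c: header.index(c) for c in header}
        extra_keys = [c for c in header if c not in RECORD_COLUMNS]
        records = []
        for row in reader:
            if not row:
                continue

            def fval(col):
                raw = row[idx[col]]
                return float(raw) if raw != "" else None

            flags_raw = row[idx["flags"]]
            records.append(
                RatioRecord(
                    scan_index=int(row[idx["scan_index"]]),
                    rt_s=fval("rt_s"),
                    tic=fval("tic"),
                    species=row[idx["species"]],
                    area_m=fval("area_m"),
                    r_c=fval("r_c"),
                    r_h_raw=fval("r_h_raw"),
                    r_n=fval("r_n"),
                    r_o=fval("r_o"),
                    mass_error_ppm=fval("mass_error_ppm"),
                    flags=tuple(f for f in flags_raw.split(";") if f),
                    extras={k: row[idx[k]] for k in extra_keys},
                )
            )
    return records


def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Tidy DataFrame of ratio records (one row per scan x species)."""
    rows = []
    for r in records:
        row = {
            "scan_index": r.scan_index,
            "rt_s": r.rt_s,
            "tic": r.tic,
            "species": r.species,
            "area_m": r.area_m,
            "r_c": r.r_c,
            "r_h_raw": r.r_h_raw,
            "r_n": r.r_n,
            "r_o": r.r_o,
            "mass_error_ppm": r.mass_error_ppm,
            "flags": ";".join(r.flags),
        }
        row.update(r.extras)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Experiment design
# ---------------------------------------------------------------------------

DESIGN_COLUMNS = [
    "file", "sample", "group", "replicate", "solvent_d2h_ppm", "species", "notes",
]


def read_design_csv(path: str | Path, check_files: bool = False) -> pd.DataFrame:
    """Read and validate the experiment-design table.

    Columns: ``file, sample, group, replicate, solvent_d2h_ppm, species,
    notes``; ``species`` is a semicolon-separated subset (empty = all).
    """
    design = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"{path}: design file missing columns {missing}")
    dup = design.duplicated(subset=["file", "sample", "replicate"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (file, sample, replicate) rows at "
            f"{list(design.index[dup])}"
        )
    design["solvent_d2h_ppm"] = pd.to_numeric(
        design["solvent_d2h_ppm"].replace("", "150")
    )
    if check_files:
        base = Path(path).parent
        missing_files = [
            f for f in design["file"]
            if not (Path(f).exists() or (base / f).exists())
        ]
        if missing_files:
            raise FileNotFoundError(
                f"design references missing files: {missing_files}"
            )
    return design
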