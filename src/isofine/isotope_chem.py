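"""Elemental and isotopic bookkeeping for immonium-ion fine structure.

Exact masses, ion m/z under the two mass conventions used for peak lookup,
and exact isotopologue fine-structure line positions and abundances for the
M, M+1 and M+2 isotope shells.

The model treats isotopic substitution as independent per atomic site: the
probability that a molecule carries exactly ``k_X`` heavy atoms of element
``X`` (out of ``n_X`` sites) is binomial with per-site heavy fraction
``a_X = r_X / (1 + r_X)``, where ``r_X`` is the heavy/light isotope ratio.
The abundance of a fine-structure line relative to the all-light
(monoisotopic) line is then the exact closed form

    A(line) / A(M) = prod_X C(n_X, k_X) * r_X**k_X

which for a single substitution reduces to ``n_X * r_X`` — the algebraic
basis of the area-ratio estimator used downstream.

Hydrogen sites may be split into two isotopically distinct classes
(carbon-bonded vs solvent-exchangeable) by using the pseudo-element symbol
``"Hx"`` for the exchangeable sites; lines that differ only in which class
carries the deuteron coincide in mass and are merged.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "IsotopeTable",
    "DEFAULT_ISOTOPES",
    "ElementalComposition",
    "AbundanceSet",
    "ImmoniumSpecies",
    "FineLine",
    "SpeciesFineStructure",
    "monoisotopic_mass",
    "theoretical_mz",
    "isotopologue_distribution",
    "fine_structure_lines",
    "default_species_registry",
    "load_species_table",
    "write_species_table",
]

# Pseudo-element aliases: isotopically identical to the target element but
# tracked as separate substitution sites (exchangeable hydrogen).
ELEMENT_ALIASES: dict[str, str] = {"Hx": "H"}

# CODATA / AME particle masses (Da)
PROTON_MASS = 1.007276466621
ELECTRON_MASS = 0.000548579909
H_ATOM_MASS = 1.00782503207


def _resolve(symbol: str) -> str:
    return ELEMENT_ALIASES.get(symbol, symbol)


@dataclass(frozen=True)
class IsotopeTable:
    """Isotope masses and natural abundances per element.

    ``isotopes`` maps an element symbol to an ordered list of
    ``(mass_da, abundance_fraction)`` pairs, lightest first. The heavy
    isotope used for fine-structure lines is +1 nominal mass unit for
    C/H/N and +2 for O (18O); 17O is carried for completeness but plays
    no role in the M+1 estimator.
    """

    isotopes: Mapping[str, tuple[tuple[float, float], ...]]
    proton_mass: float = PROTON_MASS
    electron_mass: float = ELECTRON_MASS
    hydrogen_mass: float = H_ATOM_MASS

    def __post_init__(self) -> None:
        for sym, entries in self.isotopes.items():
            total = sum(a for _, a in entries)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"abundances for {sym} sum to {total!r}, expected 1"
                )
            masses = [m for m, _ in entries]
            if masses != sorted(masses) or len(set(masses)) != len(masses):
                raise ValueError(f"isotope masses for {sym} not strictly increasing")

    def light_mass(self, symbol: str) -> float:
        sym = _resolve(symbol)
        try:
            return self.isotopes[sym][0][0]
        except KeyError:
            raise KeyError(f"unknown element symbol: {symbol!r}") from None

    def heavy_entry(self, symbol: str) -> tuple[float, float]:
        """(mass, abundance) of the fine-structure heavy isotope."""
        sym = _resolve(symbol)
        entries = self.isotopes[sym]
        # O: use 18O (the +2 isotope); all others: the +1 isotope.
        return entries[-1] if sym == "O" else entries[1]

    def mass_shift(self, symbol: str) -> float:
        """Exact heavy-minus-light isotope mass difference (Da)."""
        return self.heavy_entry(symbol)[0] - self.light_mass(symbol)

    def nominal_shift(self, symbol: str) -> int:
        return int(round(self.mass_shift(symbol)))

    def natural_ratio(self, symbol: str) -> float:
        """Natural heavy/light isotope ratio r_X."""
        return self.heavy_entry(symbol)[1] / self.isotopes[_resolve(symbol)][0][1]


DEFAULT_ISOTOPES = IsotopeTable(
    isotopes={
        "H": ((1.00782503207, 0.999885), (2.01410177785, 0.000115)),
        "C": ((12.0, 0.9893), (13.00335483507, 0.0107)),
        "N": ((14.0030740044, 0.99636), (15.0001088989, 0.00364)),
        "O": (
            (15.9949146196, 0.99757),
            (16.9991317565, 0.00038),
            (17.9991596129, 0.00205),
        ),
    }
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?x?)(\d*)")


@dataclass(frozen=True)
class ElementalComposition:
    """Non-negative atom counts per element symbol (e.g. C4H8N)."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for sym, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative atom count for {sym}: {n}")

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = match.end()
            sym = match.group(1)
            n = int(match.group(2) or 1)
            counts[sym] = counts.get(sym, 0) + n
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(counts)

    def get(self, symbol: str, default: int = 0) -> int:
        return self.counts.get(symbol, default)

    def merged(self) -> "ElementalComposition":
        """Collapse pseudo-element sites (Hx -> H)."""
        out: dict[str, int] = {}
        for sym, n in self.counts.items():
            out[_resolve(sym)] = out.get(_resolve(sym), 0) + n
        return ElementalComposition(out)

    @property
    def total_atoms(self) -> int:
        return sum(self.counts.values())

    def formula(self) -> str:
        order = ["C", "H", "Hx", "N", "O"]
        syms = [s for s in order if self.counts.get(s)] + sorted(
            s for s in self.counts if s not in order and self.counts[s]
        )
        return "".join(
            f"{s}{self.counts[s]}" if self.counts[s] != 1 else s for s in syms
        )

    def items(self):
        return self.counts.items()


@dataclass(frozen=True)
class AbundanceSet:
    """Heavy/light isotope ratios r_X per element (or per hydrogen site class).

    Ratios are dimensionless; 2H/1H is conventionally discussed in ppm
    (150 ppm = 1.5e-4). All ratios must lie in (0, 1).
    """

    ratios: Mapping[str, float]
    name: str = ""

    def __post_init__(self) -> None:
        for sym, r in self.ratios.items():
            if not (0.0 < r < 1.0):
                raise ValueError(f"ratio for {sym} out of (0,1): {r}")

    def ratio(self, symbol: str) -> float:
        if symbol in self.ratios:
            return self.ratios[symbol]
        return self.ratios[_resolve(symbol)]

    def site_fraction(self, symbol: str) -> float:
        """Per-site heavy-isotope fraction a_X = r_X / (1 + r_X)."""
        r = self.ratio(symbol)
        return r / (1.0 + r)

    def with_ratio(self, symbol: str, value: float) -> "AbundanceSet":
        ratios = dict(self.ratios)
        ratios[symbol] = value
        return replace(self, ratios=ratios)

    @classmethod
    def natural(cls, table: IsotopeTable = DEFAULT_ISOTOPES) -> "AbundanceSet":
        """IUPAC natural-abundance ratios derived from the isotope table."""
        return cls(
            {sym: table.natural_ratio(sym) for sym in table.isotopes},
            name="natural",
        )

    @classmethod
    def rounded_natural(cls) -> "AbundanceSet":
        """Rounded textbook natural abundances (1.1% 13C, 0.37% 15N,
        150 ppm 2H, 0.2% 18O), convenient for simulations."""
        return cls(
            {"C": 0.011, "N": 0.0037, "H": 150e-6, "O": 0.002},
            name="rounded_natural",
        )


def monoisotopic_mass(
    comp: ElementalComposition, table: IsotopeTable = DEFAULT_ISOTOPES
) -> float:
    """Sum of lightest-isotope masses over the composition (Da)."""
    return sum(n * table.light_mass(sym) for sym, n in comp.items())


def theoretical_mz(
    comp: ElementalComposition,
    convention: str = "h_atom",
    charge: int = 1,
    add_protons: int = 0,
    table: IsotopeTable = DEFAULT_ISOTOPES,
) -> float:
    """Theoretical m/z of a singly/multiply protonated or immonium species.

    ``convention="h_atom"`` uses neutral-radical arithmetic: each ionizing
    proton contributes a full hydrogen-atom mass and no electron is
    subtracted. This reproduces the printed reference values for both MH+
    ions (pass the neutral composition with ``add_protons=1``) and immonium
    ions (whose registry formulas already include the extra hydrogen;
    ``add_protons=0``). ``convention="cation_physical"`` subtracts one
    electron mass per charge, giving the true cation m/z.
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    mass = monoisotopic_mass(comp, table) + add_protons * table.hydrogen_mass
    if convention == "h_atom":
        return mass / charge
    if convention == "cation_physical":
        return (mass - charge * table.electron_mass) / charge
    raise ValueError(f"unknown m/z convention: {convention!r}")


# ---------------------------------------------------------------------------
# Fine-structure lines
# ---------------------------------------------------------------------------

_ISOTOPE_NAMES = {"C": "13C", "H": "2H", "Hx": "2H", "N": "15N", "O": "18O"}


@dataclass(frozen=True)
class FineLine:
    """One isotopologue line: substitution multiset, mass shift, abundance.

    ``ratio`` is the abundance relative to the all-light line M;
    ``probability`` is the absolute isotopologue probability under the
    independent-site model. ``mz`` is filled only when the line has been
    anchored to a species position.
    """

    label: str
    subs: tuple[tuple[str, int], ...]
    nominal_shift: int
    delta_m: float
    ratio: float
    probability: float
    mz: float | None = None


def _line_label(subs: tuple[tuple[str, int], ...], shell: int) -> str:
    if not subs:
        return "M"
    parts = []
    for sym, k in subs:
        iso = _ISOTOPE_NAMES[sym]
        parts.append(iso if k == 1 else f"{iso}{k}")
    return f"M{shell}_" + "".join(parts)


def _canonical_subs(subs: Iterable[tuple[str, int]]) -> tuple[tuple[str, int], ...]:
    """Merge pseudo-element sites and order substitutions for labelling."""
    merged: dict[str, int] = {}
    for sym, k in subs:
        if k:
            merged[_resolve(sym)] = merged.get(_resolve(sym), 0) + k
    order = {"O": 0, "C": 1, "N": 2, "H": 3}
    return tuple(sorted(merged.items(), key=lambda kv: order.get(kv[0], 9)))


def isotopologue_distribution(
    comp: ElementalComposition,
    abundances: AbundanceSet,
    max_shell: int = 2,
    table: IsotopeTable = DEFAULT_ISOTOPES,
) -> list[FineLine]:
    """Enumerate isotopologue lines with nominal mass shift <= ``max_shell``.

    Sites substitute independently; lines that coincide in mass (same
    canonical substitution multiset after collapsing hydrogen site classes)
    are merged by summing probabilities. Lines are returned sorted by
    (nominal shift, exact mass shift), starting with M.
    """
    if max_shell < 0:
        raise ValueError(f"max_shell must be >= 0, got {max_shell}")
    symbols = [sym for sym, n in comp.items() if n > 0]
    shifts = {sym: table.nominal_shift(sym) for sym in symbols}
    ranges = [
        range(0, min(comp.get(sym), max_shell // shifts[sym]) + 1) for sym in symbols
    ]
    merged: dict[tuple[tuple[str, int], ...], float] = {}
    for ks in product(*ranges) if symbols else [()]:
        shell = sum(k * shifts[sym] for sym, k in zip(symbols, ks))
        if shell > max_shell:
            continue
        prob = 1.0
        for sym, k in zip(symbols, ks):
            n = comp.get(sym)
            a = abundances.site_fraction(sym)
            prob *= math.comb(n, k) * a**k * (1.0 - a) ** (n - k)
        key = _canonical_subs(zip(symbols, ks))
        merged[key] = merged.get(key, 0.0) + prob
    p_mono = merged[()]
    lines = []
    for subs, prob in merged.items():
        shell = sum(k * table.nominal_shift(sym) for sym, k in subs)
        delta_m = sum(k * table.mass_shift(sym) for sym, k in subs)
        lines.append(
            FineLine(
                label=_line_label(subs, shell),
                subs=subs,
                nominal_shift=shell,
                delta_m=delta_m,
                ratio=prob / p_mono,
                probability=prob,
            )
        )
    lines.sort(key=lambda ln: (ln.nominal_shift, ln.delta_m))
    return lines


# ---------------------------------------------------------------------------
# Immonium species registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImmoniumSpecies:
    """A registry entry for one immonium ion.

    The composition is the cation written as a neutral-radical formula
    (the arithmetic that reproduces the reference m/z values), e.g. the
    proline immonium ion is C4H8N. ``h_exch`` counts solvent-exchangeable
    hydrogens (heteroatom-bonded plus the ionizing proton); the remainder
    are carbon-bonded and carry the biological deuterium signal.
    """

    name: str
    residues: str
    composition: ElementalComposition
    h_exch: int
    in_range: bool = True
    notes: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.h_exch <= self.composition.get("H")):
            raise ValueError(
                f"{self.name}: h_exch={self.h_exch} outside 0..H count"
            )

    @property
    def h_total(self) -> int:
        return self.composition.get("H")

    @property
    def h_cbonded(self) -> int:
        return self.h_total - self.h_exch

    @property
    def has_oxygen(self) -> bool:
        return self.composition.get("O") > 0

    def mz(self, convention: str = "h_atom") -> float:
        return theoretical_mz(self.composition, convention=convention)

    def site_composition(self) -> ElementalComposition:
        """Composition with hydrogen split into C-bonded (H) and
        exchangeable (Hx) site classes."""
        counts = {s: n for s, n in self.composition.items() if s != "H"}
        counts["H"] = self.h_cbonded
        counts["Hx"] = self.h_exch
        return ElementalComposition(counts)


def default_species_registry() -> dict[str, ImmoniumSpecies]:
    """Immonium ions of the amino acids used for fine-structure ratios.

    Gly and Ala fall below the m/z 50 low-mass cutoff of the analyzer
    range and are flagged out-of-range.
    """
    def sp(name, residues, formula, h_exch, in_range=True, notes=""):
        return ImmoniumSpecies(
            name=name,
            residues=residues,
            composition=ElementalComposition.from_formula(formula),
            h_exch=h_exch,
            in_range=in_range,
            notes=notes,
        )

    species = [
        sp("Pro", "Pro", "C4H8N", 1),
        sp("Hyp", "Hyp", "C4H8NO", 2, notes="only O-bearing default species"),
        sp("Val", "Val", "C4H10N", 2),
        sp("Leu/Ile", "Leu,Ile", "C5H12N", 2, notes="isomers, not distinguished"),
        sp("Phe", "Phe", "C8H10N", 2),
        sp("Gly", "Gly", "CH4N", 2, in_range=False, notes="below m/z 50"),
        sp("Ala", "Ala", "C2H6N", 2, in_range=False, notes="below m/z 50"),
    ]
    return {s.name: s for s in species}


_SPECIES_COLUMNS = ["name", "residues", "formula", "h_exch", "in_range", "notes"]


def write_species_table(species: Iterable[ImmoniumSpecies], path: str | Path) -> None:
    """Write the registry as an editable tab-separated table."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_SPECIES_COLUMNS) + "\n")
        for s in species:
            fh.write(
                "\t".join(
                    [
                        s.name,
                        s.residues,
                        s.composition.formula(),
                        str(s.h_exch),
                        str(int(s.in_range)),
                        s.notes,
                    ]
                )
                + "\n"
            )


def load_species_table(path: str | Path) -> dict[str, ImmoniumSpecies]:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != _SPECIES_COLUMNS[:4]:
            raise ValueError(
                f"bad species table header {header!r}; expected {_SPECIES_COLUMNS!r}"
            )
        out: dict[str, ImmoniumSpecies] = {}
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            row = dict(zip(header, fields))
            sp = ImmoniumSpecies(
                name=row["name"],
                residues=row["residues"],
                composition=ElementalComposition.from_formula(row["formula"]),
                h_exch=int(row["h_exch"]),
                in_range=bool(int(row.get("in_range", "1"))),
                notes=row.get("notes", ""),
            )
            out[sp.name] = sp
    return out


@dataclass(frozen=True)
class SpeciesFineStructure:
    """Fine-structure lines of one species anchored at absolute m/z."""

    species: ImmoniumSpecies
    shell: int
    lines: tuple[FineLine, ...]
    o18_present: bool


def fine_structure_lines(
    species: ImmoniumSpecies,
    abundances: AbundanceSet,
    shell: int,
    convention: str = "h_atom",
    table: IsotopeTable = DEFAULT_ISOTOPES,
) -> SpeciesFineStructure:
    """Lines of the requested shell with absolute m/z positions.

    Within M+1 the mass order is fixed by the isotope mass defects:
    15N (+0.99703) < 13C (+1.00335) < 2H (+1.00628). For an oxygen-free
    species at shell 2 the 18O line is absent (``o18_present=False``)
    and only the combination lines (13C2, 13C15N, ...) are returned.
    """
    if shell not in (1, 2):
        raise ValueError(f"shell must be 1 or 2, got {shell}")
    base = species.mz(convention)
    all_lines = isotopologue_distribution(
        species.composition, abundances, max_shell=shell, table=table
    )
    anchored = tuple(
        replace(ln, mz=base + ln.delta_m)
        for ln in all_lines
        if ln.nominal_shift == shell
    )
    o18 = any(dict(ln.subs).get("O") for ln in anchored)
    return SpeciesFineStructure(
        species=species, shell=shell, lines=anchored, o18_present=o18
    )
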