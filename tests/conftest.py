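"""Shared fixtures: species registry, instrument models, small rendered runs."""

from __future__ import annotations

import pytest

import isofine as iso


@pytest.fixture(scope="session")
def registry():
    return iso.default_species_registry()


@pytest.fixture()
def model():
    return iso.InstrumentModel()


@pytest.fixture(scope="session")
def noiseless_instrument():
    """Simulator settings with no baseline noise, jitter or offset."""
    return iso.SimInstrument(baseline_sd=0.0, jitter_ppm=0.0, cal_offset_ppm=0.0)


@pytest.fixture(scope="session")
def infusion_spectrum(registry, noiseless_instrument):
    """One noiseless Pro/Hyp/Val scan plus its truth-ledger rows."""
    mix = iso.infusion_mix(registry, ("Pro", "Hyp", "Val"))
    return iso.simulate_spectrum(mix, noiseless_instrument, rng=1234)


def brute_force_distribution(comp, abundances):
    """Independent oracle: enumerate every per-site isotope assignment.

    Returns canonical substitution multiset -> probability. Only feasible
    for molecules with a handful of atoms (2^n assignments).
    """
    from itertools import product

    sites = []
    for sym, n in comp.items():
        sites.extend([sym] * n)
    dist: dict[tuple, float] = {}
    for assignment in product((0, 1), repeat=len(sites)):
        prob = 1.0
        subs: dict[str, int] = {}
        for sym, heavy in zip(sites, assignment):
            a = abundances.site_fraction(sym)
            prob *= a if heavy else (1.0 - a)
            if heavy:
                key = "H" if sym == "Hx" else sym
                subs[key] = subs.get(key, 0) + 1
        key = tuple(sorted(subs.items()))
        dist[key] = dist.get(key, 0.0) + prob
    return dist
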