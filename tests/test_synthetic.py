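"""Forward-model invariants: ion statistics, determinism, scenarios."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import isofine as iso
from isofine.synthetic import effective_abundances


class TestSimulateSpectrum:
    def test_same_seed_bit_identical(self, registry, noiseless_instrument):
        mix = iso.infusion_mix(registry, ("Pro", "Val"))
        a, _ = iso.simulate_spectrum(mix, noiseless_instrument, rng=99)
        b, _ = iso.simulate_spectrum(mix, noiseless_instrument, rng=99)
        np.testing.assert_array_equal(a.mz, b.mz)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_ledger_counts_sum_to_agc_times_microscans(self, registry,
                                                       noiseless_instrument):
        mix = iso.infusion_mix(registry, ("Pro", "Hyp", "Val"))
        _, truth = iso.simulate_spectrum(mix, noiseless_instrument, rng=5)
        total = sum(row["count"] for row in truth)
        assert total == (
            noiseless_instrument.agc_target * noiseless_instrument.microscans
        )

    def test_total_intensity_tracks_agc(self, registry, noiseless_instrument):
        mix = iso.infusion_mix(registry, ("Pro",))
        spectrum, _ = iso.simulate_spectrum(mix, noiseless_instrument, rng=6)
        # rendered area per microscan equals the AGC target (< 1% deviation
        # from edge effects)
        area = np.trapezoid(spectrum.intensity, spectrum.mz)
        assert area == pytest.approx(noiseless_instrument.agc_target, rel=0.01)

    def test_metadata_accepted_by_isoms_selection(self, registry,
                                                  noiseless_instrument):
        mix = iso.infusion_mix(registry, ("Pro",))
        spectrum, _ = iso.simulate_spectrum(mix, noiseless_instrument, rng=7)
        kept = iso.select_isoms_scans([spectrum], iso.ScanSelectionCriteria())
        assert len(kept) == 1

    def test_out_of_range_species_skipped_with_warning(self, registry,
                                                       noiseless_instrument):
        mix = iso.infusion_mix(registry, ("Pro", "Gly"))
        with pytest.warns(UserWarning, match="Gly"):
            spectrum, truth = iso.simulate_spectrum(mix, noiseless_instrument, rng=8)
        assert {row["species"] for row in truth} == {"Pro"}

    def test_all_species_out_of_range_rejected(self, registry,
                                               noiseless_instrument):
        mix = iso.infusion_mix(registry, ("Gly",))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no species"):
                iso.simulate_spectrum(mix, noiseless_instrument, rng=9)

    def test_rendered_ratio_converges_to_planted(self, registry, model):
        """Line/M area ratio approaches planted ratio x atom count at 1e7 ions."""
        big = iso.SimInstrument(
            agc_target=500_000, baseline_sd=0.0, jitter_ppm=0.0
        )
        mix = iso.infusion_mix(registry, ("Pro",))
        rng = np.random.default_rng(10)
        ratios, recovered = [], []
        for spectrum, truth in iso.iter_spectra(mix, big, 4, rng):
            ledger = pd.DataFrame(truth).set_index("label")
            ratios.append(ledger.loc["M1_13C", "count"] / ledger.loc["M", "count"])
            recovered.append(iso.spectrum_ratios(spectrum, registry["Pro"], model).r_c)
        # 4 x 1e7 ions: binomial SE of the mean ratio ~0.08% relative
        assert np.mean(ratios) == pytest.approx(4 * 0.011, rel=2e-3)
        assert np.mean(recovered) == pytest.approx(0.011, rel=2e-3)


class TestEffectiveAbundances:
    def test_control_media_is_baseline(self):
        base = iso.AbundanceSet.rounded_natural()
        out = effective_abundances(base, 150.0, 0.04)
        assert out.ratio("H") == pytest.approx(150e-6, rel=1e-12)

    def test_partial_incorporation_arithmetic(self):
        base = iso.AbundanceSet.rounded_natural()
        out = effective_abundances(base, 1000.0, 0.04)
        assert out.ratio("H") == pytest.approx(184e-6, rel=1e-12)

    def test_full_equilibration(self):
        base = iso.AbundanceSet.rounded_natural()
        out = effective_abundances(base, 1000.0, 1.0)
        assert out.ratio("H") == pytest.approx(1000e-6, rel=1e-12)

    def test_invalid_inputs(self):
        base = iso.AbundanceSet.rounded_natural()
        with pytest.raises(ValueError):
            effective_abundances(base, 1000.0, 1.5)
        with pytest.raises(ValueError):
            effective_abundances(base, 0.0, 1.0, baseline_ppm=150.0)


class TestRuns:
    def test_direct_infusion_run_all_scans_accepted(self, registry,
                                                    noiseless_instrument):
        mix = iso.infusion_mix(registry, ("Pro",))
        run = iso.simulate_run(mix, noiseless_instrument, 20, seed=3)
        assert len(run.spectra) == 20
        kept = iso.select_isoms_scans(run.spectra, iso.ScanSelectionCriteria())
        assert len(kept) == 20
        # ledger covers every (scan, line)
        per_scan = run.truth.groupby("scan_index")["count"].sum()
        assert (per_scan == noiseless_instrument.agc_target
                * noiseless_instrument.microscans).all()

    def test_lc_mode_separates_species_in_time(self, registry,
                                               noiseless_instrument, model):
        mix = iso.infusion_mix(registry, ("Pro", "Leu/Ile"))
        elution = {"Pro": (10.0, 4.0), "Leu/Ile": (70.0, 4.0)}
        run = iso.simulate_run(
            mix, noiseless_instrument, 40, seed=4, mode="lc", elution=elution
        )
        truth = run.truth
        early = truth[(truth.scan_index <= 10) & (truth.label == "M")]
        late = truth[(truth.scan_index >= 31) & (truth.label == "M")]
        early_share = early.groupby("species")["count"].sum()
        late_share = late.groupby("species")["count"].sum()
        assert early_share["Pro"] > 100 * early_share.get("Leu/Ile", 0) + 1
        assert late_share["Leu/Ile"] > 100 * late_share.get("Pro", 0) + 1

    def test_run_round_trips_through_mzml(self, registry, noiseless_instrument,
                                          tmp_path):
        mix = iso.infusion_mix(registry, ("Pro",))
        run = iso.simulate_run(mix, noiseless_instrument, 3, seed=5)
        path = tmp_path / "run.mzML"
        iso.write_mzml(run, path)
        back = iso.read_run(path)
        assert len(back) == 3
        for orig, rt in zip(run.spectra, back):
            np.testing.assert_array_equal(orig.mz, rt.mz)
            np.testing.assert_array_equal(orig.intensity, rt.intensity)
            assert rt.microscans == orig.microscans
            assert rt.hcd_energy == orig.hcd_energy


class TestMixtureComposition:
    def test_molar_mixture_recovered_in_monoisotopic_areas(
        self, registry, noiseless_instrument, model
    ):
        """2:1:1 molar mix shows up as 50/25/25 area contributions."""
        mix = iso.infusion_mix(
            registry, ("Pro", "Hyp", "Val"), molar=[2.0, 1.0, 1.0]
        )
        records = []
        rng = np.random.default_rng(12)
        for spectrum, _ in iso.iter_spectra(mix, noiseless_instrument, 10, rng):
            for name in ("Pro", "Hyp", "Val"):
                records.append(iso.spectrum_ratios(spectrum, registry[name], model))
        frame = iso.records_to_frame(records)
        contrib, _ = iso.species_contributions(frame)
        assert contrib["Pro"] == pytest.approx(50.0, abs=1.0)
        assert contrib["Hyp"] == pytest.approx(25.0, abs=1.0)
        assert contrib["Val"] == pytest.approx(25.0, abs=1.0)


def test_depletion_scenario_recovery(registry, model):
    """20x 13C and 10x 15N depletion is read back without any standard."""
    frame = iso.run_depletion_experiment(seed=21, replicates=1, n_scans=30)
    mean_c = frame["r_c"].mean()
    mean_n = frame["r_n"].mean()
    mean_h = frame["r_h"].mean()
    assert mean_c == pytest.approx(0.011 / 20, rel=0.02)
    assert mean_n == pytest.approx(0.0037 / 10, rel=0.05)
    assert mean_h * 1e6 == pytest.approx(80.0, rel=0.10)
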