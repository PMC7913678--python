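"""Neutral masses, K-adduct m/z prediction, filtering, annotation, ATD."""

import numpy as np
import pytest

from g4kit import ms
from g4kit.ms import (
    MassSpectrum,
    adduct_spacing,
    annotate,
    composition,
    extract_atd,
    infer_quartets,
    intensity_filter,
    neutral_mass,
    species_abundance,
    species_mz,
)
from g4kit.synthgen import make_atd, make_mass_spectrum

from conftest import MYC22, TEL24

# Standard atomic weights (IUPAC 2021), frozen here as the independent
# reference for the elemental-composition oracle.
ATOMIC_AVG = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "P": 30.974}


def oracle_average_mass(comp: dict) -> float:
    return sum(ATOMIC_AVG[el] * n for el, n in comp.items())


class TestNeutralMass:
    def test_thymidine_average_mass(self):
        # free thymidine is C10H14N2O5
        comp = composition("T")
        assert comp == {"C": 10, "H": 14, "N": 2, "O": 5, "P": 0}
        assert neutral_mass("T") == pytest.approx(oracle_average_mass(comp), abs=0.01)

    def test_linkage_mass_difference(self):
        # mass(AT) - mass(A) - mass(T) = HPO3 - H2O
        diff = neutral_mass("AT") - neutral_mass("A") - neutral_mass("T")
        hpo3_minus_h2o = oracle_average_mass({"H": 1, "P": 1, "O": 3}) - \
            oracle_average_mass({"H": 2, "O": 1})
        assert diff == pytest.approx(hpo3_minus_h2o, abs=0.01)

    def test_sequence_mass_against_composition_oracle(self):
        for seq in [TEL24, MYC22, "ACGT"]:
            assert neutral_mass(seq) == pytest.approx(
                oracle_average_mass(composition(seq)), rel=5e-5
            )

    @pytest.mark.parametrize("seq", ["T", "ACGT", MYC22])
    def test_monoisotopic_below_average(self, seq):
        assert neutral_mass(seq, "monoisotopic") < neutral_mass(seq, "average")

    def test_empty_sequence_error(self):
        with pytest.raises(Exception):
            neutral_mass("")


class TestSpeciesMz:
    def test_singly_deprotonated(self):
        M = 6000.0
        assert species_mz(M, 0, 1) == pytest.approx(M - ms.MASS_H["average"])

    def test_consecutive_adduct_spacing_at_z5(self):
        M = neutral_mass(MYC22)
        for b in range(4):
            gap = species_mz(M, b + 1, 5) - species_mz(M, b, 5)
            assert gap == pytest.approx(adduct_spacing(5), rel=1e-12)

    def test_spacing_invariant_all_b_z(self):
        M = 7000.0
        for z in range(1, 9):
            for b in range(5):
                gap = species_mz(M, b + 1, z) - species_mz(M, b, z)
                assert gap == pytest.approx(
                    (ms.MASS_K["average"] - ms.MASS_H["average"]) / z, rel=1e-12
                )

    def test_algebraic_inverse(self):
        M = neutral_mass(TEL24)
        for b, z in [(0, 1), (2, 5), (3, 6)]:
            mz = species_mz(M, b, z)
            back = mz * z + z * ms.MASS_H["average"] - b * (
                ms.MASS_K["average"] - ms.MASS_H["average"]
            )
            assert back == pytest.approx(M, rel=1e-12)

    def test_zero_charge_error(self):
        with pytest.raises(ValueError):
            species_mz(6000.0, 0, 0)


class TestIntensityFilter:
    def spectrum(self):
        rng = np.random.default_rng(11)
        mz = np.linspace(1000, 1500, 100)
        inten = np.concatenate([rng.uniform(0.0005, 0.009, 37),
                                rng.uniform(0.02, 0.9, 62), [1.0]])
        return MassSpectrum(mz, inten)

    def test_zero_threshold_is_identity(self):
        s = self.spectrum()
        out = intensity_filter(s, 0.0)
        assert np.array_equal(out.mz, s.mz)

    def test_known_survivor_count(self):
        # constructed fixture: 37 of 100 points below 1% of the base peak
        out = intensity_filter(self.spectrum(), 0.01)
        assert out.mz.size == 63
        assert out.metadata["points_removed"] == 37

    def test_ties_at_threshold_retained(self):
        s = MassSpectrum(np.array([1.0, 2.0, 3.0]), np.array([0.5, 1.0, 1.0]))
        out = intensity_filter(s, 0.5)
        assert out.mz.size == 3  # 0.5 == threshold: retained

    def test_idempotent_at_fixed_threshold(self):
        once = intensity_filter(self.spectrum(), 0.01)
        twice = intensity_filter(once, 0.01)
        assert np.array_equal(once.mz, twice.mz)

    def test_monotone_in_threshold(self):
        s = self.spectrum()
        sizes = [intensity_filter(s, t).mz.size for t in (0.0, 0.005, 0.01, 0.1, 0.5)]
        assert sizes == sorted(sizes, reverse=True)

    def test_base_peak_always_survives(self):
        # "intensity >= fraction * base" with fraction < 1 can never drop the
        # base peak, so a non-empty spectrum stays non-empty
        for thresh in (0.0, 0.01, 0.5, 0.999):
            out = intensity_filter(self.spectrum(), thresh)
            assert out.mz.size >= 1
            assert out.base_peak_intensity() == self.spectrum().base_peak_intensity()


class TestAnnotate:
    def test_round_trip_with_generator(self):
        truth = {(0, 5): 10.0, (1, 5): 20.0, (2, 5): 70.0}
        spec = make_mass_spectrum(MYC22, abundances=truth, noise_floor=0.002, seed=4)
        spec = intensity_filter(spec, 0.005)
        assigns = annotate(spec, MYC22)
        got = {s.b: s.relative_abundance for s in assigns}
        for (b, _z), want in truth.items():
            assert got[b] == pytest.approx(want, abs=1.0)

    def test_abundances_sum_to_100(self):
        spec = make_mass_spectrum(MYC22, abundances={(0, 5): 33.0, (2, 5): 67.0},
                                  noise_floor=0.01, seed=9)
        assigns = annotate(spec, MYC22)
        assert sum(s.relative_abundance for s in assigns) == pytest.approx(100.0, abs=0.01)

    def test_no_peaks_in_windows_gives_zero_abundances(self):
        mz = np.linspace(500.0, 600.0, 50)
        spec = MassSpectrum(mz, np.ones_like(mz))
        assigns = annotate(spec, MYC22, charges=(5,))
        assert all(s.matched_intensity == 0.0 for s in assigns)
        assert all(s.relative_abundance == 0.0 for s in assigns)

    def test_zero_intensity_assignments_retained(self):
        spec = make_mass_spectrum(MYC22, abundances={(2, 5): 100.0}, seed=0)
        assigns = annotate(spec, MYC22)
        bs = sorted(s.b for s in assigns)
        assert bs == [0, 1, 2]

    def test_multi_charge_annotation(self):
        truth = {(2, 4): 100.0, (2, 5): 100.0, (2, 6): 100.0}
        spec = make_mass_spectrum(MYC22, charges=(4, 5, 6), abundances=truth, seed=2)
        assigns = annotate(spec, MYC22, charges=(4, 5, 6))
        for z in (4, 5, 6):
            ab = species_abundance(assigns, z)
            assert ab[(1, 2)] == pytest.approx(100.0, abs=0.5)

    def test_overlapping_windows_warn(self):
        spec = make_mass_spectrum(MYC22, abundances={(2, 5): 100.0}, seed=0)
        with pytest.warns(UserWarning, match="overlap"):
            annotate(spec, MYC22, tolerance_Th=5.0)


class TestSpeciesAbundance:
    def test_single_species_is_100(self):
        spec = make_mass_spectrum(MYC22, abundances={(2, 5): 100.0}, seed=1)
        assigns = annotate(spec, MYC22, species=[(1, 2)])
        assert species_abundance(assigns, 5)[(1, 2)] == 100.0

    def test_equal_intensities_split_evenly(self):
        spec = make_mass_spectrum(MYC22, abundances={(1, 5): 50.0, (2, 5): 50.0}, seed=1)
        ab = species_abundance(annotate(spec, MYC22, species=[(1, 1), (1, 2)]), 5)
        assert ab[(1, 1)] == pytest.approx(50.0, abs=0.5)
        assert ab[(1, 2)] == pytest.approx(50.0, abs=0.5)

    def test_zero_total_errors(self):
        mz = np.linspace(500.0, 505.0, 30)
        spec = MassSpectrum(mz, np.zeros_like(mz))
        assigns = annotate(spec, MYC22)
        with pytest.raises(ValueError, match="zero total"):
            species_abundance(assigns, 5)


class TestInferQuartets:
    @pytest.mark.parametrize("b,expected", [(1, 2), (2, 3), (3, 4)])
    def test_n_plus_one(self, b, expected):
        assert infer_quartets(b) == expected

    def test_zero_potassium_reads_unfolded(self):
        assert infer_quartets(0) == ms.UNFOLDED

    def test_negative_error(self):
        with pytest.raises(ValueError):
            infer_quartets(-1)


class TestExtractATD:
    def test_full_window_is_total_ion_atd(self):
        ims = make_atd([32.0, 40.0], [1.0, 2.0], [1.0, 0.6], mz_center=1400.0)
        trace = extract_atd(ims, (0.0, 1e6))
        # marginalization: per-time totals match a direct group-by sum
        direct = {t: ims[ims[:, 0] == t, 2].sum() for t in np.unique(ims[:, 0])}
        assert np.allclose(trace.intensity, [direct[t] for t in trace.arrival_time_ms])

    def test_single_gaussian_mode_recovered(self):
        ims = make_atd([35.0], [1.5], [1.0], mz_center=1400.0, time_step_ms=0.1)
        trace = extract_atd(ims, (1399.0, 1401.0), normalize=True)
        mode = trace.arrival_time_ms[np.argmax(trace.intensity)]
        assert mode == pytest.approx(35.0, abs=0.1)
        assert trace.intensity.max() == 1.0

    def test_bimodal_two_components(self):
        ims = make_atd([30.0, 42.0], [1.0, 1.0], [1.0, 0.8], mz_center=1400.0)
        trace = extract_atd(ims, (1399.0, 1401.0))
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(trace.intensity, height=0.1 * trace.intensity.max())
        assert len(peaks) == 2

    def test_disjoint_window_error(self):
        ims = make_atd([35.0], [1.5], [1.0], mz_center=1400.0)
        with pytest.raises(ValueError, match="window"):
            extract_atd(ims, (2000.0, 2001.0))
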