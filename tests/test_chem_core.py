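"""Mass arithmetic, formula enumeration and isotope simulation."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings, strategies as st

from cannatrace.chem_core import (
    DEFAULT_BOUNDS,
    ELECTRON_MASS,
    ISOTOPES,
    MONOISOTOPIC_MASS,
    AdductSpec,
    ElementalFormula,
    ElementBounds,
    IsotopePattern,
    PROTONATED,
    WATER_LOSS_PROTONATED,
    enumerate_formulas,
    ion_mz,
    isotope_pattern,
    isotope_similarity,
    monoisotopic_mass,
    ppm_error,
    rdbe,
)
from cannatrace.spectral_library import build_default_roster

CBD = ElementalFormula.parse("C21H30O2")


class TestElementalFormula:
    def test_parse_hill_roundtrip(self):
        f = ElementalFormula.parse("C21H27D3O2")
        assert f["C"] == 21 and f["D"] == 3 and f["H"] == 27
        assert f.hill() == "C21H27D3O2"
        assert ElementalFormula.parse(f.hill()) == f

    @pytest.mark.parametrize("bad", ["", "Xx2", "C-1", "21C", "C21H30O2 "])
    def test_rejects_malformed_text(self, bad):
        with pytest.raises(ValueError):
            ElementalFormula.parse(bad)

    def test_rejects_empty_and_unknown_elements(self):
        with pytest.raises(ValueError):
            ElementalFormula({})
        with pytest.raises(ValueError):
            ElementalFormula({"Fe": 1})
        with pytest.raises(ValueError):
            ElementalFormula({"C": -1})

    def test_subtraction_guards_negative_counts(self):
        with pytest.raises(ValueError):
            ElementalFormula.parse("CH4").add({"O": -1})


class TestMonoisotopicMass:
    def test_water(self):
        assert monoisotopic_mass(ElementalFormula.parse("H2O")) == pytest.approx(
            18.0105646, abs=1e-6
        )

    def test_neutral_cbd(self):
        assert monoisotopic_mass(CBD) == pytest.approx(314.2245802, abs=1e-6)


class TestIonMz:
    @pytest.mark.parametrize(
        "formula, adduct, expected",
        [
            ("C21H30O2", "[M+H]+", 315.2319),  # protonated CBD
            ("C23H34O2", "[M+H]+", 343.2632),  # protonated CBDP
            ("C21H30O4", "[M-H2O+H]+", 329.2111),  # diOH-CBD water-loss ion
        ],
    )
    def test_four_decimal_values(self, formula, adduct, expected):
        mz = ion_mz(ElementalFormula.parse(formula), AdductSpec.from_label(adduct))
        assert round(mz, 4) == expected

    def test_water_loss_requires_oxygen(self):
        with pytest.raises(ValueError):
            ion_mz(ElementalFormula.parse("C5H12"), WATER_LOSS_PROTONATED)

    @given(
        c=st.integers(1, 30),
        h=st.integers(1, 60),
        o=st.integers(0, 8),
    )
    @settings(max_examples=50, deadline=None)
    def test_protonation_adds_exactly_one_proton_mass(self, c, h, o):
        f = ElementalFormula({"C": c, "H": h, "O": o})
        assert ion_mz(f, PROTONATED) - monoisotopic_mass(f) == pytest.approx(
            1.00727646, abs=1e-7
        )


class TestPpmError:
    def test_identity_is_zero(self):
        assert ppm_error(315.2319, 315.2319) == 0.0

    def test_signed_values(self):
        assert ppm_error(315.2320, 315.2319) == pytest.approx(0.317, abs=1e-3)
        assert ppm_error(315.2318, 315.2319) == pytest.approx(-0.317, abs=1e-3)

    @given(st.floats(100.0, 1000.0), st.floats(1e-5, 1e-2))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_around_theoretical(self, theo, delta):
        assert ppm_error(theo + delta, theo) == pytest.approx(
            -ppm_error(theo - delta, theo), rel=1e-9
        )

    def test_requires_positive_theoretical(self):
        with pytest.raises(ValueError):
            ppm_error(100.0, 0.0)


class TestRdbe:
    @pytest.mark.parametrize(
        "formula, expected",
        [("C21H30O2", 7.0), ("C21H31O2", 6.5), ("CH4", 0.0), ("C21H27D3O2", 7.0)],
    )
    def test_known_values(self, formula, expected):
        assert rdbe(ElementalFormula.parse(formula)) == expected

    def test_packaged_neutral_formulas_have_integer_rdbe(self):
        for entry in build_default_roster():
            value = rdbe(entry.neutral_formula)
            assert value >= 0 and value == int(value), entry.abbreviation


def _brute_force_cho(mz, tol_ppm, adduct=PROTONATED, rdbe_range=(0.0, 25.0)):
    """Independent nested-loop enumeration over the default CHO bounds."""
    hits = set()
    for c in range(0, 41):
        for h in range(0, 81):
            for o in range(0, 11):
                if c + h + o == 0:
                    continue
                mass = (
                    c * MONOISOTOPIC_MASS["C"]
                    + h * MONOISOTOPIC_MASS["H"]
                    + o * MONOISOTOPIC_MASS["O"]
                )
                ion = mass + adduct.mass_delta - adduct.charge * ELECTRON_MASS
                if abs((mz - ion) / ion * 1e6) > tol_ppm:
                    continue
                r = c - h / 2.0 + 1.0
                if rdbe_range[0] <= r <= rdbe_range[1]:
                    hits.add((c, h, o))
    return hits


class TestEnumerateFormulas:
    def test_cbd_found_at_its_own_ion_mass(self):
        hits = enumerate_formulas(315.2319, 3.0, PROTONATED)
        assert CBD in {f for f, _ in hits}

    def test_zero_tolerance_keeps_only_exact_formulas(self):
        mz = ion_mz(CBD, PROTONATED)
        hits = enumerate_formulas(mz, 0.0, PROTONATED)
        assert {f for f, _ in hits} == {CBD}
        assert all(err == 0.0 for _, err in hits)

    def test_sorted_by_absolute_error(self):
        hits = enumerate_formulas(347.2216, 5.0, PROTONATED)
        errs = [abs(e) for _, e in hits]
        assert errs == sorted(errs)

    @pytest.mark.parametrize("mz", [347.2216, 315.2319, 193.1228, 450.1111])
    def test_equals_brute_force_enumeration(self, mz):
        got = {
            (f["C"], f["H"], f["O"]) for f, _ in enumerate_formulas(mz, 5.0, PROTONATED)
        }
        assert got == _brute_force_cho(mz, 5.0)

    def test_brute_force_equivalence_over_random_masses(self):
        import numpy as np

        rng = np.random.default_rng(42)
        for mz in rng.uniform(100.0, 600.0, size=30):
            got = {
                (f["C"], f["H"], f["O"])
                for f, _ in enumerate_formulas(float(mz), 5.0, PROTONATED)
            }
            assert got == _brute_force_cho(float(mz), 5.0), mz

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            enumerate_formulas(300.0, -1.0, PROTONATED)


def _exact_convolution(formula):
    """Independent exact isotopologue distribution (no binning, no
    exponentiation shortcuts): one convolution per atom."""
    dist = {0.0: 1.0}
    for elem, n in formula:
        for _ in range(n):
            new = {}
            for m, a in dist.items():
                for im, ia in ISOTOPES[elem]:
                    key = round(m + im, 7)
                    new[key] = new.get(key, 0.0) + a * ia
            dist = new
    return dist


class TestIsotopePattern:
    def test_single_hydrogen_ratio(self):
        pat = isotope_pattern(ElementalFormula({"H": 1}))
        assert len(pat.peaks) == 2
        ratio = pat.peaks[1][1] / pat.peaks[0][1]
        assert ratio == pytest.approx(0.000115 / 0.999885, rel=1e-9)

    def test_cbd_m1_matches_exact_convolution(self):
        # independent oracle: atom-by-atom convolution, nominal-mass binning
        exact = _exact_convolution(CBD)
        bins: dict[int, float] = {}
        for m, a in exact.items():
            bins[round(m)] = bins.get(round(m), 0.0) + a
        oracle_m1 = bins[315] / bins[314]
        pat = isotope_pattern(CBD)
        m1 = pat.peaks[1][1]
        assert m1 == pytest.approx(oracle_m1, rel=1e-6)
        assert m1 == pytest.approx(0.2313425, abs=1e-6)  # frozen oracle value

    def test_prune_one_keeps_only_base(self):
        pat = isotope_pattern(CBD, prune=1.0)
        assert pat.peaks == ((pytest.approx(314.2245802, abs=1e-6), 1.0),)

    def test_total_probability_mass_is_one(self):
        from cannatrace.chem_core import _raw_isotope_distribution

        total = sum(a for _, a in _raw_isotope_distribution(CBD, 0.01))
        assert total == pytest.approx(1.0, abs=1e-9)


class TestIsotopeSimilarity:
    def test_identity_scores_one(self):
        p = isotope_pattern(CBD)
        assert isotope_similarity(p, p) == 1.0

    def test_missing_peaks_penalised(self):
        theo = isotope_pattern(CBD)
        obs = IsotopePattern(((theo.peaks[0][0], 1.0),))
        assert isotope_similarity(obs, theo) < 1.0

    def test_hand_computed_two_peak_case(self):
        # obs {0: 1.0}, theo {0: 1.0, +1: 0.2}: deviation 0.2, total 2.2
        obs = IsotopePattern(((100.0, 1.0),))
        theo = IsotopePattern(((100.0, 1.0), (101.0, 0.2)))
        expected = 1.0 - 0.2 / 2.2
        assert isotope_similarity(obs, theo) == pytest.approx(expected, rel=1e-12)
        assert isotope_similarity(theo, obs) == pytest.approx(expected, rel=1e-12)

    def test_alignment_is_base_peak_relative(self):
        # same envelope shape at shifted absolute mass (ion vs neutral)
        neutral = isotope_pattern(CBD)
        shifted = IsotopePattern(tuple((m + 1.00728, a) for m, a in neutral.peaks))
        assert isotope_similarity(shifted, neutral) == pytest.approx(1.0)
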