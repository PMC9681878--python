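"""Library I/O, CCS/MS2 scoring and the five-criterion matcher."""

from __future__ import annotations

import math

import pytest

from cannatrace.chem_core import AdductSpec, ElementalFormula, ion_mz, isotope_pattern
from cannatrace.feature_io import Feature4D, FormatError, MS2Spectrum
from cannatrace.spectral_library import (
    LibraryEntry,
    MatchTolerances,
    build_default_roster,
    delta_ccs_pct,
    load_default_library,
    match_feature,
    ms2_cosine,
    read_library,
    write_library,
)


def _entry(abbrev, formula="C21H30O2", rt=4.99, ccs=186.6, peaks=((193.1228, 100.0),)):
    f = ElementalFormula.parse(formula)
    adduct = AdductSpec.from_label("[M+H]+")
    ms2 = MS2Spectrum(abbrev, ion_mz(f, adduct), tuple(peaks)) if peaks else None
    return LibraryEntry(
        name=abbrev, abbreviation=abbrev, neutral_formula=f, adduct=adduct,
        rt=rt, ccs=ccs, ms2=ms2,
    )


class TestLibraryIO:
    def test_round_trip(self, tmp_path):
        entries = [
            _entry("CBD"),
            _entry("CBDB", "C20H28O2", 3.92, 179.0, ((179.107, 100.0),)),
            _entry("EMPTY", "C19H26O2", 3.2, 175.0, peaks=None),
        ]
        path = tmp_path / "lib.msp"
        write_library(entries, path)
        back = read_library(path)
        assert [e.abbreviation for e in back] == ["CBD", "CBDB", "EMPTY"]
        assert back[0].neutral_formula == entries[0].neutral_formula
        assert back[0].rt == entries[0].rt and back[0].ccs == entries[0].ccs
        assert back[0].ms2.peaks[0][0] == pytest.approx(193.1228, abs=1e-4)
        assert back[2].ms2 is None  # NUM PEAKS 0 -> spectrum absent

    def test_packaged_library_has_39_entries(self, library):
        assert len(library) == 39
        assert len({e.abbreviation for e in library}) == 39

    def test_duplicate_abbrev_rejected(self, tmp_path):
        path = tmp_path / "dup.msp"
        write_library([_entry("CBD")], path)
        text = path.read_text()
        path.write_text(text + "\n" + text)
        with pytest.raises(FormatError, match="duplicate"):
            read_library(path)

    def test_unknown_key_warns_and_is_preserved(self, tmp_path):
        path = tmp_path / "extra.msp"
        write_library([_entry("CBD")], path)
        lines = path.read_text().splitlines()
        lines.insert(1, "VENDOR: someone")
        path.write_text("\n".join(lines))
        with pytest.warns(UserWarning, match="VENDOR"):
            (entry,) = read_library(path)
        assert "VENDOR=someone" in entry.provenance

    def test_packaged_mz_consistent_with_mass_core(self, library):
        # the MZ stored in the packaged file must equal ion_mz(formula, adduct)
        for entry in library:
            if entry.ms2 is not None:
                assert entry.ms2.precursor_mz == pytest.approx(
                    entry.theoretical_mz, abs=5e-5
                ), entry.abbreviation


class TestDeltaCcs:
    def test_equal_values_give_zero(self):
        assert delta_ccs_pct(186.0, 186.0) == 0.0

    def test_cbe_isomer_versus_cbe(self):
        # the reference CCS sits in the denominator
        assert delta_ccs_pct(184.9, 186.0) == pytest.approx(0.59140, abs=1e-4)
        assert delta_ccs_pct(186.0, 184.9) == pytest.approx(0.59492, abs=1e-4)
        assert delta_ccs_pct(184.9, 186.0) != delta_ccs_pct(186.0, 184.9)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            delta_ccs_pct(0.0, 186.0)


class TestMs2Cosine:
    def test_identity(self):
        s = MS2Spectrum("s", 315.23, ((135.0442, 60.0), (205.1224, 100.0)))
        assert ms2_cosine(s, s) == pytest.approx(1.0)

    def test_disjoint_spectra_score_zero(self):
        a = MS2Spectrum("a", 315.23, ((100.0, 50.0),))
        b = MS2Spectrum("b", 315.23, ((200.0, 50.0),))
        assert ms2_cosine(a, b) == 0.0

    def test_hand_computed_two_peak_case(self):
        # a = (3, 4) on peaks {100, 150}; b = (4, 3): cos = 24/25
        a = MS2Spectrum("a", 300.0, ((100.0, 3.0), (150.0, 4.0)))
        b = MS2Spectrum("b", 300.0, ((100.0, 4.0), (150.0, 3.0)))
        expected = (3 * 4 + 4 * 3) / (5.0 * 5.0)
        assert ms2_cosine(a, b) == pytest.approx(expected, rel=1e-12)
        assert ms2_cosine(b, a) == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_matchms_greedy_cosine(self):
        import numpy as np
        from matchms import Spectrum
        from matchms.similarity import CosineGreedy

        a = MS2Spectrum("a", 331.2268, ((135.0442, 60.0), (193.1228, 30.0), (205.1224, 100.0)))
        b = MS2Spectrum("b", 331.2268, ((135.0448, 55.0), (205.1227, 90.0), (231.1378, 10.0)))
        mine = ms2_cosine(a, b, frag_tol=0.005)

        def to_matchms(s):
            return Spectrum(
                mz=np.array([m for m, _ in s.peaks]),
                intensities=np.array([i for _, i in s.peaks]),
                metadata={"precursor_mz": s.precursor_mz},
            )

        score = CosineGreedy(tolerance=0.005).pair(to_matchms(a), to_matchms(b))
        assert mine == pytest.approx(float(score["score"]), abs=1e-6)


class TestMatchFeature:
    def _cbd_feature(self, entry, **kw):
        defaults = dict(
            feature_id="f", sample_id="s", mz=entry.theoretical_mz, rt=entry.rt,
            intensity=1e5, snr=100.0, ccs=entry.ccs, ms2_ref="f",
        )
        defaults.update(kw)
        return Feature4D(**defaults)

    def test_identity_match_is_validated(self, library):
        cbd = next(e for e in library if e.abbreviation == "CBD")
        feature = self._cbd_feature(cbd)
        observed_iso = isotope_pattern(cbd.neutral_formula)
        results = match_feature(feature, cbd.ms2, library, isotope=observed_iso)
        best = results[0]
        assert best.entry.abbreviation == "CBD"
        assert best.level == "validated"
        assert best.delta_ppm == 0.0 and best.delta_ccs_pct == 0.0

    def test_cbdb_profiling_row_validates(self, library):
        cbdb = next(e for e in library if e.abbreviation == "CBDB")
        feature = Feature4D(
            feature_id="f", sample_id="s", mz=301.2160, rt=3.92,
            intensity=5e3, snr=50.0,
            ccs=cbdb.ccs * 1.006,  # within the 0.6 % reported agreement
            ms2_ref="f",
        )
        results = match_feature(
            feature, cbdb.ms2, library, isotope=isotope_pattern(cbdb.neutral_formula)
        )
        best = results[0]
        assert best.entry.abbreviation == "CBDB"
        assert best.level == "validated"
        assert abs(best.delta_ppm) <= 1.0

    def test_mass_gate_excludes_everything_at_30_ppm(self, library):
        shifted = Feature4D(
            feature_id="f", sample_id="s", mz=315.2319 * (1 + 30e-6), rt=4.99,
            intensity=1e5, snr=100.0,
        )
        hits = match_feature(shifted, None, library)
        assert all(abs(r.delta_ppm) <= 5.0 for r in hits)
        assert not any(r.entry.abbreviation == "CBD" for r in hits)

    def test_absent_ccs_ms2_isotope_fail_their_criteria(self, library):
        cbd = next(e for e in library if e.abbreviation == "CBD")
        bare = Feature4D(
            feature_id="f", sample_id="s", mz=cbd.theoretical_mz, rt=cbd.rt,
            intensity=1e5, snr=100.0,
        )
        best = match_feature(bare, None, library)[0]
        assert best.criteria_passed == {
            "rt": True, "mass": True, "isotope": False, "ccs": False, "ms2": False,
        }
        assert best.level != "validated"

    def test_tightening_tolerances_never_adds_matches(self, library):
        feature = Feature4D(
            feature_id="f", sample_id="s", mz=331.2268, rt=3.0,
            intensity=1e4, snr=30.0,
        )
        loose = {r.entry.abbreviation for r in match_feature(feature, None, library)}
        tight = {
            r.entry.abbreviation
            for r in match_feature(
                feature, None, library, MatchTolerances(ppm=1.0, rt_min=0.05)
            )
        }
        assert tight <= loose

    def test_empty_library_is_an_error(self):
        feature = Feature4D(
            feature_id="f", sample_id="s", mz=315.2319, rt=4.99,
            intensity=1e5, snr=100.0,
        )
        with pytest.raises(ValueError):
            match_feature(feature, None, [])
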