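"""Library construction: consensus merging, the theta-blend with theoretical
spectra, Y-ion injection, and sequon-preserving decoy generation."""

import math

import pytest

from glypsearch import (
    LibraryBuildConfig,
    Modification,
    MsmsSpectrum,
    Peak,
    PeptideIdentification,
    Tolerance,
    build_consensus,
    build_library,
    make_decoy,
    optimize_spectrum,
    peptide_neutral_mass,
    sequon_preserving_reversal,
    theoretical_by_ions,
    y_core_ions,
)
from glypsearch.chem import PROTON, WATER, AA_MASSES

TOL = Tolerance(0.02, "da")


def _spec(peaks, sid="s", charge=2):
    return MsmsSpectrum(sid, 500.0, charge, [Peak(m, i) for m, i in peaks])


def _ident(sequence="ANGTK", mods=(Modification(2, "Deamidation", 0.984016),), charge=2, sid="s"):
    from glypsearch import find_glycosites

    return PeptideIdentification(
        spectrum_id=sid,
        sequence=sequence,
        modifications=tuple(mods),
        charge=charge,
        glycosites=find_glycosites(sequence),
    )


class TestConsensus:
    def test_singleton_unchanged(self):
        s = _spec([(500.0, 10.0), (600.0, 5.0)])
        assert build_consensus([s], TOL) == s.peaks

    def test_common_peaks_averaged(self):
        a = _spec([(500.00, 10.0)])
        b = _spec([(500.001, 30.0)])
        (peak,) = build_consensus([a, b], TOL)
        assert peak.intensity == pytest.approx(20.0)
        assert peak.mz == pytest.approx(500.0005)

    def test_singleton_peak_kept_at_own_intensity(self):
        a = _spec([(500.0, 10.0), (700.0, 8.0)])
        b = _spec([(500.0, 30.0)])
        peaks = build_consensus([a, b], TOL)
        assert [p.intensity for p in peaks] == [pytest.approx(20.0), pytest.approx(8.0)]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_consensus([], TOL)


class TestTheoreticalIons:
    def test_dipeptide_closed_form(self):
        ions = dict(theoretical_by_ions("AG", (), 1))
        assert ions["b1+1"] == pytest.approx(AA_MASSES["A"] + PROTON, abs=1e-9)
        assert ions["y1+1"] == pytest.approx(AA_MASSES["G"] + WATER + PROTON, abs=1e-9)

    @pytest.mark.parametrize("length", [2, 5, 12])
    def test_ion_count(self, length):
        seq = "A" * (length - 1) + "K"
        assert len(theoretical_by_ions(seq, (), 1)) == 2 * (length - 1)
        assert len(theoretical_by_ions(seq, (), 3)) == 4 * (length - 1)

    def test_modification_shifts_containing_ions(self):
        plain = dict(theoretical_by_ions("ANGTK", (), 1))
        modded = dict(theoretical_by_ions("ANGTK", (Modification(2, "x", 0.5),), 1))
        assert modded["b1+1"] == pytest.approx(plain["b1+1"])
        assert modded["b2+1"] == pytest.approx(plain["b2+1"] + 0.5)
        assert modded["y3+1"] == pytest.approx(plain["y3+1"])
        assert modded["y4+1"] == pytest.approx(plain["y4+1"] + 0.5)


def test_y_core_ladder():
    ions = dict(y_core_ions(1000.0, (1,)))
    expected = {
        "Y0+1": 1000.0,
        "Y1+1": 1203.079373,
        "Y2+1": 1406.158745,
        "Y3+1": 1568.211568,
        "Y4+1": 1730.264392,
        "Y5+1": 1892.317215,
    }
    for label, neutral in expected.items():
        assert ions[label] == pytest.approx(neutral + PROTON, abs=1e-5)
    doubly = dict(y_core_ions(1000.0, (1, 2)))
    assert doubly["Y0+2"] == pytest.approx(500.0 + PROTON, abs=1e-9)


class TestOptimize:
    def test_theta_zero_keeps_consensus_intensities_at_theoretical_mz(self):
        ident = _ident()
        config = LibraryBuildConfig(theta=0.0)
        theo = dict(theoretical_by_ions("AJGTK", (), 2))
        consensus = [Peak(theo["b2+1"] + 0.003, 50.0), Peak(1234.5, 100.0)]
        lib = optimize_spectrum(consensus, ident, config)
        annotated = {p.annotation: p for p in lib.peaks if p.is_annotated and p.annotation[0] in "by"}
        assert set(annotated) == {"b2+1"}  # unmatched theoretical peaks dropped at theta=0
        assert annotated["b2+1"].mz == pytest.approx(theo["b2+1"], abs=1e-9)  # repositioned
        assert annotated["b2+1"].intensity == pytest.approx(0.5)  # 50/100 of base

    def test_theta_one_is_purely_theoretical(self):
        ident = _ident()
        config = LibraryBuildConfig(theta=1.0)
        lib = optimize_spectrum([Peak(333.3, 80.0)], ident, config)
        by_peaks = [p for p in lib.peaks if p.annotation and p.annotation[0] in "by"]
        y_peaks = [p for p in lib.peaks if p.annotation and p.annotation.startswith("Y")]
        assert all(p.intensity == pytest.approx(1.0) for p in by_peaks)
        assert len(by_peaks) == 2 * 4 * 2  # b/y at 1+ and 2+
        assert len(y_peaks) == 12  # Y0..Y5 at 1+ and 2+
        assert not any(p.mz == pytest.approx(333.3) for p in lib.peaks)

    @pytest.mark.parametrize("theta", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_theta_affine_mix(self, theta):
        """Matched-peak intensity before renormalization is exactly
        theta*1 + (1-theta)*consensus, recomputed here by brute force."""
        ident = _ident()
        config = LibraryBuildConfig(theta=theta)
        theo = dict(theoretical_by_ions("AJGTK", (), 2))
        consensus = [Peak(theo["y2+1"], 60.0), Peak(theo["b3+1"], 30.0), Peak(777.7, 100.0)]
        lib = optimize_spectrum(consensus, ident, config)
        expected = {
            "y2+1": theta + (1 - theta) * 0.6,
            "b3+1": theta + (1 - theta) * 0.3,
        }
        scale = max(
            max(expected.values()),
            theta if theta > 0 else 0.0,
            (1 - theta) * 1.0,
        )
        found = {p.annotation: p.intensity for p in lib.peaks if p.annotation in expected}
        for label, value in expected.items():
            assert found[label] == pytest.approx(value / scale, abs=1e-12)

    def test_precursor_is_bare_peptide_mass(self):
        ident = _ident()
        lib = optimize_spectrum([Peak(500.0, 1.0)], ident, LibraryBuildConfig())
        assert lib.peptide == "AJGTK"
        assert lib.modifications == ()  # deamidation stripped at the glycosite
        assert lib.precursor_neutral_mass == pytest.approx(peptide_neutral_mass("ANGTK"), abs=1e-9)

    def test_nonsite_modifications_survive(self):
        ident = _ident(
            sequence="AMNGTK",
            mods=(Modification(2, "Oxidation", 15.994915), Modification(3, "Deamidation", 0.984016)),
        )
        lib = optimize_spectrum([Peak(500.0, 1.0)], ident, LibraryBuildConfig())
        assert lib.peptide == "AMJGTK"
        assert lib.modifications == (Modification(2, "Oxidation", 15.994915),)

    def test_y_ions_at_forty_percent(self):
        lib = optimize_spectrum([Peak(500.0, 1.0)], _ident(), LibraryBuildConfig())
        y = [p for p in lib.peaks if p.annotation and p.annotation.startswith("Y")]
        labels = {p.annotation.split("+")[0] for p in y}
        assert labels == {"Y0", "Y1", "Y2", "Y3", "Y4", "Y5"}
        assert all(p.intensity == pytest.approx(0.40) for p in y)
        assert max(p.intensity for p in lib.peaks) == pytest.approx(1.0)


class TestDecoy:
    def test_sequon_preserving_reversal(self):
        assert sequon_preserving_reversal("AJGTK", (2,))[0] == "KJGTA"
        decoy, mapping = sequon_preserving_reversal("ACDJGTWK", (4,))
        # movable positions 1,2,3,7,8 hold A,C,D,W,K -> reversed K,W,D,C,A
        assert decoy == "KWDJGTCA"
        assert mapping[1] == 8 and mapping[2] == 7 and mapping[4] == 4

    def test_decoy_matches_target_except_by_positions(self):
        ident = _ident(sequence="ACDNGTWK", mods=(Modification(4, "Deamidation", 0.984016),))
        target = optimize_spectrum([Peak(400.0, 1.0), Peak(800.0, 0.7)], ident, LibraryBuildConfig())
        decoy = make_decoy(target)
        assert decoy.is_decoy and not target.is_decoy
        assert decoy.peptide == "KWDJGTCA"
        assert decoy.precursor_neutral_mass == target.precursor_neutral_mass  # exact
        assert decoy.charge == target.charge
        assert len(decoy.peaks) == len(target.peaks)
        # Y ions and unannotated peaks are byte-identical
        t_other = [p for p in target.peaks if not (p.annotation and p.annotation[0] in "by")]
        d_other = [p for p in decoy.peaks if not (p.annotation and p.annotation[0] in "by")]
        assert t_other == d_other
        # annotated b/y intensities form the same multiset, at decoy positions
        t_by = sorted(p.intensity for p in target.peaks if p.annotation and p.annotation[0] in "by")
        d_by = sorted(p.intensity for p in decoy.peaks if p.annotation and p.annotation[0] in "by")
        assert t_by == pytest.approx(d_by)
        expected = dict(theoretical_by_ions("KWDJGTCA", (), ident.charge))
        for peak in decoy.peaks:
            if peak.annotation and peak.annotation[0] in "by":
                assert peak.mz == pytest.approx(expected[peak.annotation], abs=1e-9)

    def test_modifications_travel_with_residues(self):
        ident = _ident(
            sequence="AMNGTK",
            mods=(Modification(2, "Oxidation", 15.994915), Modification(3, "Deamidation", 0.984016)),
        )
        target = optimize_spectrum([Peak(500.0, 1.0)], ident, LibraryBuildConfig())
        decoy = make_decoy(target)
        # movable positions are 1,2,6; the middle one maps onto itself
        assert decoy.peptide == "KMJGTA"
        (mod,) = decoy.modifications
        assert mod.position == 2
        assert decoy.peptide[mod.position - 1] == "M"


class TestBuildLibrary:
    def test_grouping(self, small_bundle):
        lib = build_library(small_bundle.identifications, small_bundle.library_spectra)
        assert len(lib.targets) == len(small_bundle.peptides)
        assert len(lib.decoys) == len(lib.targets)

    def test_replicates_collapse_to_one_entry(self):
        idents = [_ident(sid=f"s{i}") for i in range(3)]
        spectra = [_spec([(300.0, 1.0)], sid=f"s{i}") for i in range(3)]
        lib = build_library(idents, spectra)
        assert len(lib.targets) == 1 and len(lib.decoys) == 1
        assert lib.targets[0].source_psm_count == 3

    def test_distinct_peptides_and_charges_split(self):
        idents = [
            _ident(sid="a"),
            _ident(sequence="GGNGTWK", sid="b"),
            _ident(charge=3, sid="c"),
        ]
        spectra = [_spec([(300.0, 1.0)], sid=s) for s in "abc"]
        lib = build_library(idents, spectra)
        assert len(lib.targets) == 3

    def test_unresolvable_and_siteless_rows_skipped(self):
        idents = [_ident(sid="present"), _ident(sid="absent"), _ident(sequence="ANPTK", sid="p2")]
        idents[2].glycosites = ()
        idents[2].has_glycosite = False
        lib = build_library(idents, [_spec([(300.0, 1.0)], sid="present")])
        assert len(lib.targets) == 1

    def test_save_load_round_trip(self, small_library, tmp_path):
        mgf = tmp_path / "lib.mgf"
        manifest = tmp_path / "manifest.tsv"
        small_library.save(mgf, manifest)
        loaded = type(small_library).load(mgf)
        assert len(loaded) == len(small_library)
        for a, b in zip(small_library.entries, loaded.entries):
            assert (a.entry_id, a.peptide, a.charge, a.is_decoy) == (
                b.entry_id, b.peptide, b.charge, b.is_decoy,
            )
            assert b.precursor_neutral_mass == pytest.approx(a.precursor_neutral_mass, abs=1e-4)
            assert b.annotated_count == a.annotated_count
            assert len(b.peaks) == len(a.peaks)
        lines = manifest.read_text().splitlines()
        assert len(lines) == 1 + len(small_library.entries)
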