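import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from exoflux import (
    Adduct,
    CompoundRecord,
    IdentificationParams,
    Polarity,
    SpectralLibrary,
    assign_identification,
    default_adducts,
    generate_library_with_decoys,
    mass_rt_gate,
    msms_similarity,
    ppm_error,
)
from exoflux.model import MsiLevel

PARAMS = IdentificationParams()


class TestPpmError:
    def test_identity_is_zero(self):
        assert ppm_error(343.1235, 343.1235) == 0.0

    def test_hand_value(self):
        assert ppm_error(343.1252, 343.1235) == pytest.approx(4.95, abs=0.01)

    def test_non_positive_mz_rejected(self):
        with pytest.raises(ValueError):
            ppm_error(-1.0, 343.1235)


class TestMassRtGate:
    ADDUCT = Adduct("[M+H]+", 343.1235, Polarity.positive)

    def gate(self, mz, rt, ref_rt=7.4, polarity=Polarity.positive):
        return mass_rt_gate(mz, rt, polarity, self.ADDUCT, ref_rt, PARAMS)

    def test_within_ppm_and_rt_passes(self):
        passed, ppm, _, rt_d, _ = self.gate(343.1252, 7.6)
        assert passed and ppm == pytest.approx(4.95, abs=0.01) and rt_d == pytest.approx(0.2)

    def test_da_branch_of_or_rule(self):
        """9 ppm at m/z 100 still passes: 0.0009 Da <= 0.001 Da."""
        adduct = Adduct("[M+H]+", 100.0, Polarity.positive)
        passed, ppm, da, _, _ = mass_rt_gate(
            100.0009, 5.0, Polarity.positive, adduct, 5.0, PARAMS
        )
        assert passed and ppm == pytest.approx(9.0, abs=0.01) and da <= 0.001

    def test_rt_gate_fails_alone(self):
        passed, _, _, _, reason = self.gate(343.1235, 8.2)
        assert not passed and reason == "rt_gate_fail"

    def test_polarity_mismatch_recorded_not_raised(self):
        passed, _, _, _, reason = self.gate(343.1235, 7.4, polarity=Polarity.negative)
        assert not passed and reason == "polarity_mismatch"

    @given(
        ppm_off=st.sampled_from([0.0, 2.0, 4.9999, 5.0, 5.0001, 8.0, 30.0]),
        rt_off=st.sampled_from([0.0, 0.3, 0.5, 0.5001, 1.5]),
    )
    @settings(max_examples=60, deadline=None)
    def test_gate_truth_table(self, ppm_off, rt_off):
        """Gate logic is exactly (ppm OR Da) AND RT, boundaries inclusive."""
        theo = 343.1235
        mz = theo * (1 + ppm_off / 1e6)
        da = abs(mz - theo)
        passed, *_ = mass_rt_gate(
            mz, 7.4 + rt_off, Polarity.positive,
            Adduct("[M+H]+", theo, Polarity.positive), 7.4, PARAMS,
        )
        expected = (ppm_off <= 5.0 + 1e-9 or da <= 0.001) and rt_off <= 0.5
        assert passed == expected


class TestMsmsSimilarity:
    def test_identical_spectra_score_one(self):
        spec = [(85.0, 0.6), (127.0, 1.0)]
        assert msms_similarity(spec, spec) == pytest.approx(1.0)

    def test_disjoint_spectra_score_zero(self):
        assert msms_similarity([(100.0, 1.0)], [(200.0, 1.0)]) == 0.0

    def test_hand_cosine(self):
        a = [(100.0, 1.0), (200.0, 1.0)]
        b = [(100.0, 1.0)]
        assert msms_similarity(a, b) == pytest.approx(1 / np.sqrt(2), abs=1e-9)

    def test_empty_spectrum_absent_not_zero(self):
        assert msms_similarity([], [(100.0, 1.0)]) is None

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = [(float(m), float(i)) for m, i in
             zip(rng.uniform(50, 500, 5), rng.uniform(0.1, 1.0, 5))]
        b = [(float(m), float(i)) for m, i in
             zip(rng.uniform(50, 500, 4), rng.uniform(0.1, 1.0, 4))]
        assert msms_similarity(a, b) == pytest.approx(msms_similarity(b, a), abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_matchms_cosine_greedy(self, seed):
        """Independent oracle: matchms CosineGreedy with sqrt weighting."""
        from matchms import Spectrum
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(seed)
        mz_a = np.sort(rng.uniform(50, 500, 6))
        mz_b = np.sort(np.concatenate([mz_a[:3] + rng.uniform(-0.005, 0.005, 3),
                                       rng.uniform(50, 500, 3)]))
        ia = rng.uniform(0.1, 1.0, 6)
        ib = rng.uniform(0.1, 1.0, 6)
        ours = msms_similarity(list(zip(mz_a, ia)), list(zip(mz_b, ib)), 0.01)
        oracle = CosineGreedy(tolerance=0.01, mz_power=0.0, intensity_power=0.5).pair(
            Spectrum(mz=mz_a, intensities=ia, metadata={}, metadata_harmonization=False),
            Spectrum(mz=np.sort(mz_b), intensities=ib[np.argsort(mz_b)],
                     metadata={}, metadata_harmonization=False),
        )
        assert ours == pytest.approx(float(oracle["score"]), abs=1e-6)


class TestAssignIdentification:
    def feature_for(self, rec, rt_shift=0.0, ppm_shift=0.0):
        mz = rec.adducts[0].mz * (1 + ppm_shift / 1e6)
        return dict(observed_mz=mz, observed_rt=rec.reference_rt + rt_shift,
                    polarity=Polarity.positive)

    def test_msms_match_gives_score_3(self, tiny_library):
        rec = tiny_library.get("trehalose")
        ident = assign_identification(
            "f1", **self.feature_for(rec), library=tiny_library,
            observed_msms=rec.msms,
        )
        assert ident.score == 3
        assert ident.msi_level == MsiLevel.level1_plus_msms
        assert ident.compound == "trehalose"

    def test_msms_mismatch_vetoes(self, tiny_library):
        rec = tiny_library.get("trehalose")
        ident = assign_identification(
            "f1", **self.feature_for(rec), library=tiny_library,
            observed_msms=[(999.0 - 700.0, 1.0)],  # no shared fragment
        )
        assert ident.msi_level == MsiLevel.unidentified
        assert ident.reason == "msms_mismatch"

    def test_no_gate_pass_unidentified(self, tiny_library):
        ident = assign_identification(
            "f1", observed_mz=500.0, observed_rt=1.0,
            polarity=Polarity.positive, library=tiny_library,
        )
        assert ident.score == 0 and ident.msi_level == MsiLevel.unidentified

    def test_mass_rt_without_msms_is_level1(self, tiny_library):
        rec = tiny_library.get("glucose")  # no reference spectrum
        ident = assign_identification(
            "f1", **self.feature_for(rec), library=tiny_library,
        )
        assert ident.score == 2 and ident.msi_level == MsiLevel.level1

    def test_tie_break_is_deterministic(self):
        recs = [
            CompoundRecord(name=n, neutral_mass=342.1162,
                           adducts=default_adducts(342.1162), reference_rt=7.4)
            for n in ("zeta", "alpha")
        ]
        lib = SpectralLibrary(records=recs)
        ident = assign_identification(
            "f1", observed_mz=343.1235, observed_rt=7.4,
            polarity=Polarity.positive, library=lib,
        )
        assert ident.compound == "alpha"  # lexical tie-break

    def test_veto_only_removes_never_adds(self, tiny_library):
        """Adding a mismatching reference spectrum cannot create an identification."""
        rec = tiny_library.get("glucose")
        before = assign_identification(
            "f1", **self.feature_for(rec), library=tiny_library,
            observed_msms=[(55.5, 1.0)],
        )
        with_spec = SpectralLibrary(records=[
            CompoundRecord(name=r.name, neutral_mass=r.neutral_mass,
                           adducts=r.adducts, reference_rt=r.reference_rt,
                           msms=[(77.7, 1.0)] if r.name == "glucose" else r.msms,
                           chem_class=r.chem_class)
            for r in tiny_library
        ])
        after = assign_identification(
            "f1", **self.feature_for(rec), library=with_spec,
            observed_msms=[(55.5, 1.0)],
        )
        assert before.compound == "glucose"
        assert after.compound is None  # removed, not replaced


class TestDecoyGates:
    def test_wide_mz_offset_decoys_never_identified(self):
        """0.01 Da (~29 ppm at m/z 343) fails both branches of the mass gate."""
        lib = generate_library_with_decoys(10, 10, decoy_mz_offset=0.0100,
                                           decoy_rt_offset=0.1, seed=3)
        for rec in lib:
            if rec.name.startswith("DECOY_"):
                continue
            ident = assign_identification(
                rec.name, observed_mz=rec.adducts[0].mz,
                observed_rt=rec.reference_rt, polarity=Polarity.positive,
                library=lib,
            )
            assert ident.compound == rec.name

    def test_small_mz_large_rt_offset_fails_rt_gate(self):
        """0.0005 Da passes the Da branch but 1.0 min fails the RT gate."""
        lib = generate_library_with_decoys(10, 10, decoy_mz_offset=0.0005,
                                           decoy_rt_offset=1.0, seed=3)
        for rec in lib:
            if rec.name.startswith("DECOY_"):
                continue
            ident = assign_identification(
                rec.name, observed_mz=rec.adducts[0].mz,
                observed_rt=rec.reference_rt, polarity=Polarity.positive,
                library=lib,
            )
            assert ident.compound == rec.name

    def test_no_decoys_library_is_clean(self):
        lib = generate_library_with_decoys(5, 0, 0.01, 0.5, seed=0)
        assert len(lib) == 5
        assert not any(r.name.startswith("DECOY_") for r in lib)
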