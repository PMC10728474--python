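"""Spectral/compound dereplication and MSI-level assignment."""

import numpy as np
import pytest

from metexpand.annotate import (
    AnnotationConfig,
    SpectrumRecord,
    annotate_all,
    assign_msi,
    cosine_score,
    search_compound_table,
    search_spectral_library,
)
from metexpand.formula import MassTolerance, adduct_mz, parse_formula
from metexpand.suspects import record_from_smiles

TOL = MassTolerance(0.01, "Da")


def spec(fid, mz, peaks, mode="positive", compound=None):
    return SpectrumRecord(
        feature_id=fid, precursor_mz=mz, retention_time=60.0, mode=mode,
        peaks=peaks, compound=compound,
    )


class TestCosine:
    def test_identical_spectra_score_one(self):
        s = spec("a", 300.0, [(100.0, 5.0), (150.0, 2.0), (200.0, 9.0)])
        score, n = cosine_score(s, s, TOL)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert n == 3

    def test_disjoint_spectra_score_zero(self):
        a = spec("a", 300.0, [(100.0, 5.0)])
        b = spec("b", 300.0, [(200.0, 5.0)])
        assert cosine_score(a, b, TOL) == (0.0, 0)

    def test_hand_computed_example(self):
        a = spec("a", 300.0, [(100.0, 1.0), (200.0, 4.0)])
        b = spec("b", 300.0, [(100.0, 4.0), (200.0, 1.0)])
        score, n = cosine_score(a, b, TOL)
        assert score == pytest.approx(0.64, abs=1e-12)
        assert n == 2

    def test_symmetry_and_scale_invariance(self, rng):
        for _ in range(20):
            mzs = np.sort(rng.uniform(80, 500, size=8))
            a = spec("a", 600.0, list(zip(mzs, rng.uniform(1, 100, 8))))
            b = spec(
                "b", 600.0,
                list(zip(mzs + rng.normal(0, 0.003, 8), rng.uniform(1, 100, 8))),
            )
            sab, nab = cosine_score(a, b, TOL)
            sba, nba = cosine_score(b, a, TOL)
            assert sab == pytest.approx(sba, abs=1e-12) and nab == nba
            scaled = spec("c", 600.0, [(m, i * 37.5) for m, i in b.peaks])
            assert cosine_score(a, scaled, TOL)[0] == pytest.approx(sab, abs=1e-12)

    def test_empty_peak_list_rejected(self):
        a = spec("a", 300.0, [(100.0, 1.0)])
        b = SpectrumRecord("b", 300.0, 0.0, "positive", [])
        with pytest.raises(ValueError):
            cosine_score(a, b, TOL)

    def test_agrees_with_matchms_greedy_cosine(self, rng):
        """Square root of our score matches matchms CosineGreedy with
        intensity_power=0.5 on well-separated peak sets."""
        from matchms import Spectrum as MSpectrum
        from matchms.similarity import CosineGreedy

        sim = CosineGreedy(tolerance=0.01, intensity_power=0.5)
        for _ in range(10):
            mza = np.sort(rng.uniform(80, 500, size=7))
            mzb = np.sort(rng.uniform(80, 500, size=7))
            ia, ib = rng.uniform(1, 100, 7), rng.uniform(1, 100, 7)
            ours, _ = cosine_score(
                spec("a", 600.0, list(zip(mza, ia))),
                spec("b", 600.0, list(zip(mzb, ib))),
                TOL,
            )
            ref = sim.pair(
                MSpectrum(mz=mza, intensities=ia, metadata={"precursor_mz": 600.0}),
                MSpectrum(mz=mzb, intensities=ib, metadata={"precursor_mz": 600.0}),
            )
            assert np.sqrt(ours) == pytest.approx(float(ref["score"]), abs=1e-9)


@pytest.fixture
def hexadecanamide_library(hexadecanamide):
    mz = adduct_mz(parse_formula("C16H33NO"), "[M+H]+")
    peaks = [(88.1, 30.0), (102.1, 80.0), (116.1, 55.0), (212.2, 10.0)]
    return [spec("lib1", mz, peaks, compound=hexadecanamide)]


class TestSearchSpectralLibrary:
    def test_exact_query_ranks_first_with_score_one(self, hexadecanamide_library):
        lib = hexadecanamide_library
        q = spec("q", lib[0].precursor_mz, list(lib[0].peaks))
        cands = search_spectral_library(
            q, lib, MassTolerance(10, "ppm"), TOL, min_score=0.5, min_peaks=3
        )
        assert cands and cands[0].compound.id == "C2"
        assert cands[0].score == pytest.approx(1.0)
        assert cands[0].msi_level == 2

    def test_mode_mismatch_returns_nothing(self, hexadecanamide_library):
        lib = hexadecanamide_library
        q = spec("q", lib[0].precursor_mz, list(lib[0].peaks), mode="negative")
        assert search_spectral_library(
            q, lib, MassTolerance(10, "ppm"), TOL, 0.5, 3
        ) == []

    def test_true_match_rank_one_in_fifty(self, zero_noise_study):
        study = zero_noise_study
        lib_ids = {s.compound.id for s in study.spectral_library}
        truth = study.ground_truth.set_index("feature_id")
        for q in study.features:
            exp = truth.loc[q.feature_id]
            if not exp.in_library:
                continue
            cands = search_spectral_library(
                q, study.spectral_library, MassTolerance(10, "ppm"), TOL, 0.5, 3
            )
            assert cands[0].compound.id == exp.compound_id


class TestSearchCompoundTable:
    def test_hexadecanamide_mass_hit(self, hexadecanamide):
        q = spec("q", 256.2635, [(100.0, 1.0)])
        cands = search_compound_table(
            q, [hexadecanamide],
            [__import__("metexpand.formula", fromlist=["ADDUCTS"]).ADDUCTS["[M+H]+"]],
            MassTolerance(10, "ppm"),
        )
        assert cands and cands[0].compound.name == "hexadecanamide"
        assert cands[0].msi_level == 3

    def test_boundary_hit_scores_zero_but_returned(self, ethanol):
        from metexpand.formula import ADDUCTS

        theo = ethanol.monoisotopic_mass + ADDUCTS["[M+H]+"].mass_shift
        observed = theo * (1 + 10e-6)  # exactly at 10 ppm
        cands = search_compound_table(
            spec("q", observed, [(40.0, 1.0)]), [ethanol],
            [ADDUCTS["[M+H]+"]], MassTolerance(10, "ppm"),
        )
        assert len(cands) == 1
        assert cands[0].score == pytest.approx(0.0, abs=1e-6)

    def test_empty_table(self):
        from metexpand.formula import ADDUCTS

        assert search_compound_table(
            spec("q", 256.2635, [(100.0, 1.0)]), [],
            [ADDUCTS["[M+H]+"]], MassTolerance(10, "ppm"),
        ) == []


class TestAssignMsi:
    def test_spectral_match_gives_level_2(self, hexadecanamide_library):
        lib = hexadecanamide_library
        q = spec("q", lib[0].precursor_mz, list(lib[0].peaks))
        cands = search_spectral_library(
            q, lib, MassTolerance(10, "ppm"), TOL, 0.5, 3
        )
        assert assign_msi(q, cands).msi_level == 2

    def test_formula_only_gives_level_4(self):
        q = spec("q", 256.2635, [(100.0, 1.0)])
        cand = assign_msi(q, [])
        assert cand.msi_level == 4
        assert cand.formula_only is not None
        assert cand.compound is None

    def test_undecomposable_precursor_gives_level_5(self):
        q = spec("q", 100.45, [(90.0, 1.0)])
        cand = assign_msi(q, [])
        assert cand.msi_level == 5
        assert cand.compound is None and cand.formula_only is None


class TestAnnotateAll:
    def test_partition_is_exhaustive_and_disjoint(self, zero_noise_study):
        study = zero_noise_study
        ledger = annotate_all(
            study.features, study.spectral_library, study.suspects
        )
        assert sum(ledger.level_counts().values()) == len(study.features)
        assert set(ledger.selected) == {f.feature_id for f in study.features}

    def test_zero_noise_reproduces_ground_truth(self, zero_noise_study):
        study = zero_noise_study
        ledger = annotate_all(
            study.features, study.spectral_library, study.suspects
        )
        truth = study.ground_truth.set_index("feature_id")
        for fid, cand in ledger.selected.items():
            assert cand.msi_level == truth.loc[fid, "expected_msi"]

    def test_duplicate_feature_ids_rejected(self):
        q = spec("dup", 256.2635, [(100.0, 1.0)])
        with pytest.raises(ValueError, match="dup"):
            annotate_all([q, q], [], [])

    def test_empty_library_means_no_level_2(self, zero_noise_study):
        study = zero_noise_study
        ledger = annotate_all(study.features, [], study.suspects)
        assert 2 not in ledger.level_counts()
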