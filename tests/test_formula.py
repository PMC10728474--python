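"""Formula parsing, mass arithmetic and bounded decomposition."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metexpand.formula import (
    ADDUCTS,
    FormulaError,
    MassTolerance,
    MolecularFormula,
    adduct_mz,
    decompose_mass,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
    rdbe,
)
from metexpand._masses import MONOISOTOPIC_MASS


@pytest.mark.parametrize(
    "text,expected",
    [
        ("C16H33NO", {"C": 16, "H": 33, "N": 1, "O": 1}),
        ("H2O", {"H": 2, "O": 1}),
        ("C6H12O7", {"C": 6, "H": 12, "O": 7}),
        ("NaCl", {"Na": 1, "Cl": 1}),
        ("C2H6O", {"C": 2, "H": 6, "O": 1}),
    ],
)
def test_parse_formula(text, expected):
    assert parse_formula(text).counts == expected


@pytest.mark.parametrize("bad", ["", "  ", "Xx2O", "C16Q", "2H"])
def test_parse_formula_rejects_garbage(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


def test_empty_formula_invalid():
    with pytest.raises(FormulaError):
        MolecularFormula({})


@pytest.mark.parametrize(
    "text,mass",
    [
        ("H2O", 18.010565),
        ("C16H33NO", 255.256215),
        ("C", 12.000000),
    ],
)
def test_monoisotopic_mass(text, mass):
    assert monoisotopic_mass(parse_formula(text)) == pytest.approx(mass, abs=1e-6)


_formula_strategy = st.dictionaries(
    st.sampled_from(["C", "H", "N", "O", "P", "S"]),
    st.integers(min_value=1, max_value=30),
    min_size=1,
    max_size=5,
)


@given(_formula_strategy)
@settings(max_examples=100, deadline=None)
def test_hill_serialization_roundtrip(counts):
    f = MolecularFormula(counts)
    assert parse_formula(f.hill()).counts == f.counts


@given(_formula_strategy, _formula_strategy)
@settings(max_examples=50, deadline=None)
def test_mass_additivity(c1, c2):
    f1, f2 = MolecularFormula(c1), MolecularFormula(c2)
    assert monoisotopic_mass(f1.combine(f2)) == pytest.approx(
        monoisotopic_mass(f1) + monoisotopic_mass(f2), abs=1e-9
    )


@pytest.mark.parametrize(
    "text,adduct,mz",
    [
        ("C16H33NO", "[M+H]+", 256.2635),
        ("C14H29NO", "[M+H]+", 228.2322),
        ("C6H12O7", "[M-H]-", 195.0510),
        ("C6H11NO4", "[M+H]+", 162.0761),
    ],
)
def test_adduct_mz(text, adduct, mz):
    assert round(adduct_mz(parse_formula(text), adduct), 4) == mz


def test_proton_adduct_gap_is_two_protons():
    for text in ("C16H33NO", "H2O", "C6H12O7"):
        f = parse_formula(text)
        gap = adduct_mz(f, "[M+H]+") - adduct_mz(f, "[M-H]-")
        assert gap == pytest.approx(2 * 1.007276, abs=1e-9)


def test_unknown_adduct_lists_supported_names():
    with pytest.raises(FormulaError, match=r"\[M\+H\]\+"):
        adduct_mz(parse_formula("H2O"), "[M+2H]2+")


def test_ppm_error():
    assert ppm_error(256.2635, 256.2635) == 0.0
    assert round(ppm_error(282.2790, 282.2791), 3) == -0.354
    x = 512.1234
    assert ppm_error(x * (1 + 1e-6), x) == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError):
        ppm_error(100.0, 0.0)


@pytest.mark.parametrize(
    "text,expected",
    [("C16H33NO", 1.0), ("H2O", 0.0), ("C6H6O3", 4.0), ("C6H6", 4.0)],
)
def test_rdbe(text, expected):
    assert rdbe(parse_formula(text)) == expected


class TestDecomposeMass:
    def test_water_is_unique_hit(self):
        hits = decompose_mass(
            19.0178, "[M+H]+", MassTolerance(5, "ppm"),
            {"C": 4, "H": 10, "N": 2, "O": 3},
        )
        assert [f.hill() for f in hits] == ["H2O"]

    def test_hexadecanamide_found(self):
        hits = decompose_mass(
            256.2635, "[M+H]+", MassTolerance(3, "ppm"),
            {"C": 40, "H": 80, "N": 5, "O": 10, "S": 2, "P": 2},
        )
        assert "C16H33NO" in [f.hill() for f in hits]

    def test_below_lightest_formula_is_empty(self):
        assert decompose_mass(
            0.5, "[M+H]+", MassTolerance(5, "ppm"), {"C": 4, "H": 10}
        ) == []

    @pytest.mark.parametrize("bad", [0.0, -3.0, 5001.0])
    def test_target_out_of_range(self, bad):
        with pytest.raises(ValueError):
            decompose_mass(bad, "[M+H]+", MassTolerance(5, "ppm"), {"C": 4})

    def test_sorted_by_abs_ppm(self):
        hits = decompose_mass(
            130.05, "[M+H]+", MassTolerance(300, "ppm"),
            {"C": 10, "H": 20, "N": 3, "O": 5},
        )
        errs = [abs(ppm_error(130.05, adduct_mz(f, "[M+H]+"))) for f in hits]
        assert errs == sorted(errs)

    def test_matches_bruteforce_oracle_spot(self, rng):
        """Exhaustive nested-loop enumeration agrees on random targets."""
        bounds = {"C": 15, "H": 30, "N": 3, "O": 6}
        tol = MassTolerance(5, "ppm")
        for _ in range(30):
            target = float(rng.uniform(30, 300))
            expected = _bruteforce(target, "[M+H]+", tol, bounds)
            got = {f.hill() for f in decompose_mass(target, "[M+H]+", tol, bounds)}
            assert got == expected


def _bruteforce(target, adduct_name, tol, bounds):
    """Independent oracle: explicit nested loops + direct filter checks."""
    shift = ADDUCTS[adduct_name].mass_shift
    half = target * tol.value * 1e-6 if tol.unit == "ppm" else tol.value
    out = set()
    for c, h, n, o in itertools.product(
        range(bounds.get("C", 0) + 1),
        range(bounds.get("H", 0) + 1),
        range(bounds.get("N", 0) + 1),
        range(bounds.get("O", 0) + 1),
    ):
        if c + h + n + o == 0:
            continue
        mass = (
            c * MONOISOTOPIC_MASS["C"]
            + h * MONOISOTOPIC_MASS["H"]
            + n * MONOISOTOPIC_MASS["N"]
            + o * MONOISOTOPIC_MASS["O"]
        )
        if abs(mass + shift - target) > half:
            continue
        if c - h / 2 + n / 2 + 1 < 0:
            continue
        if c > 0 and not (0.1 <= h / c <= 6.0):
            continue
        counts = {s: v for s, v in zip("CHNO", (c, h, n, o)) if v}
        out.add(MolecularFormula(counts).hill())
    return out


def test_roundtrip_recovery_random_formulas(rng):
    """decompose_mass(adduct_mz(f)) recovers f at 1 ppm."""
    bounds = {"C": 15, "H": 30, "N": 3, "O": 6}
    tol = MassTolerance(1, "ppm")
    tried = 0
    while tried < 40:
        counts = {
            "C": int(rng.integers(1, 16)),
            "H": int(rng.integers(1, 31)),
            "N": int(rng.integers(0, 4)),
            "O": int(rng.integers(0, 7)),
        }
        counts = {k: v for k, v in counts.items() if v}
        f = MolecularFormula(counts)
        if rdbe(f) < 0 or not (0.1 <= f["H"] / f["C"] <= 6.0):
            continue
        tried += 1
        mz = adduct_mz(f, "[M+H]+")
        assert f.hill() in {
            g.hill() for g in decompose_mass(mz, "[M+H]+", tol, bounds)
        }
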