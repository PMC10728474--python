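"""Molecular-formula arithmetic for high-resolution mass spectrometry.

Provides formula parsing/serialization in Hill order, monoisotopic masses
from an embedded IUPAC isotope table, singly-charged adduct m/z, ppm errors,
ring-and-double-bond equivalents (RDBE), and bounded molecular-formula
decomposition of an observed precursor mass.

All masses are in daltons (Da); m/z values are reported for |z| = 1 ions.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from ._masses import (
    DEFAULT_ALPHABET,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    VALENCE,
)

__all__ = [
    "MolecularFormula",
    "Adduct",
    "MassTolerance",
    "FormulaError",
    "ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "rdbe",
    "decompose_mass",
    "default_bounds",
]


class FormulaError(ValueError):
    """Raised for malformed formulas, unknown elements or bad adduct names."""


# element token: one capital letter optionally followed by lowercase letters,
# then an optional count
_TOKEN = re.compile(r"([A-Z][a-z]*)(\d*)")


def _hill_sorted(symbols) -> list[str]:
    """Hill convention: C first, H second, rest alphabetical; without carbon
    all symbols (including H) sort alphabetically."""
    symbols = list(symbols)
    if "C" in symbols:
        head = [s for s in ("C", "H") if s in symbols]
        tail = sorted(s for s in symbols if s not in ("C", "H"))
        return head + tail
    return sorted(symbols)


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition with strictly positive counts.

    Counts are stored in an immutable sorted tuple so instances are hashable
    and usable as dictionary keys.
    """

    _items: tuple[tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int], alphabet=DEFAULT_ALPHABET):
        cleaned: dict[str, int] = {}
        for sym, n in counts.items():
            if sym not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if alphabet is not None and sym not in alphabet:
                raise FormulaError(
                    f"element {sym!r} outside the configured alphabet {alphabet}"
                )
            if not isinstance(n, int) or n < 1:
                raise FormulaError(f"count for {sym} must be a positive integer, got {n!r}")
            cleaned[sym] = n
        if not cleaned:
            raise FormulaError("empty formula")
        object.__setattr__(
            self, "_items", tuple(sorted(cleaned.items()))
        )

    @property
    def counts(self) -> dict[str, int]:
        return dict(self._items)

    def __getitem__(self, sym: str) -> int:
        return dict(self._items).get(sym, 0)

    def __contains__(self, sym: str) -> bool:
        return any(s == sym for s, _ in self._items)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self._items)

    def combine(self, other: "MolecularFormula") -> "MolecularFormula":
        """Element-wise sum of two formulas (disjoint union of atoms)."""
        merged = self.counts
        for sym, n in other:
            merged[sym] = merged.get(sym, 0) + n
        return MolecularFormula(merged, alphabet=None)

    def hill(self) -> str:
        """Serialize in Hill order; unit counts are omitted."""
        counts = self.counts
        return "".join(
            f"{sym}{counts[sym] if counts[sym] > 1 else ''}"
            for sym in _hill_sorted(counts)
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    def __repr__(self) -> str:
        return f"MolecularFormula({self.hill()!r})"


def parse_formula(text: str, alphabet=DEFAULT_ALPHABET) -> MolecularFormula:
    """Parse a Hill-style formula string such as ``"C16H33NO"``.

    A missing count means one atom. Repeated element tokens accumulate.
    Raises :class:`FormulaError` on empty input or tokens that are not
    element symbols from the configured alphabet.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"unparseable token at {text[pos:]!r} in {text!r}")
        sym, num = m.group(1), m.group(2)
        if sym not in MONOISOTOPIC_MASS or (alphabet is not None and sym not in alphabet):
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        pos = m.end()
    return MolecularFormula(counts, alphabet=alphabet)


@dataclass(frozen=True)
class Adduct:
    """A singly charged ionization adduct, e.g. ``[M+H]+`` or ``[M-H]-``."""

    name: str
    charge_sign: int  # +1 or -1
    mass_shift: float  # Da, signed

    def __post_init__(self):
        if self.charge_sign not in (+1, -1):
            raise FormulaError("only singly charged adducts are supported")


#: supported adducts; the two proton adducts are the defaults for
#: positive- and negative-mode electrospray
ADDUCTS: dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", +1, +PROTON_MASS),
    "[M-H]-": Adduct("[M-H]-", -1, -PROTON_MASS),
    "[M+Na]+": Adduct("[M+Na]+", +1, +22.989218),
    "[M+NH4]+": Adduct("[M+NH4]+", +1, +18.033823),
    "[M+Cl]-": Adduct("[M+Cl]-", -1, +34.969402),
}


def get_adduct(a: "Adduct | str") -> Adduct:
    if isinstance(a, Adduct):
        return a
    try:
        return ADDUCTS[a]
    except KeyError:
        raise FormulaError(
            f"unsupported adduct {a!r}; supported: {sorted(ADDUCTS)}"
        ) from None


@dataclass(frozen=True)
class MassTolerance:
    """A mass-matching window, either relative (ppm) or absolute (Da)."""

    value: float
    unit: str = "ppm"  # "ppm" or "Da"

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("tolerance must be positive")
        if self.unit not in ("ppm", "Da"):
            raise ValueError("tolerance unit must be 'ppm' or 'Da'")

    def window(self, mz: float) -> float:
        """Absolute half-width in Da at the given m/z."""
        return mz * self.value * 1e-6 if self.unit == "ppm" else self.value


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Neutral monoisotopic mass in Da (sum of most-abundant-isotope masses)."""
    return sum(MONOISOTOPIC_MASS[sym] * n for sym, n in f)


def adduct_mz(f: MolecularFormula, a: "Adduct | str") -> float:
    """m/z of a singly charged adduct ion of the neutral formula."""
    return monoisotopic_mass(f) + get_adduct(a).mass_shift


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def rdbe(f: MolecularFormula, valence: Mapping[str, int] = VALENCE) -> float:
    """Ring-and-double-bond equivalents, 1 + sum(n_i * (v_i - 2)) / 2.

    For CHNO this reduces to C - H/2 + N/2 + 1. Negative values indicate a
    formula that cannot correspond to a connected neutral molecule.
    """
    return 1.0 + sum(n * (valence[sym] - 2) for sym, n in f) / 2.0


def default_bounds(mass: float, alphabet=("C", "H", "N", "O", "P", "S")) -> dict[str, int]:
    """Per-element maximum counts scaled to a neutral target mass.

    Carbon is capped at mass/12; hydrogen by the Senior rule maximum
    2C + N + 2 at those caps; heteroatoms by their own mass.
    """
    bounds: dict[str, int] = {}
    for sym in alphabet:
        if sym == "H":
            continue
        bounds[sym] = int(mass // MONOISOTOPIC_MASS[sym])
    if "H" in alphabet:
        bounds["H"] = min(
            int(mass // MONOISOTOPIC_MASS["H"]),
            2 * bounds.get("C", 0) + bounds.get("N", 0) + 2,
        )
    return {s: n for s, n in bounds.items() if n > 0 or s == "H"}


def _plausible(f: MolecularFormula, hc_window: tuple[float, float]) -> bool:
    if rdbe(f) < 0:
        return False
    c = f["C"]
    if c > 0:
        ratio = f["H"] / c
        if not (hc_window[0] <= ratio <= hc_window[1]):
            return False
    return True


def decompose_mass(
    target: float,
    a: "Adduct | str",
    tol: MassTolerance,
    bounds: Mapping[str, int],
    hc_window: tuple[float, float] = (0.1, 6.0),
) -> list[MolecularFormula]:
    """Enumerate molecular formulas explaining an observed precursor m/z.

    Searches every composition within the per-element ``bounds`` whose
    singly-charged adduct m/z falls within ``tol`` of ``target`` and that
    passes plausibility filters (RDBE >= 0; H/C ratio inside ``hc_window``
    whenever carbon is present). The search is exhaustive within bounds.

    Results are sorted by absolute ppm error, ties broken by Hill string.
    An empty list is a valid result. ``target`` must lie in (0, 5000].
    """
    if not (0 < target <= 5000):
        raise ValueError(f"target m/z {target} outside (0, 5000]")
    adduct = get_adduct(a)
    neutral = target - adduct.mass_shift
    half = tol.window(target)
    lo, hi = neutral - half, neutral + half

    elements = sorted(
        (s for s, n in bounds.items() if n > 0),
        key=lambda s: -MONOISOTOPIC_MASS[s],
    )
    masses = [MONOISOTOPIC_MASS[s] for s in elements]
    maxima = [int(bounds[s]) for s in elements]
    out: list[MolecularFormula] = []
    counts = [0] * len(elements)

    def rec(i: int, acc: float) -> None:
        if acc > hi:
            return
        if i == len(elements):
            if acc >= lo and any(counts):
                f = MolecularFormula(
                    {s: c for s, c in zip(elements, counts) if c},
                    alphabet=None,
                )
                if _plausible(f, hc_window):
                    out.append(f)
            return
        # remaining elements cannot bridge the gap to lo
        rest_max = sum(m * x for m, x in zip(masses[i:], maxima[i:]))
        if acc + rest_max < lo:
            return
        m = masses[i]
        n_max = min(maxima[i], int((hi - acc) / m))
        if i == len(elements) - 1:
            # last (lightest) element: jump straight to the count window
            n_min = max(0, math.ceil((lo - acc) / m - 1e-12))
            for n in range(n_min, n_max + 1):
                counts[i] = n
                rec(i + 1, acc + n * m)
        else:
            for n in range(n_max + 1):
                counts[i] = n
                rec(i + 1, acc + n * m)
        counts[i] = 0

    rec(0, 0.0)
    out.sort(
        key=lambda f: (
            abs(ppm_error(target, adduct_mz(f, adduct))),
            f.hill(),
        )
    )
    return out
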