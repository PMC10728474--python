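"""Dereplication of MS2 features and MSI confidence-level assignment.

Each measured feature (precursor m/z + retention time + MS2 peak list) is
searched first against a spectral reference library (experimental spectra
with known structures), then against a compound table by exact precursor
mass, and finally — if neither yields a structure — a bounded molecular
formula decomposition is attempted. The outcome maps onto Metabolomics
Standards Initiative (MSI) confidence levels:

    2  experimental spectral match in a spectral database
    3  tentative candidate structure from an exact-mass compound lookup
    4  molecular formula only
    5  unannotated spectral feature

Level 1 (confirmed against an authentic standard) is never assigned
automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

from .formula import (
    ADDUCTS,
    Adduct,
    MassTolerance,
    MolecularFormula,
    adduct_mz,
    decompose_mass,
    default_bounds,
    get_adduct,
    ppm_error,
)
from .suspects import CompoundRecord

__all__ = [
    "SpectrumRecord",
    "AnnotationCandidate",
    "AnnotationLedger",
    "AnnotationConfig",
    "cosine_score",
    "search_spectral_library",
    "search_compound_table",
    "assign_msi",
    "annotate_all",
]

SCAN_RANGE = (80.0, 1200.0)  # instrument acquisition window, m/z


@dataclass
class SpectrumRecord:
    """One MS2 feature: precursor, retention time, mode and peak list.

    ``compound`` carries the known structure for reference-library entries
    and is ``None`` for measured query features.
    """

    feature_id: str
    precursor_mz: float
    retention_time: float  # seconds
    mode: str  # "positive" | "negative"
    peaks: list[tuple[float, float]]  # (mz, intensity), sorted by mz
    collision_energy: list[float] | None = None
    compound: CompoundRecord | None = None

    def __post_init__(self):
        if self.mode not in ("positive", "negative"):
            raise ValueError(f"mode must be positive/negative, got {self.mode!r}")
        self.peaks = sorted(self.peaks, key=lambda p: p[0])
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("negative peak intensity")


@dataclass
class AnnotationCandidate:
    """A scored structure-or-formula hypothesis for one feature."""

    feature_id: str
    compound: CompoundRecord | None = None
    formula_only: MolecularFormula | None = None
    score: float | None = None
    source: str = ""  # spectral_db | compound_db | formula
    msi_level: int = 5
    n_matched_peaks: int = 0
    ppm: float | None = None
    in_source_suspect: bool = False

    def __post_init__(self):
        if self.msi_level != 5 and (self.compound is None) == (self.formula_only is None):
            raise ValueError(
                "exactly one of compound/formula_only must be set below level 5"
            )


@dataclass
class AnnotationConfig:
    """Tolerances and thresholds for a dereplication run.

    ``min_score`` lives on the squared-cosine scale used by
    :func:`cosine_score`; the default 0.50 corresponds to a conventional
    (unsquared) spectral cosine of about 0.71, the community's usual
    library-match cutoff.
    """

    precursor_tol: MassTolerance = field(
        default_factory=lambda: MassTolerance(10, "ppm")
    )
    fragment_tol: MassTolerance = field(
        default_factory=lambda: MassTolerance(0.01, "Da")
    )
    min_score: float = 0.50
    min_peaks: int = 3
    adducts: tuple[str, ...] = ("[M+H]+", "[M-H]-")
    decompose_tol: MassTolerance = field(
        default_factory=lambda: MassTolerance(10, "ppm")
    )
    max_decompose_mz: float = 1200.0

    def adducts_for_mode(self, mode: str) -> list[Adduct]:
        sign = +1 if mode == "positive" else -1
        return [get_adduct(a) for a in self.adducts if get_adduct(a).charge_sign == sign]


@dataclass
class AnnotationLedger:
    """Per-feature candidate lists plus the selected best candidate."""

    candidates: dict[str, list[AnnotationCandidate]]
    selected: dict[str, AnnotationCandidate]

    def level_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for cand in self.selected.values():
            counts[cand.msi_level] = counts.get(cand.msi_level, 0) + 1
        return counts


def cosine_score(
    q: SpectrumRecord, r: SpectrumRecord, frag_tol: MassTolerance
) -> tuple[float, int]:
    """Greedy one-to-one cosine match between two peak lists.

    Peaks are weighted by the square root of intensity. All cross-spectrum
    peak pairs within ``frag_tol`` are considered best-pair-first (largest
    weight product wins); each peak is used at most once. The score is

        (sum of matched weight products)^2 / (sum w_q^2 * sum w_r^2)

    which is 1 for identical spectra (Cauchy-Schwarz equality), symmetric,
    and invariant under uniform intensity rescaling of either spectrum.
    Returns ``(score, n_matched_peaks)``.
    """
    if not q.peaks or not r.peaks:
        raise ValueError("cannot score an empty peak list")
    wq = [sqrt(i) for _, i in q.peaks]
    wr = [sqrt(i) for _, i in r.peaks]
    pairs: list[tuple[float, float, int, int]] = []
    for iq, (mq, _) in enumerate(q.peaks):
        half = frag_tol.window(mq)
        for ir, (mr, _) in enumerate(r.peaks):
            if abs(mq - mr) <= half:
                pairs.append((wq[iq] * wr[ir], abs(mq - mr), iq, ir))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2], p[3]))
    used_q: set[int] = set()
    used_r: set[int] = set()
    num = 0.0
    n_matched = 0
    for w, _, iq, ir in pairs:
        if iq in used_q or ir in used_r:
            continue
        used_q.add(iq)
        used_r.add(ir)
        num += w
        n_matched += 1
    if n_matched == 0:
        return 0.0, 0
    denom = sum(w * w for w in wq) * sum(w * w for w in wr)
    return num * num / denom, n_matched


def search_spectral_library(
    q: SpectrumRecord,
    library: list[SpectrumRecord],
    prec_tol: MassTolerance,
    frag_tol: MassTolerance,
    min_score: float,
    min_peaks: int,
) -> list[AnnotationCandidate]:
    """Match a query against reference spectra carrying known structures.

    A library entry is a candidate when the ionization mode agrees, the
    precursor difference is within ``prec_tol``, the cosine score reaches
    ``min_score`` and at least ``min_peaks`` peaks match. Candidates are
    sorted by score descending, ties broken by library compound id.
    """
    out: list[AnnotationCandidate] = []
    for ref in library:
        if ref.mode != q.mode or ref.compound is None:
            continue
        if abs(ref.precursor_mz - q.precursor_mz) > prec_tol.window(q.precursor_mz):
            continue
        if not ref.peaks or not q.peaks:
            continue
        score, n = cosine_score(q, ref, frag_tol)
        if score >= min_score and n >= min_peaks:
            out.append(
                AnnotationCandidate(
                    feature_id=q.feature_id,
                    compound=ref.compound,
                    score=score,
                    source="spectral_db",
                    msi_level=2,
                    n_matched_peaks=n,
                )
            )
    out.sort(key=lambda c: (-c.score, c.compound.id))
    return out


def search_compound_table(
    q: SpectrumRecord,
    table: list[CompoundRecord],
    adducts: list[Adduct],
    prec_tol: MassTolerance,
) -> list[AnnotationCandidate]:
    """Exact-mass dereplication against a compound table.

    For each (compound, adduct) pair the theoretical singly charged m/z is
    compared with the query precursor; hits within tolerance are scored
    ``max(0, 1 - |ppm|/tol_ppm)`` so the score falls linearly with mass
    error (a hit exactly at the tolerance boundary scores 0 but is kept).
    """
    if not adducts:
        return []
    tol_ppm = (
        prec_tol.value
        if prec_tol.unit == "ppm"
        else 1e6 * prec_tol.value / q.precursor_mz
    )
    out: list[AnnotationCandidate] = []
    for rec in table:
        if rec.formula is None and rec.monoisotopic_mass is None:
            continue
        mass = (
            rec.monoisotopic_mass
            if rec.monoisotopic_mass is not None
            else adduct_mz(rec.formula, adducts[0]) - adducts[0].mass_shift
        )
        for adduct in adducts:
            theo = mass + adduct.mass_shift
            if abs(q.precursor_mz - theo) > prec_tol.window(q.precursor_mz):
                continue
            ppm = ppm_error(q.precursor_mz, theo)
            # neutral mass above the precursor-implied mass hints at an
            # in-source fragment having been selected as the precursor
            in_source = mass > (q.precursor_mz - adduct.mass_shift) + 0.5
            out.append(
                AnnotationCandidate(
                    feature_id=q.feature_id,
                    compound=rec,
                    score=max(0.0, 1.0 - abs(ppm) / tol_ppm),
                    source="compound_db",
                    msi_level=3,
                    ppm=ppm,
                    in_source_suspect=in_source,
                )
            )
    out.sort(key=lambda c: (-c.score, c.compound.id))
    return out


def assign_msi(
    feature: SpectrumRecord,
    candidates: list[AnnotationCandidate],
    config: AnnotationConfig | None = None,
) -> AnnotationCandidate:
    """Select the best candidate for a feature and fix its MSI level.

    Priority: any passing spectral-library match (level 2) beats any
    compound-table structure (level 3); with neither, a successful bounded
    formula decomposition gives level 4; otherwise the feature stays an
    unannotated level-5 spectral feature. Within a source, the highest
    score wins, ties broken by compound id.
    """
    config = config or AnnotationConfig()
    spectral = [c for c in candidates if c.source == "spectral_db"]
    if spectral:
        best = min(spectral, key=lambda c: (-c.score, c.compound.id))
        return best
    table = [c for c in candidates if c.source == "compound_db"]
    if table:
        return min(table, key=lambda c: (-c.score, c.compound.id))
    # formula-only annotation
    if feature.precursor_mz <= config.max_decompose_mz:
        mode_adducts = config.adducts_for_mode(feature.mode)
        for adduct in mode_adducts:
            neutral = feature.precursor_mz - adduct.mass_shift
            formulas = decompose_mass(
                feature.precursor_mz,
                adduct,
                config.decompose_tol,
                default_bounds(neutral),
            )
            if formulas:
                return AnnotationCandidate(
                    feature_id=feature.feature_id,
                    formula_only=formulas[0],
                    source="formula",
                    msi_level=4,
                )
    return AnnotationCandidate(feature_id=feature.feature_id, msi_level=5)


def annotate_all(
    features: list[SpectrumRecord],
    spectral_library: list[SpectrumRecord],
    compound_table: list[CompoundRecord],
    config: AnnotationConfig | None = None,
) -> AnnotationLedger:
    """Dereplicate every feature and build the annotation ledger.

    Deterministic given inputs and configuration. Every feature appears
    exactly once in the selected set, so the per-level counts form an
    exhaustive, disjoint partition of the feature list. Duplicate feature
    ids are an error.
    """
    config = config or AnnotationConfig()
    seen: set[str] = set()
    for f in features:
        if f.feature_id in seen:
            raise ValueError(f"duplicate feature_id {f.feature_id!r}")
        seen.add(f.feature_id)

    candidates: dict[str, list[AnnotationCandidate]] = {}
    selected: dict[str, AnnotationCandidate] = {}
    for feat in features:
        cands: list[AnnotationCandidate] = []
        if feat.peaks:
            cands.extend(
                search_spectral_library(
                    feat,
                    spectral_library,
                    config.precursor_tol,
                    config.fragment_tol,
                    config.min_score,
                    config.min_peaks,
                )
            )
        cands.extend(
            search_compound_table(
                feat,
                compound_table,
                config.adducts_for_mode(feat.mode),
                config.precursor_tol,
            )
        )
        candidates[feat.feature_id] = cands
        selected[feat.feature_id] = assign_msi(feat, cands, config)
    return AnnotationLedger(candidates=candidates, selected=selected)
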