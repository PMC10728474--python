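"""Ground-truth synthetic studies for the annotation pipeline.

Emulates a two-mode (positive/negative electrospray) data-dependent
LC-MS2 acquisition over a library of real metabolite structures: every
generated feature carries a known answer (its true compound and the MSI
level it should receive under zero noise), so every pipeline stage can be
tested end-to-end without downloading reference data.

Fragments are *pseudo-fragments*: deterministic hash-derived sub-masses of
the precursor, not chemically simulated fragmentation. This exercises the
matching machinery (peak pairing, tolerances, scoring, ranking) while
keeping the generator fully reproducible; it does not emulate real
fragmentation chemistry, isotope envelopes or chromatographic peak shape.

Noise model (all configurable):
  * peak and precursor m/z jitter, uniform in +- ``mz_jitter_ppm``;
  * spurious peaks, a binomial fraction of the peak count drawn uniformly
    over the scan range;
  * peak dropout, each fragment independently lost with
    ``peak_dropout_rate``.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._templates import DEFAULT_CLASS_WEIGHTS, TEMPLATES
from .annotate import SCAN_RANGE, AnnotationConfig, SpectrumRecord
from .formula import MassTolerance, adduct_mz, decompose_mass, default_bounds, get_adduct
from .network import fingerprint
from .suspects import ChemClass, CompoundRecord, record_from_smiles

log = logging.getLogger(__name__)

__all__ = ["StudyConfig", "SyntheticStudy", "generate_compound_library",
           "simulate_spectrum", "generate_study"]


@dataclass
class StudyConfig:
    """Parameters of one synthetic acquisition.

    Defaults emulate a mid-sized two-mode DDA run on an Orbitrap-class
    instrument: scan range 80-1200 m/z, 5 ppm mass jitter, 10% spurious
    peaks and 20% peak dropout.
    """

    n_compounds: int = 60
    frac_in_suspect_list: float = 0.6
    frac_in_spectral_library: float = 0.6
    n_formula_only: int = 3
    n_decoy_features: int = 3
    peaks_per_spectrum: tuple[int, int] = (8, 14)
    mz_jitter_ppm: float = 5.0
    spurious_peak_rate: float = 0.10
    peak_dropout_rate: float = 0.20
    scan_range: tuple[float, float] = SCAN_RANGE
    modes: tuple[str, ...] = ("positive", "negative")
    class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    strict_ground_truth: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_in_suspect_list", "frac_in_spectral_library",
                     "spurious_peak_rate", "peak_dropout_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.scan_range[0] >= self.scan_range[1]:
            raise ValueError("scan_range low must be below high")
        if self.peaks_per_spectrum[0] < 1:
            raise ValueError("need at least one peak per spectrum")


@dataclass
class SyntheticStudy:
    """One generated study with its ground truth."""

    suspects: list[CompoundRecord]
    spectral_library: list[SpectrumRecord]
    features: list[SpectrumRecord]
    compounds: list[CompoundRecord]  # full measured universe
    ground_truth: pd.DataFrame
    config: StudyConfig


_MODE_ADDUCT = {"positive": "[M+H]+", "negative": "[M-H]-"}


def _all_templates() -> list[tuple[str, str, str]]:
    return [
        (superclass, name, smiles)
        for superclass, entries in TEMPLATES.items()
        for name, smiles in entries
    ]


def generate_compound_library(
    cfg: StudyConfig, rng: np.random.Generator | None = None
) -> list[CompoundRecord]:
    """Sample ``cfg.n_compounds`` compound records from the template set.

    Superclasses are drawn with ``cfg.class_weights``; within a class,
    templates are used without replacement until exhausted, after which
    structures repeat under fresh ids (with a warning). Deterministic
    under a fixed seed.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    classes = sorted(cfg.class_weights)
    weights = np.array([cfg.class_weights[c] for c in classes], dtype=float)
    weights /= weights.sum()
    pools = {c: list(TEMPLATES[c]) for c in classes}
    remaining = {c: list(range(len(pools[c]))) for c in classes}
    records: list[CompoundRecord] = []
    n_repeats = 0
    for i in range(cfg.n_compounds):
        cls = classes[rng.choice(len(classes), p=weights)]
        if not remaining[cls]:
            remaining[cls] = list(range(len(pools[cls])))
            n_repeats += 1
        idx = remaining[cls].pop(int(rng.integers(len(remaining[cls]))))
        name, smiles = pools[cls][idx]
        rec = record_from_smiles(
            id=f"SM{i:05d}",
            name=name,
            smiles=smiles,
            classification=ChemClass(superclass=cls),
            sources=["synthetic-template"],
            species=["Skeletonema marinoi"],
        )
        records.append(rec)
    if n_repeats:
        log.warning(
            "template diversity exhausted %d time(s); structures repeated "
            "under distinct ids", n_repeats,
        )
    return records


def _base_fragments(
    compound_id: str, mode: str, precursor: float, cfg: StudyConfig
) -> list[tuple[float, float]]:
    """Deterministic pseudo-fragment peak list for one compound and mode.

    Seeded from a hash of (compound id, mode) only, so the reference
    spectrum in the library and the measured query share an identical
    zero-noise peak set.
    """
    digest = hashlib.sha256(f"{compound_id}|{mode}".encode()).digest()
    sub = np.random.default_rng(int.from_bytes(digest[:4], "big"))
    lo = cfg.scan_range[0]
    n_lo, n_hi = cfg.peaks_per_spectrum
    n = int(sub.integers(n_lo, n_hi + 1))
    hi = max(precursor - 1.0, lo + 1.0)
    mzs = np.sort(sub.uniform(lo, hi, size=n))
    # enforce >= 0.05 Da spacing so jittered peaks stay unambiguous
    keep = np.concatenate([[True], np.diff(mzs) > 0.05])
    mzs = mzs[keep]
    intensities = sub.uniform(10.0, 1000.0, size=len(mzs))
    return list(zip(mzs.tolist(), intensities.tolist()))


def simulate_spectrum(
    c: CompoundRecord,
    mode: str,
    cfg: StudyConfig,
    rng: np.random.Generator | None = None,
    feature_id: str | None = None,
    noisy: bool = True,
) -> SpectrumRecord:
    """MS2 spectrum of a compound in the given ionization mode.

    The precursor is the theoretical singly charged adduct m/z
    ([M+H]+ in positive, [M-H]- in negative mode), jittered when
    ``noisy``. With ``noisy=False`` the exact library (reference)
    spectrum is returned. Compounds whose precursor falls outside the
    scan range are refused with ``ValueError``.
    """
    adduct = get_adduct(_MODE_ADDUCT[mode])
    theo = c.monoisotopic_mass + adduct.mass_shift
    if not (cfg.scan_range[0] <= theo <= cfg.scan_range[1]):
        raise ValueError(
            f"precursor {theo:.4f} of {c.id} outside scan range {cfg.scan_range}"
        )
    peaks = _base_fragments(c.id, mode, theo, cfg)
    precursor = theo
    if noisy:
        if rng is None:
            raise ValueError("noisy simulation needs a random generator")
        precursor = theo * (1 + rng.uniform(-1, 1) * cfg.mz_jitter_ppm * 1e-6)
        jittered = [
            (mz * (1 + rng.uniform(-1, 1) * cfg.mz_jitter_ppm * 1e-6), inten)
            for mz, inten in peaks
        ]
        kept = [p for p in jittered if rng.random() >= cfg.peak_dropout_rate]
        if not kept:  # never emit an empty spectrum
            kept = [jittered[int(rng.integers(len(jittered)))]]
        n_spurious = int(rng.binomial(len(peaks), cfg.spurious_peak_rate))
        lo = cfg.scan_range[0]
        hi = max(precursor - 1.0, lo + 1.0)
        for _ in range(n_spurious):
            kept.append((float(rng.uniform(lo, hi)), float(rng.uniform(10.0, 1000.0))))
        peaks = sorted(kept)
    rt = 30.0 + (rng.uniform(0, 500) if noisy and rng is not None else 0.0)
    return SpectrumRecord(
        feature_id=feature_id or f"{c.id}_{mode[:3]}",
        precursor_mz=precursor,
        retention_time=rt,
        mode=mode,
        peaks=peaks,
        compound=None if noisy else c,
    )


def _decoy_precursor(
    rng: np.random.Generator, cfg: StudyConfig, ann_cfg: AnnotationConfig
) -> float:
    """A precursor m/z explained by no bounded CHNOPS formula.

    Rejection-samples the 80-400 m/z region (decomposition there is cheap
    and formula density low enough) until ``decompose_mass`` returns
    nothing at the annotation tolerance, so a decoy can never be rescued
    as a formula-only annotation.
    """
    lo = max(cfg.scan_range[0], 80.0)
    for _ in range(10_000):
        mz = float(rng.uniform(lo, 400.0))
        ok = True
        for mode in cfg.modes:
            adduct = get_adduct(_MODE_ADDUCT[mode])
            neutral = mz - adduct.mass_shift
            if decompose_mass(mz, adduct, ann_cfg.decompose_tol, default_bounds(neutral)):
                ok = False
                break
        if ok:
            return mz
    raise RuntimeError("could not sample a formula-free decoy mass")


def generate_study(
    cfg: StudyConfig, ann_cfg: AnnotationConfig | None = None
) -> SyntheticStudy:
    """Generate a complete ground-truth study.

    With ``cfg.strict_ground_truth`` (the default), measured compounds are
    sampled from the templates subject to two uniqueness constraints that
    keep the ground truth exact: pairwise distinct Morgan fingerprints
    (chain homologs and stereoisomers can collide) and pairwise
    precursor-mass separation of at least three tolerance windows (so
    exact-mass lookup is unambiguous). Without it, templates may repeat
    under distinct ids, which allows studies larger than the template set
    at the price of occasionally ambiguous level-3 ground truth.

    Each compound yields one query feature in one mode. Expected MSI
    level under zero noise: 2 if its reference spectrum is in the
    spectral library, else 3 if it is on the suspect list, else 4
    (formula-only); decoy features expect level 5.
    """
    ann_cfg = ann_cfg or AnnotationConfig()
    rng = np.random.default_rng(cfg.seed)
    classes = sorted(cfg.class_weights)
    weights = np.array([cfg.class_weights[c] for c in classes], dtype=float)
    weights /= weights.sum()

    pools = {c: list(TEMPLATES[c]) for c in classes}
    remaining = {c: list(range(len(pools[c]))) for c in classes}
    seen_fps: set = set()
    chosen_masses: list[float] = []
    compounds: list[CompoundRecord] = []
    modes: list[str] = []
    tol = ann_cfg.precursor_tol
    attempts = 0
    while len(compounds) < cfg.n_compounds and attempts < 50 * cfg.n_compounds:
        attempts += 1
        cls = classes[rng.choice(len(classes), p=weights)]
        if not remaining[cls]:
            if cfg.strict_ground_truth:
                continue
            remaining[cls] = list(range(len(pools[cls])))
        idx = remaining[cls].pop(int(rng.integers(len(remaining[cls]))))
        name, smiles = pools[cls][idx]
        mode = cfg.modes[int(rng.integers(len(cfg.modes)))]
        i = len(compounds)
        rec = record_from_smiles(
            id=f"SM{i:05d}",
            name=name,
            smiles=smiles,
            classification=ChemClass(superclass=cls),
            sources=["synthetic-template"],
            species=["Skeletonema marinoi"],
        )
        adduct = get_adduct(_MODE_ADDUCT[mode])
        theo = rec.monoisotopic_mass + adduct.mass_shift
        if not (cfg.scan_range[0] <= theo <= cfg.scan_range[1]):
            log.info("skipping %s: precursor %.4f outside scan range", name, theo)
            continue
        if cfg.strict_ground_truth:
            fp = fingerprint(rec.smiles)
            if fp.bits in seen_fps:
                continue
            window = 3 * tol.window(rec.monoisotopic_mass)
            if any(abs(rec.monoisotopic_mass - m) < window for m in chosen_masses):
                continue
            seen_fps.add(fp.bits)
            chosen_masses.append(rec.monoisotopic_mass)
        compounds.append(rec)
        modes.append(mode)
    if len(compounds) < cfg.n_compounds:
        log.warning(
            "only %d of %d requested compounds satisfy the uniqueness "
            "constraints", len(compounds), cfg.n_compounds,
        )

    n = len(compounds)
    in_library = rng.random(n) < cfg.frac_in_spectral_library
    in_suspect = rng.random(n) < cfg.frac_in_suspect_list
    # formula-only compounds are withheld from both the library and the
    # suspect table; pick them among compounds in neither set first
    candidates = [i for i in range(n) if not in_library[i] and not in_suspect[i]]
    extra = [i for i in range(n) if i not in candidates]
    formula_only = (candidates + extra)[: min(cfg.n_formula_only, n)]
    for i in formula_only:
        in_library[i] = False
        in_suspect[i] = False

    library = [
        simulate_spectrum(compounds[i], modes[i], cfg, noisy=False,
                          feature_id=f"LIB_{compounds[i].id}")
        for i in range(n)
        if in_library[i]
    ]
    suspects = [compounds[i] for i in range(n) if in_suspect[i]]

    noisy = cfg.mz_jitter_ppm > 0 or cfg.spurious_peak_rate > 0 or cfg.peak_dropout_rate > 0
    features: list[SpectrumRecord] = []
    truth_rows: list[dict] = []
    for i in range(n):
        fid = f"F{i:05d}"
        spec = simulate_spectrum(
            compounds[i], modes[i], cfg, rng=rng, feature_id=fid, noisy=noisy
        )
        spec.compound = None
        features.append(spec)
        if in_library[i]:
            expected = 2
        elif in_suspect[i]:
            expected = 3
        else:
            expected = 4
        truth_rows.append(
            {
                "feature_id": fid,
                "compound_id": compounds[i].id,
                "name": compounds[i].name,
                "is_decoy": False,
                "mode": modes[i],
                "adduct": _MODE_ADDUCT[modes[i]],
                "in_library": bool(in_library[i]),
                "in_suspect_list": bool(in_suspect[i]),
                "expected_msi": expected,
            }
        )

    for d in range(cfg.n_decoy_features):
        fid = f"D{d:05d}"
        mode = cfg.modes[int(rng.integers(len(cfg.modes)))]
        mz = _decoy_precursor(rng, cfg, ann_cfg)
        n_peaks = int(rng.integers(*cfg.peaks_per_spectrum))
        lo = cfg.scan_range[0]
        peaks = sorted(
            (float(rng.uniform(lo, max(mz - 1.0, lo + 1.0))), float(rng.uniform(10, 1000)))
            for _ in range(n_peaks)
        )
        features.append(
            SpectrumRecord(
                feature_id=fid,
                precursor_mz=mz,
                retention_time=float(rng.uniform(30, 530)),
                mode=mode,
                peaks=peaks,
            )
        )
        truth_rows.append(
            {
                "feature_id": fid,
                "compound_id": "",
                "name": "",
                "is_decoy": True,
                "mode": mode,
                "adduct": _MODE_ADDUCT[mode],
                "in_library": False,
                "in_suspect_list": False,
                "expected_msi": 5,
            }
        )

    truth = pd.DataFrame(truth_rows)
    return SyntheticStudy(
        suspects=suspects,
        spectral_library=library,
        features=features,
        compounds=compounds,
        ground_truth=truth,
        config=cfg,
    )
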