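"""Readers and writers for the pipeline's file formats.

Spectra enter and leave as MGF or NIST-style MSP peak lists (the pipeline
starts from peak-picked MS2 data; raw/mzML conversion is upstream of it).
Parsing goes through matchms/pyteomics; this module only maps their
harmonized metadata onto :class:`~metexpand.annotate.SpectrumRecord` and
back, quarantining records that lack a precursor instead of dropping them
silently.

Retention times are seconds everywhere; the MGF writer emits RTINSECONDS.
"""

from __future__ import annotations

import logging

import numpy as np
from matchms import Spectrum
from matchms.exporting import save_as_msp
from matchms.importing import load_from_mgf, load_from_msp
from pyteomics import mgf as _mgf

from .annotate import SpectrumRecord
from .suspects import CompoundRecord, record_from_smiles

logging.getLogger("matchms").setLevel(logging.ERROR)

__all__ = [
    "read_mgf",
    "read_msp",
    "write_mgf",
    "write_msp",
    "spectrum_to_record",
]


def _mode_from_metadata(meta: dict) -> str | None:
    ionmode = str(meta.get("ionmode", "")).lower()
    if ionmode in ("positive", "negative"):
        return ionmode
    charge = meta.get("charge")
    if isinstance(charge, (list, tuple)) and charge:
        charge = charge[0]
    if charge is not None:
        try:
            return "positive" if int(charge) > 0 else "negative"
        except (TypeError, ValueError):
            pass
    return None


def spectrum_to_record(
    spectrum: Spectrum, default_id: str
) -> tuple[SpectrumRecord | None, str | None]:
    """Map a matchms spectrum to a record; returns (record, problem)."""
    meta = spectrum.metadata
    precursor = meta.get("precursor_mz")
    if precursor is None:
        return None, "missing precursor m/z"
    mode = _mode_from_metadata(meta)
    if mode is None:
        return None, "missing ion mode / charge sign"
    rt = meta.get("retention_time")
    feature_id = str(
        meta.get("feature_id") or meta.get("title") or default_id
    )
    peaks = list(zip(spectrum.peaks.mz.tolist(), spectrum.peaks.intensities.tolist()))
    compound = None
    smiles = meta.get("smiles")
    if smiles:  # reference-library entry carrying a known structure
        try:
            compound = record_from_smiles(
                id=str(meta.get("compound_id") or feature_id),
                name=str(meta.get("compound_name") or ""),
                smiles=str(smiles),
            )
        except ValueError:
            return None, f"unparseable library structure {smiles!r}"
    return (
        SpectrumRecord(
            feature_id=feature_id,
            precursor_mz=float(precursor),
            retention_time=float(rt) if rt is not None else float("nan"),
            mode=mode,
            peaks=peaks,
            compound=compound,
        ),
        None,
    )


def _load(path, loader) -> tuple[list[SpectrumRecord], list[dict]]:
    records: list[SpectrumRecord] = []
    quarantine: list[dict] = []
    n = 0
    for n, spectrum in enumerate(loader(str(path)), start=1):
        if spectrum is None:
            quarantine.append({"index": n, "reason": "unreadable entry"})
            continue
        rec, problem = spectrum_to_record(spectrum, default_id=f"FEAT{n:05d}")
        if rec is None:
            quarantine.append({"index": n, "reason": problem})
        else:
            records.append(rec)
    if n == 0:
        logging.getLogger(__name__).warning("no spectra found in %s", path)
    return records, quarantine


def read_mgf(path) -> tuple[list[SpectrumRecord], list[dict]]:
    """Read an MGF file; malformed entries land in the quarantine list."""
    return _load(path, load_from_mgf)


def read_msp(path) -> tuple[list[SpectrumRecord], list[dict]]:
    """Read a NIST-style MSP file; malformed entries are quarantined."""
    return _load(path, load_from_msp)


def _charge_string(mode: str) -> str:
    return "1+" if mode == "positive" else "1-"


def write_mgf(records: list[SpectrumRecord], path) -> None:
    """Write records as MGF (PEPMASS / RTINSECONDS / CHARGE / peak lines)."""
    entries = []
    for rec in records:
        mz, inten = (
            zip(*rec.peaks) if rec.peaks else ((), ())
        )
        params = {
            "title": rec.feature_id,
            "pepmass": rec.precursor_mz,
            "charge": _charge_string(rec.mode),
            "ionmode": rec.mode,
            "feature_id": rec.feature_id,
        }
        if rec.retention_time == rec.retention_time:  # not NaN
            params["rtinseconds"] = rec.retention_time
        if rec.compound is not None:
            params["compound_name"] = rec.compound.name
            params["compound_id"] = rec.compound.id
            if rec.compound.smiles:
                params["smiles"] = rec.compound.smiles
        entries.append(
            {
                "m/z array": np.asarray(mz, dtype=float),
                "intensity array": np.asarray(inten, dtype=float),
                "params": params,
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def write_msp(records: list[SpectrumRecord], path) -> None:
    """Write records as NIST-style MSP."""
    spectra = []
    for rec in records:
        mz, inten = zip(*rec.peaks) if rec.peaks else ((), ())
        meta = {
            "precursor_mz": rec.precursor_mz,
            "charge": _charge_string(rec.mode),
            "ionmode": rec.mode,
            "feature_id": rec.feature_id,
            "retention_time": rec.retention_time,
        }
        if rec.compound is not None:
            meta["compound_name"] = rec.compound.name
            meta["compound_id"] = rec.compound.id
            if rec.compound.smiles:
                meta["smiles"] = rec.compound.smiles
        spectra.append(
            Spectrum(
                mz=np.asarray(mz, dtype=float),
                intensities=np.asarray(inten, dtype=float),
                metadata=meta,
                metadata_harmonization=False,
            )
        )
    save_as_msp(spectra, str(path), mode="w")
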