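"""Suspect-list curation: structure validation, deduplication, metadata
completion and chemical-classification attachment.

A *suspect list* is a table of compounds already reported for the organism
under study; it anchors dereplication of newly measured features. Rows come
from heterogeneous databases, so structures are normalized through RDKit
(canonical SMILES, standard InChI) before records are merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.inchi import MolFromInchi, MolToInchi

from ._masses import MONOISOTOPIC_MASS
from .formula import MolecularFormula, monoisotopic_mass, parse_formula

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

__all__ = [
    "ChemClass",
    "CompoundRecord",
    "CurationReport",
    "load_suspect_list",
    "record_from_smiles",
    "deduplicate",
    "attach_classification",
    "load_class_map",
    "summarize_classes",
    "records_to_frame",
]

_CLASS_LEVELS = ("kingdom", "superclass", "class_", "subclass")


@dataclass(frozen=True)
class ChemClass:
    """A ChemONT-style hierarchical classification path.

    Empty strings mean unclassified at that level; non-empty levels must
    form a prefix of (kingdom, superclass, class, subclass).
    """

    kingdom: str = "Organic compounds"
    superclass: str = ""
    class_: str = ""
    subclass: str = ""

    def __post_init__(self):
        values = [getattr(self, lvl) for lvl in _CLASS_LEVELS]
        seen_empty = False
        for v in values:
            if v == "":
                seen_empty = True
            elif seen_empty:
                raise ValueError(
                    f"classification levels must form a prefix, got {values}"
                )

    @property
    def path(self) -> tuple[str, ...]:
        return tuple(
            v for v in (self.kingdom, self.superclass, self.class_, self.subclass) if v
        )

    def is_classified(self) -> bool:
        return bool(self.superclass)


@dataclass
class CompoundRecord:
    """One curated chemical entity with structure, mass and provenance."""

    id: str
    name: str
    smiles: str = ""
    inchi: str = ""
    formula: MolecularFormula | None = None
    monoisotopic_mass: float | None = None
    classification: ChemClass = field(default_factory=ChemClass)
    synonyms: list[str] = field(default_factory=list)
    sources: list[str] = field(default_factory=list)
    species: list[str] = field(default_factory=list)
    origin: str = "suspect"  # suspect | novel | common

    def structure_key(self) -> str:
        """Canonical identity key: standard InChI when available, else
        canonical SMILES."""
        return self.inchi or self.smiles


@dataclass
class CurationReport:
    """Audit trail of a curation run."""

    n_input: int = 0
    n_kept: int = 0
    n_discarded: int = 0  # no identifier and no structure
    n_unclassified: int = 0
    rejects: list[dict] = field(default_factory=list)  # quarantined rows
    conflicts: list[dict] = field(default_factory=list)

    def rejects_frame(self) -> pd.DataFrame:
        cols = ["row", "name", "reason"]
        return pd.DataFrame(self.rejects, columns=cols)


def _mol_from_structure(smiles: str, inchi: str):
    if smiles:
        return Chem.MolFromSmiles(smiles)
    if inchi:
        return MolFromInchi(inchi)
    return None


def _formula_from_mol(mol) -> MolecularFormula:
    counts: dict[str, int] = {}
    h = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
        h += atom.GetTotalNumHs()
    if h:
        counts["H"] = counts.get("H", 0) + h
    unknown = set(counts) - set(MONOISOTOPIC_MASS)
    if unknown:
        raise ValueError(f"no monoisotopic mass tabulated for {sorted(unknown)}")
    return MolecularFormula(counts, alphabet=None)


def record_from_smiles(
    id: str, name: str, smiles: str, **kwargs
) -> CompoundRecord:
    """Build a fully populated record from a SMILES string.

    Canonicalizes the structure, derives the standard InChI, elemental
    formula and monoisotopic mass. Raises ``ValueError`` on unparseable
    SMILES.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    f = _formula_from_mol(mol)
    return CompoundRecord(
        id=id,
        name=name,
        smiles=Chem.MolToSmiles(mol),
        inchi=MolToInchi(mol) or "",
        formula=f,
        monoisotopic_mass=monoisotopic_mass(f),
        **kwargs,
    )


_COLUMN_ALIASES = {
    "name": ("name", "compound_name", "compound"),
    "smiles": ("smiles", "canonical_smiles"),
    "inchi": ("inchi",),
    "formula": ("formula", "molecular_formula"),
    "monoisotopic_mass": ("monoisotopic_mass", "exact_mass"),
    "species": ("species",),
    "source": ("source", "sources", "database"),
    "superclass": ("superclass",),
    "class": ("class", "class_"),
    "subclass": ("subclass",),
    "id": ("id", "identifier", "compound_id"),
}


def _get(row: pd.Series, key: str) -> str:
    for alias in _COLUMN_ALIASES[key]:
        if alias in row.index:
            v = row[alias]
            if pd.notna(v):
                return str(v).strip()
    return ""


def load_suspect_list(path) -> tuple[list[CompoundRecord], CurationReport]:
    """Read a suspect-list CSV/TSV into validated compound records.

    The table must carry a name column and at least one structure column
    (``smiles`` or ``inchi``). Rows with neither an identifier nor a
    structural notation are discarded and counted; rows whose structure
    fails to parse are quarantined into the report's rejects, never
    silently dropped. Missing formulas and masses are completed from the
    structure.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]

    has_structure_col = any(
        a in df.columns for k in ("smiles", "inchi") for a in _COLUMN_ALIASES[k]
    )
    has_name = any(a in df.columns for a in _COLUMN_ALIASES["name"])
    missing = []
    if not has_name:
        missing.append("name")
    if not has_structure_col:
        missing.append("smiles or inchi")
    if missing:
        raise ValueError(f"suspect list missing mandatory columns: {missing}")

    report = CurationReport(n_input=len(df))
    if df.empty:
        log.warning("suspect list %s is empty", path)
        return [], report

    records: list[CompoundRecord] = []
    for i, row in df.iterrows():
        name = _get(row, "name")
        rid = _get(row, "id")
        smiles = _get(row, "smiles")
        inchi = _get(row, "inchi")
        if not (rid or name) and not (smiles or inchi):
            report.n_discarded += 1
            continue
        if not (smiles or inchi):
            # identifier but no structural notation: cannot be curated
            report.n_discarded += 1
            continue
        mol = _mol_from_structure(smiles, inchi)
        if mol is None:
            report.rejects.append(
                {"row": int(i), "name": name, "reason": "unparseable structure"}
            )
            continue
        canonical = Chem.MolToSmiles(mol)
        std_inchi = MolToInchi(mol) or inchi
        try:
            f = _formula_from_mol(mol)
        except ValueError as exc:
            report.rejects.append({"row": int(i), "name": name, "reason": str(exc)})
            continue
        mass = monoisotopic_mass(f)
        given_formula = _get(row, "formula")
        if given_formula:
            try:
                gf = parse_formula(given_formula, alphabet=None)
                if gf.counts != f.counts:
                    report.conflicts.append(
                        {
                            "row": int(i),
                            "name": name,
                            "reason": f"stated formula {given_formula} != "
                            f"structure formula {f.hill()}",
                        }
                    )
            except Exception:
                pass
        cls = ChemClass(
            superclass=_get(row, "superclass"),
            class_=_get(row, "class"),
            subclass=_get(row, "subclass"),
        )
        rec = CompoundRecord(
            id=rid or f"SUS{i:05d}",
            name=name or canonical,
            smiles=canonical,
            inchi=std_inchi,
            formula=f,
            monoisotopic_mass=mass,
            classification=cls,
            sources=[s for s in _get(row, "source").split(";") if s],
            species=[s for s in _get(row, "species").split(";") if s],
        )
        records.append(rec)
    report.n_kept = len(records)
    return records, report


def deduplicate(
    records: list[CompoundRecord],
) -> tuple[list[CompoundRecord], CurationReport]:
    """Merge records that share a canonical structure key.

    Names, synonyms, sources and species are unioned (order-preserving);
    the surviving id is the lexicographically smallest. Formula conflicts
    under one key are recorded in the report rather than resolved silently.
    Output is sorted by id; the operation is idempotent.
    """
    report = CurationReport(n_input=len(records))
    groups: dict[str, list[CompoundRecord]] = {}
    for rec in sorted(records, key=lambda r: r.id):
        groups.setdefault(rec.structure_key(), []).append(rec)

    merged: list[CompoundRecord] = []
    for key, group in groups.items():
        head = group[0]
        names: list[str] = []
        sources: list[str] = []
        species: list[str] = []
        cls = head.classification
        for rec in group:
            for n in [rec.name, *rec.synonyms]:
                if n and n not in names:
                    names.append(n)
            for s in rec.sources:
                if s not in sources:
                    sources.append(s)
            for s in rec.species:
                if s not in species:
                    species.append(s)
            if not cls.is_classified() and rec.classification.is_classified():
                cls = rec.classification
            if (
                rec.formula is not None
                and head.formula is not None
                and rec.formula.counts != head.formula.counts
            ):
                report.conflicts.append(
                    {
                        "row": rec.id,
                        "name": rec.name,
                        "reason": f"formula conflict under structure key {key!r}",
                    }
                )
        merged.append(
            replace(
                head,
                name=names[0] if names else head.name,
                synonyms=names[1:],
                sources=sources,
                species=species,
                classification=cls,
            )
        )
    merged.sort(key=lambda r: r.id)
    report.n_kept = len(merged)
    return merged, report


def load_class_map(path) -> dict[str, ChemClass]:
    """Read a structure-key -> classification map from CSV/TSV.

    Expected columns: ``key`` (InChI or canonical SMILES), ``superclass``,
    ``class``, ``subclass`` (the last two optional). Malformed rows are
    skipped with a warning.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    out: dict[str, ChemClass] = {}
    for i, row in df.iterrows():
        key = str(row.get("key", "")).strip()
        if not key:
            log.warning("class map row %d has no key; skipped", i)
            continue
        try:
            out[key] = ChemClass(
                superclass=str(row.get("superclass", "")).strip(),
                class_=str(row.get("class", "")).strip(),
                subclass=str(row.get("subclass", "")).strip(),
            )
        except ValueError as exc:
            log.warning("class map row %d malformed (%s); skipped", i, exc)
    return out


def attach_classification(
    records: list[CompoundRecord], class_map: dict[str, ChemClass]
) -> tuple[list[CompoundRecord], int]:
    """Attach precomputed ontology classes by structure key.

    Returns the updated records and the number left unclassified.
    Records already classified keep their classification unless the map
    provides one (the map is authoritative).
    """
    out: list[CompoundRecord] = []
    n_unclassified = 0
    for rec in records:
        cls = class_map.get(rec.structure_key()) or class_map.get(rec.smiles)
        if cls is not None:
            rec = replace(rec, classification=cls)
        if not rec.classification.is_classified():
            n_unclassified += 1
        out.append(rec)
    return out, n_unclassified


def summarize_classes(records: list[CompoundRecord]) -> pd.DataFrame:
    """Hierarchical class-composition table.

    One row per observed path prefix at each level (kingdom, superclass,
    class, subclass) with ``count`` and ``fraction``; fractions at a level
    are taken among records classified at that level and sum to 1.
    Unclassified records are reported on a separate ``unclassified`` row
    with fraction NaN.
    """
    rows: list[dict] = []
    classified = [r for r in records if r.classification.is_classified()]
    n_unclassified = len(records) - len(classified)
    for depth, level in enumerate(_CLASS_LEVELS):
        paths: dict[tuple[str, ...], int] = {}
        for rec in classified:
            path = rec.classification.path
            if len(path) > depth:
                key = path[: depth + 1]
                paths[key] = paths.get(key, 0) + 1
        total = sum(paths.values())
        for path, count in sorted(paths.items()):
            rows.append(
                {
                    "level": level.rstrip("_"),
                    "path": " / ".join(path),
                    "count": count,
                    "fraction": count / total if total else float("nan"),
                }
            )
    if n_unclassified:
        rows.append(
            {
                "level": "unclassified",
                "path": "",
                "count": n_unclassified,
                "fraction": float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["level", "path", "count", "fraction"])


def records_to_frame(records: list[CompoundRecord]) -> pd.DataFrame:
    """Flatten records to the documented CSV column layout."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "name": r.name,
                "synonyms": ";".join(r.synonyms),
                "smiles": r.smiles,
                "inchi": r.inchi,
                "formula": r.formula.hill() if r.formula else "",
                "monoisotopic_mass": r.monoisotopic_mass,
                "superclass": r.classification.superclass,
                "class": r.classification.class_,
                "subclass": r.classification.subclass,
                "sources": ";".join(r.sources),
                "species": ";".join(r.species),
                "origin": r.origin,
            }
        )
    cols = [
        "id", "name", "synonyms", "smiles", "inchi", "formula",
        "monoisotopic_mass", "superclass", "class", "subclass",
        "sources", "species", "origin",
    ]
    return pd.DataFrame(rows, columns=cols)
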