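"""Known-vs-novel catalog construction.

Newly annotated structures are intersected with the suspect list of known
metabolites (Tanimoto similarity of exactly 1 between Morgan fingerprints,
optionally strict structure identity), then both sides are combined into a
single union catalog in which every compound carries an origin label:

    suspect  known beforehand, not re-observed
    common   known beforehand and re-annotated in the measured data
    novel    annotated in the measured data only

A declarative curation blocklist mechanizes the removal of implausible
annotations (e.g. structures of plant, fungal or animal origin) with a
complete audit log, so the reduction is reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .network import DEFAULT_NBITS, DEFAULT_RADIUS, fingerprint, tanimoto
from .suspects import ChemClass, CompoundRecord, summarize_classes

__all__ = [
    "ExpandedCatalog",
    "BlocklistRule",
    "CurationBlocklist",
    "match_common",
    "build_union",
    "apply_curation",
    "catalog_composition",
]


@dataclass
class ExpandedCatalog:
    """Union of suspect-list and newly annotated compounds."""

    records: list[CompoundRecord]
    removals: list[dict] = field(default_factory=list)

    @property
    def n_suspect_only(self) -> int:
        return sum(1 for r in self.records if r.origin == "suspect")

    @property
    def n_novel(self) -> int:
        return sum(1 for r in self.records if r.origin == "novel")

    @property
    def n_common(self) -> int:
        return sum(1 for r in self.records if r.origin == "common")

    @property
    def n_union(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class BlocklistRule:
    """One curation rule: drop records whose field matches a regex."""

    match_field: str  # name | structure_key | source_tag
    pattern: str
    reason: str

    _FIELDS = ("name", "structure_key", "source_tag")

    def __post_init__(self):
        if self.match_field not in self._FIELDS:
            raise ValueError(f"match_field must be one of {self._FIELDS}")
        if not self.pattern:
            raise ValueError("blocklist rule with empty pattern")

    def matches(self, rec: CompoundRecord) -> bool:
        if self.match_field == "name":
            values = [rec.name, *rec.synonyms]
        elif self.match_field == "structure_key":
            values = [rec.structure_key()]
        else:
            values = rec.sources
        rx = re.compile(self.pattern, re.IGNORECASE)
        return any(rx.search(v) for v in values if v)


@dataclass
class CurationBlocklist:
    rules: list[BlocklistRule]

    @classmethod
    def from_csv(cls, path) -> "CurationBlocklist":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
        rules = [
            BlocklistRule(
                match_field=row["match_field"].strip(),
                pattern=row["pattern"],
                reason=row.get("reason", ""),
            )
            for _, row in df.iterrows()
        ]
        return cls(rules=rules)


def match_common(
    suspects: list[CompoundRecord],
    annotated: list[CompoundRecord],
    strict: bool = False,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_NBITS,
) -> list[tuple[str, str]]:
    """Pairs of (suspect id, annotated id) with fingerprint Tanimoto = 1.

    Each annotated compound is paired with at most one suspect, the first
    in deterministic id order. ``strict=True`` additionally requires
    identical canonical structure keys, guarding against the (rare) hashed
    fingerprint collision between distinct molecules.
    """
    sus_sorted = sorted(suspects, key=lambda r: r.id)
    sus_fps = {}
    for rec in sus_sorted:
        try:
            sus_fps[rec.id] = fingerprint(rec.smiles, radius, n_bits)
        except ValueError:
            continue
    pairs: list[tuple[str, str]] = []
    for ann in sorted(annotated, key=lambda r: r.id):
        try:
            fp = fingerprint(ann.smiles, radius, n_bits)
        except ValueError:
            continue
        for sus in sus_sorted:
            if sus.id not in sus_fps:
                continue
            if tanimoto(sus_fps[sus.id], fp) == 1.0:
                if strict and sus.structure_key() != ann.structure_key():
                    continue
                pairs.append((sus.id, ann.id))
                break
    return pairs


def build_union(
    suspects: list[CompoundRecord],
    annotated: list[CompoundRecord],
    pairs: list[tuple[str, str]],
) -> ExpandedCatalog:
    """Combine suspects and annotated compounds into one origin-labelled set.

    Paired compounds collapse to a single ``common`` record carrying the
    provenance of both sides; the remaining suspects keep origin
    ``suspect`` and the remaining annotated compounds become ``novel``.
    Satisfies inclusion-exclusion exactly:
    ``n_union = n_suspects + n_annotated - n_pairs``.
    """
    paired_sus = {s for s, _ in pairs}
    paired_ann = dict((a, s) for s, a in pairs)
    ann_by_id = {r.id: r for r in annotated}
    out: list[CompoundRecord] = []
    for rec in sorted(suspects, key=lambda r: r.id):
        if rec.id in paired_sus:
            partners = [a for a, s in paired_ann.items() if s == rec.id]
            sources = list(rec.sources)
            synonyms = list(rec.synonyms)
            for aid in partners:
                ann = ann_by_id[aid]
                for s in ann.sources:
                    if s not in sources:
                        sources.append(s)
                for n in [ann.name, *ann.synonyms]:
                    if n and n != rec.name and n not in synonyms:
                        synonyms.append(n)
            out.append(
                replace(rec, origin="common", sources=sources, synonyms=synonyms)
            )
        else:
            out.append(replace(rec, origin="suspect"))
    for rec in sorted(annotated, key=lambda r: r.id):
        if rec.id not in paired_ann:
            out.append(replace(rec, origin="novel"))
    return ExpandedCatalog(records=out)


def apply_curation(
    catalog: ExpandedCatalog, blocklist: CurationBlocklist
) -> ExpandedCatalog:
    """Remove blocklisted records, logging every removal with its rule.

    Idempotent: records not matched by any rule are never touched, and the
    removal log explains each dropped record (rule field, pattern, reason).
    """
    kept: list[CompoundRecord] = []
    removals = list(catalog.removals)
    for rec in catalog.records:
        hit = next((rule for rule in blocklist.rules if rule.matches(rec)), None)
        if hit is None:
            kept.append(rec)
        else:
            removals.append(
                {
                    "id": rec.id,
                    "name": rec.name,
                    "origin": rec.origin,
                    "match_field": hit.match_field,
                    "pattern": hit.pattern,
                    "reason": hit.reason,
                }
            )
    return ExpandedCatalog(records=kept, removals=removals)


def catalog_composition(catalog: ExpandedCatalog) -> dict:
    """Hierarchical class composition of the catalog, overall and per origin.

    Returns a dict with an ``overall`` composition table (level, path,
    count, fraction — sunburst-ready), per-origin tables, and the headline
    counts (suspect-only / common / novel / union).
    """
    def _rows(df: pd.DataFrame) -> list[dict]:
        recs = df.to_dict(orient="records")
        for row in recs:  # JSON-safe: NaN fraction (unclassified) -> None
            v = row.get("fraction")
            if isinstance(v, float) and v != v:
                row["fraction"] = None
        return recs

    overall = summarize_classes(catalog.records)
    per_origin = {
        origin: summarize_classes([r for r in catalog.records if r.origin == origin])
        for origin in ("suspect", "common", "novel")
    }
    return {
        "counts": {
            "n_suspect_only": catalog.n_suspect_only,
            "n_common": catalog.n_common,
            "n_novel": catalog.n_novel,
            "n_union": catalog.n_union,
            "n_removed": len(catalog.removals),
        },
        "overall": _rows(overall),
        "per_origin": {k: _rows(v) for k, v in per_origin.items()},
    }
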