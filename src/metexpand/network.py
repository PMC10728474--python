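"""Chemical-similarity networking over compound structures.

Structures are encoded as circular (Morgan/ECFP-like) fingerprints and
compared all-vs-all with the Tanimoto coefficient; pairs at or above a
similarity threshold (default 0.85) become edges. Connected components of
the resulting graph group structurally related chemistry — e.g. a cluster
of polyunsaturated fatty acids, or of tetrapyrroles.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .suspects import CompoundRecord

__all__ = [
    "Fingerprint",
    "fingerprint",
    "tanimoto",
    "build_network",
    "expand_network",
    "connected_components",
    "write_graphml",
    "write_edgelist",
]

DEFAULT_RADIUS = 2
DEFAULT_NBITS = 2048
DEFAULT_THRESHOLD = 0.85


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length binary structure fingerprint."""

    bits: bytes  # packed bit field
    n_bits: int

    @property
    def n_on(self) -> int:
        return int(np.unpackbits(np.frombuffer(self.bits, dtype=np.uint8)).sum())

    def as_array(self) -> np.ndarray:
        return np.unpackbits(np.frombuffer(self.bits, dtype=np.uint8))[: self.n_bits]

    def on_bits(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.as_array()).tolist())


def fingerprint(
    smiles: str, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_NBITS
) -> Fingerprint:
    """Morgan fingerprint of a structure given as SMILES.

    Deterministic; two SMILES spellings of the same molecule yield the
    same fingerprint because hashing happens on the canonicalized graph.
    Raises ``ValueError`` for unparseable input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    arr[list(gen.GetFingerprint(mol).GetOnBits())] = 1
    return Fingerprint(bits=np.packbits(arr).tobytes(), n_bits=n_bits)


def tanimoto(f1: Fingerprint, f2: Fingerprint) -> float:
    """Tanimoto (Jaccard) coefficient |A & B| / |A | B| of two fingerprints.

    Two all-zero fingerprints are defined to be identical (1.0).
    """
    if f1.n_bits != f2.n_bits:
        raise ValueError(f"fingerprint length mismatch: {f1.n_bits} != {f2.n_bits}")
    a = np.frombuffer(f1.bits, dtype=np.uint8)
    b = np.frombuffer(f2.bits, dtype=np.uint8)
    inter = int(np.bitwise_count(a & b).sum())
    union = int(np.bitwise_count(a | b).sum())
    if union == 0:
        return 1.0
    return inter / union


def _fingerprints(
    records: list[CompoundRecord], radius: int, n_bits: int
) -> tuple[dict[str, Fingerprint], list[dict]]:
    fps: dict[str, Fingerprint] = {}
    skipped: list[dict] = []
    for rec in sorted(records, key=lambda r: r.id):
        try:
            fps[rec.id] = fingerprint(rec.smiles, radius, n_bits)
        except ValueError as exc:
            skipped.append({"id": rec.id, "name": rec.name, "reason": str(exc)})
    return fps, skipped


def build_network(
    records: list[CompoundRecord],
    threshold: float = DEFAULT_THRESHOLD,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_NBITS,
) -> tuple[nx.Graph, list[dict]]:
    """All-vs-all Tanimoto similarity network over compound records.

    Every record becomes a node (isolated nodes are retained so class
    overlays cover the full catalog); an edge joins two distinct records
    whenever their fingerprint Tanimoto similarity is >= ``threshold``.
    Records whose structure fails to parse are collected into the returned
    skip report instead of aborting the run. Node and edge ordering is
    deterministic (sorted by id).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    fps, skipped = _fingerprints(records, radius, n_bits)
    g = nx.Graph(threshold=threshold, radius=radius, n_bits=n_bits)
    by_id = {r.id: r for r in records}
    for rid in sorted(fps):
        rec = by_id[rid]
        g.add_node(
            rid,
            name=rec.name,
            superclass=rec.classification.superclass,
            origin=rec.origin,
        )
    ids = sorted(fps)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            sim = tanimoto(fps[a], fps[b])
            if sim >= threshold:
                g.add_edge(a, b, tanimoto=sim)
    return g, skipped


def expand_network(
    base: nx.Graph,
    novel: list[CompoundRecord],
    base_records: list[CompoundRecord],
    threshold: float | None = None,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_NBITS,
) -> tuple[nx.Graph, list[dict]]:
    """Incorporate newly annotated compounds into an existing network.

    New nodes are flagged ``origin="novel"``; edges are added for every
    novel-base and novel-novel pair at or above the threshold. Base nodes
    and edges are left untouched. An id collision between novel records
    and the base network is an error.
    """
    threshold = threshold if threshold is not None else base.graph.get(
        "threshold", DEFAULT_THRESHOLD
    )
    collisions = {r.id for r in novel} & set(base.nodes)
    if collisions:
        raise ValueError(f"novel ids collide with base network: {sorted(collisions)}")

    g = base.copy()
    base_fps, _ = _fingerprints(
        [r for r in base_records if r.id in base.nodes], radius, n_bits
    )
    novel_fps, skipped = _fingerprints(novel, radius, n_bits)
    by_id = {r.id: r for r in novel}
    for rid in sorted(novel_fps):
        rec = by_id[rid]
        g.add_node(
            rid,
            name=rec.name,
            superclass=rec.classification.superclass,
            origin="novel",
        )
    novel_ids = sorted(novel_fps)
    for i, a in enumerate(novel_ids):
        for b in sorted(base_fps):
            sim = tanimoto(novel_fps[a], base_fps[b])
            if sim >= threshold:
                g.add_edge(a, b, tanimoto=sim)
        for b in novel_ids[i + 1 :]:
            sim = tanimoto(novel_fps[a], novel_fps[b])
            if sim >= threshold:
                g.add_edge(a, b, tanimoto=sim)
    return g, skipped


def connected_components(g: nx.Graph) -> list[set[str]]:
    """Clusters of the similarity network, largest first."""
    return sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)[0]))


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def write_edgelist(g: nx.Graph, path) -> None:
    """Plain TSV edge list: a, b, tanimoto (6 decimals), sorted."""
    with open(path, "w") as fh:
        fh.write("a\tb\ttanimoto\n")
        for a, b, data in sorted(g.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['tanimoto']:.6f}\n")
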