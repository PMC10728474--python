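"""Run configuration and the end-to-end pipeline.

``run_pipeline`` chains the stages in the order a full study analysis
needs them: suspect-list curation, feature dereplication with MSI-level
accounting, the base chemical-similarity network, the known-vs-novel
intersection/union catalog (with optional curation blocklist), the
expanded network, and the class-composition summary. All artifacts are
plain text (CSV/TSV, GraphML, JSON, log) with stable column order, so
reruns under a fixed seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import AnnotationConfig, AnnotationLedger, SpectrumRecord, annotate_all
from .expand import CurationBlocklist, apply_curation, build_union, catalog_composition, match_common
from .formula import ADDUCTS, MassTolerance
from .network import build_network, expand_network, write_edgelist, write_graphml
from .suspects import (
    CompoundRecord,
    attach_classification,
    deduplicate,
    load_class_map,
    load_suspect_list,
    records_to_frame,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_ledger"]


@dataclass
class PipelineConfig:
    """Every tunable of a pipeline run, YAML round-trippable."""

    precursor_tol_ppm: float = 10.0
    fragment_tol_da: float = 0.01
    min_cosine: float = 0.50          # squared-cosine scale
    min_matched_peaks: int = 3
    network_threshold: float = 0.85   # Tanimoto edge cutoff
    adducts: tuple[str, ...] = ("[M+H]+", "[M-H]-")
    strict_common_matching: bool = False
    seed: int = 0
    mode_filter: str = ""             # "", "positive" or "negative"

    def __post_init__(self):
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_da <= 0:
            raise ValueError("tolerances must be positive")
        if not (0.0 <= self.min_cosine <= 1.0):
            raise ValueError("min_cosine must lie in [0, 1]")
        if not (0.0 <= self.network_threshold <= 1.0):
            raise ValueError("network_threshold must lie in [0, 1]")
        if self.min_matched_peaks < 1:
            raise ValueError("min_matched_peaks must be >= 1")
        unknown = set(self.adducts) - set(ADDUCTS)
        if unknown:
            raise ValueError(f"unknown adducts {sorted(unknown)}")
        if self.mode_filter not in ("", "positive", "negative"):
            raise ValueError("mode_filter must be '', 'positive' or 'negative'")

    def annotation_config(self) -> AnnotationConfig:
        return AnnotationConfig(
            precursor_tol=MassTolerance(self.precursor_tol_ppm, "ppm"),
            fragment_tol=MassTolerance(self.fragment_tol_da, "Da"),
            min_score=self.min_cosine,
            min_peaks=self.min_matched_peaks,
            adducts=tuple(self.adducts),
            decompose_tol=MassTolerance(self.precursor_tol_ppm, "ppm"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "adducts" in raw:
            raw["adducts"] = tuple(raw["adducts"])
        return cls(**raw)


@dataclass
class PipelineResult:
    status: int
    artifacts: dict[str, Path] = field(default_factory=dict)
    ledger: AnnotationLedger | None = None
    failed_stage: str | None = None


def write_ledger(ledger: AnnotationLedger, path) -> pd.DataFrame:
    """Flatten the selected annotations to the ledger CSV."""
    rows = []
    for fid in sorted(ledger.selected):
        cand = ledger.selected[fid]
        rows.append(
            {
                "feature_id": fid,
                "msi_level": cand.msi_level,
                "source": cand.source,
                "compound_id": cand.compound.id if cand.compound else "",
                "compound_name": cand.compound.name if cand.compound else "",
                "smiles": cand.compound.smiles if cand.compound else "",
                "formula": (
                    cand.compound.formula.hill()
                    if cand.compound and cand.compound.formula
                    else (cand.formula_only.hill() if cand.formula_only else "")
                ),
                "score": f"{cand.score:.6f}" if cand.score is not None else "",
                "n_matched_peaks": cand.n_matched_peaks,
                "in_source_suspect": cand.in_source_suspect,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def _write_candidates(ledger: AnnotationLedger, path) -> None:
    rows = []
    for fid in sorted(ledger.candidates):
        for rank, cand in enumerate(ledger.candidates[fid], start=1):
            rows.append(
                {
                    "feature_id": fid,
                    "rank": rank,
                    "source": cand.source,
                    "compound_id": cand.compound.id if cand.compound else "",
                    "compound_name": cand.compound.name if cand.compound else "",
                    "score": f"{cand.score:.6f}" if cand.score is not None else "",
                    "ppm": f"{cand.ppm:.3f}" if cand.ppm is not None else "",
                    "in_source_suspect": cand.in_source_suspect,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "feature_id", "rank", "source", "compound_id", "compound_name",
            "score", "ppm", "in_source_suspect",
        ],
    ).to_csv(path, index=False)


def _annotated_compounds(ledger: AnnotationLedger) -> list[CompoundRecord]:
    """Unique structure-bearing annotations (MSI 2/3), one per structure."""
    seen: dict[str, CompoundRecord] = {}
    for fid in sorted(ledger.selected):
        cand = ledger.selected[fid]
        if cand.compound is None:
            continue
        key = cand.compound.structure_key()
        if key not in seen:
            seen[key] = cand.compound
    return list(seen.values())


def run_pipeline(
    config: PipelineConfig,
    suspect_path,
    query_spectra: list[SpectrumRecord],
    spectral_library: list[SpectrumRecord],
    outdir,
    class_map_path=None,
    blocklist_path=None,
) -> PipelineResult:
    """Run every stage and write the artifact set into ``outdir``.

    On a stage failure, the partial artifacts written so far are retained,
    the run log names the failing stage, and the status is nonzero.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(status=0)
    log_lines: list[str] = [
        f"metexpand {__version__}",
        "config: " + json.dumps(dataclasses.asdict(config), sort_keys=True),
    ]
    stage = "curate"
    try:
        # --- suspect-list curation -----------------------------------
        records, load_report = load_suspect_list(suspect_path)
        records, dedup_report = deduplicate(records)
        n_unclassified = sum(
            1 for r in records if not r.classification.is_classified()
        )
        if class_map_path is not None:
            records, n_unclassified = attach_classification(
                records, load_class_map(class_map_path)
            )
        curated_csv = outdir / "suspects_curated.csv"
        records_to_frame(records).to_csv(curated_csv, index=False)
        rejects_csv = outdir / "suspects_rejects.csv"
        load_report.rejects_frame().to_csv(rejects_csv, index=False)
        result.artifacts["suspects_curated"] = curated_csv
        result.artifacts["suspects_rejects"] = rejects_csv
        log_lines += [
            f"curate: {load_report.n_input} rows in, {len(records)} curated, "
            f"{load_report.n_discarded} discarded (no identifier/structure), "
            f"{len(load_report.rejects)} quarantined, "
            f"{n_unclassified} unclassified",
        ]

        # --- dereplication -------------------------------------------
        stage = "annotate"
        if config.mode_filter:
            query_spectra = [q for q in query_spectra if q.mode == config.mode_filter]
        ledger = annotate_all(
            query_spectra, spectral_library, records, config.annotation_config()
        )
        result.ledger = ledger
        ledger_csv = outdir / "annotation_ledger.csv"
        write_ledger(ledger, ledger_csv)
        _write_candidates(ledger, outdir / "annotation_candidates.csv")
        result.artifacts["annotation_ledger"] = ledger_csv
        result.artifacts["annotation_candidates"] = outdir / "annotation_candidates.csv"
        counts = ledger.level_counts()
        by_mode: dict[str, int] = {}
        for q in query_spectra:
            by_mode[q.mode] = by_mode.get(q.mode, 0) + 1
        counts_df = pd.DataFrame(
            [
                {"msi_level": lvl, "n_features": counts.get(lvl, 0)}
                for lvl in (1, 2, 3, 4, 5)
            ]
        )
        counts_df.to_csv(outdir / "msi_level_counts.csv", index=False)
        result.artifacts["msi_level_counts"] = outdir / "msi_level_counts.csv"
        log_lines += [
            "annotate: features by mode "
            + json.dumps(by_mode, sort_keys=True)
            + ", MSI partition "
            + json.dumps({str(k): v for k, v in sorted(counts.items())})
            + f", total {sum(counts.values())}",
        ]

        # --- base network ---------------------------------------------
        stage = "network"
        base_net, skipped = build_network(records, config.network_threshold)
        write_graphml(base_net, outdir / "network_suspects.graphml")
        write_edgelist(base_net, outdir / "network_suspects_edges.tsv")
        result.artifacts["network_suspects"] = outdir / "network_suspects.graphml"
        log_lines.append(
            f"network: {base_net.number_of_nodes()} nodes, "
            f"{base_net.number_of_edges()} edges at threshold "
            f"{config.network_threshold}, {len(skipped)} structures skipped"
        )

        # --- expansion ------------------------------------------------
        stage = "expand"
        annotated = _annotated_compounds(ledger)
        pairs = match_common(
            records, annotated, strict=config.strict_common_matching
        )
        catalog = build_union(records, annotated, pairs)
        if blocklist_path is not None:
            catalog = apply_curation(catalog, CurationBlocklist.from_csv(blocklist_path))
        catalog_csv = outdir / "expanded_catalog.csv"
        records_to_frame(catalog.records).to_csv(catalog_csv, index=False)
        pd.DataFrame(
            catalog.removals,
            columns=["id", "name", "origin", "match_field", "pattern", "reason"],
        ).to_csv(outdir / "curation_removals.csv", index=False)
        result.artifacts["expanded_catalog"] = catalog_csv
        result.artifacts["curation_removals"] = outdir / "curation_removals.csv"
        novel = [r for r in catalog.records if r.origin == "novel"]
        expanded_net, _ = expand_network(
            base_net, novel, records, config.network_threshold
        )
        write_graphml(expanded_net, outdir / "network_expanded.graphml")
        write_edgelist(expanded_net, outdir / "network_expanded_edges.tsv")
        result.artifacts["network_expanded"] = outdir / "network_expanded.graphml"
        composition = catalog_composition(catalog)
        with open(outdir / "composition.json", "w") as fh:
            json.dump(composition, fh, indent=2, sort_keys=True, allow_nan=False,
                      default=str)
        result.artifacts["composition"] = outdir / "composition.json"
        log_lines.append(
            "expand: "
            + json.dumps(composition["counts"], sort_keys=True)
            + f", expanded network {expanded_net.number_of_nodes()} nodes / "
            f"{expanded_net.number_of_edges()} edges"
        )
    except Exception as exc:  # pragma: no cover - exercised via failure test
        result.status = 1
        result.failed_stage = stage
        log_lines.append(f"FAILED at stage {stage}: {exc!r}")
        log.error("pipeline failed at stage %s: %s", stage, exc)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    result.artifacts["run_log"] = outdir / "run.log"
    return result
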