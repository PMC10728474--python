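"""Intersection/union catalog construction and curation."""

import pytest

from metexpand.expand import (
    BlocklistRule,
    CurationBlocklist,
    apply_curation,
    build_union,
    catalog_composition,
    match_common,
)
from metexpand.suspects import ChemClass, CompoundRecord, record_from_smiles


def make(i, smiles, name=None, **kwargs):
    return record_from_smiles(f"R{i}", name or f"cmpd{i}", smiles, **kwargs)


SUSPECT_SMILES = ["CCO", "NCC(=O)O", "OC(=O)C1CCCN1", "c1ccccc1O", "CCCCCCCC(=O)O"]
NOVEL_SMILES = ["CCN", "CC(=O)O", "CCCCO"]


@pytest.fixture
def suspects():
    return [make(i, s) for i, s in enumerate(SUSPECT_SMILES)]


class TestMatchCommon:
    def test_identical_structure_pairs_once(self, suspects):
        annotated = [make(100, "OCC", "ethanol-obs")]
        assert match_common(suspects, annotated) == [("R0", "R100")]

    def test_disjoint_chemistries(self, suspects):
        annotated = [make(100, s) for s in NOVEL_SMILES]
        assert match_common(suspects, annotated) == []

    def test_planted_overlap_recovered_exactly(self, suspects):
        planted = [make(100 + i, s) for i, s in enumerate(SUSPECT_SMILES[:3])]
        novel = [make(200 + i, s) for i, s in enumerate(NOVEL_SMILES)]
        pairs = match_common(suspects, planted + novel)
        assert len(pairs) == 3
        assert {a for _, a in pairs} == {"R100", "R101", "R102"}

    def test_strict_mode_requires_structure_key(self, suspects):
        # stereoisomer sugars collide on achiral fingerprints
        glc = make(300, "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O", "glucose")
        gal = make(301, "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@H]1O", "galactose")
        assert match_common([glc], [gal]) == [("R300", "R301")]
        assert match_common([glc], [gal], strict=True) == []


class TestBuildUnion:
    def test_inclusion_exclusion(self, suspects):
        annotated = [make(100, "OCC"), make(101, "NCC(=O)O"), *[
            make(200 + i, s) for i, s in enumerate(NOVEL_SMILES[:2])
        ]]
        pairs = match_common(suspects, annotated)
        catalog = build_union(suspects, annotated, pairs)
        assert len(pairs) == 2
        assert catalog.n_union == 5 + 4 - 2 == 7
        assert catalog.n_common == 2
        assert catalog.n_novel == 2
        assert catalog.n_suspect_only == 3
        assert catalog.n_union + len(pairs) == len(suspects) + len(annotated)

    def test_no_overlap_is_concatenation(self, suspects):
        annotated = [make(100 + i, s) for i, s in enumerate(NOVEL_SMILES)]
        catalog = build_union(suspects, annotated, [])
        assert catalog.n_union == 8
        assert catalog.n_common == 0

    def test_full_overlap_keeps_suspects_as_common(self, suspects):
        annotated = [make(100 + i, s) for i, s in enumerate(SUSPECT_SMILES)]
        pairs = match_common(suspects, annotated)
        catalog = build_union(suspects, annotated, pairs)
        assert catalog.n_union == len(suspects)
        assert all(r.origin == "common" for r in catalog.records)

    def test_common_records_carry_both_provenances(self):
        sus = [make(0, "CCO", sources=["suspect-db"])]
        ann = [make(100, "OCC", sources=["lcms-annotation"])]
        catalog = build_union(sus, ann, match_common(sus, ann))
        (rec,) = catalog.records
        assert set(rec.sources) == {"suspect-db", "lcms-annotation"}


class TestCuration:
    def _catalog(self, suspects):
        annotated = [make(100 + i, s) for i, s in enumerate(NOVEL_SMILES)]
        return build_union(suspects, annotated, [])

    def test_empty_blocklist_is_identity(self, suspects):
        catalog = self._catalog(suspects)
        out = apply_curation(catalog, CurationBlocklist(rules=[]))
        assert [r.id for r in out.records] == [r.id for r in catalog.records]

    def test_removal_logged_with_rule(self, suspects):
        catalog = self._catalog(suspects)
        bl = CurationBlocklist(
            rules=[BlocklistRule("name", "^cmpd0$", "plant origin")]
        )
        out = apply_curation(catalog, bl)
        assert out.n_union == catalog.n_union - 1
        assert out.removals[0]["id"] == "R0"
        assert out.removals[0]["reason"] == "plant origin"

    def test_idempotent(self, suspects):
        catalog = self._catalog(suspects)
        bl = CurationBlocklist(rules=[BlocklistRule("name", "cmpd10", "x")])
        once = apply_curation(catalog, bl)
        twice = apply_curation(once, bl)
        assert [r.id for r in once.records] == [r.id for r in twice.records]
        assert once.removals == twice.removals

    def test_only_matched_records_removed(self, suspects):
        catalog = self._catalog(suspects)
        bl = CurationBlocklist(rules=[BlocklistRule("name", "cmpd[01]$", "x")])
        out = apply_curation(catalog, bl)
        removed = {r["id"] for r in out.removals}
        kept = {r.id for r in out.records}
        assert removed == {"R0", "R1"}
        assert removed | kept == {r.id for r in catalog.records}

    def test_empty_pattern_is_config_error(self):
        with pytest.raises(ValueError):
            BlocklistRule("name", "", "x")

    def test_source_tag_rule(self, suspects):
        sus = [make(0, "CCO", sources=["fungal-db"]), make(1, "CCN")]
        catalog = build_union(sus, [], [])
        bl = CurationBlocklist(rules=[BlocklistRule("source_tag", "fungal", "y")])
        out = apply_curation(catalog, bl)
        assert [r.id for r in out.records] == ["R1"]


class TestComposition:
    def test_fifty_fifty(self):
        recs = []
        for i, (smiles, cls) in enumerate(
            [("CCO", "A"), ("CCN", "A"), ("CCC", "B"), ("CCCC", "B")]
        ):
            recs.append(
                make(i, smiles, classification=ChemClass(superclass=cls))
            )
        catalog = build_union(recs, [], [])
        comp = catalog_composition(catalog)
        sup = {
            row["path"]: row for row in comp["overall"]
            if row["level"] == "superclass"
        }
        assert sup["Organic compounds / A"]["fraction"] == pytest.approx(0.5)
        assert sup["Organic compounds / B"]["count"] == 2

    def test_unclassified_excluded_from_fractions(self):
        recs = [
            make(0, "CCO", classification=ChemClass(superclass="A")),
            make(1, "CCN"),
        ]
        comp = catalog_composition(build_union(recs, [], []))
        rows = comp["overall"]
        sup = [r for r in rows if r["level"] == "superclass"]
        assert sum(r["fraction"] for r in sup) == pytest.approx(1.0, abs=1e-9)
        uncls = [r for r in rows if r["level"] == "unclassified"]
        assert uncls[0]["count"] == 1 and uncls[0]["fraction"] is None


def test_origin_labels_match_ground_truth(zero_noise_study):
    """End-to-end: union origins agree with the generator's bookkeeping."""
    from metexpand.annotate import annotate_all
    from metexpand.pipeline import _annotated_compounds

    study = zero_noise_study
    ledger = annotate_all(study.features, study.spectral_library, study.suspects)
    annotated = _annotated_compounds(ledger)
    pairs = match_common(study.suspects, annotated)
    catalog = build_union(study.suspects, annotated, pairs)
    truth = study.ground_truth
    measured_in_suspects = set(
        truth[truth.in_suspect_list & ~truth.is_decoy].compound_id
    )
    by_structure = {r.structure_key(): r for r in catalog.records}
    for rec in study.suspects:
        got = by_structure[rec.structure_key()].origin
        assert got == ("common" if rec.id in measured_in_suspects else "suspect")
    # measured structures recoverable at level 2/3 but absent from the
    # suspect list must surface as novel
    expected_novel = set(
        truth[truth.expected_msi.isin([2, 3]) & ~truth.in_suspect_list].compound_id
    )
    got_novel = {r.id for r in catalog.records if r.origin == "novel"}
    assert got_novel == expected_novel
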