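"""Per-gene interolog inference: query cleaning, ortholog filtering,
evidence collection, back-mapping and overlap."""

from __future__ import annotations

import pytest
from helpers import orth, rec, two_species_chain
from hypothesis import given, settings
from hypothesis import strategies as st

import interolog as il
from interolog import InteractionType, Species, UnknownGeneError
from interolog.engine import (
    analyze,
    clean_query_ids,
    collect_ortholog_interactors,
    compute_overlap,
    get_filtered_orthologs,
    predict_interologs,
)
from interolog.fixtures import oracle_predict_all
from interolog.io import GeneDataset

PPI = InteractionType.PPI


@pytest.mark.parametrize(
    "raw, expected",
    [
        (" WB:G1, WB:G2 ,WB:G1", ["WB:G1", "WB:G2"]),
        ("", []),
        (" ,  , ", []),
        ("A\nB;C", ["A", "B", "C"]),
        ("A,,B,\r\nC;;A", ["A", "B", "C"]),
    ],
)
def test_clean_query_ids(raw, expected):
    assert clean_query_ids(raw) == expected


@settings(derandomize=True, max_examples=200)
@given(st.text(alphabet=st.characters(blacklist_categories=("Cs",)), max_size=60))
def test_clean_query_ids_total_and_duplicate_free(raw):
    ids = clean_query_ids(raw)
    assert len(ids) == len(set(ids))
    assert all(tok == tok.strip() and tok for tok in ids)
    # idempotent: re-joining with commas and cleaning again changes nothing
    assert clean_query_ids(",".join(ids)) == ids


class TestOrthologRetrieval:
    def test_species_filter_semantics(self):
        ds = GeneDataset(
            [
                rec(
                    "WB:a1",
                    Species.WB,
                    orthologs=[
                        orth(Species.FB, "FB:b1"),
                        orth(Species.HGNC, "HGNC:1"),
                    ],
                ),
            ]
        )
        assert [e.gene_id for e in get_filtered_orthologs(ds, "WB:a1", Species.FB)] == [
            "FB:b1"
        ]
        assert [e.gene_id for e in get_filtered_orthologs(ds, "WB:a1", None)] == [
            "FB:b1",
            "HGNC:1",
        ]
        assert get_filtered_orthologs(ds, "WB:a1", Species.MGI) == []

    def test_ordering_is_species_then_id(self):
        ds = GeneDataset(
            [
                rec(
                    "WB:a1",
                    Species.WB,
                    orthologs=[
                        orth(Species.HGNC, "HGNC:2"),
                        orth(Species.FB, "FB:b9"),
                        orth(Species.FB, "FB:b1"),
                    ],
                )
            ]
        )
        assert [e.gene_id for e in get_filtered_orthologs(ds, "WB:a1", None)] == [
            "FB:b1",
            "FB:b9",
            "HGNC:2",
        ]

    def test_unknown_gene_signalled(self):
        ds = GeneDataset([])
        with pytest.raises(UnknownGeneError):
            get_filtered_orthologs(ds, "WB:missing", None)


class TestEvidenceCollection:
    def test_absent_ortholog_maps_to_empty_set(self):
        ds = two_species_chain()
        out = collect_ortholog_interactors(
            ds, [orth(Species.FB, "FB:b1"), orth(Species.FB, "FB:absent")], PPI
        )
        assert out == {"FB:b1": {"FB:b2"}, "FB:absent": frozenset()}

    def test_empty_ortholog_list(self):
        assert collect_ortholog_interactors(two_species_chain(), [], PPI) == {}


class TestPrediction:
    def test_relational_composition_chain(self):
        """a1~b1, b1–b2, b2~a2 composes to the predicted pair a1–a2."""
        ds = two_species_chain()
        evidence = {"FB:b1": frozenset({"FB:b2"})}
        assert predict_interologs(ds, Species.WB, evidence, "WB:a1") == {"WB:a2"}

    def test_interactor_without_ortholog_in_query_species(self):
        ds = two_species_chain()
        evidence = {"FB:b2": frozenset({"FB:b1"})}
        # b1's only ortholog is a1 == the query: self-prediction is excluded
        assert predict_interologs(ds, Species.WB, evidence, "WB:a1") == frozenset()
        # but for another query it is a legitimate prediction
        assert predict_interologs(ds, Species.WB, evidence, "WB:a2") == {"WB:a1"}

    def test_interactor_absent_from_dataset_contributes_nothing(self):
        ds = two_species_chain()
        evidence = {"FB:b1": frozenset({"FB:ghost"})}
        assert predict_interologs(ds, Species.WB, evidence, "WB:a1") == frozenset()

    def test_paralog_fanout_predicts_all_orthologs(self):
        ds = GeneDataset(
            [
                rec("WB:a1", Species.WB, orthologs=[orth(Species.FB, "FB:b1")]),
                rec("WB:a2", Species.WB),
                rec("WB:a3", Species.WB),
                rec("FB:b1", Species.FB, ppi={"FB:b2"}),
                rec(
                    "FB:b2",
                    Species.FB,
                    orthologs=[orth(Species.WB, "WB:a2"), orth(Species.WB, "WB:a3")],
                ),
            ]
        )
        evidence = {"FB:b1": frozenset({"FB:b2"})}
        assert predict_interologs(ds, Species.WB, evidence, "WB:a1") == {
            "WB:a2",
            "WB:a3",
        }

    def test_empty_evidence_map(self):
        assert predict_interologs(two_species_chain(), Species.WB, {}, "WB:a1") == frozenset()


@pytest.mark.parametrize(
    "predicted, reported, expected",
    [
        ({"a2", "a3"}, {"a3", "a4"}, {"a3"}),
        ({"a1"}, set(), set()),
        ({"a1", "a2"}, {"a1", "a2"}, {"a1", "a2"}),
    ],
)
def test_compute_overlap(predicted, reported, expected):
    assert compute_overlap(frozenset(predicted), frozenset(reported)) == expected


class TestAnalyze:
    def test_end_to_end_chain_report(self):
        ds = two_species_chain()
        (report,) = analyze(ds, "WB:a1", PPI)
        assert not report.unknown
        assert report.query_species is Species.WB
        assert [e.gene_id for e in report.orthologs_used] == ["FB:b1"]
        assert report.ortholog_interactors == {"FB:b1": {"FB:b2"}}
        assert report.predicted_interologs == {"WB:a2"}
        assert report.reported_interactors == {"WB:a3"}
        assert report.overlap == frozenset()

    def test_unknown_query_yields_flagged_empty_report(self):
        (report,) = analyze(two_species_chain(), "FOO:404", PPI)
        assert report.unknown
        assert report.predicted_interologs == frozenset()
        assert report.reported_interactors == frozenset()
        assert report.overlap == frozenset()
        assert report.orthologs_used == ()

    def test_empty_query_yields_no_reports(self):
        assert analyze(two_species_chain(), " , ", PPI) == []

    def test_order_follows_cleaned_input(self):
        reports = analyze(two_species_chain(), "FB:b2,WB:a1,FB:b2", PPI)
        assert [r.query_id for r in reports] == ["FB:b2", "WB:a1"]


class TestFixtureProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_invariants_on_random_fixtures(self, seed):
        spec = il.FixtureSpec(
            n_species=4,
            genes_per_species=40,
            n_ortholog_groups=25,
            interaction_density=2.5,
            conservation_probability=0.6,
            seed=seed,
        )
        truth, dataset, _ = il.generate_dataset(spec)
        for itype in InteractionType:
            query = ",".join(truth.genes)
            reports = analyze(dataset, query, itype)
            for report in reports:
                assert report.overlap <= report.predicted_interologs
                assert report.overlap <= report.reported_interactors
                for p in report.predicted_interologs:
                    assert dataset.by_id[p].species is report.query_species
            # filter monotonicity: ALL ⊇ every single-species evidence filter
            all_pred = {r.query_id: r.predicted_interologs for r in reports}
            for sp in truth.species:
                for report in analyze(dataset, query, itype, sp):
                    assert report.predicted_interologs <= all_pred[report.query_id]

    def test_engine_equals_oracle_per_gene(self, small_fixture):
        _, truth, dataset, _ = small_fixture
        for itype in InteractionType:
            oracle = oracle_predict_all(truth, itype)
            for report in analyze(dataset, ",".join(truth.genes), itype):
                assert report.predicted_interologs == oracle[report.query_id]
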