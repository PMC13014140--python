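"""Genome-wide unique-pair counting and fold-ratio statistics."""

from __future__ import annotations

import pytest
from helpers import orth, rec

import interolog as il
from interolog import InteractionType, Species
from interolog.fixtures import oracle_species_stats
from interolog.io import GeneDataset
from interolog.stats import (
    InteractionPair,
    compute_species_stats,
    make_pair,
    unique_curated_pairs,
    unique_predicted_pairs,
)

PPI = InteractionType.PPI


def test_canonical_pair_ordering_enforced():
    p = make_pair("WB:b", "WB:a", PPI)
    assert (p.a, p.b) == ("WB:a", "WB:b")
    with pytest.raises(ValueError):
        InteractionPair("WB:b", "WB:a", PPI)


class TestCuratedPairs:
    def test_mirrored_storage_collapses_to_one_pair(self):
        ds = GeneDataset(
            [
                rec("WB:g1", Species.WB, ppi={"WB:g2"}),
                rec("WB:g2", Species.WB, ppi={"WB:g1"}),
            ]
        )
        assert unique_curated_pairs(ds, Species.WB, PPI) == {
            make_pair("WB:g1", "WB:g2", PPI)
        }

    def test_one_sided_storage_counts_identically(self):
        ds = GeneDataset(
            [
                rec("WB:g1", Species.WB, ppi={"WB:g2"}),
                rec("WB:g2", Species.WB),
            ]
        )
        assert len(unique_curated_pairs(ds, Species.WB, PPI)) == 1

    def test_species_with_no_interactions(self):
        ds = GeneDataset([rec("WB:g1", Species.WB)])
        assert unique_curated_pairs(ds, Species.WB, PPI) == set()
        assert unique_curated_pairs(ds, Species.FB, PPI) == set()

    def test_cross_species_partner_excluded(self):
        ds = GeneDataset(
            [
                rec("WB:g1", Species.WB, ppi={"FB:b1", "WB:g2"}),
                rec("WB:g2", Species.WB),
                rec("FB:b1", Species.FB),
            ]
        )
        assert unique_curated_pairs(ds, Species.WB, PPI) == {
            make_pair("WB:g1", "WB:g2", PPI)
        }

    def test_self_pair_kept_in_curated(self):
        ds = GeneDataset([rec("WB:g1", Species.WB, ppi={"WB:g1"})])
        assert unique_curated_pairs(ds, Species.WB, PPI) == {
            make_pair("WB:g1", "WB:g1", PPI)
        }


def _expansion_dataset() -> GeneDataset:
    """Worm genes a1..a4 with 2 curated PPIs; fly orthologs b1..b4 with 6
    PPIs, so the full predicted set has 6 pairs, 2 of them already curated."""
    worm_ppi = {"WB:a1": {"WB:a2"}, "WB:a2": {"WB:a1"}, "WB:a3": {"WB:a4"}, "WB:a4": {"WB:a3"}}
    fly_adj = {
        "FB:b1": {"FB:b2", "FB:b3", "FB:b4"},
        "FB:b2": {"FB:b1", "FB:b3", "FB:b4"},
        "FB:b3": {"FB:b1", "FB:b2", "FB:b4"},
        "FB:b4": {"FB:b1", "FB:b2", "FB:b3"},
    }
    records = []
    for i in range(1, 5):
        a, b = f"WB:a{i}", f"FB:b{i}"
        records.append(
            rec(a, Species.WB, ppi=worm_ppi.get(a, ()), orthologs=[orth(Species.FB, b)])
        )
        records.append(
            rec(b, Species.FB, ppi=fly_adj[b], orthologs=[orth(Species.WB, a)])
        )
    return GeneDataset(records)


class TestPredictedPairsAndStats:
    def test_mirror_predictions_collapse_to_one_pair(self):
        ds = _expansion_dataset()
        pairs = unique_predicted_pairs(ds, Species.WB, PPI)
        assert make_pair("WB:a1", "WB:a2", PPI) in pairs
        assert len(pairs) == 6

    def test_total_and_novel_only_counts(self):
        ds = _expansion_dataset()
        (total,) = compute_species_stats(ds, [Species.WB], PPI, novel_only=False)
        assert (total.curated_count, total.predicted_count) == (2, 6)
        assert total.fold_ratio == pytest.approx(3.0)
        (novel,) = compute_species_stats(ds, [Species.WB], PPI, novel_only=True)
        assert novel.predicted_count == 4
        assert novel.fold_ratio == pytest.approx(2.0)

    def test_fold_ratio_undefined_without_curated_pairs(self):
        ds = GeneDataset(
            [
                rec("WB:a1", Species.WB, orthologs=[orth(Species.FB, "FB:b1")]),
                rec("WB:a2", Species.WB, orthologs=[orth(Species.FB, "FB:b2")]),
                rec("FB:b1", Species.FB, ppi={"FB:b2"}, orthologs=[orth(Species.WB, "WB:a1")]),
                rec("FB:b2", Species.FB, ppi={"FB:b1"}, orthologs=[orth(Species.WB, "WB:a2")]),
            ]
        )
        (st,) = compute_species_stats(ds, [Species.WB], PPI)
        assert st.curated_count == 0 and st.predicted_count == 1
        assert st.fold_ratio is None

    def test_absent_species_yields_empty_counts(self):
        ds = _expansion_dataset()
        assert unique_predicted_pairs(ds, Species.MGI, PPI) == set()
        (st,) = compute_species_stats(ds, [Species.MGI], PPI)
        assert (st.curated_count, st.predicted_count, st.fold_ratio) == (0, 0, None)

    def test_predicted_pairs_never_contain_self_pairs(self, small_fixture):
        _, truth, dataset, _ = small_fixture
        for itype in InteractionType:
            for sp in truth.species:
                for pair in unique_predicted_pairs(dataset, sp, itype):
                    assert pair.a != pair.b


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", [3, 7, 11])
    @pytest.mark.parametrize("novel_only", [True, False])
    def test_stats_table_equals_oracle_table(self, seed, novel_only):
        spec = il.FixtureSpec(
            n_species=5,
            genes_per_species=30,
            n_ortholog_groups=20,
            interaction_density=2.0,
            conservation_probability=0.5,
            seed=seed,
        )
        truth, dataset, _ = il.generate_dataset(spec)
        for itype in InteractionType:
            engine_rows = compute_species_stats(
                dataset, truth.species, itype, novel_only=novel_only
            )
            oracle_rows = [
                oracle_species_stats(truth, sp, itype, novel_only=novel_only)
                for sp in truth.species
            ]
            assert engine_rows == oracle_rows

    def test_storage_symmetry_invariance(self):
        """Counts are identical whether each planted interaction is stored
        on one row or mirrored on both."""
        base = dict(
            n_species=3,
            genes_per_species=30,
            n_ortholog_groups=20,
            interaction_density=2.0,
            conservation_probability=0.5,
            seed=5,
        )
        sym_truth, sym_ds, _ = il.generate_dataset(il.FixtureSpec(**base))
        asym_truth, asym_ds, _ = il.generate_dataset(
            il.FixtureSpec(**base, symmetric_storage=False)
        )
        assert sym_truth.interactions == asym_truth.interactions
        for itype in InteractionType:
            for sp in sym_truth.species:
                assert unique_curated_pairs(sym_ds, sp, itype) == unique_curated_pairs(
                    asym_ds, sp, itype
                )
                assert unique_predicted_pairs(
                    sym_ds, sp, itype
                ) == unique_predicted_pairs(asym_ds, sp, itype)
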