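"""Damage clustering and the seven-way DSB taxonomy."""

import numpy as np
import pandas as pd
import pytest

from nanodamage.classify import (DamageCluster, classify, cluster_damages,
                                 tally_yields)
from nanodamage.geometry import build_helix, build_plasmid

from .conftest import make_records
from .oracles import oracle_cluster, random_damage_set


@pytest.fixture(scope="module")
def helix():
    return build_helix(300, "quarter_cylinder")


def categories_of(clusters):
    return sorted(c.category for c in clusters)


class TestTaxonomyInstances:
    """Each damage-pattern archetype maps to its category."""

    def test_isolated_base(self, helix):
        cl = cluster_damages(make_records([(100, 1, "base")]), helix)
        assert categories_of(cl) == ["isolated_base"]

    def test_isolated_backbone(self, helix):
        cl = cluster_damages(make_records([(100, 1, "backbone")]), helix)
        assert categories_of(cl) == ["isolated_backbone_SSB"]

    def test_potential_dsb(self, helix):
        cl = cluster_damages(make_records([(100, 1, "backbone"),
                                           (104, 2, "base")]), helix)
        assert categories_of(cl) == ["potential_DSB"]

    def test_simple_dsb(self, helix):
        cl = cluster_damages(make_records([(100, 1, "backbone"),
                                           (105, 2, "backbone")]), helix)
        assert categories_of(cl) == ["simple_DSB"]
        assert cl[0].extremities == (100, 105)

    def test_simple_dsb_with_base(self, helix):
        cl = cluster_damages(make_records([(100, 1, "backbone"),
                                           (105, 2, "backbone"),
                                           (97, 2, "base")]), helix)
        assert categories_of(cl) == ["simple_DSB_with_base"]

    def test_complex_dsb(self, helix):
        cl = cluster_damages(make_records([(100, 1, "backbone"),
                                           (105, 2, "backbone"),
                                           (108, 1, "backbone")]), helix)
        assert categories_of(cl) == ["complex_DSB"]

    def test_complex_dsb_with_base(self, helix):
        cl = cluster_damages(make_records([(100, 1, "backbone"),
                                           (105, 2, "backbone"),
                                           (108, 1, "backbone"),
                                           (111, 2, "base")]), helix)
        assert categories_of(cl) == ["complex_DSB_with_base"]


class TestClusteringRules:
    def test_eleven_bp_gives_two_ssbs(self, helix):
        cl = cluster_damages(make_records([(100, 1, "backbone"),
                                           (111, 2, "backbone")]), helix)
        assert categories_of(cl) == ["isolated_backbone_SSB"] * 2

    def test_ten_bp_inclusive(self, helix):
        cl = cluster_damages(make_records([(100, 1, "backbone"),
                                           (110, 2, "backbone")]), helix)
        assert categories_of(cl) == ["simple_DSB"]

    def test_same_strand_never_pairs(self, helix):
        cl = cluster_damages(make_records([(100, 1, "backbone"),
                                           (101, 1, "backbone")]), helix)
        assert categories_of(cl) == ["isolated_backbone_SSB"] * 2

    def test_chained_cluster_is_one_dsb(self, helix):
        """A chain spanning more than 10 bp still counts as a single DSB."""
        recs = make_records([(100, 1, "backbone"), (108, 2, "backbone"),
                             (116, 1, "backbone"), (124, 2, "backbone")])
        cl = cluster_damages(recs, helix)
        assert categories_of(cl) == ["complex_DSB"]
        assert cl[0].extremities == (100, 124)

    def test_attached_base_same_bp_strand_discarded(self, helix):
        """A base on a damaged backbone's own nucleotide is dropped."""
        recs = make_records([(100, 1, "backbone"), (105, 2, "backbone"),
                             (100, 1, "base")])
        cl = cluster_damages(recs, helix)
        assert categories_of(cl) == ["simple_DSB"]

    def test_base_beyond_three_bp_not_attached(self, helix):
        recs = make_records([(100, 1, "backbone"), (105, 2, "backbone"),
                             (96, 2, "base")])
        cl = cluster_damages(recs, helix)
        assert categories_of(cl) == ["isolated_base", "simple_DSB"]

    def test_base_attachment_strand_agnostic(self, helix):
        for strand in (1, 2):
            recs = make_records([(100, 1, "backbone"), (105, 2, "backbone"),
                                 (103, strand, "base")])
            # bp 103 carries no damaged backbone, so no discard; it is inside
            # the cluster span hence within 3 bp of an extremity
            cl = cluster_damages(recs, helix)
            assert categories_of(cl) == ["simple_DSB_with_base"]

    def test_potential_dsb_never_promoted(self, helix):
        """One isolated backbone pairs with its nearest opposite base only."""
        recs = make_records([(100, 1, "backbone"), (104, 2, "base"),
                             (108, 2, "base")])
        cl = cluster_damages(recs, helix)
        assert categories_of(cl) == ["isolated_base", "potential_DSB"]

    def test_circular_wraparound_pairs(self):
        plasmid = build_plasmid("sphere")
        recs = make_records([(4360, 1, "backbone"), (3, 2, "backbone")])
        cl = cluster_damages(recs, plasmid)
        assert categories_of(cl) == ["simple_DSB"]

    def test_unknown_bp_rejected(self, helix):
        with pytest.raises(ValueError):
            cluster_damages(make_records([(10_000, 1, "backbone")]), helix)


class TestClassifyFunction:
    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            classify(DamageCluster(records=make_records([]).iloc[:0]))

    @pytest.mark.parametrize("n_bb,n_base,expected", [
        (2, 0, "simple_DSB"), (2, 1, "simple_DSB_with_base"),
        (3, 0, "complex_DSB"), (3, 1, "complex_DSB_with_base"),
        (5, 3, "complex_DSB_with_base"), (1, 0, "isolated_backbone_SSB"),
    ])
    def test_category_is_function_of_content(self, n_bb, n_base, expected):
        entries = [(100 + i, 1 + i % 2, "backbone") for i in range(n_bb)]
        entries += [(90 + i, 1, "base") for i in range(n_base)]
        cl = DamageCluster(records=make_records(entries))
        assert classify(cl) == expected


class TestPartitionProperties:
    def test_partition_matches_oracle_on_random_sets(self, helix):
        """Implementation partition == naive all-pairs BFS oracle."""
        rng = np.random.default_rng(42)
        for _ in range(150):
            recs = random_damage_set(rng, helix.n_bp)
            got = cluster_damages(recs, helix)
            part_expect, cats_expect = oracle_cluster(recs, helix.n_bp, False)
            assert categories_of(got) == cats_expect
            part_got = {
                frozenset(zip(sub["bp_index"], sub["strand"]))
                for c in got
                for sub in [c.records[c.records["kind"] == "backbone"]]
                if len(sub)}
            part_expect_keys = {
                frozenset((int(recs.loc[i, "bp_index"]), int(recs.loc[i, "strand"]))
                          for i in comp)
                for comp in part_expect}
            assert part_got == part_expect_keys

    def test_order_independence(self, helix):
        rng = np.random.default_rng(7)
        recs = random_damage_set(rng, helix.n_bp)
        shuffled = recs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert categories_of(cluster_damages(recs, helix)) == \
            categories_of(cluster_damages(shuffled, helix))

    def test_records_conserved(self, helix):
        """Every non-discarded record lands in exactly one cluster."""
        rng = np.random.default_rng(13)
        recs = random_damage_set(rng, helix.n_bp)
        clusters = cluster_damages(recs, helix)
        bb_keys = set(zip(recs.loc[recs["kind"] == "backbone", "bp_index"],
                          recs.loc[recs["kind"] == "backbone", "strand"]))
        discarded = ((recs["kind"] == "base")
                     & np.array([(b, s) in bb_keys for b, s in
                                 zip(recs["bp_index"], recs["strand"])])).sum()
        total = sum(len(c.records) for c in clusters)
        assert total == len(recs) - discarded


class TestYields:
    def _simple_dsb_clusters(self, helix, n):
        out = []
        for i in range(n):
            recs = make_records([(20 * i + 1, 1, "backbone"),
                                 (20 * i + 3, 2, "backbone")])
            out.extend(cluster_damages(recs, helix))
        return out

    def test_normalisation(self, helix):
        cl = self._simple_dsb_clusters(helix, 6)
        tab = tally_yields(cl, genome_bp=6e9, dose=1.0)
        assert tab.loc["DSB", "count"] == 6
        assert tab.loc["DSB", "per_gbp_gy"] == pytest.approx(1.0)

    def test_dose_halves_per_gy_yield(self, helix):
        cl = self._simple_dsb_clusters(helix, 4)
        t1 = tally_yields(cl, 1e9, dose=1.0)
        t2 = tally_yields(cl, 1e9, dose=2.0)
        assert t2.loc["DSB", "per_gbp_gy"] == pytest.approx(
            t1.loc["DSB", "per_gbp_gy"] / 2.0)

    def test_mass_conversion(self, helix):
        """650 Da/bp converts per-bp yields into per-mass yields."""
        cl = self._simple_dsb_clusters(helix, 1)
        tab = tally_yields(cl, 1e9, dose=1.0)
        assert tab.loc["DSB", "per_gda_gy"] == pytest.approx(
            tab.loc["DSB", "per_gbp_gy"] / 650.0)

    def test_invalid_inputs(self, helix):
        with pytest.raises(ValueError):
            tally_yields([], 0, 1.0)
        with pytest.raises(ValueError):
            tally_yields([], 1e9, 0.0)
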