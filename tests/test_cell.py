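"""Whole-nucleus model: dose bookkeeping, spatial clustering, libraries."""

import math

import numpy as np
import pandas as pd
import pytest

from nanodamage.cell import (ComplexityLibrary, NucleusModel, PhotonReference,
                             cluster_breaks_spatial, irradiate_nucleus,
                             photon_cell, populate_complexity)


def breaks_at(points, strands):
    pts = np.atleast_2d(points)
    return pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
                         "strand": strands, "energy": 20.0,
                         "track_id": 0})


@pytest.fixture(scope="module")
def toy_library():
    lib = ComplexityLibrary()
    lib.entries[0.2] = {
        "dsb": pd.DataFrame({"category": ["simple_DSB"] * 8 + ["complex_DSB"] * 2,
                             "n_backbones": [2] * 8 + [3] * 2,
                             "n_bases": 0}),
        "isolated": ["isolated_backbone_SSB"] * 6 + ["isolated_base"] * 3
        + ["potential_DSB"],
    }
    lib.entries[10.0] = {
        "dsb": pd.DataFrame({"category": ["complex_DSB_with_base"],
                             "n_backbones": [4], "n_bases": [2]}),
        "isolated": ["isolated_backbone_SSB"],
    }
    return lib


class TestIrradiateNucleus:
    def test_delivered_dose_within_one_percent(self):
        for seed in range(6):
            bs = irradiate_nucleus(1.0, 5.0, seed=seed)
            assert bs.delivered_dose_gy == pytest.approx(1.0, rel=0.01)

    def test_high_let_few_tracks_still_on_dose(self):
        bs = irradiate_nucleus(1.0, 30.0, seed=1)
        assert bs.delivered_dose_gy == pytest.approx(1.0, rel=0.01)
        assert bs.n_tracks < 30

    def test_zero_acceptance_gives_no_breaks(self):
        m = NucleusModel(acceptance_fraction=0.0)
        bs = irradiate_nucleus(1.0, 10.0, model=m, seed=2)
        assert len(bs.breaks) == 0

    def test_break_count_scales_with_dose(self):
        n1 = np.mean([len(irradiate_nucleus(1.0, 10.0, seed=s).breaks)
                      for s in range(5)])
        n2 = np.mean([len(irradiate_nucleus(2.0, 10.0, seed=s + 50).breaks)
                      for s in range(5)])
        assert n2 / n1 == pytest.approx(2.0, rel=0.15)

    def test_breaks_inside_nucleus(self):
        bs = irradiate_nucleus(1.0, 10.0, seed=3)
        r = np.linalg.norm(bs.breaks[["x", "y", "z"]].to_numpy(), axis=1)
        # spur jitter can push a deposit marginally past the surface
        assert r.max() < 2500.0 + 10.0

    def test_strands_are_fair_coin(self):
        bs = irradiate_nucleus(2.0, 10.0, seed=4)
        s = bs.breaks["strand"].to_numpy()
        n = len(s)
        assert abs((s == 1).sum() - n / 2) < 3 * math.sqrt(n * 0.25)

    def test_invalid_dose(self):
        with pytest.raises(ValueError):
            irradiate_nucleus(0.0, 10.0)


class TestSpatialClustering:
    def test_opposite_strands_within_eps_pair(self):
        b = breaks_at([[0, 0, 0], [0, 0, 3.3]], [1, 2])
        clusters, ssb = cluster_breaks_spatial(b)
        assert len(clusters) == 1 and len(ssb) == 0

    def test_same_strand_never_pairs(self):
        b = breaks_at([[0, 0, 0], [0, 0, 1.0]], [1, 1])
        clusters, ssb = cluster_breaks_spatial(b)
        assert len(clusters) == 0 and len(ssb) == 2

    def test_beyond_eps_stays_separate(self):
        b = breaks_at([[0, 0, 0], [0, 0, 3.5]], [1, 2])
        clusters, ssb = cluster_breaks_spatial(b)
        assert len(clusters) == 0 and len(ssb) == 2

    def test_chain_merging_transitive(self):
        b = breaks_at([[0, 0, 0], [0, 0, 3.0], [0, 0, 6.0]], [1, 2, 1])
        clusters, _ = cluster_breaks_spatial(b)
        assert len(clusters) == 1 and len(clusters[0]) == 3

    def test_matches_brute_force_transitive_closure(self):
        """Random point sets: DBSCAN partition equals the all-pairs oracle."""
        rng = np.random.default_rng(21)
        for _ in range(30):
            n = rng.integers(2, 60)
            pts = rng.uniform(0, 25, size=(n, 3))
            strands = rng.integers(1, 3, n)
            b = breaks_at(pts, strands)
            clusters, ssb = cluster_breaks_spatial(b)
            # oracle: naive adjacency + BFS
            adj = {i: set() for i in range(n)}
            for i in range(n):
                for j in range(i + 1, n):
                    if strands[i] != strands[j] and \
                            np.linalg.norm(pts[i] - pts[j]) <= 3.4:
                        adj[i].add(j)
                        adj[j].add(i)
            seen, comps = set(), []
            for i in range(n):
                if i in seen:
                    continue
                stack, comp = [i], set()
                while stack:
                    k = stack.pop()
                    if k in comp:
                        continue
                    comp.add(k)
                    stack.extend(adj[k] - comp)
                seen |= comp
                comps.append(frozenset(comp))
            expect_clusters = {c for c in comps if len(c) >= 2}
            got_clusters = {frozenset(c.tolist()) for c in clusters}
            assert got_clusters == expect_clusters
            assert set(ssb.tolist()) == set().union(
                *[c for c in comps if len(c) == 1]) if any(
                len(c) == 1 for c in comps) else len(ssb) == 0


class TestComplexityLibrary:
    def test_nearest_let_bin(self, toy_library):
        assert toy_library.nearest_key(12.0) == 10.0
        assert toy_library.nearest_key(1.0) == 0.2
        assert toy_library.nearest_key("co60") == 0.2

    def test_degenerate_library_gives_single_category(self, toy_library):
        b = breaks_at(np.random.default_rng(0).uniform(0, 100, (12, 3)),
                      [1, 2] * 6)
        clusters = [np.array([0, 1])] * 4
        out = populate_complexity(clusters, np.array([2, 3]), b, toy_library,
                                  beam_key=12.0, seed=0)
        dsb = out[out["type"] == "DSB"]
        assert (dsb["category"] == "complex_DSB_with_base").all()
        assert (dsb["n_backbones"] == 4).all()

    def test_draw_frequencies_match_library(self, toy_library):
        """Multinomial check: draws reproduce the source probabilities."""
        rng = np.random.default_rng(5)
        draws = toy_library.draw_dsb(0.2, rng, 10_000)
        f_simple = (draws["category"] == "simple_DSB").mean()
        se = math.sqrt(0.8 * 0.2 / 10_000)
        assert abs(f_simple - 0.8) < 3 * se

    def test_empty_key_raises(self):
        lib = ComplexityLibrary()
        with pytest.raises(KeyError):
            lib.nearest_key(1.0)

    def test_from_fibre_results_warns_when_thin(self):
        from nanodamage.experiments import FibreExposureResult
        res = FibreExposureResult(
            let_t=10.0, n_primaries=10, indirect_fraction=0.5,
            indirect_fraction_sem=0.1, dsb_probabilities={},
            category_counts={},
            dsb_samples=pd.DataFrame({"category": ["simple_DSB"],
                                      "n_backbones": [2], "n_bases": [0]}),
            isolated_samples=["isolated_base"])
        with pytest.warns(UserWarning, match="noisy"):
            ComplexityLibrary.from_fibre_results({10.0: res})


class TestPhotonCell:
    def test_zero_dose_empty(self):
        res = photon_cell(0.0, seed=0)
        assert res.dsb_count == 0 and res.ssb_count == 0

    def test_mean_dsb_count_at_one_gray(self):
        """4.2 DSB/Gbp/Gy x 6 Gbp -> mean 25.2 DSBs per cell."""
        counts = [photon_cell(1.0, seed=s).dsb_count for s in range(800)]
        mean = np.mean(counts)
        sem = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(mean - 25.2) < 3 * sem

    def test_poisson_dispersion(self):
        counts = np.array([photon_cell(1.0, seed=s).dsb_count
                           for s in range(800)])
        disp = counts.var(ddof=1) / counts.mean()
        assert disp == pytest.approx(1.0, abs=0.15)

    def test_ssb_ratio_within_interval(self):
        res = photon_cell(1.0, seed=3)
        if res.dsb_count:
            ratio = res.ssb_count / res.dsb_count
            assert 24.5 <= ratio <= 40.5

    def test_positions_inside_nucleus(self):
        res = photon_cell(2.0, seed=4)
        r = np.linalg.norm(res.positions, axis=1)
        assert r.max() <= 2500.0

    def test_complexity_populated_from_library(self, toy_library):
        res = photon_cell(1.0, seed=5, library=toy_library)
        assert res.classified is not None
        assert set(res.classified["category"]) <= {"simple_DSB", "complex_DSB"}

    def test_invalid_reference(self):
        with pytest.raises(ValueError):
            PhotonReference(dsb_rate_per_gbp_gy=0.0)
        with pytest.raises(ValueError):
            PhotonReference(ssb_to_dsb_ratio=(40.0, 25.0))


class TestProximity:
    def test_dsb_proximity_shrinks_with_let(self):
        """Median nearest-neighbour DSB distance decreases at higher LET."""
        from nanodamage.cell import cluster_breaks_spatial

        def median_nn(let, seed):
            d = []
            for s in range(3):
                bs = irradiate_nucleus(2.0, let, seed=(seed, s))
                clusters, _ = cluster_breaks_spatial(bs.breaks)
                if len(clusters) < 2:
                    continue
                xyz = bs.breaks[["x", "y", "z"]].to_numpy()
                cent = np.array([xyz[c].mean(axis=0) for c in clusters])
                from scipy.spatial import cKDTree
                dist, _ = cKDTree(cent).query(cent, k=2)
                d.extend(dist[:, 1])
            return np.median(d)

        assert median_nn(30.0, 31) < median_nn(2.0, 32)
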