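"""Spectral distances, linkage, detrending and the cluster-count statistic.

The small-fixture oracles here are deliberately independent of scipy: a
double-loop distance computation and a hand-rolled UPGMA, both checked
exactly against the library path.
"""

import numpy as np
import pytest

from entolidar.diversity import (
    CondensedDistances,
    compensate_linkages,
    count_noc,
    cut_labels,
    diversity_pipeline,
    linkage_tree,
    pairwise_distances,
    spectral_distance,
    summarize_clusters,
)
from entolidar.events import build_event_table
from entolidar.spectral import ModulationSpectrum, make_grid, modulation_spectrum
from entolidar.synthetic import build_class_library, generate_noise_fragments

from conftest import simulate_spectra


def _spec(P, grid, sid="s"):
    return ModulationSpectrum(sid, np.asarray(P, dtype=float), grid)


# ---------------------------------------------------------------------------
# independent oracles


def naive_distance(pa, pb):
    la = np.log(pa / pa.sum())
    lb = np.log(pb / pb.sum())
    return float(np.sqrt(((la - lb) ** 2).sum()))


def naive_upgma_heights(dmat):
    """Textbook UPGMA agglomeration; returns merge heights in merge order."""
    n = dmat.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {frozenset((i, j)): dmat[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        (a, b), h = min(
            (((i, j), d[frozenset((i, j))])
             for i in clusters for j in clusters if i < j),
            key=lambda kv: kv[1],
        )
        heights.append(h)
        merged = clusters[a] + clusters[b]
        for c in clusters:
            if c in (a, b):
                continue
            na, nb = len(clusters[a]), len(clusters[b])
            d[frozenset((next_id, c))] = (
                na * d[frozenset((a, c))] + nb * d[frozenset((b, c))]
            ) / (na + nb)
        del clusters[a], clusters[b]
        clusters[next_id] = merged
        next_id += 1
    return np.array(heights)


# ---------------------------------------------------------------------------


class TestSpectralDistance:
    def test_identity_is_zero(self, grid):
        a = _spec(np.linspace(1, 5, grid.n_bins), grid)
        assert spectral_distance(a, a) == 0.0

    def test_rescaling_invariance(self, grid):
        P = np.linspace(1, 5, grid.n_bins)
        a, b = _spec(P, grid), _spec(17.3 * P, grid)
        assert spectral_distance(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_two_bin_hand_value(self):
        g = make_grid(40.0, 1666.0, 2)
        d = spectral_distance(_spec([1.0, 1.0], g), _spec([1.0, 3.0], g))
        expected = np.sqrt(np.log(2.0) ** 2 + np.log(2.0 / 3.0) ** 2)  # 0.8030...
        assert d == pytest.approx(expected, abs=1e-12)
        assert d == pytest.approx(0.8030, abs=5e-4)

    def test_grid_mismatch_rejected(self, grid):
        g2 = make_grid(40.0, 1666.0, 40)
        with pytest.raises(ValueError):
            spectral_distance(
                _spec(np.ones(grid.n_bins), grid), _spec(np.ones(40), g2)
            )

    def test_matches_naive_double_loop_exactly(self, grid):
        rng = np.random.default_rng(3)
        specs = [_spec(rng.uniform(0.1, 5.0, grid.n_bins), grid, f"s{i}") for i in range(10)]
        cd = pairwise_distances(specs)
        k = 0
        for i in range(10):
            for j in range(i + 1, 10):
                assert cd.d[k] == pytest.approx(naive_distance(specs[i].P, specs[j].P), abs=1e-9)
                k += 1

    def test_triangle_inequality(self, grid):
        rng = np.random.default_rng(5)
        specs = [_spec(rng.uniform(0.1, 5.0, grid.n_bins), grid) for _ in range(3)]
        ab = spectral_distance(specs[0], specs[1])
        bc = spectral_distance(specs[1], specs[2])
        ac = spectral_distance(specs[0], specs[2])
        assert ac <= ab + bc + 1e-12

    def test_three_identical_spectra_all_zero(self, grid):
        s = _spec(np.linspace(1, 2, grid.n_bins), grid)
        cd = pairwise_distances([s, s, s])
        np.testing.assert_allclose(cd.d, 0.0, atol=1e-12)


class TestLinkage:
    def test_two_observations_single_merge_at_distance(self, grid):
        a = _spec(np.ones(grid.n_bins), grid)
        b = _spec(np.linspace(1, 3, grid.n_bins), grid)
        tree = linkage_tree(pairwise_distances([a, b]))
        assert tree.heights.shape == (1,)
        assert tree.heights[0] == pytest.approx(spectral_distance(a, b))

    def test_first_merge_at_minimum_distance(self):
        cd = CondensedDistances(3, np.array([1.0, 4.0, 1.1]))
        tree = linkage_tree(cd)
        assert tree.heights[0] == pytest.approx(1.0)

    def test_average_linkage_matches_naive_upgma(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (12, 6))
        from scipy.spatial.distance import pdist, squareform

        d = pdist(X)
        tree = linkage_tree(CondensedDistances(12, d), method="average")
        np.testing.assert_allclose(
            tree.heights, naive_upgma_heights(squareform(d)), rtol=1e-10
        )

    def test_nan_distance_rejected(self):
        with pytest.raises(ValueError):
            linkage_tree(CondensedDistances(3, np.array([1.0, np.nan, 1.0])))

    def test_heights_nondecreasing_for_monotone_methods(self, grid):
        rng = np.random.default_rng(1)
        specs = [_spec(rng.uniform(0.5, 2.0, grid.n_bins), grid) for _ in range(30)]
        for method in ("single", "average"):
            h = linkage_tree(pairwise_distances(specs), method=method).heights
            assert np.all(np.diff(h) >= -1e-12)


class TestCompensation:
    def test_flat_sequence_beta_zero(self):
        zc, beta = compensate_linkages(np.array([2.0, 2.0, 2.0, 2.0]))
        assert beta == 0.0
        np.testing.assert_allclose(zc, 2.0)

    def test_linear_sequence_beta_one(self):
        zc, beta = compensate_linkages(np.array([1.0, 2.0, 3.0, 4.0]))
        assert beta == pytest.approx(1.0)
        np.testing.assert_allclose(zc, 4.0, rtol=1e-12)

    @pytest.mark.parametrize("b", [0.3, 1.0, 1.7])
    def test_power_law_compensates_to_constant(self, b):
        p = np.arange(1, 41, dtype=float)
        Z = 2.5 * p**b
        zc, beta = compensate_linkages(Z)
        assert beta == pytest.approx(b, abs=1e-9)
        np.testing.assert_allclose(zc, 2.5 * 40.0**b, rtol=1e-6)

    @pytest.mark.parametrize("b", [0.3, 1.0])
    def test_descending_rank_power_law_flattens(self, b):
        # declining power law in rank compensates to a constant under the
        # descending-rank convention (signed beta)
        p = np.arange(1, 41, dtype=float)
        Z = (3.0 * p**-b)[::-1]  # stored ascending, as merge heights are
        zc, beta = compensate_linkages(Z, order="rank_desc")
        assert beta == pytest.approx(-b, abs=1e-9)
        np.testing.assert_allclose(zc, 3.0 * 40.0**-b, rtol=1e-6)

    def test_fit_estimator_agrees_on_exact_power_law(self):
        p = np.arange(1, 31, dtype=float)
        _, beta = compensate_linkages(1.3 * p**0.8, beta_method="fit")
        assert beta == pytest.approx(0.8, abs=1e-9)

    def test_all_zero_heights_degenerate(self):
        with pytest.raises(ValueError):
            compensate_linkages(np.zeros(5))


class TestCountNoc:
    def test_constant_vector_zero(self):
        assert count_noc(np.full(9, 3.3)) == 0

    def test_seven_ones_and_a_ten(self):
        assert count_noc(np.array([1, 1, 1, 1, 1, 1, 1, 10.0])) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            count_noc(np.array([]))


class TestCutLabels:
    def test_zero_noc_single_label(self, grid):
        rng = np.random.default_rng(2)
        specs = [_spec(rng.uniform(0.5, 2.0, grid.n_bins), grid) for _ in range(8)]
        tree = linkage_tree(pairwise_distances(specs))
        labels = cut_labels(tree, 0)
        assert set(labels) == {0}

    def test_noc_sets_group_count(self, grid):
        # the cut yields exactly max(NoC, 1) groups
        rng = np.random.default_rng(2)
        specs = [_spec(rng.uniform(0.5, 2.0, grid.n_bins), grid) for _ in range(8)]
        tree = linkage_tree(pairwise_distances(specs))
        for noc, expected in ((7, 7), (3, 3), (1, 1)):
            assert len(set(cut_labels(tree, noc))) == expected

    def test_two_separated_templates_recovered_exactly(self, grid, dense_schedule):
        lib = build_class_library(2, seed=4, separation=15)
        events, spectra = simulate_spectra(lib, dense_schedule, grid, seed=0, base_rate=20.0)
        truth = [ev.truth["class_id"] for ev in events]
        tree = linkage_tree(pairwise_distances(spectra))
        labels = cut_labels(tree, 2)
        # adjusted Rand of 1: partition identical up to renaming
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) == 1.0

    def test_labels_ordered_by_descending_size(self, grid):
        rng = np.random.default_rng(9)
        big = [_spec(rng.uniform(0.9, 1.1, grid.n_bins), grid) for _ in range(9)]
        small = [_spec(rng.uniform(9.0, 11.0, grid.n_bins) * np.geomspace(1, 50, grid.n_bins), grid)
                 for _ in range(3)]
        tree = linkage_tree(pairwise_distances(big + small))
        labels = cut_labels(tree, 2)
        sizes = np.bincount(labels)
        assert np.all(np.diff(sizes) <= 0)


class TestPipeline:
    def test_identical_spectra_give_zero_clusters(self, grid):
        s = _spec(np.linspace(1, 2, grid.n_bins), grid)
        res = diversity_pipeline([s] * 10)
        assert res.noc == 0
        assert set(res.labels) == {0}

    def test_too_few_spectra_rejected(self, grid):
        s = _spec(np.ones(grid.n_bins), grid)
        with pytest.raises(ValueError):
            diversity_pipeline([s, s])

    def test_separable_three_class_survey_in_band(self, grid, dense_schedule):
        # three well separated classes, ~150 events each: NoC lands in [2, 5]
        lib = build_class_library(3, seed=2, separation=12)
        _, spectra = simulate_spectra(lib, dense_schedule, grid, seed=0, base_rate=30.0)
        res = diversity_pipeline(spectra)
        assert 2 <= res.noc <= 5

    def test_species_level_spread_blends_classes(self, grid, dense_schedule):
        # the documented limitation: at ~25% within-class wingbeat spread the
        # class manifolds blend into a continuum and the outlier statistic
        # reports (correctly) almost no distinguishable groups
        from dataclasses import replace

        lib = [replace(t, wbf_cv=0.25) for t in build_class_library(3, seed=2, separation=12)]
        _, spectra = simulate_spectra(
            lib, dense_schedule, grid, seed=0, base_rate=30.0, noise_sd=0.05
        )
        res = diversity_pipeline(spectra)
        assert res.noc < 3

    def test_noise_as_signal_flags_almost_nothing(self, grid):
        frags = generate_noise_fragments(300, seed=6)
        spectra = [modulation_spectrum(f, grid) for f in frags]
        res = diversity_pipeline(spectra)
        assert res.noc <= 3

    def test_permutation_invariance(self, grid, dense_schedule):
        lib = build_class_library(3, seed=2, separation=12)
        _, spectra = simulate_spectra(lib, dense_schedule, grid, seed=3, base_rate=10.0)
        res = diversity_pipeline(spectra)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(spectra))
        res_p = diversity_pipeline([spectra[i] for i in perm])
        assert res_p.noc == res.noc
        assert res_p.beta == pytest.approx(res.beta)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(res.labels[perm], res_p.labels) == 1.0


class TestSummaries:
    def test_cluster_fractions_sum_to_one(self, grid, dense_schedule):
        lib = build_class_library(3, seed=2, separation=12)
        events, spectra = simulate_spectra(lib, dense_schedule, grid, seed=1, base_rate=10.0)
        table = build_event_table(events)
        res = diversity_pipeline(spectra)
        summaries = summarize_clusters(res.labels, table, spectra)
        assert sum(s["n"] for s in summaries) == len(events)
        for s in summaries:
            assert sum(s["layer_fractions"].values()) == pytest.approx(1.0)
            four = sum(s["time_fractions"][k] for k in ("dawn", "diurnal", "dusk", "nocturnal"))
            assert four == pytest.approx(1.0)
            assert s["time_fractions"]["crepuscular"] == pytest.approx(
                s["time_fractions"]["dawn"] + s["time_fractions"]["dusk"]
            )

    def test_single_event_cluster_one_hot(self, grid):
        rng = np.random.default_rng(0)
        specs = [_spec(rng.uniform(0.5, 2, grid.n_bins), grid, f"s{i}") for i in range(3)]
        from entolidar.synthetic import TransitSignal

        events = [TransitSignal(f"s{i}", 1000.0 * i, 3e-4, np.ones(100), np.ones(100), 30.0, 0.0)
                  for i in range(3)]
        table = build_event_table(events)
        labels = np.array([0, 1, 2])
        for s in summarize_clusters(labels, table, specs):
            assert max(s["layer_fractions"].values()) == 1.0

    def test_misaligned_lengths_rejected(self, grid):
        s = _spec(np.ones(grid.n_bins), grid)
        table = build_event_table([])
        with pytest.raises(ValueError):
            summarize_clusters(np.array([0]), table, [s])
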