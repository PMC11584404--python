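"""Graph construction, the NB null, the z statistics and module extraction.

Oracles: brute-force O(n^2) re-implementations of the graph statistics, and
spot-label permutation nulls for z-score calibration.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import prismspot as ps
from prismspot.spatial import _bh_z_threshold


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_force_knn(coords, k):
    """All-pairs distance KNN, symmetrized by union; O(n^2)."""
    n = len(coords)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    pairs = set()
    for i in range(n):
        for j in np.argsort(d[i], kind="stable")[:k]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    return pairs


def brute_force_stats(R, edges):
    """Edge sums of residual products by explicit loops."""
    G = R.shape[1]
    H = np.zeros(G)
    C = np.zeros((G, G))
    for (i, j) in edges:
        for g in range(G):
            H[g] += R[i, g] * R[j, g]
            for h in range(G):
                C[g, h] += (R[i, g] * R[j, h] + R[i, h] * R[j, g]) / 2.0
    return H, C


# ---------------------------------------------------------------------------
# graph
# ---------------------------------------------------------------------------


class TestKnnGraph:
    def test_hexagonal_interior_spot_has_its_six_neighbors(self):
        # unit hexagonal packing: odd rows offset by 0.5, row pitch sqrt(3)/2
        coords = []
        for r in range(7):
            for c in range(7):
                coords.append([r * np.sqrt(3) / 2, c + 0.5 * (r % 2)])
        coords = np.array(coords)
        g = ps.build_knn_graph(coords, k=6)
        center = 3 * 7 + 3
        nbrs = {j for i, j in g.edges if i == center} | {
            i for i, j in g.edges if j == center
        }
        d = np.sqrt(((coords - coords[center]) ** 2).sum(1))
        expected = set(np.flatnonzero(np.isclose(d, 1.0, atol=1e-9)))
        assert len(expected) == 6
        assert expected <= nbrs  # union symmetrization may add none here
        assert nbrs == expected

    def test_no_cross_sample_edges_at_identical_coords(self):
        coords = np.tile(np.column_stack([np.arange(10.0), np.zeros(10)]), (2, 1))
        samples = np.repeat(["A", "B"], 10)
        g = ps.build_knn_graph(coords, samples, k=3)
        s = np.asarray(samples)
        assert (s[g.edges[:, 0]] == s[g.edges[:, 1]]).all()

    def test_matches_brute_force_on_random_cloud(self, rng):
        coords = rng.uniform(0, 10, size=(50, 2))
        g = ps.build_knn_graph(coords, k=6)
        assert set(map(tuple, g.edges)) == brute_force_knn(coords, 6)

    def test_small_sample_reduces_k_with_warning(self):
        coords = np.column_stack([np.arange(4.0), np.zeros(4)])
        with pytest.warns(UserWarning, match="using k=3"):
            g = ps.build_knn_graph(coords, k=6)
        assert g.n_edges == 6  # complete graph on 4 nodes

    def test_structural_invariants(self, rng):
        coords = rng.uniform(0, 5, size=(40, 2))
        samples = rng.choice(["A", "B"], size=40)
        g = ps.build_knn_graph(coords, samples, k=4)
        assert (g.edges[:, 0] < g.edges[:, 1]).all()
        assert len({tuple(e) for e in g.edges}) == g.n_edges
        assert (g.weights == 1).all()
        assert (g.degrees() > 0).all()


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------


class TestNullModel:
    def test_poisson_gene_has_near_zero_dispersion(self, rng):
        depths = rng.integers(500, 1500, 500).astype(float)
        p = np.full(30, 1 / 30)
        counts = rng.poisson(depths[:, None] * p[None, :])
        null = ps.fit_null_model(counts, depths)
        assert np.abs(null.dispersion).max() < 0.05

    def test_nb_dispersion_recovered(self, rng):
        depths = rng.integers(800, 1200, 1000).astype(float)
        mu = depths[:, None] * np.full((1, 5), 0.02)
        disp = 0.5
        counts = rng.poisson(rng.gamma(1 / disp, mu * disp))
        null = ps.fit_null_model(counts, depths)
        assert np.allclose(null.dispersion, disp, rtol=0.2)

    def test_constant_counts_constant_depth_degenerate(self):
        counts = np.full((10, 3), 7)
        null = ps.fit_null_model(counts, np.full(10, 21.0))
        # mean model reproduces the data exactly: sigma^2 = mu, residuals 0
        assert np.allclose(null.mean(), counts)
        assert np.allclose(null.variance(), null.mean())
        R = null.standardized_residuals(counts)
        assert np.allclose(R, 0)

    def test_zero_total_gene_rejected(self):
        counts = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="zero total"):
            ps.fit_null_model(counts, np.array([1.0, 2.0]))

    def test_single_spot_rejected(self):
        with pytest.raises(ValueError, match="two spots"):
            ps.fit_null_model(np.array([[1, 2]]), np.array([3.0]))


# ---------------------------------------------------------------------------
# statistics vs oracles
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_counts(rng=None):
    rng = np.random.default_rng(77)
    coords = np.column_stack(
        [np.repeat(np.arange(6), 6), np.tile(np.arange(6), 6)]
    ).astype(float)
    depths = rng.integers(400, 900, 36).astype(float)
    p = rng.dirichlet(np.ones(15) * 4)
    counts = rng.poisson(depths[:, None] * p[None, :])
    counts[:, 0] += (coords[:, 0] * 3).astype(int)  # planted row gradient
    return counts, coords, depths


def test_statistics_equal_brute_force(small_counts):
    counts, coords, depths = small_counts
    graph = ps.build_knn_graph(coords, k=6)
    null = ps.fit_null_model(counts, depths)
    R = null.standardized_residuals(counts)
    H_o, C_o = brute_force_stats(R, [tuple(e) for e in graph.edges])

    ac = ps.local_autocorrelation(counts, graph, null)
    assert np.abs(ac["H"].to_numpy() - H_o).max() < 1e-9

    # exchangeability-null mean, recomputed long-hand
    n = R.shape[0]
    m = graph.sum_w2 * (R.sum(0) ** 2 - (R**2).sum(0)) / (n * (n - 1))
    w2 = graph.sum_w2
    assert np.abs(ac["z"].to_numpy() - (H_o - m) / np.sqrt(w2)).max() < 1e-9

    pz = ps.pairwise_local_correlation(counts, graph, null)
    z_o = C_o / np.sqrt(w2 / 2)
    np.fill_diagonal(z_o, (np.diagonal(C_o) - m) / np.sqrt(w2))
    assert np.abs(pz.to_numpy() - z_o).max() < 1e-9


def test_autocorrelation_permutation_null_moments():
    """Permuting spots: H is centred (up to the exact conditional permutation
    mean, -sum(r^2)*E/(n(n-1)) since residuals sum to ~0) with variance ~
    sum(w^2)."""
    rng = np.random.default_rng(41)
    n = 144
    coords = np.column_stack(
        [np.repeat(np.arange(12), 12), np.tile(np.arange(12), 12)]
    ).astype(float)
    depths = rng.integers(400, 900, n).astype(float)
    p = rng.dirichlet(np.ones(30) * 4)
    counts = rng.poisson(depths[:, None] * p[None, :])
    graph = ps.build_knn_graph(coords, k=6)

    null = ps.fit_null_model(counts, depths)
    R = null.standardized_residuals(counts)
    cond_mean = ((R.sum(0) ** 2 - (R**2).sum(0))
                 * graph.n_edges / (n * (n - 1))).mean()

    perm_rng = np.random.default_rng(5)
    Hs = []
    for _ in range(200):
        perm = perm_rng.permutation(n)
        null_p = ps.fit_null_model(counts[perm], depths[perm])
        Hs.append(ps.local_autocorrelation(counts[perm], graph, null_p)["H"])
    Hs = np.asarray(Hs)
    sd = np.sqrt(graph.sum_w2)
    assert Hs.mean() == pytest.approx(cond_mean, abs=4 * sd / np.sqrt(Hs.size))
    assert abs(Hs.mean()) < 0.2 * sd
    assert Hs.var() == pytest.approx(graph.sum_w2, rel=0.15)


def test_gradient_gene_beats_permutation_null(small_counts):
    counts, coords, depths = small_counts
    graph = ps.build_knn_graph(coords, k=6)
    null = ps.fit_null_model(counts, depths)
    z_obs = ps.local_autocorrelation(counts, graph, null)["z"].iloc[0]
    rng = np.random.default_rng(6)
    z_perm = []
    for _ in range(200):
        perm = rng.permutation(len(counts))
        null_p = ps.fit_null_model(counts[perm], depths[perm])
        z_perm.append(
            ps.local_autocorrelation(counts[perm], graph, null_p)["z"].iloc[0]
        )
    assert z_obs > 0
    assert z_obs > np.quantile(z_perm, 0.99)


def test_pairwise_diagonal_equals_autocorrelation(small_counts):
    counts, coords, depths = small_counts
    graph = ps.build_knn_graph(coords, k=6)
    null = ps.fit_null_model(counts, depths)
    ac = ps.local_autocorrelation(counts, graph, null)
    pz = ps.pairwise_local_correlation(counts, graph, null)
    assert np.allclose(np.diagonal(pz.to_numpy()), ac["z"], atol=1e-12)


def test_correlated_bump_pair_strongly_positive(rng):
    coords = np.column_stack(
        [np.repeat(np.arange(10), 10), np.tile(np.arange(10), 10)]
    ).astype(float)
    bump = np.exp(-(((coords - 4.5) ** 2).sum(1)) / 8.0)
    depths = np.full(100, 600.0)
    base = rng.poisson(20, size=(100, 10))
    base[:, 0] = rng.poisson(20 * (1 + 3 * bump))
    base[:, 1] = rng.poisson(20 * (1 + 3 * bump))
    graph = ps.build_knn_graph(coords, k=6)
    null = ps.fit_null_model(base, depths)
    pz = ps.pairwise_local_correlation(base, graph, null)
    assert pz.iloc[0, 1] > 5
    null_pairs = pz.to_numpy()[2:, 2:][np.triu_indices(8, 1)]
    assert pz.iloc[0, 1] > np.quantile(null_pairs, 0.99)


def test_unknown_gene_in_pairwise_raises(small_counts):
    counts, coords, depths = small_counts
    graph = ps.build_knn_graph(coords, k=6)
    null = ps.fit_null_model(counts, depths)
    with pytest.raises(KeyError):
        ps.pairwise_local_correlation(counts, graph, null, genes=["nope"])


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


def _block_z(rng, sizes=(20, 20, 10), strong=8.0, weak=0.0, noise=0.5):
    n = sum(sizes)
    z = rng.normal(weak, noise, size=(n, n))
    lo = 0
    for s in sizes[:2]:
        z[lo : lo + s, lo : lo + s] = rng.normal(strong, noise, size=(s, s))
        lo += s
    z = (z + z.T) / 2
    np.fill_diagonal(z, strong)
    genes = [f"g{i}" for i in range(n)]
    return pd.DataFrame(z, index=genes, columns=genes)


class TestExtractModules:
    def test_recovers_planted_blocks(self, rng):
        pz = _block_z(rng)
        ms = ps.extract_modules(pz, min_gene_threshold=15, fdr_threshold=0.05)
        a = ms.assignments
        assert ms.n_modules == 2
        assert a.iloc[:20].nunique() == 1 and a.iloc[0] >= 0
        assert a.iloc[20:40].nunique() == 1 and a.iloc[20] >= 0
        assert a.iloc[0] != a.iloc[20]
        assert (a.iloc[40:] == -1).all()

    def test_all_tied_z_is_deterministic(self):
        n = 6
        z = pd.DataFrame(np.full((n, n), 5.0),
                         index=[f"g{i}" for i in range(n)],
                         columns=[f"g{i}" for i in range(n)])
        a = ps.extract_modules(z, min_gene_threshold=2)
        b = ps.extract_modules(z, min_gene_threshold=2)
        assert a.assignments.equals(b.assignments)
        assert a.merge_tree == b.merge_tree
        # lowest-index pair merges first under the documented tie-break
        assert set(a.merge_tree[0][:2]) == {0, 1}

    def test_size_floor_leaves_all_unassigned(self, rng):
        pz = _block_z(rng, sizes=(10,), strong=9.0)
        ms = ps.extract_modules(pz, min_gene_threshold=15)
        assert (ms.assignments == -1).all()
        assert ms.n_modules == 0

    def test_empty_input(self):
        ms = ps.extract_modules(pd.DataFrame())
        assert len(ms.assignments) == 0

    def test_no_significant_pairs_no_merges(self, rng):
        z = _block_z(rng, sizes=(10, 10), strong=0.0, noise=0.3)
        ms = ps.extract_modules(z, min_gene_threshold=2)
        assert ms.z_threshold == np.inf
        assert (ms.assignments == -1).all()

    def test_bh_threshold_matches_statsmodels(self, rng):
        z = rng.normal(0, 1, 200)
        z[:10] += 6
        thr = _bh_z_threshold(z, 0.05)
        from statsmodels.stats.multitest import multipletests
        rej = multipletests(stats.norm.sf(z), alpha=0.05, method="fdr_bh")[0]
        assert thr == z[rej].min()


class TestModuleScores:
    def test_singleton_module_score_is_residual(self, small_counts):
        counts, coords, depths = small_counts
        graph = ps.build_knn_graph(coords, k=6)
        null = ps.fit_null_model(counts, depths)
        ms = ps.ModuleSet(
            assignments=pd.Series([0] + [-1] * 14,
                                  index=null.gene_props.index),
            pairwise_z=pd.DataFrame(),
        )
        raw, smooth = ps.module_scores(counts, ms, graph, null)
        R = null.standardized_residuals(counts)
        assert np.allclose(raw["module_0"], R[:, 0])

    def test_constant_scores_fixed_under_smoothing(self):
        # counts equal to the null mean everywhere -> residuals identically 0
        depths = np.full(16, 40.0)
        counts = np.full((16, 4), 10)
        coords = np.column_stack(
            [np.repeat(np.arange(4), 4), np.tile(np.arange(4), 4)]
        ).astype(float)
        graph = ps.build_knn_graph(coords, k=3)
        null = ps.fit_null_model(counts, depths)
        ms = ps.ModuleSet(
            assignments=pd.Series([0, 0, -1, -1], index=null.gene_props.index),
            pairwise_z=pd.DataFrame(),
        )
        raw, smooth = ps.module_scores(counts, ms, graph, null)
        assert np.allclose(raw, 0) and np.allclose(smooth, 0)

    def test_empty_module_set_raises(self, small_counts):
        counts, coords, depths = small_counts
        graph = ps.build_knn_graph(coords, k=6)
        null = ps.fit_null_model(counts, depths)
        ms = ps.ModuleSet(
            assignments=pd.Series(-1, index=null.gene_props.index),
            pairwise_z=pd.DataFrame(),
        )
        with pytest.raises(ValueError, match="empty"):
            ps.module_scores(counts, ms, graph, null)


def test_planted_module_scores_separate_bump_regions(spatial, prism_fit):
    """Smoothed module scores are higher inside the planted bumps."""
    ds, gt = spatial
    scores = prism_fit.module_scores(smoothed=True)
    assign = prism_fit.modules.assignments
    mm = gt.module_membership
    for m in (0, 1):
        genes_m = [g for g in assign.index
                   if mm.get(g, -1) == m and assign[g] >= 0]
        rec_mod = assign[genes_m[0]]
        col = f"module_{rec_mod}"
        field = gt.spatial_field[prism_fit.spots_used, m]
        inside = scores[col].to_numpy()[field > 0.5]
        outside = scores[col].to_numpy()[field < 0.05]
        p = stats.mannwhitneyu(inside, outside, alternative="greater")[1]
        assert p < 0.01


def test_module_z_monotone_in_amplitude():
    """Raising the planted amplitude never lowers the median planted-gene z
    (pure-tumor tissue analysed directly, fixed seed)."""
    medians = []
    for amp in (0.0, 0.5, 1.0, 2.0, 3.0):
        cfg = ps.SimConfig(grid_shape=(10, 10), module_amplitude=amp,
                           fraction_jitter=0.0, tumor_only=True,
                           depth_mean=1500, seed=17)
        ds, gt = ps.make_spatial_dataset(cfg)
        res = ps.SpatialCoexpression(
            ds.dense(), coords=ds.coords, sample_ids=ds.sample_ids,
            genes=ds.genes, k=6,
        ).fit()
        mm = gt.module_membership
        z = res.autocorrelation["z"]
        planted = [g for g in z.index if mm.get(g, -1) >= 0]
        medians.append(float(z[planted].median()))
    assert all(b >= a - 1e-9 for a, b in zip(medians, medians[1:]))
    assert medians[-1] > medians[0] + 2


def test_amplitude_zero_tumor_counts_are_null_calibrated():
    """With no planted modulation, autocorrelation z on pure-tumor counts is
    approximately standard normal."""
    cfg = ps.SimConfig(grid_shape=(12, 12), module_amplitude=0.0,
                       fraction_jitter=0.0, seed=19)
    frac = np.zeros((144, cfg.n_types))
    frac[:, 0] = 1.0  # single tumor type: no fraction structure at all
    ds, gt = ps.make_spatial_dataset(cfg, fraction_override=frac)
    res = ps.SpatialCoexpression(
        ds.dense(), coords=ds.coords, sample_ids=ds.sample_ids,
        genes=ds.genes, k=6,
    ).fit()
    z = res.autocorrelation["z"]
    assert abs(z.mean()) < 0.15
    assert z.var() == pytest.approx(1.0, abs=0.25)
    mm = gt.module_membership
    planted = [g for g in z.index if mm.get(g, -1) >= 0]
    assert abs(z[planted].mean()) < 3.5 / np.sqrt(len(planted))
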