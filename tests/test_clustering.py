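"""Elongation typing, functional clustering and composition statistics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from vistreams.clustering import (
    assign_to_centroids,
    build_training_matrix,
    cluster_elongation,
    fit_cluster_model,
    hb_cluster_proportions,
    hb_elongation_fractions,
    similarity_contrast,
    tsne_embed,
)

ARCHETYPES = {  # planted elongation-curve types
    "non-OS": np.array([1.0, 0.6, 0.3, 0.1]),
    "sharp-OS": np.array([0.1, 0.3, 0.6, 1.0]),
    "broad-OS": np.array([0.7, 0.7, 0.7, 0.7]),
}


def _planted_curves(rng, n=600, sigma=0.05):
    names = list(ARCHETYPES)
    truth = rng.integers(0, 3, n)
    curves = np.stack([ARCHETYPES[names[t]] for t in truth])
    return curves + rng.normal(0.0, sigma, curves.shape), truth, names


class TestClusterElongation:
    def test_planted_recovery(self, rng):
        curves, truth, _ = _planted_curves(rng)
        labels, _ = cluster_elongation(curves)
        assert adjusted_rand_score(truth, labels) >= 0.95

    def test_names_follow_curve_slopes(self, rng):
        curves, truth, names = _planted_curves(rng)
        labels, mapping = cluster_elongation(curves)
        # majority label of each planted type carries the matching name
        for t, expected in enumerate(names):
            lab = np.bincount(labels[truth == t]).argmax()
            assert mapping[lab] == expected

    def test_naming_invariant_to_row_order(self, rng):
        curves, truth, _ = _planted_curves(rng, n=300)
        labels, mapping = cluster_elongation(curves)
        perm = rng.permutation(len(curves))
        labels_p, mapping_p = cluster_elongation(curves[perm])
        named = np.array([mapping[la] for la in labels])[perm]
        named_p = np.array([mapping_p[la] for la in labels_p])
        assert (named == named_p).all()

    def test_identical_curves_rejected(self):
        with pytest.raises(ValueError):
            cluster_elongation(np.ones((50, 4)))


class TestHbElongationFractions:
    def test_recovers_generated_mixture(self, rng):
        rows = []
        names = list(ARCHETYPES)
        probs = {"X": [0.7, 0.15, 0.15], "Y": [0.2, 0.6, 0.2]}
        for area, p in probs.items():
            for m in range(4):
                for _ in range(200):
                    t = rng.choice(3, p=p)
                    e = ARCHETYPES[names[t]] + rng.normal(0, 0.05, 4)
                    rows.append({"mouse_id": f"m{m}", "area": area,
                                 "e_inf": e[0], "e_60": e[1],
                                 "e_30": e[2], "e_15": e[3]})
        table = pd.DataFrame(rows)
        frac = hb_elongation_fractions(table, n_sub=10, n_cells=300, seed=1)
        got = frac.set_index(["area", "type"])["fraction"]
        assert got.loc[("X", "non-OS")] == pytest.approx(0.7, abs=0.05)
        assert got.loc[("Y", "sharp-OS")] == pytest.approx(0.6, abs=0.05)

    def test_fractions_sum_to_one_and_reproduce(self, rng):
        rows = []
        names = list(ARCHETYPES)
        for m in range(3):
            for _ in range(150):
                t = rng.integers(0, 3)
                e = ARCHETYPES[names[t]] + rng.normal(0, 0.05, 4)
                rows.append({"mouse_id": f"m{m}", "area": "V1",
                             "e_inf": e[0], "e_60": e[1], "e_30": e[2],
                             "e_15": e[3]})
        table = pd.DataFrame(rows)
        f1 = hb_elongation_fractions(table, n_cells=100, seed=2)
        f2 = hb_elongation_fractions(table, n_cells=100, seed=2)
        pd.testing.assert_frame_equal(f1, f2)
        assert f1.groupby("area")["fraction"].sum().iloc[0] \
            == pytest.approx(1.0)


class TestTrainingMatrix:
    def test_rows_are_minmax_normalised(self, rng):
        iso = rng.random((40, 30))
        aniso = rng.random((40, 30))
        areas = np.repeat(["A", "B"], 20)
        mat, _ = build_training_matrix(iso, aniso, areas, n_per_area=50,
                                       seed=0)
        assert np.allclose(mat.min(axis=1), 0.0)
        assert np.allclose(mat.max(axis=1), 1.0)
        assert mat.shape == (100, 60)

    def test_constant_rows_dropped_with_warning(self, rng):
        iso = rng.random((10, 30))
        aniso = rng.random((10, 30))
        iso[3] = aniso[3] = 0.5
        with pytest.warns(UserWarning):
            mat, manifest = build_training_matrix(
                iso, aniso, np.repeat(["A"], 10), n_per_area=30, seed=1)
        assert 3 not in manifest

    def test_manifest_reconstructs_sample(self, rng):
        iso = rng.random((20, 30))
        aniso = rng.random((20, 30))
        areas = np.repeat(["A"], 20)
        mat, manifest = build_training_matrix(iso, aniso, areas,
                                              n_per_area=40, seed=2)
        full = np.hstack([iso, aniso])
        rebuilt = full[manifest]
        rebuilt = (rebuilt - rebuilt.min(axis=1, keepdims=True)) \
            / (rebuilt.max(axis=1, keepdims=True)
               - rebuilt.min(axis=1, keepdims=True))
        assert np.allclose(mat, rebuilt)


class TestClusterModel:
    @pytest.fixture(scope="class")
    def planted(self):
        rng = np.random.default_rng(3)
        centers = rng.random((12, 60))
        truth = rng.integers(0, 12, 1800)
        x = centers[truth] + rng.normal(0.0, 0.05, (1800, 60))
        x = (x - x.min(axis=1, keepdims=True)) \
            / (x.max(axis=1, keepdims=True) - x.min(axis=1, keepdims=True))
        return x, truth

    @pytest.fixture(scope="class")
    def model(self, planted):
        x, _ = planted
        return fit_cluster_model(x, k_range=range(2, 19), seed=4)

    def test_silhouette_selects_planted_k(self, planted, model):
        _, truth = planted
        assert model.k == 12
        assert adjusted_rand_score(truth, model.labels) >= 0.9

    def test_validation_curves_cover_k_range(self, model):
        assert model.validation["k"].tolist() == list(range(2, 19))
        assert model.validation["silhouette"].idxmax() is not None

    def test_variance_explained_decreasing(self, model):
        ve = model.variance_explained
        assert np.all(np.diff(ve) <= 1e-12) and ve.sum() <= 1.0

    def test_assignment_consistent_with_training_labels(self, planted,
                                                        model):
        x, _ = planted
        assert np.array_equal(assign_to_centroids(x, model), model.labels)

    def test_assignment_invariant_to_row_order(self, planted, model):
        x, _ = planted
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(x))
        assert np.array_equal(assign_to_centroids(x[perm], model),
                              model.labels[perm])

    def test_equidistant_point_takes_lowest_index(self, model):
        mid_score = 0.5 * (model.centroids[0] + model.centroids[1])
        mid = model.pca.inverse_transform(mid_score[None])
        d = ((model.pca.transform(mid)[0] - model.centroids) ** 2
             ).sum(axis=1)
        label = assign_to_centroids(mid, model)[0]
        assert label == int(np.flatnonzero(np.isclose(d, d.min()))[0])


class TestComposition:
    def _labels(self, rng, mixtures, n_mice=4, n=200):
        labels, mice, areas = [], [], []
        for area, p in mixtures.items():
            for m in range(n_mice):
                labels.append(rng.choice(len(p), size=n, p=p))
                mice.extend([f"m{m}"] * n)
                areas.extend([area] * n)
        return np.concatenate(labels), np.array(mice), np.array(areas)

    def test_uniform_labels_show_no_enrichment(self, rng):
        k = 6
        labels, mice, areas = self._labels(
            rng, {"A": [1 / k] * k, "B": [1 / k] * k})
        comp = hb_cluster_proportions(labels, mice, areas, k=k,
                                      n_boot=300, n_cells=100, n_mice=4,
                                      seed=6)
        flagged = comp.over.to_numpy().sum() + comp.under.to_numpy().sum()
        assert flagged <= 1  # at most one spurious flag across 12 cells
        assert np.allclose(comp.proportions.sum(axis=1), 1.0)

    def test_shared_and_opposing_mixtures(self, rng):
        k = 4
        ventral = [0.55, 0.25, 0.15, 0.05]
        dorsal = [0.05, 0.15, 0.25, 0.55]
        labels, mice, areas = self._labels(
            rng, {"LI": ventral, "POR": ventral, "AL": dorsal})
        comp = hb_cluster_proportions(labels, mice, areas, k=k,
                                      n_boot=300, n_cells=100, n_mice=4,
                                      seed=7)
        assert comp.similarity_mean.loc["LI", "POR"] > 0.9
        assert comp.similarity_mean.loc["LI", "AL"] < 0.0
        sym = comp.similarity_mean.to_numpy()
        assert np.allclose(sym, sym.T)
        assert np.allclose(np.diag(sym), 1.0)

    def test_similarity_contrast_effect_size(self, rng):
        k = 4
        ventral = [0.55, 0.25, 0.15, 0.05]
        dorsal = [0.05, 0.15, 0.25, 0.55]
        labels, mice, areas = self._labels(
            rng, {"LI": ventral, "POR": ventral, "AL": dorsal})
        comp = hb_cluster_proportions(labels, mice, areas, k=k,
                                      n_boot=200, n_cells=100, n_mice=4,
                                      seed=8)
        es = similarity_contrast(comp, "LI", "POR", "AL")
        assert es.d > 2 and es.category == "large"

    def test_bootstrap_proportions_sum_to_one(self, rng):
        labels, mice, areas = self._labels(rng, {"A": [0.5, 0.3, 0.2]})
        comp = hb_cluster_proportions(labels, mice, areas, k=3,
                                      n_boot=50, n_cells=50, n_mice=3,
                                      seed=9)
        assert np.allclose(comp.boot_proportions.sum(axis=2), 1.0)


class TestTsne:
    def test_duplicated_rows_land_together(self, rng):
        x = rng.random((120, 12))
        x[60:] = x[:60]
        emb = tsne_embed(x, perplexity=20.0, seed=10)
        d_dup = np.linalg.norm(emb[:60] - emb[60:], axis=1)
        spread = np.linalg.norm(emb - emb.mean(axis=0), axis=1).mean()
        assert np.median(d_dup) < 0.05 * spread

    def test_reproducible(self, rng):
        x = rng.random((80, 12))
        a = tsne_embed(x, perplexity=15.0, seed=11)
        b = tsne_embed(x, perplexity=15.0, seed=11)
        assert np.allclose(a, b)

    def test_excessive_perplexity_rejected(self, rng):
        with pytest.raises(ValueError):
            tsne_embed(rng.random((30, 5)), perplexity=10.0)
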