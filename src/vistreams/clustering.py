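"""Functional cell typing and clustering of spatiotemporal responses.

Two clustering analyses are provided.  Elongation typing groups the
4-point anisotropy tuning curves (response vs orientation bandwidth)
into three types by Ward-linkage hierarchical clustering: non-OS
(response falls with elongation), sharp-OS (response rises with
elongation) and broad-OS (elongation-invariant).  Functional clustering
of the joint ISO/ANISO spatiotemporal responses builds a 60-dimensional
per-neuron response vector (min-max normalised to [0, 1]), reduces it
to 12 principal components, and k-means-partitions the training sample
with silhouette / Davies-Bouldin / Calinski-Harabasz validation over a
range of k.  Area composition statistics (cluster proportions vs the
1/k chance level, area-similarity correlations, bootstrap effect sizes)
use the hierarchical bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .stats import cohens_d

__all__ = [
    "ClusterModel",
    "ClusterComposition",
    "ELONGATION_TYPES",
    "cluster_elongation",
    "hb_elongation_fractions",
    "build_training_matrix",
    "fit_cluster_model",
    "assign_to_centroids",
    "hb_cluster_proportions",
    "similarity_contrast",
    "tsne_embed",
]

ELONGATION_TYPES = ("non-OS", "broad-OS", "sharp-OS")  # by curve slope


def cluster_elongation(curves: np.ndarray, k: int = 3,
                       ) -> tuple[np.ndarray, dict]:
    """Ward-linkage clustering of elongation tuning curves into 3 types.

    ``curves`` has shape (n, 4) over orientation bandwidths ordered
    (infinite, 60, 30, 15) deg, i.e. increasing elongation.  Clusters
    are named by the slope of their peak-normalised mean curve over the
    bandwidth levels: the most negative slope is non-OS, the most
    positive sharp-OS, the middle broad-OS.  Returns (integer labels,
    {label: type name}).
    """
    x = np.asarray(curves, dtype=float)
    if x.ndim != 2 or x.shape[1] != 4:
        raise ValueError("curves must be an (n, 4) matrix")
    if np.unique(x, axis=0).shape[0] < k:
        raise ValueError(f"fewer than {k} distinct curves")
    z = linkage(x, method="ward")
    labels = fcluster(z, t=k, criterion="maxclust") - 1
    slopes = {}
    levels = np.arange(4)
    for lab in np.unique(labels):
        mean_curve = x[labels == lab].mean(axis=0)
        mean_curve = mean_curve / max(mean_curve.max(), 1e-12)
        slopes[lab] = float(np.polyfit(levels, mean_curve, 1)[0])
    if k == 3:
        order = sorted(slopes, key=slopes.get)
        names = {order[0]: "non-OS", order[1]: "broad-OS",
                 order[2]: "sharp-OS"}
    else:
        names = {lab: f"cluster{lab}" for lab in slopes}
    return labels, names


def hb_elongation_fractions(table: pd.DataFrame, n_sub: int = 10,
                            n_cells: int = 500, seed: int = 0,
                            ) -> pd.DataFrame:
    """Per-area elongation-type fractions from bootstrap sub-datasets.

    ``table`` has columns mouse_id, area and e_inf, e_60, e_30, e_15.
    For each area, ``n_sub`` sub-datasets of ``n_cells`` cells are drawn
    hierarchically (mice with replacement, then cells within mice); all
    sub-datasets are pooled and clustered once into the three types, and
    fractions are averaged over sub-datasets.  Returns a DataFrame with
    columns area, type, fraction, sem.
    """
    rng = np.random.default_rng(seed)
    e_cols = ["e_inf", "e_60", "e_30", "e_15"]
    chunks, meta = [], []
    for area, sub in table.groupby("area", sort=False):
        mice = sub["mouse_id"].unique()
        per_mouse = {m: g[e_cols].to_numpy()
                     for m, g in sub.groupby("mouse_id")}
        for s in range(n_sub):
            drawn = rng.choice(mice, size=len(mice), replace=True)
            quota = np.diff(np.round(np.linspace(0, n_cells, len(drawn) + 1))
                            ).astype(int)
            rows = [per_mouse[m][rng.integers(0, len(per_mouse[m]), q)]
                    for m, q in zip(drawn, quota) if q > 0]
            block = np.vstack(rows)
            chunks.append(block)
            meta.extend([(area, s)] * len(block))
    pooled = np.vstack(chunks)
    labels, names = cluster_elongation(pooled)
    types = np.array([names[la] for la in labels])
    meta = pd.DataFrame(meta, columns=["area", "sub"])
    meta["type"] = types
    frac = (meta.groupby(["area", "sub", "type"]).size()
            .unstack(fill_value=0))
    frac = frac.div(frac.sum(axis=1), axis=0)
    out = []
    for area, g in frac.groupby(level="area"):
        for t in ELONGATION_TYPES:
            vals = g[t].to_numpy() if t in g else np.zeros(len(g))
            out.append((area, t, float(vals.mean()),
                        float(vals.std(ddof=1) / np.sqrt(len(vals)))
                        if len(vals) > 1 else 0.0))
    return pd.DataFrame(out, columns=["area", "type", "fraction", "sem"])


def build_training_matrix(amp_iso: np.ndarray, amp_aniso: np.ndarray,
                          areas: np.ndarray, n_per_area: int = 2000,
                          seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Joint ISO/ANISO response matrix for cluster training.

    Per neuron the 30 ISO and 30 ANISO amplitudes are concatenated and
    min-max normalised to [0, 1]; constant rows cannot be normalised and
    are dropped with a warning.  ``n_per_area`` rows are then sampled
    with replacement within each area.  Returns ``(matrix, manifest)``
    where the manifest holds the source neuron index of each row.
    """
    x = np.hstack([np.asarray(amp_iso, float), np.asarray(amp_aniso, float)])
    areas = np.asarray(areas)
    rng = np.random.default_rng(seed)
    span = x.max(axis=1) - x.min(axis=1)
    keep = span > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant-response "
                      "rows before normalisation", stacklevel=2)
    x = (x[keep] - x[keep].min(axis=1, keepdims=True)) \
        / span[keep][:, None]
    kept_idx = np.flatnonzero(keep)
    kept_areas = areas[keep]
    rows = []
    for area in pd.unique(kept_areas):
        cand = np.flatnonzero(kept_areas == area)
        if cand.size == 0:
            raise ValueError(f"area {area} has no eligible neurons")
        rows.append(rng.choice(cand, size=n_per_area, replace=True))
    manifest = kept_idx[np.concatenate(rows)]
    sampled = x[np.concatenate(rows)]
    return sampled, manifest


@dataclass
class ClusterModel:
    """PCA basis plus k-means centroids of the training sample."""

    pca: PCA
    kmeans: KMeans
    k: int
    scores: np.ndarray  # training-sample PC scores
    labels: np.ndarray  # training-sample cluster labels
    validation: pd.DataFrame  # per-k silhouette / DB / CH curves
    manifest: np.ndarray

    @property
    def centroids(self) -> np.ndarray:
        return self.kmeans.cluster_centers_

    @property
    def variance_explained(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_


def fit_cluster_model(matrix: np.ndarray, k_range=range(2, 21),
                      n_pcs: int = 12, seed: int = 0,
                      n_restarts: int = 20,
                      manifest: np.ndarray | None = None) -> ClusterModel:
    """PCA + k-means with internal validation over a range of k.

    The matrix is reduced to ``n_pcs`` principal components; k-means
    (``n_restarts`` seeded restarts, best inertia kept) is fitted for
    each k and scored with silhouette, Davies-Bouldin and Calinski-
    Harabasz indices.  The selected k maximises the silhouette
    coefficient.
    """
    x = np.asarray(matrix, dtype=float)
    pca = PCA(n_components=n_pcs, random_state=seed)
    scores = pca.fit_transform(x)
    if np.any(pca.explained_variance_ == 0):
        raise ValueError("degenerate principal components (zero variance)")
    rows = []
    fits = {}
    for k in k_range:
        if k < 2:
            continue  # silhouette undefined for a single cluster
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(scores)
        rows.append((k, silhouette_score(scores, lab),
                     davies_bouldin_score(scores, lab),
                     calinski_harabasz_score(scores, lab)))
        fits[k] = (km, lab)
    validation = pd.DataFrame(rows, columns=["k", "silhouette",
                                             "davies_bouldin",
                                             "calinski_harabasz"])
    best_k = int(validation.loc[validation["silhouette"].idxmax(), "k"])
    km, lab = fits[best_k]
    if manifest is None:
        manifest = np.arange(len(x))
    return ClusterModel(pca=pca, kmeans=km, k=best_k, scores=scores,
                        labels=lab, validation=validation,
                        manifest=np.asarray(manifest))


def assign_to_centroids(matrix: np.ndarray, model: ClusterModel,
                        ) -> np.ndarray:
    """Nearest-centroid labels in PC space for the full dataset.

    Ties in distance resolve to the lowest-index centroid.
    """
    scores = model.pca.transform(np.asarray(matrix, dtype=float))
    d = ((scores[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d, axis=1)


@dataclass
class ClusterComposition:
    """Per-area cluster proportions vs chance, with similarity matrix."""

    areas: list
    k: int
    proportions: pd.DataFrame  # mean proportion per (area, cluster)
    ratio_to_chance: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    over: pd.DataFrame  # CI entirely above chance
    under: pd.DataFrame  # CI entirely below chance
    similarity_mean: pd.DataFrame  # area x area Pearson r
    similarity_sem: pd.DataFrame
    boot_proportions: np.ndarray  # (n_boot, n_areas, k)


def hb_cluster_proportions(labels: np.ndarray, mouse_ids: np.ndarray,
                           areas: np.ndarray, k: int,
                           n_boot: int = 1000, n_cells: int = 150,
                           n_mice: int = 5, seed: int = 0,
                           ) -> ClusterComposition:
    """Hierarchical-bootstrap cluster proportions per area.

    Each bootstrap draws ``n_mice`` mice with replacement per area and
    ``n_cells`` labelled neurons with replacement within each drawn
    mouse.  Proportions are summarised as the ratio to the 1/k chance
    level with 95% CIs; over/under-representation flags mark clusters
    whose CI excludes chance.  The area-similarity matrix holds the
    bootstrap mean and SEM of Pearson correlations between the areas'
    proportion vectors.
    """
    labels = np.asarray(labels)
    mouse_ids = np.asarray(mouse_ids)
    areas = np.asarray(areas)
    area_list = list(pd.unique(areas))
    rng = np.random.default_rng(seed)
    n_areas = len(area_list)
    boot = np.empty((n_boot, n_areas, k))
    per_area = {}
    for a in area_list:
        sel = areas == a
        per_area[a] = {m: labels[sel & (mouse_ids == m)]
                       for m in pd.unique(mouse_ids[sel])}
        per_area[a] = {m: v for m, v in per_area[a].items() if v.size > 0}
    for b in range(n_boot):
        for ai, a in enumerate(area_list):
            mice = list(per_area[a])
            drawn = rng.choice(len(mice), size=n_mice, replace=True)
            pooled = np.concatenate([
                rng.choice(per_area[a][mice[m]], size=n_cells, replace=True)
                for m in drawn])
            boot[b, ai] = np.bincount(pooled, minlength=k) / pooled.size
    chance = 1.0 / k
    mean = boot.mean(axis=0)
    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)

    def frame(arr):
        return pd.DataFrame(arr, index=area_list,
                            columns=[f"c{i}" for i in range(k)])

    # Pearson similarity between area proportion vectors per bootstrap
    sim = np.empty((n_boot, n_areas, n_areas))
    for b in range(n_boot):
        sim[b] = np.corrcoef(boot[b])
    sim_mean = pd.DataFrame(sim.mean(axis=0), index=area_list,
                            columns=area_list)
    sim_sem = pd.DataFrame(sim.std(axis=0, ddof=1) / np.sqrt(n_boot),
                           index=area_list, columns=area_list)
    return ClusterComposition(
        areas=area_list, k=k,
        proportions=frame(mean),
        ratio_to_chance=frame(mean / chance),
        ci_low=frame(lo), ci_high=frame(hi),
        over=frame(lo > chance), under=frame(hi < chance),
        similarity_mean=sim_mean, similarity_sem=sim_sem,
        boot_proportions=boot)


def similarity_contrast(comp: ClusterComposition, x: str, y: str, z: str):
    """Effect size of area x's similarity to y vs to z (Cohen's d).

    Uses the bootstrap distributions of the pairwise Pearson
    correlations between the areas' cluster-proportion vectors.
    """
    ix, iy, iz = (comp.areas.index(a) for a in (x, y, z))
    boot = comp.boot_proportions
    n_boot = boot.shape[0]
    s_xy = np.empty(n_boot)
    s_xz = np.empty(n_boot)
    for b in range(n_boot):
        s_xy[b] = np.corrcoef(boot[b, ix], boot[b, iy])[0, 1]
        s_xz[b] = np.corrcoef(boot[b, ix], boot[b, iz])[0, 1]
    return cohens_d(s_xy, s_xz)


def tsne_embed(scores: np.ndarray, perplexity: float = 120.0,
               seed: int = 0) -> np.ndarray:
    """2-D t-SNE embedding of PC scores.

    A large perplexity emphasises global structure; the learning rate
    follows the n/10 rule for large datasets.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if perplexity >= n / 3.0:
        raise ValueError("perplexity must be below n/3")
    tsne = TSNE(n_components=2, perplexity=perplexity,
                learning_rate=max(n / 10.0, 10.0), init="pca",
                random_state=seed)
    return tsne.fit_transform(scores)
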