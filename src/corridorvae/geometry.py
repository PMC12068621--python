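"""Latent-space geometry: embeddings, MDS maps, distortion matrices, channels.

The central statistic is the pairwise distortion ratio between two models
M1 and M2 embedding the same images,

    rho(u, v) = d(M2(u), M2(v)) / d(M1(u), M1(v)),   u != v,

with d the Euclidean distance in the 5-D latent space (posterior means).
rho > 1 means the pair is dilated in M2 relative to M1; rho < 1 means it is
compressed.  Ratios are aggregated into a 169x169 item matrix (cells indexed
by the flat position labels of the two images) and into a small class matrix
(cells indexed by task or frequency classes), each cell holding the mean rho
over the qualifying image pairs.

Channel-activation maps summarise what each latent dimension encodes: map k
is the 13x13 grid whose (i, j) entry is the mean posterior-mean activation
of channel k over test images with corridors at (x_UC, x_LC) = (i, j).  A
channel is counted as *active* when its mean per-dimension KL over the test
set exceeds a small threshold (default 0.05 nats).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.manifold import MDS
from sklearn.metrics import silhouette_score

from .data import GRID, N_PAIRS, Dataset
from .models import CorridorVAE, kl_per_dimension


@dataclass
class EmbeddingTable:
    """Per-image 5-D posterior means with their labels."""

    mu: np.ndarray  # (N, d)
    position_labels: np.ndarray  # (N,) flat labels l = 13 * x_UC + x_LC
    task_labels: np.ndarray | None = None  # (N, 4)
    model_id: str = ""

    def __len__(self) -> int:
        return self.mu.shape[0]


@dataclass
class DistortionMatrices:
    """Label-pair-averaged distortion ratios with their pair counts."""

    matrix: np.ndarray  # (K, K) mean rho per label pair; NaN where no pairs
    counts: np.ndarray  # (K, K) number of image pairs averaged per cell
    labels: np.ndarray  # the K label values indexing rows/columns


def embed_dataset(model: CorridorVAE, dataset: Dataset,
                  model_id: str = "") -> EmbeddingTable:
    """Encode every image to its posterior mean (deterministic)."""
    params = model.encode(dataset.images.astype(float))
    return EmbeddingTable(params.mu, np.asarray(dataset.position_labels),
                          dataset.task_labels, model_id)


def mds_project(distance_matrix: np.ndarray, out_dim: int = 2,
                seed: int = 0, n_init: int = 8) -> np.ndarray:
    """Metric MDS (SMACOF stress majorisation) of a dissimilarity matrix."""
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0) or not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distances must be non-negative with zero diagonal")
    if out_dim not in (2, 3):
        raise ValueError("out_dim must be 2 or 3")
    kw = dict(n_components=out_dim, dissimilarity="precomputed", metric=True,
              random_state=seed, normalized_stress=False, max_iter=2000,
              eps=1e-12)
    # classical (Torgerson) solution as one starting point: exact for
    # configurations that embed perfectly in out_dim dimensions
    J = np.eye(len(D)) - 1.0 / len(D)
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    top = np.argsort(w)[::-1][:out_dim]
    init = V[:, top] * np.sqrt(np.maximum(w[top], 0.0))

    mds = MDS(n_init=1, **kw)
    best = mds.fit_transform(D, init=init)
    best_stress = mds.stress_
    mds = MDS(n_init=n_init, **kw)
    alt = mds.fit_transform(D)
    return best if best_stress <= mds.stress_ else alt


def distortion_ratios(emb_ref: EmbeddingTable, emb_cmp: EmbeddingTable,
                      eps: float = 1e-8):
    """Pairwise rho = d_cmp / d_ref over all unordered image pairs.

    Pairs whose reference distance is <= eps are excluded.  Returns
    ``(rho, pair_idx, n_excluded)`` where ``pair_idx`` is an (M, 2) array of
    image indices (in condensed-pdist order before exclusion).
    """
    if len(emb_ref) != len(emb_cmp):
        raise ValueError("embedding tables must cover the same images")
    if not np.array_equal(emb_ref.position_labels, emb_cmp.position_labels):
        raise ValueError("embedding tables carry mismatched labels")
    d_ref = pdist(emb_ref.mu)
    d_cmp = pdist(emb_cmp.mu)
    n = len(emb_ref)
    iu = np.triu_indices(n, k=1)
    keep = d_ref > eps
    rho = d_cmp[keep] / d_ref[keep]
    pair_idx = np.stack([iu[0][keep], iu[1][keep]], axis=1)
    return rho, pair_idx, int((~keep).sum())


def _aggregate(rho: np.ndarray, pair_idx: np.ndarray,
               labels: np.ndarray) -> DistortionMatrices:
    """Mean rho per (label_a, label_b) cell, symmetrised over pair order."""
    uniq, inv = np.unique(labels, return_inverse=True)
    k = uniq.size
    la, lb = inv[pair_idx[:, 0]], inv[pair_idx[:, 1]]
    sums = np.zeros((k, k))
    counts = np.zeros((k, k))
    np.add.at(sums, (la, lb), rho)
    np.add.at(counts, (la, lb), 1.0)
    sums, counts = sums + sums.T, counts + counts.T
    # diagonal pairs (same label) were added twice by the symmetrisation
    di = np.diag_indices(k)
    sums[di] /= 2.0
    counts[di] /= 2.0
    with np.errstate(invalid="ignore"):
        mat = np.where(counts > 0, sums / np.maximum(counts, 1e-300), np.nan)
    return DistortionMatrices(mat, counts.astype(int), uniq)


def item_distortion_matrix(rho: np.ndarray, pair_idx: np.ndarray,
                           position_labels: np.ndarray) -> DistortionMatrices:
    """169x169 matrix of mean rho per ordered pair of flat position labels.

    The matrix is symmetric by construction; cells with no image pairs are
    NaN with count 0.  Rows/columns are indexed by all 169 labels even when
    some are absent from the sample.
    """
    dm = _aggregate(rho, pair_idx, np.asarray(position_labels))
    full = np.full((N_PAIRS, N_PAIRS), np.nan)
    cnts = np.zeros((N_PAIRS, N_PAIRS), dtype=int)
    ix = np.asarray(dm.labels, dtype=int)
    full[np.ix_(ix, ix)] = dm.matrix
    cnts[np.ix_(ix, ix)] = dm.counts
    return DistortionMatrices(full, cnts, np.arange(N_PAIRS))


def class_distortion_matrix(rho: np.ndarray, pair_idx: np.ndarray,
                            class_labels: np.ndarray) -> DistortionMatrices:
    """K x K matrix of mean rho per pair of classes (task or frequency)."""
    return _aggregate(rho, pair_idx, np.asarray(class_labels))


def stratified_subsample(dataset: Dataset, per_label: int = 20,
                         seed: int = 0) -> np.ndarray:
    """Indices of up to ``per_label`` images per position label.

    Keeps the full 169x169 item matrix tractable: cell means stay unbiased
    while the number of pairs drops from O(N^2) to O((169 * per_label)^2).
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(dataset.position_labels)
    keep = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        keep.append(idx[:per_label])
    return np.sort(np.concatenate(keep))


def channel_activation_maps(model: CorridorVAE, dataset: Dataset) -> np.ndarray:
    """(d, 13, 13) mean posterior-mean activation per channel and position pair.

    Cells for position pairs absent from the dataset are NaN.
    """
    emb = embed_dataset(model, dataset)
    d = emb.mu.shape[1]
    sums = np.zeros((d, N_PAIRS))
    counts = np.zeros(N_PAIRS)
    np.add.at(sums.T, emb.position_labels, emb.mu)
    np.add.at(counts, emb.position_labels, 1.0)
    if np.any(counts == 0):
        import warnings
        warnings.warn(f"{int((counts == 0).sum())} position pairs absent from "
                      "the dataset; their map cells are NaN")
    with np.errstate(invalid="ignore"):
        maps = sums / counts
    return maps.reshape(d, GRID, GRID)


def axis_selectivity(channel_map: np.ndarray) -> tuple[str, float]:
    """Which position axis a channel map varies along, and how exclusively.

    Decomposes the (mean-removed) map variance into a row effect (upper
    corridor), a column effect (lower corridor) and a residual.  Returns the
    dominant axis ("rows" or "cols") and its share of the total variance; a
    disentangled channel has a share close to 1.
    """
    m = np.asarray(channel_map, dtype=float)
    m = m - np.nanmean(m)
    row_eff = np.nanmean(m, axis=1)
    col_eff = np.nanmean(m, axis=0)
    total = np.nanvar(m)
    if total <= 0:
        return "rows", 0.0
    v_row = np.var(row_eff)
    v_col = np.var(col_eff)
    if v_row >= v_col:
        return "rows", float(v_row / total)
    return "cols", float(v_col / total)


def per_channel_kl(model: CorridorVAE, dataset: Dataset) -> np.ndarray:
    """Mean per-dimension KL (nats) of the posterior over a dataset."""
    params = model.encode(dataset.images.astype(float))
    return kl_per_dimension(params).mean(axis=0)


def active_channel_count(model: CorridorVAE, dataset: Dataset,
                         threshold_nats: float = 0.05) -> int:
    """Number of latent channels whose mean KL exceeds the threshold."""
    return int((per_channel_kl(model, dataset) > threshold_nats).sum())


def latent_cluster_count(emb: EmbeddingTable, k_range=range(2, 9),
                         seed: int = 0, max_points: int = 2000) -> int:
    """Silhouette-selected k-means cluster count of an embedding.

    A descriptive operationalisation of prototypization: a low-capacity
    model collapsing images onto a few prototypes shows a small number of
    well-separated latent clusters.
    """
    X = emb.mu
    if len(X) > max_points:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(len(X), max_points, replace=False)]
    best_k, best_s = None, -np.inf
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(X)
        s = silhouette_score(X, km.labels_)
        if s > best_s:
            best_k, best_s = k, s
    return int(best_k)
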