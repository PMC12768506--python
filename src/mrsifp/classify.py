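"""Unsupervised subtype separation: LOO-UMAP embedding, K-means, ROC.

Voxel-wise source-contribution profiles are embedded in 2-D with UMAP under
a leave-one-patient-out scheme: for each fold the embedding (and the
per-source z-standardization feeding it) is fitted on all other patients'
voxels, the held-out patient's voxels are transformed with the fitted
model, and only those test embeddings are kept. Concatenating the test
embeddings over folds yields a cohort-wide representation in which no
voxel was embedded by a model that saw its own patient.

K-means (default K = 3) on tumor voxels then separates the subtypes;
clusters are mapped onto subtypes by Hungarian assignment on the
cluster-by-subtype contingency table, which makes the reported accuracy
invariant to cluster relabelling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import softmax
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    roc_auc_score,
    roc_curve,
    silhouette_score,
)
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

__all__ = [
    "UmapParams",
    "EmbeddingResult",
    "ClusterResult",
    "RocResult",
    "loo_umap",
    "kmeans_subtypes",
    "roc_auc",
    "feature_importance",
]


@dataclass
class UmapParams:
    n_neighbors: int = 15
    min_dist: float = 0.1
    metric: str = "euclidean"
    n_components: int = 2
    seed: int = 0


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # n_voxels x 2, original voxel order
    fold_id: np.ndarray  # held-out patient per voxel
    umap_params: UmapParams


@dataclass
class ClusterResult:
    labels: np.ndarray  # raw K-means cluster ids
    mapping: dict[int, str]  # cluster id -> subtype
    mapped_subtype: np.ndarray
    accuracy: float  # percent
    accuracy_ci: tuple[float, float]
    per_class: dict[str, dict[str, float]]  # subtype -> recall/specificity (+ CIs)
    quality: dict[str, float]  # silhouette / davies_bouldin / calinski_harabasz


@dataclass
class RocResult:
    per_class_auc: dict[str, float]
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = field(repr=False, default=None)
    macro_auc: float = float("nan")


def _similarity_transform(A: np.ndarray, B: np.ndarray):
    """Least-squares similarity transform (scale, rotation/reflection,
    translation) mapping point set A onto B."""
    mu_a, mu_b = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - mu_a, B - mu_b
    U, S, Vt = np.linalg.svd(A0.T @ B0)
    R = U @ Vt
    denom = (A0**2).sum()
    s = S.sum() / denom if denom > 0 else 1.0
    return lambda P: s * (P - mu_a) @ R + mu_b


def _local_residual_warp(
    anchors: np.ndarray,
    targets: np.ndarray,
    points: np.ndarray,
    k: int = 10,
) -> np.ndarray:
    """Displace points by the IDW-mean residual of their k nearest anchors."""
    from sklearn.neighbors import NearestNeighbors

    disp = targets - anchors
    nn = NearestNeighbors(n_neighbors=min(k, len(anchors))).fit(anchors)
    d, idx = nn.kneighbors(points)
    w = 1.0 / np.maximum(d, 1e-8)
    w /= w.sum(axis=1, keepdims=True)
    return points + (w[:, :, None] * disp[idx]).sum(axis=1)


def loo_umap(
    features: np.ndarray,
    patient_ids: np.ndarray,
    params: UmapParams | None = None,
) -> EmbeddingResult:
    """Leave-one-patient-out UMAP embedding of voxel feature profiles.

    Per fold the feature scaler and the UMAP model are fitted on the
    training patients only, preventing leakage of the held-out patient into
    either the standardization or the manifold. Deterministic for a fixed
    ``params.seed`` (UMAP runs single-threaded when seeded).

    UMAP fixes an embedding only up to an arbitrary similarity transform,
    and small clusters can additionally be *placed* differently relative to
    the large ones from fold to fold, so naively concatenating test
    embeddings from different folds scrambles the geometry. Each fold's
    layout is therefore aligned to a common reference frame before its test
    embedding is retained: first a global Procrustes (scale + rotation +
    reflection + translation) fitted on the training voxels the fold shares
    with the reference, then a local residual correction that displaces
    every point by the inverse-distance-weighted mean residual of its
    nearest anchor voxels, which reconciles per-cluster placement
    differences a single global map cannot. All anchors are training
    voxels of *other* patients, so no information about the held-out
    patient enters its own alignment and the leave-one-out guarantee is
    intact. The reference frame accumulates each fold's aligned layout so
    every later fold finds anchors for every patient seen so far.
    """
    import umap  # deferred: numba compilation is slow at import time

    params = params or UmapParams()
    features = np.asarray(features, dtype=float)
    patient_ids = np.asarray(patient_ids)
    patients = np.unique(patient_ids)
    if patients.size < 2:
        raise ValueError("leave-one-out embedding needs at least 2 patients")

    coords = np.full((features.shape[0], params.n_components), np.nan)
    fold_id = np.empty(features.shape[0], dtype=patient_ids.dtype)
    ref_emb: dict[int, np.ndarray] = {}  # voxel index -> reference-frame coords
    for patient in patients:
        test = patient_ids == patient
        train = ~test
        if test.sum() == 0:
            logger.warning("patient %s has no voxels; fold skipped", patient)
            continue
        scaler = StandardScaler().fit(features[train])
        n_train = int(train.sum())
        nn = min(params.n_neighbors, max(2, n_train - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(
                n_neighbors=nn,
                min_dist=params.min_dist,
                metric=params.metric,
                n_components=params.n_components,
                random_state=params.seed,
            ).fit(scaler.transform(features[train]))
            test_emb = reducer.transform(scaler.transform(features[test]))
        train_idx = np.flatnonzero(train)
        train_emb = reducer.embedding_
        if not ref_emb:
            # first fold defines the reference frame
            aligned_train, aligned_test = train_emb, test_emb
        else:
            pos = {i: p for p, i in enumerate(train_idx)}
            shared = [i for i in train_idx if i in ref_emb]
            A = train_emb[[pos[i] for i in shared]]
            B = np.stack([ref_emb[i] for i in shared])
            transform = _similarity_transform(A, B)
            aligned_train, aligned_test = transform(train_emb), transform(test_emb)
            A_glob = transform(A)
            aligned_train = _local_residual_warp(A_glob, B, aligned_train)
            aligned_test = _local_residual_warp(A_glob, B, aligned_test)
        coords[test] = aligned_test
        # grow the reference with this fold's aligned layout so every later
        # fold finds anchors for every patient seen so far (in particular,
        # patients whose subtype has no other representative in the overlap)
        for i, c in zip(train_idx, aligned_train):
            ref_emb.setdefault(int(i), c)
        for i, c in zip(np.flatnonzero(test), aligned_test):
            ref_emb.setdefault(int(i), c)
        fold_id[test] = patient
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("embedding produced non-finite coordinates")
    return EmbeddingResult(coords=coords, fold_id=fold_id, umap_params=params)


def _bootstrap_ci(stat_fn, n: int, rng: np.random.Generator,
                  n_boot: int = 2000) -> tuple[float, float]:
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        vals[b] = stat_fn(idx)
    return float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))


def kmeans_subtypes(
    coords: np.ndarray,
    true_subtypes: np.ndarray,
    k: int = 3,
    seed: int = 0,
    n_boot: int = 2000,
) -> ClusterResult:
    """Cluster embedded tumor voxels and score subtype agreement.

    Clusters are mapped to subtypes by maximizing the contingency-table
    agreement with the Hungarian algorithm (majority vote with optimal tie
    resolution). Accuracy and per-class recall/specificity get percentile
    bootstrap 95% CIs over voxels. Cluster-quality indices (silhouette,
    Davies-Bouldin, Calinski-Harabasz) are computed on the coordinates and
    reported as NaN when undefined (fewer than 2 clusters).
    """
    coords = np.asarray(coords, dtype=float)
    true_subtypes = np.asarray(true_subtypes)
    if k < 1:
        raise ValueError("k must be >= 1")
    subtype_names = list(np.unique(true_subtypes))
    if k > len(subtype_names):
        logger.warning(
            "k=%d exceeds the %d observed subtypes; mapping will be surjective",
            k, len(subtype_names),
        )

    if k == 1:
        labels = np.zeros(len(coords), dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(coords)

    # contingency: clusters x subtypes; Hungarian on -counts maximizes agreement
    counts = np.zeros((k, len(subtype_names)), dtype=int)
    for c in range(k):
        for s, name in enumerate(subtype_names):
            counts[c, s] = np.sum((labels == c) & (true_subtypes == name))
    if k <= len(subtype_names):
        rows, cols = linear_sum_assignment(-counts)
        mapping = {int(c): subtype_names[s] for c, s in zip(rows, cols)}
    else:
        mapping = {c: subtype_names[int(np.argmax(counts[c]))] for c in range(k)}
    mapped = np.array([mapping[int(c)] for c in labels])

    correct = mapped == true_subtypes
    rng = np.random.default_rng(seed)
    accuracy = 100.0 * float(np.mean(correct))
    lo, hi = _bootstrap_ci(lambda idx: 100.0 * np.mean(correct[idx]),
                           len(correct), rng, n_boot)

    per_class: dict[str, dict[str, float]] = {}
    for name in subtype_names:
        pos = true_subtypes == name
        pred_pos = mapped == name
        recall = 100.0 * float(np.mean(pred_pos[pos])) if pos.any() else np.nan
        neg = ~pos
        spec = 100.0 * float(np.mean(~pred_pos[neg])) if neg.any() else np.nan

        def rec_fn(idx, pos=pos, pred_pos=pred_pos):
            sel = pos[idx]
            return 100.0 * np.mean(pred_pos[idx][sel]) if sel.any() else np.nan

        def spec_fn(idx, pos=pos, pred_pos=pred_pos):
            sel = ~pos[idx]
            return 100.0 * np.mean(~pred_pos[idx][sel]) if sel.any() else np.nan

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_lo, r_hi = _bootstrap_ci(rec_fn, len(correct), rng, n_boot)
            s_lo, s_hi = _bootstrap_ci(spec_fn, len(correct), rng, n_boot)
        per_class[name] = {
            "recall": recall, "recall_ci": (r_lo, r_hi),
            "specificity": spec, "specificity_ci": (s_lo, s_hi),
        }

    quality = {"silhouette": np.nan, "davies_bouldin": np.nan,
               "calinski_harabasz": np.nan}
    if len(np.unique(labels)) >= 2:
        quality["silhouette"] = float(silhouette_score(coords, labels))
        quality["davies_bouldin"] = float(davies_bouldin_score(coords, labels))
        quality["calinski_harabasz"] = float(calinski_harabasz_score(coords, labels))

    return ClusterResult(
        labels=labels, mapping=mapping, mapped_subtype=mapped,
        accuracy=accuracy, accuracy_ci=(lo, hi), per_class=per_class,
        quality=quality,
    )


def centroid_scores(coords: np.ndarray, mapped_subtype: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Softmax-normalized negative distance to each subtype's cluster centroid."""
    names = list(np.unique(mapped_subtype))
    centroids = np.stack([coords[mapped_subtype == n].mean(axis=0) for n in names])
    d = np.linalg.norm(coords[:, None, :] - centroids[None, :, :], axis=2)
    return softmax(-d, axis=1), names


def roc_auc(
    scores: np.ndarray,
    true_subtypes: np.ndarray,
    class_names: list[str] | None = None,
) -> RocResult:
    """One-vs-rest ROC AUC per subtype from continuous membership scores.

    ``scores`` is n_voxels x n_classes (column order ``class_names``); ties
    are handled by midranks (trapezoidal AUC equals the midrank U statistic).
    Returns NaN AUC for a class absent from the labels.
    """
    scores = np.asarray(scores, dtype=float)
    true_subtypes = np.asarray(true_subtypes)
    if class_names is None:
        class_names = list(np.unique(true_subtypes))
    if len(np.unique(true_subtypes)) < 2:
        return RocResult(per_class_auc={c: float("nan") for c in class_names},
                         curves={}, macro_auc=float("nan"))
    aucs, curves = {}, {}
    for j, name in enumerate(class_names):
        y = (true_subtypes == name).astype(int)
        if y.min() == y.max():
            aucs[name] = float("nan")
            continue
        aucs[name] = float(roc_auc_score(y, scores[:, j]))
        fpr, tpr, _ = roc_curve(y, scores[:, j])
        curves[name] = (fpr, tpr)
    finite = [v for v in aucs.values() if np.isfinite(v)]
    macro = float(np.mean(finite)) if finite else float("nan")
    return RocResult(per_class_auc=aucs, curves=curves, macro_auc=macro)


def feature_importance(
    sources: np.ndarray,
    coords: np.ndarray,
    standardize: bool = True,
) -> np.ndarray:
    """OLS coefficients of each embedding coordinate on all sources jointly.

    ``sources`` (n_voxels x r) are z-standardized predictors; ``coords``
    (n_voxels x 2) are the responses. Returns an r x n_coords coefficient
    matrix (heatmap-ready). A rank-deficient design falls back to a small
    ridge penalty, logged.
    """
    S = np.asarray(sources, dtype=float)
    Y = np.asarray(coords, dtype=float)
    if standardize:
        sd = S.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        S = (S - S.mean(axis=0)) / sd
    D = np.column_stack([np.ones(len(S)), S])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        alpha = 1e-6
        logger.warning("rank-deficient design; ridge fallback with alpha=%g", alpha)
        coef = np.linalg.solve(D.T @ D + alpha * np.eye(D.shape[1]), D.T @ Y)
    else:
        coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
    return coef[1:]  # drop intercept
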