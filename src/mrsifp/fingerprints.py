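"""Patient-level z-score metabolic fingerprints and UPGMA clustering.

For every patient and every source, the fingerprint entry is

    z[p, s] = (mean_tumor H_s - mean_healthy H_s) / sd_healthy H_s

i.e. the tumor deviation expressed in units of the patient's own healthy
standard deviation (sample SD, ddof=1). The patients x sources matrix is
then clustered hierarchically with Euclidean distance and average linkage
(UPGMA), and group structure is summarized by inter-group distances,
intra-group variance and Shannon entropy.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, dendrogram, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "FingerprintMatrix",
    "DendrogramResult",
    "zscore_matrix",
    "upgma_cluster",
    "entropy_score",
]


@dataclass
class FingerprintMatrix:
    z: pd.DataFrame  # patients x sources
    subtypes: pd.Series  # per patient
    healthy_stats: pd.DataFrame  # (patient, source) -> mean, sd, n


@dataclass
class DendrogramResult:
    linkage: np.ndarray  # standard 4-column merge format
    leaf_order: list[str]
    inter_group_distance: dict[tuple[str, str], float]
    inter_group_cophenetic: dict[tuple[str, str], float]
    intra_group: dict[str, dict[str, float]]  # subtype -> variance / entropy
    distance_matrix: pd.DataFrame = field(repr=False, default=None)


def zscore_matrix(
    table: pd.DataFrame,
    source_columns: list[str] | None = None,
    region_column: str = "region",
) -> FingerprintMatrix:
    """Per-patient tumor-vs-healthy z-scores of source contributions.

    Patients without healthy voxels (or with < 2, so the SD is undefined)
    are excluded with a warning; a zero healthy SD yields NaN for that cell.
    """
    if source_columns is None:
        source_columns = [c for c in table.columns if c.startswith("source_")]
    if not source_columns:
        raise ValueError("no source contribution columns found")
    rows, stats_rows, subtypes = {}, [], {}
    for patient, sub in table.groupby("patient_id", sort=True):
        tumor = sub[sub[region_column] == "tumor"]
        healthy = sub[sub[region_column] == "healthy"]
        if len(tumor) < 1 or len(healthy) < 2:
            logger.warning(
                "patient %s excluded from fingerprint: %d tumor / %d healthy voxels",
                patient, len(tumor), len(healthy),
            )
            continue
        z = {}
        for s in source_columns:
            mu_h = healthy[s].mean()
            sd_h = healthy[s].std(ddof=1)
            stats_rows.append({"patient_id": patient, "source": s,
                               "mean": mu_h, "sd": sd_h, "n": len(healthy)})
            if sd_h == 0:
                logger.warning("patient %s source %s: zero healthy SD", patient, s)
                z[s] = np.nan
            else:
                z[s] = (tumor[s].mean() - mu_h) / sd_h
        rows[patient] = z
        if "subtype" in sub.columns:
            subtypes[patient] = sub["subtype"].iloc[0]
    if not rows:
        raise ValueError("no patient had both tumor and healthy voxels")
    z = pd.DataFrame.from_dict(rows, orient="index")[source_columns]
    return FingerprintMatrix(
        z=z,
        subtypes=pd.Series(subtypes).reindex(z.index),
        healthy_stats=pd.DataFrame(stats_rows),
    )


def _pairwise_complete_euclidean(Z: np.ndarray) -> np.ndarray:
    """Euclidean distances using shared-finite columns, rescaled to full dim."""
    n, p = Z.shape
    D = np.zeros((n, n))
    finite = np.isfinite(Z)
    for a in range(n):
        for b in range(a + 1, n):
            shared = finite[a] & finite[b]
            used = int(shared.sum())
            if used == 0:
                raise ValueError("two fingerprints share no finite sources")
            d2 = np.sum((Z[a, shared] - Z[b, shared]) ** 2) * (p / used)
            D[a, b] = D[b, a] = np.sqrt(d2)
    return D


def upgma_cluster(
    fingerprints: FingerprintMatrix,
    scale_sources: bool = True,
) -> DendrogramResult:
    """UPGMA (average-linkage) clustering of the fingerprint matrix.

    Distances are Euclidean; cells that are NaN are handled by
    pairwise-complete distances rescaled to the full dimensionality, which
    preserves patients rather than deleting rows. Two between-group
    separations are reported per subtype pair: the mean pairwise Euclidean
    distance between members, and the mean UPGMA cophenetic height.

    With ``scale_sources`` (default) each source column is standardized
    across patients before distances are taken. Raw z columns can differ
    by orders of magnitude — a source that is nearly absent in healthy
    tissue has a tiny healthy SD, so its z values are huge and their
    sampling noise would dominate every Euclidean distance. Unit-variance
    scaling makes each source contribute comparably, the usual practice
    before hierarchically clustering a heatmap. Disable it to verify
    linkage arithmetic on a matrix whose scale is meaningful as given.
    """
    Z = fingerprints.z.to_numpy(dtype=float)
    patients = list(fingerprints.z.index)
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to cluster")
    if scale_sources:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            mu = np.nanmean(Z, axis=0)
            sd = np.nanstd(Z, axis=0, ddof=1)
        sd = np.where(np.isfinite(sd) & (sd > 0), sd, 1.0)
        Z = (Z - np.where(np.isfinite(mu), mu, 0.0)) / sd
    if np.isnan(Z).any():
        logger.warning("NaN fingerprint cells; using pairwise-complete distances")
    D = _pairwise_complete_euclidean(Z)
    condensed = squareform(D, checks=False)
    L = linkage(condensed, method="average")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        order = dendrogram(L, no_plot=True)["leaves"]
    coph = squareform(cophenet(L))

    subtypes = fingerprints.subtypes
    groups = [s for s in subtypes.dropna().unique()]
    inter, inter_coph = {}, {}
    for a, b in itertools.combinations(sorted(groups), 2):
        ia = np.flatnonzero((subtypes == a).to_numpy())
        ib = np.flatnonzero((subtypes == b).to_numpy())
        inter[(a, b)] = float(D[np.ix_(ia, ib)].mean())
        inter_coph[(a, b)] = float(coph[np.ix_(ia, ib)].mean())

    intra = {}
    for g in groups:
        idx = np.flatnonzero((subtypes == g).to_numpy())
        rows = Z[idx]
        if len(idx) > 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # <2 finite cells
                var = float(np.nanmean(np.nanvar(rows, axis=0, ddof=1)))
        else:
            var = np.nan
        ent = entropy_score(rows) if len(idx) >= 1 else np.nan
        intra[g] = {"variance": var, "entropy": ent}

    return DendrogramResult(
        linkage=L,
        leaf_order=[patients[i] for i in order],
        inter_group_distance=inter,
        inter_group_cophenetic=inter_coph,
        intra_group=intra,
        distance_matrix=pd.DataFrame(D, index=patients, columns=patients),
    )


def entropy_score(profiles: np.ndarray, n_bins: int = 64) -> float:
    """Shannon entropy (bits) of pooled standardized profile values.

    Values from all patients and sources in the group are pooled,
    standardized, and histogrammed into ``n_bins`` equal-width bins over
    their range; the entropy of the resulting distribution quantifies
    intra-group metabolic heterogeneity. A point mass has entropy 0; a
    distribution uniform over the bins reaches log2(n_bins). The magnitude
    depends on ``n_bins``, which is therefore reported with the value.
    """
    values = np.asarray(profiles, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("cannot compute entropy of an empty profile set")
    sd = values.std(ddof=0)
    if sd == 0:
        return 0.0
    z = (values - values.mean()) / sd
    counts, _ = np.histogram(z, bins=n_bins)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def plot_heatmap(
    fingerprints: FingerprintMatrix,
    result: DendrogramResult,
    path: str,
) -> None:
    """Write a dendrogram-ordered z-score heatmap PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [list(fingerprints.z.index).index(p) for p in result.leaf_order]
    Z = fingerprints.z.to_numpy(dtype=float)[order]
    fig, ax = plt.subplots(figsize=(0.6 * Z.shape[1] + 2, 0.4 * Z.shape[0] + 2))
    lim = np.nanmax(np.abs(Z)) or 1.0
    im = ax.imshow(Z, cmap="RdBu_r", vmin=-lim, vmax=lim, aspect="auto")
    ax.set_xticks(range(Z.shape[1]), fingerprints.z.columns, rotation=45, ha="right")
    labels = [f"{p} ({fingerprints.subtypes.get(p, '?')})" for p in result.leaf_order]
    ax.set_yticks(range(Z.shape[0]), labels)
    fig.colorbar(im, ax=ax, label="z (tumor vs healthy)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def to_newick(result: DendrogramResult) -> str:
    """Newick serialization of the UPGMA dendrogram (branch lengths in height units)."""
    L = result.linkage
    n = L.shape[0] + 1
    labels = list(result.distance_matrix.index)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(L):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + L.shape[0] - 1] + ";"
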