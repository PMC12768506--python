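"""End-to-end orchestration: simulate -> QC -> indices -> G-NMU -> classify
-> fingerprints -> stats, with a reproducible run manifest.

Every intermediate is written as plain TSV/JSON so any stage can be
inspected or swapped; a single config object (optionally loaded from YAML)
is the only source of parameters, and the manifest records the config
hash, per-stage row counts, timings and output checksums so reruns can be
verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import fingerprints as fp
from . import stats as st
from .basis import default_basis
from .gnmu import gnmu_decompose, project_contributions, source_composition
from .indices import IndexThresholds, assign_regions, summarize_index
from .qc import QCThresholds, apply_qc, flag_artifacts
from .synthetic import SyntheticCohortConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    seed: int = 0
    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    indices: IndexThresholds = field(default_factory=IndexThresholds)
    rank: int = 7
    gnmu_max_iter: int = 300
    gnmu_mode: str = "global"
    umap: cls.UmapParams = field(default_factory=cls.UmapParams)
    k: int = 3
    entropy_bins: int = 64
    run_qc: bool = True
    # The baseline artifact rule consumes a smooth fitted-baseline signal,
    # which the synthetic generator does not emulate; on a raw noise floor
    # the max-over-window statistic exceeds mu + 2.5 sigma for most voxels
    # simply by extreme-value behaviour of Gaussian noise. Off by default;
    # enable for real data with fitted baselines.
    run_artifact_flag: bool = False
    n_boot: int = 2000


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages: dict[str, dict]
    checksums: dict[str, str]


_SECTION_TYPES = {
    "cohort": SyntheticCohortConfig,
    "qc": QCThresholds,
    "indices": IndexThresholds,
    "umap": cls.UmapParams,
}


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            typ = _SECTION_TYPES[key]
            sub_fields = {f.name for f in dataclasses.fields(typ)}
            bad = set(value) - sub_fields
            if bad:
                raise ValueError(f"unknown keys in section {key!r}: {sorted(bad)}")
            for name in ("tumor_voxels_per_patient", "healthy_voxels_per_patient",
                         "grid_shape", "crlb_metabolites"):
                if name in value:
                    value[name] = tuple(value[name])
            kwargs[key] = typ(**value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig | None = None, outdir: str | Path = "mrsifp_run") -> RunManifest:
    """Run all stages on a synthetic cohort and write results to ``outdir``."""
    from . import __version__

    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}

    def stage(name):
        stages[name] = {"t0": time.perf_counter()}
        logger.info("stage %s started", name)
        return stages[name]

    def done(rec, **info):
        rec.update(info)
        rec["seconds"] = round(time.perf_counter() - rec.pop("t0"), 3)

    # 1. simulate -----------------------------------------------------------
    rec = stage("simulate")
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    cohort = simulate_cohort(cohort_cfg)
    table = cohort.voxel_table
    done(rec, n_voxels=len(table), n_patients=table["patient_id"].nunique(),
         clip_fraction=cohort.clip_fraction)

    # 2. qc -----------------------------------------------------------------
    rec = stage("qc")
    if config.run_qc:
        table = apply_qc(table, config.qc)
        if config.run_artifact_flag:
            # 0.5-1.0 ppm is signal-free on the default grid (lowest line: Lac 1.31)
            table["artifact_flag"] = flag_artifacts(
                cohort.spectra, cohort.ppm_axis, baseline_region=(0.5, 1.0),
                k=config.qc.artifact_k,
            )
        else:
            table["artifact_flag"] = False
        table.loc[table["artifact_flag"], "qc_pass"] = False
        table.loc[table["artifact_flag"], "region"] = "excluded"
    else:
        table = table.copy()
        table["qc_pass"] = True
        table["artifact_flag"] = False
    done(rec, n_in=len(table), n_pass=int(table["qc_pass"].sum()))

    # 3. indices / region assignment ---------------------------------------
    rec = stage("indices")
    table = assign_regions(table, config.indices)
    n_tumor = int((table["region"] == "tumor").sum())
    n_healthy = int((table["region"] == "healthy").sum())
    done(rec, n_tumor=n_tumor, n_healthy=n_healthy)
    if n_tumor < config.rank:
        raise RuntimeError(
            f"stage indices: only {n_tumor} tumor voxels for rank {config.rank}"
        )

    # 4. G-NMU on pooled tumor spectra -------------------------------------
    rec = stage("gnmu")
    tumor_idx = np.flatnonzero((table["region"] == "tumor").to_numpy())
    X_tumor = cohort.spectra[tumor_idx].T  # spectral points x voxels
    sources = gnmu_decompose(
        X_tumor, r=config.rank, max_iter=config.gnmu_max_iter,
        seed=config.seed, mode=config.gnmu_mode, ppm_axis=cohort.ppm_axis,
    )
    composition = source_composition(sources.W, cohort.basis)
    done(rec, rank=sources.r, residual=sources.residual,
         iterations=sources.iterations_run)

    # 5. least-squares contributions for tumor and healthy voxels ----------
    rec = stage("project")
    used = table["region"].isin(["tumor", "healthy"]).to_numpy()
    H_all = project_contributions(sources.W, cohort.spectra[used].T)
    source_cols = [f"source_{k+1}" for k in range(config.rank)]
    for k, col in enumerate(source_cols):
        table[col] = np.nan
        table.loc[used, col] = H_all[k]
    done(rec, n_projected=int(used.sum()))

    # 6. classification on tumor voxels ------------------------------------
    rec = stage("classify")
    tumor_mask = (table["region"] == "tumor").to_numpy()
    feats = table.loc[tumor_mask, source_cols].to_numpy()
    pids = table.loc[tumor_mask, "patient_id"].to_numpy()
    subtypes = table.loc[tumor_mask, "subtype"].to_numpy()
    umap_params = dataclasses.replace(config.umap, seed=config.seed)
    emb = cls.loo_umap(feats, pids, umap_params)
    clus = cls.kmeans_subtypes(emb.coords, subtypes, k=config.k,
                               seed=config.seed, n_boot=config.n_boot)
    scores, score_names = cls.centroid_scores(emb.coords, clus.mapped_subtype)
    roc = cls.roc_auc(scores, subtypes, score_names)
    importance = cls.feature_importance(feats, emb.coords)
    for c, col in enumerate(["umap_1", "umap_2"]):
        table[col] = np.nan
        table.loc[tumor_mask, col] = emb.coords[:, c]
    table["cluster"] = pd.NA
    table.loc[tumor_mask, "cluster"] = clus.labels
    table["mapped_subtype"] = pd.NA
    table.loc[tumor_mask, "mapped_subtype"] = clus.mapped_subtype
    done(rec, accuracy=clus.accuracy, macro_auc=roc.macro_auc)

    # 7. fingerprints + stats -----------------------------------------------
    rec = stage("fingerprint")
    fmat = fp.zscore_matrix(table, source_cols)
    dend = fp.upgma_cluster(fmat)
    done(rec, n_patients=len(fmat.z))

    rec = stage("stats")
    stat_rows = []
    z = fmat.z
    subs = fmat.subtypes
    groups = {g: z[subs == g] for g in subs.dropna().unique()}
    for col in source_cols:
        vals = [g[col].dropna().to_numpy() for g in groups.values()]
        if len(vals) >= 2 and all(len(v) >= 1 for v in vals):
            kw = st.kruskal_wallis(*vals, names=tuple(groups))
            stat_rows.append(("all_subtypes", col, kw.test_name, kw.statistic, kw.p_value, np.nan))
        if "GBM" in groups:
            gbm = groups["GBM"][col].dropna().to_numpy()
            midh = z.loc[subs.isin(["AC", "OG"]), col].dropna().to_numpy()
            if len(gbm) >= 2 and len(midh) >= 2:
                w = st.welch_t(gbm, midh, names=("GBM", "AC+OG"))
                u = st.mann_whitney(gbm, midh, names=("GBM", "AC+OG"))
                lv = st.levene(gbm, midh, names=("GBM", "AC+OG"))
                d = st.cohens_d(gbm, midh)
                stat_rows.append(("GBM_vs_mIDH", col, w.test_name, w.statistic, w.p_value, d.cohens_d))
                stat_rows.append(("GBM_vs_mIDH", col, u.test_name, u.statistic, u.p_value, np.nan))
                stat_rows.append(("GBM_vs_mIDH", col, lv.test_name, lv.statistic, lv.p_value, np.nan))
    stats_df = pd.DataFrame(
        stat_rows, columns=["comparison", "feature", "test", "statistic", "p", "cohens_d"]
    )
    done(rec, n_tests=len(stats_df))

    # ----- outputs ----------------------------------------------------------
    checksums: dict[str, str] = {}
    out_tables = {
        "voxels.tsv": table,
        "fingerprints.tsv": z.rename_axis("patient_id").reset_index(),
        "stats.tsv": stats_df,
    }
    for name, df in out_tables.items():
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        checksums[name] = _sha256(path)
    w_df = pd.DataFrame(sources.W, columns=source_cols)
    w_df.insert(0, "ppm", cohort.ppm_axis)
    w_df.to_csv(outdir / "sources_W.tsv", sep="\t", index=False)
    checksums["sources_W.tsv"] = _sha256(outdir / "sources_W.tsv")

    hgi_tumor = table.loc[table["region"] == "tumor", "hgi"]
    hgi_summary = summarize_index(hgi_tumor, config.indices.hgi_min) if len(hgi_tumor) else None
    metrics = {
        "accuracy_pct": clus.accuracy,
        "accuracy_ci_pct": list(clus.accuracy_ci),
        "per_class": clus.per_class,
        "per_class_auc": roc.per_class_auc,
        "macro_auc": roc.macro_auc,
        "cluster_quality": clus.quality,
        "tumor_hgi_median": float(hgi_summary.median) if hgi_summary else None,
        "inter_group_distance": {f"{a}-{b}": v for (a, b), v in dend.inter_group_distance.items()},
        "intra_group": dend.intra_group,
        "source_composition_pct": {
            f"source_{k+1}": dict(zip(cohort.basis.names, composition[k].round(2)))
            for k in range(config.rank)
        },
        "feature_importance": importance.tolist(),
        "gnmu": {"rank": sources.r, "residual": sources.residual,
                 "iterations": sources.iterations_run, "mode": config.gnmu_mode,
                 "seed": config.seed},
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2, default=float))
    checksums["metrics.json"] = _sha256(outdir / "metrics.json")

    manifest = RunManifest(
        version=__version__, config_hash=_config_hash(config), seed=config.seed,
        stages=stages, checksums=checksums,
    )
    (outdir / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2, default=str)
    )
    return manifest
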