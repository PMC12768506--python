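"""Metabolic index computation and tumor/healthy region assignment.

Two ratios drive voxel selection:

* ``HGI = (2HG + Gln) / Glu`` — elevated by IDH-mutant metabolism; tumor
  voxels of mIDH patients are those with HGI strictly above 1.5.
* ``CNR = tCho / tNAA`` — elevated in glioma regardless of IDH status;
  tumor voxels of wt-IDH patients are those with CNR strictly above 0.4.

The tumor rule is subtype-conditional: HGI gates mIDH patients, CNR gates
wt-IDH patients. A literal conjunction of both indices for every patient
(``rule="both"``) is available but would exclude wt-IDH tumors, whose HGI
is low.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IndexThresholds",
    "IndexSummary",
    "compute_hgi",
    "compute_cnr",
    "assign_regions",
    "summarize_index",
]


@dataclass
class IndexThresholds:
    hgi_min: float = 1.5
    cnr_min: float = 0.4
    eps: float = 1e-9  # guard against zero denominators

    def __post_init__(self) -> None:
        if self.hgi_min <= 0 or self.cnr_min <= 0 or self.eps <= 0:
            raise ValueError("index thresholds and eps must be strictly positive")


@dataclass
class IndexSummary:
    median: float
    iqr: tuple[float, float]
    frac_above_threshold: float
    histogram: tuple[np.ndarray, np.ndarray]  # (bin_edges, counts)


def _col(conc, name: str):
    try:
        return conc[name]
    except (KeyError, IndexError) as exc:
        raise KeyError(f"missing metabolite column {name!r}") from exc


def compute_hgi(conc, eps: float = 1e-9):
    """(2HG + Gln) / Glu with an eps guard on the denominator.

    Accepts a mapping, Series or DataFrame with columns ``2HG``, ``Gln``,
    ``Glu``. Zero-Glu voxels produce a large, non-physiological ratio and
    are logged.
    """
    hg, gln, glu = (np.asarray(_col(conc, m), dtype=float) for m in ("2HG", "Gln", "Glu"))
    n_zero = int(np.sum(glu < eps))
    if n_zero:
        logger.warning("%d voxel(s) with Glu < eps; HGI guarded by eps", n_zero)
    out = (hg + gln) / np.maximum(glu, eps)
    return float(out) if out.ndim == 0 else out


def compute_cnr(conc, eps: float = 1e-9):
    """total-choline / total-NAA with an eps guard on the denominator."""
    cho, naa = (np.asarray(_col(conc, m), dtype=float) for m in ("Cho", "NAA"))
    n_zero = int(np.sum(naa < eps))
    if n_zero:
        logger.warning("%d voxel(s) with NAA < eps; CNR guarded by eps", n_zero)
    out = cho / np.maximum(naa, eps)
    return float(out) if out.ndim == 0 else out


def assign_regions(
    table: pd.DataFrame,
    thresholds: IndexThresholds | None = None,
    idh_status: dict[str, str] | None = None,
    rule: str = "subtype",
    healthy_definition: str = "contralateral",
) -> pd.DataFrame:
    """Label qc_pass voxels as tumor / healthy / unassigned.

    For mIDH patients tumor means HGI > hgi_min; for wt-IDH patients tumor
    means CNR > cnr_min (both strict). With ``rule="both"`` every patient
    needs both indices above threshold. Healthy voxels are non-tumor
    qc_pass voxels in the contralateral hemisphere (i-index above the grid
    midline) by default, or all non-tumor qc_pass voxels with
    ``healthy_definition="all"``. Remaining qc_pass voxels stay unassigned.

    ``idh_status`` maps patient_id to ``"mutant"``/``"wildtype"``; if absent,
    an ``idh_status`` column in the table is used.
    """
    thresholds = thresholds or IndexThresholds()
    if "qc_pass" not in table.columns:
        raise KeyError("run apply_qc before assign_regions (qc_pass column missing)")
    out = table.copy()
    out["hgi"] = compute_hgi(out, eps=thresholds.eps)
    out["cnr"] = compute_cnr(out, eps=thresholds.eps)

    if idh_status is None:
        if "idh_status" not in out.columns:
            raise KeyError("idh_status must be given as a mapping or table column")
        status = out["idh_status"]
    else:
        status = out["patient_id"].map(idh_status)
    known = status.isin(["mutant", "wildtype"])
    if not known.all():
        bad = sorted(out.loc[~known, "patient_id"].unique())
        raise ValueError(f"unknown IDH status for patient(s): {bad}")

    hgi_hit = out["hgi"] > thresholds.hgi_min
    cnr_hit = out["cnr"] > thresholds.cnr_min
    if rule == "subtype":
        tumor = np.where(status == "mutant", hgi_hit, cnr_hit)
    elif rule == "both":
        tumor = (hgi_hit & cnr_hit).to_numpy()
    else:
        raise ValueError(f"unknown rule {rule!r}; expected 'subtype' or 'both'")

    qc = out["qc_pass"].to_numpy(dtype=bool)
    tumor &= qc
    if healthy_definition == "contralateral":
        mid = (out["i"].max() + out["i"].min()) / 2.0
        contra = (out["i"] > mid).to_numpy()
        healthy = qc & ~tumor & contra
    elif healthy_definition == "all":
        healthy = qc & ~tumor
    else:
        raise ValueError(f"unknown healthy_definition {healthy_definition!r}")

    region = np.where(qc, "unassigned", "excluded").astype(object)
    region[tumor] = "tumor"
    region[healthy] = "healthy"
    out["region"] = region
    return out


def summarize_index(values, threshold: float, n_bins: int = 30) -> IndexSummary:
    """Median, IQR (linear-interpolation quantiles), exceedance fraction, histogram."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty set of index values")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # type-7 interpolation
    frac = float(np.mean(values > threshold))
    counts, edges = np.histogram(values, bins=n_bins)
    return IndexSummary(
        median=float(med), iqr=(float(q1), float(q3)),
        frac_above_threshold=frac, histogram=(edges, counts),
    )
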