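"""Voxel-level spectral quality control.

Reliable voxels are selected with the standard spectral-fitting criteria:
FWHM strictly below 0.15 ppm, SNR strictly above 3 and every considered
CRLB strictly below 20%. A separate artifact rule flags spectra whose
baseline region rises more than k standard deviations above its own mean
(default k = 2.5); mean and SD are taken per voxel over a signal-free
baseline window, using the sample (n-1) standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["QCThresholds", "apply_qc", "flag_artifacts", "DEFAULT_CRLB_METABOLITES"]

#: CRLB rule scope: metabolites entering the HGI/CNR indices. Restricting the
#: rule to these avoids excluding voxels over irrelevant minor metabolites.
DEFAULT_CRLB_METABOLITES = ("2HG", "Gln", "Glu", "Cho", "NAA")


@dataclass
class QCThresholds:
    """Spectral-quality thresholds. All comparisons are strict inequalities."""

    fwhm_max: float = 0.15  # ppm
    snr_min: float = 3.0
    crlb_max: float = 20.0  # percent
    artifact_k: float = 2.5  # multiples of sigma for the baseline artifact rule
    crlb_metabolites: tuple[str, ...] = field(default=DEFAULT_CRLB_METABOLITES)

    def __post_init__(self) -> None:
        if min(self.fwhm_max, self.snr_min, self.crlb_max, self.artifact_k) <= 0:
            raise ValueError("all QC thresholds must be strictly positive")


def apply_qc(table: pd.DataFrame, thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Mark voxels passing QC; failing voxels get ``region='excluded'``.

    ``qc_pass`` is FWHM < fwhm_max AND SNR > snr_min AND every considered
    CRLB < crlb_max. Row order is preserved and the operation is idempotent.
    """
    thresholds = thresholds or QCThresholds()
    for col in ("fwhm", "snr"):
        if col not in table.columns:
            raise KeyError(f"voxel table is missing required QC column {col!r}")
    crlb_cols = []
    for m in thresholds.crlb_metabolites:
        col = f"crlb_{m}"
        if col not in table.columns:
            raise KeyError(f"voxel table is missing required QC column {col!r}")
        crlb_cols.append(col)

    out = table.copy()
    if len(out) == 0:
        out["qc_pass"] = pd.Series(dtype=bool)
        return out
    ok = (out["fwhm"] < thresholds.fwhm_max) & (out["snr"] > thresholds.snr_min)
    for col in crlb_cols:
        ok &= out[col] < thresholds.crlb_max
    out["qc_pass"] = ok.to_numpy()
    if "region" in out.columns:
        out.loc[~ok, "region"] = "excluded"
    else:
        out["region"] = np.where(ok, "unassigned", "excluded")
    return out


def flag_artifacts(
    spectra: np.ndarray,
    ppm_axis: np.ndarray,
    baseline_region: tuple[float, float] = (0.0, 0.5),
    k: float = 2.5,
) -> np.ndarray:
    """Flag voxels whose baseline peaks above mu + k*sigma.

    For each voxel, mu and sigma (sample SD, ddof=1) are computed over the
    spectral points inside ``baseline_region``; the voxel is flagged iff the
    maximum over that window strictly exceeds ``mu + k * sigma``. A flat
    window (sigma = 0) is never flagged.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    ppm_axis = np.asarray(ppm_axis, dtype=float)
    lo, hi = min(baseline_region), max(baseline_region)
    mask = (ppm_axis >= lo) & (ppm_axis <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"baseline region {baseline_region} covers fewer than 2 spectral points"
        )
    window = spectra[:, mask]
    mu = window.mean(axis=1)
    sigma = window.std(axis=1, ddof=1)
    return window.max(axis=1) > mu + k * sigma
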