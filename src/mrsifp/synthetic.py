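"""Synthetic multi-patient MRSI cohort generator.

Emulates the statistical structure of a small whole-brain MRSI glioma
cohort: a 3D voxel grid with a tumor region in one hemisphere and healthy
tissue in the contralateral hemisphere, subtype-specific metabolite
concentration profiles (IDH-mutant astrocytoma AC, IDH-mutant
oligodendroglioma OG, IDH-wildtype glioblastoma GBM, plus HEALTHY tissue),
Lorentzian line spectra on a ppm axis with additive Gaussian noise, and
per-voxel spectral-fitting QC metadata (FWHM, SNR, per-metabolite CRLB).

The defaults reproduce the cohort shape the analysis was designed for:
12 patients (5 AC, 5 OG, 2 GBM), tumor voxel counts drawn from 4-81 and
healthy voxel counts from 23-266 per patient.

Nothing here simulates acquisition physics — no k-space, field
inhomogeneity, water/lipid artifacts or super-resolution reconstruction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import MetaboliteBasis, default_basis

logger = logging.getLogger(__name__)

__all__ = [
    "SubtypeProfile",
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "default_profiles",
    "simulate_cohort",
    "planted_sources_cohort",
    "write_cohort",
]

SUBTYPES = ("AC", "OG", "GBM")
#: QC sampling ranges: passing voxels fall inside, injected failures outside,
#: relative to the standard thresholds (FWHM < 0.15 ppm, SNR > 3, CRLB < 20%).
_PASS_FWHM = (0.05, 0.12)
_PASS_SNR = (5.0, 30.0)
_PASS_CRLB = (2.0, 15.0)
_FAIL_FWHM = (0.16, 0.30)
_FAIL_SNR = (0.5, 2.9)
_FAIL_CRLB = (21.0, 50.0)


@dataclass
class SubtypeProfile:
    """Mean metabolite concentrations (institutional units) for one tissue class."""

    subtype: str
    mean_concentrations: dict[str, float]
    cv: dict[str, float]
    idh_status: str  # "mutant" | "wildtype" | "none" (healthy)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.mean_concentrations.values()):
            raise ValueError("mean concentrations must be non-negative")
        if any(v < 0 for v in self.cv.values()):
            raise ValueError("coefficients of variation must be non-negative")


@dataclass
class SyntheticCohortConfig:
    """Cohort-level simulation parameters.

    Defaults emulate the 12-patient study cohort: 5 AC, 5 OG, 2 GBM with
    per-patient tumor voxel counts in 4-81 and healthy counts in 23-266.
    """

    n_patients_per_subtype: dict[str, int] = field(
        default_factory=lambda: {"AC": 5, "OG": 5, "GBM": 2}
    )
    tumor_voxels_per_patient: tuple[int, int] = (4, 81)
    healthy_voxels_per_patient: tuple[int, int] = (23, 266)
    noise_sd: float = 0.15
    conc_error_cv: float = 0.05  # multiplicative error on reported concentrations
    qc_fail_fraction: float = 0.10
    seed: int = 0
    grid_shape: tuple[int, int, int] = (30, 30, 16)

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_patients_per_subtype.values()):
            raise ValueError("patient counts must be >= 1")
        for lo, hi in (self.tumor_voxels_per_patient, self.healthy_voxels_per_patient):
            if lo < 1 or hi < lo:
                raise ValueError("voxel count ranges must satisfy 1 <= lo <= hi")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.qc_fail_fraction < 1:
            raise ValueError("qc_fail_fraction must lie in [0, 1)")


@dataclass
class SyntheticCohort:
    """Generated cohort: voxel table, spectra and the generating ground truth."""

    voxel_table: pd.DataFrame
    spectra: np.ndarray  # n_voxels x n_points, non-negative
    ppm_axis: np.ndarray
    ground_truth: pd.DataFrame  # true concentrations, true region, subtype
    basis: MetaboliteBasis
    clip_fraction: float  # fraction of spectral samples clipped at zero

    def __post_init__(self) -> None:
        assert self.spectra.shape[0] == len(self.voxel_table)


def default_profiles() -> dict[str, SubtypeProfile]:
    """Subtype concentration profiles with the expected contrasts.

    AC/OG (IDH-mutant) carry substantial 2HG; GBM (wildtype) essentially
    none. All tumors have elevated choline and depleted NAA relative to
    healthy tissue; AC is myo-inositol-rich while OG is serine-rich, giving
    the two mIDH subtypes a multivariate (not single-metabolite) contrast.
    Units are arbitrary institutional units on the same scale as the basis.
    """
    tumor_cv = 0.20
    healthy_cv = 0.12
    mk = lambda d, cv: ({m: float(v) for m, v in d.items()}, {m: cv for m in d})

    ac_mean, ac_cv = mk(
        {"NAA": 5.0, "Cr": 7.0, "Cho": 3.5, "mI": 7.5, "Glu": 4.0,
         "Gln": 5.0, "2HG": 4.0, "Ser": 1.5, "Lac": 2.5}, tumor_cv)
    og_mean, og_cv = mk(
        {"NAA": 5.5, "Cr": 7.0, "Cho": 3.8, "mI": 4.0, "Glu": 4.5,
         "Gln": 5.5, "2HG": 3.0, "Ser": 4.5, "Lac": 2.0}, tumor_cv)
    gbm_mean, gbm_cv = mk(
        {"NAA": 3.5, "Cr": 6.0, "Cho": 5.0, "mI": 3.0, "Glu": 6.5,
         "Gln": 4.5, "2HG": 0.01, "Ser": 2.5, "Lac": 4.0}, tumor_cv)
    healthy_mean, healthy_cv_ = mk(
        {"NAA": 12.0, "Cr": 8.0, "Cho": 1.8, "mI": 5.0, "Glu": 9.0,
         "Gln": 3.5, "2HG": 0.01, "Ser": 1.0, "Lac": 0.8}, healthy_cv)

    return {
        "AC": SubtypeProfile("AC", ac_mean, ac_cv, "mutant"),
        "OG": SubtypeProfile("OG", og_mean, og_cv, "mutant"),
        "GBM": SubtypeProfile("GBM", gbm_mean, gbm_cv, "wildtype"),
        "HEALTHY": SubtypeProfile("HEALTHY", healthy_mean, healthy_cv_, "none"),
    }


def _lognormal(rng: np.random.Generator, mean: np.ndarray, cv: np.ndarray) -> np.ndarray:
    """Log-normal samples with the requested arithmetic mean and CV."""
    mean = np.asarray(mean, dtype=float)
    cv = np.asarray(cv, dtype=float)
    out = np.zeros_like(mean)
    pos = mean > 0
    sigma2 = np.log1p(cv[pos] ** 2)
    mu = np.log(mean[pos]) - sigma2 / 2.0
    out[pos] = rng.lognormal(mu, np.sqrt(sigma2))
    return out


def _sample_qc(rng: np.random.Generator, n: int, n_met: int, fail_fraction: float):
    """FWHM/SNR/CRLB metrics with ~fail_fraction of voxels violating one rule."""
    fwhm = rng.uniform(*_PASS_FWHM, size=n)
    snr = rng.uniform(*_PASS_SNR, size=n)
    crlb = rng.uniform(*_PASS_CRLB, size=(n, n_met))
    fail = rng.random(n) < fail_fraction
    which = rng.integers(0, 3, size=n)  # which rule a failing voxel violates
    for idx in np.nonzero(fail)[0]:
        if which[idx] == 0:
            fwhm[idx] = rng.uniform(*_FAIL_FWHM)
        elif which[idx] == 1:
            snr[idx] = rng.uniform(*_FAIL_SNR)
        else:
            crlb[idx, rng.integers(0, n_met)] = rng.uniform(*_FAIL_CRLB)
    return fwhm, snr, crlb


def simulate_cohort(
    config: SyntheticCohortConfig | None = None,
    basis: MetaboliteBasis | None = None,
    profiles: dict[str, SubtypeProfile] | None = None,
) -> SyntheticCohort:
    """Simulate a full multi-patient MRSI cohort.

    Each voxel's spectrum is the non-negative mixture
    ``sum_m conc_m * basis_m`` plus additive Gaussian noise, rectified at
    zero. Reported per-voxel concentrations are the true concentrations
    perturbed by multiplicative log-normal error, mimicking spectral-fitting
    estimates. QC metrics are drawn so that ~``qc_fail_fraction`` of voxels
    violate at least one QC rule. Deterministic given ``config.seed``.
    """
    config = config or SyntheticCohortConfig()
    basis = basis or default_basis()
    profiles = profiles or default_profiles()
    needed = set(SUBTYPES) | {"HEALTHY"}
    missing = needed - set(profiles)
    if missing:
        raise KeyError(f"missing subtype profiles: {sorted(missing)}")

    rng = np.random.default_rng(config.seed)
    mets = basis.names
    n_met = len(mets)
    ni, nj, nk = config.grid_shape
    mid = ni // 2

    rows, truth_rows, spectra = [], [], []
    healthy = profiles["HEALTHY"]
    pid = 0
    for subtype in SUBTYPES:
        for _ in range(config.n_patients_per_subtype[subtype]):
            pid += 1
            patient = f"P{pid:02d}"
            prof = profiles[subtype]
            n_tum = int(rng.integers(config.tumor_voxels_per_patient[0],
                                     config.tumor_voxels_per_patient[1] + 1))
            n_heal = int(rng.integers(config.healthy_voxels_per_patient[0],
                                      config.healthy_voxels_per_patient[1] + 1))
            # tumor blob in the left hemisphere, healthy in the contralateral one
            ti = rng.integers(0, mid - 1, size=n_tum)
            hi = rng.integers(mid + 1, ni, size=n_heal)
            jj = rng.integers(0, nj, size=n_tum + n_heal)
            kk = rng.integers(0, nk, size=n_tum + n_heal)
            ii = np.concatenate([ti, hi])
            true_region = ["tumor"] * n_tum + ["healthy"] * n_heal

            n_vox = n_tum + n_heal
            mean = np.stack(
                [np.array([prof.mean_concentrations[m] for m in mets])] * n_tum
                + [np.array([healthy.mean_concentrations[m] for m in mets])] * n_heal
            )
            cv = np.stack(
                [np.array([prof.cv[m] for m in mets])] * n_tum
                + [np.array([healthy.cv[m] for m in mets])] * n_heal
            )
            conc_true = _lognormal(rng, mean, cv)
            clean = conc_true @ basis.spectra.T
            if config.noise_sd > 0:
                noisy = clean + rng.normal(0.0, config.noise_sd, size=clean.shape)
            else:
                noisy = clean.copy()
            spec = np.maximum(noisy, 0.0)
            spectra.append((spec, noisy))

            if config.conc_error_cv > 0:
                err = _lognormal(rng, np.ones_like(conc_true),
                                 np.full_like(conc_true, config.conc_error_cv))
            else:
                err = np.ones_like(conc_true)
            conc_est = conc_true * err
            fwhm, snr, crlb = _sample_qc(rng, n_vox, n_met, config.qc_fail_fraction)

            for v in range(n_vox):
                row = {"patient_id": patient, "subtype": subtype,
                       "idh_status": prof.idh_status,
                       "i": int(ii[v]), "j": int(jj[v]), "k": int(kk[v]),
                       "region": "unassigned",
                       "fwhm": fwhm[v], "snr": snr[v]}
                for m_idx, m in enumerate(mets):
                    row[m] = conc_est[v, m_idx]
                for m_idx, m in enumerate(mets):
                    row[f"crlb_{m}"] = crlb[v, m_idx]
                rows.append(row)
                truth = {"patient_id": patient, "subtype": subtype,
                         "true_region": true_region[v]}
                for m_idx, m in enumerate(mets):
                    truth[f"true_{m}"] = conc_true[v, m_idx]
                truth_rows.append(truth)

    table = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    all_noisy = np.vstack([n for _, n in spectra])
    all_spec = np.vstack([s for s, _ in spectra])
    clip_fraction = float(np.mean(all_noisy < 0))
    if clip_fraction > 0:
        logger.info("rectified %.2f%% of spectral samples to zero", 100 * clip_fraction)
    return SyntheticCohort(
        voxel_table=table, spectra=all_spec, ppm_axis=basis.ppm_axis,
        ground_truth=truth, basis=basis, clip_fraction=clip_fraction,
    )


def planted_sources_cohort(
    W_true: np.ndarray,
    H_density: float = 0.3,
    n_voxels: int = 500,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted-factor test instance for source-recovery checks.

    Returns ``(X, W_true, H_true)`` with ``X = W_true @ H_true + noise``
    rectified at zero. ``H_true`` is non-negative with each entry active
    independently with probability ``H_density``; every voxel keeps at
    least one active source so no column of X is all-zero.
    """
    W_true = np.asarray(W_true, dtype=float)
    if np.any(W_true < 0):
        raise ValueError("W_true must be non-negative")
    if not 0 < H_density <= 1:
        raise ValueError("H_density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    r = W_true.shape[1]
    active = rng.random((r, n_voxels)) < H_density
    dead = ~active.any(axis=0)
    active[rng.integers(0, r, size=int(dead.sum())), np.nonzero(dead)[0]] = True
    H_true = active * rng.gamma(2.0, 1.0, size=(r, n_voxels))
    X = W_true @ H_true
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    X = np.maximum(X, 0.0)
    return X, W_true, H_true


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort to disk as plain interchange files.

    Produces: ``voxels.tsv`` (the voxel table), ``spectra.tsv`` (dense
    voxels x points matrix), ``spectra_axis.json`` (ppm axis sidecar),
    ``ground_truth.tsv``, and one NIfTI metabolite map per patient per
    metabolite under ``maps/``.
    """
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["voxels"] = outdir / "voxels.tsv"
    cohort.voxel_table.to_csv(paths["voxels"], sep="\t", index=False)
    paths["ground_truth"] = outdir / "ground_truth.tsv"
    cohort.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    paths["spectra"] = outdir / "spectra.tsv"
    np.savetxt(paths["spectra"], cohort.spectra, delimiter="\t", fmt="%.6g")
    paths["axis"] = outdir / "spectra_axis.json"
    paths["axis"].write_text(json.dumps({"ppm_axis": cohort.ppm_axis.tolist()}))

    maps_dir = outdir / "maps"
    maps_dir.mkdir(exist_ok=True)
    table = cohort.voxel_table
    shape = (int(table["i"].max()) + 1, int(table["j"].max()) + 1,
             int(table["k"].max()) + 1)
    # isotropic 7.3 mm voxels, matching the nominal MRSI resolution
    affine = np.diag([7.3, 7.3, 7.3, 1.0])
    for patient, sub in table.groupby("patient_id"):
        for m in cohort.basis.names:
            vol = np.zeros(shape, dtype=np.float32)
            vol[sub["i"], sub["j"], sub["k"]] = sub[m]
            img = nib.Nifti1Image(vol, affine)
            nib.save(img, maps_dir / f"{patient}_{m}.nii")
    paths["maps"] = maps_dir
    return paths
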