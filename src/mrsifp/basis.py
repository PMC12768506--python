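"""Metabolite basis spectra on a ppm axis.

A :class:`MetaboliteBasis` holds idealized 1H resonance line models for the
metabolites that dominate brain MR spectra at 3 T. Each metabolite is a sum
of one-to-few Lorentzian lines at canonical chemical shifts; full J-coupling
multiplet structure is deliberately not modelled — downstream decomposition
and unmixing only require realistic spectral overlap, not quantum-mechanical
lineshape fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MetaboliteBasis", "default_basis", "lorentzian", "DEFAULT_LINES"]

#: Canonical chemical shifts (ppm) and relative line amplitudes per metabolite.
#: Shifts are standard literature values for in-vivo brain 1H MRS.
DEFAULT_LINES: dict[str, list[tuple[float, float]]] = {
    "NAA": [(2.01, 1.0)],
    "Cr": [(3.03, 1.0), (3.93, 0.7)],
    "Cho": [(3.20, 1.0)],
    "mI": [(3.56, 1.0)],
    "Glu": [(2.35, 1.0), (3.75, 0.6)],
    "Gln": [(2.45, 1.0), (3.77, 0.6)],
    "2HG": [(2.25, 1.0), (4.02, 0.5)],
    "Ser": [(3.83, 1.0), (3.96, 0.8)],
    "Lac": [(1.31, 1.0)],
}


def lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-peak Lorentzian line: value 1 at ``center``, half max at ±fwhm/2."""
    gamma = fwhm / 2.0
    return gamma**2 / ((x - center) ** 2 + gamma**2)


@dataclass
class MetaboliteBasis:
    """Set of non-negative metabolite basis spectra on a common ppm grid.

    Attributes
    ----------
    names:
        Metabolite labels, one per basis spectrum.
    peak_positions:
        Per metabolite, the ppm position of each resonance line.
    peak_amplitudes:
        Per metabolite, the relative intensity of each line (>= 0).
    linewidth:
        FWHM (ppm) shared by all Lorentzian lines.
    ppm_axis:
        Strictly monotone ppm grid the spectra are evaluated on.
    """

    names: list[str]
    peak_positions: dict[str, list[float]]
    peak_amplitudes: dict[str, list[float]]
    linewidth: float
    ppm_axis: np.ndarray
    spectra: np.ndarray = field(init=False)  # n_points x n_metabolites

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm_axis, dtype=float)
        if ppm.ndim != 1 or ppm.size < 2:
            raise ValueError("ppm_axis must be a 1-D grid with at least 2 points")
        d = np.diff(ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm_axis must be strictly monotone")
        if self.linewidth <= 0:
            raise ValueError("linewidth must be positive")
        for name in self.names:
            if len(self.peak_positions.get(name, [])) < 1:
                raise ValueError(f"metabolite {name!r} has no resonance lines")
            if any(a < 0 for a in self.peak_amplitudes[name]):
                raise ValueError(f"negative amplitude for metabolite {name!r}")
        self.ppm_axis = ppm
        cols = []
        for name in self.names:
            s = np.zeros_like(ppm)
            for pos, amp in zip(self.peak_positions[name], self.peak_amplitudes[name]):
                s += amp * lorentzian(ppm, pos, self.linewidth)
            peak = s.max()
            if peak > 0:
                s = s / peak  # unit maximum
            cols.append(s)
        self.spectra = np.column_stack(cols)

    @property
    def n_points(self) -> int:
        return self.ppm_axis.size

    def spectrum(self, name: str) -> np.ndarray:
        """Basis spectrum for one metabolite (unit maximum)."""
        return self.spectra[:, self.names.index(name)]

    def integrals(self) -> np.ndarray:
        """Trapezoidal integral of each basis spectrum over the ppm axis."""
        ppm = self.ppm_axis
        if ppm[1] < ppm[0]:
            ppm, spec = ppm[::-1], self.spectra[::-1]
        else:
            spec = self.spectra
        return np.trapezoid(spec, ppm, axis=0)


def default_basis(
    ppm_min: float = 0.5,
    ppm_max: float = 4.2,
    n_points: int = 512,
    linewidth: float = 0.04,
) -> MetaboliteBasis:
    """Nine-metabolite basis (NAA, Cr, Cho, mI, Glu, Gln, 2HG, Ser, Lac).

    Parameters
    ----------
    ppm_min, ppm_max:
        Extent of the ppm grid (stored ascending; display reversal is a
        plotting concern).
    n_points:
        Grid size; must be at least 2 (>= 64 recommended so lines are
        resolved).
    linewidth:
        FWHM in ppm of every Lorentzian line.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    if not ppm_min < ppm_max:
        raise ValueError("ppm_min must be < ppm_max")
    ppm = np.linspace(ppm_min, ppm_max, n_points)
    names = list(DEFAULT_LINES)
    positions = {m: [p for p, _ in lines] for m, lines in DEFAULT_LINES.items()}
    amplitudes = {m: [a for _, a in lines] for m, lines in DEFAULT_LINES.items()}
    return MetaboliteBasis(
        names=names,
        peak_positions=positions,
        peak_amplitudes=amplitudes,
        linewidth=linewidth,
        ppm_axis=ppm,
    )
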