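"""Dataset container, reference-band normalization, and rank estimation.

Raman time-course datasets are held as an N x J intensity matrix (N spectra
at increasing inoculation times, J wavenumber channels).  Rows are put on a
common intensity scale by dividing each spectrum by the baseline-corrected
area of its phenylalanine band near 1005 cm^-1, the usual internal standard
for cellular Raman spectra: the band is integrated over 988-1023 cm^-1 above
a straight baseline fitted through the 986-990 and 1021-1025 cm^-1 anchor
regions.

The number of bilinear components is chosen from the singular-value spectrum
(:func:`estimate_rank` reports, the user selects), and initial concentration
profiles for the alternating least-squares loop come from integrating the
kinetic model at the user's starting rate constants
(:func:`initial_concentrations`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._exceptions import DegenerateBandError
from .kinetics import KineticModel, KineticParams, solve_kinetics

__all__ = [
    "SpectraDataset",
    "NormalizationSpec",
    "phenylalanine_area",
    "normalize_dataset",
    "estimate_rank",
    "RankEstimate",
    "initial_concentrations",
]

_WINDOW_TOL = 1e-9


@dataclass(frozen=True)
class SpectraDataset:
    """N x J matrix of spectra with a time axis (h) and wavenumber axis (cm^-1)."""

    intensities: np.ndarray
    times: np.ndarray
    wavenumbers: np.ndarray
    meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        intens = np.asarray(self.intensities, dtype=float)
        times = np.asarray(self.times, dtype=float)
        wn = np.asarray(self.wavenumbers, dtype=float)
        object.__setattr__(self, "intensities", intens)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "wavenumbers", wn)
        if intens.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        n, j = intens.shape
        if n < 2 or j < 2:
            raise ValueError("dataset needs at least 2 spectra and 2 channels")
        if times.shape != (n,):
            raise ValueError(f"times has shape {times.shape}, expected ({n},)")
        if wn.shape != (j,):
            raise ValueError(f"wavenumbers has shape {wn.shape}, expected ({j},)")
        if not np.all(np.isfinite(intens)):
            raise ValueError("intensities contain NaN/Inf")
        if np.any(np.diff(times) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any(np.diff(wn) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def with_intensities(self, intensities: np.ndarray) -> "SpectraDataset":
        return replace(self, intensities=intensities)


@dataclass(frozen=True)
class NormalizationSpec:
    """Integration window and baseline anchor windows for the reference band.

    Defaults target the phenylalanine ring-breathing band: integrate
    988-1023 cm^-1 above a least-squares line through all grid points in the
    986-990 and 1021-1025 cm^-1 anchor windows.  Window membership uses
    closed intervals with a 1e-9 cm^-1 tolerance.
    """

    band_lo: float = 988.0
    band_hi: float = 1023.0
    base_lo_window: tuple[float, float] = (986.0, 990.0)
    base_hi_window: tuple[float, float] = (1021.0, 1025.0)

    def __post_init__(self):
        if self.band_lo >= self.band_hi:
            raise ValueError("band_lo must be < band_hi")
        for lo, hi in (self.base_lo_window, self.base_hi_window):
            if lo >= hi:
                raise ValueError("baseline anchor windows must have lo < hi")


def _in_window(wavenumbers: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (wavenumbers >= lo - _WINDOW_TOL) & (wavenumbers <= hi + _WINDOW_TOL)


def phenylalanine_area(
    spectrum: np.ndarray,
    wavenumbers: np.ndarray,
    spec: NormalizationSpec | None = None,
) -> float:
    """Baseline-corrected trapezoidal area of the reference band (a.u. cm^-1).

    The baseline is one straight line fitted by least squares through every
    grid point in the two anchor windows jointly; the area is the trapezoid
    integral of (spectrum - baseline) over the band window on the native
    grid.  Raises :class:`DegenerateBandError` if the area is <= 0 (no band).
    """
    spec = spec or NormalizationSpec()
    s = np.asarray(spectrum, dtype=float)
    wn = np.asarray(wavenumbers, dtype=float)
    anchor = _in_window(wn, *spec.base_lo_window) | _in_window(wn, *spec.base_hi_window)
    if not np.any(_in_window(wn, *spec.base_lo_window)) or not np.any(
        _in_window(wn, *spec.base_hi_window)
    ):
        raise ValueError("each baseline anchor window must contain >= 1 grid point")
    band = _in_window(wn, spec.band_lo, spec.band_hi)
    if np.count_nonzero(band) < 2:
        raise ValueError("band window must contain >= 2 grid points")
    coeffs = np.polynomial.polynomial.polyfit(wn[anchor], s[anchor], 1)
    baseline = np.polynomial.polynomial.polyval(wn[band], coeffs)
    area = float(np.trapezoid(s[band] - baseline, wn[band]))
    if area <= 0:
        raise DegenerateBandError(
            f"reference band area is {area:.3g} <= 0; spectrum lacks the band"
        )
    return area


def normalize_dataset(
    ds: SpectraDataset, spec: NormalizationSpec | None = None
) -> SpectraDataset:
    """Divide each spectrum by its own reference-band area.

    After normalization every row's band area is 1 (idempotent, and invariant
    to per-row scaling of the input).  A spectrum with non-positive band area
    raises :class:`DegenerateBandError` naming the row.
    """
    spec = spec or NormalizationSpec()
    out = np.empty_like(ds.intensities)
    for i in range(ds.n_spectra):
        try:
            area = phenylalanine_area(ds.intensities[i], ds.wavenumbers, spec)
        except DegenerateBandError as e:
            raise DegenerateBandError(f"row {i} (t={ds.times[i]:g} h): {e}") from e
        out[i] = ds.intensities[i] / area
    return ds.with_intensities(out)


@dataclass(frozen=True)
class RankEstimate:
    """Full singular spectrum with per-component explained variance.

    Rank selection itself is left to the user; this only reports the
    evidence (singular values, variance fractions, cumulative fractions).
    """

    singular_values: np.ndarray
    variance_fractions: np.ndarray
    cumulative_variance: np.ndarray

    def n_above(self, rel_threshold: float = 1e-10) -> int:
        """Number of singular values above rel_threshold * sigma_1."""
        if self.singular_values.size == 0 or self.singular_values[0] == 0:
            return 0
        return int(np.sum(self.singular_values > rel_threshold * self.singular_values[0]))


def estimate_rank(ds: SpectraDataset | np.ndarray) -> RankEstimate:
    """Singular value decomposition evidence for choosing the component count."""
    mat = ds.intensities if isinstance(ds, SpectraDataset) else np.asarray(ds, float)
    s = np.linalg.svd(mat, compute_uv=False)
    total = float(np.sum(s**2))
    frac = s**2 / total if total > 0 else np.zeros_like(s)
    return RankEstimate(s, frac, np.cumsum(frac))


def initial_concentrations(
    model: KineticModel,
    k0: "KineticParams | Mapping[str, float]",
    times: Sequence[float],
    n_components: int,
    constrained_indices: Sequence[int] | None = None,
) -> np.ndarray:
    """Initial concentration matrix C0 for the alternating least-squares loop.

    Kinetically constrained columns hold the ODE solution at the starting
    constants ``k0``; unconstrained columns start as a constant 1.0 (the
    least-informative profile consistent with a time-invariant background
    component).
    """
    idx = tuple(constrained_indices) if constrained_indices is not None else model.component_map
    if len(set(idx)) != len(idx):
        raise ValueError("constrained_indices must be distinct")
    if any(i < 0 or i >= n_components for i in idx):
        raise ValueError("constrained_indices out of range")
    if len(idx) != model.n_states:
        raise ValueError("need one component index per model state")
    t = np.asarray(times, dtype=float)
    c0 = np.ones((t.size, n_components))
    profiles = solve_kinetics(model, k0, t)
    for state, comp in enumerate(idx):
        c0[:, comp] = profiles.values[:, state]
    return c0
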