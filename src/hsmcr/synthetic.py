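"""Synthetic time-course Raman datasets with ODE-driven mixing.

Emulates the inoculation of adherent lung cells with doxorubicin (DOX) as
seen by confocal Raman microspectroscopy:

* a constant baseline **cell spectrum** (phenylalanine 1005, amide III/I,
  CH2 deformation, nucleic-acid bands, ...);
* a **drug-binding signature** combining the DOX bands (440, 460 and
  1211 cm^-1, positive) with the intercalation-induced *loss* of the
  RNA/DNA bands at 785 and 811 cm^-1 (negative entries, so the bilinear
  product subtracts them from the cell background);
* a slower **cellular-response signature** centred on the protein
  CH2-deformation band at 1450 cm^-1.

Concentration dynamics follow the saturating uptake/response ODE pair, on a
0-72 h grid at 0.5 h steps (145 spectra) by default, with 1% additive
uniform noise.  Pure spectra are synthesized as sums of Gaussian bands
(default FWHM 10 cm^-1) on a 400-1800 cm^-1 axis at 2 cm^-1 spacing, since
only band positions — not full lineshapes — are prescribed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._exceptions import ClippingWarning
from .kinetics import KineticParams, get_model, solve_kinetics
from .preprocessing import SpectraDataset

__all__ = [
    "ComponentLibrary",
    "SimulationConfig",
    "SimulationResult",
    "default_library",
    "simulate_dataset",
    "add_noise",
    "gaussian_bands",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_bands(
    wavenumbers: np.ndarray,
    bands: list[tuple[float, float, float]],
    offset: float = 0.0,
) -> np.ndarray:
    """Sum of Gaussian bands given as (center cm^-1, height a.u., FWHM cm^-1)."""
    wn = np.asarray(wavenumbers, dtype=float)
    out = np.full_like(wn, float(offset))
    for center, height, fwhm in bands:
        sigma = fwhm * _FWHM_TO_SIGMA
        out += height * np.exp(-0.5 * ((wn - center) / sigma) ** 2)
    return out


@dataclass(frozen=True)
class ComponentLibrary:
    """Named pure spectra driving the simulation.

    ``binding_signature`` is *signed*: positive at the drug bands, negative
    at the nucleic-acid bands it suppresses (``subtractive_channels`` flags
    the negative entries), so the simulated matrix remains a single bilinear
    product C x S.
    """

    wavenumbers: np.ndarray
    cell_spectrum: np.ndarray
    binding_signature: np.ndarray
    response_signature: np.ndarray

    def __post_init__(self):
        wn = np.asarray(self.wavenumbers, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        for name in ("cell_spectrum", "binding_signature", "response_signature"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != wn.shape:
                raise ValueError(f"{name} length must match the wavenumber axis")
        if np.any(np.diff(wn) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if np.any(self.cell_spectrum < 0):
            raise ValueError("cell_spectrum must be non-negative")

    @property
    def subtractive_channels(self) -> np.ndarray:
        """Boolean mask of channels where the binding signature is negative."""
        return self.binding_signature < 0


# Band tables: (center cm^-1, height a.u., FWHM cm^-1).  Cell bands follow
# the canonical assignments for fixed lung cells; heights are relative to
# the phenylalanine band (1.0 at 1005 cm^-1).
_CELL_BANDS = [
    (622, 0.15, 12), (645, 0.12, 12), (718, 0.18, 14), (785, 0.55, 14),
    (811, 0.35, 12), (852, 0.30, 14), (936, 0.22, 16), (1005, 1.00, 8),
    (1094, 0.30, 18), (1127, 0.25, 14), (1250, 0.45, 30), (1340, 0.40, 24),
    (1450, 0.70, 20), (1578, 0.30, 16), (1660, 0.90, 35),
]
_BINDING_BANDS = [
    (440, 0.80, 10), (460, 1.00, 10), (1211, 0.70, 10),
    (785, -0.80, 12), (811, -0.50, 10),
]
_RESPONSE_BANDS = [(1450, 1.00, 18), (1660, 0.40, 30)]


def default_library(
    wn_start: float = 400.0, wn_stop: float = 1800.0, wn_step: float = 2.0
) -> ComponentLibrary:
    """Library of synthetic pure spectra on a 400-1800 cm^-1 axis.

    The binding signature peaks at the DOX bands (440/460/1211 cm^-1) and is
    negative at the nucleic-acid bands (785/811 cm^-1); the response
    signature peaks at 1450 cm^-1; the cell spectrum carries the
    phenylalanine reference band at 1005 cm^-1 plus a small broad offset.
    """
    wn = np.arange(wn_start, wn_stop + 0.5 * wn_step, wn_step)
    return ComponentLibrary(
        wavenumbers=wn,
        cell_spectrum=gaussian_bands(wn, _CELL_BANDS, offset=0.05),
        binding_signature=gaussian_bands(wn, _BINDING_BANDS),
        response_signature=gaussian_bands(wn, _RESPONSE_BANDS),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults reproduce the reference simulation: rapid saturating uptake
    (Kup = 0.25 h^-1, unit dose and capacities) followed by a slower
    response (Kresp = 0.05 h^-1 per unit bound drug), a 0-72 h grid at 0.5 h
    steps (145 spectra) and 1% additive uniform noise.  ``amplitudes`` scale
    the (max-normalized) binding and response signatures relative to the
    cell spectrum; the defaults keep all simulated intensities positive.
    """

    params: KineticParams = field(
        default_factory=lambda: KineticParams(Kup=0.25, Kresp=0.05, Nrecp=1.0, Nresp=1.0, D=1.0)
    )
    t_start: float = 0.0
    t_end: float = 72.0
    t_step: float = 0.5
    noise_fraction: float = 0.01
    seed: int = 0
    amplitudes: tuple[float, float] = (0.25, 0.15)

    def __post_init__(self):
        if self.t_step <= 0:
            raise ValueError("t_step must be > 0")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must be > t_start")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        self.params.validate()

    @property
    def times(self) -> np.ndarray:
        n = int(np.floor((self.t_end - self.t_start) / self.t_step + 1e-9)) + 1
        return self.t_start + np.arange(n) * self.t_step

    def to_dict(self) -> dict:
        return {
            "params": self.params.as_dict(),
            "t_start": self.t_start,
            "t_end": self.t_end,
            "t_step": self.t_step,
            "noise_fraction": self.noise_fraction,
            "seed": self.seed,
            "amplitudes": list(self.amplitudes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "params" in d:
            d["params"] = KineticParams(**d["params"])
        if "amplitudes" in d:
            d["amplitudes"] = tuple(d["amplitudes"])
        return cls(**d)


@dataclass(frozen=True)
class SimulationResult:
    """Simulated dataset plus the ground truth that generated it.

    ``C_true`` columns are (bound drug Nb, response Nr, constant cell
    background); ``S_true`` rows are the matching applied signatures
    (amplitude-scaled, binding signed).  Without noise,
    ``dataset.intensities == C_true @ S_true`` exactly.
    """

    dataset: SpectraDataset
    C_true: np.ndarray
    S_true: np.ndarray
    config: SimulationConfig
    library: ComponentLibrary


def add_noise(matrix: np.ndarray, noise_fraction: float, seed: int | np.random.Generator) -> np.ndarray:
    """Add uniform noise on [0, noise_fraction * max(matrix)) to every entry.

    Mirrors MATLAB's ``rand``-based noise: uniform, non-negative, scaled by
    the global maximum intensity.  Reproducible given the seed.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    mat = np.asarray(matrix, dtype=float)
    if noise_fraction == 0:
        return mat.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = noise_fraction * float(np.max(mat))
    return mat + rng.uniform(0.0, scale, size=mat.shape)


def simulate_dataset(
    library: ComponentLibrary | None = None,
    config: SimulationConfig | None = None,
) -> SimulationResult:
    """Simulate a drug-inoculation time course as a noisy bilinear mixture.

    Each spectrum is cell background + Nb(t) x binding signature (signed, so
    the nucleic-acid bands are subtracted) + Nr(t) x response signature,
    with the concentration profiles integrated from the uptake/response ODE
    pair at ``config.params``, plus additive uniform noise.
    """
    library = library if library is not None else default_library()
    config = config if config is not None else SimulationConfig()
    times = config.times
    model = get_model("uptake_response")
    profiles = solve_kinetics(model, config.params, times)

    amp_b, amp_r = config.amplitudes
    s_true = np.vstack(
        [
            amp_b * library.binding_signature,
            amp_r * library.response_signature,
            library.cell_spectrum,
        ]
    )
    c_true = np.column_stack(
        [profiles.values[:, 0], profiles.values[:, 1], np.ones(times.size)]
    )
    clean = c_true @ s_true
    n_neg = int(np.sum(clean < 0))
    if n_neg:
        warnings.warn(
            f"simulated mixture has {n_neg} negative intensities (clipped to 0); "
            "reduce the signature amplitudes for a physical simulation",
            ClippingWarning,
            stacklevel=2,
        )
        clean = np.clip(clean, 0.0, None)
    noisy = add_noise(clean, config.noise_fraction, config.seed)
    ds = SpectraDataset(
        intensities=noisy,
        times=times,
        wavenumbers=library.wavenumbers,
        meta={"source": "hsmcr.synthetic", "seed": str(config.seed)},
    )
    return SimulationResult(ds, c_true, s_true, config, library)
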