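"""X-ray source spectrum, energy binning, HU conversion and detector response.

The source is an analytic Kramers-type bremsstrahlung spectrum (photon fluence
per keV proportional to ``kvp/E - 1``) with configurable Beer-Lambert filtration
and no characteristic lines; the default inherent filtration is 2 mm of
aluminum-equivalent. Photon-counting behavior is modeled by threshold binning of
the spectrum, a Gaussian energy-resolution blur, and a non-paralyzable dead-time
model ``n = m / (1 - m*tau)`` relating true (n) and measured (m) count rates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d
from scipy.optimize import minimize_scalar

from .materials import MaterialTable, load_material_table

__all__ = [
    "Spectrum", "BinConfig", "DetectorModel",
    "build_spectrum", "bin_spectrum", "apply_energy_resolution",
    "dead_time_forward", "dead_time_invert", "fit_dead_time",
    "rate_per_area_at_loss", "mu_to_hu", "hu_to_mu", "effective_bin_mu",
    "bin_effective_energy", "effective_spectrum_mu",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Spectrum:
    """Photon fluence per energy sample on an ascending keV grid."""

    energies: np.ndarray
    fluence: np.ndarray

    def __post_init__(self):
        e, f = np.asarray(self.energies, float), np.asarray(self.fluence, float)
        if e.ndim != 1 or np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing 1-D")
        if f.shape != e.shape or np.any(f < 0):
            raise ValueError("fluence must be non-negative and match energies")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "fluence", f)

    @property
    def total(self) -> float:
        return float(self.fluence.sum())

    @property
    def mean_energy(self) -> float:
        return float((self.energies * self.fluence).sum() / self.fluence.sum())

    @classmethod
    def monochromatic(cls, energy_kev: float, fluence: float = 1.0,
                      table: MaterialTable | None = None) -> "Spectrum":
        """Delta spectrum on the material-table grid (all photons in one sample)."""
        table = table or load_material_table()
        f = np.zeros_like(table.energies)
        idx = int(np.argmin(np.abs(table.energies - energy_kev)))
        f[idx] = fluence
        return cls(table.energies.copy(), f)


@dataclass(frozen=True)
class BinConfig:
    """Energy thresholds (keV) of the photon counter; bins are half-open
    ``[t_i, t_{i+1})`` with the last bin closed at the tube voltage."""

    thresholds: tuple = (30.0, 50.0, 65.0)
    kvp: float = 140.0

    def __post_init__(self):
        t = tuple(float(x) for x in self.thresholds)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if t and t[-1] >= self.kvp:
            raise ValueError("last threshold must lie below kvp")
        object.__setattr__(self, "thresholds", t)

    @property
    def n_bins(self) -> int:
        return len(self.thresholds)

    def edges(self) -> list[tuple[float, float]]:
        hi = self.thresholds[1:] + (float(self.kvp),)
        return list(zip(self.thresholds, hi))


@dataclass(frozen=True)
class DetectorModel:
    """Photon-counting detector response parameters."""

    dead_time: float = 101.42e-9        # s
    fwhm_fraction: float = 0.0451       # FWHM / reference energy
    pixel_pitch: tuple = (0.190, 0.230)  # mm x mm

    def __post_init__(self):
        if self.dead_time < 0:
            raise ValueError("dead_time must be >= 0")
        if not (0 < self.fwhm_fraction < 0.5):
            raise ValueError("fwhm_fraction must be in (0, 0.5)")
        if any(p <= 0 for p in self.pixel_pitch):
            raise ValueError("pixel pitch must be positive")


def build_spectrum(kvp: float = 140.0,
                   filtration: list[tuple[str, float]] | None = None,
                   table: MaterialTable | None = None) -> Spectrum:
    """Analytic tungsten-anode bremsstrahlung spectrum.

    Parameters
    ----------
    kvp : tube voltage in kV (40-150); fluence is zero at and above ``kvp``.
    filtration : list of ``(material, thickness_mm)`` applied via Beer-Lambert
        in addition to the fixed 2 mm aluminum-equivalent inherent filtration.
    """
    if not (40.0 <= kvp <= 150.0):
        raise ValueError(f"kvp={kvp} outside supported range [40, 150]")
    table = table or load_material_table()
    e = table.energies
    fluence = np.clip(kvp / e - 1.0, 0.0, None)
    layers = [("aluminum", 2.0)] + list(filtration or [])
    for name, thickness_mm in layers:
        fluence = fluence * np.exp(-table.mu_lin(name) * thickness_mm)
    fluence[e >= kvp] = 0.0
    return Spectrum(e.copy(), fluence)


def bin_spectrum(spectrum: Spectrum, bins: BinConfig) -> list[Spectrum]:
    """Split a spectrum into per-bin spectra (half-open bins, last closed at kvp)."""
    e = spectrum.energies
    if bins.thresholds[0] < e[0]:
        raise ValueError("lowest threshold lies below the spectrum grid")
    out = []
    for i, (lo, hi) in enumerate(bins.edges()):
        last = i == bins.n_bins - 1
        sel = (e >= lo) & ((e <= hi) if last else (e < hi))
        f = np.where(sel, spectrum.fluence, 0.0)
        out.append(Spectrum(e.copy(), f))
    return out


def apply_energy_resolution(spectrum: Spectrum, model: DetectorModel,
                            reference_energy: float = 122.06) -> Spectrum:
    """Blur fluence with a Gaussian of FWHM = fwhm_fraction * reference energy.

    The blur width is held constant across the spectrum; total fluence is
    conserved up to boundary truncation.
    """
    de = float(np.diff(spectrum.energies).mean())
    sigma = model.fwhm_fraction * reference_energy * _FWHM_TO_SIGMA / de
    if sigma < 1e-9:
        return spectrum
    half = int(np.ceil(5 * sigma))
    x = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    blurred = convolve1d(spectrum.fluence, kernel, mode="constant")
    return Spectrum(spectrum.energies.copy(), blurred)


def dead_time_forward(n, tau: float):
    """Measured rate of a non-paralyzable counter: ``m = n / (1 + n*tau)``."""
    n = np.asarray(n, dtype=float)
    return n / (1.0 + n * tau)


def dead_time_invert(m, tau: float):
    """True rate from the measured rate: ``n = m / (1 - m*tau)``.

    Rejects ``m*tau >= 1`` (non-physical for a non-paralyzable counter).
    """
    m = np.asarray(m, dtype=float)
    if np.any(m * tau >= 1.0):
        raise ValueError("m*tau >= 1 is not reachable by a non-paralyzable counter")
    return m / (1.0 - m * tau)


def fit_dead_time(pairs) -> float:
    """Least-squares dead time from (true rate, measured rate) pairs.

    Minimizes squared error in measured-rate space under ``m = n/(1+n*tau)``
    with a bounded scalar search. Warns when the data never leave the linear
    regime, where tau is unidentifiable.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 3:
        raise ValueError("need at least 3 (input, measured) pairs")
    n, m = pairs[:, 0], pairs[:, 1]
    if np.all(np.abs(m - n) <= 0.02 * np.maximum(n, 1e-30)):
        warnings.warn("all pairs lie in the linear regime; "
                      "dead time is unidentifiable", stacklevel=2)
    upper = 10.0 / max(n.max(), 1e-30)

    def loss(tau):
        return float(np.sum((dead_time_forward(n, tau) - m) ** 2))

    res = minimize_scalar(loss, bounds=(0.0, upper), method="bounded",
                          options={"xatol": upper * 1e-12})
    return float(res.x)


def rate_per_area_at_loss(tau: float, loss_fraction: float,
                          pitch_mm: tuple = (0.190, 0.230)) -> float:
    """Measured count rate per detector area (Mcps/mm^2) at a given loss.

    At loss ``l = 1 - m/n`` the non-paralyzable model gives ``m = l / tau``.
    """
    if not (0 < loss_fraction < 1):
        raise ValueError("loss_fraction must lie in (0, 1)")
    m = loss_fraction / tau  # counts/s per pixel
    area = pitch_mm[0] * pitch_mm[1]
    return m / 1e6 / area


def mu_to_hu(mu_image, mu_water: float):
    """CT number: ``HU = 1000 * (mu - mu_water) / mu_water``."""
    if mu_water <= 0:
        raise ValueError("mu_water must be positive")
    return 1000.0 * (np.asarray(mu_image, float) - mu_water) / mu_water


def hu_to_mu(hu_image, mu_water: float):
    if mu_water <= 0:
        raise ValueError("mu_water must be positive")
    return mu_water * (1.0 + np.asarray(hu_image, float) / 1000.0)


def effective_bin_mu(material: str, spectrum: Spectrum, bin_index: int,
                     bins: BinConfig, table: MaterialTable | None = None) -> float:
    """Fluence-weighted mean linear attenuation (1/mm) of a material in a bin."""
    table = table or load_material_table()
    if material not in table:
        raise KeyError(f"unknown material {material!r}")
    bs = bin_spectrum(spectrum, bins)[bin_index]
    if bs.total <= 0:
        raise ValueError(f"bin {bin_index} holds no fluence")
    mu = table.mu_lin(material)
    return float((bs.fluence * mu).sum() / bs.total)


def bin_effective_energy(spectrum: Spectrum, bin_index: int, bins: BinConfig,
                         table: MaterialTable | None = None,
                         reference: str = "water") -> float:
    """Effective energy (keV) of a bin: the monoenergetic energy whose
    reference-material attenuation equals the bin's effective attenuation
    (the standard water-matched definition)."""
    table = table or load_material_table()
    eff = effective_bin_mu(reference, spectrum, bin_index, bins, table)
    mu = table.mu_lin(reference)
    # mu decreases with energy: interpolate on the reversed axis
    return float(np.interp(-eff, -mu, table.energies))


def effective_spectrum_mu(material: str, spectrum: Spectrum,
                          table: MaterialTable | None = None) -> float:
    """Fluence-weighted mean linear attenuation (1/mm) over a whole spectrum."""
    table = table or load_material_table()
    if spectrum.total <= 0:
        raise ValueError("spectrum holds no fluence")
    mu = table.mu_lin(material)
    return float((spectrum.fluence * mu).sum() / spectrum.total)
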