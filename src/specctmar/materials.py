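"""Material attenuation tables.

Mass attenuation coefficients (mu/rho, cm^2/g) are shipped as plain-text package
data on a uniform 1-keV grid from 20 to 150 keV (see ``data/mass_attenuation.csv``
and ``scripts/build_attenuation_table.py`` for provenance). Elemental K-edges fall
between grid samples, so iodine shows its characteristic discontinuity between the
33 and 34 keV samples.

Besides the tabulated base materials, derived materials can be registered as
mixtures of partial densities; the table ships with ``iodine_cal``, the
18.9 mg/mL iodine-in-water calibration solution whose decomposed fraction maps
directly onto the iodine-concentration scale used throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = ["Material", "MaterialTable", "load_material_table",
           "IODINE_CAL_MG_PER_ML"]

#: iodine concentration (mg/mL) represented by a basis fraction of 1.0
IODINE_CAL_MG_PER_ML = 18.9


@dataclass(frozen=True)
class Material:
    """A named material: mu/rho(E) on the table grid plus nominal density."""

    name: str
    mu_rho: np.ndarray  # cm^2/g on the table energy grid
    density: float      # g/cm^3


@dataclass
class MaterialTable:
    """Collection of materials sharing one energy grid (keV, ascending)."""

    energies: np.ndarray
    materials: dict[str, Material] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.materials

    def names(self) -> list[str]:
        return sorted(self.materials)

    def density(self, name: str) -> float:
        return self.materials[name].density

    def mu_rho(self, name: str) -> np.ndarray:
        """mu/rho (cm^2/g) sampled on the table grid."""
        return self.materials[name].mu_rho

    def mu_rho_at(self, name: str, energy) -> np.ndarray:
        """Log-log interpolated mu/rho at arbitrary energies within the grid."""
        energy = np.asarray(energy, dtype=float)
        if np.any(energy < self.energies[0]) or np.any(energy > self.energies[-1]):
            raise ValueError(
                f"energy outside table range "
                f"[{self.energies[0]}, {self.energies[-1]}] keV")
        m = self.materials[name]
        return np.exp(np.interp(np.log(energy), np.log(self.energies),
                                np.log(m.mu_rho)))

    def mu_lin(self, name: str) -> np.ndarray:
        """Linear attenuation (1/mm) at nominal density on the table grid."""
        m = self.materials[name]
        return m.mu_rho * m.density * 0.1  # cm^-1 -> mm^-1

    def mu_lin_at(self, name: str, energy) -> np.ndarray:
        m = self.materials[name]
        return self.mu_rho_at(name, energy) * m.density * 0.1

    def register_mixture(self, name: str, partial_densities: dict[str, float]) -> Material:
        """Register a derived material from partial densities (g/cm^3).

        The mixture density is the sum of partial densities and its mu/rho the
        mass-weighted average of the components'.
        """
        density = float(sum(partial_densities.values()))
        if density <= 0:
            raise ValueError("mixture must have positive density")
        mu_rho = np.zeros_like(self.energies)
        for comp, rho in partial_densities.items():
            mu_rho += self.materials[comp].mu_rho * (rho / density)
        mat = Material(name, mu_rho, density)
        self.materials[name] = mat
        return mat

    def mu_lin_composition(self, mass_fractions: dict[str, float],
                           density: float) -> np.ndarray:
        """Linear attenuation (1/mm) of an arbitrary composition on the grid."""
        mu_rho = np.zeros_like(self.energies)
        for comp, frac in mass_fractions.items():
            mu_rho += self.materials[comp].mu_rho * frac
        return mu_rho * density * 0.1


def _read_packaged_csv() -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, float]]:
    text = (resources.files("specctmar") / "data" / "mass_attenuation.csv").read_text()
    lines = text.splitlines()
    densities: dict[str, float] = {}
    header: list[str] = []
    rows: list[list[float]] = []
    for ln in lines:
        if ln.startswith("# density"):
            for tok in ln.split(":", 1)[1].split():
                k, v = tok.split("=")
                densities[k] = float(v)
        elif ln.startswith("#"):
            continue
        elif ln.startswith("energy_kev"):
            header = ln.split(",")[1:]
        elif ln.strip():
            rows.append([float(x) for x in ln.split(",")])
    data = np.array(rows)
    cols = {name: data[:, i + 1] for i, name in enumerate(header)}
    return data[:, 0], cols, densities


_CACHED: MaterialTable | None = None


def load_material_table() -> MaterialTable:
    """Load (and cache) the packaged material table.

    Includes the ``iodine_cal`` calibration-solution mixture (water 1.0 g/cm^3 +
    iodine 0.0189 g/cm^3) so that a decomposed basis fraction of 1 corresponds to
    18.9 mg/mL of iodine.
    """
    global _CACHED
    if _CACHED is None:
        energies, cols, densities = _read_packaged_csv()
        table = MaterialTable(energies)
        for name, mu in cols.items():
            table.materials[name] = Material(name, mu, densities[name])
        table.register_mixture(
            "iodine_cal",
            {"water": 1.0, "iodine": IODINE_CAL_MG_PER_ML / 1000.0})
        _CACHED = table
    return _CACHED
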