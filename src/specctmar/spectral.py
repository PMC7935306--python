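"""Image-domain three-material decomposition and virtual monochromatic imaging.

Each pixel's per-bin attenuation vector is modeled as a linear combination of
basis-material attenuations, ``mu_i(x) = sum_m b_m(x) * mu_m_i``, solved by one
3x3 matrix inversion shared across pixels; fractions are clipped to [0, 1]
componentwise (no renormalization). A virtual monochromatic image at energy E
recombines the maps with tabulated mass attenuation at E, interpreting each
``b_m`` as the fraction of basis material present at its nominal density so the
result is a linear attenuation (then converted to HU against water at E).

The iodine basis is by convention the 18.9 mg/mL calibration solution
(``iodine_cal``), so an iodine-map value of 1 means full calibration contrast
and concentration images are simply ``b * 18.9 mg/mL``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .materials import IODINE_CAL_MG_PER_ML, MaterialTable, load_material_table
from .physics import BinConfig, Spectrum, effective_bin_mu, mu_to_hu
from .recon import BinImage

__all__ = ["MuMatrix", "MaterialMaps", "build_mu_matrix", "decompose",
           "synthesize_vmi", "quantify_iodine", "classify_overlay"]

CONDITION_WARN = 1e3


@dataclass(frozen=True)
class MuMatrix:
    """Bin-by-material attenuation matrix (1/mm); rows = bins, cols = basis."""

    matrix: np.ndarray
    basis: tuple

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.basis), len(self.basis)):
            raise ValueError("matrix must be square over the basis")
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"mu matrix is singular (condition number {cond:.3g})")
        if cond > CONDITION_WARN:
            warnings.warn(f"mu matrix condition number {cond:.3g} exceeds "
                          f"{CONDITION_WARN:.0g}", stacklevel=2)
        object.__setattr__(self, "matrix", m)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


@dataclass
class MaterialMaps:
    """Per-pixel basis fractions in [0, 1] plus the matrix that produced them."""

    fractions: dict
    mu_matrix: MuMatrix
    pixel_size: float
    raw_fractions: dict = field(default_factory=dict)  # pre-clip solutions

    def __getitem__(self, name: str) -> np.ndarray:
        return self.fractions[name]


def build_mu_matrix(basis: tuple, spectrum: Spectrum, bins: BinConfig,
                    table: MaterialTable | None = None,
                    mode: str = "spectral",
                    calibration: list[tuple[np.ndarray, dict]] | None = None,
                    ) -> MuMatrix:
    """Basis-material attenuation per bin.

    mode="spectral": fluence-weighted averages of the tabulated attenuation
    over each bin's spectrum. mode="calibration": least-squares regression of
    the matrix from reconstructed calibration-scan ROI data; ``calibration``
    is a list of ``(mu_vector_per_bin, known_basis_fractions)`` pairs, e.g.
    ROI means from a scan of the calibration phantom.
    """
    table = table or load_material_table()
    if len(basis) != bins.n_bins:
        raise ValueError("need as many basis materials as bins")
    if mode == "spectral":
        m = np.array([[effective_bin_mu(mat, spectrum, i, bins, table)
                       for mat in basis] for i in range(bins.n_bins)])
    elif mode == "calibration":
        if not calibration or len(calibration) < len(basis):
            raise ValueError("calibration mode needs at least as many ROI "
                             "samples as basis materials")
        b = np.array([[frac.get(mat, 0.0) for mat in basis]
                      for _, frac in calibration])
        mu = np.array([np.asarray(v, float) for v, _ in calibration])
        # solve mu = b @ M.T column-block-wise
        m = np.linalg.lstsq(b, mu, rcond=None)[0].T
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return MuMatrix(m, tuple(basis))


def decompose(bin_images: list[BinImage], matrix: MuMatrix) -> MaterialMaps:
    """Per-pixel solve of the bin-attenuation system; fractions clipped to [0,1]."""
    if len(bin_images) != matrix.matrix.shape[0]:
        raise ValueError("need one image per bin")
    shapes = {im.mu.shape for im in bin_images}
    if len(shapes) != 1:
        raise ValueError("bin images must share one grid")
    stack = np.stack([im.mu for im in bin_images])  # (bins, ny, nx)
    if not np.all(np.isfinite(stack)):
        raise ValueError("bin images contain NaN")
    ny, nx = bin_images[0].mu.shape
    sol = np.linalg.solve(matrix.matrix,
                          stack.reshape(len(bin_images), -1))
    raw = sol.reshape(len(matrix.basis), ny, nx)
    clipped = np.clip(raw, 0.0, 1.0)
    return MaterialMaps(
        fractions={m: clipped[k] for k, m in enumerate(matrix.basis)},
        mu_matrix=matrix,
        pixel_size=bin_images[0].pixel_size,
        raw_fractions={m: raw[k] for k, m in enumerate(matrix.basis)})


def synthesize_vmi(maps: MaterialMaps, energy_kev: float,
                   table: MaterialTable | None = None) -> np.ndarray:
    """Virtual monochromatic image (HU) at ``energy_kev``.

    ``mu(x, E) = sum_m b_m(x) * (mu/rho)_m(E) * rho_m`` with nominal basis
    densities, converted to HU against water at E.
    """
    table = table or load_material_table()
    e = float(energy_kev)
    mu = None
    for name in maps.mu_matrix.basis:
        contrib = maps[name] * float(table.mu_lin_at(name, e))
        mu = contrib if mu is None else mu + contrib
    mu_water = float(table.mu_lin_at("water", e))
    return mu_to_hu(mu, mu_water)


def quantify_iodine(iodine_map: np.ndarray,
                    calibration_concentration: float = IODINE_CAL_MG_PER_ML,
                    ) -> np.ndarray:
    """Concentration image (mg/mL): map value 1 = full calibration contrast."""
    if calibration_concentration <= 0:
        raise ValueError("calibration concentration must be positive")
    return np.asarray(iodine_map, float) * calibration_concentration


def classify_overlay(maps: MaterialMaps, min_fraction: float = 0.02,
                     iodine: str = "iodine_cal",
                     calcium: str = "calcium") -> np.ndarray:
    """Label each pixel 0=neither, 1=iodine, 2=calcium by dominant fraction.

    Requires a decomposition whose basis contains the iodine and calcium
    materials; the dominant fraction must exceed ``min_fraction`` (on its own
    basis scale) to be labeled.
    """
    for name in (iodine, calcium):
        if name not in maps.fractions:
            raise KeyError(f"basis material {name!r} absent from the maps")
    b_i = maps[iodine]
    b_c = maps[calcium]
    labels = np.zeros(b_i.shape, dtype=np.uint8)
    labels[(b_i > min_fraction) & (b_i >= b_c)] = 1
    labels[(b_c > min_fraction) & (b_c > b_i)] = 2
    return labels
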