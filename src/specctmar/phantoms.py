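"""Digital 2-D phantoms rasterized to per-pixel material compositions.

Coordinate convention (used everywhere in the package): isocenter origin,
millimetre units, x to the right and y up. The image is stored row-major with
row 0 at the top, so pixel (i, j) has its center at
``x = (j - (nx-1)/2) * pixel_size`` and ``y = ((ny-1)/2 - i) * pixel_size``.

A phantom is a label grid plus a table mapping each label to a composition
(material mass fractions and a physical density). The head phantom is a
stylized geometric model - ellipses for the head and jaw, disks for teeth,
titanium implants and the iodine-enhanced insert - chosen so the two implants
and the insert are collinear and streaks overlap the lesion.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import MaterialTable, load_material_table
from .physics import Spectrum, build_spectrum, effective_spectrum_mu

__all__ = ["Composition", "DigitalPhantom", "make_iodine_cylinder",
           "make_calibration_phantom", "make_multi_energy_phantom",
           "make_head_phantom", "make_water_phantom"]

AIR = 0  # background label

DEFAULT_SHAPE = 512
DEFAULT_PIXEL_SIZE = 0.5  # mm
FOV_DIAMETER = 250.0      # mm

# head-phantom HU targets (broad-spectrum, noiseless)
HEAD_TISSUE_HU = 57.0
HEAD_IODINE_HU = 75.0


@dataclass(frozen=True)
class Composition:
    """Material mass fractions (summing to <= 1) and physical density."""

    mass_fractions: dict
    density: float  # g/cm^3

    def __post_init__(self):
        for frac in self.mass_fractions.values():
            if not (0.0 <= frac <= 1.0):
                raise ValueError("mass fractions must lie in [0, 1]")
        if sum(self.mass_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("mass fractions must sum to <= 1")
        if self.density <= 0:
            raise ValueError("density must be positive")


@dataclass
class DigitalPhantom:
    """2-D composition map: integer label grid + per-label compositions."""

    grid: np.ndarray                       # int16 labels, row-major
    compositions: dict                      # label -> Composition
    pixel_size: float = DEFAULT_PIXEL_SIZE  # mm
    name: str = "phantom"

    def __post_init__(self):
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        missing = set(np.unique(self.grid)) - set(self.compositions)
        if missing:
            raise ValueError(f"labels without composition: {missing}")

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center (x, y) maps in mm, isocenter origin."""
        ny, nx = self.grid.shape
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.pixel_size
        y = ((ny - 1) / 2.0 - np.arange(ny)) * self.pixel_size
        return np.meshgrid(x, y)

    def materials_used(self) -> list[str]:
        names: set = set()
        for comp in self.compositions.values():
            names |= set(comp.mass_fractions)
        return sorted(names)

    def partial_density_images(self) -> dict[str, np.ndarray]:
        """Per-material partial density (g/cm^3) images, used by the projector.

        Background air is omitted (treated as non-attenuating, the usual CT
        convention, so an object-free scan equals the air scan exactly).
        """
        out = {}
        for name in self.materials_used():
            if name == "air":
                continue
            img = np.zeros(self.grid.shape, dtype=np.float64)
            for label, comp in self.compositions.items():
                frac = comp.mass_fractions.get(name, 0.0)
                if frac:
                    img[self.grid == label] = frac * comp.density
            out[name] = img
        return out

    def mu_image(self, energy_index: int, table: MaterialTable) -> np.ndarray:
        """Noise-free linear attenuation (1/mm) at one table energy sample."""
        mu = np.zeros(self.grid.shape)
        for label, comp in self.compositions.items():
            val = sum(table.mu_rho(n)[energy_index] * f
                      for n, f in comp.mass_fractions.items()) * comp.density * 0.1
            mu[self.grid == label] = val
        return mu

    def body_radius(self) -> float:
        """Radius (mm) of the smallest isocentered circle holding all non-air pixels."""
        xx, yy = self.coords()
        mask = self.grid != AIR
        if not mask.any():
            return 0.0
        return float(np.sqrt(xx[mask] ** 2 + yy[mask] ** 2).max()) + self.pixel_size


def _empty_grid(shape: int, pixel_size: float):
    grid = np.zeros((shape, shape), dtype=np.int16)
    comps = {AIR: Composition({"air": 1.0}, 0.001205)}
    return grid, comps


def _paint_disk(grid, pixel_size, center, radius, label):
    ny, nx = grid.shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_size
    y = ((ny - 1) / 2.0 - np.arange(ny)) * pixel_size
    xx, yy = np.meshgrid(x, y)
    grid[(xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius ** 2] = label


def _paint_ellipse(grid, pixel_size, center, semi_axes, label, mask=None):
    ny, nx = grid.shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_size
    y = ((ny - 1) / 2.0 - np.arange(ny)) * pixel_size
    xx, yy = np.meshgrid(x, y)
    sel = (((xx - center[0]) / semi_axes[0]) ** 2
           + ((yy - center[1]) / semi_axes[1]) ** 2) <= 1.0
    if mask is not None:
        sel &= mask(xx, yy)
    grid[sel] = label


def _iodine_solution(conc_mg_ml: float) -> Composition:
    """Water with dissolved iodine at the stated concentration."""
    rho_i = conc_mg_ml / 1000.0
    density = 1.0 + rho_i
    if conc_mg_ml == 0:
        return Composition({"water": 1.0}, 1.0)
    return Composition({"water": 1.0 / density, "iodine": rho_i / density}, density)


def ring_positions(n: int, ring_radius: float,
                   start_angle: float = np.pi / 2) -> list[tuple[float, float]]:
    """Centers of ``n`` equally spaced inserts on a ring (mm, isocenter origin)."""
    return [(ring_radius * np.cos(start_angle + 2 * np.pi * k / n),
             ring_radius * np.sin(start_angle + 2 * np.pi * k / n))
            for k in range(n)]


#: insert layout constants shared with the analysis helpers
CALIBRATION_RING = 45.0
CALIBRATION_IODINE = (3.7, 10.1, 18.9)      # mg/mL
CALIBRATION_GADOLINIUM = (3.0, 7.5, 13.8)   # mg/mL
MULTI_ENERGY_RING = 50.0
MULTI_ENERGY_IODINE = (2.0, 5.0, 10.0, 15.0)   # mg/mL
MULTI_ENERGY_CALCIUM = (300.0, 100.0, 50.0)    # mg/mL


def iodine_cylinder_insert_centers(diameter_cm: int,
                                   n: int) -> list[tuple[float, float]]:
    ring = 0.6 * diameter_cm * 10.0 / 2.0
    return [(ring * np.cos(np.pi / 2 + 2 * np.pi * k / max(n, 1)),
             ring * np.sin(np.pi / 2 + 2 * np.pi * k / max(n, 1)))
            for k in range(n)]


def calibration_insert_centers() -> dict:
    """Centers of the calibration phantom's inserts, keyed I-1..Gd-3."""
    out = {}
    for k in range(3):
        ang = np.pi / 6 + k * np.pi / 3
        out[f"I-{k + 1}"] = (CALIBRATION_RING * np.cos(ang),
                             CALIBRATION_RING * np.sin(ang))
        out[f"Gd-{k + 1}"] = (CALIBRATION_RING * np.cos(-ang),
                              CALIBRATION_RING * np.sin(-ang))
    return out


def multi_energy_insert_centers() -> list[tuple[float, float]]:
    return ring_positions(7, MULTI_ENERGY_RING)


def _check_fov(diameter_mm: float):
    if diameter_mm > FOV_DIAMETER:
        raise ValueError(f"phantom diameter {diameter_mm} mm exceeds the "
                         f"{FOV_DIAMETER} mm FOV")


def make_iodine_cylinder(diameter_cm: int = 12,
                         concentrations=(3.5, 6.0, 9.0, 11.0, 17.0),
                         shape: int = DEFAULT_SHAPE,
                         pixel_size: float = DEFAULT_PIXEL_SIZE) -> DigitalPhantom:
    """PMMA cylinder (12/17/22 cm) with up to five 20-mm iodine-solution holes.

    Holes are placed on a ring at 60% of the body radius, 72 degrees apart.
    """
    if diameter_cm not in (12, 17, 22):
        raise ValueError("diameter_cm must be one of 12, 17, 22")
    concentrations = list(concentrations)
    if len(concentrations) > 5:
        raise ValueError("at most 5 concentrations")
    body_r = diameter_cm * 10.0 / 2.0
    _check_fov(2 * body_r)
    hole_r = 10.0
    ring = 0.6 * body_r
    if len(concentrations) > 1:
        gap = 2 * ring * np.sin(np.pi / len(concentrations))
        if gap < 2 * hole_r:
            raise ValueError("holes overlap at this ring radius")
    if ring + hole_r >= body_r:
        raise ValueError("holes extend outside the body")
    grid, comps = _empty_grid(shape, pixel_size)
    _paint_disk(grid, pixel_size, (0, 0), body_r, 1)
    comps[1] = Composition({"pmma": 1.0}, 1.19)
    centers = iodine_cylinder_insert_centers(diameter_cm, len(concentrations))
    for k, (conc, center) in enumerate(zip(concentrations, centers)):
        _paint_disk(grid, pixel_size, center, hole_r, 2 + k)
        comps[2 + k] = _iodine_solution(conc)
    return DigitalPhantom(grid, comps, pixel_size,
                          name=f"iodine_cylinder_{diameter_cm}cm")


def make_calibration_phantom(shape: int = DEFAULT_SHAPE,
                             pixel_size: float = DEFAULT_PIXEL_SIZE) -> DigitalPhantom:
    """150-mm PMMA calibration cylinder: iodine 3.7/10.1/18.9 and gadolinium
    3.0/7.5/13.8 mg/mL in six 20-mm holes on a symmetric ring layout
    (iodine on the upper half, gadolinium mirrored on the lower half)."""
    _check_fov(150.0)
    grid, comps = _empty_grid(shape, pixel_size)
    _paint_disk(grid, pixel_size, (0, 0), 75.0, 1)
    comps[1] = Composition({"pmma": 1.0}, 1.19)
    centers = calibration_insert_centers()
    hole_r = 10.0
    for k, conc in enumerate(CALIBRATION_IODINE):
        _paint_disk(grid, pixel_size, centers[f"I-{k + 1}"], hole_r, 2 + k)
        comps[2 + k] = _iodine_solution(conc)
    for k, conc in enumerate(CALIBRATION_GADOLINIUM):
        rho_g = conc / 1000.0
        density = 1.0 + rho_g
        _paint_disk(grid, pixel_size, centers[f"Gd-{k + 1}"], hole_r, 5 + k)
        comps[5 + k] = Composition(
            {"water": 1.0 / density, "gadolinium": rho_g / density}, density)
    return DigitalPhantom(grid, comps, pixel_size, name="calibration_150mm")


def make_multi_energy_phantom(shape: int = DEFAULT_SHAPE,
                              pixel_size: float = DEFAULT_PIXEL_SIZE) -> DigitalPhantom:
    """Water-equivalent body with four iodine (2/5/10/15 mg/mL) and three
    calcium (300/100/50 mg/mL) inserts on a ring, mimicking a multi-energy
    CT phantom."""
    body_r = 80.0
    _check_fov(2 * body_r)
    grid, comps = _empty_grid(shape, pixel_size)
    _paint_disk(grid, pixel_size, (0, 0), body_r, 1)
    comps[1] = Composition({"water": 1.0}, 1.0)
    iodine = MULTI_ENERGY_IODINE
    calcium = MULTI_ENERGY_CALCIUM
    hole_r = 9.5
    for k, center in enumerate(multi_energy_insert_centers()):
        _paint_disk(grid, pixel_size, center, hole_r, 2 + k)
        if k < len(iodine):
            comps[2 + k] = _iodine_solution(iodine[k])
        else:
            rho_c = calcium[k - len(iodine)] / 1000.0
            density = 1.0 + rho_c
            comps[2 + k] = Composition(
                {"water": 1.0 / density, "calcium": rho_c / density}, density)
    return DigitalPhantom(grid, comps, pixel_size, name="multi_energy")


def _broad_spectrum(table: MaterialTable) -> Spectrum:
    spec = build_spectrum(140.0, table=table)
    f = np.where(spec.energies >= 30.0, spec.fluence, 0.0)
    return Spectrum(spec.energies.copy(), f)


def _tissue_density_for_hu(target_hu: float, table: MaterialTable) -> float:
    """Soft-tissue density whose broad-spectrum effective mu hits ``target_hu``."""
    spec = _broad_spectrum(table)
    mu_w = effective_spectrum_mu("water", spec, table)
    mu_t_nominal = effective_spectrum_mu("soft_tissue", spec, table)
    rho_nominal = table.density("soft_tissue")
    mu_target = mu_w * (1.0 + target_hu / 1000.0)
    return rho_nominal * mu_target / mu_t_nominal


def _iodine_partial_density_for_hu(target_hu: float, tissue: Composition,
                                   table: MaterialTable) -> float:
    """Iodine partial density added to tissue so the mixture hits ``target_hu``."""
    spec = _broad_spectrum(table)
    mu_w = effective_spectrum_mu("water", spec, table)
    mu_t = (effective_spectrum_mu("soft_tissue", spec, table)
            / table.density("soft_tissue") * tissue.density)
    mu_i_rho = effective_spectrum_mu("iodine", spec, table) / table.density("iodine")
    mu_target = mu_w * (1.0 + target_hu / 1000.0)
    return (mu_target - mu_t) / mu_i_rho  # g/cm^3 of iodine (linear solve)


def make_head_phantom(with_metal: bool = True, with_iodine: bool = True,
                      shape: int = DEFAULT_SHAPE,
                      pixel_size: float = DEFAULT_PIXEL_SIZE,
                      table: MaterialTable | None = None) -> DigitalPhantom:
    """Stylized head cross-section at the level of the lower jaw.

    Soft-tissue head ellipse, U-shaped jawbone arch with teeth, two titanium
    disk implants embedded in the jaw, and an iodine-enhanced insert centered
    between them. The three centers are collinear (y = -52 mm) so implant
    streaks overlap the lesion. Tissue and insert compositions are solved so
    their noiseless broad-spectrum HU are ~57 and ~75.
    """
    table = table or load_material_table()
    grid, comps = _empty_grid(shape, pixel_size)

    tissue_rho = _tissue_density_for_hu(HEAD_TISSUE_HU, table)
    tissue = Composition({"soft_tissue": 1.0}, tissue_rho)

    TISSUE, JAW, TOOTH, METAL, INSERT = 1, 2, 3, 4, 5
    _paint_ellipse(grid, pixel_size, (0.0, 0.0), (78.0, 95.0), TISSUE)
    comps[TISSUE] = tissue
    # jaw = elliptical ring restricted to the lower half
    lower = lambda xx, yy: yy < -25.0
    _paint_ellipse(grid, pixel_size, (0.0, -30.0), (55.0, 65.0), JAW, mask=lower)
    _paint_ellipse(grid, pixel_size, (0.0, -30.0), (43.0, 53.0), TISSUE, mask=lower)
    comps[JAW] = Composition({"bone": 1.0}, 1.50)
    # teeth along the front of the arch
    for deg in (210, 234, 258, 282, 306, 330):
        ang = np.deg2rad(deg)
        center = (49.0 * np.cos(ang), -30.0 + 59.0 * np.sin(ang))
        _paint_disk(grid, pixel_size, center, 4.5, TOOTH)
    comps[TOOTH] = Composition({"bone": 1.0}, 2.0)

    y_line = -52.0
    if with_metal:
        for xc in (-39.0, 39.0):
            _paint_disk(grid, pixel_size, (xc, y_line), 2.5, METAL)
        comps[METAL] = Composition({"titanium": 1.0}, table.density("titanium"))
    if with_iodine:
        rho_i = _iodine_partial_density_for_hu(HEAD_IODINE_HU, tissue, table)
        density = tissue_rho + rho_i
        comps[INSERT] = Composition(
            {"soft_tissue": tissue_rho / density, "iodine": rho_i / density},
            density)
        _paint_disk(grid, pixel_size, (0.0, y_line), 5.0, INSERT)
    comps = {k: v for k, v in comps.items() if k in np.unique(grid) or k == AIR}
    return DigitalPhantom(grid, comps, pixel_size, name="head")


def make_water_phantom(diameter_mm: float = 150.0, shape: int = DEFAULT_SHAPE,
                       pixel_size: float = DEFAULT_PIXEL_SIZE) -> DigitalPhantom:
    """Uniform water disk for uniformity measurements."""
    _check_fov(diameter_mm)
    grid, comps = _empty_grid(shape, pixel_size)
    _paint_disk(grid, pixel_size, (0, 0), diameter_mm / 2.0, 1)
    comps[1] = Composition({"water": 1.0}, 1.0)
    return DigitalPhantom(grid, comps, pixel_size, name="water_150mm")
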