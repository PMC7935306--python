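"""End-to-end experiment orchestration.

Chains phantom generation, the polyenergetic scan, per-bin reconstruction,
optional per-bin NMAR, material decomposition, VMI synthesis and ROI
evaluation, and writes images (TIFF), tables (CSV) and a run manifest with
checksums so deterministic stages can be verified bit-for-bit on re-runs.

The four head-phantom comparison arms are: (a) broad-bin image, (b) broad-bin
image with NMAR, (c) 40-keV VMI from the uncorrected bins, (d) 40-keV VMI from
the NMAR-corrected bins.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__, phantoms
from .evaluation import RoiSpec, cnr_from_stats, roi_stats
from .materials import load_material_table
from .nmar import NmarParams, run_nmar_per_bin
from .physics import (BinConfig, Spectrum, bin_spectrum, build_spectrum,
                      effective_bin_mu, mu_to_hu)
from .recon import (DEFAULT_EXPOSURE, BinImage, BinSinogram, FanGeometry,
                    air_scan, fbp, forward_project, log_normalize,
                    project_materials, water_precorrection)
from .spectral import build_mu_matrix, decompose, synthesize_vmi

__all__ = ["ExperimentConfig", "RunManifest", "ScanResult", "simulate_scan",
           "head_arms", "run_experiment", "write_report", "head_rois",
           "PHANTOM_FACTORIES"]

PHANTOM_FACTORIES = {
    "head": phantoms.make_head_phantom,
    "water": phantoms.make_water_phantom,
    "iodine_cylinder": phantoms.make_iodine_cylinder,
    "calibration": phantoms.make_calibration_phantom,
    "multi_energy": phantoms.make_multi_energy_phantom,
}


def head_rois() -> list[RoiSpec]:
    """ROI fixture for the head phantom, mirroring the lesion/tissue/air scheme.

    ROI1 sits on the iodine insert; the ROI2s sample tissue in the upper half
    away from the implant streak band; the ROI3s sample surrounding air.
    """
    return [
        RoiSpec("ROI1", (0.0, -52.0), 4.0),
        RoiSpec("ROI2-1", (0.0, 40.0), 5.0),
        RoiSpec("ROI2-2", (-40.0, 25.0), 5.0),
        RoiSpec("ROI2-3", (40.0, 25.0), 5.0),
        RoiSpec("ROI3-1", (-100.0, 40.0), 5.0),
        RoiSpec("ROI3-2", (100.0, 40.0), 5.0),
        RoiSpec("ROI3-3", (0.0, 110.0), 5.0),
    ]


#: tissue ROI crossing the implant streak band (between implant and insert)
STREAK_ROI = RoiSpec("streak", (-20.0, -52.0), 4.0)


def calibration_samples(scan: "ScanResult", pixel_size: float,
                        roi_radius: float = 6.0) -> list:
    """ROI samples for a calibration-mode attenuation matrix.

    Reads per-bin ROI means off a reconstructed scan of the calibration
    phantom (three iodine inserts plus the PMMA body) and pairs them with the
    known basis fractions on the (water, iodine_cal, pmma) basis. Regressing
    the matrix from such a scan absorbs residual beam-hardening bias, which is
    why a dedicated calibration phantom is scanned at all.
    """
    centers = phantoms.calibration_insert_centers()
    samples = []
    for k, conc in enumerate(phantoms.CALIBRATION_IODINE):
        roi = RoiSpec(f"I-{k + 1}", centers[f"I-{k + 1}"], roi_radius)
        mu = np.array([roi_stats(scan.bin_images[b].mu, [roi],
                                 pixel_size).loc[roi.name, "mean"]
                       for b in range(len(scan.bin_images))])
        frac = conc / 18.9
        samples.append((mu, {"water": 1.0 - frac, "iodine_cal": frac}))
    body = RoiSpec("body", (0.0, -8.0), 8.0)
    mu = np.array([roi_stats(scan.bin_images[b].mu, [body],
                             pixel_size).loc["body", "mean"]
                   for b in range(len(scan.bin_images))])
    samples.append((mu, {"pmma": 1.0}))
    return samples


def multi_energy_samples(scan: "ScanResult", pixel_size: float,
                         roi_radius: float = 6.0) -> list:
    """ROI samples from the multi-energy phantom's known rods, for regressing
    a (water, iodine_cal, calcium) matrix used by the overlay classification."""
    iodine = phantoms.MULTI_ENERGY_IODINE
    calcium = phantoms.MULTI_ENERGY_CALCIUM
    samples = []
    for k, center in enumerate(phantoms.multi_energy_insert_centers()):
        roi = RoiSpec(f"rod{k}", center, roi_radius)
        mu = np.array([roi_stats(scan.bin_images[b].mu, [roi],
                                 pixel_size).loc[roi.name, "mean"]
                       for b in range(len(scan.bin_images))])
        if k < len(iodine):
            frac = iodine[k] / 18.9
            samples.append((mu, {"water": 1.0 - frac, "iodine_cal": frac}))
        else:
            rho_c = calcium[k - len(iodine)] / 1000.0
            samples.append((mu, {"water": 1.0,
                                 "calcium": rho_c / 1.55}))
    center_roi = RoiSpec("water", (0.0, 0.0), 8.0)
    mu = np.array([roi_stats(scan.bin_images[b].mu, [center_roi],
                             pixel_size).loc["water", "mean"]
                   for b in range(len(scan.bin_images))])
    samples.append((mu, {"water": 1.0}))
    return samples


@dataclass
class ScanResult:
    """Everything one simulated scan produces, per bin plus the broad image."""

    bin_sinos: list
    air_sinos: list
    bin_ps: list                 # line-integral sinograms per bin
    bin_images: list             # BinImage (mu, 1/mm) per bin
    broad_p: np.ndarray
    broad_image: BinImage
    mu_water_bins: list          # effective water mu per bin (1/mm)
    mu_water_broad: float

    def broad_hu(self) -> np.ndarray:
        return mu_to_hu(self.broad_image.mu, self.mu_water_broad)

    def bin_hu(self, b: int) -> np.ndarray:
        return mu_to_hu(self.bin_images[b].mu, self.mu_water_bins[b])


def simulate_scan(phantom, geometry: FanGeometry, spectrum: Spectrum,
                  bins: BinConfig, noise: bool = False, seed: int | None = None,
                  exposure: float = DEFAULT_EXPOSURE,
                  material_sinos: dict | None = None,
                  filter_name: str = "hann",
                  water_precorrect: bool = True) -> ScanResult:
    """Scan + air-correct + reconstruct each bin and the summed broad bin.

    ``water_precorrect`` applies the standard per-bin water-equivalent
    beam-hardening linearization before reconstruction (disable it to study
    raw cupping/streak behavior of air correction alone).
    """
    table = load_material_table()
    n = phantom.shape[0]
    if material_sinos is None:
        material_sinos = project_materials(phantom, geometry)
    sinos = forward_project(phantom, geometry, spectrum, bins, noise=noise,
                            seed=seed, exposure=exposure,
                            material_sinos=material_sinos)
    airs = air_scan(geometry, spectrum, bins, exposure=exposure)
    bin_specs = bin_spectrum(spectrum, bins)
    ps, images, mu_w = [], [], []
    for b in range(bins.n_bins):
        p = log_normalize(sinos[b], airs[b])
        if water_precorrect:
            p = water_precorrection(p, bin_specs[b], table)
        ps.append(p)
        images.append(BinImage(fbp(p, geometry, phantom.pixel_size, n,
                                   filter_name), b, phantom.pixel_size))
        mu_w.append(effective_bin_mu("water", spectrum, b, bins, table))
    broad_counts = sum(s.counts for s in sinos)
    broad_air = sum(a.counts for a in airs)
    broad_p = log_normalize(BinSinogram(broad_counts, -1),
                            BinSinogram(broad_air, -1))
    sel = spectrum.energies >= bins.thresholds[0]
    broad_spec = Spectrum(spectrum.energies.copy(),
                          np.where(sel, spectrum.fluence, 0.0))
    if water_precorrect:
        broad_p = water_precorrection(broad_p, broad_spec, table)
    broad_img = BinImage(fbp(broad_p, geometry, phantom.pixel_size, n,
                             filter_name), -1, phantom.pixel_size)
    mu_broad = float((broad_spec.fluence * table.mu_lin("water")).sum()
                     / broad_spec.total)
    return ScanResult(sinos, airs, ps, images, broad_p, broad_img, mu_w,
                      mu_broad)


def head_arms(scan: ScanResult, geometry: FanGeometry, spectrum: Spectrum,
              bins: BinConfig, basis: tuple = ("water", "iodine_cal", "bone"),
              vmi_kev: float = 40.0, nmar_params: NmarParams = NmarParams(),
              with_nmar: bool = True) -> dict:
    """Build the comparison arms from one head scan.

    Returns a dict of HU images: ``broad``, ``vmi`` and, when NMAR is enabled
    and metal is present, ``broad_nmar`` and ``vmi_nmar`` (plus ``metal_mask``
    and the material maps under non-image keys).
    """
    table = load_material_table()
    matrix = build_mu_matrix(basis, spectrum, bins, table)
    broad_hu = scan.broad_hu()
    arms: dict = {"broad": broad_hu}
    maps = decompose(scan.bin_images, matrix)
    arms["vmi"] = synthesize_vmi(maps, vmi_kev, table)
    arms["maps"] = maps
    if with_nmar:
        corrected, mask = run_nmar_per_bin(
            scan.bin_ps, scan.bin_images, broad_hu, scan.mu_water_bins,
            geometry, nmar_params)
        arms["metal_mask"] = mask
        if mask.any():
            broad_c, _ = run_nmar_per_bin(
                [scan.broad_p], [scan.broad_image], broad_hu,
                [scan.mu_water_broad], geometry, nmar_params)
            arms["broad_nmar"] = mu_to_hu(broad_c[0].mu, scan.mu_water_broad)
            maps_c = decompose(corrected, matrix)
            arms["vmi_nmar"] = synthesize_vmi(maps_c, vmi_kev, table)
            arms["maps_nmar"] = maps_c
    return arms


@dataclass
class ExperimentConfig:
    """Validated, file-round-trippable description of one experiment."""

    phantom: str = "head"
    phantom_params: dict = field(default_factory=dict)
    grid_shape: int = 512
    pixel_size: float = 0.5
    kvp: float = 140.0
    thresholds: tuple = (30.0, 50.0, 65.0)
    geometry_scale: int = 1
    exposure: float = DEFAULT_EXPOSURE
    noise: bool = True
    seed: int = 0
    nmar: bool = True
    nmar_params: dict = field(default_factory=dict)
    basis: tuple = ("water", "iodine_cal", "bone")
    vmi_energies: tuple = (40.0,)
    evaluate_rois: bool = True

    def __post_init__(self):
        if self.phantom not in PHANTOM_FACTORIES:
            raise ValueError(f"unknown phantom {self.phantom!r}; "
                             f"choose from {sorted(PHANTOM_FACTORIES)}")
        if self.seed is None:
            raise ValueError("seed must be explicit")
        self.thresholds = tuple(float(t) for t in self.thresholds)
        self.basis = tuple(self.basis)
        self.vmi_energies = tuple(float(e) for e in self.vmi_energies)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    outputs: dict            # filename -> sha256 of array bytes
    stage_seconds: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _save(outdir: Path, name: str, arr: np.ndarray, outputs: dict) -> None:
    tifffile.imwrite(outdir / name, arr.astype(np.float32))
    outputs[name] = _sha(arr.astype(np.float32))


def run_experiment(config: ExperimentConfig, outdir) -> RunManifest:
    """Execute phantom -> scan -> recon -> (NMAR) -> MD -> VMI -> evaluation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}
    timings: dict = {}

    t0 = time.time()
    phantom = PHANTOM_FACTORIES[config.phantom](
        shape=config.grid_shape, pixel_size=config.pixel_size,
        **config.phantom_params)
    timings["phantom"] = time.time() - t0

    spectrum = build_spectrum(config.kvp)
    bins = BinConfig(config.thresholds, config.kvp)
    geometry = FanGeometry().scaled(config.geometry_scale) \
        if config.geometry_scale > 1 else FanGeometry()

    t0 = time.time()
    scan = simulate_scan(phantom, geometry, spectrum, bins,
                         noise=config.noise, seed=config.seed,
                         exposure=config.exposure)
    timings["scan_recon"] = time.time() - t0
    for b in range(bins.n_bins):
        _save(outdir, f"bin{b + 1}_counts.tif", scan.bin_sinos[b].counts,
              outputs)
        _save(outdir, f"bin{b + 1}_hu.tif", scan.bin_hu(b), outputs)
    _save(outdir, "broad_hu.tif", scan.broad_hu(), outputs)

    t0 = time.time()
    arms = head_arms(scan, geometry, spectrum, bins, basis=config.basis,
                     vmi_kev=config.vmi_energies[0],
                     nmar_params=NmarParams(**config.nmar_params),
                     with_nmar=config.nmar)
    timings["nmar_md_vmi"] = time.time() - t0
    maps = arms["maps"]
    for name in maps.mu_matrix.basis:
        _save(outdir, f"map_{name}.tif", maps[name], outputs)
    table = load_material_table()
    for e in config.vmi_energies:
        _save(outdir, f"vmi_{e:.0f}kev.tif", synthesize_vmi(maps, e, table),
              outputs)
        if "maps_nmar" in arms:
            _save(outdir, f"vmi_{e:.0f}kev_nmar.tif",
                  synthesize_vmi(arms["maps_nmar"], e, table), outputs)
    if "broad_nmar" in arms:
        _save(outdir, "broad_hu_nmar.tif", arms["broad_nmar"], outputs)

    if config.evaluate_rois and config.phantom == "head":
        t0 = time.time()
        rows = []
        labels = {"broad": "(a) broad", "broad_nmar": "(b) broad+NMAR",
                  "vmi": "(c) VMI", "vmi_nmar": "(d) VMI+NMAR"}
        for key in ("broad", "broad_nmar", "vmi", "vmi_nmar"):
            if key not in arms:
                continue
            stats_df = roi_stats(arms[key], head_rois(), config.pixel_size)
            rep = cnr_from_stats(stats_df)
            row = {"image": labels[key]}
            for roi in stats_df.index:
                row[roi] = (f"{stats_df.loc[roi, 'mean']:.1f} "
                            f"± {stats_df.loc[roi, 'sd']:.1f}")
            for k, c in enumerate(rep.cnr, 1):
                row[f"CNR{k}"] = round(c, 1)
            row["CNR mean"] = round(rep.summary_mean, 1)
            row["CNR sd"] = round(rep.summary_sd, 1)
            rows.append(row)
        report = pd.DataFrame(rows)
        report.to_csv(outdir / "cnr_report.csv", index=False)
        outputs["cnr_report.csv"] = hashlib.sha256(
            report.to_csv(index=False).encode()).hexdigest()
        timings["evaluation"] = time.time() - t0

    config.to_yaml(outdir / "config.yaml")
    manifest = RunManifest(config.config_hash(), __version__, outputs, timings)
    manifest.to_json(outdir / "manifest.json")
    return manifest


def write_report(manifest: RunManifest, outdir) -> list:
    """Render figure panels (bin images, VMI, CNR bars) from a finished run."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    csv = outdir / "cnr_report.csv"
    if not csv.exists():
        raise ValueError("evaluation output missing; nothing to report")
    written = []
    report = pd.read_csv(csv)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(report["image"], report["CNR mean"], yerr=report["CNR sd"],
           color="#4878d0", capsize=4)
    ax.set_ylabel("CNR (mean ± SD)")
    ax.set_title("Lesion CNR by processing arm")
    plt.setp(ax.get_xticklabels(), rotation=20, ha="right")
    fig.tight_layout()
    fig.savefig(outdir / "cnr_bars.png", dpi=150)
    plt.close(fig)
    written.append(outdir / "cnr_bars.png")

    panels = [f for f in ("broad_hu.tif", "broad_hu_nmar.tif",
                          "vmi_40kev.tif", "vmi_40kev_nmar.tif")
              if (outdir / f).exists()]
    if panels:
        fig, axes = plt.subplots(1, len(panels), figsize=(4 * len(panels), 4))
        axes = np.atleast_1d(axes)
        for ax, name in zip(axes, panels):
            img = tifffile.imread(outdir / name)
            ax.imshow(img, cmap="gray", vmin=-150, vmax=450)
            ax.set_title(name.replace(".tif", ""))
            ax.axis("off")
        fig.tight_layout()
        fig.savefig(outdir / "panels.png", dpi=150)
        plt.close(fig)
        written.append(outdir / "panels.png")
    return written
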