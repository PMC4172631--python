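"""Tissue-labeled 2D digital phantoms in Hounsfield units.

The default phantom is a desk-scale stand-in for the thorax/abdomen of a
medium-sized animal: an elliptical body with subcutaneous fat, back and
abdominal muscle, two air-filled lungs, a fluid-filled gallbladder and a
vertebral body.  Each tissue carries a conventional textbook HU value and a
set of 50 mm^2 circular regions of interest (ROIs) used downstream to
measure image noise and mean CT number.

Coordinate convention: row-major (row, col) indexing; the center of pixel
(i, j) sits at ((j + 0.5) * pixel_size - fov/2, (i + 0.5) * pixel_size - fov/2)
in physical (x, y) millimetres with the origin at the grid center, x to the
right and y downward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: linear attenuation of water (1/mm) for a 100 kV beam at ~60 keV effective
MU_WATER_MM = 0.0203

HU_AIR = -1000.0

#: conventional HU per tissue (the study animal's true values are not published)
TISSUE_HU = {
    "lung": -800.0,
    "fat": -100.0,
    "fluid": 0.0,
    "muscle": 50.0,
    "bone": 700.0,
}

#: integer labels; 0 is reserved for air/background
TISSUE_LABELS = {"air": 0, "lung": 1, "fat": 2, "fluid": 3, "muscle": 4, "bone": 5}
LABEL_NAMES = {v: k for k, v in TISSUE_LABELS.items()}

HU_MIN, HU_MAX = -1024.0, 3000.0


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned or rotated ellipse in physical millimetres (origin = grid center)."""

    center_mm: tuple[float, float]  # (x, y)
    semi_axes_mm: tuple[float, float]  # (a along x, b along y) before rotation
    hu: float
    tissue: str
    angle_deg: float = 0.0


@dataclass
class PhantomImage:
    """A 2D HU slice with aligned integer tissue labels and physical pixel size."""

    hu_grid: np.ndarray
    pixel_size_mm: float
    tissue_labels: np.ndarray
    fov_mm: float

    def __post_init__(self) -> None:
        self.hu_grid = np.asarray(self.hu_grid, dtype=float)
        self.tissue_labels = np.asarray(self.tissue_labels, dtype=int)
        if self.hu_grid.ndim != 2:
            raise ValueError("hu_grid must be 2D")
        if self.hu_grid.shape != self.tissue_labels.shape:
            raise ValueError("tissue_labels and hu_grid must have identical shape")
        if self.hu_grid.min() < HU_MIN or self.hu_grid.max() > HU_MAX:
            raise ValueError(f"HU values must lie within [{HU_MIN}, {HU_MAX}]")
        n = self.hu_grid.shape[0]
        if not np.isclose(self.fov_mm, n * self.pixel_size_mm):
            raise ValueError("fov_mm must equal grid edge count x pixel_size_mm")

    @property
    def shape(self) -> tuple[int, int]:
        return self.hu_grid.shape

    def mu_grid(self, mu_water: float = MU_WATER_MM) -> np.ndarray:
        """Linear-attenuation image (1/mm) for forward projection."""
        return hu_to_mu(self.hu_grid, mu_water)

    # ---- I/O: NIfTI slice + JSON sidecar --------------------------------
    def to_nifti(self, path: str | Path, rois: list["RoiSpec"] | None = None) -> None:
        import nibabel as nib

        path = Path(path)
        affine = np.diag([self.pixel_size_mm, self.pixel_size_mm, 1.0, 1.0])
        nib.save(nib.Nifti1Image(self.hu_grid[:, :, None].astype(np.float32), affine), path)
        sidecar = {
            "pixel_size_mm": self.pixel_size_mm,
            "fov_mm": self.fov_mm,
            "tissue_labels": self.tissue_labels.tolist(),
            "rois": [r.to_dict() for r in rois] if rois else [],
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_nifti(cls, path: str | Path) -> tuple["PhantomImage", list["RoiSpec"]]:
        import nibabel as nib

        path = Path(path)
        img = nib.load(path)
        hu = np.asarray(img.dataobj, dtype=float)[:, :, 0]
        meta = json.loads(path.with_suffix(".json").read_text())
        phantom = cls(
            hu_grid=hu,
            pixel_size_mm=meta["pixel_size_mm"],
            tissue_labels=np.asarray(meta["tissue_labels"], dtype=int),
            fov_mm=meta["fov_mm"],
        )
        rois = [RoiSpec.from_dict(d) for d in meta["rois"]]
        return phantom, rois


@dataclass(frozen=True)
class RoiSpec:
    """A circular region of interest of fixed physical area (default 50 mm^2).

    ``center`` is in grid coordinates (row, col); the mask contains the pixels
    whose centers fall inside the disk, so partial edge pixels are excluded.
    """

    center: tuple[float, float]
    area_mm2: float = 50.0
    tissue_name: str = ""

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("area_mm2 must be positive")

    @property
    def radius_mm(self) -> float:
        return float(np.sqrt(self.area_mm2 / np.pi))

    def mask(self, shape: tuple[int, int], pixel_size_mm: float) -> np.ndarray:
        r0, c0 = self.center
        radius_px = self.radius_mm / pixel_size_mm
        if (
            r0 - radius_px < -0.5
            or c0 - radius_px < -0.5
            or r0 + radius_px > shape[0] - 0.5
            or c0 + radius_px > shape[1] - 0.5
        ):
            raise ValueError("ROI does not lie fully inside the grid")
        rows = np.arange(shape[0])[:, None]
        cols = np.arange(shape[1])[None, :]
        return (rows - r0) ** 2 + (cols - c0) ** 2 <= radius_px**2

    def to_dict(self) -> dict:
        return {
            "center": list(self.center),
            "area_mm2": self.area_mm2,
            "tissue_name": self.tissue_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RoiSpec":
        return cls(center=tuple(d["center"]), area_mm2=d["area_mm2"], tissue_name=d["tissue_name"])


def rois_to_csv(rois: list[RoiSpec], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "tissue_name": r.tissue_name,
                "row": r.center[0],
                "col": r.center[1],
                "area_mm2": r.area_mm2,
            }
            for r in rois
        ]
    ).to_csv(path, index=False)


def hu_to_mu(hu: np.ndarray | float, mu_water: float = MU_WATER_MM) -> np.ndarray | float:
    """Convert Hounsfield units to linear attenuation (1/mm), clipped at zero.

    mu = mu_water * (1 + HU/1000); water maps to mu_water, air (-1000 HU) to 0.
    """
    if mu_water <= 0:
        raise ValueError("mu_water must be positive")
    return np.clip(mu_water * (1.0 + np.asarray(hu, dtype=float) / 1000.0), 0.0, None)


def _pixel_centers_mm(matrix: int, fov_mm: float) -> tuple[np.ndarray, np.ndarray]:
    ps = fov_mm / matrix
    coords = (np.arange(matrix) + 0.5) * ps - fov_mm / 2.0
    x = coords[None, :]  # along columns
    y = coords[:, None]  # along rows
    return x, y


def build_phantom(shapes: list[Ellipse], matrix: int = 256, fov_mm: float = 380.0) -> PhantomImage:
    """Rasterize a list of ellipses onto an air background (-1000 HU).

    Later ellipses overwrite earlier ones, so organs are painted over the body.
    An ellipse whose bounding circle leaves the field of view is rejected.
    """
    half = fov_mm / 2.0
    for e in shapes:
        reach = max(e.semi_axes_mm)
        if abs(e.center_mm[0]) + reach > half or abs(e.center_mm[1]) + reach > half:
            raise ValueError(f"ellipse for tissue '{e.tissue}' extends outside the field of view")
        if not (HU_MIN <= e.hu <= HU_MAX):
            raise ValueError(f"HU {e.hu} outside valid range")

    hu = np.full((matrix, matrix), HU_AIR)
    labels = np.zeros((matrix, matrix), dtype=int)
    x, y = _pixel_centers_mm(matrix, fov_mm)
    for e in shapes:
        cx, cy = e.center_mm
        a, b = e.semi_axes_mm
        phi = np.deg2rad(e.angle_deg)
        dx, dy = x - cx, y - cy
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        hu[inside] = e.hu
        labels[inside] = TISSUE_LABELS.get(e.tissue, TISSUE_LABELS["air"])
    return PhantomImage(hu_grid=hu, pixel_size_mm=fov_mm / matrix, tissue_labels=labels, fov_mm=fov_mm)


def _mm_to_grid(x_mm: float, y_mm: float, matrix: int, fov_mm: float) -> tuple[float, float]:
    ps = fov_mm / matrix
    col = (x_mm + fov_mm / 2.0) / ps - 0.5
    row = (y_mm + fov_mm / 2.0) / ps - 0.5
    return row, col


def default_swine_phantom(
    seed: int = 0,
    matrix: int = 256,
    fov_mm: float = 380.0,
    rois_per_tissue: int = 10,
) -> tuple[PhantomImage, list[RoiSpec]]:
    """Deterministic body phantom with one region per tissue and its ROI set.

    Emulates the measurement sites of the animal validation study: back
    muscles, subcutaneous fat of the ventral wall, lung tissue, gallbladder
    fluid and a vertebral body.  ROI centers are laid out on fixed in-organ
    grids with a small seeded sub-pixel jitter; every ROI is checked to sit on
    a uniform tissue label.
    """
    shapes = [
        Ellipse((0.0, 0.0), (150.0, 110.0), TISSUE_HU["fat"], "fat"),
        Ellipse((0.0, 0.0), (135.0, 95.0), TISSUE_HU["muscle"], "muscle"),
        Ellipse((-60.0, -40.0), (48.0, 40.0), TISSUE_HU["lung"], "lung"),
        Ellipse((60.0, -40.0), (48.0, 40.0), TISSUE_HU["lung"], "lung"),
        Ellipse((42.0, 22.0), (28.0, 20.0), TISSUE_HU["fluid"], "fluid"),
        Ellipse((0.0, 55.0), (26.0, 20.0), TISSUE_HU["bone"], "bone"),
    ]
    phantom = build_phantom(shapes, matrix=matrix, fov_mm=fov_mm)

    rng = np.random.default_rng(seed)
    ps = phantom.pixel_size_mm

    def organ_grid(cx: float, cy: float, dxs: list[float], dys: list[float]) -> list[tuple[float, float]]:
        return [(cx + dx, cy + dy) for dy in dys for dx in dxs]

    def fat_ring_sites(n: int) -> list[tuple[float, float]]:
        # subcutaneous fat ring of the ventral wall: radial midline between the
        # outer body ellipse (150, 110) and the muscle ellipse (135, 95)
        sites = []
        for t in np.linspace(np.deg2rad(55), np.deg2rad(125), n):
            r_outer = 1.0 / np.sqrt((np.cos(t) / 150.0) ** 2 + (np.sin(t) / 110.0) ** 2)
            r_inner = 1.0 / np.sqrt((np.cos(t) / 135.0) ** 2 + (np.sin(t) / 95.0) ** 2)
            r_mid = 0.5 * (r_outer + r_inner)
            sites.append((float(r_mid * np.cos(t)), float(-r_mid * np.sin(t))))
        return sites

    site_centers_mm: dict[str, list[tuple[float, float]]] = {
        "lung": organ_grid(-60.0, -40.0, [-24, -12, 0, 12, 24], [-10, 10]),
        "fat": fat_ring_sites(rois_per_tissue),
        "fluid": organ_grid(42.0, 22.0, [-13, -6.5, 0, 6.5, 13], [-6.5, 6.5]),
        "bone": organ_grid(0.0, 55.0, [-12, -6, 0, 6, 12], [-6, 6]),
        # back muscles: two paravertebral clusters clear of the vertebral body
        "muscle": [(x, 72.0) for x in (-58, -45, -32, 32, 45, 58)]
        + [(x, 80.0) for x in (-50, -37, 37, 50)],
    }

    rois: list[RoiSpec] = []
    target_px = 50.0 / ps**2
    for tissue in ("lung", "fat", "fluid", "muscle", "bone"):
        centers = site_centers_mm[tissue][:rois_per_tissue]
        if len(centers) < rois_per_tissue:
            raise ValueError(f"not enough ROI sites for tissue '{tissue}'")
        for x_mm, y_mm in centers:
            # among a few seeded sub-pixel placements, keep the one whose
            # rasterized disk comes closest to the nominal 50 mm^2 area
            jitters = np.vstack([[0.0, 0.0], rng.uniform(-0.45, 0.45, size=(8, 2)) * ps])
            best = None
            for jx, jy in jitters:
                row, col = _mm_to_grid(x_mm + jx, y_mm + jy, matrix, fov_mm)
                roi = RoiSpec(center=(row, col), area_mm2=50.0, tissue_name=tissue)
                mask = roi.mask(phantom.shape, ps)
                lab = phantom.tissue_labels[mask]
                if lab.size == 0 or not np.all(lab == TISSUE_LABELS[tissue]):
                    continue
                err = abs(mask.sum() - target_px)
                if best is None or err < best[0]:
                    best = (err, roi)
            if best is None:
                raise RuntimeError(f"ROI at {(x_mm, y_mm)} not uniformly '{tissue}'")
            rois.append(best[1])
    return phantom, rois
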