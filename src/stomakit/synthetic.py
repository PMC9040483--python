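"""Synthetic grass-epidermis micrographs with known stoma centers.

Real input to the counting pipeline is a grayscale reflective-intensity
raster from an optical topometer: stomatal complexes arranged in
longitudinal files over elongated pavement cells.  This module emulates
that geometry — a striated pavement background, dumbbell-like stoma
motifs laid in parallel files with jitter, additive sensor noise — with
exactly known ground-truth centers, so every downstream stage (feature
extraction, classifier training, fusion tuning, density estimation) can
be tested without micrographs.

Images are float arrays in [0, 1] internally and are written as 16-bit
grayscale TIFF or PNG.  Annotations are CSV with header
``image_id,x,y`` in 0-based pixel coordinates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageGenParams",
    "AnnotationSet",
    "generate_leaf_image",
    "degrade_image",
    "write_image",
    "read_image",
    "write_annotations",
    "read_annotations",
]

#: Default µm per pixel: an 800 × 800 µm field of view rasterized at 512 px.
DEFAULT_PIXEL_SIZE_UM = 800.0 / 512.0


@dataclass
class ImageGenParams:
    """Parameters of the synthetic leaf-surface generator.

    Defaults describe one 800 × 800 µm field of view (0.64 mm²) at
    512 × 512 px, sorghum-like stoma dimensions (~35 × 12 µm) and file
    spacing (~65 µm), and moderate pavement texture and sensor noise.
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    target_density_per_mm2: float = 75.0
    stoma_length_um: float = 35.0
    stoma_width_um: float = 12.0
    file_spacing_um: float = 65.0
    min_center_spacing_um: float = 40.0
    edge_margin_um: float = 62.5
    pavement_texture_amp: float = 0.08
    noise_sd: float = 0.03
    stoma_contrast: float = 0.38
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "width_px",
            "height_px",
            "pixel_size_um",
            "stoma_length_um",
            "stoma_width_um",
            "file_spacing_um",
            "min_center_spacing_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.target_density_per_mm2 < 0:
            raise ValueError("target_density_per_mm2 must be non-negative")
        if self.pavement_texture_amp < 0 or self.noise_sd < 0:
            raise ValueError("texture amplitude and noise sd must be non-negative")
        if self.min_center_spacing_um < self.stoma_length_um:
            raise ValueError(
                "min_center_spacing_um must be at least stoma_length_um "
                f"({self.min_center_spacing_um} < {self.stoma_length_um})"
            )

    @property
    def area_mm2(self) -> float:
        return (self.width_px * self.pixel_size_um / 1000.0) * (
            self.height_px * self.pixel_size_um / 1000.0
        )

    @property
    def target_count(self) -> int:
        return int(round(self.target_density_per_mm2 * self.area_mm2))


@dataclass
class AnnotationSet:
    """Ground-truth stoma centers for one image, 0-based pixel coordinates."""

    image_id: str
    points: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=float))

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)


class InfeasibleDensityError(ValueError):
    """Requested stoma density cannot be placed under the spacing constraint."""


def _pavement_background(params: ImageGenParams, rng: np.random.Generator) -> np.ndarray:
    """Striated pavement-cell texture: longitudinal stripes + low-pass mottle."""
    h, w = params.height_px, params.width_px
    base = np.full((h, w), 0.45, dtype=float)
    if params.pavement_texture_amp == 0:
        return base
    x = np.arange(w, dtype=float)
    # Pavement cells are elongated along the leaf axis (vertical files), so the
    # dominant intensity variation runs across the image.
    cell_w_px = max(params.file_spacing_um / params.pixel_size_um / 2.0, 4.0)
    stripes = 0.6 * np.sin(2 * np.pi * x / cell_w_px + rng.uniform(0, 2 * np.pi))
    stripes += 0.3 * np.sin(2 * np.pi * x / (cell_w_px * 2.7) + rng.uniform(0, 2 * np.pi))
    base += params.pavement_texture_amp * stripes[None, :]
    # Band-limited mottle breaks the pure stripe pattern.
    mottle = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=8.0)
    sd = mottle.std()
    if sd > 0:
        base += 0.5 * params.pavement_texture_amp * mottle / sd
    return base


def _stoma_motif(params: ImageGenParams, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """One dumbbell-like stoma: bright guard-cell rim, dark central pore,
    bright subsidiary caps at both poles, long axis vertical (along the file).

    Returns (patch, half_size); the patch is additive on the background.
    """
    length_px = params.stoma_length_um / params.pixel_size_um
    width_px = params.stoma_width_um / params.pixel_size_um
    half = int(np.ceil(length_px)) + 2
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    theta = rng.normal(0.0, 0.06)  # slight orientation jitter about the file axis
    la = yy * np.cos(theta) - xx * np.sin(theta)  # long-axis coordinate
    wa = yy * np.sin(theta) + xx * np.cos(theta)  # width-axis coordinate
    amp = params.stoma_contrast * rng.uniform(0.85, 1.15)
    rim = np.exp(-0.5 * ((la / (length_px / 3.2)) ** 2 + (wa / (width_px / 2.2)) ** 2))
    pore = np.exp(-0.5 * ((la / (length_px / 4.0)) ** 2 + (wa / (width_px / 5.0)) ** 2))
    cap_sigma = width_px / 2.5
    caps = np.exp(
        -0.5 * (((la - length_px / 2.1) ** 2 + wa**2) / cap_sigma**2)
    ) + np.exp(-0.5 * (((la + length_px / 2.1) ** 2 + wa**2) / cap_sigma**2))
    return amp * (rim - 1.35 * pore + 0.7 * caps), half


def _place_centers(params: ImageGenParams, rng: np.random.Generator) -> np.ndarray:
    """Jittered lattice along vertical files with rejection for min spacing."""
    n_target = params.target_count
    if n_target == 0:
        return np.empty((0, 2), dtype=float)
    px = params.pixel_size_um
    margin = params.edge_margin_um / px
    w, h = params.width_px, params.height_px
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise InfeasibleDensityError("edge margin leaves no placeable area")
    file_spacing = params.file_spacing_um / px
    min_sp = params.min_center_spacing_um / px
    slot_pitch = max(min_sp * 1.05, 1.0)

    file_x = np.arange(margin, w - margin + 1e-9, file_spacing)
    slots_y = np.arange(margin, h - margin + 1e-9, slot_pitch)
    candidates = []
    for fx in file_x:
        phase = rng.uniform(0, slot_pitch)
        for sy in slots_y:
            cx = fx + rng.normal(0, file_spacing * 0.08)
            cy = sy + phase + rng.normal(0, slot_pitch * 0.08)
            if margin <= cx <= w - 1 - margin and margin <= cy <= h - 1 - margin:
                candidates.append((cx, cy))
    if not candidates:
        raise InfeasibleDensityError("no candidate stoma sites under the given spacing")
    cand = np.array(candidates, dtype=float)
    order = rng.permutation(len(cand))
    accepted: list[np.ndarray] = []
    for idx in order:
        p = cand[idx]
        if all(np.hypot(*(p - q)) >= min_sp for q in accepted):
            accepted.append(p)
            if len(accepted) == n_target:
                break
    if len(accepted) < n_target:
        raise InfeasibleDensityError(
            f"could only place {len(accepted)} of {n_target} stomata at "
            f"density {params.target_density_per_mm2}/mm² with spacing "
            f"{params.min_center_spacing_um} µm"
        )
    pts = np.array(accepted, dtype=float)
    return pts[np.lexsort((pts[:, 0], pts[:, 1]))]


def generate_leaf_image(
    params: ImageGenParams, image_id: str = "synthetic"
) -> tuple[np.ndarray, AnnotationSet]:
    """Generate one annotated leaf-surface image.

    Returns an (H, W) float image in [0, 1] and the ground-truth stoma
    centers.  The number of stomata equals ``round(target_density ×
    area_mm2)``; an :class:`InfeasibleDensityError` is raised when that
    count cannot be placed under the minimum-spacing constraint.
    Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    image = _pavement_background(params, rng)
    centers = _place_centers(params, rng)
    h, w = image.shape
    for cx, cy in centers:
        patch, half = _stoma_motif(params, rng)
        ix, iy = int(round(cx)), int(round(cy))
        y0, y1 = max(iy - half, 0), min(iy + half + 1, h)
        x0, x1 = max(ix - half, 0), min(ix + half + 1, w)
        image[y0:y1, x0:x1] += patch[
            y0 - (iy - half) : y1 - (iy - half), x0 - (ix - half) : x1 - (ix - half)
        ]
    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
    np.clip(image, 0.0, 1.0, out=image)
    return image, AnnotationSet(image_id=image_id, points=centers)


def degrade_image(
    image: np.ndarray, blur_sigma_px: float, contrast_scale: float, seed: int = 0
) -> np.ndarray:
    """Blur and rescale contrast about the image mean (robustness probe).

    ``blur_sigma_px=0`` with ``contrast_scale=1`` is the identity.
    """
    if blur_sigma_px < 0:
        raise ValueError("blur_sigma_px must be non-negative")
    if contrast_scale <= 0:
        raise ValueError("contrast_scale must be positive")
    out = np.asarray(image, dtype=float)
    if blur_sigma_px > 0:
        out = ndimage.gaussian_filter(out, sigma=blur_sigma_px, mode="reflect")
    if contrast_scale != 1:
        m = out.mean()
        out = m + contrast_scale * (out - m)
        out = np.clip(out, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# IO


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit grayscale TIFF or PNG."""
    path = Path(path)
    arr16 = np.clip(np.round(np.asarray(image, dtype=float) * 65535), 0, 65535).astype(
        np.uint16
    )
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, arr16)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr16)


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale raster, rescaled to float in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse any color axis
        arr = arr.mean(axis=-1)
    arr = arr.astype(float)
    if arr.max() > 1.0:
        arr /= 65535.0 if arr.max() > 255 else 255.0
    return arr


def write_annotations(path: str | Path, annotations: list[AnnotationSet]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "x", "y"])
        for ann in annotations:
            for x, y in ann.points:
                writer.writerow([ann.image_id, f"{x:.3f}", f"{y:.3f}"])


def read_annotations(path: str | Path) -> dict[str, AnnotationSet]:
    out: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or {"image_id", "x", "y"} - set(reader.fieldnames):
            raise ValueError("annotation CSV must have header image_id,x,y")
        for row in reader:
            out.setdefault(row["image_id"], []).append((float(row["x"]), float(row["y"])))
    return {
        image_id: AnnotationSet(image_id=image_id, points=np.array(pts))
        for image_id, pts in out.items()
    }
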